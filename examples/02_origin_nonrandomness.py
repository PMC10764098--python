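"""Test whether the mtDNA regions that produce NUMTs are nonrandom.

Builds per-base coverage of the first 16 kb of the linearized mitogenome,
summarizes it in 320 windows of 50 bp per species, runs all 51,040
pairwise rank-sum tests between windows across species, and contrasts the
observed number of significant tests (FDR < 0.01) with a circular
reshuffling null that preserves every NUMT's length.
"""

from numtkit import detect, origin, simulate

cfg = simulate.SimConfig(
    seed=7,
    emit_sequences=False,
    gain_rate_per_myr=1.5,
    origin_bias=((1_000, 2_500, 25.0),),  # enriched donor region
)
dataset = simulate.simulate_dataset(cfg)

numts_by_species = {}
for sp, d in dataset.data.items():
    numts_by_species[sp] = detect.merge_hsps(
        detect.filter_hsps(d.hsps), cfg.mt_length,
        species=sp, genome_index=d.genome_index,
    )

profiles = {
    sp: origin.coverage_profile(n, span=16_000)
    for sp, n in numts_by_species.items()
}
medians = origin.window_medians(profiles, window=50)
tests = origin.pairwise_window_tests(medians, alpha=0.01)
null = origin.reshuffle_null(numts_by_species, n_iter=100, seed=7)

print(f"windows: {medians.shape[1]}, pairwise tests: {tests.n_tests}")
print(f"observed significant (FDR<0.01): {tests.n_significant} "
      f"({origin.significant_fraction(tests.n_significant, tests.n_tests):.2f}%)")
print(f"reshuffle null: median {null.null_median:.0f}, "
      f"95th percentile {null.percentile(95):.0f}")

pooled = sum(origin.coverage_profile(n) for n in numts_by_species.values())
regions = origin.overrepresented_regions(pooled, z_cut=3)
print("over-represented mtDNA regions (z > 3):", regions[:5])
# An observed count far above the null 95th percentile means NUMTs sample
# the mitogenome unevenly; the z > 3 caller localizes the donor hotspots.
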