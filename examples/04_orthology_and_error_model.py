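"""Assign NUMT orthology between two species by genome microsynteny.

Anchors each NUMT with the 3 nearest protein-coding genes on each side,
pairs units across species that share anchors and whose mtDNA footprints
overlap reciprocally by >= 50%, and evaluates the analytic probability of
a by-chance assignment.
"""

from numtkit import detect, orthology, simulate

cfg = simulate.SimConfig(
    seed=19,
    emit_sequences=False,
    tree_newick="(Aaaa:5,Bbbb:5):20;",
    gain_rate_per_myr=2.0,
    loss_rate_per_myr=0.01,
)
dataset = simulate.simulate_dataset(cfg)

units, ctxs = {}, {}
for sp, d in dataset.data.items():
    ns = detect.merge_hsps(detect.filter_hsps(d.hsps), cfg.mt_length,
                           species=sp, genome_index=d.genome_index)
    units[sp] = ns
    ctxs[sp] = orthology.build_synteny_context(ns, d.genes, k=3)

pairs = orthology.assign_orthologs(
    units["Aaaa"], ctxs["Aaaa"], units["Bbbb"], ctxs["Bbbb"],
    cfg.mt_length, species_a="Aaaa", species_b="Bbbb",
)
print(f"{len(units['Aaaa'])} vs {len(units['Bbbb'])} NUMTs -> "
      f"{len(pairs)} ortholog pairs")
for p in pairs[:4]:
    print(f"  {p.unit_a} <-> {p.unit_b}  overlap {p.overlap:.2f}  "
          f"anchors {sorted(p.shared_anchors)[:3]}")

rate = orthology.error_rate(orthology.ErrorModel())
E = orthology.error_expectation(rate, len(units["Aaaa"]), len(units["Bbbb"]))
print(f"by-chance assignment rate: {rate:.3g} per unit pair")
print(f"expected false pairs for this comparison: E = {E:.4f}")
# With the default mammalian constants the rate is 3.03e-6; E far below 1
# means essentially every reported pair reflects a shared insertion event.
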