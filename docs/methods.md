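# Methods

This note documents the models and procedures `numtkit` implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
show.

## Coordinates and conventions

All internal coordinates are 0-based half-open. Parsed inputs are
normalized at the boundary: the 12-column alignment-hit dialect, GFF3 and
RepeatMasker `.out` are 1-based inclusive on disk; emitted BED is 0-based
half-open and emitted GFF3 is 1-based inclusive. The mitogenome is handled
as a *linearized* circle (tRNA-Phe first, D-loop last); a footprint that
crosses the linearization boundary is stored as two intervals, which makes
plain linear interval intersection circle-correct everywhere downstream.
Minus-orientation hits (subject start > end) are normalized to ascending
intervals at parse time with the orientation kept as a flag; orientation
gates HSP merging and is reported in output, but block assembly ignores it.

Species codes are four letters (first letter of genus + first three of
species, e.g. `Hsap`), and NUMTs are named `{Species}_numt_{k}` densely in
(scaffold order in the genome file, nuclear start) order, renumbered after
every filter.

## Detection

The calling chain and its defaults:

| step | rule | default |
|---|---|---|
| HSP filter | E-value ≤ `max_e`, alignment length ≥ `min_len` | 10⁻³, 30 bp |
| merge | same orientation, nuclear gap < `nuclear_gap_max`, mtDNA continuity within `mt_gap_max` | 10 bp, 10 bp |
| contig filter | scaffold length ≥ `min_contig` | 20 kb |
| blocks | chain NUMTs with nuclear gap < `block_gap`, any orientation | 2 kb; complex = ≥ 3 members |

"Continuous mitogenome coordinates" is quantified symmetrically: the gap
*or* overlap between consecutive hits on the mtDNA side, measured in the
orientation-consistent direction (for minus-orientation chains the mtDNA
coordinate decreases along the nuclear plus strand), must be ≤ 10 bp, with
the circular case (one hit ending at the linearization boundary, the next
beginning at 0) treated as distance zero. Only the nuclear-side 10 bp is an
external constraint; the mtDNA-side symmetry is this package's choice and
is configurable. Merging is implemented as the transitive closure
(union-find) of the pairwise predicate over nuclear-sorted hits, which
makes it order-free, idempotent, and provably equivalent to a brute-force
oracle (tested on 1,000 random instances). Opposite-orientation hits never
merge — an inverted segment inside one insertion appears as two NUMTs (in
one block). The identity of a merged NUMT is the alignment-length-weighted
mean of its member hits.

Tandem-duplicate candidates are same-scaffold pairs within 10 kb whose
mtDNA footprints have similar starts or ends (± 10 bp) and overlap
reciprocally by ≥ 50 %. They are reported but deliberately *not* subtracted
from insertion-rate numerators (rates are therefore upper bounds where
post-insertion duplication occurred).

## mtDNA-origin statistics

Coverage profiles count, per mitogenome base, the NUMT footprints covering
it. The analysis span is fixed at 16,000 bp (320 windows of 50 bp) to
avoid cross-species length heterogeneity in the D-loop tail; the full-length
profile is still available to the over-representation caller. Window
summaries are per-species medians of per-base counts, with every species
included regardless of coverage.

All W(W−1)/2 unordered window pairs (51,040 for W = 320) are compared
across species by a two-sided Mann–Whitney test on the median vectors,
adjusted jointly by Benjamini–Hochberg; significance is q < 0.01. The
rank-sum implementation is vectorized: a normal approximation with tie and
continuity corrections for group sizes ≥ 8, and the exact (subset
enumeration) null for smaller tie-free samples, falling back to the
approximation when ties make the exact distribution invalid. Both paths
agree with `scipy.stats.mannwhitneyu` to machine precision in the test
suite; the scipy routine remains the independent oracle, never the
implementation.

The reshuffling null redraws each NUMT's start uniformly on [0, span)
while keeping its footprint length; coordinates past the span wrap by
subtracting the span (circularity). The full window/test pipeline is rerun
per iteration (default 1,000; the bundled analyses use 200) and the
observed significant-test count is compared with the null distribution.
Over-represented donor regions are maximal runs of bases whose coverage
z-score (mean and SD over the full profile, zeros included) exceeds 3.

## Genomic context

TE content is profiled in ten 500 bp windows on each flank, ordered
outward from the insertion; windows truncated at scaffold edges are
flagged and computed on available bases. The background places, per
iteration (default 1,000), one same-length pseudo-insertion per unit,
uniformly over all scaffolds proportional to eligible length and never
within 5 kb of a scaffold end, so both flanks are always fully on-scaffold.
Observed and background per-window means are compared across species as
pairs (Wilcoxon signed-rank, two-sided); the weighting of scaffolds by
eligible length is this package's choice.

A unit overlapping any protein-coding gene span by ≥ 1 bp is "intronic",
otherwise "intergenic" — gene spans, not exon structure, are used, so some
intronic calls are UTR-resident; noncoding genes are excluded at parse
time. Nearest-TE distance is the mean of the 5′- and 3′-end distances (0
inside a TE) and is correlated with NUMT identity by Spearman's rho;
blocks are excluded because their identity is heterogeneous.

Expression calls require both junctions supported by ≥ 2 reads (reads are
pre-filtered upstream to ≥ 5 bp overhangs) *and* read coverage of the unit
strictly > 70 %; requiring both junction sides is a deliberate reading of
"the junctions". Enrichment of expression in intronic units is a 2×2
chi-square (with continuity correction; a warning is emitted when an
expected cell is < 5).

ORF status is evaluated only for NUMTs containing an entire mitochondrial
protein-coding gene: the NUMT-resident copy is extracted by offset mapping
(the model assumes no indels, which holds for the simulator's output and
approximates short real NUMTs), reverse-complemented as needed, and
translated under the standard nuclear code (table 1) and the vertebrate
mitochondrial code (table 2). `intact_orf` means no internal stop under
the *nuclear* code — the relevant criterion for protein-coding potential in
the nucleus; otherwise `full_with_stops`; NUMTs without a full gene are
`incomplete`. The two code tables differ at exactly {TGA, AGA, AGG, ATA},
asserted by exhaustive 64-codon comparison in the tests.

## Microsynteny orthology and the error model

Each unit (NUMT or block) is anchored by the k = 3 nearest protein-coding
genes on each side, chosen by gene-midpoint distance among genes that do
not overlap the unit; an overlapping (host) gene is recorded separately
and also usable for matching. Gene symbols duplicated within one
annotation are ambiguous and excluded. Two units from different species
are candidate orthologs when they share anchors and their mtDNA footprints
overlap reciprocally (minimum of the two coverage fractions) by ≥ 50 %,
wrap-aware. Candidates are resolved to a one-to-one matching greedily by
descending overlap, then shared-anchor count, then unit id — an automated
replacement for manual inspection that is symmetric between the two
species and tested as such.

The by-chance assignment model treats the two units as occupying uniform
inter-gene slots among G genes and uniform L-bp segments on a circular
M-bp molecule:

    rate = (window term) × ((2(L − ⌈fL⌉) + 1)/M)

The overlap term counts the segment placements overlapping by ≥ fL. The
window term depends on what "in the same synteny block" demands:
requiring a shared anchor on *both* sides of the unit gives (2k−1)/G;
accepting a single shared anchor on either side gives (4k−1)/G. With the
mammalian defaults (G = 20,000, L = 200, M = 16,600, k = 3, f = 0.5) the
both-sides form evaluates to 3.03 × 10⁻⁶. Both forms are implemented
(`anchor_mode` on the model and on the assignment), checked against a
Monte-Carlo simulation of the model and against empirical candidate counts
on randomly placed units; assignment defaults to the more permissive
either-side criterion, while the reported expectation E = rate·N_a·N_b
uses the both-sides rate. E ≥ 1 flags a species comparison as unreliable,
and such comparisons are excluded from group construction by default
(switchable).

## Ancestral reconstruction and insertion rates

Ortholog groups are connected components of the pairwise ortholog graph
over all species comparisons; units in no pair form singleton groups. A
group is ancestral on an internal node when it has members in both of the
node's two child clades — applied independently per node, so one group can
support several nested nodes. The tree must be rooted, strictly
bifurcating and ultrametric (relative tolerance 10⁻⁶), with branch lengths
in Myr; node ages derive from root-to-tip depths.

The insertion rate of a species divides its individual NUMTs belonging to
no group that reaches the sister clade by the age of its parent node.
"Most closely related species or monophyletic group" is operationalized as
the sister clade of the leaf in the analysis tree. Rates use individual
NUMTs while ancestral counts may use blocks; both unit choices are
configurable, and the pipeline translates block-level groups to member
NUMTs for rate estimation.

## Synthetic data

The simulator emulates the statistical structure the analyses assume, not
mammalian sequence evolution in detail. Gains arrive as a Poisson process
on every tree branch (including a root stem, if the newick carries one) at
`gain_rate_per_myr` (default 0.7, sized so the default six-taxon,
310-Myr-total tree yields roughly two hundred events). Each gain draws an
mtDNA start from an origin-bias profile (uniform by default; enriched
windows configurable), a length from a log-normal (median 150 bp, log-SD
1.0, clipped to [30 bp, 16 kb] — right-skewed with a ~200 bp mean, matching
the scale of typical mammalian NUMTs), an orientation, and an inter-gene
slot in the ancestral gene order. Copies are inherited by descendants with
per-branch survival exp(−loss·t) (default loss 0.02/Myr) and accumulate
substitutions binomially at 1 − exp(−sub_rate·age) per site (default
0.002/site/Myr, a mammalian-neutral scale), which sets the emitted hit
identity to 100·(1 − subs/length). Gene order is conserved except for
optional per-branch translocation events; each species' genome lays genes
on a fixed grid (default two 1-Mb scaffolds, 200 genes of 2 kb), and TE
intervals are placed at a target density (default 0.35) with
exponential lengths (mean 500 bp).

Alignment-hit tables are emitted directly from the truth — one row per
footprint interval, split in nuclear order at the linearization boundary
exactly as an aligner would report a wrapped insertion — so the pipeline
can be validated without running an aligner. Sequence emission is
optional: when on, the toy mitogenome carries 13 protein-coding genes with
realistic proportional lengths whose codons are clean under the
mitochondrial code (TGA permitted), and every copy is implanted with its
drawn substitutions, so detection-from-coordinates, identity bookkeeping
and ORF classification can all be cross-checked against the emitted FASTA.
Coordinate-only runs are used where sequences are irrelevant.

What passing synthetic tests shows: the merge/chaining logic equals its
combinatorial specification; orthology recovers exactly the true pairs
when gene order is conserved; the ancestral rule and rate estimator
recover the generating process. What it does not show: robustness to
alignment noise, indels inside NUMTs, assembly errors, annotation errors,
or heavy genome reshuffling — the known failure mode of microsynteny
anchoring, which on real data manifests as missed orthologs in highly
rearranged lineages rather than false positives.

## Numerical choices and degenerate inputs

Zero-variance window pairs get p = 1 rather than an error; zero-variance
coverage profiles yield no over-represented regions (with a warning); an
empty NUMT set produces zero counts and NaN identity statistics; an empty
mtDNA footprint is an error. Greedy matching breaks exact ties
lexicographically by unit id for determinism. All randomness flows through
`numpy.random.default_rng` seeds passed explicitly; same seed, same bytes.

## Problem sizes in the bundled analyses

The test suite and the acceptance script run the full statistics at the
native window resolution (320 windows, 51,040 tests) with 8 synthetic
species, 200 reshuffling iterations, 10–20 simulation replicates per
recovery experiment, and 10⁶ Monte-Carlo draws for the error model — sizes
chosen to give stable statistics on a single CPU while exercising every
code path at full analytical resolution.
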