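"""Genomic context of NUMTs: TE flanks, genic location, expression, ORFs.

TE content is profiled in 5 kb flanks (10 windows of 500 bp per side,
ordered outward from the insertion) and contrasted against a background of
pseudo-insertions of the same lengths placed uniformly away from scaffold
ends.  Genic context is a simple overlap rule against protein-coding gene
spans.  ORF status of NUMT-resident copies of full mitochondrial genes is
judged under both the standard and the vertebrate-mitochondrial genetic
codes.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from .core import (
    MINUS,
    GeneModel,
    GenomeIndex,
    Numt,
    NumtBlock,
    RepeatInterval,
    footprint_union_length,
)

log = logging.getLogger(__name__)

NUCLEAR_CODE = 1
VERTEBRATE_MT_CODE = 2

ORF_INTACT = "intact_orf"
ORF_FULL_WITH_STOPS = "full_with_stops"
ORF_INCOMPLETE = "incomplete"


class IntervalCoverage:
    """Merged interval set with O(log n) covered-length queries."""

    def __init__(self, intervals: Iterable[tuple[int, int]]):
        merged: list[list[int]] = []
        for s, e in sorted(intervals):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self.starts = [m[0] for m in merged]
        self.ends = [m[1] for m in merged]
        self._cum = [0]
        for s, e in merged:
            self._cum.append(self._cum[-1] + (e - s))

    def covered(self, a: int, b: int) -> int:
        """Bases of [a, b) covered by the interval union."""
        if b <= a or not self.starts:
            return 0
        lo = bisect_right(self.ends, a)  # first interval ending past a
        hi = bisect_left(self.starts, b) - 1  # last interval starting before b
        if lo > hi:
            return 0
        total = self._cum[hi + 1] - self._cum[lo]
        total -= max(0, a - self.starts[lo])
        total -= max(0, self.ends[hi] - b)
        return total

    def distance_to(self, pos: int) -> float:
        """Distance from a point to the nearest interval (0 if inside)."""
        if not self.starts:
            return math.inf
        i = bisect_right(self.starts, pos) - 1
        best = math.inf
        if i >= 0:
            if pos < self.ends[i]:
                return 0.0
            best = pos - self.ends[i] + 1
        if i + 1 < len(self.starts):
            best = min(best, self.starts[i + 1] - pos)
        return float(best)


def _repeats_by_scaffold(
    repeats: Sequence[RepeatInterval],
) -> dict[str, IntervalCoverage]:
    by: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        by.setdefault(r.scaffold, []).append((r.start, r.end))
    return {k: IntervalCoverage(v) for k, v in by.items()}


@dataclass
class FlankProfile:
    unit_id: str
    up: np.ndarray  # 10 fractions, window 1 adjoins the unit
    down: np.ndarray
    up_truncated: np.ndarray = field(default_factory=lambda: np.zeros(10, bool))
    down_truncated: np.ndarray = field(default_factory=lambda: np.zeros(10, bool))


def _unit_windows(
    start: int, end: int, scaffold_len: int, flank: int, window: int
) -> tuple[list[tuple[int, int, bool]], list[tuple[int, int, bool]]]:
    n_win = flank // window
    up, down = [], []
    for w in range(n_win):
        a, b = start - (w + 1) * window, start - w * window
        trunc = a < 0
        up.append((max(a, 0), max(b, 0), trunc))
        a, b = end + w * window, end + (w + 1) * window
        trunc = b > scaffold_len
        down.append((min(a, scaffold_len), min(b, scaffold_len), trunc))
    return up, down


def flank_te_profile(
    units: Sequence[Numt | NumtBlock],
    repeats: Sequence[RepeatInterval],
    genome_index: GenomeIndex,
    flank: int = 5_000,
    window: int = 500,
) -> list[FlankProfile]:
    """Per-window TE fraction in the flanks of each NUMT/block.

    Windows are ordered outward (window 1 adjoins the unit).  Windows
    truncated at scaffold edges are flagged; their fractions are computed on
    the available bases.
    """
    cov = _repeats_by_scaffold(repeats)
    n_win = flank // window
    profiles = []
    for u in units:
        scaffold_len = genome_index.length(u.scaffold)
        c = cov.get(u.scaffold, IntervalCoverage([]))
        up_w, down_w = _unit_windows(u.n_start, u.n_end, scaffold_len, flank, window)
        up = np.zeros(n_win)
        down = np.zeros(n_win)
        up_t = np.zeros(n_win, bool)
        down_t = np.zeros(n_win, bool)
        for w, (a, b, t) in enumerate(up_w):
            up[w] = c.covered(a, b) / (b - a) if b > a else np.nan
            up_t[w] = t
        for w, (a, b, t) in enumerate(down_w):
            down[w] = c.covered(a, b) / (b - a) if b > a else np.nan
            down_t[w] = t
        profiles.append(
            FlankProfile(
                unit_id=u.id or f"{u.scaffold}:{u.n_start}",
                up=up,
                down=down,
                up_truncated=up_t,
                down_truncated=down_t,
            )
        )
    return profiles


def mean_flank_profile(profiles: Sequence[FlankProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Species-level mean TE fraction per flank window (up, down)."""
    up = np.nanmean(np.vstack([p.up for p in profiles]), axis=0)
    down = np.nanmean(np.vstack([p.down for p in profiles]), axis=0)
    return up, down


@dataclass
class BackgroundProfile:
    up_mean: np.ndarray
    down_mean: np.ndarray
    n_units: int
    n_iter: int


def background_te_profile(
    units: Sequence[Numt | NumtBlock],
    repeats: Sequence[RepeatInterval],
    genome_index: GenomeIndex,
    n_iter: int = 1_000,
    edge_exclusion: int = 5_000,
    flank: int = 5_000,
    window: int = 500,
    seed: int | None = None,
) -> BackgroundProfile:
    """Mean flank TE profile of random same-length pseudo-insertions.

    Each unit is replaced by a pseudo-unit of the same length placed
    uniformly over all scaffolds proportional to eligible length, never
    within ``edge_exclusion`` bp of a scaffold end, so both flanks are fully
    on-scaffold.  Averaged per window over units and iterations.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    cov = _repeats_by_scaffold(repeats)
    scaffolds = genome_index.items()
    n_win = flank // window
    up_acc = np.zeros(n_win)
    down_acc = np.zeros(n_win)
    n_placed = 0
    lengths = [u.n_end - u.n_start for u in units]
    usable = []
    for length in lengths:
        eligible = [
            (name, slen - 2 * edge_exclusion - length + 1)
            for name, slen in scaffolds
            if slen - 2 * edge_exclusion - length + 1 > 0
        ]
        if not eligible:
            log.warning("no scaffold can host a %d bp pseudo-unit; skipped", length)
            continue
        usable.append((length, eligible))
    if not usable:
        raise ValueError("no unit could be placed on any scaffold")
    for _ in range(n_iter):
        for length, eligible in usable:
            weights = np.array([e[1] for e in eligible], dtype=float)
            k = rng.choice(len(eligible), p=weights / weights.sum())
            name, n_pos = eligible[k]
            start = edge_exclusion + int(rng.integers(0, n_pos))
            end = start + length
            c = cov.get(name, IntervalCoverage([]))
            for w in range(n_win):
                a, b = start - (w + 1) * window, start - w * window
                up_acc[w] += c.covered(a, b) / window
                a, b = end + w * window, end + (w + 1) * window
                down_acc[w] += c.covered(a, b) / window
            n_placed += 1
    total = n_placed or 1
    return BackgroundProfile(
        up_mean=up_acc / total,
        down_mean=down_acc / total,
        n_units=len(usable),
        n_iter=n_iter,
    )


def compare_flank_profiles(
    observed_by_species: Mapping[str, tuple[np.ndarray, np.ndarray]],
    background_by_species: Mapping[str, BackgroundProfile],
) -> dict[str, np.ndarray]:
    """Per-window paired comparison of observed vs background across species.

    Species are the pairs (their observed and background window means);
    Wilcoxon signed-rank, two-sided.  Returns p-value arrays for the
    upstream and downstream windows.
    """
    species = sorted(set(observed_by_species) & set(background_by_species))
    if len(species) < 3:
        raise ValueError("need >=3 species for a paired comparison")
    obs_up = np.vstack([observed_by_species[sp][0] for sp in species])
    obs_down = np.vstack([observed_by_species[sp][1] for sp in species])
    bg_up = np.vstack([background_by_species[sp].up_mean for sp in species])
    bg_down = np.vstack([background_by_species[sp].down_mean for sp in species])
    n_win = obs_up.shape[1]
    p_up = np.ones(n_win)
    p_down = np.ones(n_win)
    for w in range(n_win):
        for arr, obs, bg in ((p_up, obs_up, bg_up), (p_down, obs_down, bg_down)):
            diff = obs[:, w] - bg[:, w]
            if np.allclose(diff, 0):
                arr[w] = 1.0
            else:
                arr[w] = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
    return {"up": p_up, "down": p_down}


@dataclass
class CorrelationRecord:
    rho: float
    pvalue: float
    n: int


def te_distance_identity_correlation(
    numts: Sequence[Numt], repeats: Sequence[RepeatInterval]
) -> CorrelationRecord:
    """Spearman correlation of NUMT/mtDNA identity with nearest-TE distance.

    The distance of a NUMT to its closest TE is the mean of the 5' and 3'
    nearest-TE distances (0 when the end lies inside a TE).  Blocks are not
    accepted here; identity is heterogeneous within a block.
    """
    cov = _repeats_by_scaffold(repeats)
    identities, distances = [], []
    for n in numts:
        c = cov.get(n.scaffold)
        if c is None:
            continue
        d5 = c.distance_to(n.n_start)
        d3 = c.distance_to(n.n_end - 1)
        d = 0.5 * (d5 + d3)
        if math.isfinite(d):
            identities.append(n.identity)
            distances.append(d)
    if len(distances) < 5:
        raise ValueError("need >=5 NUMTs with finite TE distances")
    if len(set(distances)) == 1 or len(set(identities)) == 1:
        return CorrelationRecord(rho=math.nan, pvalue=math.nan, n=len(distances))
    rho, p = stats.spearmanr(identities, distances)
    return CorrelationRecord(rho=float(rho), pvalue=float(p), n=len(distances))


def classify_genic_context(
    units: Sequence[Numt | NumtBlock], genes: Sequence[GeneModel]
) -> tuple[dict[str, str], float]:
    """Label each unit intronic (any overlap with a gene span) or intergenic.

    Returns the per-unit labels and the intergenic:intronic ratio
    (inf when nothing is intronic, nan when there are no units).
    """
    gene_cov = {
        scaffold: IntervalCoverage(
            [(g.start, g.end) for g in genes if g.scaffold == scaffold]
        )
        for scaffold in {g.scaffold for g in genes}
    }
    labels: dict[str, str] = {}
    for u in units:
        c = gene_cov.get(u.scaffold)
        overlap = c.covered(u.n_start, u.n_end) if c else 0
        labels[u.id or f"{u.scaffold}:{u.n_start}"] = (
            "intronic" if overlap > 0 else "intergenic"
        )
    n_intronic = sum(1 for v in labels.values() if v == "intronic")
    n_intergenic = len(labels) - n_intronic
    if not labels:
        ratio = math.nan
    elif n_intronic == 0:
        ratio = math.inf
    else:
        ratio = n_intergenic / n_intronic
    return labels, ratio


@dataclass(frozen=True)
class ExpressionEvidence:
    unit_id: str
    tissue: str
    junction_5: int
    junction_3: int
    covered_fraction: float


def call_expressed(
    evidence: ExpressionEvidence,
    min_junction: int = 2,
    min_overhang: int = 5,
    min_cov: float = 0.7,
) -> bool:
    """Expressed iff both junction sides have >= ``min_junction`` supporting
    reads (already filtered upstream to >= ``min_overhang`` bp overhang) and
    read coverage of the unit is strictly above ``min_cov``.
    """
    return (
        evidence.junction_5 >= min_junction
        and evidence.junction_3 >= min_junction
        and evidence.covered_fraction > min_cov
    )


def enrichment_test(
    expressed: Mapping[str, bool], context_labels: Mapping[str, str]
) -> float:
    """Chi-square p-value of the expressed x intronic/intergenic 2x2 table."""
    table = np.zeros((2, 2))
    for unit, is_expr in expressed.items():
        ctx = context_labels.get(unit)
        if ctx is None:
            continue
        table[int(bool(is_expr)), int(ctx == "intronic")] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return math.nan
    chi2, p, _, expected = stats.chi2_contingency(table)
    if (expected < 5).any():
        log.warning("chi-square expected cell below 5; p-value approximate")
    return float(p)


def read_expression_evidence(path) -> list[ExpressionEvidence]:
    """Read a unit/tissue/junc5/junc3/cov_fraction TSV (with header)."""
    rows: list[ExpressionEvidence] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            rows.append(
                ExpressionEvidence(
                    unit_id=fields[0],
                    tissue=fields[1],
                    junction_5=int(fields[2]),
                    junction_3=int(fields[3]),
                    covered_fraction=float(fields[4]),
                )
            )
    return rows


def _mt_to_numt_offset(numt: Numt, pos: int) -> int | None:
    """Offset of mtDNA position ``pos`` within the footprint-ordered copy."""
    offset = 0
    for s, e in numt.mt_intervals:
        if s <= pos < e:
            return offset + (pos - s)
        offset += e - s
    return None


def _gene_copy_sequence(
    numt: Numt, numt_sequence: str, gene: GeneModel
) -> str | None:
    """NUMT-resident nucleotide copy of a fully contained mitochondrial gene."""
    start_off = _mt_to_numt_offset(numt, gene.start)
    end_off = _mt_to_numt_offset(numt, gene.end - 1)
    if start_off is None or end_off is None:
        return None
    if end_off - start_off != (gene.end - 1) - gene.start:
        return None  # gene split across a non-contiguous footprint
    seq = numt_sequence
    if numt.orientation == MINUS:
        seq = str(Seq(seq).reverse_complement())
    if len(seq) < end_off + 1:
        return None
    sub = seq[start_off : end_off + 1]
    if gene.strand == MINUS:
        sub = str(Seq(sub).reverse_complement())
    return sub


def classify_orf(
    numt: Numt,
    numt_sequence: str,
    mt_genes: Sequence[GeneModel],
) -> dict[str, str]:
    """ORF class of each mitochondrial protein-coding gene the NUMT contains.

    A gene not entirely inside the footprint is ``incomplete``.  A contained
    copy is ``intact_orf`` when its standard-code (nuclear) translation has
    no internal stop codon, else ``full_with_stops``.  The mitochondrial
    translation is also computed to document code-table differences.
    """
    classes: dict[str, str] = {}
    for gene in mt_genes:
        sub = _gene_copy_sequence(numt, numt_sequence, gene)
        if sub is None:
            classes[gene.symbol] = ORF_INCOMPLETE
            continue
        coding = sub[: len(sub) - len(sub) % 3]
        protein = str(Seq(coding).translate(table=NUCLEAR_CODE))
        internal = protein[:-1] if protein.endswith("*") else protein
        classes[gene.symbol] = (
            ORF_INTACT if "*" not in internal else ORF_FULL_WITH_STOPS
        )
    return classes


def summarize_orf_class(classes: Mapping[str, str]) -> str:
    """Collapse per-gene ORF classes to a per-NUMT class."""
    values = set(classes.values())
    if ORF_INTACT in values:
        return ORF_INTACT
    if ORF_FULL_WITH_STOPS in values:
        return ORF_FULL_WITH_STOPS
    return ORF_INCOMPLETE


def translate_both_codes(codon: str) -> tuple[str, str]:
    """(standard, vertebrate-mitochondrial) translation of one codon."""
    return (
        str(Seq(codon).translate(table=NUCLEAR_CODE)),
        str(Seq(codon).translate(table=VERTEBRATE_MT_CODE)),
    )
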