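"""NUMT calling: HSP filtering, merging, block assembly and summaries.

The calling chain is: ``filter_hsps`` (E-value <= 1e-3, length >= 30 bp) ->
``merge_hsps`` (adjacent same-orientation hits with a < 10 bp nuclear gap
and continuous mtDNA coordinates, wrap-aware at the linearization boundary)
-> ``filter_by_contig_length`` (drop scaffolds < 20 kb) -> dense renaming
``{Species}_numt_{k}`` in (scaffold order, nuclear start) order ->
``assemble_blocks`` (single-linkage chaining at < 2 kb, orientation-blind).
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    MINUS,
    PLUS,
    GenomeIndex,
    Hsp,
    Numt,
    NumtBlock,
    NumtSummary,
    footprint_union_length,
)

log = logging.getLogger(__name__)


def filter_hsps(
    hsps: Iterable[Hsp], max_e: float = 1e-3, min_len: int = 30
) -> list[Hsp]:
    """Keep HSPs with e_value <= max_e and alignment length >= min_len."""
    return [h for h in hsps if h.e_value <= max_e and h.aln_length >= min_len]


def _circular_gap(a_end: int, b_start: int, mt_length: int) -> int:
    """Signed mtDNA gap from position a_end forward to b_start on the circle.

    Returns a value in [-mt_length/2, mt_length/2): small positive = gap,
    small negative = overlap, either possibly across the linearization
    boundary.
    """
    d = (b_start - a_end) % mt_length
    if d > mt_length // 2:
        d -= mt_length
    return d


def _mt_continuous(prev: Hsp, nxt: Hsp, mt_length: int, mt_gap_max: int) -> bool:
    """True when nxt continues prev's mtDNA footprint in orientation order."""
    if prev.orientation == PLUS:
        d = _circular_gap(prev.mt_end, nxt.mt_start, mt_length)
    else:
        # On the minus strand the mtDNA coordinate decreases along the
        # nuclear plus strand, so the next hit must end where prev starts.
        d = _circular_gap(nxt.mt_end, prev.mt_start, mt_length)
    return abs(d) <= mt_gap_max


def mergeable(
    a: Hsp,
    b: Hsp,
    mt_length: int,
    nuclear_gap_max: int = 10,
    mt_gap_max: int = 10,
) -> bool:
    """Merge predicate for a nuclear-ordered HSP pair (a before b).

    Requires the same orientation, a nuclear gap below ``nuclear_gap_max``
    and mtDNA continuity in the orientation-consistent direction within
    ``mt_gap_max`` (gap or overlap), wrap-aware at the linearization
    boundary.
    """
    if (a.n_start, a.n_end) > (b.n_start, b.n_end):
        a, b = b, a
    if a.orientation != b.orientation:
        return False
    if b.n_start - a.n_end >= nuclear_gap_max:
        return False
    return _mt_continuous(a, b, mt_length, mt_gap_max)


def _chain_to_numt(chain: Sequence[Hsp], mt_length: int) -> Numt:
    n_start = min(h.n_start for h in chain)
    n_end = max(h.n_end for h in chain)
    total_aln = sum(h.aln_length for h in chain)
    identity = sum(h.identity * h.aln_length for h in chain) / total_aln
    # Build the footprint in nuclear order, bridging sub-threshold mtDNA
    # gaps but keeping two intervals across the linearization boundary.
    intervals: list[list[int]] = [[chain[0].mt_start, chain[0].mt_end]]
    for prev, nxt in zip(chain, chain[1:]):
        cur = intervals[-1]
        if prev.orientation == PLUS:
            wraps = nxt.mt_start < prev.mt_end and _circular_gap(
                prev.mt_end, nxt.mt_start, mt_length
            ) >= 0
            if wraps:
                intervals.append([nxt.mt_start, nxt.mt_end])
            else:
                cur[0] = min(cur[0], nxt.mt_start)
                cur[1] = max(cur[1], nxt.mt_end)
        else:
            wraps = nxt.mt_end > prev.mt_start and _circular_gap(
                nxt.mt_end, prev.mt_start, mt_length
            ) >= 0
            if wraps:
                intervals.append([nxt.mt_start, nxt.mt_end])
            else:
                cur[0] = min(cur[0], nxt.mt_start)
                cur[1] = max(cur[1], nxt.mt_end)
    return Numt(
        id=None,
        scaffold=chain[0].scaffold,
        n_start=n_start,
        n_end=n_end,
        orientation=chain[0].orientation,
        mt_intervals=tuple((s, e) for s, e in intervals),
        identity=identity,
        members=tuple(chain),
    )


def merge_hsps(
    hsps: Sequence[Hsp],
    mt_length: int,
    nuclear_gap_max: int = 10,
    mt_gap_max: int = 10,
    species: str | None = None,
    genome_index: GenomeIndex | None = None,
) -> list[Numt]:
    """Merge adjacent compatible HSPs into NUMTs.

    Two nuclear-adjacent HSPs on the same scaffold merge when they share an
    orientation, their nuclear gap is < ``nuclear_gap_max``, and their mtDNA
    coordinates continue in the orientation-consistent direction within
    ``mt_gap_max`` (gap or overlap), including continuation across the
    linearization boundary of the circular mitogenome.
    """
    by_scaffold: dict[str, list[Hsp]] = defaultdict(list)
    for h in hsps:
        by_scaffold[h.scaffold].append(h)
    numts: list[Numt] = []
    for scaffold in by_scaffold:
        rows = sorted(by_scaffold[scaffold], key=lambda h: (h.n_start, h.n_end))
        parent = list(range(len(rows)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, a in enumerate(rows):
            for j in range(i + 1, len(rows)):
                b = rows[j]
                if b.n_start - a.n_end >= nuclear_gap_max:
                    break  # n_start is sorted: later rows only get farther
                if mergeable(a, b, mt_length, nuclear_gap_max, mt_gap_max):
                    parent[find(j)] = find(i)
                elif b.n_start < a.n_end:
                    log.warning(
                        "overlapping nuclear intervals on %s from distinct mtDNA "
                        "regions kept as separate NUMTs",
                        scaffold,
                    )
        components: dict[int, list[Hsp]] = defaultdict(list)
        for i, h in enumerate(rows):
            components[find(i)].append(h)
        for root in sorted(components, key=lambda r: rows[r].n_start):
            numts.append(_chain_to_numt(components[root], mt_length))
    if species is not None:
        numts = assign_numt_ids(numts, species, genome_index)
    return numts


def assign_numt_ids(
    numts: Sequence[Numt], species: str, genome_index: GenomeIndex | None = None
) -> list[Numt]:
    """Name NUMTs ``{Species}_numt_{k}`` densely in (scaffold order, start) order."""
    if genome_index is not None:
        order = {name: i for i, name in enumerate(genome_index.ids)}
        key = lambda n: (order.get(n.scaffold, len(order)), n.scaffold, n.n_start)
    else:
        key = lambda n: (n.scaffold, n.n_start)
    ordered = sorted(numts, key=key)
    out = []
    for k, n in enumerate(ordered, start=1):
        out.append(
            Numt(
                id=f"{species}_numt_{k}",
                scaffold=n.scaffold,
                n_start=n.n_start,
                n_end=n.n_end,
                orientation=n.orientation,
                mt_intervals=n.mt_intervals,
                identity=n.identity,
                members=n.members,
                species=species,
            )
        )
    return out


def filter_by_contig_length(
    numts: Sequence[Numt],
    genome_index: GenomeIndex,
    min_contig: int = 20_000,
    species: str | None = None,
) -> list[Numt]:
    """Drop NUMTs on scaffolds shorter than ``min_contig`` and renumber."""
    for n in numts:
        if n.scaffold not in genome_index:
            raise KeyError(f"scaffold {n.scaffold!r} not in genome index")
    kept = [n for n in numts if genome_index.length(n.scaffold) >= min_contig]
    species = species or next((n.species for n in kept if n.species), None)
    if species is not None:
        kept = assign_numt_ids(kept, species, genome_index)
    return kept


def assemble_blocks(
    numts: Sequence[Numt], max_gap: int = 2_000, species: str | None = None
) -> list[NumtBlock]:
    """Chain NUMTs with nuclear gaps < ``max_gap`` into blocks.

    Single-linkage on each scaffold, regardless of orientation; every NUMT
    belongs to exactly one (possibly singleton) block.
    """
    by_scaffold: dict[str, list[Numt]] = defaultdict(list)
    for n in numts:
        by_scaffold[n.scaffold].append(n)
    species = species or next((n.species for n in numts if n.species), None)
    blocks: list[NumtBlock] = []
    for scaffold in sorted(by_scaffold):
        rows = sorted(by_scaffold[scaffold], key=lambda n: (n.n_start, n.n_end))
        chain: list[Numt] = []
        chain_end = None
        for n in rows:
            if chain and n.n_start - chain_end < max_gap:
                chain.append(n)
                chain_end = max(chain_end, n.n_end)
            else:
                if chain:
                    blocks.append(_make_block(chain))
                chain = [n]
                chain_end = n.n_end
        if chain:
            blocks.append(_make_block(chain))
    for k, b in enumerate(blocks, start=1):
        b.id = f"{species}_block_{k}" if species else f"block_{k}"
    return blocks


def _make_block(members: Sequence[Numt]) -> NumtBlock:
    return NumtBlock(
        id=None,
        scaffold=members[0].scaffold,
        span=(min(m.n_start for m in members), max(m.n_end for m in members)),
        members=tuple(members),
    )


def find_tandem_duplicates(
    numts: Sequence[Numt],
    window: int = 10_000,
    coord_tol: int = 10,
    min_overlap: float = 0.5,
) -> set[tuple[str, str]]:
    """Candidate tandem-duplicate pairs within one species.

    A pair qualifies when both NUMTs sit on the same scaffold within
    ``window`` bp of each other, share a similar mtDNA start or end
    (+-``coord_tol`` bp), and their mtDNA footprints overlap reciprocally by
    at least ``min_overlap``.
    """
    from .orthology import mt_overlap_fraction

    pairs: set[tuple[str, str]] = set()
    by_scaffold: dict[str, list[Numt]] = defaultdict(list)
    for n in numts:
        by_scaffold[n.scaffold].append(n)
    for rows in by_scaffold.values():
        rows = sorted(rows, key=lambda n: n.n_start)
        for i, a in enumerate(rows):
            for b in rows[i + 1 :]:
                dist = max(0, b.n_start - a.n_end)
                if dist > window:
                    break
                similar = (
                    abs(a.mt_start - b.mt_start) <= coord_tol
                    or abs(a.mt_end - b.mt_end) <= coord_tol
                )
                if not similar:
                    continue
                mt_len = max(a.mt_end, b.mt_end) + 1
                if mt_overlap_fraction(a.mt_intervals, b.mt_intervals, mt_len) >= min_overlap:
                    ids = sorted([a.id or f"@{a.n_start}", b.id or f"@{b.n_start}"])
                    pairs.add((ids[0], ids[1]))
    return pairs


def numt_summary(
    numts: Sequence[Numt],
    blocks: Sequence[NumtBlock],
    genome_index: GenomeIndex,
    identity_cut: float = 98.0,
) -> NumtSummary:
    """Per-species counts, cumulative length, genome fraction and identity stats."""
    species = next((n.species for n in numts if n.species), None)
    cumulative = sum(n.length for n in numts)
    total = genome_index.total_length()
    if numts:
        idents = np.array([n.identity for n in numts], dtype=float)
        mean_id = float(idents.mean())
        median_id = float(np.median(idents))
        frac_above = float((idents > identity_cut).mean())
    else:
        mean_id = median_id = frac_above = math.nan
    return NumtSummary(
        species=species,
        n_numts=len(numts),
        n_blocks=len(blocks),
        cumulative_length=cumulative,
        genome_fraction=cumulative / total if total else math.nan,
        mean_identity=mean_id,
        median_identity=median_id,
        fraction_above_cut=frac_above,
        identity_cut=identity_cut,
    )


def compare_length_distributions(
    length_sets: Mapping[str, Sequence[float]],
    order_labels: Mapping[str, str],
) -> tuple["pd.DataFrame", float]:
    """Pairwise KS tests of per-species NUMT length distributions.

    Returns the symmetric p-value table and the rank-sum p-value of the
    within-order versus across-order contrast of log10-transformed KS
    p-values.  Species with fewer than two NUMTs are excluded with a
    warning.
    """
    import pandas as pd

    usable = {}
    for sp, lengths in length_sets.items():
        if len(lengths) < 2:
            log.warning("species %s excluded from KS comparison (<2 NUMTs)", sp)
            continue
        usable[sp] = np.asarray(lengths, dtype=float)
    species = sorted(usable)
    if len(species) < 2:
        raise ValueError("need at least 2 species with >=2 NUMTs")
    table = pd.DataFrame(np.ones((len(species), len(species))), index=species, columns=species)
    within, across = [], []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            p = float(stats.ks_2samp(usable[a], usable[b]).pvalue)
            table.loc[a, b] = table.loc[b, a] = p
            logp = math.log10(max(p, 1e-300))
            if order_labels.get(a) == order_labels.get(b):
                within.append(logp)
            else:
                across.append(logp)
    if within and across:
        contrast_p = float(stats.mannwhitneyu(within, across, alternative="two-sided").pvalue)
    else:
        contrast_p = math.nan
    return table, contrast_p


def numt_lengths(numts: Sequence[Numt]) -> list[int]:
    return [n.length for n in numts]
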