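"""Nonrandomness of the mtDNA regions that produce NUMTs.

The analysis span is 16,000 bp by default (the first 320 windows of 50 bp),
avoiding the cross-species length heterogeneity of the D-loop tail.  The
workflow is: per-base coverage profiles -> per-window medians per species ->
all-pairs two-sided rank-sum tests between windows across species with
Benjamini-Hochberg adjustment -> comparison of the observed number of
significant tests against a circular-reshuffling null in which every NUMT
keeps its length but draws a uniform start, wrapping coordinates past the
span back to the origin.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Numt

log = logging.getLogger(__name__)


@dataclass
class PairTestMatrix:
    qvalues: np.ndarray  # window x window, symmetric, nan diagonal
    pvalues: np.ndarray
    n_tests: int
    n_significant: int
    alpha: float


@dataclass
class NullResult:
    observed: int
    null_counts: np.ndarray
    alpha: float

    @property
    def null_median(self) -> float:
        return float(np.median(self.null_counts))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.null_counts, q))


def coverage_profile(numts: Sequence[Numt], span: int = 16_000) -> np.ndarray:
    """Per-base NUMT coverage depth over [0, span) of the linearized mtDNA."""
    diff = np.zeros(span + 1, dtype=np.int64)
    for n in numts:
        for s, e in n.mt_intervals:
            s, e = max(0, min(s, span)), max(0, min(e, span))
            if e > s:
                diff[s] += 1
                diff[e] -= 1
    return np.cumsum(diff[:-1])


def window_medians(
    profiles: Mapping[str, np.ndarray], window: int = 50
) -> "pd.DataFrame":
    """Species x window table of median per-base coverage."""
    import pandas as pd

    species = sorted(profiles)
    spans = {len(profiles[sp]) for sp in species}
    if len(spans) != 1:
        raise ValueError("all profiles must share the same span")
    span = spans.pop()
    if span % window:
        raise ValueError(f"span {span} not divisible by window {window}")
    rows = [
        np.median(np.asarray(profiles[sp], dtype=float).reshape(-1, window), axis=1)
        for sp in species
    ]
    cols = [f"w{i + 1}" for i in range(span // window)]
    return pd.DataFrame(np.vstack(rows), index=species, columns=cols)


def _tie_term(sorted_rows: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over runs of equal values for each row of a sorted matrix."""
    n_rows, n_cols = sorted_rows.shape
    eq = sorted_rows[:, 1:] == sorted_rows[:, :-1]
    # Pad a False column per row so runs cannot cross row boundaries.
    padded = np.concatenate([eq, np.zeros((n_rows, 1), dtype=bool)], axis=1).ravel()
    shifted = np.concatenate([[False], padded[:-1]])
    starts = np.flatnonzero(padded & ~shifted)
    ends = np.flatnonzero(~padded & shifted)
    out = np.zeros(n_rows)
    if starts.size:
        t = (ends - starts + 1).astype(float)  # run of e equal diffs = e+1 tied values
        rows = starts // n_cols
        np.add.at(out, rows, t**3 - t)
    return out


def _ranksum_stats(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(U statistic, tie-corrected variance, tie term) for paired rows."""
    n, m = x.shape[1], y.shape[1]
    combined = np.concatenate([x, y], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    r_x = ranks[:, :n].sum(axis=1)
    u = r_x - n * (n + 1) / 2.0
    big_n = n + m
    ties = _tie_term(np.sort(combined, axis=1))
    var = n * m / 12.0 * ((big_n + 1) - ties / (big_n * (big_n - 1)))
    return u, var, ties


def ranksum_pvalues(x: np.ndarray, y: np.ndarray, exact_max_n: int = 8) -> np.ndarray:
    """Two-sided Mann-Whitney p-values for paired rows of x and y.

    Normal approximation with tie correction and continuity correction for
    group sizes >= ``exact_max_n``; exact (network-enumeration) null for
    smaller tie-free samples.  Rows with zero variance (all values tied)
    get p = 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, m = x.shape[1], y.shape[1]
    u, var, ties = _ranksum_stats(x, y)
    mean = n * m / 2.0
    p = np.ones(u.shape[0])
    ok = var > 0
    z = (np.abs(u[ok] - mean) - 0.5) / np.sqrt(var[ok])
    p[ok] = np.clip(2.0 * stats.norm.sf(z), 0.0, 1.0)
    if min(n, m) < exact_max_n:
        exact_rows = (ties == 0) & ok
        if exact_rows.any():
            p[exact_rows] = _exact_two_sided(u[exact_rows], n, m)
    return p


def _exact_two_sided(u: np.ndarray, n: int, m: int) -> np.ndarray:
    """Two-sided exact p-values for U statistics (tie-free samples)."""
    from itertools import combinations

    key = (n, m)
    dist = _EXACT_DIST.get(key)
    if dist is None:
        total = n + m
        counts = np.zeros(n * m + 1)
        ranks = np.arange(1, total + 1)
        for subset in combinations(range(total), n):
            r = ranks[list(subset)].sum()
            counts[int(r - n * (n + 1) / 2)] += 1
        dist = counts / counts.sum()
        _EXACT_DIST[key] = dist
    cdf = np.cumsum(dist)
    sf = np.cumsum(dist[::-1])[::-1]
    u = np.rint(u).astype(int)
    p = 2.0 * np.minimum(cdf[u], sf[u])
    return np.minimum(p, 1.0)


_EXACT_DIST: dict[tuple[int, int], np.ndarray] = {}


def pairwise_window_tests(
    table: "pd.DataFrame", alpha: float = 0.01
) -> PairTestMatrix:
    """All-pairs two-sided rank-sum tests between window columns across species.

    For W windows this performs W(W-1)/2 tests on the per-species median
    vectors and adjusts them jointly by Benjamini-Hochberg.
    """
    values = np.asarray(table, dtype=float)
    n_species, n_windows = values.shape
    if n_species < 2:
        raise ValueError("need >=2 species")
    pair_idx = np.array(list(itertools.combinations(range(n_windows), 2)))
    pvals = ranksum_pvalues(
        values[:, pair_idx[:, 0]].T, values[:, pair_idx[:, 1]].T
    )
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    pmat = np.full((n_windows, n_windows), np.nan)
    qmat = np.full((n_windows, n_windows), np.nan)
    pmat[pair_idx[:, 0], pair_idx[:, 1]] = pvals
    pmat[pair_idx[:, 1], pair_idx[:, 0]] = pvals
    qmat[pair_idx[:, 0], pair_idx[:, 1]] = qvals
    qmat[pair_idx[:, 1], pair_idx[:, 0]] = qvals
    return PairTestMatrix(
        qvalues=qmat,
        pvalues=pmat,
        n_tests=len(pvals),
        n_significant=int((qvals < alpha).sum()),
        alpha=alpha,
    )


def _reshuffled_profile(
    lengths: np.ndarray, span: int, rng: np.random.Generator
) -> np.ndarray:
    """Coverage profile after assigning each footprint a uniform start.

    Coordinates past the span wrap back by subtracting the span, mirroring
    mtDNA circularity over the analysis span.
    """
    diff = np.zeros(span + 1, dtype=np.int64)
    starts = rng.integers(0, span, size=lengths.size)
    ends = starts + np.minimum(lengths, span)
    over = ends > span
    np.add.at(diff, starts, 1)
    np.add.at(diff, np.where(over, span, ends), -1)
    if over.any():
        np.add.at(diff, np.zeros(int(over.sum()), dtype=np.int64), 1)
        np.add.at(diff, ends[over] - span, -1)
    return np.cumsum(diff[:-1])


def reshuffle_null(
    numts_by_species: Mapping[str, Sequence[Numt]],
    n_iter: int = 1_000,
    span: int = 16_000,
    window: int = 50,
    alpha: float = 0.01,
    seed: int | None = None,
) -> NullResult:
    """Null distribution of significant window tests under uniform mtDNA origin.

    Each iteration keeps every NUMT's footprint length but redraws its start
    uniformly on [0, span), wrapping past-span coordinates, then reruns the
    window-median and pairwise-test pipeline.  The observed count is computed
    from the input footprints with the identical pipeline.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    species = sorted(numts_by_species)
    observed_profiles = {
        sp: coverage_profile(numts_by_species[sp], span=span) for sp in species
    }
    observed = pairwise_window_tests(
        window_medians(observed_profiles, window=window), alpha=alpha
    ).n_significant
    lengths = {
        sp: np.array(
            [n.mt_footprint_length for n in numts_by_species[sp]], dtype=np.int64
        )
        for sp in species
    }
    counts = np.zeros(n_iter, dtype=np.int64)
    for it in range(n_iter):
        profiles = {
            sp: _reshuffled_profile(lengths[sp], span, rng) for sp in species
        }
        counts[it] = pairwise_window_tests(
            window_medians(profiles, window=window), alpha=alpha
        ).n_significant
    return NullResult(observed=observed, null_counts=counts, alpha=alpha)


def significant_fraction(n_significant: int, n_tests: int) -> float:
    """Percentage of tests called significant."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return 100.0 * n_significant / n_tests


def overrepresented_regions(
    profile: np.ndarray, z_cut: float = 3.0
) -> list[tuple[int, int]]:
    """Maximal runs of bases whose coverage z-score exceeds ``z_cut``.

    The mean and standard deviation are taken over the full profile,
    including zero-coverage bases.
    """
    profile = np.asarray(profile, dtype=float)
    sd = profile.std()
    if sd == 0:
        log.warning("zero-variance coverage profile; no over-represented regions")
        return []
    z = (profile - profile.mean()) / sd
    above = z > z_cut
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    return list(zip(starts.tolist(), ends.tolist()))
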