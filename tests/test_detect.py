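"""NUMT calling: filtering, merging, blocks, duplicates, summaries."""

import math

import numpy as np
import pytest

from numtkit import detect
from numtkit.core import GenomeIndex

from conftest import make_hsp, make_numt, random_hsps


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _oracle_pair_linkable(a, b, mt_length, nuc_gap=10, mt_gap=10):
    """Merge predicate re-derived from the stated rules (oracle)."""
    if (a.n_start, a.n_end) > (b.n_start, b.n_end):
        a, b = b, a
    if a.orientation != b.orientation:
        return False
    if b.n_start - a.n_end >= nuc_gap:
        return False
    if a.orientation == "+":
        d = (b.mt_start - a.mt_end) % mt_length
    else:
        d = (a.mt_start - b.mt_end) % mt_length
    return d <= mt_gap or d >= mt_length - mt_gap


def _oracle_merge_components(hsps, mt_length):
    """Transitive closure over all linkable pairs by naive iteration."""
    groups = [{i} for i in range(len(hsps))]
    changed = True
    while changed:
        changed = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                if any(
                    _oracle_pair_linkable(hsps[i], hsps[j], mt_length)
                    for i in groups[gi]
                    for j in groups[gj]
                ):
                    groups[gi] |= groups[gj]
                    del groups[gj]
                    changed = True
                    break
            if changed:
                break
    return {
        frozenset((hsps[i].n_start, hsps[i].n_end) for i in g) for g in groups
    }


def _oracle_block_components(numts, max_gap=2000):
    """Quadratic connected components of the interval-gap graph."""
    def linked(a, b):
        if a.scaffold != b.scaffold:
            return False
        gap = max(a.n_start, b.n_start) - min(a.n_end, b.n_end)
        return gap < max_gap

    groups = [{i} for i in range(len(numts))]
    changed = True
    while changed:
        changed = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                if any(
                    linked(numts[i], numts[j])
                    for i in groups[gi]
                    for j in groups[gj]
                ):
                    groups[gi] |= groups[gj]
                    del groups[gj]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(numts[i].id for i in g) for g in groups}


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilterHsps:
    @pytest.mark.parametrize(
        "e_value,length,kept",
        [(1e-4, 50, True), (1e-2, 500, False), (1e-10, 29, False), (1e-3, 30, True)],
    )
    def test_thresholds(self, e_value, length, kept):
        h = make_hsp(mt_end=length, n_end=1000 + length, e_value=e_value, aln_length=length)
        out = detect.filter_hsps([h])
        assert bool(out) is kept

    def test_order_preserved(self):
        hs = [make_hsp(n_start=i * 1000, n_end=i * 1000 + 100) for i in (3, 1, 2)]
        assert detect.filter_hsps(hs) == hs


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

class TestMergeHsps:
    MT = 16_600

    def test_continuous_pair_merges(self):
        h1 = make_hsp(300, 500, n_start=1000, n_end=1200)
        h2 = make_hsp(501, 696, n_start=1205, n_end=1400)
        (n,) = detect.merge_hsps([h1, h2], self.MT)
        assert (n.n_start, n.n_end) == (1000, 1400)
        assert n.mt_intervals == ((300, 696),)

    def test_wrap_at_linearization_boundary(self):
        h1 = make_hsp(16_500, 16_600, n_start=1000, n_end=1100)
        h2 = make_hsp(0, 197, n_start=1103, n_end=1300)
        (n,) = detect.merge_hsps([h1, h2], self.MT)
        assert n.mt_intervals == ((16_500, 16_600), (0, 197))
        assert (n.n_start, n.n_end) == (1000, 1300)

    def test_nuclear_gap_50_not_merged(self):
        h1 = make_hsp(300, 500, n_start=1000, n_end=1200)
        h2 = make_hsp(501, 696, n_start=1250, n_end=1445)
        assert len(detect.merge_hsps([h1, h2], self.MT)) == 2

    def test_opposite_orientations_not_merged(self):
        h1 = make_hsp(300, 500, n_start=1000, n_end=1200, orientation="+")
        h2 = make_hsp(501, 696, n_start=1205, n_end=1400, orientation="-")
        assert len(detect.merge_hsps([h1, h2], self.MT)) == 2

    def test_minus_strand_continuity(self):
        # mtDNA decreases along the nuclear plus strand for minus hits
        h1 = make_hsp(500, 700, n_start=1000, n_end=1200, orientation="-")
        h2 = make_hsp(300, 498, n_start=1205, n_end=1403, orientation="-")
        (n,) = detect.merge_hsps([h1, h2], self.MT)
        assert n.mt_intervals == ((300, 700),)

    def test_identity_is_length_weighted(self):
        h1 = make_hsp(0, 100, n_start=0, n_end=100, identity=90.0)
        h2 = make_hsp(101, 401, n_start=105, n_end=405, identity=100.0)
        (n,) = detect.merge_hsps([h1, h2], self.MT)
        assert n.identity == pytest.approx((90 * 100 + 100 * 300) / 400)

    def test_matches_bruteforce_oracle_on_random_instances(self, rng):
        for _ in range(200):
            hsps = random_hsps(rng, int(rng.integers(2, 50)))
            got = {
                frozenset((m.n_start, m.n_end) for m in n.members)
                for n in detect.merge_hsps(hsps, self.MT)
            }
            assert got == _oracle_merge_components(hsps, self.MT)

    def test_merge_is_idempotent(self, rng):
        for _ in range(50):
            hsps = random_hsps(rng, 30)
            once = detect.merge_hsps(hsps, self.MT)
            again = detect.merge_hsps(
                [m for n in once for m in n.members], self.MT
            )
            assert [(n.n_start, n.n_end, n.mt_intervals) for n in once] == [
                (n.n_start, n.n_end, n.mt_intervals) for n in again
            ]


# ---------------------------------------------------------------------------
# contig filter and naming
# ---------------------------------------------------------------------------

class TestContigFilter:
    def test_short_contig_removed_and_boundary_kept(self):
        idx = GenomeIndex([("big", 1_000_000), ("edge", 20_000), ("tiny", 15_000)])
        numts = [
            make_numt("x1", scaffold="tiny"),
            make_numt("x2", scaffold="edge"),
            make_numt("x3", scaffold="big"),
        ]
        kept = detect.filter_by_contig_length(numts, idx, species="Hsap")
        assert {n.scaffold for n in kept} == {"big", "edge"}

    def test_unknown_scaffold_errors(self):
        idx = GenomeIndex([("big", 1_000_000)])
        with pytest.raises(KeyError):
            detect.filter_by_contig_length([make_numt(scaffold="nope")], idx)

    def test_renumbering_dense_in_genome_order(self):
        idx = GenomeIndex([("s2", 100_000), ("s1", 100_000)])
        numts = [
            make_numt("a", scaffold="s1", n_start=10, n_end=200),
            make_numt("b", scaffold="s2", n_start=500, n_end=700),
            make_numt("c", scaffold="s2", n_start=10, n_end=200),
        ]
        out = detect.filter_by_contig_length(numts, idx, species="Hsap")
        assert [n.id for n in out] == ["Hsap_numt_1", "Hsap_numt_2", "Hsap_numt_3"]
        # s2 precedes s1 in the genome index
        assert [n.scaffold for n in out] == ["s2", "s2", "s1"]


# ---------------------------------------------------------------------------
# block assembly
# ---------------------------------------------------------------------------

class TestBlocks:
    def test_chaining_three_numts(self):
        numts = [
            make_numt("n1", n_start=0, n_end=100),
            make_numt("n2", n_start=1_100, n_end=1_200),  # gap 1,000
            make_numt("n3", n_start=2_700, n_end=2_800),  # gap 1,500
        ]
        (block,) = detect.assemble_blocks(numts)
        assert len(block.members) == 3
        assert block.is_complex
        assert block.span == (0, 2_800)

    def test_gap_exactly_2000_splits(self):
        numts = [
            make_numt("n1", n_start=0, n_end=100),
            make_numt("n2", n_start=2_100, n_end=2_200),
        ]
        assert len(detect.assemble_blocks(numts)) == 2

    def test_singleton_block(self):
        (b,) = detect.assemble_blocks([make_numt("n1")])
        assert len(b.members) == 1 and not b.is_complex

    def test_blocks_partition_numts(self, rng):
        for _ in range(30):
            numts = []
            cursor = 0
            for k in range(int(rng.integers(1, 40))):
                cursor += int(rng.integers(0, 4_000))
                length = int(rng.integers(50, 500))
                numts.append(
                    make_numt(f"n{k}", n_start=cursor, n_end=cursor + length)
                )
                cursor += length
            blocks = detect.assemble_blocks(numts)
            member_ids = [m.id for b in blocks for m in b.members]
            assert sorted(member_ids) == sorted(n.id for n in numts)
            got = {frozenset(m.id for m in b.members) for b in blocks}
            assert got == _oracle_block_components(numts)


# ---------------------------------------------------------------------------
# tandem duplicates
# ---------------------------------------------------------------------------

class TestTandemDuplicates:
    def test_nearby_similar_pair_found(self):
        a = make_numt("n1", n_start=0, n_end=200, mt_intervals=((100, 300),))
        b = make_numt("n2", n_start=4_200, n_end=4_405, mt_intervals=((105, 310),))
        assert detect.find_tandem_duplicates([a, b]) == {("n1", "n2")}

    def test_distant_pair_not_reported(self):
        a = make_numt("n1", n_start=0, n_end=200, mt_intervals=((100, 300),))
        b = make_numt("n2", n_start=50_000, n_end=50_200, mt_intervals=((100, 300),))
        assert detect.find_tandem_duplicates([a, b]) == set()

    def test_disjoint_footprints_not_reported(self):
        a = make_numt("n1", n_start=0, n_end=200, mt_intervals=((100, 300),))
        b = make_numt("n2", n_start=4_000, n_end=4_200, mt_intervals=((500, 700),))
        assert detect.find_tandem_duplicates([a, b]) == set()


# ---------------------------------------------------------------------------
# summaries and length distributions
# ---------------------------------------------------------------------------

class TestSummary:
    def test_cumulative_and_fraction(self):
        idx = GenomeIndex([("s1", 1_000_000)])
        numts = [
            make_numt("n1", n_start=0, n_end=100),
            make_numt("n2", n_start=5_000, n_end=5_100),
        ]
        s = detect.numt_summary(numts, detect.assemble_blocks(numts), idx)
        assert s.cumulative_length == 200
        assert s.genome_fraction == pytest.approx(2e-4)

    @pytest.mark.parametrize(
        "identities,expected",
        [((97.0, 99.0), 0.5), ((98.0,), 0.0)],  # cut is strictly > 98
    )
    def test_identity_fraction_above_cut(self, identities, expected):
        idx = GenomeIndex([("s1", 1_000_000)])
        numts = [
            make_numt(f"n{i}", n_start=i * 1000, n_end=i * 1000 + 100, identity=v)
            for i, v in enumerate(identities)
        ]
        s = detect.numt_summary(numts, [], idx)
        assert s.fraction_above_cut == pytest.approx(expected)

    def test_empty_set_reports_undefined(self):
        idx = GenomeIndex([("s1", 1_000_000)])
        s = detect.numt_summary([], [], idx)
        assert s.n_numts == 0 and math.isnan(s.mean_identity)


class TestLengthDistributions:
    def test_identical_lists_ks_p_one(self):
        lengths = {"A": [100, 200, 300] * 10, "B": [100, 200, 300] * 10}
        table, _ = detect.compare_length_distributions(lengths, {"A": "o1", "B": "o1"})
        assert table.loc["A", "B"] == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_ranges_ks_p_tiny(self):
        lengths = {"A": [100.0] * 50, "B": [10_000.0] * 50}
        table, _ = detect.compare_length_distributions(lengths, {"A": "o1", "B": "o2"})
        assert table.loc["A", "B"] < 1e-6

    def test_within_order_pvalues_stochastically_greater(self, rng):
        base = rng.lognormal(5, 1, size=60)
        shifted = base * 8
        lengths = {
            "A1": base.tolist(),
            "A2": base.tolist(),
            "B1": shifted.tolist(),
            "B2": shifted.tolist(),
        }
        orders = {"A1": "oA", "A2": "oA", "B1": "oB", "B2": "oB"}
        table, contrast_p = detect.compare_length_distributions(lengths, orders)
        within = [table.loc["A1", "A2"], table.loc["B1", "B2"]]
        across = [
            table.loc[a, b] for a in ("A1", "A2") for b in ("B1", "B2")
        ]
        assert min(within) > max(across)
        assert 0 <= contrast_p <= 1

    def test_species_with_one_numt_excluded(self):
        lengths = {"A": [100, 200, 150], "B": [120, 210, 160], "C": [99]}
        table, _ = detect.compare_length_distributions(
            lengths, {"A": "o", "B": "o", "C": "o"}
        )
        assert "C" not in table.index
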