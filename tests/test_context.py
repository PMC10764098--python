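"""Genomic context: TE flanks, background, correlations, expression, ORFs."""

import itertools
import math

import numpy as np
import pytest

from numtkit import context
from numtkit.core import GeneModel, GenomeIndex, RepeatInterval

from conftest import make_numt


def _idx(length=200_000, name="scaf1"):
    return GenomeIndex([(name, length)])


class TestIntervalCoverage:
    def test_covered_matches_naive_on_random_queries(self, rng):
        intervals = []
        for _ in range(40):
            s = int(rng.integers(0, 9_000))
            intervals.append((s, s + int(rng.integers(1, 500))))
        cov = context.IntervalCoverage(intervals)
        base = np.zeros(12_000, bool)
        for s, e in intervals:
            base[s:e] = True
        for _ in range(200):
            a = int(rng.integers(0, 11_000))
            b = a + int(rng.integers(1, 1_000))
            assert cov.covered(a, b) == int(base[a:b].sum())

    def test_distance_to(self):
        cov = context.IntervalCoverage([(100, 200), (500, 600)])
        assert cov.distance_to(150) == 0
        assert cov.distance_to(210) == 11  # last covered base is 199
        assert cov.distance_to(450) == 50


class TestFlankProfile:
    def test_fully_repeated_flank(self):
        unit = make_numt(n_start=50_000, n_end=50_100)
        reps = [RepeatInterval("scaf1", 0, 200_000)]
        (p,) = context.flank_te_profile([unit], reps, _idx())
        assert (p.up == 1.0).all() and (p.down == 1.0).all()

    def test_half_covered_adjacent_window(self):
        unit = make_numt(n_start=50_000, n_end=50_100)
        # covers the 250 bp adjoining the unit upstream: window 1 = [49500, 50000)
        reps = [RepeatInterval("scaf1", 49_750, 50_000)]
        (p,) = context.flank_te_profile([unit], reps, _idx())
        assert p.up[0] == pytest.approx(0.5)
        assert p.up[1:].sum() == 0 and p.down.sum() == 0

    def test_no_repeats_all_zero(self):
        unit = make_numt(n_start=50_000, n_end=50_100)
        (p,) = context.flank_te_profile([unit], [], _idx())
        assert p.up.sum() == 0 and p.down.sum() == 0

    def test_truncated_windows_flagged(self):
        unit = make_numt(n_start=1_200, n_end=1_300)
        (p,) = context.flank_te_profile([unit], [], _idx())
        assert p.up_truncated[-1] and not p.down_truncated.any()

    def test_invariant_to_splitting_te_intervals(self):
        unit = make_numt(n_start=50_000, n_end=50_100)
        whole = [RepeatInterval("scaf1", 48_000, 49_800)]
        split = [
            RepeatInterval("scaf1", 48_000, 48_900),
            RepeatInterval("scaf1", 48_900, 49_800),
        ]
        (a,) = context.flank_te_profile([unit], whole, _idx())
        (b,) = context.flank_te_profile([unit], split, _idx())
        np.testing.assert_allclose(a.up, b.up)


class TestBackgroundProfile:
    def test_whole_genome_te_background_is_one(self):
        unit = make_numt(n_start=50_000, n_end=50_100)
        reps = [RepeatInterval("scaf1", 0, 200_000)]
        bg = context.background_te_profile([unit], reps, _idx(), n_iter=5, seed=1)
        np.testing.assert_allclose(bg.up_mean, 1.0)
        np.testing.assert_allclose(bg.down_mean, 1.0)

    def test_seeded_determinism(self):
        unit = make_numt(n_start=50_000, n_end=50_100)
        reps = [RepeatInterval("scaf1", 10_000, 60_000)]
        a = context.background_te_profile([unit], reps, _idx(), n_iter=10, seed=5)
        b = context.background_te_profile([unit], reps, _idx(), n_iter=10, seed=5)
        np.testing.assert_array_equal(a.up_mean, b.up_mean)

    def test_unplaceable_unit_raises(self):
        unit = make_numt(n_start=2_000, n_end=2_100)
        with pytest.raises(ValueError, match="placed"):
            context.background_te_profile([unit], [], _idx(length=9_000), n_iter=2, seed=0)

    def test_te_free_first_window_detected_across_species(self):
        # TE everywhere except the 500 bp adjoining each unit: window 1
        # observed << background, later windows comparable
        observed, background = {}, {}
        for i, sp in enumerate("ABCDEF"):
            unit = make_numt(n_start=50_000 + i * 1_000, n_end=50_100 + i * 1_000)
            reps = [
                RepeatInterval("scaf1", 0, unit.n_start - 500),
                RepeatInterval("scaf1", unit.n_end + 500, 200_000),
            ]
            profs = context.flank_te_profile([unit], reps, _idx())
            observed[sp] = context.mean_flank_profile(profs)
            background[sp] = context.background_te_profile(
                [unit], reps, _idx(), n_iter=20, seed=i
            )
        pvals = context.compare_flank_profiles(observed, background)
        assert pvals["up"][0] < 0.05
        assert pvals["down"][0] < 0.05


class TestTeDistanceCorrelation:
    def test_perfect_negative_monotone(self):
        numts, reps = [], [RepeatInterval("scaf1", 0, 1_000)]
        for k in range(10):
            start = 2_000 + k * 3_000
            numts.append(
                make_numt(
                    f"n{k}", n_start=start, n_end=start + 100, identity=99.0 - k
                )
            )
        rec = context.te_distance_identity_correlation(numts, reps)
        assert rec.rho == pytest.approx(-1.0)

    def test_numt_inside_te_distance_zero(self):
        reps = [RepeatInterval("scaf1", 0, 10_000)]
        cov = context.IntervalCoverage([(0, 10_000)])
        assert cov.distance_to(5_000) == 0

    def test_random_permutation_null(self, rng):
        reps = [RepeatInterval("scaf1", 0, 500)]
        starts = rng.permutation(100) * 2_000 + 1_000
        numts = [
            make_numt(f"n{k}", n_start=int(s), n_end=int(s) + 50,
                      identity=float(rng.uniform(70, 100)))
            for k, s in enumerate(starts)
        ]
        rec = context.te_distance_identity_correlation(numts, reps)
        assert abs(rec.rho) < 0.25 and rec.pvalue > 0.05

    def test_too_few_numts_rejected(self):
        with pytest.raises(ValueError, match=">=5"):
            context.te_distance_identity_correlation(
                [make_numt()], [RepeatInterval("scaf1", 0, 10)]
            )


class TestGenicContext:
    GENES = [GeneModel("G1", "scaf1", 50, 500), GeneModel("G2", "scaf1", 5_000, 6_000)]

    @pytest.mark.parametrize(
        "start,end,label",
        [
            (100, 200, "intronic"),  # inside a gene
            (1_000, 1_100, "intergenic"),  # between genes
            (450, 600, "intronic"),  # straddles a gene boundary: any overlap
        ],
    )
    def test_overlap_rule(self, start, end, label):
        unit = make_numt("u", n_start=start, n_end=end)
        labels, _ = context.classify_genic_context([unit], self.GENES)
        assert labels["u"] == label

    def test_partition_and_ratio(self):
        units = [
            make_numt("a", n_start=100, n_end=200),
            make_numt("b", n_start=1_000, n_end=1_100),
            make_numt("c", n_start=2_000, n_end=2_100),
            make_numt("d", n_start=3_000, n_end=3_100),
        ]
        labels, ratio = context.classify_genic_context(units, self.GENES)
        assert len(labels) == 4
        assert ratio == pytest.approx(3.0)


class TestExpression:
    def _ev(self, j5, j3, cov):
        return context.ExpressionEvidence("u", "brain", j5, j3, cov)

    @pytest.mark.parametrize(
        "j5,j3,cov,expected",
        [
            (2, 2, 0.71, True),
            (2, 1, 0.99, False),  # one junction side fails
            (2, 2, 0.70, False),  # coverage strictly > 70%
            (5, 3, 0.90, True),
        ],
    )
    def test_call_expressed(self, j5, j3, cov, expected):
        assert context.call_expressed(self._ev(j5, j3, cov)) is expected

    def test_enrichment_test_detects_association(self):
        expressed, labels = {}, {}
        for k in range(40):
            uid = f"u{k}"
            labels[uid] = "intronic" if k < 20 else "intergenic"
            expressed[uid] = k < 18 or k == 39
        p = context.enrichment_test(expressed, labels)
        assert p < 0.001


class TestOrfClassification:
    MT_GENES = [GeneModel("TOY", "MT", 9, 21, "+")]

    def test_partial_gene_incomplete(self):
        numt = make_numt(mt_intervals=((0, 15),))
        classes = context.classify_orf(numt, "A" * 15, self.MT_GENES)
        assert classes["TOY"] == context.ORF_INCOMPLETE

    def test_tga_codon_full_with_stops_under_nuclear_code(self):
        # gene copy ATG TGA CCC TAA: Trp in the mitochondrial code but a
        # stop under the standard code
        seq = "AAAGCATGA" + "ATGTGACCCTAA" + "GGCCA"
        numt = make_numt(mt_intervals=((0, len(seq)),))
        classes = context.classify_orf(numt, seq, self.MT_GENES)
        assert classes["TOY"] == context.ORF_FULL_WITH_STOPS

    def test_clean_gene_intact(self):
        seq = "AAAGCATGA" + "ATGTTACCCTAA" + "GGCCA"
        numt = make_numt(mt_intervals=((0, len(seq)),))
        classes = context.classify_orf(numt, seq, self.MT_GENES)
        assert classes["TOY"] == context.ORF_INTACT

    def test_minus_orientation_copy_reverse_complemented(self):
        from Bio.Seq import Seq

        seq = "AAAGCATGA" + "ATGTTACCCTAA" + "GGCCA"
        rc = str(Seq(seq).reverse_complement())
        numt = make_numt(orientation="-", mt_intervals=((0, len(seq)),))
        classes = context.classify_orf(numt, rc, self.MT_GENES)
        assert classes["TOY"] == context.ORF_INTACT

    def test_summary_prefers_intact(self):
        assert (
            context.summarize_orf_class({"A": context.ORF_INTACT, "B": context.ORF_FULL_WITH_STOPS})
            == context.ORF_INTACT
        )
        assert context.summarize_orf_class({}) == context.ORF_INCOMPLETE

    def test_code_tables_differ_exactly_at_four_codons(self):
        differing = set()
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            nuc, mito = context.translate_both_codes(codon)
            if nuc != mito:
                differing.add(codon)
        assert differing == {"TGA", "AGA", "AGG", "ATA"}
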