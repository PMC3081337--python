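import numpy as np
import pytest
from scipy import stats as sps

from seqspace.msa import Alignment, HelixSpan, build_numbering
from seqspace.seqstats import (
    GroupPartition,
    PatternSpec,
    UndefinedStatError,
    chi2_independence,
    entropy_difference,
    frequency_band,
    frequency_correlation,
    pattern_census,
    pattern_flags,
    position_zscores,
)


def one_column_alignment(group_residues, complement_residues):
    rows = tuple(group_residues) + tuple(complement_residues)
    ids = tuple(f"s{i}" for i in range(len(rows)))
    assignment = {
        i: ("g" if k < len(group_residues) else "c") for k, i in enumerate(ids)
    }
    return Alignment(ids, rows), GroupPartition(assignment, "g")


class TestFrequencyCorrelation:
    @pytest.mark.parametrize("ng, nc", [(10, 20), (3, 3), (1, 50), (25, 7)])
    def test_fully_determining_column_gives_one(self, ng, nc):
        aln, part = one_column_alignment("A" * ng, "L" * nc)
        assert frequency_correlation(aln, part, 0) == pytest.approx(1.0)

    def test_identical_distributions_give_zero(self):
        aln, part = one_column_alignment("AAAAALLLLL", "AAAAAAAAAALLLLLLLLLL")
        assert frequency_correlation(aln, part, 0) == pytest.approx(0.0, abs=1e-15)

    def test_equals_chi2_over_n(self):
        aln, part = one_column_alignment("AAL", "ALL")
        fc = frequency_correlation(aln, part, 0)
        table = np.array([[2, 1], [1, 2]])  # group x residue counts
        chi2 = sps.chi2_contingency(table, correction=False)[0]
        assert fc == pytest.approx(chi2 / table.sum(), rel=1e-12)

    def test_chi2_equivalence_on_random_columns(self):
        # FC(l) must equal phi^2 = chi^2/N for arbitrary multi-residue columns
        rng = np.random.default_rng(0)
        residues = np.array(list("ACDEFG"))
        for _ in range(200):
            ng, nc = rng.integers(3, 15, size=2)
            col_g = rng.choice(residues[: rng.integers(2, 6)], size=ng)
            col_c = rng.choice(residues[: rng.integers(2, 6)], size=nc)
            aln, part = one_column_alignment(col_g, col_c)
            fc = frequency_correlation(aln, part, 0)
            seen = sorted(set(col_g) | set(col_c))
            table = np.array(
                [
                    [np.sum(col_g == r) for r in seen],
                    [np.sum(col_c == r) for r in seen],
                ]
            )
            keep = table.sum(axis=0) > 0
            table = table[:, keep]
            if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
                assert fc == pytest.approx(0.0, abs=1e-12)
                continue
            chi2 = sps.chi2_contingency(table, correction=False)[0]
            assert fc == pytest.approx(chi2 / table.sum(), rel=1e-10, abs=1e-12)

    def test_swap_invariance(self):
        aln, part = one_column_alignment("AALL", "ALLLAA")
        swapped = GroupPartition(part.assignment, "c")
        assert frequency_correlation(aln, part, 0) == pytest.approx(
            frequency_correlation(aln, swapped, 0)
        )

    def test_gapped_group_is_flagged(self):
        aln, part = one_column_alignment("--", "AL")
        with pytest.raises(UndefinedStatError):
            frequency_correlation(aln, part, 0)


class TestEntropyDifference:
    def test_conserved_vs_uniform_closed_form(self):
        aln, part = one_column_alignment("AAAA", "ACDE")
        ds = entropy_difference(aln, part, 0)
        assert ds == pytest.approx(-np.log(4))

    def test_identical_distributions_give_zero(self):
        aln, part = one_column_alignment("AL", "ALAL")
        assert entropy_difference(aln, part, 0) == pytest.approx(0.0)

    def test_antisymmetric_under_group_swap(self):
        aln, part = one_column_alignment("AAAL", "ACDELL")
        swapped = GroupPartition(part.assignment, "c")
        assert entropy_difference(aln, part, 0) == pytest.approx(
            -entropy_difference(aln, swapped, 0)
        )


class TestZScores:
    def make_alignment(self, seed=0, n=24, L=30, planted=None):
        rng = np.random.default_rng(seed)
        arr = rng.choice(list("ACDEFGHIKL"), size=(n, L))
        ids = tuple(f"s{i}" for i in range(n))
        assignment = {i: ("g" if k < n // 3 else "c") for k, i in enumerate(ids)}
        if planted is not None:
            arr[: n // 3, planted] = "W"
            arr[n // 3 :, planted] = "Y"
        aln = Alignment(ids, tuple("".join(r) for r in arr))
        return aln, GroupPartition(assignment, "g")

    def test_standardization_identity(self):
        aln, part = self.make_alignment(seed=1)
        stats = position_zscores(aln, part)
        z = stats.table["Z_FC"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_constant_statistic_is_an_error(self):
        aln, part = one_column_alignment("AA", "LL")
        aln = Alignment(aln.ids, tuple(r * 3 for r in aln.rows))
        with pytest.raises(ValueError, match="constant"):
            position_zscores(aln, part)

    def test_significance_threshold_matches_normal_quantile(self):
        # the 99% two-sided critical value of the standard normal is 2.58
        assert sps.norm.ppf(1 - 0.01 / 2) == pytest.approx(2.58, abs=0.005)

    def test_planted_marker_attains_max_z(self):
        aln, part = self.make_alignment(seed=2, planted=7)
        stats = position_zscores(aln, part)
        assert stats.table["Z_FC"].idxmax() == 7
        assert stats.table.loc[7, "significant"]


class TestPatternCensus:
    def motif_alignment(self):
        # columns 0-3 labeled 2.58-2.61 via an anchor at 2.50 out of span;
        # use anchor at column 0 with offset so labels start at 2.58
        rows = (
            "PAAA",
            "PAAA",
            "APAA",
            "AAAA",
            "AAAP",
            "AAAA",
        )
        ids = tuple(f"s{i}" for i in range(6))
        aln = Alignment(ids, rows)
        nm = build_numbering(aln, [HelixSpan(2, 0, 0, 3)])
        # relabel: anchor at col0 -> 2.50; cols are 2.50..2.53
        return aln, nm

    def test_fraction_and_bands(self):
        aln, nm = self.motif_alignment()
        assignment = {f"s{i}": ("G1" if i < 3 else "G2") for i in range(6)}
        pat = PatternSpec.residue_at_any("P_any", "P", ["2.50", "2.51", "2.52"])
        tab = pattern_census(aln, nm, assignment, [pat])
        assert tab.loc["G1", "P_any"] == pytest.approx(1.0)
        assert tab.loc["G2", "P_any"] == pytest.approx(0.0)
        banded = pattern_census(aln, nm, assignment, [pat], banded=True)
        assert banded.loc["G1", "P_any"] == "+++"
        assert banded.loc["G2", "P_any"] == "-"

    @pytest.mark.parametrize(
        "fraction, band",
        [(0.0, "-"), (0.3, "+"), (0.5, "+"), (0.6, "++"), (0.79, "++"), (0.8, "+++"), (1.0, "+++")],
    )
    def test_band_edges(self, fraction, band):
        assert frequency_band(fraction) == band

    def test_motif_with_wildcard(self):
        rows = ("WAFG", "WCFG", "WAFA", "AAFG")
        aln = Alignment(("a", "b", "c", "d"), rows)
        nm = build_numbering(aln, [HelixSpan(3, 0, 0, 3)])
        pat = PatternSpec.motif("WXFG", "WXFG", ["3.50", "3.51", "3.52", "3.53"])
        flags = pattern_flags(aln, nm, pat)
        np.testing.assert_array_equal(flags, [True, True, False, False])

    def test_unlabeled_position_rejected(self):
        aln, nm = self.motif_alignment()
        pat = PatternSpec.residue_at_any("bad", "P", ["5.50"])
        with pytest.raises(KeyError, match="5.50"):
            pattern_flags(aln, nm, pat)


class TestChi2Independence:
    def test_perfect_association(self):
        flags = np.array([True] * 10 + [False] * 10)
        chi2, p = chi2_independence(flags, flags)
        assert chi2 == pytest.approx(20.0)
        assert p < 1e-4

    def test_contingency_hand_formula(self):
        # table [[30,10],[10,30]]: chi2 = sum (O-E)^2/E with margins 40/40
        a = np.array([True] * 40 + [False] * 40)
        b = np.array([True] * 30 + [False] * 10 + [True] * 10 + [False] * 30)
        chi2, _ = chi2_independence(a, b)
        expected = 0.0
        obs = np.array([[30, 10], [10, 30]])
        for i in range(2):
            for j in range(2):
                e = obs.sum(axis=1)[i] * obs.sum(axis=0)[j] / obs.sum()
                expected += (obs[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(expected)

    def test_independent_flags_give_small_statistic(self):
        rng = np.random.default_rng(10)
        a = rng.random(400) < 0.5
        b = rng.random(400) < 0.5
        chi2, p = chi2_independence(a, b)
        assert p > 0.01

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi2_independence(np.array([True, True]), np.array([True, False]))
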