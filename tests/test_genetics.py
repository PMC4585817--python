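"""Stratification, allelic testing, windowing, replication and propensity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from admeta.genetics import (
    CANONICAL_STRATA,
    GeneRegion,
    GenotypeStudy,
    StratumSpec,
    allelic_test,
    genotype_propensity,
    propensity,
    region_scan,
    replication_filter,
    stratify,
    window_select,
)


def _study(genders, apoe4s, statuses, genotypes=None, positions=None):
    n = len(genders)
    ids = pd.Index([f"sub{i}" for i in range(n)], name="subject_id")
    subjects = pd.DataFrame(
        {"status": statuses, "gender": genders, "apoe4": apoe4s}, index=ids
    )
    if genotypes is None:
        genotypes = np.zeros((1, n))
    genotypes = np.atleast_2d(np.asarray(genotypes, dtype=float))
    m = genotypes.shape[0]
    positions = positions if positions is not None else list(range(100, 100 + m))
    snps = pd.DataFrame(
        {"chrom": "chr1", "pos": positions, "ref": "A", "alt": "G"},
        index=pd.Index([f"rs{i}" for i in range(m)], name="snp_id"),
    )
    return GenotypeStudy(
        name="t", subjects=subjects, snps=snps,
        genotypes=pd.DataFrame(genotypes, index=snps.index, columns=ids),
    )


class TestStratify:
    def test_filters_to_requested_subset(self):
        st_ = _study(["F", "F", "M"], ["carrier", "non-carrier", "carrier"],
                     ["case", "case", "control"])
        sub = stratify(st_, StratumSpec(gender="F", apoe4="carrier"))
        assert list(sub.subjects.index) == ["sub0"]
        assert list(sub.genotypes.columns) == ["sub0"]

    def test_any_any_is_identity(self):
        st_ = _study(["F", "M"], ["carrier", "non-carrier"], ["case", "control"])
        sub = stratify(st_, StratumSpec())
        pd.testing.assert_frame_equal(sub.subjects, st_.subjects)

    def test_four_joint_strata_partition_cohort(self):
        rng = np.random.default_rng(3)
        n = 40
        st_ = _study(
            rng.choice(["M", "F"], n), rng.choice(["carrier", "non-carrier"], n),
            rng.choice(["case", "control"], n),
        )
        joint = [s for s in CANONICAL_STRATA if s.gender != "any" and s.apoe4 != "any"]
        parts = [set(stratify(st_, s).subjects.index) for s in joint]
        assert set().union(*parts) == set(st_.subjects.index)
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                assert not parts[i] & parts[j]


class TestAllelicTest:
    def test_identical_allele_distributions(self):
        # 10 cases and 10 controls, all heterozygous: alt 10 / ref 10 in each
        g = np.ones(20)
        row = allelic_test(g, [True] * 10 + [False] * 10)
        assert row.chi2 == 0.0 and row.p == 1.0

    def test_known_table_chi2_twenty(self):
        # allele table [[30,10],[10,30]]: cases 15 hom-alt + ..., use 20+20 subjects
        g = np.array([2] * 15 + [0] * 5 + [2] * 5 + [0] * 15, dtype=float)
        status = [True] * 20 + [False] * 20
        row = allelic_test(g, status)
        assert (row.case_alt, row.case_ref, row.control_alt, row.control_ref) == (30, 10, 10, 30)
        assert row.chi2 == pytest.approx(20.0, abs=1e-12)
        assert row.p == pytest.approx(float(stats.chi2.sf(20.0, 1)), rel=1e-12)

    def test_missing_genotype_excluded(self):
        g = np.array([2.0, np.nan, 0.0, 0.0])
        row = allelic_test(g, [True, True, False, False])
        assert row.case_alt + row.case_ref == 2  # one case dropped

    def test_monomorphic_returns_p_one(self):
        row = allelic_test(np.zeros(10), [True] * 5 + [False] * 5)
        assert row.p == 1.0 and np.isnan(row.odds_ratio)

    def test_zero_cell_pseudocount_odds(self):
        g = np.array([2, 2, 0, 0], dtype=float)
        row = allelic_test(g, [True, True, False, False])
        # cells 4,0,0,4 -> +0.5 each
        assert row.odds_ratio == pytest.approx((4.5 * 4.5) / (0.5 * 0.5))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=60), min_size=4, max_size=4))
    def test_chi2_matches_textbook_formula(self, cells):
        from admeta.genetics import _chi2_2x2

        a, b, c, d = cells
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert _chi2_2x2(a, b, c, d) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_fisher_in_significant_tail(self):
        """Chi-square and Fisher p agree closely where it decides significance.

        Away from the tail the exact test's discreteness leaves gaps of a few
        percent even with large cells, so the comparison is restricted to
        p < 0.05 with all cells >= 20.
        """
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(60):
            n1, n2 = 150, 150
            g_case = rng.binomial(2, 0.45, n1).astype(float)
            g_ctrl = rng.binomial(2, 0.33, n2).astype(float)
            g = np.concatenate([g_case, g_ctrl])
            status = [True] * n1 + [False] * n2
            chi = allelic_test(g, status)
            fis = allelic_test(g, status, fisher=True)
            cell_min = min(chi.case_alt, chi.case_ref, chi.control_alt, chi.control_ref)
            if cell_min >= 20 and chi.p < 0.05:
                assert abs(chi.p - fis.p) < 0.01
                checked += 1
        assert checked >= 20


class TestWindowSelect:
    region = GeneRegion(gene="G", chrom="chr1", start=1000, end=2000, window=200)

    def _snps(self, positions, chrom="chr1"):
        return pd.DataFrame(
            {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"},
            index=pd.Index([f"rs{i}" for i in range(len(positions))]),
        )

    def test_boundaries_inclusive(self):
        snps = self._snps([799, 800, 2200, 2201])
        assert list(window_select(self.region, snps)) == ["rs1", "rs2"]

    def test_zero_window_is_gene_body(self):
        region = GeneRegion(gene="G", chrom="chr1", start=1000, end=2000, window=0)
        snps = self._snps([999, 1000, 1500, 2000, 2001])
        assert list(window_select(region, snps)) == ["rs1", "rs2", "rs3"]

    def test_other_chromosome_excluded(self):
        snps = self._snps([1500], chrom="chr2")
        assert len(window_select(self.region, snps)) == 0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=5000), min_size=1, max_size=30))
    def test_matches_brute_force(self, positions):
        snps = self._snps(sorted(positions))
        got = set(window_select(self.region, snps))
        expected = {
            f"rs{i}" for i, p in enumerate(sorted(positions)) if 800 <= p <= 2200
        }
        assert got == expected


class TestRegionScan:
    def test_no_windowed_snps_marks_untested(self):
        st_ = _study(["F", "F", "M", "M"], ["carrier"] * 4,
                     ["case", "control", "case", "control"],
                     genotypes=[[0, 1, 2, 1]], positions=[10_000_000])
        region = GeneRegion(gene="G", chrom="chr1", start=1000, end=2000)
        rows, best = region_scan(st_, [region], strata=(StratumSpec(),))
        assert rows.empty
        assert not best["tested"].iloc[0] and np.isnan(best["best_p"].iloc[0])

    def test_degenerate_threshold_flags_everything(self):
        rng = np.random.default_rng(0)
        st_ = _study(["F"] * 20 + ["M"] * 20, ["carrier"] * 40,
                     ["case", "control"] * 20,
                     genotypes=rng.binomial(2, 0.3, size=(3, 40)),
                     positions=[1200, 1500, 1900])
        region = GeneRegion(gene="G", chrom="chr1", start=1000, end=2000)
        rows, _ = region_scan(st_, [region], strata=(StratumSpec(),), p_threshold=1.0)
        assert rows["significant"].all()

    def test_empty_stratum_untested(self):
        st_ = _study(["M", "M"], ["carrier"] * 2, ["case", "control"],
                     genotypes=[[1, 0]], positions=[1500])
        region = GeneRegion(gene="G", chrom="chr1", start=1000, end=2000)
        _, best = region_scan(st_, [region], strata=(StratumSpec(gender="F"),))
        assert not best["tested"].iloc[0]


class TestReplication:
    def _best(self, p):
        return pd.DataFrame(
            {"gene": ["G"], "stratum": ["all/all"], "best_p": [p], "n_snps": [1],
             "tested": [True]}
        )

    def test_two_of_three_flags(self):
        rep = replication_filter(
            {"a": self._best(1e-5), "b": self._best(1e-5), "c": self._best(0.5)}
        )
        assert rep["flagged"].iloc[0] and rep["n_significant_studies"].iloc[0] == 2

    def test_one_study_not_flagged(self):
        rep = replication_filter(
            {"a": self._best(1e-5), "b": self._best(0.5), "c": self._best(0.5)}
        )
        assert not rep["flagged"].iloc[0]

    def test_min_studies_three(self):
        rep = replication_filter(
            {"a": self._best(1e-5), "b": self._best(1e-5), "c": self._best(0.5)},
            min_studies=3,
        )
        assert not rep["flagged"].iloc[0]

    def test_untested_stratum_counts_as_not_significant(self):
        rep = replication_filter(
            {"a": self._best(np.nan), "b": self._best(1e-5), "c": self._best(1e-5)}
        )
        assert rep["n_significant_studies"].iloc[0] == 2


class TestPropensity:
    def test_equal_fractions_give_zero(self):
        out = propensity([30, 40, 30], [60, 80, 60])
        np.testing.assert_allclose(out["propensity"], 0.0, atol=1e-12)

    def test_three_fold_enrichment(self):
        # class fraction 30% in cases vs 10% in controls -> log2(3)
        out = propensity([30, 50, 20], [10, 70, 20])
        assert out["propensity"].iloc[0] == pytest.approx(np.log2(3.0), abs=1e-12)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            case = rng.integers(0, 50, size=3)
            ctrl = rng.integers(0, 50, size=3)
            if case.sum() == 0 or ctrl.sum() == 0:
                continue
            fwd = propensity(case, ctrl)["propensity"].to_numpy()
            rev = propensity(ctrl, case)["propensity"].to_numpy()
            np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_class_absent_in_both_groups_is_nan(self):
        out = propensity([10, 20, 0], [15, 12, 0])
        assert np.isnan(out["propensity"].iloc[2])

    def test_linear_scale_flag(self):
        out = propensity([30, 50, 20], [10, 70, 20], log_scale=False)
        assert out["propensity"].iloc[0] == pytest.approx(3.0)

    def test_from_genotype_vector(self):
        g = np.array([0, 0, 1, 1, 2, 0, 1, 2, np.nan])
        out = genotype_propensity(g, [True] * 5 + [False] * 4)
        assert out["case_count"].tolist() == [2, 2, 1]
        assert out["control_count"].tolist() == [1, 1, 1]
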