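"""Differential expression, QC rules, P/A filtering, intersection, balance test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admeta.expression import (
    Contrast,
    ContrastError,
    DEResult,
    build_extreme_contrast,
    gender_balance_test,
    intersect_and_confirm,
    map_to_genes,
    presence_filter,
    run_de,
    select_compartment,
)


def _mk_de(raw_p, probes=None, log_fc=None, alpha=0.05):
    """Assemble a DEResult directly for rule-level tests."""
    from admeta.scan import bh_adjust

    raw_p = np.asarray(raw_p, dtype=float)
    probes = probes or [f"ps{i}" for i in range(len(raw_p))]
    log_fc = np.asarray(log_fc if log_fc is not None else -np.ones(len(raw_p)))
    adj = bh_adjust(raw_p)
    table = pd.DataFrame(
        {
            "log_fc": log_fc,
            "stat": np.zeros(len(raw_p)),
            "p_value": raw_p,
            "adj_p": adj,
            "direction": np.where(log_fc < 0, "down", np.where(log_fc > 0, "up", "none")),
            "significant": adj < alpha,
        },
        index=pd.Index(probes, name="probeset"),
    )
    return DEResult(table=table, alpha=alpha, n_case=5, n_control=5)


class TestRunDE:
    def test_constant_matrix_all_p_one(self, two_group_study):
        study, contrast = two_group_study
        study.matrix.loc[:, :] = 3.14
        de = run_de(study, contrast)
        assert (de.table["p_value"] == 1.0).all()
        assert not de.table["significant"].any()

    def test_planted_probeset_recovered(self, two_group_study):
        study, contrast = two_group_study
        de = run_de(study, contrast)
        row = de.table.loc["ps000"]
        assert row["significant"]
        assert row["direction"] == "down"
        assert row["log_fc"] == pytest.approx(-4.0, abs=0.5)

    def test_matches_per_row_welch_oracle(self, two_group_study):
        study, contrast = two_group_study
        de = run_de(study, contrast)
        case = study.matrix[list(contrast.case_ids)]
        ctrl = study.matrix[list(contrast.control_ids)]
        for probe in ["ps000", "ps007", "ps031"]:
            t, p = stats.ttest_ind(case.loc[probe], ctrl.loc[probe], equal_var=False)
            assert de.table.at[probe, "stat"] == pytest.approx(t, rel=1e-10)
            assert de.table.at[probe, "p_value"] == pytest.approx(p, rel=1e-10)

    def test_direction_follows_sign(self, two_group_study):
        study, contrast = two_group_study
        de = run_de(study, contrast)
        down = de.table["log_fc"] < 0
        assert (de.table.loc[down, "direction"] == "down").all()
        assert (de.table.loc[~down & (de.table["log_fc"] > 0), "direction"] == "up").all()

    def test_small_group_rejected(self, two_group_study):
        study, _ = two_group_study
        with pytest.raises(ContrastError):
            run_de(study, Contrast(case_ids=("case0",), control_ids=("ctrl0", "ctrl1")))

    def test_moderated_mode_shrinks_variance_outliers(self, two_group_study):
        """A near-zero-variance null probeset must not explode under moderation."""
        study, contrast = two_group_study
        study.matrix.loc["ps049"] = 5.0
        study.matrix.loc["ps049", "case0"] = 5.0001  # tiny sd, tiny mean diff
        welch = run_de(study, contrast, moderated=False)
        mod = run_de(study, contrast, moderated=True)
        assert mod.table.at["ps049", "p_value"] > welch.table.at["ps049", "p_value"]
        assert not mod.table.at["ps049", "significant"]
        # the genuinely shifted probeset stays highly significant
        assert mod.table.at["ps000", "significant"]


class TestExtremeContrast:
    def test_top_and_bottom_ranks(self):
        scores = pd.Series(range(1, 21), index=[f"s{i:02d}" for i in range(20)])
        c = build_extreme_contrast(scores, n=9)
        assert set(c.control_ids) == {f"s{i:02d}" for i in range(9)}
        assert set(c.case_ids) == {f"s{i:02d}" for i in range(11, 20)}

    def test_exactly_two_n_uses_everyone(self):
        scores = pd.Series(range(18), index=[f"s{i:02d}" for i in range(18)])
        c = build_extreme_contrast(scores, n=9)
        assert len(set(c.case_ids) | set(c.control_ids)) == 18

    def test_boundary_tie_lower_id_wins(self):
        scores = pd.Series([1, 2, 2, 3], index=["a", "b", "c", "d"])
        c = build_extreme_contrast(scores, n=2)
        assert set(c.control_ids) == {"a", "b"}  # b beats c at the tie
        assert set(c.case_ids) == {"d", "c"}

    def test_missing_scores_ignored(self):
        scores = pd.Series([1.0, np.nan, 2.0, 3.0, 4.0], index=list("abcde"))
        c = build_extreme_contrast(scores, n=2)
        assert "b" not in set(c.case_ids) | set(c.control_ids)
        with pytest.raises(ContrastError):
            build_extreme_contrast(scores, n=3)


class TestSelectCompartment:
    is_ctrl = staticmethod(lambda p: p.startswith("AFFX-"))

    def test_max_significant_wins(self):
        de = {
            "hippocampus": _mk_de([1e-4] * 120 + [0.9] * 80),
            "cortex": _mk_de([1e-4] * 80 + [0.9] * 120),
        }
        label, report = select_compartment(de, self.is_ctrl)
        assert label == "hippocampus"
        assert report["selected"] == "hippocampus"

    def test_control_probe_in_top_ten_discards(self):
        probes_a = ["AFFX-x" if i == 2 else f"a{i}" for i in range(300)]
        de = {
            "A": _mk_de(np.linspace(1e-6, 0.04, 300), probes=probes_a),  # ctrl at p-rank 3
            "B": _mk_de([1e-4] * 50 + [0.9] * 250),
        }
        label, report = select_compartment(de, self.is_ctrl)
        assert label == "B"
        assert report["compartments"]["A"]["discarded"]

    def test_control_fraction_above_quarter_percent_discards(self):
        # 1000 significant, 3 of them controls (0.3% > 0.25%), none in top ten
        probes = [f"a{i}" for i in range(1000)]
        for i in (500, 600, 700):
            probes[i] = f"AFFX-{i}"
        de = {"A": _mk_de(np.linspace(1e-4, 0.01, 1000), probes=probes)}
        label, report = select_compartment(de, self.is_ctrl)
        assert label is None
        assert report["compartments"]["A"]["discarded"]

    def test_excluded_compartment_never_chosen(self):
        de = {"visual_cortex": _mk_de([1e-4] * 50), "cortex": _mk_de([1e-4] * 10 + [0.9] * 40)}
        label, _ = select_compartment(de, self.is_ctrl, exclude={"visual_cortex"})
        assert label == "cortex"

    def test_tie_breaks_lexicographically(self):
        de = {"b": _mk_de([1e-4] * 10), "a": _mk_de([1e-4] * 10)}
        label, _ = select_compartment(de, self.is_ctrl)
        assert label == "a"


class TestPresenceFilter:
    def _pa(self, code, probes, samples):
        return pd.DataFrame(code, index=pd.Index(probes), columns=samples)

    def _setup(self, control_code):
        de = _mk_de([1e-4, 0.9], probes=["p1", "p2"])
        contrast = Contrast(case_ids=("c1", "c2"), control_ids=("h1", "h2"))
        pa = pd.DataFrame(
            {"c1": ["A", "P"], "c2": ["A", "P"],
             "h1": [control_code, "P"], "h2": [control_code, "P"]},
            index=["p1", "p2"],
        )
        return de, pa, contrast

    def test_present_in_high_group_kept(self):
        de, pa, contrast = self._setup("P")
        out = presence_filter(de, pa, contrast)
        assert out.table.at["p1", "significant"]

    def test_absent_in_high_group_removed(self):
        de, pa, contrast = self._setup("A")
        out = presence_filter(de, pa, contrast)
        assert not out.table.at["p1", "significant"]

    def test_exactly_marginal_is_kept(self):
        de, pa, contrast = self._setup("M")  # mean code exactly 1.0
        out = presence_filter(de, pa, contrast)
        assert out.table.at["p1", "significant"]

    def test_no_calls_passes_through(self):
        de, _, contrast = self._setup("P")
        out = presence_filter(de, None, contrast)
        pd.testing.assert_frame_equal(out.table, de.table)

    def test_monotone_in_calls(self):
        """Raising every call can only keep more probesets."""
        de, pa, contrast = self._setup("A")
        kept_low = presence_filter(de, pa, contrast).table["significant"]
        raised = pa.replace({"A": "M", "M": "P"})
        kept_high = presence_filter(de, raised, contrast).table["significant"]
        assert (kept_high | ~kept_low).all()


class TestGeneMapping:
    def test_any_probeset_rule(self):
        de = _mk_de([1e-4, 0.9], probes=["p1", "p2"])
        sets = map_to_genes(de, pd.Series({"p1": "G1", "p2": "G1"}))
        assert sets.down == {"G1"}

    def test_conflicting_directions_flagged(self):
        de = _mk_de([1e-4, 1e-4], probes=["p1", "p2"], log_fc=[-1.0, 1.0])
        sets = map_to_genes(de, pd.Series({"p1": "G1", "p2": "G1"}))
        assert sets.down == {"G1"} and sets.up == {"G1"}
        assert sets.ambiguous == {"G1"}

    def test_empty_significance_gives_empty_sets(self):
        de = _mk_de([0.9, 0.8])
        sets = map_to_genes(de, pd.Series({"ps0": "G1", "ps1": "G2"}))
        assert sets.down == set() and sets.up == set()

    def test_unmapped_probesets_counted(self):
        de = _mk_de([1e-4, 1e-4], probes=["p1", "p2"])
        sets = map_to_genes(de, pd.Series({"p1": "G1"}))
        assert sets.n_unmapped == 1


class TestIntersection:
    def test_set_algebra(self):
        lists = [{"A", "B", "C"}, {"B", "C", "D"}, {"C", "B"}]
        inter, confirmed = intersect_and_confirm(lists, holdout=None)
        assert inter == {"B", "C"} == confirmed

    def test_holdout_confirmation(self):
        lists = [{"A", "B", "C"}, {"A", "B", "C"}, {"A", "B", "D"}]
        inter, confirmed = intersect_and_confirm(lists, holdout=2)
        assert inter == {"A", "B", "C"}
        assert confirmed == {"A", "B"}

    def test_disjoint_lists_empty(self):
        inter, confirmed = intersect_and_confirm([{"A"}, {"B"}, {"C"}], holdout=2)
        assert inter == set() == confirmed


def _fisher_two_sided_oracle(table):
    """Enumerate all tables with the observed margins; sum P <= P(observed)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestGenderBalance:
    def test_perfect_balance(self):
        assert gender_balance_test([[10, 10], [10, 10]]) == 1.0

    def test_matches_enumeration_oracle(self):
        for table in [[[2, 8], [8, 2]], [[5, 1], [2, 7]], [[12, 3], [4, 9]]]:
            assert gender_balance_test(table) == pytest.approx(
                _fisher_two_sided_oracle(table), rel=1e-9
            )

    def test_zero_margin_convention(self):
        assert gender_balance_test([[0, 5], [0, 7]]) == 1.0

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            gender_balance_test([[1, -1], [2, 3]])
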