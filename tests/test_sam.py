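"""Differential expression: the moderated statistic, the fudge factor,
permutation FDR and threshold selection."""

import numpy as np
import pandas as pd
import pytest

from fmcm import sam, simulate
from conftest import paired_matrix


def two_sample(control, case):
    """One-gene matrix with explicit unpaired groups."""
    control, case = np.asarray(control, float), np.asarray(case, float)
    cols = [f"c{i}" for i in range(control.size)] + [f"t{i}" for i in range(case.size)]
    values = pd.DataFrame([np.concatenate([control, case])], index=["g"], columns=cols)
    condition = pd.Series(
        {**{f"c{i}": "control" for i in range(control.size)},
         **{f"t{i}": "case" for i in range(case.size)}}
    )
    from fmcm.io import ExpressionMatrix
    return ExpressionMatrix(values, condition)


class TestStatistic:
    @pytest.mark.parametrize(
        "s0,expected",
        [(0.0, 4 / np.sqrt(2)), (0.586, 2.0)],
    )
    def test_pooled_se_formula(self, s0, expected):
        m = two_sample([1, 3], [5, 7])
        d = sam.sam_statistic(m, s0)["d"].iloc[0]
        assert d == pytest.approx(expected, abs=2e-3)

    def test_identical_groups_give_zero(self):
        m = two_sample([1, 2, 3], [1, 2, 3])
        assert sam.sam_statistic(m, 0.5)["d"].iloc[0] == 0.0

    def test_fold_change_is_linear_scale(self):
        m = two_sample([3, 3], [5, 5])  # log2 diff = 2
        assert sam.sam_statistic(m, 1.0)["fold_change"].iloc[0] == pytest.approx(4.0)

    def test_one_condition_empty_is_error(self):
        from fmcm.io import ExpressionMatrix
        values = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"])
        m = ExpressionMatrix(values, pd.Series({"a": "control", "b": "control"}))
        with pytest.raises(ValueError, match="condition"):
            sam.sam_statistic(m, 0.0)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(3)
        control, case = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
        d1 = sam.sam_statistic(two_sample(control[0], case[0]), 0.1)["d"].iloc[0]
        d2 = sam.sam_statistic(two_sample(case[0], control[0]), 0.1)["d"].iloc[0]
        assert d1 == pytest.approx(-d2)

    def test_zero_pooled_se_flagged_infinite(self):
        m = two_sample([1, 1], [2, 2])
        stats = sam.sam_statistic(m, 0.0)
        assert not stats["finite"].iloc[0]
        assert np.isposinf(stats["d"].iloc[0])


def brute_force_s0(s, r, n_windows):
    """Independent re-implementation of the fudge-factor search."""
    order = np.argsort(s, kind="stable")
    s_sorted, r_sorted = s[order], r[order]
    nw = max(2, min(n_windows, s.size // 5))
    bounds = np.array_split(np.arange(s.size), nw)
    best, best_cv = None, np.inf
    for pct in range(0, 100, 5):
        s0 = np.percentile(s, pct)
        d = r_sorted / (s_sorted + s0)
        mads = []
        for w in bounds:
            dw = d[w]
            mads.append(np.median(np.abs(dw - np.median(dw))))
        mads = np.array(mads)
        if mads.mean() == 0:
            continue
        cv = mads.std() / mads.mean()
        if cv < best_cv - 1e-12:
            best_cv, best = cv, s0
    return best


class TestS0:
    def test_degenerate_all_equal(self):
        assert sam.estimate_s0(np.ones(20), np.zeros(20)) == 1.0

    def test_matches_independent_search(self):
        rng = np.random.default_rng(11)
        s = rng.gamma(2.0, 0.5, size=500)
        r = rng.normal(0, 1 + s, size=500)
        assert sam.estimate_s0(s, r) == pytest.approx(brute_force_s0(s, r, 100))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            sam.estimate_s0([], [])


class TestFDR:
    def test_label_invariant_data_has_q_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(7, 1, size=(30, 10))
        m = paired_matrix(base, base)  # case == control per subject
        q = sam.sam_fdr(m, s0=0.1, n_perm=100, seed=1)
        assert (q == 1.0).all()

    def test_planted_effect_has_small_q(self):
        rng = np.random.default_rng(5)
        control = rng.normal(7, 0.5, size=(200, 12))
        case = control + rng.normal(0, 0.5, size=control.shape)
        case[0] += 3.0  # strong planted shift
        m = paired_matrix(control, case)
        q = sam.sam_fdr(m, s0=0.1, n_perm=200, seed=2)
        assert q.iloc[0] < 0.02

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(8)
        m = paired_matrix(rng.normal(size=(50, 8)), rng.normal(size=(50, 8)))
        q1 = sam.sam_fdr(m, 0.2, n_perm=100, seed=42)
        q2 = sam.sam_fdr(m, 0.2, n_perm=100, seed=42)
        pd.testing.assert_series_equal(q1, q2)

    def test_q_monotone_in_abs_d(self):
        rng = np.random.default_rng(9)
        control = rng.normal(size=(80, 10))
        case = control + rng.normal(0, 1, size=control.shape)
        m = paired_matrix(control, case)
        d = sam.sam_statistic(m, 0.1)["d"]
        q = sam.sam_fdr(m, 0.1, n_perm=100, seed=0)
        ordered = q.loc[d.abs().sort_values(ascending=False).index]
        assert (np.diff(ordered.to_numpy()) >= -1e-12).all()


class TestSelect:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "d": [3.0, -2.5, 2.0, 1.0],
                "fold_change": [3.0, 0.4, 3.0, 1.5],
                "q": [0.005, 0.005, 0.02, 0.001],
                "direction": ["up", "down", "up", "up"],
            },
            index=["a", "b", "c", "d"],
        )

    def test_selection_rules(self, table):
        picked = sam.select_degs(table, fdr_max=0.01, fc_min=2.0)
        assert list(picked.index) == ["a", "b"]  # c fails q, d fails FC
        assert picked.loc["b", "direction"] == "down"  # 0.4 < 1/2

    def test_fc_min_must_exceed_one(self, table):
        with pytest.raises(ValueError):
            sam.select_degs(table, 0.01, 1.0)

    def test_thresholds_nest(self, table):
        loose = set(sam.select_degs(table, 0.05, 1.5).index)
        tight = set(sam.select_degs(table, 0.01, 2.5).index)
        assert tight <= loose


class TestPlantedRecovery:
    def test_recovers_planted_genes_and_controls_nulls(self):
        cfg = simulate.ScenarioConfig(
            n_genes=500,
            n_subjects=20,
            modules=(
                simulate.ModuleSpec("At", "apoptosis", size=25, direction="up"),
                simulate.ModuleSpec("CC", "cell cycle", size=25, direction="down"),
            ),
            n_drugs=4, instances_per_drug=1, n_reverse=1, n_mimic=1,
            seed=13,
        )
        m, truth = simulate.gen_cohort(cfg)
        table = sam.deg_table(m, n_perm=200, seed=13)
        picked = sam.select_degs(table, fdr_max=0.01, fc_min=2.0)
        planted = set(truth.index[truth["module"] != ""])
        nulls = set(truth.index) - planted
        recovered = len(planted & set(picked.index)) / len(planted)
        false_rate = len(set(picked.index) & nulls) / len(nulls)
        assert recovered >= 0.90
        assert false_rate <= 0.05
        # directions match the planted truth
        for g in planted & set(picked.index):
            assert picked.loc[g, "direction"] == truth.loc[g, "direction"]
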