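"""K-fold protocol, P/U/O metrics, model comparison, odds ratios."""

import numpy as np
import pytest

from hepasafe import (
    RegressorSpec,
    compare_models,
    compute_puo,
    kfold_split,
    odds_ratio_2x2,
    paired_sign_test,
    run_kfold,
)


def naive_puo(y_pred, y_true):
    """Element-by-element oracle for the P/U/O metrics."""
    over = [abs(p - t) for p, t in zip(y_pred, y_true) if p >= t]
    under = [abs(p - t) for p, t in zip(y_pred, y_true) if p < t]
    p = 100 * len(over) / len(y_pred)
    u = sum(under) / len(under) if under else 0.0
    o = sum(over) / len(over) if over else 0.0
    return p, u, o


# -- folds -------------------------------------------------------------------

def test_52_into_5_gives_canonical_sizes():
    plan = kfold_split(52, 5, seed=123)
    assert sorted(plan.fold_sizes()) == [10, 10, 10, 11, 11]


def test_folds_partition_every_sample_once():
    for seed in range(5):
        plan = kfold_split(52, 5, seed=seed)
        seen = np.concatenate([plan.fold_indices(f) for f in range(5)])
        assert sorted(seen) == list(range(52))


def test_ten_into_five_and_determinism():
    plan = kfold_split(10, 5, seed=4)
    assert plan.fold_sizes() == [2, 2, 2, 2, 2]
    assert plan == kfold_split(10, 5, seed=4)
    assert plan != kfold_split(10, 5, seed=5)


def test_bad_fold_counts():
    with pytest.raises(ValueError):
        kfold_split(5, 6)
    with pytest.raises(ValueError):
        kfold_split(5, 1)


# -- P / U / O ---------------------------------------------------------------

@pytest.mark.parametrize(
    "y_pred,y_true,expected",
    [
        ([5, 9, 12], [6, 7, 10], (200 / 3, 1.0, 2.0)),
        ([10, 8], [8, 10], (50.0, 2.0, 2.0)),
        ([1, 2, 3], [1, 2, 3], (100.0, 0.0, 0.0)),  # ties count as over
    ],
)
def test_puo_hand_examples(y_pred, y_true, expected):
    m = compute_puo(y_pred, y_true)
    assert (m.p, m.u, m.o) == pytest.approx(expected)


def test_puo_empty_side_flags():
    m = compute_puo([5.0, 6.0], [1.0, 2.0])
    assert m.under_empty and m.u == 0.0 and not m.over_empty


def test_puo_matches_naive_loop_and_mae_identity():
    rng = np.random.default_rng(21)
    for _ in range(1000):
        n = int(rng.integers(1, 30))
        y_pred = rng.normal(700, 150, n)
        y_true = rng.normal(700, 150, n)
        m = compute_puo(y_pred, y_true)
        p, u, o = naive_puo(y_pred, y_true)
        assert (m.p, m.u, m.o) == pytest.approx((p, u, o), rel=1e-12)
        mae = np.abs(y_pred - y_true).mean()
        assert m.under_count * m.u + m.over_count * m.o == pytest.approx(
            n * mae, rel=1e-9
        )


def test_puo_length_mismatch():
    with pytest.raises(ValueError):
        compute_puo([1.0], [1.0, 2.0])


# -- K-fold evaluation -------------------------------------------------------

def test_run_kfold_with_perfect_oracle(monkeypatch):
    """A predict-truth-plus-1mL oracle must score P=100, U=0, O=1."""
    import hepasafe.evaluation as ev

    X = np.arange(52, dtype=float).reshape(-1, 1)
    y = np.linspace(500, 900, 52)

    class Plus1:
        def fit(self, Xtr, ytr):
            return self

        def predict(self, Xte):
            return y[Xte[:, 0].astype(int)] + 1.0

    monkeypatch.setattr(ev, "make_baseline", lambda spec: Plus1())
    rep = ev.run_kfold(RegressorSpec("linear"), (X, y), k=5, seed=0)
    assert rep.mean_p == 100.0
    assert rep.mean_u == 0.0
    assert rep.mean_o == pytest.approx(1.0)


def test_run_kfold_constant_zero_model(monkeypatch):
    import hepasafe.evaluation as ev

    class Zero:
        def fit(self, X, y):
            return self

        def predict(self, X):
            return np.zeros(len(X))

    monkeypatch.setattr(ev, "make_baseline", lambda spec: Zero())
    X = np.zeros((20, 1))
    y = np.full(20, 700.0)
    rep = ev.run_kfold(RegressorSpec("linear"), (X, y), k=5, seed=0)
    assert rep.mean_p == 0.0


def test_run_kfold_deterministic_under_seed(cohort52):
    a = run_kfold(RegressorSpec("linear"), cohort52, k=5, seed=3)
    b = run_kfold(RegressorSpec("linear"), cohort52, k=5, seed=3)
    assert a == b


def test_run_kfold_decomposition_holds_per_fold(cohort52):
    rep = run_kfold(RegressorSpec("linear"), cohort52, k=5, seed=1)
    sizes = sorted(f.under_count + f.over_count for f in rep.folds)
    assert sizes == [10, 10, 10, 11, 11]


# -- model comparison --------------------------------------------------------

def test_identical_models_give_near_zero_f(cohort52):
    specs = [RegressorSpec("linear"), RegressorSpec("linear")]
    rep = compare_models(specs, cohort52, k=5, seeds=(0, 1, 2))
    # both groups are literally the same numbers; F is 0/0-protected
    assert rep.anova_f["p"] == pytest.approx(0.0, abs=1e-12) or np.isnan(
        rep.anova_f["p"]
    )


def test_anova_on_toy_groups_matches_hand_value():
    from scipy.stats import f_oneway

    f, _ = f_oneway([1, 2, 3], [4, 5, 6])
    assert f == pytest.approx(13.5)


def test_comparison_ranked_by_mean_p(cohort52):
    specs = [RegressorSpec("linear"), RegressorSpec("decision_tree")]
    rep = compare_models(specs, cohort52, k=5, seeds=(0, 1))
    ps = [rep.mean[m]["p"] for m in rep.models]
    assert ps == sorted(ps, reverse=True)


def test_compare_requires_two_specs(cohort52):
    with pytest.raises(ValueError):
        compare_models([RegressorSpec("linear")], cohort52)


def test_paired_sign_test_extremes():
    n_pos, n_eff, p = paired_sign_test([2, 3, 4, 5], [1, 1, 1, 1])
    assert (n_pos, n_eff) == (4, 4)
    assert p == pytest.approx(0.5**4)
    _, _, p_tie = paired_sign_test([1, 1], [1, 1])
    assert p_tie == 1.0


# -- odds ratios -------------------------------------------------------------

def test_odds_ratio_unity():
    res = odds_ratio_2x2(1, 1, 1, 1)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.ci_low < 1 < res.ci_high


def test_odds_ratio_hbv_worked_example():
    res = odds_ratio_2x2(4, 2, 8, 38)
    assert res.odds_ratio == pytest.approx(9.5)
    rec = odds_ratio_2x2(4, 2, 8, 38, reciprocal=True)
    assert rec.odds_ratio == pytest.approx(1 / 9.5)
    assert round(rec.odds_ratio, 2) == 0.11 or round(rec.odds_ratio, 1) == 0.1


def test_odds_ratio_dm_worked_example():
    res = odds_ratio_2x2(4, 2, 10, 36)
    assert res.odds_ratio == pytest.approx(7.2)
    assert round(odds_ratio_2x2(4, 2, 10, 36, reciprocal=True).odds_ratio, 2) == 0.14


def test_odds_ratio_ci_against_statsmodels():
    sm_stats = pytest.importorskip("statsmodels.stats.contingency_tables")
    table = np.array([[4, 2], [8, 38]])
    t22 = sm_stats.Table2x2(table)
    ours = odds_ratio_2x2(4, 2, 8, 38)
    lo, hi = t22.oddsratio_confint(0.05)
    assert ours.ci_low == pytest.approx(lo, rel=1e-6)
    assert ours.ci_high == pytest.approx(hi, rel=1e-6)


def test_odds_ratio_zero_cell_requires_haldane():
    with pytest.raises(ValueError, match="haldane"):
        odds_ratio_2x2(0, 2, 8, 38)
    res = odds_ratio_2x2(0, 2, 8, 38, haldane=True)
    assert res.odds_ratio > 0
    with pytest.raises(ValueError):
        odds_ratio_2x2(-1, 2, 8, 38)
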