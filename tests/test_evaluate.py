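"""Evaluation protocol: splits, outliers, metrics, screening, conversion."""

import math

import numpy as np
import pytest
from sklearn.base import BaseEstimator, RegressorMixin

import graphbind as gb
from graphbind.errors import InsufficientDataError, SchemaError
from graphbind.evaluate import (ConformerTable, EvalConfig, GibbsParams,
                                MetricsReport, active_decoy_eval,
                                compute_metrics, conformer_summary,
                                cross_validate, gibbs_to_pk, kfold_split,
                                remove_outliers)

# ------------------------------------------------------------------ kfold


def test_exact_division_folds():
    folds = kfold_split(16, EvalConfig(K=8, seed=0))
    assert [len(f) for f in folds] == [2] * 8


def test_balanced_remainder_rule():
    folds = kfold_split(17, EvalConfig(K=8, seed=1))
    sizes = [len(f) for f in folds]
    assert sorted(sizes, reverse=True) == [3] + [2] * 7
    assert sizes[0] == 3  # the extra sample goes to the first fold


@pytest.mark.parametrize("n,k,seed", [(16, 8, 0), (23, 5, 3), (100, 8, 7)])
def test_folds_partition_the_index_set(n, k, seed):
    folds = kfold_split(n, EvalConfig(K=k, seed=seed))
    all_idx = np.concatenate(folds)
    assert len(all_idx) == n
    assert set(all_idx.tolist()) == set(range(n))


def test_too_few_samples_rejected():
    with pytest.raises(InsufficientDataError):
        kfold_split(5, EvalConfig(K=8))


# --------------------------------------------------------------- outliers

def test_equal_residuals_drop_nothing():
    kept, report = remove_outliers(np.full(10, 0.7))
    assert len(kept) == 10
    assert len(report.dropped_indices) == 0


def test_planted_extremes_are_dropped():
    rng = np.random.default_rng(0)
    r = np.concatenate([rng.normal(size=98), [50.0, -50.0]])
    kept, report = remove_outliers(r, EvalConfig(z_threshold=3.0))
    assert set(report.dropped_indices.tolist()) == {98, 99}
    assert len(kept) == 98


def test_huge_threshold_is_identity():
    rng = np.random.default_rng(1)
    r = rng.normal(size=50)
    kept, _ = remove_outliers(r, EvalConfig(z_threshold=1e9))
    assert len(kept) == 50


@pytest.mark.parametrize("seed", range(20))
def test_outlier_removal_matches_brute_force_scan(seed):
    rng = np.random.default_rng(seed)
    r = rng.standard_t(df=3, size=rng.integers(5, 60))
    kept, report = remove_outliers(r, EvalConfig(z_threshold=2.5))
    mu, sd = r.mean(), r.std()
    expected = [i for i in range(len(r)) if abs(r[i] - mu) / sd <= 2.5]
    assert kept.tolist() == expected


# ---------------------------------------------------------------- metrics

def test_perfect_prediction_metrics():
    truth = np.array([4.0, 5.0, 7.0, 8.0])
    row = compute_metrics(truth, truth)
    assert row.pcc == pytest.approx(1.0)
    assert row.mse == 0.0 and row.mae == 0.0
    assert row.r2 == pytest.approx(1.0)
    assert row.auc == pytest.approx(1.0)


def test_anticorrelated_prediction():
    truth = np.array([4.0, 5.0, 7.0, 8.0])
    assert compute_metrics(-truth, truth).pcc == pytest.approx(-1.0)


def test_auc_hand_case():
    # binarized at 6: labels F F T T; predictions rank them perfectly
    row = compute_metrics(np.array([1.0, 2.0, 3.0, 4.0]),
                          np.array([4.0, 5.0, 7.0, 8.0]))
    assert row.auc == pytest.approx(1.0)


def test_constant_prediction_flags_pcc():
    truth = np.array([4.0, 5.0, 7.0, 8.0])
    row = compute_metrics(np.full(4, 6.0), truth)
    assert not row.pcc_defined and row.pcc == 0.0
    # constant prediction at the truth mean: MSE equals the variance
    row2 = compute_metrics(np.full(4, truth.mean()), truth)
    assert row2.mse == pytest.approx(truth.var(), abs=1e-12)


def test_single_class_flags_auc():
    row = compute_metrics(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
    assert not row.auc_defined and math.isnan(row.auc)


@pytest.mark.parametrize("seed", range(5))
def test_metrics_match_textbook_formulas(seed):
    rng = np.random.default_rng(seed)
    truth = rng.normal(6, 2, size=30)
    pred = truth + rng.normal(0, 1, size=30)
    row = compute_metrics(pred, truth)
    assert row.mse == pytest.approx(np.mean((pred - truth) ** 2), abs=1e-10)
    assert row.mae == pytest.approx(np.mean(np.abs(pred - truth)), abs=1e-10)
    ss_res = np.sum((truth - pred) ** 2)
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    assert row.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
    pc = (np.mean(pred * truth) - pred.mean() * truth.mean()) / (
        pred.std() * truth.std())
    assert row.pcc == pytest.approx(pc, abs=1e-10)


# -------------------------------------------------------------- screening

def brute_force_auc(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_separated_groups_auc_one():
    res = active_decoy_eval(np.full(5, 8.0), np.full(7, 4.0))
    assert res.auc == 1.0
    assert res.p_value < 1e-6 or math.isnan(res.p_value)


def test_identical_constant_groups_auc_half():
    res = active_decoy_eval(np.full(4, 5.0), np.full(4, 5.0))
    assert res.auc == 0.5
    assert not res.t_test_performed


@pytest.mark.parametrize("seed", range(15))
def test_auc_matches_rank_pair_brute_force(seed):
    rng = np.random.default_rng(seed)
    pos = np.round(rng.normal(6, 2, size=rng.integers(2, 16)), 1)
    neg = np.round(rng.normal(5, 2, size=rng.integers(2, 16)), 1)
    res = active_decoy_eval(pos, neg)
    assert res.auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)


def test_null_distribution_auc_near_half():
    rng = np.random.default_rng(123)
    a = rng.normal(5, 1, size=500)
    d = rng.normal(5, 1, size=500)
    res = active_decoy_eval(a, d)
    assert abs(res.auc - 0.5) < 0.05


def test_welch_t_test_direction():
    rng = np.random.default_rng(3)
    res = active_decoy_eval(rng.normal(8, 1, 50), rng.normal(4, 1, 50))
    assert res.t_statistic > 0
    assert res.p_value < 1e-10
    assert res.median_active > res.median_decoy


# -------------------------------------------------------------- gibbs

def test_gibbs_zero_energy():
    assert gibbs_to_pk(GibbsParams(delta_g=0.0)) == pytest.approx(0.0)


def test_gibbs_micromolar_point():
    # dG chosen so Kd = 1e-6 M -> pK = 6
    dg = -0.0019872 * 298.0 * math.log(10.0) * 6.0
    assert gibbs_to_pk(GibbsParams(delta_g=dg)) == pytest.approx(6.0, abs=1e-9)


def test_gibbs_monotone_decreasing():
    vals = [gibbs_to_pk(GibbsParams(delta_g=dg))
            for dg in np.linspace(-12, 2, 30)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


# ------------------------------------------------------------- conformers

def test_single_conformer_is_best():
    t = ConformerTable([0.0], [5.0], experimental=7.0, reference_prediction=4.0)
    s = conformer_summary(t)
    assert s.best_time_ps == 0.0
    assert s.improved_over_reference is True


def test_reference_better_than_all_conformers():
    t = ConformerTable([0.0, 500.0], [4.0, 4.5], experimental=7.0,
                       reference_prediction=6.9)
    assert conformer_summary(t).improved_over_reference is False


def test_duplicate_times_rejected():
    with pytest.raises(ValueError):
        ConformerTable([0.0, 0.0], [5.0, 6.0], experimental=7.0)


# ---------------------------------------------------------- cross_validate

class FixedConstant(BaseEstimator, RegressorMixin):
    """Base learner that ignores the data and predicts a fixed constant."""

    def __init__(self, value=0.0):
        self.value = value

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.value)


def test_cross_validate_constant_predictor(small_dataset, tiny_model_config):
    """With constant base learners the stacked head collapses to the
    training-fold mean: PCC is flagged per fold and the averaged MSE equals
    an independent recomputation over the same deterministic folds."""
    _, graphs, y = small_dataset
    ecfg = EvalConfig(K=2, seed=9)
    report = cross_validate(graphs, y, tiny_model_config, ecfg,
                            outlier_removal=False,
                            base_estimators=(FixedConstant(5.0),
                                             FixedConstant(5.0)))
    assert all(not row.pcc_defined for row in report.folds)
    # independent oracle over the same seeded folds
    folds = kfold_split(len(graphs), ecfg)
    expected = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(graphs)), test_idx)
        expected.append(np.mean((y[test_idx] - y[train_idx].mean()) ** 2))
    assert report.mse == pytest.approx(np.mean(expected), abs=1e-9)
    # averaged MSE is the mean of fold MSEs
    assert report.mse == pytest.approx(
        np.mean([row.mse for row in report.folds]), abs=1e-12)


def test_cross_validate_each_complex_tested_once(small_dataset,
                                                 tiny_model_config):
    _, graphs, y = small_dataset
    folds = kfold_split(len(graphs), EvalConfig(K=3, seed=2))
    seen = np.concatenate(folds)
    assert sorted(seen.tolist()) == list(range(len(graphs)))


def test_ablation_unknown_group_rejected(small_dataset, tiny_model_config):
    _, graphs, y = small_dataset
    with pytest.raises(SchemaError):
        gb.ablation_run(graphs, y, "not_a_group", tiny_model_config, reps=1)
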