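"""Split, logistic fits, Boruta selection, AUC/DeLong machinery, model suite."""

import numpy as np
import pandas as pd
import pytest

from pgseval.cohort_stats import encode_covariate
from pgseval.models import (
    ModelSpec,
    boruta_select,
    delong_paired_test,
    evaluate_model_suite,
    fit_logistic,
    roc_auc,
    stratified_split,
)


def binary_cohort(n_cases, n_controls):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n_cases + n_controls)],
            "status": ["case"] * n_cases + ["control"] * n_controls,
        }
    )


# ---------------------------------------------------------------------------
# Split


def test_split_preserves_proportions():
    train, test = stratified_split(binary_cohort(100, 100), 0.8, seed=1)
    assert len(train) == 160 and len(test) == 40
    cohort = binary_cohort(100, 100).set_index("sample_id")
    assert (cohort.loc[train, "status"] == "case").sum() == 80
    assert (cohort.loc[test, "status"] == "case").sum() == 20


def test_split_deterministic_and_seed_sensitive():
    cohort = binary_cohort(100, 100)
    assert stratified_split(cohort, seed=5) == stratified_split(cohort, seed=5)
    assert stratified_split(cohort, seed=5) != stratified_split(cohort, seed=6)


def test_split_partitions_all_ids(rng):
    n_cases, n_controls = 73, 91
    cohort = binary_cohort(n_cases, n_controls)
    train, test = stratified_split(cohort, 0.8, seed=2)
    assert set(train) | set(test) == set(cohort["sample_id"])
    assert set(train) & set(test) == set()


def test_split_needs_both_classes():
    with pytest.raises(ValueError):
        stratified_split(binary_cohort(1, 50))


# ---------------------------------------------------------------------------
# Logistic regression


def test_single_binary_feature_equals_cross_product_or(rng):
    # 2x2: exposed cases 40, exposed controls 20, unexposed 60/80
    x = np.r_[np.ones(60), np.zeros(140)]
    y = np.r_[np.ones(40), np.zeros(20), np.ones(60), np.zeros(80)]
    fit = fit_logistic(x, y)
    expected = np.log((40 * 80) / (20 * 60))
    assert fit.params[1] == pytest.approx(expected, abs=1e-8)


def test_null_model_intercept(rng):
    n = 2000
    y = (rng.random(n) < 0.3).astype(float)
    x = rng.normal(size=n)
    fit = fit_logistic(x, y)
    expected = np.log(y.sum() / (n - y.sum()))
    assert fit.params[0] == pytest.approx(expected, abs=0.15)
    assert abs(fit.params[1]) < 3 * np.sqrt(fit.cov[1, 1])


def test_parameter_recovery_within_3_se(rng):
    n = 5000
    beta = np.array([-0.4, 0.8, -0.5])
    X = rng.normal(size=(n, 2))
    logit = beta[0] + X @ beta[1:]
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    fit = fit_logistic(X, y)
    se = np.sqrt(np.diag(fit.cov))
    np.testing.assert_array_less(np.abs(fit.params - beta), 3 * se)


def test_constant_column_is_named():
    X = np.column_stack([np.ones(50), np.arange(50.0)])
    y = (np.arange(50) % 2).astype(float)
    with pytest.raises(ValueError, match="const_col"):
        fit_logistic(X, y, feature_names=["const_col", "x"])


def test_rank_deficiency_is_an_error(rng):
    x = rng.normal(size=100)
    X = np.column_stack([x, 2 * x])
    y = (rng.random(100) < 0.5).astype(float)
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_logistic(X, y)


def test_separation_flagged_not_raised():
    x = np.r_[np.ones(20), np.zeros(20)] + np.linspace(0, 0.01, 40)
    y = np.r_[np.ones(20), np.zeros(20)]
    fit = fit_logistic(x, y)
    assert fit.separation


# ---------------------------------------------------------------------------
# Boruta


def test_boruta_confirms_signal_rejects_noise(rng):
    n = 500
    y = (rng.random(n) < 0.5).astype(int)
    signal = y + rng.normal(0, 0.1, n)
    noise = rng.normal(size=(n, 5))
    X = pd.DataFrame(
        np.column_stack([signal, noise]),
        columns=["signal"] + [f"noise{i}" for i in range(5)],
    )
    res = boruta_select(X, y, n_iterations=25, seed=3)
    assert res.decisions["signal"] == "confirmed"
    assert all(
        res.decisions[f"noise{i}"] != "confirmed" for i in range(5)
    )
    assert res.hit_counts["signal"] == 25


def test_boruta_all_noise_confirms_nothing(rng):
    n = 300
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, 6))
    res = boruta_select(X, y, n_iterations=25, seed=4)
    assert "confirmed" not in res.decisions.values()


def test_boruta_zero_variance_feature_rejected(rng):
    n = 300
    y = (rng.random(n) < 0.5).astype(int)
    X = np.column_stack([np.full(n, 7.0), y + rng.normal(0, 0.3, n)])
    res = boruta_select(
        X, y, n_iterations=25, seed=5, feature_names=["flat", "signal"]
    )
    assert res.decisions["flat"] == "rejected"


def test_boruta_input_contracts(rng):
    y = (rng.random(40) < 0.5).astype(int)
    with pytest.raises(ValueError, match="2 candidate"):
        boruta_select(rng.normal(size=(40, 1)), y)
    with pytest.raises(ValueError, match="20"):
        boruta_select(rng.normal(size=(40, 3)), y, n_iterations=5)


# ---------------------------------------------------------------------------
# ROC / AUC


def test_perfectly_separating_score():
    y = np.r_[np.ones(5), np.zeros(5)]
    s = np.r_[np.arange(5, 10), np.arange(5)].astype(float)
    res = roc_auc(y, s)
    assert res.auc == 1.0
    assert res.roc_points[0].tolist() == [0.0, 0.0]
    assert res.roc_points[-1].tolist() == [1.0, 1.0]


def test_auc_matches_brute_force_pair_counting(rng):
    y = (rng.random(150) < 0.4).astype(int)
    s = rng.integers(0, 10, size=150).astype(float)  # many ties
    res = roc_auc(y, s)
    cases, controls = s[y == 1], s[y == 0]
    wins = sum(
        (c > d) + 0.5 * (c == d) for c in cases for d in controls
    )
    assert res.auc == pytest.approx(wins / (len(cases) * len(controls)), abs=1e-12)


def test_auc_null_score_near_half(rng):
    y = (rng.random(2000) < 0.5).astype(int)
    res = roc_auc(y, rng.normal(size=2000))
    assert res.auc == pytest.approx(0.5, abs=0.03)
    assert res.ci_low <= 0.5 <= res.ci_high


def test_auc_invariant_under_increasing_transform(rng):
    y = (rng.random(300) < 0.5).astype(int)
    s = rng.normal(size=300)
    assert roc_auc(y, s).auc == pytest.approx(
        roc_auc(y, np.exp(2 * s)).auc, abs=1e-12
    )


def test_auc_single_class_is_an_error():
    with pytest.raises(ValueError):
        roc_auc(np.ones(10), np.arange(10.0))


def test_delong_variance_close_to_binormal_approximation(rng):
    """On a large balanced normal fixture the DeLong variance agrees with
    the closed-form binormal (Hanley-McNeil) approximation within 20%."""
    n = 4000
    y = np.r_[np.ones(n), np.zeros(n)]
    s = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
    res = roc_auc(y, s)
    a = res.auc
    q1, q2 = a / (2 - a), 2 * a**2 / (1 + a)
    hm = (a * (1 - a) + (n - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / n**2
    assert res.variance == pytest.approx(hm, rel=0.2)


# ---------------------------------------------------------------------------
# DeLong paired test


def test_delong_identical_scores():
    y = np.r_[np.ones(20), np.zeros(20)]
    s = np.arange(40.0)
    res = delong_paired_test(y, s, s)
    assert res.delta == 0.0
    assert res.z_statistic == 0.0
    assert res.p_value == 1.0


def test_delong_delta_is_auc_difference(rng):
    y = (rng.random(200) < 0.5).astype(int)
    a, b = rng.normal(size=200), rng.normal(size=200)
    res = delong_paired_test(y, a, b)
    assert res.delta == pytest.approx(
        roc_auc(y, a).auc - roc_auc(y, b).auc, abs=1e-12
    )


def test_delong_variance_agrees_with_bootstrap(rng):
    n = 300
    y = (rng.random(n) < 0.5).astype(int)
    latent = rng.normal(size=n) + y
    a = latent + rng.normal(0, 0.8, n)
    b = latent + rng.normal(0, 0.8, n)
    res = delong_paired_test(y, a, b)
    var_delong = (res.delta / res.z_statistic) ** 2
    deltas = []
    for _ in range(2000):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        d = delong_paired_test(y[idx], a[idx], b[idx])
        deltas.append(d.delta)
    var_boot = np.var(deltas, ddof=1)
    assert var_delong == pytest.approx(var_boot, rel=0.15)


def test_delong_detects_genuinely_better_score(rng):
    n = 600
    y = (rng.random(n) < 0.5).astype(int)
    good = y + rng.normal(0, 0.8, n)
    bad = rng.normal(size=n)
    res = delong_paired_test(y, good, bad)
    assert res.p_value < 1e-6
    assert res.delta > 0


# ---------------------------------------------------------------------------
# Model suite


def suite_cohort(rng, n=1200, pgs_effect=1.0):
    age = rng.normal(50, 8, n)
    bmi = rng.normal(26, 4, n)
    z = rng.normal(size=n)
    logit = 0.05 * (bmi - 26) + pgs_effect * z
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    cohort = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "status": np.where(y, "case", "control"),
            "age": age,
            "bmi": bmi,
        }
    )
    return cohort, z


def test_pgs_only_model_auc_equals_score_auc(rng):
    """A single-feature logistic model is a monotone transform of its score,
    so the test AUC equals the raw score's AUC on the test samples."""
    cohort, z = suite_cohort(rng)
    spec = ModelSpec(
        features=["age", "bmi"], seed=9, cv_repeats=1, select_features=False
    )
    result = evaluate_model_suite(cohort, {"PGS": z}, spec)
    by_model = {c.model: c for c in result.comparisons}
    test_idx = cohort.set_index("sample_id").index.get_indexer(result.test_ids)
    y_te = (cohort["status"].to_numpy() == "case").astype(int)[test_idx]
    direct = roc_auc(y_te, z[test_idx])
    assert by_model["pgs_only"].test_auc.auc == pytest.approx(
        direct.auc, abs=1e-12
    )


def test_combined_model_beats_covariates_with_planted_pgs(rng):
    wins = 0
    for rep in range(8):
        cohort, z = suite_cohort(
            np.random.default_rng(100 + rep), n=1500, pgs_effect=np.log(2)
        )
        spec = ModelSpec(
            features=["age", "bmi"], seed=rep, cv_repeats=1,
            select_features=False,
        )
        result = evaluate_model_suite(cohort, {"PGS": z}, spec)
        by_model = {c.model: c for c in result.comparisons}
        wins += (
            by_model["combined"].test_auc.auc > by_model["covariates"].test_auc.auc
        )
    assert wins >= 7


def test_suite_output_shape_and_delong(rng):
    cohort, z = suite_cohort(rng, n=800)
    spec = ModelSpec(
        features=["age", "bmi"], seed=1, cv_repeats=1, select_features=False
    )
    result = evaluate_model_suite(cohort, {"A": z, "B": rng.normal(size=800)}, spec)
    frame = result.to_frame()
    assert len(frame) == 6  # 2 scores x 3 models
    combined = frame[frame.model == "combined"]
    assert combined["delong_p_vs_covariates"].notna().all()
    assert set(result.train_ids) & set(result.test_ids) == set()
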