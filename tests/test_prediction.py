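"""Risk models, ROC/AUC, Youden thresholds, bootstrap AUC comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adsig.prediction import (
    MODEL_SPECS,
    bootstrap_auc_compare,
    confusion_metrics,
    fit_risk_model,
    roc_auc,
    run_model_suite,
    youden_threshold,
)


def test_model_specs_match_published_sets():
    assert MODEL_SPECS[1] == ("age", "prs")
    assert MODEL_SPECS[4] == ("age", "prs", "tv_signature", "md_signature")
    assert MODEL_SPECS[5] == ("age", "prs", "tv_pbad_adj", "md_pbad_adj")


# ---------------------------------------------------------------------------
# GLMM fit
# ---------------------------------------------------------------------------


def _sim_logistic(rng, n=600, beta=(0.5, -0.8), intercept=-1.5, sigma=0.0, cluster=2):
    m = n // cluster
    pair = np.repeat(np.arange(m), cluster)
    X = pd.DataFrame({f"x{j}": rng.normal(size=n) for j in range(len(beta))})
    b = sigma * rng.normal(size=m)[pair]
    lp = intercept + X.to_numpy() @ np.asarray(beta) + b
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    return X, y, pair


def test_sigma_zero_matches_plain_logistic(rng):
    import statsmodels.api as sm

    X, y, pair = _sim_logistic(rng)
    fit = fit_risk_model(X, y, pair, standardize=False, fix_sigma=0.0)
    glm = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert np.abs(fit.coef - glm.params.to_numpy()).max() < 1e-3


def test_free_sigma_shrinks_when_pairs_are_independent(rng):
    # paired clusters identify sigma; with no true pair effect it collapses
    X, y, pair = _sim_logistic(rng, n=1200, sigma=0.0, cluster=2)
    fit = fit_risk_model(X, y, pair, standardize=False)
    assert fit.sigma < 0.5
    assert np.isfinite(fit.coef).all() and np.abs(fit.coef).max() < 3.0


def test_null_predictors_give_null_log_odds(rng):
    X, y, pair = _sim_logistic(rng, n=2000, beta=(0.0, 0.0), sigma=0.5)
    fit = fit_risk_model(X, y, pair)
    for coef, se in zip(fit.coef[1:], fit.se[1:]):
        assert abs(coef) <= 3 * se


def test_fitted_probs_use_fixed_effects_only(rng):
    X, y, pair = _sim_logistic(rng, sigma=1.0)
    fit = fit_risk_model(X, y, pair, standardize=False)
    from scipy.special import expit

    design = np.column_stack([np.ones(len(y)), X.to_numpy()])
    assert np.allclose(fit.fitted_probs, expit(design @ fit.coef))


def test_zero_variance_predictor_errors(rng):
    X = pd.DataFrame({"a": np.ones(50)})
    y = np.r_[np.ones(25), np.zeros(25)]
    with pytest.raises(ValueError):
        fit_risk_model(X, y, np.arange(50))


def test_single_class_outcome_errors(rng):
    X = pd.DataFrame({"a": rng.normal(size=50)})
    with pytest.raises(ValueError):
        fit_risk_model(X, np.zeros(50), np.arange(50))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _auc_bruteforce(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_trivials():
    assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert roc_auc([0.1, 0.9], [1, 0]) == 0.0
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


@settings(max_examples=150, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_auc_matches_pairwise_concordance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 60))
    # coarse grid forces ties
    scores = rng.integers(0, 6, n) / 5.0
    labels = rng.random(n) < 0.4
    if labels.all() or not labels.any():
        return
    assert roc_auc(scores, labels) == pytest.approx(
        _auc_bruteforce(scores, labels), rel=1e-12
    )


def test_auc_agrees_with_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.normal(size=300)
    labels = rng.random(300) < 0.3
    assert roc_auc(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), rel=1e-12
    )


def test_auc_invariant_under_monotone_transform(rng):
    scores = rng.normal(size=200)
    labels = rng.random(200) < 0.25
    a = roc_auc(scores, labels)
    assert roc_auc(np.exp(scores), labels) == pytest.approx(a, rel=1e-12)
    assert roc_auc(np.tanh(scores / 2), labels) == pytest.approx(a, rel=1e-12)


# ---------------------------------------------------------------------------
# Youden threshold
# ---------------------------------------------------------------------------


def _youden_bruteforce(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(scores)
    cands = np.r_[-np.inf, (uniq[:-1] + uniq[1:]) / 2.0, np.inf]
    best = None
    for thr in cands:
        called = scores >= thr
        sens = (called & labels).sum() / labels.sum()
        spec = (~called & ~labels).sum() / (~labels).sum()
        key = (sens + spec - 1.0, thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    return best[1], best[2], best[3]


def test_youden_perfect_separation():
    thr, sens, spec = youden_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert sens == 1.0 and spec == 1.0 and 0.2 < thr < 0.8


def test_youden_degenerate_equal_scores():
    thr, sens, spec = youden_threshold([0.5] * 6, [1, 1, 0, 0, 0, 0])
    assert sens + spec - 1.0 == pytest.approx(0.0)


@settings(max_examples=150, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_youden_matches_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 50))
    scores = np.round(rng.random(n), 2)
    labels = rng.random(n) < 0.4
    if labels.all() or not labels.any():
        return
    got = youden_threshold(scores, labels)
    want = _youden_bruteforce(scores, labels)
    assert got == pytest.approx(want)


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------


def test_confusion_metrics_from_operating_points():
    got = confusion_metrics(0.80, 0.6510, n_pos=20, n_neg=149)
    assert (got["tp"], got["tn"]) == (16, 97)
    assert got["accuracy"] == pytest.approx(113 / 169)
    assert got["ppv"] == pytest.approx(16 / 68)
    assert got["npv"] == pytest.approx(97 / 101)
    got = confusion_metrics(0.85, 0.7785, n_pos=20, n_neg=149)
    assert got["accuracy"] == pytest.approx(133 / 169)


def test_confusion_metrics_perfect_and_invalid():
    got = confusion_metrics(1.0, 1.0, 10, 90)
    assert got["accuracy"] == 1.0 and got["ppv"] == 1.0 and got["npv"] == 1.0
    assert np.isnan(confusion_metrics(0.0, 1.0, 10, 90)["ppv"])
    with pytest.raises(ValueError):
        confusion_metrics(1.2, 0.5, 10, 10)
    with pytest.raises(ValueError):
        confusion_metrics(0.5, 0.5, 0, 10)


# ---------------------------------------------------------------------------
# bootstrap AUC comparison
# ---------------------------------------------------------------------------


def test_identical_models_give_p_one(rng):
    p = rng.random(100)
    labels = rng.random(100) < 0.3
    got = bootstrap_auc_compare(p, p, labels, n_boot=200, seed=0)
    assert got["p"] == 1.0 and got["diff"] == 0.0


def test_bootstrap_detects_dominant_model(rng):
    n = 200
    labels = rng.random(n) < 0.15
    perfect = labels.astype(float) + 0.01 * rng.random(n)
    small_p = 0
    for seed in range(10):
        noise = np.random.default_rng(seed).random(n)
        got = bootstrap_auc_compare(perfect, noise, labels, n_boot=500, seed=seed)
        small_p += got["p"] < 0.01
    assert small_p >= 10 * 0.95 - 1  # at least 9 of 10 seeds


def test_bootstrap_symmetric_in_model_order(rng):
    labels = rng.random(150) < 0.3
    a, b = rng.random(150), rng.random(150)
    p_ab = bootstrap_auc_compare(a, b, labels, n_boot=300, seed=5)
    p_ba = bootstrap_auc_compare(b, a, labels, n_boot=300, seed=5)
    assert p_ab["p"] == pytest.approx(p_ba["p"])
    assert p_ab["diff"] == pytest.approx(-p_ba["diff"])


def test_bootstrap_deterministic_given_seed(rng):
    labels = rng.random(150) < 0.3
    a, b = rng.random(150), rng.random(150)
    x = bootstrap_auc_compare(a, b, labels, n_boot=300, seed=9)
    y = bootstrap_auc_compare(a, b, labels, n_boot=300, seed=9)
    assert x == y


def test_bootstrap_warns_for_tiny_n_boot(rng):
    labels = np.r_[np.ones(10), np.zeros(20)].astype(bool)
    with pytest.warns(UserWarning):
        bootstrap_auc_compare(
            rng.random(30), rng.random(30), labels, n_boot=50, seed=0
        )


# ---------------------------------------------------------------------------
# model suite on a synthetic cohort
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def suite_report(small_cohort):
    from adsig.diagnosis import diagnose_cohort
    from adsig.signatures import compute_pbad, pbad_adjust, score_signatures
    from adsig.prediction import build_predictor_frame

    scores = score_signatures(small_cohort)
    adjusted = pbad_adjust(scores, compute_pbad(small_cohort))
    diag = diagnose_cohort(small_cohort)
    frame = build_predictor_frame(small_cohort, scores, adjusted, diag.tracks)
    return run_model_suite(frame, n_boot=300, seed=1)


def test_suite_emits_five_models(suite_report):
    assert suite_report.models["model"].tolist() == [1, 2, 3, 4, 5]
    assert suite_report.models["auc"].between(0, 1).all()
    assert len(suite_report.comparisons) == 4


def test_nested_models_never_lose_in_sample_auc(suite_report):
    """Adding predictors cannot reduce in-sample fit quality by much; the
    MD model should beat the age+PRS base model here by construction."""
    aucs = suite_report.models.set_index("model")["auc"]
    assert aucs[3] >= aucs[1] - 1e-9
    assert aucs[4] >= aucs[1] - 1e-9


def test_operating_points_consistent_with_confusion_counts(suite_report):
    m = suite_report.models
    assert ((m["tp"] + m["fn"]) == suite_report.n_pos).all()
    assert ((m["tn"] + m["fp"]) == suite_report.n_neg).all()
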