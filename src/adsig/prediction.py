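"""Baseline risk models for CN -> MCI conversion and ROC comparison.

Five nested logistic models predict conversion from baseline measures:

1. age + AD-PRS
2. age + AD-PRS + thickness/volume signature
3. age + AD-PRS + MD signature
4. age + AD-PRS + thickness/volume + MD signatures
5. age + AD-PRS + PBAD-adjusted thickness/volume + PBAD-adjusted MD

All predictors are z-scored within the analysis sample.  Each model carries
a twin-pair random intercept; the marginal likelihood is maximized with
Gauss-Hermite quadrature (written here because no installed package fits a
quadrature/Laplace logistic GLMM).  Predicted probabilities are computed
from the fixed effects only — the pair intercept absorbs non-independence
during estimation but plays no role in scoring.

ROC AUC is the Mann-Whitney concordance probability with midrank tie
handling.  Operating points come from Youden's J (max sensitivity +
specificity - 1) over the midpoints of sorted unique scores, ties broken
toward higher specificity.  Model AUCs are compared with a stratified
bootstrap (cases and controls resampled separately, paired resamples across
models): the two-sided p-value is taken from a normal approximation of the
bootstrap AUC-difference distribution, with a percentile variant available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp
from statsmodels.tools.numdiff import approx_hess

#: Predictor sets of the five published model specifications.
MODEL_SPECS: dict[int, tuple[str, ...]] = {
    1: ("age", "prs"),
    2: ("age", "prs", "tv_signature"),
    3: ("age", "prs", "md_signature"),
    4: ("age", "prs", "tv_signature", "md_signature"),
    5: ("age", "prs", "tv_pbad_adj", "md_pbad_adj"),
}


# ---------------------------------------------------------------------------
# Random-intercept logistic regression (pair-clustered)
# ---------------------------------------------------------------------------


@dataclass
class RiskModelFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    sigma: float  # random-intercept SD
    odds_ratios: pd.DataFrame  # term, or, ci_low, ci_high, p
    fitted_probs: np.ndarray  # fixed-effects-only probabilities
    loglik: float
    converged: bool
    separation_flag: bool
    n_obs: int
    n_clusters: int


def _cluster_loglik(
    beta: np.ndarray,
    log_sigma: float,
    X: np.ndarray,
    y_sign: np.ndarray,
    cluster_starts: np.ndarray,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    """Marginal log-likelihood via Gauss-Hermite quadrature.

    ``nodes``/``log_weights`` are probabilists' Hermite nodes, so the
    random intercept at node k is ``sigma * node_k``.
    """
    sigma = np.exp(log_sigma)
    eta = X @ beta
    # log P(y_i | b): log sigmoid(y_sign * (eta + b)), shape (n, K)
    ll = log_expit(y_sign[:, None] * (eta[:, None] + sigma * nodes[None, :]))
    per_cluster = np.add.reduceat(ll, cluster_starts, axis=0)  # (J, K)
    return float(logsumexp(per_cluster + log_weights[None, :], axis=1).sum())


def fit_risk_model(
    X: pd.DataFrame,
    y: np.ndarray,
    pair_id: np.ndarray,
    standardize: bool = True,
    n_quad: int = 25,
    alpha_ci: float = 0.05,
    fix_sigma: float | None = None,
) -> RiskModelFit:
    """Fit a pair-random-intercept logistic model by GH quadrature.

    Parameters
    ----------
    X
        Predictor frame (columns in model order); z-scored within the
        analysis sample unless ``standardize=False``.
    y
        Binary outcome (0/1).
    pair_id
        Cluster labels (twin pairs).
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    sds = Xm.std(axis=0, ddof=1)
    if np.any(sds == 0.0):
        bad = names[int(np.argmin(sds))]
        raise ValueError(f"zero-variance predictor {bad!r}")
    if standardize:
        Xm = (Xm - Xm.mean(axis=0)) / sds
    design = np.column_stack([np.ones(len(y)), Xm])
    term_names = ["intercept"] + names

    order = np.argsort(np.asarray(pair_id), kind="stable")
    design_o, y_o = design[order], y[order]
    pid_o = np.asarray(pair_id)[order]
    starts = np.flatnonzero(np.r_[True, pid_o[1:] != pid_o[:-1]])
    y_sign = 2.0 * y_o - 1.0

    nodes, weights = hermegauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(2.0 * np.pi)

    # start from the independence logistic fit
    beta0 = np.zeros(design.shape[1])
    res0 = minimize(
        lambda b: -float(log_expit(y_sign * (design_o @ b)).sum()),
        beta0,
        method="BFGS",
    )
    if fix_sigma is not None:
        # sigma held fixed (fix_sigma=0 reduces to ordinary logistic regression)
        log_sig_fixed = np.log(max(fix_sigma, 1e-12))

        def nll(theta: np.ndarray) -> float:
            return -_cluster_loglik(
                theta, log_sig_fixed, design_o, y_sign, starts, nodes, log_w
            )

        opt = minimize(nll, res0.x, method="L-BFGS-B", options={"maxiter": 500})
        beta, sigma = opt.x, float(fix_sigma)
        theta = np.r_[beta]
    else:

        def nll(theta: np.ndarray) -> float:
            return -_cluster_loglik(
                theta[:-1], theta[-1], design_o, y_sign, starts, nodes, log_w
            )

        # bound log(sigma): below ~e^-8 the model is independence; above ~5
        # on the logit scale the intercept variance is no longer identified
        bounds = [(None, None)] * design.shape[1] + [(-8.0, np.log(5.0))]
        opt = minimize(
            nll,
            np.r_[res0.x, np.log(0.5)],
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500},
        )
        theta = opt.x
        beta = theta[:-1]
        sigma = float(np.exp(theta[-1]))

    separation = bool(np.any(np.abs(beta) > 10.0))
    if separation:
        warnings.warn("possible complete separation: |coef| > 10", stacklevel=2)

    hess = approx_hess(theta, nll)
    try:
        cov = np.linalg.inv(hess)
        se_full = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_full = np.full(theta.size, np.nan)
    se = se_full if fix_sigma is not None else se_full[:-1]

    zq = stats.norm.ppf(1.0 - alpha_ci / 2.0)
    wald_z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(wald_z))
    or_table = pd.DataFrame(
        {
            "term": term_names,
            "coef": beta,
            "se": se,
            "or": np.exp(beta),
            "or_ci_low": np.exp(beta - zq * se),
            "or_ci_high": np.exp(beta + zq * se),
            "p": pvals,
        }
    )
    fitted = expit(design @ beta)  # fixed effects only, original row order
    return RiskModelFit(
        names=term_names,
        coef=beta,
        se=se,
        sigma=sigma,
        odds_ratios=or_table,
        fitted_probs=fitted,
        loglik=-float(opt.fun),
        converged=bool(opt.success),
        separation_flag=separation,
        n_obs=len(y),
        n_clusters=len(starts),
    )


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _auc_rows(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC for matrices of positive/negative scores (B, n_pos/neg)."""
    n_pos = pos.shape[1]
    n_neg = neg.shape[1]
    ranks = stats.rankdata(np.concatenate([pos, neg], axis=1), axis=1)
    rsum = ranks[:, :n_pos].sum(axis=1)
    return (rsum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def youden_threshold(scores, labels) -> tuple[float, float, float]:
    """Youden-optimal cutoff: maximize sensitivity + specificity - 1.

    Candidates are the midpoints between sorted unique scores plus +/-inf;
    a subject is called positive when its score is at or above the cutoff.
    Ties in J are broken toward higher specificity (the higher cutoff).

    Returns ``(threshold, sensitivity, specificity)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    candidates = np.r_[-np.inf, (uniq[:-1] + uniq[1:]) / 2.0, np.inf]
    best = (-np.inf, -np.inf, None)  # (J, threshold) lexicographic
    for thr in candidates:
        called = scores >= thr
        sens = (called & labels).sum() / n_pos
        spec = (~called & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        # ties toward higher specificity == higher threshold
        if (j, thr) > (best[0], best[1]):
            best = (j, thr, (sens, spec))
    sens, spec = best[2]
    return float(best[1]), float(sens), float(spec)


def confusion_metrics(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> dict:
    """Confusion counts and derived rates from an operating point.

    Counts use nearest-integer rounding of ``sens*n_pos`` and
    ``spec*n_neg``; PPV is missing when no subject is called positive.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("counts must be positive")
    tp = int(np.floor(sensitivity * n_pos + 0.5))
    tn = int(np.floor(specificity * n_neg + 0.5))
    fn = n_pos - tp
    fp = n_neg - tn
    accuracy = (tp + tn) / (n_pos + n_neg)
    ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "accuracy": accuracy,
        "ppv": ppv,
        "npv": npv,
    }


def bootstrap_auc_compare(
    probs_a,
    probs_b,
    labels,
    n_boot: int = 2000,
    seed: int | None = None,
    method: str = "normal",
) -> dict:
    """Compare two models' AUCs with a stratified bootstrap.

    Cases and controls are resampled separately with replacement; the same
    resamples score both models, so ``p(a, b) == p(b, a)``.  The default
    two-sided p-value treats the observed difference divided by the
    bootstrap SD as standard normal; ``method='percentile'`` uses the
    bootstrap distribution of the difference directly.
    """
    probs_a = np.asarray(probs_a, dtype=float)
    probs_b = np.asarray(probs_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if probs_a.shape != probs_b.shape or probs_a.shape != labels.shape:
        raise ValueError("inputs must share one shape")
    if n_boot < 100:
        warnings.warn("n_boot < 100: bootstrap p-value will be unstable", stacklevel=2)
    auc_a = roc_auc(probs_a, labels)
    auc_b = roc_auc(probs_b, labels)
    diff = auc_a - auc_b

    if np.array_equal(probs_a, probs_b):
        return {
            "p": 1.0,
            "auc_a": auc_a,
            "auc_b": auc_b,
            "diff": 0.0,
            "boot_sd": 0.0,
            "n_boot": n_boot,
            "n_skipped": 0,
        }

    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    ip = rng.integers(0, pos.size, size=(n_boot, pos.size))
    ineg = rng.integers(0, neg.size, size=(n_boot, neg.size))
    boot_a = _auc_rows(probs_a[pos][ip], probs_a[neg][ineg])
    boot_b = _auc_rows(probs_b[pos][ip], probs_b[neg][ineg])
    diffs = boot_a - boot_b
    ok = np.isfinite(diffs)
    n_skipped = int((~ok).sum())
    diffs = diffs[ok]
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    if method == "normal":
        if sd == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(diff) / sd)))
    elif method == "percentile":
        lo = float(np.mean(diffs <= 0.0))
        hi = float(np.mean(diffs >= 0.0))
        p = float(min(1.0, 2.0 * min(lo, hi)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "p": p,
        "auc_a": auc_a,
        "auc_b": auc_b,
        "diff": diff,
        "boot_sd": sd,
        "n_boot": n_boot,
        "n_skipped": n_skipped,
    }


def bootstrap_auc_ci(
    probs, labels, n_boot: int = 2000, seed: int | None = None, level: float = 0.95
) -> tuple[float, float]:
    """Stratified-bootstrap percentile CI of a single model's AUC."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(bool)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    ip = rng.integers(0, pos.size, size=(n_boot, pos.size))
    ineg = rng.integers(0, neg.size, size=(n_boot, neg.size))
    aucs = _auc_rows(probs[pos][ip], probs[neg][ineg])
    a = (1.0 - level) / 2.0
    return float(np.quantile(aucs, a)), float(np.quantile(aucs, 1.0 - a))


# ---------------------------------------------------------------------------
# Model-suite orchestration
# ---------------------------------------------------------------------------


@dataclass
class ModelReport:
    """Fitted model suite: per-model ROC reports and pairwise comparisons."""

    models: pd.DataFrame  # one row per model id
    odds_ratios: dict[int, pd.DataFrame]
    comparisons: pd.DataFrame  # models 2..5 vs model 1
    n_pos: int
    n_neg: int
    fitted_probs: dict[int, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def build_predictor_frame(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    adjusted_scores: pd.DataFrame,
    diag_tracks: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the baseline predictive-analysis sample.

    Included subjects are CN at wave 1, have both baseline signature scores
    and a PRS, and have a diagnostic label at the final wave.  The outcome
    ``converted`` is MCI at the final wave.
    """
    final_wave = int(diag_tracks["wave"].max())
    lab = diag_tracks.pivot_table(
        index="subject_id", columns="wave", values="label", aggfunc="first"
    )
    eligible = lab.index[(lab.get(1) == "CN") & lab.get(final_wave).notna()]
    base = cohort[(cohort["wave"] == 1) & cohort["subject_id"].isin(eligible)][
        ["subject_id", "pair_id", "age", "prs"]
    ].copy()

    def wide(tbl: pd.DataFrame, tv_name: str, md_name: str) -> pd.DataFrame:
        w = tbl[tbl["wave"] == 1].pivot_table(
            index="subject_id", columns="modality", values="score"
        )
        return w.rename(
            columns={"thickness_volume": tv_name, "md": md_name}
        ).reset_index()

    base = base.merge(wide(scores, "tv_signature", "md_signature"), on="subject_id")
    base = base.merge(wide(adjusted_scores, "tv_pbad_adj", "md_pbad_adj"), on="subject_id")
    base["converted"] = (
        lab.loc[base["subject_id"], final_wave].to_numpy() == "MCI"
    ).astype(int)
    return base.dropna(
        subset=["age", "prs", "tv_signature", "md_signature", "tv_pbad_adj", "md_pbad_adj"]
    ).reset_index(drop=True)


def run_model_suite(
    frame: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    fdr_q: float = 0.05,
) -> ModelReport:
    """Fit Models 1-5, derive ROC reports and compare each against Model 1.

    The bootstrap seed stream is derived once from ``seed``; comparison
    p-values form the predictive FDR family.
    """
    from adsig.concurrent import fdr_bh  # local import avoids a cycle

    y = frame["converted"].to_numpy()
    pair = frame["pair_id"].to_numpy()
    n_pos = int(y.sum())
    n_neg = int((1 - y).sum())
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(20)]

    rows, ors, probs, notes = [], {}, {}, []
    for mid, predictors in MODEL_SPECS.items():
        fit = fit_risk_model(frame[list(predictors)], y, pair)
        if not fit.converged:
            notes.append(f"model {mid}: optimizer did not report convergence")
        if fit.separation_flag:
            notes.append(f"model {mid}: possible separation")
        p = fit.fitted_probs
        auc = roc_auc(p, y)
        ci = bootstrap_auc_ci(p, y, n_boot=n_boot, seed=child_seeds[mid])
        thr, sens, spec = youden_threshold(p, y)
        conf = confusion_metrics(sens, spec, n_pos, n_neg)
        rows.append(
            {
                "model": mid,
                "predictors": "+".join(predictors),
                "auc": auc,
                "auc_ci_low": ci[0],
                "auc_ci_high": ci[1],
                "threshold": thr,
                "sensitivity": sens,
                "specificity": spec,
                **conf,
                "sigma_pair": fit.sigma,
            }
        )
        ors[mid] = fit.odds_ratios
        probs[mid] = p

    comp_rows = []
    for mid in (2, 3, 4, 5):
        res = bootstrap_auc_compare(
            probs[mid], probs[1], y, n_boot=n_boot, seed=child_seeds[10 + mid]
        )
        comp_rows.append(
            {
                "model": mid,
                "vs": 1,
                "auc_diff": res["diff"],
                "p": res["p"],
                "boot_sd": res["boot_sd"],
            }
        )
    comparisons = pd.DataFrame(comp_rows)
    comparisons["fdr_significant"] = fdr_bh(comparisons["p"].to_numpy(), q=fdr_q)
    return ModelReport(
        models=pd.DataFrame(rows),
        odds_ratios=ors,
        comparisons=comparisons,
        n_pos=n_pos,
        n_neg=n_neg,
        fitted_probs=probs,
        warnings=notes,
    )
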