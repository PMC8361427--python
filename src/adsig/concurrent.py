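"""Concurrent robust-CN vs MCI comparisons via linear mixed models.

Signature scores are compared between groups across waves with a linear
mixed model: fixed effects for group, wave and (initially) their
interaction; random intercepts for twin pair and for subject nested within
pair, so both the twin-dyad correlation and the repeated measures within
subject are absorbed.  When the interaction is non-significant the model is
refit with main effects only, and the group effect is summarized as a
standardized mean difference (SMD, Cohen's-d-like): the model-adjusted
group difference divided by the raw pooled within-group SD of the outcome.

Estimation is delegated to statsmodels ``MixedLM``.  statsmodels does not
provide Satterthwaite denominator degrees of freedom; Wald t-tests use
residual degrees of freedom instead and the result is labelled accordingly
(``df_method='residual'``).  On non-convergence the model falls back to an
independence (OLS) fit flagged as degraded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests


@dataclass
class LmmResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df: float
    df_method: str
    smd: float
    group_term: str
    interaction_p: float | None
    n_obs: int
    n_subjects: int
    converged: bool
    model: str = "lmm"  # 'lmm' or 'ols-fallback'
    warnings: list[str] = field(default_factory=list)

    @property
    def group_p(self) -> float:
        return float(self.pvalues[self.group_term])


def smd_from_difference(diff: float, outcome: np.ndarray, group: np.ndarray) -> float:
    """Adjusted group difference divided by the pooled within-group SD.

    The pooled SD is computed from the raw outcome values,
    ``sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))``.
    """
    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError("SMD needs exactly two groups")
    a = outcome[group == levels[0]]
    b = outcome[group == levels[1]]
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if not pooled > 0:
        raise ValueError("zero pooled outcome SD")
    return float(diff / pooled)


def _fit_mixedlm(df: pd.DataFrame, formula: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            formula,
            data=df,
            groups=df["pair_id"],
            re_formula="1",
            vc_formula={"subject": "0 + C(subject_id)"},
        )
        return model.fit(reml=True, method=["lbfgs", "bfgs"], maxiter=200)


def fit_concurrent_lmm(
    data: pd.DataFrame,
    outcome: str = "score",
    group_col: str = "group",
    include_interaction: bool = True,
    refit_main_if_ns: bool = True,
    alpha: float = 0.05,
) -> LmmResult:
    """Fit the concurrent group-comparison mixed model.

    ``data`` is long format with columns ``outcome``, ``group_col``,
    ``wave``, ``subject_id``, ``pair_id``.  The group factor is coded with
    robust_CN as reference, so a positive group coefficient means
    MCI > robust-CN.
    """
    df = data.dropna(subset=[outcome, group_col, "wave"]).copy()
    levels = sorted(df[group_col].unique(), key=lambda g: g != "robust_CN")
    if len(levels) != 2:
        raise ValueError("concurrent comparison needs exactly two groups")
    df["_group"] = pd.Categorical(df[group_col], categories=levels)
    group_term = f"C(_group)[T.{levels[1]}]"
    notes: list[str] = []

    main = f"{outcome} ~ C(_group) + C(wave)"
    full = main + " + C(_group):C(wave)" if include_interaction else main
    interaction_p: float | None = None
    used = full
    try:
        res = _fit_mixedlm(df, full)
        converged = bool(res.converged)
        if include_interaction:
            inter_terms = [t for t in res.fe_params.index if ":" in t]
            if inter_terms:
                # joint Wald chi-square on the interaction block
                b = res.fe_params[inter_terms].to_numpy()
                cov = res.cov_params().loc[inter_terms, inter_terms].to_numpy()
                chi2 = float(b @ np.linalg.solve(cov, b))
                interaction_p = float(stats.chi2.sf(chi2, len(inter_terms)))
                if refit_main_if_ns and interaction_p > alpha:
                    res = _fit_mixedlm(df, main)
                    used = main
                    converged = bool(res.converged)
        fe = res.fe_params
        bse = res.bse_fe
        model_kind = "lmm"
    except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
        import statsmodels.formula.api as smf

        notes.append(f"mixed model failed ({exc}); degraded independence fit")
        ols = smf.ols(main, data=df).fit()
        fe, bse = ols.params, ols.bse
        used, converged, model_kind = main, True, "ols-fallback"

    n_obs = len(df)
    p = len(fe)
    dof = max(n_obs - p, 1)
    tvals = fe / bse
    pvals = pd.Series(
        2.0 * stats.t.sf(np.abs(tvals.to_numpy()), dof), index=fe.index
    )
    smd = smd_from_difference(
        float(fe[group_term]),
        df[outcome].to_numpy(),
        df["_group"].to_numpy(),
    )
    return LmmResult(
        params=fe,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        df=float(dof),
        df_method="residual",
        smd=smd,
        group_term=group_term,
        interaction_p=interaction_p,
        n_obs=n_obs,
        n_subjects=df["subject_id"].nunique(),
        converged=converged,
        model=model_kind,
        warnings=notes,
    )


def wave_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between the two modality scores at each wave.

    ``scores`` is the long signature table (subject_id, wave, modality,
    score); returns one row per wave with r, p and n over paired complete
    observations.
    """
    wide = scores.pivot_table(
        index=["subject_id", "wave"], columns="modality", values="score"
    ).reset_index()
    rows = []
    for wave, grp in wide.groupby("wave"):
        sub = grp.dropna(subset=["thickness_volume", "md"])
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 paired observations at wave {wave}")
        x = sub["thickness_volume"].to_numpy()
        y = sub["md"].to_numpy()
        if x.std() == 0 or y.std() == 0:
            raise ValueError("constant scores; correlation undefined")
        r, p = stats.pearsonr(x, y)
        rows.append({"wave": wave, "r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def concurrent_group_table(diag_tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-subject analysis group for the concurrent comparison.

    robust-CN subjects keep every attended wave; MCI subjects (including
    converters) are the non-reverting ever-MCI group; reverters are
    excluded entirely.
    """
    status = diag_tracks.drop_duplicates("subject_id")[["subject_id", "status"]]
    status = status[status["status"].isin(["robust_CN", "MCI", "converter"])]
    status = status.assign(
        group=np.where(status["status"] == "robust_CN", "robust_CN", "MCI")
    )
    return status[["subject_id", "group"]]
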