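"""Alzheimer's disease signature scoring.

A signature score is a weighted sum of standardized ROI residuals over 16
region x hemisphere entries: seven bilateral cortical regions (thickness for
the thickness/volume modality, grey-matter MD for the MD modality) plus the
hippocampus (volume, or MD).  Per wave, each ROI measure is residualized on
age and scanner (hippocampal volume additionally on estimated intracranial
volume), the residuals are standardized, weighted by the published ROI
weights and summed, and the resulting composite is z-scored over the
analysis sample at that wave.

The weighted *sum* is used rather than a weight-normalized average: the
final per-wave z-scoring makes the two differ only by a positive scale
factor, so the simpler sum is kept.

Scores can additionally be adjusted for the predicted brain age difference
(PBAD = chronological age - predicted brain age; more negative values mean
an older-appearing brain) by residualizing on PBAD per wave and
re-standardizing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Cortical regions of the signature (FreeSurfer/Desikan-Killiany labels).
CORTICAL_REGIONS = (
    "entorhinal",
    "middletemporal",
    "bankssts",
    "superiortemporal",
    "isthmuscingulate",
    "lateralorbitofrontal",
    "medialorbitofrontal",
)

#: All signature regions; the hippocampus contributes volume (or MD).
SIGNATURE_REGIONS = CORTICAL_REGIONS + ("hippocampus",)

HEMISPHERES = ("lh", "rh")

#: Published signature weights, keyed (region, hemisphere).  Derived in an
#: independent case-control sample to reflect differential regional atrophy
#: rates; the same weights are applied to both modalities.
SIGNATURE_WEIGHTS: dict[tuple[str, str], float] = {
    ("entorhinal", "lh"): 0.626,
    ("entorhinal", "rh"): 0.586,
    ("middletemporal", "lh"): 0.554,
    ("middletemporal", "rh"): 0.496,
    ("bankssts", "lh"): 0.444,
    ("bankssts", "rh"): 0.435,
    ("superiortemporal", "lh"): 0.410,
    ("superiortemporal", "rh"): 0.322,
    ("isthmuscingulate", "lh"): 0.377,
    ("isthmuscingulate", "rh"): 0.387,
    ("lateralorbitofrontal", "lh"): 0.303,
    ("lateralorbitofrontal", "rh"): 0.245,
    ("medialorbitofrontal", "lh"): 0.263,
    ("medialorbitofrontal", "rh"): 0.279,
    ("hippocampus", "lh"): 0.696,
    ("hippocampus", "rh"): 0.621,
}

MODALITIES = ("thickness_volume", "md")


def default_weight_table() -> pd.DataFrame:
    """Return the immutable 16-row weight table (region, hemisphere, weight)."""
    rows = [
        {"region": r, "hemisphere": h, "weight": w}
        for (r, h), w in SIGNATURE_WEIGHTS.items()
    ]
    return pd.DataFrame(rows)


def _weights_dict(weights: pd.DataFrame | None) -> dict[tuple[str, str], float]:
    if weights is None:
        return dict(SIGNATURE_WEIGHTS)
    if len(weights) != 16:
        raise ValueError(f"weight table must have 16 rows, got {len(weights)}")
    if (weights["weight"] <= 0).any():
        raise ValueError("signature weights must be positive")
    return {
        (r.region, r.hemisphere): float(r.weight)
        for r in weights.itertuples(index=False)
    }


def roi_column(modality: str, region: str, hemisphere: str) -> str:
    """Cohort-table column holding the measure for one signature entry."""
    if modality == "thickness_volume":
        if region == "hippocampus":
            return f"volume_hippocampus_{hemisphere}"
        return f"thickness_{region}_{hemisphere}"
    if modality == "md":
        return f"md_{region}_{hemisphere}"
    raise ValueError(f"unknown modality {modality!r}")


def residualize_roi(
    values: np.ndarray,
    age: np.ndarray,
    scanner: np.ndarray | None = None,
    icv: np.ndarray | None = None,
) -> np.ndarray:
    """OLS-residualize an ROI measure on covariates and standardize.

    Parameters
    ----------
    values
        The ROI measure (one wave's worth of subjects).
    age
        Chronological age in years.
    scanner
        Scanner labels, entered as unordered categorical indicators
        (reference level = first label alphabetically).
    icv
        Estimated intracranial volume; included for hippocampal volume only.

    Returns
    -------
    Standardized residuals (mean 0, sample SD 1, ddof=1).

    Raises
    ------
    ValueError
        On fewer than 3 complete observations, a singular design, or
        residuals with (numerically) zero variance.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("residualization needs at least 3 observations")
    cols = [np.ones(n), np.asarray(age, dtype=float)]
    if scanner is not None:
        labels = np.asarray(scanner)
        for lab in sorted(pd.unique(labels))[1:]:  # first label = reference
            cols.append((labels == lab).astype(float))
    if icv is not None:
        cols.append(np.asarray(icv, dtype=float))
    design = np.column_stack(cols)
    if not np.all(np.isfinite(design)) or not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in residualization inputs")
    beta, _, rank, _ = np.linalg.lstsq(design, values, rcond=None)
    if rank < design.shape[1]:
        raise ValueError("singular design in ROI residualization")
    resid = values - design @ beta
    sd = resid.std(ddof=1)
    if not sd > 1e-10 * max(1.0, float(np.abs(values).max())):
        raise ValueError("constant residuals: ROI is fully explained by covariates")
    return resid / sd


def composite_score(
    std_residuals: pd.DataFrame, weights: pd.DataFrame | None = None
) -> pd.Series:
    """Weighted sum of standardized residuals over the 16 signature entries.

    ``std_residuals`` columns are named ``{region}_{hemisphere}``.  Any
    missing entry makes the subject's score missing (the 16 fixed components
    define the signature; no partial reweighting).
    """
    wdict = _weights_dict(weights)
    total = pd.Series(np.zeros(len(std_residuals)), index=std_residuals.index)
    for (region, hemi), w in wdict.items():
        col = f"{region}_{hemi}"
        if col not in std_residuals.columns:
            raise KeyError(f"missing residual column {col!r}")
        total = total + w * std_residuals[col]
    return total


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError("cannot z-score a constant series")
    return (x - x.mean()) / sd


def score_signatures(
    cohort: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    modalities: tuple[str, ...] = MODALITIES,
    icv_adjust_hippocampus: bool = True,
) -> pd.DataFrame:
    """Score the thickness/volume and/or MD signatures for a cohort table.

    Regressions (age + scanner, plus ICV for hippocampal volume) are fit on
    the full analysis sample at each wave; residuals are standardized,
    weighted and summed, and the composite is z-scored within wave.

    Returns a long table ``subject_id, wave, modality, score``.
    """
    wtable = default_weight_table() if weights is None else weights
    out = []
    for modality in modalities:
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        for wave, grp in cohort.groupby("wave"):
            resid = {}
            for region, hemi in _weights_dict(wtable):
                col = roi_column(modality, region, hemi)
                use_icv = (
                    icv_adjust_hippocampus
                    and modality == "thickness_volume"
                    and region == "hippocampus"
                )
                resid[f"{region}_{hemi}"] = residualize_roi(
                    grp[col].to_numpy(),
                    grp["age"].to_numpy(),
                    scanner=grp["scanner"].to_numpy(),
                    icv=grp["icv"].to_numpy() if use_icv else None,
                )
            resid_df = pd.DataFrame(resid, index=grp.index)
            raw = composite_score(resid_df, wtable)
            out.append(
                pd.DataFrame(
                    {
                        "subject_id": grp["subject_id"].to_numpy(),
                        "wave": wave,
                        "modality": modality,
                        "score": _zscore(raw).to_numpy(),
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


def compute_pbad(cohort: pd.DataFrame) -> pd.DataFrame:
    """Predicted brain age difference per subject-wave.

    PBAD = chronological age - predicted brain age; lower (more negative)
    values indicate more advanced brain ageing.
    """
    for col in ("age", "predicted_brain_age"):
        if cohort[col].isna().any():
            raise ValueError(f"missing {col} when computing PBAD")
    return pd.DataFrame(
        {
            "subject_id": cohort["subject_id"].to_numpy(),
            "wave": cohort["wave"].to_numpy(),
            "chronological_age": cohort["age"].to_numpy(),
            "predicted_brain_age": cohort["predicted_brain_age"].to_numpy(),
            "pbad": (cohort["age"] - cohort["predicted_brain_age"]).to_numpy(),
        }
    )


def pbad_adjust(scores: pd.DataFrame, pbad: pd.DataFrame) -> pd.DataFrame:
    """Adjust signature scores for PBAD.

    Per wave and modality, scores are OLS-residualized on PBAD and
    re-standardized; the adjusted score is therefore uncorrelated with PBAD
    in-sample.  Raises if PBAD is constant.
    """
    merged = scores.merge(
        pbad[["subject_id", "wave", "pbad"]], on=["subject_id", "wave"], how="left"
    )
    if merged["pbad"].isna().any():
        raise ValueError("PBAD missing for some subject-wave keys")
    out = merged.copy()
    for (_, _), grp in merged.groupby(["wave", "modality"]):
        p = grp["pbad"].to_numpy()
        if p.std(ddof=1) <= 0:
            raise ValueError("PBAD is constant; adjustment is undefined")
        design = np.column_stack([np.ones(len(grp)), p])
        beta, *_ = np.linalg.lstsq(design, grp["score"].to_numpy(), rcond=None)
        resid = grp["score"].to_numpy() - design @ beta
        sd = resid.std(ddof=1)
        if not sd > 1e-12:
            raise ValueError("scores are a linear function of PBAD")
        out.loc[grp.index, "score"] = resid / sd
    return out.drop(columns="pbad")
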