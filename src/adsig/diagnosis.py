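"""Actuarial (Jak-Bondi) MCI classification with practice/attrition correction.

A subject-wave is labelled MCI when at least one cognitive domain is
impaired, a domain being impaired when 2+ of its tests each fall more than
1.5 SDs below the age- and education-adjusted normative mean (strictly
``z < -1.5``).  Before classification, scores are

1. adjusted for general cognitive ability (GCA) measured at ~age 20, by
   removing the across-subject GCA slope per test and wave (so longstanding
   ability differences are not misread as acquired impairment), and
2. corrected for practice and attrition with the replacement-subjects
   method: returnees' inflation from having seen the tests before is
   estimated as the returnee-vs-replacement difference at the current wave
   minus the attrition effect (returnees' prior-wave mean minus the full
   prior-wave sample mean), and subtracted from returnee scores.

Longitudinal statuses: robust-CN subjects are CN at every attended wave;
subjects who revert from MCI back to CN at a later wave are excluded;
converters are CN at wave 1 and MCI at the final wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from adsig.cohort import DOMAINS, CohortConfig, test_columns

MCI_THRESHOLD = 1.5
MIN_IMPAIRED_TESTS = 2


def cohort_test_scores(cohort: pd.DataFrame, config: CohortConfig | None = None) -> pd.DataFrame:
    """Reshape cohort test columns into a long TestScore table.

    Output columns: subject_id, wave, test_id, domain, normative_z, plus the
    entry_wave needed to flag returnees and replacements.
    """
    cfg = config or CohortConfig()
    cols = [c for c in test_columns(cfg) if c in cohort.columns]
    if not cols:
        cols = [c for c in cohort.columns if c.startswith("test_")]
    long = cohort.melt(
        id_vars=["subject_id", "wave", "entry_wave"],
        value_vars=cols,
        var_name="test_id",
        value_name="normative_z",
    )
    long["domain"] = long["test_id"].str.replace("test_", "", regex=False).str.rsplit(
        "_", n=1
    ).str[0]
    return long


def gca_adjust(test_scores: pd.DataFrame, gca: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Remove the per-test, per-wave GCA slope from normative-z scores.

    Only the slope is removed (``z - b*(gca - mean(gca))``), so the sample
    level relative to the external norms is preserved while adjusted scores
    become uncorrelated with GCA.  Raises if GCA is constant or if a test is
    an exact linear function of GCA (constant residual).
    """
    if isinstance(gca, pd.DataFrame):
        gca = gca.set_index("subject_id")["gca_age20"]
    merged = test_scores.merge(
        gca.rename("gca_age20"), left_on="subject_id", right_index=True, how="left"
    )
    if merged["gca_age20"].isna().any():
        raise ValueError("GCA missing for some subjects")
    out = merged.copy()
    for (_, _), grp in merged.groupby(["test_id", "wave"]):
        g = grp["gca_age20"].to_numpy(dtype=float)
        z = grp["normative_z"].to_numpy(dtype=float)
        if g.std() <= 0:
            raise ValueError("GCA is constant; adjustment is undefined")
        b = np.cov(g, z, ddof=1)[0, 1] / g.var(ddof=1)
        adj = z - b * (g - g.mean())
        if adj.std() <= 1e-12 * max(1.0, np.abs(z).std() + 1.0):
            raise ValueError("scores are an exact function of GCA (constant residual)")
        out.loc[grp.index, "normative_z"] = adj
    return out.drop(columns="gca_age20")


def attrition_effect(returnee_prior: np.ndarray, all_prior: np.ndarray) -> float:
    """Mean(returnees at the prior wave) - mean(all subjects at that wave)."""
    returnee_prior = np.asarray(returnee_prior, dtype=float)
    all_prior = np.asarray(all_prior, dtype=float)
    if returnee_prior.size == 0:
        raise ValueError("empty returnee set")
    if all_prior.size < returnee_prior.size:
        raise ValueError("returnees must be a subset of all prior-wave subjects")
    return float(returnee_prior.mean() - all_prior.mean())


def practice_effect(
    returnee_current_mean: float,
    replacement_current_mean: float,
    attrition: float,
) -> float:
    """Returnee-vs-replacement difference score minus the attrition effect."""
    return float(returnee_current_mean - replacement_current_mean - attrition)


def build_adjustment_ledger(test_scores: pd.DataFrame) -> pd.DataFrame:
    """Estimate practice and attrition effects per test and wave >= 2.

    Returnees at wave w are subjects first tested at an earlier wave;
    replacements are subjects whose first exposure is wave w itself.  Waves
    with no replacement subjects get no ledger row (the practice effect is
    undefined there).
    """
    rows = []
    waves = sorted(test_scores["wave"].unique())
    for test_id, tgrp in test_scores.groupby("test_id"):
        by_wave = {w: g for w, g in tgrp.groupby("wave")}
        for w in waves[1:]:
            cur = by_wave.get(w)
            prev = by_wave.get(w - 1)
            if cur is None or prev is None:
                continue
            returnees = cur[cur["entry_wave"] < w]
            replacements = cur[cur["entry_wave"] == w]
            if returnees.empty or replacements.empty:
                continue
            ret_prior = prev[prev["subject_id"].isin(returnees["subject_id"])]
            att = attrition_effect(
                ret_prior["normative_z"].to_numpy(),
                prev["normative_z"].to_numpy(),
            )
            prac = practice_effect(
                returnees["normative_z"].mean(),
                replacements["normative_z"].mean(),
                att,
            )
            rows.append(
                {
                    "test_id": test_id,
                    "wave": w,
                    "attrition_effect": att,
                    "practice_effect": prac,
                    "returnee_n": len(returnees),
                    "replacement_n": len(replacements),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "test_id",
            "wave",
            "attrition_effect",
            "practice_effect",
            "returnee_n",
            "replacement_n",
        ],
    )


def apply_adjustments(test_scores: pd.DataFrame, ledger: pd.DataFrame) -> pd.DataFrame:
    """Subtract the estimated practice effect from returnee scores.

    First-exposure scores are unchanged.  Raises if a returnee test-wave
    cell has no ledger entry.
    """
    out = test_scores.copy()
    is_returnee = out["wave"] > out["entry_wave"]
    if not is_returnee.any():
        return out
    led = ledger.set_index(["test_id", "wave"])["practice_effect"]
    keys = pd.MultiIndex.from_frame(out.loc[is_returnee, ["test_id", "wave"]])
    effects = led.reindex(keys)
    if effects.isna().any():
        missing = keys[effects.isna().to_numpy()][0]
        raise KeyError(f"no practice-effect ledger entry for {missing}")
    out.loc[is_returnee, "normative_z"] = (
        out.loc[is_returnee, "normative_z"].to_numpy() - effects.to_numpy()
    )
    return out


def classify_wave(
    scores: pd.DataFrame,
    threshold: float = MCI_THRESHOLD,
    min_tests: int = MIN_IMPAIRED_TESTS,
) -> tuple[str | None, frozenset[str]]:
    """Classify one subject-wave from its test scores.

    A domain is impaired iff >= ``min_tests`` of its tests have
    ``normative_z < -threshold`` (strict).  Label is MCI iff any domain is
    impaired.  A domain with fewer than ``min_tests`` scoreable tests is
    indeterminate; the label is None (missing) if any domain is
    indeterminate and no other domain is already impaired.
    """
    impaired = set()
    indeterminate = False
    for domain, grp in scores.groupby("domain"):
        z = grp["normative_z"].to_numpy(dtype=float)
        z = z[np.isfinite(z)]
        if z.size < min_tests:
            indeterminate = True
            continue
        if int((z < -threshold).sum()) >= min_tests:
            impaired.add(domain)
    if impaired:
        return "MCI", frozenset(impaired)
    if indeterminate:
        return None, frozenset()
    return "CN", frozenset()


def classify_all(
    test_scores: pd.DataFrame,
    threshold: float = MCI_THRESHOLD,
    min_tests: int = MIN_IMPAIRED_TESTS,
) -> pd.DataFrame:
    """Vectorized per-subject-wave classification over a long score table."""
    df = test_scores.copy()
    df["impaired"] = (df["normative_z"] < -threshold) & np.isfinite(df["normative_z"])
    df["scored"] = np.isfinite(df["normative_z"])
    agg = (
        df.groupby(["subject_id", "wave", "domain"])
        .agg(n_impaired=("impaired", "sum"), n_scored=("scored", "sum"))
        .reset_index()
    )
    agg["domain_impaired"] = (agg["n_impaired"] >= min_tests) & (
        agg["n_scored"] >= min_tests
    )
    agg["domain_indeterminate"] = agg["n_scored"] < min_tests
    per_sw = (
        agg.groupby(["subject_id", "wave"])
        .agg(
            any_impaired=("domain_impaired", "any"),
            any_indeterminate=("domain_indeterminate", "any"),
        )
        .reset_index()
    )
    impaired_sets = (
        agg[agg["domain_impaired"]]
        .groupby(["subject_id", "wave"])["domain"]
        .apply(lambda s: frozenset(s))
    )
    per_sw["label"] = np.where(
        per_sw["any_impaired"],
        "MCI",
        np.where(per_sw["any_indeterminate"], None, "CN"),
    )
    per_sw["impaired_domains"] = [
        impaired_sets.get((s, w), frozenset())
        for s, w in zip(per_sw["subject_id"], per_sw["wave"])
    ]
    return per_sw[["subject_id", "wave", "label", "impaired_domains"]]


def longitudinal_status(labels: pd.DataFrame, final_wave: int | None = None) -> pd.DataFrame:
    """Derive per-subject longitudinal status from per-wave labels.

    robust_CN: CN at every attended (labelled) wave.
    excluded_reverter: any MCI -> CN transition across attended waves.
    converter: CN at wave 1 and MCI at the final wave (predictive flag).
    MCI: ever MCI otherwise.
    """
    if final_wave is None:
        final_wave = int(labels["wave"].max())
    rows = []
    for subject_id, grp in labels.sort_values("wave").groupby("subject_id"):
        attended = grp[grp["label"].notna()]
        seq = attended["label"].tolist()
        wave_of = dict(zip(attended["wave"], attended["label"]))
        if not seq:
            rows.append({"subject_id": subject_id, "status": None, "converter": False})
            continue
        reverted = any(a == "MCI" and b == "CN" for a, b in zip(seq, seq[1:]))
        is_conv = (
            wave_of.get(1) == "CN" and wave_of.get(final_wave) == "MCI" and not reverted
        )
        if reverted:
            status = "excluded_reverter"
        elif all(lab == "CN" for lab in seq):
            status = "robust_CN"
        elif is_conv:
            status = "converter"
        else:
            status = "MCI"
        rows.append({"subject_id": subject_id, "status": status, "converter": is_conv})
    return pd.DataFrame(rows)


@dataclass
class DiagnosisResult:
    """Per-wave labels plus longitudinal statuses and the adjustment ledger."""

    tracks: pd.DataFrame  # subject_id, wave, label, impaired_domains, status
    status: pd.DataFrame  # subject_id, status, converter
    ledger: pd.DataFrame


def diagnose_cohort(
    cohort: pd.DataFrame,
    config: CohortConfig | None = None,
    threshold: float = MCI_THRESHOLD,
    min_tests: int = MIN_IMPAIRED_TESTS,
    adjust_gca: bool = True,
    adjust_practice: bool = True,
) -> DiagnosisResult:
    """Run the full diagnostic pipeline on a cohort table."""
    scores = cohort_test_scores(cohort, config)
    if adjust_gca:
        gca = cohort.drop_duplicates("subject_id").set_index("subject_id")["gca_age20"]
        scores = gca_adjust(scores, gca)
    ledger = build_adjustment_ledger(scores)
    if adjust_practice and not ledger.empty:
        scores = apply_adjustments(scores, ledger)
    labels = classify_all(scores, threshold=threshold, min_tests=min_tests)
    status = longitudinal_status(labels, final_wave=int(cohort["wave"].max()))
    tracks = labels.merge(status[["subject_id", "status"]], on="subject_id", how="left")
    return DiagnosisResult(tracks=tracks, status=status, ledger=ledger)
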