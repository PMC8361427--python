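"""Synthetic longitudinal twin-cohort generator.

The original cohort (middle-aged male twins followed over three waves about
5.7 years apart, baseline age 51-60, ~12% progressing from cognitively
normal to MCI by the final wave) is access-restricted, so the generator
emulates its statistical structure: twin-pair correlation, per-wave scanner
batches, an AD polygenic risk score ~ N(58.4, 7.5^2), 18 cognitive tests in
6 domains with practice and attrition effects, and latent converters whose
signature-ROI measures are shifted by configured standardized mean
differences (MD up, thickness/volume down) and whose cognition declines by
the final wave.

Group effects enter as latent-group mean shifts on every signature ROI,
scaled in closed form so the *downstream signature* SMD (not the raw-ROI
SMD) matches the configured value: each ROI's standardized measure is
``sqrt(g)*F + sqrt(1-g)*eps`` for a subject-wave global factor F (share
``g``) and per-ROI noise, so a uniform per-ROI shift ``delta`` moves the
weighted composite (weights w, S1 = sum w, S2 = sum w^2) by ``delta*S1``
against a composite SD of ``sqrt(g*S1^2 + (1-g)*S2)``.

Attrition is injected by flagging "low-functioning" subjects (everyone who
will drop out before the final wave, plus replacement entrants marked at the
rate that makes them representative of the prior-wave population) and
depressing their cognitive ability by the configured deficit; practice
effects are a one-time mean shift for returnees.  This construction makes
the replacement-subjects practice estimator unbiased by design.

MD voxel phantoms (3-D arrays of MD values plus grey-matter volume-fraction
maps with known ground truth) are provided as fixtures for the MD
reconstruction operators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from adsig.signatures import (
    CORTICAL_REGIONS,
    HEMISPHERES,
    SIGNATURE_WEIGHTS,
)

#: The six cognitive domains of the diagnostic battery.
DOMAINS = (
    "memory",
    "executive",
    "attention",
    "language",
    "visuospatial",
    "processing_speed",
)

# Plausible ROI-level means for the raw measures (mm, mm^3, 1e-3 mm^2/s).
_THICKNESS_MEAN = {
    "entorhinal": 3.30,
    "middletemporal": 2.90,
    "bankssts": 2.50,
    "superiortemporal": 2.80,
    "isthmuscingulate": 2.40,
    "lateralorbitofrontal": 2.60,
    "medialorbitofrontal": 2.50,
}
_MD_MEAN = {
    "entorhinal": 1.05,
    "middletemporal": 0.95,
    "bankssts": 0.92,
    "superiortemporal": 0.94,
    "isthmuscingulate": 0.98,
    "lateralorbitofrontal": 0.96,
    "medialorbitofrontal": 1.00,
    "hippocampus": 1.02,
}
_THICKNESS_SD = 0.15
_MD_SD = 0.05
_HIPPO_VOL_MEAN = 4200.0
_HIPPO_VOL_SD = 250.0
_ICV_MEAN = 1.55e6
_ICV_SD = 1.3e5
_ICV_HIPPO_SLOPE = 0.0015  # mm^3 hippocampus per mm^3 ICV
_AGE_SLOPE = {"thickness": -0.010, "md": 0.004, "volume": -8.0}
_SCANNER_STEP = {"thickness": 0.03, "md": 0.010, "volume": 40.0}


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the study conditions."""

    seed: int = 0
    n_pairs: int = 300
    p_mz: float = 0.5
    waves: int = 3
    wave_gap_mean: float = 5.7
    wave_gap_sd: float = 0.5
    baseline_age_range: tuple[float, float] = (51.0, 60.0)
    conversion_rate: float = 0.118
    #: group SMDs on the downstream signature scores
    effect_size_md: float = 0.36
    effect_size_tv: float = 0.16
    #: within-pair intraclass correlation of each trait (DZ pairs);
    #: MZ pairs get ``twin_icc + mz_extra_icc``
    twin_icc: float = 0.5
    mz_extra_icc: float = 0.1
    #: variance share of the subject-wave global factor in each ROI measure
    global_share: float = 0.75
    #: share of the global factor that is a stable per-subject component
    subject_share: float = 0.10
    prs_mean: float = 58.4
    prs_sd: float = 7.5
    practice_effect: float = 0.15
    attrition_effect: float = 0.20
    dropout_rate: float = 0.12
    replacement_rate: float | None = None  # defaults to dropout_rate
    scanner_labels: tuple[tuple[str, ...], ...] = (
        ("siemens_15t_a", "siemens_15t_b"),
        ("ge_3t", "siemens_3t"),
        ("ge_3t_a", "ge_3t_b"),
    )
    tests_per_domain: int = 3
    #: target cross-modality (thickness/volume vs MD) factor correlation per wave
    cross_modality_corr: tuple[float, ...] = (-0.28, -0.50, -0.62)
    # cognition
    domain_sd: float = 0.45
    test_noise_sd: float = 0.35
    gca_loading: float = 0.45
    affected_domain_decline: float = 2.2
    general_decline: float = 0.3
    n_affected_domains: int = 2
    #: per-wave drift of everyone's normative scores; 0 because normative
    #: z-scores are age-adjusted by construction
    secular_trend: float = 0.0
    # conversion risk model (log-odds per SD of covariate)
    conversion_age_logodds: float = 0.35
    conversion_prs_logodds: float = 0.30
    # brain-age inputs
    pbad_noise_sd: float = 2.5
    pbad_converter_shift: float = -1.2
    pbad_md_loading: float = -0.8

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.waves < 1:
            raise ValueError("waves must be >= 1")
        for name in ("p_mz", "conversion_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.replacement_rate is not None and not 0.0 <= self.replacement_rate <= 1.0:
            raise ValueError("replacement_rate must be in [0, 1]")
        if not 0.0 < self.global_share <= 1.0:
            raise ValueError("global_share must be in (0, 1]")
        lo, hi = self.baseline_age_range
        if not lo < hi:
            raise ValueError("baseline_age_range must be increasing")
        if len(self.scanner_labels) < self.waves:
            raise ValueError("scanner_labels must cover every wave")
        if (self.twin_icc + self.mz_extra_icc) / self.global_share + self.subject_share > 1.0 + 1e-9:
            raise ValueError(
                "pair + subject factor shares exceed the global-factor variance; "
                "lower twin_icc/mz_extra_icc or raise global_share"
            )
        if not 1 <= self.n_affected_domains <= len(DOMAINS):
            raise ValueError("n_affected_domains out of range")

    @property
    def n_tests(self) -> int:
        return self.tests_per_domain * len(DOMAINS)


def test_columns(config: CohortConfig) -> list[str]:
    """Cohort-table columns holding the cognitive normative-z scores."""
    return [
        f"test_{d}_{k + 1}"
        for d in DOMAINS
        for k in range(config.tests_per_domain)
    ]


def roi_shift_scale(effect_size: float, global_share: float) -> float:
    """Per-ROI standardized shift giving a target signature SMD.

    With weights w (S1 = sum w, S2 = sum w^2) and per-ROI variance split
    ``g`` global / ``1-g`` independent, the composite SD is
    ``sqrt(g*S1^2 + (1-g)*S2)`` and a uniform per-ROI shift ``delta`` moves
    the composite by ``delta*S1``.
    """
    w = np.array(list(SIGNATURE_WEIGHTS.values()))
    s1 = w.sum()
    s2 = (w**2).sum()
    comp_sd = np.sqrt(global_share * s1**2 + (1.0 - global_share) * s2)
    return float(effect_size * comp_sd / s1)


def _pair_structured(
    rng: np.random.Generator,
    pair_of: np.ndarray,
    icc: np.ndarray,
    shape_extra: tuple[int, ...] = (),
) -> np.ndarray:
    """Standard-normal trait with within-pair correlation ``icc`` per subject.

    ``icc`` is per-subject (both members of a pair share the same value).
    ``shape_extra`` appends trailing axes (e.g. waves) of independent noise
    sharing the same pair component.
    """
    n_pairs = pair_of.max() + 1
    shared = rng.standard_normal((n_pairs, *shape_extra))[pair_of]
    indiv = rng.standard_normal((pair_of.size, *shape_extra))
    icc = np.asarray(icc, dtype=float).reshape((-1,) + (1,) * len(shape_extra))
    return np.sqrt(icc) * shared + np.sqrt(1.0 - icc) * indiv


def _global_factor(
    rng: np.random.Generator,
    pair_of: np.ndarray,
    pair_share: np.ndarray,
    subject_share: float,
    waves: int,
) -> np.ndarray:
    """Subject-wave latent factor: pair + stable-subject + wave components."""
    n_pairs = pair_of.max() + 1
    n = pair_of.size
    p = rng.standard_normal(n_pairs)[pair_of]
    b = rng.standard_normal(n)
    w = rng.standard_normal((n, waves))
    ps = np.asarray(pair_share)[:, None]
    rest = 1.0 - ps - subject_share
    return np.sqrt(ps) * p[:, None] + np.sqrt(subject_share) * b[:, None] + np.sqrt(rest) * w


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a long-format cohort table (one row per subject x attended wave).

    Deterministic given ``config.seed``.  The latent conversion label is
    exposed as ``true_group`` (generator-only column).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    W = config.waves
    fd = config.dropout_rate
    rr = config.replacement_rate if config.replacement_rate is not None else fd

    # --- pairs and entry waves -------------------------------------------
    n_repl_pairs = int(round(config.n_pairs * rr)) if W > 1 else 0
    pair_counts = [config.n_pairs] + [n_repl_pairs] * (W - 1)
    entry_wave_pair = np.repeat(np.arange(1, W + 1), pair_counts)
    P = entry_wave_pair.size
    pair_of = np.repeat(np.arange(P), 2)  # subject -> pair index
    N = 2 * P
    entry_wave = entry_wave_pair[pair_of]
    is_mz = rng.random(P) < config.p_mz
    zygosity = np.where(is_mz, "MZ", "DZ")[pair_of]
    icc_subj = np.where(
        is_mz[pair_of], config.twin_icc + config.mz_extra_icc, config.twin_icc
    )

    # --- ages -------------------------------------------------------------
    lo, hi = config.baseline_age_range
    base_age = rng.uniform(lo, hi, P)[pair_of]  # twins share birth year
    gaps = np.clip(
        rng.normal(config.wave_gap_mean, config.wave_gap_sd, (P, max(W - 1, 1))),
        1.0,
        None,
    )[pair_of]
    age = base_age[:, None] + np.concatenate(
        [np.zeros((N, 1)), np.cumsum(gaps, axis=1)[:, : W - 1]], axis=1
    )

    # --- stable subject traits -------------------------------------------
    gca = _pair_structured(rng, pair_of, icc_subj)
    prs = config.prs_mean + config.prs_sd * _pair_structured(rng, pair_of, icc_subj)
    icv = _ICV_MEAN + _ICV_SD * _pair_structured(rng, pair_of, icc_subj)
    education = np.clip(
        np.round(14.0 + 1.3 * gca + 1.8 * rng.standard_normal(N)), 8, 20
    ).astype(int)

    # --- latent conversion -------------------------------------------------
    z_age = (base_age - base_age.mean()) / max(base_age.std(), 1e-9)
    z_prs = (prs - prs.mean()) / max(prs.std(), 1e-9)
    lp = config.conversion_age_logodds * z_age + config.conversion_prs_logodds * z_prs
    rate = config.conversion_rate
    if rate <= 0.0:
        converter = np.zeros(N, dtype=bool)
    elif rate >= 1.0:
        converter = np.ones(N, dtype=bool)
    else:
        alpha = brentq(lambda a: expit(a + lp).mean() - rate, -30.0, 30.0)
        converter = rng.random(N) < expit(alpha + lp)

    # --- attendance, dropout, low-functioning flag ------------------------
    attends = np.arange(1, W + 1)[None, :] >= entry_wave[:, None]
    if W > 1:
        drop_draw = rng.random((N, W - 1)) < fd
        at_risk = attends[:, :-1]
        surv = np.cumprod(np.where(at_risk, ~drop_draw, True), axis=1)
        attends[:, 1:] &= surv.astype(bool)
    ever_drop = ~attends[:, -1]  # dropped out before the final wave
    # Replacement entrants are drawn from the general population, which at the
    # prior wave still contains its dropout-prone tail at rate fd per
    # remaining transition; mark extras so their composition matches it.
    extra_mark = (entry_wave > 1) & (rng.random(N) < fd)
    low_functioning = ever_drop | extra_mark
    ability_offset = -config.attrition_effect * low_functioning.astype(float)

    # --- scanners ----------------------------------------------------------
    scanner = np.empty((N, W), dtype=object)
    scan_step = np.zeros((N, W))
    for w in range(W):
        labels = config.scanner_labels[w]
        idx = rng.integers(len(labels), size=P)[pair_of]
        scanner[:, w] = np.asarray(labels, dtype=object)[idx]
        scan_step[:, w] = idx - (len(labels) - 1) / 2.0

    # --- imaging latent factors -------------------------------------------
    g = config.global_share
    pair_share = icc_subj / g
    f_tv = _global_factor(rng, pair_of, pair_share, config.subject_share, W)
    f_ind = _global_factor(rng, pair_of, pair_share, config.subject_share, W)
    rho = np.array(
        [
            config.cross_modality_corr[min(w, len(config.cross_modality_corr) - 1)]
            for w in range(W)
        ]
    )
    f_md = rho[None, :] * f_tv + np.sqrt(1.0 - rho**2)[None, :] * f_ind

    delta_tv = roi_shift_scale(config.effect_size_tv, g)
    delta_md = roi_shift_scale(config.effect_size_md, g)
    conv_f = converter.astype(float)[:, None]
    shift_tv = -delta_tv * conv_f  # thinner cortex / smaller hippocampus
    shift_md = +delta_md * conv_f  # degraded microstructure

    sqrt_g, sqrt_e = np.sqrt(g), np.sqrt(1.0 - g)
    cols: dict[str, np.ndarray] = {}
    age_c = age - 60.0
    for region in CORTICAL_REGIONS + ("hippocampus",):
        for hemi in HEMISPHERES:
            z_tv = sqrt_g * f_tv + sqrt_e * rng.standard_normal((N, W)) + shift_tv
            z_md = sqrt_g * f_md + sqrt_e * rng.standard_normal((N, W)) + shift_md
            if region == "hippocampus":
                cols[f"volume_hippocampus_{hemi}"] = (
                    _HIPPO_VOL_MEAN
                    + _AGE_SLOPE["volume"] * age_c
                    + _ICV_HIPPO_SLOPE * (icv[:, None] - _ICV_MEAN)
                    + _SCANNER_STEP["volume"] * scan_step
                    + _HIPPO_VOL_SD * z_tv
                )
            else:
                cols[f"thickness_{region}_{hemi}"] = (
                    _THICKNESS_MEAN[region]
                    + _AGE_SLOPE["thickness"] * age_c
                    + _SCANNER_STEP["thickness"] * scan_step
                    + _THICKNESS_SD * z_tv
                )
            cols[f"md_{region}_{hemi}"] = (
                _MD_MEAN[region]
                + _AGE_SLOPE["md"] * age_c
                + _SCANNER_STEP["md"] * scan_step
                + _MD_SD * z_md
            )

    # --- predicted brain age ----------------------------------------------
    pbad = (
        config.pbad_converter_shift * conv_f
        + config.pbad_md_loading * f_md
        + config.pbad_noise_sd * rng.standard_normal((N, W))
    )
    predicted_brain_age = age - pbad

    # --- cognition ----------------------------------------------------------
    ramp = (
        (np.arange(W) / (W - 1))[None, :] if W > 1 else np.zeros((1, W))
    )
    affected = np.zeros((N, len(DOMAINS)), dtype=bool)
    affected[:, 0] = True  # memory is always an affected domain
    if config.n_affected_domains > 1:
        others = np.argsort(
            rng.random((N, len(DOMAINS) - 1)), axis=1
        )[:, : config.n_affected_domains - 1] + 1
        np.put_along_axis(affected, others, True, axis=1)
    is_returnee = attends & (np.arange(1, W + 1)[None, :] > entry_wave[:, None])
    test_cols: dict[str, np.ndarray] = {}
    for d_idx, domain in enumerate(DOMAINS):
        # domain ability: pair 0.30 / stable-subject 0.45 / wave 0.25 split
        dom_factor = _pair_structured(rng, pair_of, np.full(N, 0.30), (W,))
        stable = rng.standard_normal(N)[:, None]
        wavec = rng.standard_normal((N, W))
        dom = (
            np.sqrt(0.30) * dom_factor
            + np.sqrt(0.45) * stable
            + np.sqrt(0.25) * wavec
        )
        decline = conv_f * ramp * (
            config.general_decline
            + config.affected_domain_decline * affected[:, d_idx : d_idx + 1]
        )
        ability = (
            config.gca_loading * gca[:, None]
            + ability_offset[:, None]
            + config.secular_trend * np.arange(W)[None, :]
            - decline
            + config.domain_sd * dom
        )
        for k in range(config.tests_per_domain):
            z = (
                ability
                + config.test_noise_sd * rng.standard_normal((N, W))
                + config.practice_effect * is_returnee
            )
            test_cols[f"test_{domain}_{k + 1}"] = z

    # --- assemble long table ------------------------------------------------
    subj_ids = np.array([f"s{pair_of[i]:05d}{i % 2 + 1}" for i in range(N)])
    pair_ids = np.array([f"p{pair_of[i]:05d}" for i in range(N)])
    rows_i, rows_w = np.nonzero(attends)
    frame = {
        "subject_id": subj_ids[rows_i],
        "pair_id": pair_ids[rows_i],
        "zygosity": zygosity[rows_i],
        "wave": rows_w + 1,
        "entry_wave": entry_wave[rows_i],
        "age": age[rows_i, rows_w],
        "education": education[rows_i],
        "scanner": scanner[rows_i, rows_w],
        "icv": icv[rows_i],
        "prs": prs[rows_i],
        "predicted_brain_age": predicted_brain_age[rows_i, rows_w],
        "gca_age20": gca[rows_i],
        "true_group": np.where(converter[rows_i], "converter", "CN-stable"),
    }
    for name, arr in {**cols, **test_cols}.items():
        frame[name] = arr[rows_i, rows_w]
    df = pd.DataFrame(frame)
    return df.sort_values(["pair_id", "subject_id", "wave"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# MD voxel phantoms
# ---------------------------------------------------------------------------


@dataclass
class MdPhantom:
    """Voxel phantom with known grey-matter MD ground truth."""

    md: np.ndarray  # voxelwise MD (1e-3 mm^2/s)
    gm_fraction: np.ndarray  # grey-matter volume fraction in [0, 1]
    true_gm_md: float


def default_fraction_field(shape: tuple[int, int, int]) -> np.ndarray:
    """Pure-GM interior with a CSF-contaminated rim (fractions < 0.5).

    The outermost voxel layer has GM fraction 0.1, the next layer 0.35; the
    interior is pure grey matter.  The partial-volume weighting zeroes the
    rim, so the weighted ROI estimate recovers the interior value exactly.
    """
    field = np.ones(shape)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = slice(0, 1)
        field[tuple(sl)] = np.minimum(field[tuple(sl)], 0.1)
        sl[ax] = slice(-1, None)
        field[tuple(sl)] = np.minimum(field[tuple(sl)], 0.1)
        if shape[ax] > 3:
            sl[ax] = slice(1, 2)
            field[tuple(sl)] = np.minimum(field[tuple(sl)], 0.35)
            sl[ax] = slice(-2, -1)
            field[tuple(sl)] = np.minimum(field[tuple(sl)], 0.35)
    return field


def generate_md_phantom(
    seed: int,
    shape: tuple[int, int, int] = (16, 16, 16),
    true_gm_md: float = 0.90,
    true_wm_md: float = 0.70,
    true_csf_md: float = 3.00,
    fraction_field: np.ndarray | None = None,
    noise_sd: float = 0.0,
    contaminant: str = "csf",
) -> MdPhantom:
    """Build a voxel MD phantom as a GM/contaminant partial-volume mixture.

    Each voxel's MD is ``f*gm + (1-f)*contaminant`` plus optional Gaussian
    noise, where ``f`` is the grey-matter volume fraction.
    """
    if any(s > 64 for s in shape):
        raise ValueError("phantom shape must be at most 64 per axis")
    if fraction_field is None:
        fraction_field = default_fraction_field(shape)
    fraction_field = np.asarray(fraction_field, dtype=float)
    if fraction_field.shape != tuple(shape):
        raise ValueError("fraction_field shape does not match requested shape")
    if fraction_field.min() < 0.0 or fraction_field.max() > 1.0:
        raise ValueError("volume fractions must lie in [0, 1]")
    other = {"csf": true_csf_md, "wm": true_wm_md}[contaminant]
    md = fraction_field * true_gm_md + (1.0 - fraction_field) * other
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        md = md + rng.normal(0.0, noise_sd, size=md.shape)
    return MdPhantom(md=md, gm_fraction=fraction_field, true_gm_md=float(true_gm_md))


def null_config(**overrides) -> CohortConfig:
    """Config with all injected group effects removed (null cohort)."""
    base = CohortConfig(
        effect_size_md=0.0,
        effect_size_tv=0.0,
        general_decline=0.0,
        affected_domain_decline=0.0,
        pbad_converter_shift=0.0,
    )
    return replace(base, **overrides)
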