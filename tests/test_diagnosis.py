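"""Actuarial MCI classification and practice/attrition correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adsig.cohort import DOMAINS, CohortConfig, generate_cohort
from adsig.diagnosis import (
    apply_adjustments,
    attrition_effect,
    build_adjustment_ledger,
    classify_all,
    classify_wave,
    cohort_test_scores,
    diagnose_cohort,
    gca_adjust,
    longitudinal_status,
    practice_effect,
)


def _score_table(domain_scores: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for domain, zs in domain_scores.items():
        for k, z in enumerate(zs):
            rows.append(
                {
                    "subject_id": "s1",
                    "wave": 1,
                    "test_id": f"test_{domain}_{k + 1}",
                    "domain": domain,
                    "normative_z": z,
                }
            )
    return pd.DataFrame(rows)


def _full_battery(fill: float = 0.0, **overrides) -> dict[str, list[float]]:
    scores = {d: [fill] * 3 for d in DOMAINS}
    scores.update(overrides)
    return scores


class TestClassifyWave:
    def test_two_impaired_memory_tests_give_mci(self):
        label, impaired = classify_wave(
            _score_table(_full_battery(memory=[-1.6, -1.6, 0.0]))
        )
        assert label == "MCI" and impaired == frozenset({"memory"})

    def test_single_deep_deficit_is_not_mci(self):
        label, impaired = classify_wave(
            _score_table(_full_battery(memory=[-2.5, 0.0, 0.0]))
        )
        assert label == "CN" and not impaired

    def test_boundary_minus_1_5_is_not_impaired(self):
        # impairment requires strictly below -1.5
        label, _ = classify_wave(_score_table(_full_battery(memory=[-1.5, -1.5, 0.0])))
        assert label == "CN"

    def test_indeterminate_domain_blocks_cn_label(self):
        scores = _score_table(_full_battery())
        scores = scores[~scores["test_id"].isin(["test_language_1", "test_language_2"])]
        label, _ = classify_wave(scores)
        assert label is None

    def test_impairment_trumps_indeterminate_domain(self):
        scores = _score_table(_full_battery(memory=[-2.0, -2.0, 0.0]))
        scores = scores[~scores["test_id"].isin(["test_language_1", "test_language_2"])]
        label, impaired = classify_wave(scores)
        assert label == "MCI" and "memory" in impaired


@settings(max_examples=100, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_classify_all_matches_per_subject_oracle(seed):
    """The vectorized classifier agrees with a direct per-domain re-count."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(6):
        for d in DOMAINS:
            for k in range(3):
                if rng.random() < 0.05:
                    continue  # missing test
                rows.append(
                    {
                        "subject_id": f"s{s}",
                        "wave": 1,
                        "test_id": f"test_{d}_{k}",
                        "domain": d,
                        "normative_z": rng.normal(-1.0, 1.0),
                    }
                )
    table = pd.DataFrame(rows)
    got = classify_all(table).set_index("subject_id")
    for s, grp in table.groupby("subject_id"):
        label, impaired = classify_wave(grp)
        assert got.loc[s, "label"] == label
        assert got.loc[s, "impaired_domains"] == impaired


@settings(max_examples=60, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_lowering_a_score_never_clears_mci(seed):
    rng = np.random.default_rng(seed)
    table = _score_table({d: list(rng.normal(-1.2, 0.8, 3)) for d in DOMAINS})
    label, _ = classify_wave(table)
    worse = table.copy()
    idx = rng.integers(len(worse))
    worse.loc[idx, "normative_z"] -= rng.uniform(0.1, 2.0)
    label_worse, _ = classify_wave(worse)
    if label == "MCI":
        assert label_worse == "MCI"


class TestLongitudinalStatus:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["CN", "CN", "CN"], "robust_CN"),
            (["CN", "MCI", "CN"], "excluded_reverter"),
            (["CN", "CN", "MCI"], "converter"),
            (["MCI", "MCI", "MCI"], "MCI"),
            (["CN", "MCI", "MCI"], "converter"),
        ],
    )
    def test_status_sequences(self, labels, expected):
        df = pd.DataFrame(
            {"subject_id": "s1", "wave": [1, 2, 3], "label": labels}
        )
        got = longitudinal_status(df, final_wave=3)
        assert got["status"].item() == expected

    def test_missing_wave_is_ignored(self):
        df = pd.DataFrame(
            {"subject_id": "s1", "wave": [1, 2, 3], "label": ["CN", None, "CN"]}
        )
        assert longitudinal_status(df, final_wave=3)["status"].item() == "robust_CN"


# ---------------------------------------------------------------------------
# practice / attrition arithmetic
# ---------------------------------------------------------------------------


def test_attrition_effect_arithmetic():
    assert attrition_effect([10.5, 10.5], [10.5, 10.5, 9.0, 10.5]) == pytest.approx(
        10.5 - 40.5 / 4
    )
    assert attrition_effect([1.0, 2.0], [1.0, 2.0]) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        attrition_effect([], [1.0])


def test_attrition_effect_null_sampling(rng):
    pool = rng.normal(size=5000)
    returnees = rng.choice(pool, size=4000, replace=False)
    se = pool.std() * np.sqrt(1 / 4000 + 1 / 5000)
    assert abs(attrition_effect(returnees, pool)) <= 3 * se


def test_practice_effect_arithmetic():
    assert practice_effect(0.7, 0.0, 0.5) == pytest.approx(0.2)
    assert practice_effect(1.0, 1.0, 0.0) == pytest.approx(0.0)


def test_apply_adjustments_only_touches_returnees():
    scores = pd.DataFrame(
        {
            "subject_id": ["a", "a", "b"],
            "wave": [1, 2, 2],
            "entry_wave": [1, 1, 2],
            "test_id": ["test_memory_1"] * 3,
            "domain": ["memory"] * 3,
            "normative_z": [12.0, 12.0, 12.0],
        }
    )
    ledger = pd.DataFrame(
        {
            "test_id": ["test_memory_1"],
            "wave": [2],
            "attrition_effect": [0.0],
            "practice_effect": [0.2],
            "returnee_n": [1],
            "replacement_n": [1],
        }
    )
    out = apply_adjustments(scores, ledger)
    assert out["normative_z"].tolist() == [12.0, 11.8, 12.0]
    with pytest.raises(KeyError):
        apply_adjustments(scores, ledger.assign(wave=3))


def test_zero_practice_effect_is_identity():
    scores = pd.DataFrame(
        {
            "subject_id": ["a"],
            "wave": [2],
            "entry_wave": [1],
            "test_id": ["test_memory_1"],
            "domain": ["memory"],
            "normative_z": [0.5],
        }
    )
    ledger = pd.DataFrame(
        {
            "test_id": ["test_memory_1"],
            "wave": [2],
            "attrition_effect": [0.1],
            "practice_effect": [0.0],
            "returnee_n": [1],
            "replacement_n": [1],
        }
    )
    assert apply_adjustments(scores, ledger)["normative_z"].item() == 0.5


# ---------------------------------------------------------------------------
# GCA adjustment
# ---------------------------------------------------------------------------


def _gca_frame(rng, slope):
    n = 800
    gca = rng.normal(size=n)
    z = slope * gca + rng.normal(size=n)
    scores = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "wave": 1,
            "entry_wave": 1,
            "test_id": "test_memory_1",
            "domain": "memory",
            "normative_z": z,
        }
    )
    gca_s = pd.Series(gca, index=[f"s{i}" for i in range(n)], name="gca_age20")
    gca_s.index.name = "subject_id"
    return scores, gca_s


def test_gca_adjust_noop_when_uncorrelated(rng):
    scores, gca = _gca_frame(rng, slope=0.0)
    adjusted = gca_adjust(scores, gca)
    assert np.corrcoef(adjusted["normative_z"], scores["normative_z"])[0, 1] > 0.99


def test_gca_adjust_orthogonalizes(rng):
    scores, gca = _gca_frame(rng, slope=0.6)
    adjusted = gca_adjust(scores, gca)
    assert abs(np.corrcoef(adjusted["normative_z"], gca.to_numpy())[0, 1]) < 1e-10


def test_gca_adjust_exact_function_errors(rng):
    scores, gca = _gca_frame(rng, slope=1.0)
    scores["normative_z"] = gca.to_numpy()
    with pytest.raises(ValueError):
        gca_adjust(scores, gca)


# ---------------------------------------------------------------------------
# parameter recovery on synthetic cohorts
# ---------------------------------------------------------------------------


def test_practice_effect_recovered(large_cohort):
    """The injected 0.15-SD practice effect is recovered by the
    replacement-subjects estimator to within 0.03 SD."""
    scores = cohort_test_scores(large_cohort)
    ledger = build_adjustment_ledger(scores)
    assert not ledger.empty
    recovered = ledger["practice_effect"].mean()
    assert abs(recovered - 0.15) <= 0.03


def test_conversion_rate_recovered_and_practice_bias_direction():
    """After practice/attrition adjustment the pipeline conversion rate sits
    within 3 binomial SDs of the configured 11.8%; without the adjustment
    the inflated returnee scores mask decline, so the rate is biased low."""
    cohort = generate_cohort(CohortConfig(seed=11, n_pairs=2000))
    adjusted = diagnose_cohort(cohort)
    unadjusted = diagnose_cohort(cohort, adjust_practice=False)

    def conv_rate(res):
        lab = res.tracks.pivot_table(
            index="subject_id", columns="wave", values="label", aggfunc="first"
        )
        eligible = lab[(lab[1] == "CN") & lab[3].notna()]
        return (eligible[3] == "MCI").mean(), len(eligible)

    rate, n = conv_rate(adjusted)
    sd = np.sqrt(0.118 * 0.882 / n)
    assert abs(rate - 0.118) <= 3 * sd
    rate_unadj, _ = conv_rate(unadjusted)
    assert rate_unadj < rate  # practice inflation hides wave-3 impairment


def test_diagnose_cohort_statuses_partition(small_cohort):
    res = diagnose_cohort(small_cohort)
    assert set(res.status["status"].dropna()) <= {
        "robust_CN",
        "MCI",
        "converter",
        "excluded_reverter",
    }
    # converters are CN at wave 1 and MCI at the final wave
    conv_ids = res.status.loc[res.status["converter"], "subject_id"]
    lab = res.tracks.pivot_table(
        index="subject_id", columns="wave", values="label", aggfunc="first"
    )
    assert (lab.loc[conv_ids, 1] == "CN").all()
    assert (lab.loc[conv_ids, 3] == "MCI").all()
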