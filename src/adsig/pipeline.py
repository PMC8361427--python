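"""End-to-end staged pipeline with a run manifest.

Stages (in dependency order): ``simulate`` -> ``md_extract`` ->
``signatures`` -> ``diagnose`` -> ``concurrent`` -> ``predict``.  Each
stage reads and writes plain files under a run directory; a JSON manifest
records the config hash, the seed, and a SHA-256 digest of every input and
output.  On re-run, a stage executes only when one of its files has changed
since the manifest was written (or an upstream stage re-executed), so a
repeated run with identical config is a no-op and corrupting an
intermediate file re-executes exactly that file's producer and everything
downstream of it.

All randomness is seeded from one root seed; stage sub-seeds are derived
with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from adsig import cohort as cohort_mod
from adsig import concurrent as conc_mod
from adsig import diagnosis as diag_mod
from adsig import mdrecon
from adsig import prediction as pred_mod
from adsig import signatures as sig_mod

MANIFEST_NAME = "run_manifest.json"
STAGE_ORDER = ["simulate", "md_extract", "signatures", "diagnose", "concurrent", "predict"]

STAGE_FILES = {
    "simulate": ([], ["cohort.csv"]),
    "md_extract": ([], ["phantom_md.csv"]),
    "signatures": (["cohort.csv"], ["signatures.csv"]),
    "diagnose": (["cohort.csv"], ["diagnosis.csv", "ledger.csv"]),
    "concurrent": (["cohort.csv", "signatures.csv", "diagnosis.csv"], ["concurrent.json"]),
    "predict": (
        ["cohort.csv", "signatures.csv", "diagnosis.csv"],
        ["prediction.json", "roc_points.tsv", "model_table.txt"],
    ),
}


def default_config() -> dict:
    cfg = dataclasses.asdict(cohort_mod.CohortConfig())
    return {
        "seed": 0,
        "cohort": cfg,
        "n_boot": 2000,
        "fdr_q": 0.05,
        "mci_threshold": 1.5,
        "min_impaired_tests": 2,
    }


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the default config with a YAML/JSON file and explicit overrides."""
    cfg = default_config()
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            user = yaml.safe_load(text)
        else:
            user = json.loads(text)
        for key, val in (user or {}).items():
            if key == "cohort":
                cfg["cohort"].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key == "cohort":
            cfg["cohort"].update(val)
        else:
            cfg[key] = val
    return cfg


def _cohort_config(cfg: dict, seed: int) -> cohort_mod.CohortConfig:
    kw = dict(cfg["cohort"])
    kw["seed"] = seed
    for name in ("baseline_age_range", "cross_modality_corr"):
        if name in kw and kw[name] is not None:
            kw[name] = tuple(kw[name])
    if "scanner_labels" in kw:
        kw["scanner_labels"] = tuple(tuple(w) for w in kw["scanner_labels"])
    return cohort_mod.CohortConfig(**kw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(len(STAGE_ORDER))
    return {
        name: int(k.generate_state(1)[0] % (2**31))
        for name, k in zip(STAGE_ORDER, kids)
    }


# ---------------------------------------------------------------------------
# Stage bodies
# ---------------------------------------------------------------------------


def _stage_simulate(run_dir: Path, cfg: dict, seed: int) -> None:
    table = cohort_mod.generate_cohort(_cohort_config(cfg, seed))
    table.to_csv(run_dir / "cohort.csv", index=False)


def _stage_md_extract(run_dir: Path, cfg: dict, seed: int) -> None:
    phantom = cohort_mod.generate_md_phantom(seed=seed)
    full = phantom.gm_fraction >= 0.0
    # the median/MAD weighting needs clean voxels in the majority, so the
    # subcortical ROI excludes the outermost (mostly-CSF) rim layer
    inner = phantom.gm_fraction >= 0.35
    rows = [
        {
            "roi": "phantom_cortical",
            "estimate": mdrecon.phantom_roi_md(
                phantom.md, phantom.gm_fraction, full, method="cortical"
            ),
            "unweighted_mean": float(phantom.md[full].mean()),
            "true_gm_md": phantom.true_gm_md,
        },
        {
            "roi": "phantom_subcortical",
            "estimate": mdrecon.phantom_roi_md(
                phantom.md,
                phantom.gm_fraction,
                inner,
                method="subcortical",
                roi_mad=0.02,
            ),
            "unweighted_mean": float(phantom.md[inner].mean()),
            "true_gm_md": phantom.true_gm_md,
        },
    ]
    pd.DataFrame(rows).to_csv(run_dir / "phantom_md.csv", index=False)


def _stage_signatures(run_dir: Path, cfg: dict, seed: int) -> None:
    cohort = pd.read_csv(run_dir / "cohort.csv")
    scores = sig_mod.score_signatures(cohort)
    pbad = sig_mod.compute_pbad(cohort)
    adjusted = sig_mod.pbad_adjust(scores, pbad)
    merged = scores.merge(
        adjusted.rename(columns={"score": "score_pbad_adj"}),
        on=["subject_id", "wave", "modality"],
    )
    merged.to_csv(run_dir / "signatures.csv", index=False)


def _stage_diagnose(run_dir: Path, cfg: dict, seed: int) -> None:
    cohort = pd.read_csv(run_dir / "cohort.csv")
    result = diag_mod.diagnose_cohort(
        cohort,
        threshold=cfg["mci_threshold"],
        min_tests=cfg["min_impaired_tests"],
    )
    tracks = result.tracks.copy()
    tracks["impaired_domains"] = tracks["impaired_domains"].apply(
        lambda s: ";".join(sorted(s))
    )
    tracks.to_csv(run_dir / "diagnosis.csv", index=False)
    result.ledger.to_csv(run_dir / "ledger.csv", index=False)


def _stage_concurrent(run_dir: Path, cfg: dict, seed: int) -> None:
    cohort = pd.read_csv(run_dir / "cohort.csv")
    sig = pd.read_csv(run_dir / "signatures.csv")
    diag = pd.read_csv(run_dir / "diagnosis.csv")
    groups = conc_mod.concurrent_group_table(diag)
    keys = cohort[["subject_id", "wave", "pair_id"]]
    out: dict = {"outcomes": {}, "wave_correlations": None}
    pvals, labels = [], []
    for modality in sig_mod.MODALITIES:
        for col, tag in (("score", "raw"), ("score_pbad_adj", "pbad_adjusted")):
            sub = (
                sig[sig["modality"] == modality][["subject_id", "wave", col]]
                .rename(columns={col: "score"})
                .merge(groups, on="subject_id")
                .merge(keys, on=["subject_id", "wave"])
            )
            res = conc_mod.fit_concurrent_lmm(sub)
            name = f"{modality}_{tag}"
            out["outcomes"][name] = {
                "smd": res.smd,
                "group_t": float(res.tvalues[res.group_term]),
                "group_p": res.group_p,
                "df": res.df,
                "df_method": res.df_method,
                "interaction_p": res.interaction_p,
                "n_obs": res.n_obs,
                "n_subjects": res.n_subjects,
                "model": res.model,
            }
            pvals.append(res.group_p)
            labels.append(name)
    rejected = conc_mod.fdr_bh(np.array(pvals), q=cfg["fdr_q"])
    for name, rej in zip(labels, rejected):
        out["outcomes"][name]["fdr_significant"] = bool(rej)
    analysis_ids = groups["subject_id"]
    corr = conc_mod.wave_correlations(sig[sig["subject_id"].isin(analysis_ids)])
    out["wave_correlations"] = corr.to_dict(orient="records")
    (run_dir / "concurrent.json").write_text(json.dumps(out, indent=2, sort_keys=True))


def _stage_predict(run_dir: Path, cfg: dict, seed: int) -> None:
    cohort = pd.read_csv(run_dir / "cohort.csv")
    sig = pd.read_csv(run_dir / "signatures.csv")
    diag = pd.read_csv(run_dir / "diagnosis.csv")
    scores = sig[["subject_id", "wave", "modality", "score"]]
    adjusted = sig[["subject_id", "wave", "modality", "score_pbad_adj"]].rename(
        columns={"score_pbad_adj": "score"}
    )
    frame = pred_mod.build_predictor_frame(cohort, scores, adjusted, diag)
    report = pred_mod.run_model_suite(
        frame, n_boot=cfg["n_boot"], seed=seed, fdr_q=cfg["fdr_q"]
    )
    payload = {
        "n_pos": report.n_pos,
        "n_neg": report.n_neg,
        "models": report.models.to_dict(orient="records"),
        "comparisons": report.comparisons.to_dict(orient="records"),
        "odds_ratios": {
            str(k): v.to_dict(orient="records") for k, v in report.odds_ratios.items()
        },
        "warnings": report.warnings,
    }
    (run_dir / "prediction.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    from sklearn.metrics import roc_curve

    frames = []
    y = frame["converted"].to_numpy()
    for mid, probs in report.fitted_probs.items():
        fpr, tpr, thr = roc_curve(y, probs)
        frames.append(
            pd.DataFrame({"model": mid, "fpr": fpr, "tpr": tpr, "threshold": thr})
        )
    pd.concat(frames, ignore_index=True).to_csv(
        run_dir / "roc_points.tsv", sep="\t", index=False
    )

    cols = ["model", "auc", "sensitivity", "specificity", "accuracy", "ppv", "npv"]
    table = report.models[cols].round(2)
    (run_dir / "model_table.txt").write_text(table.to_string(index=False) + "\n")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "md_extract": _stage_md_extract,
    "signatures": _stage_signatures,
    "diagnose": _stage_diagnose,
    "concurrent": _stage_concurrent,
    "predict": _stage_predict,
}


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path = "runs/default",
    stages: list[str] | None = None,
    force: bool = False,
) -> dict:
    """Execute the pipeline stages, skipping those whose files are unchanged.

    Returns the run manifest (also written to ``run_manifest.json``).
    """
    cfg = config or default_config()
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    wanted = stages or STAGE_ORDER
    unknown = set(wanted) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    seeds = _stage_seeds(int(cfg["seed"]))
    cfg_hash = _config_hash(cfg)

    manifest_path = run_dir / MANIFEST_NAME
    previous = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != cfg_hash:
            previous = {}  # config changed: everything is stale

    recorded = previous.get("stages", {})
    manifest = {
        "config_hash": cfg_hash,
        "seed": int(cfg["seed"]),
        "stage_seeds": seeds,
        "stages": dict(recorded),
        "executed": [],
        "warnings": [],
    }

    dirty_files: set[str] = set()
    for name in STAGE_ORDER:
        if name not in wanted:
            continue
        inputs, outputs = STAGE_FILES[name]
        rec = recorded.get(name)

        def dirty(rel: str) -> bool:
            if rel in dirty_files:
                return True
            path = run_dir / rel
            if not path.exists():
                return True
            if rec is None:
                return True
            want = {**rec.get("inputs", {}), **rec.get("outputs", {})}.get(rel)
            return want is None or _digest(path) != want

        must_run = force or rec is None or any(dirty(rel) for rel in inputs + outputs)
        if must_run:
            _STAGE_FUNCS[name](run_dir, cfg, seeds[name])
            manifest["executed"].append(name)
            dirty_files.update(outputs)
            manifest["stages"][name] = {
                "inputs": {rel: _digest(run_dir / rel) for rel in inputs},
                "outputs": {rel: _digest(run_dir / rel) for rel in outputs},
                "seed": seeds[name],
            }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
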