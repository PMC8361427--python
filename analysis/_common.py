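"""Shared settings for the analysis drivers.

One run directory, one root seed, one cohort size.  Every driver executes
its pipeline stage (plus any stale upstream stages) through the manifest
runner, so re-running a later script never silently uses stale inputs.
"""

from pathlib import Path

from adsig.pipeline import default_config

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "run"


def analysis_config() -> dict:
    cfg = default_config()
    cfg["seed"] = 1
    cfg["cohort"]["n_pairs"] = 1000
    cfg["n_boot"] = 2000
    return cfg
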