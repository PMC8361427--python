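"""Demonstrate partial-volume-weighted MD extraction on a voxel phantom.

The phantom has a pure-grey-matter interior and a CSF-contaminated rim.
The bisquare volume-fraction weighting recovers the interior MD exactly;
the unweighted ROI mean is pulled far upward by the rim.  Writes
results/run/phantom_md.csv.
"""

import pandas as pd

from _common import RUN_DIR, analysis_config
from adsig.pipeline import run_pipeline

run_pipeline(analysis_config(), RUN_DIR, stages=["md_extract"])
table = pd.read_csv(RUN_DIR / "phantom_md.csv")
print(table.round(4).to_string(index=False))
bias = table["unweighted_mean"] - table["true_gm_md"]
print(f"\nunweighted bias: {bias.iloc[0]:+.3f} x 1e-3 mm^2/s; "
      "weighted estimators are exact on the noise-free phantom")
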