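"""Run the full simulate -> correct -> fit -> ROI -> stats pipeline.

One reproducible end-to-end run on a small phantom: writes NIfTI maps,
ROI masks, a cohort table and a statistics report into ./scratch/pipeline_demo,
and prints the manifest summary.  Re-running with the same seed yields
byte-identical tables.
"""

import pandas as pd

from cswater.pipeline import RunConfig, run_pipeline

config = RunConfig(
    out_dir="scratch/pipeline_demo",
    seed=1,
    shape=(16, 16, 8),        # small demo phantom
    snr_te1=2000.0,
    lambda_laplacian=0.0,     # independent fits to keep the demo quick
    n_subjects=40,
)
manifest = run_pipeline(config)
print("stages:", ", ".join(manifest["stages"]))
print("artifacts:", ", ".join(sorted(manifest["artifacts"])))

means = pd.read_csv("scratch/pipeline_demo/regional_means.csv")
print("\nregional water-fraction means (phantom truth: WM CSFF 0.05):")
print(means.to_string(index=False))
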