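"""Full pipeline: phantom -> T1 maps -> AHA table -> Deming regression.

Simulates the complete study on the digital phantom: fits pre- and
post-contrast R1 maps from noisy SPGR images, builds the per-segment
regional table (delta-R1, SWT, tissue class), cuts a virtual
mid-ventricular slice into four sectors with emulated ICP-MS masses, and
fits the orthogonal (Deming) regression of delta-R1 on Gd concentration.
The slope estimates the effective in vivo relaxivity.  Takes ~40 s.
"""

import json

import pandas as pd

from cardiot1.pipeline import RunConfig, run_pipeline

config = RunConfig(out_dir="scratch/example_run", seed=11)
manifest = run_pipeline(config)
print("stages:", {k: v["status"] for k, v in manifest["stages"].items()})

table = pd.read_csv("scratch/example_run/regional_table.csv")
print(table[["segment_id", "delta_r1", "swt_percent", "tissue_class"]].round(3).to_string(index=False))

fit = json.loads(open("scratch/example_run/deming_fit.json").read())
print(f"\nDeming slope = {fit['slope_mM_s']:.3f} mM^-1 s^-1 "
      f"(phantom truth {config.phantom.relaxivity_mM_s}),  r = {fit['pearson_r']:.3f}")
print("The recovered slope is the effective in vivo relaxivity; on real "
      "tissue it comes out well below the in vitro calibration value.")
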