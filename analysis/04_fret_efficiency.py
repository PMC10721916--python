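"""Sensitized-emission FRET round-trip at the unloaded-sensor efficiency.

Generates seeded three-channel scenes whose ground-truth efficiency is the
unloaded tension-sensor calibration value (28.6%), calibrates bleed-through
and the G factor from matching single-fluorophore and fusion-construct
scenes, computes pixelwise efficiency maps, and averages over segmented
adhesions per scene.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from catchquant.workflows import fret_roundtrip

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

result = fret_roundtrip(n_scenes=50, seed=1, d_bt=0.6, a_bt=0.2)
pd.DataFrame({"scene": np.arange(result["n_scenes"]),
              "mean_efficiency_pct": result["per_scene_pct"]}).to_csv(
    OUT / "fret_roundtrip.csv", index=False)

print(f"scenes: {result['n_scenes']} (ground truth 28.6%, d_bt = 0.6, a_bt = 0.2)")
print(f"cell-averaged FRET efficiency: {result['mean_efficiency_pct']:.2f}%")
print(f"per-scene spread (sd): {np.std(result['per_scene_pct']):.3f} percentage points")
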