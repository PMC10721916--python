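"""Intra-adhesion tension gradients and tension-sensitive exchange dynamics.

First half: renders adhesions carrying a planted efficiency ramp, extracts
smoothed line profiles and spatial variation indices (positive SVI = tension
skewed away from the cell centre).  Second half: fits photobleaching
recovery curves over a parameter grid and regresses recovery half-time on
sensor efficiency to detect tension-stabilised exchange.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from catchquant import fa_morphometrics
from catchquant.frap_dynamics import fit_recovery, normalize_recovery, tension_dynamics_regression
from catchquant.synth import FaSpec, FrapSpec, SceneSpec, gen_frap_series, gen_fret_scene
from catchquant.tension_spatial import fa_line_profile, svi_table

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# --- tension gradients: distal halves loaded (low FRET) -----------------
fas = [
    FaSpec(center=(60, 100), axes=(26, 10), orientation=0.0, efficiency=0.3,
           efficiency_gradient=0.004),
    FaSpec(center=(140, 100), axes=(26, 10), orientation=0.0, efficiency=0.3,
           efficiency_gradient=-0.004),
]
_, truth = gen_fret_scene(SceneSpec(shape=(200, 200), fas=fas, poisson_noise=False,
                                    read_noise_sd=0.0))
records = fa_morphometrics(truth["labels"])
svis = svi_table(truth["labels"], truth["efficiency"], records)
svis.to_csv(OUT / "svi.csv", index=False)
print("spatial variation indices (planted distal tension -> positive):")
print(svis[["id", "svi"]].round(4).to_string(index=False))
prof = fa_line_profile(truth["efficiency"], records.iloc[0])
print(f"line profile of adhesion 1: {len(prof.positions)} samples, "
      f"E from {prof.efficiency_smooth[0]:.3f} to {prof.efficiency_smooth[-1]:.3f}")

# --- FRAP fits and the FRET-FRAP regression -----------------------------
rows = []
for r_f in (0.6, 0.8, 1.0):
    for tau in (10.0, 30.0, 60.0):
        est = []
        for rep in range(25):
            s = gen_frap_series(FrapSpec(r_f=r_f, r_0=0.2, k=np.log(2) / tau, noise_sd=0.02,
                                         seed=rep * 13 + int(tau) + int(r_f * 10) * 997))
            t, y = normalize_recovery(s)
            est.append(fit_recovery(t, y).tau_half)
        rows.append({"r_f": r_f, "tau_true_s": tau, "tau_mean_s": np.mean(est),
                     "bias_pct": 100 * (np.mean(est) / tau - 1)})
fits = pd.DataFrame(rows)
fits.to_csv(OUT / "frap_recovery_grid.csv", index=False)
print("\nFRAP half-time recovery (25 replicates per cell):")
print(fits.round(2).to_string(index=False))

# tension-stabilised exchange: tau rises as E falls (higher load)
rng = np.random.default_rng(11)
e = rng.uniform(0.15, 0.30, size=24)
tau = 80.0 - 180.0 * e + rng.normal(0, 3.0, size=e.size)
res = tension_dynamics_regression(tau, e)
print(f"\nFRET-FRAP regression: slope {res.slope:.1f} s per unit E "
      f"(SE {res.slope_se:.1f}), F-test p = {res.p_value:.2e}")
pd.DataFrame({"tau_half_s": tau, "efficiency": e}).to_csv(OUT / "fret_frap_pairs.csv", index=False)
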