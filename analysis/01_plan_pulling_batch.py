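"""Enumerate the constant-force pulling batch.

Plans the full force sweep of the pulling study: 0-150 pN sampled at 1 pN in
the pointed, barbed and normal directions with ten replicates per condition,
and the discrete energy step that realises a ~1 pN force at a 1 A pull step.
"""

from pathlib import Path

from catchquant import force_from_energy_step, plan_pulling_batch

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

plan = plan_pulling_batch(0.0, 150.0, 1.0, ("pointed", "barbed", "normal"), replicates=10)
plan.entries.to_csv(OUT / "pulling_plan.csv", index=False)

print(f"forces: {plan.n_forces} (0-150 pN at 1 pN)")
print(f"directions: {plan.n_directions}, replicates: {plan.n_replicates}")
print(f"total pulling simulations: {plan.n_simulations}")
print(f"energy step for ~1 pN at dR = 1 A: f(dE=0.015 kcal/mol) = "
      f"{force_from_energy_step(0.015, 1.0):.3f} pN")
print(f"plan written to {OUT / 'pulling_plan.csv'}")
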