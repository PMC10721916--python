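# catchquant

Quantitative analysis of **directional catch bonding** between the vinculin
tail domain (Vt) and F-actin, and of its cellular readouts.

Vinculin links integrin-based focal adhesions (FAs) to the actomyosin
cytoskeleton and forms a *directional catch bond* with F-actin: the
Vt:F-actin interaction strengthens under force, but only when the force
points toward the pointed end of the polar actin filament.  Probing this
behaviour takes two very different kinds of bespoke computation, both
implemented here as a tested, reusable library:

- **Simulation side** — mining constant-force pulling trajectories of the
  Vt:F-actin complex: geometric hydrogen-bond detection (D–A ≤ 3.5 Å,
  ≤ 30° from linearity at the donor), per-bond occupancy tables, the
  fraction of native bonds maintained under load, salt-bridge/vdW/buried-
  area interface metrics, binding energies ΔG from potential-of-mean-force
  profiles, Kabsch superposition RMSD, and the classification of
  **DAFS bonds** (directionally asymmetric force-strengthening: occupancy
  ratio > 1.1 over the unloaded state within the 124–132 pN dissociation
  window, in the pointed direction only).
- **Cell-imaging side** — the FRET tension-sensor pipeline: three-channel
  sensitized-emission efficiency maps
  (F_c = I_f − d_bt·I_d − a_bt·I_a, E = (F_c/G)/(I_d + F_c/G)),
  adhesion segmentation and equivalent-ellipse morphometrics (central
  moments → axis lengths, axis ratio, orientation), PR/SF maturity
  features and a decision-tree classifier, intra-adhesion tension
  gradients (line profiles and the FRET⁻¹-weighted spatial variation
  index), photobleaching-recovery fitting
  (R(t) = R_f − (R_f − R_0)e^(−kt), τ½ = ln2/k) with the τ½-vs-E
  tension-sensitivity regression, and structure-tensor stress-fiber
  orientation with Voronoi-based FA–SF coalignment (θ_Rel = |θ_SF − θ_FA|).

Every input the pipeline consumes can be produced by seeded synthetic
generators with attached ground truth (`catchquant.synth`), so the whole
chain is testable end to end without simulations or microscopy.

## Layout

```
src/catchquant/      library: mdcontacts, fretquant, fa_morphometrics,
                     tension_spatial, frap_dynamics, cytoskeleton,
                     synth (generators), workflows (end-to-end pipelines)
analysis/            numbered narrative drivers writing tables to results/
tests/               pytest suite incl. end-to-end acceptance checks
docs/methods.md      models, defaults, numerical choices, limitations
scripts/acceptance.py  reproduction script (below)
```

## Worked example

Plant a ten-bond pulling study with two true DAFS bonds and call them back:

```python
from catchquant import classify_dafs, occupancy_table
from catchquant.synth import gen_pulling_ensemble
from catchquant.workflows import dafs_benchmark_spec

spec, planted = dafs_benchmark_spec(seed=0)
ensemble = gen_pulling_ensemble(spec)
table = occupancy_table(ensemble)
for call in classify_dafs(table):
    if call.is_dafs:
        print(call.bond, call.lifetime, call.response_by_direction)
```

prints exactly the two planted bonds:

```
VT:DON900|ACTIN:ACC100 long {'pointed': 'strengthening', 'barbed': 'weakening', 'normal': 'weakening'}
VT:DON901|ACTIN:ACC101 long {'pointed': 'strengthening', 'barbed': 'stable', 'normal': 'stable'}
```

— a native long-lived bond that strengthens only toward the pointed end,
and a bond formed only under pointed-direction load; both are the
signatures of directional catch bonding.  Running the analysis drivers in
order tells the same story at full scale, e.g.

```
$ python analysis/01_plan_pulling_batch.py
total pulling simulations: 4530
$ python analysis/03_pmf_binding_energy.py
ordering: pointed > barbed > normal
$ python analysis/04_fret_efficiency.py
cell-averaged FRET efficiency: 28.62%
```

4530 is the full 0–150 pN × 3 directions × 10 replicates sweep; the ΔG
ordering is the energetic face of directional asymmetry; and 28.62% is the
unloaded-sensor calibration efficiency read back through the complete
sensitized-emission pipeline (bleed-through and G-factor calibration,
pixelwise efficiency, adhesion segmentation) on 50 noisy synthetic image
sets whose ground truth is 28.6%.

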