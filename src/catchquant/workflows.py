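"""End-to-end pipelines composing the generators with the analysis modules.

These are the study-condition workflows the analysis scripts and the
reproduction script run: each generates its own inputs (seeded), executes
the full measurement path, and returns summary numbers.
"""

from __future__ import annotations

import numpy as np

from .fa_morphometrics import segment_fas
from .fretquant import calibrate_bleedthrough, calibrate_g, fret_efficiency_map
from .synth.scene import (
    UNLOADED_SENSOR_EFFICIENCY,
    FaSpec,
    SceneSpec,
    gen_calibration_scenes,
    gen_fret_scene,
)

__all__ = [
    "random_fa_layout",
    "fret_roundtrip",
    "dafs_benchmark_spec",
    "dafs_benchmark",
    "UNLOADED_SENSOR_EFFICIENCY",
]


def random_fa_layout(
    rng: np.random.Generator,
    shape: tuple[int, int] = (200, 200),
    n_fas: int = 6,
    efficiency: float = UNLOADED_SENSOR_EFFICIENCY,
) -> list[FaSpec]:
    """Non-overlapping elliptical adhesions scattered over the cell interior."""
    h, w = shape
    fas: list[FaSpec] = []
    attempts = 0
    while len(fas) < n_fas and attempts < 200:
        attempts += 1
        major = rng.uniform(22, 38)
        minor = rng.uniform(8, 13)
        cx = rng.uniform(0.22 * w, 0.78 * w)
        cy = rng.uniform(0.22 * h, 0.78 * h)
        # keep the whole ellipse inside the default elliptical cell outline
        rho = np.hypot((cx - w / 2) / (0.44 * w), (cy - h / 2) / (0.44 * h))
        if rho > 0.72:
            continue
        if any(np.hypot(cx - f.center[0], cy - f.center[1]) < 0.75 * (major + f.axes[0]) / 2 + 6 for f in fas):
            continue
        fas.append(
            FaSpec(center=(cx, cy), axes=(major, minor),
                   orientation=rng.uniform(-np.pi / 2, np.pi / 2),
                   efficiency=efficiency, peak=rng.uniform(6000, 9000))
        )
    return fas


DAFS_FORCES = (0.0, 124.0, 128.0, 132.0)


def _occ(pointed, barbed, normal):
    return {
        "pointed": dict(zip(DAFS_FORCES, pointed)),
        "barbed": dict(zip(DAFS_FORCES, barbed)),
        "normal": dict(zip(DAFS_FORCES, normal)),
    }


def dafs_benchmark_spec(
    n_frames: int = 50,
    n_replicates: int = 10,
    flip_probability: float = 0.0,
    seed: int = 0,
):
    """Planted ten-bond occupancy study for the DAFS caller.

    Occupancy profiles emulate the census observed in pulling simulations of
    the Vt:F-actin complex over the dissociation force window: two bonds
    strengthen only toward the pointed end (one native long-lived, one formed
    under load like the non-native helix-5 contacts), long- and
    medium-duration bonds hold stable occupancy, short-lived bonds weaken,
    and control bonds strengthen in every direction or in a single other
    direction.  Ten replicates per condition mirror the simulation batch
    design.  Returns the trajectory spec and the planted DAFS plan ids.
    """
    from .synth.trajectory import BondPlan, TrajectorySpec

    bonds = [
        BondPlan("dafs_native", _occ([20, 30, 45, 60], [20, 16, 14, 12], [20, 16, 14, 12]), native=True),
        BondPlan("dafs_induced", _occ([0, 30, 40, 50], [0, 0, 0, 0], [0, 0, 0, 0])),
        BondPlan("long_stable_a", _occ([50] * 4, [50] * 4, [50] * 4), native=True),
        BondPlan("long_stable_b", _occ([46] * 4, [46] * 4, [46] * 4), native=True),
        BondPlan("medium_stable", _occ([30] * 4, [30] * 4, [30] * 4), native=True),
        BondPlan("short_weakening", _occ([30, 10, 6, 2], [30, 10, 6, 2], [30, 10, 6, 2]), native=True),
        BondPlan("all_strengthening", _occ([30, 45, 60, 70], [30, 45, 60, 70], [30, 45, 60, 70])),
        BondPlan("barbed_only", _occ([30] * 4, [30, 45, 60, 70], [30, 20, 12, 8])),
        BondPlan("medium_weakening", _occ([36, 26, 18, 12], [36, 26, 18, 12], [36, 26, 18, 12]), native=True),
        BondPlan("normal_only", _occ([30, 24, 20, 18], [30] * 4, [30, 50, 60, 66])),
    ]
    spec = TrajectorySpec(
        n_frames=n_frames,
        bonds=bonds,
        forces=DAFS_FORCES,
        n_replicates=n_replicates,
        flip_probability=flip_probability,
        seed=seed,
    )
    return spec, ("dafs_native", "dafs_induced")


def dafs_benchmark(seed: int = 0, flip_probability: float = 0.0) -> dict:
    """Run the planted study end to end and score the DAFS caller."""
    from .mdcontacts import classify_dafs, occupancy_table
    from .synth.trajectory import gen_pulling_ensemble

    spec, true_plan_ids = dafs_benchmark_spec(flip_probability=flip_probability, seed=seed)
    ensemble = gen_pulling_ensemble(spec)
    true_ids = {ensemble.metadata["pair_ids"][p] for p in true_plan_ids}
    table = occupancy_table(ensemble)
    calls = classify_dafs(table)
    called = {c.bond for c in calls if c.is_dafs}
    tp = len(called & true_ids)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(true_ids)
    return {"precision": precision, "recall": recall, "called": sorted(called),
            "n_bonds": len(calls)}


def fret_roundtrip(
    n_scenes: int = 50,
    seed: int = 0,
    efficiency: float = UNLOADED_SENSOR_EFFICIENCY,
    d_bt: float = 0.6,
    a_bt: float = 0.2,
    g_factor: float = 2.0,
    use_segmentation: bool = True,
) -> dict:
    """Generate scenes at a known sensor efficiency and measure it back.

    For each seeded scene: render the three-channel image set, calibrate
    bleed-through from matching single-fluorophore scenes, calibrate G from
    two constant-efficiency fusion-construct scenes, compute the pixelwise
    efficiency map, segment the adhesions from the acceptor channel and
    average the measured efficiency over adhesion pixels (one cell-averaged
    value per scene).  Returns the grand mean as a percentage along with
    per-scene values.
    """
    rng = np.random.default_rng(seed)
    per_scene = []
    for i in range(n_scenes):
        scene_seed = int(rng.integers(0, 2**31 - 1))
        scene_rng = np.random.default_rng(scene_seed)
        fas = random_fa_layout(scene_rng, efficiency=efficiency)
        spec = SceneSpec(fas=fas, d_bt=d_bt, a_bt=a_bt, g_factor=g_factor, seed=scene_seed)
        triplet, truth = gen_fret_scene(spec)
        donor_only, acceptor_only = gen_calibration_scenes(spec)
        calibration = calibrate_bleedthrough(donor_only, acceptor_only, min_level=50.0)
        low, _ = gen_fret_scene(
            SceneSpec(fas=(), cyto_efficiency=0.10, d_bt=d_bt, a_bt=a_bt,
                      g_factor=g_factor, cyto_level=3000.0, seed=scene_seed + 7)
        )
        high, _ = gen_fret_scene(
            SceneSpec(fas=(), cyto_efficiency=0.50, d_bt=d_bt, a_bt=a_bt,
                      g_factor=g_factor, cyto_level=3000.0, seed=scene_seed + 8)
        )
        calibration.g = calibrate_g(low, high, calibration, min_level=50.0)
        emap = fret_efficiency_map(triplet, calibration)
        if use_segmentation:
            labels = segment_fas(triplet.acceptor, truth["cell_mask"])
            mask = (labels > 0) & emap.valid
        else:
            mask = (truth["labels"] > 0) & emap.valid
        per_scene.append(float(emap.efficiency[mask].mean()))
    values = np.asarray(per_scene)
    return {
        "mean_efficiency_pct": float(100.0 * values.mean()),
        "per_scene_pct": 100.0 * values,
        "n_scenes": n_scenes,
    }
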