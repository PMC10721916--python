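"""Pulling-trajectory generator with planted hydrogen-bond occupancies.

Each planted bond is a donor-H-acceptor triad whose geometry is placed
either inside the detection criterion (2.9 A donor-acceptor distance, near
zero deviation from linearity) or far outside it (6 A), frame by frame.
Which frames carry the bond is decided by exact quota placement --
``round(occupancy x n_frames)`` present frames, seeded shuffle of their
positions -- so the realised occupancy equals the request without sampling
noise and downstream classifier tests are deterministic.  An optional
frame-flip probability re-introduces Bernoulli noise for robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..trajectory import DIRECTIONS, Topology, Trajectory, TrajectoryEnsemble

_BOND_SPACING = 30.0  # A between planted triads; far beyond every cutoff
_PRESENT_DA = 2.9  # A, inside the 3.5 A criterion
_ABSENT_DA = 6.0  # A, outside every contact cutoff


@dataclass(frozen=True)
class BondPlan:
    """One planted bond: a donor residue on Vt, an acceptor residue on actin.

    ``occupancy`` maps direction -> {force (pN) -> target occupancy (%)}.
    """

    pair_id: str
    occupancy: Mapping[str, Mapping[float, float]]
    native: bool = False


@dataclass(frozen=True)
class TrajectorySpec:
    n_frames: int
    bonds: Sequence[BondPlan]
    forces: Sequence[float]
    directions: Sequence[str] = DIRECTIONS
    n_replicates: int = 1
    flip_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0, 1]")
        for bond in self.bonds:
            for per_force in bond.occupancy.values():
                for occ in per_force.values():
                    if not 0.0 <= occ <= 100.0:
                        raise ValueError(f"occupancy {occ} outside [0, 100] for {bond.pair_id}")


def _build_topology(bonds: Sequence[BondPlan]) -> Topology:
    rows = []
    donor_pairs = []
    acceptors = []
    for i, bond in enumerate(bonds):
        base = 3 * i
        rows.append(
            {"name": "N", "element": "N", "res_id": 900 + i, "res_name": "DON",
             "chain": "V", "molecule": "VT", "charge": 0}
        )
        rows.append(
            {"name": "H", "element": "H", "res_id": 900 + i, "res_name": "DON",
             "chain": "V", "molecule": "VT", "charge": 0}
        )
        rows.append(
            {"name": "O", "element": "O", "res_id": 100 + i, "res_name": "ACC",
             "chain": "A", "molecule": "ACTIN", "charge": 0}
        )
        donor_pairs.append((base, base + 1))
        acceptors.append(base + 2)
    return Topology(atoms=pd.DataFrame(rows), donor_pairs=np.array(donor_pairs), acceptors=np.array(acceptors))


def _frame_coords(present: np.ndarray, n_bonds: int) -> np.ndarray:
    """Coordinates of all triads for one frame given per-bond presence flags."""
    coords = np.zeros((3 * n_bonds, 3))
    for i in range(n_bonds):
        x0 = _BOND_SPACING * i
        coords[3 * i] = (x0, 0.0, 0.0)  # donor heavy atom
        coords[3 * i + 1] = (x0 + 1.0, 0.0, 0.0)  # hydrogen, along D->A
        da = _PRESENT_DA if present[i] else _ABSENT_DA
        coords[3 * i + 2] = (x0 + da, 0.0, 0.0)
    return coords


def gen_pulling_ensemble(spec: TrajectorySpec) -> TrajectoryEnsemble:
    """Generate a pulling ensemble realising the planted occupancy profiles.

    The returned ensemble carries ``metadata["planted_occupancy"]``, a table
    with the realised occupancy per (bond pair id, direction, force) --
    identical to the request whenever ``occupancy x n_frames`` is an integer
    and ``flip_probability`` is zero -- and ``metadata["pair_ids"]`` mapping
    each plan's ``pair_id`` to the detector's residue-pair identifier.
    """
    topology = _build_topology(spec.bonds)
    n_bonds = len(spec.bonds)
    pair_ids = {
        bond.pair_id: f"VT:DON{900 + i}|ACTIN:ACC{100 + i}" for i, bond in enumerate(spec.bonds)
    }
    rng = np.random.default_rng(spec.seed)
    trajectories = []
    truth_rows = []
    for direction in spec.directions:
        for force in spec.forces:
            presence = np.zeros((spec.n_replicates, spec.n_frames, n_bonds), dtype=bool)
            for b, bond in enumerate(spec.bonds):
                occ = float(bond.occupancy.get(direction, {}).get(force, 0.0))
                quota = int(round(occ / 100.0 * spec.n_frames))
                for r in range(spec.n_replicates):
                    order = rng.permutation(spec.n_frames)
                    presence[r, order[:quota], b] = True
            if spec.flip_probability > 0:
                flips = rng.random(presence.shape) < spec.flip_probability
                presence ^= flips
            for r in range(spec.n_replicates):
                coords = np.stack([_frame_coords(presence[r, f], n_bonds) for f in range(spec.n_frames)])
                trajectories.append(Trajectory(coords=coords, force=force, direction=direction, replicate=r))
            realised = presence.mean(axis=(0, 1)) * 100.0
            for b, bond in enumerate(spec.bonds):
                truth_rows.append(
                    {
                        "bond": pair_ids[bond.pair_id],
                        "plan_id": bond.pair_id,
                        "direction": direction,
                        "force": force,
                        "occupancy": realised[b],
                        "native": bond.native,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return TrajectoryEnsemble(
        topology=topology,
        trajectories=trajectories,
        metadata={"planted_occupancy": truth, "pair_ids": pair_ids, "spec": spec},
    )


def reference_frame(spec: TrajectorySpec) -> np.ndarray:
    """Unloaded reference coordinates in which every *native* bond is formed."""
    present = np.array([bond.native for bond in spec.bonds])
    return _frame_coords(present, len(spec.bonds))
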