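"""Containers for constant-force pulling trajectories of a two-molecule complex.

The substrate of the contact analysis is an ensemble of coordinate frames of
the vinculin-tail (Vt) : F-actin complex, one trajectory per
(pulling force, pulling direction, replicate).  Atom metadata carries the
hydrogen-bond roles (donor heavy atom with its attached hydrogen, acceptor)
and formal side-chain charges needed by the contact detectors; no force-field
information is stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIRECTIONS = ("pointed", "barbed", "normal")


@dataclass(frozen=True)
class Topology:
    """Static atom metadata shared by every frame of an ensemble.

    Parameters
    ----------
    atoms : pandas.DataFrame
        One row per atom with columns ``name`` (atom name), ``element``,
        ``res_id`` (int), ``res_name``, ``chain`` and ``molecule`` (one of
        ``"VT"`` / ``"ACTIN"``, i.e. which side of the interface the atom
        belongs to) and ``charge`` (formal side-chain charge sign,
        -1 / 0 / +1).
    donor_pairs : ndarray of shape (n_donors, 2)
        Integer index pairs ``(heavy_donor, hydrogen)``.  A negative hydrogen
        index marks a donor whose hydrogen is missing; such donors are
        skipped (with a warning) by the detector.
    acceptors : ndarray of shape (n_acceptors,)
        Indices of hydrogen-bond acceptor heavy atoms.
    """

    atoms: pd.DataFrame
    donor_pairs: np.ndarray
    acceptors: np.ndarray

    def __post_init__(self):
        required = {"name", "element", "res_id", "res_name", "chain", "molecule", "charge"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ValueError(f"topology table missing columns: {sorted(missing)}")
        object.__setattr__(self, "donor_pairs", np.asarray(self.donor_pairs, dtype=int).reshape(-1, 2))
        object.__setattr__(self, "acceptors", np.asarray(self.acceptors, dtype=int).reshape(-1))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_tag(self, index: int) -> str:
        """Stable residue identifier, e.g. ``"VT:ARG976"``."""
        row = self.atoms.iloc[index]
        return f"{row['molecule']}:{row['res_name']}{row['res_id']}"


@dataclass
class Trajectory:
    """Frames of one pulling run at a fixed force and direction."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    force: float  # pN
    direction: str
    replicate: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class TrajectoryEnsemble:
    """A set of pulling trajectories over a common topology."""

    topology: Topology
    trajectories: list[Trajectory]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.topology.n_atoms
        for traj in self.trajectories:
            if traj.coords.shape[1] != n:
                raise ValueError("inconsistent atom count across trajectories")

    def grouped(self) -> dict[tuple[float, str], list[Trajectory]]:
        """Trajectories pooled by (force, direction) across replicates."""
        groups: dict[tuple[float, str], list[Trajectory]] = {}
        for traj in self.trajectories:
            groups.setdefault((traj.force, traj.direction), []).append(traj)
        return groups
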