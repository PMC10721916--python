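"""File round-trips for the pipeline's interchange formats.

Trajectories travel as multi-model PDB (via biotite), images as TIFF (via
tifffile), PMF profiles as two-column whitespace text, and tables as CSV
through pandas directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .trajectory import Topology, Trajectory, TrajectoryEnsemble


def write_trajectory_pdb(path, trajectory: Trajectory, topology: Topology) -> None:
    """Write one trajectory as a multi-model PDB file."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms, _ = trajectory.coords.shape
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = trajectory.coords.astype(np.float32)
    tab = topology.atoms
    stack.chain_id = tab["chain"].to_numpy(dtype="U4")
    stack.res_id = tab["res_id"].to_numpy(dtype=int)
    stack.res_name = tab["res_name"].to_numpy(dtype="U5")
    stack.atom_name = tab["name"].to_numpy(dtype="U6")
    stack.element = tab["element"].to_numpy(dtype="U2")
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def read_trajectory_pdb(path, force: float = 0.0, direction: str = "pointed",
                        molecule_of_chain: dict[str, str] | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a (multi-)model PDB into coordinates and an atom table.

    Returns ``(coords (n_models, n_atoms, 3), atoms)`` where the atom table
    carries name/element/res_id/res_name/chain plus a ``molecule`` column
    mapped from chain ids (identity when no mapping is given).  Role flags
    (donors/acceptors/charges) are topology-level decisions left to the
    caller.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None, altloc="first")
    atoms = pd.DataFrame(
        {
            "name": stack.atom_name,
            "element": stack.element,
            "res_id": stack.res_id,
            "res_name": stack.res_name,
            "chain": stack.chain_id,
        }
    )
    mapping = molecule_of_chain or {}
    atoms["molecule"] = [mapping.get(c, c) for c in atoms["chain"]]
    atoms["charge"] = 0
    return np.asarray(stack.coord, dtype=float), atoms


def write_image(path, image: np.ndarray, as_uint16: bool = True) -> None:
    img = np.asarray(image)
    if as_uint16:
        img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    else:
        img = img.astype(np.float32)
    tifffile.imwrite(path, img)


def read_image(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_pmf(path, xi: np.ndarray, energy: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([xi, energy]), fmt="%.6f")
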