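"""Readers and writers for trajectories, feature matrices and manifests.

Two trajectory formats are supported: multi-model PDB (MODEL/ENDMDL
delimited, parsed with biotite) and a flat CSV dialect with one row per
atom per frame.  The CSV dialect is the minimal interchange format: it
carries explicit per-atom masses and radii, so toy systems with
non-chemical beads round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import (ATOMIC_MASSES, FEATURE_COLUMNS, METADATA_COLUMNS,
                        VDW_RADII, Topology, Trajectory)

__all__ = [
    "read_pdb_trajectory",
    "write_pdb_trajectory",
    "read_csv_trajectory",
    "write_csv_trajectory",
    "read_feature_matrix",
    "write_feature_matrix",
]

CSV_TRAJECTORY_COLUMNS = [
    "frame_index", "monomer_id", "residue_number", "residue_name",
    "atom_name", "element", "mass", "radius", "x", "y", "z",
]


def _lookup(table: dict, element: str, kind: str) -> float:
    key = element.upper()
    if key not in table:
        raise ValueError(f"no {kind} tabulated for element {element!r}")
    return table[key]


def read_pdb_trajectory(path: str | Path, frame_interval_ps: float = 20.0
                        ) -> Trajectory:
    """Read a multi-model PDB file; chain ids become monomer ids.

    Masses and Bondi-style vdW radii are assigned from the element column.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    elements = [str(e) for e in stack.element]
    topology = Topology(
        atom_names=np.asarray(stack.atom_name, dtype=object),
        elements=np.asarray(elements, dtype=object),
        residue_numbers=np.asarray(stack.res_id, dtype=np.int64),
        residue_names=np.asarray(stack.res_name, dtype=object),
        monomer_ids=np.asarray(stack.chain_id, dtype=object),
        masses=np.array([_lookup(ATOMIC_MASSES, e, "mass") for e in elements]),
        radii=np.array([_lookup(VDW_RADII, e, "vdW radius") for e in elements]),
    )
    return Trajectory(topology, np.asarray(stack.coord, dtype=float),
                      frame_interval_ps, source={"path": str(path),
                                                 "format": "pdb"})


def write_pdb_trajectory(traj: Trajectory, path: str | Path
                         ) -> dict[str, str]:
    """Write a trajectory as a multi-model PDB (one MODEL per frame).

    PDB chain ids are single characters, so monomer ids are mapped to
    letters in order of first appearance; the mapping is returned.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    chain_map: dict[str, str] = {}
    for m in traj.topology.monomer_ids:
        if str(m) not in chain_map:
            if len(chain_map) >= len(letters):
                raise ValueError("too many monomers for PDB chain ids")
            chain_map[str(m)] = letters[len(chain_map)]

    n_atoms = traj.topology.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    stack.chain_id = np.asarray(
        [chain_map[str(m)] for m in traj.topology.monomer_ids])
    stack.res_id = traj.topology.residue_numbers
    stack.res_name = np.asarray(
        [str(r)[:5] for r in traj.topology.residue_names])
    stack.atom_name = np.asarray(
        [str(a)[:6] for a in traj.topology.atom_names])
    stack.element = np.asarray([str(e) for e in traj.topology.elements])
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
    return chain_map


def read_csv_trajectory(path: str | Path, frame_interval_ps: float = 20.0
                        ) -> Trajectory:
    """Read the flat CSV trajectory dialect (one row per atom per frame)."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV trajectory lacks columns {missing}")
    frames = np.sort(df["frame_index"].unique())
    first = df[df["frame_index"] == frames[0]].reset_index(drop=True)
    topology = Topology(
        atom_names=first["atom_name"].to_numpy(dtype=object),
        elements=first["element"].to_numpy(dtype=object),
        residue_numbers=first["residue_number"].to_numpy(),
        residue_names=first["residue_name"].to_numpy(dtype=object),
        monomer_ids=first["monomer_id"].astype(str).to_numpy(dtype=object),
        masses=first["mass"].to_numpy(dtype=float),
        radii=first["radius"].to_numpy(dtype=float),
    )
    n_atoms = len(first)
    coords = np.empty((len(frames), n_atoms, 3))
    for k, f in enumerate(frames):
        block = df[df["frame_index"] == f]
        if len(block) != n_atoms:
            raise ValueError(
                f"frame {f} has {len(block)} atoms, expected {n_atoms}")
        coords[k] = block[["x", "y", "z"]].to_numpy(dtype=float)
    return Trajectory(topology, coords, frame_interval_ps,
                      source={"path": str(path), "format": "csv"})


def write_csv_trajectory(traj: Trajectory, path: str | Path) -> None:
    top = traj.topology
    blocks = []
    for k in range(traj.n_frames):
        block = pd.DataFrame({
            "frame_index": k,
            "monomer_id": top.monomer_ids,
            "residue_number": top.residue_numbers,
            "residue_name": top.residue_names,
            "atom_name": top.atom_names,
            "element": top.elements,
            "mass": top.masses,
            "radius": top.radii,
            "x": traj.coords[k, :, 0],
            "y": traj.coords[k, :, 1],
            "z": traj.coords[k, :, 2],
        })
        blocks.append(block)
    pd.concat(blocks, ignore_index=True).to_csv(path, index=False)


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix as CSV: 8 feature columns + provenance.

    Computation metadata (radii set, probe, cutoff) travels in a JSON
    sidecar comment line so round-trips preserve it.
    """
    cols = [c for c in FEATURE_COLUMNS if c in matrix.columns]
    cols += [c for c in METADATA_COLUMNS if c in matrix.columns]
    path = Path(path)
    with path.open("w") as fh:
        if matrix.attrs:
            fh.write("# " + json.dumps(matrix.attrs, sort_keys=True) + "\n")
        matrix[cols].to_csv(fh, index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    attrs = {}
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("#"):
            attrs = json.loads(first[1:].strip())
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    df.attrs.update(attrs)
    return df
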