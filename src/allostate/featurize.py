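"""Turn coordinate trajectories into per-frame descriptor matrices.

Each frame of a two-monomer system is reduced to an 8-vector of local
descriptors, four per monomer:

* cross-monomer contacts between the N-terminal strap (residues 85-108)
  of one monomer and the NTD core (residues 109-308) of the other,
  counted over heavy-atom pairs closer than 4.5 A;
* solvent-accessible surface area (SASA) of the ATP-lid side chains
  (residues 191-217), probe radius 1.4 A;
* distance between the centers of mass of the R417 guanidinium group and
  the gamma-phosphate of the bound nucleotide;
* SASA of the S582 hydroxymethyl side chain.

Descriptors are rigid-motion invariant, so trajectories need no prior
superposition.  Coordinates are assumed whole (no periodic wrapping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "FEATURE_COLUMNS",
    "METADATA_COLUMNS",
    "Topology",
    "Trajectory",
    "SelectionGroup",
    "SelectionSpec",
    "default_selections",
    "count_cross_contacts",
    "shrake_rupley_sasa",
    "com_distance",
    "select_frame_indices",
    "featurize_frame",
    "featurize_trajectory",
    "VDW_RADII",
    "ATOMIC_MASSES",
]

#: Canonical residue ranges of the descriptor machinery (author numbering
#: of the zebrafish TRAP1 crystal structure; inclusive on both ends).
STRAP_RANGE = (85, 108)
NTD_CORE_RANGE = (109, 308)
ATP_LID_RANGE = (191, 217)
R417_RESIDUE = 417
S582_RESIDUE = 582

GUANIDINIUM_ATOMS = ("NE", "CZ", "NH1", "NH2")
GAMMA_PHOSPHATE_ATOMS = ("PG", "O1G", "O2G", "O3G")
SERINE_SIDECHAIN_ATOMS = ("CB", "OG")
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

DEFAULT_CONTACT_CUTOFF = 4.5  # A, strict upper bound
DEFAULT_PROBE_RADIUS = 1.4  # A
DEFAULT_N_SPHERE_POINTS = 960
MAX_COORDINATE_SPAN = 500.0  # A; larger spans indicate unwrapped PBC images

FEATURE_COLUMNS = (
    "contacts_strap_ntd_1",
    "contacts_strap_ntd_2",
    "lid_sasa_1",
    "lid_sasa_2",
    "r417_gpo4_dist_1",
    "r417_gpo4_dist_2",
    "s582_sasa_1",
    "s582_sasa_2",
)
METADATA_COLUMNS = ("label", "system_id", "replicate_id", "ligand_id", "time_ps")

# Bondi-style van der Waals radii (A); recorded in output metadata.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "NA": 2.27, "K": 2.75, "FE": 1.94,
}

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "MG": 24.305, "ZN": 65.38, "NA": 22.990, "K": 39.098, "FE": 55.845,
}


class SelectionError(ValueError):
    """A selection resolved to an invalid atom group."""


@dataclass
class Topology:
    """Shared per-atom annotation of every frame in a trajectory.

    All fields are parallel arrays of length ``n_atoms``.  ``monomer_ids``
    distinguish the two protomers (conventionally ``"buckled"`` and
    ``"straight"``); nucleotides and ligands may carry their own ids.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    monomer_ids: np.ndarray
    masses: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for name in ("elements", "residue_numbers", "residue_names",
                     "monomer_ids", "masses", "radii"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology field {name!r} length mismatch")
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(
            [str(e).upper() for e in self.elements], dtype=object)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.monomer_ids = np.asarray(self.monomer_ids, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be positive")
        if np.any(self.radii <= 0):
            raise ValueError("all atom radii must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def is_heavy(self) -> np.ndarray:
        return self.elements != "H"


@dataclass
class Trajectory:
    """Ordered frames over a fixed atom roster.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Angstrom.  Frame k
    carries the timestamp ``(k + 1) * frame_interval_ps``: the first saved
    frame sits one save interval after the trajectory origin, so an 80 ns
    span saved every 20 ps holds exactly 4000 frames.
    """

    topology: Topology
    coords: np.ndarray
    frame_interval_ps: float
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("coords atom count does not match topology")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame interval must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        span = self.coords.reshape(-1, 3)
        extent = span.max(axis=0) - span.min(axis=0)
        if np.any(extent > MAX_COORDINATE_SPAN):
            raise ValueError(
                f"coordinate span {extent.max():.1f} A exceeds "
                f"{MAX_COORDINATE_SPAN} A; input looks periodic-image wrapped")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def frame_times_ps(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 1) * self.frame_interval_ps


SubsetRule = Literal["all-heavy", "side-chain-heavy", "atom-names"]


@dataclass(frozen=True)
class SelectionGroup:
    """One named atom group: a monomer, residue ranges, and a subset rule."""

    name: str
    monomer_id: str
    residue_ranges: tuple[tuple[int, int], ...]
    rule: SubsetRule = "all-heavy"
    atom_names: tuple[str, ...] = ()
    residue_names: tuple[str, ...] = ()

    def resolve(self, topology: Topology, *, allow_hydrogen: bool = False
                ) -> np.ndarray:
        """Return sorted atom indices; error if empty or (unless allowed)
        containing hydrogens."""
        mask = topology.monomer_ids == self.monomer_id
        if self.residue_ranges:
            in_range = np.zeros(topology.n_atoms, dtype=bool)
            for lo, hi in self.residue_ranges:
                in_range |= ((topology.residue_numbers >= lo)
                             & (topology.residue_numbers <= hi))
            mask &= in_range
        if self.residue_names:
            wanted = {r.upper() for r in self.residue_names}
            mask &= np.isin(
                np.char.upper(topology.residue_names.astype(str)),
                sorted(wanted))
        if self.rule == "all-heavy":
            mask &= topology.is_heavy
        elif self.rule == "side-chain-heavy":
            mask &= topology.is_heavy
            mask &= ~np.isin(topology.atom_names.astype(str),
                             sorted(BACKBONE_ATOMS))
        elif self.rule == "atom-names":
            if not self.atom_names:
                raise SelectionError(
                    f"group {self.name!r}: atom-names rule needs atom_names")
            mask &= np.isin(topology.atom_names.astype(str), self.atom_names)
        else:  # pragma: no cover - guarded by Literal typing
            raise SelectionError(f"unknown subset rule {self.rule!r}")
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise SelectionError(f"selection group {self.name!r} is empty")
        if not allow_hydrogen and np.any(topology.elements[idx] == "H"):
            raise SelectionError(
                f"selection group {self.name!r} resolved hydrogen atoms; "
                "descriptor groups must be heavy-atom only")
        return idx


@dataclass(frozen=True)
class SelectionSpec:
    """The full set of named groups feeding the 8 descriptors."""

    groups: tuple[SelectionGroup, ...]

    def __getitem__(self, name: str) -> SelectionGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


def default_selections(monomer_1: str = "buckled", monomer_2: str = "straight",
                       nucleotide_residue_name: str = "ATP") -> SelectionSpec:
    """Build the canonical descriptor groups for a two-monomer system.

    Descriptor i=1 pairs the strap of ``monomer_1`` with the NTD core of
    ``monomer_2``; descriptor i=2 the reverse.  SASA and distance groups
    are per-monomer.
    """
    groups = []
    for i, (own, other) in enumerate(
            [(monomer_1, monomer_2), (monomer_2, monomer_1)], start=1):
        groups += [
            SelectionGroup(f"strap_{i}", own, (STRAP_RANGE,)),
            SelectionGroup(f"ntd_core_{i}", other, (NTD_CORE_RANGE,)),
            SelectionGroup(f"lid_{i}", own, (ATP_LID_RANGE,),
                           rule="side-chain-heavy"),
            SelectionGroup(f"r417_{i}", own, ((R417_RESIDUE, R417_RESIDUE),),
                           rule="atom-names", atom_names=GUANIDINIUM_ATOMS),
            SelectionGroup(f"gpo4_{i}", own, (),
                           rule="atom-names",
                           atom_names=GAMMA_PHOSPHATE_ATOMS,
                           residue_names=(nucleotide_residue_name,)),
            SelectionGroup(f"s582_{i}", own, ((S582_RESIDUE, S582_RESIDUE),),
                           rule="atom-names",
                           atom_names=SERINE_SIDECHAIN_ATOMS),
        ]
    return SelectionSpec(tuple(groups))


# ---------------------------------------------------------------------------
# descriptor primitives
# ---------------------------------------------------------------------------

def count_cross_contacts(coords_a: np.ndarray, coords_b: np.ndarray,
                         cutoff: float = DEFAULT_CONTACT_CUTOFF) -> int:
    """Count unordered atom pairs (a in A, b in B) strictly closer than
    ``cutoff``.

    The groups must be disjoint atom sets; the caller resolves them through
    :class:`SelectionGroup`, which enforces heavy-atom membership.  Pairs at
    exactly the cutoff distance are excluded.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if coords_a.size == 0 or coords_b.size == 0:
        raise SelectionError("contact groups must be non-empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree_a = cKDTree(coords_a)
    tree_b = cKDTree(coords_b)
    # query_ball_tree returns pairs with distance <= cutoff; re-check each
    # candidate to enforce the strict inequality.
    count = 0
    for ia, neighbours in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        if not neighbours:
            continue
        d = np.linalg.norm(coords_b[neighbours] - coords_a[ia], axis=1)
        count += int(np.sum(d < cutoff))
    return count


def _unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden-spiral
    lattice)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    theta = 2.0 * math.pi * i / golden
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       report_indices: np.ndarray,
                       probe_radius: float = DEFAULT_PROBE_RADIUS,
                       n_sphere_points: int = DEFAULT_N_SPHERE_POINTS
                       ) -> float:
    """Sphere-point (Shrake-Rupley) SASA of ``report_indices``, in A^2.

    Every atom in ``coords`` occludes; the reported area is summed over the
    report group only, so a buried side chain in a full system scores near
    zero even though its isolated area would not.
    """
    if n_sphere_points < 16:
        raise ValueError("n_sphere_points < 16 gives a meaningless surface")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    report_indices = np.asarray(report_indices, dtype=np.int64)
    if report_indices.size == 0:
        raise SelectionError("SASA report group is empty")
    if report_indices.max() >= len(coords):
        raise SelectionError("report group indexes atoms outside the frame")

    expanded = radii + probe_radius
    unit = _unit_sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_expanded = expanded.max()

    total = 0.0
    for i in report_indices:
        r_i = expanded[i]
        neighbours = tree.query_ball_point(coords[i], r_i + max_expanded)
        neighbours = [j for j in neighbours if j != i]
        points = coords[i] + r_i * unit
        accessible = np.ones(n_sphere_points, dtype=bool)
        if neighbours:
            nb = np.asarray(neighbours, dtype=np.int64)
            d = np.linalg.norm(coords[nb] - coords[i], axis=1)
            nb = nb[d < r_i + expanded[nb]]
            for j in nb:
                if not accessible.any():
                    break
                d2 = np.einsum("ij,ij->i", points - coords[j],
                               points - coords[j])
                accessible &= d2 >= expanded[j] ** 2
        total += 4.0 * math.pi * r_i * r_i * accessible.mean()
    return float(total)


def com_distance(coords_a: np.ndarray, masses_a: np.ndarray,
                 coords_b: np.ndarray, masses_b: np.ndarray) -> float:
    """Distance between the mass-weighted centroids of two atom groups."""
    masses_a = np.asarray(masses_a, dtype=float)
    masses_b = np.asarray(masses_b, dtype=float)
    if masses_a.sum() <= 0 or masses_b.sum() <= 0:
        raise ValueError("group total mass must be positive")
    com_a = np.average(np.asarray(coords_a, dtype=float), axis=0,
                       weights=masses_a)
    com_b = np.average(np.asarray(coords_b, dtype=float), axis=0,
                       weights=masses_b)
    return float(np.linalg.norm(com_a - com_b))


# ---------------------------------------------------------------------------
# frame -> 8-vector -> matrix
# ---------------------------------------------------------------------------

def featurize_frame(topology: Topology, frame_coords: np.ndarray,
                    selections: SelectionSpec,
                    cutoff: float = DEFAULT_CONTACT_CUTOFF,
                    probe_radius: float = DEFAULT_PROBE_RADIUS,
                    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS
                    ) -> np.ndarray:
    """Compute the 8 descriptors of one frame, ordered as FEATURE_COLUMNS."""
    values = np.empty(8)
    for i in (1, 2):
        strap = selections[f"strap_{i}"].resolve(topology)
        core = selections[f"ntd_core_{i}"].resolve(topology)
        if np.intersect1d(strap, core).size:
            raise SelectionError("strap and NTD-core groups must be disjoint")
        lid = selections[f"lid_{i}"].resolve(topology)
        r417 = selections[f"r417_{i}"].resolve(topology)
        gpo4 = selections[f"gpo4_{i}"].resolve(topology)
        s582 = selections[f"s582_{i}"].resolve(topology)

        values[i - 1] = count_cross_contacts(
            frame_coords[strap], frame_coords[core], cutoff)
        values[1 + i] = shrake_rupley_sasa(
            frame_coords, topology.radii, lid, probe_radius, n_sphere_points)
        values[3 + i] = com_distance(
            frame_coords[r417], topology.masses[r417],
            frame_coords[gpo4], topology.masses[gpo4])
        values[5 + i] = shrake_rupley_sasa(
            frame_coords, topology.radii, s582, probe_radius, n_sphere_points)
    return values


def select_frame_indices(n_frames: int, frame_interval_ps: float,
                         stride_ps: float, discard_ns: float) -> np.ndarray:
    """Indices of the frames kept after equilibration discard and striding.

    Frame k carries time (k+1)*interval.  Frames with time <= discard are
    dropped; of the remainder, every (stride/interval)-th frame is kept,
    so an 80 ns production span saved every 20 ps keeps 4000 rows and a
    200 ns span sampled every 100 ps keeps 2000.
    """
    ratio = stride_ps / frame_interval_ps
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"stride {stride_ps} ps is not an integer multiple of the "
            f"frame interval {frame_interval_ps} ps")
    step = int(round(ratio))
    times = (np.arange(n_frames) + 1) * frame_interval_ps
    kept = np.flatnonzero(times > discard_ns * 1000.0)
    kept = kept[step - 1 :: step]
    if kept.size == 0:
        raise ValueError("no frames remain after discard and striding")
    return kept


def featurize_trajectory(traj: Trajectory, selections: SelectionSpec,
                         stride_ps: float | None = None,
                         discard_ns: float = 0.0,
                         label: str = "unlabeled",
                         system_id: str = "system",
                         replicate_id: str | int = 0,
                         ligand_id: str = "none",
                         cutoff: float = DEFAULT_CONTACT_CUTOFF,
                         probe_radius: float = DEFAULT_PROBE_RADIUS,
                         n_sphere_points: int = DEFAULT_N_SPHERE_POINTS
                         ) -> pd.DataFrame:
    """Reduce a trajectory to a labeled feature matrix.

    Returns a DataFrame with the 8 feature columns followed by the
    provenance columns in METADATA_COLUMNS; rows are in time order.
    """
    if label not in ("A", "I", "unlabeled"):
        raise ValueError("label must be 'A', 'I' or 'unlabeled'")
    if stride_ps is None:
        stride_ps = traj.frame_interval_ps
    kept = select_frame_indices(traj.n_frames, traj.frame_interval_ps,
                                stride_ps, discard_ns)
    rows = np.empty((kept.size, 8))
    for out_row, k in enumerate(kept):
        rows[out_row] = featurize_frame(
            traj.topology, traj.coords[k], selections,
            cutoff=cutoff, probe_radius=probe_radius,
            n_sphere_points=n_sphere_points)
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    df["label"] = label
    df["system_id"] = system_id
    df["replicate_id"] = replicate_id
    df["ligand_id"] = ligand_id
    df["time_ps"] = traj.frame_times_ps[kept]
    df.attrs["vdw_radii_set"] = "bondi"
    df.attrs["probe_radius"] = probe_radius
    df.attrs["n_sphere_points"] = n_sphere_points
    df.attrs["contact_cutoff"] = cutoff
    return df


def feature_array(matrix: pd.DataFrame) -> np.ndarray:
    """The (n, 8) float view of a feature matrix's descriptor columns."""
    missing = [c for c in FEATURE_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"feature matrix lacks columns {missing}")
    return matrix[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
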