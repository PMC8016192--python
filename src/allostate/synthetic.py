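"""Desk-scale stand-ins for the comparative MD ensemble.

The underlying MD trajectories are not publicly deposited, so the
pipeline is exercised on two kinds of synthetic input with recoverable
ground truth:

* **feature-level ensembles** — per-frame 8-vectors drawn from per-feature
  Gaussian mixtures with class-dependent weights, emulating the
  overlapping, multimodal descriptor densities of the bound (I) and free
  (A) states.  Each ligand's distribution is an occupancy-weighted blend
  of the two anchor mixtures, so the fraction of I-like frames is known
  exactly and a linear "% inhibition" readout can be injected and later
  recovered by the regression stage.
* **toy dimer trajectories** — two bead-built protomers whose geometry
  (domain separation, lid burial, ion-pair distance) is state-dependent,
  so every descriptor responds monotonically to a known knob.  These
  exercise the featurization code path, not the physics.

Everything is deterministic under a base seed; each system draws from its
own RNG stream keyed by (base seed, system id).
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import (FEATURE_COLUMNS, Topology, Trajectory,
                        _unit_sphere_points)

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "SyntheticEnsembleSpec",
    "EnsembleResult",
    "StateGeometry",
    "ToyDimerSpec",
    "sample_feature_matrix",
    "sample_ligand_matrix",
    "ligand_mixture_components",
    "generate_ensemble",
    "generate_toy_trajectory",
    "default_anchor_mixtures",
]

CLASS_LABELS = ("A", "I")


class SpecValidationError(ValueError):
    """A synthetic spec field is out of its admissible range."""


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    sd: float


@dataclass
class MixtureSpec:
    """Per-class, per-feature univariate Gaussian mixtures.

    ``components[label]`` holds one component list per feature column, in
    FEATURE_COLUMNS order.  Features are sampled independently, matching
    the naive-Bayes factorization the downstream generative models assume.
    """

    components: dict[str, list[list[MixtureComponent]]]
    class_priors: dict[str, float] = field(
        default_factory=lambda: {"A": 0.5, "I": 0.5})

    def validate(self) -> None:
        if set(self.components) != set(CLASS_LABELS):
            raise SpecValidationError(
                f"components must cover classes {CLASS_LABELS}")
        n_feat = {len(v) for v in self.components.values()}
        if n_feat != {len(FEATURE_COLUMNS)}:
            raise SpecValidationError(
                f"each class needs {len(FEATURE_COLUMNS)} feature mixtures")
        for label, feats in self.components.items():
            for j, comps in enumerate(feats):
                if not comps:
                    raise SpecValidationError(
                        f"class {label} feature {j}: empty mixture")
                total = sum(c.weight for c in comps)
                if abs(total - 1.0) > 1e-12:
                    raise SpecValidationError(
                        f"class {label} feature {j}: weights sum to {total}")
                for c in comps:
                    if c.weight < 0:
                        raise SpecValidationError(
                            f"class {label} feature {j}: negative weight")
                    if c.sd <= 0:
                        raise SpecValidationError(
                            f"class {label} feature {j}: sd must be > 0")
        priors = self.class_priors
        if set(priors) != set(CLASS_LABELS):
            raise SpecValidationError("class priors must cover A and I")
        if abs(sum(priors.values()) - 1.0) > 1e-12:
            raise SpecValidationError("class priors must sum to 1")
        if any(not (0.0 < p < 1.0) for p in priors.values()):
            raise SpecValidationError("class priors must lie in (0, 1)")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "class_priors": self.class_priors,
            "components": {
                label: [[(c.weight, c.mean, c.sd) for c in comps]
                        for comps in feats]
                for label, feats in self.components.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "MixtureSpec":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        payload = json.loads(text)
        spec = cls(
            components={
                label: [[MixtureComponent(*c) for c in comps]
                        for comps in feats]
                for label, feats in payload["components"].items()
            },
            class_priors={k: float(v)
                          for k, v in payload["class_priors"].items()},
        )
        spec.validate()
        return spec


def _system_rng(base_seed: int, system_id: str) -> np.random.Generator:
    """One independent, reproducible stream per system id."""
    key = zlib.crc32(system_id.encode())
    return np.random.default_rng(np.random.SeedSequence([base_seed, key]))


def _sample_mixture(rng: np.random.Generator,
                    comps: list[MixtureComponent], n: int) -> np.ndarray:
    weights = np.array([c.weight for c in comps])
    means = np.array([c.mean for c in comps])
    sds = np.array([c.sd for c in comps])
    which = rng.choice(len(comps), size=n, p=weights)
    return rng.normal(means[which], sds[which])


def sample_feature_matrix(spec: MixtureSpec, n_frames: int, label: str,
                          rng_seed: int, *, system_id: str = "synthetic",
                          replicate_id: str | int = 0,
                          ligand_id: str = "none",
                          frame_interval_ps: float = 20.0) -> pd.DataFrame:
    """Draw an (n_frames x 8) feature matrix from one class mixture."""
    spec.validate()
    if n_frames < 1:
        raise SpecValidationError("n_frames must be >= 1")
    if label not in CLASS_LABELS:
        raise SpecValidationError(f"label must be one of {CLASS_LABELS}")
    rng = np.random.default_rng(rng_seed)
    return _matrix_from_components(spec.components[label], n_frames, rng,
                                   label, system_id, replicate_id, ligand_id,
                                   frame_interval_ps)


def _matrix_from_components(feats: list[list[MixtureComponent]], n_frames: int,
                            rng: np.random.Generator, label: str,
                            system_id: str, replicate_id, ligand_id: str,
                            frame_interval_ps: float) -> pd.DataFrame:
    data = {col: _sample_mixture(rng, comps, n_frames)
            for col, comps in zip(FEATURE_COLUMNS, feats)}
    df = pd.DataFrame(data)
    df["label"] = label
    df["system_id"] = system_id
    df["replicate_id"] = replicate_id
    df["ligand_id"] = ligand_id
    df["time_ps"] = (np.arange(n_frames) + 1) * frame_interval_ps
    return df


def ligand_mixture_components(mixtures: MixtureSpec, effect: float
                              ) -> list[list[MixtureComponent]]:
    """Marginal per-feature blend of the A and I anchor mixtures.

    Describes the per-feature distribution of a ligand with effect e:
    the I anchor with probability e, the A anchor otherwise.  Sampling
    of whole frames goes through :func:`sample_ligand_matrix`, which
    shares one latent state per frame across all 8 features so that a
    frame is wholly A-like or wholly I-like and the true bound-state
    occupancy equals e.
    """
    if not 0.0 <= effect <= 1.0:
        raise SpecValidationError(f"ligand effect {effect} outside [0, 1]")
    blended = []
    for comps_a, comps_i in zip(mixtures.components["A"],
                                mixtures.components["I"]):
        comps = [MixtureComponent(c.weight * (1.0 - effect), c.mean, c.sd)
                 for c in comps_a]
        comps += [MixtureComponent(c.weight * effect, c.mean, c.sd)
                  for c in comps_i]
        blended.append([c for c in comps if c.weight > 0.0])
    return blended


def sample_ligand_matrix(mixtures: MixtureSpec, effect: float, n_frames: int,
                         rng: np.random.Generator, *, label: str = "I",
                         system_id: str = "synthetic",
                         replicate_id: str | int = 0,
                         ligand_id: str = "none",
                         frame_interval_ps: float = 20.0) -> pd.DataFrame:
    """Sample frames of a ligand-perturbed system at a given effect.

    Each frame draws one latent state — inhibited with probability
    ``effect`` — and then all 8 features from that anchor, so frames are
    internally coherent and the expected fraction of I-like frames is
    exactly the effect.
    """
    if not 0.0 <= effect <= 1.0:
        raise SpecValidationError(f"ligand effect {effect} outside [0, 1]")
    i_like = rng.random(n_frames) < effect
    data = {}
    for col, comps_a, comps_i in zip(FEATURE_COLUMNS,
                                     mixtures.components["A"],
                                     mixtures.components["I"]):
        x = np.empty(n_frames)
        n_i = int(i_like.sum())
        if n_frames - n_i:
            x[~i_like] = _sample_mixture(rng, comps_a, n_frames - n_i)
        if n_i:
            x[i_like] = _sample_mixture(rng, comps_i, n_i)
        data[col] = x
    df = pd.DataFrame(data)
    df["label"] = label
    df["system_id"] = system_id
    df["replicate_id"] = replicate_id
    df["ligand_id"] = ligand_id
    df["time_ps"] = (np.arange(n_frames) + 1) * frame_interval_ps
    return df


@dataclass
class SyntheticEnsembleSpec:
    """Design of a balanced synthetic A/I ensemble.

    Mirrors the comparative design of matched inhibitor-free and inhibitor-bound
    replicate sets: each ligand contributes ``n_replicates`` bound systems,
    the free side contributes the same total number of replicates grouped
    in blocks of ``n_replicates``.  ``inhibition_link`` is (slope,
    intercept, noise sd) mapping true bound-state occupancy in [0, 1] to a
    simulated % inhibition, clipped to [0, 100] after noise.
    """

    ligand_effect_map: dict[str, float]
    n_replicates: int = 3
    production_ns: float = 80.0
    frame_stride_ps: float = 20.0
    equilibration_discard_ns: float = 20.0
    rng_seed: int = 0
    inhibition_link: tuple[float, float, float] = (76.0, 0.0, 3.0)
    n_systems_per_state: int | None = None

    def validate(self) -> None:
        if not self.ligand_effect_map:
            raise SpecValidationError("ligand_effect_map must be non-empty")
        for lig, eff in self.ligand_effect_map.items():
            if not 0.0 <= eff <= 1.0:
                raise SpecValidationError(
                    f"ligand {lig}: effect {eff} outside [0, 1]")
        if self.n_replicates < 1:
            raise SpecValidationError("n_replicates must be >= 1")
        frames = self.production_ns * 1000.0 / self.frame_stride_ps
        if abs(frames - round(frames)) > 1e-9:
            raise SpecValidationError(
                "production_ns / frame_stride_ps must give an integer "
                f"frame count, got {frames}")
        if round(frames) < 1:
            raise SpecValidationError(
                "zero frames after stride; shorten the stride or extend "
                "the production span")
        if self.inhibition_link[2] < 0:
            raise SpecValidationError("inhibition noise sd must be >= 0")
        expected = len(self.ligand_effect_map) * self.n_replicates
        if (self.n_systems_per_state is not None
                and self.n_systems_per_state != expected):
            raise SpecValidationError(
                f"n_systems_per_state={self.n_systems_per_state} but "
                f"ligand map x replicates gives {expected}")

    @property
    def n_frames(self) -> int:
        return int(round(self.production_ns * 1000.0 / self.frame_stride_ps))


@dataclass
class EnsembleResult:
    matrices: dict[str, pd.DataFrame]
    ground_truth: pd.DataFrame
    manifest: pd.DataFrame

    def combined_matrix(self, labeled: bool = True) -> pd.DataFrame:
        df = pd.concat(self.matrices.values(), ignore_index=True)
        if not labeled:
            df = df.assign(label="unlabeled")
        return df


def generate_ensemble(spec: SyntheticEnsembleSpec, mixtures: MixtureSpec
                      ) -> EnsembleResult:
    """Generate a balanced labeled ensemble plus its ground-truth table.

    Bound systems of ligand L draw each frame wholly from the I anchor
    with probability equal to L's effect (else the A anchor); free
    systems draw from the A anchor.  The simulated % inhibition is one
    draw per ligand (replicates share the assay value).
    """
    spec.validate()
    mixtures.validate()
    n_frames = spec.n_frames
    slope, intercept, noise_sd = spec.inhibition_link

    matrices: dict[str, pd.DataFrame] = {}
    truth_rows = []
    manifest_rows = []

    ligands = sorted(spec.ligand_effect_map)
    assay_rng = np.random.default_rng(
        np.random.SeedSequence([spec.rng_seed, zlib.crc32(b"assay")]))
    for lig in ligands:
        effect = spec.ligand_effect_map[lig]
        inhibition = slope * effect + intercept
        if noise_sd > 0:
            inhibition += assay_rng.normal(0.0, noise_sd)
        inhibition = float(np.clip(inhibition, 0.0, 100.0))
        for rep in range(1, spec.n_replicates + 1):
            system_id = f"I-{lig}-r{rep}"
            rng = _system_rng(spec.rng_seed, system_id)
            matrices[system_id] = sample_ligand_matrix(
                mixtures, effect, n_frames, rng, label="I",
                system_id=system_id, replicate_id=rep, ligand_id=lig,
                frame_interval_ps=spec.frame_stride_ps)
            truth_rows.append(dict(system_id=system_id, state="I",
                                   ligand_id=lig, group_id=f"lig-{lig}",
                                   replicate_id=rep,
                                   true_I_occupancy=effect,
                                   pct_inhibition=inhibition))
            manifest_rows.append(dict(system_id=system_id, state="I",
                                      ligand_id=lig, group_id=f"lig-{lig}",
                                      replicate_id=rep,
                                      production_ns=spec.production_ns,
                                      stride_ps=spec.frame_stride_ps,
                                      n_frames=n_frames))

    n_free = len(ligands) * spec.n_replicates
    for k in range(1, n_free + 1):
        group = (k - 1) // spec.n_replicates + 1
        system_id = f"A-g{group}-r{(k - 1) % spec.n_replicates + 1}"
        rng = _system_rng(spec.rng_seed, system_id)
        matrices[system_id] = _matrix_from_components(
            mixtures.components["A"], n_frames, rng, "A", system_id,
            (k - 1) % spec.n_replicates + 1, "none", spec.frame_stride_ps)
        truth_rows.append(dict(system_id=system_id, state="A",
                               ligand_id="none", group_id=f"free-g{group}",
                               replicate_id=(k - 1) % spec.n_replicates + 1,
                               true_I_occupancy=0.0, pct_inhibition=0.0))
        manifest_rows.append(dict(system_id=system_id, state="A",
                                  ligand_id="none", group_id=f"free-g{group}",
                                  replicate_id=(k - 1) % spec.n_replicates + 1,
                                  production_ns=spec.production_ns,
                                  stride_ps=spec.frame_stride_ps,
                                  n_frames=n_frames))

    return EnsembleResult(matrices, pd.DataFrame(truth_rows),
                          pd.DataFrame(manifest_rows))


# ---------------------------------------------------------------------------
# toy bead dimer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateGeometry:
    """State-dependent geometry knobs of the toy dimer, per state label."""

    domain_separation: float = 14.0  # A between the two protomer origins
    lid_burial_fraction: float = 0.5  # 0 = fully exposed, 1 = buried in core
    ion_pair_distance: float = 4.0  # A between guanidinium and gamma-PO4 COMs
    s582_burial_fraction: float = 0.5

    def validate(self) -> None:
        if self.domain_separation <= 0:
            raise SpecValidationError("domain separation must be positive")
        if not 0.0 <= self.lid_burial_fraction <= 1.0:
            raise SpecValidationError("lid burial fraction outside [0, 1]")
        if not 0.0 <= self.s582_burial_fraction <= 1.0:
            raise SpecValidationError("s582 burial fraction outside [0, 1]")
        if self.ion_pair_distance < 0:
            raise SpecValidationError("ion-pair distance must be >= 0")


@dataclass
class ToyDimerSpec:
    """Bead-level blueprint of a two-protomer toy system.

    Beads carry explicit masses and radii; no chemistry is implied beyond
    element tags that make the selection rules (heavy atoms, side chains,
    named nucleotide atoms) resolve exactly as on a real structure.
    """

    n_strap_beads: int = 6
    n_core_beads: int = 24
    n_lid_beads: int = 4
    strap_length: float = 8.0  # A, fixed reach toward the partner protomer
    core_radius: float = 4.0  # A, radius of the core bead shell
    bead_radius: float = 1.7
    bead_mass: float = 12.011
    jitter_sd: float = 0.25  # A, isotropic thermal noise per coordinate
    rng_seed: int = 0
    geometry: dict[str, StateGeometry] = field(default_factory=lambda: {
        "A": StateGeometry(domain_separation=14.0, lid_burial_fraction=0.8,
                           ion_pair_distance=4.0, s582_burial_fraction=0.8),
        "I": StateGeometry(domain_separation=17.0, lid_burial_fraction=0.2,
                           ion_pair_distance=9.0, s582_burial_fraction=0.2),
    })

    def validate(self) -> None:
        for name, value in [("n_strap_beads", self.n_strap_beads),
                            ("n_core_beads", self.n_core_beads),
                            ("n_lid_beads", self.n_lid_beads)]:
            if value < 1:
                raise SpecValidationError(f"{name} must be >= 1")
        if self.bead_radius <= 0:
            raise SpecValidationError("bead radius must be positive")
        if self.bead_mass <= 0:
            raise SpecValidationError("bead mass must be positive")
        if self.jitter_sd < 0:
            raise SpecValidationError("jitter sd must be >= 0")
        for geo in self.geometry.values():
            geo.validate()


def _spread_residues(lo: int, hi: int, n: int, skip: tuple[int, int] | None
                     ) -> np.ndarray:
    """n distinct-ish residue numbers in [lo, hi], avoiding a skipped range."""
    candidates = [r for r in range(lo, hi + 1)
                  if skip is None or not (skip[0] <= r <= skip[1])]
    idx = np.linspace(0, len(candidates) - 1, n).round().astype(int)
    return np.array([candidates[i] for i in idx])


def _monomer_beads(spec: ToyDimerSpec, geo: StateGeometry, monomer_id: str,
                   origin: np.ndarray, toward: np.ndarray) -> dict:
    """Ideal (jitter-free) bead layout of one protomer."""
    names, elements, resnums, resnames, coords = [], [], [], [], []

    def add(name, element, resnum, resname, xyz):
        names.append(name)
        elements.append(element)
        resnums.append(resnum)
        resnames.append(resname)
        coords.append(xyz)

    # NTD core: quasi-uniform shell plus a center bead
    shell = _unit_sphere_points(spec.n_core_beads - 1) * spec.core_radius
    core_res = _spread_residues(109, 308, spec.n_core_beads, skip=(191, 217))
    add("CA", "C", int(core_res[0]), "GLY", origin.copy())
    for k in range(spec.n_core_beads - 1):
        add("CA", "C", int(core_res[k + 1]), "GLY", origin + shell[k])

    # strap: straight run of beads reaching toward the partner protomer
    strap_res = _spread_residues(85, 108, spec.n_strap_beads, skip=None)
    for k in range(spec.n_strap_beads):
        t = (k + 1) / spec.n_strap_beads
        add("CA", "C", int(strap_res[k]), "GLY",
            origin + toward * (t * spec.strap_length))

    # ATP lid: ring whose radius interpolates between buried and exposed
    r_exposed = spec.core_radius + 4.0
    r_buried = 1.2
    r_lid = geo.lid_burial_fraction * r_buried \
        + (1.0 - geo.lid_burial_fraction) * r_exposed
    lid_res = _spread_residues(191, 217, spec.n_lid_beads, skip=None)
    side = np.cross(toward, [0.0, 0.0, 1.0])
    side /= np.linalg.norm(side)
    for k in range(spec.n_lid_beads):
        ang = 2.0 * math.pi * k / spec.n_lid_beads
        direction = math.cos(ang) * np.array([0.0, 0.0, 1.0]) \
            + math.sin(ang) * side
        add("CB", "C", int(lid_res[k]), "LID", origin + r_lid * direction)

    # R417 guanidinium proxy: planar 4-atom cluster, COM at its center
    p417 = origin - toward * (spec.core_radius + 4.0)
    guan = {"NE": 14.007, "CZ": 12.011, "NH1": 14.007, "NH2": 14.007}
    offsets = 0.7 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]],
                             dtype=float)
    for (aname, _), off in zip(guan.items(), offsets):
        add(aname, aname[0], 417, "ARG", p417 + off)
    guan_masses = np.array(list(guan.values()))
    guan_com = (guan_masses[:, None] * (p417 + offsets)).sum(0) \
        / guan_masses.sum()

    # gamma-phosphate proxy, placed so the COM distance equals the knob
    shift = p417 + (guan_com - p417)  # = guan_com
    ppos = shift - toward * 0.0 + np.array([0.0, 0.0, -1.0]) \
        * geo.ion_pair_distance
    gp = {"PG": 30.974, "O1G": 15.999, "O2G": 15.999, "O3G": 15.999}
    gp_off = 0.6 * np.array([[0, 0, 0], [1, 0, 0],
                             [-0.5, math.sqrt(3) / 2, 0],
                             [-0.5, -math.sqrt(3) / 2, 0]])
    gp_masses = np.array(list(gp.values()))
    centroid = (gp_masses[:, None] * gp_off).sum(0) / gp_masses.sum()
    for (aname, _), off in zip(gp.items(), gp_off):
        add(aname, aname[0], 901, "ATP", ppos + off - centroid)

    # S582 hydroxymethyl proxy: CB + OG pair at a burial-controlled radius
    r_s = geo.s582_burial_fraction * r_buried \
        + (1.0 - geo.s582_burial_fraction) * r_exposed
    s_dir = -side
    add("CB", "C", 582, "SER", origin + r_s * s_dir)
    add("OG", "O", 582, "SER", origin + (r_s + 1.4) * s_dir)

    return dict(names=names, elements=elements, resnums=resnums,
                resnames=resnames, coords=np.asarray(coords),
                monomer=[monomer_id] * len(names))


def generate_toy_trajectory(spec: ToyDimerSpec, state: str, n_frames: int,
                            frame_interval_ps: float = 20.0) -> Trajectory:
    """Build an annotated bead-dimer trajectory for one state label.

    The ideal geometry is fixed by the state's knobs; frames differ only
    by isotropic Gaussian jitter, so descriptor responses to the knobs are
    monotone by construction and a zero-jitter spec freezes the geometry.
    """
    spec.validate()
    if state not in spec.geometry:
        raise SpecValidationError(f"no geometry defined for state {state!r}")
    if n_frames < 1:
        raise SpecValidationError("n_frames must be >= 1")
    geo = spec.geometry[state]

    d = geo.domain_separation
    origins = [np.zeros(3), np.array([d, 0.0, 0.0])]
    towards = [np.array([1.0, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0])]
    parts = [_monomer_beads(spec, geo, mono, origin, toward)
             for mono, origin, toward in
             zip(("buckled", "straight"), origins, towards)]

    names = np.concatenate([p["names"] for p in parts])
    elements = np.concatenate([p["elements"] for p in parts])
    resnums = np.concatenate([p["resnums"] for p in parts])
    resnames = np.concatenate([p["resnames"] for p in parts])
    monomers = np.concatenate([p["monomer"] for p in parts])
    base = np.concatenate([p["coords"] for p in parts])

    masses = np.array([{"C": 12.011, "N": 14.007, "O": 15.999,
                        "P": 30.974}[e] for e in elements])
    radii = np.where(np.isin(elements, ["N"]), 1.55,
                     np.where(elements == "O", 1.52,
                              np.where(elements == "P", 1.80,
                                       spec.bead_radius)))

    topology = Topology(atom_names=names, elements=elements,
                        residue_numbers=resnums, residue_names=resnames,
                        monomer_ids=monomers, masses=masses, radii=radii)

    rng = np.random.default_rng(
        np.random.SeedSequence([spec.rng_seed, zlib.crc32(state.encode())]))
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    if spec.jitter_sd > 0:
        coords = coords + rng.normal(0.0, spec.jitter_sd, size=coords.shape)
    return Trajectory(topology, coords, frame_interval_ps,
                      source={"generator": "toy-dimer", "state": state,
                              "seed": spec.rng_seed})


def default_anchor_mixtures() -> MixtureSpec:
    """Anchor mixtures with overlapping, partly multimodal densities.

    Values are in descriptor units (contacts, A^2, A).  The free state
    keeps the strap engaged (more cross contacts), the lid and S582 less
    exposed, and the ion pair formed (short distance); inhibition loosens
    all four, with deliberate overlap so classification is non-trivial.
    The shapes are plausible knobs, not calibrated to any measured density.
    """
    c = MixtureComponent
    components = {
        "A": [
            [c(0.7, 30.0, 5.0), c(0.3, 22.0, 4.0)],   # contacts, monomer 1
            [c(1.0, 26.0, 5.0)],                       # contacts, monomer 2
            [c(0.6, 300.0, 35.0), c(0.4, 345.0, 30.0)],  # lid SASA 1
            [c(1.0, 310.0, 40.0)],                     # lid SASA 2
            [c(0.8, 4.2, 0.7), c(0.2, 6.5, 1.0)],      # R417-gPO4 dist 1
            [c(1.0, 4.5, 0.8)],                        # R417-gPO4 dist 2
            [c(1.0, 55.0, 12.0)],                      # S582 SASA 1
            [c(1.0, 60.0, 12.0)],                      # S582 SASA 2
        ],
        "I": [
            [c(0.6, 20.0, 5.0), c(0.4, 13.0, 4.0)],
            [c(1.0, 18.0, 5.0)],
            [c(0.5, 360.0, 35.0), c(0.5, 410.0, 30.0)],
            [c(1.0, 370.0, 40.0)],
            [c(0.6, 7.5, 1.2), c(0.4, 10.0, 1.5)],
            [c(1.0, 8.0, 1.2)],
            [c(1.0, 80.0, 14.0)],
            [c(1.0, 88.0, 14.0)],
        ],
    }
    spec = MixtureSpec(components=components)
    spec.validate()
    return spec
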