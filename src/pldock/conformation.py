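"""Pose parameterization and forward kinematics.

A ligand pose is (position of the root frame, a unit orientation
quaternion, one angle per *active* torsion).  ``realize`` turns a pose
into Cartesian coordinates: the root frame is rigidly transformed, then
each branch frame is rotated about its (already transformed) rotor axis by
its torsion angle, depth-first; inactive torsions stay at the input
geometry.  RMSD between two realizations of the same template is computed
on heavy atoms with fixed correspondence and no superposition — docked
poses share the receptor frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .pdbqt import LigandTemplate

__all__ = [
    "Conformation",
    "ScoredPose",
    "MutationAmplitudes",
    "identity_conformation",
    "realize",
    "mutate",
    "rmsd",
    "random_unit_quaternion",
]


@dataclass(frozen=True)
class Conformation:
    """Pose variables: root position (A), orientation quaternion (x,y,z,w
    scalar-last), and one angle (radians) per active torsion."""

    position: np.ndarray
    orientation: np.ndarray
    torsions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))
        q = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-6:
            q = q / norm
        object.__setattr__(self, "orientation", q)
        object.__setattr__(self, "torsions",
                           np.asarray(self.torsions, dtype=float))


@dataclass
class ScoredPose:
    """A realized conformation with its score decomposition and outputs."""

    conformation: Conformation
    coords: np.ndarray            # all template atoms, file order
    breakdown: object = None      # energetics.ScoreBreakdown
    energy_kcal: float = 0.0
    rf_pkd: float | None = None
    consensus_pkd: float | None = None
    hbonds: list = field(default_factory=list)

    def heavy_coords(self, template: LigandTemplate) -> np.ndarray:
        return self.coords[template.heavy_indices()]


def root_origin(template: LigandTemplate) -> np.ndarray:
    """Reference point of the root frame: its first atom's input position."""
    return np.asarray(template.root.atoms[0].coords, dtype=float)


def identity_conformation(template: LigandTemplate) -> Conformation:
    """The pose that reproduces the input geometry exactly."""
    return Conformation(
        position=root_origin(template),
        orientation=np.array([0.0, 0.0, 0.0, 1.0]),
        torsions=np.zeros(template.n_active),
    )


def _active_torsion_order(template: LigandTemplate) -> list[int]:
    """Frame indices of active torsions, in tree (DFS) order."""
    return [
        i for i, f in enumerate(template.frames)
        if f.rotor_axis is not None and f.active
    ]


def realize(template: LigandTemplate, conf: Conformation) -> np.ndarray:
    """Forward kinematics: pose variables -> coordinates of every atom."""
    if len(conf.torsions) != template.n_active:
        raise ValueError(
            f"conformation has {len(conf.torsions)} torsions; template "
            f"has {template.n_active} active"
        )
    origin = root_origin(template)
    input_coords = template.input_coords()
    R0 = Rotation.from_quat(conf.orientation).as_matrix()
    t0 = conf.position - R0 @ origin
    if len(template.frames) == 1:  # rigid ligand: a single matmul
        return input_coords @ R0.T + t0

    serial_to_idx = template.serial_to_index
    coords = np.empty_like(input_coords)
    active_frames = _active_torsion_order(template)
    angle_of_frame = {f: conf.torsions[k] for k, f in enumerate(active_frames)}

    # per-frame rigid transform (R, t): x -> R @ x + t, parents first
    transforms: list = [None] * len(template.frames)
    transforms[0] = (R0, t0)
    for fi, frame in enumerate(template.frames):
        if fi > 0:
            Rp, tp = transforms[template.frame_parent[fi]]
            pa, pc = frame.rotor_axis
            a0 = Rp @ input_coords[serial_to_idx[pa]] + tp
            a1 = Rp @ input_coords[serial_to_idx[pc]] + tp
            angle = angle_of_frame.get(fi, 0.0)
            if angle == 0.0:
                transforms[fi] = (Rp, tp)
            else:
                axis = a1 - a0
                axis = axis / np.linalg.norm(axis)
                Rax = Rotation.from_rotvec(angle * axis).as_matrix()
                transforms[fi] = (Rax @ Rp, a1 - Rax @ a1 + Rax @ tp)
        Rf, tf = transforms[fi]
        idx = template.frame_atom_idx[fi]
        coords[idx] = input_coords[idx] @ Rf.T + tf
    return coords


@dataclass(frozen=True)
class MutationAmplitudes:
    """Perturbation scales of the Monte-Carlo mutation move.

    The rotation amplitude spans the full half-turn by default: local
    optimization after each mutation repairs the pose anyway, and
    near-180-degree proposals are what let a chain escape an
    end-for-end flipped binding mode without leaving the site.
    """

    position: float = 2.0      # A, radius of the uniform displacement ball
    rotation: float = np.pi    # rad, max random-axis rotation angle
    # torsions are resampled uniformly on (-pi, pi)


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform sample on the rotation group (normalized 4-normal)."""
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _random_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        v = rng.uniform(-1.0, 1.0, size=3)
        if v @ v <= 1.0:
            return radius * v


def mutate(conf: Conformation, rng: np.random.Generator,
           amplitudes: MutationAmplitudes = MutationAmplitudes()) -> Conformation:
    """Perturb exactly one degree-of-freedom class, chosen at random.

    Rigid ligands mutate position or orientation only; reproducible under a
    fixed generator state.
    """
    n_tor = len(conf.torsions)
    n_classes = 2 + (1 if n_tor else 0)
    choice = int(rng.integers(n_classes))
    if choice == 0:
        return replace(conf,
                       position=conf.position + _random_in_ball(
                           rng, amplitudes.position))
    if choice == 1:
        axis = _random_in_ball(rng, 1.0)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            axis, norm = np.array([0.0, 0.0, 1.0]), 1.0
        angle = rng.uniform(0.0, amplitudes.rotation)
        dq = Rotation.from_rotvec(angle * axis / norm)
        q = (dq * Rotation.from_quat(conf.orientation)).as_quat()
        return replace(conf, orientation=q / np.linalg.norm(q))
    k = int(rng.integers(n_tor))
    torsions = conf.torsions.copy()
    torsions[k] = rng.uniform(-np.pi, np.pi)
    return replace(conf, torsions=torsions)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Root mean square deviation with fixed correspondence, no fitting."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("rmsd of empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
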