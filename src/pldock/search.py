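"""Monte-Carlo global search with BFGS quasi-Newton local optimization.

Independent chains each run (mutate -> BFGS local optimization ->
Metropolis acceptance) for a budget of iterations that grows with ligand
complexity (heavy atoms and active torsions).  The local optimizer works
on the pose variable vector [position(3), rotation increment(3),
active torsions]; the rotation increment is a rotation vector composed
onto the chain's current base quaternion, re-centered after every BFGS
run.  The gradient is assembled by torsion-tree back-propagation of
per-atom Cartesian forces read from the grid maps (inter) and the pair
table (intra).  BFGS terminates exactly when the backtracking line search
can find no acceptable step.  Accepted local minima from all chains are
pooled, greedily clustered by RMSD, converted to output free energies with
the flexibility penalty, and at most ``max_poses`` are returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .conformation import (
    Conformation,
    MutationAmplitudes,
    ScoredPose,
    mutate,
    random_unit_quaternion,
    realize,
    rmsd,
)
from .energetics import (
    IntraPairs,
    PairPotentialTable,
    ScoreBreakdown,
    ScoringWeights,
    detect_hbonds,
    flexibility_penalized_energy,
    intra_score_and_gradient,
    precalculate_table,
)
from .gridmaps import (
    GridMap,
    OutOfBoxError,
    SearchBox,
    build_grid_maps,
    grid_lookup,
)
from .pdbqt import LigandTemplate, Receptor

__all__ = [
    "SearchConfig",
    "Scorer",
    "score_and_gradient",
    "bfgs_local_optimize",
    "metropolis_accept",
    "monte_carlo_dock",
    "cluster_and_select",
]


@dataclass(frozen=True)
class SearchConfig:
    """Tunable knobs of the global search; defaults are logged at startup."""

    n_runs: int = 64
    iterations_base: int = 100
    metropolis_temperature: float = 1.2  # score units
    max_poses: int = 9
    cluster_rmsd: float = 1.0  # A
    seed: int = 0
    refine_iterations: int = 48  # greedy basin-hops around top candidates
    amplitudes: MutationAmplitudes = field(default_factory=MutationAmplitudes)

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.max_poses < 1:
            raise ValueError("max_poses must be >= 1")
        if self.metropolis_temperature <= 0:
            raise ValueError("metropolis temperature must be positive")

    def iteration_budget(self, template: LigandTemplate) -> int:
        """Per-chain iterations, scaled by ligand complexity."""
        return max(1, int(round(self.iterations_base * (
            1.0 + template.n_heavy / 32.0 + template.n_active / 4.0))))


class Scorer:
    """Bundles template, grids and table into a pose -> (score, grad) map.

    ``exact=True`` bypasses the grid lattices and evaluates the
    inter-molecular part by direct pair summation over the receptor — the
    smooth reference path used by gradient checks and fixture
    certification.
    """

    def __init__(self, template: LigandTemplate, receptor: Receptor,
                 box: SearchBox, table: PairPotentialTable,
                 maps: dict[str, GridMap] | None = None,
                 exact: bool = False):
        self.template = template
        self.receptor = receptor
        self.box = box
        self.table = table
        self.exact = exact
        self.heavy_idx = template.heavy_indices()
        self.heavy_types = [template.atoms[i].type for i in self.heavy_idx]
        self.intra_pairs = IntraPairs(template)
        needed = set(self.heavy_types)
        if exact:
            self.maps = maps
        else:
            self.maps = maps if maps is not None else build_grid_maps(
                receptor, box, table, needed)
        # hot-path precomputation: heavy rows grouped by atom type, the
        # receptor pair-index matrix for the exact path, and the subtree
        # heavy rows + axis atom indices of each active torsion
        from .energetics import pair_index
        rec_types = receptor.heavy_types()
        self._rec_coords = receptor.heavy_coords()
        self._pair_idx = np.array(
            [[pair_index(t, rt) for rt in rec_types]
             for t in self.heavy_types], dtype=int)
        heavy_row = {int(a): r for r, a in enumerate(self.heavy_idx)}
        self._type_groups = [
            (code, np.array([r for r, t in enumerate(self.heavy_types)
                             if t == code], dtype=int))
            for code in sorted(needed)
        ]
        self._torsion_info = []
        for fi, frame in enumerate(template.frames):
            if frame.rotor_axis is None or not frame.active:
                continue
            pa, pc = frame.rotor_axis
            rows = np.array(
                [heavy_row[template.serial_to_index[a.serial]]
                 for sub in frame.walk() for a in sub.atoms
                 if template.serial_to_index[a.serial] in heavy_row],
                dtype=int,
            )
            self._torsion_info.append(
                (template.serial_to_index[pa], template.serial_to_index[pc],
                 rows)
            )

    # -- value ------------------------------------------------------------

    def _exact_inter(self, heavy: np.ndarray, with_gradient: bool = False):
        """Vectorized analytic inter score (and per-atom gradient)."""
        from .energetics import analytic_by_pair, analytic_deriv_by_pair
        delta = heavy[:, None, :] - self._rec_coords[None, :, :]
        r = np.sqrt((delta ** 2).sum(axis=-1))
        per_atom = analytic_by_pair(self.table.weights, r, self._pair_idx,
                                    self.table.r_cutoff).sum(axis=1)
        if not with_gradient:
            return float(per_atom.sum()), per_atom, None
        dvdr = analytic_deriv_by_pair(self.table.weights, r, self._pair_idx,
                                      self.table.r_cutoff)
        scale = np.where(r > 1e-12, dvdr / np.maximum(r, 1e-12), 0.0)
        grads = (scale[..., None] * delta).sum(axis=1)
        return float(per_atom.sum()), per_atom, grads

    def score_coords(self, coords: np.ndarray) -> ScoreBreakdown:
        """Score realized coordinates (heavy atoms clamped into the box)."""
        heavy = self.box.clamp(coords[self.heavy_idx])
        if self.exact:
            e_inter, per_atom, _ = self._exact_inter(heavy)
        else:
            e_inter, per_atom = grid_lookup(self.maps, heavy, self.heavy_types)
        e_intra, _ = intra_score_and_gradient(
            self.template, coords, self.table, self.intra_pairs,
            analytic=self.exact)
        return ScoreBreakdown(
            e_total=e_inter + e_intra,
            e_inter=e_inter,
            e_intra=e_intra,
            per_atom_inter=per_atom,
        )

    def score(self, conf: Conformation) -> float:
        return self.score_coords(realize(self.template, conf)).e_total

    # -- value + gradient over the DOF vector ------------------------------

    def n_dof(self) -> int:
        return 6 + self.template.n_active

    def conf_to_vector(self, conf: Conformation) -> np.ndarray:
        """DOF chart centred on ``conf``: zero rotation increment."""
        return np.concatenate([conf.position, np.zeros(3), conf.torsions])

    def vector_to_conf(self, v: np.ndarray, base: Conformation) -> Conformation:
        rot = Rotation.from_rotvec(v[3:6]) * Rotation.from_quat(base.orientation)
        q = rot.as_quat()
        return Conformation(position=v[:3], orientation=q / np.linalg.norm(q),
                            torsions=v[6:])

    def _grid_value_grad(self, heavy: np.ndarray):
        per_atom = np.empty(len(heavy))
        grads = np.empty((len(heavy), 3))
        for code, rows in self._type_groups:
            m = self.maps[code]
            rel = (heavy[rows] - m.origin) / m.spacing
            idx = np.rint(rel).astype(int)
            if np.any(idx < 0) or np.any(idx >= np.asarray(m.dims)):
                raise OutOfBoxError("atom outside the search box lattice")
            per_atom[rows] = m.values[idx[:, 0], idx[:, 1], idx[:, 2]]
            grads[rows] = m.gradients[idx[:, 0], idx[:, 1], idx[:, 2]]
        return float(per_atom.sum()), per_atom, grads

    def value_and_gradient(self, v: np.ndarray, base: Conformation):
        conf = self.vector_to_conf(v, base)
        coords = realize(self.template, conf)
        heavy = self.box.clamp(coords[self.heavy_idx])
        if self.exact:
            e_inter, _, g_inter = self._exact_inter(heavy, with_gradient=True)
        else:
            e_inter, _, g_inter = self._grid_value_grad(heavy)
        e_intra, g_intra_all = intra_score_and_gradient(
            self.template, coords, self.table, self.intra_pairs,
            analytic=self.exact)
        # per-atom Cartesian forces on heavy atoms
        g_atoms = g_inter + g_intra_all[self.heavy_idx]
        grad = self._backpropagate(conf, coords, g_atoms, v[3:6])
        return e_inter + e_intra, grad

    @staticmethod
    def _so3_left_jacobian(rotvec: np.ndarray) -> np.ndarray:
        """Left Jacobian of the exponential map on the rotation group.

        Maps a perturbation of the rotation-vector coordinate to the
        equivalent infinitesimal rotation; identity at zero, where the
        orientation gradient reduces to the plain torque.
        """
        theta = float(np.linalg.norm(rotvec))
        if theta < 1e-8:
            return np.eye(3)
        k = rotvec / theta
        K = np.array([[0.0, -k[2], k[1]],
                      [k[2], 0.0, -k[0]],
                      [-k[1], k[0], 0.0]])
        return (np.eye(3)
                + (1.0 - np.cos(theta)) / theta * K
                + (1.0 - np.sin(theta) / theta) * (K @ K))

    def _backpropagate(self, conf: Conformation, coords: np.ndarray,
                       g_atoms: np.ndarray,
                       rotvec: np.ndarray) -> np.ndarray:
        """Torsion-tree back-propagation of per-atom forces to the DOFs."""
        heavy_pos = coords[self.heavy_idx]
        grad = np.zeros(self.n_dof())
        grad[:3] = g_atoms.sum(axis=0)
        rel = heavy_pos - conf.position
        torque = np.cross(rel, g_atoms).sum(axis=0)
        grad[3:6] = self._so3_left_jacobian(rotvec).T @ torque
        for k, (ia0, ia1, rows) in enumerate(self._torsion_info):
            a1 = coords[ia1]
            axis = a1 - coords[ia0]
            axis = axis / np.linalg.norm(axis)
            torque = np.cross(heavy_pos[rows] - a1, g_atoms[rows]).sum(axis=0)
            grad[6 + k] = float(axis @ torque)
        return grad


def score_and_gradient(template: LigandTemplate, conf: Conformation,
                       maps: dict[str, GridMap], table: PairPotentialTable,
                       receptor: Receptor, box: SearchBox,
                       exact: bool = False):
    """Convenience wrapper: score and DOF gradient of one conformation."""
    scorer = Scorer(template, receptor, box, table, maps=maps, exact=exact)
    v = scorer.conf_to_vector(conf)
    return scorer.value_and_gradient(v, conf)


# ---------------------------------------------------------------------------
# BFGS with backtracking line search
# ---------------------------------------------------------------------------

def bfgs_local_optimize(x0: np.ndarray, value_and_grad,
                        max_iterations: int = 200,
                        c1: float = 1e-4,
                        shrink: float = 0.5,
                        max_backtracks: int = 12):
    """Quasi-Newton minimization; stops iff the line search finds no step.

    Maintains an inverse-Hessian approximation (reset to identity on
    curvature breakdown).  The backtracking Armijo line search halves the
    step until sufficient decrease; if no acceptable length exists the
    optimization terminates.  The returned value never exceeds the start.
    """
    x = np.asarray(x0, dtype=float).copy()
    f, g = value_and_grad(x)
    n = len(x)
    h_inv = np.eye(n)
    for _ in range(max_iterations):
        p = -h_inv @ g
        slope = float(g @ p)
        if slope >= 0.0:  # not a descent direction: restart steepest
            h_inv = np.eye(n)
            p = -g
            slope = float(g @ p)
            if slope >= 0.0:  # zero gradient
                break
        alpha = 1.0
        accepted = False
        for _ in range(max_backtracks):
            x_new = x + alpha * p
            f_new, g_new = value_and_grad(x_new)
            if f_new <= f + c1 * alpha * slope:
                accepted = True
                break
            alpha *= shrink
        if not accepted:
            break  # line-search failure is the sole stopping rule
        s = x_new - x
        y = g_new - g
        sy = float(s @ y)
        if sy > 1e-12:
            rho = 1.0 / sy
            outer_sy = np.outer(s, y)
            h_inv = (np.eye(n) - rho * outer_sy) @ h_inv @ \
                    (np.eye(n) - rho * outer_sy.T) + rho * np.outer(s, s)
        else:
            h_inv = np.eye(n)
        x, f, g = x_new, f_new, g_new
    return x, f


def metropolis_accept(delta: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Accept improvements always; worsenings with prob exp(-delta/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta <= 0:
        return True
    return bool(rng.random() < np.exp(-delta / temperature))


# ---------------------------------------------------------------------------
# Global search
# ---------------------------------------------------------------------------

def _ligand_fits_box(template: LigandTemplate, box: SearchBox) -> bool:
    heavy = template.heavy_coords()
    if len(heavy) < 2:
        return True
    span = float(np.linalg.norm(heavy.max(axis=0) - heavy.min(axis=0)))
    return span <= box.size * np.sqrt(3.0)


def _random_conformation(template: LigandTemplate, box: SearchBox,
                         rng: np.random.Generator) -> Conformation:
    return Conformation(
        position=box.random_point(rng),
        orientation=random_unit_quaternion(rng),
        torsions=rng.uniform(-np.pi, np.pi, size=template.n_active),
    )


def cluster_and_select(minima: list[tuple[Conformation, float, np.ndarray]],
                       cluster_rmsd: float, max_poses: int):
    """Greedy best-first selection of distinct minima.

    ``minima`` entries are (conformation, score, heavy coordinates); a
    candidate within ``cluster_rmsd`` of an already selected pose is
    discarded.  Stable under ties (input order breaks them).
    """
    selected: list[tuple[Conformation, float, np.ndarray]] = []
    for entry in sorted(minima, key=lambda t: t[1]):
        if any(rmsd(entry[2], s[2]) < cluster_rmsd for s in selected):
            continue
        selected.append(entry)
        if len(selected) >= max_poses:
            break
    return selected


def monte_carlo_dock(template: LigandTemplate, receptor: Receptor,
                     box: SearchBox, config: SearchConfig = SearchConfig(),
                     weights: ScoringWeights | None = None,
                     table: PairPotentialTable | None = None,
                     maps: dict[str, GridMap] | None = None,
                     rf_model=None,
                     initial_conformations: list[Conformation] | None = None,
                     ) -> list[ScoredPose]:
    """Run the full global search and return at most ``max_poses`` poses.

    Chains are independent given their derived seeds (seed + chain index),
    so results do not depend on execution order.  ``initial_conformations``
    optionally seeds the first chains (e.g. to inject a crystal pose).
    Poses come back sorted by output free energy ascending; the flexibility
    penalty uses the intra-molecular score of the best pose.
    """
    weights = weights or ScoringWeights()
    if not _ligand_fits_box(template, box):
        raise ValueError("ligand is larger than the search box")
    table = table or precalculate_table(weights)
    scorer = Scorer(template, receptor, box, table, maps=maps)

    heavy_idx = scorer.heavy_idx
    minima: list[tuple[Conformation, float, np.ndarray]] = []
    n_iter = config.iteration_budget(template)

    def local_opt(conf: Conformation):
        v0 = scorer.conf_to_vector(conf)
        v, f = bfgs_local_optimize(
            v0, lambda v_: scorer.value_and_gradient(v_, conf))
        out = scorer.vector_to_conf(v, conf)
        # keep the optimizer inside the feasible region
        out = Conformation(position=box.clamp(out.position),
                           orientation=out.orientation,
                           torsions=out.torsions)
        return out, f

    for chain in range(config.n_runs):
        rng = np.random.default_rng(config.seed + chain)
        if initial_conformations and chain < len(initial_conformations):
            current = initial_conformations[chain]
            # keep the unoptimized start in the pool: an injected pose
            # (e.g. a crystal conformation) can never rank below itself
            minima.append((current, scorer.score(current),
                           realize(template, current)[heavy_idx]))
        else:
            current = _random_conformation(template, box, rng)
        current, f_current = local_opt(current)
        minima.append((current, f_current,
                       realize(template, current)[heavy_idx]))
        for _ in range(n_iter):
            candidate = mutate(current, rng, config.amplitudes)
            candidate, f_cand = local_opt(candidate)
            if metropolis_accept(f_cand - f_current,
                                 config.metropolis_temperature, rng):
                current, f_current = candidate, f_cand
                minima.append((current, f_current,
                               realize(template, current)[heavy_idx]))

    # The grid drives the search; the final ranking works on the exact
    # pair sums.  Each distinct candidate is first polished by an exact
    # BFGS pass: nearest-node lookups quantize the landscape at the
    # lattice spacing, so grid-driven minima stop short of the true
    # optimum by up to a node, which is enough to reorder near-degenerate
    # poses.
    exact = Scorer(template, receptor, box, table, exact=True)
    minima = [
        (conf, exact.score_coords(realize(template, conf)).e_total, heavy)
        for conf, _, heavy in minima
    ]
    candidates = cluster_and_select(minima, config.cluster_rmsd,
                                    2 * config.max_poses)
    # greedy basin-hopping refinement around the leading candidates:
    # chains often stop one barrier short of the basin floor; a short
    # improvement-only walk (grid-driven proposals, exact acceptance)
    # takes the last hops
    def exact_of(conf: Conformation) -> float:
        return exact.score_coords(realize(template, conf)).e_total

    def flip_proposals(conf: Conformation, heavy: np.ndarray):
        """End-over-end flips about the axes normal to the pose's long axis.

        An elongated ligand bound backwards is a classic trapped state:
        no sequence of small moves can reverse it inside the site.  A
        half-turn about either perpendicular axis through the centroid,
        followed by local optimization, proposes the reversed binding
        mode directly.
        """
        centroid = heavy.mean(axis=0)
        _, _, vt = np.linalg.svd(heavy - centroid)
        for axis in vt[1:]:
            rot = Rotation.from_rotvec(np.pi * axis)
            q = (rot * Rotation.from_quat(conf.orientation)).as_quat()
            yield Conformation(
                position=centroid + rot.apply(conf.position - centroid),
                orientation=q / np.linalg.norm(q),
                torsions=conf.torsions.copy(),
            )

    refined = []
    for c_idx, (conf, f_exact, heavy) in enumerate(candidates):
        current, f_current = conf, f_exact
        if c_idx < config.max_poses:
            for proposal in flip_proposals(conf, heavy):
                cand, _ = local_opt(proposal)
                f_cand = exact_of(cand)
                if f_cand < f_current:
                    current, f_current = cand, f_cand
            rng = np.random.default_rng(config.seed + 100_000 + c_idx)
            for _ in range(config.refine_iterations):
                cand, _ = local_opt(mutate(current, rng, config.amplitudes))
                f_cand = exact_of(cand)
                if f_cand < f_current:
                    current, f_current = cand, f_cand
        refined.append((current, f_current,
                        realize(template, current)[heavy_idx]))
    candidates = refined
    polished = []
    for conf, _, _ in candidates:
        v, f = bfgs_local_optimize(
            exact.conf_to_vector(conf),
            lambda v_: exact.value_and_gradient(v_, conf))
        out = exact.vector_to_conf(v, conf)
        polished.append((out, f, realize(template, out)[heavy_idx]))
    selected = cluster_and_select(polished, config.cluster_rmsd,
                                  config.max_poses)
    if not selected:
        return []

    # output free energies: subtract the best pose's intra score, penalize
    # flexibility, and attach the per-atom decomposition plus H-bonds
    poses: list[ScoredPose] = []
    best_breakdown = exact.score_coords(realize(template, selected[0][0]))
    e_intra_1 = best_breakdown.e_intra
    for conf, _, _ in selected:
        coords = realize(template, conf)
        breakdown = exact.score_coords(coords)
        energy = flexibility_penalized_energy(
            breakdown.e_total, e_intra_1,
            template.n_active, template.n_inactive, weights)
        hbonds = detect_hbonds(receptor, coords[heavy_idx],
                               scorer.heavy_types)
        poses.append(ScoredPose(conformation=conf, coords=coords,
                                breakdown=breakdown, energy_kcal=energy,
                                hbonds=hbonds))
    poses.sort(key=lambda p: p.energy_kcal)
    if rf_model is not None:
        from .rescoring import rescore_poses
        rescore_poses(poses, receptor, rf_model, template)
    return poses
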