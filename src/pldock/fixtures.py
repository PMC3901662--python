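"""Programmatic toy complexes and synthetic training data.

Everything the test suite and the acceptance checks need is generated
here, so no external structure or affinity dataset is required:

* ``make_funnel_complex`` builds a short zigzag ligand chain (terminal
  acceptor oxygen, then nitrogen, then carbons) seated in a surface
  pocket: a solid floor slab of hydrophobic carbons captures approaches
  from anywhere in the box onto a smooth attractive surface, flanking
  ridges funnel surface diffusion into a groove, and the groove's buried
  end is recognized by a carbon cap plus two donor nitrogens that
  hydrogen-bond the oxygen (a flipped chain presents carbon instead and
  is repelled).  The
  nominal geometry is first *relaxed* to the scoring function's own
  local minimum and the ligand replanted there, so the planted pose is a
  true optimum of the engine's potential; certification then scans an
  exhaustive translation grid crossed with 180-degree flips and quarter
  turns, plus random rigid probes, and requires every competitive score
  to lie within 1 A RMSD of the plant — retrying with a jittered cage on
  failure.  Search tests never trust construction geometry alone.

* ``make_rf_training_set`` emulates the statistical shape the rescoring
  forest assumes: non-negative Poisson contact counts linked to a pKd
  label through a sparse linear map with a mild pairwise interaction and
  Gaussian noise.  The ground-truth function is returned for recovery
  tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .conformation import rmsd
from .energetics import (
    PairPotentialTable,
    intra_score,
    lookup_by_pair,
    pair_index,
    precalculate_table,
)
from .evaluation import auto_search_box
from .gridmaps import SearchBox, direct_inter_score
from .pdbqt import LigandTemplate, Receptor, parse_ligand, parse_receptor

__all__ = [
    "FixtureSpec",
    "FunnelComplex",
    "FixtureError",
    "make_funnel_complex",
    "make_rf_training_set",
]


class FixtureError(RuntimeError):
    """Fixture construction could not certify its planted optimum."""


class _DeeperMinimum(Exception):
    """Certification found a strictly deeper basin: replant the ligand there."""

    def __init__(self, coords: np.ndarray, score: float):
        super().__init__(f"deeper minimum at {score:.3f}")
        self.coords = coords
        self.score = score


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry and noise knobs of the toy complex generator."""

    seed: int = 0
    n_pocket_atoms: int = 2      # ridge atoms flanking each ligand atom
    pocket_radius: float = 4.1   # A, groove half-width (~ VdW contact)
    ligand_n_heavy: int = 5
    ligand_n_torsions: int = 0
    noise_sigma: float = 0.0     # A, jitter on cage atom positions

    def __post_init__(self):
        if self.n_pocket_atoms < 0 or self.ligand_n_heavy < 4:
            raise ValueError("need n_pocket_atoms >= 0, ligand_n_heavy >= 4")
        if self.ligand_n_heavy < 4 + self.ligand_n_torsions:
            raise ValueError("need at least 4 + torsions heavy atoms")


@dataclass
class FunnelComplex:
    receptor_text: str
    ligand_text: str
    receptor: Receptor
    template: LigandTemplate
    box: SearchBox
    planted_heavy_coords: np.ndarray
    planted_score: float


def _atom_line(serial: int, name: str, xyz, ad_type: str,
               record: str = "ATOM") -> str:
    name_f = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {name_f:<4s}{'LIG':>4s} A{1:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"    {0.0:6.3f} {ad_type:<2s}"
    )


def _ligand_geometry(spec: FixtureSpec) -> tuple[np.ndarray, list[str]]:
    """Zigzag heavy-atom chain along x: acceptor O first, then N, carbons.

    The oxygen sits at the buried end of the pocket; the zigzag keeps
    chain bonds off the x axis so torsions genuinely move heavy atoms.
    """
    n = spec.ligand_n_heavy
    coords = np.array(
        [[1.4 * i, 0.25 * (-1) ** i, 0.0] for i in range(n)], dtype=float
    )
    ad_types = ["OA", "NA"] + ["C"] * (n - 2)
    return coords, ad_types


def _ligand_pdbqt(spec: FixtureSpec, coords: np.ndarray,
                  ad_types: list[str]) -> str:
    """Emit the L with the requested number of BRANCH frames.

    With one torsion the N-O arm becomes a branch about the C-N bond; the
    bent oxygen guarantees the torsion moves a heavy atom and stays
    active.  Further torsions peel chain bonds off the root, innermost
    first.
    """
    n = spec.ligand_n_heavy
    t = spec.ligand_n_torsions
    names = []
    for i, ad in enumerate(ad_types):
        elem = {"OA": "O"}.get(ad, ad)
        names.append(f"{elem}{i + 1}"[:4])

    # frame f holds atoms [starts[f], starts[f+1]); frame 0 is the root
    n_root = n - 2 - (t - 1) if t else n
    starts = [0, n_root] + [n_root + 1 + k for k in range(max(t - 1, 0))]
    starts = starts[: t + 1] + [n]
    lines = ["ROOT"]
    for i in range(starts[0], starts[1]):
        lines.append(_atom_line(i + 1, names[i], coords[i], ad_types[i]))
    lines.append("ENDROOT")
    for f in range(1, t + 1):
        first = starts[f]
        lines.append(f"BRANCH {first:>3d} {first + 1:>3d}")
        for i in range(starts[f], starts[f + 1]):
            lines.append(_atom_line(i + 1, names[i], coords[i], ad_types[i]))
    for f in reversed(range(1, t + 1)):
        first = starts[f]
        lines.append(f"ENDBRANCH {first:>3d} {first + 1:>3d}")
    lines.append(f"TORSDOF {t}")
    return "\n".join(lines) + "\n"


def _receptor_cage(spec: FixtureSpec, lig_coords: np.ndarray,
                   rng: np.random.Generator) -> str:
    """A surface pocket: solid floor slab, flanking ridges, seat anchors.

    A lattice of hydrophobic floor carbons at Van-der-Waals contact below
    the ligand plane captures approaches from anywhere in the box onto a
    smooth, gently attractive surface; two ridges flanking the chain
    funnel surface diffusion into the groove; and the buried (-x) end is
    recognized by a carbon cap plus two donor nitrogens hydrogen-bonding
    the terminal acceptor oxygen.  A flipped chain presents carbon to the
    donors and is sterically repelled, so the seated pose is unique.
    """
    R = spec.pocket_radius
    o_end = lig_coords[0]
    x_lo, x_hi = lig_coords[:, 0].min(), lig_coords[:, 0].max()
    atoms: list[tuple[np.ndarray, str]] = []
    floor_z = -(R - 0.25)
    for fx in np.arange(x_lo - 6.5, x_hi + 6.6, 2.0):
        for fy in np.arange(-8.0, 8.1, 2.0):
            atoms.append((np.array([fx, fy, floor_z]), "C"))
            # second slab layer: leaves no habitable space between the
            # floor's underside and the box wall
            atoms.append((np.array([fx, fy, floor_z - 2.8]), "C"))
    # ridges flank the full chain so the tail cannot swing onto the open
    # floor; registry discrimination comes from the hydrogen-bond seat
    for p in lig_coords:
        for row in range(max(spec.n_pocket_atoms // 2, 1)):
            for side in (1.0, -1.0):
                atoms.append((np.array([p[0], side * (R + 0.3 * row),
                                        -1.0 - 1.2 * row]), "C"))
    for k, flare in ((1, 1.3), (2, 2.6)):  # widen the entrance
        for side in (1.0, -1.0):
            atoms.append((np.array([x_hi + 1.4 * k,
                                    side * (R + flare), -1.0]), "C"))
    atoms.append((o_end + np.array([-3.7, 0.0, 0.0]), "C"))  # seat cap
    donor_sites = [o_end + np.array([-2.2, sign * 2.2, 0.0])
                   for sign in (1.0, -1.0)]
    # donors sunk into the floor beneath the oxygen seat: they reward the
    # correctly oriented chain (O leads into the seat) but sit at the end
    # of the slide-in path, so a flipped chain only meets them — as a
    # steric bump under its terminal carbon — once fully seated
    donor_sites += [o_end + np.array([0.0, sign * 1.0, -3.0])
                    for sign in (1.0, -1.0)]
    for donor_n in donor_sites:
        atoms.append((donor_n, "N"))
        to_o = (o_end - donor_n) / np.linalg.norm(o_end - donor_n)
        atoms.append((donor_n + 0.95 * to_o, "HD"))
    lines = []
    for serial, (xyz, ad) in enumerate(atoms, start=1):
        if spec.noise_sigma > 0 and ad != "HD":
            xyz = xyz + rng.normal(0.0, spec.noise_sigma, 3)
        name = {"C": f"C{serial}", "N": f"N{serial}", "HD": f"H{serial}"}[ad]
        lines.append(_atom_line(serial, name[:4], xyz, ad))
    return "\n".join(lines) + "\n"


def _relax(nominal: LigandTemplate, receptor: Receptor, box: SearchBox,
           table: PairPotentialTable, rng: np.random.Generator,
           n_starts: int = 128) -> np.ndarray:
    """Settle the nominal geometry into the potential's deepest near basin.

    Runs BFGS on the exact (grid-free) potential from the nominal pose
    and from jittered copies, keeping the best minimum, so the replanted
    pose is the true optimum of the analytic potential in the pocket
    neighbourhood — not a shallower sub-basin of the hand-built geometry.
    Returns relaxed coordinates for every template atom.
    """
    from .conformation import Conformation, identity_conformation, realize
    from .search import Scorer, bfgs_local_optimize
    from scipy.spatial.transform import Rotation as _Rot

    scorer = Scorer(nominal, receptor, box, table, exact=True)
    conf0 = identity_conformation(nominal)

    def _descend(conf):
        v, f = bfgs_local_optimize(
            scorer.conf_to_vector(conf),
            lambda vv: scorer.value_and_gradient(vv, conf),
        )
        return scorer.vector_to_conf(v, conf), f

    best_conf, best_f = _descend(conf0)
    for _ in range(n_starts):
        dq = _Rot.from_rotvec(rng.normal(0.0, 0.35, 3))
        q = (dq * _Rot.from_quat(conf0.orientation)).as_quat()
        start = Conformation(
            position=conf0.position + rng.uniform(-2.0, 2.0, 3),
            orientation=q / np.linalg.norm(q),
            torsions=rng.uniform(-0.7, 0.7, nominal.n_active),
        )
        conf, f = _descend(start)
        if f < best_f - 1e-9:
            best_conf, best_f = conf, f
    return realize(nominal, best_conf)


#: proper rotations probed by certification: identity, the three
#: 180-degree flips, and in-plane quarter turns
_CERT_ROTATIONS = [
    Rotation.identity(),
    Rotation.from_rotvec([np.pi, 0, 0]),
    Rotation.from_rotvec([0, np.pi, 0]),
    Rotation.from_rotvec([0, 0, np.pi]),
    Rotation.from_rotvec([0, 0, np.pi / 2]),
    Rotation.from_rotvec([0, 0, -np.pi / 2]),
    Rotation.from_rotvec([np.pi / 2, 0, 0]),
    Rotation.from_rotvec([0, np.pi / 2, 0]),
]


def _batch_inter_scores(receptor: Receptor, probes: np.ndarray,
                        types: list[str],
                        table: PairPotentialTable) -> np.ndarray:
    """Inter-molecular score of many rigid probes at once.

    ``probes`` has shape (n_probes, n_heavy, 3); returns (n_probes,).
    """
    rec_coords = receptor.heavy_coords()
    rec_types = receptor.heavy_types()
    pair_idx = np.array(
        [[pair_index(t, rt) for rt in rec_types] for t in types], dtype=int
    )
    delta = probes[:, :, None, :] - rec_coords[None, None, :, :]
    r = np.sqrt((delta ** 2).sum(axis=-1))
    return lookup_by_pair(
        table, r, np.broadcast_to(pair_idx, r.shape)
    ).sum(axis=(1, 2))


def _certify(receptor: Receptor, template: LigandTemplate, box: SearchBox,
             table: PairPotentialTable, planted: np.ndarray,
             rng: np.random.Generator, scan_step: float = 1.0,
             n_random_probes: int = 300, gap: float = 0.2,
             rmsd_tol: float = 1.0, n_polish: int = 48) -> float:
    """Exhaustive-scan certification of the planted optimum.

    Rigid copies of the ligand are scored at every translation on a
    ``scan_step`` grid over the box, under each certification rotation,
    and at random rigid placements.  Certification fails if any probe
    scores within ``gap`` of the planted score while lying more than
    ``rmsd_tol`` away from the planted pose.  Because rigid probes can
    hide decoys that only become competitive after relaxation, the
    ``n_polish`` lowest-scoring off-plant probes are additionally driven
    to their local minima by BFGS on the exact potential and must stay
    outside the gap there too.
    """
    from .conformation import Conformation, realize
    from .search import Scorer, bfgs_local_optimize

    heavy_idx = template.heavy_indices()
    types = [template.atoms[i].type for i in heavy_idx]
    heavy0 = template.input_coords()[heavy_idx]
    center0 = heavy0.mean(axis=0)
    origin0 = np.asarray(template.root.atoms[0].coords, dtype=float)
    e_intra_planted = intra_score(template, planted, table)

    e_inter_planted, _ = direct_inter_score(receptor, planted, types, table)
    planted_score = e_inter_planted + e_intra_planted

    lo, hi = box.origin, box.upper
    axes = [np.arange(lo[k], hi[k] + 1e-9, scan_step) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    all_scores: list[np.ndarray] = []
    all_rots: list[Rotation] = []
    all_shifts: list[np.ndarray] = []

    def _scan(rots: Rotation, shifts: np.ndarray, paired: bool) -> None:
        """Score probes; ``paired`` pairs rotations with shifts 1:1."""
        mats = rots.as_matrix()
        if mats.ndim == 2:
            mats = mats[None]
        if paired:
            probes = np.einsum("nij,aj->nai", mats, heavy0 - center0) \
                + shifts[:, None, :]
            rot_seq = rots
        else:  # one rotation against every shift
            probes = (heavy0 - center0) @ mats[0].T + shifts[:, None, :]
            rot_seq = Rotation.concatenate([rots] * len(shifts))
        scores = _batch_inter_scores(receptor, probes, types, table) \
            + e_intra_planted
        for s in np.flatnonzero(scores <= planted_score + gap):
            if rmsd(probes[s], planted) > rmsd_tol:
                raise FixtureError(
                    f"off-plant minimum {scores[s]:.3f} (planted "
                    f"{planted_score:.3f})"
                )
        all_scores.append(scores)
        all_rots.append(rot_seq)
        all_shifts.append(shifts)

    for rot in _CERT_ROTATIONS:
        _scan(rot, grid, paired=False)
    shifts = lo + rng.random((n_random_probes, 3)) * (hi - lo)
    _scan(Rotation.random(n_random_probes,
                          random_state=int(rng.integers(2**31 - 1))),
          shifts, paired=True)

    # polish the most competitive off-plant probes: rigid probes can hide
    # decoys that deepen under relaxation
    scores = np.concatenate(all_scores)
    rots = Rotation.concatenate(all_rots)
    shifts = np.concatenate(all_shifts)
    exact = Scorer(template, receptor, box, table, exact=True)
    deepest: tuple[float, np.ndarray] | None = None
    for s in np.argsort(scores)[:n_polish]:
        rot = rots[int(s)]
        conf = Conformation(
            position=rot.apply(origin0 - center0) + shifts[s],
            orientation=rot.as_quat(),
            torsions=np.zeros(template.n_active),
        )
        v, f = bfgs_local_optimize(
            exact.conf_to_vector(conf),
            lambda v_: exact.value_and_gradient(v_, conf))
        out_all = realize(template, exact.vector_to_conf(v, conf))
        if deepest is None or f < deepest[0]:
            deepest = (f, out_all)
        if f <= planted_score + gap and \
                rmsd(out_all[heavy_idx], planted) > rmsd_tol:
            raise FixtureError(
                f"relaxed off-plant minimum {f:.3f} (planted "
                f"{planted_score:.3f})"
            )
    if deepest is not None and deepest[0] < planted_score - 1e-6:
        raise _DeeperMinimum(deepest[1], deepest[0])
    return planted_score


def make_funnel_complex(spec: FixtureSpec = FixtureSpec(),
                        table: PairPotentialTable | None = None,
                        max_retries: int = 5,
                        granularity: float | None = None) -> FunnelComplex:
    """Build and certify a single-minimum ('funnel') toy complex.

    Deterministic under ``spec.seed``.  Retries with a freshly jittered
    cage when certification finds a competitive off-plant minimum; raises
    :class:`FixtureError` after ``max_retries`` failures.
    """
    table = table or precalculate_table()
    lig_coords, ad_types = _ligand_geometry(spec)
    nominal_text = _ligand_pdbqt(spec, lig_coords, ad_types)
    nominal = parse_ligand(nominal_text)
    box_kwargs = {} if granularity is None else {"granularity": granularity}
    box = auto_search_box(nominal.heavy_coords(), **box_kwargs)

    last_error: FixtureError | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(spec.seed + 1000 * attempt)
        jitter = spec.noise_sigma if attempt == 0 else 0.05 * attempt
        eff_spec = FixtureSpec(
            seed=spec.seed, n_pocket_atoms=spec.n_pocket_atoms,
            pocket_radius=spec.pocket_radius,
            ligand_n_heavy=spec.ligand_n_heavy,
            ligand_n_torsions=spec.ligand_n_torsions,
            noise_sigma=jitter,
        )
        receptor_text = _receptor_cage(eff_spec, lig_coords, rng)
        receptor = parse_receptor(receptor_text)
        relaxed = _relax(nominal, receptor, box, table, rng)
        score = None
        try:
            # replant whenever certification's polish pass uncovers a
            # strictly deeper basin, until the plant is the deepest
            for _ in range(8):
                ligand_text = _ligand_pdbqt(spec, relaxed, ad_types)
                template = parse_ligand(ligand_text)
                planted = template.heavy_coords()
                try:
                    score = _certify(receptor, template, box, table,
                                     planted, rng)
                    break
                except _DeeperMinimum as deeper:
                    relaxed = deeper.coords
            else:
                raise FixtureError("replanting did not converge")
        except FixtureError as exc:
            last_error = exc
            continue
        if score is None:
            continue
        return FunnelComplex(
            receptor_text=receptor_text,
            ligand_text=ligand_text,
            receptor=receptor,
            template=template,
            box=box,
            planted_heavy_coords=planted,
            planted_score=score,
        )
    raise FixtureError(
        f"could not certify a funnel complex in {max_retries} attempts: "
        f"{last_error}"
    )


def make_rf_training_set(n: int = 500, sigma: float = 0.1, seed: int = 0,
                         n_features: int = 36, n_informative: int = 8):
    """Synthetic contact-count features with a known affinity function.

    Features are Poisson counts (per-feature rates drawn once from
    U[0.5, 8]); labels are a sparse linear combination plus one mild
    pairwise interaction plus N(0, sigma) noise.  Returns
    ``(X, y, truth)`` where ``truth(X)`` reproduces the noiseless labels.
    """
    rng = np.random.default_rng(seed)
    rates = rng.uniform(0.5, 8.0, size=n_features)
    X = rng.poisson(rates, size=(n, n_features)).astype(float)
    support = rng.choice(n_features, size=n_informative, replace=False)
    coef = np.zeros(n_features)
    coef[support] = rng.normal(0.0, 0.25, size=n_informative)
    ia, ib = support[0], support[1]

    def truth(features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return features @ coef + 0.02 * features[:, ia] * features[:, ib] + 5.0

    y = truth(X) + rng.normal(0.0, sigma, size=n)
    return X, y, truth
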