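"""Empirical scoring function and its precalculated machinery.

The conformation-dependent score is a weighted sum of five closed-form
terms of the *surface distance* d = r - (R_a + R_b) between two heavy
atoms, cut off at r = 8 A:

    gauss1      = exp(-(d / 0.5)^2)
    gauss2      = exp(-((d - 3) / 2)^2)
    repulsion   = d^2 for d < 0, else 0
    hydrophobic = 1 for d <= 0.5, linear ramp to 0 over [0.5, 1.5]
    hbond       = 1 for d <= -0.7, linear ramp to 0 over [-0.7, 0]

The first three act on every heavy pair; the hydrophobic term only when
both atoms are hydrophobic; the hydrogen-bond term only on donor-acceptor
pairs (metal ions count as donors).  To make evaluation O(1) the weighted,
masked curve for each of the 120 unordered type pairs is sampled at 16,384
points over [0, 8 A] together with its analytic d/dr derivative; scoring
reads the nearest sample, no interpolation.

The conformation-independent part converts the best conformation-dependent
score into an output free energy by subtracting the intra-molecular score
of the top conformation and dividing by a flexibility penalty
1 + w_flex * (N_active + 0.5 * N_inactive).  Helpers convert kcal/mol to
pKd (-dG / (R T ln 10)), average two affinities into a consensus, compute
ligand efficiency, and detect putative hydrogen bonds geometrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .pdbqt import ATOM_TYPES, TYPE_CODES, LigandTemplate, Receptor
from .pdbqt import mobile_heavy_pairs

__all__ = [
    "ScoringWeights",
    "ScoreBreakdown",
    "PairPotentialTable",
    "ThermoConstants",
    "surface_distance",
    "term_values",
    "pair_score",
    "pair_score_derivative",
    "precalculate_table",
    "lookup_score",
    "lookup_derivative",
    "intra_score",
    "intra_score_and_gradient",
    "flexibility_penalized_energy",
    "kcal_to_pkd",
    "pkd_to_kcal",
    "consensus_score",
    "ligand_efficiency",
    "detect_hbonds",
    "pair_index",
    "N_TYPE_PAIRS",
    "DEFAULT_CUTOFF",
    "DEFAULT_N_SAMPLES",
    "HBOND_DISTANCE_MAX",
]

DEFAULT_CUTOFF = 8.0  # A
DEFAULT_N_SAMPLES = 16384
HBOND_DISTANCE_MAX = 3.5  # A, donor-acceptor heavy-atom distance

_N_TYPES = len(TYPE_CODES)
N_TYPE_PAIRS = _N_TYPES * (_N_TYPES + 1) // 2  # 120
_TYPE_INDEX = {code: i for i, code in enumerate(TYPE_CODES)}


@dataclass(frozen=True)
class ScoringWeights:
    """Term weights of the empirical score plus the flexibility coefficient.

    Defaults are the published regression values of the Vina-family scoring
    function this engine inherits; every value is overridable in config.
    """

    w_gauss1: float = -0.035579
    w_gauss2: float = -0.005156
    w_repulsion: float = 0.840245
    w_hydrophobic: float = -0.035069
    w_hbond: float = -0.587439
    w_flex: float = 0.05846

    def as_vector(self) -> np.ndarray:
        return np.array([
            self.w_gauss1, self.w_gauss2, self.w_repulsion,
            self.w_hydrophobic, self.w_hbond,
        ])


@dataclass(frozen=True)
class ThermoConstants:
    """R in kcal/(mol K) and T in K for the free-energy/pKd conversion."""

    gas_constant: float = 1.9872e-3
    temperature: float = 298.15


@dataclass
class ScoreBreakdown:
    e_total: float
    e_inter: float
    e_intra: float
    per_atom_inter: np.ndarray
    term_sums: np.ndarray | None = None


def pair_index(type_a: str, type_b: str) -> int:
    """Canonical index of an unordered type pair in [0, 120)."""
    i, j = sorted((_TYPE_INDEX[type_a], _TYPE_INDEX[type_b]))
    return i * _N_TYPES - i * (i + 1) // 2 + j


def surface_distance(r, type_a: str, type_b: str):
    """d = r - (R_a + R_b); negative when the Van der Waals surfaces overlap."""
    return r - (ATOM_TYPES[type_a].vdw_radius + ATOM_TYPES[type_b].vdw_radius)


def term_values(d):
    """The five unweighted, unmasked terms at surface distance d.

    Vectorized over d; returns shape (5,) + shape(d).
    """
    d = np.asarray(d, dtype=float)
    gauss1 = np.exp(-((d / 0.5) ** 2))
    gauss2 = np.exp(-(((d - 3.0) / 2.0) ** 2))
    repulsion = np.where(d < 0.0, d * d, 0.0)
    hydrophobic = np.clip(1.5 - d, 0.0, 1.0)
    hbond = np.clip(-d / 0.7, 0.0, 1.0)
    return np.stack([gauss1, gauss2, repulsion, hydrophobic, hbond])


def _term_derivatives(d):
    """d(term)/dd for the five terms (vectorized)."""
    d = np.asarray(d, dtype=float)
    gauss1 = -8.0 * d * np.exp(-((d / 0.5) ** 2))
    gauss2 = -0.5 * (d - 3.0) * np.exp(-(((d - 3.0) / 2.0) ** 2))
    repulsion = np.where(d < 0.0, 2.0 * d, 0.0)
    hydrophobic = np.where((d > 0.5) & (d < 1.5), -1.0, 0.0)
    hbond = np.where((d > -0.7) & (d < 0.0), -1.0 / 0.7, 0.0)
    return np.stack([gauss1, gauss2, repulsion, hydrophobic, hbond])


def _pair_mask(type_a: str, type_b: str) -> np.ndarray:
    """Term mask for a type pair: hydrophobic and hbond terms are gated."""
    a, b = ATOM_TYPES[type_a], ATOM_TYPES[type_b]
    hydrophobic = a.is_hydrophobic and b.is_hydrophobic
    hbond = (a.is_hbond_donor and b.is_hbond_acceptor) or \
            (a.is_hbond_acceptor and b.is_hbond_donor)
    return np.array([1.0, 1.0, 1.0, float(hydrophobic), float(hbond)])


def pair_score(r, type_a: str, type_b: str,
               weights: ScoringWeights | None = None,
               r_cutoff: float = DEFAULT_CUTOFF):
    """Analytic pair score at interatomic distance r (0 at/beyond cutoff)."""
    weights = weights or ScoringWeights()
    r = np.asarray(r, dtype=float)
    d = surface_distance(r, type_a, type_b)
    w = weights.as_vector() * _pair_mask(type_a, type_b)
    value = np.tensordot(w, term_values(d), axes=(0, 0))
    return np.where(r < r_cutoff, value, 0.0)[()]


def pair_score_derivative(r, type_a: str, type_b: str,
                          weights: ScoringWeights | None = None,
                          r_cutoff: float = DEFAULT_CUTOFF):
    """d(pair_score)/dr (0 at/beyond cutoff; d(d)/dr = 1)."""
    weights = weights or ScoringWeights()
    r = np.asarray(r, dtype=float)
    d = surface_distance(r, type_a, type_b)
    w = weights.as_vector() * _pair_mask(type_a, type_b)
    deriv = np.tensordot(w, _term_derivatives(d), axes=(0, 0))
    return np.where(r < r_cutoff, deriv, 0.0)[()]


@dataclass
class PairPotentialTable:
    """Sampled score and derivative curves for all 120 type pairs.

    ``values[p, i]`` is the weighted, masked score of pair ``p`` at
    r = i * r_cutoff / (n_samples - 1); the final sample sits exactly at the
    cutoff and is zero by construction.
    """

    n_samples: int
    r_cutoff: float
    values: np.ndarray       # (120, n_samples)
    derivatives: np.ndarray  # (120, n_samples)
    weights: ScoringWeights = field(default_factory=ScoringWeights)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def sample_spacing(self) -> float:
        return self.r_cutoff / (self.n_samples - 1)


def precalculate_table(weights: ScoringWeights | None = None,
                       n_samples: int = DEFAULT_N_SAMPLES,
                       r_cutoff: float = DEFAULT_CUTOFF) -> PairPotentialTable:
    """Sample every pair curve uniformly in r over [0, cutoff]."""
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    weights = weights or ScoringWeights()
    r = np.linspace(0.0, r_cutoff, n_samples)
    values = np.empty((N_TYPE_PAIRS, n_samples))
    derivs = np.empty((N_TYPE_PAIRS, n_samples))
    wvec = weights.as_vector()
    for i, code_a in enumerate(TYPE_CODES):
        for code_b in TYPE_CODES[i:]:
            p = pair_index(code_a, code_b)
            d = surface_distance(r, code_a, code_b)
            w = wvec * _pair_mask(code_a, code_b)
            values[p] = w @ term_values(d)
            derivs[p] = w @ _term_derivatives(d)
    # the cutoff sample is identically zero: score vanishes at r >= cutoff
    values[:, -1] = 0.0
    derivs[:, -1] = 0.0
    return PairPotentialTable(n_samples, r_cutoff, values, derivs, weights)


def _sample_indices(table: PairPotentialTable, r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("interatomic distance must be non-negative")
    idx = np.rint(r / table.sample_spacing).astype(int)
    return np.minimum(idx, table.n_samples - 1)


def lookup_score(table: PairPotentialTable, r, type_a: str, type_b: str):
    """Nearest-sample table read; exactly 0 at and beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    idx = _sample_indices(table, np.minimum(r, table.r_cutoff))
    value = table.values[pair_index(type_a, type_b), idx]
    return np.where(r < table.r_cutoff, value, 0.0)[()]


def lookup_derivative(table: PairPotentialTable, r, type_a: str, type_b: str):
    r = np.asarray(r, dtype=float)
    idx = _sample_indices(table, np.minimum(r, table.r_cutoff))
    value = table.derivatives[pair_index(type_a, type_b), idx]
    return np.where(r < table.r_cutoff, value, 0.0)[()]


# vectorized reads over arrays of pair indices (used by grids and intra)

def lookup_by_pair(table: PairPotentialTable, r: np.ndarray,
                   pair_idx: np.ndarray) -> np.ndarray:
    idx = _sample_indices(table, np.minimum(r, table.r_cutoff))
    return np.where(r < table.r_cutoff, table.values[pair_idx, idx], 0.0)


def lookup_deriv_by_pair(table: PairPotentialTable, r: np.ndarray,
                         pair_idx: np.ndarray) -> np.ndarray:
    idx = _sample_indices(table, np.minimum(r, table.r_cutoff))
    return np.where(r < table.r_cutoff, table.derivatives[pair_idx, idx], 0.0)


# analytic (table-free) vectorized evaluation over arrays of pair indices:
# the smooth reference path used by exact rescoring and gradient checks

_PAIR_RADII_SUM = np.empty(N_TYPE_PAIRS)
for _i, _a in enumerate(TYPE_CODES):
    for _b in TYPE_CODES[_i:]:
        _PAIR_RADII_SUM[pair_index(_a, _b)] = (
            ATOM_TYPES[_a].vdw_radius + ATOM_TYPES[_b].vdw_radius)

_WEIGHT_MATRIX_CACHE: dict[ScoringWeights, np.ndarray] = {}


def _pair_weight_matrix(weights: ScoringWeights) -> np.ndarray:
    """(120, 5) masked term weights per canonical pair index."""
    cached = _WEIGHT_MATRIX_CACHE.get(weights)
    if cached is None:
        cached = np.empty((N_TYPE_PAIRS, 5))
        wvec = weights.as_vector()
        for i, a in enumerate(TYPE_CODES):
            for b in TYPE_CODES[i:]:
                cached[pair_index(a, b)] = wvec * _pair_mask(a, b)
        _WEIGHT_MATRIX_CACHE[weights] = cached
    return cached


def analytic_by_pair(weights: ScoringWeights, r: np.ndarray,
                     pair_idx: np.ndarray,
                     r_cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    d = r - _PAIR_RADII_SUM[pair_idx]
    terms = term_values(d)
    w = _pair_weight_matrix(weights)[pair_idx]
    value = np.einsum("k...,...k->...", terms, w)
    return np.where(r < r_cutoff, value, 0.0)


def analytic_deriv_by_pair(weights: ScoringWeights, r: np.ndarray,
                           pair_idx: np.ndarray,
                           r_cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    d = r - _PAIR_RADII_SUM[pair_idx]
    terms = _term_derivatives(d)
    w = _pair_weight_matrix(weights)[pair_idx]
    value = np.einsum("k...,...k->...", terms, w)
    return np.where(r < r_cutoff, value, 0.0)


# ---------------------------------------------------------------------------
# Intra-molecular score
# ---------------------------------------------------------------------------

class IntraPairs:
    """Precomputed mobile heavy-atom pair list of one ligand template.

    Pairs rigidly coupled (no active torsion on the tree path between their
    frames) and 1-4 exclusions contribute nothing and are dropped once here.
    Indices are positions in the template's full atom list.
    """

    def __init__(self, template: LigandTemplate):
        pairs = mobile_heavy_pairs(template)
        self.i = np.array([p[0] for p in pairs], dtype=int)
        self.j = np.array([p[1] for p in pairs], dtype=int)
        self.pair_idx = np.array(
            [
                pair_index(template.atoms[a].type, template.atoms[b].type)
                for a, b in pairs
            ],
            dtype=int,
        )

    def __len__(self):
        return len(self.i)


def intra_score(template: LigandTemplate, coords: np.ndarray,
                table: PairPotentialTable,
                pairs: IntraPairs | None = None) -> float:
    """Sum of table reads over mobile, non-1-4 heavy-atom pairs."""
    pairs = pairs or IntraPairs(template)
    if len(pairs) == 0:
        return 0.0
    delta = coords[pairs.i] - coords[pairs.j]
    r = np.linalg.norm(delta, axis=1)
    return float(lookup_by_pair(table, r, pairs.pair_idx).sum())


def intra_score_and_gradient(template: LigandTemplate, coords: np.ndarray,
                             table: PairPotentialTable,
                             pairs: IntraPairs | None = None,
                             analytic: bool = False):
    """Intra score plus its Cartesian gradient over all template atoms."""
    pairs = pairs or IntraPairs(template)
    grad = np.zeros_like(coords)
    if len(pairs) == 0:
        return 0.0, grad
    delta = coords[pairs.i] - coords[pairs.j]
    r = np.linalg.norm(delta, axis=1)
    r_safe = np.maximum(r, 1e-12)
    if analytic:
        value = analytic_by_pair(table.weights, r, pairs.pair_idx,
                                 table.r_cutoff)
        dvdr = analytic_deriv_by_pair(table.weights, r, pairs.pair_idx,
                                      table.r_cutoff)
    else:
        value = lookup_by_pair(table, r, pairs.pair_idx)
        dvdr = lookup_deriv_by_pair(table, r, pairs.pair_idx)
    force = (dvdr / r_safe)[:, None] * delta
    np.add.at(grad, pairs.i, force)
    np.add.at(grad, pairs.j, -force)
    return float(value.sum()), grad


# ---------------------------------------------------------------------------
# Conformation-independent part and output quantities
# ---------------------------------------------------------------------------

def flexibility_penalized_energy(e_i: float, e_intra_1: float,
                                 n_active: int, n_inactive: int,
                                 weights: ScoringWeights | None = None) -> float:
    """Output free energy of one conformation (kcal/mol).

    Subtracts the intra-molecular score of the top-ranked conformation
    (keeping the within-ligand ranking intact, since the subtrahend and the
    denominator are constant per ligand) and divides by the flexibility
    penalty; inactive torsions count half.
    """
    weights = weights or ScoringWeights()
    penalty = 1.0 + weights.w_flex * (n_active + 0.5 * n_inactive)
    return (e_i - e_intra_1) / penalty


def kcal_to_pkd(delta_g: float,
                constants: ThermoConstants = ThermoConstants()) -> float:
    """pKd = -dG / (R T ln 10); about -dG / 1.364 at room temperature."""
    rt = constants.gas_constant * constants.temperature
    return -delta_g / (rt * math.log(10.0))


def pkd_to_kcal(pkd: float,
                constants: ThermoConstants = ThermoConstants()) -> float:
    rt = constants.gas_constant * constants.temperature
    return -pkd * rt * math.log(10.0)


def consensus_score(pkd_a: float, pkd_b: float) -> float:
    """Arithmetic mean of two affinity predictions on the pKd scale."""
    return 0.5 * (pkd_a + pkd_b)


def ligand_efficiency(delta_g: float, n_heavy: int) -> float:
    """Free energy per heavy atom (kcal/mol per heavy atom)."""
    if n_heavy < 1:
        raise ValueError("ligand efficiency requires at least one heavy atom")
    return delta_g / n_heavy


def detect_hbonds(receptor: Receptor, ligand_coords: np.ndarray,
                  ligand_types: list[str],
                  threshold: float = HBOND_DISTANCE_MAX):
    """Putative hydrogen bonds: donor-acceptor heavy pairs within threshold.

    Geometric criterion only (no angles: hydrogen placement in PDBQT input
    is not reliable).  Returns (receptor serial, ligand index, distance)
    tuples sorted by distance.
    """
    out = []
    for atom in receptor.heavy_atoms:
        info_r = atom.type_info
        for li, code in enumerate(ligand_types):
            info_l = ATOM_TYPES[code]
            paired = (info_r.is_hbond_donor and info_l.is_hbond_acceptor) or \
                     (info_r.is_hbond_acceptor and info_l.is_hbond_donor)
            if not paired:
                continue
            dist = float(np.linalg.norm(atom.coords - ligand_coords[li]))
            if dist <= threshold:
                out.append((atom.serial, li, dist))
    return sorted(out, key=lambda t: t[2])
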