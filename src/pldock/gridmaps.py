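"""Per-atom-type energy lattices over the search box.

A grid map for heavy-atom type *t* stores, at every lattice node of the
cubic search box, the inter-molecular score a probe atom of type *t* would
receive there: the sum of pair-potential reads over all receptor heavy
atoms within the 8 A cutoff.  Three companion lattices hold the Cartesian
gradient of that value.  During search, each ligand heavy atom reads the
nearest node — no interpolation — making an inter-molecular evaluation
O(number of ligand heavy atoms).

Maps are built lazily, only for the atom types a ligand actually contains,
and cached per (receptor, box, granularity, weights) so a batch of ligands
against one receptor reuses them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .energetics import (
    PairPotentialTable,
    analytic_by_pair,
    analytic_deriv_by_pair,
    lookup_by_pair,
    lookup_deriv_by_pair,
    pair_index,
)
from .pdbqt import Receptor

__all__ = [
    "SearchBox",
    "GridMap",
    "build_grid_maps",
    "grid_lookup",
    "grid_gradient_lookup",
    "direct_inter_score",
    "direct_inter_gradient",
    "GridMapCache",
    "OutOfBoxError",
    "DEFAULT_GRANULARITY",
]

DEFAULT_GRANULARITY = 0.15625  # A


class OutOfBoxError(ValueError):
    """A ligand atom lies outside the search box lattice."""


@dataclass(frozen=True)
class SearchBox:
    """Cubic search box: center, edge length, and lattice granularity (A)."""

    center: tuple[float, float, float]
    size: float
    granularity: float = DEFAULT_GRANULARITY

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError("box size must be positive")
        if self.granularity <= 0:
            raise ValueError("granularity must be positive")

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float) - self.size / 2.0

    @property
    def dims(self) -> tuple[int, int, int]:
        n = max(2, int(math.ceil(self.size / self.granularity)) + 1)
        return (n, n, n)

    @property
    def upper(self) -> np.ndarray:
        return self.origin + (self.dims[0] - 1) * self.granularity

    def contains(self, coords: np.ndarray) -> bool:
        coords = np.atleast_2d(coords)
        return bool(
            np.all(coords >= self.origin - 1e-9)
            and np.all(coords <= self.upper + 1e-9)
        )

    def clamp(self, coords: np.ndarray) -> np.ndarray:
        return np.clip(coords, self.origin, self.upper)

    def random_point(self, rng: np.random.Generator) -> np.ndarray:
        return self.origin + rng.random(3) * (self.upper - self.origin)


@dataclass
class GridMap:
    atom_type: str
    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    values: np.ndarray     # (nx, ny, nz)
    gradients: np.ndarray  # (nx, ny, nz, 3)


def _node_axes(box: SearchBox):
    nx, ny, nz = box.dims
    o = box.origin
    g = box.granularity
    return (o[0] + g * np.arange(nx),
            o[1] + g * np.arange(ny),
            o[2] + g * np.arange(nz))


def build_grid_maps(receptor: Receptor, box: SearchBox,
                    table: PairPotentialTable,
                    needed_types: set[str]) -> dict[str, GridMap]:
    """Accumulate probe-atom energies and gradients on the box lattice.

    Each receptor heavy atom touches only the lattice window within the
    pair cutoff of itself, so construction is linear in receptor size for a
    fixed box.  A receptor with no atom near the box yields all-zero maps.
    """
    xs, ys, zs = _node_axes(box)
    dims = box.dims
    cutoff = table.r_cutoff
    rec_coords = receptor.heavy_coords()
    rec_types = receptor.heavy_types()

    maps: dict[str, GridMap] = {}
    for probe in needed_types:
        values = np.zeros(dims)
        grads = np.zeros(dims + (3,))
        for atom_xyz, atom_type in zip(rec_coords, rec_types):
            # lattice window intersecting the cutoff sphere of this atom
            i0 = np.searchsorted(xs, atom_xyz[0] - cutoff)
            i1 = np.searchsorted(xs, atom_xyz[0] + cutoff, side="right")
            j0 = np.searchsorted(ys, atom_xyz[1] - cutoff)
            j1 = np.searchsorted(ys, atom_xyz[1] + cutoff, side="right")
            k0 = np.searchsorted(zs, atom_xyz[2] - cutoff)
            k1 = np.searchsorted(zs, atom_xyz[2] + cutoff, side="right")
            if i0 >= i1 or j0 >= j1 or k0 >= k1:
                continue
            dx = xs[i0:i1, None, None] - atom_xyz[0]
            dy = ys[None, j0:j1, None] - atom_xyz[1]
            dz = zs[None, None, k0:k1] - atom_xyz[2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            p = np.full(r.shape, pair_index(probe, atom_type), dtype=int)
            values[i0:i1, j0:j1, k0:k1] += lookup_by_pair(table, r, p)
            dvdr = lookup_deriv_by_pair(table, r, p)
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(r > 1e-12, dvdr / r, 0.0)
            grads[i0:i1, j0:j1, k0:k1, 0] += scale * dx
            grads[i0:i1, j0:j1, k0:k1, 1] += scale * dy
            grads[i0:i1, j0:j1, k0:k1, 2] += scale * dz
        maps[probe] = GridMap(probe, box.origin.copy(), box.granularity,
                              dims, values, grads)
    return maps


def _node_indices(box_map: GridMap, coords: np.ndarray) -> tuple:
    rel = (np.atleast_2d(coords) - box_map.origin) / box_map.spacing
    idx = np.rint(rel).astype(int)
    dims = np.asarray(box_map.dims)
    if np.any(idx < 0) or np.any(idx >= dims):
        raise OutOfBoxError(
            "ligand atom outside the search box; clamp before lookup"
        )
    return idx[:, 0], idx[:, 1], idx[:, 2]


def grid_lookup(maps: dict[str, GridMap], coords: np.ndarray,
                types: list[str]):
    """Nearest-node inter-molecular score: total and per-atom vector."""
    per_atom = np.empty(len(types))
    for i, code in enumerate(types):
        m = maps[code]
        ix, iy, iz = _node_indices(m, coords[i])
        per_atom[i] = m.values[ix[0], iy[0], iz[0]]
    return float(per_atom.sum()), per_atom


def grid_gradient_lookup(maps: dict[str, GridMap], coords: np.ndarray,
                         types: list[str]) -> np.ndarray:
    """Per-atom Cartesian gradient of the inter-molecular score."""
    grad = np.empty((len(types), 3))
    for i, code in enumerate(types):
        m = maps[code]
        ix, iy, iz = _node_indices(m, coords[i])
        grad[i] = m.gradients[ix[0], iy[0], iz[0]]
    return grad


def direct_inter_score(receptor: Receptor, coords: np.ndarray,
                       types: list[str], table: PairPotentialTable,
                       analytic: bool = False):
    """Brute-force inter-molecular score (no grid): total and per-atom.

    With ``analytic=False`` every pair is read from the table, exactly as
    a grid node would be — the construction-time oracle for grid maps.
    With ``analytic=True`` the smooth closed forms are evaluated instead,
    giving the differentiable reference used by exact rescoring and
    gradient checks.
    """
    rec_coords = receptor.heavy_coords()
    rec_types = receptor.heavy_types()
    per_atom = np.zeros(len(types))
    for i, code in enumerate(types):
        r = np.linalg.norm(rec_coords - coords[i], axis=1)
        p = np.array([pair_index(code, t) for t in rec_types])
        if analytic:
            per_atom[i] = analytic_by_pair(table.weights, r, p,
                                           table.r_cutoff).sum()
        else:
            per_atom[i] = lookup_by_pair(table, r, p).sum()
    return float(per_atom.sum()), per_atom


def direct_inter_gradient(receptor: Receptor, coords: np.ndarray,
                          types: list[str], table: PairPotentialTable,
                          analytic: bool = False) -> np.ndarray:
    rec_coords = receptor.heavy_coords()
    rec_types = receptor.heavy_types()
    grad = np.zeros((len(types), 3))
    for i, code in enumerate(types):
        delta = coords[i] - rec_coords
        r = np.linalg.norm(delta, axis=1)
        p = np.array([pair_index(code, t) for t in rec_types])
        if analytic:
            dvdr = analytic_deriv_by_pair(table.weights, r, p,
                                          table.r_cutoff)
        else:
            dvdr = lookup_deriv_by_pair(table, r, p)
        scale = np.where(r > 1e-12, dvdr / np.maximum(r, 1e-12), 0.0)
        grad[i] = (scale[:, None] * delta).sum(axis=0)
    return grad


class GridMapCache:
    """Grid maps keyed by (receptor, box, granularity, weights).

    Lets a batch of ligands against one receptor share lattices; maps for
    atom types not yet seen are built on demand and merged in.
    """

    def __init__(self):
        self._store: dict[tuple, dict[str, GridMap]] = {}

    @staticmethod
    def _key(receptor: Receptor, box: SearchBox,
             table: PairPotentialTable) -> tuple:
        return (id(receptor), box.center, box.size, box.granularity,
                table.weights)

    def get(self, receptor: Receptor, box: SearchBox,
            table: PairPotentialTable,
            needed_types: set[str]) -> dict[str, GridMap]:
        key = self._key(receptor, box, table)
        maps = self._store.setdefault(key, {})
        missing = needed_types - set(maps)
        if missing:
            maps.update(build_grid_maps(receptor, box, table, missing))
        return maps
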