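"""Benchmark machinery: box definition, success rates, metrics, filtering.

``auto_search_box`` reproduces the automatic redocking protocol: the
smallest cube covering the ligand, extended by 10 A.  ``success_table``
summarizes per-complex redocking records into the standard success-rate
conditions (rank-1 RMSD and best-over-ranks RMSD below a set of
thresholds, 2.0 A being the conventional positive control, plus the rank
at which the minimum RMSD is first attained).  ``correlation_metrics``
computes Pearson/Spearman correlations, the standard deviation of the
prediction error and the RMSE between predicted and experimental
affinities.  ``filter_ligands`` applies the nine-descriptor closed-interval
screen (logical AND) used to select ligands before docking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gridmaps import DEFAULT_GRANULARITY, SearchBox

__all__ = [
    "RedockRecord",
    "PropertyRecord",
    "PROPERTY_NAMES",
    "SUCCESS_THRESHOLDS",
    "auto_search_box",
    "success_table",
    "correlation_metrics",
    "filter_ligands",
    "stratify_success",
]

SUCCESS_THRESHOLDS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5)

#: the nine ligand descriptors used for pre-docking filtering
PROPERTY_NAMES: tuple[str, ...] = (
    "mwt",            # molecular weight, g/mol
    "xlogp",          # partition coefficient
    "apolar_desolv",  # apolar desolvation, kcal/mol
    "polar_desolv",   # polar desolvation, kcal/mol
    "hbd",            # hydrogen-bond donors
    "hba",            # hydrogen-bond acceptors
    "tpsa",           # topological polar surface area, A^2
    "charge",         # net charge
    "rotors",         # rotatable bonds
)


@dataclass
class RedockRecord:
    """One complex's redocking outcome: RMSD of each ranked pose (A)."""

    case_id: str
    rmsd_by_rank: np.ndarray
    n_rotatable: int = 0
    n_metals_in_site: int = 0

    def __post_init__(self):
        self.rmsd_by_rank = np.asarray(self.rmsd_by_rank, dtype=float)
        if self.rmsd_by_rank.size == 0:
            raise ValueError("record needs at least one ranked pose")

    @property
    def rmsd_min(self) -> float:
        return float(self.rmsd_by_rank.min())

    @property
    def first_min_rank(self) -> int:
        """1-based rank first attaining the minimum RMSD (ties -> smallest)."""
        return int(np.argmin(self.rmsd_by_rank)) + 1


@dataclass
class PropertyRecord:
    """Nine-descriptor property record of one ligand."""

    ligand_id: str
    mwt: float
    xlogp: float
    apolar_desolv: float
    polar_desolv: float
    hbd: int
    hba: int
    tpsa: float
    charge: int
    rotors: int

    def descriptor(self, name: str) -> float:
        return getattr(self, name)


def auto_search_box(ligand_coords: np.ndarray, margin: float = 10.0,
                    granularity: float = DEFAULT_GRANULARITY) -> SearchBox:
    """Smallest cube covering the ligand, extended by ``margin`` (A).

    The extension is read as +margin on the cube edge (margin/2 per face),
    so a single atom yields a cube of edge ``margin`` centred on it.
    """
    coords = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    if coords.size == 0:
        raise ValueError("cannot define a box around zero atoms")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    center = tuple((lo + hi) / 2.0)
    edge = float((hi - lo).max()) + margin
    return SearchBox(center=center, size=edge, granularity=granularity)


def success_table(records: list[RedockRecord],
                  thresholds: tuple[float, ...] = SUCCESS_THRESHOLDS,
                  max_rank: int = 9) -> pd.Series:
    """Success-rate fractions over a set of redocking records.

    Conditions: ``rank{i}_eq_min`` — the minimum RMSD is first attained at
    rank i (a partition over ranks); ``rmsd1_lt_{t}`` and ``rmsdmin_lt_{t}``
    — rank-1 / best-over-ranks RMSD strictly below threshold t.
    """
    if not records:
        raise ValueError("no records")
    n = len(records)
    out: dict[str, float] = {}
    for i in range(1, max_rank + 1):
        out[f"rank{i}_eq_min"] = sum(
            r.first_min_rank == i for r in records) / n
    for t in thresholds:
        out[f"rmsd1_lt_{t:g}"] = sum(
            r.rmsd_by_rank[0] < t for r in records) / n
        out[f"rmsdmin_lt_{t:g}"] = sum(r.rmsd_min < t for r in records) / n
    return pd.Series(out)


def correlation_metrics(predicted, experimental,
                        sd_mode: str = "difference"):
    """(Rp, Rs, SD, RMSE) between predicted and experimental affinities.

    Spearman uses average ranks on ties.  ``sd_mode='difference'`` takes
    the sample standard deviation of (predicted - experimental);
    ``'residual'`` the residual standard error about the least-squares line
    of experimental on predicted (the convention of some scoring-function
    benchmarks).
    """
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if p.shape != e.shape or p.ndim != 1 or len(p) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(p) == 0.0 or np.std(e) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    rp = float(stats.pearsonr(p, e).statistic)
    rs = float(stats.spearmanr(p, e).statistic)
    rmse = float(np.sqrt(np.mean((p - e) ** 2)))
    if sd_mode == "difference":
        sd = float(np.std(p - e, ddof=1))
    elif sd_mode == "residual":
        slope, intercept = np.polyfit(p, e, 1)
        resid = e - (slope * p + intercept)
        sd = float(np.sqrt(np.sum(resid ** 2) / (len(p) - 2)))
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    return rp, rs, sd, rmse


def filter_ligands(records: list[PropertyRecord],
                   intervals: dict[str, tuple[float, float]]):
    """Keep ligands whose nine descriptors all lie in their closed intervals.

    Expanding an interval to the full range nullifies that condition; the
    kept count is reported before any docking happens (preview semantics).
    """
    for name, (lo, hi) in intervals.items():
        if name not in PROPERTY_NAMES:
            raise ValueError(f"unknown descriptor {name!r}")
        if lo > hi:
            raise ValueError(f"interval for {name} has lo > hi")
    kept = [
        r for r in records
        if all(
            intervals[name][0] <= r.descriptor(name) <= intervals[name][1]
            for name in intervals
        )
    ]
    return kept, len(kept)


def stratify_success(records: list[RedockRecord], by: str = "rotors",
                     threshold: float = 2.0, cut: int | None = None):
    """Rank-1 success rate per stratum of a complexity covariate.

    ``by='rotors'`` splits at ``cut`` rotatable bonds (default 10);
    ``by='metals'`` splits complexes with / without metal ions in the
    binding site.  Also reports the covariate's mean in the success and
    failure groups.
    """
    if by == "rotors":
        cut = 10 if cut is None else cut
        covariate = np.array([r.n_rotatable for r in records], dtype=float)
        low = covariate <= cut
        labels = (f"rotors<={cut}", f"rotors>{cut}")
    elif by == "metals":
        covariate = np.array([r.n_metals_in_site for r in records],
                             dtype=float)
        low = covariate == 0
        labels = ("no_metal", "metal")
    else:
        raise ValueError(f"unknown stratification {by!r}")
    success = np.array([r.rmsd_by_rank[0] < threshold for r in records])

    def _rate(mask):
        return float(success[mask].mean()) if mask.any() else float("nan")

    return {
        "rate_by_stratum": {labels[0]: _rate(low), labels[1]: _rate(~low)},
        "mean_covariate_success": float(covariate[success].mean())
        if success.any() else float("nan"),
        "mean_covariate_failure": float(covariate[~success].mean())
        if (~success).any() else float("nan"),
    }
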