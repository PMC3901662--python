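"""Random-forest rescoring of docked poses.

The feature vector of a protein-ligand complex counts, for each of the
4 protein elements (C, N, O, S) crossed with the 9 ligand elements
(C, N, O, F, P, S, Cl, Br, I), the occurrences of that element pair within
a 12 A distance cutoff — 36 non-negative integers.  The generous cutoff
implicitly captures solvation-shell structure.  A regression forest (500
unpruned CART trees grown on bootstrap samples, best variance-reducing
split among ``mtry`` randomly chosen features, nodes with at most 5
samples become leaves) maps the counts to a binding affinity in pKd units;
the forest prediction is the mean of the per-tree traversed-leaf means.

The forest itself is scikit-learn's RandomForestRegressor configured to
this protocol (``min_samples_split = min_node + 1`` realizes the
leaf-size-5 stopping rule); this module owns the feature definition,
training protocol, serialization and the pose-rescoring workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestRegressor

from .energetics import consensus_score, kcal_to_pkd
from .pdbqt import LigandTemplate, Receptor

__all__ = [
    "PROTEIN_ELEMENTS",
    "LIGAND_ELEMENTS",
    "N_FEATURES",
    "DEFAULT_FEATURE_CUTOFF",
    "FeatureVector",
    "RFConfig",
    "RandomForestModel",
    "extract_features",
    "train_rf",
    "predict_rf",
    "rescore_poses",
    "save_model",
    "load_model",
]

PROTEIN_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")
LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
N_FEATURES = len(PROTEIN_ELEMENTS) * len(LIGAND_ELEMENTS)  # 36
DEFAULT_FEATURE_CUTOFF = 12.0  # A

_P_INDEX = {e: i for i, e in enumerate(PROTEIN_ELEMENTS)}
_L_INDEX = {e: i for i, e in enumerate(LIGAND_ELEMENTS)}


@dataclass
class FeatureVector:
    """36 element-pair contact counts (protein element x ligand element)."""

    counts: np.ndarray
    cutoff: float = DEFAULT_FEATURE_CUTOFF

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_FEATURES,):
            raise ValueError(
                f"feature vector must have length {N_FEATURES}, "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    @staticmethod
    def feature_index(protein_element: str, ligand_element: str) -> int:
        return _P_INDEX[protein_element] * len(LIGAND_ELEMENTS) + \
            _L_INDEX[ligand_element]


def extract_features(receptor: Receptor, ligand_coords: np.ndarray,
                     ligand_elements: list[str],
                     cutoff: float = DEFAULT_FEATURE_CUTOFF) -> FeatureVector:
    """Count cross element-pair contacts within the cutoff (<= comparison).

    Atoms whose element is outside the 4/9 sets (hydrogens, metals,
    receptor halogens) are ignored.  Depends only on pairwise distances,
    hence invariant to atom order and to rigid motions of the complex.
    """
    counts = np.zeros(N_FEATURES, dtype=int)
    rec = [(a.coords, a.element) for a in receptor.heavy_atoms
           if a.element in _P_INDEX]
    lig = [(c, e) for c, e in zip(np.atleast_2d(ligand_coords),
                                  ligand_elements) if e in _L_INDEX]
    if rec and lig:
        rec_tree = cKDTree(np.array([c for c, _ in rec]))
        lig_tree = cKDTree(np.array([c for c, _ in lig]))
        for ri, neighbours in enumerate(
                rec_tree.query_ball_tree(lig_tree, r=cutoff)):
            pi = _P_INDEX[rec[ri][1]]
            for li in neighbours:
                counts[pi * len(LIGAND_ELEMENTS) + _L_INDEX[lig[li][1]]] += 1
    return FeatureVector(counts, cutoff)


@dataclass(frozen=True)
class RFConfig:
    """Forest hyper-parameters.

    ``min_node`` is the largest sample count at which a node stops
    splitting; ``mtry`` the number of features tried per split (about p/3
    for regression on 36 features).
    """

    n_trees: int = 500
    min_node: int = 5
    mtry: int = 12
    seed: int = 0


@dataclass
class RandomForestModel:
    config: RFConfig
    estimator: RandomForestRegressor
    y_min: float
    y_max: float

    @property
    def n_trees(self) -> int:
        return self.config.n_trees

    @property
    def trees(self) -> list:
        return list(self.estimator.estimators_)


def train_rf(features: np.ndarray, pkd: np.ndarray,
             config: RFConfig = RFConfig()) -> RandomForestModel:
    """Grow the regression forest; deterministic under ``config.seed``."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(pkd, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be a 2-D matrix matching pkd length")
    estimator = RandomForestRegressor(
        n_estimators=config.n_trees,
        criterion="squared_error",
        min_samples_split=config.min_node + 1,
        min_samples_leaf=1,
        max_features=min(config.mtry, X.shape[1]),
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    estimator.fit(X, y)
    return RandomForestModel(config, estimator, float(y.min()), float(y.max()))


def predict_rf(model: RandomForestModel, features) -> float | np.ndarray:
    """Mean over trees of traversed-leaf means (pKd units)."""
    if isinstance(features, FeatureVector):
        X = features.counts[None, :].astype(float)
        return float(model.estimator.predict(X)[0])
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.estimator.n_features_in_:
        raise ValueError(
            f"feature length {X.shape[1]} does not match the model "
            f"({model.estimator.n_features_in_})"
        )
    return model.estimator.predict(X)


def save_model(model: RandomForestModel, path) -> None:
    """Serialize (joblib): config + fitted trees + training label range."""
    joblib.dump(
        {"config": model.config, "estimator": model.estimator,
         "y_min": model.y_min, "y_max": model.y_max},
        path,
    )


def load_model(path) -> RandomForestModel:
    blob = joblib.load(path)
    return RandomForestModel(blob["config"], blob["estimator"],
                             blob["y_min"], blob["y_max"])


@dataclass
class RescoreSummary:
    """The two pose-selection rules compared in redocking benchmarks."""

    first_pose_pkd: float
    max_pose_pkd: float


def rescore_poses(poses, receptor: Receptor, model: RandomForestModel,
                  template: LigandTemplate) -> RescoreSummary:
    """Fill each pose's forest affinity and consensus score in place.

    The consensus is the mean of the forest pKd and the engine's own free
    energy converted to pKd.  Returns the first-pose and the best-over-
    poses forest affinities.
    """
    if not poses:
        raise ValueError("no poses to rescore")
    heavy_idx = template.heavy_indices()
    elements = [template.atoms[i].element for i in heavy_idx]
    for pose in poses:
        fv = extract_features(receptor, pose.coords[heavy_idx], elements)
        pose.rf_pkd = predict_rf(model, fv)
        pose.consensus_pkd = consensus_score(
            kcal_to_pkd(pose.energy_kcal), pose.rf_pkd)
    return RescoreSummary(
        first_pose_pkd=poses[0].rf_pkd,
        max_pose_pkd=max(p.rf_pkd for p in poses),
    )
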