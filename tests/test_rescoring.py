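"""Contact-count features and random-forest affinity rescoring."""

import numpy as np
import pytest

from pldock.conformation import identity_conformation, realize, ScoredPose
from pldock.energetics import kcal_to_pkd
from pldock.fixtures import make_rf_training_set
from pldock.pdbqt import parse_receptor
from pldock.rescoring import (
    DEFAULT_FEATURE_CUTOFF,
    FeatureVector,
    LIGAND_ELEMENTS,
    N_FEATURES,
    PROTEIN_ELEMENTS,
    RFConfig,
    extract_features,
    load_model,
    predict_rf,
    rescore_poses,
    save_model,
    train_rf,
)


def brute_force_features(receptor, lig_coords, lig_elements, cutoff=12.0):
    """O(n*m) double loop: the feature-extraction oracle."""
    counts = np.zeros(36, dtype=int)
    for atom in receptor.heavy_atoms:
        if atom.element not in PROTEIN_ELEMENTS:
            continue
        for coord, elem in zip(lig_coords, lig_elements):
            if elem not in LIGAND_ELEMENTS:
                continue
            if np.linalg.norm(atom.coords - coord) <= cutoff:
                counts[FeatureVector.feature_index(atom.element, elem)] += 1
    return counts


class TestExtractFeatures:
    def test_dimensions_and_cutoff_defaults(self):
        assert N_FEATURES == 36
        assert DEFAULT_FEATURE_CUTOFF == 12.0

    def test_single_pair_counted_once(self, tiny_receptor_text):
        rec = parse_receptor(tiny_receptor_text)
        # one ligand carbon 4 A from the receptor C, > 12 A from N and O
        fv = extract_features(rec, np.array([[0.0, 0.0, 4.0]]), ["C"])
        idx = FeatureVector.feature_index("C", "C")
        assert fv.counts[idx] >= 1
        assert fv.counts.sum() == brute_force_features(
            rec, np.array([[0.0, 0.0, 4.0]]), ["C"]).sum()

    def test_pair_beyond_cutoff_ignored(self, tiny_receptor_text):
        rec = parse_receptor(tiny_receptor_text)
        fv = extract_features(rec, np.array([[100.0, 0.0, 0.0]]), ["C"])
        assert fv.counts.sum() == 0

    def test_matches_brute_force_on_random_complex(self, funnel, rng):
        coords = rng.uniform(-10, 15, size=(40, 3))
        elements = list(rng.choice(["C", "N", "O", "F", "S", "Cl", "B"],
                                   size=40))
        fv = extract_features(funnel.receptor, coords, elements)
        expected = brute_force_features(funnel.receptor, coords, elements)
        assert np.array_equal(fv.counts, expected)

    def test_invariant_to_order_and_rigid_motion(self, funnel, rng):
        from scipy.spatial.transform import Rotation
        coords = rng.uniform(-5, 10, size=(15, 3))
        elements = list(rng.choice(["C", "N", "O"], size=15))
        base = extract_features(funnel.receptor, coords, elements)
        perm = rng.permutation(15)
        shuffled = extract_features(funnel.receptor, coords[perm],
                                    [elements[i] for i in perm])
        assert np.array_equal(base.counts, shuffled.counts)
        # rotate receptor and ligand together: distances unchanged
        rot = Rotation.random(random_state=1)
        shift = np.array([3.0, -1.0, 2.0])
        moved_rec = parse_receptor(funnel.receptor_text)
        for atom in moved_rec.atoms:
            atom.coords = rot.apply(atom.coords) + shift
        moved = extract_features(moved_rec, rot.apply(coords) + shift,
                                 elements)
        assert np.array_equal(base.counts, moved.counts)

    def test_vector_length_enforced(self):
        with pytest.raises(ValueError):
            FeatureVector(np.zeros(35))
        with pytest.raises(ValueError):
            FeatureVector(np.full(36, -1))


def exhaustive_cart(X, y, min_node):
    """Brute-force CART regression tree (exhaustive split search)."""

    def build(idx):
        if len(idx) <= min_node or np.ptp(y[idx]) == 0:
            return ("leaf", float(np.mean(y[idx])))
        best = None
        parent_sse = np.sum((y[idx] - y[idx].mean()) ** 2)
        for j in range(X.shape[1]):
            values = np.unique(X[idx, j])
            for cut in (values[:-1] + values[1:]) / 2:
                left = idx[X[idx, j] <= cut]
                right = idx[X[idx, j] > cut]
                if len(left) == 0 or len(right) == 0:
                    continue
                sse = (np.sum((y[left] - y[left].mean()) ** 2)
                       + np.sum((y[right] - y[right].mean()) ** 2))
                gain = parent_sse - sse
                if best is None or gain > best[0] + 1e-12:
                    best = (gain, j, cut, left, right)
        if best is None or best[0] <= 1e-12:
            return ("leaf", float(np.mean(y[idx])))
        _, j, cut, left, right = best
        return ("node", j, cut, build(left), build(right))

    def predict_one(tree, x):
        while tree[0] == "node":
            _, j, cut, l, r = tree
            tree = l if x[j] <= cut else r
        return tree[1]

    tree = build(np.arange(len(y)))
    return lambda Q: np.array([predict_one(tree, q) for q in Q])


class TestTrainPredict:
    def test_constant_labels_reproduced(self, rng):
        X = rng.poisson(3.0, size=(40, 36)).astype(float)
        y = np.full(40, 6.2)
        model = train_rf(X, y, RFConfig(n_trees=20, seed=1))
        assert np.allclose(predict_rf(model, X), 6.2)

    def test_held_out_correlation_on_synthetic_counts(self):
        X, y, _ = make_rf_training_set(n=500, sigma=0.1, seed=7)
        model = train_rf(X[:400], y[:400], RFConfig(seed=7))
        pred = predict_rf(model, X[400:])
        r = np.corrcoef(pred, y[400:])[0, 1]
        assert r > 0.9

    def test_single_tree_matches_exhaustive_cart(self, rng):
        """One unpruned tree with all features tried per split equals the
        brute-force CART oracle (bootstrap disabled for comparability)."""
        from sklearn.ensemble import RandomForestRegressor
        X = rng.normal(size=(16, 3)).round(2)
        y = (2 * X[:, 0] - X[:, 1] + 0.1 * rng.normal(size=16)).round(3)
        tree = RandomForestRegressor(
            n_estimators=1, max_features=None, min_samples_split=6,
            bootstrap=False, random_state=0).fit(X, y)
        oracle = exhaustive_cart(X, y, min_node=5)
        assert np.allclose(tree.predict(X), oracle(X), atol=1e-9)

    def test_prediction_bounded_by_training_labels(self, rng):
        X, y, _ = make_rf_training_set(n=200, sigma=0.2, seed=3)
        model = train_rf(X, y, RFConfig(n_trees=50, seed=3))
        Q = rng.poisson(4.0, size=(50, 36)).astype(float)
        pred = predict_rf(model, Q)
        assert np.all(pred >= y.min() - 1e-9)
        assert np.all(pred <= y.max() + 1e-9)

    def test_deterministic_under_seed(self):
        X, y, _ = make_rf_training_set(n=120, sigma=0.2, seed=5)
        a = predict_rf(train_rf(X, y, RFConfig(n_trees=30, seed=9)), X)
        b = predict_rf(train_rf(X, y, RFConfig(n_trees=30, seed=9)), X)
        assert np.array_equal(a, b)

    def test_feature_length_mismatch_rejected(self):
        X, y, _ = make_rf_training_set(n=60, sigma=0.2, seed=5)
        model = train_rf(X, y, RFConfig(n_trees=5, seed=1))
        with pytest.raises(ValueError):
            predict_rf(model, np.zeros((2, 35)))

    def test_default_hyperparameters(self):
        cfg = RFConfig()
        assert cfg.n_trees == 500
        assert cfg.min_node == 5

    def test_model_round_trips_through_disk(self, tmp_path):
        X, y, _ = make_rf_training_set(n=80, sigma=0.2, seed=2)
        model = train_rf(X, y, RFConfig(n_trees=10, seed=2))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert np.array_equal(predict_rf(loaded, X), predict_rf(model, X))
        assert loaded.config == model.config


class TestRescorePoses:
    def _poses(self, funnel, n=2):
        conf = identity_conformation(funnel.template)
        coords = realize(funnel.template, conf)
        return [
            ScoredPose(conformation=conf, coords=coords,
                       energy_kcal=-6.0 - k)
            for k in range(n)
        ]

    def _model(self):
        X, y, _ = make_rf_training_set(n=100, sigma=0.2, seed=4)
        return train_rf(X, y, RFConfig(n_trees=10, seed=4))

    def test_fills_rf_and_consensus(self, funnel):
        poses = self._poses(funnel)
        model = self._model()
        summary = rescore_poses(poses, funnel.receptor, model,
                                funnel.template)
        for pose in poses:
            assert pose.rf_pkd is not None
            expected = 0.5 * (kcal_to_pkd(pose.energy_kcal) + pose.rf_pkd)
            assert pose.consensus_pkd == pytest.approx(expected)
        assert summary.max_pose_pkd >= summary.first_pose_pkd

    def test_single_pose_rules_agree(self, funnel):
        poses = self._poses(funnel, n=1)
        summary = rescore_poses(poses, funnel.receptor, self._model(),
                                funnel.template)
        assert summary.first_pose_pkd == summary.max_pose_pkd

    def test_composes_extract_and_predict(self, funnel):
        poses = self._poses(funnel, n=1)
        model = self._model()
        rescore_poses(poses, funnel.receptor, model, funnel.template)
        heavy_idx = funnel.template.heavy_indices()
        elements = [funnel.template.atoms[i].element for i in heavy_idx]
        fv = extract_features(funnel.receptor,
                              poses[0].coords[heavy_idx], elements)
        assert poses[0].rf_pkd == pytest.approx(predict_rf(model, fv))

    def test_empty_pose_list_rejected(self, funnel):
        with pytest.raises(ValueError):
            rescore_poses([], funnel.receptor, self._model(),
                          funnel.template)
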