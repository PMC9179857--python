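import warnings

import numpy as np
import pandas as pd
import pytest

import netmark as nm
from netmark.errors import DegenerateLabelsError, SchemaError, ValidationError
from netmark.topology import FEATURE_NAMES


def blob_features(seed=0, n_per=20, gap=10.0, partition=None):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_per, 2)), rng.normal(gap, 1, (n_per, 2))])
    idx = [f"n{i:03d}" for i in range(2 * n_per)]
    feats = pd.DataFrame(X, index=idx, columns=["f1", "f2"])
    if partition is None:
        partition = ["train"] * (2 * n_per)
    frame = pd.DataFrame(
        {
            "label": ["biomarker"] * n_per + ["non_biomarker"] * n_per,
            "partition": partition,
        },
        index=feats.index,
    )
    return feats, nm.LabeledSet(frame)


class TestSelectFeatures:
    def test_single_perfect_splitter(self, labeled_features):
        X, labels = labeled_features(3, rule=False)
        y = labels.frame["label"] == "biomarker"
        X = X.copy()
        X["stress"] = np.where(y, 5.0, -5.0)
        result = nm.select_features(X, labels)
        assert result.selected_features == ["stress"]

    def test_planted_conjunction_recovered(self, labeled_features):
        hits = 0
        for seed in range(20):
            X, labels = labeled_features(seed, rule=True)
            sel = set(nm.select_features(X, labels).selected_features)
            hits += {"clustering_coefficient", "betweenness_centrality"} <= sel
        assert hits >= 16

    def test_noise_labels_prune_to_root_and_fallback(self, labeled_features):
        # at this pruning strength a pure-noise tree collapses to its root;
        # the caller contract is the fallback to the full feature battery
        X, labels = labeled_features(0, rule=False)
        result = nm.select_features(X, labels, complexity=0.3)
        assert result.selected_features == []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            used = nm.selected_or_all(result)
        assert used == list(FEATURE_NAMES)
        assert len(caught) == 1

    def test_selected_subset_of_canonical_names(self, labeled_features):
        for seed in (1, 5, 9):
            X, labels = labeled_features(seed, rule=True)
            sel = nm.select_features(X, labels).selected_features
            assert set(sel) <= set(FEATURE_NAMES)

    def test_single_class_rejected(self, labeled_features):
        X, labels = labeled_features(0, rule=False)
        frame = labels.frame.copy()
        frame["label"] = "biomarker"
        with pytest.raises(DegenerateLabelsError):
            nm.select_features(X, nm.LabeledSet(frame))


class TestTrainSvm:
    def test_separable_blobs_perfect_training_accuracy(self):
        feats, labels = blob_features(seed=0)
        model = nm.fit_svm(feats, labels, nm.KernelSpec("linear"))
        X = model.standardize(feats.to_numpy())
        assert (np.sign(model.decision_function(X)) == labels.y(labels.nodes())).all()

    def test_duplicating_rows_leaves_decision_unchanged(self):
        feats, labels = blob_features(seed=2, n_per=10)
        doubled = pd.concat([feats, feats.set_axis([f"{i}_dup" for i in feats.index])])
        frame2 = pd.concat(
            [labels.frame, labels.frame.set_axis([f"{i}_dup" for i in labels.frame.index])]
        )
        m1 = nm.fit_svm(feats, labels, nm.KernelSpec("linear"))
        m2 = nm.fit_svm(doubled, nm.LabeledSet(frame2), nm.KernelSpec("linear"))
        probe = np.random.default_rng(5).normal(0, 3, size=(15, 2))
        d1 = m1.decision_function(m1.standardize(probe))
        d2 = m2.decision_function(m2.standardize(probe))
        assert np.allclose(d1, d2, atol=1e-6)

    def test_xor_needs_nonlinear_kernel(self):
        rng = np.random.default_rng(1)
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]] * 6, float)
        X += rng.normal(0, 0.05, X.shape)
        y = np.array([1, 1, -1, -1] * 6)
        feats = pd.DataFrame(X, index=[f"x{i:02d}" for i in range(24)],
                             columns=["a", "b"])
        frame = pd.DataFrame(
            {"label": np.where(y == 1, "biomarker", "non_biomarker"),
             "partition": "train"},
            index=feats.index,
        )
        labels = nm.LabeledSet(frame)
        rbf = nm.fit_svm(feats, labels, nm.KernelSpec("rbf", sigma=1.0), C=10.0)
        lin = nm.fit_svm(feats, labels, nm.KernelSpec("linear"), C=10.0)
        acc = lambda m: (np.sign(m.decision_function(m.standardize(feats.to_numpy()))) == y).mean()
        assert acc(rbf) == 1.0
        assert acc(lin) <= 0.75

    def test_dual_coefficients_bounded_by_c(self):
        feats, labels = blob_features(seed=3, gap=0.5)  # overlapping classes
        model = nm.fit_svm(feats, labels, nm.KernelSpec("linear"), C=0.7)
        assert np.abs(model.dual_coef).max() <= 0.7 + 1e-8

    def test_asymmetric_gram_rejected(self):
        G = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValidationError):
            nm.train_svm(G, np.array([1, -1]))

    def test_one_class_rejected(self):
        G = np.eye(3)
        with pytest.raises(DegenerateLabelsError):
            nm.train_svm(G, np.array([1, 1, 1]))

    def test_model_json_roundtrip(self, tmp_path):
        feats, labels = blob_features(seed=4)
        model = nm.fit_svm(feats, labels, nm.KernelSpec("bessel"))
        path = tmp_path / "model.json"
        model.save(path)
        back = nm.SVMModel.load(path)
        probe = model.standardize(feats.to_numpy()[:7])
        assert np.allclose(model.point(probe), back.point(probe), atol=1e-12)


class TestCalibration:
    def test_separated_decisions_push_probabilities_to_targets(self):
        f = np.concatenate([np.full(10, 2.0), np.full(10, -2.0)])
        f += np.linspace(-0.01, 0.01, 20)
        y = np.array([1] * 10 + [-1] * 10)
        a, b = nm.calibrate_probabilities(f, y)
        p = 1.0 / (1.0 + np.exp(a * f + b))
        assert (p[:10] >= 0.9).all()
        assert (p[10:] <= 0.1).all()

    def test_symmetric_decisions_give_half_at_zero(self):
        f = np.array([1.5, -1.5] * 8)
        y = np.array([1, -1] * 8)
        a, b = nm.calibrate_probabilities(f, y)
        assert 1.0 / (1.0 + np.exp(b)) == pytest.approx(0.5, abs=1e-6)

    def test_probabilities_monotone_in_decision(self):
        rng = np.random.default_rng(6)
        f = rng.normal(size=40)
        y = np.where(f + rng.normal(0, 0.5, 40) > 0, 1, -1)
        a, b = nm.calibrate_probabilities(f, y)
        grid = np.linspace(-3, 3, 50)
        p = 1.0 / (1.0 + np.exp(a * grid + b))
        assert (np.diff(p) >= -1e-12).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            nm.calibrate_probabilities(np.array([np.inf, 0.0]), np.array([1, -1]))


class TestPredictCandidates:
    @pytest.fixture()
    def trained(self):
        feats, labels = blob_features(seed=8)
        return feats, nm.fit_svm(feats, labels, nm.KernelSpec("linear"))

    def test_cutoff_zero_returns_everything(self, trained):
        feats, model = trained
        table = nm.predict_candidates(model, feats, cutoff=0.0)
        assert len(table) == len(feats)

    def test_cutoff_above_one_rejected(self, trained):
        feats, model = trained
        with pytest.raises(ValidationError):
            nm.predict_candidates(model, feats, cutoff=1.0 + 1e-9)

    def test_exclusion_and_ranking(self, trained):
        feats, model = trained
        full = nm.predict_candidates(model, feats, cutoff=0.0)
        top = full.index[0]
        without = nm.predict_candidates(model, feats, cutoff=0.0, exclude={top})
        assert top not in without.index
        assert (without["point"].diff().dropna() <= 1e-12).all()

    def test_row_order_invariance(self, trained):
        feats, model = trained
        shuffled = feats.sample(frac=1.0, random_state=3)
        a = nm.score_nodes(model, feats)
        b = nm.score_nodes(model, shuffled)
        assert list(a.index) == list(b.index)
        assert np.allclose(a["point"], b["point"])

    def test_missing_feature_column_rejected(self, trained):
        feats, model = trained
        with pytest.raises(SchemaError):
            nm.score_nodes(model, feats.drop(columns=["f2"]))


class TestCompareKernels:
    def test_identical_specs_identical_aucs(self):
        feats, labels = blob_features(
            seed=9, partition=["train"] * 14 + ["test"] * 6 + ["train"] * 14 + ["test"] * 6
        )
        specs = [nm.KernelSpec("rbf"), nm.KernelSpec("rbf")]
        table = nm.compare_kernels(feats, labels, specs)
        assert table.loc[0, "auc"] == table.loc[1, "auc"]

    def test_radial_geometry_favors_rbf_over_linear(self):
        rng = np.random.default_rng(12)
        r_in = rng.uniform(0, 1, 30)
        r_out = rng.uniform(2.5, 3.5, 30)
        ang = rng.uniform(0, 2 * np.pi, 60)
        r = np.concatenate([r_in, r_out])
        X = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        feats = pd.DataFrame(X, index=[f"p{i:02d}" for i in range(60)],
                             columns=["u", "v"])
        part = (["train"] * 20 + ["test"] * 10) * 2
        frame = pd.DataFrame(
            {"label": ["biomarker"] * 30 + ["non_biomarker"] * 30,
             "partition": part},
            index=feats.index,
        )
        labels = nm.LabeledSet(frame)
        table = nm.compare_kernels(
            feats, labels, [nm.KernelSpec("rbf"), nm.KernelSpec("linear")]
        ).set_index("kernel")
        assert table.loc["rbf", "auc"] > table.loc["linear", "auc"]

    def test_randomized_labels_auc_near_half(self):
        rng = np.random.default_rng(21)
        feats = pd.DataFrame(
            rng.normal(size=(62, 3)),
            index=[f"q{i:02d}" for i in range(62)],
            columns=["a", "b", "c"],
        )
        lab = np.array(["biomarker", "non_biomarker"] * 31)
        part = ["train"] * 44 + ["test"] * 18
        labels = nm.LabeledSet(
            pd.DataFrame({"label": lab, "partition": part}, index=feats.index)
        )
        table = nm.compare_kernels(feats, labels, [nm.KernelSpec("linear")])
        assert abs(table.loc[0, "auc"] - 0.5) <= 0.25
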