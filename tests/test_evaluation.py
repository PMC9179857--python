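import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import netmark as nm
from netmark.errors import DegenerateLabelsError, GeneLookupError, ValidationError
from netmark.synthetic import PlantedTruth

from _oracles import auc_pairwise


class TestRocAuc:
    def test_perfect_separation(self):
        r = nm.roc_auc([1, 2, 3, 4], ["control", "control", "case", "case"])
        assert r.auc == 1.0
        assert r.orientation == "higher_is_case"

    def test_pure_ties_give_half(self):
        r = nm.roc_auc([2.0] * 6, ["case"] * 3 + ["control"] * 3)
        assert r.auc == pytest.approx(0.5)

    def test_hand_counted_pairs(self):
        # case scores {1, 4} vs control scores {2, 3}: 2 wins of 4 pairs
        r = nm.roc_auc([2, 1, 3, 4], ["control", "case", "control", "case"])
        assert r.auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(size=n), 1)  # rounding makes ties
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                continue
            assert nm.auc_statistic(scores, y) == pytest.approx(
                auc_pairwise(scores, y), abs=1e-12
            )

    def test_orientation_flip_for_down_markers(self):
        scores = np.array([5.0, 4.0, 1.0, 2.0])
        labels = np.array(["case", "case", "control", "control"])
        r_down = nm.roc_auc(-scores, labels)
        assert r_down.auc == 1.0
        assert r_down.orientation == "lower_is_case"

    def test_curve_monotone_and_matches_trapezoid(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=60)
        y = np.array(["case"] * 30 + ["control"] * 30)
        scores[:30] += 1.0
        r = nm.roc_auc(scores, y)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auc, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 9999))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        y = np.array([True] * 15 + [False] * 15)
        before = nm.auc_statistic(scores, y)
        after = nm.auc_statistic(np.exp(2.0 * scores) + 7, y)
        assert before == pytest.approx(after, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            nm.roc_auc([1, 2], ["case", "case"])


class TestSingleGene:
    def test_null_gene_auc_half(self, small_sim):
        # background gene: no planted expression shift
        gene = sorted(set(small_sim.expression.index) - small_sim.truth.module_nodes)[0]
        r = nm.single_gene_diagnostics(
            small_sim.expression, small_sim.sample_labels, gene
        )
        assert 0.5 <= r.auc <= 0.65  # oriented AUC is >= 0.5 by construction

    def test_biomarker_gene_near_target_auc(self):
        expr, labels = nm.generate_expression(
            ["g0", "g1"], 500, 500, {"g0": nm.effect_size_for_auc(0.9)}, 1.0, seed=3
        )
        r = nm.single_gene_diagnostics(expr, labels, "g0")
        assert r.auc == pytest.approx(0.9, abs=0.03)

    def test_negated_expression_same_auc_flipped_orientation(self):
        expr, labels = nm.generate_expression(
            ["g0"], 100, 100, {"g0": 1.5}, 1.0, seed=4
        )
        up = nm.single_gene_diagnostics(expr, labels, "g0")
        down = nm.single_gene_diagnostics(-expr, labels, "g0")
        assert up.auc == pytest.approx(down.auc, abs=1e-12)
        assert {up.orientation, down.orientation} == {
            "higher_is_case", "lower_is_case"
        }

    def test_unknown_gene(self, small_sim):
        with pytest.raises(GeneLookupError):
            nm.single_gene_diagnostics(
                small_sim.expression, small_sim.sample_labels, "NOPE"
            )


class TestLogisticPanel:
    def test_single_gene_panel_equals_single_gene_auc(self):
        expr, labels = nm.generate_expression(
            ["g0"], 200, 200, {"g0": 1.2}, 1.0, seed=9
        )
        single = nm.single_gene_diagnostics(expr, labels, "g0")
        panel = nm.combine_biomarkers_logistic(expr, labels, ["g0"])
        assert panel.roc.auc == pytest.approx(single.auc, abs=1e-12)

    def test_two_independent_genes_combine_favorably(self):
        delta = nm.effect_size_for_auc(0.75)
        expr, labels = nm.generate_expression(
            ["g0", "g1"], 500, 500, {"g0": delta, "g1": delta}, 1.0, seed=2
        )
        panel = nm.combine_biomarkers_logistic(expr, labels, ["g0", "g1"])
        best_single = max(
            nm.single_gene_diagnostics(expr, labels, g).auc for g in ("g0", "g1")
        )
        assert panel.roc.auc >= best_single - 0.01
        # theory: combined binormal AUC = Phi(sqrt(2) * delta / sqrt(2)) at
        # equal weights; just confirm the panel approaches it
        from scipy.stats import norm

        assert panel.roc.auc == pytest.approx(
            norm.cdf(np.sqrt(2) * delta / np.sqrt(2)), abs=0.03
        )

    def test_null_gene_does_not_hurt_panel(self):
        delta = nm.effect_size_for_auc(0.85)
        expr, labels = nm.generate_expression(
            ["g0", "g1"], 500, 500, {"g0": delta}, 1.0, seed=6
        )
        alone = nm.combine_biomarkers_logistic(expr, labels, ["g0"])
        both = nm.combine_biomarkers_logistic(expr, labels, ["g0", "g1"])
        assert both.roc.auc == pytest.approx(alone.roc.auc, abs=0.02)

    def test_separable_panel_uses_ridge_not_failure(self):
        expr = pd.DataFrame(
            {"s%d" % i: [float(i < 10) * 10 - 5] for i in range(20)},
            index=["g0"],
        )
        labels = pd.Series(["case"] * 10 + ["control"] * 10, index=expr.columns)
        panel = nm.combine_biomarkers_logistic(expr, labels, ["g0"])
        assert panel.roc.auc == 1.0

    def test_empty_gene_list_rejected(self, small_sim):
        with pytest.raises(ValidationError):
            nm.combine_biomarkers_logistic(
                small_sim.expression, small_sim.sample_labels, []
            )


class TestRecovery:
    def make_scored(self, order, points=None):
        table = pd.DataFrame(
            {"point": points if points is not None else np.linspace(1, 0, len(order))},
            index=pd.Index(order, name="node"),
        )
        table["rank"] = np.arange(1, len(order) + 1)
        return table

    def test_perfect_candidates(self):
        truth = PlantedTruth({"a", "b", "c"}, {"a", "b"})
        scored = self.make_scored(["a", "b", "x", "y"], [1.0, 1.0, 0.1, 0.0])
        m = nm.evaluate_recovery(scored, truth, cutoff=0.99)
        assert m["precision_at_k"] == 1.0
        assert m["recall_at_cutoff"] == 1.0
        assert m["auc"] == 1.0

    def test_reversed_ranking_flags_orientation(self):
        truth = PlantedTruth({"a", "b"}, {"a", "b"})
        scored = self.make_scored(["x", "y", "a", "b"], [0.9, 0.8, 0.2, 0.1])
        m = nm.evaluate_recovery(scored, truth)
        assert m["auc_unoriented"] == 0.0
        assert m["auc"] == 1.0
        assert m["orientation"] == "lower_is_case"

    def test_random_ranking_matches_binomial_baseline(self):
        rng = np.random.default_rng(10)
        nodes = [f"n{i:04d}" for i in range(1000)]
        truth = PlantedTruth(set(nodes[:12]), set(nodes[:12]))
        precisions = []
        for _ in range(50):
            order = list(rng.permutation(nodes))
            m = nm.evaluate_recovery(self.make_scored(order), truth)
            precisions.append(m["precision_at_k"])
        expected = 12 / 1000
        se = np.sqrt(expected * (1 - expected) / 12 / 50)
        assert abs(np.mean(precisions) - expected) <= 3 * se

    def test_empty_truth_rejected(self):
        with pytest.raises(ValidationError):
            nm.evaluate_recovery(self.make_scored(["a"]), PlantedTruth(set(), set()))
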