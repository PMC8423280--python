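"""The tanh-fused weighting scheme and the comparison ensembles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metricfuse.data_model import ClassifierBundle, ProbabilityTable
from metricfuse.errors import (
    DegenerateWeightsError,
    FusionSpecError,
    ValidationError,
)
from metricfuse.fusion import (
    MAX_CONTRIBUTION,
    MAX_WEIGHT,
    FusionSpec,
    WeightVector,
    accuracy_weights,
    fit_weights,
    fuse_baseline,
    fuse_weighted,
    learner_weight,
    majority_vote,
    predict_argmax,
    tanh_contribution,
    uniform_weights,
)
from metricfuse.metrics import MetricVector

from conftest import make_labels, random_bundle, random_table

P, N = "Pneumonia", "Normal"

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestLearnerWeight:
    def test_all_ones_gives_four_tanh_one(self):
        w = learner_weight(MetricVector(1, 1, 1, 1))
        assert w == pytest.approx(4 * math.tanh(1))
        assert w == pytest.approx(3.046, abs=5e-4)

    def test_all_zeros_gives_zero(self):
        assert learner_weight(MetricVector(0, 0, 0, 0)) == 0.0

    def test_all_halves_closed_form(self):
        assert learner_weight(
            MetricVector(0.5, 0.5, 0.5, 0.5)
        ) == pytest.approx(4 * math.tanh(0.5))

    @given(x=unit)
    def test_per_metric_contribution_bounded_by_tanh_one(self, x):
        assert 0.0 <= tanh_contribution(x) <= MAX_CONTRIBUTION
        assert MAX_CONTRIBUTION == pytest.approx(0.762, abs=5e-4)

    @pytest.mark.parametrize("bad", [-0.1, 1.01])
    def test_metric_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValidationError):
            tanh_contribution(bad)

    @given(pre=unit, rec=unit, f1=unit, auc=unit, bump=st.floats(0, 1))
    @settings(max_examples=200)
    def test_monotone_in_each_metric(self, pre, rec, f1, auc, bump):
        f1 = min(f1, (pre + rec) / 2) if pre and rec else f1
        try:
            base = MetricVector(pre, rec, f1, auc)
        except ValidationError:
            return
        w0 = learner_weight(base)
        bumped = MetricVector(pre, rec, f1, min(1.0, auc + bump))
        assert learner_weight(bumped) >= w0 - 1e-15
        assert 0.0 <= w0 <= MAX_WEIGHT


class TestWeightVector:
    def test_all_zero_weights_rejected(self):
        with pytest.raises(DegenerateWeightsError):
            WeightVector({"a": 0.0, "b": 0.0}, provenance="manual")

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            WeightVector({"a": -1.0}, provenance="manual")

    def test_tanh_fused_weights_bounded(self):
        with pytest.raises(ValidationError):
            WeightVector({"a": MAX_WEIGHT + 0.1}, provenance="tanh-fused")


class TestFitWeights:
    def _bundle(self, catalog, labels, tables):
        return ClassifierBundle(tables)

    def test_perfect_learner_outweighs_always_wrong(self, catalog):
        labels = make_labels(catalog, (P, P, N, N))
        right = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
        perfect = ProbabilityTable("good", labels.sample_ids, right, catalog)
        # "bad" is exactly anti-correlated: class columns flipped
        wrong = ProbabilityTable(
            "bad", labels.sample_ids, right[:, ::-1].copy(), catalog
        )
        wv = fit_weights(
            ClassifierBundle([perfect, wrong]), labels, P, "positive"
        )
        assert wv.provenance == "tanh-fused"
        assert wv.weights["good"] == pytest.approx(4 * math.tanh(1))
        # the inverted learner earns nothing but tanh of its (zero) AUC
        assert wv.weights["bad"] == pytest.approx(0.0, abs=1e-12)
        assert wv.weights["good"] > wv.weights["bad"]

    def test_identical_learners_get_equal_weights(self, catalog, rng):
        labels = make_labels(catalog, (P, P, N, N, P))
        t = random_table(catalog, 5, rng, name="a")
        b = ProbabilityTable("b", t.sample_ids, t.probabilities, catalog)
        wv = fit_weights(ClassifierBundle([t, b]), labels)
        assert wv.weights["a"] == pytest.approx(wv.weights["b"])

    def test_weights_invariant_to_classifier_order(self, catalog, rng):
        labels = make_labels(catalog, tuple(rng.choice([P, N], 20)))
        if len(set(labels.labels)) < 2:
            pytest.skip("degenerate draw")
        tables = [random_table(catalog, 20, rng, name=f"c{i}") for i in range(3)]
        w1 = fit_weights(ClassifierBundle(tables), labels)
        w2 = fit_weights(ClassifierBundle(tables[::-1]), labels)
        assert w1.weights == w2.weights


class TestFuseWeighted:
    def test_equal_weights_give_arithmetic_mean(self, catalog):
        rows = [np.array([[0.6, 0.4]]), np.array([[0.2, 0.8]])]
        bundle = ClassifierBundle([
            ProbabilityTable(f"c{i}", ("s0",), r, catalog)
            for i, r in enumerate(rows)
        ])
        fused = fuse_weighted(bundle, {"c0": 1.0, "c1": 1.0})
        assert fused.probabilities[0] == pytest.approx([0.4, 0.6])

    def test_one_three_weighting_by_hand(self, catalog):
        bundle = ClassifierBundle([
            ProbabilityTable("c0", ("s0",), np.array([[1.0, 0.0]]), catalog),
            ProbabilityTable("c1", ("s0",), np.array([[0.0, 1.0]]), catalog),
        ])
        fused = fuse_weighted(bundle, {"c0": 1.0, "c1": 3.0})
        assert fused.probabilities[0] == pytest.approx([0.25, 0.75])
        assert predict_argmax(fused) == [P]

    def test_single_classifier_identity(self, catalog, rng):
        t = random_table(catalog, 10, rng, name="only")
        fused = fuse_weighted(ClassifierBundle([t]), {"only": 2.5})
        assert np.allclose(fused.probabilities, t.probabilities)

    def test_rows_remain_normalized(self, catalog, rng):
        bundle = random_bundle(catalog, 50, 4, rng)
        w = {n: float(v) for n, v in zip(bundle.names, rng.random(4) + 0.01)}
        fused = fuse_weighted(bundle, w)
        assert np.allclose(fused.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_weight_rescaling(self, catalog, rng):
        bundle = random_bundle(catalog, 30, 3, rng)
        w = {n: float(v) for n, v in zip(bundle.names, [0.2, 1.1, 0.7])}
        f1 = fuse_weighted(bundle, w)
        f2 = fuse_weighted(bundle, {k: 37.5 * v for k, v in w.items()})
        assert np.allclose(f1.probabilities, f2.probabilities, atol=1e-12)

    def test_zero_weight_sum_rejected(self, catalog, rng):
        bundle = random_bundle(catalog, 5, 2, rng)
        with pytest.raises(DegenerateWeightsError):
            fuse_weighted(bundle, dict.fromkeys(bundle.names, 0.0))


class TestPredictArgmax:
    def test_majority_class_row(self, catalog):
        t = ProbabilityTable("c", ("s0",), np.array([[0.3, 0.7]]), catalog)
        assert predict_argmax(t) == [P]

    def test_tie_breaks_to_first_catalog_class(self, catalog):
        t = ProbabilityTable("c", ("s0",), np.array([[0.5, 0.5]]), catalog)
        assert predict_argmax(t) == [N]


def brute_force_vote(bundle):
    """Independent oracle: explicit per-sample vote tally with the
    documented tie-break (mean probability, then catalog order)."""
    classes = bundle.catalog.classes
    out = []
    for j in range(len(bundle.sample_ids)):
        tallies = {c: 0 for c in classes}
        for t in bundle:
            row = t.probabilities[j]
            best = classes[int(np.argmax(row))]
            tallies[best] += 1
        top = max(tallies.values())
        tied = [c for c in classes if tallies[c] == top]
        if len(tied) > 1:
            means = {
                c: np.mean([t.probabilities[j][classes.index(c)] for t in bundle])
                for c in tied
            }
            best_mean = max(means.values())
            tied = [c for c in tied if means[c] == best_mean]
        out.append(tied[0])
    return out


class TestBaselines:
    def test_majority_vote_simple_tally(self, catalog):
        ids = ("s0",)
        rows = [[0.1, 0.9], [0.4, 0.6], [0.8, 0.2]]  # votes: P, P, N
        bundle = ClassifierBundle([
            ProbabilityTable(f"c{i}", ids, np.array([r]), catalog)
            for i, r in enumerate(rows)
        ])
        assert majority_vote(bundle) == [P]

    def test_two_way_tie_broken_by_mean_probability(self, catalog):
        ids = ("s0",)
        rows = [[0.2, 0.8], [0.6, 0.4]]  # 1 vote each; mean positive 0.6
        bundle = ClassifierBundle([
            ProbabilityTable(f"c{i}", ids, np.array([r]), catalog)
            for i, r in enumerate(rows)
        ])
        assert majority_vote(bundle) == [P]
        assert brute_force_vote(bundle) == [P]

    @pytest.mark.parametrize("k", [2, 3, 5, 7])
    def test_majority_vote_matches_brute_force(self, catalog, rng, k):
        bundle = random_bundle(catalog, 200, k, rng)
        assert majority_vote(bundle) == brute_force_vote(bundle)

    def test_average_equals_tanh_with_equal_weights(self, catalog, rng):
        bundle = random_bundle(catalog, 100, 3, rng)
        avg = fuse_baseline(bundle, FusionSpec("average"))
        eq = fuse_weighted(bundle, dict.fromkeys(bundle.names, 1.234))
        assert np.array_equal(avg.probabilities, eq.probabilities)

    def test_max_method_prediction_matches_per_class_sum(self, catalog, rng):
        bundle = random_bundle(catalog, 80, 3, rng)
        table = fuse_baseline(bundle, FusionSpec("max"))
        sums = bundle.stacked().sum(axis=0)
        expect = [
            catalog.classes[i] for i in np.argmax(sums, axis=1)
        ]
        assert predict_argmax(table) == expect

    def test_accuracy_weighting_uses_fitting_labels(self, catalog, rng):
        labels = make_labels(catalog, (P, P, N, N, P, N))
        bundle = random_bundle(catalog, 6, 3, rng)
        wv = accuracy_weights(bundle, labels)
        assert wv.provenance == "accuracy-only"
        fused = fuse_baseline(bundle, FusionSpec("accuracy"), labels)
        expect = fuse_weighted(bundle, wv)
        assert np.allclose(fused.probabilities, expect.probabilities)

    def test_weighted_method_without_labels_rejected(self, catalog, rng):
        bundle = random_bundle(catalog, 5, 2, rng)
        with pytest.raises(FusionSpecError):
            fuse_baseline(bundle, FusionSpec("accuracy"))

    def test_unknown_method_tag_rejected(self):
        with pytest.raises(FusionSpecError):
            FusionSpec("stacking")

    def test_agreeing_majority_with_margin_beats_third_learner(self, catalog):
        """If two of three learners put overwhelming mass on one class,
        no admissible weight for the third can flip the fused argmax."""
        ids = ("s0",)
        bundle = ClassifierBundle([
            ProbabilityTable("a", ids, np.array([[0.02, 0.98]]), catalog),
            ProbabilityTable("b", ids, np.array([[0.03, 0.97]]), catalog),
            ProbabilityTable("c", ids, np.array([[0.90, 0.10]]), catalog),
        ])
        # dissenter at the maximal admissible tanh weight; the agreers'
        # weighted margin still exceeds its maximal pull
        w = {"a": 1.5, "b": 1.5, "c": MAX_WEIGHT}
        margin = w["a"] * 0.48 + w["b"] * 0.47
        pull = w["c"] * 0.40
        assert margin > pull
        fused = fuse_weighted(bundle, w)
        assert predict_argmax(fused) == [P]
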