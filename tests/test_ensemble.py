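"""Tests of majority voting, classification metrics and paired significance
testing, each against an independent oracle (brute-force vote counting,
per-definition metric computation, scikit-learn, the textbook t formula)."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import precision_recall_fscore_support

from densehar.ensemble import (
    VoteInput,
    compute_metrics,
    ensemble_predict,
    majority_vote,
    paired_f1_test,
)
from densehar.io import SignalWindow
from densehar.models import DenseLabeller, reduced_gru_preset


def brute_force_vote(labels, probs):
    """Exhaustive per-frame count-then-sum-probability oracle."""
    K, T = labels.shape
    C = probs.shape[2]
    out = np.empty(T, dtype=int)
    for t in range(T):
        counts = [(labels[:, t] == c).sum() for c in range(C)]
        top = max(counts)
        cand = [c for c in range(C) if counts[c] == top]
        if len(cand) == 1:
            out[t] = cand[0]
        else:
            sums = [probs[:, t, c].sum() for c in cand]
            out[t] = cand[int(np.argmax(sums))]
    return out


def random_votes(rng, K, T, C):
    labels = rng.integers(0, C, size=(K, T))
    probs = rng.dirichlet(np.ones(C), size=(K, T))
    # make probabilities consistent-ish with labels so argmax ties are real
    return VoteInput(labels, probs)


class TestMajorityVote:
    def test_strict_majority_wins(self):
        labels = np.array([[0] * 12 + [1] * 10]).reshape(22, 1)
        probs = np.full((22, 1, 2), 0.5)
        assert majority_vote(VoteInput(labels, probs))[0] == 0

    def test_tie_resolved_by_summed_probability(self):
        # 11 votes each; class 1 has the larger summed probability (13.2 vs 12.9)
        labels = np.array([0] * 11 + [1] * 11).reshape(22, 1)
        probs = np.empty((22, 1, 2))
        probs[:11, 0] = [0.9, 0.1]       # class-0 voters: 9.9 for class 0
        probs[11:, 0] = [0.3 / 11 * 10, 1 - 0.3 / 11 * 10]
        probs[:, 0] /= probs[:, 0].sum(axis=-1, keepdims=True)
        summed = probs[:, 0].sum(axis=0)
        winner = majority_vote(VoteInput(labels, probs))[0]
        assert winner == int(np.argmax(summed))

    def test_matches_brute_force_oracle(self, rng):
        votes = random_votes(rng, K=6, T=400, C=5)
        np.testing.assert_array_equal(
            majority_vote(votes),
            brute_force_vote(votes.per_model_labels, votes.per_model_probabilities),
        )

    def test_even_split_forced_ties_match_oracle(self, rng):
        T, C = 200, 4
        half = rng.integers(0, C, size=(1, T))
        other = (half + rng.integers(1, C, size=(1, T))) % C
        labels = np.vstack([half, half, other, other])  # guaranteed 2-2 ties
        probs = rng.dirichlet(np.ones(C), size=(4, T))
        votes = VoteInput(labels, probs)
        np.testing.assert_array_equal(
            majority_vote(votes), brute_force_vote(labels, probs)
        )

    def test_permutation_invariance_and_duplicate_winner(self, rng):
        votes = random_votes(rng, K=5, T=100, C=3)
        base = majority_vote(votes)
        perm = rng.permutation(5)
        shuffled = VoteInput(
            votes.per_model_labels[perm], votes.per_model_probabilities[perm]
        )
        np.testing.assert_array_equal(majority_vote(shuffled), base)
        # duplicating a strict-majority frame's winning voter never flips it
        strict = np.array([
            (votes.per_model_labels[:, t] == base[t]).sum() * 2
            > 5 + ((votes.per_model_labels[:, t] == base[t]).sum())
            for t in range(100)
        ])
        winner_idx = np.argmax(votes.per_model_labels == base[None, :], axis=0)
        dup_labels = np.vstack([votes.per_model_labels,
                                base[None, :]])
        dup_probs = np.vstack([
            votes.per_model_probabilities,
            votes.per_model_probabilities[winner_idx, np.arange(100)][None],
        ])
        dup = majority_vote(VoteInput(dup_labels, dup_probs))
        np.testing.assert_array_equal(dup, base)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            VoteInput(np.empty((0, 5), int), np.empty((0, 5, 2)))


class TestEnsemblePredict:
    def test_single_model_equals_its_argmax(self, rng):
        model = DenseLabeller(reduced_gru_preset(), seed=0)
        window = SignalWindow(rng.normal(size=(6, 120)))
        fused, votes = ensemble_predict([model], window)
        np.testing.assert_array_equal(fused, model.predict(window).argmax_labels)
        assert votes.per_model_labels.shape == (1, 120)

    def test_identical_models_equal_any_one(self, rng):
        model = DenseLabeller(reduced_gru_preset(), seed=1)
        window = SignalWindow(rng.normal(size=(6, 80)))
        fused, _ = ensemble_predict([model, model, model], window)
        np.testing.assert_array_equal(fused, model.predict(window).argmax_labels)

    def test_output_length_equals_recording_length(self, rng):
        models = [DenseLabeller(reduced_gru_preset(), seed=s) for s in range(3)]
        window = SignalWindow(rng.normal(size=(6, 333)))
        fused, _ = ensemble_predict(models, window)
        assert fused.shape == (333,)

    def test_channel_mismatch_rejected(self, rng):
        model = DenseLabeller(reduced_gru_preset(input_channels=6), seed=0)
        window = SignalWindow(
            rng.normal(size=(3, 50)), ("thigh_x", "thigh_y", "thigh_z")
        )
        with pytest.raises(ValueError, match="channels"):
            ensemble_predict([model], window)


class TestComputeMetrics:
    def test_perfect_predictions(self, rng):
        y = rng.integers(0, 4, 500)
        report = compute_metrics(y, y)
        assert report.accuracy == 1.0
        np.testing.assert_allclose(report.f1, 1.0)
        assert report.macro["f1"] == 1.0 and report.weighted["f1"] == 1.0

    def test_two_class_hand_computation(self):
        truth = np.array([0] * 10 + [1] * 10)
        pred = np.array([0] * 8 + [1] * 2 + [0] * 1 + [1] * 9)
        report = compute_metrics(pred, truth)
        np.testing.assert_array_equal(report.confusion_matrix, [[8, 2], [1, 9]])
        assert report.precision[0] == pytest.approx(8 / 9)
        assert report.recall[0] == pytest.approx(0.8)
        assert report.f1[0] == pytest.approx(2 * (8 / 9 * 0.8) / (8 / 9 + 0.8))

    @pytest.mark.parametrize("C", [3, 5, 9])
    def test_matches_sklearn_on_random_labels(self, rng, C):
        truth = rng.integers(0, C, 1000)
        pred = rng.integers(0, C, 1000)
        report = compute_metrics(pred, truth)
        p, r, f, s = precision_recall_fscore_support(
            truth, pred, labels=report.labels, zero_division=0
        )
        np.testing.assert_allclose(report.precision, p, atol=1e-12)
        np.testing.assert_allclose(report.recall, r, atol=1e-12)
        np.testing.assert_allclose(report.f1, f, atol=1e-12)
        np.testing.assert_array_equal(report.support, s)
        pw, rw, fw, _ = precision_recall_fscore_support(
            truth, pred, labels=report.labels, average="weighted", zero_division=0
        )
        assert report.weighted["f1"] == pytest.approx(fw, abs=1e-12)

    def test_out_of_set_predictions_counted_as_errors(self, rng):
        """A predicted class with zero truth support adds false positives that
        depress the other classes' precision, exactly as scikit-learn counts
        them over the union label set."""
        truth = rng.integers(0, 3, 400)
        pred = truth.copy()
        pred[:40] = 7  # class outside the truth repertoire
        report = compute_metrics(pred, truth)
        assert 7 in report.labels
        idx7 = report.labels.index(7)
        assert report.support[idx7] == 0
        assert report.confusion_matrix[:, idx7].sum() == 40
        p, r, f, _ = precision_recall_fscore_support(
            truth, pred, labels=report.labels, zero_division=0
        )
        np.testing.assert_allclose(report.precision, p, atol=1e-12)
        # zero-support class excluded from the averages
        present = [i for i, lab in enumerate(report.labels) if report.support[i] > 0]
        assert report.macro["f1"] == pytest.approx(report.f1[present].mean())

    def test_accuracy_is_trace_over_total(self, rng):
        truth = rng.integers(0, 5, 700)
        pred = rng.integers(0, 5, 700)
        report = compute_metrics(pred, truth)
        cm = report.confusion_matrix
        assert report.accuracy == np.trace(cm) / cm.sum()
        assert report.weighted["recall"] == pytest.approx(report.accuracy, abs=1e-12)

    def test_weighted_average_bounded_by_class_extremes(self, rng):
        truth = rng.integers(0, 4, 600)
        pred = rng.integers(0, 4, 600)
        report = compute_metrics(pred, truth)
        for metric, per_class in [("f1", report.f1), ("precision", report.precision)]:
            assert per_class.min() - 1e-12 <= report.weighted[metric] <= per_class.max() + 1e-12

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0, 1]), np.array([0]))
        with pytest.raises(ValueError):
            compute_metrics(np.array([], dtype=int), np.array([], dtype=int))


class TestPairedF1Test:
    def test_identical_scores_not_significant(self):
        res = paired_f1_test([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert res.t_statistic == 0.0 and res.p_value == 1.0
        assert not res.significant and res.degenerate

    def test_constant_offset_flagged_degenerate(self):
        b = [0.5, 0.6, 0.7, 0.8, 0.9]
        res = paired_f1_test([x + 0.1 for x in b], b)
        assert res.degenerate
        assert res.t_statistic == np.inf and res.p_value == 0.0

    def test_matches_textbook_formula_and_scipy(self, rng):
        a = rng.uniform(0.5, 1.0, 12)
        b = rng.uniform(0.5, 1.0, 12)
        res = paired_f1_test(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t), len(d) - 1)
        assert res.t_statistic == pytest.approx(t, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_short_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            paired_f1_test([0.5], [0.6])
        with pytest.raises(ValueError):
            paired_f1_test([0.5, 0.6], [0.6])
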