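"""Pixel-wise scoring protocol: confusion, F1 forms, ROC, temporal fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaseg.evaluate import (ConfusionCounts, confusion, evaluate_series,
                            make_splits, roc_curve, scores, temporal_fusion)
from gaseg.phantom import PhantomConfig, generate_series


def brute_force_auc(probs, truth):
    """P(random positive outranks random negative), ties at half."""
    p = probs.ravel()
    t = truth.ravel().astype(bool)
    pos = p[t]
    neg = p[~t]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_enumerated_two_by_two(self):
        truth = np.array([[1, 1], [0, 0]])
        pred = np.array([[1, 0], [1, 0]])
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_perfect_and_inverted(self):
        t = np.array([[1, 0], [1, 0]])
        perfect = confusion(t, t)
        assert perfect.fp == perfect.fn == 0
        inverted = confusion(1 - t, t)
        assert inverted.tp == inverted.tn == 0

    def test_shape_and_binary_validation(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            confusion(np.array([[2, 0]]), np.array([[1, 0]]))


class TestScores:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (50, 50, 50, (0.5, 0.5, 0.5)),
        (80, 10, 30, (80 / 90, 80 / 110, 0.8)),
        (0, 0, 0, (1.0, 1.0, 1.0)),          # empty truth, empty prediction
    ])
    def test_examples(self, tp, fp, fn, expected):
        prec, rec, f1 = scores(ConfusionCounts(tp, fp, fn, tn=10))
        assert (prec, rec, f1) == pytest.approx(expected)

    def test_empty_truth_nonempty_prediction_convention(self):
        prec, rec, f1 = scores(ConfusionCounts(tp=0, fp=5, fn=0, tn=10))
        assert (prec, rec, f1) == (0.0, 1.0, 0.0)

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_both_f1_forms_agree(self, tp, fp, fn):
        """2PR/(P+R) == TP/(TP+(FP+FN)/2) on all non-degenerate counts."""
        prec, rec, f1 = scores(ConfusionCounts(tp, fp, fn, tn=1))
        counts_form = tp / (tp + 0.5 * (fp + fn)) if tp + fp + fn else 1.0
        harmonic = (2 * prec * rec / (prec + rec)) if prec + rec else 0.0
        assert f1 == pytest.approx(counts_form, abs=1e-12)
        assert f1 == pytest.approx(harmonic, abs=1e-12)


class TestRoc:
    def test_perfect_classifier_auc_one(self):
        truth = np.array([[1, 1, 0, 0]])
        _, _, auc = roc_curve(truth.astype(float), truth)
        assert auc == pytest.approx(1.0)

    def test_constant_probabilities_auc_half(self):
        truth = np.array([[1, 1, 0, 0]])
        _, _, auc = roc_curve(np.full((1, 4), 0.5), truth)
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_ranking_oracle(self, rng):
        for _ in range(5):
            probs = rng.random((20, 20))
            truth = (rng.random((20, 20)) < 0.3).astype(np.uint8)
            truth[0, 0] = 1
            truth[0, 1] = 0
            _, _, auc = roc_curve(probs, truth)
            assert auc == pytest.approx(brute_force_auc(probs, truth), abs=1e-9)

    def test_curve_includes_endpoints(self, rng):
        probs = rng.random((8, 8))
        truth = (probs > 0.6).astype(np.uint8)
        fpr, tpr, _ = roc_curve(probs, truth)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0)

    def test_single_class_truth_rejected(self, rng):
        with pytest.raises(ValueError):
            roc_curve(rng.random((4, 4)), np.ones((4, 4), dtype=np.uint8))


class TestTemporalFusion:
    def test_union_semantics(self):
        a = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        b = np.array([[0, 1], [0, 0]], dtype=np.uint8)
        fused = temporal_fusion(a, b)
        assert fused.sum() == a.sum() + b.sum()  # disjoint -> areas add
        assert np.array_equal(temporal_fusion(a, a), a)

    def test_subset_absorption(self):
        big = np.array([[1, 1], [1, 0]], dtype=np.uint8)
        small = np.array([[1, 0], [0, 0]], dtype=np.uint8)
        assert np.array_equal(temporal_fusion(big, small), big)

    def test_fusion_never_lowers_recall(self, rng):
        """Union can only add predicted-positive pixels."""
        from gaseg.evaluate import confusion, scores
        for _ in range(10):
            truth = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            pred = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            prev = (rng.random((16, 16)) < 0.4).astype(np.uint8)
            r_plain = scores(confusion(pred, truth))[1]
            r_fused = scores(confusion(temporal_fusion(pred, prev), truth))[1]
            assert r_fused >= r_plain - 1e-12


@pytest.fixture(scope="module")
def growth_series():
    cfg = PhantomConfig(image_size=64, n_lesions=2, seed=21)
    return generate_series(cfg, n_frames=5, growth_rate=0.6, name="s0")


class TestEvaluateSeries:

    def test_perfect_predictions_score_one(self, growth_series):
        preds = {"s0": [f.mask for f in growth_series.frames]}
        rep = evaluate_series(preds, [growth_series], method="oracle")
        agg = rep.aggregate()
        assert agg["f1_mean"] == pytest.approx(1.0)
        assert agg["f1_std"] == pytest.approx(0.0)

    def test_fusion_improves_recall_on_growing_series(self, growth_series):
        """Predicting the previous frame's lesion undersegments; fusing with
        the earlier prediction can only help recall."""
        masks = [f.mask for f in growth_series.frames]
        preds = {"s0": [masks[0]] + masks[:-1]}  # lag-one predictions
        plain = evaluate_series(preds, [growth_series]).aggregate()
        fused = evaluate_series(preds, [growth_series], fusion=True).aggregate()
        assert fused["recall_mean"] >= plain["recall_mean"] - 1e-12

    def test_single_frame_fusion_is_identity(self, growth_series):
        f0 = growth_series.frames[0]
        preds = {"s0": [f0.mask]}
        truth = {"s0": [f0.mask]}
        plain = evaluate_series(preds, truth).frame_scores
        fused = evaluate_series(preds, truth, fusion=True).frame_scores
        assert plain.equals(fused)

    def test_missing_truth_skipped_with_warning(self, growth_series):
        preds = {"s0": [f.mask for f in growth_series.frames]}
        truth = {"s0": [f.mask for f in growth_series.frames[:-1]] + [None]}
        with pytest.warns(UserWarning, match="missing truth"):
            rep = evaluate_series(preds, truth)
        assert len(rep.frame_scores) == len(growth_series) - 1


class TestSplits:
    def test_split_protocol_shape(self):
        splits = make_splits(n_series=18, n_train=12, n_repeats=8, seed=1)
        assert len(splits) == 8
        for train, test in splits:
            assert len(train) == 12 and len(test) == 6
            assert set(train) | set(test) == set(range(18))
            assert not set(train) & set(test)

    def test_seeded_reproducibility(self):
        assert make_splits(seed=3) == make_splits(seed=3)
        assert make_splits(seed=3) != make_splits(seed=4)
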