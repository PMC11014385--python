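"""Metric identities, subset splits, and the evaluation protocols."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import (jaccard_score, precision_recall_fscore_support)

import noisymix as nm
from noisymix.evaluation import (eval_clean_noisy, multilabel_metrics,
                                 per_label_confusion, per_sample_f1,
                                 robustness_sweep, split_clean_noisy)


def _sets_to_multihot(truth_sets, pred_sets, c=6):
    t = np.zeros((len(truth_sets), c), np.int8)
    p = np.zeros_like(t)
    for i, s in enumerate(truth_sets):
        t[i, list(s)] = 1
    for i, s in enumerate(pred_sets):
        p[i, list(s)] = 1
    return p, t


class TestMultilabelMetrics:
    def test_worked_example_set_123_vs_234(self):
        p, t = _sets_to_multihot([{1, 2, 3}], [{2, 3, 4}])
        rep = multilabel_metrics(p, t)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)
        assert rep.jaccard == pytest.approx(0.5)

    def test_perfect_prediction_scores_one_everywhere(self, rng):
        t = (rng.random((10, 5)) < 0.4).astype(np.int8)
        t[t.sum(1) == 0, 0] = 1
        for avg in ("micro", "sample"):
            rep = multilabel_metrics(t, t, avg)
            assert (rep.precision, rep.recall, rep.f1, rep.jaccard) == (1, 1, 1, 1)

    def test_empty_prediction_nonempty_truth(self):
        p, t = _sets_to_multihot([{0, 1}], [set()])
        rep = multilabel_metrics(p, t, "sample")
        assert rep.recall == 0 and rep.jaccard == 0 and rep.precision == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_micro_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        t = (rng.random((20, 6)) < 0.3).astype(np.int8)
        p = (rng.random((20, 6)) < 0.3).astype(np.int8)
        rep = multilabel_metrics(p, t)
        prec, rec, f1, _ = precision_recall_fscore_support(
            t, p, average="micro", zero_division=0)
        ji = jaccard_score(t, p, average="micro", zero_division=0)
        assert rep.precision == pytest.approx(prec)
        assert rep.recall == pytest.approx(rec)
        assert rep.f1 == pytest.approx(f1)
        assert rep.jaccard == pytest.approx(ji)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_jaccard_never_exceeds_f1(self, seed):
        rng = np.random.default_rng(seed)
        t = (rng.random((15, 5)) < 0.4).astype(np.int8)
        p = (rng.random((15, 5)) < 0.4).astype(np.int8)
        for avg in ("micro", "sample"):
            rep = multilabel_metrics(p, t, avg)
            assert rep.jaccard <= rep.f1 + 1e-12

    def test_invariant_to_sample_ordering(self, rng):
        t = (rng.random((12, 4)) < 0.4).astype(np.int8)
        p = (rng.random((12, 4)) < 0.4).astype(np.int8)
        perm = rng.permutation(12)
        for avg in ("micro", "sample"):
            a = multilabel_metrics(p, t, avg)
            b = multilabel_metrics(p[perm], t[perm], avg)
            assert a.f1 == pytest.approx(b.f1)
            assert a.jaccard == pytest.approx(b.jaccard)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            multilabel_metrics(np.zeros((2, 3)), np.zeros((2, 4)))


class TestPerLabelConfusion:
    def test_absent_label_is_all_true_negative(self):
        p, t = _sets_to_multihot([{0}, {1}], [{0}, {1}])
        c = per_label_confusion(p, t, 5)
        assert c == {"tp": 0, "fp": 0, "fn": 0, "tn": 2}

    def test_counts_partition_the_samples(self, rng):
        t = (rng.random((25, 4)) < 0.4).astype(np.int8)
        p = (rng.random((25, 4)) < 0.4).astype(np.int8)
        for label in range(4):
            c = per_label_confusion(p, t, label)
            assert sum(c.values()) == 25

    def test_matches_brute_force_loop(self, rng):
        t = (rng.random((30, 3)) < 0.5).astype(np.int8)
        p = (rng.random((30, 3)) < 0.5).astype(np.int8)
        for label in range(3):
            c = per_label_confusion(p, t, label)
            tp = fp = fn = tn = 0
            for i in range(30):
                if p[i, label] and t[i, label]:
                    tp += 1
                elif p[i, label]:
                    fp += 1
                elif t[i, label]:
                    fn += 1
                else:
                    tn += 1
            assert c == {"tp": tp, "fp": fp, "fn": fn, "tn": tn}

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            per_label_confusion(np.zeros((2, 3)), np.zeros((2, 3)), 7)


class TestCleanNoisySplit:
    def test_zero_noise_gives_empty_noisy_subset(self, small_scenes,
                                                 tiny_model):
        out = eval_clean_noisy(tiny_model, small_scenes)
        assert out["noisy"] is None
        assert out["clean"] is not None
        assert out["clean"].n_samples == len(small_scenes)

    def test_split_partitions_training_set(self, small_scenes):
        noisy = nm.inject_label_noise(small_scenes,
                                      nm.NoiseSpec(rate=0.3, seed=2))
        split = split_clean_noisy(noisy)
        assert len(split.clean_indices) + len(split.noisy_indices) == len(noisy)
        assert not set(split.clean_indices) & set(split.noisy_indices)

    def test_perfect_memorizer_scores_one_on_both_subsets(self, small_scenes):
        noisy = nm.inject_label_noise(small_scenes,
                                      nm.NoiseSpec(rate=0.3, seed=2))

        class Memorizer:
            def predict_images(self, images, threshold=0.5):
                labels = np.stack([s.labels for s in noisy])
                return labels, labels.astype(float)

        out = eval_clean_noisy(Memorizer(), noisy)
        assert out["clean"].f1 == 1.0
        assert out["noisy"].f1 == 1.0


class TestRobustnessSweep:
    def test_identity_row_reproduces_unperturbed_metrics(
            self, trained_model_and_scenes):
        model, scenes = trained_model_and_scenes
        rows = robustness_sweep(model, scenes[:40], grid=())
        assert rows[0]["perturbation"] == "none"
        images = np.stack([s.image for s in scenes[:40]])
        truths = np.stack([s.clean_labels for s in scenes[:40]])
        preds, _ = model.predict_images(images)
        direct = multilabel_metrics(preds, truths)
        assert rows[0]["f1"] == direct.f1
        assert rows[0]["jaccard"] == direct.jaccard

    def test_full_grid_emits_table_shaped_report(self,
                                                 trained_model_and_scenes):
        model, scenes = trained_model_and_scenes
        rows = robustness_sweep(model, scenes[:40])
        kinds = [(r["perturbation"], r["magnitude"]) for r in rows]
        assert kinds == [("none", None), ("rotation", 45), ("rotation", 135),
                         ("rotation", 225), ("rotation", 315),
                         ("brightness", 0.9), ("saturation", 0.9),
                         ("hue", 0.1), ("gamma", 0.9)]
        assert all(0 <= r["f1"] <= 1 for r in rows)

    def test_rotations_degrade_f1_on_oriented_shapes(
            self, trained_model_and_scenes):
        model, scenes = trained_model_and_scenes
        rows = robustness_sweep(model, scenes[:60])
        base = rows[0]["f1"]
        rot = [r["f1"] for r in rows if r["perturbation"] == "rotation"]
        assert np.mean(rot) < base


def test_per_sample_f1_matches_single_sample_reports(rng):
    t = (rng.random((8, 5)) < 0.4).astype(np.int8)
    p = (rng.random((8, 5)) < 0.4).astype(np.int8)
    vec = per_sample_f1(p, t)
    for i in range(8):
        rep = multilabel_metrics(p[i:i + 1], t[i:i + 1], "sample")
        assert vec[i] == pytest.approx(rep.f1)
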