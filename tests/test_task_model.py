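"""Preprocessing contract, confusion metrics against brute-force counting,
cut-off calibration, and the training/prediction contracts of the frame
classifier."""

import numpy as np
import pytest

from sonoskill import task_model as tm


class TestPreprocess:
    def test_moments(self, rng):
        out = tm.preprocess(rng.uniform(0, 255, (50, 60)), target_shape=(56, 72))
        assert out.shape == (56, 72)
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6

    def test_resize_doubles(self, rng):
        out = tm.preprocess(rng.uniform(0, 1, (112, 144)), target_shape=(224, 288))
        assert out.shape == (224, 288)

    def test_idempotent_at_target_shape(self, rng):
        x = rng.standard_normal((56, 72))
        once = tm.preprocess(x, (56, 72))
        twice = tm.preprocess(once, (56, 72))
        assert np.allclose(once, twice, atol=1e-12)

    def test_constant_image_left_unscaled(self):
        out = tm.preprocess(np.full((56, 72), 7.0), (56, 72))
        assert np.allclose(out, 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tm.preprocess(np.zeros((0, 5)))
        with pytest.raises(ValueError):
            tm.preprocess(np.zeros(5))


def _brute_confusion(g_hat, y, c):
    tp = tn = fp = fn = 0
    for p, t in zip(g_hat, y):
        pred = 1 if p > c else 0
        if pred and t:
            tp += 1
        elif pred and not t:
            fp += 1
        elif not pred and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestEvaluate:
    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 50))
            g_hat = rng.uniform(0, 1, n)
            y = rng.integers(0, 2, n)
            c = float(rng.uniform(0, 1))
            tp, tn, fp, fn = _brute_confusion(g_hat, y, c)
            acc, sens, spec = tm.evaluate_task_model(g_hat, y, c)
            assert acc == pytest.approx((tp + tn) / n)
            if tp + fn:
                assert sens == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert spec == pytest.approx(tn / (tn + fp))

    def test_hand_example(self):
        acc, sens, spec = tm.evaluate_task_model(
            np.array([0.9, 0.2, 0.4, 0.6]), np.array([1, 0, 1, 0]), 0.5
        )
        assert (acc, sens, spec) == (0.5, 0.5, 0.5)

    def test_perfect_and_degenerate(self):
        acc, sens, spec = tm.evaluate_task_model(
            np.array([0.9, 0.1]), np.array([1, 0]), 0.5
        )
        assert (acc, sens, spec) == (1.0, 1.0, 1.0)
        acc, sens, spec = tm.evaluate_task_model(
            np.zeros(6), np.array([1, 0, 1, 0, 1, 0]), 0.5
        )
        assert sens == 0.0 and spec == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tm.evaluate_task_model(np.array([]), np.array([]), 0.5)

    def test_balanced_accuracy_identity(self, rng):
        g_hat = rng.uniform(0, 1, 100)
        y = rng.integers(0, 2, 100)
        _, sens, spec = tm.evaluate_task_model(g_hat, y, 0.5)
        assert tm.balanced_accuracy(y, g_hat, 0.5) == pytest.approx((sens + spec) / 2)


class TestCalibrateCutoff:
    def test_enumerated_example(self):
        g_hat = np.arange(0.1, 1.01, 0.1)
        labels = np.zeros(10, dtype=int)
        c, spec = tm.calibrate_cutoff(g_hat, labels, 0.8)
        assert c == pytest.approx(0.8)
        assert spec == pytest.approx(0.8)

    def test_target_one(self, rng):
        g_hat = rng.uniform(0, 1, 30)
        labels = np.zeros(30, dtype=int)
        c, spec = tm.calibrate_cutoff(g_hat, labels, 1.0)
        assert spec == 1.0
        assert np.all(~(g_hat > c))

    def test_achieves_target(self, rng):
        g_hat = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        c, spec = tm.calibrate_cutoff(g_hat, labels, 0.5)
        assert spec >= 0.5

    def test_monotone_in_target(self, rng):
        g_hat = rng.uniform(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        cs, sens = [], []
        for target in (0.5, 0.7, 0.8, 0.9, 0.99):
            c, _ = tm.calibrate_cutoff(g_hat, labels, target)
            cs.append(c)
            sens.append(tm.evaluate_task_model(g_hat, labels, c).sensitivity)
        assert all(a <= b + 1e-12 for a, b in zip(cs, cs[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError):
            tm.calibrate_cutoff(np.array([0.5]), np.array([1]), 0.8)


def _separable_clips(rng, n_clips=6, j=40, shape=(28, 36)):
    """Tiny two-class clips with an unmistakable appearance gap."""
    clips = []
    for _ in range(n_clips):
        y = rng.integers(0, 2, j)
        frames = rng.normal(0, 0.05, (j, *shape))
        frames[y == 1, 8:20, 10:26] += 2.0  # bright block only on positives
        clips.append((frames.astype(np.float32), y))
    return clips


class TestTraining:
    def _config(self, **kw):
        defaults = dict(lr=1e-2, epochs=8, resize_shape=(28, 36), seed=0)
        defaults.update(kw)
        return tm.TaskModelConfig(**defaults)

    def test_learns_separable_data(self, rng):
        clips = _separable_clips(rng)
        model = tm.train_task_model(clips[:4], clips[4:], self._config())
        assert max(model.history["val_metric"]) >= 0.95

    def test_single_class_rejected(self, rng):
        clips = [(rng.standard_normal((10, 28, 36)), np.ones(10, dtype=int))]
        with pytest.raises(ValueError):
            tm.train_task_model(clips, clips, self._config())

    def test_deterministic_given_seed(self, rng):
        clips = _separable_clips(rng, n_clips=4, j=20)
        m1 = tm.train_task_model(clips[:3], clips[3:], self._config(epochs=4))
        m2 = tm.train_task_model(clips[:3], clips[3:], self._config(epochs=4))
        assert m1.history["best_epoch"] == m2.history["best_epoch"]
        assert m1.history["val_metric"] == m2.history["val_metric"]

    def test_predictions_shape_and_range(self, rng):
        clips = _separable_clips(rng, n_clips=4, j=20)
        model = tm.train_task_model(clips[:3], clips[3:], self._config(epochs=4))
        for context in (1, 5):
            cfg5 = self._config(context=context, epochs=2)
            m = tm.train_task_model(clips[:3], clips[3:], cfg5)
            g_hat = m.predict_proba(clips[0][0])
            assert g_hat.shape == (20,)
            assert g_hat.min() >= 0 and g_hat.max() <= 1

    def test_separates_class_means(self, rng):
        clips = _separable_clips(rng)
        model = tm.train_task_model(clips[:4], clips[4:], self._config())
        frames, y = clips[5]
        g_hat = model.predict_proba(frames)
        assert g_hat[y == 1].mean() > g_hat[y == 0].mean()

    def test_save_load_roundtrip(self, rng, tmp_path):
        clips = _separable_clips(rng, n_clips=4, j=20)
        model = tm.train_task_model(clips[:3], clips[3:], self._config(epochs=3))
        path = tmp_path / "model.npz"
        tm.save_task_model(model, path)
        back = tm.load_task_model(path)
        assert np.allclose(
            back.predict_proba(clips[0][0]), model.predict_proba(clips[0][0])
        )
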