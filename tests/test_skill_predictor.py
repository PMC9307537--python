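"""Window-sample bookkeeping, training contracts and prediction shape/range
guarantees of the multi-modal skill regressor."""

import numpy as np
import pytest

import sonoskill as sk
from sonoskill import skill_predictor as sp
from sonoskill import skill_scores as ss


def _toy_clips(rng, n_clips=3, js=(200, 250, 300), shape=(20, 24)):
    clips, motions = [], []
    for k in range(n_clips):
        j = js[k % len(js)]
        frames = rng.normal(0, 1, (j, *shape)).astype(np.float32)
        clips.append(
            sk.ScanClip(frames=frames, fps=30, subject_id=f"S{k}",
                        operator_id=f"O{k}", dp_index=j // 2)
        )
        motions.append(sk.MotionTrace(omega=rng.normal(0, 1, (3, j)), fps=30))
    return clips, motions


class TestBuildTrainingSet:
    def test_sample_count_formula(self, rng):
        clips, motions = _toy_clips(rng)
        tau = 60
        series = [
            ss.SkillScoreSeries(scores=rng.uniform(0, 1, c.n_frames - tau + 1),
                                criterion="pos", tau=tau)
            for c in clips
        ]
        samples = sp.build_training_set(clips, motions, series, tau)
        assert len(samples) == 141 + 191 + 241

    def test_random_bookkeeping(self, rng):
        for _ in range(50):
            j = int(rng.integers(30, 400))
            tau = int(rng.integers(1, j + 1))
            clips, motions = _toy_clips(rng, n_clips=1, js=(j,), shape=(8, 10))
            series = [ss.SkillScoreSeries(scores=np.zeros(j - tau + 1),
                                          criterion="pos", tau=tau)]
            assert len(sp.build_training_set(clips, motions, series, tau)) == j - tau + 1

    def test_alignment_audit(self, rng):
        clips, motions = _toy_clips(rng, n_clips=1, js=(100,))
        tau = 10
        series = [ss.SkillScoreSeries(scores=rng.uniform(0, 1, 91),
                                      criterion="pos", tau=tau)]
        samples = sp.build_training_set(clips, motions, series, tau)
        s = samples[17]
        assert s.n == 17
        assert np.array_equal(s.frames, clips[0].frames[17:27])
        assert np.array_equal(s.motion, motions[0].omega[:, 17:27])
        assert s.target == series[0].scores[17]

    def test_tau_mismatch_rejected(self, rng):
        clips, motions = _toy_clips(rng, n_clips=1, js=(50,))
        series = [ss.SkillScoreSeries(scores=np.zeros(41), criterion="pos", tau=10)]
        with pytest.raises(ValueError):
            sp.build_training_set(clips, motions, series, tau=12)


def _config(**kw):
    defaults = dict(tau=20, lr=1e-2, epochs=30, patience=10, seed=0)
    defaults.update(kw)
    return sp.PredictorConfig(**defaults)


def _samples_with_signal(rng, n_clips=6, j=120, tau=20):
    """Clips whose frame brightness and motion amplitude both encode the
    score-generating signal."""
    clips, motions, series = [], [], []
    for k in range(n_clips):
        phase = rng.uniform(0, 2 * np.pi)
        level = 0.5 + 0.5 * np.sin(2 * np.pi * np.arange(j) / 60.0 + phase)
        # signal as spatial contrast (survives per-frame z-scoring) and as
        # motion amplitude modulation
        frames = rng.normal(0, 0.3, (j, 20, 24))
        frames[:, 6:14, 8:18] += 3.0 * level[:, None, None]
        omega = rng.normal(0, 0.2, (3, j)) * (0.3 + level[None, :])
        clips.append(sk.ScanClip(frames=frames.astype(np.float32), fps=30,
                                 subject_id=f"S{k}", operator_id=f"O{k}",
                                 dp_index=0))
        motions.append(sk.MotionTrace(omega=omega, fps=30))
        w = np.lib.stride_tricks.sliding_window_view(level, tau)
        series.append(ss.SkillScoreSeries(scores=np.clip(w.mean(1), 0, 1),
                                          criterion="pos", tau=tau))
    return sp.build_training_set(clips, motions, series, tau), clips, motions, series


class TestTraining:
    def test_near_constant_targets_regress_to_level(self, rng):
        clips, motions = _toy_clips(rng, n_clips=4, js=(80,))
        tau = 20
        series = [
            ss.SkillScoreSeries(
                scores=np.full(c.n_frames - tau + 1, 0.7)
                + rng.uniform(-0.01, 0.01, c.n_frames - tau + 1),
                criterion="pos", tau=tau,
            )
            for c in clips
        ]
        samples = sp.build_training_set(clips, motions, series, tau)
        model = sp.train_predictor(samples, _config())
        pred = sp.predict_scores(model, clips[3], motions[3], tau)
        assert abs(pred.scores.mean() - 0.7) < 0.02

    def test_constant_targets_rejected(self, rng):
        clips, motions = _toy_clips(rng, n_clips=2, js=(60,))
        tau = 10
        series = [ss.SkillScoreSeries(scores=np.full(51, 0.5), criterion="pos",
                                      tau=tau) for _ in clips]
        samples = sp.build_training_set(clips, motions, series, tau)
        with pytest.raises(ValueError):
            sp.train_predictor(samples, _config(tau=10))

    def test_missing_motion_rejected(self, rng):
        clips, _ = _toy_clips(rng, n_clips=2, js=(60,))
        tau = 10
        series = [ss.SkillScoreSeries(scores=rng.uniform(0, 1, 51),
                                      criterion="pos", tau=tau) for _ in clips]
        samples = sp.build_training_set(clips, [None, None], series, tau)
        with pytest.raises(ValueError):
            sp.train_predictor(samples, _config(tau=10, modality="both"))
        # video-only training works without motion
        model = sp.train_predictor(samples, _config(tau=10, modality="video"))
        assert model.history["train_loss"]

    def test_deterministic_given_seed(self, rng):
        samples, *_ = _samples_with_signal(rng, n_clips=4)
        m1 = sp.train_predictor(samples, _config(epochs=10))
        m2 = sp.train_predictor(samples, _config(epochs=10))
        assert m1.history["val_rmse"] == m2.history["val_rmse"]
        assert m1.blend_alpha == m2.blend_alpha

    def test_learns_visible_signal(self, rng):
        samples, clips, motions, series = _samples_with_signal(rng)
        held = clips[-1].subject_id
        train = [s for s in samples if s.clip_id != held]
        model = sp.train_predictor(train, _config(epochs=60))
        pred = sp.predict_scores(model, clips[-1], motions[-1], 20)
        true = series[-1].scores
        baseline = np.full_like(true, np.mean([s.target for s in train]))
        assert sk.rmse(true, pred.scores) < sk.rmse(true, baseline)
        assert sk.pcc(true, pred.scores) > 0

    def test_save_load_roundtrip(self, rng, tmp_path):
        samples, clips, motions, _ = _samples_with_signal(rng, n_clips=4)
        model = sp.train_predictor(samples, _config(epochs=5))
        sp.save_predictor(model, tmp_path / "m.npz")
        back = sp.load_predictor(tmp_path / "m.npz")
        p1 = sp.predict_scores(model, clips[0], motions[0], 20)
        p2 = sp.predict_scores(back, clips[0], motions[0], 20)
        assert np.allclose(p1.scores, p2.scores)


class TestPredictScores:
    def test_output_contract(self, rng):
        samples, clips, motions, _ = _samples_with_signal(rng, n_clips=4)
        model = sp.train_predictor(samples, _config(epochs=5))
        pred = sp.predict_scores(model, clips[0], motions[0], 20)
        assert pred.n_windows == clips[0].n_frames - 20 + 1
        assert pred.scores.min() >= 0 and pred.scores.max() <= 1

    def test_short_clip_rejected(self, rng):
        samples, clips, motions, _ = _samples_with_signal(rng, n_clips=4)
        model = sp.train_predictor(samples, _config(epochs=2))
        short = sk.ScanClip(frames=clips[0].frames[:5], fps=30, subject_id="S",
                            operator_id="O", dp_index=0)
        with pytest.raises(ValueError):
            sp.predict_scores(model, short, motions[0], 20)

    def test_tau_mismatch_rejected(self, rng):
        samples, clips, motions, _ = _samples_with_signal(rng, n_clips=4)
        model = sp.train_predictor(samples, _config(epochs=2))
        with pytest.raises(ValueError):
            sp.predict_scores(model, clips[0], motions[0], 30)
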