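"""View classifiers: spec validation, grid search, training contracts."""

import numpy as np
import pytest

from patternpipe import nn
from patternpipe import viewclass as vc


def toy_task(n=60, size=16, seed=0):
    """Perfectly separable: dark vs bright images."""
    rng = np.random.default_rng(seed)
    dark = rng.uniform(0.0, 0.3, (n // 2, size, size, 1))
    bright = rng.uniform(0.7, 1.0, (n // 2, size, size, 1))
    X = np.concatenate([dark, bright]).astype(np.float32)
    y = np.repeat([0, 1], n // 2)
    order = rng.permutation(n)
    return X[order], y[order]


class TestClassifierSpec:
    def test_canonical_best_architectures_build(self):
        pose = vc.best_pose_spec()
        flank = vc.best_flank_spec()
        assert pose.conv_layers == (32, 64) and pose.learning_rate == 1e-5
        assert flank.conv_layers == (64, 32, 32) and flank.learning_rate == 1e-4
        assert flank.avg_pool_front and not pose.avg_pool_front
        for spec in (pose, flank):
            model = vc.build_classifier(spec)
            out = model.forward(np.zeros((2, 64, 64, 1), dtype=np.float32))
            assert out.shape == (2, 2)

    @pytest.mark.parametrize("bad", [
        dict(conv_layers=(128,)),
        dict(conv_layers=()),
        dict(conv_layers=(16, 16, 16, 16)),
        dict(learning_rate=5e-3),
        dict(kernel=5),
    ])
    def test_out_of_grid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            vc.ClassifierSpec(**bad)

    def test_avg_pool_front_reduces_resolution_by_four(self):
        pool = nn.AvgPool(4)
        x = np.arange(64, dtype=np.float32).reshape(1, 8, 8, 1)
        out = pool.forward(x, train=False)
        assert out.shape == (1, 2, 2, 1)
        assert out[0, 0, 0, 0] == pytest.approx(x[0, :4, :4, 0].mean())


class TestTrain:
    def test_separable_toy_task_perfect(self):
        X, y = toy_task()
        spec = vc.ClassifierSpec(conv_layers=(16,), learning_rate=1e-3,
                                 input_size=16, epochs=10)
        fitted = vc.train(spec, X, y, split=(0.7, 0.15, 0.15), seed=0)
        assert fitted.metrics["test"]["accuracy"] == 1.0

    def test_wilson_interval_matches_field_report(self):
        # accuracy 0.90 at n=2000 -> 95% CI ~ (0.886, 0.912)
        point, lo, hi = vc.accuracy_ci(1800, 2000)
        assert point == pytest.approx(0.90)
        assert lo == pytest.approx(0.886, abs=0.001)
        assert hi == pytest.approx(0.912, abs=0.001)
        assert lo <= 0.90 <= hi

    def test_ci_contains_point_and_shrinks_with_n(self):
        _, lo1, hi1 = vc.accuracy_ci(45, 50)
        _, lo2, hi2 = vc.accuracy_ci(450, 500)
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_label_shuffled_data_near_chance(self):
        rng = np.random.default_rng(5)
        X, _ = toy_task(n=400, seed=5)
        y = rng.integers(0, 2, 400)  # labels carry no signal
        spec = vc.ClassifierSpec(conv_layers=(16,), learning_rate=1e-3,
                                 input_size=16, epochs=3)
        fitted = vc.train(spec, X, y, split=(0.5, 0.0, 0.5), seed=1)
        assert 0.35 <= fitted.metrics["test"]["accuracy"] <= 0.65

    def test_single_class_training_rejected(self):
        X, _ = toy_task(n=40)
        with pytest.raises(ValueError):
            vc.train(vc.ClassifierSpec(conv_layers=(16,), learning_rate=1e-3,
                                       input_size=16, epochs=1),
                     X, np.zeros(40, dtype=int), seed=0)

    def test_weights_roundtrip_deterministic_classify(self):
        X, y = toy_task()
        spec = vc.ClassifierSpec(conv_layers=(16,), learning_rate=1e-3,
                                 input_size=16, epochs=5)
        fitted = vc.train(spec, X, y, seed=0,
                          label_map={0: "dark", 1: "bright"})
        labels1, s1 = vc.classify(fitted, X[:8])
        labels2, s2 = vc.classify(fitted, X[:8])
        assert labels1 == labels2
        assert np.array_equal(s1, s2)
        assert set(labels1) <= {"dark", "bright"}

    def test_empty_crop_list(self):
        X, y = toy_task()
        spec = vc.ClassifierSpec(conv_layers=(16,), learning_rate=1e-3,
                                 input_size=16, epochs=1)
        fitted = vc.train(spec, X, y, seed=0)
        labels, scores = vc.classify(fitted, np.zeros((0, 16, 16, 1)))
        assert labels == [] and len(scores) == 0


class TestTune:
    def test_grid_has_39_cells(self):
        grid = vc.spec_grid()
        assert len(grid) == 3 + 9 + 27
        assert len(set(grid)) == 39

    def test_tune_samples_distinct_cells_and_stays_in_grid(self):
        X, y = toy_task(n=40)
        best, history = vc.tune(X, y, n_trials=5, epochs=1, seed=0,
                                input_size=16, base_lr=1e-3)
        archs = [tuple(h["conv_layers"]) for h in history[:5]]
        assert len(set(archs)) == 5
        assert all(a in vc.spec_grid() for a in archs)
        assert best.conv_layers in vc.spec_grid()
        assert any(np.isclose(best.learning_rate, lr) for lr in vc.ALLOWED_LR)

    def test_tie_break_prefers_fewer_parameters(self):
        X, y = toy_task(n=60)
        # separable task: most archs reach val accuracy 1.0 and tie
        best, history = vc.tune(X, y, n_trials=4, epochs=6, seed=3,
                                input_size=16, base_lr=1e-3)
        top_acc = max(h["val_accuracy"] for h in history[:4])
        tied = [h for h in history[:4] if h["val_accuracy"] == top_acc]
        assert best.conv_layers == tuple(
            min(tied, key=lambda h: (h["n_parameters"], h["trial"]))["conv_layers"]
        )

    def test_deterministic_trial_sequence(self):
        X, y = toy_task(n=40)
        _, h1 = vc.tune(X, y, n_trials=3, epochs=1, seed=9, input_size=16,
                        base_lr=1e-3)
        _, h2 = vc.tune(X, y, n_trials=3, epochs=1, seed=9, input_size=16,
                        base_lr=1e-3)
        assert [h["conv_layers"] for h in h1] == [h["conv_layers"] for h in h2]

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            vc.tune(np.zeros((0, 16, 16, 1)), np.zeros(0, dtype=int))


class TestEngine:
    def test_dropout_scales_and_masks_only_in_training(self):
        rng = np.random.default_rng(0)
        layer = nn.Dropout(0.5, rng)
        x = np.ones((4, 10), dtype=np.float32)
        out_eval = layer.forward(x, train=False)
        assert np.array_equal(out_eval, x)
        out_train = layer.forward(x, train=True)
        assert set(np.unique(out_train)) <= {0.0, 2.0}

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(1)
        spec = vc.ClassifierSpec(conv_layers=(16,), learning_rate=1e-3,
                                 input_size=8, dense_units=8, dropout_rate=0.0)
        model = vc.build_classifier(spec, seed=0)
        X = rng.random((4, 8, 8, 1)).astype(np.float32)
        y = np.array([0, 1, 0, 1])
        trainer = nn.AdamTrainer(model, lr=0.0)

        def loss():
            logits = model.forward(X)
            p = np.exp(logits - logits.max(1, keepdims=True))
            p /= p.sum(1, keepdims=True)
            return -np.mean(np.log(p[np.arange(4), y]))

        trainer.step_batch(X, y)  # lr=0: fills grads without updating
        for layer in model.layers:
            for pi, p in enumerate(layer.params):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                eps, old = 1e-3, p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = layer.grads[pi][idx]
                assert abs(num - ana) / max(1e-4, abs(num) + abs(ana)) < 0.05
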