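"""Mean-Teacher components: perturbation, ramp, losses, EMA, training loops."""

import dataclasses
import math

import numpy as np
import pytest

from moltox import (
    FixtureSpec,
    GCNConfig,
    MTConfig,
    assign_labels,
    classification_loss,
    consistency_loss,
    consistency_weight,
    ema_update,
    fit,
    fit_supervised,
    generate_library,
    perturb,
    scaffold_split,
)

GCN_SMALL = GCNConfig(hidden_dims=(8, 8), dropout_rates=(0.1, 0.1),
                      mlp_hidden_dim=6)


def small_split(seed=42, n=60, noise=0.1):
    lib = generate_library(n, seed, positive_fraction=0.3)
    ds = assign_labels(lib, FixtureSpec(label_noise=noise, seed=seed))
    split = scaffold_split(ds)
    return ds.subset(split.train), ds.subset(split.validation)


class TestPerturb:
    def test_zero_sigma_is_identity(self, rng):
        x = rng.normal(size=(5, 74))
        assert perturb(x, 0.0, rng) is x

    def test_noise_mean_near_zero(self):
        x = np.zeros((1000, 100))
        out = perturb(x, 0.5, np.random.default_rng(0))
        n = x.size
        assert abs(out.mean()) < 3 * 0.5 / math.sqrt(n)

    def test_independent_streams_differ(self):
        x = np.zeros((4, 4))
        a = perturb(x, 1.0, np.random.default_rng(1))
        b = perturb(x, 1.0, np.random.default_rng(2))
        assert not np.array_equal(a, b)


class TestConsistencyRamp:
    def test_endpoints(self):
        assert consistency_weight(100, 100) == pytest.approx(1.0)
        assert consistency_weight(0, 100) == pytest.approx(math.exp(-5.0))
        assert consistency_weight(0, 100) == pytest.approx(0.006738, abs=1e-6)

    def test_monotone_nondecreasing(self):
        ws = [consistency_weight(i, 500) for i in range(0, 700, 7)]
        assert all(b >= a for a, b in zip(ws, ws[1:]))
        assert all(math.exp(-5.0) <= w <= 1.0 for w in ws)

    def test_negative_step_rejected(self):
        with pytest.raises(ValueError):
            consistency_weight(-1, 10)


class TestClassificationLoss:
    def test_perfect_prediction_zero(self):
        z = np.array([[1.0, 0.0]])
        assert classification_loss(z, np.array([0.0])) < 1e-9

    def test_uniform_prediction_ln2(self):
        z = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert classification_loss(z, np.array([0.0, 1.0])) == pytest.approx(
            math.log(2.0), abs=1e-12
        )

    def test_all_missing_batch_is_zero(self):
        z = np.array([[0.3, 0.7], [0.9, 0.1]])
        assert classification_loss(z, np.array([np.nan, np.nan])) == 0.0

    def test_missing_rows_do_not_change_loss(self, rng):
        z = rng.dirichlet([1, 1], size=6)
        labels = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        base = classification_loss(z, labels)
        z_aug = np.vstack([z, rng.dirichlet([1, 1], size=3)])
        labels_aug = np.concatenate([labels, [np.nan] * 3])
        assert classification_loss(z_aug, labels_aug) == pytest.approx(base, abs=1e-12)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            classification_loss(np.array([[0.5, 0.5]]), np.array([2.0]))


class TestConsistencyLoss:
    def test_identical_outputs_zero(self, rng):
        z = rng.dirichlet([1, 1], size=4)
        assert consistency_loss(z, z.copy()) == 0.0

    def test_opposite_certainty_is_one(self):
        assert consistency_loss(np.array([[1.0, 0.0]]),
                                np.array([[0.0, 1.0]])) == pytest.approx(1.0)

    def test_nonnegative_and_shape_checked(self, rng):
        z = rng.dirichlet([1, 1], size=3)
        assert consistency_loss(z, rng.dirichlet([1, 1], size=3)) >= 0.0
        with pytest.raises(ValueError):
            consistency_loss(z, z[:2])


class TestEMA:
    def weights(self, value):
        return {"w": np.full(3, float(value))}

    def test_alpha_zero_copies_student(self):
        out = ema_update(self.weights(1.0), self.weights(5.0), 0.0)
        assert np.allclose(out["w"], 5.0)

    def test_alpha_one_freezes_teacher(self):
        out = ema_update(self.weights(1.0), self.weights(5.0), 1.0)
        assert np.allclose(out["w"], 1.0)

    def test_geometric_decay(self):
        t = self.weights(1.0)
        for n in range(1, 30):
            t = ema_update(t, self.weights(0.0), 0.9)
            assert t["w"][0] == pytest.approx(0.9 ** n, abs=1e-15)

    def test_telescoping_closed_form(self, rng):
        """n EMA steps with constant alpha equal the explicit geometric sum."""
        alpha, n = 0.95, 40
        students = [{"w": rng.normal(size=4)} for _ in range(n)]
        t0 = {"w": rng.normal(size=4)}
        t = {"w": t0["w"].copy()}
        for s in students:
            t = ema_update(t, s, alpha)
        closed = alpha ** n * t0["w"]
        for k, s in enumerate(students, start=1):
            closed = closed + (1 - alpha) * alpha ** (n - k) * s["w"]
        assert np.max(np.abs(t["w"] - closed)) < 1e-12

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            ema_update(self.weights(0), self.weights(1), 1.5)


class TestConfigs:
    def test_invalid_mt_config_rejected(self):
        with pytest.raises(ValueError):
            MTConfig(r_u=-1.0)
        with pytest.raises(ValueError):
            MTConfig(alpha_max=1.0)
        with pytest.raises(ValueError):
            MTConfig(patience=0)

    def test_empty_pool_with_positive_ru_rejected(self):
        tr, va = small_split()
        with pytest.raises(ValueError):
            fit(tr, va, [], MTConfig(r_u=1.0, max_epochs=1), GCN_SMALL)


class TestTrainingLoops:
    def test_early_stopping_bounds_epochs(self):
        tr, va = small_split()
        cfg = MTConfig(r_u=0.0, max_epochs=50, patience=3, seed=0,
                       batch_size=16)
        _, hist = fit(tr, va, [], cfg, GCN_SMALL)
        best_epoch = int(np.argmax([h["val_auc"] for h in hist]))
        assert len(hist) <= best_epoch + cfg.patience + 1

    def test_seeded_run_reproducible(self):
        tr, va = small_split()
        cfg = MTConfig(r_u=0.0, noise_sigma=0.1, max_epochs=3, patience=30,
                       seed=5)
        p1, h1 = fit(tr, va, [], cfg, GCN_SMALL)
        p2, h2 = fit(tr, va, [], cfg, GCN_SMALL)
        assert all(np.array_equal(p1[k], p2[k]) for k in p1)
        assert h1 == h2

    def test_degenerate_ssl_is_bitwise_supervised(self):
        """r_u=0, sigma=0, alpha=0: the Mean-Teacher trajectory collapses to
        plain supervised training exactly."""
        tr, va = small_split()
        cfg = MTConfig(r_u=0.0, noise_sigma=0.0, alpha_max=0.0,
                       max_epochs=4, patience=30, seed=3)
        p_mt, h_mt = fit(tr, va, [], cfg, GCN_SMALL)
        p_sl, h_sl = fit_supervised(tr, va, cfg, GCN_SMALL)
        assert all(np.array_equal(p_mt[k], p_sl[k]) for k in p_mt)
        assert [h["val_auc"] for h in h_mt] == [h["val_auc"] for h in h_sl]

    def test_consistency_loss_recorded_with_pool(self, benchmark):
        subsets, pool = benchmark
        cfg = MTConfig(r_u=1.0, max_epochs=2, patience=30, seed=0)
        _, hist = fit(subsets["train"], subsets["validation"],
                      pool.smiles[:len(subsets["train"])], cfg, GCN_SMALL)
        assert all(h["loss_con"] > 0.0 for h in hist)
        assert all(0 < h["w"] <= 1.0 for h in hist)
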