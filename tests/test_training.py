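"""Loss algebra, class weighting, masking, splits and the fit loop."""

import numpy as np
import pytest

import pairconn as pc
from pairconn import autodiff as ad
from pairconn.training import (_batch_losses, class_weights, combined_loss,
                               make_cv_splits, masked_weighted_bce, train_model)


class TestClassWeights:
    def test_balanced_classes_give_unit_weight(self):
        y = np.array([[0], [1], [0], [1]])
        m = np.ones_like(y)
        np.testing.assert_allclose(class_weights(y, m), [1.0])

    def test_study_prevalence_72_percent(self):
        """A 72%-positive time-point weights positives by 28/72."""
        y = np.zeros((100, 1), dtype=int)
        y[:72] = 1
        w = class_weights(y, np.ones_like(y))
        np.testing.assert_allclose(w, [28 / 72])

    def test_counts_respect_mask_per_split(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=(50, 3))
        m = rng.integers(0, 2, size=(50, 3))
        m[:, 0] = 1
        w = class_weights(y, m)
        for h in range(3):
            pos = ((y[:, h] == 1) & (m[:, h] == 1)).sum()
            neg = ((y[:, h] == 0) & (m[:, h] == 1)).sum()
            assert w[h] == pytest.approx(neg / pos)

    def test_single_class_head_warns_weight_one(self):
        y = np.ones((10, 1), dtype=int)
        with pytest.warns(UserWarning, match="single observed class"):
            w = class_weights(y, np.ones_like(y))
        assert w[0] == 1.0


class TestMaskedBCE:
    def test_balanced_weighted_equals_unweighted(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(8, 2))
        y = np.tile([[0, 1], [1, 0]], (4, 1)).astype(float)
        m = np.ones_like(y)
        w = class_weights(y, m)
        assert masked_weighted_bce(logits, y, m, w) == pytest.approx(
            masked_weighted_bce(logits, y, m, np.ones(2)), abs=1e-10)

    def test_masked_coordinate_value_is_ignored(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(4, 3))
        y = rng.integers(0, 2, size=(4, 3)).astype(float)
        m = np.ones_like(y)
        m[1, 2] = 0
        base = masked_weighted_bce(logits, y, m, 1.0)
        y2 = y.copy()
        y2[1, 2] = 1 - y2[1, 2]
        assert masked_weighted_bce(logits, y2, m, 1.0) == base  # bit-identical

    def test_equals_scalar_double_loop(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(4, 3))
        y = rng.integers(0, 2, size=(4, 3)).astype(float)
        m = rng.integers(0, 2, size=(4, 3)).astype(float)
        m[0, 0] = 1
        w = np.array([0.5, 1.5, 2.0])
        total, count = 0.0, 0
        for i in range(4):
            for j in range(3):
                if m[i, j]:
                    x = logits[i, j]
                    p = 1 / (1 + np.exp(-x))
                    total += -(w[j] * y[i, j] * np.log(p)
                               + (1 - y[i, j]) * np.log(1 - p))
                    count += 1
        assert masked_weighted_bce(logits, y, m, w) == pytest.approx(
            total / count, rel=1e-12)


class TestCombinedLoss:
    @pytest.mark.parametrize("lam,l1,l2,expect", [
        (1.0, 1.0, 0.5, 1.0),
        (0.0, 1.0, 0.5, 0.5),
        (0.6, 1.0, 0.5, 0.8),
    ])
    def test_affine_combination(self, lam, l1, l2, expect):
        b = combined_loss(l1, l2, lam)
        assert b.L == pytest.approx(expect, abs=1e-15)
        assert b.L == pytest.approx(lam * b.L1 + (1 - lam) * b.L2, abs=1e-15)

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            combined_loss(1.0, 1.0, 1.5)


class TestSplits:
    def test_sizes_and_disjointness(self):
        ids = [f"s{i}" for i in range(10)]
        for tr, te in make_cv_splits(ids, 5, 0.8, seed=0):
            assert len(tr) == 8 and len(te) == 2
            assert not set(tr) & set(te)
            assert sorted(tr + te) == sorted(ids)

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(30)]
        assert make_cv_splits(ids, 5, 0.8, 7) == make_cv_splits(ids, 5, 0.8, 7)
        assert make_cv_splits(ids, 5, 0.8, 7) != make_cv_splits(ids, 5, 0.8, 8)

    def test_study_scale_160_subjects(self):
        tr, te = make_cv_splits([f"s{i}" for i in range(160)], 1, 0.8, 0)[0]
        assert len(tr) == 128 and len(te) == 32

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            make_cv_splits(["a", "b"], 5, 0.8, 0)


class TestTrainModel:
    def _xy(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 4, 16))
        Y = rng.integers(0, 2, size=(n, 3)).astype(float)
        M = np.ones_like(Y)
        return X, Y, M

    def _configs(self, **kw):
        mc = pc.ModelConfig(n_regions=4, n_timepoints=16, embed_dim=3, head_size=3,
                            conv_filters=(2, 3, 3, 4, 4, 4), similarity_hidden=(5, 4),
                            classifier_hidden=(100, 6), dropout=0.0, **kw)
        tc = pc.TrainConfig(epochs=2, batch_size=6, learning_rate=1e-3, seed=1)
        return mc, tc

    def test_reproducible_histories(self):
        X, Y, M = self._xy()
        mc, tc = self._configs()
        _, h1 = train_model(X, Y, M, mc, tc)
        _, h2 = train_model(X, Y, M, mc, tc)
        assert h1.equals(h2)

    def test_lambda_one_zeroes_Kprime_gradient_contribution(self):
        """With lambda=1 the combined gradient equals the L1-only gradient."""
        X, Y, M = self._xy(n=6)
        mc, _ = self._configs(lam=1.0)
        net = pc.PairwiseAttentionNet(mc, seed=0)
        total, L1, L2 = _batch_losses(net, X, Y, M, np.ones(3),
                                      np.random.default_rng(0))
        for p in net.params.values():
            p.grad = None
        total.backward()
        g_total = {k: p.grad.copy() if p.grad is not None else None
                   for k, p in net.params.items()}
        for p in net.params.values():
            p.grad = None
        out = net.forward_graph(X, train=True, rng=np.random.default_rng(0))
        ad.masked_weighted_bce_with_logits(out["logits_K"], Y, M, np.ones(3)).backward()
        for k, p in net.params.items():
            if g_total[k] is None:
                assert p.grad is None or not p.grad.any()
            else:
                np.testing.assert_allclose(g_total[k], p.grad, atol=1e-12)

    def test_loss_history_columns_and_identity(self):
        X, Y, M = self._xy()
        mc, tc = self._configs()
        _, hist = train_model(X, Y, M, mc, tc)
        np.testing.assert_allclose(
            hist["L"], mc.lam * hist["L1"] + (1 - mc.lam) * hist["L2"], atol=1e-12)

    def test_masking_invariance_through_training_step(self):
        X, Y, M = self._xy()
        M[2, 1] = 0
        mc, tc = self._configs()
        m1, h1 = train_model(X, Y, M, mc, tc)
        Y2 = Y.copy()
        Y2[2, 1] = 1 - Y2[2, 1]
        m2, h2 = train_model(X, Y2, M, mc, tc, pos_weight=class_weights(Y, M))
        assert h1.equals(h2)
        np.testing.assert_array_equal(m1.predict(X).logits, m2.predict(X).logits)

    def test_lr_schedule_divides_by_ten(self):
        tc = pc.TrainConfig(epochs=1, lr_decay_every=30)
        assert tc.lr_at_epoch(0) == pytest.approx(1e-4)
        assert tc.lr_at_epoch(29) == pytest.approx(1e-4)
        assert tc.lr_at_epoch(30) == pytest.approx(1e-5)
        assert tc.lr_at_epoch(90) == pytest.approx(1e-7)

    def test_regression_mode_beats_mean_predictor_on_synthetic_caps(self):
        """MSE against z-scored severity must beat the variance floor."""
        rng = np.random.default_rng(5)
        n = 40
        X = rng.normal(size=(n, 4, 16))
        signal = X[:, 0, :4].mean(axis=1)
        Y = np.tile((signal - signal.mean())[:, None] / signal.std(), (1, 3))
        M = np.ones_like(Y)
        mc, _ = self._configs(regression_mode=True)
        tc = pc.TrainConfig(epochs=30, batch_size=10, learning_rate=3e-3, seed=2)
        model, hist = train_model(X, Y, M, mc, tc)
        pred = model.predict(X).logits
        mse = float(((pred - Y) ** 2).mean())
        assert mse < 1.0  # variance of the standardized target

    def test_all_masked_training_set_rejected(self):
        X, Y, M = self._xy()
        with pytest.raises(ValueError, match="no observed"):
            train_model(X, Y, np.zeros_like(M), *self._configs())
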