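"""Forward-pass oracles, loss oracles, gradient checks and training
contracts for the sparse RNN decomposition."""

import numpy as np
import pytest

from erpbss.rnn import (
    RNNConfig,
    RNNWeights,
    SparseRNN,
    SparseRNNResults,
    _loss_and_grads,
    forward,
    init_weights,
    l1_activity,
    loss_phase1,
    loss_phase2,
)


def scalar_weights(wf=1.0, wr=0.5, b=0.0, wout=1.0, n_layers=1):
    """Single-unit network; extra layers pass the signal through."""
    Wf = [np.array([[wf]])] + [np.array([[1.0]])] * (n_layers - 1)
    Wr = [np.array([[wr]])] + [np.array([[0.0]])] * (n_layers - 1)
    biases = [np.array([b])] * (n_layers - 1) + [None]
    if n_layers == 1:
        biases = [None] if b == 0.0 else [np.array([b])]
    return RNNWeights(Wf=Wf, Wr=Wr, b=biases, Wout=np.array([[wout]]))


class TestForward:
    def test_scalar_geometric_recurrence(self):
        # unit step input, Wf=1, Wr=0.5: z[t] = 1, 1.5, 1.75, ... -> 2
        w = scalar_weights()
        Z, y = forward(w, np.ones((5, 1)))
        expect = np.array([1.0, 1.5, 1.75, 1.875, 1.9375])
        np.testing.assert_allclose(Z[0].ravel(), expect, atol=1e-10)
        np.testing.assert_allclose(y.ravel(), expect, atol=1e-10)

    def test_scalar_recurrence_through_stacked_layers(self):
        # pass-through upper layers preserve the hand-iterated sequence
        w = scalar_weights(n_layers=4)
        Z, y = forward(w, np.ones((5, 1)))
        expect = np.array([1.0, 1.5, 1.75, 1.875, 1.9375])
        np.testing.assert_allclose(Z[-1].ravel(), expect, atol=1e-10)

    def test_zero_input_zero_bias_fixed_point(self):
        cfg = RNNConfig(n_hidden=4, seed=0)
        w = init_weights(2, 3, cfg)
        Z, y = forward(w, np.zeros((7, 2)))
        for z in Z:
            assert not z.any()
        assert not y.any()

    def test_positive_bias_zero_weights(self):
        H = 3
        w = RNNWeights(
            Wf=[np.zeros((2, H)), np.zeros((H, H))],
            Wr=[np.zeros((H, H)), np.zeros((H, H))],
            b=[np.full(H, 0.7), None],
            Wout=np.zeros((H, 2)),
        )
        Z, y = forward(w, np.ones((4, 2)))
        np.testing.assert_allclose(Z[0], 0.7)  # ReLU(b) held constant
        assert not Z[1].any() and not y.any()

    def test_batch_matches_single(self):
        cfg = RNNConfig(n_hidden=5, seed=2)
        w = init_weights(3, 4, cfg)
        X = np.random.default_rng(0).normal(size=(3, 6, 3))
        Zb, Yb = forward(w, X)
        for k in range(3):
            Zs, ys = forward(w, X[k])
            np.testing.assert_allclose(Zb[-1][k], Zs[-1], atol=1e-12)
            np.testing.assert_allclose(Yb[k], ys, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        w = init_weights(3, 4, RNNConfig(n_hidden=5, seed=2))
        with pytest.raises(ValueError):
            forward(w, np.zeros((6, 2)))

    def test_activations_nonnegative(self):
        w = init_weights(2, 3, RNNConfig(n_hidden=6, seed=4))
        Z, _ = forward(w, np.random.default_rng(1).normal(size=(4, 9, 2)))
        for z in Z:
            assert np.all(z >= 0)


class TestLosses:
    def test_single_sample_oracle(self):
        Y = np.array([[[1.0, 0.0]]])
        Yhat = np.zeros((1, 1, 2))
        # literal channel-sum convention: ||(1,0)||^2 = 1
        assert loss_phase1(Y, Yhat, reduction="channel_sum") == pytest.approx(1.0)
        # element-wise mean differs by the channel count only
        assert loss_phase1(Y, Yhat, reduction="mean") == pytest.approx(0.5)

    def test_two_by_two_toy_oracle(self):
        # residuals chosen by hand; squared channel sums: [[1,4],[2,8]]
        R = np.array([[[1.0, 0.0], [0.0, 2.0]], [[-1.0, 1.0], [2.0, -2.0]]])
        Y = np.zeros_like(R)
        assert loss_phase1(Y, -R, reduction="channel_sum") == pytest.approx(15 / 4)
        assert loss_phase1(Y, -R, reduction="mean") == pytest.approx(15 / 8)

    def test_homogeneity_and_zero(self):
        rng = np.random.default_rng(0)
        Y, Yhat = rng.normal(size=(3, 4, 2)), rng.normal(size=(3, 4, 2))
        base = loss_phase1(Y, Yhat)
        assert loss_phase1(Y, Y) == 0.0
        c = 3.0
        assert loss_phase1(c * Y, c * Yhat) == pytest.approx(c**2 * base)

    def test_phase2_reduces_to_phase1_at_zero_coefficients(self):
        rng = np.random.default_rng(1)
        Y, Yhat = rng.normal(size=(3, 4, 2)), rng.normal(size=(3, 4, 2))
        Z4 = np.abs(rng.normal(size=(3, 4, 5)))
        Wout = rng.normal(size=(5, 2))
        assert loss_phase2(Y, Yhat, Z4, Wout, 0.0, 0.0) == pytest.approx(
            loss_phase1(Y, Yhat)
        )

    def test_phase2_all_zero(self):
        Y = np.ones((2, 3, 2))
        assert loss_phase2(Y, Y, np.zeros((2, 3, 4)), np.zeros((4, 2)), 0.1, 0.1) == 0.0

    def test_penalty_linearity(self):
        rng = np.random.default_rng(2)
        Y, Yhat = rng.normal(size=(2, 3, 2)), rng.normal(size=(2, 3, 2))
        Z4 = np.abs(rng.normal(size=(2, 3, 4)))
        Wout = rng.normal(size=(4, 2))
        base = loss_phase1(Y, Yhat)
        l1 = loss_phase2(Y, Yhat, Z4, Wout, 0.01, 0.0) - base
        l1_doubled = loss_phase2(Y, Yhat, Z4, Wout, 0.02, 0.0) - base
        assert l1_doubled == pytest.approx(2 * l1)
        # documented reduction conventions
        assert l1 == pytest.approx(0.01 * np.abs(Z4).sum() / 2)
        l2 = loss_phase2(Y, Yhat, Z4, Wout, 0.0, 0.03) - base
        assert l2 == pytest.approx(0.03 * (Wout**2).sum())

    def test_l1_activity_batch_average(self):
        Z = np.ones((4, 3, 2))
        assert l1_activity(Z) == pytest.approx(6.0)  # sum within instance


class TestGradients:
    @pytest.mark.parametrize("phase", [1, 2])
    def test_finite_difference_agreement(self, phase):
        """BPTT gradients match central differences on a tiny network."""
        rng = np.random.default_rng(0)
        cfg = RNNConfig(n_hidden=3, seed=1, alpha_l1=0.01, alpha_l2=0.02)
        X = rng.normal(size=(2, 5, 2))
        Y = rng.normal(size=(2, 5, 4))
        w = init_weights(2, 4, cfg)
        _, grads = _loss_and_grads(w, X, Y, cfg, phase)
        eps = 1e-6
        for name, arr in w.arrays():
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                old = arr[idx]
                arr[idx] = old + eps
                lp, _ = _loss_and_grads(w, X, Y, cfg, phase)
                arr[idx] = old - eps
                lm, _ = _loss_and_grads(w, X, Y, cfg, phase)
                arr[idx] = old
                num[idx] = (lp - lm) / (2 * eps)
            denom = np.abs(num) + np.abs(grads[name]) + 1e-8
            rel = np.abs(num - grads[name]) / denom
            assert rel.max() < 1e-4, f"{name}: rel err {rel.max():.2e}"


class TestTraining:
    def test_loss_descends_and_history_recorded(self, tiny_fit):
        h1 = tiny_fit.history["phase1"]
        assert min(h1) <= h1[0]
        assert len(h1) <= tiny_fit.config.max_iterations
        h2 = tiny_fit.history["phase2"]
        assert min(h2) <= h2[0]

    def test_activations_nonnegative_after_training(self, tiny_fit):
        for z in tiny_fit.activations:
            assert np.all(z >= 0)

    def test_reconstruction_identity(self, tiny_fit):
        # with threshold 0, sum of all unit projections equals the output
        ss = tiny_fit.sources(threshold=0.0)
        for c, cond in enumerate(tiny_fit.tensors.conditions):
            rec = ss.reconstruction(cond)
            scale = np.abs(tiny_fit.predicted[c]).max()
            np.testing.assert_allclose(
                rec, tiny_fit.predicted[c], atol=1e-6 * max(scale, 1)
            )

    def test_active_plus_inactive_partition(self, tiny_fit):
        all_units = tiny_fit.sources(threshold=0.0)
        active = tiny_fit.sources()
        assert active.n_sources <= all_units.n_sources <= tiny_fit.config.n_hidden

    def test_extract_threshold_extremes(self, tiny_fit):
        assert tiny_fit.sources(threshold=np.inf).n_sources == 0
        nz = tiny_fit.sources(threshold=0.0)
        peaks = tiny_fit.Z_last.max(axis=(0, 1))
        assert nz.n_sources == int((peaks > 0).sum())

    def test_empty_sourceset_warns(self, tiny_fit):
        with pytest.warns(UserWarning, match="no active units"):
            ss = tiny_fit.sources(threshold=np.inf)
        assert ss.n_sources == 0

    def test_projection_examples(self, tiny_fit):
        ss = tiny_fit.sources(threshold=0.0)
        cond = ss.conditions[0]
        p = ss.project(0, cond)
        assert p.shape == (tiny_fit.tensors.X.shape[1], len(ss.channel_names))
        np.testing.assert_allclose(
            p, np.outer(ss.waveforms[0, 0], ss.scalp_maps[0]), atol=1e-14
        )

    def test_seed_reproducibility(self, small_tensors):
        cfg = RNNConfig(n_hidden=6, max_iterations=40, patience=40, seed=5)
        a = SparseRNN(small_tensors, cfg).fit()
        b = SparseRNN(small_tensors, cfg).fit()
        np.testing.assert_allclose(a.weights.Wout, b.weights.Wout, atol=1e-12)
        assert a.history == b.history

    def test_summary_and_persistence_roundtrip(self, tiny_fit, tmp_path):
        text = tiny_fit.summary()
        assert "active sources" in text and "phase2" in text
        tiny_fit.save(tmp_path / "model.npz")
        back = SparseRNNResults.load(tmp_path / "model.npz", tiny_fit.tensors)
        np.testing.assert_array_equal(back.predicted, tiny_fit.predicted)
        assert back.history == tiny_fit.history
        assert back.n_active() == tiny_fit.n_active()
        assert back.phase1().n_active() == tiny_fit.phase1().n_active()

    def test_degenerate_inputs_rejected(self, small_tensors):
        import dataclasses

        cfg = RNNConfig(n_hidden=4)
        single = dataclasses.replace(
            small_tensors,
            X=small_tensors.X[:1],
            Y=small_tensors.Y[:1],
            condition_of_instance=small_tensors.condition_of_instance[:1],
        )
        with pytest.raises(ValueError):
            SparseRNN(single, cfg)
        cond_a = small_tensors.condition_of_instance[0]
        idx = [i for i, c in enumerate(small_tensors.condition_of_instance) if c == cond_a]
        missing = dataclasses.replace(
            small_tensors,
            X=small_tensors.X[idx],
            Y=small_tensors.Y[idx],
            condition_of_instance=tuple(
                small_tensors.condition_of_instance[i] for i in idx
            ),
        )
        with pytest.raises(ValueError, match="without instances"):
            SparseRNN(missing, cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RNNConfig(n_hidden=0)
        with pytest.raises(ValueError):
            RNNConfig(patience=100, max_iterations=50)
        with pytest.raises(NotImplementedError):
            RNNConfig(activation="tanh")


class TestSparsification:
    def test_phase2_prunes_sources_on_clean_data(self, noise_free_dws):
        """L1 fine-tuning reduces the active-unit count on noise-free
        data generated from 3 well-separated sources."""
        from erpbss.tensors import build_tensors

        gt, dws = noise_free_dws
        tens = build_tensors(dws)
        cfg = RNNConfig(
            n_hidden=16, max_iterations=600, patience=250, seed=0
        )
        res = SparseRNN(tens, cfg).fit()
        n1 = res.phase1().n_active()
        n2 = res.n_active()
        assert n2 <= n1
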