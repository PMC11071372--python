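"""Input/label tensor construction and ERP preprocessing contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from erpbss.datasets import DifferenceWaveSet
from erpbss.tensors import (
    build_input_tensor,
    build_label_tensor,
    build_tensors,
    common_average_reference,
    grand_average,
    subtract_conditions,
)


def make_dws(waves, labels, conditions, fs=10.0, t0=-0.2):
    K, T, C = waves.shape
    return DifferenceWaveSet(
        waveforms=waves,
        condition_of_instance=labels,
        conditions=conditions,
        channel_names=tuple(f"ch{i}" for i in range(C)),
        sampling_rate=fs,
        time_vector=t0 + np.arange(T) / fs,
    )


class TestBuildInputTensor:
    def test_two_condition_example(self):
        # 11 samples at 10 Hz spanning -0.2..0.8 s, pulse 0..0.2 s inclusive
        X = build_input_tensor(("A", "B"), ("A", "B"), T=11, sampling_rate=10.0,
                               pulse_window=(0.0, 0.2), epoch_start=-0.2)
        assert X.shape == (2, 11, 2)
        np.testing.assert_array_equal(X[0, :, 0], [0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        np.testing.assert_array_equal(X[0, :, 1], np.zeros(11))
        np.testing.assert_array_equal(X[1, :, 1], [0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0])

    def test_degenerate_window_single_sample(self):
        X = build_input_tensor(("A",), ("A",) * 3, T=11, sampling_rate=10.0,
                               pulse_window=(0.0, 0.0), epoch_start=-0.2)
        assert X.sum(axis=(1, 2)).tolist() == [1.0, 1.0, 1.0]
        assert X[0, 2, 0] == 1.0  # the t=0 sample

    def test_reference_configuration_shape_and_pulse_count(self):
        # 4 conditions, 149 instances, T=101 at 100 Hz: 21 high samples each
        labels = tuple(["MMN"] * 39 + ["N170"] * 37 + ["N400"] * 39 + ["P3"] * 34)
        X = build_input_tensor(("MMN", "N170", "N400", "P3"), labels, T=101,
                               sampling_rate=100.0)
        assert X.shape == (149, 101, 4)
        assert np.all(X.sum(axis=(1, 2)) == 21)
        # exactly one channel non-zero per instance
        assert np.all((X.sum(axis=1) > 0).sum(axis=1) == 1)

    def test_half_open_window(self):
        X = build_input_tensor(("A",), ("A",), T=11, sampling_rate=10.0,
                               pulse_window=(0.0, 0.2), epoch_start=-0.2,
                               inclusive=False)
        np.testing.assert_array_equal(X[0, :, 0], [0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            build_input_tensor(("A",), ("A", "Z"), T=11, sampling_rate=10.0)

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="outside epoch"):
            build_input_tensor(("A",), ("A",), T=11, sampling_rate=10.0,
                               pulse_window=(0.0, 2.0), epoch_start=-0.2)

    def test_binary_and_total_sum_invariant(self):
        labels = ("A", "B", "A")
        X = build_input_tensor(("A", "B"), labels, T=21, sampling_rate=20.0,
                               pulse_window=(0.0, 0.2), epoch_start=-0.2)
        assert set(np.unique(X)) <= {0.0, 1.0}
        n_high = int(X[0].sum())
        assert X.sum() == n_high * len(labels)


class TestLabelTensor:
    def test_volts_to_microvolts(self):
        waves = np.full((1, 3, 2), 3.5e-6)
        dws = make_dws(waves, ("A",), ("A",), fs=10.0)
        Y = build_label_tensor(dws, scale=1e6)
        np.testing.assert_allclose(Y, 3.5)

    def test_identity_scale_and_zeros(self):
        waves = np.random.default_rng(0).normal(size=(2, 4, 3))
        dws = make_dws(waves, ("A", "A"), ("A",), fs=10.0)
        np.testing.assert_array_equal(build_label_tensor(dws, 1.0), waves)
        dws0 = make_dws(np.zeros((2, 4, 3)), ("A", "A"), ("A",), fs=10.0)
        assert not build_label_tensor(dws0).any()


class TestCommonAverageReference:
    def test_hand_examples(self):
        np.testing.assert_allclose(
            common_average_reference(np.array([[1.0, 2.0, 3.0]])), [[-1, 0, 1]]
        )
        z = np.array([[1.0, -1.0, 0.0]])
        np.testing.assert_allclose(common_average_reference(z), z)
        np.testing.assert_allclose(
            common_average_reference(np.full((2, 3), 7.0)), 0.0
        )

    @given(arrays(np.float64, (4, 5),
                  elements=st.floats(-1e6, 1e6, allow_nan=False)))
    @settings(max_examples=50, deadline=None)
    def test_zero_mean_and_idempotent(self, x):
        y = common_average_reference(x)
        np.testing.assert_allclose(y.mean(axis=-1), 0.0, atol=1e-6)
        np.testing.assert_allclose(common_average_reference(y), y, atol=1e-6)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(np.ones((3, 1)))


class TestSubtractAndAverage:
    def test_subtract_examples(self):
        b = np.arange(6.0).reshape(3, 2) + 1
        np.testing.assert_array_equal(subtract_conditions(b, b), np.zeros_like(b))
        np.testing.assert_array_equal(subtract_conditions(2 * b, b), b)
        with pytest.raises(ValueError):
            subtract_conditions(b, b[:2])

    def test_grand_average_examples(self):
        y = np.random.default_rng(1).normal(size=(3, 2))
        dws = make_dws(np.stack([y, -y]), ("A", "A"), ("A",), fs=10.0)
        np.testing.assert_allclose(grand_average(dws, "A"), 0.0, atol=1e-15)
        dws1 = make_dws(y[None], ("A",), ("A",), fs=10.0)
        np.testing.assert_array_equal(grand_average(dws1, "A"), y)
        dws3 = make_dws(np.stack([y] * 3), ("A",) * 3, ("A",), fs=10.0)
        np.testing.assert_allclose(grand_average(dws3, "A"), y)

    def test_grand_average_commutes_with_referencing(self):
        rng = np.random.default_rng(2)
        waves = rng.normal(size=(4, 5, 3))
        labels = ("A",) * 4
        dws = make_dws(waves, labels, ("A",), fs=10.0)
        dws_ref = make_dws(common_average_reference(waves), labels, ("A",), fs=10.0)
        np.testing.assert_allclose(
            grand_average(dws_ref, "A"),
            common_average_reference(grand_average(dws, "A")),
        )

    def test_empty_condition_errors(self):
        y = np.zeros((1, 3, 2))
        dws = make_dws(y, ("A",), ("A", "B"), fs=10.0)
        with pytest.raises(ValueError):
            dws.grand_average("B")


def test_build_tensors_pairs_and_roundtrip(small_dws, tmp_path):
    tens = build_tensors(small_dws)
    assert tens.X.shape[:2] == tens.Y.shape[:2]
    assert tens.X.shape[2] == len(small_dws.conditions)
    # all instances of a condition share one input pattern
    for cond in small_dws.conditions:
        idx = small_dws.instances_of(cond)
        assert all(np.array_equal(tens.X[idx[0]], tens.X[k]) for k in idx)
    tens.save(tmp_path / "t.npz")
    back = type(tens).load(tmp_path / "t.npz")
    np.testing.assert_array_equal(back.X, tens.X)
    np.testing.assert_array_equal(back.Y, tens.Y)
    assert back.conditions == tens.conditions
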