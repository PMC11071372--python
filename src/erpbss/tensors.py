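"""Build the paired step-pulse input / waveform label tensors.

The decomposition network learns a map from condition-indicator step
pulses to multi-channel difference waveforms.  Each instance (one subject's
difference wave for one condition) gets an input pattern that is 1 on its
condition's channel inside the pulse window and 0 everywhere else; all
instances of a condition share the same input (one-to-many mapping).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .datasets import DifferenceWaveSet, InputLabelTensors

__all__ = [
    "build_input_tensor",
    "build_label_tensor",
    "build_tensors",
    "common_average_reference",
    "subtract_conditions",
    "grand_average",
    "bandpass_filter",
    "resample",
]

# Half-sample-scaled tolerance so the inclusive window test is robust to
# floating-point time vectors (t = epoch_start + i/fs).
_REL_EPS = 1e-9


def build_input_tensor(
    conditions,
    condition_of_instance,
    T: int,
    sampling_rate: float,
    pulse_window=(0.0, 0.2),
    epoch_start: float = -0.2,
    inclusive: bool = True,
) -> np.ndarray:
    """Binary step-pulse input tensor, shape (K, T, n_conditions).

    For every instance exactly one channel — the one assigned to its
    condition, in the declared condition order — carries a unit pulse on
    the samples whose time t satisfies start <= t <= end (both endpoints
    included by default; set ``inclusive=False`` for a half-open
    [start, end) window).

    Raises ``ValueError`` for unknown condition labels or a pulse window
    outside the epoch.
    """
    conditions = tuple(conditions)
    if len(set(conditions)) != len(conditions):
        raise ValueError("condition labels must be distinct")
    labels = tuple(condition_of_instance)
    unknown = set(labels) - set(conditions)
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    t = epoch_start + np.arange(T) / float(sampling_rate)
    start, end = float(pulse_window[0]), float(pulse_window[1])
    if start > end:
        raise ValueError("pulse window start must not exceed end")
    if start < t[0] - _REL_EPS or end > t[-1] + _REL_EPS:
        raise ValueError(
            f"pulse window ({start}, {end}) s outside epoch ({t[0]:g}, {t[-1]:g}) s"
        )
    eps = _REL_EPS * max(1.0, abs(end), abs(start))
    if inclusive:
        high = (t >= start - eps) & (t <= end + eps)
    else:
        high = (t >= start - eps) & (t < end - eps)
    chan = {c: i for i, c in enumerate(conditions)}
    X = np.zeros((len(labels), T, len(conditions)))
    for k, lab in enumerate(labels):
        X[k, high, chan[lab]] = 1.0
    return X


def build_label_tensor(dws: DifferenceWaveSet, scale: float = 1.0) -> np.ndarray:
    """Label tensor Y = waveforms x scale, shape (K, T, n_channels).

    Data recorded in volts uses ``scale=1e6`` to convert to microvolts;
    :class:`DifferenceWaveSet` already stores microvolts, so the default
    is the identity.
    """
    return np.asarray(dws.waveforms, dtype=float) * float(scale)


def build_tensors(
    dws: DifferenceWaveSet,
    pulse_window=(0.0, 0.2),
    scale: float = 1.0,
    inclusive: bool = True,
) -> InputLabelTensors:
    """Pair the input and label tensors for a difference-wave set."""
    X = build_input_tensor(
        dws.conditions,
        dws.condition_of_instance,
        dws.n_samples,
        dws.sampling_rate,
        pulse_window=pulse_window,
        epoch_start=float(dws.time_vector[0]),
        inclusive=inclusive,
    )
    return InputLabelTensors(
        X=X,
        Y=build_label_tensor(dws, scale),
        conditions=dws.conditions,
        condition_of_instance=dws.condition_of_instance,
        channel_names=dws.channel_names,
        sampling_rate=dws.sampling_rate,
        time_vector=dws.time_vector,
        pulse_window=tuple(pulse_window),
    )


def common_average_reference(epochs: np.ndarray) -> np.ndarray:
    """Re-reference to the channel average (last axis).

    Subtracts each time sample's mean over channels, so every sample is
    zero-mean across channels afterwards; idempotent.  Reduces the data
    rank by one.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.shape[-1] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return epochs - epochs.mean(axis=-1, keepdims=True)


def subtract_conditions(erp_a: np.ndarray, erp_b: np.ndarray) -> np.ndarray:
    """Difference wave a - b (e.g. deviant - standard yields the MMN)."""
    erp_a = np.asarray(erp_a, dtype=float)
    erp_b = np.asarray(erp_b, dtype=float)
    if erp_a.shape != erp_b.shape:
        raise ValueError(f"shape mismatch: {erp_a.shape} vs {erp_b.shape}")
    return erp_a - erp_b


def grand_average(dws: DifferenceWaveSet, condition: str) -> np.ndarray:
    """Arithmetic mean over the condition's instances, (T, n_channels)."""
    return dws.grand_average(condition)


def bandpass_filter(
    epochs: np.ndarray,
    sampling_rate: float,
    low: float = 0.1,
    high: float = 20.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (axis -2).

    Thin convenience for users bringing raw epochs; synthetic data are
    generated band-limited at the target rate and do not need it.
    """
    sos = butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(epochs, dtype=float), axis=-2)


def resample(epochs: np.ndarray, sampling_rate: float, target_rate: float) -> np.ndarray:
    """Polyphase resampling along the time axis (axis -2)."""
    from fractions import Fraction

    frac = Fraction(target_rate / sampling_rate).limit_denominator(1000)
    return resample_poly(np.asarray(epochs, dtype=float), frac.numerator, frac.denominator, axis=-2)
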