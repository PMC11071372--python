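import numpy as np
import pytest

from erpbss.rnn import RNNConfig, SparseRNN
from erpbss.simulate import generate_ground_truth, generate_subjects
from erpbss.tensors import build_tensors

# 12-channel sub-montage keeps the small fixtures fast while still
# exercising spatial structure.
CHANNELS_12 = ("FP1", "FP2", "F3", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "O2")


@pytest.fixture(scope="session")
def small_gt():
    return generate_ground_truth(
        n_sources=3, n_conditions=2, T=51, channel_names=CHANNELS_12,
        sampling_rate=50.0, baseline_samples=10, seed=11,
    )


@pytest.fixture(scope="session")
def small_dws(small_gt):
    return generate_subjects(
        small_gt, n_subjects_per_condition=6, amplitude_jitter_sd=0.15,
        latency_jitter_sd_s=0.01, noise_sd_uv=0.3, seed=12,
    )


@pytest.fixture(scope="session")
def small_tensors(small_dws):
    return build_tensors(small_dws)


@pytest.fixture(scope="session")
def tiny_fit(small_tensors):
    """A short two-phase fit on the small dataset (seconds, not minutes)."""
    cfg = RNNConfig(
        n_hidden=8, max_iterations=250, patience=250, seed=3, alpha_l1=1e-3
    )
    return SparseRNN(small_tensors, cfg).fit()


@pytest.fixture(scope="session")
def noise_free_dws():
    gt = generate_ground_truth(
        n_sources=3, n_conditions=2, T=51, channel_names=CHANNELS_12,
        sampling_rate=50.0, baseline_samples=10, seed=21,
    )
    dws = generate_subjects(
        gt, n_subjects_per_condition=4, amplitude_jitter_sd=0.0,
        latency_jitter_sd_s=0.0, noise_sd_uv=0.0, seed=22,
    )
    return gt, dws
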