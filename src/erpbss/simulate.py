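"""Synthetic multi-subject ERP difference-wave generator.

Emulates the generative assumptions behind source decomposition of evoked
responses: a small number of latent neural sources, each with a fixed
scalp projection (static orientation and polarity) and a non-negative,
condition-specific time-varying magnitude.  Subject variability enters as
multiplicative amplitude jitter and peak-latency jitter; measurement noise
is spatio-temporally smooth.  Ground truth is fully known, so sparsity and
source-recovery behaviour of the decomposition methods can be tested
without any external recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import linear_sum_assignment

from .datasets import DifferenceWaveSet, SourceSet
from .montage import DEFAULT_28, channel_positions
from .tensors import common_average_reference

__all__ = [
    "SyntheticGroundTruth",
    "generate_ground_truth",
    "generate_subjects",
    "match_sources",
    "MatchResult",
]


@dataclass
class SyntheticGroundTruth:
    """Known latent sources and scalp maps behind a synthetic dataset.

    ``source_waveforms`` is (n_conditions, T, n_sources), non-negative and
    zero throughout the pre-stimulus baseline; ``scalp_maps`` is
    (n_sources, n_channels) in microvolts per unit activation, zero-mean
    across channels (consistent with common-average-referenced labels);
    ``activity_mask`` is a binary (n_conditions, n_sources) matrix.
    ``bump_params`` stores (peak_s, width_s, amplitude) per condition and
    source so that jittered copies can be regenerated analytically.
    """

    source_waveforms: np.ndarray
    scalp_maps: np.ndarray
    activity_mask: np.ndarray
    bump_params: np.ndarray
    conditions: tuple
    channel_names: tuple
    sampling_rate: float
    time_vector: np.ndarray
    rng_seed: int

    @property
    def n_sources(self) -> int:
        return self.source_waveforms.shape[2]

    @property
    def baseline_samples(self) -> int:
        return int(np.sum(self.time_vector < 0))

    def noise_free_waveform(self, condition: str) -> np.ndarray:
        """Forward projection Σ_s waveform_s x map_s, shape (T, n_channels)."""
        c = list(self.conditions).index(condition)
        return self.source_waveforms[c] @ self.scalp_maps

    def to_source_set(self) -> SourceSet:
        return SourceSet(
            waveforms=np.transpose(self.source_waveforms, (2, 0, 1)),
            scalp_maps=self.scalp_maps,
            conditions=self.conditions,
            channel_names=self.channel_names,
            method_tag="truth",
            time_vector=self.time_vector,
        )

    def save(self, path) -> None:
        np.savez(
            path,
            source_waveforms=self.source_waveforms,
            scalp_maps=self.scalp_maps,
            activity_mask=self.activity_mask,
            bump_params=self.bump_params,
            conditions=np.array(self.conditions),
            channel_names=np.array(self.channel_names),
            sampling_rate=self.sampling_rate,
            time_vector=self.time_vector,
            rng_seed=self.rng_seed,
        )

    @classmethod
    def load(cls, path) -> "SyntheticGroundTruth":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                source_waveforms=f["source_waveforms"],
                scalp_maps=f["scalp_maps"],
                activity_mask=f["activity_mask"],
                bump_params=f["bump_params"],
                conditions=tuple(f["conditions"]),
                channel_names=tuple(f["channel_names"]),
                sampling_rate=float(f["sampling_rate"]),
                time_vector=f["time_vector"],
                rng_seed=int(f["rng_seed"]),
            )


def _bump(t: np.ndarray, peak: float, width: float, amp: float, baseline: int) -> np.ndarray:
    """Truncated Gaussian bump: smooth, unimodal, non-negative, zero baseline."""
    w = amp * np.exp(-0.5 * ((t - peak) / width) ** 2)
    w[:baseline] = 0.0
    w[t < 0] = 0.0
    return w


def _draw_map(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n_blobs = 3
    centers = rng.uniform(-0.9, 0.9, size=(n_blobs, 2))
    coeffs = rng.normal(size=n_blobs)
    sigma = rng.uniform(0.35, 0.6, size=n_blobs)
    d2 = ((pos[None, :, :] - centers[:, None, :]) ** 2).sum(-1)
    m = (coeffs[:, None] * np.exp(-d2 / (2 * sigma[:, None] ** 2))).sum(0)
    m -= m.mean()
    peak = np.abs(m).max()
    if peak < 1e-12:  # essentially flat draw; fall back to white pattern
        m = rng.normal(size=pos.shape[0])
        m -= m.mean()
        peak = np.abs(m).max()
    return m / peak


# Distinctness bound for scalp maps: real ERP topographies overlap, but
# sources are only identifiable when their maps are not near-collinear.
_MAX_MAP_CORR = 0.7


def _smooth_maps(n_sources: int, pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random low-spatial-frequency scalp patterns, zero-mean, max |.| = 1.

    Maps are rejection-sampled so every pair correlates at |r| <= 0.7:
    moderately overlapping, as real topographies are, yet distinct
    enough that the mixture is identifiable.
    """
    n_ch = pos.shape[0]
    maps = np.empty((n_sources, n_ch))
    for s in range(n_sources):
        best, best_c = None, np.inf
        for _ in range(200):
            m = _draw_map(pos, rng)
            c = (
                0.0
                if s == 0
                else np.abs([np.corrcoef(m, maps[j])[0, 1] for j in range(s)]).max()
            )
            if c < best_c:
                best, best_c = m, c
            if c <= _MAX_MAP_CORR:
                break
        maps[s] = best
    return maps


def generate_ground_truth(
    n_sources: int,
    n_conditions: int = 4,
    T: int = 101,
    channel_names=DEFAULT_28,
    sampling_rate: float = 100.0,
    baseline_samples: int = 20,
    peak_separation_s: float = 0.1,
    amplitude_range=(2.0, 5.0),
    seed: int = 0,
) -> SyntheticGroundTruth:
    """Draw latent sources, scalp maps and a condition-activity mask.

    Source time courses are truncated Gaussian bumps with peak latencies
    spread over the post-stimulus window at least ``peak_separation_s``
    apart (well-separated sources); each source keeps one characteristic
    peak/width across conditions, with condition-specific amplitude.
    Every condition activates between 1 and ``n_sources`` sources and
    every source is active in at least one condition.  Reproducible from
    ``seed``.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if baseline_samples >= T:
        raise ValueError("baseline_samples must be < T")
    rng = np.random.default_rng(seed)
    channel_names = tuple(channel_names)
    pos = channel_positions(channel_names)
    t = (np.arange(T) - baseline_samples) / sampling_rate

    # Peak latencies: evenly spaced slots over the post-stimulus window,
    # jittered within a fraction of the slot so separation is guaranteed.
    post0, post1 = 0.08, float(t[-1]) - 0.08
    slots = np.linspace(post0, post1, n_sources)
    slot_w = (post1 - post0) / max(n_sources - 1, 1)
    jitter_amp = max(0.0, min(0.45 * slot_w, 0.5 * (slot_w - peak_separation_s)))
    peaks = slots + rng.uniform(-jitter_amp, jitter_amp, size=n_sources)
    rng.shuffle(peaks)
    widths = rng.uniform(0.035, 0.065, size=n_sources)

    # Activity mask: each source active in 1-2 conditions, then patch any
    # condition left empty.
    mask = np.zeros((n_conditions, n_sources), dtype=int)
    for s in range(n_sources):
        k = 1 + int(rng.random() < 0.5)
        conds = rng.choice(n_conditions, size=min(k, n_conditions), replace=False)
        mask[conds, s] = 1
    for c in range(n_conditions):
        if mask[c].sum() == 0:
            mask[c, rng.integers(n_sources)] = 1

    lo, hi = amplitude_range
    amps = rng.uniform(lo, hi, size=(n_conditions, n_sources)) * mask
    bump_params = np.stack(
        [
            np.broadcast_to(peaks, (n_conditions, n_sources)).copy(),
            np.broadcast_to(widths, (n_conditions, n_sources)).copy(),
            amps,
        ],
        axis=-1,
    )
    waves = np.zeros((n_conditions, T, n_sources))
    for c in range(n_conditions):
        for s in range(n_sources):
            if mask[c, s]:
                waves[c, :, s] = _bump(t, peaks[s], widths[s], amps[c, s], baseline_samples)
    maps = _smooth_maps(n_sources, pos, rng)
    return SyntheticGroundTruth(
        source_waveforms=waves,
        scalp_maps=maps,
        activity_mask=mask,
        bump_params=bump_params,
        conditions=tuple(f"C{c + 1}" for c in range(n_conditions)),
        channel_names=channel_names,
        sampling_rate=float(sampling_rate),
        time_vector=t,
        rng_seed=int(seed),
    )


def _smooth_noise(T: int, n_ch: int, pos: np.ndarray, sd: float, rng) -> np.ndarray:
    """Spatio-temporally smooth noise with per-sample channel std ``sd``."""
    if sd == 0:
        return np.zeros((T, n_ch))
    white = rng.normal(size=(T, n_ch))
    sm = gaussian_filter1d(white, sigma=2.0, axis=0)
    # spatial mixing through a Gaussian distance kernel over the montage
    d2 = ((pos[None, :, :] - pos[:, None, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2 * 0.4**2))
    sm = sm @ K
    sm *= sd / sm.std()
    return sm


def generate_subjects(
    gt: SyntheticGroundTruth,
    n_subjects_per_condition=20,
    amplitude_jitter_sd: float = 0.2,
    latency_jitter_sd_s: float = 0.02,
    noise_sd_uv: float = 0.5,
    seed: int = 0,
) -> DifferenceWaveSet:
    """Simulate per-subject difference waves from the ground truth.

    Each subject-condition waveform is the sum over active sources of a
    jittered bump (lognormal multiplicative amplitude with mean 1,
    Gaussian peak-latency shift) projected through the source's scalp
    map, plus smooth additive noise; the result is common-average
    referenced.  Instances are grouped by condition in declared order.
    """
    if amplitude_jitter_sd < 0 or latency_jitter_sd_s < 0 or noise_sd_uv < 0:
        raise ValueError("jitter and noise parameters must be >= 0")
    rng = np.random.default_rng(seed)
    pos = channel_positions(gt.channel_names)
    t = gt.time_vector
    T = t.size
    baseline = gt.baseline_samples
    n_cond = len(gt.conditions)
    if np.isscalar(n_subjects_per_condition):
        counts = {c: int(n_subjects_per_condition) for c in gt.conditions}
    else:
        counts = {c: int(n_subjects_per_condition[c]) for c in gt.conditions}

    # lognormal with exact mean 1
    if amplitude_jitter_sd > 0:
        sig2 = np.log(1.0 + amplitude_jitter_sd**2)
        mu, sig = -0.5 * sig2, np.sqrt(sig2)
    waves, labels = [], []
    for c, cond in enumerate(gt.conditions):
        for _ in range(counts[cond]):
            y = np.zeros((T, len(gt.channel_names)))
            for s in range(gt.n_sources):
                if not gt.activity_mask[c, s]:
                    continue
                peak, width, amp = gt.bump_params[c, s]
                if amplitude_jitter_sd > 0:
                    amp = amp * rng.lognormal(mu, sig)
                peak = peak + rng.normal(0.0, latency_jitter_sd_s)
                y += np.outer(_bump(t, peak, width, amp, baseline), gt.scalp_maps[s])
            y += _smooth_noise(T, len(gt.channel_names), pos, noise_sd_uv, rng)
            waves.append(common_average_reference(y))
            labels.append(cond)
    return DifferenceWaveSet(
        waveforms=np.stack(waves),
        condition_of_instance=tuple(labels),
        conditions=gt.conditions,
        channel_names=gt.channel_names,
        sampling_rate=gt.sampling_rate,
        time_vector=t,
    )


@dataclass
class MatchResult:
    """Optimal one-to-one assignment between recovered and true sources."""

    pairs: list  # (recovered index, true index)
    correlations: np.ndarray  # |r| per pair, on concatenated projections
    n_unmatched_recovered: int
    n_unmatched_true: int

    def n_matched(self, r_threshold: float = 0.0) -> int:
        return int(np.sum(self.correlations > r_threshold))


def match_sources(recovered: SourceSet, truth) -> MatchResult:
    """Match recovered sources to ground truth by projection correlation.

    Builds the |Pearson r| matrix between each recovered source's
    concatenated per-condition projection (flattened over time and
    channels) and each true source's, then solves the optimal linear
    assignment maximising the summed |r|.  ``truth`` may be a
    :class:`SyntheticGroundTruth` or any :class:`SourceSet`.
    """
    true_set = truth.to_source_set() if isinstance(truth, SyntheticGroundTruth) else truth
    if recovered.n_sources == 0 or true_set.n_sources == 0:
        raise ValueError("both source sets must be non-empty")
    R = np.empty((recovered.n_sources, true_set.n_sources))
    rec = [recovered.concatenated_projection(i) for i in range(recovered.n_sources)]
    tru = [true_set.concatenated_projection(j) for j in range(true_set.n_sources)]
    for i, x in enumerate(rec):
        for j, y in enumerate(tru):
            sx, sy = x.std(), y.std()
            R[i, j] = 0.0 if sx == 0 or sy == 0 else abs(np.corrcoef(x, y)[0, 1])
    rows, cols = linear_sum_assignment(-R)
    return MatchResult(
        pairs=list(zip(rows.tolist(), cols.tolist())),
        correlations=R[rows, cols],
        n_unmatched_recovered=recovered.n_sources - len(rows),
        n_unmatched_true=true_set.n_sources - len(rows),
    )
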