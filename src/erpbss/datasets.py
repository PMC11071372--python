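"""Core data containers shared by the RNN and ICA decomposition paths.

All arrays are plain numpy; amplitudes are in microvolts unless noted.
Containers are frozen-ish dataclasses validated on construction, with
``save``/``load`` methods that write a single ``.npz`` archive plus, for
dataset directories, a plain-text key/value sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "DifferenceWaveSet",
    "InputLabelTensors",
    "SourceSet",
    "read_evoked_dir",
    "write_evoked_dir",
]


def _as_tuple(x) -> tuple:
    return tuple(str(c) for c in x)


@dataclass
class DifferenceWaveSet:
    """Per-subject multi-channel ERP difference waveforms.

    Parameters
    ----------
    waveforms : ndarray, shape (K, T, n_channels)
        One difference waveform per instance (subject x condition), in
        microvolts.
    condition_of_instance : sequence of str, length K
        Condition label of each instance.
    conditions : sequence of str
        Declared condition order (e.g. ``("MMN", "N170", "N400", "P3")``).
    channel_names : sequence of str
    sampling_rate : float, Hz
    time_vector : ndarray, shape (T,)
        Seconds relative to stimulus onset; spans a pre-stimulus baseline
        and a post-stimulus window (e.g. -0.2 ... 0.8 s).
    """

    waveforms: np.ndarray
    condition_of_instance: tuple
    conditions: tuple
    channel_names: tuple
    sampling_rate: float
    time_vector: np.ndarray

    def __post_init__(self):
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        self.time_vector = np.asarray(self.time_vector, dtype=float)
        self.condition_of_instance = _as_tuple(self.condition_of_instance)
        self.conditions = _as_tuple(self.conditions)
        self.channel_names = _as_tuple(self.channel_names)
        if self.waveforms.ndim != 3:
            raise ValueError("waveforms must be (K, T, n_channels)")
        K, T, n_ch = self.waveforms.shape
        if len(self.condition_of_instance) != K:
            raise ValueError("condition_of_instance length must equal K")
        if len(self.channel_names) != n_ch:
            raise ValueError("channel_names length must equal n_channels")
        if self.time_vector.shape != (T,):
            raise ValueError("time_vector length must equal T")
        unknown = set(self.condition_of_instance) - set(self.conditions)
        if unknown:
            raise ValueError(f"instance labels not in declared conditions: {sorted(unknown)}")

    # -- basic views ------------------------------------------------------
    @property
    def n_instances(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    @property
    def n_channels(self) -> int:
        return self.waveforms.shape[2]

    @property
    def subjects_per_condition(self) -> dict:
        return {c: self.condition_of_instance.count(c) for c in self.conditions}

    def instances_of(self, condition: str) -> np.ndarray:
        """Indices of the instances belonging to ``condition``."""
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return np.array([i for i, c in enumerate(self.condition_of_instance) if c == condition])

    def grand_average(self, condition: str) -> np.ndarray:
        """Mean waveform (T, n_channels) over the condition's instances."""
        idx = self.instances_of(condition)
        if idx.size == 0:
            raise ValueError(f"condition {condition!r} has no instances")
        return self.waveforms[idx].mean(axis=0)

    def grand_averages(self) -> np.ndarray:
        """(n_conditions, T, n_channels) stacked in declared condition order."""
        return np.stack([self.grand_average(c) for c in self.conditions])

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        np.savez(
            path,
            waveforms=self.waveforms,
            condition_of_instance=np.array(self.condition_of_instance),
            conditions=np.array(self.conditions),
            channel_names=np.array(self.channel_names),
            sampling_rate=self.sampling_rate,
            time_vector=self.time_vector,
        )

    @classmethod
    def load(cls, path) -> "DifferenceWaveSet":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                waveforms=f["waveforms"],
                condition_of_instance=tuple(f["condition_of_instance"]),
                conditions=tuple(f["conditions"]),
                channel_names=tuple(f["channel_names"]),
                sampling_rate=float(f["sampling_rate"]),
                time_vector=f["time_vector"],
            )


@dataclass
class InputLabelTensors:
    """Paired step-pulse input tensor X and waveform label tensor Y.

    ``X`` is binary, shape (K, T, n_conditions): for instance k only the
    channel of k's condition is non-zero, equal to 1 inside the pulse
    window.  ``Y`` is (K, T, n_channels) in microvolts.
    """

    X: np.ndarray
    Y: np.ndarray
    conditions: tuple
    condition_of_instance: tuple
    channel_names: tuple
    sampling_rate: float
    time_vector: np.ndarray
    pulse_window: tuple = (0.0, 0.2)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.conditions = _as_tuple(self.conditions)
        self.condition_of_instance = _as_tuple(self.condition_of_instance)
        self.channel_names = _as_tuple(self.channel_names)
        self.time_vector = np.asarray(self.time_vector, dtype=float)
        if self.X.ndim != 3 or self.Y.ndim != 3:
            raise ValueError("X and Y must be 3-D (K, T, channels)")
        if self.X.shape[:2] != self.Y.shape[:2]:
            raise ValueError("X and Y must agree on (K, T)")
        if self.X.shape[2] != len(self.conditions):
            raise ValueError("X channel count must equal number of conditions")

    @property
    def condition_channel(self) -> dict:
        """Condition label -> input channel index."""
        return {c: i for i, c in enumerate(self.conditions)}

    def representative_inputs(self) -> np.ndarray:
        """One X pattern per condition, shape (n_conditions, T, n_conditions).

        All instances of a condition share the same input pattern
        (one-to-many mapping), so the first instance is representative.
        """
        reps = []
        for c in self.conditions:
            k = self.condition_of_instance.index(c)
            reps.append(self.X[k])
        return np.stack(reps)

    def save(self, path) -> None:
        np.savez(
            path,
            X=self.X,
            Y=self.Y,
            conditions=np.array(self.conditions),
            condition_of_instance=np.array(self.condition_of_instance),
            channel_names=np.array(self.channel_names),
            sampling_rate=self.sampling_rate,
            time_vector=self.time_vector,
            pulse_window=np.array(self.pulse_window, dtype=float),
        )

    @classmethod
    def load(cls, path) -> "InputLabelTensors":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                X=f["X"],
                Y=f["Y"],
                conditions=tuple(f["conditions"]),
                condition_of_instance=tuple(f["condition_of_instance"]),
                channel_names=tuple(f["channel_names"]),
                sampling_rate=float(f["sampling_rate"]),
                time_vector=f["time_vector"],
                pulse_window=tuple(f["pulse_window"]),
            )


@dataclass
class SourceSet:
    """Active sources from either decomposition path.

    ``waveforms`` has shape (n_sources, n_conditions, T); RNN source
    waveforms are non-negative, ICA ones may be signed.  ``scalp_maps`` is
    (n_sources, n_channels).  ``method_tag`` is ``"rnn"`` or ``"ica"``.
    """

    waveforms: np.ndarray
    scalp_maps: np.ndarray
    conditions: tuple
    channel_names: tuple
    method_tag: str = "rnn"
    source_ids: tuple = ()
    time_vector: np.ndarray | None = None

    def __post_init__(self):
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        self.scalp_maps = np.asarray(self.scalp_maps, dtype=float)
        self.conditions = _as_tuple(self.conditions)
        self.channel_names = _as_tuple(self.channel_names)
        if self.waveforms.ndim != 3:
            raise ValueError("waveforms must be (n_sources, n_conditions, T)")
        n_src = self.waveforms.shape[0]
        if self.scalp_maps.shape != (n_src, len(self.channel_names)):
            raise ValueError("scalp_maps must be (n_sources, n_channels)")
        if self.waveforms.shape[1] != len(self.conditions):
            raise ValueError("waveforms condition axis mismatch")
        if not self.source_ids:
            self.source_ids = tuple(f"{self.method_tag}{i + 1:02d}" for i in range(n_src))
        self.source_ids = _as_tuple(self.source_ids)
        if len(self.source_ids) != n_src:
            raise ValueError("source_ids length mismatch")

    @property
    def n_sources(self) -> int:
        return self.waveforms.shape[0]

    def project(self, i: int, condition: str) -> np.ndarray:
        """Projection of source i for one condition: (T, n_channels).

        Outer product of the source's condition waveform with its scalp
        map — the source's contribution to every channel over time.
        """
        c = self.conditions.index(condition)
        return np.outer(self.waveforms[i, c], self.scalp_maps[i])

    def projections(self, condition: str) -> np.ndarray:
        """(n_sources, T, n_channels) projections for one condition."""
        c = self.conditions.index(condition)
        return self.waveforms[:, c, :, None] * self.scalp_maps[:, None, :]

    def concatenated_signal(self, i: int) -> np.ndarray:
        """Source i's waveforms concatenated over conditions, length T*n_cond."""
        return self.waveforms[i].reshape(-1)

    def concatenated_projection(self, i: int) -> np.ndarray:
        """Flattened per-condition projections concatenated, length T*n_cond*n_ch."""
        return np.concatenate(
            [self.project(i, c).reshape(-1) for c in self.conditions]
        )

    def reconstruction(self, condition: str) -> np.ndarray:
        """Sum of all source projections for one condition, (T, n_channels)."""
        return self.projections(condition).sum(axis=0)

    def subset(self, indices) -> "SourceSet":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            waveforms=self.waveforms[idx],
            scalp_maps=self.scalp_maps[idx],
            source_ids=tuple(self.source_ids[i] for i in idx),
        )

    def save(self, path) -> None:
        np.savez(
            path,
            waveforms=self.waveforms,
            scalp_maps=self.scalp_maps,
            conditions=np.array(self.conditions),
            channel_names=np.array(self.channel_names),
            method_tag=np.array(self.method_tag),
            source_ids=np.array(self.source_ids),
            time_vector=(
                self.time_vector
                if self.time_vector is not None
                else np.zeros(0)
            ),
        )

    @classmethod
    def load(cls, path) -> "SourceSet":
        with np.load(path, allow_pickle=False) as f:
            tv = f["time_vector"]
            return cls(
                waveforms=f["waveforms"],
                scalp_maps=f["scalp_maps"],
                conditions=tuple(f["conditions"]),
                channel_names=tuple(f["channel_names"]),
                method_tag=str(f["method_tag"]),
                source_ids=tuple(f["source_ids"]),
                time_vector=tv if tv.size else None,
            )


# ---------------------------------------------------------------------------
# Directory reader/writer: one array file per subject per condition plus a
# plain-text metadata sidecar.
# ---------------------------------------------------------------------------

_SIDECAR = "dataset.json"


def write_evoked_dir(dws: DifferenceWaveSet, directory) -> None:
    """Write one ``.npy`` per instance plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counters: dict = {}
    files = []
    for k in range(dws.n_instances):
        cond = dws.condition_of_instance[k]
        counters[cond] = counters.get(cond, 0) + 1
        name = f"sub{counters[cond]:03d}_{cond}.npy"
        np.save(directory / name, dws.waveforms[k])
        files.append({"file": name, "condition": cond})
    meta = {
        "conditions": list(dws.conditions),
        "channel_names": list(dws.channel_names),
        "sampling_rate": dws.sampling_rate,
        "epoch_start": float(dws.time_vector[0]),
        "instances": files,
    }
    (directory / _SIDECAR).write_text(json.dumps(meta, indent=1))


def read_evoked_dir(directory) -> DifferenceWaveSet:
    """Read a dataset written by :func:`write_evoked_dir`."""
    directory = Path(directory)
    meta = json.loads((directory / _SIDECAR).read_text())
    waves, labels = [], []
    for entry in meta["instances"]:
        waves.append(np.load(directory / entry["file"]))
        labels.append(entry["condition"])
    waveforms = np.stack(waves)
    T = waveforms.shape[1]
    fs = float(meta["sampling_rate"])
    t0 = float(meta["epoch_start"])
    return DifferenceWaveSet(
        waveforms=waveforms,
        condition_of_instance=tuple(labels),
        conditions=tuple(meta["conditions"]),
        channel_names=tuple(meta["channel_names"]),
        sampling_rate=fs,
        time_vector=t0 + np.arange(T) / fs,
    )


def from_mne_evokeds(evokeds_by_condition, conditions=None) -> DifferenceWaveSet:
    """Build a :class:`DifferenceWaveSet` from MNE ``Evoked`` objects.

    ``evokeds_by_condition`` maps condition label -> list of per-subject
    ``mne.Evoked`` difference waves (volts; converted to microvolts).
    Requires the optional ``mne`` dependency only at call time.
    """
    if conditions is None:
        conditions = tuple(evokeds_by_condition)
    first = evokeds_by_condition[conditions[0]][0]
    ch_names = tuple(first.ch_names)
    fs = float(first.info["sfreq"])
    tv = np.asarray(first.times, dtype=float)
    waves, labels = [], []
    for cond in conditions:
        for ev in evokeds_by_condition[cond]:
            if tuple(ev.ch_names) != ch_names:
                raise ValueError("all evokeds must share the channel set")
            waves.append(ev.data.T * 1e6)  # volts -> microvolts
            labels.append(cond)
    return DifferenceWaveSet(
        waveforms=np.stack(waves),
        condition_of_instance=tuple(labels),
        conditions=tuple(conditions),
        channel_names=ch_names,
        sampling_rate=fs,
        time_vector=tv,
    )
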