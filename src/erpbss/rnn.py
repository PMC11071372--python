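"""Sparse recurrent-network decomposition of ERP difference waves.

A stack of simple (Elman) recurrent layers with ReLU activations maps
condition-indicator step pulses to multi-channel difference waveforms.
Per time step t, with hidden state zero at t = -1:

    z1[t] = ReLU(x[t]  Wf1 + z1[t-1] Wr1 + b1)
    zm[t] = ReLU(zm-1[t] Wfm + zm[t-1] Wrm + bm)      m = 2 .. M-1
    zM[t] = ReLU(zM-1[t] WfM + zM[t-1] WrM)           (no bias)
    yhat[t] = zM[t] Wout                              (linear, no bias)

Training runs in two phases of full-batch Adam: phase 1 minimises the
mean squared reconstruction error; phase 2 continues from the phase-1
weights with an L1 activity penalty on the last hidden layer (driving
most units to zero — the surviving units are the source waveforms) and an
L2 penalty on the output weights (whose rows are the scalp maps).

Everything here — forward pass, backpropagation through time, Adam, the
two-phase schedule — is implemented directly in numpy; gradients are
validated against central finite differences in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .datasets import InputLabelTensors, SourceSet

__all__ = [
    "RNNConfig",
    "RNNWeights",
    "SparseRNN",
    "SparseRNNResults",
    "forward",
    "loss_phase1",
    "loss_phase2",
    "train",
    "extract_sources",
    "project_source",
]

_FORMAT_VERSION = 1


@dataclass
class RNNConfig:
    """Hyperparameters of the sparse RNN decomposition.

    Defaults follow the reference configuration: 4 recurrent layers of 64
    units, activity penalty ``alpha_l1 = 1e-4`` on the last hidden layer,
    output-weight penalty ``alpha_l2 = 1e-2``, Adam at learning rate 1e-3
    (beta_1 = 0.9, beta_2 = 0.999), up to 5000 full-batch iterations per
    phase with early stop after 250 iterations without loss reduction.

    ``loss_reduction`` fixes the norm convention of the reconstruction
    loss: ``"mean"`` (default) averages squared errors over instances,
    time AND channels; ``"channel_sum"`` sums over channels and averages
    over instances and time only.  The two differ by the constant factor
    n_channels and share the same optimum, but the effective strength of
    the regularisers relative to the data term depends on the choice.
    """

    n_hidden: int = 64
    n_recurrent_layers: int = 4
    alpha_l1: float = 1e-4
    alpha_l2: float = 1e-2
    learning_rate: float = 1e-3
    beta_1: float = 0.9
    beta_2: float = 0.999
    epsilon: float = 1e-7
    max_iterations: int = 5000
    patience: int = 250
    seed: int = 0
    activation: str = "relu"
    loss_reduction: str = "mean"

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.n_recurrent_layers < 2:
            raise ValueError("need at least 2 recurrent layers")
        if min(self.alpha_l1, self.alpha_l2, self.learning_rate) < 0:
            raise ValueError("coefficients must be >= 0")
        if self.patience > self.max_iterations:
            raise ValueError("patience must be <= max_iterations")
        if self.activation != "relu":
            raise NotImplementedError("only the ReLU activation is supported")
        if self.loss_reduction not in ("mean", "channel_sum"):
            raise ValueError("loss_reduction must be 'mean' or 'channel_sum'")


@dataclass
class RNNWeights:
    """Weight container: per-layer forward/recurrent kernels and biases.

    ``Wf[m]`` has shape (n_in_m, H), ``Wr[m]`` is (H, H); ``b[m]`` is (H,)
    for all layers except the last, which carries no bias (``None``);
    ``Wout`` is (H, n_channels), no bias.
    """

    Wf: list
    Wr: list
    b: list
    Wout: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.Wf)

    @property
    def n_hidden(self) -> int:
        return self.Wf[0].shape[1]

    def copy(self) -> "RNNWeights":
        return RNNWeights(
            Wf=[w.copy() for w in self.Wf],
            Wr=[w.copy() for w in self.Wr],
            b=[None if v is None else v.copy() for v in self.b],
            Wout=self.Wout.copy(),
        )

    def arrays(self):
        """(name, array) pairs over all trainable arrays, fixed order."""
        out = []
        for m in range(self.n_layers):
            out.append((f"Wf{m}", self.Wf[m]))
            out.append((f"Wr{m}", self.Wr[m]))
            if self.b[m] is not None:
                out.append((f"b{m}", self.b[m]))
        out.append(("Wout", self.Wout))
        return out


def _orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


def _glorot(n_in: int, n_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def init_weights(n_input: int, n_output: int, config: RNNConfig) -> RNNWeights:
    """Glorot-uniform kernels, orthogonal recurrent matrices, zero biases."""
    rng = np.random.default_rng(config.seed)
    H, M = config.n_hidden, config.n_recurrent_layers
    Wf = [_glorot(n_input if m == 0 else H, H, rng) for m in range(M)]
    Wr = [_orthogonal(H, rng) for _ in range(M)]
    b = [np.zeros(H) for _ in range(M - 1)] + [None]
    Wout = _glorot(H, n_output, rng)
    return RNNWeights(Wf=Wf, Wr=Wr, b=b, Wout=Wout)


# ---------------------------------------------------------------------------
# Forward / backward
# ---------------------------------------------------------------------------


def forward(weights: RNNWeights, x: np.ndarray):
    """Run the recurrence; returns (activations per layer, output).

    ``x`` may be a single instance (T, n_in) or a batch (K, T, n_in).
    Activations have matching leading shape with ``n_hidden`` channels;
    the output has the label channel count.  Hidden state is zero at
    t = -1 for every layer.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    X = x[None] if single else x
    if X.ndim != 3 or X.shape[2] != weights.Wf[0].shape[0]:
        raise ValueError(
            f"input shape {x.shape} incompatible with Wf1 {weights.Wf[0].shape}"
        )
    K, T, _ = X.shape
    M, H = weights.n_layers, weights.n_hidden
    Z = [np.zeros((K, T, H)) for _ in range(M)]
    for t in range(T):
        inp = X[:, t]
        for m in range(M):
            a = inp @ weights.Wf[m]
            if t > 0:
                a += Z[m][:, t - 1] @ weights.Wr[m]
            if weights.b[m] is not None:
                a += weights.b[m]
            np.maximum(a, 0.0, out=a)
            Z[m][:, t] = a
            inp = a
    Yhat = Z[-1] @ weights.Wout
    if single:
        return [z[0] for z in Z], Yhat[0]
    return Z, Yhat


def _backward(weights: RNNWeights, X: np.ndarray, Z: list, dYhat: np.ndarray,
              dZ_last_extra=None):
    """Backpropagation through time for the stacked ReLU recurrence.

    ``dYhat`` is dLoss/dYhat, shape (K, T, n_out); ``dZ_last_extra`` is an
    optional direct gradient on the last hidden layer's activations (the
    L1 activity penalty).  Returns a dict name -> gradient matching
    ``weights.arrays()`` (the Wout gradient excludes any weight-decay
    term, which the caller adds).
    """
    K, T, _ = X.shape
    M = weights.n_layers
    grads = {"Wout": np.einsum("kth,ktc->hc", Z[-1], dYhat)}
    dZ = dYhat @ weights.Wout.T
    if dZ_last_extra is not None:
        dZ = dZ + dZ_last_extra
    for m in reversed(range(M)):
        WrT = weights.Wr[m].T
        D = np.empty_like(Z[m])  # dLoss/d(pre-activation)
        delta = np.zeros((K, weights.n_hidden))
        for t in reversed(range(T)):
            d = dZ[:, t] + delta @ WrT
            d *= Z[m][:, t] > 0  # ReLU subgradient (0 at the kink)
            D[:, t] = d
            delta = d
        inp = X if m == 0 else Z[m - 1]
        grads[f"Wf{m}"] = np.einsum("kti,kth->ih", inp, D)
        grads[f"Wr{m}"] = np.einsum("kth,ktg->hg", Z[m][:, :-1], D[:, 1:])
        if weights.b[m] is not None:
            grads[f"b{m}"] = D.sum(axis=(0, 1))
        if m > 0:
            dZ = D @ weights.Wf[m].T
    return grads


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def loss_phase1(Y: np.ndarray, Yhat: np.ndarray, reduction: str = "mean") -> float:
    """Phase-1 reconstruction loss.

    ``reduction="channel_sum"`` is the literal (1/KT) Σ_k Σ_t ||y - yhat||²
    with the squared Euclidean norm taken across channels;
    ``reduction="mean"`` (default, used in training) additionally divides
    by the channel count, i.e. the element-wise mean squared error.  The
    two differ by the constant n_channels only.
    """
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    se = (Y - Yhat) ** 2
    if reduction == "mean":
        return float(se.mean())
    if reduction == "channel_sum":
        return float(se.sum(axis=-1).mean())
    raise ValueError("reduction must be 'mean' or 'channel_sum'")


def l1_activity(Z_last: np.ndarray) -> float:
    """L1 activity of the last hidden layer: sum of |activations| within
    an instance, averaged over the batch."""
    Z_last = np.asarray(Z_last, dtype=float)
    K = Z_last.shape[0] if Z_last.ndim == 3 else 1
    return float(np.abs(Z_last).sum() / K)


def loss_phase2(
    Y: np.ndarray,
    Yhat: np.ndarray,
    Z_last: np.ndarray,
    Wout: np.ndarray,
    alpha_l1: float,
    alpha_l2: float,
    reduction: str = "mean",
) -> float:
    """Phase-2 loss: reconstruction + L1 activity + L2 output-weight terms.

    = loss_phase1 + alpha_l1 * mean_k Σ|Z_last| + alpha_l2 * Σ Wout²;
    reduces to the phase-1 loss at zero coefficients.
    """
    if alpha_l1 < 0 or alpha_l2 < 0:
        raise ValueError("penalty coefficients must be >= 0")
    base = loss_phase1(Y, Yhat, reduction=reduction)
    return base + alpha_l1 * l1_activity(Z_last) + alpha_l2 * float((np.asarray(Wout) ** 2).sum())


def _loss_and_grads(weights, X, Y, cfg: RNNConfig, phase: int):
    Z, Yhat = forward(weights, X)
    K, T, C = Y.shape
    denom = K * T * (C if cfg.loss_reduction == "mean" else 1)
    resid = Yhat - Y
    dYhat = (2.0 / denom) * resid
    if phase == 1:
        loss = loss_phase1(Y, Yhat, cfg.loss_reduction)
        grads = _backward(weights, X, Z, dYhat)
    else:
        loss = loss_phase2(
            Y, Yhat, Z[-1], weights.Wout, cfg.alpha_l1, cfg.alpha_l2, cfg.loss_reduction
        )
        dZ_extra = (cfg.alpha_l1 / K) * (Z[-1] > 0).astype(float)
        grads = _backward(weights, X, Z, dYhat, dZ_last_extra=dZ_extra)
        grads["Wout"] = grads["Wout"] + 2.0 * cfg.alpha_l2 * weights.Wout
    return loss, grads


class _Adam:
    """Plain Adam with bias correction, one slot pair per named array."""

    def __init__(self, cfg: RNNConfig):
        self.lr, self.b1, self.b2, self.eps = (
            cfg.learning_rate,
            cfg.beta_1,
            cfg.beta_2,
            cfg.epsilon,
        )
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, weights: RNNWeights, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for name, arr in weights.arrays():
            g = grads[name]
            m = self.m.setdefault(name, np.zeros_like(arr))
            v = self.v.setdefault(name, np.zeros_like(arr))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            arr -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def _train_phase(weights: RNNWeights, X, Y, cfg: RNNConfig, phase: int,
                 callback=None):
    """Full-batch Adam with best-weight restoration on early stop.

    One iteration = one full-batch update = one epoch.  Stops after
    ``cfg.patience`` iterations without improvement of the recorded loss,
    or after ``cfg.max_iterations``; the weights at the best-loss
    iteration are restored before returning.
    """
    opt = _Adam(cfg)
    history = []
    best_loss = np.inf
    best_weights = weights.copy()
    since_best = 0
    for it in range(cfg.max_iterations):
        loss, grads = _loss_and_grads(weights, X, Y, cfg, phase)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss {loss} at phase {phase} iteration {it}"
            )
        history.append(loss)
        if callback is not None:
            callback(phase, it, loss)
        if loss < best_loss:
            best_loss = loss
            best_weights = weights.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        opt.step(weights, grads)
    return best_weights, history


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class SparseRNN:
    """Sparse RNN decomposition model for paired input/label tensors.

    Parameters
    ----------
    tensors : InputLabelTensors
        Step-pulse inputs X (K, T, n_conditions) paired with difference-
        waveform labels Y (K, T, n_channels), e.g. from
        :func:`erpbss.tensors.build_tensors`.
    config : RNNConfig, optional

    Examples
    --------
    >>> model = SparseRNN(tensors, RNNConfig(n_hidden=32, seed=7))
    >>> res = model.fit()
    >>> sources = res.sources()
    """

    def __init__(self, tensors: InputLabelTensors, config: RNNConfig | None = None):
        self.tensors = tensors
        self.config = config or RNNConfig()
        K = tensors.X.shape[0]
        if K < 2:
            raise ValueError("training requires at least 2 instances")
        present = set(tensors.condition_of_instance)
        missing = set(tensors.conditions) - present
        if missing:
            raise ValueError(f"condition(s) without instances: {sorted(missing)}")

    def fit(self, callback=None, weights: RNNWeights | None = None) -> "SparseRNNResults":
        """Run the two-phase training schedule and return results.

        ``callback(phase, iteration, loss)`` is invoked once per
        iteration; ``weights`` lets a caller warm-start from a previous
        fit instead of the seeded random initialisation.
        """
        X, Y = self.tensors.X, self.tensors.Y
        w = (
            weights.copy()
            if weights is not None
            else init_weights(X.shape[2], Y.shape[2], self.config)
        )
        w, hist1 = _train_phase(w, X, Y, self.config, phase=1, callback=callback)
        w1 = w.copy()
        w, hist2 = _train_phase(w, X, Y, self.config, phase=2, callback=callback)
        return SparseRNNResults(
            model=self,
            weights=w,
            history={"phase1": hist1, "phase2": hist2},
            weights_phase1=w1,
        )


def _active_units(Z_cond: np.ndarray, threshold: float | None) -> np.ndarray:
    """Indices of units whose peak activation exceeds the threshold.

    ``Z_cond`` is (n_conditions, T, H).  ``threshold=None`` uses the
    relative rule: 1e-6 times the largest activation over all units —
    exact zeros are only guaranteed when ReLU inputs are strictly
    negative, so an absolute test on floating-point dust is fragile.
    """
    peak = Z_cond.max(axis=(0, 1))
    if threshold is None:
        threshold = 1e-6 * max(peak.max(), 0.0)
    return np.flatnonzero(peak > threshold)


class SparseRNNResults:
    """Fitted decomposition: weights, activations, history, sources."""

    def __init__(self, model: SparseRNN, weights: RNNWeights, history: dict,
                 weights_phase1: RNNWeights | None = None):
        self.model = model
        self.weights = weights
        self.history = history
        self.weights_phase1 = weights_phase1
        tens = model.tensors
        self._X_rep = tens.representative_inputs()
        Z, Yhat = forward(weights, self._X_rep)
        #: activations per layer on one representative input per condition,
        #: each (n_conditions, T, n_hidden)
        self.activations = Z
        #: predicted output per condition, (n_conditions, T, n_channels)
        self.predicted = Yhat

    # -- convenience views -------------------------------------------------
    @property
    def config(self) -> RNNConfig:
        return self.model.config

    @property
    def tensors(self) -> InputLabelTensors:
        return self.model.tensors

    @property
    def Z_last(self) -> np.ndarray:
        """(n_conditions, T, n_hidden) last-hidden-layer activations."""
        return self.activations[-1]

    def grand_averages(self) -> np.ndarray:
        """Per-condition mean of the label tensor, (n_cond, T, n_channels)."""
        tens = self.tensors
        out = []
        for c in tens.conditions:
            idx = [i for i, lab in enumerate(tens.condition_of_instance) if lab == c]
            out.append(tens.Y[idx].mean(axis=0))
        return np.stack(out)

    def n_active(self, threshold: float | None = None) -> int:
        return _active_units(self.Z_last, threshold).size

    def phase1(self) -> "SparseRNNResults":
        """A results view of the model as it stood after phase 1.

        Lets phase-1 and phase-2 source counts and reconstruction fits
        be compared, quantifying what the activity penalty removed.
        """
        if self.weights_phase1 is None:
            raise ValueError("phase-1 weights were not retained")
        return SparseRNNResults(
            model=self.model,
            weights=self.weights_phase1,
            history={"phase1": self.history["phase1"], "phase2": []},
        )

    def sources(self, threshold: float | None = None) -> SourceSet:
        """Extract the active sources (see :func:`extract_sources`)."""
        return extract_sources(self, threshold)

    def reconstruction_fit(self):
        """Per-condition (r, MSE) of the predicted output vs grand average."""
        from .metrics import projection_fit

        ga = self.grand_averages()
        return projection_fit(self.predicted, ga, self.tensors.conditions)

    def final_losses(self) -> dict:
        return {k: (min(v) if v else np.nan) for k, v in self.history.items()}

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cfg = self.config
        lines = [
            "Sparse RNN decomposition",
            "=" * 58,
            f"layers: {cfg.n_recurrent_layers} x {cfg.n_hidden} units"
            f"   instances: {self.tensors.X.shape[0]}"
            f"   samples: {self.tensors.X.shape[1]}",
            f"alpha_l1={cfg.alpha_l1:g}  alpha_l2={cfg.alpha_l2:g}"
            f"  lr={cfg.learning_rate:g}  seed={cfg.seed}",
            "-" * 58,
        ]
        for ph in ("phase1", "phase2"):
            h = self.history.get(ph) or []
            if not h:
                continue
            lines.append(
                f"{ph}: {len(h)} iterations, best loss {min(h):.6g}"
                f" (start {h[0]:.6g})"
            )
        lines.append(f"active sources: {self.n_active()} of {cfg.n_hidden}")
        lines.append("-" * 58)
        lines.append("condition      r        MSE")
        fits = self.reconstruction_fit()
        for cond, (r, mse, _flag) in zip(self.tensors.conditions, fits):
            lines.append(f"{cond:<10} {r:8.4f}  {mse:10.5g}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        arrays = {name: a for name, a in self.weights.arrays()}
        if self.weights_phase1 is not None:
            arrays.update(
                {f"p1_{name}": a for name, a in self.weights_phase1.arrays()}
            )
        meta = {
            "format_version": _FORMAT_VERSION,
            "config": asdict(self.config),
            "history": {k: list(map(float, v)) for k, v in self.history.items()},
            "has_phase1_weights": self.weights_phase1 is not None,
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path, tensors: InputLabelTensors) -> "SparseRNNResults":
        def _read(f, prefix, M):
            return RNNWeights(
                Wf=[f[f"{prefix}Wf{m}"] for m in range(M)],
                Wr=[f[f"{prefix}Wr{m}"] for m in range(M)],
                b=[f[f"{prefix}b{m}"] for m in range(M - 1)] + [None],
                Wout=f[f"{prefix}Wout"],
            )

        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            cfg = RNNConfig(**meta["config"])
            M = cfg.n_recurrent_layers
            w = _read(f, "", M)
            w1 = _read(f, "p1_", M) if meta.get("has_phase1_weights") else None
        model = SparseRNN(tensors, cfg)
        return cls(model=model, weights=w, history=meta["history"], weights_phase1=w1)


# ---------------------------------------------------------------------------
# Source extraction
# ---------------------------------------------------------------------------


def extract_sources(results: SparseRNNResults, threshold: float | None = None) -> SourceSet:
    """Active units of the last hidden layer as a :class:`SourceSet`.

    A unit is active iff its peak activation over conditions and time
    exceeds the threshold (default: relative rule, 1e-6 x the largest
    activation).  Waveforms are the unit's per-condition activations;
    the scalp map is the unit's row of Wout.  Sources are ordered by
    descending overall correlation of their concatenated projection with
    the concatenated grand-average difference waves (presentation only).
    """
    tens = results.tensors
    Z = results.Z_last
    active = _active_units(Z, threshold)
    if active.size == 0:
        warnings.warn("no active units above threshold; returning empty SourceSet")
    waveforms = np.transpose(Z[:, :, active], (2, 0, 1))  # (n_act, n_cond, T)
    maps = results.weights.Wout[active]
    ss = SourceSet(
        waveforms=waveforms,
        scalp_maps=maps,
        conditions=tens.conditions,
        channel_names=tens.channel_names,
        method_tag="rnn",
        source_ids=tuple(f"rnn{u + 1:02d}" for u in active),
        time_vector=tens.time_vector,
    )
    if ss.n_sources > 1:
        ga = results.grand_averages().reshape(-1)
        rs = []
        for i in range(ss.n_sources):
            p = ss.concatenated_projection(i)
            rs.append(0.0 if p.std() == 0 or ga.std() == 0 else abs(np.corrcoef(p, ga)[0, 1]))
        order = np.argsort(rs)[::-1]
        ss = ss.subset(order)
        ss.source_ids = tuple(f"rnn{i + 1:02d}" for i in range(ss.n_sources))
    return ss


def project_source(source_set: SourceSet, i: int, condition: str) -> np.ndarray:
    """Projection of one source for one condition, (T, n_channels)."""
    return source_set.project(i, condition)


def train(config: RNNConfig, tensors: InputLabelTensors, callback=None) -> SparseRNNResults:
    """Functional entry point: ``SparseRNN(tensors, config).fit()``."""
    return SparseRNN(tensors, config).fit(callback=callback)
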