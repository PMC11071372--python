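"""Source-comparison battery.

Quantifies how decomposition sources relate to the data and to each
other: Pearson correlation and MSE of source projections against
grand-average difference waves; Shannon entropy of a source's
correlation profile across conditions (0 = specific to one difference
wave); pairwise mutual information between source signals (k-nearest-
neighbour estimate for continuous variables, k = 3); and the composite
similarity score

    SS(i, j) = MI(x_i, x_j) + |r(x_i, x_j)| + |r(w_i, w_j)|

where x are condition-concatenated source signals and w scalp maps.
Absolute correlations are used throughout because ICA sources have
arbitrary polarity: flipping a component's waveform and map together
leaves every projection unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy
from scipy.stats import pearsonr
from sklearn.feature_selection import mutual_info_regression

from .datasets import SourceSet

__all__ = [
    "projection_fit",
    "entropy_of_profile",
    "mutual_information",
    "similarity_score",
    "build_report",
    "SimilarityReport",
]


def _safe_r(x: np.ndarray, y: np.ndarray):
    """Pearson r with constant-input handling: returns (r, degenerate).

    A zero-variance input (e.g. an inactive condition's all-zero source
    waveform) makes r undefined; it is reported as 0 with a flag rather
    than raising, so comparison tables stay rectangular.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.std() == 0 or y.std() == 0:
        return 0.0, True
    return float(pearsonr(x, y)[0]), False


def projection_fit(projections, grand_averages, conditions=None):
    """Per-condition (r, MSE, degenerate_flag) of projections vs targets.

    ``projections`` and ``grand_averages`` are (n_conditions, T,
    n_channels); each condition's pair is compared on the flattened
    time-by-channel array.  Works both for a single source's projections
    and for full reconstructions (sums of projections).
    """
    P = np.asarray(projections, dtype=float)
    G = np.asarray(grand_averages, dtype=float)
    if P.shape != G.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {G.shape}")
    out = []
    for c in range(P.shape[0]):
        r, degen = _safe_r(P[c], G[c])
        mse = float(np.mean((P[c] - G[c]) ** 2))
        out.append((r, mse, degen))
    return out


def entropy_of_profile(r_values, base: float | None = None) -> float:
    """Shannon entropy of a correlation profile across conditions.

    The profile is made non-negative by absolute value, normalised to a
    probability vector p = |r| / Σ|r|, and SE = -Σ p ln p is returned in
    nats (``base=2`` for bits).  SE = 0 means the source correlates with
    exactly one difference wave; ln(n_conditions) is the maximum.
    Raises on an all-zero profile.
    """
    r = np.abs(np.asarray(r_values, dtype=float))
    total = r.sum()
    if total == 0:
        raise ValueError("all-zero correlation profile has undefined entropy")
    return float(_shannon_entropy(r / total, base=base))


def mutual_information(x, y, seed: int = 0, n_neighbors: int = 3) -> float:
    """k-NN mutual information between two continuous signals, in nats.

    Uses the Kraskov-style k-nearest-neighbour estimator (k = 3 by
    default) with seeded tie-breaking jitter, clipped at 0: the estimator
    is noisy around independence and can go slightly negative.  Signals
    are the per-source concatenations over conditions (length T x
    n_conditions), compared raw (no standardisation).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mi = mutual_info_regression(
        x.reshape(-1, 1), y, n_neighbors=n_neighbors, random_state=seed
    )[0]
    return float(max(mi, 0.0))


def similarity_score(xi, xj, wi, wj, seed: int = 0) -> float:
    """SS = MI(x_i, x_j) + |r(x_i, x_j)| + |r(w_i, w_j)|."""
    mi = mutual_information(xi, xj, seed=seed)
    r_sig, _ = _safe_r(xi, xj)
    r_map, _ = _safe_r(wi, wj)
    return mi + abs(r_sig) + abs(r_map)


@dataclass
class SimilarityReport:
    """Pairwise source-similarity matrices and per-source diagnostics.

    Matrices are pandas DataFrames indexed by source id over the union
    of the compared source sets.  The SS matrix omits the diagonal
    (NaN); r matrices are exactly symmetric, MI symmetric to estimator
    tolerance.  ``per_source`` holds per-condition projection r and MSE,
    the entropy SE of each source's |r| profile, and its most similar
    other source with the SS value.
    """

    mi: pd.DataFrame
    r_signal: pd.DataFrame
    r_map: pd.DataFrame
    ss: pd.DataFrame
    per_source: pd.DataFrame
    most_similar: dict
    summary: pd.DataFrame
    method_of_source: dict = field(default_factory=dict)

    def check_ss_identity(self, atol: float = 1e-12) -> bool:
        """SS = MI + |r_signal| + |r_map| for every off-diagonal cell."""
        expect = self.mi.to_numpy() + np.abs(self.r_signal.to_numpy()) + np.abs(
            self.r_map.to_numpy()
        )
        got = self.ss.to_numpy()
        off = ~np.eye(got.shape[0], dtype=bool)
        return bool(np.allclose(got[off], expect[off], atol=atol))

    def save(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("mi", "r_signal", "r_map", "ss"):
            getattr(self, name).to_csv(directory / f"{name}.csv")
        self.per_source.to_csv(directory / "per_source.csv")
        self.summary.to_csv(directory / "summary.csv")


def build_report(
    sets,
    grand_averages,
    conditions,
    seed: int = 0,
) -> SimilarityReport:
    """Full comparison battery over one or more source sets.

    ``sets`` is an iterable of :class:`SourceSet` (e.g. the RNN and ICA
    decompositions); ``grand_averages`` is (n_conditions, T, n_channels).
    Computes all pairwise MI / signal-r / map-r / SS matrices over the
    union of sources, per-source per-condition projection fits and SE,
    and each source's most similar other source (highest SS, self
    excluded).  The MI seed makes the jittered estimator reproducible.
    """
    sets = list(sets)
    if sum(s.n_sources for s in sets) < 1:
        raise ValueError("need at least one source overall")
    ids, methods, signals, maps, proj = [], [], [], [], []
    for s in sets:
        for i in range(s.n_sources):
            ids.append(s.source_ids[i])
            methods.append(s.method_tag)
            signals.append(s.concatenated_signal(i))
            maps.append(s.scalp_maps[i])
            proj.append(np.stack([s.project(i, c) for c in conditions]))
    if len(set(ids)) != len(ids):
        raise ValueError("source ids must be unique across the compared sets")
    n = len(ids)
    G = np.asarray(grand_averages, dtype=float)

    # per-source projection fits + entropy of the |r| profile
    rows = []
    degen_any = False
    for sid, meth, P in zip(ids, methods, proj):
        fits = projection_fit(P, G)
        r_prof = np.array([f[0] for f in fits])
        degen_any |= any(f[2] for f in fits)
        try:
            se = entropy_of_profile(r_prof)
        except ValueError:
            se = np.nan
        row = {"source": sid, "method": meth, "SE": se}
        for cond, (r, mse, flag) in zip(conditions, fits):
            row[f"r_{cond}"] = r
            row[f"mse_{cond}"] = mse
        rows.append(row)
    per_source = pd.DataFrame(rows).set_index("source")
    if degen_any:
        warnings.warn("constant projection(s) encountered; their r reported as 0")

    MI = np.zeros((n, n))
    Rs = np.eye(n)
    Rm = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            MI[i, j] = MI[j, i] = mutual_information(signals[i], signals[j], seed=seed)
            Rs[i, j] = Rs[j, i] = _safe_r(signals[i], signals[j])[0]
            Rm[i, j] = Rm[j, i] = _safe_r(maps[i], maps[j])[0]
    SS = MI + np.abs(Rs) + np.abs(Rm)
    np.fill_diagonal(SS, np.nan)

    most_similar = {}
    for i in range(n):
        row = SS[i].copy()
        j = int(np.nanargmax(row))
        most_similar[ids[i]] = (ids[j], float(row[j]))

    # summary: SE and within-method pairwise MI means per method
    summ_rows = []
    for s in sets:
        tag = s.method_tag
        mask = np.array([m == tag for m in methods])
        se_vals = per_source.loc[mask, "SE"].to_numpy(dtype=float)
        idx = np.flatnonzero(mask)
        mi_pairs = [MI[a, b] for ai, a in enumerate(idx) for b in idx[ai + 1:]]
        summ_rows.append(
            {
                "method": tag,
                "n_sources": int(mask.sum()),
                "SE_mean": float(np.nanmean(se_vals)) if se_vals.size else np.nan,
                "SE_sd": float(np.nanstd(se_vals)) if se_vals.size else np.nan,
                "MI_mean": float(np.mean(mi_pairs)) if mi_pairs else np.nan,
                "MI_sd": float(np.std(mi_pairs)) if mi_pairs else np.nan,
                "n_MI_pairs": len(mi_pairs),
            }
        )
    summary = pd.DataFrame(summ_rows).set_index("method")

    def _df(a):
        return pd.DataFrame(a, index=ids, columns=ids)

    return SimilarityReport(
        mi=_df(MI),
        r_signal=_df(Rs),
        r_map=_df(Rm),
        ss=_df(SS),
        per_source=per_source,
        most_similar=most_similar,
        summary=summary,
        method_of_source=dict(zip(ids, methods)),
    )
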