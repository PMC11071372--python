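"""Group ICA baseline decomposition of stacked difference waves.

All subjects' difference waveforms are concatenated along time into one
(samples x channels) matrix; the principal component with least
explained variance is removed first, because common-average-referenced
data are rank deficient and running ICA at full channel count produces
spurious "ghost" components.  Extended infomax ICA (the established
implementation from MNE-Python) is then fitted on the retained
subspace.  Per-condition source waveforms are the component time
courses averaged over that condition's subjects; scalp maps are the
columns of the mixing matrix.  Components have arbitrary polarity:
flipping a component's time course and map together leaves every
projection unchanged, which is why downstream comparisons use absolute
correlations.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.decomposition import PCA

from .datasets import DifferenceWaveSet, SourceSet

__all__ = ["GroupICA", "GroupICAResults", "run_group_ica", "ica_source_set"]


class GroupICA:
    """Group-level extended-infomax ICA of a difference-wave set.

    Parameters
    ----------
    dws : DifferenceWaveSet
    n_drop : int
        Number of trailing principal components to remove before ICA
        (default 1: the dimension lost to common-average referencing).
    """

    def __init__(self, dws: DifferenceWaveSet, n_drop: int = 1):
        if n_drop < 0 or n_drop >= dws.n_channels:
            raise ValueError("n_drop must be in [0, n_channels)")
        self.dws = dws
        self.n_drop = n_drop

    def fit(self, seed: int = 0, max_iter: int = 500) -> "GroupICAResults":
        from mne.preprocessing import infomax

        dws = self.dws
        K, T, n_ch = dws.waveforms.shape
        data = dws.waveforms.reshape(K * T, n_ch)
        if data.shape[0] < n_ch:
            raise ValueError("need at least n_channels total samples")

        rank = np.linalg.matrix_rank(data - data.mean(0))
        n_comp = n_ch - self.n_drop
        if rank < n_comp:
            warnings.warn(
                f"detected data rank {rank} < requested {n_comp} components; "
                "proceeding at the detected rank"
            )
            n_comp = rank

        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(data)  # (K*T, n_comp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W_ica = infomax(
                scores, extended=True, max_iter=max_iter,
                rng=np.random.default_rng(seed), verbose="error",
            )
        # channel-space unmixing / mixing for the retained subspace
        unmixing = W_ica @ pca.components_  # (n_comp, n_ch)
        mixing = np.linalg.pinv(unmixing)  # (n_ch, n_comp)
        sources = scores @ W_ica.T  # (K*T, n_comp)
        return GroupICAResults(
            model=self,
            unmixing=unmixing,
            mixing=mixing,
            pca_components=pca.components_,
            pca_mean=pca.mean_,
            source_timecourses=sources.reshape(K, T, n_comp),
            seed=seed,
        )


class GroupICAResults:
    """Fitted group ICA: unmixing/mixing matrices and component courses."""

    def __init__(self, model, unmixing, mixing, pca_components, pca_mean,
                 source_timecourses, seed):
        self.model = model
        self.unmixing = np.asarray(unmixing)
        self.mixing = np.asarray(mixing)
        self.pca_components = np.asarray(pca_components)
        self.pca_mean = np.asarray(pca_mean)
        #: (K, T, n_components) per-subject component time courses
        self.source_timecourses = np.asarray(source_timecourses)
        self.seed = seed

    @property
    def dws(self) -> DifferenceWaveSet:
        return self.model.dws

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def rank_reduced(self) -> np.ndarray:
        """The dataset projected onto the retained PCA subspace, (K, T, n_ch).

        This — not the raw input — is what the full component set
        reconstructs exactly: the dropped low-variance direction (and the
        grand mean removed by PCA centring) cannot be recovered from the
        components.
        """
        K, T, n_ch = self.dws.waveforms.shape
        data = self.dws.waveforms.reshape(K * T, n_ch) - self.pca_mean
        red = data @ self.pca_components.T @ self.pca_components
        return red.reshape(K, T, n_ch)

    def reconstruct(self) -> np.ndarray:
        """Back-project all components to channel space, (K, T, n_ch)."""
        K, T, _ = self.source_timecourses.shape
        rec = self.source_timecourses.reshape(K * T, -1) @ self.mixing.T
        return rec.reshape(K, T, self.dws.n_channels)

    def condition_averages(self) -> np.ndarray:
        """Component time courses averaged per condition, (n_cond, T, n_comp)."""
        dws = self.dws
        out = []
        for c in dws.conditions:
            out.append(self.source_timecourses[dws.instances_of(c)].mean(axis=0))
        return np.stack(out)

    def sources(self, order: bool = True) -> SourceSet:
        """Components as a :class:`SourceSet` (see :func:`ica_source_set`)."""
        return ica_source_set(self, order=order)

    def summary(self) -> str:
        from .metrics import projection_fit

        dws = self.dws
        ss = self.sources(order=False)
        ga = dws.grand_averages()
        recon = np.stack([ss.reconstruction(c) for c in dws.conditions])
        red = self.rank_reduced()
        ga_red = np.stack(
            [red[dws.instances_of(c)].mean(axis=0) for c in dws.conditions]
        )
        lines = [
            "Group ICA decomposition (extended infomax)",
            "=" * 58,
            f"components: {self.n_components} of {dws.n_channels} channels"
            f" (dropped {self.model.n_drop})   seed: {self.seed}",
            "-" * 58,
            "condition      r (vs GA)   r (vs rank-reduced GA)",
        ]
        fit_full = projection_fit(recon, ga)
        fit_red = projection_fit(recon, ga_red)
        for cond, (r1, _m1, _f1), (r2, _m2, _f2) in zip(dws.conditions, fit_full, fit_red):
            lines.append(f"{cond:<12} {r1:8.4f}     {r2:8.4f}")
        return "\n".join(lines)


def run_group_ica(dws: DifferenceWaveSet, seed: int = 0, n_drop: int = 1) -> GroupICAResults:
    """Functional entry point: ``GroupICA(dws, n_drop).fit(seed)``."""
    return GroupICA(dws, n_drop=n_drop).fit(seed=seed)


def ica_source_set(res: GroupICAResults, order: bool = True) -> SourceSet:
    """Per-condition averaged component courses + mixing-column maps.

    With ``order=True`` components are sorted by descending overall
    correlation of their concatenated projection with the grand-average
    difference waves (presentation only), mirroring the RNN convention.
    """
    dws = res.dws
    cond_avg = res.condition_averages()  # (n_cond, T, n_comp)
    ss = SourceSet(
        waveforms=np.transpose(cond_avg, (2, 0, 1)),
        scalp_maps=res.mixing.T,
        conditions=dws.conditions,
        channel_names=dws.channel_names,
        method_tag="ica",
        time_vector=dws.time_vector,
    )
    if order and ss.n_sources > 1:
        ga = dws.grand_averages().reshape(-1)
        rs = []
        for i in range(ss.n_sources):
            p = ss.concatenated_projection(i)
            rs.append(0.0 if p.std() == 0 else abs(np.corrcoef(p, ga)[0, 1]))
        idx = np.argsort(rs)[::-1]
        ss = ss.subset(idx)
        ss.source_ids = tuple(f"ica{i + 1:02d}" for i in range(ss.n_sources))
    return ss
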