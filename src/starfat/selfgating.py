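"""Respiratory self-gating: navigator extraction, uniform binning, frame selection.

Stack-of-stars sampling passes through the k-space center once per view and
partition, so a superior-inferior projection of the object is available for
every view: the echo-1 center samples across partitions, Fourier-transformed
along z, give a z-profile whose displacement tracks respiration.  Per-coil
profile stacks are reduced by principal component analysis over time, the
coils carrying coherent motion are found by correlation clustering,
sign-aligned and averaged into a single surrogate amplitude per view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import RadialKSpace


@dataclass
class RespSignal:
    """One surrogate amplitude per radial view (a.u., sign-aligned)."""

    amplitude_per_view: np.ndarray
    components_kept: list = field(default_factory=list)
    quality: float = 0.0
    motion_detected: bool = True

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.amplitude_per_view)):
            raise ValueError("navigator must be finite")


@dataclass
class BinAssignment:
    """Respiratory bin index per view; per-bin counts differ by at most one."""

    bin_of_view: np.ndarray
    n_bin: int
    edges: np.ndarray

    def views_in_bin(self, b: int) -> np.ndarray:
        return np.nonzero(self.bin_of_view == b)[0]

    def counts(self) -> np.ndarray:
        return np.bincount(self.bin_of_view, minlength=self.n_bin)


def _pca_time_courses(profiles: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Leading principal-component time courses of a (n_views, n_feat) stack."""
    x = profiles - profiles.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, u.shape[1])
    return u[:, :k] * s[:k]


def _cluster_and_average(signals: np.ndarray, corr_threshold: float = 0.9):
    """Connected-component clustering of per-coil signals by |correlation|.

    Returns (navigator, members, quality).  The largest cluster wins; its
    members are sign-aligned to the first member before averaging.
    """
    n_coil = signals.shape[0]
    std = signals.std(axis=1)
    valid = np.nonzero(std > 1e-12)[0]
    if len(valid) == 0:
        return np.zeros(signals.shape[1]), [], 0.0
    normed = signals[valid] / std[valid][:, None]
    corr = np.corrcoef(normed)
    corr = np.atleast_2d(corr)
    adj = np.abs(corr) >= corr_threshold
    # connected components by BFS
    unseen = set(range(len(valid)))
    clusters = []
    while unseen:
        seed_node = unseen.pop()
        comp = {seed_node}
        frontier = [seed_node]
        while frontier:
            node = frontier.pop()
            for other in list(unseen):
                if adj[node, other]:
                    unseen.remove(other)
                    comp.add(other)
                    frontier.append(other)
        clusters.append(sorted(comp))
    best = max(clusters, key=len)
    ref = normed[best[0]]
    aligned = []
    for idx in best:
        sgn = np.sign(np.dot(normed[idx], ref)) or 1.0
        aligned.append(sgn * normed[idx])
    nav = np.mean(aligned, axis=0)
    quality = float(np.mean([np.abs(np.corrcoef(a, nav)[0, 1]) for a in aligned]))
    return nav, [int(valid[i]) for i in best], quality


def extract_navigator(
    data: RadialKSpace,
    n_components: int = 3,
    corr_threshold: float = 0.9,
    interp_factor: int = 4,
) -> RespSignal:
    """Respiratory surrogate from k-space centers.

    Multi-partition data (n_z >= 8): per coil, echo-1 center samples across
    partitions per view -> FFT along z -> magnitude profile -> interpolate
    (x ``interp_factor``) -> normalize -> PCA over views -> coil clustering
    on the first components -> sign-aligned average.  2-D data fall back to
    the center-sample magnitude time course per coil.
    """
    center = data.n_read // 2
    if data.n_z >= 8:
        # (proj, z, coil), echo 1
        c = data.samples[center, :, :, :, 0]
        prof = np.abs(
            np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(c, axes=1), axis=1), axes=1)
        )
        n_z = prof.shape[1]
        fine = np.linspace(0, n_z - 1, n_z * interp_factor)
        coarse = np.arange(n_z)
        per_coil = []
        for coil in range(data.n_coil):
            p = np.stack(
                [np.interp(fine, coarse, prof[v, :, coil]) for v in range(data.n_proj)]
            )
            mu, sd = p.mean(), p.std()
            p = (p - mu) / (sd if sd > 1e-12 else 1.0)
            per_coil.append(_pca_time_courses(p, n_components))
        first_components = np.stack([pc[:, 0] for pc in per_coil])
    else:
        mags = np.abs(data.samples[center, :, 0, :, 0]).T  # (coil, proj)
        first_components = mags - mags.mean(axis=1, keepdims=True)
    nav, members, quality = _cluster_and_average(first_components, corr_threshold)
    if np.std(nav) <= 1e-12:
        return RespSignal(
            amplitude_per_view=np.zeros(data.n_proj),
            components_kept=[],
            quality=0.0,
            motion_detected=False,
        )
    return RespSignal(
        amplitude_per_view=nav, components_kept=members, quality=quality
    )


def bin_views(sig: RespSignal, n_bin: int) -> BinAssignment:
    """Variable-amplitude (uniform-count) binning.

    Views sorted by amplitude are split into contiguous quantile groups of
    near-equal size, so scan time is uniformly distributed over respiratory
    states.  Ties break by view index; bin 0 holds the lowest amplitudes.
    """
    amp = sig.amplitude_per_view
    n_views = len(amp)
    if n_bin < 1 or n_bin > n_views:
        raise ValueError("n_bin must be in [1, n_views]")
    order = np.argsort(amp, kind="stable")  # stable: ties -> earlier view lower bin
    bin_of_view = np.empty(n_views, dtype=int)
    groups = np.array_split(order, n_bin)
    edges = []
    for b, grp in enumerate(groups):
        bin_of_view[grp] = b
        edges.append(amp[grp[-1]])
    return BinAssignment(bin_of_view=bin_of_view, n_bin=n_bin, edges=np.array(edges))


def select_best_frame(sig: RespSignal, bins: BinAssignment) -> int:
    """Bin whose member amplitudes have the smallest variance (ties: lowest index)."""
    variances = [
        float(np.var(sig.amplitude_per_view[bins.views_in_bin(b)]))
        for b in range(bins.n_bin)
    ]
    return int(np.argmin(variances))
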