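"""Coil sensitivity simulation, PCA coil compression, and adaptive map estimation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .containers import RadialKSpace


@dataclass
class CoilSet:
    """Complex receive sensitivities, shape (n_coil, Nx, Ny)."""

    sensitivities: np.ndarray
    geometry: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sensitivities.ndim != 3:
            raise ValueError("sensitivities must be [n_coil, Nx, Ny]")

    @property
    def n_coil(self) -> int:
        return self.sensitivities.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.sensitivities) ** 2, axis=0))


def make_coils(
    grid_size: int, n_coil: int, seed: int = 0, uniform: bool = False
) -> CoilSet:
    """Smooth synthetic receive profiles.

    Coils are placed on a ring around the FOV; each profile is a broad
    Gaussian falloff from the coil center with a smooth random phase, so
    the set is band-limited and no coil is identically zero.
    """
    if n_coil < 1:
        raise ValueError("n_coil must be >= 1")
    n = int(grid_size)
    if uniform:
        sens = np.ones((n_coil, n, n), dtype=complex)
        return CoilSet(sens, geometry=[{"uniform": True}] * n_coil)
    rng = np.random.default_rng(seed)
    ii = (np.arange(n) - n // 2) / n  # FOV units
    x, y = np.meshgrid(ii, ii, indexing="ij")
    sens = np.empty((n_coil, n, n), dtype=complex)
    geometry = []
    for c in range(n_coil):
        ang = 2 * np.pi * c / n_coil + rng.uniform(-0.1, 0.1)
        cx, cy = 0.55 * np.cos(ang), 0.55 * np.sin(ang)
        width = 0.55 + rng.uniform(-0.05, 0.05)
        mag = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * width**2))
        # smooth low-order phase, distinct per coil
        phase = (
            rng.uniform(-np.pi, np.pi)
            + rng.uniform(-2, 2) * x
            + rng.uniform(-2, 2) * y
            + rng.uniform(-1, 1) * x * y
        )
        sens[c] = mag * np.exp(1j * phase)
        geometry.append({"center": (cx, cy), "width": width})
    return CoilSet(sens, geometry=geometry)


def compress_coils(data: RadialKSpace, n_modes: int):
    """Partition-wise PCA coil compression onto the leading virtual coils.

    Returns the compressed container and the fraction of signal energy
    retained (worst partition).
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    if n_modes > data.n_coil:
        raise ValueError("n_modes exceeds coil count")
    out = np.empty(
        (data.n_read, data.n_proj, data.n_z, n_modes, data.n_echo), dtype=complex
    )
    energy = []
    for z in range(data.n_z):
        mat = data.samples[:, :, z].reshape(-1, data.n_coil, data.n_echo)
        mat = mat.transpose(0, 2, 1).reshape(-1, data.n_coil)  # samples x coils
        cov = mat.conj().T @ mat
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        proj = mat @ vecs[:, :n_modes]
        total = float(np.sum(vals))
        energy.append(float(np.sum(vals[:n_modes]) / total) if total > 0 else 1.0)
        out[:, :, z] = proj.reshape(
            data.n_read * data.n_proj, data.n_echo, n_modes
        ).transpose(0, 2, 1).reshape(data.n_read, data.n_proj, n_modes, data.n_echo)
    compressed = RadialKSpace(
        out, data.traj, data.calib, dict(data.meta, energy_retained=min(energy))
    )
    return compressed, min(energy)


def estimate_coil_maps(echo1_coil_images: np.ndarray, block: int = 8) -> CoilSet:
    """Adaptive (Walsh-style) sensitivity estimation from regridded coil images.

    The local coil covariance is smoothed over ``block``-sized neighbourhoods
    and the per-pixel dominant eigenvector, phase-referenced to the first
    coil and normalized to unit root-sum-of-squares, is the sensitivity.
    Pixels with negligible signal are masked to zero.
    """
    imgs = np.asarray(echo1_coil_images, dtype=complex)
    if imgs.ndim != 3:
        raise ValueError("expected [n_coil, Nx, Ny] images")
    nc, nx, ny = imgs.shape
    # smoothed outer-product covariance per pixel
    cov = np.empty((nx, ny, nc, nc), dtype=complex)
    for a in range(nc):
        for b in range(nc):
            prod = imgs[a] * np.conj(imgs[b])
            cov[:, :, a, b] = uniform_filter(prod.real, block) + 1j * uniform_filter(
                prod.imag, block
            )
    vals, vecs = np.linalg.eigh(cov.reshape(-1, nc, nc))
    dom = vecs[:, :, -1]  # leading eigenvector per pixel
    power = vals[:, -1].real
    mask = power > 1e-6 * power.max()
    # phase reference: make the first significant coil component real-positive
    ref = dom[:, 0].copy()
    ref_phase = np.where(np.abs(ref) > 0, ref / np.maximum(np.abs(ref), 1e-30), 1.0)
    dom = dom * np.conj(ref_phase)[:, None]
    norm = np.linalg.norm(dom, axis=1)
    dom = dom / np.maximum(norm, 1e-30)[:, None]
    dom[~mask] = 0.0
    sens = dom.T.reshape(nc, nx, ny)
    return CoilSet(sens, geometry=[{"estimated": True}] * nc)
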