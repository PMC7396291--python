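"""Non-uniform FFT via Kaiser-Bessel gridding.

Conventions (single source of truth for all phase/shift choices in this
package):

* Image pixels live at positions ``r = (i - N/2) / N`` in FOV units,
  ``i = 0..N-1`` (even ``N``), so the image origin sits at pixel ``N/2``.
* k-space coordinates are in cycles/FOV; the forward transform evaluates
  the centered DFT sum ``s(k) = sum_r x(r) exp(-2 pi i k . r)``.
* The oversampled Cartesian grid has size ``M = oversampling * N`` with
  its origin at index ``M/2``; a sample at ``u`` cycles/FOV lands at grid
  coordinate ``u * oversampling + M/2``.

The forward operator is type-2 (image -> arbitrary samples); its exact
algebraic adjoint (type-1) is provided.  Interpolation coefficients are
precomputed per coordinate set into a sparse CSR matrix and reused across
coils, echoes and solver iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import i0


@dataclass(frozen=True)
class GriddingConfig:
    """Kaiser-Bessel gridding parameters.

    ``kb_beta`` defaults to the Beatty closed form for the given kernel
    width and oversampling factor.
    """

    oversampling: float = 2.0
    kernel_width: int = 6
    kb_beta: float | None = None

    def __post_init__(self) -> None:
        if not self.oversampling > 1:
            raise ValueError("oversampling must be > 1")
        if self.kernel_width < 2:
            raise ValueError("kernel_width must be >= 2")

    @property
    def beta(self) -> float:
        if self.kb_beta is not None:
            return float(self.kb_beta)
        w, os = self.kernel_width, self.oversampling
        return float(np.pi * np.sqrt((w / os) ** 2 * (os - 0.5) ** 2 - 0.8))


def _kb_kernel(d: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel kernel evaluated at grid distance ``d`` (cells)."""
    arg = 1.0 - (2.0 * d / width) ** 2
    out = np.zeros_like(d, dtype=float)
    inside = arg > 0
    out[inside] = i0(beta * np.sqrt(arg[inside]))
    return out


def _kb_apodization(p: np.ndarray, width: int, beta: float, m: int) -> np.ndarray:
    """Fourier transform of the KB kernel at image offset ``p`` (cells from center)."""
    x = np.pi * width * p / m
    sq = np.sqrt(beta**2 - x**2 + 0j)
    c = np.real(np.sinh(sq) / sq)
    # limit sq -> 0 handled by sinh(z)/z -> 1
    c = np.where(np.abs(sq) < 1e-12, 1.0, c)
    return width * c  # continuous FT of the kernel carries its support width


class GriddingPlan:
    """Precomputed interpolation structure for one set of k-space coordinates.

    Parameters
    ----------
    coords : array, shape (n_samples, 2)
        (kx, ky) in cycles/FOV.
    grid_size : int
        Image side length N (even).
    cfg : GriddingConfig
    """

    def __init__(self, coords: np.ndarray, grid_size: int, cfg: GriddingConfig | None = None):
        cfg = cfg or GriddingConfig()
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        n = int(grid_size)
        if n % 2:
            raise ValueError("grid_size must be even")
        m = int(round(cfg.oversampling * n))
        m += m % 2
        # the oversampled grid is periodic in k with period m/oversampling
        # cycles/FOV, so small excursions past the nominal +-N/2 edge (e.g.
        # gradient-delay shifts) wrap exactly; reject only clearly bad input
        kmax = m / cfg.oversampling
        if np.any(np.abs(coords) > kmax):
            raise ValueError("k-space coordinates out of supported range")
        self.cfg = cfg
        self.n = n
        self.m = m
        self.n_samples = coords.shape[0]
        self._build(coords)
        # apodization correction on the embedded N x N image
        p = np.arange(n) - n // 2
        c1d = _kb_apodization(p.astype(float), cfg.kernel_width, cfg.beta, m)
        self._deapod = 1.0 / np.outer(c1d, c1d)

    def _build(self, coords: np.ndarray) -> None:
        w = self.cfg.kernel_width
        beta = self.cfg.beta
        os = self.cfg.oversampling
        m = self.m
        gx = coords[:, 0] * os  # grid coordinate relative to center
        gy = coords[:, 1] * os
        offs = np.arange(-(w // 2) + 1, w // 2 + 1)  # w nearest cells
        jx = np.floor(gx)[:, None] + offs[None, :]
        jy = np.floor(gy)[:, None] + offs[None, :]
        wx = _kb_kernel(jx - gx[:, None], w, beta)
        wy = _kb_kernel(jy - gy[:, None], w, beta)
        ix = (jx.astype(int) + m // 2) % m
        iy = (jy.astype(int) + m // 2) % m
        # separable outer product per sample -> w*w entries
        rows = np.repeat(np.arange(self.n_samples), w * w)
        cols = (ix[:, :, None] * m + iy[:, None, :]).reshape(-1)
        vals = (wx[:, :, None] * wy[:, None, :]).reshape(-1)
        self._interp = sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_samples, m * m)
        )
        self._interp_h = self._interp.conj().T.tocsr()

    # -- centered FFT helpers ------------------------------------------------
    def _cfft2(self, x: np.ndarray) -> np.ndarray:
        return np.fft.fftshift(
            np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1)),
            axes=(-2, -1),
        )

    def _cfft2_adj(self, x: np.ndarray) -> np.ndarray:
        # exact conjugate transpose of _cfft2 (unnormalized fft -> m^2 * ifft)
        return (
            np.fft.fftshift(
                np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1)),
                axes=(-2, -1),
            )
            * (self.m**2)
        )

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Type-2 NUFFT.  ``image`` is (..., N, N); returns (..., n_samples)."""
        image = np.asarray(image)
        if image.shape[-2:] != (self.n, self.n):
            raise ValueError("image shape mismatch")
        lead = image.shape[:-2]
        x = image.reshape(-1, self.n, self.n) * self._deapod
        pad = np.zeros((x.shape[0], self.m, self.m), dtype=complex)
        lo = (self.m - self.n) // 2
        pad[:, lo : lo + self.n, lo : lo + self.n] = x
        spec = self._cfft2(pad).reshape(x.shape[0], -1)
        out = self._interp @ spec.T  # (n_samples, batch)
        return np.ascontiguousarray(out.T).reshape(*lead, self.n_samples)

    def adjoint(self, samples: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        """Adjoint (type-1) NUFFT; optional per-sample density weights."""
        samples = np.asarray(samples, dtype=complex)
        if samples.shape[-1] != self.n_samples:
            raise ValueError("sample count mismatch")
        lead = samples.shape[:-1]
        y = samples.reshape(-1, self.n_samples)
        if weights is not None:
            y = y * np.asarray(weights)[None, :]
        grid = (self._interp_h @ y.T).T.reshape(-1, self.m, self.m)
        img = self._cfft2_adj(grid)
        lo = (self.m - self.n) // 2
        img = img[:, lo : lo + self.n, lo : lo + self.n] * self._deapod
        return img.reshape(*lead, self.n, self.n)


def nufft_forward(
    image: np.ndarray, coords: np.ndarray, cfg: GriddingConfig | None = None
) -> np.ndarray:
    """One-shot type-2 NUFFT (builds a plan; prefer GriddingPlan in loops)."""
    plan = GriddingPlan(coords, image.shape[-1], cfg)
    return plan.forward(image)


def nufft_adjoint(
    samples: np.ndarray,
    coords: np.ndarray,
    grid_size: int,
    cfg: GriddingConfig | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """One-shot adjoint NUFFT."""
    plan = GriddingPlan(coords, grid_size, cfg)
    return plan.adjoint(samples, weights=weights)


def ramp_density_weights(
    coords: np.ndarray,
    grid_size: int | None = None,
    cfg: GriddingConfig | None = None,
) -> np.ndarray:
    """Ram-Lak style radial density compensation.

    Weight is proportional to |k| with a finite center value (each center
    sample takes the area of the innermost disk shared by all spokes).
    When ``grid_size`` is given the weights are calibrated so that a
    uniform disk reconstructs with unit mean under ``adjoint(forward(.))``.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    r = np.hypot(coords[:, 0], coords[:, 1])
    # in w = |k| units the center disk (radius 1/2, one sample per spoke)
    # carries an equivalent radius of 1/4
    w = np.where(r < 0.5, 0.25, r)
    # golden-angle spokes are not azimuthally equispaced: scale each sample
    # by its spoke's angular Voronoi gap (diameters folded into [0, pi))
    ang = np.arctan2(coords[:, 1], coords[:, 0])
    ang = np.where(r < 0.5, np.nan, np.mod(ang, np.pi))
    spoke_angles = np.unique(np.round(ang[~np.isnan(ang)], 9))
    if len(spoke_angles) > 1:
        order = np.argsort(spoke_angles)
        sa = spoke_angles[order]
        gaps = np.diff(np.concatenate([[sa[-1] - np.pi], sa, [sa[0] + np.pi]]))
        half = 0.5 * (gaps[:-1] + gaps[1:])
        gap_of = dict(zip(np.round(sa, 9), half * len(sa) / np.pi))
        factors = np.array([gap_of.get(a, 1.0) if np.isfinite(a) else 1.0
                            for a in np.round(ang, 9)])
        w = w * factors
    if grid_size is not None:
        n = int(grid_size)
        plan = GriddingPlan(coords, n, cfg)
        ii = np.arange(n) - n // 2
        disk = ((ii[:, None] ** 2 + ii[None, :] ** 2) <= (n // 4) ** 2).astype(complex)
        rec = plan.adjoint(plan.forward(disk), weights=w)
        mean_rec = np.real(rec[disk != 0]).mean()
        if mean_rec > 0:
            w = w / mean_rec
    return w
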