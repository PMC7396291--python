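"""Quantitative evaluation: VOI statistics, linear regression, Bland-Altman."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class VoiSpec:
    """Circular volume of interest spanning two consecutive slices."""

    center: tuple  # (x, y) voxel coordinates
    radius: float  # voxels
    slices: tuple = (0, 1)
    label: str = ""


@dataclass(frozen=True)
class AgreementReport:
    """Regression and Bland-Altman agreement between two measurement series."""

    slope: float
    intercept: float
    pearson_r: float
    slope_ci: tuple
    intercept_ci: tuple
    r_ci: tuple
    p_value: float
    mae: float
    bias: float
    loa: tuple  # bias -+ 1.96 sd of differences
    bias_ci: tuple
    loa_ci_width: float
    n: int


def voi_mask(voi: VoiSpec, shape) -> np.ndarray:
    """Boolean (Nx, Ny, Nz) mask of the VOI; raises if out of bounds."""
    nx, ny = shape[0], shape[1]
    nz = shape[2] if len(shape) > 2 else 1
    cx, cy = voi.center
    r = voi.radius
    if not (r <= cx <= nx - 1 - r and r <= cy <= ny - 1 - r):
        raise ValueError("VOI out of bounds in-plane")
    if min(voi.slices) < 0 or max(voi.slices) >= nz:
        raise ValueError("VOI slices out of bounds")
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    disk = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    mask = np.zeros((nx, ny, nz), dtype=bool)
    for s in voi.slices:
        mask[:, :, s] = disk
    return mask


def voi_stats(volume: np.ndarray, vois) -> np.ndarray:
    """Mean map value over each two-slice circular VOI."""
    vol = np.asarray(volume)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    means = []
    for voi in vois:
        mask = voi_mask(voi, vol.shape)
        means.append(float(vol[mask].mean()))
    return np.asarray(means)


def agreement(x: np.ndarray, y: np.ndarray, ci: float = 0.95) -> AgreementReport:
    """OLS regression of y on x, Pearson r, and Bland-Altman bias / LoA.

    Confidence intervals use the standard closed forms: t-based for slope,
    intercept, bias and LoA; Fisher z for the correlation coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.5 + ci / 2, n - 2)
    slope_ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    intercept_ci = (
        res.intercept - tcrit * res.intercept_stderr,
        res.intercept + tcrit * res.intercept_stderr,
    )
    # Fisher z interval for r (degenerate when |r| = 1)
    r = res.rvalue
    if abs(r) < 1.0 and n > 3:
        zr = np.arctanh(r)
        zse = 1.0 / np.sqrt(n - 3)
        zcrit = stats.norm.ppf(0.5 + ci / 2)
        r_ci = (np.tanh(zr - zcrit * zse), np.tanh(zr + zcrit * zse))
    else:
        r_ci = (r, r)
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    tcrit1 = stats.t.ppf(0.5 + ci / 2, n - 1)
    bias_se = sd / np.sqrt(n)
    loa_se = sd * np.sqrt(3.0 / n)  # standard approximation for LoA CIs
    return AgreementReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(r),
        slope_ci=slope_ci,
        intercept_ci=intercept_ci,
        r_ci=r_ci,
        p_value=float(res.pvalue),
        mae=float(np.mean(np.abs(diff))),
        bias=bias,
        loa=loa,
        bias_ci=(bias - tcrit1 * bias_se, bias + tcrit1 * bias_se),
        loa_ci_width=float(tcrit1 * loa_se),
        n=n,
    )
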