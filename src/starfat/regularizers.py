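"""Smoothed total-variation regularizers (spatial and temporal).

The l1 TV terms are smoothed as sqrt(|d|^2 + eps) so the whole objective is
differentiable and can be handed to L-BFGS.  Spatial TV is anisotropic with
Neumann boundaries (boundary differences are zero and contribute only the
sqrt(eps) floor, giving a constant image the value Nx*Ny*2*sqrt(eps));
temporal TV differences along the leading bin axis only, non-circular.
Both accept complex maps: differences are penalized through their modulus,
and complex gradients use the d/dRe + i d/dIm convention.
"""

from __future__ import annotations

import numpy as np


def _smooth_abs(d: np.ndarray, eps: float):
    s = np.sqrt(np.abs(d) ** 2 + eps)
    return s, d / s


def tv_spatial(image: np.ndarray, epsilon: float = 1e-6):
    """Anisotropic smoothed spatial TV: (value, gradient)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = np.asarray(image)
    dx = np.zeros_like(x)
    dy = np.zeros_like(x)
    dx[:-1, :] = x[1:, :] - x[:-1, :]  # Neumann: last row difference = 0
    dy[:, :-1] = x[:, 1:] - x[:, :-1]
    sx, gx = _smooth_abs(dx, epsilon)
    sy, gy = _smooth_abs(dy, epsilon)
    value = float(np.sum(sx) + np.sum(sy))
    grad = np.zeros_like(x)
    grad[1:, :] += gx[:-1, :]
    grad[:-1, :] -= gx[:-1, :]
    grad[:, 1:] += gy[:, :-1]
    grad[:, :-1] -= gy[:, :-1]
    return value, grad


def tv_temporal(maps_over_bins: np.ndarray, epsilon: float = 1e-6):
    """Smoothed TV along the leading (respiratory bin) axis: (value, gradient)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = np.asarray(maps_over_bins)
    if x.shape[0] < 2:
        raise ValueError("temporal TV undefined for a single bin")
    d = x[1:] - x[:-1]
    s, g = _smooth_abs(d, epsilon)
    value = float(np.sum(s))
    grad = np.zeros_like(x)
    grad[1:] += g
    grad[:-1] -= g
    return value, grad
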