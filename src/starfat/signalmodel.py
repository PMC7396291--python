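"""Forward signal model for joint water/fat/R2* estimation and its gradient.

For each receive coil c and echo n the model predicts radial k-space as

    E(W, F, R2*)_{c,n} = FT( C_c e^{2 pi i Phi te_n} e^{-R2* te_n} W )
                       + D_n FT( C_c e^{2 pi i Phi te_n} e^{-R2* te_n} F )

where FT is the NUFFT onto echo n's spoke coordinates, Phi is the fixed B0
field map (Hz), a single effective R2* decay is shared by water and fat,
and D_n is the multi-peak fat dephasing evaluated at the exact readout time
of every sample.  The data-consistency cost is the summed squared residual
magnitude over coils, echoes and samples; analytic gradients use the
conjugate (Wirtinger) convention for the complex W and F and the ordinary
real convention for R2*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fatmodel import FatModel, fat_kspace_weights
from .nufft import GriddingConfig, GriddingPlan
from .trajectory import Trajectory


@dataclass
class ParameterMaps:
    """Complex water/fat images (a.u.) and nonnegative R2* (1/s)."""

    water: np.ndarray
    fat: np.ndarray
    r2s: np.ndarray

    def __post_init__(self) -> None:
        if not (self.water.shape == self.fat.shape == self.r2s.shape):
            raise ValueError("map shapes must match")

    @property
    def shape(self):
        return self.water.shape

    def copy(self) -> "ParameterMaps":
        return ParameterMaps(self.water.copy(), self.fat.copy(), self.r2s.copy())


@dataclass
class FieldMap:
    """B0 off-resonance in Hz."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("field map must be finite")


def compute_pdff(
    maps: ParameterMaps,
    rel_threshold: float = 1e-9,
    return_mask: bool = False,
):
    """Proton-density fat fraction with magnitude discrimination.

    Per voxel: |F| / |F + W| where |F| >= |W|, else 1 - |W| / |F + W|.
    Picking the branch from the larger magnitude avoids the noise bias a
    plain ratio of magnitudes would introduce near PDFF 0 or 1.  Voxels
    where |F + W| falls below ``rel_threshold * max|F + W|`` are masked
    and reported as 0.
    """
    w, f = maps.water, maps.fat
    total = np.abs(f + w)
    thresh = rel_threshold * max(float(total.max()), np.finfo(float).tiny)
    mask = total > thresh
    safe_total = np.where(mask, total, 1.0)
    fat_branch = np.abs(f) / safe_total
    water_branch = 1.0 - np.abs(w) / safe_total
    pdff = np.where(np.abs(f) >= np.abs(w), fat_branch, water_branch)
    pdff = np.where(mask, pdff, 0.0)
    if return_mask:
        return pdff, mask
    return pdff


class SignalOperator:
    """Precomputed forward model for one slice and one view subset.

    Builds one gridding plan and one fat-weight vector per echo, reused
    across coils and across every solver iteration.
    """

    def __init__(
        self,
        traj: Trajectory,
        coils: np.ndarray,
        phi: np.ndarray,
        fat: FatModel,
        cfg: Optional[GriddingConfig] = None,
        views: np.ndarray | slice = slice(None),
        grid_size: Optional[int] = None,
    ):
        coils = np.asarray(coils, dtype=complex)
        if coils.ndim != 3:
            raise ValueError("coils must be [n_coil, Nx, Ny]")
        n = grid_size or coils.shape[-1]
        if coils.shape[-2:] != (n, n) or np.asarray(phi).shape != (n, n):
            raise ValueError("coil / field-map grids inconsistent")
        self.coils = coils
        self.phi = np.asarray(phi, dtype=float)
        self.te = traj.te
        self.n = n
        self.n_echo = traj.n_echo
        self.plans = [GriddingPlan(traj.coords(e, views), n, cfg) for e in range(self.n_echo)]
        self.fat_weights = [
            fat_kspace_weights(fat, traj.times(e, views)) for e in range(self.n_echo)
        ]
        self.n_samples = self.plans[0].n_samples

    def _echo_factor(self, r2s: np.ndarray, echo: int) -> np.ndarray:
        te = self.te[echo]
        return np.exp((2j * np.pi * self.phi - r2s) * te)

    def forward(self, maps: ParameterMaps) -> np.ndarray:
        """Predicted samples, shape (n_coil, n_echo, n_samples)."""
        out = np.empty((len(self.coils), self.n_echo, self.n_samples), dtype=complex)
        for e in range(self.n_echo):
            a = self._echo_factor(maps.r2s, e)
            yw = self.plans[e].forward(self.coils * (a * maps.water)[None])
            yf = self.plans[e].forward(self.coils * (a * maps.fat)[None])
            out[:, e] = yw + self.fat_weights[e][None, :] * yf
        return out

    def cost_grad(self, maps: ParameterMaps, data: np.ndarray):
        """Data-consistency cost and gradients (grad_w, grad_f, grad_r2s).

        Complex gradients follow the d/dRe + i d/dIm convention so that a
        real optimizer over interleaved parts sees exact derivatives.
        """
        if data.shape != (len(self.coils), self.n_echo, self.n_samples):
            raise ValueError("data shape mismatch")
        n = self.n
        cost = 0.0
        gw = np.zeros((n, n), dtype=complex)
        gf = np.zeros((n, n), dtype=complex)
        gr = np.zeros((n, n), dtype=float)
        for e in range(self.n_echo):
            a = self._echo_factor(maps.r2s, e)
            ca = self.coils * a[None]
            yw = self.plans[e].forward(ca * maps.water[None])
            yf = self.plans[e].forward(ca * maps.fat[None])
            res = yw + self.fat_weights[e][None, :] * yf - data[:, e]
            cost += float(np.sum(np.abs(res) ** 2))
            adj_w = self.plans[e].adjoint(res)
            adj_f = self.plans[e].adjoint(np.conj(self.fat_weights[e])[None, :] * res)
            ca_conj = np.conj(ca)
            gw += 2.0 * np.sum(ca_conj * adj_w, axis=0)
            gf += 2.0 * np.sum(ca_conj * adj_f, axis=0)
            gr += (
                -2.0
                * self.te[e]
                * np.real(
                    np.sum(
                        np.conj(ca * maps.water[None]) * adj_w
                        + np.conj(ca * maps.fat[None]) * adj_f,
                        axis=0,
                    )
                )
            )
        return cost, gw, gf, gr


def forward_operator(
    maps: ParameterMaps,
    phi: FieldMap | np.ndarray,
    coils: np.ndarray,
    traj: Trajectory,
    fat: FatModel,
    cfg: Optional[GriddingConfig] = None,
) -> np.ndarray:
    """One-shot forward model; returns samples (n_coil, n_echo, n_samples)."""
    phi_arr = phi.phi if isinstance(phi, FieldMap) else np.asarray(phi)
    op = SignalOperator(traj, coils, phi_arr, fat, cfg)
    return op.forward(maps)


def data_cost_and_grad(
    maps: ParameterMaps,
    data: np.ndarray,
    phi: FieldMap | np.ndarray,
    coils: np.ndarray,
    traj: Trajectory,
    fat: FatModel,
    cfg: Optional[GriddingConfig] = None,
):
    """One-shot data-consistency cost and analytic gradients."""
    phi_arr = phi.phi if isinstance(phi, FieldMap) else np.asarray(phi)
    op = SignalOperator(traj, coils, phi_arr, fat, cfg)
    return op.cost_grad(maps, data)
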