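"""Field-map and parameter-map initialization.

Robust water/fat separation needs a B0 field-map estimate, which is a
non-convex problem riddled with water/fat-swap local minima.  The
initializer here evaluates, per voxel, the variable-projection residual of
the two-compartment signal (water + multi-peak fat, shared R2* decay) on a
discretized (Phi, R2*) grid built from conventional density-compensated
NUFFT echo images, then enforces spatial smoothness of Phi with a
confidence-ordered region-growing pass that picks, for each voxel, the
local residual minimum closest to its already-labelled neighbours.  This is
a deliberately simple stand-in for full graph-cut field-map solvers; its
output seeds the iterative model-based reconstruction, which refines W, F
and R2* (Phi stays fixed thereafter).
"""

from __future__ import annotations

import heapq

import numpy as np

from .coils import CoilSet
from .containers import RadialKSpace
from .fatmodel import FatModel, fat_kspace_weights
from .nufft import GriddingConfig, GriddingPlan, ramp_density_weights
from .signalmodel import FieldMap, ParameterMaps


def echo_images(
    data: RadialKSpace,
    grid_size: int,
    z: int = 0,
    cfg: GriddingConfig | None = None,
) -> np.ndarray:
    """Density-compensated adjoint-NUFFT coil images per echo.

    Returns complex array (n_echo, n_coil, N, N).
    """
    sl = data.slice_data(z)  # (coil, echo, samples)
    out = np.empty((data.n_echo, data.n_coil, grid_size, grid_size), dtype=complex)
    for e in range(data.n_echo):
        coords = data.traj.coords(e)
        plan = GriddingPlan(coords, grid_size, cfg)
        w = ramp_density_weights(coords, grid_size, cfg)
        out[e] = plan.adjoint(sl[:, e, :], weights=w)
    return out


def _local_minima(curve: np.ndarray) -> np.ndarray:
    """Indices of local minima of a 1-D curve (endpoints included)."""
    n = len(curve)
    idx = []
    for i in range(n):
        left = curve[i - 1] if i > 0 else np.inf
        right = curve[i + 1] if i < n - 1 else np.inf
        if curve[i] <= left and curve[i] <= right:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def init_maps(
    data: RadialKSpace,
    coils: CoilSet,
    fat: FatModel,
    z: int = 0,
    n_phi: int = 121,
    r2s_max: float = 300.0,
    n_r2s: int = 13,
    phi_range_hz: float | None = None,
    cfg: GriddingConfig | None = None,
    mask_rel_threshold: float = 0.05,
):
    """Initial (W, F, R2*, Phi) from discretized variable projection.

    The Phi search spans +-1/(2 dTE) (the unambiguous bandwidth of the echo
    spacing) unless ``phi_range_hz`` overrides it.  Returns
    ``(ParameterMaps, FieldMap)``.
    """
    if data.n_echo < 3:
        raise ValueError("field-map initialization needs >= 3 echoes")
    n = coils.sensitivities.shape[-1]
    te = data.traj.te
    d_te = float(np.median(np.diff(te)))
    if phi_range_hz is None:
        phi_range_hz = 1.0 / (2.0 * d_te)

    imgs = echo_images(data, n, z=z, cfg=cfg)
    sens = coils.sensitivities
    combined = np.einsum("cij,ecij->eij", np.conj(sens), imgs)  # (n_echo, N, N)
    y = combined.reshape(data.n_echo, -1)
    energy = np.sum(np.abs(y) ** 2, axis=0)
    signal_mask = energy > (mask_rel_threshold**2) * energy.max()

    phi_grid = np.linspace(-phi_range_hz, phi_range_hz, n_phi)
    r2s_grid = np.linspace(0.0, r2s_max, n_r2s)
    d_te_fat = fat_kspace_weights(fat, te)  # fat dephasing at the echo times

    # projection energy |P y|^2 for every (phi, r2s) grid point
    proj = np.empty((n_phi, n_r2s, y.shape[1]))
    pinvs = {}
    for ip, phi in enumerate(phi_grid):
        for ir, r2 in enumerate(r2s_grid):
            decay = np.exp((2j * np.pi * phi - r2) * te)
            a = np.stack([decay, d_te_fat * decay], axis=1)  # (n_echo, 2)
            gram = a.conj().T @ a
            pinv = np.linalg.solve(gram, a.conj().T)
            p = a @ pinv  # projector onto the model subspace
            proj[ip, ir] = np.real(np.einsum("ij,iv,jv->v", p, np.conj(y), y))
            pinvs[(ip, ir)] = pinv
    residual = energy[None, None, :] - proj
    res_phi = residual.min(axis=1)  # (n_phi, n_vox)
    r2s_idx = residual.argmin(axis=1)

    # confidence-ordered region growing over the phi dimension
    phi_assigned = np.full(y.shape[1], np.nan)
    ny = n
    order_energy = energy.copy()
    seed_vox = int(np.argmax(order_energy))
    heap = [(-order_energy[seed_vox], seed_vox, None)]
    visited = np.zeros(y.shape[1], dtype=bool)
    phi_idx_map = np.zeros(y.shape[1], dtype=int)
    while heap:
        negq, vox, neighbor_phi = heapq.heappop(heap)
        if visited[vox]:
            continue
        visited[vox] = True
        minima = _local_minima(res_phi[:, vox])
        if neighbor_phi is None:
            choice = minima[np.argmin(res_phi[minima, vox])]
        else:
            choice = minima[np.argmin(np.abs(phi_grid[minima] - neighbor_phi))]
        phi_idx_map[vox] = choice
        phi_assigned[vox] = phi_grid[choice]
        r, c = divmod(vox, ny)
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < n and 0 <= cc < ny:
                nb = rr * ny + cc
                if not visited[nb]:
                    heapq.heappush(heap, (-order_energy[nb], nb, phi_assigned[vox]))

    # sub-grid refinement: parabola through the residual at the chosen index
    phi_ref = phi_assigned.copy()
    dphi = phi_grid[1] - phi_grid[0]
    for vox in range(y.shape[1]):
        i = phi_idx_map[vox]
        if 0 < i < n_phi - 1:
            cm, c0, cp = res_phi[i - 1, vox], res_phi[i, vox], res_phi[i + 1, vox]
            denom = cm - 2 * c0 + cp
            if denom > 1e-30:
                phi_ref[vox] += dphi * 0.5 * (cm - cp) / denom

    # amplitudes at the refined phi (grid R2*), batched 2x2 normal equations
    r2s_vals = r2s_grid[r2s_idx[phi_idx_map, np.arange(y.shape[1])]]
    decay = np.exp((2j * np.pi * phi_ref[None, :] - r2s_vals[None, :]) * te[:, None])
    a0 = decay
    a1 = d_te_fat[:, None] * decay
    g00 = np.sum(np.abs(a0) ** 2, axis=0)
    g01 = np.sum(np.conj(a0) * a1, axis=0)
    g11 = np.sum(np.abs(a1) ** 2, axis=0)
    b0 = np.sum(np.conj(a0) * y, axis=0)
    b1 = np.sum(np.conj(a1) * y, axis=0)
    det = g00 * g11 - np.abs(g01) ** 2
    det = np.where(np.abs(det) < 1e-30, 1.0, det)
    w = (g11 * b0 - g01 * b1) / det
    f = (g00 * b1 - np.conj(g01) * b0) / det

    w[~signal_mask] = 0
    f[~signal_mask] = 0
    r2s_vals = np.where(signal_mask, r2s_vals, 0.0)
    maps = ParameterMaps(
        water=w.reshape(n, n),
        fat=f.reshape(n, n),
        r2s=r2s_vals.reshape(n, n).astype(float),
    )
    phi_map = FieldMap(phi=phi_ref.reshape(n, n))
    return maps, phi_map
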