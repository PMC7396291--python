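"""Model-based reconstruction engine.

`WaterFatRecon` is the model object: it owns the acquired radial k-space,
the acquisition geometry and the reconstruction configuration, and its
``fit()`` assembles and minimizes the regularized least-squares objective

    argmin_{W,F,R2*}  sum_{c,n} || E(W,F,R2*)_{c,n} - Y_{c,n} ||_2^2
                      + lam_W ||S(W)||_1 + lam_F ||S(F)||_1 + lam_R2s ||S(R2*)||_1

with L-BFGS over (Re W, Im W, Re F, Im F, R2*), returning a
`ReconResults` object with the parameter maps, PDFF, diagnostics and a
``summary()`` table.

Three variants are supported:

* ``averaged`` — all views in one data term, spatial TV (default weights 0,
  i.e. plain least squares on fully sampled data);
* ``xd`` — views sorted into respiratory bins, jointly reconstructed with
  temporal TV along the bin axis; the frame with the most consistent
  respiration signal is flagged as the best frame;
* ``gated`` — only the best frame's views are used, either through NUFFT +
  image-space separation (the initializer machinery) or through the
  model-based path with zero regularization.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .coils import CoilSet, compress_coils, estimate_coil_maps
from .containers import RadialKSpace
from .fatmodel import FatModel
from .initialization import echo_images, init_maps
from .nufft import GriddingConfig
from .regularizers import tv_spatial, tv_temporal
from .selfgating import BinAssignment, RespSignal, bin_views, extract_navigator, select_best_frame
from .signalmodel import FieldMap, ParameterMaps, SignalOperator, compute_pdff
from .trajectory import Trajectory, apply_kspace_shifts, estimate_kspace_shifts

NYQUIST_FACTOR = np.pi / 2.0  # radial Nyquist spoke count = base_resolution * pi/2


@dataclass
class ReconConfig:
    """Reconstruction settings; unset weights default per variant."""

    variant: str = "averaged"
    lambda_w: Optional[float] = None
    lambda_f: Optional[float] = None
    lambda_r2s: Optional[float] = None
    n_bin: int = 4
    accept_fraction: float = 0.25
    gated_mode: str = "nufft"  # "nufft" (image-space separation) or "model"
    n_coil_modes: Optional[int] = None
    max_iter: int = 100
    rel_tol: float = 1e-6
    tv_epsilon: float = 1e-6  # relative to the map dynamic range
    seed: int = 0
    grid_size: Optional[int] = None
    gridding: Optional[GriddingConfig] = None
    r2s_parameterization: str = "bounded"  # "bounded" (L-BFGS-B) or "exp"

    def __post_init__(self) -> None:
        if self.variant not in ("averaged", "xd", "gated"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.gated_mode not in ("nufft", "model"):
            raise ValueError(f"unknown gated mode {self.gated_mode!r}")
        defaults = {
            "averaged": (0.0, 0.0, 0.0),
            "xd": (0.4, 0.4, 0.01),
            "gated": (0.0, 0.0, 0.0),
        }[self.variant]
        if self.lambda_w is None:
            self.lambda_w = defaults[0]
        if self.lambda_f is None:
            self.lambda_f = defaults[1]
        if self.lambda_r2s is None:
            self.lambda_r2s = defaults[2]
        if self.n_coil_modes is None:
            self.n_coil_modes = 8 if self.variant == "averaged" else 4


@dataclass
class ReconResults:
    """Fitted maps and diagnostics; per-bin leading axis for the xd variant."""

    maps: ParameterMaps
    pdff: np.ndarray
    phi: FieldMap
    navigator: Optional[RespSignal]
    bins: Optional[BinAssignment]
    best_frame: Optional[int]
    cost_trace: np.ndarray
    r2s_scale: float
    config: ReconConfig
    diagnostics: dict = dc_field(default_factory=dict)

    @property
    def per_bin(self) -> bool:
        return self.maps.water.ndim == 3

    def best_frame_maps(self) -> ParameterMaps:
        if not self.per_bin:
            return self.maps
        b = self.best_frame or 0
        return ParameterMaps(
            self.maps.water[b].copy(), self.maps.fat[b].copy(), self.maps.r2s[b].copy()
        )

    def best_frame_pdff(self) -> np.ndarray:
        return self.pdff[self.best_frame or 0] if self.per_bin else self.pdff

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Water/fat/R2* model-based reconstruction",
            "=" * 48,
            f"variant            : {self.config.variant}",
            f"grid               : {d.get('grid_size')} x {d.get('grid_size')}",
            f"views used         : {d.get('views_used')} / {d.get('n_proj')}",
            f"coils (compressed) : {d.get('n_coil_modes')}",
            f"undersampling      : {d.get('undersampling_factor'):.2f}"
            if d.get("undersampling_factor")
            else "undersampling      : n/a",
            f"iterations         : {len(self.cost_trace)}",
            f"final cost         : {self.cost_trace[-1]:.6g}" if len(self.cost_trace) else "",
            f"R2* scale factor   : {self.r2s_scale:.4g}",
        ]
        if self.best_frame is not None:
            lines.append(f"best frame         : {self.best_frame}")
        total = np.abs(self.best_frame_maps().water + self.best_frame_maps().fat)
        mask = total > 0.05 * total.max()  # object support, not background haze
        if mask.any():
            pdff = self.best_frame_pdff()[mask]
            r2s = self.best_frame_maps().r2s[mask]
            lines.append(f"PDFF (support)     : {100 * pdff.mean():.2f} % mean")
            lines.append(f"R2* (support)      : {r2s.mean():.1f} 1/s mean")
        return "\n".join(x for x in lines if x)


def r2s_scale_factor(
    maps0: ParameterMaps, op: SignalOperator, data: np.ndarray
) -> float:
    """||dcost/dW||_2 / ||dcost/dR2*||_2 at the initial maps.

    Applied as an internal variable scaling of R2* so water/fat and R2*
    influence the cost on a similar scale.  The R2* gradient carries one
    more factor of the signal amplitude than the W gradient, so the ratio
    scales inversely with overall data amplitude; the reconstruction
    neutralizes this by normalizing k-space to unit median spoke energy
    before the factor is computed.  Returns 1 when the R2* gradient
    vanishes (e.g. exactly at a perfect fit).
    """
    _, gw, _, gr = op.cost_grad(maps0, data)
    norm_w = float(np.linalg.norm(gw))
    norm_r = float(np.linalg.norm(gr))
    if norm_r <= 1e-10 * float(np.linalg.norm(data)):
        return 1.0
    return norm_w / norm_r


def _subset_views(traj: Trajectory, views: np.ndarray) -> Trajectory:
    return Trajectory(
        kx=traj.kx[:, views],
        ky=traj.ky[:, views],
        t_sample=traj.t_sample[:, views],
        view_angle=traj.view_angle[views],
        te=traj.te.copy(),
        shift_per_echo=traj.shift_per_echo.copy(),
    )


class _Objective:
    """Joint objective over one or more respiratory bins."""

    def __init__(self, ops, datas, cfg: ReconConfig, r2s_scale: float, init: ParameterMaps):
        self.ops = ops
        self.datas = datas
        self.cfg = cfg
        self.scale = r2s_scale
        self.n = ops[0].n
        self.n_bin = len(ops)
        dyn_w = max(float(np.abs(init.water).max()), float(np.abs(init.fat).max()), 1e-12)
        dyn_r = max(float(init.r2s.max()), 1.0)
        self.eps_wf = (cfg.tv_epsilon * dyn_w) ** 2
        self.eps_r = (cfg.tv_epsilon * dyn_r) ** 2
        self.exp_param = cfg.r2s_parameterization == "exp"

    # -- packing ------------------------------------------------------------
    def pack(self, maps_list) -> np.ndarray:
        parts = []
        for m in maps_list:
            rho = (
                np.log(np.maximum(m.r2s, 1e-6)) if self.exp_param else m.r2s / self.scale
            )
            parts += [m.water.real, m.water.imag, m.fat.real, m.fat.imag, rho]
        return np.concatenate([p.ravel() for p in parts])

    def unpack(self, x: np.ndarray):
        n2 = self.n * self.n
        maps_list = []
        for b in range(self.n_bin):
            o = b * 5 * n2
            wr, wi, fr, fi, rho = (
                x[o + i * n2 : o + (i + 1) * n2].reshape(self.n, self.n) for i in range(5)
            )
            r2s = np.exp(rho) if self.exp_param else self.scale * rho
            maps_list.append(ParameterMaps(wr + 1j * wi, fr + 1j * fi, r2s))
        return maps_list

    def bounds(self):
        if self.exp_param:
            return None
        n2 = self.n * self.n
        bounds = []
        for _ in range(self.n_bin):
            bounds += [(None, None)] * (4 * n2) + [(0.0, None)] * n2
        return bounds

    # -- value and gradient --------------------------------------------------
    def __call__(self, x: np.ndarray):
        maps_list = self.unpack(x)
        cfg = self.cfg
        n2 = self.n * self.n
        cost = 0.0
        grads = []
        for b in range(self.n_bin):
            c, gw, gf, gr = self.ops[b].cost_grad(maps_list[b], self.datas[b])
            cost += c
            grads.append([gw, gf, gr])
        # regularization
        if self.n_bin == 1:
            m = maps_list[0]
            for idx, (lam, arr, eps) in enumerate(
                [
                    (cfg.lambda_w, m.water, self.eps_wf),
                    (cfg.lambda_f, m.fat, self.eps_wf),
                    (cfg.lambda_r2s, m.r2s, self.eps_r),
                ]
            ):
                if lam > 0:
                    v, g = tv_spatial(arr, eps)
                    cost += lam * v
                    grads[0][idx] = grads[0][idx] + lam * (
                        2 * g if idx < 2 else np.real(g)
                    )
        else:
            stacks = [
                np.stack([m.water for m in maps_list]),
                np.stack([m.fat for m in maps_list]),
                np.stack([m.r2s for m in maps_list]),
            ]
            lams = [cfg.lambda_w, cfg.lambda_f, cfg.lambda_r2s]
            epss = [self.eps_wf, self.eps_wf, self.eps_r]
            for idx, (lam, stack, eps) in enumerate(zip(lams, stacks, epss)):
                if lam > 0:
                    v, g = tv_temporal(stack, eps)
                    cost += lam * v
                    for b in range(self.n_bin):
                        grads[b][idx] = grads[b][idx] + lam * (
                            2 * g[b] if idx < 2 else np.real(g[b])
                        )
        # assemble real gradient vector
        gout = np.empty_like(x)
        for b in range(self.n_bin):
            o = b * 5 * n2
            gw, gf, gr = grads[b]
            if self.exp_param:
                r2s = maps_list[b].r2s
                grho = gr * r2s  # chain rule through r2s = exp(rho)
            else:
                grho = gr * self.scale
            gout[o : o + n2] = gw.real.ravel()
            gout[o + n2 : o + 2 * n2] = gw.imag.ravel()
            gout[o + 2 * n2 : o + 3 * n2] = gf.real.ravel()
            gout[o + 3 * n2 : o + 4 * n2] = gf.imag.ravel()
            gout[o + 4 * n2 : o + 5 * n2] = grho.ravel()
        return cost, gout


class WaterFatRecon:
    """Model object: radial k-space + configuration -> fitted parameter maps.

    Parameters
    ----------
    data : RadialKSpace
        Multi-echo radial k-space (with optional calibration spokes).
    config : ReconConfig, optional
    fat : FatModel, optional
        Defaults to the six-peak liver spectrum at 3T.
    coils : CoilSet, optional
        Known sensitivities; estimated from the data when omitted.
    """

    def __init__(
        self,
        data: RadialKSpace,
        config: Optional[ReconConfig] = None,
        fat: Optional[FatModel] = None,
        coils: Optional[CoilSet] = None,
        navigator: Optional[RespSignal] = None,
    ):
        self.data = data
        self.config = config or ReconConfig()
        self.fat = fat or FatModel.liver_6peak()
        self._coils = coils
        self._navigator = navigator
        self.grid_size = self.config.grid_size or data.n_read

    # -- pipeline pieces -----------------------------------------------------
    def _prepare(self):
        cfg = self.config
        data = self.data
        diagnostics: dict = {"n_proj": data.n_proj, "grid_size": self.grid_size}

        traj = data.traj
        if data.calib is not None:
            shifts = estimate_kspace_shifts(data.calib)
            traj = apply_kspace_shifts(traj, shifts)
            diagnostics["kspace_shifts"] = shifts.tolist()
        else:
            diagnostics["kspace_shifts"] = None

        # navigator must see the kz dimension, before the partition FFT
        navigator = None
        bins = None
        best = None
        if cfg.variant in ("xd", "gated"):
            navigator = self._navigator or extract_navigator(data)
            n_bin = cfg.n_bin
            if cfg.variant == "gated":
                n_bin = max(int(round(1.0 / cfg.accept_fraction)), 1)
            bins = bin_views(navigator, n_bin)
            best = select_best_frame(navigator, bins)
            diagnostics["bin_counts"] = bins.counts().tolist()
            diagnostics["best_frame"] = best

        sliced = data.to_slices()
        samples = sliced.samples
        # normalize k-space to unit median spoke energy
        spoke_energy = np.sum(np.abs(samples) ** 2, axis=0)
        med = float(np.median(spoke_energy[spoke_energy > 0]))
        knorm = 1.0 / np.sqrt(med) if med > 0 else 1.0
        samples = samples * knorm
        diagnostics["kspace_norm"] = knorm

        n_modes = min(cfg.n_coil_modes, data.n_coil)
        working = RadialKSpace(samples, traj, None, dict(data.meta))
        if n_modes < data.n_coil:
            working, energy = compress_coils(working, n_modes)
            diagnostics["coil_energy_retained"] = energy
        diagnostics["n_coil_modes"] = working.n_coil
        return working, traj, navigator, bins, best, knorm, diagnostics

    def fit(self, z: int = 0) -> ReconResults:
        """Reconstruct slice ``z`` and return the results object."""
        cfg = self.config
        working, traj, navigator, bins, best, knorm, diag = self._prepare()
        n = self.grid_size

        # coil sensitivities from density-compensated echo-1 images
        imgs = echo_images(working, n, z=z, cfg=cfg.gridding)
        coil_maps = estimate_coil_maps(imgs[0])

        maps0, phi = init_maps(working, coil_maps, self.fat, z=z, cfg=cfg.gridding)

        nyquist = self.data.n_read * NYQUIST_FACTOR
        if cfg.variant == "averaged":
            views_used = working.n_proj
        else:
            views_used = len(bins.views_in_bin(best))
        diag["views_used"] = int(views_used)
        diag["nyquist_spokes"] = nyquist
        diag["undersampling_factor"] = nyquist / views_used

        sl = working.slice_data(z)  # (coil, echo, read*proj)

        def bin_op_data(view_idx, phi_map=None, init=None):
            sub_traj = _subset_views(traj, view_idx)
            op = SignalOperator(
                sub_traj,
                coil_maps.sensitivities,
                phi_map.phi if phi_map is not None else phi.phi,
                self.fat,
                cfg.gridding,
            )
            d = sl.reshape(working.n_coil, working.n_echo, working.n_read, working.n_proj)
            d = d[:, :, :, view_idx].reshape(working.n_coil, working.n_echo, -1)
            return op, d

        def bin_init(view_idx):
            """Per-bin field map and seed maps from the bin's own echo images.

            Each respiratory state carries its own mean B0 offset
            (susceptibility shifts with diaphragm position), so the field
            map is re-estimated from the bin's views; a field map frozen at
            the motion-averaged state would push that offset into R2*.
            """
            sub_traj = _subset_views(traj, view_idx)
            d5 = working.samples[:, view_idx]
            sub = RadialKSpace(d5, sub_traj, None, dict(working.meta))
            return init_maps(sub, coil_maps, self.fat, z=z, cfg=cfg.gridding)

        if cfg.variant == "gated" and cfg.gated_mode == "nufft":
            views = bins.views_in_bin(best)
            sub_traj = _subset_views(traj, views)
            d5 = working.samples[:, views]
            sub = RadialKSpace(d5, sub_traj, None, dict(working.meta))
            g_imgs = echo_images(sub, n, z=z, cfg=cfg.gridding)
            g_coils = estimate_coil_maps(g_imgs[0])
            maps_g, phi_g = init_maps(sub, g_coils, self.fat, z=z, cfg=cfg.gridding)
            maps_g.water /= knorm
            maps_g.fat /= knorm
            pdff = compute_pdff(maps_g)
            return ReconResults(
                maps=maps_g,
                pdff=pdff,
                phi=phi_g,
                navigator=navigator,
                bins=bins,
                best_frame=best,
                cost_trace=np.array([]),
                r2s_scale=1.0,
                config=cfg,
                diagnostics=diag,
            )

        phi_out = phi
        if cfg.variant == "averaged":
            ops_datas = [bin_op_data(np.arange(working.n_proj))]
            inits = [maps0]
        elif cfg.variant == "xd":
            per_bin = [bin_init(bins.views_in_bin(b)) for b in range(bins.n_bin)]
            inits = [m for m, _ in per_bin]
            ops_datas = [
                bin_op_data(bins.views_in_bin(b), phi_map=per_bin[b][1])
                for b in range(bins.n_bin)
            ]
            phi_out = FieldMap(phi=np.stack([p.phi for _, p in per_bin]))
        else:  # gated, model-based
            maps_b, phi_b = bin_init(bins.views_in_bin(best))
            ops_datas = [bin_op_data(bins.views_in_bin(best), phi_map=phi_b)]
            inits = [maps_b]
            phi_out = phi_b

        ops = [od[0] for od in ops_datas]
        datas = [od[1] for od in ops_datas]
        scale = r2s_scale_factor(inits[0], ops[0], datas[0])
        diag["r2s_scale"] = scale

        objective = _Objective(ops, datas, cfg, scale, inits[0])
        x0 = objective.pack(inits)
        trace: list[float] = []

        def cb(xk):
            trace.append(objective(xk)[0])

        result = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=objective.bounds(),
            callback=cb,
            options={"maxiter": cfg.max_iter, "ftol": cfg.rel_tol, "maxcor": 10},
        )
        fitted = objective.unpack(result.x)
        for m in fitted:
            m.water /= knorm
            m.fat /= knorm

        if cfg.variant == "xd":
            maps = ParameterMaps(
                np.stack([m.water for m in fitted]),
                np.stack([m.fat for m in fitted]),
                np.stack([m.r2s for m in fitted]),
            )
            pdff = np.stack(
                [compute_pdff(ParameterMaps(m.water, m.fat, m.r2s)) for m in fitted]
            )
        else:
            maps = fitted[0]
            pdff = compute_pdff(maps)
        diag["n_iterations"] = int(result.nit)
        diag["converged"] = bool(result.success)
        return ReconResults(
            maps=maps,
            pdff=pdff,
            phi=phi_out,
            navigator=navigator,
            bins=bins,
            best_frame=best,
            cost_trace=np.asarray(trace),
            r2s_scale=scale,
            config=cfg,
            diagnostics=diag,
        )


def reconstruct(data: RadialKSpace, cfg: Optional[ReconConfig] = None, **kwargs) -> ReconResults:
    """Functional entry point: build the model object and fit it."""
    return WaterFatRecon(data, cfg, **kwargs).fit()
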