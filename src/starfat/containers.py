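"""Shared data containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trajectory import CalibSpokes, Trajectory


@dataclass
class RadialKSpace:
    """Acquired (or simulated) multi-echo radial k-space.

    samples : complex (n_read, n_proj, n_z, n_coil, n_echo)
    traj : in-plane trajectory with per-sample timing
    calib : optional gradient-delay calibration spokes
    meta : free-form acquisition metadata (fov_mm, noise_sigma, ...)
    """

    samples: np.ndarray
    traj: Trajectory
    calib: Optional[CalibSpokes] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.samples.ndim != 5:
            raise ValueError("samples must be 5-D [read, proj, z, coil, echo]")
        nr, np_, _, _, ne = self.samples.shape
        if (nr, np_) != (self.traj.n_read, self.traj.n_proj) or ne != self.traj.n_echo:
            raise ValueError("samples inconsistent with trajectory")

    @property
    def n_read(self) -> int:
        return self.samples.shape[0]

    @property
    def n_proj(self) -> int:
        return self.samples.shape[1]

    @property
    def n_z(self) -> int:
        return self.samples.shape[2]

    @property
    def n_coil(self) -> int:
        return self.samples.shape[3]

    @property
    def n_echo(self) -> int:
        return self.samples.shape[4]

    def slice_data(self, z: int = 0) -> np.ndarray:
        """One slice reordered to (n_coil, n_echo, n_read * n_proj)."""
        d = self.samples[:, :, z]  # (read, proj, coil, echo)
        return np.ascontiguousarray(
            d.reshape(-1, self.n_coil, self.n_echo).transpose(1, 2, 0)
        )

    def to_slices(self) -> "RadialKSpace":
        """Inverse FFT along the partition axis (kz -> z).

        Stack-of-stars data are Cartesian along kz, so after this transform
        every z index is an independent 2-D reconstruction problem.
        """
        if self.n_z == 1:
            return self
        sl = np.fft.fftshift(
            np.fft.ifft(np.fft.ifftshift(self.samples, axes=2), axis=2), axes=2
        )
        return RadialKSpace(sl, self.traj, self.calib, dict(self.meta, domain="z"))
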