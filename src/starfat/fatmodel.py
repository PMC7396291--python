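"""Multi-peak fat spectral model evaluated in k-space.

Fat signal is modelled as a sum of spectral peaks at fixed chemical-shift
offsets from water.  Because each radial k-space sample has its own readout
time, the dephasing factor D(t) is evaluated at the exact time of every
sample, which inherently deconvolves the off-resonant blurring of fat that
a per-echo approximation would leave behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAMMA_MHZ_PER_T = 42.577  # proton gyromagnetic ratio / 2 pi

# Standard in-vivo liver six-peak calibration: chemical shift of each fat
# peak relative to water (ppm; negative = lower frequency than water) and
# relative peak areas.  Overridable via FatModel or a plain-text table.
LIVER_6PEAK_DELTA_PPM = (-3.80, -3.40, -2.60, -1.94, -0.39, 0.59)
LIVER_6PEAK_AMPLITUDES = (0.087, 0.693, 0.128, 0.004, 0.039, 0.048)


@dataclass(frozen=True)
class FatModel:
    """Fat peak offsets (Hz) and relative amplitudes summing to one."""

    peak_offsets_hz: np.ndarray
    relative_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        off = np.atleast_1d(np.asarray(self.peak_offsets_hz, dtype=float))
        amp = np.atleast_1d(np.asarray(self.relative_amplitudes, dtype=float))
        if off.shape != amp.shape:
            raise ValueError("offsets and amplitudes must have equal length")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be nonnegative")
        if not np.all(np.isfinite(off)):
            raise ValueError("offsets must be finite")
        s = amp.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1 (+-1e-9)")
        object.__setattr__(self, "peak_offsets_hz", off)
        object.__setattr__(self, "relative_amplitudes", amp)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_offsets_hz)

    @classmethod
    def liver_6peak(cls, field_strength_t: float = 3.0) -> "FatModel":
        """Default six-peak liver spectrum at the given field strength."""
        hz_per_ppm = GAMMA_MHZ_PER_T * field_strength_t
        amp = np.array(LIVER_6PEAK_AMPLITUDES)
        return cls(
            peak_offsets_hz=np.array(LIVER_6PEAK_DELTA_PPM) * hz_per_ppm,
            relative_amplitudes=amp / amp.sum(),
        )

    @classmethod
    def from_table(cls, path, field_strength_t: float = 3.0) -> "FatModel":
        """Read a two-column (ppm, amplitude) plain-text table."""
        rows = np.loadtxt(path, ndmin=2)
        hz_per_ppm = GAMMA_MHZ_PER_T * field_strength_t
        amp = rows[:, 1]
        return cls(rows[:, 0] * hz_per_ppm, amp / amp.sum())


def fat_kspace_weights(fat: FatModel, t_sample: np.ndarray) -> np.ndarray:
    """D(t) = sum_p a_p exp(2 pi i f_p t) at each sample's own readout time."""
    t = np.asarray(t_sample, dtype=float)
    phase = 2j * np.pi * t[..., None] * fat.peak_offsets_hz
    return np.exp(phase) @ fat.relative_amplitudes.astype(complex)
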