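"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def direct_dft2(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Direct evaluation of s(k) = sum_r x(r) exp(-2 pi i k . r).

    Pixel positions r = (i - N/2) / N in FOV units, matching the package's
    centered convention.  O(N^2) per sample; small inputs only.
    """
    n = image.shape[0]
    ii = (np.arange(n) - n // 2) / n
    x, y = np.meshgrid(ii, ii, indexing="ij")
    out = np.empty(len(coords), dtype=complex)
    for s, (kx, ky) in enumerate(coords):
        out[s] = np.sum(image * np.exp(-2j * np.pi * (kx * x + ky * y)))
    return out


def scalar_signal(w, f, r2s, phi_hz, te, t_sample, fat_offsets, fat_amps):
    """Single-voxel signal for one echo: the model evaluated by hand.

    Image-space factors use the echo time; the fat dephasing uses the exact
    per-sample time.
    """
    a = np.exp((2j * np.pi * phi_hz - r2s) * te)
    d = np.sum(fat_amps * np.exp(2j * np.pi * fat_offsets * t_sample))
    return a * w + d * a * f
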