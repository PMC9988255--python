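"""Brute-force reference implementations used only to check the package.

These are deliberately naive (explicit loops / dense summation) and stay
independent of the code paths they verify.
"""

from __future__ import annotations

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy * dy + dx * dx <= radius * radius:
                offs.append((dy, dx))
    return offs


def median_disk_brute(plane: np.ndarray, radius: int) -> np.ndarray:
    """Sliding-disk median with reflective (symmetric) borders."""
    pad = np.pad(plane, radius, mode="symmetric")
    h, w = plane.shape
    offs = disk_offsets(radius)
    out = np.empty_like(plane, dtype=float)
    for y in range(h):
        for x in range(w):
            vals = [pad[y + radius + dy, x + radius + dx] for dy, dx in offs]
            out[y, x] = np.median(vals)
    return out


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_smooth_brute(plane: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian smoothing by explicit summation, symmetric borders."""
    k = gaussian_kernel_1d(sigma)
    r = (len(k) - 1) // 2

    def along_axis0(a):
        pad = np.pad(a, ((r, r), (0, 0)), mode="symmetric")
        out = np.zeros_like(a, dtype=float)
        for i, kv in enumerate(k):
            out += kv * pad[i:i + a.shape[0], :]
        return out

    return along_axis0(along_axis0(plane).T).T


def highpass_brute(plane: np.ndarray, sigma: float, stain_dark: bool = True) -> np.ndarray:
    """Centered difference-of-smoothing, mirroring the library's contract."""
    centered = plane - np.median(plane)
    d = centered - gaussian_smooth_brute(centered, sigma)
    return -d if stain_dark else d
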