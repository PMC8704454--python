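"""Deterministic synthetic images and occlusion masks for the completion demos.

The generators emulate the study's test material: a chirped sinusoidal arc
pattern (concentric arcs about the top-left corner whose radial frequency
grows linearly with radius), arc-shaped occluders about the opposite corner,
crossing vertical/horizontal occluding bars, and plain oriented gratings used
as unit fixtures for channel selectivity.

Frequencies here are in cycles per pixel (the carrier is written with an
explicit 2*pi); the matching filter-bank channel frequency is 2*pi times the
cycles-per-pixel value.  All generators are parameter-validated and
deterministic.

Convention: array axis 0 is x, axis 1 is y; the "top-left" corner is index
(0, 0) and "top-right" is (0, N-1) along the y axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "chirped_arcs_image", "occluding_arcs_mask", "crossing_bars_mask",
    "oriented_grating",
]


def _xy(N: int) -> tuple[np.ndarray, np.ndarray]:
    if N < 16:
        raise ValueError("image side N must be >= 16")
    idx = np.arange(N, dtype=float)
    return np.meshgrid(idx, idx, indexing="ij")


def chirped_arcs_image(N: int, f_low: float = 0.23, f_high: float = 0.40) -> np.ndarray:
    """Concentric sinusoidal arcs with linearly increasing radial frequency.

    The pattern is ``0.5 + 0.5 sin(Phi(rho))`` on circles about the top-left
    corner, where the instantaneous radial frequency ``Phi'(rho)/(2 pi)``
    rises linearly from ``f_low`` (cycles/pixel) at the centre to ``f_high``
    at the far corner.
    """
    if not 0 < f_low < f_high:
        raise ValueError("need 0 < f_low < f_high")
    x, y = _xy(N)
    rho = np.hypot(x, y)
    rho_max = np.sqrt(2.0) * (N - 1)
    # Phi(rho) = 2 pi (f_low rho + (f_high - f_low) rho^2 / (2 rho_max))
    phase = 2.0 * np.pi * (f_low * rho + (f_high - f_low) * rho**2 / (2.0 * rho_max))
    return 0.5 + 0.5 * np.sin(phase)


def occluding_arcs_mask(N: int, n_arcs: int = 3, width: int = 3) -> np.ndarray:
    """Annular occluder bands about the top-right corner.

    ``n_arcs`` bands of thickness ``width`` pixels, with radii spread evenly
    between 0.25 N and 0.9 N.  Returns a boolean mask, True = occluded.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if n_arcs < 0:
        raise ValueError("n_arcs must be >= 0")
    x, y = _xy(N)
    rho = np.hypot(x, y - (N - 1.0))
    mask = np.zeros((N, N), dtype=bool)
    if n_arcs == 0:
        return mask
    radii = np.linspace(0.25 * N, 0.9 * N, n_arcs)
    for r in radii:
        mask |= np.abs(rho - r) <= width / 2.0
    return mask


def crossing_bars_mask(N: int, spacing: int = 16, width: int = 3) -> np.ndarray:
    """Union of evenly spaced vertical and horizontal occluding bars.

    Bars of thickness ``width`` start at index ``spacing // 2`` and repeat
    every ``spacing`` pixels along both axes (only bars fully inside the image
    are drawn); where they cross, both cover the pixel.
    """
    if not spacing > width >= 1:
        raise ValueError("need spacing > width >= 1")
    _xy(N)  # validates N
    starts = [s for s in range(spacing // 2, N - width + 1, spacing)]
    mask = np.zeros((N, N), dtype=bool)
    for s in starts:
        mask[s:s + width, :] = True   # bar across y (constant-x band)
        mask[:, s:s + width] = True   # bar across x (constant-y band)
    return mask


def oriented_grating(N: int, theta: float = 0.0, f: float = 0.25,
                     phase: float = 0.0) -> np.ndarray:
    """Plane-wave grating I = 0.5 + 0.5 cos(2 pi f (-x sin th + y cos th) + phase).

    ``f`` is in cycles per pixel and must stay below the Nyquist limit 0.5;
    the matching filter-bank channel has angular frequency ``2 pi f``.
    """
    if not 0 < f < 0.5:
        raise ValueError("grating frequency must lie in (0, 0.5) cycles/pixel")
    x, y = _xy(N)
    arg = 2.0 * np.pi * f * (-x * np.sin(theta) + y * np.cos(theta)) + phase
    return 0.5 + 0.5 * np.cos(arg)
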