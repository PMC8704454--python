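"""Gabor receptive-profile bank over a sampled orientation/frequency/phase grid.

The model treats each simple cell of the primary visual cortex as a linear
filter whose impulse response (*receptive profile*) is a complex Gabor
function

    Psi(dx, dy) = 1/(2 sigma^2) * exp(-i (r . (dx, dy) + phi))
                  * exp(-(dx^2 + dy^2) / (2 sigma^2)),

with wave vector ``r = (-f sin(theta), f cos(theta))``.  A cell is indexed by
its preferred orientation ``theta`` (period pi), its angular spatial frequency
``f`` (radians per pixel, so the carrier wavelength is ``2 pi / f``) and its
reference phase ``phi``; ``sigma`` is the scale of the localizing Gaussian.

The exponent grouping follows one fixed convention: the phase enters as a
multiplicative factor ``exp(-i phi)``.  The opposite sign would merely
conjugate every channel and cancels in the lift/invert round trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureGrid",
    "ReceptiveProfile",
    "FilterBank",
    "make_feature_grid",
    "gabor_profile",
    "build_filter_bank",
    "default_half_width",
]


@dataclass(frozen=True)
class FeatureGrid:
    """Sampled feature axes of the 5D cortical grid.

    Orientations cover ``[0, pi)`` uniformly (``theta_k = k pi / K``),
    frequencies are ``L`` evenly spaced values in ``[f_min, f_max]`` and
    phases are ``phi_m = m * delta_s``.
    """

    K: int
    L: int
    M: int
    theta: np.ndarray = field(repr=False)
    f: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    delta_theta: float
    delta_f: float
    delta_s: float

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1 or self.M < 1:
            raise ValueError("feature counts must be >= 1")
        if np.any(self.f <= 0):
            raise ValueError("frequencies must be positive")
        if self.L > 1 and np.any(np.diff(self.f) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.K * self.L * self.M


def make_feature_grid(
    K: int,
    L: int,
    M: int,
    f_min: float,
    f_max: float,
    s_step: float = np.pi / 8,
) -> FeatureGrid:
    """Build the orientation x frequency x phase sampling grid.

    Parameters
    ----------
    K, L, M
        Number of orientation, frequency and phase samples.
    f_min, f_max
        Frequency band endpoints (angular units, radians/pixel).  For a
        single-frequency grid (``L == 1``) they must coincide.
    s_step
        Phase spacing ``delta_s``; phases are ``{0, s_step, ..., (M-1) s_step}``.
    """
    if K < 1 or L < 1 or M < 1:
        raise ValueError("K, L, M must all be >= 1")
    if f_min <= 0 or f_max <= 0:
        raise ValueError("frequencies must be positive")
    if f_min > f_max:
        raise ValueError(f"f_min={f_min} exceeds f_max={f_max}")
    if L == 1 and f_min != f_max:
        raise ValueError("a single-frequency grid requires f_min == f_max")

    theta = np.arange(K) * (np.pi / K)
    f = np.linspace(f_min, f_max, L)
    phi = np.arange(M) * s_step
    delta_f = (f_max - f_min) / (L - 1) if L > 1 else 1.0
    return FeatureGrid(
        K=K, L=L, M=M, theta=theta, f=f, phi=phi,
        delta_theta=np.pi / K, delta_f=delta_f, delta_s=float(s_step),
    )


@dataclass(frozen=True)
class ReceptiveProfile:
    """One discrete Gabor filter: the complex window on an odd square grid.

    ``window[u, v]`` holds the profile at spatial offset
    ``(dx, dy) = (u - half_width, v - half_width)`` from the cell's centre.
    """

    theta: float
    f: float
    phi: float
    sigma: float
    half_width: int
    window: np.ndarray = field(repr=False)

    @property
    def r(self) -> tuple[float, float]:
        """Wave vector (r1, r2) = (-f sin(theta), f cos(theta))."""
        return (-self.f * np.sin(self.theta), self.f * np.cos(self.theta))

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width + 1)


def default_half_width(sigma: float) -> int:
    """Truncation radius ceil(4 sigma): envelope < 3.4e-4 of peak at the edge."""
    return int(np.ceil(4.0 * sigma))


def gabor_profile(
    theta: float,
    f: float,
    phi: float = 0.0,
    sigma: float = 2.0,
    half_width: int | None = None,
) -> ReceptiveProfile:
    """Sample one Gabor receptive profile on a (2*half_width+1)^2 grid.

    The window is the profile evaluated at phase variable ``s = 0``, which is
    the slice used by the lifting transform.
    """
    if f <= 0:
        raise ValueError("frequency f must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if half_width is None:
        half_width = default_half_width(sigma)
    if half_width < 1:
        raise ValueError("half_width must be >= 1")

    offs = np.arange(-half_width, half_width + 1, dtype=float)
    dx, dy = np.meshgrid(offs, offs, indexing="ij")
    r1, r2 = -f * np.sin(theta), f * np.cos(theta)
    carrier = np.exp(-1j * (r1 * dx + r2 * dy + phi))
    envelope = np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
    window = (1.0 / (2.0 * sigma**2)) * carrier * envelope

    center = 1.0 / (2.0 * sigma**2)
    edge = envelope[0, half_width] * center
    if edge > 1e-3 * center:
        warnings.warn(
            f"half_width={half_width} truncates the Gaussian envelope at "
            f"{edge / center:.2e} of its peak; expect round-trip loss",
            stacklevel=2,
        )
    return ReceptiveProfile(
        theta=float(theta), f=float(f), phi=float(phi), sigma=float(sigma),
        half_width=int(half_width), window=window,
    )


@dataclass(frozen=True)
class FilterBank:
    """All K*L*M receptive profiles on a feature grid.

    Profiles at phases ``phi_m`` differ from the ``phi = 0`` profile only by
    the scalar ``exp(-i phi_m)``; the bank stores the ``phi = 0`` windows as a
    ``(K, L, W, W)`` array and materializes full profiles on demand.
    """

    grid: FeatureGrid
    sigma: float
    half_width: int
    base_windows: np.ndarray = field(repr=False)  # (K, L, W, W), phi = 0

    def __len__(self) -> int:
        return self.grid.n_channels

    def profile(self, k: int, l: int, m: int) -> ReceptiveProfile:
        g = self.grid
        return ReceptiveProfile(
            theta=float(g.theta[k]), f=float(g.f[l]), phi=float(g.phi[m]),
            sigma=self.sigma, half_width=self.half_width,
            window=self.base_windows[k, l] * np.exp(-1j * g.phi[m]),
        )

    def profiles(self):
        """Iterate over all (k, l, m) profiles in C order."""
        g = self.grid
        for k in range(g.K):
            for l in range(g.L):
                for m in range(g.M):
                    yield self.profile(k, l, m)

    def frequency_norm_sq(self, l: int) -> float:
        """L2 norm squared of the frequency-l windows (theta/phi independent)."""
        w = self.base_windows[0, l]
        return float(np.sum(np.abs(w) ** 2))


def build_filter_bank(
    grid: FeatureGrid,
    sigma: float = 2.0,
    half_width: int | None = None,
) -> FilterBank:
    """Construct the discrete Gabor bank for every grid channel."""
    if half_width is None:
        half_width = default_half_width(sigma)
    W = 2 * half_width + 1
    base = np.empty((grid.K, grid.L, W, W), dtype=complex)
    for k in range(grid.K):
        for l in range(grid.L):
            base[k, l] = gabor_profile(
                grid.theta[k], grid.f[l], 0.0, sigma, half_width
            ).window
    return FilterBank(grid=grid, sigma=float(sigma), half_width=int(half_width),
                      base_windows=base)
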