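"""Forward Gabor lift of an image into the 5D cortical grid and its inverse.

The lift computes, for every channel ``(theta_k, f_l, phi_m)``, the output
response of the corresponding simple cell at every pixel:

    O_I[i, j, k, l, m] = sum_{di, dj} Psi_klm(di, dj) * I[i + di, j + dj],

i.e. a cross-correlation of the image with the channel's receptive profile.
Because the phase enters the profile only as the factor ``exp(-i phi_m)``,
only K*L spatial correlations are computed and phases are applied as scalars.

The inverse transform maps evolved responses back to the image plane with the
conjugate kernels, weighting each frequency by ``f_l / ||Psi_{f_l}||^2`` and a
single scalar gain calibrated so that a plane-wave stack round-trips with unit
gain (the discrete, truncated Gabor frame is only approximately tight).

Channels with f > 0 carry no DC: the image mean is removed before the lift,
stored on the response, and restored after inversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .filters import FeatureGrid, FilterBank, make_feature_grid

__all__ = ["LiftedResponse", "lift", "invert", "project",
           "calibration_gain", "save_lifted", "load_lifted"]

_PAD_MODES = {"reflect": "reflect", "periodic": "wrap"}


def _as_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError(f"expected a square 2D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


@dataclass
class LiftedResponse:
    """Complex cell responses on the (x, y, theta, f, phi) grid.

    ``values`` has shape (N, N, K, L, M); ``dc_offset`` is the image mean
    removed before lifting; ``boundary`` records the spatial padding used so
    the inverse can match it.
    """

    values: np.ndarray = field(repr=False)
    grid: FeatureGrid
    dc_offset: float = 0.0
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 5:
            raise ValueError("lifted values must be 5-dimensional")
        if v.shape[2:] != (self.grid.K, self.grid.L, self.grid.M):
            raise ValueError(
                f"lifted shape {v.shape} inconsistent with grid "
                f"(K,L,M)=({self.grid.K},{self.grid.L},{self.grid.M})"
            )

    @property
    def N(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "LiftedResponse":
        return replace(self, values=self.values.copy())


def _check_bank(bank: FilterBank, grid: FeatureGrid) -> None:
    if bank.grid is not grid and (
        bank.grid.K != grid.K or bank.grid.L != grid.L or bank.grid.M != grid.M
        or not np.allclose(bank.grid.f, grid.f)
        or not np.allclose(bank.grid.theta, grid.theta)
        or not np.allclose(bank.grid.phi, grid.phi)
    ):
        raise ValueError("filter bank was not built on the supplied grid")


def lift(
    image: np.ndarray,
    bank: FilterBank,
    grid: FeatureGrid,
    boundary: str = "reflect",
) -> LiftedResponse:
    """Gabor-transform ``image`` into the 5D response field.

    ``boundary`` selects the spatial padding used for pixels whose filter
    support leaves the image: ``reflect`` (default) or ``periodic``.
    """
    _check_bank(bank, grid)
    if boundary not in _PAD_MODES:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    img = _as_image(image)
    N = img.shape[0]
    hw = bank.half_width
    dc = float(img.mean())
    padded = np.pad(img - dc, hw, mode=_PAD_MODES[boundary])

    out = np.empty((N, N, grid.K, grid.L, grid.M), dtype=complex)
    phase_factors = np.exp(-1j * grid.phi)
    for k in range(grid.K):
        for l in range(grid.L):
            w = bank.base_windows[k, l]
            # correlation = convolution with the spatially flipped window
            resp = fftconvolve(padded, w[::-1, ::-1], mode="valid")
            out[:, :, k, l, :] = resp[:, :, None] * phase_factors
    return LiftedResponse(values=out, grid=grid, dc_offset=dc, boundary=boundary)


def _invert_raw(lifted: LiftedResponse, bank: FilterBank) -> np.ndarray:
    """Adjoint-style inverse without gain calibration or DC restoration."""
    grid = lifted.grid
    U = lifted.values
    N = lifted.N
    hw = bank.half_width
    mode = _PAD_MODES[lifted.boundary]

    # phase sum: conj(window_m) = conj(window_0) * exp(+i phi_m)
    U_phased = np.tensordot(U, np.exp(1j * grid.phi), axes=([4], [0]))
    acc = np.zeros((N, N), dtype=complex)
    for l in range(grid.L):
        weight = grid.f[l] / bank.frequency_norm_sq(l)
        for k in range(grid.K):
            w = np.conj(bank.base_windows[k, l])
            padded = np.pad(U_phased[:, :, k, l], hw, mode=mode)
            acc += weight * fftconvolve(padded, w, mode="valid")
    return np.real(acc)


def calibration_gain(bank: FilterBank, grid: FeatureGrid, N: int,
                     boundary: str = "reflect") -> float:
    """Scalar gain making the inverse a left inverse of the lift in the band.

    A calibration image is built as a sum of plane waves, one per sampled
    frequency, at rotating orientations; the gain is the least-squares scale
    between the image and its uncalibrated round trip.  The result depends on
    (grid, sigma, half_width, N, boundary) only and is cached on the bank.
    """
    _check_bank(bank, grid)
    key = (N, boundary)
    cache = getattr(bank, "_gain_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(bank, "_gain_cache", cache)
    if key in cache:
        return cache[key]

    x, y = np.meshgrid(np.arange(N, dtype=float), np.arange(N, dtype=float),
                       indexing="ij")
    cal = np.zeros((N, N))
    thetas = np.linspace(0.0, np.pi, grid.L, endpoint=False)
    for l, f in enumerate(grid.f):
        th = thetas[l]
        cal += np.cos(f * (-x * np.sin(th) + y * np.cos(th)) + 0.7 * l)
    cal -= cal.mean()

    rt = _invert_raw(lift(cal, bank, grid, boundary=boundary), bank)
    denom = float(np.sum(rt * rt))
    if denom == 0.0:
        raise RuntimeError("degenerate calibration: zero round-trip energy")
    gain = float(np.sum(cal * rt)) / denom
    cache[key] = gain
    return gain


def invert(lifted: LiftedResponse, bank: FilterBank, grid: FeatureGrid) -> np.ndarray:
    """Inverse Gabor transform of a (possibly evolved) 5D response field.

    Valid for multi-frequency grids (L >= 2); the single-frequency lift loses
    the out-of-band content, so its readout is :func:`project` instead.
    """
    _check_bank(bank, grid)
    if grid.L < 2:
        raise ValueError("exact inversion requires L >= 2; use project() for L == 1")
    gain = calibration_gain(bank, grid, lifted.N, lifted.boundary)
    return gain * _invert_raw(lifted, bank) + lifted.dc_offset


def project(lifted: LiftedResponse) -> np.ndarray:
    """Single-frequency readout: real channel sum, rescaled linearly to [0,1].

    Sums the responses over orientation, frequency and phase per pixel and
    maps the result affinely onto [0, 1] (a constant projection maps to 0.5).
    """
    proj = np.real(lifted.values.sum(axis=(2, 3, 4)))
    lo, hi = proj.min(), proj.max()
    if hi - lo < 1e-15:
        return np.full_like(proj, 0.5)
    return (proj - lo) / (hi - lo)


def save_lifted(lifted: LiftedResponse, path: str) -> None:
    """Save a lifted response as one .npz plus grid metadata (lossless)."""
    meta = {
        "K": lifted.grid.K, "L": lifted.grid.L, "M": lifted.grid.M,
        "f_min": float(lifted.grid.f[0]), "f_max": float(lifted.grid.f[-1]),
        "s_step": float(lifted.grid.delta_s),
        "dc_offset": lifted.dc_offset, "boundary": lifted.boundary,
    }
    np.savez_compressed(path, values=lifted.values,
                        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_lifted(path: str) -> LiftedResponse:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        grid = make_feature_grid(meta["K"], meta["L"], meta["M"],
                                 meta["f_min"], meta["f_max"], meta["s_step"])
        return LiftedResponse(values=data["values"], grid=grid,
                              dc_offset=meta["dc_offset"], boundary=meta["boundary"])
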