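"""Sub-Riemannian diffusion of lifted responses on the 5D cortical grid.

The diffusion operator is built from the second-order horizontal derivatives

    L  = X1^2 + b2^2 X2^2 + b3^2 X3^2 + b4^2 X4^2        (exact, 5D)
    L~ = X1^2 + b2^2 X2^2                                 (approximate, per
                                                           frequency/phase
                                                           channel, SE(2))

with unit-coherence coefficients b2 = K/N^2, b3 = L/N^2, b4 = M/N^2.  The
spatial second derivatives X1X1 and the spatial part of X3X3 are central
differences along the rotated unit offsets

    e_xi  = (cos theta_k, sin theta_k),   e_eta = (-sin theta_k, cos theta_k),

whose off-grid samples are obtained by B-spline interpolation (replicate
spatial boundary).  The orientation axis wraps with period pi, the phase axis
wraps, and the frequency axis wraps by default (a reflecting option exists
because wrapping couples the extreme scales).

X3 contains the shear ``f d_s``; its square expands to

    X3X3 = D_eta_eta + 2 f D_{eta,s} + f^2 D_ss,

implemented with centered (and centered-mixed) differences.  A combined-offset
form sampling along the full X3 direction is provided for cross-validation.

The corrupted sub-region of the grid evolves by explicit Euler steps while the
known responses are re-imposed after every step (Dirichlet boundary data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .filters import FeatureGrid
from .lifting import LiftedResponse

__all__ = [
    "DiffusionConfig", "DiffusionRun",
    "coherence_coefficients", "offset_vectors", "spline_sample",
    "second_derivatives", "x3x3_combined_offset", "apply_operator",
    "euler_step", "run_diffusion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffusionConfig:
    """Settings of the diffusion solver.

    ``mode`` selects the exact 5D operator or the per-channel SE(2)
    approximation; ``beta*`` override the derived unit-coherence coefficients
    when given.  ``stop_tol`` enables an early steady-state stop on the
    relative per-step change.
    """

    mode: str = "exact"
    dt: float = 0.1
    T: float = 10.0
    beta2: float | None = None
    beta3: float | None = None
    beta4: float | None = None
    spline_order: int = 3
    freq_boundary: str = "wrap"
    stop_tol: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "approximate"):
            raise ValueError("mode must be 'exact' or 'approximate'")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < self.dt:
            raise ValueError("T must be >= dt")
        if self.spline_order not in (1, 2, 3):
            raise ValueError("spline_order must be 1, 2 or 3")
        if self.freq_boundary not in ("wrap", "reflect"):
            raise ValueError("freq_boundary must be 'wrap' or 'reflect'")
        for b in (self.beta2, self.beta3, self.beta4):
            if b is not None and b <= 0:
                raise ValueError("beta overrides must be positive")

    def betas(self, N: int, grid: FeatureGrid) -> tuple[float, float, float]:
        b2, b3, b4 = coherence_coefficients(N, grid.K, grid.L, grid.M)
        return (self.beta2 or b2, self.beta3 or b3, self.beta4 or b4)


def coherence_coefficients(N: int, K: int, L: int, M: int) -> tuple[float, float, float]:
    """Unit-coherence coefficients (b2, b3, b4) = (K, L, M) / N^2."""
    if min(N, K, L, M) < 1:
        raise ValueError("all counts must be >= 1")
    return (K / N**2, L / N**2, M / N**2)


def offset_vectors(theta_k: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotated unit stencil offsets (e_xi, e_eta) for orientation theta_k."""
    c, s = np.cos(theta_k), np.sin(theta_k)
    return np.array([c, s]), np.array([-s, c])


# ---------------------------------------------------------------------------
# B-spline fractional shifts (vectorized over trailing axes)

def _bspline_value(order: int, s: np.ndarray | float) -> np.ndarray | float:
    a = abs(s)
    if order == 1:
        return max(1.0 - a, 0.0)
    if order == 2:
        if a < 0.5:
            return 0.75 - a * a
        if a < 1.5:
            return 0.5 * (a - 1.5) ** 2
        return 0.0
    if order == 3:
        if a < 1.0:
            return 2.0 / 3.0 - a * a + 0.5 * a**3
        if a < 2.0:
            return (2.0 - a) ** 3 / 6.0
        return 0.0
    raise ValueError("spline order must be 1, 2 or 3")


def _prefilter_xy(u: np.ndarray, order: int) -> np.ndarray:
    """Spline-prefilter along the two leading (spatial) axes only."""
    if order < 2:
        return u
    c = ndimage.spline_filter1d(u, order=order, axis=0, mode="nearest",
                                output=complex if np.iscomplexobj(u) else float)
    return ndimage.spline_filter1d(c, order=order, axis=1, mode="nearest",
                                   output=c.dtype)


def _shift_axis(c: np.ndarray, delta: float, axis: int, order: int) -> np.ndarray:
    """Evaluate the spline (coefficients ``c``) at positions i + delta along axis."""
    n = c.shape[axis]
    base = math.floor(delta)
    t = delta - base
    idx0 = np.arange(n) + base
    out = None
    for m in (-1, 0, 1, 2):
        w = _bspline_value(order, t - m)
        if w == 0.0:
            continue
        taken = np.take(c, np.clip(idx0 + m, 0, n - 1), axis=axis)
        out = w * taken if out is None else out + w * taken
    return out


def _shift2d(c_xy: np.ndarray, dx: float, dy: float, order: int) -> np.ndarray:
    """Sample a field (prefiltered on axes 0,1) at (i+dx, j+dy)."""
    return _shift_axis(_shift_axis(c_xy, dx, 0, order), dy, 1, order)


def spline_sample(u_slice: np.ndarray, points, order: int = 3) -> np.ndarray:
    """B-spline interpolate a 2D field at fractional (x, y) points.

    Reproduces grid values exactly at grid nodes and polynomials up to the
    spline order.  Points may lie at most 2 pixels outside the grid (the
    replicate-padded domain); farther points raise.
    """
    u_slice = np.asarray(u_slice)
    if u_slice.ndim != 2:
        raise ValueError("u_slice must be 2D")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n0, n1 = u_slice.shape
    if (pts[:, 0].min() < -2 or pts[:, 0].max() > n0 + 1
            or pts[:, 1].min() < -2 or pts[:, 1].max() > n1 + 1):
        raise ValueError("sample point outside the padded domain")
    return ndimage.map_coordinates(u_slice, pts.T, order=order,
                                   mode="nearest", prefilter=True)


# ---------------------------------------------------------------------------
# Horizontal second-difference stencils

def _as_values(u) -> np.ndarray:
    if isinstance(u, LiftedResponse):
        return u.values
    return np.asarray(u)


def _second_diff_freq(u: np.ndarray, delta_f: float, boundary: str) -> np.ndarray:
    """Centered second difference along the frequency axis (axis 3)."""
    if u.shape[3] == 1:
        return np.zeros_like(u)
    if boundary == "wrap":
        up = np.roll(u, -1, axis=3)
        dn = np.roll(u, 1, axis=3)
    else:  # reflect
        padded = np.pad(u, ((0, 0),) * 3 + ((1, 1),) + ((0, 0),), mode="reflect")
        up = padded[:, :, :, 2:, :]
        dn = padded[:, :, :, :-2, :]
    return (up - 2.0 * u + dn) / delta_f**2


def _horizontal_diffs(u: np.ndarray, grid: FeatureGrid, config: DiffusionConfig,
                      exact: bool) -> dict[str, np.ndarray]:
    """Compute D11, D22 (and D33, D44 when ``exact``) for a 5D field."""
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite values in the diffused field")
    order = config.spline_order
    c = _prefilter_xy(u, order)

    D11 = np.empty_like(u)
    D33 = np.empty_like(u) if exact else None
    f_bc = grid.f[None, None, :, None]  # broadcast over (N, N, L, M) blocks
    ds = grid.delta_s

    for k in range(grid.K):
        ex, ee = offset_vectors(grid.theta[k])
        ck = c[:, :, k]
        uk = u[:, :, k]
        sxp = _shift2d(ck, ex[0], ex[1], order)
        sxm = _shift2d(ck, -ex[0], -ex[1], order)
        D11[:, :, k] = sxp - 2.0 * uk + sxm
        if not exact:
            continue
        sep = _shift2d(ck, ee[0], ee[1], order)
        sem = _shift2d(ck, -ee[0], -ee[1], order)
        d_ee = sep - 2.0 * uk + sem
        # phase axis (last axis of the k-block) wraps
        up = np.roll(uk, -1, axis=-1)
        dn = np.roll(uk, 1, axis=-1)
        d_ss = (up - 2.0 * uk + dn) / ds**2
        d_es = (
            np.roll(sep, -1, axis=-1) - np.roll(sem, -1, axis=-1)
            - np.roll(sep, 1, axis=-1) + np.roll(sem, 1, axis=-1)
        ) / (4.0 * ds)
        D33[:, :, k] = d_ee + 2.0 * f_bc * d_es + f_bc**2 * d_ss

    if grid.K > 1:
        D22 = (np.roll(u, -1, axis=2) - 2.0 * u + np.roll(u, 1, axis=2)) \
            / grid.delta_theta**2
    else:
        D22 = np.zeros_like(u)

    out = {"D11": D11, "D22": D22}
    if exact:
        out["D33"] = D33
        out["D44"] = _second_diff_freq(u, grid.delta_f, config.freq_boundary)
    return out


def second_derivatives(u, grid: FeatureGrid,
                       config: DiffusionConfig | None = None):
    """The four horizontal second-derivative fields (D11, D22, D33, D44)."""
    config = config or DiffusionConfig()
    d = _horizontal_diffs(_as_values(u), grid, config, exact=True)
    return d["D11"], d["D22"], d["D33"], d["D44"]


def x3x3_combined_offset(u, grid: FeatureGrid, eps: float = 1.0,
                         order: int = 3) -> np.ndarray:
    """X3X3 via a single directional stencil [u(p+eps*v) - 2u(p) + u(p-eps*v)]/eps^2.

    The offset v follows the full X3 direction (-sin th, cos th, f d_s), so the
    phase axis is interpolated fractionally (periodic).  Serves as an
    independent check of the expanded stencil in :func:`second_derivatives`.
    """
    u = _as_values(u)
    N = u.shape[0]
    M = grid.M
    out = np.empty_like(u)
    pad = max(4, int(np.ceil(eps * grid.f[-1] / grid.delta_s)) + order)
    x, y, m = np.meshgrid(np.arange(N, dtype=float), np.arange(N, dtype=float),
                          np.arange(M, dtype=float), indexing="ij")
    for k in range(grid.K):
        vx, vy = -np.sin(grid.theta[k]), np.cos(grid.theta[k])
        for l in range(grid.L):
            vs = grid.f[l] / grid.delta_s
            block = u[:, :, k, l, :]
            # periodic extension along the phase axis, replicate spatially
            ext = np.concatenate([block[..., -pad:], block, block[..., :pad]],
                                 axis=-1) if M > 1 else np.repeat(block, 2 * pad + 1, -1)
            def samp(sign):
                coords = np.stack([x + sign * eps * vx, y + sign * eps * vy,
                                   m + pad + sign * eps * vs])
                re = ndimage.map_coordinates(ext.real, coords, order=order,
                                             mode="nearest")
                im = ndimage.map_coordinates(ext.imag, coords, order=order,
                                             mode="nearest") if np.iscomplexobj(ext) else 0
                return re + 1j * im if np.iscomplexobj(ext) else re
            out[:, :, k, l, :] = (samp(+1) - 2.0 * block + samp(-1)) / eps**2
    return out


def apply_operator(u, grid: FeatureGrid, config: DiffusionConfig) -> np.ndarray:
    """Evaluate L u (exact mode) or L~ u (approximate mode)."""
    values = _as_values(u)
    exact = config.mode == "exact"
    b2, b3, b4 = config.betas(values.shape[0], grid)
    d = _horizontal_diffs(values, grid, config, exact=exact)
    out = d["D11"] + b2**2 * d["D22"]
    if exact:
        out += b3**2 * d["D33"] + b4**2 * d["D44"]
    return out


def euler_step(u: np.ndarray, u0: np.ndarray, mask: np.ndarray,
               grid: FeatureGrid, config: DiffusionConfig) -> np.ndarray:
    """One explicit Euler step with Dirichlet restoration of known responses.

    ``mask`` is True on the corrupted sub-region (which diffuses); everywhere
    else the initial responses ``u0`` are re-imposed.
    """
    if u.shape != u0.shape or mask.shape != u.shape:
        raise ValueError("u, u0 and mask shapes must agree")
    new = u + config.dt * apply_operator(u, grid, config)
    if not np.all(np.isfinite(new)):
        raise FloatingPointError(
            "diffusion produced non-finite values; reduce dt "
            f"(currently {config.dt})"
        )
    np.copyto(new, u0, where=~mask)
    return new


@dataclass
class DiffusionRun:
    """Evolved responses plus per-iteration relative-change and amplitude data.

    ``amplification`` is max over all iterations of sup|u| / sup|u0| — the
    scheme obeys a near-maximum principle, so values stay close to 1.
    """

    response: LiftedResponse
    changes: np.ndarray = field(repr=False)
    iterations: int
    amplification: float = 1.0


def run_diffusion(u0: LiftedResponse, mask: np.ndarray, grid: FeatureGrid,
                  config: DiffusionConfig) -> DiffusionRun:
    """Iterate the explicit scheme until time T (or early steady state).

    The number of steps is ceil(T / dt); with an empty corrupted region the
    input is returned unchanged (every grid point is boundary data).
    """
    base = u0.values
    if mask.shape != base.shape:
        raise ValueError(
            f"lifted mask shape {mask.shape} != response shape {base.shape}")
    n_steps = int(math.ceil(config.T / config.dt - 1e-12))
    if not mask.any():
        return DiffusionRun(response=u0.copy(), changes=np.zeros(0), iterations=0)

    ref = np.linalg.norm(base) + 1e-30
    sup0 = np.abs(base).max() + 1e-30
    u = base.copy()
    changes = []
    sup_max = sup0
    for v in range(n_steps):
        new = euler_step(u, base, mask, grid, config)
        rel = np.linalg.norm(new - u) / ref
        changes.append(rel)
        sup_max = max(sup_max, np.abs(new).max())
        logger.info("diffusion step %d/%d: relative change %.3e", v + 1, n_steps, rel)
        u = new
        if config.stop_tol is not None and rel < config.stop_tol:
            break
    evolved = LiftedResponse(values=u, grid=grid, dc_offset=u0.dc_offset,
                             boundary=u0.boundary)
    return DiffusionRun(response=evolved, changes=np.array(changes),
                        iterations=len(changes), amplification=float(sup_max / sup0))
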