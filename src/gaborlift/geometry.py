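"""The 5D sub-Riemannian frame of the cortical model and its integral curves.

Points live in Q = R^2 x S^1 x R^+ x S^1 with coordinates
(q1, q2, theta, f, phi).  The contact one-form

    Theta = -f sin(theta) dx + f cos(theta) dy - ds

annihilates the four horizontal vector fields

    X1 = cos(theta) dx + sin(theta) dy
    X2 = d_theta
    X3 = -sin(theta) dx + cos(theta) dy + f d_s
    X4 = d_f .

Their only nonzero commutators are [X1,X2], [X2,X3] (spatial rotations of
each other) and [X3,X4] = -d_s; together with [X1,X2] the frame spans the
full 5D tangent space at every point (the bracket-generating / Hörmander
property), so any two cortical points are joined by a horizontal curve.

Horizontal integral curves solve gamma' = (X1 + c2 X2 + c3 X3 + c4 X4) with
constant coefficients; their spatial projections reproduce the association
fields of contour grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorticalPoint", "HorizontalCurve",
    "one_form", "one_form_pairing", "horizontal_frame",
    "lie_bracket_numeric", "span_rank", "integrate_curve", "curve_fan",
]


@dataclass(frozen=True)
class CorticalPoint:
    """A point (q1, q2, theta, f, phi) of the 5D cortical geometry."""

    q1: float
    q2: float
    theta: float
    f: float
    phi: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("frequency coordinate f must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.theta, self.f, self.phi])

    @staticmethod
    def from_array(a: np.ndarray) -> "CorticalPoint":
        return CorticalPoint(*(float(v) for v in a))


@dataclass(frozen=True)
class HorizontalCurve:
    """An integrated horizontal curve: states (n_steps+1, 5) at uniform times."""

    states: np.ndarray = field(repr=False)
    times: np.ndarray = field(repr=False)
    c2: float
    c3: float
    c4: float

    @property
    def endpoint(self) -> CorticalPoint:
        return CorticalPoint.from_array(self.states[-1])

    @property
    def spatial(self) -> np.ndarray:
        """(n, 2) projection onto the image plane."""
        return self.states[:, :2]


def one_form(theta: float, f: float) -> tuple[float, float, float]:
    """Coefficients (a_dx, a_dy, a_ds) of the contact form Theta at (theta, f)."""
    if f <= 0:
        raise ValueError("frequency f must be positive")
    return (-f * np.sin(theta), f * np.cos(theta), -1.0)


def one_form_pairing(theta: float, f: float, vec: np.ndarray) -> float:
    """Theta applied to a 5-vector (dx, dy, dtheta, df, ds components)."""
    a_dx, a_dy, a_ds = one_form(theta, f)
    return a_dx * vec[0] + a_dy * vec[1] + a_ds * vec[4]


def horizontal_frame(point: CorticalPoint) -> np.ndarray:
    """The four horizontal fields at ``point`` as rows of a (4, 5) array."""
    th, f = point.theta, point.f
    return np.array([
        [np.cos(th), np.sin(th), 0.0, 0.0, 0.0],   # X1
        [0.0, 0.0, 1.0, 0.0, 0.0],                 # X2
        [-np.sin(th), np.cos(th), 0.0, 0.0, f],    # X3
        [0.0, 0.0, 0.0, 1.0, 0.0],                 # X4
    ])


def _field_at(i: int, p: np.ndarray) -> np.ndarray:
    """Horizontal field X_i (i in 1..4) at coordinate array p."""
    th, f = p[2], p[3]
    if i == 1:
        return np.array([np.cos(th), np.sin(th), 0.0, 0.0, 0.0])
    if i == 2:
        return np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    if i == 3:
        return np.array([-np.sin(th), np.cos(th), 0.0, 0.0, f])
    if i == 4:
        return np.array([0.0, 0.0, 0.0, 1.0, 0.0])
    raise ValueError("field index must be in 1..4")


def lie_bracket_numeric(
    i: int,
    j: int,
    point: CorticalPoint,
    test_fn=None,
    h: float = 1e-3,
):
    """Finite-difference Lie bracket [X_i, X_j] at ``point``.

    The bracket acts on a smooth test function g as X_i(X_j g) - X_j(X_i g);
    directional derivatives are taken with second-order central differences of
    step ``h``.  With ``test_fn=None`` the bracket is applied to the five
    coordinate functions, recovering the bracket's components as a 5-vector;
    otherwise the scalar action on ``test_fn`` is returned.
    """
    if h <= 0:
        raise ValueError("finite-difference step h must be positive")
    p0 = point.as_array()

    def directional(g, idx, p):
        X = _field_at(idx, p)
        return (g(p + h * X) - g(p - h * X)) / (2.0 * h)

    def commutator(g):
        return (directional(lambda p: directional(g, j, p), i, p0)
                - directional(lambda p: directional(g, i, p), j, p0))

    if test_fn is not None:
        return commutator(test_fn)
    return np.array([commutator(lambda p, c=c: p[c]) for c in range(5)])


def span_rank(point: CorticalPoint) -> int:
    """Rank of {X1..X4, [X1,X2]}; equals 5 everywhere (Hörmander condition)."""
    th = point.theta
    bracket = np.array([np.sin(th), -np.cos(th), 0.0, 0.0, 0.0])
    mat = np.vstack([horizontal_frame(point), bracket])
    return int(np.linalg.matrix_rank(mat))


def integrate_curve(
    initial: CorticalPoint,
    c2: float = 0.0,
    c3: float = 0.0,
    c4: float = 0.0,
    T: float = 1.0,
    dt: float | None = None,
    c1: float = 1.0,
) -> HorizontalCurve:
    """RK4 integration of gamma' = (c1 X1 + c2 X2 + c3 X3 + c4 X4)(gamma).

    The spatial-advance coefficient c1 defaults to 1 (unit-speed along the
    preferred orientation); set it to 0 for pure X3/X4-type flows.  Default
    step is T/1000; curves are used for validation and association-field
    visualization, not in the completion hot path.
    """
    if T <= 0:
        raise ValueError("final time T must be positive")
    if dt is None:
        dt = 1e-3 * T
    if dt <= 0:
        raise ValueError("dt must be positive")

    def rhs(p: np.ndarray) -> np.ndarray:
        return (c1 * _field_at(1, p) + c2 * _field_at(2, p)
                + c3 * _field_at(3, p) + c4 * _field_at(4, p))

    n = int(np.ceil(T / dt - 1e-12))
    dt = T / n
    states = np.empty((n + 1, 5))
    states[0] = initial.as_array()
    p = states[0].copy()
    for step in range(n):
        k1 = rhs(p)
        k2 = rhs(p + 0.5 * dt * k1)
        k3 = rhs(p + 0.5 * dt * k2)
        k4 = rhs(p + dt * k3)
        p = p + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        states[step + 1] = p
    return HorizontalCurve(states=states, times=np.linspace(0.0, T, n + 1),
                           c2=float(c2), c3=float(c3), c4=float(c4))


def curve_fan(
    initial: CorticalPoint,
    c_values,
    T: float = 1.0,
    dt: float | None = None,
    vary: str = "c2",
    **base,
) -> list[HorizontalCurve]:
    """A fan of horizontal curves with one coefficient swept over ``c_values``.

    ``vary`` selects which coefficient is swept ('c2', 'c3' or 'c4'); the
    remaining coefficients come from ``base`` (c1 defaults to 1, others to 0),
    so a pure X3 + c4 X4 fan is ``curve_fan(p, cs, vary="c4", c1=0, c3=1)``.
    Spatial projections of a c2-fan reproduce the association-field pattern.
    """
    c_values = list(c_values)
    if not c_values:
        raise ValueError("c_values must be non-empty")
    if vary not in ("c2", "c3", "c4"):
        raise ValueError("vary must be one of 'c2', 'c3', 'c4'")
    fans = []
    for c in c_values:
        kwargs = {"c2": 0.0, "c3": 0.0, "c4": 0.0, **base, vary: float(c)}
        fans.append(integrate_curve(initial, T=T, dt=dt, **kwargs))
    return fans
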