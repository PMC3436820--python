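"""Cubic-spline input representation with curvature penalty.

Time-dependent stimuli (ligand or receptor activity measured at a handful
of time points) are represented as natural cubic splines parametrized by
their *control points* — the spline values at the measurement times.  The
control points are what the joint estimator optimizes, so everything here
is written in terms of the value-at-knot parametrization:

* ``interpolating_spline`` — natural cubic interpolant through the points.
* ``smoothing_spline`` — minimizer of the penalized weighted least squares
  criterion  sum_i ((S(t_i)-y_i)/sigma_i)^2 + lambda * int (S''(t))^2 dt
  over natural cubic splines, returned via its values at the knots.
* ``curvature_penalty`` — the exact integral of the squared second
  derivative (closed form; S'' is piecewise linear).
* ``select_lambda`` — discrepancy-principle choice of the smoothing
  parameter from a chi-square criterion.

When ``log_scale`` is set the spline lives on the log10-input scale and
evaluation returns ``10**S(t)``, which keeps the reconstructed input
strictly positive between measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, CubicSpline
from scipy.stats import chi2

__all__ = [
    "InputSpline",
    "bspline_basis",
    "interpolating_spline",
    "smoothing_spline",
    "select_lambda",
    "curvature_penalty",
    "curvature_matrix",
    "penalty_root",
]


@dataclass
class InputSpline:
    """A natural cubic spline defined by knots and control points.

    Parameters
    ----------
    knots : array
        Strictly increasing measurement times ``t_1 .. t_N``.
    control_points : array
        Spline values at the knots, ``v_i = S(t_i)``.  On the log10-input
        scale when ``log_scale`` is set.
    degree : int
        Polynomial degree; only cubic (3) splines are constructed here.
    lam : float
        Smoothing parameter the control points were obtained with
        (0 for plain interpolation); metadata, not used in evaluation.
    log_scale : bool
        If set, :meth:`__call__` returns ``10**S(t)``.

    Outside ``[t_1, t_N]`` the spline is continued as a constant at the
    boundary value, so ODE integrators may step marginally outside the
    data window without extrapolation blow-up.
    """

    knots: np.ndarray
    control_points: np.ndarray
    degree: int = 3
    lam: float = 0.0
    log_scale: bool = False
    _pp: CubicSpline = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.knots.ndim != 1 or self.knots.size < 2:
            raise ValueError("need at least two knots")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.control_points.shape != self.knots.shape:
            raise ValueError("control_points must match knots in length")
        self._pp = CubicSpline(self.knots, self.control_points, bc_type="natural")

    # -- evaluation ---------------------------------------------------

    def log_value(self, t):
        """Value of the underlying spline S(t) (before any 10** transform)."""
        t = np.clip(np.asarray(t, dtype=float), self.knots[0], self.knots[-1])
        return self._pp(t)

    def __call__(self, t):
        """Input value at time ``t`` (natural scale if ``log_scale``)."""
        s = self.log_value(t)
        return 10.0 ** s if self.log_scale else s

    def second_derivative(self, t):
        t = np.asarray(t, dtype=float)
        inside = (t >= self.knots[0]) & (t <= self.knots[-1])
        return np.where(inside, self._pp(np.clip(t, self.knots[0], self.knots[-1]), 2), 0.0)

    def ppoly_arrays(self):
        """(breakpoints, 4 x m coefficient matrix) of the cubic pieces."""
        return self._pp.x, self._pp.c

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "knots": self.knots.tolist(),
            "control_points": self.control_points.tolist(),
            "degree": self.degree,
            "lambda": self.lam,
            "log_scale": self.log_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InputSpline":
        return cls(
            knots=np.asarray(d["knots"], dtype=float),
            control_points=np.asarray(d["control_points"], dtype=float),
            degree=int(d.get("degree", 3)),
            lam=float(d.get("lambda", 0.0)),
            log_scale=bool(d.get("log_scale", False)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "InputSpline":
        return cls.from_dict(json.loads(s))


def bspline_basis(knots, degree, t):
    """Evaluate all B-spline basis functions at ``t``.

    The knot vector is clamped (first and last knot repeated ``degree+1``
    times), so the basis functions form a partition of unity on
    ``[knots[0], knots[-1]]``.  Returns the vector ``b_{i,p}(t)`` for all
    ``i``; length is ``N + degree - 1`` for ``N`` interior knots.
    """
    knots = np.asarray(knots, dtype=float)
    if degree < 0:
        raise ValueError("degree must be non-negative")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    t = float(t)
    if t < knots[0] or t > knots[-1]:
        raise ValueError(f"t={t} outside the basis support [{knots[0]}, {knots[-1]}]")
    kv = np.concatenate([np.repeat(knots[0], degree), knots, np.repeat(knots[-1], degree)])
    # design_matrix rejects t == last knot unless extrapolate; nudge inside.
    tq = min(t, np.nextafter(knots[-1], knots[0])) if t == knots[-1] else t
    row = BSpline.design_matrix(np.asarray([tq]), kv, degree).toarray()[0]
    return row


def interpolating_spline(times, values, log_scale: bool = False) -> InputSpline:
    """Natural cubic spline through ``(times, values)`` exactly.

    Curvature vanishes at both end points (S''(t_1) = S''(t_N) = 0).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    return InputSpline(times, values, degree=3, lam=0.0, log_scale=log_scale)


def _gs_matrices(knots: np.ndarray):
    """Green–Silverman Q (N x N-2) and R (N-2 x N-2) matrices.

    For a natural cubic spline with values g at the knots, the roughness
    integral is g' K g with K = Q R^{-1} Q'.
    """
    h = np.diff(knots)
    n = knots.size
    if n < 3:
        return np.zeros((n, 0)), np.zeros((0, 0))
    q = np.zeros((n, n - 2))
    r = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        q[j - 1, j - 1] = 1.0 / h[j - 1]
        q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        q[j + 1, j - 1] = 1.0 / h[j]
        r[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            r[j - 1, j] = h[j] / 6.0
            r[j, j - 1] = h[j] / 6.0
    return q, r


def curvature_matrix(knots) -> np.ndarray:
    """Penalty matrix K with  int (S'')^2 dt = v' K v  for control points v."""
    knots = np.asarray(knots, dtype=float)
    q, r = _gs_matrices(knots)
    if r.size == 0:
        return np.zeros((knots.size, knots.size))
    return q @ np.linalg.solve(r, q.T)


def penalty_root(knots) -> np.ndarray:
    """Matrix L with K = L L', for folding the penalty into residuals.

    The pseudo-residual block of the joint objective is sqrt(lambda) * L' v;
    its squared norm is exactly lambda * v' K v.  L has N-2 columns (K has a
    two-dimensional null space: straight lines are penalty-free).
    """
    k = curvature_matrix(knots)
    w, v = np.linalg.eigh(k)
    keep = w > max(w.max(), 1.0) * 1e-12 if w.size else np.zeros(0, bool)
    return v[:, keep] * np.sqrt(w[keep])


def curvature_penalty(spline: InputSpline) -> float:
    """Exact integral of (S'')^2 over the knot span.

    S'' is piecewise linear with values m_i at the knots, so per interval
    the integral is h/3 (m_i^2 + m_i m_{i+1} + m_{i+1}^2).
    """
    m = spline._pp(spline.knots, 2)
    h = np.diff(spline.knots)
    return float(np.sum(h / 3.0 * (m[:-1] ** 2 + m[:-1] * m[1:] + m[1:] ** 2)))


def smoothing_spline(times, values, sigmas=None, lam: float = 0.0,
                     log_scale: bool = False) -> InputSpline:
    """Weighted natural cubic smoothing spline.

    Minimizes ``sum_i ((S(t_i)-y_i)/sigma_i)^2 + lam * int (S'')^2`` over
    all natural cubic splines; the minimizer is itself a natural cubic
    spline with knots at the data times, returned through its values at
    the knots (the control points).  ``lam=0`` reproduces the
    interpolating spline; ``lam -> inf`` tends to the sigma-weighted
    straight-line fit.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if sigmas is None:
        sigmas = np.ones_like(values)
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be positive")
    if lam == 0:
        return interpolating_spline(times, values, log_scale=log_scale)
    # Reinsch formulation: with gamma the interior knot curvatures,
    # (R + lam Q' W^-1 Q) gamma = Q' y  and  g = y - lam W^-1 Q gamma.
    # Solved for gamma at small lam and for delta = lam*gamma at large lam,
    # which keeps both the interpolation and the straight-line limit
    # numerically clean.
    winv = sigmas**2
    q, r = _gs_matrices(times)
    a = q.T @ (winv[:, None] * q)
    b = q.T @ values
    if lam >= 1.0:
        delta = np.linalg.solve(r / lam + a, b)
    else:
        delta = lam * np.linalg.solve(r + lam * a, b)
    g = values - winv * (q @ delta)
    return InputSpline(times, g, degree=3, lam=lam, log_scale=log_scale)


def weighted_rss(spline: InputSpline, times, values, sigmas) -> float:
    """Weighted residual sum of squares of the spline against the data."""
    r = spline.log_value(np.asarray(times, dtype=float))
    return float(np.sum(((r - np.asarray(values)) / np.asarray(sigmas)) ** 2))


def select_lambda(times, values, sigmas, grid=None) -> float:
    """Choose the smoothing parameter by the discrepancy principle.

    Returns the largest lambda on a log-spaced grid whose smoothing spline
    keeps the weighted residual sum of squares at or below the median of
    the chi-square distribution with N degrees of freedom.  Intuition: the
    spline should sit as smooth as the noise level allows — residuals of
    the size the measurement errors predict, but no larger.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if times.size < 4:
        raise ValueError("need at least 4 points to select lambda")
    if grid is None:
        grid = np.logspace(-6, 6, 25)
    bound = chi2.ppf(0.5, df=times.size)
    best = None
    for lam in np.sort(np.asarray(grid, dtype=float)):
        sp = smoothing_spline(times, values, sigmas, lam=lam)
        if weighted_rss(sp, times, values, sigmas) <= bound:
            best = lam
    if best is None:
        # RSS(lambda -> 0) -> 0 < bound, so an interpolation-level lambda
        # always qualifies; reaching here means the grid excluded it.
        raise RuntimeError("no lambda on the grid satisfies the chi-square bound")
    return float(best)
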