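"""Profile likelihood and likelihood-based confidence intervals.

For one parameter at a time, the objective is re-minimized over all other
free parameters (including input control points in the joint mode) while
the target parameter walks away from its MLE in adaptive steps.  The
profile crosses the threshold chi2(MLE) + Delta_alpha — with Delta_alpha
the alpha-quantile of the chi-square distribution with one degree of
freedom (point-wise convention, 3.841 at 95%) — at the confidence bounds.
A profile that reaches the box bound while still below the threshold
yields an *open* interval (upper bound infinity / lower bound 0 on the
natural scale), the signature of practical non-identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2

__all__ = ["ProfileCurve", "profile", "confidence_interval"]


@dataclass
class ProfileCurve:
    """One likelihood profile with its confidence bounds.

    Grid and bounds are on the fitting (log10) scale; ``ci_lower`` /
    ``ci_upper`` convert to the natural scale when the parameter is
    log10-flagged (open ends become 0 / inf).  A side whose walk ended
    without either crossing the threshold or hitting a bound is flagged
    *not determined* (NaN) — distinct from an open interval.
    """

    parameter: str
    grid: np.ndarray
    values: np.ndarray
    alpha: float
    threshold: float
    mle: float
    fmin: float
    is_log10: bool
    lower_open: bool = False
    upper_open: bool = False
    lower_determined: bool = True
    upper_determined: bool = True

    def _crossings(self, threshold: float):
        limit = self.fmin + threshold
        g, v = self.grid, self.values
        i_mle = int(np.argmin(np.abs(g - self.mle)))
        lo = hi = self.mle
        lo_found = hi_found = False
        for i in range(i_mle, 0, -1):
            if v[i - 1] > limit >= v[i]:
                w = (limit - v[i]) / (v[i - 1] - v[i])
                lo = g[i] + w * (g[i - 1] - g[i])
                lo_found = True
                break
        for i in range(i_mle, g.size - 1):
            if v[i + 1] > limit >= v[i]:
                w = (limit - v[i]) / (v[i + 1] - v[i])
                hi = g[i] + w * (g[i + 1] - g[i])
                hi_found = True
                break
        return lo, lo_found, hi, hi_found

    def interval_log10(self, alpha: float | None = None):
        """(lower, upper) on the fitting scale; -inf/inf for open ends,
        NaN for undetermined sides."""
        thr = self.threshold if alpha is None else chi2.ppf(alpha, df=1)
        if thr > self.threshold + 1e-12:
            raise ValueError("curve was walked only up to its own alpha level")
        lo, lo_found, hi, hi_found = self._crossings(thr)
        if not lo_found:
            lo = -np.inf if self.lower_open else np.nan
        if not hi_found:
            hi = np.inf if self.upper_open else np.nan
        return float(lo), float(hi)

    @property
    def ci_lower_log10(self) -> float:
        return self.interval_log10()[0]

    @property
    def ci_upper_log10(self) -> float:
        return self.interval_log10()[1]

    @property
    def ci_lower(self) -> float:
        lo = self.ci_lower_log10
        return 10.0 ** lo if self.is_log10 else lo  # 10**-inf == 0.0

    @property
    def ci_upper(self) -> float:
        hi = self.ci_upper_log10
        return 10.0 ** hi if self.is_log10 else hi

    def plot(self, ax=None):
        """Plot the profile with its threshold line and CI crossings."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.values, "-o", ms=3)
        ax.axhline(self.fmin + self.threshold, color="r", ls="--",
                   label=f"threshold (alpha={self.alpha})")
        ax.axvline(self.mle, color="k", lw=0.8)
        lo, hi = self.interval_log10()
        for b in (lo, hi):
            if np.isfinite(b):
                ax.axvline(b, color="r", lw=0.8)
        ax.set_xlabel(f"{self.parameter}" + (" (log10)" if self.is_log10 else ""))
        ax.set_ylabel("profiled chi-square")
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "grid": self.grid.tolist(),
            "values": self.values.tolist(),
            "alpha": self.alpha,
            "threshold": self.threshold,
            "mle": self.mle,
            "fmin": self.fmin,
            "is_log10": self.is_log10,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "lower_open": self.lower_open,
            "upper_open": self.upper_open,
        }


def confidence_interval(curve: ProfileCurve, alpha: float | None = None):
    """Threshold crossings of a computed profile, natural scale.

    Requires the curve to have been walked at a level >= ``alpha``;
    nested levels on the same curve give nested intervals.
    """
    lo, hi = curve.interval_log10(alpha)
    if curve.is_log10:
        return 10.0 ** lo, 10.0 ** hi
    return lo, hi


def _reoptimize(objective, x_full, idx, x0_others, xtol, max_nfev):
    """Minimize over all parameters except ``idx`` held at x_full[idx]."""
    free = np.ones(x_full.size, dtype=bool)
    free[idx] = False
    lo, hi = objective.bounds[:, 0], objective.bounds[:, 1]

    def resid(z):
        x = x_full.copy()
        x[free] = z
        return objective.residuals(x)

    if free.sum() == 0:
        r = objective.residuals(x_full)
        return float(r @ r), x_full[free]
    sol = least_squares(resid, np.clip(x0_others, lo[free], hi[free]),
                        bounds=(lo[free], hi[free]), method="trf",
                        xtol=xtol, gtol=1e-8, ftol=xtol,
                        diff_step=1e-6, max_nfev=max_nfev)
    if sol.status <= 0:
        raise RuntimeError(f"re-optimization failed: {sol.message}")
    return float(sol.cost * 2), sol.x


def profile(result, parameter: str, alpha: float = 0.95, target_frac: float = 1.0 / 50,
            step_bounds=(1e-4, 0.5), max_steps: int = 200, xtol: float = 1e-9,
            max_nfev: int | None = 200, refine_tol: float = 1e-7) -> ProfileCurve:
    """Walk the likelihood profile of one free parameter.

    ``result`` is an :class:`~odeinput.estimation.EstimationResult` (or
    any object exposing ``objective`` with ``residuals``/``bounds``/
    ``free_names``, plus ``params`` and ``objective_value``).  Step sizes
    adapt toward an objective increase of ``Delta_alpha * target_frac``
    per step within ``step_bounds`` (log10 units).  Once the threshold is
    bracketed, the crossing is refined by root finding to ``refine_tol``
    (parameter units).  Points where the re-optimization fails are
    skipped with a shrunken step.
    """
    from scipy.optimize import brentq
    objective = result.objective
    names = list(objective.free_names)
    if parameter not in names:
        raise KeyError(f"{parameter!r} is not a free parameter")
    idx = names.index(parameter)
    x_mle = np.asarray(result.params, dtype=float)
    fmin = float(result.objective_value)
    delta = float(chi2.ppf(alpha, df=1))
    limit = fmin + delta
    target = delta * target_frac
    lo_b, hi_b = objective.bounds[idx]
    is_log10 = bool(getattr(objective, "free_log10", np.zeros(len(names), bool))[idx])

    grid = [x_mle[idx]]
    values = [fmin]
    side_flags = {}

    for direction in (+1.0, -1.0):
        x_full = x_mle.copy()
        others = np.delete(x_mle, idx)
        step = min(step_bounds[1], max(step_bounds[0], 0.01))
        prev_val = fmin
        p_prev = x_mle[idx]
        open_end = False
        determined = False
        fails = 0
        for _ in range(max_steps):
            p_new = x_full[idx] + direction * step
            hit_bound = False
            if p_new >= hi_b:
                p_new, hit_bound = hi_b, True
            elif p_new <= lo_b:
                p_new, hit_bound = lo_b, True
            x_full[idx] = p_new
            try:
                val, others = _reoptimize(objective, x_full, idx, others, xtol, max_nfev)
                fails = 0
            except RuntimeError:
                fails += 1
                step = max(step * 0.3, step_bounds[0])
                if fails >= 4:
                    break
                continue
            grid.append(p_new)
            values.append(val)
            if val > limit:
                determined = True
                # refine the bracketed threshold crossing
                p_below = p_prev
                if abs(p_new - p_below) > refine_tol:
                    warm = others.copy()

                    def excess(p):
                        xq = x_full.copy()
                        xq[idx] = p
                        v, w = _reoptimize(objective, xq, idx, warm, xtol, max_nfev)
                        warm[:] = w
                        grid.append(p)
                        values.append(v)
                        return v - limit

                    try:
                        brentq(excess, min(p_below, p_new), max(p_below, p_new),
                               xtol=refine_tol)
                    except (ValueError, RuntimeError):
                        pass  # keep the linear-interpolation bracket
                break
            if hit_bound:
                open_end = True
                break
            inc = val - prev_val
            prev_val = val
            p_prev = p_new
            if inc > 1e-12:
                step = float(np.clip(step * target / inc, step_bounds[0], step_bounds[1]))
            else:
                step = min(step * 3.0, step_bounds[1])
        side_flags[direction] = (open_end, determined)

    order = np.argsort(grid)
    grid_arr = np.asarray(grid)[order]
    val_arr = np.asarray(values)[order]
    up_open, up_det = side_flags[+1.0]
    lo_open, lo_det = side_flags[-1.0]
    return ProfileCurve(
        parameter=parameter, grid=grid_arr, values=val_arr, alpha=alpha,
        threshold=delta, mle=float(x_mle[idx]), fmin=fmin, is_log10=is_log10,
        lower_open=lo_open, upper_open=up_open,
        lower_determined=lo_det or lo_open, upper_determined=up_det or up_open,
    )
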