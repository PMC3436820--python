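"""Maximum-likelihood estimation of kinetic parameters and input functions.

Two estimation modes are supported, differing in how the measured input
enters the fit:

standard
    The input time course is pre-fitted by an (optionally smoothing)
    spline from the input data alone, frozen, and only the downstream
    observables contribute residuals.  Input measurement uncertainty is
    ignored by construction.

comprehensive
    The spline control points of the (log10-scale) input join the
    parameter vector and one objective is minimized over everything:
    weighted residuals of *all* observables, including the input, plus a
    curvature penalty lambda * int (S'')^2 folded in as pseudo-residuals
    so that a least-squares backend applies.

Weighted least squares equals twice the negative Gaussian log-likelihood
up to a constant, so the minimizer is the MLE.  All free parameters are
optimized on log10 scale within explicit bounds (default [-5, 5]),
starting either from a user start, the template values, or Latin
hypercube samples for multistart.

The public surface follows the familiar model/results split: build an
:class:`OdeMLE` from an :class:`~odeinput.models.OdeModel` plus a
:class:`Dataset`, call :meth:`OdeMLE.fit`, and work with the returned
:class:`EstimationResult` (``params``, ``bse``, ``conf_int``,
``profile``, ``summary``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2
from scipy.stats.qmc import LatinHypercube, scale as qmc_scale

from .models import (BLOCKS, IntegrationError, OdeModel, ParameterSet,
                     Trajectory, simulate)
from .splines import InputSpline, interpolating_spline, penalty_root, select_lambda, smoothing_spline

__all__ = ["Dataset", "Objective", "OdeMLE", "EstimationResult", "lhs_starts", "fit"]


class Dataset:
    """Long-format measurement table: (time, observable, value, sigma).

    Each observable carries a role: *input* observables directly measure
    the stimulus u(t); everything else is *downstream*.  Sigmas must be
    positive everywhere.
    """

    COLUMNS = ("time", "observable", "value", "sigma")

    def __init__(self, df: pd.DataFrame, input_observables: Sequence[str] = ()):
        df = pd.DataFrame(df).reset_index(drop=True)
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if not np.all(df["sigma"].to_numpy() > 0):
            bad = int(np.argmin(df["sigma"].to_numpy() > 0))
            raise ValueError(f"non-positive sigma at row {bad}")
        self.df = df[list(self.COLUMNS)].copy()
        self.df["time"] = self.df["time"].astype(float)
        self.df["value"] = self.df["value"].astype(float)
        self.df["sigma"] = self.df["sigma"].astype(float)
        self.input_observables = tuple(input_observables)

    # -- views ---------------------------------------------------------

    @property
    def observables(self) -> list[str]:
        return list(dict.fromkeys(self.df["observable"]))

    def records(self, observable: str) -> pd.DataFrame:
        return self.df[self.df["observable"] == observable]

    def arrays(self, observable: str):
        sub = self.records(observable).sort_values("time")
        return (sub["time"].to_numpy(), sub["value"].to_numpy(), sub["sigma"].to_numpy())

    @property
    def downstream(self) -> pd.DataFrame:
        return self.df[~self.df["observable"].isin(self.input_observables)]

    @property
    def input_data(self) -> pd.DataFrame:
        return self.df[self.df["observable"].isin(self.input_observables)]

    def __len__(self) -> int:
        return len(self.df)


def lhs_starts(n_starts: int, bounds, seed=0) -> np.ndarray:
    """Latin hypercube start points: each dimension stratified into
    ``n_starts`` equal bins with exactly one sample per bin.

    ``bounds`` is a sequence of (low, high) per free parameter on the
    fitting (log10) scale.  Returns an (n_starts, d) array.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise ValueError("LHS requires finite bounds")
    sampler = LatinHypercube(d=bounds.shape[0], seed=seed)
    unit = sampler.random(n_starts)
    return qmc_scale(unit, lo, hi)


class Objective:
    """Weighted least-squares objective for one model/dataset pair.

    ``input_mode='frozen'`` reproduces the standard two-step approach
    (``frozen_input`` required); ``input_mode='free'`` is the joint
    objective whose parameter vector includes the input control points.
    The callable returns the scalar chi-square; :meth:`residuals` exposes
    the stacked residual vector for least-squares backends.  Integration
    failures yield a large sentinel value (and are counted), keeping the
    optimizer inside the feasible region.
    """

    def __init__(self, model: OdeModel, dataset: Dataset, template: ParameterSet,
                 input_mode: str = "free", lam: float = 0.0,
                 frozen_input: InputSpline | None = None,
                 bounds=(-5.0, 5.0), n_chain: int = 8,
                 rtol: float = 1e-8, atol: float = 1e-10, sentinel: float = 1e10):
        if input_mode not in ("frozen", "free"):
            raise ValueError("input_mode must be 'frozen' or 'free'")
        if input_mode == "frozen" and frozen_input is None:
            raise ValueError("frozen mode requires a pre-fitted input spline")
        if input_mode == "free" and template.input_control.size == 0:
            raise ValueError("free mode requires input control points in the template")
        if input_mode == "free" and not dataset.input_observables:
            raise ValueError("free mode requires at least one input-tagged observable")
        self.model = model
        self.dataset = dataset
        self.template = template
        self.input_mode = input_mode
        self.lam = float(lam)
        self.frozen_input = frozen_input
        self.n_chain = n_chain
        self.rtol, self.atol = rtol, atol
        self.sentinel = float(sentinel)
        self.n_failures = 0

        # residual bookkeeping: rows of the relevant dataset slice mapped
        # onto the (time x observable) matrix simulate() produces
        rows = dataset.df if input_mode == "free" else dataset.downstream
        self._values = rows["value"].to_numpy()
        self._sigmas = rows["sigma"].to_numpy()
        times = np.unique(dataset.df["time"].to_numpy())
        self._sim_times = times
        tindex = {t: i for i, t in enumerate(times)}
        oindex = {o: j for j, o in enumerate(model.observable_names)}
        unknown = set(rows["observable"]) - set(oindex)
        if unknown:
            raise ValueError(f"dataset observables {sorted(unknown)} unknown to model {model.name!r}")
        self._ti = rows["time"].map(tindex).to_numpy()
        self._oi = rows["observable"].map(oindex).to_numpy()

        if input_mode == "free":
            tin, _, _ = dataset.arrays(dataset.input_observables[0])
            if tin.size != template.input_control.size:
                raise ValueError("control-point count must match input measurement times")
            self._knots = tin
            self._lroot_t = penalty_root(self._knots).T  # (N-2, N)
        else:
            self._knots = None
            self._lroot_t = np.zeros((0, 0))

        self._n_res = self._values.size + (self._lroot_t.shape[0] if self.lam > 0 else 0)

        nfree = len(template.free_names)
        b = np.asarray(bounds, dtype=float)
        if b.ndim == 1:
            b = np.tile(b, (nfree, 1))
        if b.shape != (nfree, 2):
            raise ValueError("bounds must be (low, high) or per-free-parameter array")
        self.bounds = b
        # log10 flag per free entry (control points live on log10-input scale
        # already and are not re-transformed)
        flags = []
        for blk in BLOCKS:
            flags.extend(np.asarray(template.log10[blk])[~template.fixed[blk]])
        self.free_log10 = np.asarray(flags, dtype=bool)

    @property
    def free_names(self) -> list[str]:
        return self.template.free_names

    def _input_spline(self, ps: ParameterSet) -> InputSpline:
        if self.input_mode == "frozen":
            return self.frozen_input
        return InputSpline(self._knots, ps.input_control, lam=self.lam, log_scale=True)

    def residual_blocks(self, x: np.ndarray) -> dict:
        """Residuals split into data and penalty blocks (diagnostics)."""
        ps = self.template.with_free(np.asarray(x, dtype=float))
        spline = self._input_spline(ps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traj = simulate(self.model, ps, spline, self._sim_times,
                            rtol=self.rtol, atol=self.atol, n_chain=self.n_chain)
        ymodel = traj.observables[self._ti, self._oi]
        data_res = (self._values - ymodel) / self._sigmas
        if self.input_mode == "free" and self.lam > 0:
            pen_res = np.sqrt(self.lam) * (self._lroot_t @ ps.input_control)
        else:
            pen_res = np.zeros(self._lroot_t.shape[0] if self.lam > 0 else 0)
        return {"data": data_res, "penalty": pen_res}

    def residuals(self, x: np.ndarray) -> np.ndarray:
        try:
            blocks = self.residual_blocks(x)
        except (IntegrationError, ValueError, FloatingPointError):
            self.n_failures += 1
            return np.full(self._n_res, np.sqrt(self.sentinel / self._n_res))
        r = np.concatenate([blocks["data"], blocks["penalty"]])
        if not np.all(np.isfinite(r)):
            self.n_failures += 1
            return np.full(self._n_res, np.sqrt(self.sentinel / self._n_res))
        return r

    def __call__(self, x: np.ndarray) -> float:
        r = self.residuals(x)
        return float(r @ r)


def fit(objective: Objective, starts, xtol: float = 1e-10, gtol: float = 1e-8,
        ftol: float = 1e-10, diff_step: float = 1e-6, max_nfev: int | None = None,
        approach: str | None = None) -> "EstimationResult":
    """Minimize ``objective`` from each start; return the best result.

    Trust-region-reflective least squares on the residual vector, with
    finite-difference Jacobians (step ``diff_step`` on the log10 scale,
    comfortably above the integrator tolerance).  Raises if every start
    fails; the per-start table is carried either way.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    lo, hi = objective.bounds[:, 0], objective.bounds[:, 1]
    rows, solutions = [], []
    for i, x0 in enumerate(starts):
        x0c = np.clip(x0, lo, hi)
        try:
            sol = least_squares(objective.residuals, x0c, bounds=(lo, hi),
                                method="trf", xtol=xtol, gtol=gtol, ftol=ftol,
                                diff_step=diff_step, max_nfev=max_nfev)
            ok = bool(sol.status > 0)
            rows.append({"start": i, "converged": ok, "objective": float(sol.cost * 2),
                         "nfev": sol.nfev, "message": sol.message,
                         "params": sol.x.copy() if ok else None})
            solutions.append(sol if ok else None)
        except Exception as exc:  # noqa: BLE001 - start table must survive
            rows.append({"start": i, "converged": False, "objective": np.inf,
                         "nfev": 0, "message": str(exc), "params": None})
            solutions.append(None)
    table = pd.DataFrame(rows)
    conv = [i for i, s in enumerate(solutions) if s is not None]
    if not conv:
        raise RuntimeError(f"all {len(starts)} starts failed:\n{table}")
    best_i = min(conv, key=lambda i: table.loc[i, "objective"])
    best = solutions[best_i]
    return EstimationResult(
        params=pd.Series(best.x, index=objective.free_names),
        objective_value=float(best.cost * 2),
        start_table=table,
        approach=approach or ("comprehensive" if objective.input_mode == "free" else "standard"),
        objective=objective,
        _jac=best.jac,
    )


@dataclass
class EstimationResult:
    """Fit results: log10-scale estimates, uncertainty and diagnostics.

    ``params`` is indexed by free-parameter name on the fitting (log10)
    scale; ``params_natural`` transforms log10-flagged entries back.
    ``bse``/``conf_int`` use the quadratic (Wald-type) approximation from
    the residual Jacobian; :meth:`profile` walks the full likelihood
    profile instead.
    """

    params: pd.Series
    objective_value: float
    start_table: pd.DataFrame
    approach: str
    objective: Objective
    _jac: np.ndarray | None = None
    _cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_free(self) -> int:
        return self.params.size

    @property
    def params_natural(self) -> pd.Series:
        v = self.params.to_numpy().copy()
        lg = self.objective.free_log10
        v[lg] = 10.0 ** v[lg]
        return pd.Series(v, index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        """Covariance of the log10-scale estimates, (J'J)^-1 of the
        unit-variance weighted residuals at the optimum."""
        if self._cov is None:
            if self._jac is None:
                raise ValueError("no Jacobian stored")
            jtj = self._jac.T @ self._jac
            self._cov = np.linalg.pinv(jtj, hermitian=True)
        return pd.DataFrame(self._cov, index=self.params.index, columns=self.params.index)

    @property
    def bse(self) -> pd.Series:
        c = self.cov_params().to_numpy()
        return pd.Series(np.sqrt(np.maximum(np.diag(c), 0.0)), index=self.params.index)

    def conf_int(self, alpha: float = 0.95, method: str = "wald") -> pd.DataFrame:
        """Confidence intervals at level ``alpha`` on the log10 scale.

        ``wald`` uses the chi-square(1) threshold on the quadratic
        approximation, theta +- sqrt(chi2_{1,alpha}) * se, which matches
        the profile-likelihood threshold convention exactly when the
        objective is quadratic; ``profile`` walks each profile.
        """
        if method == "wald":
            half = np.sqrt(chi2.ppf(alpha, df=1)) * self.bse
            return pd.DataFrame({"lower": self.params - half, "upper": self.params + half})
        if method == "profile":
            from .profile import profile as _profile
            rows = {}
            for name in self.params.index:
                curve = _profile(self, name, alpha=alpha)
                rows[name] = (curve.ci_lower_log10, curve.ci_upper_log10)
            return pd.DataFrame(rows, index=["lower", "upper"]).T
        raise ValueError("method must be 'wald' or 'profile'")

    def profile(self, name: str, alpha: float = 0.95, **kwargs):
        from .profile import profile as _profile
        return _profile(self, name, alpha=alpha, **kwargs)

    def parameter_set(self) -> ParameterSet:
        return self.objective.template.with_free(self.params.to_numpy())

    def input_spline(self) -> InputSpline:
        return self.objective._input_spline(self.parameter_set())

    def simulate(self, times) -> Trajectory:
        ps = self.parameter_set()
        return simulate(self.objective.model, ps, self.objective._input_spline(ps),
                        np.asarray(times, dtype=float),
                        rtol=self.objective.rtol, atol=self.objective.atol,
                        n_chain=self.objective.n_chain)

    def plot_fit(self, n_dense: int = 200, axes=None):
        """Fitted observable trajectories overlaid on the data."""
        import matplotlib.pyplot as plt

        ds = self.objective.dataset
        t0 = ds.df["time"].min()
        t1 = ds.df["time"].max()
        traj = self.simulate(np.linspace(t0, t1, n_dense))
        names = self.objective.model.observable_names
        if axes is None:
            _, axes = plt.subplots(1, len(names), figsize=(3 * len(names), 2.5),
                                   squeeze=False)
            axes = axes[0]
        for ax, name in zip(axes, names):
            j = names.index(name)
            ax.plot(traj.times, traj.observables[:, j], "-", color="tab:blue")
            if name in ds.observables:
                t, v, s = ds.arrays(name)
                ax.errorbar(t, v, yerr=s, fmt="k.", ms=4, lw=0.8)
            ax.set_title(name)
        return axes

    def summary(self, alpha: float = 0.95) -> str:
        ci = self.conf_int(alpha)
        nat = self.params_natural
        lg = self.objective.free_log10
        lo = np.where(lg, 10.0 ** ci["lower"].to_numpy(), ci["lower"].to_numpy())
        hi = np.where(lg, 10.0 ** ci["upper"].to_numpy(), ci["upper"].to_numpy())
        lines = [
            f"{self.approach} approach MLE  (chi2 = {self.objective_value:.6g}, "
            f"{self.n_free} free parameters, {len(self.start_table)} starts)",
            f"{'parameter':<14}{'log10':>10}{'natural':>12}"
            f"{'se(log10)':>12}{f'ci{int(alpha*100)}_lb':>12}{f'ci{int(alpha*100)}_ub':>12}",
        ]
        for i, name in enumerate(self.params.index):
            lines.append(
                f"{name:<14}{self.params.iloc[i]:>10.4f}{nat.iloc[i]:>12.4g}"
                f"{self.bse.iloc[i]:>12.4f}{lo[i]:>12.4g}{hi[i]:>12.4g}")
        return "\n".join(lines)


class OdeMLE:
    """Maximum-likelihood model: an ODE model bound to a dataset.

    Parameters
    ----------
    model : OdeModel
    dataset : Dataset
    approach : 'comprehensive' or 'standard'
        Joint estimation of input control points, or pre-fitted frozen
        input with downstream-only residuals.
    lam : 'auto', 0 or float
        Curvature penalty weight; 'auto' selects it once from the input
        data by the chi-square discrepancy rule and keeps it fixed during
        optimization.
    free_initials : bool
        Free the initial concentrations (log10 scale) instead of fixing
        them at the template values.
    template : ParameterSet, optional
        Full override of the parameter template (names/values/flags).
    bounds : pair or array
        Box bounds on the log10 fitting scale, default (-5, 5).

    Examples
    --------
    >>> mle = OdeMLE(toy_model(), dataset, approach="comprehensive", lam=0)
    >>> res = mle.fit(start=start_vector)
    >>> print(res.summary())
    """

    def __init__(self, model: OdeModel, dataset: Dataset, approach: str = "comprehensive",
                 lam="auto", free_initials: bool = False, template: ParameterSet | None = None,
                 bounds=(-5.0, 5.0), n_chain: int = 8, rtol: float = 1e-8, atol: float = 1e-10):
        if approach not in ("comprehensive", "standard"):
            raise ValueError("approach must be 'comprehensive' or 'standard'")
        self.model = model
        self.dataset = dataset
        self.approach = approach

        if not dataset.input_observables:
            # fall back to the model's convention
            dataset.input_observables = tuple(model.input_observables)
        if not dataset.input_observables:
            raise ValueError("no input-tagged observable in dataset or model")
        tin, vin, sin = dataset.arrays(dataset.input_observables[0])
        if tin.size < 2:
            raise ValueError(
                f"no usable measurements for input observable "
                f"{dataset.input_observables[0]!r}")

        if lam == "auto":
            self.lam = select_lambda(tin, vin, sin)
        else:
            self.lam = float(lam)

        prefit = (smoothing_spline(tin, vin, sin, lam=self.lam, log_scale=True)
                  if self.lam > 0 else interpolating_spline(tin, vin, log_scale=True))
        self.prefit_input = prefit

        if template is None:
            template = self._default_template(model, free_initials, prefit)
        self.template = template

        self.objective = Objective(
            model, dataset, template,
            input_mode="free" if approach == "comprehensive" else "frozen",
            lam=self.lam if approach == "comprehensive" else 0.0,
            frozen_input=None if approach == "comprehensive" else prefit,
            bounds=bounds, n_chain=n_chain, rtol=rtol, atol=atol)

    def _default_template(self, model: OdeModel, free_initials: bool,
                          prefit: InputSpline) -> ParameterSet:
        names = {
            "dynamic": list(model.dynamic_names),
            "scaling_offset": list(model.scaling_names),
            "initial": [f"{s}_0" for s in model.state_names],
            "input_control": ([f"v{i+1}" for i in range(prefit.knots.size)]
                              if self.approach == "comprehensive" else []),
        }
        init = (model.default_initial if model.default_initial is not None
                else np.ones(model.n_states))
        values = {
            "dynamic": np.ones(len(model.dynamic_names)),
            "scaling_offset": np.ones(len(model.scaling_names)),
            "initial": np.asarray(init, dtype=float),
            "input_control": (prefit.control_points
                              if self.approach == "comprehensive" else np.zeros(0)),
        }
        # zero initials cannot be log-transformed or meaningfully freed
        init_pos = values["initial"] > 0
        log10 = {
            "dynamic": [True] * len(names["dynamic"]),
            "scaling_offset": [True] * len(names["scaling_offset"]),
            "initial": list(init_pos),
            "input_control": [False] * len(names["input_control"]),
        }
        fixed_scaling = [n == "s3" for n in names["scaling_offset"]]  # convention s3 = 1
        fixed = {
            "dynamic": [False] * len(names["dynamic"]),
            "scaling_offset": fixed_scaling,
            "initial": [True] * model.n_states if not free_initials else list(~init_pos),
            "input_control": [False] * len(names["input_control"]),
        }
        return ParameterSet.create(names, values, log10, fixed)

    def fit(self, start=None, n_starts: int = 1, seed=0, **kwargs) -> EstimationResult:
        """Fit by multistart trust-region least squares.

        ``start`` may be a vector on the fitting scale or a dict of
        name -> natural-scale value overriding the template defaults.
        With ``n_starts > 1``, Latin hypercube starts are drawn inside the
        bounds (any explicit ``start`` is prepended).
        """
        x0 = self.template.free_vector()
        if isinstance(start, dict):
            ps = self.template
            d = ps.as_dict(natural=False)
            for k, v in start.items():
                blk = next(b for b in BLOCKS if k in ps.names[b])
                i = ps.names[blk].index(k)
                d[k] = np.log10(v) if ps.log10[blk][i] else v
            x0 = np.array([d[n] for n in ps.free_names])
        elif start is not None:
            x0 = np.asarray(start, dtype=float)
        starts = [x0]
        if n_starts > 1:
            starts = list(lhs_starts(n_starts, self.objective.bounds, seed=seed))
            if start is not None:
                starts = [x0] + starts
        return fit(self.objective, np.asarray(starts), approach=self.approach, **kwargs)
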