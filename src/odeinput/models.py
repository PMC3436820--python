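"""ODE model class, built-in reaction networks and trajectory simulation.

A model couples internal states x(t) driven by mass-action kinetics to a
time-dependent external stimulus u(t) (the *input function*) and maps the
states onto noisy observables y(t).  Two networks ship with the package:

``toy_model``
    A closed three-state interconversion chain X1 <-> X2 <-> X3 where the
    first forward reaction is catalyzed by the input, observed on log10
    scale.  Total mass is conserved, which the tests exploit.

``jakstat_model``
    The Epo-induced JAK2/STAT5 signaling cascade: cytoplasmic STAT5 is
    phosphorylated at a rate proportional to phosphorylated Epo receptor
    (the input), dimerizes, translocates to the nucleus and returns to the
    cytoplasm as unphosphorylated monomers after a discrete residence
    delay tau.  The delay is integrated with a linear chain of first-order
    compartments so that a standard stiff ODE solver suffices.

``simulate`` integrates a model for a given :class:`ParameterSet` and
input function and returns a :class:`Trajectory`.  For the toy model with
spline or Gaussian inputs a compiled fast path is used transparently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .splines import InputSpline

__all__ = [
    "OdeModel",
    "ParameterSet",
    "Trajectory",
    "GaussianInput",
    "IntegrationError",
    "toy_model",
    "jakstat_model",
    "get_model",
    "model_from_config",
    "simulate",
    "LOG_FLOOR",
]

#: floor applied inside log10 observation maps; never applied in the RHS
LOG_FLOOR = 1e-12

BLOCKS = ("dynamic", "scaling_offset", "initial", "input_control")


class IntegrationError(RuntimeError):
    """ODE integration failed (stiffness, step underflow, negative states)."""


@dataclass
class GaussianInput:
    """Gaussian-bell stimulus u(t) = height * exp(-(t-center)^2 / (2 w^2))."""

    height: float = 100.0
    center: float = 25.0
    width: float = 7.5

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.height * np.exp(-((t - self.center) ** 2) / (2.0 * self.width**2))


@dataclass
class OdeModel:
    """Declarative ODE model: states, RHS, observation map, parameter roles.

    ``rhs(t, x, u, k, xdel)`` returns dx/dt; ``u`` is the vector of input
    values at ``t``, ``k`` the natural-scale dynamic parameters and
    ``xdel(j)`` an accessor for the delayed value of state ``j`` (the
    current value when the state carries no lag).  ``observation(x, u, s)``
    maps one state/input sample to the observable vector given the
    scaling/offset parameters ``s``.
    """

    name: str
    state_names: list[str]
    input_names: list[str]
    observable_names: list[str]
    dynamic_names: list[str]
    scaling_names: list[str]
    rhs: Callable
    observation: Callable
    delay_lags: list[tuple[int, float]] = field(default_factory=list)
    input_observables: tuple[str, ...] = ()
    default_initial: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def with_delay(self, tau: float) -> "OdeModel":
        if not self.delay_lags:
            raise ValueError(f"model {self.name!r} has no delayed state")
        lags = [(idx, float(tau)) for idx, _ in self.delay_lags]
        return replace(self, delay_lags=lags)


@dataclass
class Trajectory:
    """Time grid with state, input and observable matrices (rows = times)."""

    times: np.ndarray
    states: np.ndarray
    inputs: np.ndarray
    observables: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for m in (self.states, self.inputs, self.observables):
            if m.shape[0] != self.times.size:
                raise ValueError("matrix row count must equal number of times")


@dataclass
class ParameterSet:
    """Full parameter vector of a model, split into its four roles.

    Block order is fixed and documented: dynamic (rate constants),
    scaling_offset, initial (x(0)), input_control (spline control points,
    already on the log10-input scale).  Entries flagged ``log10`` are
    *stored* on log10 scale — all estimation happens on that scale — and
    converted back by :meth:`natural`.  Entries flagged ``fixed`` are
    excluded from :meth:`free_vector` and never change during fitting.
    """

    dynamic: np.ndarray
    scaling_offset: np.ndarray
    initial: np.ndarray
    input_control: np.ndarray
    names: dict
    log10: dict
    fixed: dict

    @classmethod
    def create(cls, names: dict, values: dict, log10: dict | None = None,
               fixed: dict | None = None) -> "ParameterSet":
        """Build from natural-scale ``values``; log10-flagged entries are
        transformed for storage.  Control points are taken as given (they
        already live on the log10-input scale)."""
        log10 = dict(log10 or {})
        fixed = dict(fixed or {})
        arrays = {}
        for b in BLOCKS:
            nm = list(names.get(b, []))
            val = np.asarray(values.get(b, np.zeros(len(nm))), dtype=float).copy()
            if val.size != len(nm):
                raise ValueError(f"block {b}: {val.size} values for {len(nm)} names")
            lg = np.asarray(log10.get(b, [b != "input_control"] * len(nm)), dtype=bool)
            fx = np.asarray(fixed.get(b, [False] * len(nm)), dtype=bool)
            if np.any(lg & (val <= 0)):
                raise ValueError(f"block {b}: log10-flagged entries must be positive")
            val[lg] = np.log10(val[lg])
            arrays[b] = val
            log10[b] = lg
            fixed[b] = fx
            names[b] = nm
        allnames = sum((names[b] for b in BLOCKS), [])
        if len(set(allnames)) != len(allnames):
            raise ValueError("parameter names must be unique across blocks")
        return cls(arrays["dynamic"], arrays["scaling_offset"], arrays["initial"],
                   arrays["input_control"], names, log10, fixed)

    def _block(self, b: str) -> np.ndarray:
        return getattr(self, b if b != "scaling_offset" else "scaling_offset")

    def stored(self, b: str) -> np.ndarray:
        return getattr(self, b)

    def natural(self, b: str) -> np.ndarray:
        v = getattr(self, b).copy()
        lg = self.log10[b]
        v[lg] = 10.0 ** v[lg]
        return v

    # -- free-parameter view ------------------------------------------

    @property
    def free_names(self) -> list[str]:
        out = []
        for b in BLOCKS:
            out.extend(n for n, fx in zip(self.names[b], self.fixed[b]) if not fx)
        return out

    def free_vector(self) -> np.ndarray:
        return np.concatenate([getattr(self, b)[~self.fixed[b]] for b in BLOCKS])

    def with_free(self, x: np.ndarray) -> "ParameterSet":
        x = np.asarray(x, dtype=float)
        new = {}
        pos = 0
        for b in BLOCKS:
            v = getattr(self, b).copy()
            nfree = int((~self.fixed[b]).sum())
            v[~self.fixed[b]] = x[pos:pos + nfree]
            pos += nfree
            new[b] = v
        if pos != x.size:
            raise ValueError(f"expected {pos} free values, got {x.size}")
        return ParameterSet(new["dynamic"], new["scaling_offset"], new["initial"],
                            new["input_control"], self.names, self.log10, self.fixed)

    def as_dict(self, natural: bool = False) -> dict:
        out = {}
        for b in BLOCKS:
            vals = self.natural(b) if natural else getattr(self, b)
            out.update(zip(self.names[b], vals))
        return out


# ---------------------------------------------------------------------
# built-in models
# ---------------------------------------------------------------------

def _log10_obs(x, floor=LOG_FLOOR):
    x = np.asarray(x, dtype=float)
    if np.any(x < floor):
        warnings.warn("state clipped to positivity floor inside log10 observation",
                      RuntimeWarning, stacklevel=2)
    return np.log10(np.maximum(x, floor))


def toy_model() -> OdeModel:
    """Closed 3-state interconversion chain driven by an input.

    Mass-action fluxes v1 = k1*u*x1, v-1 = k-1*x2, v2 = k2*x2,
    v-2 = k-2*x3; observables y_i = log10(x_i) and y4 = log10(u), the
    log scale matching multiplicative (log-normal) measurement error of
    typical protein quantification.
    """

    def rhs(t, x, u, k, xdel=None):
        v1 = k[0] * u[0] * x[0]
        vm1 = k[1] * x[1]
        v2 = k[2] * x[1]
        vm2 = k[3] * x[2]
        return np.array([-v1 + vm1, v1 - vm1 - v2 + vm2, v2 - vm2])

    def observation(x, u, s):
        return np.concatenate([_log10_obs(x), _log10_obs(np.atleast_1d(u))])

    return OdeModel(
        name="toy",
        state_names=["X1", "X2", "X3"],
        input_names=["u"],
        observable_names=["y1", "y2", "y3", "y4"],
        dynamic_names=["k1", "km1", "k2", "km2"],
        scaling_names=[],
        rhs=rhs,
        observation=observation,
        input_observables=("y4",),
        default_initial=np.array([30.0, 20.0, 50.0]),
    )


def jakstat_model(tau: float = 6.0, n_chain: int = 8) -> OdeModel:
    """Epo-induced JAK2/STAT5 cascade with delayed nuclear export.

    States: STAT5 (x1), pSTAT5 (x2), pSTAT5 dimer (x3), nuclear pSTAT5
    dimer (x4).  Phosphorylation k1*u*x1 is driven by the input pEpoR;
    dimerization k2*x2^2 consumes two monomers per dimer; nuclear import
    k3*x3; delayed export k4*x4(t-tau) returns two monomers per dimer to
    the cytoplasm, so x1 + x2 + 2*x3 + 2*x4 is conserved.

    Observables (immunoblotting sums, relative units): y1 = s1*(x2+2x3)
    total phosphorylated STAT5, y2 = s2*(x1+x2+2x3) total cytoplasmic
    STAT5, y3 = s3*u the input measurement.  Conventions: x(0) =
    (1, 0, 0, 0) and s3 = 1 to remove structural non-identifiabilities.
    """

    def rhs(t, x, u, k, xdel):
        x4d = xdel(3)
        v1 = k[0] * u[0] * x[0]
        v2 = k[1] * x[1] ** 2
        v3 = k[2] * x[2]
        v4 = k[3] * x4d
        return np.array([-v1 + 2.0 * v4, v1 - 2.0 * v2, v2 - v3, v3 - v4])

    def observation(x, u, s):
        return np.array([
            s[0] * (x[1] + 2.0 * x[2]),
            s[1] * (x[0] + x[1] + 2.0 * x[2]),
            s[2] * u[0],
        ])

    return OdeModel(
        name="jakstat",
        state_names=["STAT5", "pSTAT5", "pSTAT5_2", "npSTAT5_2"],
        input_names=["pEpoR"],
        observable_names=["y1", "y2", "y3"],
        dynamic_names=["k1", "k2", "k3", "k4"],
        scaling_names=["s1", "s2", "s3"],
        rhs=rhs,
        observation=observation,
        delay_lags=[(3, float(tau))],
        input_observables=("y3",),
        default_initial=np.array([1.0, 0.0, 0.0, 0.0]),
    )


# ---------------------------------------------------------------------
# config-file models
# ---------------------------------------------------------------------

def model_from_config(cfg: dict) -> OdeModel:
    """Build an :class:`OdeModel` from a declarative config dictionary.

    Expected keys: ``name``, ``states``, ``inputs``, ``dynamic``,
    ``scaling`` (optional), ``odes`` (one arithmetic expression per
    state), ``observables`` (mapping name -> expression), optional
    ``delays`` ([{state, tau}]; the RHS may reference
    ``<state>_delayed``), optional ``input_observables`` and
    ``initial`` defaults.  Expressions are parsed with sympy.
    """
    import sympy as sp

    states = list(cfg["states"])
    inputs = list(cfg.get("inputs", []))
    dyn = list(cfg.get("dynamic", []))
    scal = list(cfg.get("scaling", []))
    delays = [(states.index(d["state"]), float(d["tau"])) for d in cfg.get("delays", [])]
    delayed_syms = [f"{states[idx]}_delayed" for idx, _ in delays]

    symtab = {n: sp.Symbol(n) for n in states + inputs + dyn + scal + delayed_syms + ["t"]}

    ode_exprs = [sp.sympify(e, locals=symtab) for e in cfg["odes"]]
    obs_items = list(cfg["observables"].items())
    obs_exprs = [sp.sympify(e, locals=symtab) for _, e in obs_items]

    argsyms = ([symtab["t"]] + [symtab[n] for n in states] + [symtab[n] for n in inputs]
               + [symtab[n] for n in dyn] + [symtab[n] for n in scal]
               + [symtab[n] for n in delayed_syms])
    f_rhs = sp.lambdify(argsyms, ode_exprs, modules="numpy")
    f_obs = sp.lambdify(argsyms, obs_exprs, modules="numpy")

    def rhs(t, x, u, k, xdel):
        dstates = [xdel(idx) for idx, _ in delays]
        return np.asarray(f_rhs(t, *x, *u, *k, *np.zeros(len(scal)), *dstates), dtype=float)

    def observation(x, u, s):
        dstates = [x[idx] for idx, _ in delays]  # delays immaterial in observation
        return np.asarray(f_obs(0.0, *x, *u, *np.zeros(len(dyn)), *s, *dstates), dtype=float)

    init = cfg.get("initial")
    return OdeModel(
        name=str(cfg.get("name", "config")),
        state_names=states,
        input_names=inputs,
        observable_names=[n for n, _ in obs_items],
        dynamic_names=dyn,
        scaling_names=scal,
        rhs=rhs,
        observation=observation,
        delay_lags=delays,
        input_observables=tuple(cfg.get("input_observables", [])),
        default_initial=None if init is None else np.asarray(init, dtype=float),
    )


def get_model(ref: str) -> OdeModel:
    """Retrieve a built-in model by name or load one from a YAML/JSON file."""
    if ref == "toy":
        return toy_model()
    if ref == "jakstat":
        return jakstat_model()
    import os
    if os.path.exists(ref):
        import yaml
        with open(ref) as fh:
            return model_from_config(yaml.safe_load(fh))
    raise ValueError(f"unknown model {ref!r} (expected 'toy', 'jakstat' or a config path)")


# ---------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------

def _eval_input(input_fn, t):
    if isinstance(input_fn, InputSpline):
        return np.atleast_1d(input_fn(t))
    return np.atleast_1d(input_fn(t))


def simulate(model: OdeModel, params: ParameterSet, input_fn, times,
             rtol: float = 1e-8, atol: float = 1e-10, n_chain: int = 8,
             method: str = "LSODA", backend: str = "auto") -> Trajectory:
    """Integrate ``model`` and return states, inputs and observables.

    ``input_fn`` is any callable t -> input value(s); :class:`InputSpline`
    (evaluated on its natural scale) and :class:`GaussianInput` are
    recognized by the compiled toy-model fast path.  Discrete delays are
    realized by a linear chain of ``n_chain`` first-order compartments
    with zero initial history, consistent with delayed states that start
    at zero.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    k = params.natural("dynamic")
    s = params.natural("scaling_offset")
    x0 = params.natural("initial")
    if x0.size != model.n_states:
        raise ValueError("initial block size does not match the model")

    if backend in ("auto", "fast") and model.name == "toy":
        states = _simulate_toy_fast(k, x0, input_fn, times, rtol, atol)
        if states is not None:
            u = _eval_input(input_fn, times).reshape(times.size, -1)
            obs = np.column_stack([_log10_obs(states), _log10_obs(u)])
            return Trajectory(times, states, u, obs)
    if (backend in ("auto", "fast") and model.name == "jakstat"
            and isinstance(input_fn, InputSpline) and input_fn.log_scale):
        from . import _fastpath as fp
        tau = model.delay_lags[0][1] if model.delay_lags else 0.0
        brk, c = input_fn.ppoly_arrays()
        states = fp.integrate_jakstat_spline(k, tau, n_chain, x0, times, brk,
                                             np.ascontiguousarray(c), rtol, atol)
        u = _eval_input(input_fn, times).reshape(times.size, -1)
        obs = np.stack([model.observation(states[i], u[i], s) for i in range(times.size)])
        return Trajectory(times, states, u, obs)
    if backend == "fast":
        raise ValueError("no fast path available for this model/input combination")

    lags = [(idx, tau) for idx, tau in model.delay_lags if tau > 0]
    ns = model.n_states
    nch = n_chain

    def aug_rhs(t, y):
        x = y[:ns]
        u = _eval_input(input_fn, t)
        if lags:
            chains = y[ns:].reshape(len(lags), nch)

            def xdel(j):
                for m, (idx, _tau) in enumerate(lags):
                    if idx == j:
                        return chains[m, -1]
                return x[j]
        else:
            def xdel(j):
                return x[j]
        dx = np.asarray(model.rhs(t, x, u, k, xdel), dtype=float)
        if not lags:
            return dx
        dch = np.empty((len(lags), nch))
        for m, (idx, tau) in enumerate(lags):
            rate = nch / tau
            dch[m, 0] = rate * (x[idx] - chains[m, 0])
            dch[m, 1:] = rate * (chains[m, :-1] - chains[m, 1:])
        return np.concatenate([dx, dch.ravel()])

    y0 = np.concatenate([x0, np.zeros(len(lags) * nch)])
    sol = solve_ivp(aug_rhs, (times[0], times[-1]), y0, t_eval=times,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"integration failed near t={sol.t[-1] if sol.t.size else times[0]}: {sol.message}")
    states = sol.y[:ns].T
    scale = max(np.max(np.abs(x0)), 1.0)
    if np.any(states < -1e-6 * scale):
        raise IntegrationError("negative state beyond tolerance: model/parameter inconsistency")
    u = np.stack([_eval_input(input_fn, t) for t in times])
    obs = np.stack([model.observation(states[i], u[i], s) for i in range(times.size)])
    return Trajectory(times, states, u, obs)


def _simulate_toy_fast(k, x0, input_fn, times, rtol, atol):
    """Compiled LSODA path for the toy model; returns None if unsupported."""
    from . import _fastpath as fp

    if isinstance(input_fn, InputSpline) and input_fn.log_scale:
        brk, c = input_fn.ppoly_arrays()
        return fp.integrate_toy_spline(k, x0, times, brk, np.ascontiguousarray(c), rtol, atol)
    if isinstance(input_fn, GaussianInput):
        return fp.integrate_toy_gauss(k, x0, times, input_fn.height, input_fn.center,
                                      input_fn.width, rtol, atol)
    return None
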