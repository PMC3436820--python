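"""Ground truth and noisy data generation for the simulation study.

The study design drives the 3-state network with a Gaussian-bell stimulus
peaking at u(25) = 100, samples N = 12 equidistant time points on [0, 50],
observes every state and the input on log10 scale and adds Gaussian noise
there (log-normal on the natural scale): sigma_X = 0.1 for the states and
sigma_u = 0.3 for the input.  Rate constants (0.01, 1, 0.5, 0.1) and
initial concentrations (30, 20, 50) — close to the steady state, which
maximizes the visible effect of the stimulus — complete the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import Dataset
from .models import GaussianInput, ParameterSet, Trajectory, simulate, toy_model

__all__ = ["StudyDesign", "true_input", "true_parameter_set", "true_trajectory",
           "generate_realization"]


@dataclass
class StudyDesign:
    """Defaults of the simulation study; all values configurable."""

    t0: float = 0.0
    t_end: float = 50.0
    n_times: int = 12
    k_true: tuple = (0.01, 1.0, 0.5, 0.1)
    x0_true: tuple = (30.0, 20.0, 50.0)
    input_height: float = 100.0
    input_peak: float = 25.0
    input_width: float = 7.5
    sigma_x: float = 0.1
    sigma_u: float = 0.3

    def __post_init__(self):
        if not (self.t0 <= self.input_peak <= self.t_end):
            raise ValueError("input peak must lie within [t0, t_end]")
        if self.sigma_x < 0 or self.sigma_u < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def times(self) -> np.ndarray:
        """Equidistant sampling times, endpoints included."""
        return np.linspace(self.t0, self.t_end, self.n_times)

    @property
    def input(self) -> GaussianInput:
        return GaussianInput(self.input_height, self.input_peak, self.input_width)


def true_input(t, design: StudyDesign | None = None):
    """Gaussian stimulus u(t) = height * exp(-(t - peak)^2 / (2 w^2))."""
    design = design or StudyDesign()
    return design.input(t)


def true_parameter_set(design: StudyDesign | None = None) -> ParameterSet:
    design = design or StudyDesign()
    model = toy_model()
    return ParameterSet.create(
        names={"dynamic": list(model.dynamic_names), "scaling_offset": [],
               "initial": ["X1_0", "X2_0", "X3_0"], "input_control": []},
        values={"dynamic": np.asarray(design.k_true, dtype=float),
                "initial": np.asarray(design.x0_true, dtype=float)},
    )


def true_trajectory(design: StudyDesign | None = None, times=None) -> Trajectory:
    """Noise-free trajectory of the toy model at the true parameters."""
    design = design or StudyDesign()
    times = design.times if times is None else np.asarray(times, dtype=float)
    return simulate(toy_model(), true_parameter_set(design), design.input, times)


def generate_realization(design: StudyDesign | None = None, seed=0,
                         truth: Trajectory | None = None) -> Dataset:
    """One noisy dataset: log10 observables plus additive Gaussian noise.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    Deterministic given the seed.  Raises if a sampled state is
    non-positive (log10 undefined), naming the offending time.  A zero
    noise level yields exactly the true log10 trajectory; the recorded
    sigma column then falls back to 1 (unit weights) since downstream
    weighting requires positive uncertainties.  ``truth`` may carry a
    precomputed noise-free trajectory at the design times to avoid
    re-simulation in tight replicate loops.
    """
    design = design or StudyDesign()
    traj = truth if truth is not None else true_trajectory(design)
    if np.any(traj.states <= 0):
        i, j = np.argwhere(traj.states <= 0)[0]
        raise ValueError(f"non-positive state {j} at t={traj.times[i]}: cannot take log10")
    rng = np.random.default_rng(seed)
    times = traj.times
    records = []
    obs_names = ["y1", "y2", "y3", "y4"]
    sig = [design.sigma_x] * 3 + [design.sigma_u]
    noise = rng.normal(size=(times.size, 4)) * np.asarray(sig)
    for jcol, (name, s) in enumerate(zip(obs_names, sig)):
        s_rep = s if s > 0 else 1.0
        for irow, t in enumerate(times):
            records.append((t, name, traj.observables[irow, jcol] + noise[irow, jcol], s_rep))
    import pandas as pd

    df = pd.DataFrame(records, columns=["time", "observable", "value", "sigma"])
    return Dataset(df, input_observables=("y4",))
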