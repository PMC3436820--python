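from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from odeinput.assessment import run_study
from odeinput.synthetic import StudyDesign, generate_realization


class GaussianMeanObjective:
    """chi2(mu) = sum ((y_i - mu)/sigma)^2 — closed-form profile oracle.

    Optionally carries a second parameter with no influence on the fit
    (a perfectly flat likelihood direction).
    """

    def __init__(self, y, sigma, extra_flat_param=False):
        self.y = np.asarray(y, dtype=float)
        self.sigma = float(sigma)
        self.extra = extra_flat_param
        n = 2 if extra_flat_param else 1
        self.free_names = ["mu"] + (["ghost"] if extra_flat_param else [])
        self.bounds = np.tile([-5.0, 5.0], (n, 1))
        self.free_log10 = np.array([False] + ([True] if extra_flat_param else []))
        self.input_mode = "frozen"
        self.lam = 0.0

    def residuals(self, x):
        return (self.y - x[0]) / self.sigma

    def __call__(self, x):
        r = self.residuals(x)
        return float(r @ r)


def gaussian_result(y, sigma, **kw):
    """Duck-typed estimation result for the Gaussian-mean oracle."""
    obj = GaussianMeanObjective(y, sigma, **kw)
    mu_hat = float(np.mean(y))
    params = [mu_hat] + ([0.0] if obj.extra else [])
    return SimpleNamespace(objective=obj,
                           params=pd.Series(params, index=obj.free_names),
                           objective_value=obj(np.asarray(params)))


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def noisefree_dataset():
    return generate_realization(StudyDesign(sigma_x=0.0, sigma_u=0.0), seed=0)


@pytest.fixture(scope="session")
def noisy_dataset(design):
    return generate_realization(design, seed=1)


@pytest.fixture(scope="session")
def mc200():
    """Shared M=200 Monte-Carlo study at the reference noise levels,
    default layout (rate constants free, initials known).

    Session-scoped: the distribution-level checks (accuracy, precision
    ratios, score ordering) all read from this one run.
    """
    return run_study(m=200, seed=0)


@pytest.fixture(scope="session")
def mc200_coverage():
    """Companion M=200 study in the seven-parameter layout (rates plus
    initial concentrations free) used for the coverage calibration."""
    return run_study(m=200, seed=0, free_initials=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
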