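"""Compiled integration kernels for the built-in 3-state network.

The Monte-Carlo assessment fits thousands of objectives, each requiring a
full ODE solve; these numba kernels evaluate the right-hand side (with the
input given either as a natural-cubic-spline of the log10 input or as a
Gaussian bell) fast enough that LSODA's Python-callback overhead dominates.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .models import IntegrationError


@njit(cache=True)
def _ppval_clamped(t, brk, c):
    # constant continuation outside the knot span
    if t <= brk[0]:
        t = brk[0]
    elif t >= brk[-1]:
        t = brk[-1]
    i = np.searchsorted(brk, t) - 1
    if i < 0:
        i = 0
    m = brk.shape[0] - 2
    if i > m:
        i = m
    dt = t - brk[i]
    return ((c[0, i] * dt + c[1, i]) * dt + c[2, i]) * dt + c[3, i]


@njit(cache=True)
def _toy_rhs_spline(x, t, k1, km1, k2, km2, brk, c):
    u = 10.0 ** _ppval_clamped(t, brk, c)
    v1 = k1 * u * x[0]
    vm1 = km1 * x[1]
    v2 = k2 * x[1]
    vm2 = km2 * x[2]
    out = np.empty(3)
    out[0] = -v1 + vm1
    out[1] = v1 - vm1 - v2 + vm2
    out[2] = v2 - vm2
    return out


@njit(cache=True)
def _toy_rhs_gauss(x, t, k1, km1, k2, km2, height, center, width):
    u = height * np.exp(-((t - center) ** 2) / (2.0 * width * width))
    v1 = k1 * u * x[0]
    vm1 = km1 * x[1]
    v2 = k2 * x[1]
    vm2 = km2 * x[2]
    out = np.empty(3)
    out[0] = -v1 + vm1
    out[1] = v1 - vm1 - v2 + vm2
    out[2] = v2 - vm2
    return out


@njit(cache=True)
def _jakstat_rhs_spline(y, t, k1, k2, k3, k4, tau, nch, brk, c):
    u = 10.0 ** _ppval_clamped(t, brk, c)
    x4d = y[3] if tau <= 0.0 else y[4 + nch - 1]
    v1 = k1 * u * y[0]
    v2 = k2 * y[1] * y[1]
    v3 = k3 * y[2]
    v4 = k4 * x4d
    out = np.empty(y.shape[0])
    out[0] = -v1 + 2.0 * v4
    out[1] = v1 - 2.0 * v2
    out[2] = v2 - v3
    out[3] = v3 - v4
    if tau > 0.0:
        rate = nch / tau
        out[4] = rate * (y[3] - y[4])
        for i in range(1, nch):
            out[4 + i] = rate * (y[4 + i - 1] - y[4 + i])
    return out


def integrate_jakstat_spline(k, tau, n_chain, x0, times, brk, c, rtol, atol):
    nch = n_chain if tau > 0 else 0
    y0 = np.concatenate([np.asarray(x0, dtype=float), np.zeros(nch)])
    states = _run_odeint(_jakstat_rhs_spline, y0, times,
                         (k[0], k[1], k[2], k[3], float(tau), nch, brk, c), rtol, atol)
    return states[:, :4]


def _run_odeint(rhs, x0, times, args, rtol, atol):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # failures surface as IntegrationError
        states, info = odeint(rhs, np.asarray(x0, dtype=float), times, args=args,
                              rtol=rtol, atol=atol, full_output=True, mxstep=20000)
    if info["message"] != "Integration successful.":
        raise IntegrationError(f"integration failed: {info['message']} (t0={times[0]})")
    return states


def integrate_toy_spline(k, x0, times, brk, c, rtol, atol):
    return _run_odeint(_toy_rhs_spline, x0, times,
                       (k[0], k[1], k[2], k[3], brk, c), rtol, atol)


def integrate_toy_gauss(k, x0, times, height, center, width, rtol, atol):
    return _run_odeint(_toy_rhs_gauss, x0, times,
                       (k[0], k[1], k[2], k[3], height, center, width), rtol, atol)
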