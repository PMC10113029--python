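"""Numba hot loops for year-by-year iteration.

A strategy diagram's projection matrix has exactly two nonzero entries per
column (germination and dormancy), so one year costs O(L) instead of a
dense O(L^2) matvec.  Population state is renormalised to unit total every
year and log growth factors accumulated, the standard stabilisation for
Lyapunov-exponent estimation over 10^5-10^6 years.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lyapunov_logs(eps, grow, drow, gv0, gv1, dv0, dv1, N, burn_in):
    """Iterate N_t = M(eps_t) N_{t-1} with 1-norm renormalisation.

    Returns (per-year log growth factors after burn-in, years completed,
    extinct flag).  ``grow``/``drow`` are germination/dormancy successor
    rows; ``gv*``/``dv*`` the column weights per environment.
    """
    T = eps.shape[0]
    L = N.shape[0]
    logs = np.zeros(T - burn_in)
    Nn = np.zeros(L)
    for t in range(T):
        for i in range(L):
            Nn[i] = 0.0
        if eps[t] == 1:
            for s in range(L):
                Nn[grow[s]] += gv1[s] * N[s]
                Nn[drow[s]] += dv1[s] * N[s]
        else:
            for s in range(L):
                Nn[grow[s]] += gv0[s] * N[s]
                Nn[drow[s]] += dv0[s] * N[s]
        tot = 0.0
        for i in range(L):
            tot += Nn[i]
        if tot <= 0.0:
            return logs, t, True
        inv = 1.0 / tot
        for i in range(L):
            N[i] = Nn[i] * inv
        if t >= burn_in:
            logs[t - burn_in] = np.log(tot)
    return logs, T, False


@njit(cache=True)
def lineage_selected(eps, q, grow, drow, f00, f01, f10, f11, u, s0):
    """Selection-weighted single-lineage simulation.

    Each year the phenotype is drawn with probability proportional to
    strategy weight times fitness: P(germinate) =
    q_s*f[eps,1] / (q_s*f[eps,1] + (1-q_s)*f[eps,0]).  ``u`` are
    pre-drawn Uniform(0,1) variates, one per year.  Returns
    (state-before-year, phenotype, error_year); error_year >= 0 flags a
    year whose total weight was zero.
    """
    T = eps.shape[0]
    alpha_prev = np.empty(T, dtype=np.int64)
    phi = np.empty(T, dtype=np.int8)
    s = s0
    for t in range(T):
        alpha_prev[t] = s
        if eps[t] == 1:
            w0 = (1.0 - q[s]) * f10
            w1 = q[s] * f11
        else:
            w0 = (1.0 - q[s]) * f00
            w1 = q[s] * f01
        tot = w0 + w1
        if tot <= 0.0:
            return alpha_prev, phi, t
        if u[t] * tot < w1:
            phi[t] = 1
            s = grow[s]
        else:
            phi[t] = 0
            s = drow[s]
    return alpha_prev, phi, -1


@njit(cache=True)
def lineage_neutral(T, q, grow, drow, u, s0):
    """Neutral single-lineage simulation: P(germinate) = q_s, no fitness
    weighting and no environment."""
    alpha_prev = np.empty(T, dtype=np.int64)
    phi = np.empty(T, dtype=np.int8)
    s = s0
    for t in range(T):
        alpha_prev[t] = s
        if u[t] < q[s]:
            phi[t] = 1
            s = grow[s]
        else:
            phi[t] = 0
            s = drow[s]
    return alpha_prev, phi
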