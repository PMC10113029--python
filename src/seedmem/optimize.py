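"""Maximising the growth rate over germination schedules.

The Lyapunov exponent is a Monte-Carlo quantity; optimisation uses common
random numbers — one fixed training environment sequence per run, making
the objective deterministic — with an independent sequence for the final
evaluation.  Germination probabilities are optimised through a logistic
reparameterisation (unconstrained reals mapped to (0,1)) with
derivative-free Nelder-Mead and multi-start: one start at the constant
analytic optimum q*, the rest random.

Three levels of search:

* ``optimize_weights`` — per-state probabilities for a fixed topology;
* ``memory_sweep`` — the age diagram across memory capacities L,
  warm-starting each L from the previous optimum (the nested family makes
  Lambda(L) non-decreasing on the training sequence by construction);
* ``diagram_search`` — every deduplicated topology of a given size.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy.special import expit, logit

from .analytic import optimal_q
from .diagrams import FitnessMatrix, StrategyDiagram, make_age_diagram, enumerate_diagrams
from .environment import EnvironmentSequence, stationary_frequency
from .growth import DEFAULT_BURN_IN, GrowthEstimate, lyapunov_exponent, lyapunov_value
from .lineage import lineage_mutual_information, simulate_lineage_selected

__all__ = [
    "OptimizationResult",
    "optimize_weights",
    "memory_sweep",
    "diagram_search",
    "leader_set",
]

DEFAULT_RESTARTS = 5
DEFAULT_TOL = 1e-6
Q_CLIP = 1e-6


@dataclasses.dataclass(frozen=True)
class OptimizationResult:
    """Optimised strategy with training and held-out growth estimates."""

    diagram: StrategyDiagram
    lambda_train: float
    lambda_opt: GrowthEstimate
    restarts: int
    converged: bool
    n_eval: int


def _as_values(env) -> np.ndarray:
    v = env.values if isinstance(env, EnvironmentSequence) else np.asarray(env)
    return v.astype(np.int8)


def optimize_weights(d: StrategyDiagram, f: FitnessMatrix,
                     env_train: EnvironmentSequence | np.ndarray,
                     env_eval: EnvironmentSequence | np.ndarray | None = None,
                     restarts: int = DEFAULT_RESTARTS,
                     tol: float = DEFAULT_TOL,
                     rng: np.random.Generator | int | None = None,
                     q0: np.ndarray | None = None,
                     burn_in: int = DEFAULT_BURN_IN) -> OptimizationResult:
    """Maximise Lambda(q) for a fixed topology on a fixed training sequence.

    Starts from the constant analytic optimum q* (computed at the training
    sequence's empirical good-year frequency), from ``q0`` if given (warm
    start), and from ``restarts - 1`` random vectors; returns the best.
    ``lambda_opt`` is re-estimated on ``env_eval`` when provided (else on
    the training sequence).
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eps = _as_values(env_train)
    L = d.L

    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        lam = lyapunov_value(d.with_q(expit(x)), f, eps, burn_in=burn_in)
        return 1e12 if not np.isfinite(lam) else -lam

    p_hat = float(np.mean(eps[burn_in:]))
    try:
        q_star = optimal_q(p_hat, f.V, f.Y1)
    except ValueError:
        q_star = 0.5
    starts = [np.full(L, np.clip(q_star, 1e-3, 1 - 1e-3))]
    if q0 is not None:
        starts.append(np.clip(np.asarray(q0, dtype=float), 1e-3, 1 - 1e-3))
    for _ in range(restarts - 1):
        starts.append(gen.uniform(0.05, 0.95, size=L))

    best = None
    converged = False
    for q_init in starts:
        res = sp_optimize.minimize(
            objective, logit(q_init), method="Nelder-Mead",
            options={"fatol": tol, "xatol": 2e-3, "maxfev": 150 * L,
                     "adaptive": L >= 6})
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    q_opt = np.clip(expit(best.x), Q_CLIP, 1 - Q_CLIP)
    d_opt = d.with_q(q_opt)
    lam_train = -float(best.fun)
    eval_env = env_eval if env_eval is not None else env_train
    est = lyapunov_exponent(d_opt, f, eval_env, burn_in=burn_in)
    return OptimizationResult(diagram=d_opt, lambda_train=lam_train,
                              lambda_opt=est, restarts=restarts,
                              converged=converged, n_eval=n_eval)


def memory_sweep(L_values, f: FitnessMatrix,
                 env_train: EnvironmentSequence | np.ndarray,
                 env_eval: EnvironmentSequence | np.ndarray,
                 restarts: int = DEFAULT_RESTARTS,
                 rng: np.random.Generator | int | None = None,
                 burn_in: int = DEFAULT_BURN_IN,
                 attach_info: bool = True) -> pd.DataFrame:
    """Optimise the age diagram for each memory capacity L.

    Returns a DataFrame with one row per L: the optimised germination
    schedule, Lambda with standard error on the held-out sequence, and
    (optionally) the lineage mutual information I(eps_t; alpha_{t-1}) of
    the optimised strategy, in nats.
    """
    L_values = list(L_values)
    if L_values != sorted(L_values):
        raise ValueError("L_values must be sorted ascending")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    prev_q = None
    for L in L_values:
        d = make_age_diagram(L, 0.5)
        warm = None
        if prev_q is not None and len(prev_q) <= L:
            warm = np.concatenate([prev_q, np.full(L - len(prev_q), prev_q[-1])])
        res = optimize_weights(d, f, env_train, env_eval=env_eval,
                               restarts=restarts, rng=gen, q0=warm,
                               burn_in=burn_in)
        prev_q = res.diagram.q
        info = np.nan
        if attach_info:
            rec = simulate_lineage_selected(res.diagram, f, env_eval, rng=gen)
            info = lineage_mutual_information(rec, burn_in=burn_in).I
        rows.append({"L": L, "lambda": res.lambda_opt.lam,
                     "se": res.lambda_opt.se, "I": info,
                     "lambda_train": res.lambda_train,
                     "q": res.diagram.q.tolist()})
    return pd.DataFrame(rows)


def diagram_search(L: int, f: FitnessMatrix,
                   env_train: EnvironmentSequence | np.ndarray,
                   env_eval: EnvironmentSequence | np.ndarray,
                   restarts: int = DEFAULT_RESTARTS,
                   rng: np.random.Generator | int | None = None,
                   burn_in: int = DEFAULT_BURN_IN) -> list[OptimizationResult]:
    """Optimise every deduplicated topology on L states; rank by held-out
    Lambda (descending).  Monte-Carlo noise cannot resolve sub-se gaps, so
    consumers should treat ``leader_set`` as the winners, not just rank 0."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    results = []
    for topo in enumerate_diagrams(L, dedup=True):
        res = optimize_weights(topo, f, env_train, env_eval=env_eval,
                               restarts=restarts, rng=gen, burn_in=burn_in)
        results.append(res)
    results.sort(key=lambda r: r.lambda_opt.lam, reverse=True)
    return results


def leader_set(results: list[OptimizationResult],
               k_se: float = 1.0) -> list[OptimizationResult]:
    """Results within ``k_se`` combined standard errors of the best."""
    if not results:
        return []
    best = results[0]
    out = []
    for r in results:
        combined = float(np.hypot(best.lambda_opt.se, r.lambda_opt.se))
        if best.lambda_opt.lam - r.lambda_opt.lam <= k_se * combined:
            out.append(r)
    return out
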