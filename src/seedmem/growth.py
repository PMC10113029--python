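"""Long-term growth rate as a Lyapunov exponent.

The age-structured population N_t evolves by N_t = M(eps_t; q) N_{t-1}
with environment-dependent projection matrices, and the long-term growth
rate Lambda is the Lyapunov exponent of the random matrix product.  It is
estimated by iterating the population vector with yearly 1-norm
renormalisation and averaging the accumulated log factors; the standard
error comes from batch means.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernels
from .diagrams import FitnessMatrix, StrategyDiagram, TransitionMatrix
from .environment import EnvironmentSequence

__all__ = [
    "PopulationVector",
    "GrowthEstimate",
    "population_step",
    "lyapunov_exponent",
]

DEFAULT_BURN_IN = 1000
DEFAULT_BATCHES = 100


@dataclasses.dataclass(frozen=True)
class PopulationVector:
    """Abundances per diagram state at one point in time."""

    N: np.ndarray
    t: int = 0

    @property
    def extinct(self) -> bool:
        return not (np.asarray(self.N) > 0).any()


@dataclasses.dataclass(frozen=True)
class GrowthEstimate:
    """Estimated Lyapunov exponent (nats/year) with batch-means error."""

    lam: float
    se: float
    T_used: int
    burn_in: int
    extinct: bool = False


def population_step(N: PopulationVector | np.ndarray,
                    M: TransitionMatrix | np.ndarray) -> np.ndarray:
    """One year of the matrix model: N_t = M . N_{t-1} (no normalisation)."""
    n = N.N if isinstance(N, PopulationVector) else np.asarray(N, dtype=float)
    m = M.M if isinstance(M, TransitionMatrix) else np.asarray(M, dtype=float)
    if m.shape[1] != n.shape[0]:
        raise ValueError(f"dimension mismatch: matrix {m.shape} vs vector {n.shape}")
    return m @ n


def _sparse_action(d: StrategyDiagram, f: FitnessMatrix):
    """Per-environment column weights for the two-nonzeros-per-column form."""
    q = d.q
    gv0 = q * f.yield_in(0)
    gv1 = q * f.yield_in(1)
    dv0 = (1 - q) * f.viability_in(0)
    dv1 = (1 - q) * f.viability_in(1)
    return d.germ_succ, d.dorm_succ, gv0, gv1, dv0, dv1


def lyapunov_exponent(d: StrategyDiagram, f: FitnessMatrix,
                      env: EnvironmentSequence | np.ndarray,
                      burn_in: int = DEFAULT_BURN_IN,
                      batches: int = DEFAULT_BATCHES,
                      N0: np.ndarray | None = None) -> GrowthEstimate:
    """Estimate Lambda on a given environment sequence.

    Iterates from the uniform vector (or ``N0``), renormalising yearly and
    averaging post-burn-in log factors; ``se`` is the batch-means standard
    error over ``batches`` equal batches.  An exactly zero population
    (possible with q=1, Y0=0 in a bad year) sets ``extinct`` and
    lam = -inf.
    """
    eps = env.values if isinstance(env, EnvironmentSequence) else np.asarray(env, dtype=np.int8)
    if eps.size <= burn_in:
        raise ValueError(f"environment length {eps.size} must exceed burn_in {burn_in}")
    N = (np.full(d.L, 1.0 / d.L) if N0 is None
         else np.asarray(N0, dtype=float) / np.sum(N0))
    grow, drow, gv0, gv1, dv0, dv1 = _sparse_action(d, f)
    logs, t_done, extinct = _kernels.lyapunov_logs(
        eps.astype(np.int8), grow, drow, gv0, gv1, dv0, dv1, N, burn_in)
    if extinct:
        return GrowthEstimate(lam=-np.inf, se=0.0, T_used=t_done,
                              burn_in=burn_in, extinct=True)
    lam = float(np.mean(logs))
    nb = min(batches, logs.size)
    per = logs.size // nb
    bm = logs[:nb * per].reshape(nb, per).mean(axis=1)
    se = float(np.std(bm, ddof=1) / np.sqrt(nb)) if nb > 1 else 0.0
    return GrowthEstimate(lam=lam, se=se, T_used=eps.size, burn_in=burn_in)


def lyapunov_value(d: StrategyDiagram, f: FitnessMatrix, eps: np.ndarray,
                   burn_in: int = DEFAULT_BURN_IN) -> float:
    """Fast objective-only Lambda (no standard error); -inf if extinct."""
    N = np.full(d.L, 1.0 / d.L)
    grow, drow, gv0, gv1, dv0, dv1 = _sparse_action(d, f)
    logs, _, extinct = _kernels.lyapunov_logs(
        eps, grow, drow, gv0, gv1, dv0, dv1, N, burn_in)
    return -np.inf if extinct else float(np.mean(logs))
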