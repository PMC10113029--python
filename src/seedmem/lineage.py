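"""Single-lineage simulations and their information/duration statistics.

Two samplers over a strategy diagram:

* *selection-weighted*: follow one line of descent through the varying
  environment, drawing each year's phenotype with probability
  proportional to strategy weight times fitness, so that the lineage
  statistics reflect what selection leaves behind.  The joint
  distribution of (coming environment, seed state) estimated from such a
  lineage quantifies how informative the internal state is about the
  environment.
* *neutral*: the same machine run without environment or fitness —
  the thought experiment of germinating fresh seeds in constant
  conditions.  The run-length distribution of the dormant phenotype is
  then the experimental signature of memory: geometric means memoryless,
  a bell shape means the seed tracks how long it has been dormant.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from . import _kernels
from .analytic import InfoSummary, mutual_information_table
from .diagrams import FitnessMatrix, StrategyDiagram
from .environment import EnvironmentSequence

__all__ = [
    "LineageRecord",
    "JointTable",
    "RunLengthSummary",
    "simulate_lineage_selected",
    "simulate_lineage_neutral",
    "joint_env_age",
    "phenotype_run_lengths",
    "lineage_mutual_information",
]

DEFAULT_BURN_IN = 1000
Q_CLIP = 1e-6
MIN_RELIABLE_RUNS = 30


class SimulationError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class LineageRecord:
    """One simulated lineage: per-year environment (if any), the diagram
    state at the start of the year, and the phenotype chosen."""

    eps: np.ndarray | None          # environment per year, or None (neutral)
    alpha_prev: np.ndarray          # state before the year's decision
    phi: np.ndarray                 # 0 dormant, 1 germinate
    L: int
    selected: bool
    seed: int | None = None

    def __len__(self) -> int:
        return self.phi.size


@dataclasses.dataclass(frozen=True)
class JointTable:
    """Empirical joint P(eps, alpha): rows eps in {0,1}, columns states."""

    probs: np.ndarray
    n: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != 2 or (p < 0).any():
            raise ValueError("joint table must be nonnegative with 2 rows")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("joint table must sum to 1")
        object.__setattr__(self, "probs", p)

    def conditional_env(self) -> np.ndarray:
        """P(eps = 1 | alpha) per state (nan where a state was never seen)."""
        col = self.probs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.probs[1] / col

    def marginal_env(self) -> float:
        return float(self.probs[1].sum())


@dataclasses.dataclass(frozen=True)
class RunLengthSummary:
    """Histograms of maximal constant-phenotype runs and geometric GOF.

    A 'duration' is the length of a maximal block of consecutive identical
    phenotypes, in years, with boundary-truncated blocks excluded.  The
    geometric fit uses the MLE continuation parameter from the mean and a
    chi-square with tail pooling so every expected bin count is >= 5.
    """

    germ_lengths: np.ndarray
    dorm_lengths: np.ndarray
    germ_mean: float
    dorm_mean: float
    germ_gof: tuple[float, float]   # (chi2 statistic, p-value)
    dorm_gof: tuple[float, float]
    reliable: bool


def _clip_q(d: StrategyDiagram) -> StrategyDiagram:
    return d.with_q(np.clip(d.q, Q_CLIP, 1 - Q_CLIP))


def simulate_lineage_selected(d: StrategyDiagram, f: FitnessMatrix,
                              env: EnvironmentSequence | np.ndarray,
                              rng: np.random.Generator | int | None = None,
                              s0: int = 0) -> LineageRecord:
    """Selection-weighted lineage along a given environment sequence.

    With the default Y0 = 0 fitness, a lineage never germinates in a bad
    year (zero weight), so dormancy runs become entrained to bad runs.
    Germination probabilities are clipped to [1e-6, 1-1e-6] to keep the
    weighting normaliser positive.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eps = env.values if isinstance(env, EnvironmentSequence) else np.asarray(env, dtype=np.int8)
    dc = _clip_q(d)
    fa = f.as_array()
    u = gen.random(eps.size)
    alpha_prev, phi, err = _kernels.lineage_selected(
        eps.astype(np.int8), dc.q, dc.germ_succ, dc.dorm_succ,
        fa[0, 0], fa[0, 1], fa[1, 0], fa[1, 1], u, s0)
    if err >= 0:
        raise SimulationError(
            f"zero total weight at year {err} (state {int(alpha_prev[err])}, "
            f"eps {int(eps[err])}): both fitness entries vanish")
    return LineageRecord(eps=eps, alpha_prev=alpha_prev, phi=phi, L=d.L,
                         selected=True, seed=seed)


def simulate_lineage_neutral(d: StrategyDiagram, T: int,
                             rng: np.random.Generator | int | None = None,
                             s0: int = 0) -> LineageRecord:
    """Neutral lineage: germinate with probability q_s, no environment."""
    if T < 1:
        raise ValueError("T must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    u = gen.random(T)
    alpha_prev, phi = _kernels.lineage_neutral(T, d.q, d.germ_succ, d.dorm_succ,
                                               u, s0)
    return LineageRecord(eps=None, alpha_prev=alpha_prev, phi=phi, L=d.L,
                         selected=False, seed=seed)


def joint_env_age(rec: LineageRecord,
                  burn_in: int = DEFAULT_BURN_IN) -> JointTable:
    """Empirical joint P(eps_t, alpha_{t-1}) from a selection-weighted lineage."""
    if rec.eps is None:
        raise ValueError("joint environment/age table requires a "
                         "selection-weighted record with environments")
    if len(rec) <= burn_in:
        raise ValueError("record shorter than burn-in")
    eps = rec.eps[burn_in:]
    alpha = rec.alpha_prev[burn_in:]
    counts = np.zeros((2, rec.L))
    np.add.at(counts, (eps.astype(np.int64), alpha), 1.0)
    n = eps.size
    return JointTable(probs=counts / n, n=n)


def lineage_mutual_information(rec: LineageRecord,
                               burn_in: int = DEFAULT_BURN_IN) -> InfoSummary:
    """I(eps_t; alpha_{t-1}) in nats, plug-in from the empirical joint."""
    return mutual_information_table(joint_env_age(rec, burn_in=burn_in).probs)


def _complete_runs(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(lengths, phenotype per run) with boundary-truncated runs dropped."""
    edges = np.flatnonzero(np.diff(phi)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [phi.size]))
    lengths, vals = ends - starts, phi[starts]
    if lengths.size <= 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int8)
    return lengths[1:-1], vals[1:-1]


def geometric_gof(lengths: np.ndarray, min_expected: float = 5.0,
                  ) -> tuple[float, float]:
    """Chi-square goodness of fit of run lengths to a geometric law.

    The continuation parameter is the MLE from the sample mean
    (c = 1 - 1/mean, support k >= 1); bins are pooled from the upper tail
    downward so that every expected count is at least ``min_expected``;
    one degree of freedom is removed for the estimated parameter.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    n = lengths.size
    if n < 2:
        return np.nan, np.nan
    m = lengths.mean()
    c = 1.0 - 1.0 / m
    if c <= 0.0:  # all runs of length 1: degenerate, perfect geometric fit
        return 0.0, 1.0
    kmax = int(lengths.max())
    obs = np.bincount(lengths, minlength=kmax + 2)[1:kmax + 1].astype(float)
    pk = (1 - c) * c ** (np.arange(1, kmax + 1) - 1.0)
    pk[-1] += c ** kmax  # fold the infinite tail into the last bin
    exp = n * pk
    # pool from the top until the tail bin's expectation reaches the floor
    while exp.size > 2 and exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        exp, obs = exp[:-1], obs[:-1]
    if exp.size < 3:
        return 0.0, 1.0  # too few distinct lengths to test against
    stat, p = stats.chisquare(obs, exp, ddof=1)
    return float(stat), float(p)


def phenotype_run_lengths(rec: LineageRecord,
                          burn_in: int = 0) -> RunLengthSummary:
    """Run-length statistics of germination and dormancy along a lineage."""
    phi = rec.phi[burn_in:] if burn_in else rec.phi
    if phi.size == 0:
        raise ValueError("empty phenotype sequence")
    lengths, vals = _complete_runs(phi)
    germ = lengths[vals == 1]
    dorm = lengths[vals == 0]
    return RunLengthSummary(
        germ_lengths=germ,
        dorm_lengths=dorm,
        germ_mean=float(germ.mean()) if germ.size else np.nan,
        dorm_mean=float(dorm.mean()) if dorm.size else np.nan,
        germ_gof=geometric_gof(germ),
        dorm_gof=geometric_gof(dorm),
        reliable=(germ.size >= MIN_RELIABLE_RUNS and dorm.size >= MIN_RELIABLE_RUNS),
    )
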