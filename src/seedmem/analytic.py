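"""Closed-form bet-hedging theory for seed dormancy.

Cohen's model: a constant fraction q of seeds germinates each year.  In a
good year (frequency p) the seed count multiplies by (1-q)V + qY; in a bad
year germinated plants yield nothing and only the dormant, still-viable
fraction (1-q)V survives.  The long-term (log) growth rate is

    Lambda(q) = p*ln((1-q)V + qY) + (1-p)*ln((1-q)V)

maximised at q* = (pY - V)/(Y - V) for p > V/Y (else 0), which tends to
the classic q* ~ p as Y >> V.

In the extreme-selection limit the fitness matrix is diagonal (germinating
in a bad year and staying dormant in a good year both contribute nothing),
and the growth-rate hierarchy becomes exact Kelly/proportional-betting
information arithmetic:

    Lambda_max  = p*ln(Y) + (1-p)*ln(V)          (perfect foresight)
    Lambda_bet  = Lambda_max - H(eps)            (no cue)
    Lambda_cue  = Lambda_bet + I(eps; xi)        (external cue xi)

All information quantities are in nats, so growth rates (nats/year) and
information share an axis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import xlogy

__all__ = [
    "CueTable",
    "InfoSummary",
    "growth_rate_constant_q",
    "optimal_q",
    "entropy_binary",
    "mutual_information_table",
    "diagonal_growth_rates",
]

NATS_PER_BIT = float(np.log(2.0))


@dataclasses.dataclass(frozen=True)
class CueTable:
    """Joint distribution P(eps, xi) over environment (rows, eps in {0,1})
    and a discrete cue xi (columns)."""

    joint: np.ndarray

    def __post_init__(self) -> None:
        j = np.asarray(self.joint, dtype=float)
        if j.ndim != 2 or j.shape[0] != 2:
            raise ValueError("cue table must be 2 x m (rows are eps = 0, 1)")
        if (j < 0).any():
            raise ValueError("cue table entries must be nonnegative")
        if abs(j.sum() - 1.0) > 1e-9:
            raise ValueError(f"cue table sums to {j.sum()}, not 1")
        object.__setattr__(self, "joint", j)

    @property
    def p_good(self) -> float:
        return float(self.joint[1].sum())


@dataclasses.dataclass(frozen=True)
class InfoSummary:
    """Entropy budget of a binary environment given a cue or internal state.

    ``H_env`` is the marginal entropy H(eps), ``H_cond`` the conditional
    entropy given the cue, and ``I = H_env - H_cond`` the mutual
    information, all in nats.
    """

    H_env: float
    H_cond: float
    I: float

    def in_bits(self) -> "InfoSummary":
        return InfoSummary(self.H_env / NATS_PER_BIT, self.H_cond / NATS_PER_BIT,
                           self.I / NATS_PER_BIT)


def growth_rate_constant_q(q: float, p: float, V: float, Y: float) -> float:
    """Long-term growth rate of the constant-q strategy (nats/year).

    Returns -inf on the q = 1, p < 1 boundary (with Y0 = 0, one bad year
    wipes out a fully germinating population); optimizers traverse it.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if not 0.0 < V <= 1.0:
        raise ValueError("V must be in (0, 1]")
    if Y < 0 or not 0.0 <= p <= 1.0:
        raise ValueError("need Y >= 0 and 0 <= p <= 1")
    good = (1 - q) * V + q * Y
    bad = (1 - q) * V
    with np.errstate(divide="ignore"):
        return float(p * np.log(good) + (1 - p) * np.log(bad)) if p < 1 \
            else float(np.log(good))


def optimal_q(p: float, V: float, Y: float) -> float:
    """Germination fraction maximising the constant-q growth rate.

    q* = (pY - V)/(Y - V) when p > V/Y, else 0; tends to p as Y -> inf.
    """
    if not 0.0 < V <= 1.0:
        raise ValueError("V must be in (0, 1]")
    if Y <= V:
        raise ValueError("optimum undefined for Y <= V")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p <= V / Y:
        return 0.0
    return (p * Y - V) / (Y - V)


def entropy_binary(p: float) -> float:
    """Shannon entropy of a Bernoulli(p) year, in nats (0*ln 0 = 0)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return float(-(xlogy(p, p) + xlogy(1 - p, 1 - p)))


def mutual_information_table(joint: CueTable | np.ndarray) -> InfoSummary:
    """Plug-in mutual information of a 2 x m joint table (nats).

    Works for external-cue tables P(eps, xi) and for lineage joint tables
    P(eps, age) alike; rows are the two environments.
    """
    j = joint.joint if isinstance(joint, CueTable) else np.asarray(joint, dtype=float)
    if j.ndim != 2:
        raise ValueError("joint table must be 2-dimensional")
    if (j < 0).any():
        raise ValueError("joint table entries must be nonnegative")
    total = j.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"joint table sums to {total}, not 1")
    j = j / total
    p_env = j.sum(axis=1)
    p_cue = j.sum(axis=0)
    outer = np.outer(p_env, p_cue)
    nz = j > 0
    info = float(np.sum(j[nz] * np.log(j[nz] / outer[nz])))
    info = max(info, 0.0)
    h_env = float(-np.sum(xlogy(p_env, p_env)))
    return InfoSummary(H_env=h_env, H_cond=h_env - info, I=info)


def diagonal_growth_rates(p: float, V: float, Y: float,
                          cue: CueTable | None = None,
                          ) -> tuple[float, float, float | None]:
    """(Lambda_max, Lambda_bet, Lambda_cue) in the diagonal-fitness limit.

    With fitness f = [[V, 0], [0, Y]] the optimal strategy bets
    proportionally on the environment (Kelly), so the three rates are
    computed by three *independent* routes:

    - Lambda_max: always-correct phenotype, p*ln Y + (1-p)*ln V;
    - Lambda_bet: proportional betting q = p without a cue,
      p*ln(pY) + (1-p)*ln((1-p)V);
    - Lambda_cue: per-cue proportional betting q(xi) = P(eps=1 | xi),
      sum_xi P(xi) [ P(1|xi) ln(P(1|xi) Y) + P(0|xi) ln(P(0|xi) V) ].

    The identities Lambda_bet = Lambda_max - H(eps) and
    Lambda_cue = Lambda_bet + I(eps; xi) then hold exactly.
    """
    if not 0.0 < V <= 1.0 or Y <= 0 or not 0.0 <= p <= 1.0:
        raise ValueError("need 0 < V <= 1, Y > 0, 0 <= p <= 1")
    lam_max = float(p * np.log(Y) + (1 - p) * np.log(V))
    lam_bet = float(xlogy(p, p * Y) + xlogy(1 - p, (1 - p) * V))
    lam_cue = None
    if cue is not None:
        if abs(cue.p_good - p) > 1e-9:
            raise ValueError(f"cue table environment marginal {cue.p_good} "
                             f"does not match p = {p}")
        j = cue.joint
        p_xi = j.sum(axis=0)
        lam_cue = 0.0
        for col in range(j.shape[1]):
            if p_xi[col] <= 0:
                continue
            c0, c1 = j[0, col] / p_xi[col], j[1, col] / p_xi[col]
            lam_cue += p_xi[col] * (xlogy(c1, c1 * Y) + xlogy(c0, c0 * V))
        lam_cue = float(lam_cue)
    return lam_max, lam_bet, lam_cue
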