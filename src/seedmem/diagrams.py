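"""Finite-state germination strategies and their projection matrices.

A strategy diagram is a finite-state machine over L internal seed states.
A seed in state s germinates with probability q_s; if it germinates, the
new seeds it produces start in state ``germ_succ[s]``; if it stays
dormant, it moves to state ``dorm_succ[s]``.  The *age diagram* is the
special case where dormancy increments the age (capped at L-1) and every
new seed starts at age 0 — L is then the memory capacity: L=1 is
memoryless bet-hedging, L=2 is Markovian phenotypic switching.

Per environment eps the population of state-counts N evolves by a
projection matrix M(eps; q) whose column s carries q_s*Y_eps into row
germ_succ[s] and (1-q_s)*V into row dorm_succ[s].  For the age diagram
this is the Leslie-like layout: first row q_alpha*Y_eps, sub-diagonal
(1-q_alpha)*V, terminal self-loop (1-q_{L-1})*V.

The module also enumerates all diagram topologies of a given size (every
pair of successor maps), pruned of states unreachable from germination
targets and optionally deduplicated up to state relabeling — the search
space for asking which *form* of memory is optimal.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from typing import Iterator

import numpy as np

__all__ = [
    "FitnessMatrix",
    "StrategyDiagram",
    "TransitionMatrix",
    "make_age_diagram",
    "transition_matrix",
    "enumerate_diagrams",
    "canonical_form",
]


@dataclasses.dataclass(frozen=True)
class FitnessMatrix:
    """Per-year multiplicative fitness f[eps, phi].

    Rows are environments (bad, good); columns are phenotypes (dormant,
    germinate): f = [[V, Y0], [V, Y1]].  V is the probability a dormant
    seed stays viable for another year; Y0/Y1 the seed yield of a plant
    germinating in a bad/good year.  ``diagonal=True`` selects the
    extreme-selection variant f = [[V, 0], [0, Y1]] in which a dormant
    seed also contributes nothing in a good year.
    """

    V: float = 0.9
    Y0: float = 0.0
    Y1: float = 4.0
    diagonal: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.V <= 1.0:
            raise ValueError("V must be in (0, 1]")
        if self.Y0 < 0 or self.Y1 < 0:
            raise ValueError("yields must be nonnegative")

    def as_array(self) -> np.ndarray:
        if self.diagonal:
            return np.array([[self.V, 0.0], [0.0, self.Y1]])
        return np.array([[self.V, self.Y0], [self.V, self.Y1]])

    def yield_in(self, eps: int) -> float:
        return float(self.as_array()[eps, 1])

    def viability_in(self, eps: int) -> float:
        return float(self.as_array()[eps, 0])


@dataclasses.dataclass(frozen=True)
class StrategyDiagram:
    """L states with germination probabilities and successor maps."""

    L: int
    q: np.ndarray
    dorm_succ: np.ndarray
    germ_succ: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        ds = np.asarray(self.dorm_succ, dtype=np.int64)
        gs = np.asarray(self.germ_succ, dtype=np.int64)
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if q.shape != (self.L,) or ds.shape != (self.L,) or gs.shape != (self.L,):
            raise ValueError("q, dorm_succ, germ_succ must all have length L")
        if ((q < 0) | (q > 1)).any():
            raise ValueError("germination probabilities must lie in [0, 1]")
        for m in (ds, gs):
            if ((m < 0) | (m >= self.L)).any():
                raise ValueError("successor maps must land in 0..L-1")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "dorm_succ", ds)
        object.__setattr__(self, "germ_succ", gs)

    def with_q(self, q: np.ndarray) -> "StrategyDiagram":
        return StrategyDiagram(self.L, np.asarray(q, dtype=float),
                               self.dorm_succ, self.germ_succ)

    def is_age_diagram(self) -> bool:
        L = self.L
        return (np.array_equal(self.dorm_succ, np.minimum(np.arange(L) + 1, L - 1))
                and (self.germ_succ == 0).all())

    def reachable_states(self) -> np.ndarray:
        """States reachable from germination targets (where new seeds land)."""
        reach = set(int(s) for s in self.germ_succ)
        frontier = list(reach)
        while frontier:
            s = frontier.pop()
            for t in (int(self.dorm_succ[s]), int(self.germ_succ[s])):
                if t not in reach:
                    reach.add(t)
                    frontier.append(t)
        return np.array(sorted(reach), dtype=np.int64)

    def pruned(self) -> "StrategyDiagram":
        """Drop unreachable states and relabel compactly (order-preserving)."""
        keep = self.reachable_states()
        if keep.size == self.L:
            return self
        relabel = -np.ones(self.L, dtype=np.int64)
        relabel[keep] = np.arange(keep.size)
        return StrategyDiagram(int(keep.size), self.q[keep],
                               relabel[self.dorm_succ[keep]],
                               relabel[self.germ_succ[keep]])

    def to_json(self) -> str:
        return json.dumps({"L": self.L, "q": self.q.tolist(),
                           "dorm_succ": self.dorm_succ.tolist(),
                           "germ_succ": self.germ_succ.tolist()})

    @staticmethod
    def from_json(text: str) -> "StrategyDiagram":
        d = json.loads(text)
        return StrategyDiagram(int(d["L"]), np.array(d["q"], dtype=float),
                               np.array(d["dorm_succ"]), np.array(d["germ_succ"]))


@dataclasses.dataclass(frozen=True)
class TransitionMatrix:
    """Dense projection matrix M for one environment."""

    M: np.ndarray
    eps: int


def make_age_diagram(L: int, q: np.ndarray | float) -> StrategyDiagram:
    """Age diagram: dormancy ages the seed (capped at L-1), new seeds are age 0.

    A scalar q gives the constant-germination (bet-hedging) strategy on L
    truncated age states.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    q = np.full(L, float(q)) if np.isscalar(q) else np.asarray(q, dtype=float)
    if q.shape != (L,):
        raise ValueError(f"q must have length L = {L}")
    dorm = np.minimum(np.arange(L) + 1, L - 1)
    germ = np.zeros(L, dtype=np.int64)
    return StrategyDiagram(L, q, dorm, germ)


def transition_matrix(d: StrategyDiagram, f: FitnessMatrix,
                      eps: int) -> TransitionMatrix:
    """Projection matrix for one year in environment eps."""
    if eps not in (0, 1):
        raise ValueError("eps must be 0 (bad) or 1 (good)")
    Y = f.yield_in(eps)
    V = f.viability_in(eps)
    M = np.zeros((d.L, d.L))
    for s in range(d.L):
        M[d.germ_succ[s], s] += d.q[s] * Y
        M[d.dorm_succ[s], s] += (1 - d.q[s]) * V
    return TransitionMatrix(M=M, eps=eps)


# ---------------------------------------------------------------------------
# topology enumeration and canonicalisation

def canonical_form(d: StrategyDiagram) -> tuple:
    """Relabeling-invariant encoding of a diagram topology.

    Unreachable states are pruned first; the encoding is the
    lexicographically minimal (germ_succ, dorm_succ) tuple over all
    permutations of the remaining states.  Two diagrams get the same
    encoding iff their pruned topologies are related by a state
    relabeling.  The age diagram of size L encodes as
    germ = (0,)*L, dorm = (1, 2, ..., L-1, L-1).
    """
    p = d.pruned()
    L = p.L
    best = None
    for perm in itertools.permutations(range(L)):
        relabel = np.empty(L, dtype=np.int64)
        relabel[list(perm)] = np.arange(L)
        order = np.argsort(relabel)
        enc = (tuple(relabel[p.germ_succ[order]].tolist()),
               tuple(relabel[p.dorm_succ[order]].tolist()))
        if best is None or enc < best:
            best = enc
    return (L,) + best


def enumerate_diagrams(L: int, dedup: bool = True,
                       prune: bool = True) -> Iterator[StrategyDiagram]:
    """Yield every diagram topology on L states (q initialised to 0.5).

    Iterates all L**(2L) successor-map pairs; with ``prune`` each is
    reduced to its reachable core, and with ``dedup`` only one
    representative per relabeling-isomorphism class (of the pruned
    topology) is emitted.  L <= 3 is desk-scale; L >= 4 grows as
    L**(2L) and is long-running.
    """
    if not 1 <= L <= 6:
        raise ValueError("enumeration supported for 1 <= L <= 6")
    seen: set[tuple] = set()
    q0 = np.full(L, 0.5)
    for germ in itertools.product(range(L), repeat=L):
        for dorm in itertools.product(range(L), repeat=L):
            d = StrategyDiagram(L, q0, np.array(dorm), np.array(germ))
            if prune:
                d = d.pruned()
            if dedup:
                key = canonical_form(d)
                if key in seen:
                    continue
                seen.add(key)
            yield d
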