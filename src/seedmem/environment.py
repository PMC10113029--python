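"""Synthetic binary environments with temporal structure.

Years are either good (``1``) or bad (``0``) for an annual plant.  The
default environment alternates runs of good and bad years: good runs are
geometrically distributed with mean 5 years, while bad runs follow a
discretised Gaussian with mean 5 and standard deviation 2, truncated to
[0, 10] — disasters with a characteristic duration interrupting otherwise
memoryless growth conditions.  An i.i.d. Bernoulli alternative with the
same stationary frequency of good years serves as the no-structure
control.

Besides generation, this module provides run-length extraction, the
stationary good-year frequency, and a plug-in estimator of the predictive
information I(eps_t; eps_{t-1..t-k}) — the upper bound on what any memory
can exploit about the coming year.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "DurationDistribution",
    "EnvironmentModel",
    "EnvironmentSequence",
    "sample_duration",
    "generate_environment",
    "run_lengths",
    "stationary_frequency",
    "predictive_information",
    "default_structured_model",
    "iid_model",
    "write_environment",
    "read_environment",
]

#: default number of initial years discarded before stationary statistics
DEFAULT_BURN_IN = 1000

_REJECTION_CAP = 10**6


class ConfigurationError(ValueError):
    """Invalid model or distribution configuration."""


class SamplingError(RuntimeError):
    """A rejection sampler exceeded its iteration cap."""


@dataclasses.dataclass(frozen=True)
class DurationDistribution:
    """Distribution of run durations, supported on positive integers.

    Kinds
    -----
    ``geometric``
        P(k) = (1-theta)^(k-1) * theta with theta = 1/mean, k >= 1.
    ``truncated-normal-integer``
        Draw x ~ Normal(mean, sd), reject unless lower <= x <= upper,
        round to the nearest integer, re-draw if the result is 0.
    ``fixed``
        Degenerate at round(mean).
    ``categorical``
        Explicit probability table over positive integer durations.
    """

    kind: Literal["geometric", "truncated-normal-integer", "fixed", "categorical"]
    mean: float = 0.0
    sd: float | None = None
    lower: float | None = None
    upper: float | None = None
    table: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == "geometric":
            if self.mean < 1:
                raise ConfigurationError("geometric mean must be >= 1")
        elif self.kind == "truncated-normal-integer":
            if self.sd is None or self.sd <= 0:
                raise ConfigurationError("truncated-normal-integer requires sd > 0")
            if self.lower is None or self.upper is None or self.lower >= self.upper:
                raise ConfigurationError("truncation bounds must satisfy lower < upper")
        elif self.kind == "fixed":
            if round(self.mean) < 1:
                raise ConfigurationError("fixed duration must round to >= 1")
        elif self.kind == "categorical":
            if not self.table:
                raise ConfigurationError("categorical requires a probability table")
            ks = np.array(sorted(self.table), dtype=int)
            ps = np.array([self.table[int(k)] for k in ks], dtype=float)
            if ks.min() < 1 or (ps < 0).any():
                raise ConfigurationError("categorical support must be positive integers "
                                         "with nonnegative probabilities")
            if abs(ps.sum() - 1.0) > 1e-12:
                raise ConfigurationError("categorical probabilities must sum to 1")
        else:
            raise ConfigurationError(f"unknown duration kind {self.kind!r}")

    # -- exact pmf, used both by samplers (categorical) and as an oracle ----

    def pmf(self, k_max: int = 200) -> tuple[np.ndarray, np.ndarray]:
        """Exact probability table P(k) for k = 1..k_max (renormalised tail).

        For the truncated-normal-integer kind this enumerates the
        rejection/rounding/re-draw rule in closed form: P(k) is the Gaussian
        mass rounding to k within the truncation window, conditioned on
        k >= 1.
        """
        if self.kind == "fixed":
            k = int(round(self.mean))
            return np.array([k]), np.array([1.0])
        if self.kind == "categorical":
            ks = np.array(sorted(self.table), dtype=int)
            return ks, np.array([self.table[int(k)] for k in ks], dtype=float)
        if self.kind == "geometric":
            theta = 1.0 / self.mean
            ks = np.arange(1, k_max + 1)
            ps = (1 - theta) ** (ks - 1) * theta
            return ks, ps / ps.sum()
        # truncated-normal-integer
        lo, hi = float(self.lower), float(self.upper)
        k_lo, k_hi = int(np.ceil(lo)), int(np.floor(hi))
        ks = np.arange(k_lo, k_hi + 1)
        a = np.maximum(ks - 0.5, lo)
        b = np.minimum(ks + 0.5, hi)
        z = stats.norm(self.mean, self.sd)
        ps = z.cdf(b) - z.cdf(a)
        keep = ks >= 1
        ks, ps = ks[keep], ps[keep]
        return ks, ps / ps.sum()

    def exact_mean(self) -> float:
        ks, ps = self.pmf(k_max=10_000 if self.kind == "geometric" else 200)
        return float(np.dot(ks, ps))


def sample_duration(dist: DurationDistribution, rng: np.random.Generator) -> int:
    """Draw a single run duration (integer >= 1)."""
    return int(_sample_durations(dist, rng, 1)[0])


def _sample_durations(dist: DurationDistribution, rng: np.random.Generator,
                      n: int) -> np.ndarray:
    if dist.kind == "fixed":
        return np.full(n, int(round(dist.mean)), dtype=np.int64)
    if dist.kind == "geometric":
        return rng.geometric(1.0 / dist.mean, size=n).astype(np.int64)
    if dist.kind == "categorical":
        ks, ps = dist.pmf()
        return rng.choice(ks, size=n, p=ps).astype(np.int64)
    # truncated-normal-integer: vectorised rejection
    out = np.empty(n, dtype=np.int64)
    filled = 0
    drawn = 0
    while filled < n:
        batch = max(2 * (n - filled), 64)
        x = rng.normal(dist.mean, dist.sd, size=batch)
        drawn += batch
        k = np.rint(x[(x >= dist.lower) & (x <= dist.upper)]).astype(np.int64)
        k = k[k >= 1]
        take = min(len(k), n - filled)
        out[filled:filled + take] = k[:take]
        filled += take
        if drawn > _REJECTION_CAP and filled == 0:
            raise SamplingError("rejection sampler made no progress "
                                f"after {drawn} draws (degenerate bounds?)")
    return out


@dataclasses.dataclass(frozen=True)
class EnvironmentModel:
    """Binary-environment generator specification.

    ``alternating-runs`` draws i.i.d. run durations for good and bad years
    and concatenates alternating blocks (a semi-Markov renewal process);
    ``iid`` draws each year independently as Bernoulli(p).
    """

    mode: Literal["alternating-runs", "iid"]
    good_dist: DurationDistribution | None = None
    bad_dist: DurationDistribution | None = None
    p: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "alternating-runs":
            if self.good_dist is None or self.bad_dist is None:
                raise ConfigurationError("alternating-runs requires both duration "
                                         "distributions")
        elif self.mode == "iid":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ConfigurationError("iid mode requires 0 <= p <= 1")
        else:
            raise ConfigurationError(f"unknown mode {self.mode!r}")

    def describe(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}


def default_structured_model() -> EnvironmentModel:
    """Good runs geometric(mean 5); bad runs discretised N(5, 2) on [0, 10]."""
    return EnvironmentModel(
        mode="alternating-runs",
        good_dist=DurationDistribution("geometric", mean=5.0),
        bad_dist=DurationDistribution("truncated-normal-integer", mean=5.0,
                                      sd=2.0, lower=0.0, upper=10.0),
    )


def iid_model(p: float = 0.5) -> EnvironmentModel:
    return EnvironmentModel(mode="iid", p=p)


@dataclasses.dataclass(frozen=True)
class EnvironmentSequence:
    """A realised binary year sequence eps_t, 1 = good."""

    values: np.ndarray  # int8, in {0, 1}
    seed: int | None
    model: dict

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("environment sequence must be a nonempty 1-d array")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("environment values must be binary")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def T(self) -> int:
        return self.values.size


def generate_environment(model: EnvironmentModel, T: int,
                         rng: np.random.Generator | int | None = None,
                         burn_in: int = 0) -> EnvironmentSequence:
    """Generate T years of environment after discarding ``burn_in`` years.

    Alternating-runs sequences start at the beginning of a good run (the
    burn-in then removes the initial-phase bias for stationary statistics).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    need = T + burn_in
    if model.mode == "iid":
        vals = (gen.random(need) < model.p).astype(np.int8)
    else:
        vals, _, _ = _generate_alternating(model, need, gen)
    return EnvironmentSequence(values=vals[burn_in:], seed=seed,
                               model=model.describe())


def _generate_alternating(model: EnvironmentModel, need: int,
                          gen: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating good/bad blocks starting with a good run.

    Returns (values of length ``need``, the run durations actually drawn,
    the state of each run); the final run is truncated by ``need``.
    """
    chunks: list[np.ndarray] = []
    durations: list[int] = []
    states: list[int] = []
    total = 0
    state = 1  # start at the beginning of a good run
    mean_run = 0.5 * (model.good_dist.mean + model.bad_dist.mean)
    good: list[int] = []
    bad: list[int] = []
    while total < need:
        if not good or not bad:
            n_runs = max(int((need - total) / max(mean_run, 1.0)) + 8, 16)
            good.extend(_sample_durations(model.good_dist, gen,
                                          (n_runs + 1) // 2).tolist())
            bad.extend(_sample_durations(model.bad_dist, gen,
                                         n_runs // 2).tolist())
        dur = good.pop(0) if state == 1 else bad.pop(0)
        chunks.append(np.full(dur, state, dtype=np.int8))
        durations.append(dur)
        states.append(state)
        total += dur
        state = 1 - state
    return (np.concatenate(chunks)[:need], np.array(durations, dtype=np.int64),
            np.array(states, dtype=np.int8))


def run_lengths(seq: EnvironmentSequence | np.ndarray,
                drop_truncated: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Lengths of maximal good and bad runs, in order of occurrence.

    The first and last runs of a finite window are censored (their true
    duration extends beyond the window); with ``drop_truncated`` they are
    excluded, which is required for unbiased distribution fits.
    """
    v = seq.values if isinstance(seq, EnvironmentSequence) else np.asarray(seq)
    v = v.astype(np.int8)
    if v.size == 0:
        raise ValueError("empty sequence")
    lengths, states = _runs(v)
    if drop_truncated and len(lengths) > 0:
        keep = slice(1, -1) if len(lengths) > 2 else slice(0, 0)
        lengths, states = lengths[keep], states[keep]
    return lengths[states == 1], lengths[states == 0]


def _runs(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All maximal runs: (lengths, value of each run)."""
    edges = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate(([0], edges))
    ends = np.concatenate((edges, [v.size]))
    return ends - starts, v[starts]


def stationary_frequency(seq: EnvironmentSequence | np.ndarray) -> float:
    """Empirical fraction of good years."""
    v = seq.values if isinstance(seq, EnvironmentSequence) else np.asarray(seq)
    if v.size == 0:
        raise ValueError("empty sequence")
    return float(np.mean(v))


def predictive_information(seq: EnvironmentSequence | np.ndarray, k: int) -> float:
    """Plug-in estimate of I(eps_t; eps_{t-1..t-k}) in nats.

    Block-entropy estimator over all length-(k+1) windows:
    I = H(eps_t) + H(history) - H(joint).  Requires k <= 12 and a sequence
    much longer than 2^k; the plug-in bias is of order 2^k / (2T) nats.
    """
    v = seq.values if isinstance(seq, EnvironmentSequence) else np.asarray(seq, dtype=np.int8)
    if not 1 <= k <= 12:
        raise ValueError("history length k must be in 1..12")
    if v.size < 2 ** (k + 1) * 4:
        raise ValueError(f"sequence too short (T={v.size}) for k={k} plug-in estimate")
    codes = _window_codes(v.astype(np.int64), k + 1)
    h_joint = _entropy_of_codes(codes)
    h_hist = _entropy_of_codes(codes >> 1)          # drop the current year bit
    h_now = _entropy_of_codes(codes & 1)
    return max(h_now + h_hist - h_joint, 0.0)


def _window_codes(v: np.ndarray, w: int) -> np.ndarray:
    """Encode every length-w window as an integer (oldest year = high bit ...
    current year = bit 0)."""
    code = np.zeros(v.size - w + 1, dtype=np.int64)
    for j in range(w):
        code |= v[j:v.size - w + 1 + j] << (w - 1 - j)
    return code


def _entropy_of_codes(codes: np.ndarray) -> float:
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# serialization: single-column TSV + JSON sidecar

def write_environment(seq: EnvironmentSequence, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("epsilon\n")
        fh.write("\n".join(map(str, seq.values.tolist())))
        fh.write("\n")
    sidecar = {"model": seq.model, "seed": seq.seed, "T": seq.T}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_environment(path: str | Path) -> EnvironmentSequence:
    path = Path(path)
    lines = path.read_text().strip().split("\n")
    if lines[0].strip() != "epsilon":
        raise ValueError(f"{path}: expected header 'epsilon'")
    vals = np.array([int(x) for x in lines[1:]], dtype=np.int8)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: non-binary environment values")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return EnvironmentSequence(values=vals, seed=meta.get("seed"),
                               model=meta.get("model", {}))
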