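# seedmem

Age-dependent seed dormancy as *internal memory* in temporally structured
random environments.

## The problem

Annual plants hedge against catastrophic years by keeping part of the seed
bank dormant. In the classic bet-hedging model (Cohen), each year is good
(ε = 1, frequency *p*) or bad (ε = 0); a germinating seed yields *Y* new
seeds in a good year and nothing (*Y*₀ = 0) in a bad one, while a dormant
seed survives to the next year with viability *V*. A constant germination
fraction *q* gives the long-term (log) growth rate

    Λ(q) = p·ln((1−q)V + qY) + (1−p)·ln((1−q)V),

maximised at q* = (pY − V)/(Y − V) for p > V/Y (q* ≈ p when Y ≫ V).

When the environment has *temporal structure* — here, geometrically
distributed good runs (mean 5 years) interrupted by bad runs with a narrow,
bell-shaped duration (discretised Gaussian 5 ± 2 on [0, 10]) — a seed's
**age** becomes informative about the coming year, purely through
selection: lineages that germinated in the wrong phase of a bad run are
gone, so the survivors' ages are entrained to the environment. A
germination fraction q_α that depends on seed age (a finite-state
"strategy diagram" with L internal states) can then exploit this internal
cue. The package quantifies that benefit:

- **Λ as a Lyapunov exponent** of the random product of environment-
  dependent projection matrices M(ε; q), with column α carrying q_α·Y_ε
  into the newborn state and (1−q_α)·V into the next age;
- **optimisation** of {q₀…q_{L−1}} per memory capacity L, and exhaustive
  search over all L-state diagram topologies;
- **information accounting**: H(ε), I(ε; cue), the diagonal-fitness
  (extreme-selection) identities Λ_bet = Λ_max − H(ε) and
  Λ_cue = Λ_bet + I(ε; ξ), and the lineage-based mutual information
  I(ε_t; α_{t−1});
- **duration signatures**: along a neutral lineage, geometric run lengths
  mean "no memory", while a bell-shaped dormancy-duration law is the
  experimental fingerprint of age-dependent germination.

Audience: theoretical ecologists and evolution-of-plasticity modellers who
want a reproducible, tested implementation of these computations.

## Worked example

```python
import numpy as np
import seedmem as sm

fitness = sm.FitnessMatrix()                    # V=0.9, Y0=0, Y1=4
model = sm.default_structured_model()           # good ~ Geom(5), bad ~ N(5,2) on [0,10]
q_star = sm.optimal_q(0.5, 0.9, 4.0)
print(f"q* = {q_star:.6f}")
print(f"Lambda_bet = {sm.growth_rate_constant_q(q_star, 0.5, 0.9, 4.0):.6f}")

env_train = sm.generate_environment(model, 201_000, rng=11, burn_in=1000)
env_eval = sm.generate_environment(model, 201_000, rng=12, burn_in=1000)
sweep = sm.memory_sweep([1, 2, 5, 10], fitness, env_train, env_eval,
                        restarts=2, rng=0)
print(sweep[["L", "lambda", "se", "I"]].round(4).to_string(index=False))
```

prints

```
q* = 0.354839
Lambda_bet = 0.074766
 L  lambda     se      I
 1  0.0738 0.0021 0.0000
 2  0.2310 0.0030 0.1044
 5  0.2509 0.0030 0.1302
10  0.2531 0.0030 0.1303
```

Reading: with no memory (L = 1) the population grows at the bet-hedging
rate ≈ 0.074 nats/year (the held-out Monte-Carlo estimate, within 2 se of
the closed form). Two internal states — Markovian phenotypic switching —
already more than triple the growth rate, and Λ saturates once L exceeds
the ~5-year bad-run duration. The mutual information between seed age and
the coming environment (column `I`, in nats) rises alongside Λ.

A `seedmem` command-line tool exposes the same stages
(`seedmem env | analytic | growth | optimize | sweep | search | lineage |
durations | run`); `seedmem run --config cfg.toml` executes a whole
TOML-configured pipeline into TSV/JSON outputs with a hash manifest.

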