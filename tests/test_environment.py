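"""Environment generator: duration laws, run statistics, predictive information."""

import numpy as np
import pytest
from scipy import stats

import seedmem as sm
from seedmem.environment import DurationDistribution, SamplingError

# Exact oracle for the discretised truncated Gaussian bad-year law
# (mass of N(5,2) rounding to k within [0,10], conditioned on k >= 1),
# computed by direct enumeration of the truncation/rounding rule.
TRUNCNORM_MEAN = 5.030638837198839
TRUNCNORM_PMF = [0.028357, 0.066822, 0.12325, 0.177947, 0.20112,
                 0.177947, 0.12325, 0.066822, 0.028357, 0.006128]


class TestDurationDistribution:
    def test_fixed_is_degenerate(self):
        dist = DurationDistribution("fixed", mean=5)
        rng = np.random.default_rng(0)
        assert all(sm.sample_duration(dist, rng) == 5 for _ in range(20))

    def test_geometric_mean_five(self):
        dist = DurationDistribution("geometric", mean=5.0)
        rng = np.random.default_rng(1)
        draws = np.array([sm.sample_duration(dist, rng) for _ in range(1000)])
        # vectorised path for the bulk of the draws
        from seedmem.environment import _sample_durations
        draws = np.concatenate([draws, _sample_durations(dist, rng, 99_000)])
        assert draws.min() >= 1
        assert draws.mean() == pytest.approx(5.0, abs=0.05)

    def test_truncnorm_pmf_matches_enumeration_oracle(self):
        dist = DurationDistribution("truncated-normal-integer", mean=5.0, sd=2.0,
                                    lower=0.0, upper=10.0)
        ks, ps = dist.pmf()
        assert ks.tolist() == list(range(1, 11))
        np.testing.assert_allclose(ps, TRUNCNORM_PMF, atol=1e-6)
        assert dist.exact_mean() == pytest.approx(TRUNCNORM_MEAN, abs=1e-9)

    def test_truncnorm_sample_mean_matches_oracle(self):
        dist = DurationDistribution("truncated-normal-integer", mean=5.0, sd=2.0,
                                    lower=0.0, upper=10.0)
        from seedmem.environment import _sample_durations
        draws = _sample_durations(dist, np.random.default_rng(2), 100_000)
        assert draws.min() >= 1 and draws.max() <= 10
        assert draws.mean() == pytest.approx(TRUNCNORM_MEAN, abs=0.03)

    def test_degenerate_bounds_raise_sampling_error(self):
        dist = DurationDistribution("truncated-normal-integer", mean=-200.0,
                                    sd=0.001, lower=0.0, upper=10.0)
        with pytest.raises(SamplingError):
            sm.sample_duration(dist, np.random.default_rng(0))

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            DurationDistribution("weibull", mean=5.0)


class TestGenerateEnvironment:
    def test_deterministic_durations_give_exact_blocks(self):
        model = sm.EnvironmentModel(
            mode="alternating-runs",
            good_dist=DurationDistribution("fixed", mean=2),
            bad_dist=DurationDistribution("fixed", mean=3))
        seq = sm.generate_environment(model, 10, rng=0, burn_in=0)
        assert seq.values.tolist() == [1, 1, 0, 0, 0, 1, 1, 0, 0, 0]

    def test_iid_p_one_is_all_good(self):
        seq = sm.generate_environment(sm.iid_model(1.0), 5, rng=0)
        assert seq.values.tolist() == [1, 1, 1, 1, 1]

    def test_same_seed_replays_bit_exactly(self, structured_model):
        a = sm.generate_environment(structured_model, 50_000, rng=7, burn_in=100)
        b = sm.generate_environment(structured_model, 50_000, rng=7, burn_in=100)
        np.testing.assert_array_equal(a.values, b.values)

    def test_stationary_frequency_matches_renewal_oracle(self, structured_model):
        # renewal theory: p = E[good] / (E[good] + E[bad]) = 5 / (5 + 5.0306)
        seq = sm.generate_environment(structured_model, 1_000_000, rng=3,
                                      burn_in=1000)
        expected = 5.0 / (5.0 + TRUNCNORM_MEAN)
        assert sm.stationary_frequency(seq) == pytest.approx(0.5, abs=0.005)
        assert sm.stationary_frequency(seq) == pytest.approx(expected, abs=0.003)


class TestRunLengths:
    def test_boundary_runs_are_excluded(self):
        seq = np.array([1, 1, 0, 0, 0, 1], dtype=np.int8)
        good, bad = sm.run_lengths(seq)
        assert good.tolist() == [] and bad.tolist() == [3]
        good, bad = sm.run_lengths(seq, drop_truncated=False)
        assert good.tolist() == [2, 1] and bad.tolist() == [3]

    def test_constant_sequence_is_one_run(self):
        good, bad = sm.run_lengths(np.ones(9, dtype=np.int8), drop_truncated=False)
        assert good.tolist() == [9] and bad.tolist() == []

    def test_good_runs_pass_geometric_gof(self, structured_model):
        seq = sm.generate_environment(structured_model, 1_100_000, rng=5,
                                      burn_in=1000)
        good, _ = sm.run_lengths(seq)
        assert good.size > 100_000
        # chi-square against the exact geometric(theta = 0.2) law
        kmax = int(good.max())
        obs = np.bincount(good, minlength=kmax + 1)[1:].astype(float)
        pk = 0.8 ** (np.arange(1, kmax + 1) - 1.0) * 0.2
        pk[-1] += 0.8 ** kmax
        exp = good.size * pk
        while exp[-1] < 5:
            exp[-2] += exp[-1]; obs[-2] += obs[-1]
            exp, obs = exp[:-1], obs[:-1]
        _, p = stats.chisquare(obs, exp)
        assert p > 0.01

    def test_run_lengths_replay_sampled_durations(self, structured_model):
        """Emitted runs equal the sampled durations exactly (same seed)."""
        from seedmem.environment import _generate_alternating, _runs
        vals, durations, states = _generate_alternating(
            structured_model, 30_000, np.random.default_rng(9))
        lengths, run_vals = _runs(vals)
        # every run except the T-truncated last one matches its drawn duration
        np.testing.assert_array_equal(lengths[:-1], durations[:lengths.size - 1])
        np.testing.assert_array_equal(run_vals, states[:lengths.size])
        assert lengths[-1] <= durations[lengths.size - 1]


class TestPredictiveInformation:
    def test_iid_has_no_predictive_information(self):
        seq = sm.generate_environment(sm.iid_model(0.5), 1_000_000, rng=4)
        assert sm.predictive_information(seq, k=5) == pytest.approx(0.0, abs=1e-4)

    def test_alternating_sequence_gives_ln2(self):
        # 10001 values -> 10000 windows, exactly 5000 of each kind
        seq = np.tile([1, 0], 5000).astype(np.int8)
        seq = np.append(seq, 1)
        assert sm.predictive_information(seq, k=1) == pytest.approx(np.log(2), abs=1e-12)

    def test_structured_beats_iid_tenfold(self, structured_model):
        seq = sm.generate_environment(structured_model, 1_000_000, rng=6,
                                      burn_in=1000)
        iid = sm.generate_environment(sm.iid_model(0.5), 1_000_000, rng=6)
        i_str = sm.predictive_information(seq, k=8)
        i_iid = sm.predictive_information(iid, k=8)
        assert i_str > 0.0
        assert i_str > 10 * i_iid

    def test_monotone_in_history_length(self, structured_model):
        seq = sm.generate_environment(structured_model, 500_000, rng=8,
                                      burn_in=1000)
        vals = [sm.predictive_information(seq, k=k) for k in range(1, 7)]
        assert all(v >= 0 for v in vals)
        # plug-in estimates on the same sequence: non-decreasing within bias
        bias = 2 ** 7 / (2 * 500_000)
        assert all(b >= a - bias for a, b in zip(vals, vals[1:]))


def test_environment_tsv_round_trip(tmp_path, structured_model):
    seq = sm.generate_environment(structured_model, 5000, rng=13, burn_in=100)
    path = tmp_path / "env.tsv"
    sm.write_environment(seq, path)
    back = sm.read_environment(path)
    np.testing.assert_array_equal(back.values, seq.values)
    assert back.seed == 13
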