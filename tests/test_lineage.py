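"""Lineage simulations: selection weighting, joint tables, run-length laws."""

import numpy as np
import pytest

import seedmem as sm
from seedmem.lineage import (LineageRecord, SimulationError, geometric_gof,
                             joint_env_age)

Q_STAR = 0.354839


class TestSelectedLineage:
    def test_never_germinates_in_bad_years(self, fitness, env_train):
        """With Y0 = 0 the germination weight vanishes in bad years: exact."""
        d = sm.make_age_diagram(5, 0.6)
        rec = sm.simulate_lineage_selected(d, fitness, env_train.values[:100_000],
                                           rng=1)
        assert not np.any(rec.phi[rec.eps == 0])

    def test_good_year_germination_probability(self, fitness):
        # P(phi=1) = q*Y / (q*Y + (1-q)*V) = 1.419356/2.0 = 0.709678
        env = np.ones(200_000, dtype=np.int8)
        rec = sm.simulate_lineage_selected(sm.make_age_diagram(1, Q_STAR),
                                           fitness, env, rng=2)
        expected = Q_STAR * 4.0 / (Q_STAR * 4.0 + (1 - Q_STAR) * 0.9)
        assert expected == pytest.approx(0.709678, abs=1e-6)
        assert np.mean(rec.phi) == pytest.approx(expected, abs=0.004)

    def test_boundary_q_clipped_not_stuck(self, fitness):
        env = np.ones(5000, dtype=np.int8)
        rec = sm.simulate_lineage_selected(sm.make_age_diagram(1, 1.0), fitness,
                                           env, rng=3)
        assert np.mean(rec.phi) > 0.999

    def test_zero_weight_raises_with_location(self):
        # diagonal fitness with zero yield: a good year kills dormant seeds
        # (f10 = 0) and germinating yields nothing, so both weights vanish
        f = sm.FitnessMatrix(V=0.9, Y1=0.0, diagonal=True)
        env = np.ones(100, dtype=np.int8)
        with pytest.raises(SimulationError, match="eps 1"):
            sm.simulate_lineage_selected(sm.make_age_diagram(1, 0.5), f, env, rng=4)


class TestNeutralLineage:
    def test_all_or_nothing_germination(self):
        d1 = sm.make_age_diagram(3, 1.0)
        rec = sm.simulate_lineage_neutral(d1, 1000, rng=5)
        assert rec.phi.all()
        d0 = sm.make_age_diagram(3, 0.0)
        rec = sm.simulate_lineage_neutral(d0, 1000, rng=5)
        assert not rec.phi.any()

    def test_two_state_germination_fraction_matches_chain_oracle(self):
        """Fraction of germination years equals pi_0*q_0 + pi_1*q_1 with
        pi the stationary vector of the two-state chain."""
        q0, q1 = 0.5, 0.25
        d = sm.make_age_diagram(2, np.array([q0, q1]))
        rec = sm.simulate_lineage_neutral(d, 1_000_000, rng=6)
        pi0 = q1 / (1 - q0 + q1)
        expected = pi0 * q0 + (1 - pi0) * q1
        assert expected == pytest.approx(1 / 3, abs=1e-12)
        assert np.mean(rec.phi) == pytest.approx(expected, abs=0.005)


class TestJointTable:
    def test_hand_built_record_counts(self):
        rec = LineageRecord(eps=np.array([1, 0, 0, 1, 1, 0], dtype=np.int8),
                            alpha_prev=np.array([0, 0, 1, 2, 0, 0]),
                            phi=np.array([1, 0, 0, 1, 1, 0], dtype=np.int8),
                            L=3, selected=True)
        jt = joint_env_age(rec, burn_in=0)
        expected = np.array([[2, 1, 0], [2, 0, 1]]) / 6.0
        np.testing.assert_allclose(jt.probs, expected, atol=1e-15)
        assert jt.marginal_env() == pytest.approx(0.5)

    def test_iid_environment_carries_no_age_information(self, fitness):
        env = sm.generate_environment(sm.iid_model(0.5), 1_000_000, rng=7)
        d = sm.make_age_diagram(4, Q_STAR)
        rec = sm.simulate_lineage_selected(d, fitness, env, rng=8)
        info = sm.lineage_mutual_information(rec)
        bias_bound = 3 * (4 - 1) / (2 * (1_000_000 - 1000))
        assert info.I <= bias_bound

    def test_structured_environment_is_predictable_from_age(self, fitness,
                                                            env_long):
        d = sm.make_age_diagram(10, Q_STAR)
        rec = sm.simulate_lineage_selected(d, fitness, env_long, rng=9)
        jt = joint_env_age(rec)
        dev = np.abs(jt.conditional_env() - jt.marginal_env())
        assert np.nanmax(dev) > 0.05

    def test_neutral_record_rejected(self):
        rec = sm.simulate_lineage_neutral(sm.make_age_diagram(1, 0.5), 100, rng=0)
        with pytest.raises(ValueError):
            joint_env_age(rec, burn_in=0)


class TestRunLengths:
    def test_boundary_runs_excluded(self):
        rec = LineageRecord(eps=None, alpha_prev=np.zeros(6, dtype=np.int64),
                            phi=np.array([1, 1, 0, 0, 0, 1], dtype=np.int8),
                            L=1, selected=False)
        runs = sm.phenotype_run_lengths(rec)
        assert runs.germ_lengths.tolist() == []
        assert runs.dorm_lengths.tolist() == [3]

    def test_geometric_sample_passes_gof(self):
        rng = np.random.default_rng(10)
        stat, p = geometric_gof(rng.geometric(0.3, size=50_000))
        assert p > 0.01

    def test_non_geometric_sample_fails_gof(self):
        rng = np.random.default_rng(11)
        lengths = np.clip(np.rint(rng.normal(5, 2, size=50_000)), 1, 10).astype(int)
        _, p = geometric_gof(lengths)
        assert p < 1e-6

    def test_germination_runs_geometric_with_mean_from_q0(self):
        """New seeds always restart at state 0, so germination runs continue
        with probability q_0: geometric, mean 1/(1-q_0)."""
        q = np.array([0.6, 0.1, 0.3, 0.5])
        rec = sm.simulate_lineage_neutral(sm.make_age_diagram(4, q), 1_000_000,
                                          rng=12)
        runs = sm.phenotype_run_lengths(rec)
        assert runs.reliable
        assert runs.germ_gof[1] > 0.01
        assert runs.germ_mean == pytest.approx(1 / (1 - q[0]), rel=0.02)

    def test_two_state_dormancy_geometric_with_mean_from_q1(self):
        """L = 2 dormancy runs terminate with probability q_1 each year:
        geometric with mean 1/q_1 (brute-force chain algebra)."""
        q0, q1 = 0.5, 0.2
        rec = sm.simulate_lineage_neutral(sm.make_age_diagram(2, [q0, q1]),
                                          1_500_000, rng=13)
        runs = sm.phenotype_run_lengths(rec)
        assert runs.dorm_gof[1] > 0.01
        assert runs.dorm_mean == pytest.approx(1 / q1, rel=0.02)
        # chain-enumeration oracle: P(K = k) = (1-q1)^(k-1) q1
        ks, counts = np.unique(runs.dorm_lengths, return_counts=True)
        emp = counts / counts.sum()
        for k in range(1, 6):
            oracle = (1 - q1) ** (k - 1) * q1
            assert emp[ks == k][0] == pytest.approx(oracle, abs=0.01)

    def test_few_runs_flagged_unreliable(self):
        rec = sm.simulate_lineage_neutral(sm.make_age_diagram(1, 0.5), 40, rng=14)
        assert not sm.phenotype_run_lengths(rec).reliable


class TestDiagonalLimitDurationMatching:
    def test_optimized_dormancy_matches_bad_year_distribution(
            self, structured_model, env_train, env_eval):
        """Under diagonal (extreme-selection) fitness the optimal strategy
        reproduces the environment's duration statistics: the neutral
        dormancy-run law approaches the bad-year law (TV distance < 0.1)."""
        f_diag = sm.FitnessMatrix(diagonal=True)
        res = sm.optimize_weights(sm.make_age_diagram(10, 0.5), f_diag,
                                  env_train.values[:121_000], restarts=2, rng=15)
        rec = sm.simulate_lineage_neutral(res.diagram, 1_000_000, rng=16)
        runs = sm.phenotype_run_lengths(rec)
        ks, ps = structured_model.bad_dist.pmf()
        emp = np.zeros(ks.max() + 1)
        lengths, counts = np.unique(runs.dorm_lengths, return_counts=True)
        for k, c in zip(lengths, counts):
            if k <= ks.max():
                emp[k] = c
        emp /= counts.sum()
        tv = 0.5 * (np.abs(emp[ks] - ps).sum() + (1 - emp[ks].sum()))
        assert tv < 0.1
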