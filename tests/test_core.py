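"""Exact-model unit and property tests: validation, recursion, moments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wordage.core as core
from wordage import (
    AgeDistribution,
    DiffusionNetwork,
    TransientConfig,
    equilibrium_age_distribution,
    equilibrium_mean,
    equilibrium_sd,
    heterozygosity,
    mean_trajectory,
    step_distribution,
    transient_age_distribution,
    validate_network,
)
from wordage.errors import (
    CutoffError,
    MissingInitError,
    NegativeRateError,
    RowSumError,
    SingularityError,
    UnreachableError,
)
from wordage.networks import build_bidirectional_chain, build_unidirectional_chain

from conftest import fixed_point_mean, random_valid_network


class TestValidation:
    def test_single_population_valid(self):
        net = DiffusionNetwork(source_rates=[0.5], A=[[0.5]])
        assert validate_network(net) is net

    def test_self_copying_island_unreachable(self):
        net = DiffusionNetwork(source_rates=[0.1, 0.0], A=[[0.9, 0.0], [0.0, 1.0]])
        with pytest.raises(UnreachableError, match="P2"):
            validate_network(net)

    def test_row_sum_error_names_row(self):
        net = DiffusionNetwork(source_rates=[0.5, 0.1], A=[[0.5, 0.0], [0.1, 0.9]])
        with pytest.raises(RowSumError, match="P2"):
            validate_network(net)

    def test_negative_rate(self):
        net = DiffusionNetwork(source_rates=[1.2], A=[[-0.2]])
        with pytest.raises(NegativeRateError):
            validate_network(net)

    def test_chain_builder_rows_sum_to_one(self):
        net = build_unidirectional_chain(9, 0.1)
        np.testing.assert_allclose(net.row_sums(), 1.0, atol=1e-15)


class TestStepDistribution:
    def test_one_step_moves_all_mass_to_age_one(self):
        net = build_bidirectional_chain(4, 0.2)
        start = AgeDistribution(
            freqs=np.eye(5)[[0]].repeat(4, axis=0), t=0, tail_mass=np.zeros(4)
        )
        out = step_distribution(net, start)
        np.testing.assert_allclose(out.freqs[:, 1], 1.0, atol=1e-15)
        assert out.freqs[:, 0].max() == 0.0

    def test_single_population_substitution(self):
        a = 0.3
        net = DiffusionNetwork(source_rates=[a], A=[[1 - a]])
        start = AgeDistribution(freqs=[[0.0, 1.0, 0.0]], t=0, tail_mass=[0.0])
        out = step_distribution(net, start)
        np.testing.assert_allclose(out.freqs[0], [0.0, a, 1 - a], atol=1e-15)

    def test_iteration_converges_to_equilibrium(self):
        net = build_unidirectional_chain(3, 0.25)
        eq = equilibrium_age_distribution(net, rho_max=120)
        dist = AgeDistribution(freqs=np.zeros((3, 121)), t=0, tail_mass=np.zeros(3))
        dist.freqs[:, 0] = 1.0
        for _ in range(400):
            dist = step_distribution(net, dist)
        assert np.abs(dist.freqs - eq.freqs).max() < 1e-9

    def test_mass_conserved_each_step(self):
        net = build_bidirectional_chain(5, 0.1)
        dist = AgeDistribution(freqs=np.zeros((5, 20)), t=0, tail_mass=np.zeros(5))
        dist.freqs[:, 0] = 1.0
        for _ in range(60):
            dist = step_distribution(net, dist)
            total = dist.freqs.sum(axis=1) + dist.tail_mass
            np.testing.assert_allclose(total, 1.0, atol=1e-12)


class TestTransient:
    def test_age_zero_is_empty_in_periphery(self):
        net = build_bidirectional_chain(4, 0.1)
        dist = transient_age_distribution(net, TransientConfig(), t=7)
        assert dist.freqs[:, 0].max() == 0.0

    def test_age_one_equals_source_rates(self):
        net = build_bidirectional_chain(4, 0.1)
        dist = transient_age_distribution(net, TransientConfig(), t=5)
        np.testing.assert_allclose(dist.freqs[:, 1], net.source_rates, atol=1e-15)

    def test_word_needs_k_hops_on_unidirectional_chain(self):
        net = build_unidirectional_chain(6, 0.2)
        dist = transient_age_distribution(net, TransientConfig(), t=6)
        for k in range(6):
            assert dist.freqs[k, : k + 1].max() == 0.0, f"P{k+1} got a word early"

    def test_pre_existing_mass_requires_f0(self):
        net = build_bidirectional_chain(2, 0.1)
        with pytest.raises(MissingInitError):
            transient_age_distribution(net, TransientConfig(), t=3, rho_max=10)

    def test_initial_distribution_propagates_and_conserves(self):
        net = build_bidirectional_chain(3, 0.1)
        f0 = np.zeros((3, 2))
        f0[:, 0] = 1.0  # everyone starts with an age-1 pre-existing variant
        dist = transient_age_distribution(net, TransientConfig(f0=f0), t=4)
        total = dist.freqs.sum(axis=1) + dist.tail_mass
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        assert dist.freqs[:, 5].sum() > 0  # the old variant, aged 1 + 4

    def test_agrees_with_step_recursion(self):
        net = build_bidirectional_chain(3, 0.2)
        t = 12
        dist = AgeDistribution(freqs=np.zeros((3, t + 1)), t=0, tail_mass=np.ones(3))
        for _ in range(t):
            dist = step_distribution(net, dist)
        direct = transient_age_distribution(net, TransientConfig(), t=t)
        np.testing.assert_allclose(direct.freqs, dist.freqs, atol=1e-12)


class TestEquilibriumDistribution:
    def test_single_population_is_geometric(self):
        a = 0.1
        net = DiffusionNetwork(source_rates=[a], A=[[1 - a]])
        dist = equilibrium_age_distribution(net, rho_max=2000)
        rho = np.arange(1, 2001)
        np.testing.assert_allclose(
            dist.freqs[0, 1:], a * (1 - a) ** (rho - 1), atol=1e-14
        )

    def test_tail_tolerance_met(self):
        net = build_bidirectional_chain(9, 0.1)
        dist = equilibrium_age_distribution(net, tail_tol=1e-9)
        assert dist.tail_mass.max() < 1e-9
        np.testing.assert_allclose(
            dist.freqs.sum(axis=1) + dist.tail_mass, 1.0, atol=1e-12
        )

    def test_cutoff_error_when_limit_hit(self, monkeypatch):
        monkeypatch.setattr(core, "MAX_CUTOFF", 50)
        net = build_bidirectional_chain(9, 0.1)
        with pytest.raises(CutoffError):
            equilibrium_age_distribution(net, tail_tol=1e-12)

    def test_interior_peak_with_heavy_tail_on_bidirectional_chain(self):
        # each population's distribution has a single interior mode and keeps
        # old variants at much higher frequency than the unidirectional chain
        bi = build_bidirectional_chain(9, 0.1)
        uni = build_unidirectional_chain(9, 0.1)
        d_bi = equilibrium_age_distribution(bi, rho_max=10000)
        d_uni = equilibrium_age_distribution(uni, rho_max=10000)
        for k in (0, 4, 8):
            f = d_bi.freqs[k, 1:]
            peak = f.argmax()
            assert peak > 0 or k == 0
            diffs = np.sign(np.diff(f[f > 1e-300]))
            # unimodal: sign changes at most once
            assert (np.diff(diffs) != 0).sum() <= 1
        assert d_bi.freqs[8, 2000] > 100 * d_uni.freqs[8, 2000]


class TestMoments:
    def test_unidirectional_means_match_fixed_point_oracle(self):
        net = build_unidirectional_chain(9, 0.1)
        r = equilibrium_mean(net)
        np.testing.assert_allclose(r, np.arange(1, 10) * 10.0, atol=1e-8)
        np.testing.assert_allclose(r, fixed_point_mean(net), atol=1e-8)

    def test_bidirectional_far_end_mean(self):
        net = build_bidirectional_chain(9, 0.1)
        assert equilibrium_mean(net)[-1] == pytest.approx(450.0, abs=1e-8)

    def test_relay_chain_is_deterministic(self):
        net = build_unidirectional_chain(5, 1.0)
        np.testing.assert_allclose(equilibrium_mean(net), np.arange(1, 6), atol=1e-12)
        np.testing.assert_allclose(equilibrium_sd(net), 0.0, atol=1e-9)

    def test_singular_when_validation_bypassed(self):
        net = DiffusionNetwork(source_rates=[0.0], A=[[1.0]])
        with pytest.raises(SingularityError):
            equilibrium_mean(net)

    def test_mean_trajectory_identity_and_first_step(self):
        net = build_bidirectional_chain(4, 0.1)
        r0 = np.array([3.0, 1.0, 4.0, 1.0])
        traj = mean_trajectory(net, TransientConfig(r0=r0, horizon=0))
        np.testing.assert_allclose(traj[0], r0)
        traj = mean_trajectory(net, TransientConfig(horizon=1))
        np.testing.assert_allclose(traj[1], 1.0, atol=1e-15)

    def test_equilibrium_is_fixed_point_of_trajectory(self):
        net = build_bidirectional_chain(4, 0.1)
        r = equilibrium_mean(net)
        traj = mean_trajectory(net, TransientConfig(r0=r, horizon=20))
        np.testing.assert_allclose(traj, np.tile(r, (21, 1)), atol=1e-8)

    def test_trajectory_from_zero_monotone_and_convergent(self):
        net = build_bidirectional_chain(5, 0.1)
        traj = mean_trajectory(net, TransientConfig(horizon=20000))
        assert (np.diff(traj, axis=0) >= -1e-12).all()
        np.testing.assert_allclose(traj[-1], equilibrium_mean(net), atol=1e-6)

    def test_sd_single_population_geometric(self):
        net = DiffusionNetwork(source_rates=[0.5], A=[[0.5]])
        assert equilibrium_sd(net)[0] == pytest.approx(np.sqrt(2.0), abs=1e-10)

    def test_sd_matches_truncated_distribution_oracle(self):
        net = build_unidirectional_chain(9, 0.1)
        sd = equilibrium_sd(net)
        assert sd[-1] == pytest.approx(np.sqrt(9 * 0.9 / 0.01), abs=1e-8)
        dist = equilibrium_age_distribution(net, tail_tol=1e-13)
        rho = np.arange(dist.freqs.shape[1])
        m1 = dist.freqs @ rho
        m2 = dist.freqs @ rho.astype(float) ** 2
        np.testing.assert_allclose(sd, np.sqrt(m2 - m1**2), atol=1e-6)


class TestHeterozygosity:
    def test_point_mass_has_no_diversity(self):
        d = AgeDistribution(freqs=[[0, 1, 0, 0]], t=0, tail_mass=[0.0])
        assert heterozygosity(d)[0] == pytest.approx(0.0, abs=1e-15)

    def test_uniform_over_four_ages(self):
        d = AgeDistribution(freqs=[[0.25] * 4], t=0, tail_mass=[0.0])
        assert heterozygosity(d)[0] == pytest.approx(0.75, abs=1e-15)

    def test_geometric_closed_form(self):
        a = 0.1
        net = DiffusionNetwork(source_rates=[a], A=[[1 - a]])
        d = equilibrium_age_distribution(net, tail_tol=1e-13)
        assert heterozygosity(d)[0] == pytest.approx(1 - a / (2 - a), abs=1e-10)

    def test_warns_on_large_tail(self):
        d = AgeDistribution(freqs=[[0.5, 0.4]], t=0, tail_mass=[0.1])
        with pytest.warns(UserWarning, match="tail"):
            heterozygosity(d)


class TestNetworkProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=12),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_random_network_invariants(self, n, seed):
        net = random_valid_network(np.random.default_rng(seed), n)
        # equilibrium mass identity: (E - A)^{-1} source = all-ones
        total = core.spsolve_eye_minus_a(net, net.source_rates)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)
        # mean is the fixed point of r <- A r + 1
        r = equilibrium_mean(net)
        np.testing.assert_allclose(net.A @ r + 1.0, r, atol=1e-10)
        # conservation through one recursion step
        dist = equilibrium_age_distribution(net, rho_max=60)
        stepped = step_distribution(net, dist)
        np.testing.assert_allclose(
            stepped.freqs.sum(axis=1) + stepped.tail_mass, 1.0, atol=1e-12
        )

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_chain_means_scale_inversely_with_rate(self, c):
        base = equilibrium_mean(build_bidirectional_chain(6, 0.1))
        scaled = equilibrium_mean(build_bidirectional_chain(6, 0.1 * c))
        np.testing.assert_allclose(scaled, base / c, atol=1e-8)
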