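"""Route-choice core: velocities, perceived times, discomfort minimization.

The polynomial solver is checked against the in-package exhaustive
enumeration, which itself is checked against an independent pure-Python
itertools oracle on small instances.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crowdroute import (Configuration, FundamentalDiagram, Geometry,
                        NoiseParameters, PedestrianEnsemble, V_MIN,
                        activation_threshold_deterministic,
                        deterministic_split, individual_velocity,
                        local_mean_velocity, minimize_bruteforce,
                        minimize_exact, minimize_split_batch,
                        optical_length_residual, perceived_time,
                        speed_ratio_squared, total_discomfort)


def itertools_minimum(geom, fd, ens):
    """Independent oracle: enumerate every labeling with pure Python."""
    best = np.inf
    for labels in itertools.product("AB", repeat=ens.n):
        cost = total_discomfort(geom, fd, ens, Configuration(labels))
        best = min(best, cost)
    return best


@pytest.fixture
def fd_simple():
    return FundamentalDiagram(1.0, 0.3, NoiseParameters(0.0))


class TestVelocities:
    def test_local_mean_examples(self, fd_ref):
        assert local_mean_velocity(fd_ref, 0) == pytest.approx(1.012)
        assert local_mean_velocity(fd_ref, 10) == pytest.approx(0.842)
        flat = FundamentalDiagram(0.9, 0.0)
        assert local_mean_velocity(flat, 57) == pytest.approx(0.9)

    def test_individual_velocity(self, fd_ref):
        assert individual_velocity(fd_ref, 5, 0.0) == \
            pytest.approx(local_mean_velocity(fd_ref, 5))
        assert individual_velocity(fd_ref, 5, 0.15) == pytest.approx(1.077)
        assert individual_velocity(fd_ref, 5, -10.0) == V_MIN

    def test_monotone_in_occupancy(self, fd_ref):
        speeds = [local_mean_velocity(fd_ref, n) for n in range(40)]
        assert all(a >= b for a, b in zip(speeds, speeds[1:]))


class TestPerceivedTime:
    def test_path_a_geometric_time(self, geom, fd_simple):
        # n_j=1 at v0=1, kappa=0.3 with eps=+0.1 gives v=0.8
        t = perceived_time(geom, fd_simple, "A", 1, 0.1, 1.0)
        assert t == pytest.approx(1.25)

    def test_unit_ratio_makes_paths_symmetric(self, geom, fd_ref):
        ta = perceived_time(geom, fd_ref, "A", 3, 0.05, 1.0)
        tb = perceived_time(geom, fd_ref, "B", 3, 0.05, 1.0)
        assert ta == pytest.approx(tb)

    def test_path_b_scales_with_perceived_ratio(self, geom):
        fd = FundamentalDiagram(1.0, 0.0, NoiseParameters(0.0))
        assert perceived_time(geom, fd, "B", 1, 0.0, 1.45) == \
            pytest.approx(1.45)

    def test_invalid_label(self, geom, fd_ref):
        with pytest.raises(ValueError):
            perceived_time(geom, fd_ref, "C", 1, 0.0, 1.0)


class TestDiscomfort:
    def test_empty_crowd(self, geom, fd_simple):
        ens = PedestrianEnsemble(np.array([]), 1.0)
        assert total_discomfort(geom, fd_simple, ens, Configuration(())) == 0

    def test_two_pedestrians_both_on_a(self, geom, fd_simple):
        ens = PedestrianEnsemble(np.zeros(2), 1.0)
        cost = total_discomfort(geom, fd_simple, ens,
                                Configuration(("A", "A")))
        assert cost == pytest.approx(5.0)  # 2 / (1 - 0.3*2)

    def test_two_pedestrians_split(self, geom, fd_simple):
        ens = PedestrianEnsemble(np.zeros(2), 1.0)
        cost = total_discomfort(geom, fd_simple, ens,
                                Configuration(("A", "B")))
        assert cost == pytest.approx(2.0 / 0.7)

    def test_size_mismatch(self, geom, fd_simple):
        with pytest.raises(ValueError):
            total_discomfort(geom, fd_simple,
                             PedestrianEnsemble(np.zeros(2), 1.0),
                             Configuration(("A",)))


class TestBruteForce:
    def test_matches_itertools_oracle(self, geom, fd_ref):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(1, 8))
            ens = PedestrianEnsemble(rng.normal(0, 0.15, n),
                                     float(rng.uniform(0.5, 2.5)))
            _, cost = minimize_bruteforce(geom, fd_ref, ens)
            assert cost == pytest.approx(
                itertools_minimum(geom, fd_ref, ens), rel=1e-12)

    def test_symmetric_two_pedestrian_split(self, geom, fd_simple):
        ens = PedestrianEnsemble(np.zeros(2), 1.0)
        config, cost = minimize_bruteforce(geom, fd_simple, ens)
        assert cost == pytest.approx(2.0 / 0.7)
        assert {config.n_a, config.n_b} == {1, 1}

    def test_single_pedestrian_prefers_short_path(self, geom, fd_ref):
        ens = PedestrianEnsemble(np.zeros(1), 1.3)
        config, _ = minimize_bruteforce(geom, fd_ref, ens)
        assert config.labels == ("A",)

    def test_no_congestion_all_on_a(self, geom):
        fd = FundamentalDiagram(1.0, 0.0, NoiseParameters(0.0))
        ens = PedestrianEnsemble(np.zeros(6), 1.2)
        config, _ = minimize_bruteforce(geom, fd, ens)
        assert config.n_b == 0

    def test_guard(self, geom, fd_ref):
        with pytest.raises(ValueError):
            minimize_bruteforce(geom, fd_ref,
                                PedestrianEnsemble(np.zeros(25), 1.0))


class TestExactSolver:
    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(n=st.integers(1, 10),
           lam=st.floats(0.3, 3.0),
           seed=st.integers(0, 10_000))
    def test_equals_bruteforce(self, geom, fd_ref, n, lam, seed):
        rng = np.random.default_rng(seed)
        ens = PedestrianEnsemble(rng.normal(0, 0.2, n), lam)
        _, cost_bf = minimize_bruteforce(geom, fd_ref, ens)
        _, cost_ex = minimize_exact(geom, fd_ref, ens)
        assert cost_ex == pytest.approx(cost_bf, rel=1e-9)

    def test_empty(self, geom, fd_ref):
        config, cost = minimize_exact(geom, fd_ref,
                                      PedestrianEnsemble(np.array([]), 1.0))
        assert config.n == 0 and cost == 0.0

    def test_symmetric_case_balances(self, geom):
        # gentle slope so no speed ever hits the floor
        fd = FundamentalDiagram(1.0, 0.05, NoiseParameters(0.0))
        ens = PedestrianEnsemble(np.zeros(7), 1.0)
        config, _ = minimize_exact(geom, fd, ens)
        assert abs(config.n_a - config.n_b) <= 1

    def test_beats_random_configurations(self, geom, fd_ref):
        rng = np.random.default_rng(3)
        ens = PedestrianEnsemble(rng.normal(0, 0.15, 14), 1.4)
        _, best = minimize_exact(geom, fd_ref, ens)
        for _ in range(100):
            labels = tuple(rng.choice(["A", "B"], size=14))
            assert best <= total_discomfort(
                geom, fd_ref, ens, Configuration(labels)) + 1e-12

    def test_reference_length_scaling_invariance(self, fd_ref):
        rng = np.random.default_rng(8)
        ens = PedestrianEnsemble(rng.normal(0, 0.15, 9), 1.5)
        g1 = Geometry(l_a=1.0)
        g2 = Geometry(l_a=7.3)
        c1, cost1 = minimize_exact(g1, fd_ref, ens)
        c2, cost2 = minimize_exact(g2, fd_ref, ens)
        assert c1.labels == c2.labels
        assert cost2 == pytest.approx(7.3 * cost1, rel=1e-12)

    def test_batch_agrees_with_scalar(self, geom, fd_ref):
        rng = np.random.default_rng(21)
        m, n = 40, 9
        eps = rng.normal(0, 0.15, (m, n))
        lam = rng.uniform(0.6, 2.4, m)
        n_b, on_b, cost = minimize_split_batch(fd_ref, lam, eps)
        for i in range(m):
            config, c = minimize_exact(
                geom, fd_ref, PedestrianEnsemble(eps[i], lam[i]))
            assert cost[i] == pytest.approx(c, rel=1e-12)
            assert n_b[i] == config.n_b
            assert tuple("B" if b else "A" for b in on_b[i]) == config.labels


class TestDeterministicLimit:
    def test_symmetric_ratio_halves(self, geom, fd_ref):
        assert deterministic_split(geom, fd_ref, 12, ratio=1.0) == \
            pytest.approx(6.0)

    def test_interior_branch_value(self, geom, fd_ref):
        assert deterministic_split(geom, fd_ref, 20, ratio=1.45) == \
            pytest.approx(14.59, abs=0.01)

    def test_first_branch_all_on_a(self, geom, fd_ref):
        assert deterministic_split(geom, fd_ref, 5, ratio=1.45) == 5.0

    def test_kappa_zero_error(self, geom):
        fd = FundamentalDiagram(1.0, 0.0)
        with pytest.raises(ValueError):
            deterministic_split(geom, fd, 10, ratio=1.3)

    def test_residual_vanishes_at_continuum_optimum(self, geom, fd_ref):
        for n in [12, 20, 28]:
            n_a = deterministic_split(geom, fd_ref, n, ratio=1.45)
            assert n_a < n  # interior branch
            r = optical_length_residual(geom, fd_ref, n_a, n, ratio=1.45)
            assert abs(r) < 1e-10

    def test_residual_symmetric_case(self, geom, fd_ref):
        assert optical_length_residual(geom, fd_ref, 8, 16, ratio=1.0) == \
            pytest.approx(0.0, abs=1e-12)

    def test_residual_sign_on_overcrowded_a(self, geom, fd_ref):
        n = 20
        n_a = deterministic_split(geom, fd_ref, n, ratio=1.45)
        assert optical_length_residual(geom, fd_ref, n_a + 1, n,
                                       ratio=1.45) > 0

    def test_speed_ratio_identity(self, geom, fd_ref):
        n = 24
        n_a = deterministic_split(geom, fd_ref, n, ratio=1.45)
        assert speed_ratio_squared(fd_ref, n_a, n) == \
            pytest.approx(1.45, rel=1e-10)

    def test_activation_threshold_examples(self, geom, fd_ref):
        assert activation_threshold_deterministic(geom, fd_ref,
                                                  ratio=1.0) == 0.0
        assert activation_threshold_deterministic(geom, fd_ref,
                                                  ratio=1.45) == \
            pytest.approx(10.09, abs=0.01)

    def test_threshold_monotonicity(self, geom):
        base = activation_threshold_deterministic(
            geom, FundamentalDiagram(1.012, 0.017), ratio=1.45)
        assert activation_threshold_deterministic(
            geom, FundamentalDiagram(1.012, 0.017), ratio=1.6) > base
        assert activation_threshold_deterministic(
            geom, FundamentalDiagram(1.2, 0.017), ratio=1.45) > base
        assert activation_threshold_deterministic(
            geom, FundamentalDiagram(1.012, 0.03), ratio=1.45) < base

    def test_discrete_optimum_tracks_continuum(self, geom, fd_ref):
        lam = 1.48
        for n in range(1, 31):
            ens = PedestrianEnsemble(np.zeros(n), lam)
            config, _ = minimize_exact(geom, fd_ref, ens)
            cont = deterministic_split(geom, fd_ref, n, ratio=lam)
            assert abs(config.n_a - cont) < 1.0

    def test_sharp_transition_below_and_above_threshold(self, geom, fd_ref):
        lam = 1.48
        n_star = activation_threshold_deterministic(geom, fd_ref, ratio=lam)
        for n in range(1, int(n_star) + 1):
            config, _ = minimize_exact(
                geom, fd_ref, PedestrianEnsemble(np.zeros(n), lam))
            assert config.n_b == 0
        for n in range(int(np.ceil(n_star)) + 2, 31):
            config, _ = minimize_exact(
                geom, fd_ref, PedestrianEnsemble(np.zeros(n), lam))
            assert config.n_b >= 1
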