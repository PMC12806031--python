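"""Flux QP, sink weights, lactate fate weighting and partition."""

import numpy as np
import pandas as pd
import pytest

from glucoflux.errors import DomainError, InfeasibleError
from glucoflux.flux import (
    allocation_fractions,
    compute_flux_bounds,
    compute_sink_weights,
    lactate_fate_weights,
    partition_lactate,
    solve_flux_qp,
)
from glucoflux.simulate import simulate_network
from tests.conftest import two_sink_kkt


@pytest.fixture(scope="module")
def two_sink_net():
    network, _ = simulate_network(1, 2, seed=7)
    return network


class TestBoundsAndWeights:
    def test_bound_product(self):
        assert compute_flux_bounds(np.array([1.0]), np.array([2.0]))[0] == 2.0
        e = np.exp(1)
        B = compute_flux_bounds(np.array([e, 1 / e]), np.array([1.0, 1.0]))
        assert np.allclose(B, [e, 1 / e])

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            compute_flux_bounds(np.array([-1.0]), np.array([1.0]))

    def test_sqrt_normalization(self):
        w = compute_sink_weights(np.array([4.0, 1.0]))
        assert np.allclose(w, [2 / 3, 1 / 3])

    def test_uniform_cases(self):
        assert np.allclose(compute_sink_weights(np.array([3.0, 3.0, 3.0])),
                           1 / 3)
        assert compute_sink_weights(np.array([5.0]))[0] == 1.0
        with pytest.warns(UserWarning):
            w = compute_sink_weights(np.zeros(4))
        assert np.allclose(w, 0.25)

    def test_linear_mode(self):
        w = compute_sink_weights(np.array([4.0, 1.0]), sqrt_normalize=False)
        assert np.allclose(w, [0.8, 0.2])


class TestSolveFluxQP:
    def test_symmetric_split(self, two_sink_net):
        sol = solve_flux_qp(two_sink_net, np.array([10.0, 10.0]),
                            np.array([0.5, 0.5]), vglc_in=4.0, lambda_qp=0.3)
        assert np.allclose(sol.sink_flux.to_numpy(), [2.0, 2.0], atol=1e-9)

    def test_closed_form_example(self, two_sink_net):
        """w=(0.6,0.4), lambda=0.5, V=1 with slack bounds gives (0.6, 0.4)."""
        sol = solve_flux_qp(two_sink_net, np.array([5.0, 5.0]),
                            np.array([0.6, 0.4]), vglc_in=1.0, lambda_qp=0.5)
        assert np.allclose(sol.sink_flux.to_numpy(), [0.6, 0.4], atol=1e-9)
        frac = allocation_fractions(sol)
        assert np.allclose(frac.to_numpy(), [0.6, 0.4], atol=1e-9)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_bound_pinches_flux(self, two_sink_net):
        sol = solve_flux_qp(two_sink_net, np.array([5.0, 0.0]),
                            np.array([0.5, 0.5]), vglc_in=2.0, lambda_qp=0.3)
        assert sol.sink_flux.iloc[1] == 0.0
        assert sol.sink_flux.iloc[0] == pytest.approx(2.0)

    def test_kkt_oracle_grid(self, two_sink_net):
        """Two-sink optimum equals the clipped analytic KKT point."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            w = rng.dirichlet([2, 2])
            lam = rng.uniform(0.05, 2.0)
            B = rng.uniform(0.2, 3.0, 2)
            V = rng.uniform(0, 0.95) * B.sum()
            sol = solve_flux_qp(two_sink_net, B, w, V, lam)
            v1, v2 = two_sink_kkt(w[0], w[1], B[0], B[1], V, lam)
            assert abs(sol.sink_flux.iloc[0] - v1) < 1e-8
            assert abs(sol.sink_flux.iloc[1] - v2) < 1e-8

    def test_constraints_on_random_instances(self):
        """Conservation, bounds and internal balance hold on random networks."""
        rng = np.random.default_rng(5)
        for _ in range(40):
            k = int(rng.integers(1, 6))
            n_sinks = int(rng.integers(2, 9))
            network, _ = simulate_network(k, n_sinks, seed=int(rng.integers(1e6)))
            B = rng.uniform(0.1, 5.0, n_sinks)
            w = rng.dirichlet(np.ones(n_sinks))
            V = rng.uniform(0.1, 0.99) * B.sum()
            sol = solve_flux_qp(network, B, w, V, lambda_qp=rng.uniform(0.05, 1))
            tol = 1e-6 * max(V, 1.0)
            assert abs(sol.sink_flux.sum() - V) <= tol
            assert (sol.sink_flux.to_numpy() >= -1e-12).all()
            assert (sol.sink_flux.to_numpy() <= B + 1e-9).all()
            assert np.abs(sol.residuals.to_numpy()).max() <= tol
            assert (sol.v.to_numpy() >= -1e-9).all()

    def test_weight_monotonicity(self, two_sink_net):
        """Raising a sink's weight never lowers its optimal flux."""
        fluxes = []
        for w1 in np.linspace(0.1, 0.9, 9):
            sol = solve_flux_qp(two_sink_net, np.array([10.0, 10.0]),
                                np.array([w1, 1 - w1]), 3.0, lambda_qp=0.2)
            fluxes.append(sol.sink_flux.iloc[0])
        assert (np.diff(fluxes) >= -1e-10).all()

    def test_infeasibility_reports_gap(self, two_sink_net):
        with pytest.raises(InfeasibleError, match="gap"):
            solve_flux_qp(two_sink_net, np.array([1.0, 1.0]),
                          np.array([0.5, 0.5]), vglc_in=5.0, lambda_qp=0.5)

    def test_infeasibility_rescale_flag(self, two_sink_net):
        sol = solve_flux_qp(two_sink_net, np.array([1.0, 1.0]),
                            np.array([0.5, 0.5]), vglc_in=5.0, lambda_qp=0.5,
                            rescale_infeasible=True)
        assert sol.vglc_in == pytest.approx(2.0)
        assert np.allclose(sol.sink_flux.to_numpy(), [1.0, 1.0])

    def test_zero_uptake_fraction_error(self, two_sink_net):
        sol = solve_flux_qp(two_sink_net, np.array([1.0, 1.0]),
                            np.array([0.5, 0.5]), vglc_in=0.0, lambda_qp=0.5)
        with pytest.raises(DomainError):
            allocation_fractions(sol)


class TestLactateFate:
    def test_equal_scores_symmetric(self):
        w = lactate_fate_weights(2.0, 2.0, tau=0.7, alpha=0.3)
        assert w.w_export == pytest.approx(0.5)
        assert w.w_export + w.w_lactylation == pytest.approx(1.0)

    def test_prior_dominates_as_alpha_tends_to_one(self):
        w = lactate_fate_weights(10.0, 0.0, tau=1.0, alpha=0.999)
        assert w.w_export == pytest.approx(0.5, abs=1e-3)

    def test_hand_value(self):
        """s = (e-1, 0), tau=1, alpha=0.2 gives w_export ~ 0.6849."""
        w = lactate_fate_weights(np.e - 1, 0.0, tau=1.0, alpha=0.2)
        expected = 0.2 * 0.5 + 0.8 * np.e / (np.e + 1)
        assert w.w_export == pytest.approx(expected, abs=1e-6)
        assert w.w_export == pytest.approx(0.6849, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            lactate_fate_weights(1.0, 1.0, tau=0.0, alpha=0.2)
        with pytest.raises(DomainError):
            lactate_fate_weights(1.0, 1.0, tau=1.0, alpha=1.0)


class TestPartitionLactate:
    def test_zero_flux(self):
        w = lactate_fate_weights(1.0, 1.0)
        p = partition_lactate(0.0, w)
        assert p.v_export == 0.0 and p.v_lactylation == 0.0

    def test_equal_weights_split_evenly(self):
        w = lactate_fate_weights(3.0, 3.0)
        p = partition_lactate(4.0, w, lambda_qp=0.7)
        assert p.v_export == pytest.approx(2.0)

    def test_closed_form_case(self):
        class W:  # direct weight injection
            w_export, w_lactylation = 0.6, 0.4

        p = partition_lactate(1.0, W(), lambda_qp=0.5)
        assert p.v_export == pytest.approx(0.6)
        assert p.v_lactylation == pytest.approx(0.4)

    def test_matches_clipped_closed_form_everywhere(self):
        """Partition always reproduces clip(L/2 + (w1-w2)/(4 lam), 0, L)."""
        rng = np.random.default_rng(3)
        for _ in range(300):
            L = rng.uniform(0, 5)
            lam = rng.uniform(0.01, 2)
            we = rng.uniform(0, 1)

            class W:
                w_export, w_lactylation = we, 1 - we

            p = partition_lactate(L, W(), lam)
            expected = float(np.clip(L / 2 + (2 * we - 1) / (4 * lam), 0, L))
            assert p.v_export == pytest.approx(expected, abs=1e-12)
            assert p.v_export + p.v_lactylation == pytest.approx(L, abs=1e-12)
            assert p.v_export >= 0 and p.v_lactylation >= 0
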