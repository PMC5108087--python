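"""Covalent modification cycle: reaction sets, conservation, the
steady-state map, the four regime presets and regime fitting."""

import numpy as np
import pytest

from analogcrn.crn import count_reactions, simulate, dual_value
from analogcrn.cmc import (CMCParams, REGIME_PRESETS, build_cmc_crn, cmc_rhs,
                           steady_state_output, regime_curve, fit_regime,
                           preset)


HYP = preset("hyperbolic")


def _simulated_output(params: CMCParams, x_in: float, dual: bool,
                      t_final: float) -> float:
    crn = build_cmc_crn(params, dual_rail=dual, input_value=x_in)
    traj = simulate(crn, t_final, method="LSODA", rtol=1e-9, atol=1e-13,
                    check=False)
    if dual:
        return float(dual_value(traj, "x_out")[-1])
    return traj.final("x_out")


class TestReactionSets:
    def test_dual_rail_has_fourteen_reactions(self):
        assert count_reactions(build_cmc_crn(HYP, dual_rail=True)) == 14

    def test_single_rail_has_four_reactions(self):
        assert count_reactions(build_cmc_crn(HYP, dual_rail=False)) == 4

    def test_phosphatase_total_conserved_along_trajectory(self):
        crn = build_cmc_crn(HYP, dual_rail=False, input_value=3.0)
        traj = simulate(crn, 200.0)  # conservation checked to 1e-6 inside
        total = traj.value("x_e") + traj.value("x_C2")
        assert np.max(np.abs(total - HYP.xe_total)) < 1e-6 * HYP.xe_total

    def test_substrate_total_conserved(self):
        crn = build_cmc_crn(HYP, dual_rail=False, input_value=3.0)
        traj = simulate(crn, 200.0)
        total = sum(traj.value(n) for n in ("x_p", "x_out", "x_C1", "x_C2"))
        assert np.max(np.abs(total - HYP.substrate_total)) \
            < 1e-6 * HYP.substrate_total


class TestReducedOde:
    def test_zero_state_zero_input_is_stationary(self):
        d = cmc_rhs(HYP, (0.0, 0.0, 0.0), 0.0)
        assert np.all(d == 0.0)

    def test_flux_balance_at_steady_state(self):
        """At steady state the release and back-binding fluxes match."""
        x_in = 4.0
        out = steady_state_output(HYP, x_in)
        k1, k2, k3, k4 = HYP.rates()
        # recover the companion steady-state values from the flux
        xe = HYP.xe_total / (1.0 + k3 * out / k4)
        v = k3 * out * xe
        c1, c2 = v / k2, v / k4
        d = cmc_rhs(HYP, (out, c1, c2), v / (k1 * (HYP.substrate_total
                                                   - out - c1 - c2)))
        assert np.max(np.abs(d)) < 1e-8 * v


class TestSteadyStateMap:
    def test_zero_input_zero_output(self):
        assert steady_state_output(HYP, 0.0) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            steady_state_output(HYP, -1.0)

    def test_monotone_in_input(self):
        for label in REGIME_PRESETS:
            p = preset(label)
            scale = 1e-6 if label == "ultrasensitive" else 1.0
            grid = np.linspace(0.2, 6.0, 12) * scale
            curve = regime_curve(p, grid)
            assert np.all(np.diff(curve) > -1e-12 * np.max(curve)), label

    def test_root_matches_long_time_integration(self, rng):
        """Root-finding and simulation agree to 1e-4 over random cycles."""
        for _ in range(100):
            params = CMCParams(
                k1=10.0 ** rng.uniform(-1, 1),
                k2=10.0 ** rng.uniform(-1, 1),
                k3=10.0 ** rng.uniform(-1, 1),
                k4=10.0 ** rng.uniform(-1, 1),
                xe_total=10.0 ** rng.uniform(-0.5, 0.5),
                substrate_total=10.0 ** rng.uniform(0.3, 1.0))
            x_in = float(rng.uniform(0.5, 5.0))
            expected = steady_state_output(params, x_in)
            slowest = min(params.k2, params.k4,
                          params.k1 * params.substrate_total,
                          params.k3 * params.xe_total)
            got = _simulated_output(params, x_in, dual=False,
                                    t_final=50.0 / slowest)
            assert got == pytest.approx(expected, rel=1e-4)

    def test_dual_rail_matches_single_rail_for_positive_inputs(self):
        for label, x_in in [("hyperbolic", 4.0), ("threshold_hyperbolic", 3.0),
                            ("signal_transducing", 2.0),
                            ("ultrasensitive", 2e-6)]:
            p = preset(label)
            single = steady_state_output(p, x_in)
            t_final = 5000.0
            dualv = _simulated_output(p, x_in, dual=True, t_final=t_final)
            assert dualv == pytest.approx(single, rel=1e-3), label


class TestRegimeShapes:
    def test_ultrasensitive_switch_saturates_near_1e_minus_3(self):
        p = preset("ultrasensitive")
        lo = steady_state_output(p, 1e-10)
        hi = steady_state_output(p, 2e-6)
        hi2 = steady_state_output(p, 6e-6)
        assert hi == pytest.approx(1e-3, rel=0.02)
        assert hi2 == pytest.approx(1e-3, rel=0.02)   # flat plateau
        assert lo < 0.1 * hi                          # switch-like

    def test_ultrasensitive_negative_branch_saturates_symmetrically(self):
        p = preset("ultrasensitive")
        out = _simulated_output(p, -3e-6, dual=True, t_final=5000.0)
        assert out == pytest.approx(-1e-3, rel=0.05)

    def test_threshold_hyperbolic_dead_zone_then_rise(self):
        p = preset("threshold_hyperbolic")
        assert steady_state_output(p, 0.3) < 0.1       # dead zone
        mid = steady_state_output(p, 3.0)
        assert 2.0 < mid < 4.5                         # near-unit gradient
        # near-linear region: local slope about 1
        slope = (steady_state_output(p, 3.5) - steady_state_output(p, 2.5))
        assert 0.5 < slope < 1.6

    def test_signal_transducing_linear_then_plateau(self):
        p = preset("signal_transducing")
        grid = np.array([0.2, 0.5, 1.0, 4.0, 8.0, 16.0, 40.0, 100.0])
        c = regime_curve(p, grid)
        early = (c[1] - c[0]) / (grid[1] - grid[0])
        late = (c[-1] - c[-2]) / (grid[-1] - grid[-2])
        assert early > 5.0            # steep linear response
        assert late < 0.25 * early    # flattening plateau

    def test_rectification_of_negative_inputs(self):
        """TH and ST regimes give ~no output for negative inputs: the
        minus-rail pathway recycles and cancels."""
        for label, scale in [("threshold_hyperbolic", 3.0),
                             ("signal_transducing", 2.0)]:
            p = preset(label)
            out = _simulated_output(p, -scale, dual=True, t_final=5000.0)
            pos = steady_state_output(p, scale)
            assert abs(out) < 5e-3 * pos, label


class TestFitRegime:
    def test_recovers_perturbed_hyperbolic_preset(self):
        grid = np.linspace(0.5, 8.0, 9)
        target = np.column_stack([grid, regime_curve(HYP, grid)])
        start = CMCParams(HYP.k1 * 2, HYP.k2 * 2, HYP.k3 * 2, HYP.k4 * 2,
                          xe_total=HYP.xe_total,
                          substrate_total=HYP.substrate_total)
        result = fit_regime(target, start, seed=0)
        norm = float(np.sum(target[:, 1] ** 2))
        assert result.improved
        assert result.sse < 1e-4 * norm

    def test_sse_never_worse_than_start(self):
        grid = np.linspace(0.5, 6.0, 7)
        target = np.column_stack([grid, np.log1p(grid)])
        result = fit_regime(target, HYP, seed=0, max_iter=200)
        assert result.sse <= result.sse_initial

    def test_constant_zero_target_flagged_degenerate(self):
        target = [(1.0, 0.0), (2.0, 0.0), (3.0, 0.0)]
        result = fit_regime(target, HYP, seed=0)
        assert result.degenerate

    def test_deterministic_under_seed(self):
        grid = np.linspace(1.0, 5.0, 5)
        target = np.column_stack([grid, np.sqrt(grid)])
        r1 = fit_regime(target, HYP, seed=3, max_iter=300)
        r2 = fit_regime(target, HYP, seed=3, max_iter=300)
        assert r1.sse == r2.sse
        assert r1.params == r2.params


class TestValidation:
    def test_positive_rates_enforced(self):
        with pytest.raises(ValueError):
            CMCParams(-1.0, 1.0, 1.0, 1.0, xe_total=1.0)
        with pytest.raises(ValueError):
            CMCParams(1.0, 1.0, 1.0, 1.0, xe_total=1.0, substrate_total=-2.0)

    def test_preset_lookup(self):
        with pytest.raises(KeyError):
            preset("sigmoid")
        assert preset("hyperbolic").k4 == 35.10
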