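"""Composite circuits: the series-logarithm oracle, the reaction-count
ledger, end-to-end accuracy of the CMC designs and series/CMC agreement."""

import math

import numpy as np
import pytest

from analogcrn.circuits import (atanh_series_ln, build_ln_series_circuit,
                                build_log_arbitrary, build_sqrt_block,
                                build_signum, build_abs, evaluate_circuit,
                                CircuitError, compile_diagram)
from analogcrn.crn import count_reactions


def series_oracle(x: float, l: int) -> float:
    """Independent direct summation of the area-tanh series."""
    z = (x - 1.0) / (x + 1.0)
    return 2.0 * sum(z ** (2 * i + 1) / (2 * i + 1) for i in range(l + 1))


class TestSeriesLogarithm:
    def test_x_equals_one_is_zero(self):
        assert atanh_series_ln(1.0) == 0.0

    # frozen from the direct-summation oracle above
    @pytest.mark.parametrize("x,l,expected", [
        (8.0, 10, 2.0788305682662926),
        (10.0, 10, 2.300312264911263),
        (5.0, 10, 1.6094247669918942),
        (2.0, 5, 0.6931470737597851),
    ])
    def test_frozen_series_values(self, x, l, expected):
        assert atanh_series_ln(x, l) == pytest.approx(expected, abs=1e-12)
        assert atanh_series_ln(x, l) == pytest.approx(series_oracle(x, l),
                                                      abs=1e-12)

    def test_order_ten_covers_arguments_up_to_ten(self):
        """The order-10 truncation stays within 0.5% relative of ln(x)
        across (0, 10]; the absolute tail at x=10 is ~2.5e-3."""
        for x in (0.5, 2.0, 5.0, 8.0, 10.0):
            assert atanh_series_ln(x, 10) == pytest.approx(
                math.log(x), rel=5e-3)
        assert abs(atanh_series_ln(10.0, 10) - math.log(10.0)) < 3e-3

    def test_domain_error(self):
        with pytest.raises(CircuitError):
            atanh_series_ln(0.0)


LEDGER = [
    ("ln series l=10", lambda: build_ln_series_circuit(10), 928),
    ("log arbitrary series", lambda: build_log_arbitrary("series"), 1875),
    ("log arbitrary cmc", lambda: build_log_arbitrary("cmc"), 47),
    ("sqrt", build_sqrt_block, 50),
    ("signum series", lambda: build_signum("series"), 83),
    ("signum cmc", lambda: build_signum("cmc"), 19),
    ("abs series", lambda: build_abs("series"), 57),
    ("abs cmc", lambda: build_abs("cmc"), 45),
]


class TestCountLedger:
    @pytest.mark.parametrize("name,builder,expected",
                             LEDGER, ids=[c[0] for c in LEDGER])
    def test_published_totals(self, name, builder, expected):
        assert builder().total_count == expected

    def test_totals_equal_sum_of_block_counts(self):
        for name, builder, expected in LEDGER:
            d = builder()
            assert sum(d.inventory().values()) == expected, name

    def test_power_block_subtotal_in_ln_series(self):
        inv = build_ln_series_circuit(10).inventory()
        powers = sum(v for k, v in inv.items() if k.startswith("power"))
        assert powers == 770  # 7 * (2 + 4 + ... + 20)

    def test_small_order_by_hand_enumeration(self):
        # l=2: exponents 3 and 5; 5 sum/sub, 4 gains, 1 mult, powers 3+5
        expected = 7 * 5 + 5 * 4 + 7 + 7 * (2 + 4)
        assert build_ln_series_circuit(2).total_count == expected == 104

    def test_compiled_crn_matches_declared_totals(self):
        for name, builder, expected in LEDGER:
            d = builder()
            crn = compile_diagram(d, {s: 1.0 for s in d.inputs})
            assert count_reactions(crn) == expected, name


class TestLogCircuit:
    def test_log2_of_8(self):
        d = build_log_arbitrary("cmc")
        rep = evaluate_circuit(d, {"a": 8.0, "b": 2.0}, t_final=2000.0,
                               settle_tol=1e-3)
        assert rep.settled["log_b_a"]
        assert rep.outputs["log_b_a"] == pytest.approx(3.0, rel=0.05)

    def test_log10_of_5(self):
        d = build_log_arbitrary("cmc")
        rep = evaluate_circuit(d, {"a": 5.0, "b": 10.0}, t_final=2000.0,
                               settle_tol=1e-3)
        assert rep.outputs["log_b_a"] == pytest.approx(math.log10(5.0),
                                                       rel=0.05)

    def test_natural_log_block_value(self):
        """The log-regime cycle itself produces ~ln(5) for input 5."""
        from analogcrn.circuits import LOG_DESIGN
        from analogcrn.cmc import steady_state_output
        assert steady_state_output(LOG_DESIGN, 5.0) == pytest.approx(
            math.log(5.0), rel=0.05)

    def test_series_and_cmc_variants_agree(self):
        cmcd = build_log_arbitrary("cmc")
        serd = build_log_arbitrary("series")
        got_c = evaluate_circuit(cmcd, {"a": 8.0, "b": 2.0}, t_final=2000.0,
                                 settle_tol=1e-3).outputs["log_b_a"]
        got_s = evaluate_circuit(serd, {"a": 8.0, "b": 2.0}, t_final=600.0,
                                 mode="effective",
                                 settle_tol=1e-3).outputs["log_b_a"]
        assert got_s == pytest.approx(3.0, rel=0.01)
        assert got_c == pytest.approx(got_s, rel=0.10)


class TestSqrtBlock:
    @pytest.mark.parametrize("mode", ["effective", "crn"])
    def test_sqrt_of_two(self, mode):
        d = build_sqrt_block()
        rep = evaluate_circuit(d, {"w": 2.0}, t_final=200.0, mode=mode,
                               settle_tol=1e-4)
        assert rep.outputs["sqrt_w"] == pytest.approx(math.sqrt(2.0),
                                                      abs=1e-3)

    def test_sqrt_of_four(self):
        d = build_sqrt_block()
        rep = evaluate_circuit(d, {"w": 4.0}, t_final=200.0, mode="effective")
        assert rep.outputs["sqrt_w"] == pytest.approx(2.0, rel=1e-4)

    def test_newton_flow_converges_across_basin(self):
        d = build_sqrt_block()
        for w in (0.25, 2.0, 9.0, 36.0):
            rep = evaluate_circuit(d, {"w": w}, t_final=300.0,
                                   mode="effective", settle_tol=1e-3)
            assert rep.outputs["sqrt_w"] == pytest.approx(math.sqrt(w),
                                                          rel=1e-3), w


class TestSignum:
    PAPER_INPUTS = (2.0e-6, 5.5e-6, -3.0e-6, -0.5e-6)

    def test_cmc_variant_on_published_inputs(self):
        d = build_signum("cmc")
        for x in self.PAPER_INPUTS:
            rep = evaluate_circuit(d, {"x": x}, t_final=5000.0,
                                   settle_tol=1e-2)
            y = rep.outputs["sgn_x"]
            assert math.copysign(1.0, y) == math.copysign(1.0, x)
            assert abs(y) == pytest.approx(1.0, rel=0.05)

    def test_series_variant_at_unit_scale(self):
        """sgn is scale-invariant; the series design is validated at
        unit-scale inputs where the reciprocal stage is well conditioned."""
        d = build_signum("series", divider_gain=1e4)
        for x in (0.5, -0.5, 2.0):
            rep = evaluate_circuit(d, {"x": x}, t_final=400.0,
                                   mode="effective", settle_tol=1e-3)
            y = rep.outputs["sgn_x"]
            assert y == pytest.approx(math.copysign(1.0, x), rel=0.01)

    def test_variants_agree_on_sign_and_magnitude(self):
        cm = build_signum("cmc")
        se = build_signum("series", divider_gain=1e4)
        for x_cmc, x_ser in ((2.0e-6, 2.0), (-3.0e-6, -3.0)):
            yc = evaluate_circuit(cm, {"x": x_cmc}, t_final=5000.0,
                                  settle_tol=1e-2).outputs["sgn_x"]
            ys = evaluate_circuit(se, {"x": x_ser}, t_final=400.0,
                                  mode="effective",
                                  settle_tol=1e-3).outputs["sgn_x"]
            assert yc == pytest.approx(ys, rel=0.10)


class TestAbs:
    def test_cmc_variant_within_ten_percent(self):
        d = build_abs("cmc")
        for u in (2.0, 3.0, 4.0, 5.0, -2.0, -3.0, -4.0, -5.0):
            rep = evaluate_circuit(d, {"u": u}, t_final=8000.0,
                                   settle_tol=1e-2)
            assert rep.outputs["abs_u"] == pytest.approx(abs(u), rel=0.10), u

    def test_series_variant(self):
        d = build_abs("series")
        for u in (3.0, -4.0):
            rep = evaluate_circuit(d, {"u": u}, t_final=300.0,
                                   mode="effective", settle_tol=1e-3)
            assert rep.outputs["abs_u"] == pytest.approx(abs(u), rel=1e-3)

    def test_variants_agree(self):
        cm, se = build_abs("cmc"), build_abs("series")
        for u in (3.0, -4.0):
            yc = evaluate_circuit(cm, {"u": u}, t_final=8000.0,
                                  settle_tol=1e-2).outputs["abs_u"]
            ys = evaluate_circuit(se, {"u": u}, t_final=300.0,
                                  mode="effective",
                                  settle_tol=1e-3).outputs["abs_u"]
            assert yc == pytest.approx(ys, rel=0.10)


class TestEvaluation:
    def test_identity_gain_passes_input_through(self):
        from analogcrn.circuits import Block, BlockDiagram
        d = BlockDiagram([Block("gain", "g", "y", ("x",),
                                {"K": 1.0, "gamma": 10.0})],
                         inputs=("x",), outputs=("y",))
        rep = evaluate_circuit(d, {"x": 1.5}, t_final=10.0)
        assert rep.outputs["y"] == pytest.approx(1.5, rel=1e-4)

    def test_missing_input_rejected(self):
        d = build_sqrt_block()
        with pytest.raises(CircuitError):
            evaluate_circuit(d, {}, t_final=10.0)

    def test_short_horizon_flags_unsettled(self):
        d = build_sqrt_block()
        rep = evaluate_circuit(d, {"w": 2.0}, t_final=2.0, mode="effective",
                               settle_tol=1e-6)
        assert not rep.settled["sqrt_w"]

    def test_undeclared_signal_rejected(self):
        from analogcrn.circuits import Block, BlockDiagram
        with pytest.raises(CircuitError):
            BlockDiagram([Block("gain", "g", "y", ("ghost",), {})],
                         inputs=("x",), outputs=("y",))

    def test_undeclared_feedback_loop_rejected(self):
        from analogcrn.circuits import Block, BlockDiagram
        with pytest.raises(CircuitError):
            BlockDiagram([
                Block("gain", "g1", "y", ("z",), {}),
                Block("gain", "g2", "z", ("y",), {}),
            ], inputs=(), outputs=("y",))
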