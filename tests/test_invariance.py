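"""Equivariance consistency, rescaling compensation, paired output tests."""

import numpy as np
import pytest
import sympy as sp

from adaptivepi.invariance import (
    B, C, D, L, R, S, X1, X2,
    Protocol,
    Verdict,
    dc_rescaling,
    equivariance_consistency,
    equivariance_residual,
    paired_output_test,
    undo_rescaling,
    _system,
)


class TestEquivarianceConsistency:
    def test_gain_scale_admits_alpha(self):
        cand = equivariance_consistency("s")
        assert sp.simplify(cand.alpha - X1 / S) == 0
        assert cand.consistent
        assert cand.violated_conditions == []
        assert sp.simplify(cand.d_alpha_dx1 - 1 / S) == 0
        assert cand.d_alpha_dx2 == 0

    def test_growth_rate_candidate_inconsistent(self):
        cand = equivariance_consistency("b")
        assert not cand.consistent
        # the solved candidate has d(alpha)/dx1 = 1, not alpha/x1, and a
        # nonzero d(alpha)/dx2 — both hidden-row conditions fail
        assert sp.simplify(cand.d_alpha_dx1 - 1) == 0
        assert sp.simplify(cand.d_alpha_dx2) != 0
        assert set(cand.violated_conditions) == {"ratio_dx1", "zero_dx2"}

    def test_adaptation_rate_candidate_inconsistent(self):
        cand = equivariance_consistency("c")
        expected = ((C - 1) * R + X1) / C
        assert sp.simplify(cand.alpha - expected) == 0
        assert not cand.consistent
        # d(alpha)/dx1 = 1/c satisfies neither the required ratio ...
        assert cand.violated_conditions == ["ratio_dx1"]
        # ... while d(alpha)/dx2 = 0 does hold for this candidate
        assert cand.d_alpha_dx2 == 0

    def test_unknown_parameter(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            equivariance_consistency("l")

    def test_initial_condition_map_fixes_output(self):
        cand = equivariance_consistency("s")
        assert str(cand.initial_condition_map[1]) == "gamma2"

    def test_gain_scale_identity_is_symbolic(self):
        """Both sides of the intertwining identity agree as expressions."""
        f, f_ref, p = _system("s")
        alpha = X1 / S
        lhs = f.subs({X1: alpha}, simultaneous=True)
        jac = sp.Matrix([[sp.diff(alpha, X1), sp.diff(alpha, X2)], [0, 1]])
        rhs = jac * f_ref
        assert sp.simplify(lhs - rhs) == sp.zeros(2, 1)


class TestEquivarianceResidual:
    def test_gain_scale_residual_vanishes(self, rng):
        cand = equivariance_consistency("s")
        for s_value in (0.25, 1.5):
            for _ in range(50):
                state = rng.uniform(0.1, 10.0, size=2)
                res = equivariance_residual(cand, state, r=11.0, d=0.01, p_value=s_value)
                assert np.linalg.norm(res) < 1e-12

    def test_identity_at_reference_parameter(self, rng):
        cand = equivariance_consistency("s")
        state = rng.uniform(0.1, 10.0, size=2)
        res = equivariance_residual(cand, state, r=11.0, d=0.01, p_value=1.0)
        assert np.linalg.norm(res) == 0.0

    def test_growth_rate_residual_nonzero(self, rng):
        cand = equivariance_consistency("b")
        norms = [
            np.linalg.norm(
                equivariance_residual(cand, rng.uniform(0.5, 10.0, size=2),
                                      r=11.0, d=0.01, p_value=0.6)
            )
            for _ in range(20)
        ]
        assert min(norms) > 1e-3

    def test_degenerate_gain_scale(self):
        cand = equivariance_consistency("s")
        with pytest.raises(ZeroDivisionError):
            equivariance_residual(cand, (1.0, 1.0), r=11.0, d=0.01, p_value=0.0)


class TestDCRescaling:
    def test_gain_scale_is_eliminated(self):
        rsc = dc_rescaling("s")
        assert rsc.parameter_eliminated
        v1, v2 = sp.symbols("v1 v2", real=True)
        expected = (-C * v1 * (R - v2), B * v2 + D + v1 * (L * R - v2))
        for got, want in zip(rsc.transformed_rhs, expected):
            assert sp.simplify(got - want) == 0

    def test_growth_rate_survives(self):
        rsc = dc_rescaling("b")
        assert not rsc.parameter_eliminated
        assert all(B in expr.free_symbols for expr in rsc.transformed_rhs)

    def test_adaptation_rate_survives(self):
        rsc = dc_rescaling("c")
        assert not rsc.parameter_eliminated
        # c survives as the s/c coefficient of the feedback term
        v1 = sp.Symbol("v1", real=True)
        coeff = sp.expand(rsc.transformed_rhs[1]).coeff(v1 * L * R)
        assert sp.simplify(coeff - S / C) == 0

    @pytest.mark.parametrize("name", ["s", "b", "c"])
    def test_round_trip_recovers_original(self, name):
        f, _, _ = _system("s")
        rsc = dc_rescaling(name)
        x1_dot, x2_dot = undo_rescaling(rsc)
        assert sp.simplify(x1_dot - f[0]) == 0
        assert sp.simplify(x2_dot - f[1]) == 0

    def test_unknown_parameter(self):
        with pytest.raises(ValueError):
            dc_rescaling("q")


class TestPairedOutputTest:
    def test_identical_runs_give_exact_zero(self):
        report = paired_output_test("s", 0.25, 0.25,
                                    protocol=Protocol.DC_AFTER_ADAPTATION,
                                    shared_seed=5, t_end=60.0)
        assert report.max_abs_output_diff == 0.0
        assert report.verdict is Verdict.INVARIANT

    def test_gain_scale_strict_invariance(self):
        report = paired_output_test("s", 0.25, 1.5, protocol=Protocol.STRICT,
                                    shared_seed=5, t_end=100.0)
        assert report.verdict is Verdict.INVARIANT
        assert report.max_abs_output_diff < 1e-5
        assert report.adaptation_window == (0.0, 100.0)

    def test_gain_scale_invariance_random_pairs(self, rng):
        """Strict invariance holds across the admissible gain-scale range."""
        for _ in range(5):
            p1, p2 = rng.uniform(0.1, 10.0, size=2)
            report = paired_output_test("s", p1, p2, protocol=Protocol.STRICT,
                                        shared_seed=9)
            assert report.verdict is Verdict.INVARIANT, (p1, p2)

    def test_growth_rate_not_invariant(self):
        report = paired_output_test("b", 0.3, 0.6,
                                    protocol=Protocol.DC_AFTER_ADAPTATION,
                                    shared_seed=5)
        assert report.verdict is Verdict.NOT_INVARIANT
        assert report.max_abs_output_diff > 1e-1

    def test_adaptation_rate_transient_differs_terminal_agrees(self):
        """c: 2 vs 4 perturbs transients but both settle onto y = r."""
        report = paired_output_test("c", 2.0, 4.0,
                                    protocol=Protocol.DC_AFTER_ADAPTATION,
                                    shared_seed=5)
        assert report.verdict is Verdict.NOT_INVARIANT
        assert report.max_abs_output_diff > 1e-1
        assert abs(report.output_diff[-1]) < 1e-3

    def test_report_serialization(self):
        report = paired_output_test("s", 0.25, 1.5, shared_seed=2, t_end=50.0)
        payload = report.to_dict()
        assert payload["parameter_name"] == "s"
        assert payload["seed"] == 2
        frame = report.diff_frame()
        assert list(frame.columns) == ["t", "delta_y"]
        assert len(frame) == len(report.times)

    def test_unknown_parameter(self):
        with pytest.raises(ValueError):
            paired_output_test("l", 0.5, 0.9)
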