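"""Equilibrium binding model: solver correctness, limits, sweeps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crispri_circuits.equilibrium_model import (
    BindingParams,
    SpeciesTotals,
    explicit_output,
    solve_equilibrium,
    solve_equilibrium_oracle,
    sweep_transfer_curve,
    switch_point,
)
from crispri_circuits.equilibrium_model import TransferCurve

conc = st.floats(min_value=0.01, max_value=1e4)

# hypothesis-driven tests share one parameter set (module constant rather
# than a function-scoped fixture)
P = BindingParams(K1=0.3, K2=2.0)


class TestSolveEquilibrium:
    def test_no_sgrna_means_no_repression(self, params):
        state = solve_equilibrium(params, SpeciesTotals(Ctot=100, gtot=0, Dtot=10))
        assert state.D == 10
        assert state.Cg == 0
        assert state.CgD == 0
        assert state.C == 100

    def test_no_dcas9_means_no_repression(self, params):
        state = solve_equilibrium(params, SpeciesTotals(Ctot=0, gtot=100, Dtot=10))
        assert state.D == 10
        assert state.g == 100

    def test_agrees_with_oracle_at_high_occupancy(self, params, totals_mid):
        state = solve_equilibrium(params, totals_mid)
        oracle = solve_equilibrium_oracle(params, totals_mid)
        for attr in ("C", "g", "D", "Cg", "CgD"):
            a, b = getattr(state, attr), getattr(oracle, attr)
            assert a == pytest.approx(b, rel=1e-6, abs=1e-12)
        assert state.converged

    def test_no_dna_reduces_to_single_binding_quadratic(self, params):
        # closed form: smaller root of x^2 - (Ctot+gtot+K1)x + Ctot*gtot
        Ctot = gtot = 1.0
        s = Ctot + gtot + params.K1
        expected = (s - math.sqrt(s * s - 4 * Ctot * gtot)) / 2
        state = solve_equilibrium(params, SpeciesTotals(Ctot=Ctot, gtot=gtot, Dtot=0))
        assert state.CgD == 0
        assert state.Cg == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonfinite_and_negative_inputs(self, params):
        with pytest.raises(ValueError):
            SpeciesTotals(Ctot=-1, gtot=0, Dtot=0)
        with pytest.raises(ValueError):
            SpeciesTotals(Ctot=float("nan"), gtot=0, Dtot=0)
        with pytest.raises(ValueError):
            solve_equilibrium(params, SpeciesTotals(1, 1, 1), tol=0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(Ctot=conc, gtot=conc, Dtot=conc)
    def test_conservation_and_mass_action_residuals(self, Ctot, gtot, Dtot):
        totals = SpeciesTotals(Ctot, gtot, Dtot)
        state = solve_equilibrium(P, totals)
        assert max(state.conservation_residuals(totals)) <= 1e-8
        assert max(state.mass_action_residuals(P)) <= 1e-8
        assert min(state.C, state.g, state.D, state.Cg, state.CgD) >= 0
        assert state.R == pytest.approx(P.theta * state.D)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=conc, b=conc)
    def test_dcas9_sgrna_exchange_symmetry(self, a, b):
        # the conservation/mass-action structure is symmetric in C and g
        d1 = solve_equilibrium(P, SpeciesTotals(Ctot=a, gtot=b, Dtot=10)).D
        d2 = solve_equilibrium(P, SpeciesTotals(Ctot=b, gtot=a, Dtot=10)).D
        assert d1 == pytest.approx(d2, rel=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(g1=conc, g2=conc)
    def test_free_dna_monotone_in_sgrna(self, g1, g2):
        lo, hi = sorted((g1, g2))
        d_lo = solve_equilibrium(P, SpeciesTotals(100, lo, 10)).D
        d_hi = solve_equilibrium(P, SpeciesTotals(100, hi, 10)).D
        assert d_hi <= d_lo * (1 + 1e-9)


class TestOracle:
    def test_zero_sgrna_gives_zero_repressed_complex(self, params):
        state = solve_equilibrium_oracle(params, SpeciesTotals(50, 0, 5))
        assert state.CgD == 0

    def test_machine_precision_conservation(self, params):
        totals = SpeciesTotals(Ctot=100, gtot=100, Dtot=1)
        state = solve_equilibrium_oracle(params, totals)
        assert max(state.conservation_residuals(totals)) <= 1e-10
        assert max(state.mass_action_residuals(params)) <= 1e-10


class TestExplicitLimit:
    def test_no_sgrna_limit_is_full_output(self, totals_mid):
        params = BindingParams(K1=0.3, K2=2.0, theta=3.0)
        totals = SpeciesTotals(Ctot=100, gtot=0, Dtot=10)
        assert explicit_output(params, totals) == pytest.approx(3.0 * 10)

    def test_saturating_sgrna_at_ctot_equal_k2_gives_half_output(self):
        params = BindingParams(K1=0.3, K2=2.0, theta=1.0)
        totals = SpeciesTotals(Ctot=2.0, gtot=1e12, Dtot=10)
        assert explicit_output(params, totals) == pytest.approx(5.0, rel=1e-6)

    def test_matches_implicit_solver_in_validity_regime(self, params):
        totals = SpeciesTotals(Ctot=100, gtot=1e4, Dtot=0.1)
        implicit = solve_equilibrium(params, totals).R
        explicit = explicit_output(params, totals)
        assert explicit == pytest.approx(implicit, rel=0.02)


class TestSweep:
    def test_endpoints_of_sgrna_sweep(self, params):
        fixed = SpeciesTotals(Ctot=100, gtot=0, Dtot=10)
        curve = sweep_transfer_curve(params, fixed, "gtot", np.array([0.0, 1e6]))
        assert curve.output_values[0] == pytest.approx(1.0)
        # saturating sgRNA: all dCas9 is in complex, so the floor is the
        # single-binding equilibrium of complex (Ctot) with DNA (Dtot):
        # CgD = smaller root of y^2 - (Ctot+Dtot+K2) y + Ctot*Dtot
        s = 100.0 + 10.0 + params.K2
        y = (s - math.sqrt(s * s - 4 * 100.0 * 10.0)) / 2
        assert curve.output_values[-1] == pytest.approx((10.0 - y) / 10.0, rel=1e-3)

    def test_fraction_bounded_and_monotone(self, params):
        fixed = SpeciesTotals(Ctot=100, gtot=0, Dtot=10)
        grid = np.geomspace(1e-2, 1e4, 40)
        curve = sweep_transfer_curve(params, fixed, "gtot", grid)
        assert np.all(curve.output_values >= 0)
        assert np.all(curve.output_values <= 1)
        assert np.all(np.diff(curve.output_values) <= 1e-9)

    def test_sgrna_dcas9_sweep_exchange_gives_same_curve(self, params):
        grid = np.geomspace(1e-2, 1e4, 25)
        by_g = sweep_transfer_curve(
            params, SpeciesTotals(Ctot=100, gtot=0, Dtot=10), "gtot", grid
        )
        by_c = sweep_transfer_curve(
            params, SpeciesTotals(Ctot=0, gtot=100, Dtot=10), "Ctot", grid
        )
        np.testing.assert_allclose(
            by_g.output_values, by_c.output_values, rtol=1e-6
        )

    def test_rejects_bad_grid(self, params):
        fixed = SpeciesTotals(100, 0, 10)
        with pytest.raises(ValueError):
            sweep_transfer_curve(params, fixed, "gtot", np.array([1.0]))
        with pytest.raises(ValueError):
            sweep_transfer_curve(params, fixed, "gtot", np.array([2.0, 1.0]))


class TestSwitchPoint:
    def test_exact_grid_hit(self):
        curve = TransferCurve("gtot", [1.0, 10.0, 100.0], "D_over_Dtot",
                              [1.0, 0.5, 0.0])
        sp = switch_point(curve, level=0.5)
        assert sp.found and sp.value == pytest.approx(10.0)

    def test_level_outside_output_range_reports_no_crossing(self):
        curve = TransferCurve("gtot", [1.0, 10.0], "D_over_Dtot", [0.9, 0.8])
        sp = switch_point(curve, level=0.5)
        assert not sp.found and sp.value is None

    def test_log_interpolation_between_grid_points(self):
        curve = TransferCurve("gtot", [1.0, 100.0], "D_over_Dtot", [1.0, 0.0])
        sp = switch_point(curve, level=0.5)
        assert sp.value == pytest.approx(10.0)  # geometric midpoint

    def test_switch_point_increases_with_dna_copy_number(self, params):
        # higher target DNA needs more repressor complex: the half-repression
        # point moves right
        grid = np.geomspace(1e-2, 1e4, 120)
        points = []
        for dtot in (1.0, 100.0):
            fixed = SpeciesTotals(Ctot=100.0, gtot=0.0, Dtot=dtot)
            curve = sweep_transfer_curve(
                params, fixed, "gtot", grid, solver=solve_equilibrium_oracle
            )
            points.append(switch_point(curve).value)
        assert points[0] < points[1]
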