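"""Trajectory model: program structure, solutions, derived maps, checks."""
import numpy as np
import pytest

from conftest import identity_model, lagged_sweep_rows, make_one_row_grid
from flatbeam.grid import FieldGrid, LeafRow
from flatbeam.model import LeafTrajectoryModel, Weights, build_model, solve
from flatbeam.results import (effective_time, tng_times, validate_solution)


class TestWeights:
    def test_published_default_ratios(self):
        w = Weights.from_ratios(1.0, 1000.0, 0.1)
        assert w.lambda2 == pytest.approx(1e-3)
        assert w.lambda3 == pytest.approx(10.0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            Weights(lambda1=0.0)
        with pytest.raises(ValueError):
            Weights(lambda2=-1.0)


class TestBuild:
    def test_square_10x10_dimensions(self, machine, grid_10x10):
        from flatbeam.beam import BeamModel
        from flatbeam.dose import build_dose_influence, reference_flat_dose
        from flatbeam.beam import flat_reference_beam
        infl = build_dose_influence(grid_10x10, BeamModel(mode="fff"),
                                    resolution=0.2)
        ref = reference_flat_dose(grid_10x10, flat_reference_beam(),
                                  resolution=0.2)
        model = build_model(grid_10x10, infl, ref, machine=machine)
        assert model.grid.n_rows == 20
        assert all(L["J"] + 1 == 51 for L in model._layout)
        # 4 crossing-time variables per bixel boundary beyond the parked
        # ones, plus the shared beam-off time
        assert model.n_variables == 20 * 4 * (50 - 3) + 1

    def test_lambda_zeroing_reduces_to_least_squares(self, machine):
        # with lambda2 = lambda3 = 0 the objective value equals the pure
        # least-squares dose misfit at any trajectory
        m = identity_model(machine, n_bixels=8, lambda2=0.0)
        assert m.n_aux == 0
        v = m.initial_point()
        qp_obj = 0.5 * v @ (m.P_sparse @ v) + m.q @ v
        DR = m.machine.dose_rate_mod_per_s
        F = (m.M @ v).reshape(1, -1) * DR
        ls = float(((F - m._target_plane) ** 2).sum() - (m._target_plane ** 2).sum())
        assert qp_obj == pytest.approx(ls, rel=1e-10)

    def test_tng_term_adds_epigraph_auxiliaries(self, machine):
        rows = [LeafRow(index=40, y_low=0.0, y_high=0.5, x_start=0.0, x_end=1.2),
                LeafRow(index=41, y_low=0.5, y_high=1.0, x_start=0.4, x_end=1.6)]
        grid = FieldGrid(rows, 0.2, machine)
        from conftest import IdentityInfluence
        from flatbeam.dose import DoseMap
        infl = IdentityInfluence(grid)
        ref = DoseMap(np.full(infl.plane_shape, 3.0 / 35.0), 0.2,
                      infl.x[0], infl.y[0])
        model = LeafTrajectoryModel(grid, infl, ref, machine=machine,
                                    weights=Weights(lambda3=10.0))
        assert model.n_aux > 0
        assert np.all(model.q[model.n_core + len(model._carr_u):] > 0)

    def test_carriage_pair_constraints_present_both_orderings(self, machine):
        rows = [
            LeafRow(index=40, y_low=0.0, y_high=0.5, x_start=-12.0, x_end=-2.0),
            LeafRow(index=41, y_low=0.5, y_high=1.0, x_start=9.0, x_end=14.0),
        ]
        grid = FieldGrid(rows, 0.2, machine)
        from conftest import IdentityInfluence
        from flatbeam.dose import DoseMap
        infl = IdentityInfluence(grid)
        ref = DoseMap(np.full(infl.plane_shape, 0.05), 0.2,
                      infl.x[0], infl.y[0])
        model = LeafTrajectoryModel(grid, infl, ref, machine=machine)
        assert len(model.carriage_flags) == 4  # both banks, both orderings
        assert not model._carriage_aggregated
        # find constraint rows coupling trailing-leaf variables of the two rows
        L0, L1 = model._layout
        lo0 = range(L0["off"] + L0["nro"] + L0["nri"],
                    L0["off"] + L0["nro"] + L0["nri"] + L0["nlo"])
        lo1 = range(L1["off"] + L1["nro"] + L1["nri"],
                    L1["off"] + L1["nro"] + L1["nri"] + L1["nlo"])
        A = model.A.tocsr()
        cross = []
        for r in range(A.shape[0]):
            cols = set(A.indices[A.indptr[r]:A.indptr[r + 1]])
            if cols & set(lo0) and cols & set(lo1):
                cross.append(r)
        assert cross, "no carriage coupling constraints generated"

    def test_gap_index_must_be_integral(self, machine):
        grid = make_one_row_grid(machine, n_bixels=4, bixel=0.2)
        bad = machine.replace(min_gap=0.5)
        from conftest import IdentityInfluence
        from flatbeam.dose import DoseMap
        infl = IdentityInfluence(grid)
        ref = DoseMap(np.full(infl.plane_shape, 0.1), 0.2, infl.x[0], infl.y[0])
        with pytest.raises(ValueError, match="integer multiple"):
            LeafTrajectoryModel(grid, infl, ref, machine=bad)


class TestSolveTiny:
    def test_flat_target_gives_equal_interior_times(self, machine):
        # interior bixels reach the flat target exactly and equally; the
        # G bixels at each edge are exposed while the window opens or
        # closes, where the leaf speed limit forces exposure steps of
        # bixel_width / v_max per bixel (a structural staircase)
        model = identity_model(machine, n_bixels=8, target_mu=3.0)
        res = solve(model)
        t = res.fluence().t[0]
        G = model.gap_index
        DR = machine.dose_rate_mod_per_s
        interior = t[G:-G]
        assert np.ptp(interior) < 1e-4
        assert interior.mean() * DR == pytest.approx(3.0, rel=1e-3)
        dt_min = 0.2 / machine.v_max
        np.testing.assert_allclose(np.diff(t[:G]), dt_min, rtol=1e-2)
        np.testing.assert_allclose(np.diff(t[-G:]), -dt_min, rtol=1e-2)

    def test_deterministic_objective(self, machine):
        model = identity_model(machine)
        o1 = model.fit().qp.objective
        o2 = model.fit().qp.objective
        assert o1 == pytest.approx(o2, rel=1e-6)

    def test_scale_covariance_of_interior_times(self, machine):
        # in the window interior the target is exactly reachable, so the
        # optimal exposure scales linearly with the desired dose (the
        # opening/closing staircase has a fixed kinematic step and is
        # exempt from covariance)
        m1 = identity_model(machine, n_bixels=8, target_mu=3.0, lambda2=0.0)
        m2 = identity_model(machine, n_bixels=8, target_mu=6.0, lambda2=0.0)
        G = m1.gap_index
        t1 = m1.fit().fluence().t[0][G:-G]
        t2 = m2.fit().fluence().t[0][G:-G]
        np.testing.assert_allclose(t2, 2.0 * t1, rtol=1e-4)

    def test_fff_compensation_increases_offaxis_times(self, solved_6x6):
        # the fluence compensates the forward-peaked beam: x * off_axis
        # is nearly constant in-field, so exposure grows off axis (the
        # kernel leaves high-frequency wiggle weakly determined, hence
        # the comparison of region means rather than per-bixel slopes)
        from flatbeam.beam import fff_off_axis
        model, res = solved_6x6
        fl = res.fluence()
        i = model.grid.n_rows // 2
        row = fl.t[i]
        n = len(row)
        center = row[n // 2 - 2:n // 2 + 2].mean()
        edge = row[n - 7:n - 3].mean()
        assert edge > center
        y = model.grid.rows[i].y_center
        x_edge = (model.col0 + 0.5 + (n - 5)) * 0.2
        expected = fff_off_axis(np.hypot(0.1, y)) / fff_off_axis(
            np.hypot(x_edge, y))
        assert edge / center == pytest.approx(expected, rel=0.1)

    def test_mirror_symmetric_fluence(self, solved_6x6):
        model, res = solved_6x6
        x = res.fluence().x
        assert np.abs(x - x[:, ::-1]).max() < 2e-3 * x.max()
        assert np.abs(x - x[::-1, :]).max() < 2e-3 * x.max()

    def test_optimum_validates_at_spec_tolerances(self, solved_6x6):
        _, res = solved_6x6
        rep = res.validate(tol_time=1e-5, tol_space=1e-4)
        assert rep.passed, rep.summary()


class TestEffectiveTime:
    def test_closed_aperture_zero_time(self, machine):
        grid = make_one_row_grid(machine, n_bixels=6)
        sol = lagged_sweep_rows(grid, machine, lag=2.0)
        for row in sol.rows:
            row.l_in[:] = row.r_in[:]
            row.l_out[:] = row.r_out[:]
            row.l_in[0] = 0.0
        t = effective_time(sol).t
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_direct_substitution_example(self, machine):
        # l_out[j]=5, r_out[j]=2, l_in[j+1]=6, r_in[j+1]=3 -> t = 3 s
        grid = make_one_row_grid(machine, n_bixels=4)
        sol = lagged_sweep_rows(grid, machine)
        row = sol.rows[0]
        j = 1
        row.l_out[j], row.r_out[j] = 5.0, 2.0
        row.l_in[j + 1], row.r_in[j + 1] = 6.0, 3.0
        t = effective_time(sol).t
        assert t[0, j] == pytest.approx(0.5 * ((5 - 2) + (6 - 3)))

    def test_constant_velocity_lag_gives_uniform_time(self, machine):
        grid = make_one_row_grid(machine, n_bixels=10)
        sol = lagged_sweep_rows(grid, machine, rate=0.4, lag=2.5)
        t = effective_time(sol).t[0]
        G = int(round(machine.min_gap / grid.bixel_width))
        # exposure = time between the two tips crossing a bixel, i.e. the
        # trailing lag plus the G-bixel positional offset at fixed speed
        np.testing.assert_allclose(t[G:-G], 2.5 + G * 0.4, atol=1e-9)


class TestTnGTimes:
    def _two_row_grid(self, machine, n_bixels=8):
        rows = [LeafRow(index=40, y_low=0.0, y_high=0.5, x_start=0.0,
                        x_end=n_bixels * 0.2),
                LeafRow(index=41, y_low=0.5, y_high=1.0, x_start=0.0,
                        x_end=n_bixels * 0.2)]
        return FieldGrid(rows, 0.2, machine)

    def test_synchronized_rows_have_zero_tng(self, machine):
        grid = self._two_row_grid(machine)
        sol = lagged_sweep_rows(grid, machine)
        m = tng_times(sol)
        np.testing.assert_allclose(m.t_ltg, 0.0, atol=1e-12)
        np.testing.assert_allclose(m.t_rtg, 0.0, atol=1e-12)

    def test_uniform_lag_appears_as_strip_time(self, machine):
        grid = self._two_row_grid(machine, n_bixels=10)
        sol = lagged_sweep_rows(grid, machine, rate=0.4, lag=2.0,
                                row_lags=[0.0, 2.0])
        m = tng_times(sol)
        G = int(round(machine.min_gap / grid.bixel_width))
        # interior bixels: row 1 lags row 0 by 2 s on both banks
        np.testing.assert_allclose(m.t_ltg[0, G:-G], 2.0, atol=1e-9)
        np.testing.assert_allclose(m.t_rtg[0, G:-G], 2.0, atol=1e-9)

    def test_single_row_yields_empty_map(self, machine):
        grid = make_one_row_grid(machine, n_bixels=6)
        sol = lagged_sweep_rows(grid, machine)
        m = tng_times(sol)
        assert m.t_ltg.shape[0] == 0

    def test_penalty_reduces_tng_sum(self, machine):
        # two rows with offset intervals; identity dose, so the optimizer
        # is free to synchronize timings when told to
        rows = [LeafRow(index=40, y_low=0.0, y_high=0.5, x_start=0.0, x_end=1.6),
                LeafRow(index=41, y_low=0.5, y_high=1.0, x_start=0.6, x_end=2.2)]
        grid = FieldGrid(rows, 0.2, machine)
        from conftest import IdentityInfluence
        from flatbeam.dose import DoseMap
        infl = IdentityInfluence(grid)
        rng = np.random.default_rng(0)
        target = 3.0 + rng.random(infl.plane_shape)
        target *= infl.mask
        ref = DoseMap(target / 35.0, 0.2, infl.x[0], infl.y[0])
        sums = {}
        for l3 in (0.0, 10.0):
            model = LeafTrajectoryModel(grid, infl, ref, machine=machine,
                                        weights=Weights(lambda3=l3))
            sums[l3] = model.fit().tng().total
        assert sums[10.0] < sums[0.0]


class TestValidate:
    def test_hand_built_gap_violation_detected(self, machine):
        grid = make_one_row_grid(machine, n_bixels=10)
        sol = lagged_sweep_rows(grid, machine, rate=0.4, lag=0.0)
        row = sol.rows[0]
        # base sweep holds the gap at exactly 0.6 cm; pulling the trailing
        # leaf half a bixel ahead of schedule dips it to 0.5 cm
        j = 4
        mid = 0.5 * (row.l_out[j] + row.l_in[j + 1])
        row.l_in[j + 1] = mid - 1e-9
        rep = validate_solution(sol, machine, grid)
        assert not rep["min_gap"].passed
        assert rep["min_gap"].worst_slack == pytest.approx(-0.1, abs=0.01)

    def test_hand_built_speed_violation_detected(self, machine):
        grid = make_one_row_grid(machine, n_bixels=10)
        sol = lagged_sweep_rows(grid, machine, rate=0.4, lag=2.0)
        row = sol.rows[0]
        # traverse one 0.2 cm bixel in 0.02 s = 10 cm/s > 6 cm/s
        row.r_in[5] = row.r_out[4] + 0.02
        row.r_out[5] = row.r_in[5]
        rep = validate_solution(sol, machine, grid)
        assert not rep["speed"].passed

    def test_feasible_sweep_passes(self, machine):
        grid = make_one_row_grid(machine, n_bixels=10)
        sol = lagged_sweep_rows(grid, machine, rate=0.4, lag=2.0)
        rep = validate_solution(sol, machine, grid)
        assert rep.passed, rep.summary()


class TestResultsApi:
    def test_summary_contains_key_sections(self, solved_6x6):
        _, res = solved_6x6
        s = res.summary()
        assert "beam-on time" in s
        assert "min_gap" in s
        assert "optimal" in s

    def test_objective_breakdown_consistent(self, solved_6x6):
        _, res = solved_6x6
        terms = res.objective_breakdown()
        assert terms["total"] == pytest.approx(
            terms["dose"] + terms["time"] + terms["tng"])
        assert terms["dose"] >= 0 and terms["time"] >= 0
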