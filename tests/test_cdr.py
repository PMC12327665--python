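"""Tumor transport model: pore-model source, conservation, limits."""

import numpy as np
import pytest

from rptsim.angiogenesis import LatticeGrid
from rptsim.cdr import (CDRParameters, field_time_integrals, run_transport,
                        transvascular_source, well_mixed_reference)


@pytest.fixture(scope="module")
def tiny_grid():
    # 5 mm domain at 0.5 mm spacing; ~21-cell tumor
    return LatticeGrid(nx=11, ny=11, h=5e-4, tumor_radius=1.2e-3, margin=0.0)


def flat_cv(value_l=1.0, value_u=0.0, t_end=30000.0):
    t = np.array([0.0, t_end])
    return (t, np.full(2, value_l), np.full(2, value_u))


class TestTransvascularSource:
    def test_pure_diffusive_limit_at_zero_filtration(self):
        p = CDRParameters()
        sv = 1000.0
        phi = transvascular_source(2.0, 0.5, 0.0, sv, p)
        assert phi == pytest.approx(p.P * sv * 1.5, rel=1e-12)

    def test_equal_concentrations_no_filtration_gives_zero(self):
        phi = transvascular_source(1.0, 1.0, 0.0, 500.0, CDRParameters())
        assert phi == pytest.approx(0.0, abs=1e-15)

    def test_unit_peclet_diffusive_fraction(self):
        # Pe = 1 with unit P*S/V: diffusive part = (Cv - Cint)/(e - 1)
        p = CDRParameters()
        sv = 1.0 / p.P  # makes P*SV = 1 per min
        psi_b = (1.0) / (1.0 - p.sigma_f)  # makes Pe = 1
        phi = transvascular_source(1.0, 0.0, psi_b, sv, p)
        conv = psi_b * (1 - p.sigma_f) * 1.0
        assert phi - conv == pytest.approx(1.0 / (np.e - 1.0), rel=1e-12)

    def test_zero_wall_area_pure_convection(self):
        p = CDRParameters()
        phi = transvascular_source(3.0, 1.0, 0.6, 0.0, p)
        assert phi == pytest.approx(0.6 * (1 - p.sigma_f) * 3.0, rel=1e-12)

    def test_negative_sv_rejected(self):
        with pytest.raises(ValueError):
            transvascular_source(1.0, 0.0, 0.0, -1.0, CDRParameters())


class TestStepConservation:
    def test_closed_cells_conserve_total_moles(self, tiny_grid):
        # no wall exchange, convection, decay or degradation: interstitial +
        # bound + internalized is invariant over 1000 steps
        p = CDRParameters(P_cm_s=0.0, lambda_phy=0.0, lambda_deg=0.0, R=5.0)
        tf = run_transport(None, flat_cv(0.0, 0.0, 1000.0), p, grid=tiny_grid,
                           sv=0.0, t_end=1000.0, dt=1.0, record_every=100,
                           initial={"C_int_l": 1.0, "C_bound_l": 0.25})
        tot = (tf.mean_series["C_int_l"] + tf.mean_series["C_bound_l"]
               + tf.mean_series["C_intern_l"])
        assert np.abs(tot - tot[0]).max() < 1e-8

    def test_decay_transmutes_between_species_conservatively(self, tiny_grid):
        p = CDRParameters(P_cm_s=0.0, lambda_deg=0.0, R=5.0)
        tf = run_transport(None, flat_cv(0.0, 0.0, 2000.0), p, grid=tiny_grid,
                           sv=0.0, t_end=2000.0, dt=1.0, record_every=100,
                           initial={"C_int_l": 1.0})
        tot = sum(tf.mean_series[k] for k in tf.FIELDS)
        assert np.abs(tot - tot[0]).max() < 1e-8
        assert tf.mean_series["C_int_u"][-1] > 0

    def test_fields_stay_nonnegative(self, tiny_grid):
        p = CDRParameters(R=2.0)
        tf = run_transport(None, flat_cv(1.0, 0.5, 3000.0), p, grid=tiny_grid,
                           sv=2000.0, t_end=3000.0, dt=1.0, record_every=50)
        for name in tf.FIELDS:
            assert min(tf.mean_series[name].min(), 0.0) == 0.0

    def test_receptor_cap_respected(self, tiny_grid):
        p = CDRParameters(R=1.0)
        tf = run_transport(None, flat_cv(5.0, 5.0, 2000.0), p, grid=tiny_grid,
                           sv=3000.0, t_end=2000.0, dt=1.0,
                           snapshot_times=(2000.0,))
        cb = tf.snapshots["C_bound_l"][-1] + tf.snapshots["C_bound_u"][-1]
        assert cb.max() <= p.R * (1 + 1e-6)


class TestEquilibriaAndLimits:
    def test_binding_equilibrium_matches_fixed_point(self, tiny_grid):
        # constant vascular feed, no decay: at steady state the bound pool
        # satisfies C_bound = k_on (R - C_bound) C_int / (k_off + k_int)
        p = CDRParameters(lambda_phy=0.0, lambda_deg=1e-3, R=3.0)
        tf = run_transport(None, flat_cv(1.0, 0.0, 60000.0), p, grid=tiny_grid,
                           sv=2000.0, t_end=60000.0, dt=2.0, record_every=500)
        ci = tf.mean_series["C_int_l"][-1]
        cb = tf.mean_series["C_bound_l"][-1]
        want = p.k_on * (p.R - cb) * ci / (p.k_off + p.k_int)
        assert cb == pytest.approx(want, rel=1e-4)

    def test_relaxation_toward_vascular_concentration(self, tiny_grid):
        # pure wall exchange: C_int -> C_v monotonically
        p = CDRParameters(R=0.0, k_on=1e-12, lambda_phy=0.0)
        tf = run_transport(None, flat_cv(1.0, 0.0, 5000.0), p, grid=tiny_grid,
                           sv=2000.0, t_end=5000.0, dt=1.0, record_every=20)
        ci = tf.mean_series["C_int_l"]
        assert np.all(np.diff(ci) >= -1e-12)
        assert ci[-1] == pytest.approx(1.0, rel=1e-3)

    def test_zero_vascular_input_keeps_fields_zero(self, tiny_grid):
        p = CDRParameters()
        tf = run_transport(None, flat_cv(0.0, 0.0, 500.0), p, grid=tiny_grid,
                           sv=2000.0, t_end=500.0, dt=1.0)
        assert all(tf.mean_series[k].max() == 0.0 for k in tf.FIELDS)

    def test_homogeneous_limit_matches_single_compartment_ode(self):
        # uniform vasculature, no convection: spatial mean of the PDE equals
        # the well-mixed ODE within 0.5% on time-integrated amounts
        grid = LatticeGrid(nx=21, ny=21, h=1e-3, tumor_radius=8e-3, margin=1e-3)
        p = CDRParameters(R=1.5)
        t = np.linspace(0.0, 3000.0, 301)
        cv = (t, 1.0 * np.exp(-t / 800.0), 0.5 * (1 - np.exp(-t / 2000.0)))
        tf = run_transport(None, cv, p, grid=grid, sv=2000.0, psi_b=0.0,
                           t_end=3000.0, dt=0.25, record_every=4)
        tt, ref = well_mixed_reference(p, cv, sv=2000.0, t_end=3000.0)
        for name in ("C_int_l", "C_bound_l", "C_intern_l"):
            pde = np.trapezoid(tf.mean_series[name], tf.series_t)
            ode = np.trapezoid(ref[name], tt)
            assert pde == pytest.approx(ode, rel=5e-3), name

    def test_time_step_refinement_converges_below_one_percent(self, tiny_grid):
        p = CDRParameters(R=1.5)
        t = np.linspace(0, 2000.0, 201)
        cv = (t, np.exp(-t / 500.0), np.zeros_like(t))
        res = []
        for dt in (1.0, 0.5):
            tf = run_transport(None, cv, p, grid=tiny_grid, sv=1500.0,
                               t_end=2000.0, dt=dt, record_every=int(1 / dt))
            res.append(np.trapezoid(tf.mean_series["C_int_l"], tf.series_t))
        assert abs(res[1] - res[0]) / res[1] < 0.01

    def test_outward_convection_reduces_interstitial_retention(self, small_pressure, patients):
        # the IFP-driven velocity field expels peptide: total time-integrated
        # interstitial labeled amount is lower than in the no-convection run
        p = patients["P1"]
        cp = CDRParameters(R=p.meta["rd_tum"], lambda_deg=p.meta["rel_tum"])
        t = np.linspace(0.0, 4000.0, 401)
        cv = (t, np.exp(-t / 1000.0), np.zeros_like(t))
        with_v = run_transport(small_pressure, cv, cp, t_end=4000.0, dt=1.0,
                               record_every=10)
        no_v = run_transport(small_pressure, cv, cp, t_end=4000.0, dt=1.0,
                             record_every=10, v=np.zeros(
                                 (2, small_pressure.grid.ny, small_pressure.grid.nx)))
        vol = 7e-4
        i_with = field_time_integrals(with_v, vol)["C_int_l"]
        i_no = field_time_integrals(no_v, vol)["C_int_l"]
        assert i_with < i_no


class TestIntegrals:
    def test_constant_field_integral(self, tiny_grid):
        p = CDRParameters(P_cm_s=0.0, lambda_phy=0.0, lambda_deg=0.0,
                          k_on=1e-12, R=0.0)
        tf = run_transport(None, flat_cv(0, 0, 100.0), p, grid=tiny_grid,
                           sv=0.0, t_end=100.0, dt=1.0,
                           initial={"C_int_l": 2.0})
        out = field_time_integrals(tf, 0.5)
        assert out["C_int_l"] == pytest.approx(2.0 * 0.5 * 100.0, rel=1e-6)

    def test_exponential_decay_integral_analytic(self, tiny_grid):
        lam = 5e-3
        p = CDRParameters(P_cm_s=0.0, lambda_phy=lam, lambda_deg=0.0,
                          k_on=1e-12, R=0.0)
        T = 2000.0
        tf = run_transport(None, flat_cv(0, 0, T), p, grid=tiny_grid, sv=0.0,
                           t_end=T, dt=1.0, initial={"C_int_l": 1.0})
        got = field_time_integrals(tf, 1.0)["C_int_l"]
        want = (1.0 - np.exp(-lam * T)) / lam
        assert got == pytest.approx(want, rel=3e-3)

    def test_integral_additive_over_subintervals(self, tiny_grid):
        p = CDRParameters(R=1.0)
        cv = flat_cv(1.0, 0.0, 1000.0)
        tf = run_transport(None, cv, p, grid=tiny_grid, sv=1000.0,
                           t_end=1000.0, dt=1.0)
        t, y = tf.series_t, tf.mean_series["C_int_l"]
        k = len(t) // 2
        whole = np.trapezoid(y, t)
        parts = np.trapezoid(y[:k + 1], t[:k + 1]) + np.trapezoid(y[k:], t[k:])
        assert whole == pytest.approx(parts, rel=1e-12)
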