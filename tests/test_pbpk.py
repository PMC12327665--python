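"""Whole-body PBPK model: oracle equivalence, conservation laws, kinetics."""

import numpy as np
import pytest

from rptsim.organs import OrganSpec, PatientParameters, default_patient
from rptsim.pbpk import (PBPKModel, default_time_grid, simulate,
                         tumor_vascular_input)
from rptsim.units import LAMBDA_PHY_LU177


def toy_patient() -> PatientParameters:
    """Five-organ body small enough to hand-code: lungs, liver, GI (drains to
    liver), PSMA-positive kidneys and tumor."""
    organs = {
        "lungs": OrganSpec("lungs", kind="lung", V_v=0.4, V_int=0.3, F=2.0, PS=0.2),
        "liver": OrganSpec("liver", kind="liver", V_v=0.2, V_int=0.3, F=0.5, PS=0.05),
        "gi": OrganSpec("gi", kind="gi", V_v=0.1, V_int=0.2, F=0.9, PS=0.09,
                        drains_to_liver=True),
        "kidneys": OrganSpec("kidneys", kind="kidney", psma_positive=True,
                             V_v=0.03, V_int=0.05, V_intra=0.15, F=0.6, PS=0.0,
                             R0=5.0, lambda_int=0.002, lambda_release=3e-4),
        "tumor": OrganSpec("tumor", kind="tumor", psma_positive=True,
                           V_v=1.4e-4, V_int=7e-4, F=4e-4, PS=2e-4,
                           R0=3.0, lambda_int=0.001, lambda_release=4e-4),
    }
    organs["lungs"].F = sum(o.F for o in organs.values() if o.kind != "lung")
    return PatientParameters(organs=organs, V_ART=1.0, V_VEN=2.5, V_p=3.0,
                             k_pr=0.01, F_fil=0.2, fex=0.8, name="toy")


def toy_rhs(p: PatientParameters, model: PBPKModel, y: np.ndarray) -> np.ndarray:
    """Hand-written derivative of the toy body, compartment by compartment."""
    lam = p.lambda_phy
    F_ex = p.fex * p.F_fil
    out = np.zeros_like(y)
    idx = model.index

    def a(species, comp):
        return y[idx[(species, comp)]]

    for sp_i, (species, sgn) in enumerate((("labeled", -1.0), ("unlabeled", +1.0))):
        o = p.organs

        def c(comp, vol):
            return a(species, comp) / vol

        C_art = c("ART", p.V_ART)
        C_ven = c("VEN", p.V_VEN)
        d = {}
        # arterial: outflow to all tissues but the lungs; inflow from lungs
        tissue_F = sum(oo.F for oo in o.values() if oo.kind != "lung")
        d["ART"] = -tissue_F * C_art + o["lungs"].F * c("lungs.v", o["lungs"].V_v)
        # venous: inflow from kidneys + liver (carrying GI); outflow to lungs
        d["VEN"] = (o["kidneys"].F * c("kidneys.v", o["kidneys"].V_v)
                    + (o["liver"].F + o["gi"].F) * c("liver.v", o["liver"].V_v)
                    + o["tumor"].F * c("tumor.v", o["tumor"].V_v)
                    - o["lungs"].F * C_ven - p.k_pr * a(species, "VEN"))
        d["PRP"] = p.k_pr * a(species, "VEN")
        # lungs: venous inflow
        d["lungs.v"] = (o["lungs"].PS * (c("lungs.int", o["lungs"].V_int)
                                         - c("lungs.v", o["lungs"].V_v))
                        + o["lungs"].F * (C_ven - c("lungs.v", o["lungs"].V_v)))
        d["lungs.int"] = o["lungs"].PS * (c("lungs.v", o["lungs"].V_v)
                                          - c("lungs.int", o["lungs"].V_int))
        # GI: arterial inflow, outflow to liver
        d["gi.v"] = (o["gi"].PS * (c("gi.int", o["gi"].V_int) - c("gi.v", o["gi"].V_v))
                     + o["gi"].F * C_art - o["gi"].F * c("gi.v", o["gi"].V_v))
        d["gi.int"] = o["gi"].PS * (c("gi.v", o["gi"].V_v) - c("gi.int", o["gi"].V_int))
        # liver: arterial + splanchnic inflow
        d["liver.v"] = (o["liver"].PS * (c("liver.int", o["liver"].V_int)
                                         - c("liver.v", o["liver"].V_v))
                        + o["liver"].F * C_art + o["gi"].F * c("gi.v", o["gi"].V_v)
                        - (o["liver"].F + o["gi"].F) * c("liver.v", o["liver"].V_v))
        d["liver.int"] = o["liver"].PS * (c("liver.v", o["liver"].V_v)
                                          - c("liver.int", o["liver"].V_int))
        # kidneys: filtration; unspecific intracellular loop with catabolism
        d["kidneys.v"] = (o["kidneys"].F * C_art
                          - (o["kidneys"].F + p.F_fil) * c("kidneys.v", o["kidneys"].V_v)
                          + (p.F_fil - F_ex) * c("kidneys.intra", o["kidneys"].V_intra))
        d["kidneys.intra"] = ((p.F_fil - F_ex) * (c("kidneys.int", o["kidneys"].V_int)
                                                  - c("kidneys.intra", o["kidneys"].V_intra))
                              - o["kidneys"].lambda_release * a(species, "kidneys.intra"))
        # tumor: generic vascular exchange
        d["tumor.v"] = (o["tumor"].PS * (c("tumor.int", o["tumor"].V_int)
                                         - c("tumor.v", o["tumor"].V_v))
                        + o["tumor"].F * (C_art - c("tumor.v", o["tumor"].V_v)))
        # receptor kinetics (free receptors shared between species)
        for organ in ("kidneys", "tumor"):
            oo = o[organ]
            r_free = max(oo.R0 * oo.V_int
                         - y[idx[("labeled", f"{organ}.bound")]]
                         - y[idx[("unlabeled", f"{organ}.bound")]], 0.0)
            bind = p.k_on * a(species, f"{organ}.int") * r_free / oo.V_int
            unbind = p.k_off * a(species, f"{organ}.bound")
            base = (p.F_fil * (c("kidneys.v", oo.V_v) - c("kidneys.int", oo.V_int))
                    if organ == "kidneys" else
                    oo.PS * (c(f"{organ}.v", oo.V_v) - c(f"{organ}.int", oo.V_int)))
            d[f"{organ}.int"] = base - bind + unbind
            d[f"{organ}.bound"] = bind - (p.k_off + oo.lambda_int) * a(species, f"{organ}.bound")
            d[f"{organ}.intern"] = (oo.lambda_int * a(species, f"{organ}.bound")
                                    - oo.lambda_release * a(species, f"{organ}.intern"))
        for comp, val in d.items():
            lab = y[idx[("labeled", comp)]]
            out[idx[(species, comp)]] = val + sgn * lam * lab
    return out


class TestBuildModel:
    def test_generic_rhs_matches_hand_coded_toy_oracle(self, rng):
        p = toy_patient()
        model = PBPKModel(p, validate=False)
        for _ in range(10):
            y = rng.uniform(0.0, 5.0, model.nstate)
            np.testing.assert_allclose(model.rhs(0.0, y), toy_rhs(p, model, y),
                                       rtol=1e-12, atol=1e-12)

    def test_brain_interstitial_is_decay_coupling_only(self, patient):
        model = PBPKModel(patient)
        y = np.random.default_rng(0).uniform(0, 1, model.nstate)
        dy = model.rhs(0.0, y)
        lam = patient.lambda_phy
        il = model.index[("labeled", "brain.int")]
        iu = model.index[("unlabeled", "brain.int")]
        assert dy[il] == pytest.approx(-lam * y[il], rel=1e-12)
        assert dy[iu] == pytest.approx(+lam * y[il], rel=1e-12)

    def test_missing_required_organ_raises(self, patient):
        q = patient.copy()
        del q.organs["kidneys"]
        with pytest.raises(Exception, match="kidney"):
            PBPKModel(q)

    def test_negative_parameter_rejected(self, patient):
        q = patient.copy()
        q.organ("liver").F = -1.0
        with pytest.raises(ValueError):
            PBPKModel(q)


class TestConservation:
    def _closed(self, patient):
        q = patient.copy()
        q.fex = 0.0
        for o in q.organs.values():
            o.lambda_release = 0.0
        return q

    def test_closed_system_mass_conserved(self, patient):
        # all-unlabeled injection: decay acts on an empty labeled pool, so
        # the only candidate losses are urinary/degradation, both disabled
        q = self._closed(patient)
        traj = simulate(PBPKModel(q), 0.0, default_time_grid(30000.0, 301))
        tot = traj.total_moles("labeled") + traj.total_moles("unlabeled")
        assert np.abs(tot - tot[0]).max() / tot[0] < 1e-6

    def test_label_decay_conserves_total_moles(self, patient):
        # physical decay only transmutes labeled into unlabeled peptide
        q = self._closed(patient)
        traj = simulate(PBPKModel(q), 7400.0, default_time_grid(30000.0, 301))
        tot = traj.total_moles("labeled") + traj.total_moles("unlabeled")
        assert np.abs(tot - tot[0]).max() / tot[0] < 1e-6
        # and the labeled pool alone does decay
        assert traj.total_moles("labeled")[-1] < 0.2 * traj.total_moles("labeled")[0]

    def test_receptor_pools_never_exceed_capacity(self, patient):
        traj = simulate(PBPKModel(patient), 7400.0, default_time_grid(30000.0, 501))
        for o in patient.organs.values():
            if not o.psma_positive:
                continue
            cap = o.R0 * o.V_int
            occ = (traj.amount("labeled", f"{o.name}.bound")
                   + traj.amount("unlabeled", f"{o.name}.bound"))
            assert occ.max() <= cap * (1 + 1e-6)

    def test_all_concentrations_nonnegative_over_full_run(self, patient):
        traj = simulate(PBPKModel(patient), 7400.0, default_time_grid(30000.0, 501))
        assert traj.states.min() > -1e-9


class TestSimulate:
    def decay_only_patient(self):
        p = default_patient()
        for o in p.organs.values():
            o.F = 0.0
            o.PS = 0.0
        p.k_pr = 0.0
        p.F_fil = 1e-30
        return p

    def test_decay_only_venous_kinetics_analytic(self):
        p = self.decay_only_patient()
        model = PBPKModel(p, validate=False)
        t = np.linspace(0.0, 30000.0, 61)
        traj = simulate(model, 7400.0, t)
        lam = p.lambda_phy
        c0 = traj.concentration("labeled", "VEN")[0]
        np.testing.assert_allclose(traj.concentration("labeled", "VEN"),
                                   c0 * np.exp(-lam * t), rtol=1e-6)
        u0 = traj.concentration("unlabeled", "VEN")[0]
        np.testing.assert_allclose(
            traj.concentration("unlabeled", "VEN") - u0,
            c0 * (1.0 - np.exp(-lam * t)), rtol=1e-6, atol=1e-9)

    def test_labeled_half_life_is_9694_min(self):
        # ln 2 / 7.15e-5 per min
        assert np.log(2) / LAMBDA_PHY_LU177 == pytest.approx(9694, rel=1e-3)
        p = self.decay_only_patient()
        traj = simulate(PBPKModel(p, validate=False), 7400.0,
                        np.array([0.0, 9694.0]))
        ratio = (traj.concentration("labeled", "VEN")[1]
                 / traj.concentration("labeled", "VEN")[0])
        assert ratio == pytest.approx(0.5, rel=1e-4)

    def test_dose_linearity_in_non_saturating_limit(self, patient):
        q = patient.copy()
        for o in q.organs.values():
            if o.psma_positive:
                o.R0 *= 1e6
        t = default_time_grid(30000.0, 301)
        tr1 = simulate(PBPKModel(q), 3700.0, t)
        tr2 = simulate(PBPKModel(q), 7400.0, t)
        for organ in q.organs:
            a1 = np.trapezoid(tr1.organ_activity_mbq(organ), t)
            a2 = np.trapezoid(tr2.organ_activity_mbq(organ), t)
            assert a2 / a1 == pytest.approx(2.0, rel=1e-3)

    def test_bad_time_grid_rejected(self, patient):
        with pytest.raises(ValueError):
            simulate(PBPKModel(patient), 100.0, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            simulate(PBPKModel(patient), 100.0, np.array([0.0, 2.0, 2.0]))


class TestTumorVascularInput:
    def test_zero_injection_gives_zero_labeled_series(self, patient):
        traj = simulate(PBPKModel(patient), 0.0, default_time_grid(1000.0, 51))
        _, cl, _ = tumor_vascular_input(traj)
        np.testing.assert_array_equal(cl, 0.0)

    def test_series_nonnegative_and_on_grid(self, patient):
        t_grid = default_time_grid(5000.0, 101)
        traj = simulate(PBPKModel(patient), 7400.0, t_grid)
        t, cl, cu = tumor_vascular_input(traj)
        assert t is traj.t and len(cl) == len(t_grid)
        assert cl.min() >= 0 and cu.min() >= 0

    def test_extraction_commutes_with_time_slicing(self, patient):
        t_grid = default_time_grid(5000.0, 101)
        traj = simulate(PBPKModel(patient), 7400.0, t_grid)
        _, cl, _ = tumor_vascular_input(traj)
        k = 37
        assert cl[k] == traj.concentration("labeled", "tumor.v")[k]
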