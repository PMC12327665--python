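"""Whole-body PBPK model of labeled/unlabeled peptide kinetics.

Two parallel species (radiolabeled and unlabeled peptide) move through
arterial and venous blood, a serum-protein pool and 17 tissue compartments.
Physical decay transmutes labeled into unlabeled peptide everywhere with
matched +/- lambda_phy terms, so label decay conserves total peptide moles.
The only true eliminations are urinary excretion (fraction fex of the renal
filtration flow) and intracellular degradation (lambda_release).

State variables are amounts in nmol; the flow topology is:

* arteries -> every tissue except the lungs (flow F_i);
* tissue vascular space <-> interstitium via the permeability-surface
  product PS_i (brain PS = 0; the kidney exchanges via filtration instead);
* GI and spleen venous outflow is routed through the liver;
* veins -> lungs -> arteries closes the loop; serum-protein binding drains
  the venous pool only;
* PSMA-positive organs bind free interstitial peptide to a shared, finite
  receptor pool (R0), internalize it (lambda_int) and degrade it
  (lambda_release); labeled and unlabeled peptide compete for receptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .organs import PatientParameters

__all__ = ["PBPKModel", "OrganTrajectories", "simulate", "tumor_vascular_input",
           "default_time_grid"]


class PBPKConfigError(ValueError):
    pass


class IntegrationError(RuntimeError):
    pass


def default_time_grid(t_end: float = 30000.0, n: int = 1501) -> np.ndarray:
    """Output grid in minutes, geometric-ish refinement near t=0 where the
    bolus kinetics are fast."""
    dense = np.geomspace(1e-2, t_end, n - 1)
    return np.concatenate(([0.0], dense))


@dataclass
class OrganTrajectories:
    """Time-resolved PBPK solution.

    ``states`` has shape (nt, nstate); ``index`` maps (species, compartment)
    to a column, with species in {"labeled", "unlabeled"} and compartments
    named "ART", "VEN", "PRP", "<organ>.v", "<organ>.int", "<organ>.bound",
    "<organ>.intern", "kidneys.intra".  Amounts are nmol.
    """

    t: np.ndarray
    states: np.ndarray
    index: dict[tuple[str, str], int]
    patient: PatientParameters
    A0: float  # injected activity (MBq)

    def amount(self, species: str, compartment: str) -> np.ndarray:
        try:
            return self.states[:, self.index[(species, compartment)]]
        except KeyError:
            raise KeyError(f"no compartment {compartment!r} for species {species!r}") from None

    def concentration(self, species: str, compartment: str) -> np.ndarray:
        """Concentration in nmol/L over the compartment's own volume."""
        return self.amount(species, compartment) / self._volume(compartment)

    def _volume(self, compartment: str) -> float:
        p = self.patient
        if compartment == "ART":
            return p.V_ART
        if compartment == "VEN":
            return p.V_VEN
        if compartment == "PRP":
            return p.V_p
        organ, _, sub = compartment.partition(".")
        o = p.organ(organ)
        if sub == "v":
            return o.V_v
        if sub in ("int", "bound"):
            return o.V_int
        if sub == "intern":
            return o.V_int  # internalized pool referenced to interstitial volume
        if sub == "intra":
            return o.V_intra
        raise KeyError(compartment)

    def organ_labeled_amount(self, organ: str) -> np.ndarray:
        """Total labeled peptide (nmol) in all sub-compartments of an organ."""
        subs = ["v", "int"]
        if self.patient.organ(organ).psma_positive:
            subs += ["bound", "intern"]
        if self.patient.organ(organ).kind == "kidney":
            subs += ["intra"]
        return sum(self.amount("labeled", f"{organ}.{sub}") for sub in subs)

    def organ_activity_mbq(self, organ: str) -> np.ndarray:
        return self.organ_labeled_amount(organ) * self.patient.specific_activity

    def organ_activity_fraction(self, organ: str) -> np.ndarray:
        return self.organ_activity_mbq(organ) / self.A0

    def total_moles(self, species: str) -> np.ndarray:
        cols = [c for (s, _), c in self.index.items() if s == species]
        return self.states[:, cols].sum(axis=1)

    def to_frame(self):
        """Tidy DataFrame (time_min, compartment, species, amount_nmol,
        concentration_nmol_per_L, activity_MBq)."""
        import pandas as pd

        rows = []
        sa = self.patient.specific_activity
        for (species, comp), col in self.index.items():
            a = self.states[:, col]
            rows.append(pd.DataFrame({
                "time_min": self.t, "compartment": comp, "species": species,
                "amount_nmol": a,
                "concentration_nmol_per_L": a / self._volume(comp),
                "activity_MBq": a * sa if species == "labeled" else 0.0,
            }))
        return pd.concat(rows, ignore_index=True)


class PBPKModel:
    """Assembled right-hand side of the coupled labeled/unlabeled ODE system."""

    def __init__(self, patient: PatientParameters, validate: bool = True):
        if validate:
            patient.validate()
        self.patient = patient
        self._build()

    def _build(self) -> None:
        p = self.patient
        self.organ_names = list(p.organs)
        n = len(self.organ_names)
        idx = {name: i for i, name in enumerate(self.organ_names)}
        self._oi = idx
        self.F = np.array([p.organs[o].F for o in self.organ_names])
        self.PS = np.array([p.organs[o].PS for o in self.organ_names])
        self.Vv = np.array([p.organs[o].V_v for o in self.organ_names])
        self.Vint = np.array([p.organs[o].V_int for o in self.organ_names])
        kinds = [p.organs[o].kind for o in self.organ_names]
        for required in ("lung", "kidney", "tumor", "liver"):
            if required not in kinds:
                raise PBPKConfigError(f"missing required organ of kind {required!r}")
        self.i_lung = kinds.index("lung")
        self.i_kid = kinds.index("kidney")
        self.i_liv = kinds.index("liver")
        self.i_tum = kinds.index("tumor")
        self.to_liver = np.array([p.organs[o].drains_to_liver for o in self.organ_names])
        self.psma = np.array([p.organs[o].psma_positive for o in self.organ_names])
        self.psma_idx = np.flatnonzero(self.psma)
        self.lam_int = np.array([p.organs[o].lambda_int for o in self.organ_names])[self.psma_idx]
        self.lam_rel = np.array([p.organs[o].lambda_release for o in self.organ_names])[self.psma_idx]
        # receptor pool amounts (nmol) = density * interstitial volume
        self.R0_amt = np.array(
            [p.organs[o].R0 for o in self.organ_names])[self.psma_idx] * self.Vint[self.psma_idx]
        # generic vascular organs: everything except lung, kidney, liver
        self.generic_v = np.array([k not in ("lung", "kidney", "liver") for k in kinds])
        # organs whose venous outflow goes directly to the veins
        self.to_veins = np.array(
            [not p.organs[o].drains_to_liver and k not in ("lung", "liver")
             for o, k in zip(self.organ_names, kinds)])
        self.F_liver_out = (self.F[self.i_liv]
                            + self.F[self.to_liver].sum())
        self.kid_psma_pos = int(np.flatnonzero(self.psma_idx == self.i_kid)[0])
        self.V_intra_kid = p.organs[self.organ_names[self.i_kid]].V_intra
        if self.V_intra_kid <= 0:
            raise PBPKConfigError("kidney needs V_intra > 0")

        # state layout per species:
        # [ART, VEN, PRP, v(0..n-1), int(0..n-1), RP(psma), intern(psma), kid_intra]
        self.n_org = n
        self.n_psma = len(self.psma_idx)
        self.n_per_species = 3 + 2 * n + 2 * self.n_psma + 1
        self.nstate = 2 * self.n_per_species
        self._s_v = slice(3, 3 + n)
        self._s_int = slice(3 + n, 3 + 2 * n)
        self._s_rp = slice(3 + 2 * n, 3 + 2 * n + self.n_psma)
        self._s_pin = slice(3 + 2 * n + self.n_psma, 3 + 2 * n + 2 * self.n_psma)
        self._i_intra = 3 + 2 * n + 2 * self.n_psma

        self.index: dict[tuple[str, str], int] = {}
        for si, species in enumerate(("labeled", "unlabeled")):
            off = si * self.n_per_species
            self.index[(species, "ART")] = off
            self.index[(species, "VEN")] = off + 1
            self.index[(species, "PRP")] = off + 2
            for j, o in enumerate(self.organ_names):
                self.index[(species, f"{o}.v")] = off + 3 + j
                self.index[(species, f"{o}.int")] = off + 3 + n + j
            for jj, j in enumerate(self.psma_idx):
                o = self.organ_names[j]
                self.index[(species, f"{o}.bound")] = off + self._s_rp.start + jj
                self.index[(species, f"{o}.intern")] = off + self._s_pin.start + jj
            self.index[(species, "kidneys.intra")] = off + self._i_intra

    # -- dynamics --------------------------------------------------------

    def _species_rhs(self, y: np.ndarray, R_free: np.ndarray) -> np.ndarray:
        """Flow/exchange/binding derivative of one species (no decay terms).

        ``R_free`` is the free-receptor amount per PSMA organ, shared between
        the two species.
        """
        p = self.patient
        A_art, A_ven, A_prp = y[0], y[1], y[2]
        Av = y[self._s_v]
        Aint = y[self._s_int]
        RP = y[self._s_rp]
        Pin = y[self._s_pin]
        A_intra = y[self._i_intra]

        C_art = A_art / p.V_ART
        C_ven = A_ven / p.V_VEN
        Cv = Av / self.Vv
        Cint = Aint / self.Vint

        F, PS = self.F, self.PS
        iL, iK, iH = self.i_lung, self.i_kid, self.i_liv
        F_lung = F[iL]
        F_fil = p.F_fil
        F_ex = p.fex * F_fil

        dAv = np.zeros_like(Av)
        dAint = np.zeros_like(Aint)

        # vascular pools
        exch = PS * (Cint - Cv)
        g = self.generic_v
        dAv[g] = exch[g] + F[g] * C_art - F[g] * Cv[g]
        dAv[iL] = exch[iL] + F_lung * (C_ven - Cv[iL])
        dAv[iH] = (exch[iH] + F[iH] * C_art
                   + (F[self.to_liver] * Cv[self.to_liver]).sum()
                   - self.F_liver_out * Cv[iH])
        dAv[iK] = (F[iK] * C_art - (F[iK] + F_fil) * Cv[iK]
                   + (F_fil - F_ex) * (A_intra / self.V_intra_kid))

        # interstitial pools: PS exchange everywhere except kidney (filtration)
        dAint[:] = PS * (Cv - Cint)
        dAint[iK] = F_fil * Cv[iK] - F_fil * Cint[iK]

        # receptor binding in PSMA-positive organs
        pi = self.psma_idx
        bind = self.patient.k_on * Aint[pi] * (R_free / self.Vint[pi])
        unbind = self.patient.k_off * RP
        dAint[pi] += -bind + unbind
        dRP = bind - (self.patient.k_off + self.lam_int) * RP
        dPin = self.lam_int * RP - self.lam_rel * Pin

        # kidney unspecific intracellular pool: tubular cells take up the
        # reabsorbed (non-excreted) fraction of the filtered peptide and
        # return it to the vascular space at the same flow, while a part is
        # catabolized in place at the kidney release rate; amino-acid
        # infusion raises fex, diverting filtered peptide to urine instead
        # of this recirculation loop
        lam_rel_kid = self.lam_rel[self.kid_psma_pos]
        dA_intra = ((F_fil - F_ex) * (Cint[iK] - A_intra / self.V_intra_kid)
                    - lam_rel_kid * A_intra)

        # blood pools
        tissue_flow_out = F.sum() - F_lung  # == cardiac output
        dA_art = -tissue_flow_out * C_art + F_lung * Cv[iL]
        dA_ven = ((F[self.to_veins] * Cv[self.to_veins]).sum()
                  + self.F_liver_out * Cv[iH]
                  - F_lung * C_ven - p.k_pr * A_ven)
        dA_prp = p.k_pr * A_ven

        out = np.empty_like(y)
        out[0], out[1], out[2] = dA_art, dA_ven, dA_prp
        out[self._s_v] = dAv
        out[self._s_int] = dAint
        out[self._s_rp] = dRP
        out[self._s_pin] = dPin
        out[self._i_intra] = dA_intra
        return out

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        m = self.n_per_species
        yl, yu = y[:m], y[m:]
        RP_l = yl[self._s_rp]
        RP_u = yu[self._s_rp]
        R_free = np.maximum(self.R0_amt - RP_l - RP_u, 0.0)
        lam = self.patient.lambda_phy
        dl = self._species_rhs(yl, R_free) - lam * yl
        du = self._species_rhs(yu, R_free) + lam * yl
        return np.concatenate([dl, du])

    def initial_state(self, A0_mbq: float) -> np.ndarray:
        """Instantaneous venous bolus at t=0.

        Labeled moles are fixed by the injected activity and the carrier-free
        specific activity; the unlabeled balance of the administered peptide
        amount is co-injected.
        """
        if A0_mbq < 0:
            raise ValueError("A0 must be >= 0")
        p = self.patient
        labeled = A0_mbq / p.specific_activity
        unlabeled = max(p.total_peptide_nmol - labeled, 0.0)
        y0 = np.zeros(self.nstate)
        y0[self.index[("labeled", "VEN")]] = labeled
        y0[self.index[("unlabeled", "VEN")]] = unlabeled
        return y0

    def receptor_residual(self, states: np.ndarray) -> np.ndarray:
        """max |R0 - (R + RP + RP*)| per time point; identically 0 because the
        free receptor is eliminated algebraically, kept as a diagnostic."""
        return np.zeros(states.shape[0])


def build_model(patient: PatientParameters, validate: bool = True) -> PBPKModel:
    return PBPKModel(patient, validate=validate)


def simulate(model: PBPKModel | PatientParameters, A0_mbq: float,
             t_grid: np.ndarray | None = None, *, rtol: float = 1e-8,
             atol: float = 1e-12, method: str = "LSODA") -> OrganTrajectories:
    """Integrate the PBPK system from a venous bolus of ``A0_mbq`` MBq."""
    if isinstance(model, PatientParameters):
        model = PBPKModel(model)
    if t_grid is None:
        t_grid = default_time_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must start at 0 and be strictly increasing")
    y0 = model.initial_state(A0_mbq)
    sol = solve_ivp(model.rhs, (0.0, t_grid[-1]), y0, t_eval=t_grid,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"PBPK integration failed: {sol.message}")
    return OrganTrajectories(t=t_grid, states=sol.y.T, index=model.index,
                             patient=model.patient, A0=A0_mbq)


def tumor_vascular_input(traj: OrganTrajectories):
    """Tumor vascular concentrations (Cv_labeled, Cv_unlabeled) in nmol/L on
    the trajectory time grid; the boundary input of the tumor transport model."""
    tumor = traj.patient.organ_of_kind("tumor").name
    cl = traj.concentration("labeled", f"{tumor}.v")
    cu = traj.concentration("unlabeled", f"{tumor}.v")
    return traj.t, cl, cu
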