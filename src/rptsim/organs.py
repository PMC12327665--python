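"""Patient parameterisation of the whole-body PBPK model.

The body is resolved into arterial and venous blood pools, a serum-protein
pool, and 17 tissue compartments, each with vascular and interstitial
sub-compartments.  PSMA-positive organs (kidney, liver, spleen, GI, prostate,
salivary glands, tumor) additionally carry receptor-bound and internalized
pools; the kidney has a fifth, unspecific intracellular pool fed by
glomerular filtration.

Default organ volumes and blood flows are standard adult reference-physiology
values; every number is config-overridable (see :func:`load_patient`).  The
four study patients of the underlying clinical dataset are reconstructed by
:func:`table2_patients` from their printed measured/estimated parameters
(tubular extraction rate, organ volumes, receptor densities, release rates,
background coefficient, salivary perfusion).
"""

from __future__ import annotations

import copy
import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .units import LAMBDA_PHY_LU177, specific_activity_mbq_per_nmol

__all__ = [
    "OrganSpec",
    "PatientParameters",
    "default_patient",
    "table2_patients",
    "apply_amino_acid_infusion",
    "load_patient",
    "save_patient",
    "patients_from_csv",
]

ORGAN_KINDS = {"generic", "kidney", "lung", "brain", "liver", "spleen", "gi",
               "muscle", "tumor"}


@dataclass
class OrganSpec:
    """One tissue compartment of the PBPK body.

    Volumes in litres, flows in L/min, receptor density R0 in nmol per litre
    of interstitial volume, rates in 1/min.
    """

    name: str
    kind: str = "generic"
    psma_positive: bool = False
    V_v: float = 0.0          # vascular sub-compartment volume (L)
    V_int: float = 0.0        # interstitial sub-compartment volume (L)
    V_intra: float = 0.0      # intracellular volume (L); kidney only
    F: float = 0.0            # blood flow (L/min)
    PS: float = 0.0           # permeability-surface product (L/min)
    R0: float = 0.0           # total receptor density (nmol/L interstitial)
    lambda_int: float = 0.0   # internalization rate (1/min)
    lambda_release: float = 0.0  # intracellular release/degradation (1/min)
    drains_to_liver: bool = False

    def validate(self) -> None:
        if self.kind not in ORGAN_KINDS:
            raise ValueError(f"organ {self.name}: unknown kind {self.kind!r}")
        if self.V_v <= 0 or self.V_int <= 0 or self.F <= 0:
            raise ValueError(f"organ {self.name}: volumes and flow must be > 0")
        if self.PS < 0 or (self.PS == 0 and self.kind not in ("brain", "kidney")):
            raise ValueError(f"organ {self.name}: PS must be > 0 (0 only for brain/kidney)")
        if self.R0 < 0 or self.lambda_int < 0 or self.lambda_release < 0:
            raise ValueError(f"organ {self.name}: rates and R0 must be >= 0")
        if self.psma_positive and self.R0 <= 0:
            raise ValueError(f"organ {self.name}: PSMA-positive organ needs R0 > 0")


@dataclass
class PatientParameters:
    """All per-patient constants of the PBPK and tumor-transport systems."""

    organs: dict[str, OrganSpec]
    V_ART: float = 1.2            # arterial blood volume (L)
    V_VEN: float = 3.1            # venous blood volume (L)
    V_p: float = 3.0              # total body serum volume (L)
    k_pr: float = 0.05            # serum-protein binding rate (1/min)
    F_fil: float = 0.110          # renal filtration flow = TER (L/min)
    fex: float = 0.80             # renal excretion fraction (AAI raises to 0.96)
    lambda_phy: float = LAMBDA_PHY_LU177
    k_on: float = 0.046           # association rate (L/(nmol*min))
    k_off: float = 0.046          # dissociation rate (1/min)
    c_BG: float = 0.01            # muscle background-correction coefficient
    tumor_volume_ml: float = 2.0  # modeled tumor lesion volume (mL)
    total_peptide_nmol: float = 185.0  # administered peptide amount (nmol)
    cardiac_output_tol: float = 0.05
    name: str = "default"
    meta: dict = field(default_factory=dict)

    # -- derived ---------------------------------------------------------
    @property
    def specific_activity(self) -> float:
        """Carrier-free specific activity (MBq per nmol of labeled peptide)."""
        return specific_activity_mbq_per_nmol(self.lambda_phy)

    @property
    def cardiac_output(self) -> float:
        """Total blood flow through the lungs (L/min)."""
        return sum(o.F for o in self.organs.values() if o.kind != "lung")

    def organ(self, name: str) -> OrganSpec:
        try:
            return self.organs[name]
        except KeyError:
            raise KeyError(f"patient {self.name!r} has no organ {name!r}") from None

    def organ_of_kind(self, kind: str) -> OrganSpec:
        hits = [o for o in self.organs.values() if o.kind == kind]
        if len(hits) != 1:
            raise ValueError(f"expected exactly one organ of kind {kind!r}, found {len(hits)}")
        return hits[0]

    def validate(self) -> None:
        required = {"lung", "kidney", "tumor", "liver", "spleen", "gi", "brain", "muscle"}
        kinds = [o.kind for o in self.organs.values()]
        missing = required - set(kinds)
        if missing:
            raise ValueError(f"patient {self.name!r} missing required organ kinds: {sorted(missing)}")
        for k in ("lung", "kidney", "tumor"):
            if kinds.count(k) != 1:
                raise ValueError(f"patient {self.name!r} must have exactly one {k}")
        for o in self.organs.values():
            o.validate()
        if not (0.0 <= self.fex <= 1.0):
            raise ValueError("fex must lie in [0, 1]")
        if self.lambda_phy <= 0 or self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("lambda_phy, k_on, k_off must be > 0")
        if self.V_ART <= 0 or self.V_VEN <= 0 or self.V_p <= 0 or self.F_fil <= 0:
            raise ValueError("blood volumes and filtration flow must be > 0")
        co = self.cardiac_output
        lung = self.organ_of_kind("lung")
        if lung.F > 0 and abs(lung.F - co) / co > self.cardiac_output_tol:
            raise ValueError(
                f"lung flow {lung.F:.3f} inconsistent with summed tissue flows {co:.3f}")

    def copy(self) -> "PatientParameters":
        return copy.deepcopy(self)


def _reference_organs() -> dict[str, OrganSpec]:
    """Reference-adult tissue compartments (volumes L, flows L/min).

    Vascular/interstitial splits use typical fractional blood and interstitial
    volumes; PS defaults scale with organ flow (brain 0 for the blood-brain
    barrier; the kidney exchanges via filtration, not PS).
    """
    # name: (kind, psma, V_total, f_vasc, f_int, F)
    table = {
        "lungs":           ("lung",    False, 1.00, 0.45, 0.30, 0.0),
        "heart":           ("generic", False, 0.33, 0.10, 0.15, 0.25),
        "liver":           ("liver",   True,  1.80, 0.11, 0.16, 0.39),
        "spleen":          ("spleen",  True,  0.18, 0.12, 0.15, 0.20),
        "gi":              ("gi",      True,  1.20, 0.07, 0.16, 1.00),
        "kidneys":         ("kidney",  True,  0.31, 0.11, 0.15, 1.20),
        "brain":           ("brain",   False, 1.45, 0.04, 0.15, 0.78),
        "muscle":          ("muscle",  False, 29.0, 0.02, 0.12, 1.10),
        "bone":            ("generic", False, 5.50, 0.03, 0.10, 0.30),
        "red_marrow":      ("generic", False, 1.20, 0.10, 0.15, 0.20),
        "skin":            ("generic", False, 3.30, 0.03, 0.30, 0.33),
        "adipose":         ("generic", False, 14.0, 0.015, 0.13, 0.33),
        "prostate":        ("generic", True,  0.025, 0.06, 0.16, 0.03),
        "salivary_glands": ("generic", True,  0.021, 0.06, 0.20, 0.0016),
        "tumor":           ("tumor",   True,  0.002, 0.07, 0.35, 0.0004),
        "remainder":       ("generic", False, 2.00, 0.05, 0.15, 0.29),
        "rest":            ("generic", False, 1.00, 0.05, 0.15, 0.10),
    }
    psma_r0 = {"liver": 5.0, "spleen": 15.0, "gi": 5.0, "prostate": 15.0,
               "salivary_glands": 38.0, "kidneys": 14.0, "tumor": 1.5}
    organs: dict[str, OrganSpec] = {}
    for name, (kind, psma, v_tot, f_v, f_i, flow) in table.items():
        ps = 0.0 if kind in ("brain", "kidney") else 0.10 * max(flow, 1e-6)
        organs[name] = OrganSpec(
            name=name, kind=kind, psma_positive=psma,
            V_v=v_tot * f_v, V_int=v_tot * f_i,
            V_intra=v_tot * 0.5 if kind == "kidney" else 0.0,
            F=flow, PS=ps,
            R0=psma_r0.get(name, 0.0),
            lambda_int=0.001 if psma else 0.0,
            lambda_release=3e-4 if psma else 0.0,
            drains_to_liver=kind in ("gi", "spleen"),
        )
    # tumor PS: permeability-surface product per unit mass k_tumor (default
    # 0.1 mL/(g*min)) times the 2 g lesion
    organs["tumor"].PS = 0.1 * 2.0 / 1000.0
    organs["lungs"].F = sum(o.F for o in organs.values() if o.kind != "lung")
    organs["lungs"].PS = 0.10 * organs["lungs"].F
    return organs


def default_patient(name: str = "default") -> PatientParameters:
    """A reference adult with a 2 mL PSMA-positive tumor lesion."""
    p = PatientParameters(organs=_reference_organs(), name=name)
    p.validate()
    return p


# Printed per-patient measurements/estimates: age, BSA (m2), TER (mL/min),
# measured volumes (mL: salivary glands, kidney, primary tumor), receptor
# densities (nmol/L: kidney, SG, tumor), release rates (1e-4/min: kidney,
# tumor), tumor background coefficient, SG perfusion (mL/(g*min)).
_TABLE2 = {
    "P1": dict(age=69, bsa=1.9, ter=201.0, v_sg=21.0, v_kid=311.0, v_ptum=57.0,
               rd_kid=14.0, rd_sg=38.0, rd_tum=1.5, rel_kid=2.9e-4,
               rel_tum=4.2e-4, c_bg=0.0064, sg_perf=0.074),
    "P2": dict(age=78, bsa=1.8, ter=136.0, v_sg=17.0, v_kid=394.0, v_ptum=282.0,
               rd_kid=22.0, rd_sg=108.0, rd_tum=0.88, rel_kid=2.4e-4,
               rel_tum=3.5e-4, c_bg=0.053, sg_perf=0.53),
    "P3": dict(age=54, bsa=2.1, ter=252.0, v_sg=52.0, v_kid=268.0, v_ptum=52.0,
               rd_kid=24.0, rd_sg=41.0, rd_tum=2.0, rel_kid=2.3e-4,
               rel_tum=3.3e-4, c_bg=0.0016, sg_perf=0.16),
    "P4": dict(age=53, bsa=2.0, ter=176.0, v_sg=29.0, v_kid=296.0, v_ptum=136.0,
               rd_kid=46.0, rd_sg=80.0, rd_tum=2.0, rel_kid=3.1e-4,
               rel_tum=4.8e-4, c_bg=0.018, sg_perf=0.16),
}


def table2_patients() -> dict[str, PatientParameters]:
    """The four metastatic prostate-cancer study patients.

    Each starts from the reference adult and is personalized with the printed
    per-patient measurements: tubular extraction rate (used as the renal
    filtration flow), kidney and salivary-gland volumes, receptor densities,
    intracellular release rates, tumor background coefficient and salivary
    perfusion.  The modeled tumor lesion is 2 mL for every patient.
    """
    out = {}
    for name, row in _TABLE2.items():
        p = default_patient(name)
        p.F_fil = row["ter"] / 1000.0
        p.c_BG = row["c_bg"]
        kid = p.organ("kidneys")
        v_kid = row["v_kid"] / 1000.0
        kid.V_v, kid.V_int, kid.V_intra = 0.11 * v_kid, 0.15 * v_kid, 0.5 * v_kid
        kid.R0 = row["rd_kid"]
        kid.lambda_release = row["rel_kid"]
        sg = p.organ("salivary_glands")
        v_sg = row["v_sg"] / 1000.0
        sg.V_v, sg.V_int = 0.06 * v_sg, 0.20 * v_sg
        sg.R0 = row["rd_sg"]
        sg.F = row["sg_perf"] * row["v_sg"] / 1000.0  # mL/(g min) * g -> L/min
        tum = p.organ("tumor")
        tum.R0 = row["rd_tum"]
        tum.lambda_release = row["rel_tum"]
        p.organ("lungs").F = p.cardiac_output
        p.meta = dict(row)
        p.validate()
        out[name] = p
    return out


def apply_amino_acid_infusion(patient: PatientParameters, enabled: bool, *,
                              fex_on: float = 0.96,
                              fex_off: float = 0.80) -> PatientParameters:
    """Return a copy with the renal excretion fraction set for AAI on/off.

    Co-infused amino acids (lysine/arginine) compete with the peptide for
    tubular reabsorption, raising the excreted fraction of the filtered flow
    from 0.80 to 0.96 by default.
    """
    patient.validate()
    q = patient.copy()
    q.fex = fex_on if enabled else fex_off
    return q


# -- I/O ----------------------------------------------------------------

def _patient_to_dict(p: PatientParameters) -> dict:
    d = dataclasses.asdict(p)
    return d


def save_patient(p: PatientParameters, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_patient_to_dict(p), indent=2))


def load_patient(path: str | Path) -> PatientParameters:
    """Load patient parameters from a JSON or TOML file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"patient parameter file not found: {path}")
    if path.suffix.lower() == ".toml":
        import tomllib
        d = tomllib.loads(path.read_text())
    else:
        d = json.loads(path.read_text())
    organs = {name: OrganSpec(**spec) for name, spec in d.pop("organs").items()}
    p = PatientParameters(organs=organs, **d)
    p.validate()
    return p


def patients_from_csv(path: str | Path) -> dict[str, PatientParameters]:
    """Import per-patient rows shaped like the printed patient table.

    Expected columns: patient, ter_ml_min, v_sg_ml, v_kidney_ml,
    rd_kidney, rd_sg, rd_tumor, rel_kidney_per_min, rel_tumor_per_min,
    c_bg, sg_perfusion_ml_g_min.
    """
    import pandas as pd

    df = pd.read_csv(path)
    out = {}
    for _, r in df.iterrows():
        row = dict(age=0, bsa=0.0, ter=float(r["ter_ml_min"]),
                   v_sg=float(r["v_sg_ml"]), v_kid=float(r["v_kidney_ml"]),
                   v_ptum=float(r.get("v_primary_tumor_ml", math.nan)),
                   rd_kid=float(r["rd_kidney"]), rd_sg=float(r["rd_sg"]),
                   rd_tum=float(r["rd_tumor"]),
                   rel_kid=float(r["rel_kidney_per_min"]),
                   rel_tum=float(r["rel_tumor_per_min"]),
                   c_bg=float(r["c_bg"]), sg_perf=float(r["sg_perfusion_ml_g_min"]))
        name = str(r["patient"])
        p = default_patient(name)
        p.F_fil = row["ter"] / 1000.0
        p.c_BG = row["c_bg"]
        kid = p.organ("kidneys")
        v_kid = row["v_kid"] / 1000.0
        kid.V_v, kid.V_int, kid.V_intra = 0.11 * v_kid, 0.15 * v_kid, 0.5 * v_kid
        kid.R0, kid.lambda_release = row["rd_kid"], row["rel_kid"]
        sg = p.organ("salivary_glands")
        v_sg = row["v_sg"] / 1000.0
        sg.V_v, sg.V_int = 0.06 * v_sg, 0.20 * v_sg
        sg.R0 = row["rd_sg"]
        sg.F = row["sg_perf"] * row["v_sg"] / 1000.0
        tum = p.organ("tumor")
        tum.R0, tum.lambda_release = row["rd_tum"], row["rel_tum"]
        p.organ("lungs").F = p.cardiac_output
        p.meta = dict(row)
        p.validate()
        out[name] = p
    return out
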