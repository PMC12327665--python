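"""Unit conventions and physical constants.

Internal unit system: time in minutes, volume in litres, amount of peptide in
nmol, concentration in nmol/L, activity in MBq, pressure in Pa, length in
metres (microcirculation / transport grids), absorbed dose in Gy.
"""

MMHG_PER_PA = 1.0 / 133.322
PA_PER_MMHG = 133.322

#: Avogadro's number per nmol
N_A_PER_NMOL = 6.02214076e14

#: Physical decay constant of Lu-177 (1/min); half-life 6.647 d.
LAMBDA_PHY_LU177 = 7.15e-5

#: Mean energy emitted per Lu-177 decay that is absorbed locally under the
#: full-local-absorption approximation (beta component only), in joules.
#: 133.5 keV mean beta energy per decay.
DELTA_BETA_LU177_J = 133.5e3 * 1.602176634e-19

SECONDS_PER_MIN = 60.0
MBQ_PER_BQ = 1e-6


def specific_activity_mbq_per_nmol(lambda_phy_per_min: float) -> float:
    """Carrier-free specific activity A/N = lambda * N_A for a nuclide with
    decay constant ``lambda_phy_per_min`` (1/min), in MBq per nmol."""
    return lambda_phy_per_min / SECONDS_PER_MIN * N_A_PER_NMOL * MBQ_PER_BQ


def mmhg_to_pa(p: float) -> float:
    return p * PA_PER_MMHG


def pa_to_mmhg(p: float) -> float:
    return p * MMHG_PER_PA
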