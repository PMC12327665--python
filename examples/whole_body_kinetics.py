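"""Whole-body kinetics of a 7.4 GBq Lu-177-PSMA bolus, with and without
amino-acid infusion (AAI).

AAI raises the renal excretion fraction fex from 0.80 to 0.96, diverting
filtered peptide from tubular reabsorption to urine, which lowers kidney
exposure and slightly speeds whole-body clearance.
"""

import numpy as np

from rptsim import (PBPKModel, apply_amino_acid_infusion, default_time_grid,
                    simulate, table2_patients, tumor_vascular_input)

patient = table2_patients()["P1"]
t_grid = default_time_grid(30000.0, 601)

for aai in (False, True):
    p = apply_amino_acid_infusion(patient, aai)
    traj = simulate(PBPKModel(p), 7400.0, t_grid)
    label = "with AAI" if aai else "no AAI "
    for organ in ("kidneys", "salivary_glands", "tumor"):
        frac = traj.organ_activity_fraction(organ)
        tia = np.trapezoid(frac, t_grid)
        print(f"[{label}] {organ:16s} peak {frac.max():.4f} of injected, "
              f"time-integrated coefficient {tia:8.3f} min")
    t, cv_l, _ = tumor_vascular_input(traj)
    print(f"[{label}] tumor vascular peak {cv_l.max():.2f} nmol/L "
          f"(input to the spatial transport model)")

# The kidney time-integrated activity coefficient drops under AAI while the
# salivary glands barely move - the reason AAI helps when the kidney, not
# the salivary gland, is the dose-limiting organ.
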