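# rptsim

Multiscale simulation of ¹⁷⁷Lu-PSMA radiopharmaceutical therapy (RPT) for
prostate cancer: whole-body pharmacokinetics, tumor microenvironment fluid
dynamics, spatially resolved drug transport, absorbed-dose calculation and
amino-acid-infusion (AAI) treatment planning.

It is written for researchers in computational nuclear medicine and tumor
physiology who want to ask questions like: *how much activity can this
patient receive before the kidney hits its dose limit, and how much does
co-infusing amino acids buy?* — and to check how much the answer changes
when interstitial fluid pressure and heterogeneous microvasculature are
resolved instead of treating the tumor as a well-mixed compartment.

## What is inside

* **Whole-body PBPK model** (`rptsim.pbpk`, `rptsim.organs`) — arterial and
  venous blood, a serum-protein pool and 17 tissue compartments, each with
  vascular/interstitial sub-compartments.  PSMA-positive organs bind free
  peptide to a finite receptor pool (labeled and unlabeled ligand compete),
  internalize (λ_int) and degrade (λ_release) it; the kidney adds tubular
  filtration with an excreted fraction *f*ex (0.80, raised to 0.96 by AAI).
  Physical decay (λ_phy = 7.15×10⁻⁵ min⁻¹) transmutes labeled into
  unlabeled peptide everywhere, so the two ODE systems are coupled.
* **Stochastic angiogenesis** (`rptsim.angiogenesis`) — tip endothelial
  cells walk on a lattice from two parent vessels (400 µm) with
  chemotactic bias up a tumor-angiogenic-factor gradient, branching and
  anastomosing into a 20 µm capillary network over 30 days.
* **Microcirculation** (`rptsim.microcirculation`) — Poiseuille flow on the
  network coupled to Darcy flow in the interstitium through Starling's law
  v_t = L_p (P_B − P_i − σ(π_b − π_i)), solved as one sparse linear system;
  yields intravascular pressure (IVP), interstitial fluid pressure (IFP)
  and velocity fields.
* **Tumor transport** (`rptsim.cdr`) — convection–diffusion–reaction fields
  for interstitial, receptor-bound and internalized peptide (both species),
  driven by the PBPK tumor-vascular concentration through a pore-model
  transvascular source with Péclet-weighted diffusive exchange.
* **Dosimetry and planning** (`rptsim.dosimetry`) — MIRD formalism
  D = A₀ · ã · S with self-dose S-values (analytic Δ_β/m default or a CSV
  table), serum-protein and muscle-background contributions, and
  root-finding for the organ-at-risk-limited maximum safe activity
  (kidney 8 Gy, salivary glands 7.5 Gy per cycle).
* **Statistics and calibration** (`rptsim.stats`, `rptsim.calibration`) —
  exact-enumeration Wilcoxon signed-rank test, normalized local sensitivity
  indices SI = (ΔD/D)/(ΔP/P) over four decade-scaling ranges, and
  nonlinear-least-squares personalization against (synthetic) γ-camera
  time–activity curves with SSE/MSE/AIC/BIC reporting.

Four virtual patients reconstructed from published per-patient measurements
(tubular extraction rate, organ volumes, receptor densities, release rates)
ship as `rptsim.table2_patients()`.

## Worked example

```python
from rptsim import (LatticeGrid, FlowParameters, make_taf_field,
                    grow_network, couple)

grid = LatticeGrid()                      # 20 mm domain, 100 um lattice
net = grow_network(grid, make_taf_field(grid), seed=42)
sol = couple(net, grid, FlowParameters()) # inlet 25 / outlet 10 mmHg
print(f"{sol.mean_tumor_ivp_mmhg():.1f} {sol.mean_tumor_ifp_mmhg():.1f}")
```

prints

```
17.6 13.5
```

— the mean microvascular pressure over tumor capillaries and the mean
interstitial fluid pressure in the tumor, in mmHg.  The IFP sits only a few
mmHg below the vessel pressure (the osmotic jump σΔπ ≈ 4.1 mmHg): with no
functional lymphatics the tumor interstitium pressurizes until filtration
and reabsorption balance, which is the elevated-IFP regime that hampers
convective drug delivery in solid tumors.

The `examples/` directory has one short script per capability
(`grow_and_flow.py`, `whole_body_kinetics.py`, `tumor_transport.py`,
`treatment_planning.py`, `fit_patient.py`, `sensitivity_and_stats.py`);
each prints the quantities it computes and a line on what they mean.  A
thin CLI mirrors them (`rptsim grow|flow|pbpk|plan|synth|fit|wilcoxon|
sensitivity|run`).

## Limitations

The 2-D vasculature, fixed tumor geometry, self-dose-only S-values and
reference-physiology defaults are deliberate simplifications; see
`docs/methods.md` for the model assumptions, parameter provenance, and
numerical choices.
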