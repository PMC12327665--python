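# Methods

This note documents the models, parameter choices and numerics behind
`rptsim`, in the order the pipeline runs them, and closes with what the
synthetic data and tests do and do not establish.

## Whole-body PBPK model

The body is 19 pools: arterial blood, venous blood, a serum-protein pool,
and 17 tissue compartments (lungs, heart, liver, spleen, GI, kidneys,
brain, muscle, bone, red marrow, skin, adipose, prostate, salivary glands,
a 2 mL tumor lesion, and two remainder pools), each split into vascular and
interstitial sub-compartments.  State variables are amounts (nmol); writing
the balance equations in amounts makes every exchange term manifestly
mass-conserving, which the test suite exploits (closed-system drift
< 10⁻⁶ over 30 000 min).

Flow topology: arteries feed every tissue except the lungs proportionally
to organ blood flow F_i; venous return passes through the lungs
(F_lung = cardiac output) back to the arteries; GI and spleen drain through
the liver.  Vascular–interstitial exchange uses a permeability–surface
product PS_i (brain PS = 0, the blood–brain barrier).  Serum-protein
binding removes peptide from the venous pool only, at rate k_pr, one-way;
the protein-bound pool is eliminated only by physical decay.

**PSMA binding.**  In PSMA-positive organs (kidney, liver, spleen, GI,
prostate, salivary glands, tumor) free interstitial peptide binds a shared
finite receptor pool R₀ (k_on = 0.046 L/(nmol·min), k_off = 0.046 min⁻¹),
is internalized at λ_int and degraded intracellularly at λ_release, with
degradation products cleared from the body.  The free receptor
concentration is eliminated algebraically (R = R₀ − RP − RP*), so the
receptor-site constraint holds exactly at all times, and labeled and
unlabeled peptide compete for the same sites.

**Kidney.**  The filtered flow F_fil (identified with the per-patient
tubular extraction rate, the only filtration flow printed per patient)
carries free peptide into the tubular compartment; a fraction f_ex = f·F_fil
is excreted to urine (f = 0.80, or 0.96 under amino-acid infusion), while
the reabsorbed remainder transits tubular cells and returns to the blood,
with a part catabolized in place at the kidney release rate.  This
recirculation form makes AAI lower the kidney dose by ~8 % per patient —
the order of the published per-patient planning gains — whereas a
fully-retained tubular pool (tried and rejected) makes AAI a ~5× effect,
far beyond them.

**Radioactive decay** converts labeled to unlabeled peptide in every pool
with matched ±λ_phy terms; total peptide moles are invariant under decay.
Injection is an instantaneous venous bolus: labeled moles are fixed by the
injected activity and the carrier-free specific activity
(λ_phy·N_A ≈ 718 MBq/nmol); the balance of the administered peptide amount
(default 185 nmol, a typical clinical ligand mass) is co-injected
unlabeled.  Receptor saturation by the total ligand mass is what makes
organ dose nonlinear in injected activity.

**Parameter provenance.**  Patient-specific values (filtration flow, kidney
and salivary volumes, receptor densities, release rates, background
coefficient, salivary perfusion) come from the published four-patient
table; the release-rate pair is read as (kidney, tumor) because the tumor
transport model requires a per-patient tumor release rate.  Organ volumes,
flows and vascular/interstitial fractions are reference-adult physiology;
PS_i defaults to 0.1·F_i.  k_pr = 0.05 min⁻¹ was chosen once so that the
serum-protein pool dominates late blood retention — the regime the dose
model presumes by carrying explicit protein-bound contributions — and so
that organ doses land in the clinically reported range for this ligand
(kidney ≈ 0.4–0.5, salivary ≈ 0.7–1.2 Gy/GBq).  All defaults are plain
dataclass fields and JSON/TOML-overridable; none is hard-coded truth.

**Integration.**  `scipy.integrate.solve_ivp` (LSODA, rtol 10⁻⁸ by
default, dense output sampled onto a geometric grid refined near t = 0).

## Angiogenesis

Sprouting angiogenesis is a biased lattice walk: each tip endothelial cell
either stays (weight s₀) or moves to one of its four neighbours with weight
max(0, m + χ·(c_neighbour − c_here)) — the discrete chemotaxis rule — where
c is a static, radially symmetric tumor-angiogenic-factor field (1 at the
tumor centre, Gaussian decay, length scale 8 mm).  Tips branch with
probability 0.2·c per step after a 5-step maturation, die on leaving the
domain, and fuse (anastomose) when stepping onto existing vasculature,
closing loops; immediate back-steps are excluded.  30 days at 24 steps/day,
15 initial sprouts per parent vessel.  The sprout count and branching
coefficient are not published at desk scale; they were fixed once so the
resulting intercapillary spacing inside the tumor is ~250 µm, typical of
vascularized tumors, and are flagged as non-authoritative defaults.
Growth is reproducible bit-for-bit for a given seed.

## Microcirculation

Capillaries (20 µm) and parent vessels (400 µm) carry Poiseuille flow
(g = πd⁴/128µL, blood viscosity 3×10⁻³ Pa·s); the parent vessels are
pressure reservoirs at 25 mmHg (inlet) and 10 mmHg (outlet).  Each
capillary's wall leaks at the Starling velocity with L_p = 2.7×10⁻¹²
m/(Pa·s), σ = 0.82, π_b = 2666 Pa, π_i = 2000 Pa; half of each segment's
wall area is lumped at each endpoint node, which is exactly the
midpoint-deposition rule on node-centred cells.  The interstitium obeys
Darcy's law with κ = 6.4×10⁻¹⁴ m²/(Pa·s) on a 5-point stencil.

The coupled vascular/interstitial problem is linear, so it is assembled as
one sparse system and solved directly (SuperLU); the reported residual is
the verified algebraic defect (< 10⁻⁶).  A global flux audit (boundary
inflow = total transvascular leak) holds to < 0.1 %.

**Outer boundary.**  Default: no-flux walls and no lymphatics anywhere,
matching the stated neglect of lymphatic drainage.  The interstitium then
pressurizes until filtration balances reabsorption, giving mean tumor IFP
within ~4 mmHg (the osmotic jump σΔπ) of the mean vessel pressure — the
elevated-IFP regime with "minimal disparity" between the two pressures that
the source imaging literature reports.  A Dirichlet-0 rim (a perfectly
draining far field) is available in config but collapses tumor IFP to a few
mmHg when the domain margin is only 2 mm, so it is not the default.  With
the defaults, 10-seed means are IVP ≈ 17.7 mmHg and IFP ≈ 13.6 mmHg; note
that with two statistically equivalent parent vessels at 25/10 mmHg the
mean tumor vessel pressure is anchored near the 17.5 midpoint, an ~11 %
structural low bias against the published 19.8 mmHg, which would require an
inlet-dominated network realization.

## Tumor transport

Six fields on the tumor disk (labeled/unlabeled × interstitial, bound,
internalized).  Transvascular source: φ_B = Ψ_B(1−σ_f)C_v +
P·(S/V)·(C_v−C_int)·Pe/(e^Pe−1), Pe = Ψ_B(1−σ_f)/(P·S/V), with the
Pe → 0 limit taken analytically; Ψ_B and S/V come from the pressure
solution and network, C_v from the PBPK tumor vascular compartment.
Parameters: D = 8.7×10⁻⁷ cm²/s, P = 3.3×10⁻⁴ cm/s, σ_f = 0.9,
k_int = 10⁻³ min⁻¹, per-patient receptor density (uniform field by default)
and release rate.

Time stepping (default dt = 1 min) is operator-split:

1. local exchange/binding/decay — backward-Euler on the (interstitial,
   bound) pair per cell with the free receptor lagged; all internal
   transfers use end-of-step values, so the update conserves moles exactly
   and preserves positivity without clipping;
2. convection by v_i — explicit first-order upwind; the tumor rim is
   outflow-open (outward IFP-driven flow sheds peptide into the host, whose
   contribution to dose is carried by the well-mixed background model), a
   CFL check refuses too-large steps;
3. diffusion — implicit, factorized once, no-flux.

The 2-mm muscle shell is not resolved by the PDE; its contribution to tumor
dose uses the background-corrected muscle concentration
c_BG·(C_mus,v* + C_mus,int* + PRP*·(V_mus,v/V_p + V_tum,v)) from the PBPK
solution, as the dose model prescribes.  In the uniform-vasculature,
no-convection limit the spatial mean of the PDE matches the equivalent
single-compartment ODE within 0.5 % (tested), so compartmental and spatial
predictions diverge only through heterogeneity and convection — the effect
under study.

## Dosimetry and planning

MIRD self-dose: D = A₀·ã·S with ã the 30 000-min trapezoidal
time-integrated activity coefficient (no tail extrapolation).  S-values:
log-log-interpolated CSV table per region if supplied; otherwise the
analytic full-local-absorption value S = Δ_β/m with Δ_β the 133.5 keV mean
beta energy per decay (photons escape; a documented underestimate of a few
per cent for organ-sized spheres).  Organ doses add the serum-protein-bound
peptide resident in the organ's vascular volume; tumor dose sums vascular,
interstitial, bound, internalized and muscle-background components (the
spatial engine replaces the middle three with transport-model integrals).
Maximum safe activity solves D_OAR(A₀) = limit by Brent root-finding on an
auto-expanding bracket (0.1–50 GBq, ×2 up to four times, relative tolerance
10⁻³); D_OAR(A₀) is monotone, super-linear only through receptor
saturation.

## Statistics and calibration

*Wilcoxon signed-rank:* zeros dropped, average ranks for ties, two-sided
p = min(1, 2·min(P(W≤w), P(W≥w))) by full enumeration of the 2ⁿ sign
assignments conditional on the observed |d| ranks (n ≤ 20).

*Sensitivity:* SI = (ΔD/D_ref)/(ΔP/P_ref) over the scaling ranges
100→10, 10→1, 1→0.1, 0.1→0.01, with the lower endpoint of each range as
reference so a linear dose–parameter relation gives SI = 1 on every range
(the baseline-reference convention is selectable).  The dose evaluator
holds the administered peptide *moles* fixed while a parameter is scaled
and computes activity as moles·λ_phy; this is the physically meaningful
experiment for λ_phy (same syringe, different half-life) and is what makes
SI(λ_phy) → 1 at low scalings, as reported.

*Calibration:* bounded `least_squares` on dotted parameter names, optional
inverse-uncertainty weighting (necessary when small-organ TACs carry the
signal), finite-difference step 10⁻³ (well above the ODE solver noise
floor; smaller steps produce garbage Jacobians), Gaussian-MLE logLik,
AIC = 2k − 2logLik, BIC = k ln n − 2logLik.

## Synthetic data

The TAC generator simulates the PBPK model at the default post-therapy
imaging schedule (1, 24, 48, 72, 168 h), samples organ activity fractions
and applies mean-one log-normal multiplicative noise (default CV 5 %,
seeded).  It emulates quantification noise only: no attenuation/scatter/
partial-volume structure, no inter-observer segmentation error, no organ
overlap.  Passing parameter-recovery tests therefore show identifiability
under ideal quantification, not robustness to real γ-camera physics.

## Problem sizes and reproducibility

Default study scale: 201×201 lattice at 100 µm (flow headline numbers,
~0.5 s per seed); transport comparisons run on a 51×51 lattice at 400 µm
with dt = 1 min, and shorter horizons are used in unit tests.  All
stochastic stages take explicit seeds; the pipeline embeds the config hash,
seed and package version in every artifact.

## Known limitations

2-D single-layer vasculature with uniform capillary diameter; static tumor
and vasculature over the treatment window; one-way serum-protein binding;
self-dose-only S-values; uniform receptor field in the tumor; no
radiobiology (BED/EQD2), no multi-cycle accumulation.  Planning magnitudes
inherit the reference-physiology defaults: with carrier-free specific
activity, a 2 mL lesion and printed receptor densities of 0.9–2 nmol/L,
tumor doses of tens of Gy are unreachable — absolute published planning
numbers depend on per-patient fitted parameters and volume-specific
S-values not reproduced here.
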