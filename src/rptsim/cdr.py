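"""Spatiotemporal peptide transport in the tumor interstitium.

Six coupled fields on the tumor region of the lattice grid - labeled and
unlabeled peptide in the interstitium (C_int*, C_int), bound to PSMA
receptors (C_bound*, C_bound), and internalized (C_intern*, C_intern) - are
advanced with an operator-split scheme:

* local exchange/reaction/decay terms: semi-implicit (losses backward-Euler,
  gains explicit), which preserves non-negativity without clipping;
* convection by the interstitial Darcy velocity: explicit first-order upwind;
* diffusion: implicit (factorized once), no-flux at the tumor boundary.

The transvascular source follows the pore model: a convective part
Psi_B (1-sigma_f) C_v plus a diffusive part P*(S/V)*(C_v - C_int) weighted by
the Peclet factor Pe/(e^Pe - 1), Pe = Psi_B (1-sigma_f) / (P S/V).  The
vascular concentrations C_v*, C_v come from the whole-body PBPK solution;
Psi_B, S/V and v_i come from the microcirculation solve.  Labeled and
unlabeled peptide compete for the same finite receptor density R; physical
decay converts labeled into unlabeled in every pool.  Internalized peptide
is cell-fixed (neither advected nor diffused).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import factorized

from .angiogenesis import LatticeGrid
from .microcirculation import PressureSolution
from .units import LAMBDA_PHY_LU177

__all__ = ["CDRParameters", "TumorFields", "transvascular_source",
           "run_transport", "field_time_integrals", "well_mixed_reference"]


class TransportInstabilityError(RuntimeError):
    pass


@dataclass
class CDRParameters:
    """Transport/reaction constants (values in the units noted; converted to
    the internal m/min system on use)."""

    D_psma_cm2_s: float = 8.7e-7     # ligand diffusivity
    k_on: float = 0.046              # L/(nmol min)
    k_off: float = 0.046             # 1/min
    lambda_phy: float = LAMBDA_PHY_LU177
    R: float = 1.5                   # receptor density (nmol/L), patient-specific
    P_cm_s: float = 3.3e-4           # vessel-wall permeability
    sigma_f: float = 0.9             # filtration reflection coefficient
    k_int: float = 0.001             # internalization rate (1/min)
    lambda_deg: float = 4.2e-4       # intracellular release rate (1/min)
    psi_l: float = 0.0               # lymphatic sink coefficient (1/min); 0 in tumor

    @property
    def D(self) -> float:
        """Diffusivity in m^2/min."""
        return self.D_psma_cm2_s * 1e-4 * 60.0

    @property
    def P(self) -> float:
        """Wall permeability in m/min."""
        return self.P_cm_s * 1e-2 * 60.0


def _peclet_factor(pe: np.ndarray) -> np.ndarray:
    """Pe/(e^Pe - 1), with the Pe -> 0 limit of 1."""
    pe = np.asarray(pe, dtype=float)
    out = np.ones_like(pe)
    m = np.abs(pe) > 1e-6
    out[m] = pe[m] / np.expm1(pe[m])
    return out


def transvascular_source(Cv, C_int, psi_b, sv, params: CDRParameters):
    """Pore-model source phi_B in nmol/(L min).

    ``psi_b`` is the transvascular volumetric flow per tissue volume in
    1/min, ``sv`` the wall area per tissue volume in 1/m.  Where sv = 0 the
    diffusive wall exchange vanishes and only the convective term remains.
    """
    Cv = np.asarray(Cv, dtype=float)
    C_int = np.asarray(C_int, dtype=float)
    psi_b = np.asarray(psi_b, dtype=float)
    sv = np.asarray(sv, dtype=float)
    if np.any(sv < 0):
        raise ValueError("S/V must be >= 0")
    psv = params.P * sv                       # 1/min
    conv = psi_b * (1.0 - params.sigma_f) * Cv
    with np.errstate(divide="ignore", invalid="ignore"):
        pe = np.where(psv > 0, psi_b * (1.0 - params.sigma_f) / np.where(psv > 0, psv, 1.0), 0.0)
    diff = psv * (Cv - C_int) * _peclet_factor(pe)
    return conv + np.where(psv > 0, diff, 0.0)


@dataclass
class TumorFields:
    """Solution fields and running time integrals of the transport model.

    ``snapshots`` maps field name -> (n_snap, ny, nx) stacks at
    ``snapshot_times``; ``series_t``/``mean_series`` record the spatial mean
    concentration (nmol/L over the tumor mask) of every field at every step,
    which is what the dosimetry integrals consume.
    """

    grid: LatticeGrid
    tumor_mask: np.ndarray
    snapshot_times: np.ndarray
    snapshots: dict[str, np.ndarray]
    series_t: np.ndarray
    mean_series: dict[str, np.ndarray]
    params: CDRParameters

    FIELDS = ("C_int_l", "C_int_u", "C_bound_l", "C_bound_u",
              "C_intern_l", "C_intern_u")


def field_time_integrals(fields: TumorFields, tumor_volume_l: float) -> dict[str, float]:
    """Trapezoidal time-integrated amounts (nmol*min) per sub-compartment,
    spatial mean concentration times the compartment volume."""
    t = fields.series_t
    if np.any(np.diff(t) <= 0):
        raise ValueError("time series must be strictly increasing")
    return {name: float(np.trapezoid(series, t)) * tumor_volume_l
            for name, series in fields.mean_series.items()}


def _masked_diffusion_operator(mask: np.ndarray, h: float):
    """No-flux 5-point Laplacian (1/m^2 scale) restricted to masked cells."""
    ny, nx = mask.shape
    idx = -np.ones((ny, nx), dtype=int)
    idx[mask] = np.arange(int(mask.sum()))
    jj, ii = np.nonzero(mask)
    center = idx[jj, ii]
    rows, cols, vals = [], [], []
    diag = np.zeros(len(center))
    for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        nj, ni = jj + dj, ii + di
        ok = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < ny)
        nb = np.where(ok, idx[nj % ny, ni % nx], -1)
        m = nb >= 0
        diag[m] += 1.0
        rows.append(center[m])
        cols.append(nb[m])
        vals.append(np.full(int(m.sum()), -1.0))
    rows.append(center)
    cols.append(center)
    vals.append(diag)
    L = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(len(center), len(center))).tocsc() / h ** 2
    return L, idx


def _upwind_div(c: np.ndarray, vx: np.ndarray, vy: np.ndarray, h: float,
                mask: np.ndarray) -> np.ndarray:
    """-div(v c) with first-order upwinding.

    The edge of the mask is an outflow-open boundary: outward velocity
    carries peptide into the surrounding host tissue (handled by the
    well-mixed background model), while inflow from outside carries nothing
    (outside concentration is not tracked and enters as zero).
    """
    cm = np.where(mask, c, 0.0)
    flux = np.zeros_like(c)
    # x-faces between (j,i) and (j,i+1)
    vfx = 0.5 * (vx[:, :-1] + vx[:, 1:])
    fx = vfx * np.where(vfx > 0, cm[:, :-1], cm[:, 1:])
    flux[:, :-1] -= fx / h
    flux[:, 1:] += fx / h
    vfy = 0.5 * (vy[:-1, :] + vy[1:, :])
    fy = vfy * np.where(vfy > 0, cm[:-1, :], cm[1:, :])
    flux[:-1, :] -= fy / h
    flux[1:, :] += fy / h
    return np.where(mask, flux, 0.0)


def run_transport(pressure: PressureSolution | None, cv_series,
                  params: CDRParameters, *, grid: LatticeGrid | None = None,
                  sv=None, psi_b=None, v=None,
                  t_end: float = 30000.0, dt: float = 1.0,
                  snapshot_times=(500.0, 1000.0, 3000.0, 6000.0, 30000.0),
                  record_every: int = 1,
                  initial: dict | None = None) -> TumorFields:
    """March the tumor fields from 0 to ``t_end`` minutes.

    ``cv_series`` is (t, Cv_labeled, Cv_unlabeled) from the PBPK tumor
    vascular compartment (nmol/L).  ``dt`` defaults to 1 minute.  The wall
    area density ``sv`` (1/m), transvascular flow ``psi_b`` (1/s) and Darcy
    velocity ``v`` (2, ny, nx in m/s) are derived from ``pressure`` but can
    be overridden (scalar or field), e.g. for the uniform-vasculature limit.
    Convective CFL violations and non-finite fields raise
    :class:`TransportInstabilityError` advising a smaller step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if pressure is None and grid is None:
        raise ValueError("either a pressure solution or a grid is required")
    grid = grid or pressure.grid
    mask = grid.tumor_mask()
    n = int(mask.sum())
    h = grid.h

    shape = (grid.ny, grid.nx)
    if sv is None:
        from .angiogenesis import network_stats
        sv = network_stats(pressure.net, grid)["sv_field"]  # 1/m
    sv = np.broadcast_to(np.asarray(sv, dtype=float), shape)
    if psi_b is None:
        psi_b = pressure.psi_b if pressure is not None else 0.0
    psi_b = np.broadcast_to(np.asarray(psi_b, dtype=float), shape) * 60.0  # 1/min
    if v is None:
        v = pressure.v_i if pressure is not None else np.zeros((2,) + shape)
    vx = np.broadcast_to(np.asarray(v[0], dtype=float), shape) * 60.0      # m/min
    vy = np.broadcast_to(np.asarray(v[1], dtype=float), shape) * 60.0

    cfl = max(np.abs(vx)[mask].max(), np.abs(vy)[mask].max()) * dt / h
    if cfl > 1.0:
        raise TransportInstabilityError(
            f"convective CFL {cfl:.2f} > 1; reduce dt below {dt / cfl:.3f} min")

    L, _ = _masked_diffusion_operator(mask, h)
    diff_solve = factorized(sp.eye(n, format="csc") + dt * params.D * L)

    t_cv, cv_l_s, cv_u_s = cv_series
    lam = params.lambda_phy
    R = params.R

    fields = {name: np.zeros((grid.ny, grid.nx)) for name in TumorFields.FIELDS}
    for name, val in (initial or {}).items():
        if name not in fields:
            raise KeyError(f"unknown field {name!r}")
        fields[name] = np.where(mask, np.broadcast_to(
            np.asarray(val, dtype=float), (grid.ny, grid.nx)), 0.0).copy()
    n_steps = int(round(t_end / dt))
    snap_steps = {int(round(ts / dt)): ts for ts in snapshot_times if ts <= t_end}
    snaps = {name: [] for name in TumorFields.FIELDS}
    snap_t = []
    rec_t = [0.0]
    means = {name: [float(fields[name][mask].mean())] for name in TumorFields.FIELDS}

    psi_b_m = np.where(mask, psi_b, 0.0)
    sv_m = np.where(mask, sv, 0.0)

    for step in range(1, n_steps + 1):
        t_mid = (step - 0.5) * dt
        cv_l = np.interp(t_mid, t_cv, cv_l_s)
        cv_u = np.interp(t_mid, t_cv, cv_u_s)

        ci_l, ci_u = fields["C_int_l"], fields["C_int_u"]
        cb_l, cb_u = fields["C_bound_l"], fields["C_bound_u"]
        cn_l, cn_u = fields["C_intern_l"], fields["C_intern_u"]

        r_free = np.maximum(R - cb_l - cb_u, 0.0)

        # --- local exchange / binding / decay (losses implicit) ----------
        phi_l = transvascular_source(cv_l, ci_l, psi_b_m, sv_m, params)
        phi_u = transvascular_source(cv_u, ci_u, psi_b_m, sv_m, params)
        # separate the C_int-proportional part so it can be taken implicitly
        psv_f = params.P * sv_m * _peclet_factor(
            np.where(params.P * sv_m > 0,
                     psi_b_m * (1 - params.sigma_f) / np.maximum(params.P * sv_m, 1e-300),
                     0.0))
        gain_l = np.where(mask, phi_l + psv_f * ci_l, 0.0)  # Cv-driven part
        gain_u = np.where(mask, phi_u + psv_f * ci_u, 0.0)

        # backward-Euler 2x2 solve of the (interstitial, bound) pair with the
        # free-receptor concentration lagged; all internal transfer fluxes use
        # end-of-step values, so binding/unbinding/internalization conserve
        # moles exactly and the update is positivity-preserving
        a = params.k_on * r_free
        koi = params.k_off + params.k_int

        def local_pair(ci, cb, cn, gain, lam_loss, decay_gains):
            g_ci, g_cb, g_cn = decay_gains
            a11 = 1.0 + dt * (a + psv_f + params.psi_l + lam_loss)
            a12 = -dt * params.k_off
            a21 = -dt * a
            a22 = 1.0 + dt * (koi + lam_loss)
            b1 = ci + dt * (gain + g_ci)
            b2 = cb + dt * g_cb
            det = a11 * a22 - a12 * a21
            ci_n = (b1 * a22 - a12 * b2) / det
            cb_n = (a11 * b2 - a21 * b1) / det
            cn_n = (cn + dt * (params.k_int * cb_n + g_cn)) / (
                1.0 + dt * (params.lambda_deg + lam_loss))
            return ci_n, cb_n, cn_n

        ci_l_new, cb_l_new, cn_l_new = local_pair(
            ci_l, cb_l, cn_l, gain_l, lam, (0.0, 0.0, 0.0))
        ci_u_new, cb_u_new, cn_u_new = local_pair(
            ci_u, cb_u, cn_u, gain_u, 0.0,
            (lam * ci_l_new, lam * cb_l_new, lam * cn_l_new))

        # --- convection (explicit upwind) --------------------------------
        ci_l_new = ci_l_new + dt * _upwind_div(ci_l_new, vx, vy, h, mask)
        ci_u_new = ci_u_new + dt * _upwind_div(ci_u_new, vx, vy, h, mask)

        # --- diffusion (implicit) ----------------------------------------
        ci_l_new[mask] = diff_solve(ci_l_new[mask])
        ci_u_new[mask] = diff_solve(ci_u_new[mask])

        fields["C_int_l"], fields["C_int_u"] = ci_l_new, ci_u_new
        fields["C_bound_l"], fields["C_bound_u"] = cb_l_new, cb_u_new
        fields["C_intern_l"], fields["C_intern_u"] = cn_l_new, cn_u_new

        if not np.isfinite(ci_l_new[mask]).all():
            raise TransportInstabilityError(
                f"non-finite field at t={step * dt:.0f} min; reduce dt or refine grid")

        if step % record_every == 0 or step == n_steps:
            rec_t.append(step * dt)
            for name in TumorFields.FIELDS:
                means[name].append(float(fields[name][mask].mean()))
        if step in snap_steps:
            snap_t.append(snap_steps[step])
            for name in TumorFields.FIELDS:
                snaps[name].append(fields[name].copy())

    return TumorFields(
        grid=grid, tumor_mask=mask,
        snapshot_times=np.array(snap_t),
        snapshots={k: np.array(v) if v else np.zeros((0, grid.ny, grid.nx))
                   for k, v in snaps.items()},
        series_t=np.array(rec_t),
        mean_series={k: np.array(v) for k, v in means.items()},
        params=params,
    )


def well_mixed_reference(params: CDRParameters, cv_series, *, sv: float,
                         psi_b: float = 0.0, t_end: float = 30000.0,
                         rtol: float = 1e-9):
    """Single-compartment ODE twin of the transport model (uniform fields,
    no convection/diffusion); the homogeneous-vasculature limit against
    which the PDE solution is validated."""
    from scipy.integrate import solve_ivp

    t_cv, cv_l_s, cv_u_s = cv_series
    lam = params.lambda_phy
    sva = np.array([sv])
    psa = np.array([psi_b])

    def rhs(t, y):
        ci_l, ci_u, cb_l, cb_u, cn_l, cn_u = y
        r_free = max(params.R - cb_l - cb_u, 0.0)
        cv_l = np.interp(t, t_cv, cv_l_s)
        cv_u = np.interp(t, t_cv, cv_u_s)
        phi_l = float(transvascular_source(cv_l, ci_l, psa, sva, params)[0])
        phi_u = float(transvascular_source(cv_u, ci_u, psa, sva, params)[0])
        bind_l = params.k_on * r_free * ci_l
        bind_u = params.k_on * r_free * ci_u
        d_ci_l = phi_l + params.k_off * cb_l - bind_l - lam * ci_l - params.psi_l * ci_l
        d_ci_u = phi_u + params.k_off * cb_u - bind_u + lam * ci_l - params.psi_l * ci_u
        d_cb_l = bind_l - (params.k_off + params.k_int + lam) * cb_l
        d_cb_u = bind_u - (params.k_off + params.k_int) * cb_u + lam * cb_l
        d_cn_l = params.k_int * cb_l - (params.lambda_deg + lam) * cn_l
        d_cn_u = params.k_int * cb_u - params.lambda_deg * cn_u + lam * cn_l
        return [d_ci_l, d_ci_u, d_cb_l, d_cb_u, d_cn_l, d_cn_u]

    t_eval = np.linspace(0.0, t_end, 601)
    sol = solve_ivp(rhs, (0.0, t_end), np.zeros(6), t_eval=t_eval,
                    method="LSODA", rtol=rtol, atol=1e-14)
    return sol.t, dict(zip(
        ("C_int_l", "C_int_u", "C_bound_l", "C_bound_u", "C_intern_l", "C_intern_u"),
        sol.y))
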