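"""Steady-state coupled intravascular / interstitial fluid flow.

The microvessel network carries Poiseuille flow between Dirichlet pressure
boundary conditions on the parent vessels; its leaky walls exchange plasma
with the interstitium at the Starling filtration velocity

    v_t = Lp * (P_B - P_i - sigma * (pi_b - pi_i)),

and the interstitium is a Darcy porous medium,

    v_i = -kappa * grad(P_i),      div(v_i) = Psi_B - Psi_L,

solved on the lattice grid with a 5-point stencil.  The two solves are
iterated to a fixed point: network pressures -> wall leak -> distributed
source on the grid -> interstitial pressure -> updated extravascular pressure
felt by each vessel segment.

All pressures are in Pa internally (mmHg at the API edges where stated);
kappa is the interstitial hydraulic conductivity in m^2/(Pa s) (tissue
permeability over interstitial-fluid viscosity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import factorized

from .angiogenesis import LatticeGrid, VascularNetwork
from .units import PA_PER_MMHG

__all__ = ["FlowParameters", "PressureSolution", "starling_velocity",
           "solve_network_flow", "solve_interstitial_pressure", "couple"]


class FlowSolveError(RuntimeError):
    pass


@dataclass
class FlowParameters:
    Lp: float = 2.7e-12          # capillary-wall hydraulic conductivity (m/(Pa s))
    sigma: float = 0.82          # osmotic reflection coefficient
    pi_b: float = 2666.0         # blood osmotic pressure (Pa)
    pi_i: float = 2000.0         # interstitial osmotic pressure (Pa)
    kappa: float = 6.4e-14       # interstitial hydraulic conductivity (m^2/(Pa s))
    mu: float = 3e-3             # blood viscosity (Pa s)
    p_inlet_mmhg: float = 25.0   # parent-vessel boundary pressures
    p_outlet_mmhg: float = 10.0
    lymph_coef_host: float = 0.0  # lymphatic sink coefficient in host (1/(Pa s)); 0 in tumor
    leaky_parents: bool = False  # parent vessels exchange with tissue if True
    boundary: str = "neumann"    # outer interstitial BC: "neumann" (no flux,
                                 # closed lymph-free domain) or "dirichlet0"

    @property
    def p_inlet(self) -> float:
        return self.p_inlet_mmhg * PA_PER_MMHG

    @property
    def p_outlet(self) -> float:
        return self.p_outlet_mmhg * PA_PER_MMHG

    @property
    def osmotic_jump(self) -> float:
        return self.sigma * (self.pi_b - self.pi_i)


def starling_velocity(P_B, P_i, params: FlowParameters):
    """Transvascular filtration velocity (m/s); negative = reabsorption."""
    return params.Lp * (np.asarray(P_B) - np.asarray(P_i) - params.osmotic_jump)


@dataclass
class PressureSolution:
    """Converged coupled pressure/velocity fields."""

    net: VascularNetwork
    grid: LatticeGrid
    params: FlowParameters
    node_ij: np.ndarray          # (n, 2) lattice node of each network node
    node_pressure: np.ndarray    # IVP per node (Pa)
    ifp: np.ndarray              # (ny, nx) interstitial pressure (Pa)
    v_i: np.ndarray              # (2, ny, nx) interstitial velocity (m/s)
    v_t: np.ndarray              # per-segment transvascular velocity (m/s)
    psi_b: np.ndarray            # (ny, nx) transvascular volumetric source (1/s)
    segment_flow: np.ndarray     # per-segment axial flow (m^3/s)
    node_leak: np.ndarray | None = None    # transvascular leak per node (m^3/s)
    node_fixed: np.ndarray | None = None   # Dirichlet (parent) node mask
    iterations: int = 0
    residuals: list = field(default_factory=list)

    def flux_audit(self) -> dict:
        """Global balance: flow crossing from the pressure-boundary (parent)
        nodes into the free network must equal the total transvascular leak
        at the free nodes; returns both sides and the relative defect."""
        if self.node_leak is None or self.node_fixed is None:
            raise FlowSolveError("solution carries no leak bookkeeping")
        key = {tuple(n): k for k, n in enumerate(self.node_ij)}
        a_idx = np.array([key[tuple(s[0])] for s in self.net.segments])
        b_idx = np.array([key[tuple(s[1])] for s in self.net.segments])
        fixed = self.node_fixed
        cross = fixed[a_idx] != fixed[b_idx]
        # positive = into the free set
        into_free = np.where(fixed[a_idx[cross]], self.segment_flow[cross],
                             -self.segment_flow[cross]).sum()
        free_leak = self.node_leak[~fixed].sum()
        scale = max(abs(into_free), abs(free_leak),
                    np.abs(self.segment_flow).max(), 1e-300)
        return {"boundary_inflow": float(into_free),
                "total_free_leak": float(free_leak),
                "relative_defect": float(abs(into_free - free_leak) / scale)}

    def mean_tumor_ivp_mmhg(self) -> float:
        """Mean intravascular pressure over capillary nodes inside the tumor."""
        r = self.grid.radius_map()
        cap_nodes = self._capillary_node_mask()
        inside = r[self.node_ij[:, 1], self.node_ij[:, 0]] <= self.grid.tumor_radius
        sel = cap_nodes & inside
        if not sel.any():
            raise FlowSolveError("no capillary nodes inside the tumor")
        return float(self.node_pressure[sel].mean() / PA_PER_MMHG)

    def mean_tumor_ifp_mmhg(self) -> float:
        """Spatial mean interstitial pressure over the tumor mask."""
        m = self.grid.tumor_mask()
        return float(self.ifp[m].mean() / PA_PER_MMHG)

    def _capillary_node_mask(self) -> np.ndarray:
        cap = self.net.kinds == "capillary"
        cap_nodes = set(map(tuple, self.net.segments[cap].reshape(-1, 2)))
        return np.array([tuple(n) in cap_nodes for n in self.node_ij])


def _network_system(net: VascularNetwork, params: FlowParameters):
    """Node indexing, Poiseuille Laplacian, per-node leak conductance and
    Dirichlet structure for a network.  Leak conductance lumps half of each
    incident leaky segment's wall area (Lp * pi * d * h/2) at each endpoint."""
    nodes = net.nodes()
    key = {tuple(n): k for k, n in enumerate(nodes)}
    n = len(nodes)
    a_idx = np.array([key[tuple(s[0])] for s in net.segments])
    b_idx = np.array([key[tuple(s[1])] for s in net.segments])
    L = net.grid.h
    g = np.pi * net.diameters ** 4 / (128.0 * params.mu * L)

    G = sp.coo_matrix(
        (np.concatenate([g, g, -g, -g]),
         (np.concatenate([a_idx, b_idx, a_idx, b_idx]),
          np.concatenate([a_idx, b_idx, b_idx, a_idx]))),
        shape=(n, n)).tocsr()

    leaky = np.ones(len(net.segments), dtype=bool)
    if not params.leaky_parents:
        leaky = net.kinds == "capillary"
    kl = np.zeros(n)
    wall = params.Lp * np.pi * net.diameters * L / 2.0
    np.add.at(kl, a_idx[leaky], wall[leaky])
    np.add.at(kl, b_idx[leaky], wall[leaky])

    fixed = np.zeros(n, dtype=bool)
    p_fix = np.zeros(n)
    for ij in net.inlet_nodes:
        if tuple(ij) in key:
            fixed[key[tuple(ij)]] = True
            p_fix[key[tuple(ij)]] = params.p_inlet
    for ij in net.outlet_nodes:
        if tuple(ij) in key:
            fixed[key[tuple(ij)]] = True
            p_fix[key[tuple(ij)]] = params.p_outlet
    if not fixed.any():
        raise FlowSolveError("no inlet/outlet nodes present in the network")

    # every connected component must touch a Dirichlet node
    ncomp, labels = connected_components(sp.csr_matrix(
        (np.ones(len(a_idx)), (a_idx, b_idx)), shape=(n, n)), directed=False)
    for comp in range(ncomp):
        if not fixed[labels == comp].any():
            raise FlowSolveError(
                f"network component {comp} ({np.sum(labels == comp)} nodes) "
                "is not connected to any pressure boundary")
    return nodes, key, a_idx, b_idx, g, G, kl, fixed, p_fix


class _NodalSolver:
    """Factorized solver of the nodal conservation system with Dirichlet
    nodes eliminated; reusable across coupling iterations."""

    def __init__(self, G, kl, fixed, p_fix, params: FlowParameters):
        A = (G + sp.diags(kl)).tocsr()
        free = ~fixed
        self.free = free
        self.kl = kl
        self.p_fix = p_fix
        self.osm = params.osmotic_jump
        self.solve = factorized(A[free][:, free].tocsc())
        self.a_fd_pd = A[free][:, fixed] @ p_fix[fixed]

    def __call__(self, ifp_nodes: np.ndarray) -> np.ndarray:
        b = (self.kl * (ifp_nodes + self.osm))[self.free] - self.a_fd_pd
        p = self.p_fix.copy()
        p[self.free] = self.solve(b)
        return p


def solve_network_flow(net: VascularNetwork, ifp_at_nodes, params: FlowParameters):
    """Nodal pressures (Pa) and segment flows (m^3/s) with distributed
    Starling leak against the given extravascular pressure (scalar or
    per-node array)."""
    nodes, _, a_idx, b_idx, g, G, kl, fixed, p_fix = _network_system(net, params)
    solver = _NodalSolver(G, kl, fixed, p_fix, params)
    p = solver(np.broadcast_to(np.asarray(ifp_at_nodes, dtype=float),
                               (len(nodes),)).astype(float))
    q = g * (p[a_idx] - p[b_idx])
    return nodes, p, q


def _grid_operator(grid: LatticeGrid, kappa: float, sink_coef: np.ndarray,
                   boundary: str):
    """Sparse operator of -kappa * lap(P) + sink_coef * P with a 5-point
    stencil.  "dirichlet0": homogeneous Dirichlet, unknowns are interior
    cells.  "neumann": no-flux walls, every cell is an unknown (missing
    neighbours dropped)."""
    nx, ny = grid.nx, grid.ny
    h2 = grid.h ** 2
    idx = -np.ones((ny, nx), dtype=int)
    interior = np.zeros((ny, nx), dtype=bool)
    if boundary == "dirichlet0":
        interior[1:-1, 1:-1] = True
    elif boundary == "neumann":
        interior[:, :] = True
    else:
        raise ValueError(f"unknown boundary condition {boundary!r}")
    n_int = int(interior.sum())
    idx[interior] = np.arange(n_int)
    rows, cols, vals = [], [], []
    jj, ii = np.nonzero(interior)
    center = idx[jj, ii]
    diag = sink_coef[jj, ii].astype(float).copy()
    for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        nj, ni = jj + dj, ii + di
        inside = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < ny)
        if boundary == "dirichlet0":
            # a neighbour outside the unknown set but inside the domain is a
            # boundary cell with P = 0: it still contributes to the diagonal
            diag += np.where(inside, kappa / h2, 0.0)
            nb = np.where(inside, idx[nj % ny, ni % nx], -1)
            m = nb >= 0
        else:
            diag += np.where(inside, kappa / h2, 0.0)
            nb = np.where(inside, idx[nj % ny, ni % nx], -1)
            m = nb >= 0
        rows.append(center[m])
        cols.append(nb[m])
        vals.append(np.full(int(m.sum()), -kappa / h2))
    rows.append(center)
    cols.append(center)
    vals.append(diag)
    A = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n_int, n_int)).tocsc()
    return A, idx, interior


def solve_interstitial_pressure(grid: LatticeGrid, psi_b: np.ndarray,
                                params: FlowParameters, *,
                                psi_l_coef: np.ndarray | None = None,
                                solver_cache: dict | None = None):
    """Solve -kappa lap(P_i) + L_s P_i = Psi_B on the grid (Dirichlet P_i = 0
    at the domain boundary); returns (P_i, v_i).

    ``psi_b`` is the transvascular volumetric source in 1/s; ``psi_l_coef``
    an optional linear lymphatic-sink coefficient field (1/(Pa s)).
    """
    psi_b = np.asarray(psi_b, dtype=float)
    if psi_b.shape != (grid.ny, grid.nx):
        raise ValueError("source field shape does not match grid")
    if not np.all(np.isfinite(psi_b)):
        raise ValueError("source field must be finite")
    sink = np.zeros_like(psi_b) if psi_l_coef is None else np.asarray(psi_l_coef)

    cache_key = ("ifp", grid.nx, grid.ny, grid.h, params.kappa,
                 params.boundary, sink.tobytes())
    if solver_cache is not None and cache_key in solver_cache:
        solve, idx, interior = solver_cache[cache_key]
    else:
        A, idx, interior = _grid_operator(grid, params.kappa, sink, params.boundary)
        if params.boundary == "neumann" and not np.any(sink > 0):
            # singular up to a constant: check compatibility, pin the gauge
            A = A.tolil()
            A[0, :] = 0.0
            A[0, 0] = 1.0
            A = A.tocsc()
        solve = factorized(A)
        if solver_cache is not None:
            solver_cache[cache_key] = (solve, idx, interior)

    b = psi_b[interior]
    if params.boundary == "neumann" and not np.any(sink > 0):
        total = float(b.sum())
        if abs(total) > 1e-10 * max(np.abs(b).sum(), 1e-300):
            raise FlowSolveError(
                "all-Neumann interstitial problem with nonzero net source is ill-posed")
        b = b.copy()
        b[0] = 0.0
    P = np.zeros((grid.ny, grid.nx))
    P[interior] = solve(b)
    if params.boundary == "neumann" and not np.any(sink > 0):
        P -= P.mean()
    v = np.zeros((2, grid.ny, grid.nx))
    v[0, :, 1:-1] = -params.kappa * (P[:, 2:] - P[:, :-2]) / (2 * grid.h)
    v[1, 1:-1, :] = -params.kappa * (P[2:, :] - P[:-2, :]) / (2 * grid.h)
    return P, v


def couple(net: VascularNetwork, grid: LatticeGrid | None = None,
           params: FlowParameters | None = None, *, tol: float = 1e-6,
           max_iter: int = 200) -> PressureSolution:
    """Steady coupled vascular/interstitial pressure solve.

    The coupled problem is linear, so the network nodal-conservation
    equations and the discrete Darcy equations are assembled into a single
    sparse system (network pressures stacked on interior grid pressures) and
    solved directly; the reported residual is the verified fixed-point defect
    of the separate vascular and interstitial solves, which must be below
    ``tol``.
    """
    grid = grid or net.grid
    params = params or FlowParameters()
    nodes, key, a_idx, b_idx, g, G, kl, fixed, p_fix = _network_system(net, params)

    r = grid.radius_map()
    sink = np.where(r <= grid.tumor_radius, 0.0, params.lymph_coef_host)
    A_grid, idx, interior = _grid_operator(grid, params.kappa, sink, params.boundary)
    n_int = A_grid.shape[0]
    vol = grid.cell_volume
    ni, nj = nodes[:, 0], nodes[:, 1]
    cell_of_node = idx[nj, ni]           # -1 for nodes in boundary cells (IFP = 0)
    osm = params.osmotic_jump

    free = ~fixed
    nf = int(free.sum())
    fmap = -np.ones(len(nodes), dtype=int)
    fmap[free] = np.arange(nf)

    A_nn = (G + sp.diags(kl)).tocsr()[free][:, free]
    rhs_n = kl[free] * osm - (G + sp.diags(kl)).tocsr()[free][:, fixed] @ p_fix[fixed]

    # coupling blocks
    rows_nc, cols_nc, vals_nc = [], [], []      # network row <- grid unknown
    rows_cn, cols_cn, vals_cn = [], [], []      # grid row <- network unknown
    diag_extra = np.zeros(n_int)
    rhs_c = np.zeros(n_int)
    for k in range(len(nodes)):
        c = cell_of_node[k]
        if kl[k] == 0.0:
            continue
        w = kl[k] / vol
        if c >= 0:
            diag_extra[c] += w
            rhs_c[c] += -w * osm
            if free[k]:
                rows_cn.append(c)
                cols_cn.append(fmap[k])
                vals_cn.append(-w)
            else:
                rhs_c[c] += w * p_fix[k]
            if free[k]:
                rows_nc.append(fmap[k])
                cols_nc.append(c)
                vals_nc.append(-kl[k])
        # c < 0: leak against the Dirichlet-0 boundary cell, no grid coupling
    A_cn = sp.coo_matrix((vals_cn, (rows_cn, cols_cn)), shape=(n_int, nf))
    A_nc = sp.coo_matrix((vals_nc, (rows_nc, cols_nc)), shape=(nf, n_int))
    A_gg = (A_grid + sp.diags(diag_extra)).tocsc()
    if (params.boundary == "neumann" and diag_extra.max() == 0.0
            and not np.any(sink > 0)):
        # decoupled all-Neumann interstitium (e.g. Lp = 0): pin the gauge
        A_gg = A_gg.tolil()
        A_gg[0, :] = 0.0
        A_gg[0, 0] = 1.0
        A_gg = A_gg.tocsc()
    A = sp.bmat([[A_nn, A_nc],
                 [A_cn, A_gg]], format="csc")
    x = sp.linalg.spsolve(A, np.concatenate([rhs_n, rhs_c]))

    p = p_fix.copy()
    p[free] = x[:nf]
    ifp = np.zeros((grid.ny, grid.nx))
    ifp[interior] = x[nf:]

    # algebraic residual of the assembled coupled system
    rhs = np.concatenate([rhs_n, rhs_c])
    scale = max(np.abs(rhs).max(), 1e-300)
    res = float(np.abs(A @ x - rhs).max() / scale)
    residuals = [res]
    it = 1
    if res > max(tol, 1e-8):
        raise FlowSolveError(f"coupled solve residual {res:.3e} exceeds tolerance")

    ifp_nodes = np.where(cell_of_node >= 0, ifp[nj, ni], 0.0)
    leak = kl * (p - ifp_nodes - osm)
    psi_b = np.zeros_like(ifp)
    np.add.at(psi_b, (nj, ni), leak / vol)
    v_i = np.zeros((2, grid.ny, grid.nx))
    v_i[0, :, 1:-1] = -params.kappa * (ifp[:, 2:] - ifp[:, :-2]) / (2 * grid.h)
    v_i[1, 1:-1, :] = -params.kappa * (ifp[2:, :] - ifp[:-2, :]) / (2 * grid.h)

    seg_mid_p = 0.5 * (p[a_idx] + p[b_idx])
    seg_ifp = 0.5 * (ifp[nodes[a_idx, 1], nodes[a_idx, 0]]
                     + ifp[nodes[b_idx, 1], nodes[b_idx, 0]])
    v_t = starling_velocity(seg_mid_p, seg_ifp, params)
    q = g * (p[a_idx] - p[b_idx])
    return PressureSolution(net=net, grid=grid, params=params, node_ij=nodes,
                            node_pressure=p, ifp=ifp, v_i=v_i, v_t=v_t,
                            psi_b=psi_b, segment_flow=q, node_leak=leak,
                            node_fixed=fixed, iterations=it,
                            residuals=residuals)
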