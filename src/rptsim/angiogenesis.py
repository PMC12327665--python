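"""Stochastic tumor-induced angiogenesis on a 2D lattice.

Capillary sprouts grow from two parent vessels on opposite domain edges by a
biased random walk of tip endothelial cells, following the classic sprouting
model of Anderson & Chaplain: at every step a tip either stays put (P0) or
moves to one of its four lattice neighbours (P1..P4), with the move weights
biased up the gradient of a tumor angiogenic factor (TAF) field.  Branching
spawns new tips with a probability increasing with local TAF; a tip stepping
onto a node already occupied by vasculature fuses with it (anastomosis) and
is retired, closing a loop.  The network is held static afterwards - the
vasculature is assumed frozen over the treatment window.

Capillaries are 20 um in diameter, the parent vessels 400 um; the default
domain holds a 16 mm tumor plus a 2 mm host margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["LatticeGrid", "TAFField", "VascularNetwork", "GrowthParams",
           "make_taf_field", "tip_move_probabilities", "grow_network",
           "network_stats", "save_network", "load_network"]


@dataclass(frozen=True)
class LatticeGrid:
    """Regular node lattice; node (i, j) sits at origin + (i*h, j*h) (metres).

    i indexes x (column), j indexes y (row).  Grid cells used for field
    quantities are centred on the nodes, with volume h^2 * depth (unit depth
    of one cell, depth = h).
    """

    nx: int = 201
    ny: int = 201
    h: float = 100e-6                # lattice spacing (m)
    origin: tuple[float, float] = (0.0, 0.0)
    tumor_center: tuple[float, float] | None = None  # default: domain centre
    tumor_radius: float = 8e-3       # m (16 mm diameter tumor)
    margin: float = 2e-3             # host-tissue shell width (m)

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("lattice spacing must be > 0")
        if self.tumor_center is None:
            object.__setattr__(self, "tumor_center",
                               ((self.nx - 1) / 2 * self.h + self.origin[0],
                                (self.ny - 1) / 2 * self.h + self.origin[1]))
        lx, ly = (self.nx - 1) * self.h, (self.ny - 1) * self.h
        cx, cy = self.tumor_center
        r = self.tumor_radius
        if (cx - r < self.origin[0] - 1e-12 or cx + r > self.origin[0] + lx + 1e-12
                or cy - r < self.origin[1] - 1e-12 or cy + r > self.origin[1] + ly + 1e-12):
            raise ValueError("tumor does not fit inside the domain")

    @property
    def depth(self) -> float:
        return self.h

    @property
    def cell_volume(self) -> float:
        return self.h * self.h * self.depth

    def node_xy(self, i, j):
        return (self.origin[0] + np.asarray(i) * self.h,
                self.origin[1] + np.asarray(j) * self.h)

    def radius_map(self) -> np.ndarray:
        """(ny, nx) array of node distances to the tumor centre."""
        x, y = np.meshgrid(np.arange(self.nx), np.arange(self.ny))
        px, py = self.node_xy(x, y)
        return np.hypot(px - self.tumor_center[0], py - self.tumor_center[1])

    def tumor_mask(self) -> np.ndarray:
        return self.radius_map() <= self.tumor_radius

    def shell_mask(self) -> np.ndarray:
        """2 mm-wide host shell just outside the tumor (emission range)."""
        r = self.radius_map()
        return (r > self.tumor_radius) & (r <= self.tumor_radius + self.margin)


@dataclass
class TAFField:
    """Normalized tumor-angiogenic-factor concentration on the lattice, (ny, nx)."""

    grid: LatticeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("TAF field shape does not match grid")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("TAF values must lie in [0, 1]")


def make_taf_field(grid: LatticeGrid, *, length_scale: float = 8e-3,
                   profile: str = "gaussian") -> TAFField:
    """Static radial TAF profile: 1 at the tumor centre, decaying outward.

    ``profile`` is "gaussian" (exp(-(r/L)^2)), "exponential" (exp(-r/L)) or
    "constant" (uniform 1, zero gradient everywhere).
    """
    r = grid.radius_map()
    if profile == "gaussian":
        v = np.exp(-((r / length_scale) ** 2))
    elif profile == "exponential":
        v = np.exp(-r / length_scale)
    elif profile == "constant":
        v = np.ones_like(r)
    else:
        raise ValueError(f"unknown TAF profile {profile!r}")
    return TAFField(grid=grid, values=v)


#: neighbour offsets in P1..P4 order: right, up, left, down
_MOVES = np.array([(1, 0), (0, 1), (-1, 0), (0, -1)])


def tip_move_probabilities(taf: TAFField, i: int, j: int, *,
                           chemotaxis: float = 150.0,
                           motility: float = 1.0,
                           stay_weight: float = 1.0,
                           forbidden: set[tuple[int, int]] | None = None):
    """Five-state weights (P0, P1..P4) for a tip at node (i, j).

    The directional weight toward neighbour d is
    ``motility + chemotaxis * (c_d - c_0)`` clipped at zero, the discrete
    chemotactic bias of the Anderson-Chaplain walk; out-of-domain (and
    explicitly forbidden) neighbours get weight 0.  Weights are normalized to
    probabilities.
    """
    g = taf.grid
    c0 = taf.values[j, i]
    w = np.zeros(5)
    w[0] = max(stay_weight, 0.0)
    for k, (di, dj) in enumerate(_MOVES):
        ni, nj = i + di, j + dj
        if not (0 <= ni < g.nx and 0 <= nj < g.ny):
            continue
        if forbidden and (ni, nj) in forbidden:
            continue
        w[k + 1] = max(motility + chemotaxis * (taf.values[nj, ni] - c0), 0.0)
    s = w.sum()
    if s <= 0:
        raise ValueError(f"tip at ({i}, {j}) has no admissible state")
    return w / s


@dataclass
class GrowthParams:
    """Knobs of the tip-cell walk; defaults give a 30-day growth at 24
    steps/day with ten sprouts per parent vessel."""

    n_tips_per_parent: int = 15
    days: float = 30.0
    steps_per_day: int = 24
    chemotaxis: float = 150.0
    motility: float = 1.0
    stay_weight: float = 1.0
    branch_prob_coef: float = 0.2    # per-step branch probability = coef * TAF
    branch_min_age: int = 5          # steps before a tip may branch
    anastomosis_min_age: int = 2     # steps before fusing is allowed
    max_tips: int = 5000
    capillary_diameter: float = 20e-6
    parent_diameter: float = 400e-6

    @property
    def steps(self) -> int:
        return int(round(self.days * self.steps_per_day))


@dataclass
class VascularNetwork:
    """Lattice microvessel network.

    ``segments`` is an (m, 2, 2) int array of ((i1, j1), (i2, j2)) node
    pairs between lattice neighbours; ``diameters`` (m,) in metres;
    ``kinds`` (m,) of {"parent", "capillary"}.
    """

    grid: LatticeGrid
    segments: np.ndarray
    diameters: np.ndarray
    kinds: np.ndarray
    inlet_nodes: list[tuple[int, int]]
    outlet_nodes: list[tuple[int, int]]
    meta: dict = field(default_factory=dict)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def nodes(self) -> np.ndarray:
        """Unique (i, j) node array."""
        return np.unique(self.segments.reshape(-1, 2), axis=0)

    def validate(self) -> None:
        d = np.abs(self.segments[:, 0] - self.segments[:, 1]).sum(axis=1)
        if not np.all(d == 1):
            raise ValueError("segments must connect lattice neighbours")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be > 0")
        key = self._segment_keys()
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate segments present")

    def _segment_keys(self) -> np.ndarray:
        a = self.segments[:, 0, 0] + self.segments[:, 0, 1] * self.grid.nx
        b = self.segments[:, 1, 0] + self.segments[:, 1, 1] * self.grid.nx
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        return lo * (self.grid.nx * self.grid.ny) + hi

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for (a, b), d, k in zip(self.segments, self.diameters, self.kinds):
            g.add_edge(tuple(a), tuple(b), diameter=float(d), kind=str(k),
                       length=self.grid.h)
        return g


def _parent_vessel_nodes(grid: LatticeGrid) -> tuple[list, list]:
    """Two parent vessels running along the left and right domain edges."""
    left = [(0, j) for j in range(grid.ny)]
    right = [(grid.nx - 1, j) for j in range(grid.ny)]
    return left, right


def grow_network(grid: LatticeGrid, taf: TAFField,
                 params: GrowthParams | None = None, *,
                 seed: int = 0) -> VascularNetwork:
    """Grow the capillary network from the two parent vessels.

    Tips are updated in fixed index order within a step; the walk is fully
    reproducible for a given seed.
    """
    params = params or GrowthParams()
    rng = np.random.default_rng(seed)
    left, right = _parent_vessel_nodes(grid)

    occupied = np.zeros((grid.ny, grid.nx), dtype=bool)
    for i, j in left + right:
        occupied[j, i] = True

    segments: list[tuple[tuple[int, int], tuple[int, int]]] = []
    seg_set: set[frozenset] = set()
    diameters: list[float] = []
    kinds: list[str] = []

    def add_segment(a, b, diameter, kind):
        key = frozenset((a, b))
        if key in seg_set:
            return
        seg_set.add(key)
        segments.append((a, b))
        diameters.append(diameter)
        kinds.append(kind)

    for chain in (left, right):
        for a, b in zip(chain[:-1], chain[1:]):
            add_segment(a, b, params.parent_diameter, "parent")

    # initial sprout positions, evenly spaced along each parent
    tips: list[dict] = []
    for chain, direction in ((left, 1), (right, -1)):
        js = np.linspace(0, grid.ny - 1, params.n_tips_per_parent + 2)[1:-1]
        for j in np.round(js).astype(int):
            i = chain[0][0]
            tips.append(dict(pos=(i, int(j)), prev=None, age=0, alive=True))

    n_branch = 0
    n_anastomosis = 0
    c = taf.values
    for _ in range(params.steps):
        new_tips = []
        for tip in tips:
            if not tip["alive"]:
                continue
            i, j = tip["pos"]
            tip["age"] += 1
            # movement
            w = np.zeros(5)
            w[0] = params.stay_weight
            c0 = c[j, i]
            for k, (di, dj) in enumerate(_MOVES):
                ni, nj = i + di, j + dj
                if not (0 <= ni < grid.nx and 0 <= nj < grid.ny):
                    continue
                if tip["prev"] == (ni, nj):
                    continue
                w[k + 1] = max(params.motility + params.chemotaxis * (c[nj, ni] - c0), 0.0)
            s = w.sum()
            if s <= 0:
                tip["alive"] = False
                continue
            choice = rng.choice(5, p=w / s)
            if choice == 0:
                pass
            else:
                di, dj = _MOVES[choice - 1]
                ni, nj = i + di, j + dj
                add_segment((i, j), (ni, nj), params.capillary_diameter, "capillary")
                if occupied[nj, ni] and tip["age"] >= params.anastomosis_min_age:
                    n_anastomosis += 1
                    tip["alive"] = False
                occupied[nj, ni] = True
                tip["prev"] = (i, j)
                tip["pos"] = (ni, nj)
            # branching
            if (tip["alive"] and tip["age"] >= params.branch_min_age
                    and len(tips) + len(new_tips) < params.max_tips):
                pb = min(params.branch_prob_coef * c[tip["pos"][1], tip["pos"][0]], 1.0)
                if rng.random() < pb:
                    n_branch += 1
                    new_tips.append(dict(pos=tip["pos"], prev=tip["prev"],
                                         age=0, alive=True))
        tips.extend(new_tips)
        if not any(t["alive"] for t in tips):
            break

    seg_arr = (np.array([(a, b) for a, b in segments], dtype=int)
               if segments else np.zeros((0, 2, 2), dtype=int))
    net = VascularNetwork(
        grid=grid,
        segments=seg_arr,
        diameters=np.array(diameters),
        kinds=np.array(kinds, dtype=object),
        inlet_nodes=list(left),
        outlet_nodes=list(right),
        meta=dict(seed=seed, steps=params.steps, branch_count=n_branch,
                  anastomosis_count=n_anastomosis),
    )
    net.validate()
    return net


def network_stats(net: VascularNetwork, grid: LatticeGrid | None = None) -> dict:
    """Region summaries and the per-cell surface-area-per-volume field.

    S/V of a cell = sum over capillary half-segments lumped at their endpoint
    nodes of pi * d * (h/2), divided by the cell volume (a lattice-edge
    segment's midpoint lies exactly on the face between its endpoint cells,
    so the half-half split is the midpoint rule).  Parent vessels are
    excluded from the tissue S/V (they are conduits, not exchange vessels).
    """
    grid = grid or net.grid
    sv = np.zeros((grid.ny, grid.nx))
    cap = net.kinds == "capillary"
    vol = grid.cell_volume
    for (a, b), d in zip(net.segments[cap], net.diameters[cap]):
        area_half = np.pi * d * grid.h / 2.0
        sv[a[1], a[0]] += area_half / vol
        sv[b[1], b[0]] += area_half / vol
    tumor = grid.tumor_mask()
    cap_len = np.zeros((grid.ny, grid.nx))
    for (a, b) in net.segments[cap]:
        cap_len[a[1], a[0]] += grid.h / 2
        cap_len[b[1], b[0]] += grid.h / 2
    area = grid.h * grid.h
    density_in = cap_len[tumor].sum() / (tumor.sum() * area)
    density_out = cap_len[~tumor].sum() / ((~tumor).sum() * area)
    return {
        "sv_field": sv,
        "length_density_tumor": density_in,     # m per m^2 (unit depth)
        "length_density_host": density_out,
        "branch_count": net.meta.get("branch_count", 0),
        "loop_count": net.meta.get("anastomosis_count", 0),
        "n_capillary_segments": int(cap.sum()),
    }


def save_network(net: VascularNetwork, path: str | Path) -> None:
    """GraphML (.graphml) or edge-list CSV export."""
    path = Path(path)
    if path.suffix == ".graphml":
        import networkx as nx

        g = net.to_networkx()
        g.graph.update({k: str(v) for k, v in net.meta.items()})
        nx.write_graphml(nx.relabel_nodes(g, lambda n: f"{n[0]},{n[1]}"), path)
    else:
        import pandas as pd

        rows = []
        for (a, b), d, k in zip(net.segments, net.diameters, net.kinds):
            x1, y1 = net.grid.node_xy(*a)
            x2, y2 = net.grid.node_xy(*b)
            rows.append((x1 * 1e6, y1 * 1e6, x2 * 1e6, y2 * 1e6, d * 1e6, k))
        pd.DataFrame(rows, columns=["x1_um", "y1_um", "x2_um", "y2_um",
                                    "diameter_um", "kind"]).to_csv(path, index=False)


def load_network(path: str | Path, grid: LatticeGrid) -> VascularNetwork:
    """Read an edge-list CSV written by :func:`save_network`."""
    import pandas as pd

    df = pd.read_csv(path)
    segs, dias, kinds = [], [], []
    for _, r in df.iterrows():
        a = (round((r.x1_um * 1e-6 - grid.origin[0]) / grid.h),
             round((r.y1_um * 1e-6 - grid.origin[1]) / grid.h))
        b = (round((r.x2_um * 1e-6 - grid.origin[0]) / grid.h),
             round((r.y2_um * 1e-6 - grid.origin[1]) / grid.h))
        segs.append((a, b))
        dias.append(r.diameter_um * 1e-6)
        kinds.append(r.kind)
    left, right = _parent_vessel_nodes(grid)
    net = VascularNetwork(grid=grid, segments=np.array(segs, dtype=int),
                          diameters=np.array(dias),
                          kinds=np.array(kinds, dtype=object),
                          inlet_nodes=left, outlet_nodes=right)
    net.validate()
    return net
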