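"""Hybrid tissue simulator: a diffusing Hh field coupled to cell ODEs.

The tissue is a hexagonal array of cells (default 10x10) whose centers
sit on a triangular lattice with nearest-neighbour spacing equal to the
cell diameter; each cell is the Voronoi hexagon of its center,
rasterized onto the finite-difference grid that carries the Hh field.
The Hh source is a production band, by default the lower boundary of
the field; it can translocate upward at constant speed to emulate the
morphogenetic furrow, with overrun cells set to differentiate (frozen
and no longer consuming Hh).

Each time step executes six sub-steps in order: (1) the field is
updated by source production and 2D diffusion (explicit Euler, 5-point
Laplacian, zero-flux boundaries); (2) each cell's Hh input is the mean
field value over its own nodes; (3) the intracellular rate equations
advance one Euler step; (4) the cell's net binding/unbinding exchange
with the field is computed; (5) that exchange, and free-Hh degradation,
are written back to the field nodes; (6) repeat.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .pathway import (
    PathwayParameters,
    basal_partition,
    hill_activation,
    sample_cell_parameters,
)

__all__ = [
    "HhField", "Tissue", "SourceDescriptor", "SimulationConfig",
    "SimulationTrace", "build_tissue", "diffusion_step", "apply_source",
    "step", "move_source", "run_simulation",
]

SQRT3 = np.sqrt(3.0)

STATE_NAMES = ("ptc", "hh_ptc", "smo", "smo_ptc", "cia")


class ConfigurationError(ValueError):
    """Geometry or stability constraint violated."""


class IntegratorError(RuntimeError):
    """The explicit update produced an invalid state."""


@dataclass
class HhField:
    """2D ligand concentration on a regular grid (row index = y)."""

    values: np.ndarray
    dx: float

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ConfigurationError("field must be 2D")
        if np.any(self.values < 0):
            raise ConfigurationError("field concentrations must be >= 0")

    @property
    def extent(self):
        ny, nx = self.values.shape
        return ((nx - 1) * self.dx, (ny - 1) * self.dx)

    @property
    def y_coords(self):
        return np.arange(self.values.shape[0]) * self.dx

    def copy(self):
        return HhField(self.values.copy(), self.dx)


@dataclass
class Tissue:
    """Cell geometry plus vectorized intracellular state."""

    centroids: np.ndarray          # (n, 2) cell centers, um
    node_to_cell: np.ndarray       # (ny, nx) int; -1 = outside tessellation
    cell_diameter: float
    nrows: int
    ncols: int
    cell_params: dict = dc_field(default_factory=dict)
    state: dict = dc_field(default_factory=dict)
    differentiated: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.centroids)

    @property
    def ptc_total(self) -> np.ndarray:
        """Total Ptc protein per cell: free + Hh-bound + Smo-bound."""
        return self.state["ptc"] + self.state["hh_ptc"] + self.state["smo_ptc"]

    def cell_average(self, field: HhField) -> np.ndarray:
        flat = self.node_to_cell.ravel()
        inside = flat >= 0
        sums = np.bincount(flat[inside], weights=field.values.ravel()[inside],
                           minlength=self.n_cells)
        return sums / self._node_counts

    @property
    def _node_counts(self) -> np.ndarray:
        if not hasattr(self, "_counts"):
            flat = self.node_to_cell.ravel()
            self._counts = np.bincount(flat[flat >= 0],
                                       minlength=self.n_cells).astype(float)
        return self._counts


@dataclass
class SourceDescriptor:
    """Location, extent, production level and motion of the Hh source.

    ``geometry``: "edge-band" (a band starting at the lower field edge,
    the default) or "interior-stripe" (a band centered at ``position``,
    producing symmetrically to both sides, as in ectopic-stripe
    experiments).  ``speed`` is in cell diameters per hour; 0 = static.
    """

    geometry: str = "edge-band"
    position: float = 0.0
    band_width: float = 5.0
    speed: float = 0.0
    alpha1: float = 20.0
    trailing: bool = False   # overrun region keeps secreting (off by default)

    def __post_init__(self):
        if self.geometry not in ("edge-band", "interior-stripe"):
            raise ConfigurationError(f"unknown source geometry {self.geometry!r}")
        if self.speed < 0 or self.band_width <= 0 or self.alpha1 < 0:
            raise ConfigurationError("speed, band_width, alpha1 must be valid")

    def band_interval(self, t: float, dx: float, cell_diameter: float):
        """Band [lo, hi) at time t; motion quantized to whole grid rows."""
        v = self.speed * cell_diameter / 60.0  # um/min
        shift = np.floor(v * t / dx) * dx
        if self.geometry == "edge-band":
            lo = self.position + shift
            return lo, lo + self.band_width
        center = self.position + shift
        return center - self.band_width / 2.0, center + self.band_width / 2.0

    def leading_edge(self, t: float, dx: float, cell_diameter: float) -> float:
        return self.band_interval(t, dx, cell_diameter)[1]


def build_tissue(nrows: int = 10, ncols: int = 10, cell_diameter: float = 5.0,
                 dx: float = 1.0, band_width: float = 5.0,
                 field_size: tuple | None = None):
    """Construct the hexagonal tissue and a zero Hh field.

    Cell centers lie on a triangular lattice (row pitch sqrt(3)/2 times
    the diameter, alternate rows offset by half a diameter), leaving a
    band of width ``band_width`` below the first row for the source.
    Grid nodes are assigned to the cell whose center is nearest,
    provided that distance is within the hexagon circumradius
    (diameter / sqrt(3)); other nodes belong to no cell.
    """
    if nrows < 1 or ncols < 1:
        raise ConfigurationError("nrows and ncols must be >= 1")
    if dx > cell_diameter / 2.0:
        raise ConfigurationError(
            f"dx={dx} too coarse for cell_diameter={cell_diameter}; "
            "need dx <= cell_diameter/2")
    d = cell_diameter
    ys = band_width + d / 2.0 + (SQRT3 / 2.0 * d) * np.arange(nrows)
    cx, cy = [], []
    for i in range(nrows):
        off = d / 2.0 if i % 2 else 0.0
        for j in range(ncols):
            cx.append(d / 2.0 + d * j + off)
            cy.append(ys[i])
    centroids = np.column_stack([cx, cy])

    if field_size is None:
        Lx = np.ceil((max(cx) + d / 2.0) / dx) * dx
        Ly = ys[-1] + d / 2.0 + dx  # margin of one node row above the top cells
        Ly = np.ceil(Ly / dx) * dx
    else:
        Lx, Ly = field_size
    nx = int(round(Lx / dx)) + 1
    ny = int(round(Ly / dx)) + 1
    gx, gy = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dx, indexing="xy")
    d2 = (gx[..., None] - centroids[:, 0]) ** 2 + (gy[..., None] - centroids[:, 1]) ** 2
    nearest = np.argmin(d2, axis=-1)
    dist = np.sqrt(np.take_along_axis(d2, nearest[..., None], -1)[..., 0])
    node_to_cell = np.where(dist <= d / SQRT3 + 1e-9, nearest, -1)

    tissue = Tissue(centroids=centroids, node_to_cell=node_to_cell,
                    cell_diameter=d, nrows=nrows, ncols=ncols,
                    differentiated=np.zeros(len(centroids), bool))
    return tissue, HhField(np.zeros((ny, nx)), dx)


def check_stability(D: float, dt: float, dx: float) -> None:
    number = D * dt / dx**2
    if number > 0.25:
        raise ConfigurationError(
            f"explicit diffusion unstable: D*dt/dx^2 = {number:.3f} > 0.25; "
            "reduce dt or refine dx")


def diffusion_step(field: HhField, D: float, dt: float) -> HhField:
    """One explicit Euler step of 2D diffusion, zero-flux boundaries."""
    check_stability(D, dt, field.dx)
    H = field.values
    Hp = np.pad(H, 1, mode="edge")
    lap = (Hp[:-2, 1:-1] + Hp[2:, 1:-1] + Hp[1:-1, :-2] + Hp[1:-1, 2:]
           - 4.0 * H)
    return HhField(H + (D * dt / field.dx**2) * lap, field.dx)


def apply_source(field: HhField, src: SourceDescriptor, dt: float,
                 t: float = 0.0, cell_diameter: float = 5.0) -> HhField:
    """Add alpha1*dt to every node in the source band (production term)."""
    lo, hi = src.band_interval(t, field.dx, cell_diameter)
    y = field.y_coords
    if hi <= y[0] or lo > y[-1]:
        raise ConfigurationError("source band lies outside the field")
    if src.trailing and src.geometry == "edge-band":
        mask = y < hi
    else:
        mask = (y >= lo) & (y < hi)
    values = field.values.copy()
    values[mask, :] += src.alpha1 * dt
    return HhField(values, field.dx)


def move_source(src: SourceDescriptor, tissue: Tissue, t: float,
                dx: float) -> tuple:
    """Advance the band to its position at time t; differentiate overrun cells.

    The band position is quantized to whole grid rows so its mean
    velocity matches ``speed``.  Cells whose centroids fall behind the
    leading edge are flagged differentiated (frozen, non-consuming,
    excluded from profiles).  Returns (leading_edge, newly_differentiated).
    """
    lead = src.leading_edge(t, dx, tissue.cell_diameter)
    if src.geometry == "edge-band":
        newly = (~tissue.differentiated) & (tissue.centroids[:, 1] < lead)
        tissue.differentiated |= newly
    else:
        newly = np.zeros(tissue.n_cells, bool)
    return lead, newly


def step(tissue: Tissue, field: HhField, src: SourceDescriptor,
         p: PathwayParameters, dt: float, t: float = 0.0) -> HhField:
    """Advance tissue and field by one time step (the six sub-steps)."""
    check_stability(p.D, dt, field.dx)
    # (1) production at the source + diffusion
    field = diffusion_step(field, p.D, dt)
    field = apply_source(field, src, dt, t, tissue.cell_diameter)
    # (2) per-cell Hh input
    hh_cell = tissue.cell_average(field)
    # (3) intracellular Euler update
    cp = tissue.cell_params
    st = tissue.state
    m = cp["m"]
    bind = cp["k1"] * hh_cell * st["ptc"]
    unbind = cp["k2"] * st["hh_ptc"]
    smo_bind = cp["k3"] * st["ptc"] * st["smo"]
    smo_unbind = cp["k4"] * st["smo_ptc"]
    d_hh_ptc = bind - unbind - cp["beta3"] * st["hh_ptc"]
    d_ptc = (-bind + unbind - smo_bind + smo_unbind - cp["beta3"] * st["ptc"]
             + cp["alpha3"] * hill_activation(st["cia"], cp["M3"], m))
    d_smo = -smo_bind + smo_unbind
    d_cia = cp["alpha2"] * hill_activation(st["smo"], cp["M2"], m) - cp["beta2"] * st["cia"]
    live = ~tissue.differentiated
    st["ptc"] = st["ptc"] + np.where(live, d_ptc, 0.0) * dt
    st["hh_ptc"] = st["hh_ptc"] + np.where(live, d_hh_ptc, 0.0) * dt
    st["smo"] = st["smo"] + np.where(live, d_smo, 0.0) * dt
    st["smo_ptc"] = cp["smo_total"] - st["smo"]   # exact Smo conservation
    st["cia"] = st["cia"] + np.where(live, d_cia, 0.0) * dt
    for name in ("ptc", "hh_ptc", "smo", "cia"):
        if np.any(st[name] < 0):
            raise IntegratorError(
                f"{name} went negative at t={t:.2f} min; reduce dt")
    # (4)-(5) local exchange with the field + free-Hh degradation
    consumption = np.where(live, bind - unbind, 0.0)
    flat = tissue.node_to_cell.ravel()
    inside = flat >= 0
    values = field.values.ravel().copy()
    values[inside] -= consumption[flat[inside]] * dt
    values = values.reshape(field.values.shape)
    values -= p.beta1 * dt * values
    # cell-average-based uptake can overdraw individual low nodes inside a
    # cell by a sliver; clip it, but refuse to run if the deficit is a
    # meaningful fraction of the field (a genuine time-step problem).
    negative = values < 0
    if negative.any():
        deficit = -values[negative].sum()
        if deficit > 1e-3 * (values[~negative].sum() + 1e-12):
            raise IntegratorError(
                f"Hh field overdrawn at t={t:.2f} min; reduce dt")
        values[negative] = 0.0
    return HhField(values, field.dx)


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run."""

    params: PathwayParameters = dc_field(default_factory=PathwayParameters)
    source: SourceDescriptor | None = None
    nrows: int = 10
    ncols: int = 10
    dx: float = 1.0
    dt: float = 0.04
    total_time: float = 620.0
    snapshot_interval: float = 10.0
    seed: int = 0
    equilibrate_init: bool = True
    trailing_production: bool = False  # overrun cells keep secreting (off)

    def __post_init__(self):
        if self.source is None:
            self.source = SourceDescriptor(alpha1=self.params.alpha1)
        if self.trailing_production:
            self.source = dataclasses.replace(self.source, trailing=True)
        if self.snapshot_interval > self.total_time:
            raise ConfigurationError("snapshot interval exceeds total time")


@dataclass
class SimulationTrace:
    """Snapshots of a run: cell states, fields and source positions."""

    times: np.ndarray                 # (n_snap,)
    state: dict                       # name -> (n_snap, n_cells)
    hh_cell: np.ndarray               # (n_snap, n_cells)
    differentiated: np.ndarray        # (n_snap, n_cells) bool
    fields: np.ndarray                # (n_snap, ny, nx)
    source_lead: np.ndarray           # (n_snap,)
    centroids: np.ndarray
    cell_diameter: float
    dx: float
    seed: int
    config: SimulationConfig
    truncated: bool = False

    def index_of(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-6:
            raise KeyError(f"t={t} is not a snapshot time")
        return i

    def snapshot(self, t: float) -> dict:
        i = self.index_of(t)
        snap = {name: self.state[name][i] for name in STATE_NAMES}
        snap.update(t=self.times[i], hh_cell=self.hh_cell[i],
                    differentiated=self.differentiated[i],
                    field=self.fields[i], source_lead=self.source_lead[i])
        snap["ptc_total"] = snap["ptc"] + snap["hh_ptc"] + snap["smo_ptc"]
        return snap

    def to_directory(self, outdir) -> None:
        """Write one CSV per snapshot, the field, and run metadata."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, t in enumerate(self.times):
            df = pd.DataFrame({
                "cell_id": np.arange(len(self.centroids)),
                "x_um": self.centroids[:, 0],
                "y_um": self.centroids[:, 1],
                **{name: self.state[name][i] for name in STATE_NAMES},
                "differentiated": self.differentiated[i].astype(int),
            })
            df.to_csv(outdir / f"cells_t{int(round(t)):05d}.csv", index=False)
            ny, nx = self.fields[i].shape
            gy, gx = np.mgrid[0:ny, 0:nx]
            pd.DataFrame({
                "x_um": gx.ravel() * self.dx, "y_um": gy.ravel() * self.dx,
                "hh": self.fields[i].ravel(),
            }).to_csv(outdir / f"field_t{int(round(t)):05d}.csv", index=False)
        meta = {
            "seed": self.seed,
            "times_min": self.times.tolist(),
            "source_lead_um": self.source_lead.tolist(),
            "truncated": self.truncated,
            "parameters": self.config.params.to_dict(),
            "source": dataclasses.asdict(self.config.source),
            "geometry": {"nrows": self.config.nrows, "ncols": self.config.ncols,
                         "dx": self.dx, "dt": self.config.dt},
        }
        (outdir / "run.json").write_text(json.dumps(meta, indent=1))


def run_simulation(config: SimulationConfig) -> SimulationTrace:
    """Seeded, reproducible hybrid simulation."""
    p = config.params
    check_stability(p.D, config.dt, config.dx)
    rng = np.random.default_rng(config.seed)
    tissue, field = build_tissue(config.nrows, config.ncols, p.cell_diameter,
                                 config.dx, config.source.band_width
                                 if config.source.geometry == "edge-band" else 5.0)
    tissue.cell_params = sample_cell_parameters(p, tissue.n_cells, rng)
    if config.equilibrate_init:
        tissue.state = basal_partition(tissue.cell_params)
    else:
        tissue.state = {
            "ptc": tissue.cell_params["ptc_basal"].copy(),
            "hh_ptc": np.zeros(tissue.n_cells),
            "smo": tissue.cell_params["smo_total"].copy(),
            "smo_ptc": np.zeros(tissue.n_cells),
            "cia": np.zeros(tissue.n_cells),
        }
    src = dataclasses.replace(config.source, alpha1=config.source.alpha1)

    n_steps = int(round(config.total_time / config.dt))
    snap_stride = max(1, int(round(config.snapshot_interval / config.dt)))
    rec = {name: [] for name in STATE_NAMES}
    rec_hh, rec_diff, rec_fields, rec_lead, rec_times = [], [], [], [], []
    truncated = False
    field_top = field.y_coords[-1]

    for i in range(n_steps + 1):
        t = i * config.dt
        lead, _ = move_source(src, tissue, t, config.dx)
        if src.geometry == "edge-band" and lead - src.band_width > field_top:
            truncated = True
            break
        if i % snap_stride == 0 or i == n_steps:
            rec_times.append(t)
            for name in STATE_NAMES:
                rec[name].append(tissue.state[name].copy())
            rec_hh.append(tissue.cell_average(field))
            rec_diff.append(tissue.differentiated.copy())
            rec_fields.append(field.values.copy())
            rec_lead.append(lead)
        if i == n_steps:
            break
        field = step(tissue, field, src, p, config.dt, t)

    return SimulationTrace(
        times=np.array(rec_times),
        state={name: np.array(rec[name]) for name in STATE_NAMES},
        hh_cell=np.array(rec_hh),
        differentiated=np.array(rec_diff),
        fields=np.array(rec_fields),
        source_lead=np.array(rec_lead),
        centroids=tissue.centroids,
        cell_diameter=tissue.cell_diameter,
        dx=config.dx,
        seed=config.seed,
        config=config,
        truncated=truncated,
    )
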