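"""Compartmentalized embryo geometry: cells, membranes, barriers, channels.

The simulation domain is an axis-aligned box. Coordinates are in um with the
origin at the proximal-bottom-left corner of the interstitial space: x runs
along the proximal-distal axis, y is the apicobasal axis (0 = visceral
endoderm floor), and z (3D only) runs along the anterior-posterior axis with
periodic wrap.

Vertical structure (bottom to top):

* ``[0, H_I)`` - interstitial space, spanning the full width;
* ``[H_I, H_I + cell_height)`` - the cell band: cell columns separated by
  2-um lateral gaps (accessible from the interstitial side);
* ``[apical_y, apical_y + H_P)`` - the pre-amniotic cavity.

Tight junctions are zero-thickness reflecting caps across the apical end of
every lateral gap, except at the ExE-epiblast border gap: that gap is the
sole channel connecting cavity and interstitial space. In the hESC-colony
variant there are no ExE columns and both colony-edge gaps are open.

All boundaries follow a half-open convention: intervals include their
lower/left edge and exclude the upper/right one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig, ConfigError

__all__ = [
    "Surface",
    "Cell",
    "Region",
    "EmbryoGeometry",
    "build_geometry",
    "open_box_geometry",
    "COMPARTMENT_LABELS",
]

#: classification codes returned by :meth:`EmbryoGeometry.classify_points`
COMPARTMENT_LABELS = ("cavity", "interstitial", "lateral_gap", "channel",
                      "inside_cell", "outside")
CAVITY, INTERSTITIAL, LATERAL_GAP, CHANNEL, INSIDE_CELL, OUTSIDE = range(6)

# surface kinds
KIND_WALL = 0        # reflecting: outer walls, bare cell faces
KIND_MEMBRANE = 1    # receptor-bearing membrane (has a pool id)
KIND_JUNCTION = 2    # reflecting tight-junction cap

_TANGENT_AXES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


@dataclass(frozen=True)
class Surface:
    """An axis-aligned reflecting or receptor-bearing rectangle.

    ``orient`` is the axis of the surface normal (0=x, 1=y, 2=z) and ``c``
    the plane coordinate along it. ``(lo1, hi1)`` and ``(lo2, hi2)`` bound
    the surface along the two tangent axes, in axis order (2D surfaces use a
    dummy (0, 1) second extent).
    """

    orient: int
    c: float
    lo1: float
    hi1: float
    lo2: float = 0.0
    hi2: float = 1.0
    kind: int = KIND_WALL
    pool: int = -1
    owner_cell: int = -1
    face: str | None = None

    def x_extent(self) -> tuple[float, float]:
        if self.orient == 0:
            return (self.c, self.c)
        return (self.lo1, self.hi1)


@dataclass(frozen=True)
class Cell:
    """One cell column (2D) or cell slab (3D)."""

    index: int
    tissue: str          # "exe" | "epiblast"
    array: int           # anterior-posterior row index
    column: int          # proximal-distal column index within the array
    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float
    z_lo: float = 0.0
    z_hi: float = 1.0


@dataclass(frozen=True)
class Region:
    """A labeled axis-aligned accessible region (half-open box)."""

    label: str
    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float
    z_lo: float = 0.0
    z_hi: float = 1.0

    def measure(self, dim: int) -> float:
        a = (self.x_hi - self.x_lo) * (self.y_hi - self.y_lo)
        if dim == 3:
            a *= self.z_hi - self.z_lo
        return a


@dataclass
class EmbryoGeometry:
    """The compiled simulation geometry.

    Holds the cell census, every membrane/barrier surface, the open
    channels, the accessible-region decomposition, and the receptor pools
    (``pool_total[p]`` receptors shared by all surfaces with ``pool == p``).
    """

    config: SimulationConfig
    dim: int
    width: float
    height: float
    depth: float                  # z period in 3D; 0.0 in 2D
    apical_y: float               # cavity floor = apical plane
    basal_y: float                # cell bottom = interstitial ceiling
    cells: list[Cell]
    membranes: list[Surface]
    barriers: list[Surface]
    channels: list[Region]
    compartments: list[Region]
    pool_total: np.ndarray        # (n_pools,) int64
    pool_cell: np.ndarray         # (n_pools,) cell index
    pool_face: list[str]          # "lateral" | "basal" | "apical"
    periodic_z: bool = False

    # -- queries -------------------------------------------------------
    @property
    def surfaces(self) -> list[Surface]:
        return self.membranes + self.barriers

    def epiblast_cells(self) -> list[Cell]:
        return [c for c in self.cells if c.tissue == "epiblast"]

    def exe_cells(self) -> list[Cell]:
        return [c for c in self.cells if c.tissue == "exe"]

    def d_edge_of_cell(self, cell_id: int) -> int:
        """Distance of an epiblast cell from the epithelial edge, in cell widths.

        Index 1 is the epiblast column adjacent to the channel. In
        hESC-colony mode both colony edges are open and the nearest one
        counts.
        """
        cell = self.cells[cell_id]
        if cell.tissue != "epiblast":
            raise ValueError(f"cell {cell_id} is {cell.tissue!r}, not an epiblast cell")
        n_exe = self.config.n_exe_cells_per_array if self.config.exe_present else 0
        k = cell.column - n_exe  # 0-based epiblast column
        if self.config.exe_present:
            return k + 1
        n_epi = self.config.n_epi_cells_per_array
        return min(k + 1, n_epi - k)

    def d_source_of_cell(self, cell_id: int) -> int:
        """Distance from the morphogen source edge (the ExE border / the
        proximal colony edge), in cell widths."""
        cell = self.cells[cell_id]
        if cell.tissue != "epiblast":
            raise ValueError(f"cell {cell_id} is {cell.tissue!r}, not an epiblast cell")
        n_exe = self.config.n_exe_cells_per_array if self.config.exe_present else 0
        return cell.column - n_exe + 1

    def classify_points(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point classification.

        Parameters
        ----------
        points:
            ``(n, dim)`` array of positions in um (z wrapped into the
            periodic box first in 3D).

        Returns
        -------
        ``(n,)`` integer codes indexing :data:`COMPARTMENT_LABELS`.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] < self.dim:
            raise ValueError(f"points must have {self.dim} coordinates")
        x, y = pts[:, 0], pts[:, 1]
        if self.dim == 3:
            z = np.mod(pts[:, 2], self.depth)
        else:
            z = np.zeros_like(x)
        out = np.full(len(pts), OUTSIDE, dtype=np.int8)
        code = {"cavity": CAVITY, "interstitial": INTERSTITIAL,
                "lateral_gap": LATERAL_GAP, "channel": CHANNEL}
        for reg in self.compartments:
            m = ((x >= reg.x_lo) & (x < reg.x_hi)
                 & (y >= reg.y_lo) & (y < reg.y_hi))
            if self.dim == 3:
                m &= (z >= reg.z_lo) & (z < reg.z_hi)
            out[m] = code[reg.label]
        for cell in self.cells:
            m = ((x >= cell.x_lo) & (x < cell.x_hi)
                 & (y >= cell.y_lo) & (y < cell.y_hi))
            if self.dim == 3:
                m &= (z >= cell.z_lo) & (z < cell.z_hi)
            out[m] = INSIDE_CELL
        return out

    def classify_point(self, point) -> str:
        """Classify one point; returns a :data:`COMPARTMENT_LABELS` string."""
        return COMPARTMENT_LABELS[int(self.classify_points(np.asarray(point)[None, :])[0])]

    def accessible_volume(self) -> dict[str, float]:
        """Exact per-compartment area (2D, um^2) or volume (3D, um^3)."""
        out: dict[str, float] = {}
        for reg in self.compartments:
            out[reg.label] = out.get(reg.label, 0.0) + reg.measure(self.dim)
        out["total"] = float(sum(v for k, v in out.items() if k != "total"))
        return out

    def bounding_measure(self) -> float:
        a = self.width * self.height
        if self.dim == 3:
            a *= self.depth
        return a

    def cell_measure(self) -> float:
        total = 0.0
        for c in self.cells:
            a = (c.x_hi - c.x_lo) * (c.y_hi - c.y_lo)
            if self.dim == 3:
                a *= c.z_hi - c.z_lo
            total += a
        return total

    # -- modification helpers -----------------------------------------
    def seal_channels(self) -> "EmbryoGeometry":
        """Return a copy with every open channel capped by a reflecting
        barrier (used to probe the insulation of the basolateral side)."""
        caps = [
            Surface(orient=1, c=self.apical_y, lo1=ch.x_lo, hi1=ch.x_hi,
                    lo2=ch.z_lo, hi2=ch.z_hi, kind=KIND_JUNCTION)
            for ch in self.channels
        ]
        return EmbryoGeometry(
            config=self.config, dim=self.dim, width=self.width,
            height=self.height, depth=self.depth, apical_y=self.apical_y,
            basal_y=self.basal_y, cells=self.cells,
            membranes=self.membranes, barriers=self.barriers + caps,
            channels=[], compartments=self.compartments,
            pool_total=self.pool_total, pool_cell=self.pool_cell,
            pool_face=self.pool_face, periodic_z=self.periodic_z)

    # -- export --------------------------------------------------------
    def to_json(self) -> str:
        """JSON dump of cells, membranes, barriers and channels (debug/plotting)."""
        def surf(s: Surface) -> dict:
            return {"orient": s.orient, "c": s.c, "lo1": s.lo1, "hi1": s.hi1,
                    "lo2": s.lo2, "hi2": s.hi2, "kind": s.kind, "pool": s.pool,
                    "owner_cell": s.owner_cell, "face": s.face}
        doc = {
            "dim": self.dim, "width": self.width, "height": self.height,
            "depth": self.depth, "apical_y": self.apical_y, "basal_y": self.basal_y,
            "cells": [vars(c) for c in self.cells],
            "membranes": [surf(s) for s in self.membranes],
            "barriers": [surf(s) for s in self.barriers],
            "channels": [vars(r) for r in self.channels],
            "compartments": [vars(r) for r in self.compartments],
            "pool_total": self.pool_total.tolist(),
            "pool_cell": self.pool_cell.tolist(),
            "pool_face": list(self.pool_face),
        }
        return json.dumps(doc, indent=2)


# ----------------------------------------------------------------------
def _column_x_ranges(config: SimulationConfig) -> tuple[list[tuple[float, float]],
                                                        list[tuple[float, float]],
                                                        list[int], float]:
    """Cell and gap x-ranges of one array plus open-gap indices and width."""
    w, g, pitch = config.cell_width, config.lateral_gap, config.pitch
    if config.exe_present:
        n_cols = config.n_columns
        cells = [(i * pitch, i * pitch + w) for i in range(n_cols)]
        # gap i sits to the right of cell i; the last one is a dead-end
        # against the distal wall, apically sealed like any same-tissue gap.
        gaps = [(i * pitch + w, (i + 1) * pitch) for i in range(n_cols)]
        open_gaps = [config.n_exe_cells_per_array - 1]  # ExE-epiblast border
        width = n_cols * pitch
    else:
        n_cols = config.n_epi_cells_per_array
        cells = [(g + i * pitch, g + i * pitch + w) for i in range(n_cols)]
        gaps = [(0.0, g)] + [(g + i * pitch + w, g + (i + 1) * pitch)
                             for i in range(n_cols - 1)] + \
               [(g + (n_cols - 1) * pitch + w, n_cols * pitch + g)]
        open_gaps = [0, n_cols]  # both colony edges
        width = n_cols * pitch + g
    return cells, gaps, open_gaps, width


def build_geometry(config: SimulationConfig) -> EmbryoGeometry:
    """Construct the full embryo (or hESC-colony) geometry from a config.

    The cavity spans the full domain width above the cells, the
    interstitial space below them; lateral gaps between same-tissue
    neighbours are sealed apically by tight-junction caps (when
    ``tight_junctions`` is on) and the ExE-epiblast border gap is the open
    channel. In 3D the cross-section is extruded into ``n_arrays`` cell
    slabs with accessible, apically sealed gaps between arrays and periodic
    wrap along z.
    """
    cfg = config
    dim = cfg.dim
    col_cells, col_gaps, open_gap_idx, width = _column_x_ranges(cfg)
    n_exe = cfg.n_exe_cells_per_array if cfg.exe_present else 0

    basal_y = cfg.interstitial_height
    apical_y = basal_y + cfg.cell_height
    height = apical_y + cfg.cavity_height
    pitch = cfg.pitch

    if dim == 3:
        depth = cfg.n_arrays * pitch
        slabs = [(j * pitch, j * pitch + cfg.cell_width) for j in range(cfg.n_arrays)]
        zgaps = [(j * pitch + cfg.cell_width, (j + 1) * pitch) for j in range(cfg.n_arrays)]
        z_full = (0.0, depth)
    else:
        depth = 0.0
        slabs = [(0.0, 1.0)]
        zgaps = []
        z_full = (0.0, 1.0)

    cells: list[Cell] = []
    membranes: list[Surface] = []
    barriers: list[Surface] = []
    pool_total: list[int] = []
    pool_cell: list[int] = []
    pool_face: list[str] = []

    def new_pool(cell_idx: int, face: str, total: int) -> int:
        pool_total.append(total)
        pool_cell.append(cell_idx)
        pool_face.append(face)
        return len(pool_total) - 1

    apical_rec = cfg.receptor_localization == "apical"

    for j, (z_lo, z_hi) in enumerate(slabs):
        for i, (x_lo, x_hi) in enumerate(col_cells):
            tissue = "exe" if i < n_exe else "epiblast"
            idx = len(cells)
            cells.append(Cell(index=idx, tissue=tissue, array=j, column=i,
                              x_lo=x_lo, x_hi=x_hi, y_lo=basal_y, y_hi=apical_y,
                              z_lo=z_lo, z_hi=z_hi))
            if tissue == "epiblast":
                if apical_rec:
                    p_ap = new_pool(idx, "apical", cfg.receptors_per_epi_cell)
                    p_lat = p_bas = -1
                else:
                    p_lat = new_pool(idx, "lateral", cfg.receptors_lateral)
                    p_bas = new_pool(idx, "basal", cfg.receptors_basal)
                    p_ap = -1
            else:
                p_lat = p_bas = p_ap = -1  # ExE cells carry no receptors

            def add_face(orient, c, lo1, hi1, lo2, hi2, face, pool):
                s = Surface(orient=orient, c=c, lo1=lo1, hi1=hi1, lo2=lo2,
                            hi2=hi2, kind=KIND_MEMBRANE if pool >= 0 else KIND_WALL,
                            pool=pool, owner_cell=idx, face=face)
                (membranes if pool >= 0 else barriers).append(s)

            add_face(1, basal_y, x_lo, x_hi, z_lo, z_hi, "basal", p_bas)
            add_face(1, apical_y, x_lo, x_hi, z_lo, z_hi, "apical", p_ap)
            add_face(0, x_lo, basal_y, apical_y, z_lo, z_hi, "lateral_left", p_lat)
            add_face(0, x_hi, basal_y, apical_y, z_lo, z_hi, "lateral_right", p_lat)
            if dim == 3:
                add_face(2, z_lo, x_lo, x_hi, basal_y, apical_y, "lateral_front", p_lat)
                add_face(2, z_hi, x_lo, x_hi, basal_y, apical_y, "lateral_back", p_lat)

    # outer walls (z faces are periodic in 3D, not walls)
    barriers.append(Surface(1, 0.0, 0.0, width, *z_full, KIND_WALL, face="floor"))
    barriers.append(Surface(1, height, 0.0, width, *z_full, KIND_WALL, face="ceiling"))
    barriers.append(Surface(0, 0.0, 0.0, height, *z_full, KIND_WALL, face="wall_proximal"))
    barriers.append(Surface(0, width, 0.0, height, *z_full, KIND_WALL, face="wall_distal"))

    # channel z-extent(s)
    if dim == 3 and cfg.channel_mode == "posterior_only":
        open_z = [(depth - cfg.posterior_open_arrays * pitch, depth)]
        sealed_z = [(0.0, depth - cfg.posterior_open_arrays * pitch)]
    else:
        open_z = [z_full]
        sealed_z = []

    channels: list[Region] = []
    if cfg.tight_junctions:
        for gi, (g_lo, g_hi) in enumerate(col_gaps):
            if gi in open_gap_idx:
                for z_lo, z_hi in open_z:
                    channels.append(Region("channel", g_lo, g_hi, apical_y, apical_y,
                                           z_lo, z_hi))
                for z_lo, z_hi in sealed_z:
                    barriers.append(Surface(1, apical_y, g_lo, g_hi, z_lo, z_hi,
                                            KIND_JUNCTION, face="junction"))
            else:
                barriers.append(Surface(1, apical_y, g_lo, g_hi, *z_full,
                                        KIND_JUNCTION, face="junction"))
        if dim == 3:
            # apical caps over the between-array gaps, split around open channels
            channel_x = sorted({(col_gaps[gi][0], col_gaps[gi][1]) for gi in open_gap_idx})
            for z_lo, z_hi in zgaps:
                x0 = 0.0
                pieces = []
                for cx_lo, cx_hi in channel_x:
                    if cx_lo > x0:
                        pieces.append((x0, cx_lo))
                    x0 = cx_hi
                if x0 < width:
                    pieces.append((x0, width))
                # the channel x-strip is excluded: where the channel is sealed
                # along z the gap-loop barrier above already covers it
                for p_lo, p_hi in pieces:
                    barriers.append(Surface(1, apical_y, p_lo, p_hi, z_lo, z_hi,
                                            KIND_JUNCTION, face="junction"))
    else:
        # no junctions anywhere: every gap is an open passage
        for gi, (g_lo, g_hi) in enumerate(col_gaps):
            channels.append(Region("channel", g_lo, g_hi, apical_y, apical_y, *z_full))

    # accessible-region decomposition (tiles exactly with cells + bounding box)
    compartments: list[Region] = [
        Region("cavity", 0.0, width, apical_y, height, *z_full),
        Region("interstitial", 0.0, width, 0.0, basal_y, *z_full),
    ]
    channel_gaps = set(open_gap_idx) if cfg.tight_junctions else set(range(len(col_gaps)))
    for gi, (g_lo, g_hi) in enumerate(col_gaps):
        label = "channel" if gi in channel_gaps else "lateral_gap"
        compartments.append(Region(label, g_lo, g_hi, basal_y, apical_y, *z_full))
    if dim == 3:
        for z_lo, z_hi in zgaps:
            for x_lo, x_hi in col_cells:
                compartments.append(Region("lateral_gap", x_lo, x_hi,
                                           basal_y, apical_y, z_lo, z_hi))

    geom = EmbryoGeometry(
        config=cfg, dim=dim, width=width, height=height, depth=depth,
        apical_y=apical_y, basal_y=basal_y, cells=cells,
        membranes=membranes, barriers=barriers, channels=channels,
        compartments=compartments,
        pool_total=np.asarray(pool_total, dtype=np.int64),
        pool_cell=np.asarray(pool_cell, dtype=np.int64),
        pool_face=pool_face, periodic_z=(dim == 3))

    _check_tiling(geom)
    return geom


def open_box_geometry(width: float, height: float, depth: float | None = None) -> EmbryoGeometry:
    """A bare reflecting box with no cells, receptors or junctions.

    Used for free-diffusion (MSD) and equilibration oracles; the whole
    interior is a single "cavity" compartment.
    """
    if width <= 0 or height <= 0 or (depth is not None and depth <= 0):
        raise ConfigError("open box dimensions must be strictly positive")
    dim = 2 if depth is None else 3
    d = depth if depth is not None else 0.0
    z_full = (0.0, d) if dim == 3 else (0.0, 1.0)
    barriers = [
        Surface(1, 0.0, 0.0, width, *z_full, KIND_WALL, face="floor"),
        Surface(1, height, 0.0, width, *z_full, KIND_WALL, face="ceiling"),
        Surface(0, 0.0, 0.0, height, *z_full, KIND_WALL, face="wall_proximal"),
        Surface(0, width, 0.0, height, *z_full, KIND_WALL, face="wall_distal"),
    ]
    if dim == 3:
        barriers.append(Surface(2, 0.0, 0.0, width, 0.0, height, KIND_WALL, face="front"))
        barriers.append(Surface(2, d, 0.0, width, 0.0, height, KIND_WALL, face="back"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # dummy config; widths are the box's own
        cfg = SimulationConfig(dim=dim, n_arrays=1,
                               exe_present=False, secretion_mode="uniform_cavity",
                               cavity_width=width, interstitial_width=width,
                               cavity_height=height)
    return EmbryoGeometry(
        config=cfg, dim=dim, width=width, height=height, depth=d,
        apical_y=0.0, basal_y=0.0, cells=[], membranes=[], barriers=barriers,
        channels=[], compartments=[Region("cavity", 0.0, width, 0.0, height, *z_full)],
        pool_total=np.zeros(0, dtype=np.int64),
        pool_cell=np.zeros(0, dtype=np.int64),
        pool_face=[], periodic_z=False)


def _check_tiling(geom: EmbryoGeometry) -> None:
    """Accessible regions + cell interiors must tile the bounding box exactly."""
    acc = geom.accessible_volume()["total"]
    total = acc + geom.cell_measure()
    box = geom.bounding_measure()
    if not np.isclose(total, box, rtol=1e-9, atol=1e-6):
        raise ConfigError(
            f"geometry does not tile its bounding box: accessible {acc} + "
            f"cells {geom.cell_measure()} != box {box}; check widths/heights")
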