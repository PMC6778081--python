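"""Synthetic inputs with known ground truth.

Everything here is generated, never measured: label vectors drawn from a
known joint distribution (with closed-form H, I and U for oracle tests),
synthetic segmented-colony cell tables whose marker levels depend on
d_edge and/or d_source by construction, and open-box configurations for
free-diffusion oracles. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .geometry import EmbryoGeometry, open_box_geometry
from .infostats import CELL_DIAMETER_UM

__all__ = [
    "KnownJointSpec",
    "sample_known_joint",
    "synthetic_colony_table",
    "open_box_config",
]


@dataclass(frozen=True)
class KnownJointSpec:
    """A joint probability table over (X, Y) bins to sample from."""

    joint: tuple[tuple[float, ...], ...]
    n: int
    seed: int = 0

    def table(self) -> np.ndarray:
        t = np.asarray(self.joint, dtype=float)
        if t.ndim != 2 or np.any(t < 0) or not np.isclose(t.sum(), 1.0):
            raise ValueError("joint must be a non-negative 2D table summing to 1")
        return t

    # closed forms, computed from the table itself (not from samples)
    def entropy_y(self, base: float = 2.0) -> float:
        py = self.table().sum(axis=0)
        py = py[py > 0]
        return float(-np.sum(py * np.log(py)) / np.log(base))

    def mutual_information(self, base: float = 2.0) -> float:
        t = self.table()
        px = t.sum(axis=1, keepdims=True)
        py = t.sum(axis=0, keepdims=True)
        m = t > 0
        return float(np.sum(t[m] * np.log(t[m] / (px @ py)[m])) / np.log(base))

    def proficiency(self) -> float:
        hy = self.entropy_y()
        if hy == 0.0:
            raise ValueError("H(Y) = 0 for this joint")
        return self.mutual_information() / hy


def sample_known_joint(spec: KnownJointSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw i.i.d. (x, y) label pairs from the joint table."""
    t = spec.table()
    nx, ny = t.shape
    rng = np.random.default_rng(spec.seed)
    flat = rng.choice(nx * ny, size=spec.n, p=t.ravel())
    return (flat // ny).astype(np.int64), (flat % ny).astype(np.int64)


def synthetic_colony_table(n_cells: int,
                           edge_effect_depth: float = 5.0,
                           noise_sd: float = 0.05,
                           seed: int = 0,
                           colony_width_cw: float = 40.0,
                           colony_height_cw: float = 20.0,
                           source_effect: float = 0.0) -> pd.DataFrame:
    """Emulate a segmented epithelial-colony cell table.

    Cells are scattered uniformly over a rectangular colony measured in
    cell widths (1 cell width = 13 um). ``d_edge`` is the distance to the
    nearest colony edge and ``d_source`` the distance from the left
    (source-facing) edge. The marker level decays logistically with d_edge
    over ``edge_effect_depth`` cell widths, optionally plus a linear
    ``source_effect`` term in d_source, plus Gaussian noise:

        marker = 1 / (1 + exp(d_edge - depth)) + source_effect * (1 - d_source/W) + noise

    With ``edge_effect_depth = 0`` the edge term is dropped entirely, so
    the marker is driven by d_source alone.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    x = colony_width_cw * rng.random(n_cells)
    y = colony_height_cw * rng.random(n_cells)
    d_edge = np.minimum.reduce([x, colony_width_cw - x, y, colony_height_cw - y])
    d_source = x
    marker = np.zeros(n_cells)
    if edge_effect_depth > 0:
        marker = marker + 1.0 / (1.0 + np.exp(d_edge - edge_effect_depth))
    if source_effect != 0.0:
        marker = marker + source_effect * (1.0 - d_source / colony_width_cw)
    marker = marker + noise_sd * rng.standard_normal(n_cells)
    return pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "x_um": x * CELL_DIAMETER_UM,
        "y_um": y * CELL_DIAMETER_UM,
        "d_edge": d_edge,
        "d_source": d_source,
        "marker": marker,
    })


def open_box_config(size: float = 1000.0,
                    n_ligands: int = 1000,
                    duration: float = 30.0,
                    h: float = 0.003,
                    snapshot_interval: float | None = None,
                    depth: float | None = None,
                    seed: int = 0) -> tuple[SimulationConfig, EmbryoGeometry]:
    """A receptor-free, junction-free box for diffusion-law oracles.

    Returns (config, geometry); run with
    ``engine.run(config, geometry=geometry, ...)``. Ligands seed uniformly
    unless explicit ``initial_positions`` are passed to the engine.
    """
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # box widths differ from colony layout
        cfg = SimulationConfig(
            dim=2 if depth is None else 3,
            n_arrays=1,
            exe_present=False,
            secretion_mode="uniform_cavity",
            n_ligands=n_ligands,
            duration=duration,
            h=h,
            snapshot_interval=snapshot_interval or duration / 10,
            cavity_width=size, interstitial_width=size, cavity_height=size,
            P_binding=0.0,  # no membranes exist anyway
            n_replicates=1,
            seed=seed)
    geom = open_box_geometry(size, size, depth)
    return cfg, geom
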