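"""Summary statistics over simulation output.

Reduces engine snapshots and event logs to the study's observables: the
bound-receptor fraction profile over distance from the epithelial edge
(``d_edge``, in cell widths), the ligand partition between cavity and
interstitial space, capture-time (T_L) statistics, the gradient half-depth,
and per-cell tables consumed by the information statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SimResult, FREE
from .geometry import (CAVITY, INTERSTITIAL, LATERAL_GAP, CHANNEL,
                       INSIDE_CELL, OUTSIDE)

__all__ = [
    "OccupancyProfile",
    "CompartmentOccupancy",
    "occupancy_profile",
    "compartment_occupancy",
    "gradient_depth",
    "GradientDepth",
    "capture_time_stats",
    "to_cell_table",
]


@dataclass
class OccupancyProfile:
    """Bound-receptor fraction vs distance from the epithelial edge.

    ``by_d_edge`` maps integer d_edge (cell widths) to the mean bound
    fraction across replicates; ``sem`` holds the standard error of that
    mean over replicates.
    """

    time: float
    by_d_edge: dict[int, float]
    sem: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        d = sorted(self.by_d_edge)
        return pd.DataFrame({
            "d_edge": d,
            "bound_fraction": [self.by_d_edge[k] for k in d],
            "sem": [self.sem[k] for k in d],
        })


@dataclass
class CompartmentOccupancy:
    """Free-ligand fractions per compartment at one time point.

    Ligands in lateral gaps and the channel count as interstitial (they sit
    on the basolateral side of the junctions); fractions sum to one.
    """

    time: float
    fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"compartment": list(self.fractions),
                             "fraction": list(self.fractions.values())})


def _per_cell_bound_fraction(result: SimResult, snap: int) -> pd.DataFrame:
    """(replicate, cell_id) -> bound fraction for epiblast cells."""
    geom = result.geometry
    cfg = result.config
    rows = []
    epi = geom.epiblast_cells()
    cell_pools: dict[int, list[int]] = {c.index: [] for c in epi}
    for pid, cell_idx in enumerate(geom.pool_cell):
        cell_pools.setdefault(int(cell_idx), []).append(pid)
    for r, rep in enumerate(result.replicates):
        bound = rep.pool_bound[snap]
        for cell in epi:
            pools = cell_pools[cell.index]
            nb = int(sum(bound[p] for p in pools))
            rows.append({
                "replicate": r,
                "cell_id": cell.index,
                "d_edge": geom.d_edge_of_cell(cell.index),
                "d_source": geom.d_source_of_cell(cell.index),
                "bound_fraction": nb / cfg.receptors_per_epi_cell,
            })
    return pd.DataFrame(rows)


def occupancy_profile(result: SimResult, at_time: float) -> OccupancyProfile:
    """Mean bound fraction per d_edge at ``at_time``, with replicate SEM.

    Cells sharing a d_edge (several arrays in 3D, or mirror-symmetric
    columns in colony mode) are averaged within each replicate first.
    """
    snap = result.snapshot_index(at_time)
    df = _per_cell_bound_fraction(result, snap)
    per_rep = df.groupby(["replicate", "d_edge"])["bound_fraction"].mean()
    mean = per_rep.groupby("d_edge").mean()
    n = per_rep.groupby("d_edge").count()
    sd = per_rep.groupby("d_edge").std(ddof=1).fillna(0.0)
    sem = sd / np.sqrt(n)
    return OccupancyProfile(
        time=at_time,
        by_d_edge={int(k): float(v) for k, v in mean.items()},
        sem={int(k): float(v) for k, v in sem.items()})


def compartment_occupancy(result: SimResult, at_time: float) -> CompartmentOccupancy:
    """Partition of free ligands between cavity and interstitial space."""
    snap = result.snapshot_index(at_time)
    geom = result.geometry
    n_cavity = 0
    n_interstitial = 0
    for rep in result.replicates:
        pos = rep.positions[snap, rep.status[snap] == FREE, :geom.dim]
        lab = geom.classify_points(pos)
        if np.any((lab == INSIDE_CELL) | (lab == OUTSIDE)):
            raise AssertionError("free ligand classified inside a cell or outside")
        n_cavity += int(np.sum(lab == CAVITY))
        n_interstitial += int(np.sum(np.isin(lab, (INTERSTITIAL, LATERAL_GAP, CHANNEL))))
    total = n_cavity + n_interstitial
    if total == 0:
        raise ValueError(f"no free ligands at t={at_time}")
    return CompartmentOccupancy(
        time=at_time,
        fractions={"cavity": n_cavity / total,
                   "interstitial": n_interstitial / total})


@dataclass(frozen=True)
class GradientDepth:
    """Half-depth of an occupancy profile, in cell widths."""

    d_half: float
    saturated: bool = False


def gradient_depth(profile: OccupancyProfile) -> GradientDepth:
    """Smallest d_edge at which the bound fraction falls below half of its
    value at d_edge = 1, linearly interpolated between integer columns.

    A profile that never drops below half is returned as the maximal
    d_edge flagged ``saturated``; an all-zero profile has no depth.
    """
    d = sorted(profile.by_d_edge)
    vals = np.array([profile.by_d_edge[k] for k in d])
    if not np.any(vals > 0):
        raise ValueError("gradient depth is undefined for an all-zero profile")
    ref = profile.by_d_edge[d[0]]
    half = 0.5 * ref
    for i in range(1, len(d)):
        if vals[i] < half:
            # linear interpolation between the bracketing columns
            x0, x1 = d[i - 1], d[i]
            y0, y1 = vals[i - 1], vals[i]
            return GradientDepth(d_half=x0 + (y0 - half) / (y0 - y1) * (x1 - x0))
    return GradientDepth(d_half=float(d[-1]), saturated=True)


def capture_time_stats(events: pd.DataFrame) -> dict[str, float]:
    """Median / mean / IQR of the capture time T_L pooled over replicates.

    T_L is the interval between a ligand's first entry into the
    interstitial space and its binding; bind events without a recorded
    entry (never left the cavity) are excluded.
    """
    binds = events[(events["event"] == "bind") & events["T_L"].notna()]
    if len(binds) == 0:
        return {"n": 0, "median": np.nan, "mean": np.nan,
                "iqr_low": np.nan, "iqr_high": np.nan}
    tl = binds["T_L"].to_numpy()
    q1, med, q3 = np.percentile(tl, [25, 50, 75])
    return {"n": int(len(tl)), "median": float(med), "mean": float(tl.mean()),
            "iqr_low": float(q1), "iqr_high": float(q3)}


def to_cell_table(result: SimResult, at_time: float,
                  per_replicate: bool = False) -> pd.DataFrame:
    """Per-epiblast-cell table of (d_edge, d_source, signal).

    ``signal`` is the cell's bound-receptor fraction, the simulation's
    readout of signaling activity. With ``per_replicate`` each replicate
    contributes its own rows; otherwise replicates are averaged so the
    table has one row per epiblast cell. The schema matches the cell tables
    consumed by :mod:`morphograd.infostats`.
    """
    snap = result.snapshot_index(at_time)
    df = _per_cell_bound_fraction(result, snap)
    df = df.rename(columns={"bound_fraction": "signal"})
    if per_replicate:
        return df[["replicate", "cell_id", "d_edge", "d_source", "signal"]]
    out = (df.groupby(["cell_id", "d_edge", "d_source"], as_index=False)["signal"]
           .mean())
    return out[["cell_id", "d_edge", "d_source", "signal"]]
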