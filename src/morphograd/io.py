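"""Config files, run manifests, and CSV serialization.

Config files are JSON objects mirroring :class:`SimulationConfig` field
names; precedence is defaults < file < overrides. Every run directory gets
exactly one ``manifest.json`` recording config hash, seed, package version
and timestamps; re-running into the same directory requires ``overwrite``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, ConfigError

__all__ = [
    "load_config", "write_config", "config_hash",
    "RunManifest", "write_manifest", "read_manifest",
    "write_events", "write_profile", "write_occupancy", "write_cell_table",
    "write_snapshots", "read_snapshots",
]


def _parse_override(item: str) -> tuple[str, object]:
    if "=" not in item:
        raise ConfigError(f"override {item!r} is not of the form key=value")
    key, raw = item.split("=", 1)
    try:
        val = json.loads(raw)
    except json.JSONDecodeError:
        val = raw  # bare strings (e.g. secretion_mode=apical)
    return key.strip(), val


def load_config(path: str | Path | None, overrides=()) -> SimulationConfig:
    """Build a config from a JSON file plus ``key=value`` overrides.

    ``path=None`` or an empty file yields the full default configuration.
    Unknown keys, type mismatches and invariant violations raise
    :class:`ConfigError` naming the offending field.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text().strip()
        if text:
            loaded = json.loads(text)
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: config file must hold a JSON object")
            data.update(loaded)
    for item in overrides:
        if isinstance(item, str):
            key, val = _parse_override(item)
        else:
            key, val = item
        data[key] = val
    try:
        return SimulationConfig.from_dict(data)
    except TypeError as exc:  # wrong type for a field
        raise ConfigError(str(exc)) from exc


def write_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def config_hash(config: SimulationConfig) -> str:
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: str
    finished: str = ""
    outputs: tuple[str, ...] = ()


def write_manifest(manifest: RunManifest, out_dir: str | Path,
                   overwrite: bool = False) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    if path.exists() and not overwrite:
        raise FileExistsError(
            f"{path} exists; pass overwrite to replace a previous run")
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path


def read_manifest(out_dir: str | Path) -> RunManifest:
    data = json.loads((Path(out_dir) / "manifest.json").read_text())
    data["outputs"] = tuple(data.get("outputs", ()))
    return RunManifest(**data)


def now_iso() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


# ---------------------------------------------------------------- CSV writers
def write_events(result, path: str | Path) -> None:
    """Event log CSV: replicate, t, event, ligand_id, pool_id, cell_id,
    d_edge, T_L."""
    result.events().to_csv(path, index=False)


def write_profile(profile, path: str | Path) -> None:
    """Occupancy profile CSV: d_edge, bound_fraction, sem."""
    profile.to_frame().to_csv(path, index=False)


def write_occupancy(occ, path: str | Path) -> None:
    """Compartment occupancy CSV: compartment, fraction."""
    occ.to_frame().to_csv(path, index=False)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Cell table CSV (cell_id, d_edge, d_source, signal/markers)."""
    table.to_csv(path, index=False)


def write_snapshots(result, out_dir: str | Path) -> tuple[Path, Path]:
    """Long-format snapshot CSVs.

    ``receptors.csv``: replicate, t, pool_id, cell_id, face, bound, total.
    ``ligands.csv``: replicate, t, ligand_id, status, x, y[, z].
    """
    out = Path(out_dir)
    geom = result.geometry
    rec_rows = []
    lig_frames = []
    for r, rep in enumerate(result.replicates):
        for k, t in enumerate(rep.times):
            for pid in range(len(geom.pool_total)):
                rec_rows.append((r, t, pid, int(geom.pool_cell[pid]),
                                 geom.pool_face[pid],
                                 int(rep.pool_bound[k, pid]),
                                 int(geom.pool_total[pid])))
            df = pd.DataFrame({
                "replicate": r, "t": t,
                "ligand_id": np.arange(rep.positions.shape[1]),
                "status": rep.status[k],
                "x": rep.positions[k, :, 0],
                "y": rep.positions[k, :, 1],
            })
            if geom.dim == 3:
                df["z"] = rep.positions[k, :, 2]
            lig_frames.append(df)
    rec_path = out / "receptors.csv"
    lig_path = out / "ligands.csv"
    pd.DataFrame(rec_rows, columns=["replicate", "t", "pool_id", "cell_id",
                                    "face", "bound", "total"]).to_csv(
        rec_path, index=False)
    pd.concat(lig_frames, ignore_index=True).to_csv(lig_path, index=False)
    return rec_path, lig_path


def read_snapshots(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(out_dir)
    return (pd.read_csv(out / "receptors.csv"),
            pd.read_csv(out / "ligands.csv"))
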