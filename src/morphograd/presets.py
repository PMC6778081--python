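"""Named experiment presets, one per study condition."""

from __future__ import annotations

import warnings

from .config import SimulationConfig

__all__ = ["experiment_presets", "get_preset"]


def _hesc() -> SimulationConfig:
    cfg = SimulationConfig(dim=3, exe_present=False,
                           secretion_mode="uniform_cavity")
    # colony layout width (open edge gaps on both sides)
    w = cfg.expected_width
    return cfg.with_(cavity_width=w, interstitial_width=w)


def experiment_presets() -> dict[str, SimulationConfig]:
    """Complete, reproducible configs for each simulated condition."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        presets = {
            "default_2d": SimulationConfig(),
            "default_3d": SimulationConfig(dim=3),
            "apical_secretion": SimulationConfig(secretion_mode="apical"),
            "apical_receptors": SimulationConfig(receptor_localization="apical"),
            "no_tight_junctions": SimulationConfig(tight_junctions=False),
            "uniform_cavity": SimulationConfig(secretion_mode="uniform_cavity"),
            "tenfold_ligand": SimulationConfig(n_ligands=10 * SimulationConfig.n_ligands),
            "posterior_only_channel": SimulationConfig(dim=3,
                                                       channel_mode="posterior_only"),
            "hesc_colony": _hesc(),
            "variant_decreasing": SimulationConfig(turnover_variant="decreasing"),
            "variant_increasing": SimulationConfig(turnover_variant="increasing"),
        }
        for h_i in (1, 2, 4, 8):
            presets[f"hi_{h_i}um"] = SimulationConfig(
                interstitial_height=float(h_i))
    return presets


def get_preset(name: str) -> SimulationConfig:
    presets = experiment_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
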