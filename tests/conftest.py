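"""Shared fixtures.

The heavier simulations are session-scoped and shared between the unit
suite and the acceptance tests so each condition is run only once. Scales
(ligand counts, durations, replicate counts) are the package's documented
reduced-scale study conditions; seeds are fixed.
"""

import warnings

import numpy as np
import pytest

from morphograd import engine, synthetic
from morphograd.config import SimulationConfig


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def gradient_result():
    """Reduced-scale default (basolateral) condition: 200 ligands, 30 min,
    5 replicates."""
    cfg = SimulationConfig(n_ligands=200, duration=1800.0,
                           snapshot_interval=450.0, n_replicates=5, seed=42)
    return engine.run(cfg)


@pytest.fixture(scope="session")
def equilibration_results():
    """Binding disabled, 90 simulated minutes at h = 10 ms, both secretion
    sides; used for the entropic-partition checks."""
    out = {}
    for i, mode in enumerate(("apical", "basolateral")):
        cfg = SimulationConfig(n_ligands=200, duration=5400.0, h=0.010,
                               snapshot_interval=1350.0, P_binding=0.0,
                               secretion_mode=mode, n_replicates=5,
                               seed=100 + i)
        out[mode] = engine.run(cfg)
    return out


@pytest.fixture(scope="session")
def tl_sweep_results():
    """Capture-time sweep over interstitial heights H_I = 1, 2, 4, 8 um.

    Apically secreted ligands enter the interstitial space through the
    border channel, so T_L isolates the entry-to-capture leg the height
    H_I throttles."""
    out = {}
    for h_i in (1.0, 2.0, 4.0, 8.0):
        cfg = SimulationConfig(n_ligands=200, duration=1800.0,
                               interstitial_height=h_i,
                               secretion_mode="apical",
                               snapshot_interval=900.0, n_replicates=10,
                               seed=300)
        out[h_i] = engine.run(cfg)
    return out


@pytest.fixture(scope="session")
def robustness_results():
    """Source-strength robustness at steady state (90 min), apically
    secreted ligands: ligand/receptor ratio 0.1 (baseline) and 1.0 (10x),
    the 10x condition also under apical receptor mis-localization and with
    tight junctions removed."""
    base = SimulationConfig(n_ligands=200, duration=5400.0,
                            snapshot_interval=2700.0,
                            secretion_mode="apical", seed=7)
    ten = base.with_(n_ligands=2000)
    return {
        "baseline": engine.run(base, n_replicates=3),
        "tenfold": engine.run(ten, n_replicates=2),
        "tenfold_apical_receptors": engine.run(
            ten.with_(receptor_localization="apical"), n_replicates=2),
        "tenfold_no_junctions": engine.run(
            ten.with_(tight_junctions=False), n_replicates=2),
    }


@pytest.fixture(scope="session")
def hesc_result():
    """Small 3D colony variant: uniform ligand bath, open edges on both
    sides, two arrays."""
    from morphograd.presets import get_preset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = get_preset("hesc_colony").with_(
            n_arrays=2, n_ligands=200, duration=1800.0,
            snapshot_interval=900.0, n_replicates=2, seed=9)
    return engine.run(cfg)


@pytest.fixture(scope="session")
def msd_run():
    """Open-box free-diffusion ensemble: 1000 ligands, 10^4 steps."""
    cfg, geom = synthetic.open_box_config(size=1000.0, n_ligands=1000,
                                          duration=30.0, h=0.003)
    start = np.full((1000, 2), 500.0)
    times = np.linspace(3.0, 30.0, 10)
    res = engine.run(cfg, geometry=geom, snapshot_times=times,
                     initial_positions=start, n_replicates=1)
    return res, start, times
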