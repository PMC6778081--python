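"""Run configuration for the embryo morphogen-transport simulator.

The model domain is an unrolled pre-gastrulation mouse embryo: a row of
secreting extraembryonic-ectoderm (ExE) cell columns and receptor-bearing
epiblast cell columns, sandwiched between a large apical lumen (the
pre-amniotic cavity, height ``cavity_height``) and a narrow basolateral
interstitial space (height ``interstitial_height``). All lengths are in
micrometres, times in seconds.

:class:`SimulationConfig` collects every numeric parameter and variant flag
of a run. Defaults are the reference parameter set of the study this package
models: 8x18 um cells separated by 2 um gaps, a 260x30 um cavity over a
260x2 um interstitial space, 100 receptors per epiblast cell (80 lateral,
20 basal), 1000 ligands in 2D, D = 20 um^2/s, h = 3 ms, P_binding = 0.002,
ligand-receptor turnover after T_t = 45 min, 90 min of simulated time, and
10 replicates per condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict, replace

__all__ = [
    "SimulationConfig",
    "ConcentrationMap",
    "ligand_receptor_ratio",
    "SECRETION_MODES",
    "RECEPTOR_LOCALIZATIONS",
    "TURNOVER_VARIANTS",
    "CHANNEL_MODES",
]

SECRETION_MODES = ("apical", "basolateral", "uniform_cavity")
RECEPTOR_LOCALIZATIONS = ("basolateral", "apical")
TURNOVER_VARIANTS = ("constant_total", "decreasing", "increasing")
CHANNEL_MODES = ("all_edges", "posterior_only")


class ConfigError(ValueError):
    """A configuration value violates a model invariant."""


@dataclass
class SimulationConfig:
    """Parameters and variant flags of one simulation condition.

    Attributes
    ----------
    dim:
        2 for a single cell array, 3 for ``n_arrays`` parallel arrays
        extruded along the anterior-posterior axis with periodic wrap.
    n_exe_cells_per_array, n_epi_cells_per_array:
        Number of secreting ExE and receiving epiblast cell columns per
        array (6 and 20 by default).
    n_arrays:
        Number of parallel cell arrays; defaults to 1 in 2D and 20 in 3D.
    cell_width, cell_height, lateral_gap:
        Cell column footprint and the accessible gap between neighbouring
        cells (um).
    cavity_width, cavity_height:
        Pre-amniotic cavity extent (um); the default 260 um width equals
        26 columns x 10 um pitch.
    interstitial_width, interstitial_height:
        Interstitial space extent (um); its height H_I throttles ligand
        capture time and hence gradient depth.
    receptors_per_epi_cell, receptors_lateral, receptors_basal:
        Receptor budget per epiblast cell and its split between the lateral
        and basal membrane pools (basolateral localization).
    n_ligands:
        Initial ligand count (1000 in the 2D reference condition).
    D, h:
        Ligand diffusion coefficient (um^2/s) and integration time step (s).
    P_binding:
        Per-contact binding probability scale; the realized probability is
        ``P_binding * R_unbound`` of the contacted membrane pool.
    T_t:
        Ligand-receptor pair turnover time (s); bound pairs dissolve exactly
        T_t after binding.
    duration, snapshot_interval:
        Simulated time span and state-recording cadence (s). The defaults
        (90 min, 7.5 min) give 12 snapshots.
    secretion_mode:
        Where ligands are introduced: the ExE apical faces (into the
        cavity), the ExE basal faces (into the interstitial space), or
        uniformly throughout the cavity.
    receptor_localization:
        "basolateral" (lateral + basal pools) or "apical" (all receptors
        mis-localized to the apical face).
    tight_junctions:
        When on, every same-tissue gap is sealed apically by a junction
        barrier; the sole open passage is the ExE-epiblast border gap.
    turnover_variant:
        "constant_total" re-secretes one ligand per dissolved pair,
        "decreasing" does not, "increasing" additionally secretes fresh
        ligands at a constant rate ``n_ligands / T_t``.
    channel_mode:
        "all_edges" opens the border channel along the whole AP axis;
        "posterior_only" restricts it to the posterior
        ``posterior_open_arrays`` array pitches (3D).
    exe_present:
        Off switches to the hESC-colony variant: no ExE columns and open
        channels at both colony edges.
    seed:
        Base RNG seed; replicate r uses ``seed + r``.
    """

    dim: int = 2
    n_exe_cells_per_array: int = 6
    n_epi_cells_per_array: int = 20
    n_arrays: int | None = None
    cell_width: float = 8.0
    cell_height: float = 18.0
    lateral_gap: float = 2.0
    cavity_width: float = 260.0
    cavity_height: float = 30.0
    interstitial_width: float = 260.0
    interstitial_height: float = 2.0
    receptors_per_epi_cell: int = 100
    receptors_lateral: int = 80
    receptors_basal: int = 20
    n_ligands: int = 1000
    D: float = 20.0
    h: float = 0.003
    P_binding: float = 0.002
    T_t: float = 2700.0
    duration: float = 5400.0
    snapshot_interval: float = 450.0
    n_replicates: int = 10
    secretion_mode: str = "basolateral"
    receptor_localization: str = "basolateral"
    tight_junctions: bool = True
    turnover_variant: str = "constant_total"
    channel_mode: str = "all_edges"
    posterior_open_arrays: int = 2
    exe_present: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_arrays is None:
            self.n_arrays = 1 if self.dim == 2 else 20
        self.validate()

    # ------------------------------------------------------------------
    @property
    def c(self) -> int:
        """Brownian variance coefficient; <|Gamma|^2> = c*D*h with c = 2*dim."""
        return 2 * self.dim

    @property
    def pitch(self) -> float:
        """Cell-to-cell pitch (cell width + lateral gap)."""
        return self.cell_width + self.lateral_gap

    @property
    def n_columns(self) -> int:
        n_exe = self.n_exe_cells_per_array if self.exe_present else 0
        return n_exe + self.n_epi_cells_per_array

    @property
    def expected_width(self) -> float:
        """Domain width implied by the column layout (um)."""
        if self.exe_present:
            return self.n_columns * self.pitch
        # hESC colony: open edge gap on both sides, cells in between
        return self.n_epi_cells_per_array * self.pitch + self.lateral_gap

    @property
    def n_epi_cells(self) -> int:
        return self.n_epi_cells_per_array * self.n_arrays

    @property
    def n_exe_cells(self) -> int:
        return (self.n_exe_cells_per_array if self.exe_present else 0) * self.n_arrays

    @property
    def n_receptors(self) -> int:
        return self.n_epi_cells * self.receptors_per_epi_cell

    # ------------------------------------------------------------------
    def validate(self) -> None:
        pos_fields = (
            "n_epi_cells_per_array", "n_arrays", "cell_width", "cell_height",
            "lateral_gap", "cavity_width", "cavity_height",
            "interstitial_width", "interstitial_height",
            "receptors_per_epi_cell", "n_ligands", "D", "h", "T_t",
            "duration", "snapshot_interval", "n_replicates",
        )
        for name in pos_fields:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if self.exe_present and self.n_exe_cells_per_array <= 0:
            raise ConfigError("n_exe_cells_per_array must be strictly positive")
        if self.dim not in (2, 3):
            raise ConfigError(f"dim must be 2 or 3, got {self.dim}")
        if self.dim == 2 and self.n_arrays != 1:
            raise ConfigError("2D simulations use a single cell array (n_arrays=1)")
        # P_binding = 0 is allowed: it disables capture entirely, which the
        # equilibration analyses rely on.
        if not (0.0 <= self.P_binding <= 1.0):
            raise ConfigError(f"P_binding must lie in [0, 1], got {self.P_binding}")
        # A run shorter than T_t is legitimate (no turnover occurs within it),
        # so only the step size is bounded by the other time scales.
        if not (self.h < self.T_t and self.h < self.duration):
            raise ConfigError(
                f"the time step must satisfy h < T_t and h < duration, got "
                f"h={self.h}, T_t={self.T_t}, duration={self.duration}")
        if self.receptor_localization == "basolateral" and (
                self.receptors_lateral + self.receptors_basal != self.receptors_per_epi_cell):
            raise ConfigError(
                "receptors_lateral + receptors_basal must equal receptors_per_epi_cell "
                f"({self.receptors_lateral} + {self.receptors_basal} != {self.receptors_per_epi_cell})")
        if self.receptors_lateral < 0 or self.receptors_basal < 0:
            raise ConfigError("receptor counts must be non-negative")
        if self.secretion_mode not in SECRETION_MODES:
            raise ConfigError(f"secretion_mode must be one of {SECRETION_MODES}")
        if self.receptor_localization not in RECEPTOR_LOCALIZATIONS:
            raise ConfigError(f"receptor_localization must be one of {RECEPTOR_LOCALIZATIONS}")
        if self.turnover_variant not in TURNOVER_VARIANTS:
            raise ConfigError(f"turnover_variant must be one of {TURNOVER_VARIANTS}")
        if self.channel_mode not in CHANNEL_MODES:
            raise ConfigError(f"channel_mode must be one of {CHANNEL_MODES}")
        if self.channel_mode == "posterior_only" and not (
                0 < self.posterior_open_arrays <= self.n_arrays):
            raise ConfigError("posterior_open_arrays must lie in [1, n_arrays]")
        if not self.exe_present and self.secretion_mode != "uniform_cavity":
            raise ConfigError(
                "apical/basolateral secretion requires ExE cells; use "
                "secretion_mode='uniform_cavity' when exe_present is off")
        # Consistency of declared compartment widths with the column layout is
        # advisory: overriding is allowed (e.g. reduced-cavity variants).
        if not math.isclose(self.cavity_width, self.expected_width, rel_tol=1e-9):
            warnings.warn(
                f"cavity_width ({self.cavity_width}) != column layout width "
                f"({self.expected_width}); the geometry uses the layout width",
                stacklevel=2)
        if not math.isclose(self.interstitial_width, self.expected_width, rel_tol=1e-9):
            warnings.warn(
                f"interstitial_width ({self.interstitial_width}) != column layout "
                f"width ({self.expected_width}); the geometry uses the layout width",
                stacklevel=2)

    # ------------------------------------------------------------------
    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = cls.__dataclass_fields__
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class ConcentrationMap:
    """Linear map between ligand/receptor ratio and BMP4 concentration.

    Anchored at ratio 0.1 <-> 0.16 ng/mL, the correspondence used to label
    simulated source strengths with experimental concentrations.
    """

    anchor_ratio: float = 0.1
    anchor_ng_per_ml: float = 0.16

    def concentration(self, ratio: float) -> float:
        """ng/mL equivalent of a ligand/receptor ratio (ratio >= 0)."""
        if ratio < 0:
            raise ValueError("ligand/receptor ratio must be non-negative")
        return ratio * self.anchor_ng_per_ml / self.anchor_ratio

    def ratio(self, ng_per_ml: float) -> float:
        """Ligand/receptor ratio equivalent of a concentration in ng/mL."""
        if ng_per_ml < 0:
            raise ValueError("concentration must be non-negative")
        return ng_per_ml * self.anchor_ratio / self.anchor_ng_per_ml


def ligand_receptor_ratio(config: SimulationConfig) -> float:
    """Total-ligand to total-receptor ratio of a configuration."""
    return config.n_ligands / config.n_receptors
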