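"""Simulation configuration and ground truth.

The generator's defaults describe a moist Central African old-growth forest
site: four 9-ha (300 x 300 m) permanent plots, 144 20 x 20 m liana quadrats
(4 per hectare) with 10-m buffers, all trees >= 10 cm DBH mapped in two
censuses, ~1077 liana stems/ha dominated by 1-2 cm stems and a handful of
hyperdominant taxa, a giant-herb cover index on a 10-m point lattice, and a
low-relief plateau dotted with large termite mounds (about 2 per hectare,
radius ~9.9 +/- 3.3 m, height ~4.1 +/- 1.5 m) under a tall, patchy canopy.

Effect-size knobs (``beta_structure``, ``env_response`` / trait-niche
coupling, ``theta_host``) control how strongly the environment drives liana
structure, composition and host choice; all can be set to zero to generate
data under the global null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["SimulationConfig", "GroundTruth", "TRAIT_RANGES", "DEFAULT_BETA"]

#: observed trait ranges (min, max) for the leaf and stem economics traits
TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "Thick": (0.04, 0.2),     # leaf thickness, mm
    "SLA": (13.0, 64.7),      # specific leaf area, mm^2/mg
    "pctC": (38.9, 48.2),     # leaf carbon, %
    "pctN": (2.1, 5.8),       # leaf nitrogen, %
    "pctPO4": (0.07, 0.27),   # leaf phosphorus, %
    "pctK": (0.3, 2.2),       # leaf potassium, %
    "TD": (0.16, 0.59),       # stem tissue density, g/cm^3
}

#: default effects of standardized environment on log liana stem count per
#: quadrat: denser, taller, harder-wooded forest and giant-herb cover all
#: depress liana abundance (the "gap hypothesis" signs); ~-0.15 on the log
#: scale per SD matches a ~15% drop per SD around a 1077 stems/ha mean
DEFAULT_BETA: dict[str, float] = {
    "QMD_T": -0.16,
    "meanTCH": -0.15,
    "WD_T": -0.14,
    "dBA_T": -0.06,
    "GHFC": -0.075,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    # layout
    n_plots: int = 4
    plot_side: float = 300.0
    quadrat_side: float = 20.0
    buffer: float = 10.0
    cell_size: float = 1.0
    quadrat_spacing: float = 50.0
    quadrat_offset: float = 10.0
    # terrain
    base_relief: float = 6.0            # smooth relief amplitude within a plot, m
    terrain_corr_length: float = 60.0   # Gaussian filter sigma, m
    mound_density: float = 2.25         # mounds per ha
    mound_radius_mean_sd: tuple[float, float] = (9.9, 3.3)
    mound_height_mean_sd: tuple[float, float] = (4.1, 1.5)
    # canopy
    canopy_max: float = 45.0            # tallest canopy, m
    canopy_corr_length: float = 20.0
    gap_fraction: float = 0.08          # area fraction of low-canopy gap discs
    gap_radius: float = 12.0
    # trees
    tree_density: float = 450.0         # stems/ha, >= 10 cm DBH
    n_tree_species: int = 60
    tree_dominance: float = 0.4         # Dirichlet concentration of rank abundance
    dbh_scale: float = 12.0             # truncated-exponential DBH scale, cm
    growth_mean_sd: tuple[float, float] = (0.5, 0.4)  # cm between censuses
    mortality: float = 0.02             # per stem between censuses
    recruitment_fraction: float = 0.02  # new stems as fraction of standing count
    # giant herbs
    herb_spacing: float = 10.0
    herb_base_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    herb_canopy_coef: float = 0.12      # latent decrease per m of canopy height
    # lianas
    liana_density: float = 1077.0       # stems/ha
    n_liana_taxa: int = 44
    liana_dominance: float = 0.15       # low concentration -> hyperdominance
    beta_structure: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    env_niche_sd: float = 0.0           # sd of per-taxon env responses (0 = no niches)
    trait_niche_correlation: float = 0.0  # coupling of traits to taxon niches
    theta_host_factor: float = 1.0      # preference multiplier for planted pairs
    n_preferred_pairs: int = 0          # planted (liana taxon, tree species) pairs
    second_host_fraction: float = 0.15
    diameter_mixture: tuple[float, float, float] = (0.62, 0.32, 0.06)
    max_diameter: float = 27.0
    trait_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TRAIT_RANGES))

    def __post_init__(self) -> None:
        if self.plot_side % self.quadrat_side:
            raise ValueError("plot_side must be divisible by quadrat_side")
        for name in ("tree_density", "liana_density", "cell_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mound_density < 0:
            raise ValueError("mound_density must be >= 0")
        for t, (lo, hi) in self.trait_ranges.items():
            if not lo < hi:
                raise ValueError(f"trait range for {t} inverted: [{lo}, {hi}]")
        if not 0 <= self.trait_niche_correlation <= 1:
            raise ValueError("trait_niche_correlation must be in [0, 1]")
        if self.theta_host_factor <= 0:
            raise ValueError("theta_host preference weights must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Generating parameters, kept for recovery tests."""
    beta_structure: dict[str, float]
    env_response: np.ndarray            # n_liana_taxa x n_env
    env_columns: list[str]
    theta_host: np.ndarray              # n_liana_taxa x n_tree_species
    liana_taxa: list[str]
    tree_species: list[str]
    liana_base_abundance: np.ndarray
    tree_base_abundance: np.ndarray
    traits: "object" = None             # TraitTable (pandas DataFrame)
    preferred_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.env_response.shape[0] != len(self.liana_taxa):
            raise ValueError("env_response rows must match liana taxa")
        if self.theta_host.shape != (len(self.liana_taxa), len(self.tree_species)):
            raise ValueError("theta_host shape mismatch")
        if np.any(self.theta_host.sum(axis=1) <= 0):
            raise ValueError("theta_host has an all-zero row")
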