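"""Synthetic census generator.

Generates, from a single seeded :class:`numpy.random.Generator` stream,
everything the analysis pipeline consumes: per-plot DEM/DSM rasters, a
two-census mapped tree inventory, a giant-herb cover lattice, a quadrat-level
liana inventory with host-tree links, and a taxon trait table — together
with the :class:`~lianascape.config.GroundTruth` parameters that produced
them, so recovery and calibration properties can be tested.

The generative model, stage by stage:

* terrain: Gaussian-filtered white noise rescaled to a low relief, plus
  Gaussian-bump termite mounds at Poisson locations;
* canopy: an independent autocorrelated height field in [0, canopy_max] with
  low-canopy gap discs; DSM = DEM + canopy;
* trees: uniform positions, Dirichlet-multinomial species abundances, DBH
  10 + exponential, per-species wood density; census 2 applies growth,
  mortality and recruitment;
* giant herbs: ordered-logit cover index whose latent mean decreases with
  local canopy height (herbs favour gaps);
* lianas: per-quadrat counts are Poisson with log-rate linear in the
  standardized environment (coefficients ``beta_structure``); taxa are drawn
  with probability proportional to base abundance times exp(env niche);
  diameters come from a three-component mixture dominated by 1-2 cm stems;
  each liana picks a host among the tree stems of its buffered window with
  probability proportional to ``theta_host[taxon, species]``;
* traits: uniform within observed ranges, optionally coupled to each taxon's
  environmental niche so a trait-environment signal exists by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import GroundTruth, SimulationConfig
from .io import Raster, build_quadrat_frame, TRAIT_COLUMNS
from .metrics import env_table, ENV_COLUMNS

__all__ = [
    "SyntheticDataset",
    "simulate_landscape",
    "simulate_trees",
    "simulate_giant_herbs",
    "simulate_lianas",
    "simulate_traits",
    "simulate",
]


def _smooth_field(shape: tuple[int, int], sigma_cells: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), sigma_cells, mode="reflect")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def simulate_landscape(config: SimulationConfig, rng: np.random.Generator,
                       ) -> tuple[Raster, Raster]:
    """One plot's DEM and DSM at ``config.cell_size`` resolution."""
    cs = config.cell_size
    n = int(round(config.plot_side / cs))
    if n < 1:
        raise ValueError("zero-area landscape")
    shape = (n, n)
    dem = config.base_relief * _smooth_field(shape, config.terrain_corr_length / cs, rng)
    # termite mounds: Poisson number, Gaussian bumps (sd = radius / 2)
    area_ha = (config.plot_side / 100.0) ** 2
    n_mounds = rng.poisson(config.mound_density * area_ha)
    x, y = np.meshgrid(np.arange(n) * cs, np.arange(n) * cs)
    for _ in range(n_mounds):
        cx, cy = rng.uniform(0, config.plot_side, 2)
        radius = max(2.0, rng.normal(*config.mound_radius_mean_sd))
        height = max(0.5, rng.normal(*config.mound_height_mean_sd))
        sigma = radius / 2.0
        dem += height * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma**2))
    canopy = config.canopy_max * _smooth_field(shape, config.canopy_corr_length / cs, rng)
    # gap discs: canopy knocked down to near zero
    gap_area = config.gap_fraction * config.plot_side**2
    n_gaps = max(0, rng.poisson(gap_area / (np.pi * config.gap_radius**2)))
    for _ in range(n_gaps):
        cx, cy = rng.uniform(0, config.plot_side, 2)
        disc = (x - cx) ** 2 + (y - cy) ** 2 <= config.gap_radius**2
        canopy[disc] = np.minimum(canopy[disc], rng.uniform(0, 2))
    dsm = dem + np.maximum(canopy, 0.0)
    return (Raster(0.0, 0.0, cs, dem), Raster(0.0, 0.0, cs, dsm))


def _rank_abundance(k: int, concentration: float, rng: np.random.Generator) -> np.ndarray:
    p = rng.dirichlet(np.full(k, concentration))
    return np.sort(p)[::-1]


def _raster_at(r: Raster, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    col = np.clip((x - r.x0) / r.cell_size, 0, r.ncols - 1).astype(int)
    row = np.clip(r.nrows - 1 - (y - r.y0) / r.cell_size, 0, r.nrows - 1).astype(int)
    return r.values[row, col]


def simulate_trees(config: SimulationConfig, dem: Raster, rng: np.random.Generator,
                   plot_id: str, species_probs: np.ndarray,
                   species_wd: np.ndarray, start_id: int = 0) -> pd.DataFrame:
    """Two-census tree stem table for one plot."""
    area_ha = (config.plot_side / 100.0) ** 2
    n = rng.poisson(config.tree_density * area_ha)
    if n < 1:
        raise ValueError("tree density implies < 1 stem per plot")
    x = rng.uniform(0, config.plot_side, n)
    y = rng.uniform(0, config.plot_side, n)
    sp = rng.choice(len(species_probs), size=n, p=species_probs)
    dbh1 = 10.0 + rng.exponential(config.dbh_scale, n)
    growth = np.maximum(rng.normal(*config.growth_mean_sd, n), 0.0)
    dead = rng.random(n) < config.mortality
    dbh2 = np.where(dead, np.nan, dbh1 + growth)
    # recruits: present only in census 2, DBH just over the 10 cm threshold
    n_rec = rng.poisson(config.recruitment_fraction * n)
    xr = rng.uniform(0, config.plot_side, n_rec)
    yr = rng.uniform(0, config.plot_side, n_rec)
    spr = rng.choice(len(species_probs), size=n_rec, p=species_probs)
    dbhr = 10.0 + rng.uniform(0, 1.0, n_rec)
    df = pd.DataFrame({
        "stem_id": [f"{plot_id}-T{start_id + i:05d}" for i in range(n + n_rec)],
        "species": [f"TS{j + 1:02d}" for j in np.concatenate([sp, spr])],
        "plot_id": plot_id,
        "x": np.concatenate([x, xr]),
        "y": np.concatenate([y, yr]),
        "dbh_census1": np.concatenate([dbh1, np.full(n_rec, np.nan)]),
        "dbh_census2": np.concatenate([dbh2, dbhr]),
        "wood_density": species_wd[np.concatenate([sp, spr])],
    })
    return df


def simulate_giant_herbs(config: SimulationConfig, dsm: Raster, dem: Raster,
                         rng: np.random.Generator, plot_id: str) -> pd.DataFrame:
    """Ordinal cover index on a 10-m lattice (100 points/ha)."""
    pts = np.arange(0, config.plot_side, config.herb_spacing)
    gx, gy = np.meshgrid(pts, pts)
    gx, gy = gx.ravel(), gy.ravel()
    chm = np.clip(_raster_at(dsm, gx, gy) - _raster_at(dem, gx, gy), 0, None)
    p1, p2, _ = config.herb_base_probs
    # ordered logit: cutpoints from the base marginal, latent shifted by canopy
    c1 = np.log(p1 / (1 - p1))
    c2 = np.log((p1 + p2) / (1 - p1 - p2))
    latent = -config.herb_canopy_coef * (chm - chm.mean()) + rng.logistic(size=gx.size)
    idx = np.where(latent <= c1, 1, np.where(latent <= c2, 2, 3))
    return pd.DataFrame({"plot_id": plot_id, "x": gx, "y": gy,
                         "cover_index": idx.astype(float)})


def _diameters(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(3, size=n, p=np.asarray(config.diameter_mixture)
                      / np.sum(config.diameter_mixture))
    d = np.empty(n)
    d[comp == 0] = rng.uniform(1, 2, (comp == 0).sum())
    d[comp == 1] = rng.uniform(2, 5, (comp == 1).sum())
    tail = 5.0 + rng.exponential(3.0, (comp == 2).sum())
    d[comp == 2] = np.minimum(tail, config.max_diameter)
    return d


def simulate_lianas(config: SimulationConfig, trees: pd.DataFrame,
                    env: pd.DataFrame, quadrats: pd.DataFrame,
                    truth: GroundTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Quadrat-level liana census with host links.

    Requires the standardized environment table (``z_`` columns of
    :func:`lianascape.metrics.env_table`) for the same quadrat frame.
    """
    beta = np.array([truth.beta_structure.get(c, 0.0) for c in truth.env_columns])
    Z = env[[f"z_{c}" for c in truth.env_columns]].to_numpy(dtype=float)
    quad_area_ha = (config.quadrat_side / 100.0) ** 2
    base_log = np.log(config.liana_density * quad_area_ha)
    lam = np.exp(base_log + Z @ beta)
    counts = rng.poisson(lam)
    taxa = truth.liana_taxa
    theta = truth.theta_host
    mech_by_taxon = {t: ("active" if i % 2 == 0 else "passive")
                     for i, t in enumerate(taxa)}
    sp_index = {s: j for j, s in enumerate(truth.tree_species)}

    rows = []
    k = 0
    for pos, ((_, q), n_q) in enumerate(zip(quadrats.iterrows(), counts)):
        if n_q == 0:
            continue
        z = Z[pos]
        logits = np.log(truth.liana_base_abundance) + truth.env_response @ z
        pt = np.exp(logits - logits.max())
        pt /= pt.sum()
        tax_idx = rng.choice(len(taxa), size=n_q, p=pt)
        d = _diameters(n_q, config, rng)
        # host pool: tree stems (census 2) in the buffered window
        t = trees[trees["plot_id"] == q["plot_id"]]
        inw = ((t["x"] >= q["bx0"]) & (t["x"] < q["bx0"] + q["bside"])
               & (t["y"] >= q["by0"]) & (t["y"] < q["by0"] + q["bside"])
               & t["dbh_census2"].notna())
        pool = t[inw]
        pool_ids = pool["stem_id"].to_numpy()
        pool_sp = np.array([sp_index[s] for s in pool["species"]])
        for i in range(n_q):
            ti = tax_idx[i]
            host1 = host2 = None
            if pool_ids.size:
                w = theta[ti, pool_sp].astype(float)
                w /= w.sum()
                host1 = pool_ids[rng.choice(pool_ids.size, p=w)]
                if pool_ids.size > 1 and rng.random() < config.second_host_fraction:
                    host2 = host1
                    while host2 == host1:
                        host2 = pool_ids[rng.choice(pool_ids.size, p=w)]
            rows.append({
                "liana_id": f"L{k:05d}",
                "taxon": taxa[ti],
                "quadrat_id": q["quadrat_id"],
                "diameter": d[i],
                "host1_stem_id": host1,
                "host2_stem_id": host2,
                "mechanism": mech_by_taxon[taxa[ti]],
            })
            k += 1
    return pd.DataFrame(rows, columns=["liana_id", "taxon", "quadrat_id", "diameter",
                                       "host1_stem_id", "host2_stem_id", "mechanism"])


def simulate_traits(config: SimulationConfig, truth_env_response: np.ndarray,
                    taxa: list[str], rng: np.random.Generator) -> pd.DataFrame:
    """Per-taxon traits within configured ranges, coupled to env niches.

    Trait ``m`` is tied to environmental axis ``m mod n_env``: the latent
    trait score is ``rho * z(niche) + sqrt(1 - rho^2) * noise``, mapped into
    the trait range through the normal CDF, so ``rho = 0`` gives independent
    traits and ``rho = 1`` makes the trait a monotone function of the niche.
    """
    from scipy.stats import norm

    rho = config.trait_niche_correlation
    n_taxa = len(taxa)
    n_env = truth_env_response.shape[1]
    out = {"taxon": taxa}
    for m, (tname, (lo, hi)) in enumerate(config.trait_ranges.items()):
        niche = truth_env_response[:, m % n_env]
        sd = niche.std()
        zn = (niche - niche.mean()) / sd if sd > 0 else np.zeros(n_taxa)
        z = rho * zn + np.sqrt(1 - rho**2) * rng.standard_normal(n_taxa)
        u = norm.cdf(z)
        out[tname] = lo + (hi - lo) * np.clip(u, 0.005, 0.995)
    return pd.DataFrame(out)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    quadrats: pd.DataFrame
    rasters: dict[str, tuple[Raster, Raster]]  # plot_id -> (dem, dsm)
    trees: pd.DataFrame
    herbs: pd.DataFrame
    env: pd.DataFrame
    lianas: pd.DataFrame
    traits: pd.DataFrame
    truth: GroundTruth


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator from the single configured seed."""
    rng = np.random.default_rng(config.seed)
    quadrats = build_quadrat_frame(
        n_plots=config.n_plots, plot_side=config.plot_side,
        quadrat_side=config.quadrat_side, buffer=config.buffer,
        spacing=config.quadrat_spacing, offset=config.quadrat_offset,
    )
    tree_species = [f"TS{j + 1:02d}" for j in range(config.n_tree_species)]
    liana_taxa = [f"LT{j + 1:02d}" for j in range(config.n_liana_taxa)]
    tree_probs = _rank_abundance(config.n_tree_species, config.tree_dominance, rng)
    species_wd = np.clip(rng.normal(0.6, 0.15, config.n_tree_species), 0.2, 1.2)
    liana_probs = _rank_abundance(config.n_liana_taxa, config.liana_dominance, rng)
    env_response = config.env_niche_sd * rng.standard_normal(
        (config.n_liana_taxa, len(ENV_COLUMNS)))
    theta = np.ones((config.n_liana_taxa, config.n_tree_species))
    preferred: list[tuple[str, str]] = []
    for k in range(config.n_preferred_pairs):
        # plant preferences between abundant liana taxa and abundant tree species
        i, j = k % config.n_liana_taxa, k % config.n_tree_species
        theta[i, j] = config.theta_host_factor
        preferred.append((liana_taxa[i], tree_species[j]))

    rasters: dict[str, tuple[Raster, Raster]] = {}
    trees_parts, herbs_parts = [], []
    for p in range(config.n_plots):
        plot_id = f"P{p + 1}"
        dem, dsm = simulate_landscape(config, rng)
        rasters[plot_id] = (dem, dsm)
        trees_parts.append(simulate_trees(config, dem, rng, plot_id,
                                          tree_probs, species_wd))
        herbs_parts.append(simulate_giant_herbs(config, dsm, dem, rng, plot_id))
    trees = pd.concat(trees_parts, ignore_index=True)
    herbs = pd.concat(herbs_parts, ignore_index=True)
    env = env_table(trees, quadrats, rasters=rasters, herbs=herbs)
    truth = GroundTruth(
        beta_structure=dict(config.beta_structure),
        env_response=env_response, env_columns=list(ENV_COLUMNS),
        theta_host=theta, liana_taxa=liana_taxa, tree_species=tree_species,
        liana_base_abundance=liana_probs, tree_base_abundance=tree_probs,
        preferred_pairs=preferred,
    )
    lianas = simulate_lianas(config, trees, env, quadrats, truth, rng)
    traits = simulate_traits(config, env_response, liana_taxa, rng).set_index("taxon")
    truth.traits = traits
    return SyntheticDataset(
        config=config, quadrats=quadrats, rasters=rasters, trees=trees,
        herbs=herbs, env=env, lianas=lianas, traits=traits, truth=truth,
    )
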