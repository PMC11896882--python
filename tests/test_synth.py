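import numpy as np
import pandas as pd
import pytest

from conftest import null_config
from lianascape import io
from lianascape.config import SimulationConfig
from lianascape.synth import (simulate, simulate_giant_herbs, simulate_landscape,
                              simulate_traits)


class TestConfigValidation:
    def test_quadrat_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            SimulationConfig(plot_side=310.0)

    def test_positive_densities(self):
        with pytest.raises(ValueError):
            SimulationConfig(tree_density=0.0)

    def test_inverted_trait_range(self):
        with pytest.raises(ValueError, match="inverted"):
            SimulationConfig(trait_ranges={"TD": (0.6, 0.2)})


class TestLandscape:
    def test_no_mounds_leaves_base_relief_only(self):
        cfg = null_config(0, mound_density=0.0)
        rng = np.random.default_rng(0)
        dem, dsm = simulate_landscape(cfg, rng)
        assert np.ptp(dem.values) <= cfg.base_relief + 1e-9
        assert np.all(dsm.values - dem.values >= 0.0)

    def test_relief_stays_plausibly_low(self):
        # the emulated site is a plateau: total relief well under ~25 m
        cfg = null_config(0)
        dem, _ = simulate_landscape(cfg, np.random.default_rng(3))
        assert np.ptp(dem.values) <= 25.0

    def test_mound_count_is_poisson_with_expected_mean(self):
        # 2 mounds/ha on 9 ha -> mean 18; check the generator draw directly
        cfg = SimulationConfig(seed=0, mound_density=2.0, plot_side=300.0)
        area_ha = (cfg.plot_side / 100) ** 2
        rng = np.random.default_rng(99)
        draws = rng.poisson(cfg.mound_density * area_ha, size=2000)
        assert draws.mean() == pytest.approx(18.0, rel=0.05)
        assert draws.var() == pytest.approx(18.0, rel=0.15)

    def test_mound_raises_summit_above_neighbourhood(self):
        cfg = null_config(0, mound_density=10.0, base_relief=0.5)
        dem, _ = simulate_landscape(cfg, np.random.default_rng(5))
        i, j = np.unravel_index(np.argmax(dem.values), dem.values.shape)
        assert dem.values[i, j] > np.median(dem.values) + 1.0


class TestTrees:
    def test_species_frequencies_follow_rank_abundance(self):
        cfg = null_config(1, tree_density=2000.0)  # large n for the LLN check
        ds = simulate(cfg)
        freq = (ds.trees["species"].value_counts(normalize=True)
                .reindex(ds.truth.tree_species).fillna(0.0).to_numpy())
        assert np.corrcoef(freq, ds.truth.tree_base_abundance)[0, 1] > 0.99
        assert np.abs(freq - ds.truth.tree_base_abundance).max() < 0.03

    def test_census_change_zero_without_dynamics(self):
        from lianascape.metrics import window_tree_metrics
        from lianascape.synth import simulate_trees
        cfg = null_config(2, growth_mean_sd=(0.0, 0.0), mortality=0.0,
                          recruitment_fraction=0.0)
        rng = np.random.default_rng(2)
        probs = np.full(cfg.n_tree_species, 1 / cfg.n_tree_species)
        wd = np.full(cfg.n_tree_species, 0.6)
        trees = simulate_trees(cfg, None, rng, "P1", probs, wd)
        qf = io.build_quadrat_frame(n_plots=1, plot_side=cfg.plot_side)
        m = window_tree_metrics(trees, qf)
        assert np.allclose(m["dBA_T"], 0.0, atol=1e-12)

    def test_stem_table_passes_validation(self, demo_dataset):
        io.validate_stem_table(demo_dataset.trees,
                               plot_side=demo_dataset.config.plot_side)


class TestGiantHerbs:
    def test_marginal_matches_base_probs_without_canopy_effect(self):
        cfg = null_config(3, herb_canopy_coef=0.0)
        rng = np.random.default_rng(7)
        dem, dsm = simulate_landscape(cfg, rng)
        parts = [simulate_giant_herbs(cfg, dsm, dem, rng, "P1") for _ in range(20)]
        herbs = pd.concat(parts)
        freq = herbs["cover_index"].value_counts(normalize=True).sort_index()
        np.testing.assert_allclose(freq.to_numpy(), cfg.herb_base_probs, atol=0.02)

    def test_strong_canopy_effect_pushes_herbs_into_gaps(self):
        cfg = null_config(4, herb_canopy_coef=1.0)
        rng = np.random.default_rng(8)
        dem, dsm = simulate_landscape(cfg, rng)
        herbs = simulate_giant_herbs(cfg, dsm, dem, rng, "P1")
        from lianascape.synth import _raster_at
        chm = _raster_at(dsm, herbs["x"].to_numpy(), herbs["y"].to_numpy()) - \
            _raster_at(dem, herbs["x"].to_numpy(), herbs["y"].to_numpy())
        gap = chm < np.median(chm)
        assert herbs.loc[gap, "cover_index"].mean() > herbs.loc[~gap, "cover_index"].mean()


class TestLianas:
    def test_diameter_mixture_matches_census_quantiles(self, demo_dataset):
        d = demo_dataset.lianas["diameter"]
        assert (d >= 1).all() and (d <= 27).all()
        assert (d < 2).mean() == pytest.approx(0.62, abs=0.04)
        assert (d < 5).mean() == pytest.approx(0.94, abs=0.03)

    def test_neutral_host_choice_tracks_availability(self, demo_dataset):
        from lianascape import hosts
        ds = demo_dataset
        links, _ = hosts.build_links(ds.lianas, ds.trees, ds.quadrats)
        host_freq = links["host_species"].value_counts(normalize=True)
        tree_freq = ds.trees["species"].value_counts(normalize=True)
        common = host_freq.index.intersection(tree_freq.index)
        assert np.corrcoef(host_freq[common], tree_freq[common])[0, 1] > 0.98

    def test_preferred_pair_links_exceed_neutral_expectation(self):
        cfg = null_config(9, theta_host_factor=10.0, n_preferred_pairs=1)
        ds = simulate(cfg)
        from lianascape import hosts
        links, _ = hosts.build_links(ds.lianas, ds.trees, ds.quadrats)
        la = links[links["taxon"] == "LT01"]
        share = (la["host_species"] == "TS01").mean()
        neutral = (ds.trees["species"] == "TS01").mean()
        assert share > 1.5 * neutral

    def test_homogeneous_counts_without_structure_effects(self, demo_dataset):
        # beta = 0: per-quadrat counts should be Poisson-homogeneous
        counts = (demo_dataset.lianas.groupby("quadrat_id").size()
                  .reindex(demo_dataset.quadrats["quadrat_id"], fill_value=0))
        ratio = counts.var() / counts.mean()
        assert 0.6 < ratio < 1.6  # index of dispersion near 1


class TestTraits:
    def test_values_within_configured_ranges(self, demo_dataset):
        from lianascape.config import TRAIT_RANGES
        tr = demo_dataset.traits
        for name, (lo, hi) in TRAIT_RANGES.items():
            assert tr[name].between(lo, hi).all()

    def test_strong_coupling_creates_cwm_env_correlation(self):
        from lianascape.traitenv import cwm
        cfg = null_config(10, env_niche_sd=0.5, trait_niche_correlation=0.9)
        ds = simulate(cfg)
        A = io.build_abundance_matrix(ds.lianas, ds.quadrats)
        A = A.loc[A.sum(1) > 0]
        m = cwm(A, ds.traits)
        # trait column 0 is tied to the first environmental axis
        r = np.corrcoef(m.iloc[:, 0], ds.env["z_N_T"].loc[m.index])[0, 1]
        assert abs(r) > 0.3

    def test_zero_coupling_leaves_traits_independent(self, rng):
        resp = rng.standard_normal((20, 8))
        cfg = null_config(11)
        tr = simulate_traits(cfg, resp, [f"LT{j}" for j in range(20)],
                             np.random.default_rng(0))
        r = np.corrcoef(tr["Thick"], resp[:, 0])[0, 1]
        assert abs(r) < 0.5  # no systematic coupling


class TestDeterminism:
    def test_same_seed_reproduces_tables_bit_for_bit(self):
        a = simulate(null_config(123))
        b = simulate(null_config(123))
        pd.testing.assert_frame_equal(a.trees, b.trees)
        pd.testing.assert_frame_equal(a.lianas, b.lianas)
        pd.testing.assert_frame_equal(a.herbs, b.herbs)
        pd.testing.assert_frame_equal(a.traits, b.traits)
        for p in a.rasters:
            np.testing.assert_array_equal(a.rasters[p][0].values,
                                          b.rasters[p][0].values)
        np.testing.assert_array_equal(a.truth.theta_host, b.truth.theta_host)

    def test_different_seeds_differ(self):
        a = simulate(null_config(1))
        b = simulate(null_config(2))
        assert not a.trees["x"].equals(b.trees["x"])
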