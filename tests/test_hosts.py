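import numpy as np
import pandas as pd
import pytest

from lianascape import hosts, io


def toy_world():
    """One quadrat whose window holds 4 trees of 2 species, plus 5 lianas."""
    qf = io.build_quadrat_frame(n_plots=1).iloc[:1].copy()
    qid = qf["quadrat_id"].iloc[0]
    trees = pd.DataFrame({
        "stem_id": ["t1", "t2", "t3", "t4"],
        "species": ["X", "X", "Y", "Y"],
        "plot_id": ["P1"] * 4,
        "x": [12.0, 18.0, 22.0, 28.0],
        "y": [12.0, 18.0, 22.0, 28.0],
        "dbh_census1": [15.0] * 4,
        "dbh_census2": [15.5] * 4,
        "wood_density": [0.6] * 4,
    })
    lianas = pd.DataFrame({
        "liana_id": [f"l{i}" for i in range(5)],
        "taxon": ["LA"] * 5,
        "quadrat_id": [qid] * 5,
        "diameter": [2.0] * 5,
        "host1_stem_id": ["t1", "t1", "t2", "t3", None],
        "host2_stem_id": [None, "t4", None, None, None],
        "mechanism": ["active"] * 5,
    })
    return qf, trees, lianas


class TestRvCoefficient:
    def test_self_similarity_is_one(self, rng):
        X = rng.standard_normal((12, 5))
        assert hosts.rv_coefficient(X, X) == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        X = rng.standard_normal((15, 4))
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert hosts.rv_coefficient(X, X @ Q) == pytest.approx(1.0)

    def test_bounded_and_nonnegative(self, rng):
        for _ in range(10):
            X = rng.standard_normal((10, 3))
            Y = rng.standard_normal((10, 4))
            rv = hosts.rv_coefficient(X, Y)
            assert 0.0 <= rv <= 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            hosts.rv_coefficient(np.ones((5, 2)), np.random.default_rng(0).normal(size=(5, 2)))

    def test_permutation_p_valid(self, rng):
        X = rng.standard_normal((12, 3))
        Y = rng.standard_normal((12, 3))
        res = hosts.rv_test(X, Y, n_perm=99, rng=rng)
        assert 0 < res.p_value <= 1
        assert res.null.shape == (99,)


class TestBuildLinks:
    def test_second_host_makes_two_links(self):
        qf, trees, lianas = toy_world()
        links, excluded = hosts.build_links(lianas, trees, qf)
        assert excluded == 1  # the host-less liana
        assert len(links) == 5  # 4 primary + 1 secondary
        assert (links[links["liana_id"] == "l1"].shape[0]) == 2

    def test_host_outside_window_rejected(self):
        qf, trees, lianas = toy_world()
        trees.loc[trees["stem_id"] == "t3", ["x", "y"]] = [200.0, 200.0]
        with pytest.warns(UserWarning, match="outside"):
            links, _ = hosts.build_links(lianas, trees, qf)
        assert "t3" not in set(links["host_stem_id"])

    def test_all_generated_hosts_inside_windows(self, demo_dataset):
        import warnings
        ds = demo_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # any out-of-window host would warn
            links, _ = hosts.build_links(ds.lianas, ds.trees, ds.quadrats)
        assert len(links) > len(ds.lianas) * 0.9


class TestClassification:
    @pytest.mark.parametrize("observed, lo, hi, expected", [
        (43, 7, 18, "attraction"),
        (0, 3, 12, "repulsion"),
        (18, 7, 19, "ns"),
        (6, 0, 6, "ns"),   # upper bound inclusive
        (3, 3, 12, "ns"),  # lower bound inclusive
    ])
    def test_envelope_convention(self, observed, lo, hi, expected):
        assert hosts.classify_association(observed, lo, hi) == expected

    def test_invalid_envelope_rejected(self):
        with pytest.raises(ValueError):
            hosts.classify_association(1, 5, 2)


class TestRandomization:
    def test_single_species_window_is_never_significant(self, rng):
        qf, trees, lianas = toy_world()
        trees["species"] = "X"  # no freedom in the null
        links, _ = hosts.build_links(lianas, trees, qf)
        res = hosts.host_randomization_test(links, trees, qf, liana_min=0,
                                            tree_min=0, n_rep=199, rng=rng)
        assert (res["class"] == "ns").all()
        assert (res["observed"] == res["lo"]).all()
        assert (res["observed"] == res["hi"]).all()

    def test_single_link_two_trees_exact_envelope(self, rng):
        # one liana, window of 2 trees (species X, Y): null count on X is
        # Binomial(1, 1/2) -> envelope [0, 1] and class ns
        qf = io.build_quadrat_frame(n_plots=1).iloc[:1].copy()
        qid = qf["quadrat_id"].iloc[0]
        trees = pd.DataFrame({
            "stem_id": ["t1", "t2"], "species": ["X", "Y"], "plot_id": ["P1"] * 2,
            "x": [15.0, 25.0], "y": [15.0, 25.0],
            "dbh_census1": [15.0] * 2, "dbh_census2": [15.0] * 2,
            "wood_density": [0.6] * 2,
        })
        lianas = pd.DataFrame({
            "liana_id": ["l0"], "taxon": ["LA"], "quadrat_id": [qid],
            "diameter": [2.0], "host1_stem_id": ["t1"], "host2_stem_id": [None],
            "mechanism": ["active"],
        })
        links, _ = hosts.build_links(lianas, trees, qf)
        res = hosts.host_randomization_test(links, trees, qf, liana_min=0,
                                            tree_min=0, n_rep=999, rng=rng)
        row = res.set_index("tree_species").loc["X"]
        assert (row["lo"], row["hi"]) == (0, 1)
        assert row["class"] == "ns"
        assert row["null_mean"] == pytest.approx(0.5, abs=0.06)

    def test_null_mean_matches_exact_expectation(self, rng):
        # E[count(taxon, species)] = sum over links of the species' share of
        # that link's window pool
        qf, trees, lianas = toy_world()
        links, _ = hosts.build_links(lianas, trees, qf)
        res = hosts.host_randomization_test(links, trees, qf, liana_min=0,
                                            tree_min=0, n_rep=2999, rng=rng)
        expect_x = len(links) * 0.5  # 2 of 4 pool trees are species X
        got = res.set_index("tree_species")["null_mean"]
        assert got["X"] == pytest.approx(expect_x, rel=0.05)
        assert got["Y"] == pytest.approx(expect_x, rel=0.05)

    def test_replicates_conserve_links_per_taxon(self, demo_dataset, rng):
        ds = demo_dataset
        links, _ = hosts.build_links(ds.lianas, ds.trees, ds.quadrats)
        res = hosts.host_randomization_test(links, ds.trees, ds.quadrats,
                                            n_rep=99, rng=rng)
        # the null only moves links among trees: per-taxon null totals over
        # ALL species equal the observed link totals, so over the reported
        # (filtered) species the null mean total cannot exceed them
        per_taxon = links.groupby("taxon").size()
        for t, g in res.groupby("taxon"):
            assert g["null_mean"].sum() <= per_taxon[t] + 1e-9
            assert g["observed"].sum() <= per_taxon[t]

    def test_filters_remove_rare_taxa(self, demo_dataset, rng):
        ds = demo_dataset
        links, _ = hosts.build_links(ds.lianas, ds.trees, ds.quadrats)
        res = hosts.host_randomization_test(links, ds.trees, ds.quadrats,
                                            liana_min=60, tree_min=100,
                                            n_rep=49, rng=rng)
        counts = links.groupby("taxon")["liana_id"].nunique()
        assert set(res["taxon"]) == set(counts.index[counts > 60])


class TestSummaries:
    def test_published_census_tallies_reproduced(self):
        table = hosts.load_published_associations()
        s = hosts.summarize_associations(table)
        assert s["n_pairs"] == 240
        assert s["n_attraction"] == 23
        assert s["n_repulsion"] == 22
        assert s["percent_significant"] == 19

    def test_all_ns_summary(self):
        df = pd.DataFrame({"taxon": ["a"], "tree_species": ["X"],
                           "mechanism": ["active"], "observed": [1],
                           "lo": [0], "hi": [2], "class": ["ns"]})
        s = hosts.summarize_associations(df)
        assert (s["n_attraction"], s["n_repulsion"], s["percent_significant"]) == (0, 0, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hosts.summarize_associations(pd.DataFrame())
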