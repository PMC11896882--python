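import subprocess

import numpy as np
import pandas as pd
import pytest

from lianascape import ordination


def direct_nsca_inertia(A: pd.DataFrame) -> float:
    """Independent elementwise oracle: sum_i r_i sum_j (p_ij/r_i - c_j)^2."""
    P = A.to_numpy(float) / A.to_numpy().sum()
    r = P.sum(1)
    c = P.sum(0)
    return float(sum(r[i] * sum((P[i, j] / r[i] - c[j]) ** 2 for j in range(P.shape[1]))
                     for i in range(P.shape[0])))


class TestNsca:
    def test_identical_profiles_have_zero_inertia(self):
        A = pd.DataFrame([[2, 4, 6], [1, 2, 3], [3, 6, 9]])
        res = ordination.nsca(A)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_hand_computation(self):
        res = ordination.nsca(pd.DataFrame([[10, 0], [0, 10]]))
        assert res.total_inertia == pytest.approx(0.5)
        assert res.eigenvalues[0] == pytest.approx(0.5)
        assert np.sum(res.eigenvalues > 1e-12) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_eigenvalue_sum_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        A = pd.DataFrame(rng.integers(0, 25, (10, 6)) + np.eye(10, 6, dtype=int))
        res = ordination.nsca(A)
        assert res.eigenvalues.sum() == pytest.approx(direct_nsca_inertia(A), abs=1e-10)
        assert res.total_inertia == pytest.approx(direct_nsca_inertia(A), abs=1e-10)

    def test_site_scores_orthogonal_under_row_weights(self, rng):
        A = pd.DataFrame(rng.integers(1, 30, (12, 8)))
        res = ordination.nsca(A)
        F = res.site_scores.to_numpy()
        G = F.T @ (res.row_weights.to_numpy()[:, None] * F)
        np.testing.assert_allclose(G, np.diag(np.diag(G)), atol=1e-12)
        np.testing.assert_allclose(np.diag(G), res.eigenvalues, atol=1e-12)

    def test_orientation_deterministic(self, rng):
        A = pd.DataFrame(rng.integers(0, 20, (9, 5)))
        res = ordination.nsca(A)
        for ax in res.taxon_scores.columns:
            v = res.taxon_scores[ax]
            assert v.iloc[int(np.argmax(np.abs(v.to_numpy())))] > 0

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            ordination.nsca(pd.DataFrame([[1, 2, 3]]))
        with pytest.raises(ValueError, match="zero-total"):
            ordination.nsca(pd.DataFrame([[1, 2], [0, 0]]))


class TestNscaiv:
    def test_saturated_gradient_fully_explained(self):
        # two site profiles alternating along one axis perfectly coded by E
        A = pd.DataFrame([[10, 0], [0, 10], [10, 0], [0, 10]])
        E = pd.DataFrame({"e": [1.0, -1.0, 1.0, -1.0]})
        res = ordination.nscaiv(A, E, n_perm=0)
        assert res.constrained_fraction == pytest.approx(1.0)

    def test_fraction_bounds_and_monotonicity(self, rng):
        A = pd.DataFrame(rng.integers(0, 20, (15, 6)) + 1)
        E = pd.DataFrame(rng.standard_normal((15, 3)), columns=list("abc"))
        full = ordination.nscaiv(A, E, n_perm=0).constrained_fraction
        sub = ordination.nscaiv(A, E[["a", "b"]], n_perm=0).constrained_fraction
        assert 0.0 <= sub <= full <= 1.0 + 1e-12

    def test_permutation_p_in_unit_interval(self, rng):
        A = pd.DataFrame(rng.integers(0, 20, (12, 5)) + 1)
        E = pd.DataFrame(rng.standard_normal((12, 2)))
        res = ordination.nscaiv(A, E, n_perm=99, rng=rng)
        assert 0 < res.p_value <= 1
        assert res.null_fractions.shape == (99,)

    def test_collinear_environment_rejected(self, rng):
        A = pd.DataFrame(rng.integers(1, 9, (8, 4)))
        E = pd.DataFrame({"a": np.arange(8.0)})
        E["b"] = 2 * E["a"]
        with pytest.raises(np.linalg.LinAlgError):
            ordination.nscaiv(A, E, n_perm=0)


class TestPcca:
    def test_empty_conditioning_equals_cca(self, rng):
        A = pd.DataFrame(rng.integers(0, 30, (12, 7)) + 1)
        E = pd.DataFrame(rng.standard_normal((12, 3)))
        a = ordination.pcca(A, E, None, n_perm=0)
        b = ordination.cca(A, E, n_perm=0)
        assert a.constrained_fraction == pytest.approx(b.constrained_fraction, abs=1e-12)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-12)

    def test_env_inside_conditioning_span_explains_nothing(self, rng):
        A = pd.DataFrame(rng.integers(1, 20, (10, 5)))
        coords = pd.DataFrame({"x": rng.uniform(0, 100, 10),
                               "y": rng.uniform(0, 100, 10)})
        E = pd.DataFrame({"e": coords["x"] - coords["x"].mean()})
        res = ordination.pcca(A, E, coords, n_perm=0)
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-10)

    def test_projection_decomposition_inequality(self, rng):
        A = pd.DataFrame(rng.integers(0, 15, (14, 6)) + 1)
        Z = pd.DataFrame(rng.standard_normal((14, 2)), columns=["z1", "z2"])
        E = pd.DataFrame(rng.standard_normal((14, 2)), columns=["e1", "e2"])
        both = ordination.cca(A, pd.concat([Z, E], axis=1), n_perm=0).constrained_inertia
        z_only = ordination.cca(A, Z, n_perm=0).constrained_inertia
        e_after = ordination._constrained(A, E, chi_square=True, n_axes=None,
                                          n_perm=0, rng=None, Z=Z).constrained_inertia
        assert z_only + e_after <= both + 1e-8

    def test_cca_fraction_matches_vegan(self, rng, tmp_path):
        A = pd.DataFrame(rng.integers(0, 30, (12, 7)),
                         columns=[f"sp{j}" for j in range(7)])
        A += 1  # avoid zero rows
        E = pd.DataFrame(rng.standard_normal((12, 3)), columns=["e1", "e2", "e3"])
        A.to_csv(tmp_path / "A.csv", index=False)
        E.to_csv(tmp_path / "E.csv", index=False)
        script = (
            'suppressMessages(library(vegan));'
            f'A <- read.csv("{tmp_path}/A.csv"); E <- read.csv("{tmp_path}/E.csv");'
            'm <- cca(A ~ e1 + e2 + e3, data = E);'
            'cat(sprintf("%.10f", m$CCA$tot.chi / m$tot.chi))'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        mine = ordination.cca(A, E, n_perm=0).constrained_fraction
        assert mine == pytest.approx(float(out.stdout.strip()), abs=1e-8)


class TestVariogram:
    def coords(self, n, rng):
        return pd.DataFrame({"x": rng.uniform(0, 100, n), "y": rng.uniform(0, 100, n)})

    def test_constant_scores_give_zero_semivariance(self, rng):
        v = ordination.variogram_permutation_test(
            np.full(20, 3.0), self.coords(20, rng), n_classes=5, n_perm=49, rng=rng)
        assert np.all(v.semivariance[v.n_pairs > 0] == 0.0)

    def test_two_sites_half_squared_difference(self, rng):
        coords = pd.DataFrame({"x": [0.0, 10.0], "y": [0.0, 0.0]})
        v = ordination.variogram_permutation_test(
            np.array([0.0, 1.0]), coords, n_classes=1, n_perm=19, rng=rng)
        assert v.semivariance[0] == pytest.approx(0.5)

    def test_envelope_ordering_and_flags(self, rng):
        scores = rng.standard_normal(30)
        v = ordination.variogram_permutation_test(
            scores, self.coords(30, rng), n_classes=6, n_perm=199, rng=rng)
        ok = v.n_pairs > 0
        assert np.all(v.envelope_lo[ok] <= v.envelope_hi[ok] + 1e-12)
        assert np.all(v.semivariance[ok] >= 0)

    def test_strong_gradient_detected(self, rng):
        n = 40
        coords = self.coords(n, rng)
        scores = coords["x"].to_numpy() / 10.0  # deterministic spatial trend
        v = ordination.variogram_permutation_test(scores, coords, n_classes=6,
                                                  n_perm=199, rng=rng)
        assert v.exceeds.any()
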