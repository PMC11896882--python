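"""Trait-environment association via Hill-N2 weighted CWM/SNC regressions.

The fourth-corner problem asks whether a species trait t and a site
environmental variable e are linked through the abundance table A.  Two
one-sided views exist: regress the community weighted mean trait

    CWM_k = sum_j a_kj t_j / sum_j a_kj          (one value per site k)

on e across sites, or regress the species niche centroid

    SNC_j = sum_k a_kj e_k / sum_k a_kj          (one value per species j)

on t across species.  Each regression is weighted by Hill numbers of order 2
(N2 = (sum w)^2 / sum w^2, the inverse Simpson effective number), of the
site's abundance vector for CWM and of the species' occurrence vector for
SNC, which down-weights sites and species whose means rest on few
individuals.  The site-level p-value permutes environment values across
sites, the species-level p-value permutes trait values across species, and
the reported p-value is the maximum of the two ("max-test"); taking the
maximum protects against inflated type-I error from either a few dominant
species or spatially structured environments, at the price of conservatism.

The reported fourth-corner correlation is the N2-site-weighted Pearson
correlation between the CWM of the abundance-standardized trait and the
abundance-standardized environment; it is invariant to affine rescaling of
either variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "hill_n2",
    "cwm",
    "snc",
    "fourth_corner_r",
    "maxtest",
    "cwm_axis_null",
    "TraitEnvResult",
]


def hill_n2(weights: np.ndarray | pd.Series) -> float:
    """Effective number of categories of order 2: (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    s2 = float(np.sum(w**2))
    if s2 == 0:
        raise ValueError("all-zero weight vector")
    return float(np.sum(w)) ** 2 / s2


def _align(A: pd.DataFrame, traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subset A to trait-covered taxa (site totals renormalize implicitly)."""
    taxa = [t for t in A.columns if t in set(traits.index)]
    if not taxa:
        raise ValueError("no taxa shared between abundance matrix and trait table")
    return A[taxa], traits.loc[taxa]


def cwm(A: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Community weighted means, sites x traits.

    Sites with zero covered abundance get NaN (flagged missing).
    """
    A, traits = _align(A, traits)
    W = A.to_numpy(dtype=float)
    tot = W.sum(axis=1)
    T = traits.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        M = (W @ T) / tot[:, None]
    M[tot == 0] = np.nan
    return pd.DataFrame(M, index=A.index, columns=traits.columns)


def snc(A: pd.DataFrame, env: pd.DataFrame) -> pd.DataFrame:
    """Species niche centroids, taxa x environmental variables."""
    W = A.to_numpy(dtype=float).T  # taxa x sites
    tot = W.sum(axis=1)
    E = env.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        M = (W @ E) / tot[:, None]
    M[tot == 0] = np.nan
    return pd.DataFrame(M, index=A.columns, columns=env.columns)


def _wmean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _wcorr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    xm = x - _wmean(x, w)
    ym = y - _wmean(y, w)
    den = np.sqrt(np.sum(w * xm**2) * np.sum(w * ym**2))
    if den == 0:
        return 0.0
    return float(np.sum(w * xm * ym) / den)


def fourth_corner_r(A: pd.DataFrame, trait: pd.Series, env: pd.Series) -> float:
    """N2-weighted fourth-corner correlation of one trait with one variable."""
    W = A.to_numpy(dtype=float)
    t = trait.reindex(A.columns).to_numpy(dtype=float)
    e = env.reindex(A.index).to_numpy(dtype=float)
    col_w = W.sum(axis=0)  # species abundance weights for trait standardization
    row_w = W.sum(axis=1)
    t_sd = np.sqrt(max(np.sum(col_w * (t - _wmean(t, col_w)) ** 2) / np.sum(col_w), 0.0))
    e_sd = np.sqrt(max(np.sum(row_w * (e - _wmean(e, row_w)) ** 2) / np.sum(row_w), 0.0))
    if t_sd == 0 or e_sd == 0:
        return 0.0
    t_std = (t - _wmean(t, col_w)) / t_sd
    e_std = (e - _wmean(e, row_w)) / e_sd
    tot = row_w.copy()
    tot[tot == 0] = np.nan
    cwm_t = (W @ t_std) / tot
    ok = np.isfinite(cwm_t)
    n2_sites = np.where(W.sum(axis=1) > 0,
                        np.square(W.sum(axis=1)) / np.maximum((W**2).sum(axis=1), 1e-300), 0.0)
    return _wcorr(cwm_t[ok], e_std[ok], n2_sites[ok])


@dataclass
class TraitEnvResult:
    table: pd.DataFrame  # one row per trait x env pair: r, p_site, p_species, p_max

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_max"] < alpha]


def maxtest(A: pd.DataFrame, traits: pd.DataFrame, env: pd.DataFrame,
            n_perm: int = 999, rng: np.random.Generator | None = None) -> TraitEnvResult:
    """CWM and SNC regressions with the permutation max-test, per pair.

    Statistic on each side is the absolute N2-weighted correlation (between
    CWM and environment across sites; between SNC and trait across species).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    A, traits = _align(A, traits)
    env = env.loc[A.index]
    W = A.to_numpy(dtype=float)
    n_sites, n_taxa = W.shape
    n2_sites = np.array([hill_n2(W[k]) if W[k].sum() > 0 else 0.0 for k in range(n_sites)])
    n2_species = np.array([hill_n2(W[:, j]) if W[:, j].sum() > 0 else 0.0 for j in range(n_taxa)])
    site_perms = np.array([rng.permutation(n_sites) for _ in range(n_perm)])
    species_perms = np.array([rng.permutation(n_taxa) for _ in range(n_perm)])
    rows = []
    for tname in traits.columns:
        t = traits[tname].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            for ename in env.columns:
                rows.append({"trait": tname, "env": ename, "r": 0.0,
                             "p_site": 1.0, "p_species": 1.0, "p_max": 1.0})
            continue
        tot = W.sum(axis=1)
        cwm_t = np.divide(W @ t, tot, out=np.full(n_sites, np.nan), where=tot > 0)
        ok_s = np.isfinite(cwm_t)
        for ename in env.columns:
            e = env[ename].to_numpy(dtype=float)
            if np.ptp(e) == 0:
                raise ValueError(f"environment variable {ename!r} is constant")
            tot_j = W.sum(axis=0)
            snc_e = np.divide(W.T @ e, tot_j, out=np.full(n_taxa, np.nan), where=tot_j > 0)
            ok_j = np.isfinite(snc_e)
            obs_site = abs(_wcorr(cwm_t[ok_s], e[ok_s], n2_sites[ok_s]))
            obs_species = abs(_wcorr(snc_e[ok_j], t[ok_j], n2_species[ok_j]))
            ex_site = sum(
                abs(_wcorr(cwm_t[ok_s], e[perm][ok_s], n2_sites[ok_s])) >= obs_site - 1e-12
                for perm in site_perms)
            ex_species = sum(
                abs(_wcorr(snc_e[ok_j], t[perm][ok_j], n2_species[ok_j])) >= obs_species - 1e-12
                for perm in species_perms)
            p_site = (1 + ex_site) / (1 + n_perm)
            p_species = (1 + ex_species) / (1 + n_perm)
            rows.append({
                "trait": tname, "env": ename,
                "r": fourth_corner_r(A, traits[tname], env[ename]),
                "p_site": p_site, "p_species": p_species,
                "p_max": max(p_site, p_species),
            })
    return TraitEnvResult(table=pd.DataFrame(rows))


def cwm_axis_null(A: pd.DataFrame, traits: pd.DataFrame, axis_scores: pd.Series,
                  n_perm: int = 999, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Trait-shuffle null for correlations of CWM traits with ordination scores.

    Observed Pearson r(CWM(t), score) per trait; the null shuffles trait
    values among taxa and recomputes the CWM.  Two-sided p-value.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    A, traits = _align(A, traits)
    s = axis_scores.reindex(A.index).to_numpy(dtype=float)
    W = A.to_numpy(dtype=float)
    tot = W.sum(axis=1)
    perms = [rng.permutation(W.shape[1]) for _ in range(n_perm)]
    rows = []
    for tname in traits.columns:
        t = traits[tname].to_numpy(dtype=float)
        cwm_t = np.divide(W @ t, tot, out=np.full(len(tot), np.nan), where=tot > 0)
        ok = np.isfinite(cwm_t)
        obs = _pearson(cwm_t[ok], s[ok])
        exceed = 0
        for perm in perms:
            null_cwm = np.divide(W @ t[perm], tot, out=np.full(len(tot), np.nan), where=tot > 0)
            if abs(_pearson(null_cwm[ok], s[ok])) >= abs(obs) - 1e-12:
                exceed += 1
        rows.append({"trait": tname, "r": obs, "p": (1 + exceed) / (1 + n_perm)})
    return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xm = x - x.mean()
    ym = y - y.mean()
    den = np.sqrt(np.sum(xm**2) * np.sum(ym**2))
    return float(np.sum(xm * ym) / den) if den > 0 else 0.0
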