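"""Ordination of site x taxa count tables.

Non-symmetric correspondence analysis (NSCA) decomposes the deviations of
site profiles from the mean taxon profile,

    q_ij = p_ij / r_i - c_j,

under the row-mass metric diag(r) and the identity column metric.  Unlike
classical CA (which divides by sqrt(c_j)), NSCA does not inflate rare taxa,
so the leading axes follow the abundant species.  Total inertia is
sum_i r_i sum_j q_ij^2 (the Goodman-Kruskal tau numerator).

The constrained variant (NSCAIV, with environmental instrumental variables)
projects Q onto the span of the standardized environment table by row-
weighted least squares before decomposing; the explained fraction is the
inertia ratio, tested by permuting environment rows.  CCA and partial CCA
use the same machinery on the chi-square scaled matrix, with a second-order
polynomial of the quadrat coordinates as the usual conditioning table.

All permutation p-values follow p = (1 + #exceedances) / (1 + n_perm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = [
    "OrdinationResult",
    "VariogramTest",
    "nsca",
    "nscaiv",
    "cca",
    "pcca",
    "polynomial_coords",
    "variogram_permutation_test",
]


@dataclass
class OrdinationResult:
    site_scores: pd.DataFrame
    taxon_scores: pd.DataFrame
    eigenvalues: np.ndarray
    total_inertia: float
    row_weights: pd.Series
    constrained_inertia: float | None = None
    constrained_fraction: float | None = None
    p_value: float | None = None
    null_fractions: np.ndarray | None = None
    residual_q: np.ndarray | None = None  # site x taxa residual deviations (weighted space)

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues)
        if ev.size and (np.any(np.diff(ev) > 1e-10) or np.any(ev < -1e-10)):
            raise ValueError("eigenvalues must be nonincreasing and nonnegative")


def _profiles(A: pd.DataFrame, chi_square: bool) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """Return (Q, r, kept column labels) for NSCA or chi-square (CA) scaling."""
    X = A.to_numpy(dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("abundance matrix must have at least 2 rows and 2 columns")
    if np.any(X < 0):
        raise ValueError("abundance matrix must be nonnegative")
    total = X.sum()
    if total <= 0:
        raise ValueError("abundance matrix is empty")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(r == 0):
        raise ValueError("zero-total rows are not allowed in ordination")
    Q = P / r[:, None] - c[None, :]
    cols = A.columns
    if chi_square:
        keep = c > 0
        Q = Q[:, keep] / np.sqrt(c[keep])[None, :]
        cols = A.columns[keep]
    return Q, r, cols


def _decompose(Q: np.ndarray, r: np.ndarray, index: pd.Index, columns: pd.Index,
               n_axes: int | None) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    M = np.sqrt(r)[:, None] * Q
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if n_axes is None:
        n_axes = int(np.sum(s > 1e-12 * max(1.0, s[0] if s.size else 0.0)))
        n_axes = max(n_axes, 1)
    n_axes = min(n_axes, s.size)
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    # deterministic orientation: the taxon with the largest |loading| is positive
    for k in range(n_axes):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    F = (U * s) / np.sqrt(r)[:, None]  # site principal coordinates (= Q V)
    axes = [f"axis{k + 1}" for k in range(n_axes)]
    site = pd.DataFrame(F, index=index, columns=axes)
    taxa = pd.DataFrame(Vt.T, index=columns, columns=axes)
    return site, taxa, s**2


def nsca(A: pd.DataFrame, n_axes: int | None = None) -> OrdinationResult:
    """Non-symmetric correspondence analysis of a site x taxa count table."""
    Q, r, cols = _profiles(A, chi_square=False)
    inertia = float(np.sum(r[:, None] * Q**2))
    site, taxa, ev = _decompose(Q, r, A.index, cols, n_axes)
    return OrdinationResult(
        site_scores=site, taxon_scores=taxa, eigenvalues=ev,
        total_inertia=inertia, row_weights=pd.Series(r, index=A.index),
    )


def _wproject(Q: np.ndarray, X: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-weighted least-squares projection of the columns of Q onto span(X)."""
    W = r[:, None]
    G = X.T @ (W * X)
    B = np.linalg.solve(G, X.T @ (W * Q))
    return X @ B


def _env_matrix(E: pd.DataFrame | np.ndarray, n: int) -> np.ndarray:
    X = E.to_numpy(dtype=float) if isinstance(E, pd.DataFrame) else np.asarray(E, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("environment table and abundance matrix row mismatch")
    full = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise np.linalg.LinAlgError("environment table is collinear")
    return full


def _constrained(A: pd.DataFrame, E, chi_square: bool, n_axes: int | None,
                 n_perm: int, rng: np.random.Generator | None,
                 Z: pd.DataFrame | np.ndarray | None = None) -> OrdinationResult:
    Q, r, cols = _profiles(A, chi_square=chi_square)
    n = Q.shape[0]
    total = float(np.sum(r[:, None] * Q**2))
    Xe = _env_matrix(E, n)[:, 1:]  # env columns without intercept
    ones = np.ones((n, 1))
    if Z is not None:
        Zm = Z.to_numpy(dtype=float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, dtype=float)
        if Zm.ndim == 1:
            Zm = Zm[:, None]
        cond = np.column_stack([ones, Zm])
    else:
        cond = ones
    # partial out the conditioning table (intercept alone when Z is None)
    Qr = Q - _wproject(Q, cond, r)
    Er = Xe - _wproject(Xe, cond, r)

    def fraction(Erm: np.ndarray) -> tuple[float, np.ndarray]:
        keep = np.linalg.norm(Erm, axis=0) > 1e-10
        if not keep.any():
            return 0.0, np.zeros_like(Qr)
        Qhat = _wproject(Qr, Erm[:, keep], r)
        return float(np.sum(r[:, None] * Qhat**2)), Qhat

    constrained, Qhat = fraction(Er)
    frac = constrained / total if total > 0 else 0.0
    site, taxa, ev = _decompose(Qhat, r, A.index, cols, n_axes)
    p = None
    nulls = None
    if n_perm:
        if rng is None:
            rng = np.random.default_rng(0)
        nulls = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(n)
            nulls[b] = fraction(Er[perm])[0] / total if total > 0 else 0.0
        p = float((1 + np.sum(nulls >= frac - 1e-12)) / (1 + n_perm))
    return OrdinationResult(
        site_scores=site, taxon_scores=taxa, eigenvalues=ev,
        total_inertia=total, row_weights=pd.Series(r, index=A.index),
        constrained_inertia=constrained, constrained_fraction=frac,
        p_value=p, null_fractions=nulls, residual_q=Qr - Qhat,
    )


def nscaiv(A: pd.DataFrame, E: pd.DataFrame, n_axes: int | None = None,
           n_perm: int = 999, rng: np.random.Generator | None = None) -> OrdinationResult:
    """NSCA with instrumental variables (non-symmetric canonical CA)."""
    return _constrained(A, E, chi_square=False, n_axes=n_axes, n_perm=n_perm, rng=rng)


def cca(A: pd.DataFrame, E: pd.DataFrame, n_axes: int | None = None,
        n_perm: int = 999, rng: np.random.Generator | None = None) -> OrdinationResult:
    """Canonical correspondence analysis (chi-square metric)."""
    return _constrained(A, E, chi_square=True, n_axes=n_axes, n_perm=n_perm, rng=rng)


def pcca(A: pd.DataFrame, E: pd.DataFrame, coords: pd.DataFrame | None,
         n_axes: int | None = None, n_perm: int = 999,
         rng: np.random.Generator | None = None) -> OrdinationResult:
    """Partial CCA conditioning on a 2nd-order polynomial of site coordinates.

    With ``coords=None`` this reduces exactly to plain :func:`cca`.
    """
    Z = polynomial_coords(coords) if coords is not None else None
    return _constrained(A, E, chi_square=True, n_axes=n_axes, n_perm=n_perm, rng=rng, Z=Z)


def polynomial_coords(coords: pd.DataFrame) -> np.ndarray:
    """Centered (x, y, x^2, xy, y^2) conditioning table from site coordinates."""
    x = coords["x"].to_numpy(dtype=float)
    y = coords["y"].to_numpy(dtype=float)
    x = x - x.mean()
    y = y - y.mean()
    Z = np.column_stack([x, y, x**2, x * y, y**2])
    return Z - Z.mean(axis=0)


# ---------------------------------------------------------------------------
# variogram permutation test
# ---------------------------------------------------------------------------


@dataclass
class VariogramTest:
    bounds: np.ndarray          # class upper bounds (len n_classes)
    semivariance: np.ndarray
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    exceeds: np.ndarray         # bool per class
    n_pairs: np.ndarray
    merged_classes: list[int] = field(default_factory=list)


def variogram_permutation_test(
    scores: pd.Series | np.ndarray,
    coords: pd.DataFrame,
    n_classes: int = 11,
    n_perm: int = 9999,
    rng: np.random.Generator | None = None,
) -> VariogramTest:
    """Empirical semivariogram of axis scores with a permutation envelope.

    gamma(class) = half the mean squared score difference over site pairs in
    the distance class (equal-width classes up to the maximum inter-site
    distance).  The null envelope (2.5/97.5 percentiles) comes from permuting
    scores over locations; a class whose observed gamma leaves the envelope
    flags spatial structure at that lag.  Empty classes are merged leftward.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    v = np.asarray(scores, dtype=float)
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    n = v.size
    if xy.shape[0] != n:
        raise ValueError("scores and coordinates length mismatch")
    d = pdist(xy)
    dmax = d.max()
    edges = np.linspace(0, dmax, n_classes + 1)
    cls = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_classes - 1)
    counts = np.bincount(cls, minlength=n_classes)
    merged: list[int] = []
    for k in range(1, n_classes):
        if counts[k] < 2:
            merged.append(k)
    if merged:
        warnings.warn(f"distance classes {merged} have < 2 pairs; merged leftward")
        for k in merged:
            cls[cls == k] = k - 1
        counts = np.bincount(cls, minlength=n_classes)
    ii, jj = np.triu_indices(n, k=1)

    def gamma(vals: np.ndarray) -> np.ndarray:
        sq = 0.5 * (vals[ii] - vals[jj]) ** 2
        sums = np.bincount(cls, weights=sq, minlength=n_classes)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    obs = gamma(v)
    null = np.empty((n_perm, n_classes))
    for b in range(n_perm):
        null[b] = gamma(v[rng.permutation(n)])
    ok = counts > 0
    lo = np.full(n_classes, np.nan)
    hi = np.full(n_classes, np.nan)
    lo[ok] = np.percentile(null[:, ok], 2.5, axis=0)
    hi[ok] = np.percentile(null[:, ok], 97.5, axis=0)
    with np.errstate(invalid="ignore"):
        exceeds = (obs < lo) | (obs > hi)
    exceeds[~ok] = False
    return VariogramTest(
        bounds=edges[1:], semivariance=obs, envelope_lo=lo, envelope_hi=hi,
        exceeds=exceeds, n_pairs=counts, merged_classes=merged,
    )
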