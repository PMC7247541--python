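"""Spatial statistics: distances, stratified Mantel, Moran's I, local Geary.

The weighting scheme is an explicit modelling choice here (inverse
distance over the k nearest neighbours, row-standardized, by default) and
is recorded in every result object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EARTH_RADIUS_KM",
    "SpatialWeights",
    "MantelResult",
    "MoranResult",
    "GearyResult",
    "geographic_distances",
    "mismatch_distances",
    "inverse_distance_weights",
    "env_space_weights",
    "stratified_mantel",
    "morans_i",
    "morans_i_panel",
    "local_gearys_c",
    "local_geary_panel",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class SpatialWeights:
    """Nonnegative spatial weight matrix with its provenance."""

    matrix: np.ndarray
    scheme: str
    row_standardized: bool

    def __post_init__(self) -> None:
        w = np.asarray(self.matrix, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.diag(w).any():
            raise ValueError("weight matrix must have a zero diagonal")
        self.matrix = w

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    strata: str


@dataclass
class MoranResult:
    """Panel-level Moran's I summary (mean over polymorphic loci)."""

    i_obs: float
    i_est: float
    p: float
    n_perm: int
    n_loci: int
    per_locus: np.ndarray
    scheme: str
    adjusted_p: float = np.nan


@dataclass
class GearyResult:
    """Per-individual local Geary's C values."""

    c: pd.Series
    threshold: float
    n_above: int
    scheme: str


# ----------------------------------------------------------------- distances


def geographic_distances(lon, lat) -> np.ndarray:
    """Great-circle (haversine) distance matrix in kilometres."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if (np.abs(lat) > 90).any():
        raise ValueError("latitudes must lie in [-90, 90]")
    if (np.abs(lon) > 360).any():
        raise ValueError("longitudes out of range")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def mismatch_distances(binary) -> np.ndarray:
    """Fraction of epiloci at which two individuals differ."""
    from scipy.spatial.distance import pdist, squareform

    x = np.asarray(binary, dtype=float)
    if x.ndim != 2:
        raise ValueError("binary matrix must be 2-D")
    return squareform(pdist(x, metric="hamming"))


# ------------------------------------------------------------------- weights


def _row_standardize(w: np.ndarray) -> np.ndarray:
    sums = w.sum(axis=1, keepdims=True)
    out = np.divide(w, sums, out=np.zeros_like(w), where=sums > 0)
    return out


def inverse_distance_weights(
    distances: np.ndarray,
    k: int = 10,
    row_standardize: bool = True,
    eps: float = 1e-6,
) -> SpatialWeights:
    """Inverse-distance weights restricted to the k nearest neighbours."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    k = min(k, n - 1)
    w = 1.0 / (eps + d)
    np.fill_diagonal(w, 0.0)
    if k < n - 1:
        keep = np.zeros_like(w, dtype=bool)
        for i in range(n):
            order = np.argsort(d[i])
            nn = [j for j in order if j != i][:k]
            keep[i, nn] = True
        keep = keep | keep.T  # symmetrize before any standardization
        w = np.where(keep, w, 0.0)
    scheme = f"inverse_geographic(k={k})"
    if row_standardize:
        w = _row_standardize(w)
    return SpatialWeights(matrix=w, scheme=scheme,
                          row_standardized=row_standardize)


def env_space_weights(
    env,
    eps: float = 1e-6,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Inverse environmental-distance weights: w_ij = 1/(eps + |e_i - e_j|).

    Feeding these weights to Moran's I yields an autocorrelation of
    epilocus values along the environmental gradient rather than across
    geographic space.
    """
    e = np.asarray(env, dtype=float)
    w = 1.0 / (eps + np.abs(e[:, None] - e[None, :]))
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        w = _row_standardize(w)
    return SpatialWeights(matrix=w, scheme=f"env_similarity(eps={eps})",
                          row_standardized=row_standardize)


# -------------------------------------------------------------------- Mantel


def _condensed(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def stratified_mantel(
    d_epi,
    d_geo,
    strata=None,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel matrix correlation with within-strata permutations.

    ``r`` is the Pearson correlation of the upper triangles; the null is
    built by permuting sample labels of one matrix within strata only
    (a single stratum reduces to the ordinary Mantel test).  One-sided
    (positive association) by default.
    """
    d1 = np.asarray(d_epi, dtype=float)
    d2 = np.asarray(d_geo, dtype=float)
    if d1.shape != d2.shape or d1.shape[0] != d1.shape[1]:
        raise ValueError("distance matrices must be square and matching")
    n = d1.shape[0]
    if strata is None:
        strata = np.zeros(n)
    strata = np.asarray(strata)
    v1, v2 = _condensed(d1), _condensed(d2)
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("degenerate (constant) distance matrix")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])

    rng = np.random.default_rng(seed)
    members = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
    exceed = 0
    for _ in range(n_perm):
        perm = np.arange(n)
        for idx in members:
            perm[idx] = idx[rng.permutation(idx.size)]
        r_p = float(np.corrcoef(_condensed(d1[np.ix_(perm, perm)]), v2)[0, 1])
        if alternative == "greater":
            hit = r_p >= r_obs
        elif alternative == "two-sided":
            hit = abs(r_p) >= abs(r_obs)
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
        if hit:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    label = ",".join(str(s) for s in pd.unique(strata))
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, strata=label)


# ------------------------------------------------------------------- Moran's


def _moran_stat(z: np.ndarray, w: np.ndarray, s0: float) -> float:
    denom = float(z @ z)
    return float(len(z) / s0 * (z @ w @ z) / denom)


def morans_i(values, weights: SpatialWeights) -> float:
    """Global Moran's I of one variable under the given weights."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Moran's I needs at least three samples")
    if x.std() == 0:
        raise ValueError("Moran's I undefined for constant values")
    w = weights.matrix
    s0 = w.sum()
    return _moran_stat(x - x.mean(), w, s0)


def morans_i_panel(
    binary,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
) -> MoranResult:
    """Mean per-locus Moran's I over polymorphic loci, with permutation p.

    Constant (monomorphic) loci are undefined and excluded from the mean.
    The permutation test jointly permutes the sample rows and compares the
    permuted panel means against the observed one (one-sided, positive
    autocorrelation).
    """
    x = np.asarray(binary, dtype=float)
    n = x.shape[0]
    keep = x.std(axis=0) > 0
    if keep.sum() == 0:
        raise ValueError("no polymorphic loci: Moran's I undefined")
    z = x[:, keep] - x[:, keep].mean(axis=0)
    w = weights.matrix
    s0 = w.sum()
    denom = (z * z).sum(axis=0)
    per_locus = n / s0 * (z * (w @ z)).sum(axis=0) / denom
    i_obs = float(per_locus.mean())

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        zp = z[perm]
        i_p = float((n / s0 * (zp * (w @ zp)).sum(axis=0) / denom).mean())
        if i_p >= i_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return MoranResult(
        i_obs=i_obs,
        i_est=-1.0 / (n - 1),
        p=p,
        n_perm=n_perm,
        n_loci=int(keep.sum()),
        per_locus=per_locus,
        scheme=weights.scheme,
    )


def adjust_moran_p(results: list, method: str = "holm") -> list:
    """Fill ``adjusted_p`` across a family of MoranResults in place."""
    ps = [r.p for r in results]
    adj = multipletests(ps, method=method)[1]
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return results


# ----------------------------------------------------------------- Geary's C


def local_gearys_c(values, weights: SpatialWeights) -> np.ndarray:
    """Anselin's local Geary: c_i = sum_j w_ij (x_i - x_j)^2 / (2 m2).

    ``m2`` is the (n-1)-denominator variance of the values.  Values are
    always nonnegative; under spatial randomness the mean is close to 1,
    and large values flag locally dissimilar individuals.
    """
    x = np.asarray(values, dtype=float)
    if x.std() == 0:
        raise ValueError("local Geary undefined for constant values")
    n = x.size
    m2 = ((x - x.mean()) ** 2).sum() / (n - 1)
    diff2 = (x[:, None] - x[None, :]) ** 2
    return (weights.matrix * diff2).sum(axis=1) / (2.0 * m2)


def local_geary_panel(
    binary,
    weights: SpatialWeights,
    threshold: float = 1.0,
) -> GearyResult:
    """Per-individual mean of per-locus local Geary values over a panel.

    Loci with constant values are skipped.  Individuals whose mean exceeds
    ``threshold`` are counted as showing negative local autocorrelation.
    """
    if isinstance(binary, pd.DataFrame):
        index = binary.index
    else:
        index = pd.RangeIndex(np.asarray(binary).shape[0])
    x = np.asarray(binary, dtype=float)
    n = x.shape[0]
    keep = x.std(axis=0) > 0
    if keep.sum() == 0:
        raise ValueError("no polymorphic loci: local Geary undefined")
    xs = x[:, keep]
    m2 = ((xs - xs.mean(axis=0)) ** 2).sum(axis=0) / (n - 1)
    w = weights.matrix
    if np.isin(xs, (0.0, 1.0)).all():
        # binary shortcut: (x_i - x_j)^2 = x_i + x_j - 2 x_i x_j
        row_w = w.sum(axis=1, keepdims=True)
        s = w @ xs
        num = row_w * xs + s - 2.0 * xs * s
        c = (num / (2.0 * m2)).mean(axis=1)
    else:
        cols = [
            (w * (xs[:, j][:, None] - xs[:, j][None, :]) ** 2).sum(axis=1)
            / (2.0 * m2[j])
            for j in range(xs.shape[1])
        ]
        c = np.mean(cols, axis=0)
    series = pd.Series(c, index=index, name="local_geary_c")
    return GearyResult(
        c=series,
        threshold=threshold,
        n_above=int((series > threshold).sum()),
        scheme=weights.scheme,
    )
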