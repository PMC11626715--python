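"""Population-level migration statistics.

* Mantel test between the capture-location distance matrix and the
  origin-centroid distance matrix — the migratory-connectivity
  statistic.  The permutation scheme jointly permutes rows and columns
  of one matrix; the default alternative is one-sided (connectivity is
  a positive-association hypothesis).
* Agglomerative centroid clustering of specimens in isotope space
  (d2H, 87Sr/86Sr), z-scored per axis because the two scales differ by
  four orders of magnitude.
* The seasonal trend of migrant d2H against capture day-of-year, the
  leapfrog-migration signal: early arrivals from higher (more negative
  d2H) latitudes give a positive slope over the season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from isomigrate import geo


@dataclass
class DistanceMatrixPair:
    """Aligned capture-site and origin-centroid distance matrices (km)."""

    capture_dist: np.ndarray
    origin_dist: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        for name, m in (("capture_dist", self.capture_dist),
                        ("origin_dist", self.origin_dist)):
            m = np.asarray(m, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(m, m.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(m), 0.0, atol=1e-8):
                raise ValueError(f"{name} must have a zero diagonal")
        if self.capture_dist.shape != self.origin_dist.shape:
            raise ValueError("matrices must have the same shape")
        if len(self.ids) != self.capture_dist.shape[0]:
            raise ValueError("ids must match matrix order")


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int
    alternative: str = "greater"


@dataclass
class TrendResult:
    slope: float
    intercept: float
    p: float
    n: int
    r2: float


def distance_matrices(metrics: pd.DataFrame) -> DistanceMatrixPair:
    """Build the Mantel input from an assignment metrics table.

    Requires columns id, lon, lat (capture) and centroid_lon,
    centroid_lat (origin).  Distances are great-circle km.
    """
    cap = geo.pairwise_distance_matrix(metrics["lon"], metrics["lat"],
                                       "geographic")
    org = geo.pairwise_distance_matrix(metrics["centroid_lon"],
                                       metrics["centroid_lat"], "geographic")
    return DistanceMatrixPair(cap, org, [str(i) for i in metrics["id"]])


def mantel_test(
    pair: DistanceMatrixPair,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Permutation Mantel correlation between two distance matrices.

    r is the Pearson correlation of the strictly-upper-triangle entries.
    The null distribution is generated by jointly permuting rows and
    columns of the origin matrix; the p-value is
    ``(1 + #{r_perm as extreme as r_obs}) / (1 + n_perm)``.
    ``alternative`` is "greater" (default; positive association) or
    "two-sided".
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    a = np.asarray(pair.capture_dist, dtype=float)
    b = np.asarray(pair.origin_dist, dtype=float)
    n = a.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 individuals")
    iu0, iu1 = np.triu_indices(n, k=1)
    va = a[iu0, iu1]

    va_c = va - va.mean()
    va_norm = np.sqrt(np.sum(va_c**2))
    if va_norm == 0:
        raise ValueError("capture distance matrix is constant")

    def corr_with(vb: np.ndarray) -> float:
        vb_c = vb - vb.mean()
        denom = va_norm * np.sqrt(np.sum(vb_c**2))
        if denom == 0:
            return 0.0
        return float(np.dot(va_c, vb_c) / denom)

    r_obs = corr_with(b[iu0, iu1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = corr_with(b[perm[iu0], perm[iu1]])
        if alternative == "greater":
            if r_perm >= r_obs:
                count += 1
        else:
            if abs(r_perm) >= abs(r_obs):
                count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed,
                        alternative=alternative)


def isotope_centroid_cluster(
    specimens: pd.DataFrame,
    k: int | str = "auto",
    standardize: bool = True,
) -> np.ndarray:
    """Group specimens by isotopic composition via centroid clustering.

    Agglomerative clustering with centroid linkage on (d2H, 87Sr/86Sr),
    z-scored per axis when ``standardize``.  ``k="auto"`` picks the k in
    2..min(6, n-1) maximizing the silhouette score.  Returns integer
    labels (1-based, as cut from the dendrogram).
    """
    X = specimens[["d2h", "sr"]].to_numpy(dtype=float)
    n = len(X)
    if isinstance(k, str):
        if k != "auto":
            raise ValueError("k must be an integer or 'auto'")
    else:
        if not 2 <= k <= n:
            raise ValueError("need n >= k >= 2")
    if standardize:
        sds = X.std(axis=0)
        if np.any(sds == 0):
            raise ValueError(
                "a column is constant; z-scoring is undefined — "
                "call with standardize=False"
            )
        X = (X - X.mean(axis=0)) / sds
    Z = linkage(X, method="centroid")
    if k == "auto":
        best_k, best_s = None, -np.inf
        for kk in range(2, min(6, n - 1) + 1):
            labels = fcluster(Z, t=kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            s = silhouette_score(X, labels)
            if s > best_s:
                best_k, best_s = kk, s
        if best_k is None:
            raise ValueError("silhouette undefined for every candidate k")
        k = best_k
    labels = fcluster(Z, t=k, criterion="maxclust")
    return labels


def seasonal_trend(migrants: pd.DataFrame, day_col: str = "day_of_year",
                   value_col: str = "d2h") -> TrendResult:
    """OLS of migrant d2H on capture day-of-year.

    Capture dates are linearized to day-of-year; multi-year data pool by
    day-of-year.  A positive, significant slope indicates that later
    captures carry less negative d2H, i.e. progressively more southern
    origins over the season.
    """
    if day_col not in migrants.columns and "date" in migrants.columns:
        days = pd.to_datetime(migrants["date"]).dt.dayofyear.to_numpy(float)
    else:
        days = migrants[day_col].to_numpy(dtype=float)
    vals = migrants[value_col].to_numpy(dtype=float)
    ok = np.isfinite(days) & np.isfinite(vals)
    days, vals = days[ok], vals[ok]
    if days.size < 3:
        raise ValueError("need at least 3 migrants with dates and values")
    if np.ptp(days) == 0:
        raise ValueError("capture dates are constant; trend undefined")
    res = stats.linregress(days, vals)
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept),
                       p=float(res.pvalue), n=int(days.size),
                       r2=float(res.rvalue**2))
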