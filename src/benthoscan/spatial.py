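"""Spatial autocorrelation of abundances along survey tracks.

Sampling units are connected to their k nearest neighbours (great-circle
distance between unit centroids; k = 6 by default, following the point where
the Moran's I neighbourhood curve typically stabilises). Global Moran's I
summarises track-wide autocorrelation; per-unit local Moran statistics
(LISA) with conditional-permutation significance classify units as hotspots
(high value among high neighbours), coldspots (low-low) or spatial outliers
(high-low / low-high), via the Moran scatterplot quadrants.

Weights are row-standardised so the spatial lag is the mean neighbour value,
which is what the scatterplot interpretation requires. With standardised
values the mean of the local statistics equals global Moran's I exactly (the
LISA decomposition identity), which the test-suite asserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import pairwise_haversine_m

QUADRANTS = ("HH", "LL", "LH", "HL")
CLASSES = ("hotspot", "coldspot", "outlier", "not-significant")


@dataclass
class SpatialWeights:
    """k-nearest-neighbour weights, row-standardised (each row sums to 1)."""

    ids: list
    neighbours: np.ndarray  # (n, k) int indices
    weights: np.ndarray  # (n, k) floats

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def k(self) -> int:
        return self.neighbours.shape[1]

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Weighted mean of each unit's neighbours."""
        values = np.asarray(values, dtype=float)
        return (values[self.neighbours] * self.weights).sum(axis=1)

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i in range(self.n):
            W[i, self.neighbours[i]] = self.weights[i]
        return W


def knn_graph(lon, lat, k: int = 6, ids=None) -> SpatialWeights:
    """k nearest neighbours by great-circle distance, ties broken by unit id.

    No self-neighbours; every row gets exactly k entries with weight 1/k.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = lon.size
    if n <= k:
        raise ValueError(f"need more than k={k} units, got {n}")
    ids = list(ids) if ids is not None else list(range(n))
    dist = pairwise_haversine_m(lon, lat)
    np.fill_diagonal(dist, np.inf)
    order = np.lexsort((np.tile(np.arange(n), (n, 1)), dist), axis=1)  # distance, then id
    neighbours = order[:, :k]
    weights = np.full((n, k), 1.0 / k)
    return SpatialWeights(ids=ids, neighbours=neighbours, weights=weights)


def morans_i(values, weights: SpatialWeights) -> float:
    """Global Moran's I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("values have zero variance")
    s0 = weights.weights.sum()
    # sum_ij w_ij z_i z_j with sparse neighbour lists
    num = (z[:, None] * z[weights.neighbours] * weights.weights).sum()
    return float(len(x) / s0 * num / denom)


def neighbourhood_curve(values, lon, lat, k_max: int = 12, threshold: float = 0.02,
                        default_k: int = 6) -> tuple[pd.DataFrame, int]:
    """Moran's I as a function of neighbourhood size k = 1..k_max.

    The suggested k is the smallest k at which |I(k) - I(k-1)| stays below
    ``threshold`` for two consecutive steps; if the curve never stabilises
    the default (6) is returned.
    """
    n = np.asarray(lon).size
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of units")
    rows = []
    prev = None
    for k in range(1, k_max + 1):
        I = morans_i(values, knn_graph(lon, lat, k=k))
        dI = np.nan if prev is None else I - prev
        rows.append({"k": k, "moran_i": I, "delta_i": dI})
        prev = I
    curve = pd.DataFrame(rows)
    small = np.abs(curve["delta_i"].to_numpy()) < threshold
    suggested = default_k
    for i in range(1, len(small) - 1):
        if small[i] and small[i + 1]:
            suggested = int(curve["k"].iloc[i])
            break
    return curve, suggested


@dataclass
class LisaResult:
    """Per-unit local Moran statistics and their classification."""

    table: pd.DataFrame  # unit_id, value, z, lag, local_i, quadrant, pseudo_p, class
    alpha: float
    n_perm: int

    def __getitem__(self, col):
        return self.table[col]


def local_moran(values, weights: SpatialWeights, n_perm: int = 999, seed: int = 0,
                alpha: float = 0.05) -> LisaResult:
    """Local Moran I_i with conditional-permutation pseudo p-values.

    Values are standardised (population sd); I_i = z_i * lag_i where the lag
    is the weighted neighbour mean. For each unit the remaining values are
    permuted among the other units (conditional permutation) and the
    two-sided pseudo p-value is (#{|I_perm| >= |I_obs|} + 1)/(n_perm + 1).
    Quadrants come from the signs of (z_i, lag_i); classification requires
    pseudo_p <= alpha.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = x.std()
    if sd == 0:
        raise ValueError("values have zero variance")
    z = (x - x.mean()) / sd
    lag = weights.lag(z)
    local_i = z * lag
    k = weights.k
    rng = np.random.default_rng(seed)
    pseudo_p = np.empty(n)
    others_buf = np.empty(n - 1)
    for i in range(n):
        others_buf[:i] = z[:i]
        others_buf[i:] = z[i + 1 :]
        # draw k neighbour values per permutation, without replacement
        pick = np.argpartition(rng.random((n_perm, n - 1)), k - 1, axis=1)[:, :k]
        perm_lag = (others_buf[pick] * weights.weights[i]).sum(axis=1)
        perm_i = z[i] * perm_lag
        pseudo_p[i] = (np.count_nonzero(np.abs(perm_i) >= abs(local_i[i])) + 1) / (n_perm + 1)
    quadrant = np.where(z >= 0, np.where(lag >= 0, "HH", "HL"), np.where(lag >= 0, "LH", "LL"))
    table = pd.DataFrame(
        {
            "unit_id": weights.ids,
            "value": x,
            "z": z,
            "lag": lag,
            "local_i": local_i,
            "quadrant": quadrant,
            "pseudo_p": pseudo_p,
        }
    )
    result = LisaResult(table=table, alpha=alpha, n_perm=n_perm)
    result.table["class"] = classify_lisa(result, alpha)
    return result


def classify_lisa(lisa: LisaResult, alpha: float | None = None) -> np.ndarray:
    """Map significant quadrants to hotspot / coldspot / outlier."""
    alpha = lisa.alpha if alpha is None else alpha
    quad = lisa.table["quadrant"].to_numpy()
    sig = lisa.table["pseudo_p"].to_numpy() <= alpha
    out = np.full(len(quad), "not-significant", dtype=object)
    out[sig & (quad == "HH")] = "hotspot"
    out[sig & (quad == "LL")] = "coldspot"
    out[sig & ((quad == "HL") | (quad == "LH"))] = "outlier"
    return out


def quantile_bins(values, n_bins: int = 8) -> np.ndarray:
    """Quantile classification into ``n_bins`` classes (choropleth binning).

    Bin edges sit at i/n_bins sample quantiles; ties go to the lowest
    admissible bin. If there are fewer distinct values than bins the bin
    count is reduced with a warning; all-equal input collapses to one bin.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    n_distinct = len(np.unique(x))
    if n_bins > n_distinct:
        warnings.warn(f"only {n_distinct} distinct values; reducing bins from {n_bins}", stacklevel=2)
        n_bins = max(n_distinct, 1)
    if n_bins == 1:
        return np.zeros(x.size, dtype=int)
    edges = np.unique(np.quantile(x, np.arange(1, n_bins) / n_bins))
    return np.searchsorted(edges, x, side="left").astype(int)


def lisa_per_dive(matrix, k: int = 6, n_perm: int = 999, seed: int = 0,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Run local Moran separately per dive on total unit abundances.

    Transects are far apart, so cross-dive neighbourhoods are not meaningful;
    dives with too few units (<= k) or zero variance are skipped with a
    warning.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for dive_id, sub in matrix.units.groupby("dive_id", sort=False):
        vals = matrix.abundance.loc[sub.index].sum(axis=1).to_numpy()
        if len(sub) <= k:
            warnings.warn(f"dive {dive_id}: {len(sub)} units <= k={k}, skipping LISA", stacklevel=2)
            continue
        if np.std(vals) == 0:
            warnings.warn(f"dive {dive_id}: zero abundance variance, skipping LISA", stacklevel=2)
            continue
        w = knn_graph(sub["centroid_lon"], sub["centroid_lat"], k=k, ids=list(sub.index))
        res = local_moran(vals, w, n_perm=n_perm, seed=int(rng.integers(2**31)), alpha=alpha)
        t = res.table.copy()
        t.insert(0, "dive_id", dive_id)
        rows.append(t)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
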