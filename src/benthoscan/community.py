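"""Multivariate community structure of sampling-unit abundances.

The standard non-parametric toolkit for taxon-by-sample matrices: a severe
double-root (fourth-root) transform to damp dominant taxa, Bray-Curtis
dissimilarity, group-average (UPGMA) hierarchical clustering, the ANOSIM
rank permutation test for group separation, SIMPER decomposition of the
average between-group dissimilarity into per-taxon contributions, Shannon
diversity, non-metric multidimensional scaling (Kruskal stress-1), and
envfit-style fitting of environmental/taxon vectors onto the ordination.

Dissimilarity matrices are held in :class:`skbio.DistanceMatrix`; ANOSIM is
implemented from the rank formula here (R = (mean between-rank - mean
within-rank) / (M/2), M = n(n-1)/2) and cross-checked against scikit-bio in
the test-suite. All-zero units (no megafauna at all) carry no compositional
information and are excluded from dissimilarities with a logged list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.decomposition import PCA
from sklearn.manifold import smacof

logger = logging.getLogger(__name__)


def double_root(matrix, mode: str = "fourth-root"):
    """Severe variance-stabilising transform: the square root applied twice.

    ``mode`` may be "fourth-root" (default) or "sqrt". Monotone, 0 -> 0.
    """
    X = matrix.to_numpy(dtype=float) if hasattr(matrix, "to_numpy") else np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    if mode == "fourth-root":
        out = np.sqrt(np.sqrt(X))
    elif mode == "sqrt":
        out = np.sqrt(X)
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    if hasattr(matrix, "to_numpy"):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities d(x,y) = sum|x-y| / sum(x+y) in [0,1].

    Rows that are entirely zero have no defined dissimilarity to each other
    and are dropped with a logged list before computing the matrix.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    nonzero = X.sum(axis=1) > 0
    if not nonzero.all():
        dropped = list(np.asarray(matrix.index)[~nonzero])
        logger.warning("excluding %d all-zero units from dissimilarities: %s", len(dropped), dropped)
    kept = matrix.loc[nonzero]
    d = squareform(pdist(kept.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in kept.index])


def upgma(d: DistanceMatrix, cut_height: float | None = None):
    """Group-average (UPGMA) agglomerative clustering of a dissimilarity matrix.

    Returns (linkage_matrix, flat_labels); labels are None unless a cut
    height is given. Merge heights are non-decreasing (UPGMA is monotone).
    """
    if d.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Z = linkage(d.condensed_form(), method="average")
    labels = fcluster(Z, t=cut_height, criterion="distance") if cut_height is not None else None
    return Z, labels


@dataclass
class AnosimResult:
    r: float
    p: float
    n_perm: int
    groups: list


def _anosim_r(ranks_condensed: np.ndarray, between_mask: np.ndarray, n: int) -> float:
    m = n * (n - 1) / 2
    r_between = ranks_condensed[between_mask].mean()
    r_within = ranks_condensed[~between_mask].mean()
    return (r_between - r_within) / (m / 2.0)


def anosim(d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """Analysis of similarities: are between-group dissimilarities larger?

    All n(n-1)/2 dissimilarities are ranked (mid-ranks for ties);
    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2, so R = 1 means every between-group pair is more dissimilar
    than every within-group pair and R ~ 0 means no separation. The one-sided
    p-value permutes group labels: p = (#{R_perm >= R_obs} + 1)/(n_perm + 1).
    """
    from scipy.stats import rankdata

    labels = np.asarray(list(groups))
    n = d.shape[0]
    if labels.size != n:
        raise ValueError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    ranks = rankdata(d.condensed_form())
    iu, ju = np.triu_indices(n, k=1)
    group_idx = np.searchsorted(uniq, labels)
    between = group_idx[iu] != group_idx[ju]
    r_obs = _anosim_r(ranks, between, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(group_idx)
        if _anosim_r(ranks, perm[iu] != perm[ju], n) >= r_obs:
            count += 1
    return AnosimResult(r=float(r_obs), p=(count + 1) / (n_perm + 1), n_perm=n_perm, groups=list(uniq))


def simper(matrix: pd.DataFrame, groups) -> pd.DataFrame:
    """SIMPER: per-taxon contributions to between-group dissimilarity.

    For every between-group sample pair (x, y) the Bray-Curtis numerator is
    split per taxon: delta_j = |x_j - y_j| / sum_k(x_k + y_k). Averaging over
    all between-group pairs gives contributions whose sum equals the average
    between-group Bray-Curtis dissimilarity exactly. Run it on the same
    transformed matrix that feeds the dissimilarities.

    Returns a table sorted by contribution with percent and cumulative
    percent columns.
    """
    labels = np.asarray(list(groups))
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError("SIMPER here compares exactly 2 groups")
    A = matrix.loc[labels == uniq[0]].to_numpy(dtype=float)
    B = matrix.loc[labels == uniq[1]].to_numpy(dtype=float)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("both groups need at least one member")
    # pairwise |x-y| per taxon, normalised by the pair's total
    diffs = np.abs(A[:, None, :] - B[None, :, :])  # (na, nb, p)
    totals = (A[:, None, :] + B[None, :, :]).sum(axis=2)  # (na, nb)
    contrib = (diffs / totals[:, :, None]).mean(axis=(0, 1))
    total = contrib.sum()
    table = pd.DataFrame(
        {
            "taxon": matrix.columns,
            "contribution": contrib,
            "percent": 100.0 * contrib / total,
        }
    ).sort_values("contribution", ascending=False, ignore_index=True)
    table["cumulative_percent"] = table["percent"].cumsum()
    table.attrs["mean_between_dissimilarity"] = float(total)
    return table


def shannon(abundances) -> float:
    """Shannon diversity H = -sum p_j ln p_j (natural log)."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector has no diversity")
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # n x dims
    stress: float  # Kruskal stress-1
    converged: bool
    env_fits: pd.DataFrame | None = None
    taxa_fits: pd.DataFrame | None = None


def nmds(d: DistanceMatrix, dims: int = 2, n_starts: int = 20, max_iter: int = 300,
         tol: float = 1e-6, seed: int = 0) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Disparities are monotone-regressed on the rank order of the input
    dissimilarities (pool-adjacent-violators inside SMACOF); the best of one
    classical-scaling start plus ``n_starts - 1`` random starts is kept. The
    result is centred and rotated so axis 1 carries the most variance (stress
    is rotation-invariant, so this is purely a display convention).
    """
    D = d.data
    n = D.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for a 2-D ordination")
    if not np.isfinite(D).all():
        raise ValueError("dissimilarities must be finite")
    # classical (metric) scaling start
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:dims]
    init = evecs[:, idx] * np.sqrt(np.clip(evals[idx], 0, None))
    best_coords, best_stress, best_iter = None, np.inf, 0
    rng = np.random.default_rng(seed)
    starts = [init] + [None] * max(n_starts - 1, 0)
    for start in starts:
        coords, stress, n_iter = smacof(
            D, metric=False, n_components=dims, init=start, n_init=1,
            max_iter=max_iter, eps=tol, normalized_stress=True,
            random_state=int(rng.integers(2**31)), return_n_iter=True,
        )
        if stress < best_stress:
            best_coords, best_stress, best_iter = coords, float(stress), n_iter
    best_coords = best_coords - best_coords.mean(axis=0)
    if dims > 1:
        best_coords = PCA(n_components=dims).fit_transform(best_coords)
    cols = [f"nmds{i+1}" for i in range(dims)]
    coords = pd.DataFrame(best_coords, index=list(d.ids), columns=cols)
    return OrdinationResult(coordinates=coords, stress=best_stress, converged=best_iter < max_iter)


def kruskal_stress(coords: np.ndarray, d: DistanceMatrix) -> float:
    """Stress-1 of a given configuration against a dissimilarity matrix.

    Uses isotonic disparities (pool-adjacent-violators on the dissimilarity
    rank order), sqrt(sum (dhat - disparity)^2 / sum dhat^2).
    """
    from sklearn.isotonic import IsotonicRegression

    dhat = pdist(np.asarray(coords, dtype=float))
    delta = d.condensed_form()
    order = np.argsort(delta, kind="stable")
    disp = IsotonicRegression().fit_transform(np.arange(order.size), dhat[order])
    back = np.empty_like(disp)
    back[order] = disp
    return float(np.sqrt(((dhat - back) ** 2).sum() / (dhat**2).sum()))


def fit_vectors(coordinates: pd.DataFrame, variables: pd.DataFrame, n_perm: int = 999,
                seed: int = 0) -> pd.DataFrame:
    """Fit each variable as a direction in ordination space (envfit-style).

    For each numeric variable the least-squares direction maximising the
    correlation with the coordinates is found; r^2 is the squared multiple
    correlation and the p-value permutes the variable across units.
    Zero-variance variables are skipped with a warning. Directions are unit
    vectors; scale them by r to draw arrows.
    """
    import warnings as _warnings

    X = coordinates.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = []
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        if np.std(y) == 0:
            _warnings.warn(f"variable {name!r} has zero variance; skipped", stacklevel=2)
            continue
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        r2 = _envfit_r2(Xc, yc, beta)
        count = 0
        for _ in range(n_perm):
            yp = yc[rng.permutation(len(yc))]
            bp, *_ = np.linalg.lstsq(Xc, yp, rcond=None)
            if _envfit_r2(Xc, yp, bp) >= r2:
                count += 1
        direction = beta / (np.linalg.norm(beta) + 1e-300)
        rows.append(
            {"variable": name, "r2": r2, "p": (count + 1) / (n_perm + 1),
             **{f"dir{i+1}": direction[i] for i in range(len(direction))}}
        )
    return pd.DataFrame(rows)


def _envfit_r2(Xc: np.ndarray, yc: np.ndarray, beta: np.ndarray) -> float:
    resid = yc - Xc @ beta
    return float(1.0 - (resid**2).sum() / (yc**2).sum())
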