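"""Exclusion-zone inference and APD-space clustering.

The exclusion-zone hypothesis says the high-alignment / high-performance-
difference corner of APD space is systematically underpopulated.  Two
statistics operationalize it on a scatter of (alignment, perf_diff) points:

* **Quantile-grid binomial tests** — for every pair of quantile levels
  (q_a, q_p), count the points above both marginal quantiles.  Under
  independence of the two axes the expected occupancy fraction of that
  upper-right region is p0 = (1 − q_a)(1 − q_p); the cell's one-sided
  exact binomial p-value asks whether the region is *under*-populated.

* **Cluster-based permutation test** — neighboring grid cells with p-values
  below a cell-forming threshold are merged into 4-connected clusters whose
  mass is the summed −log10(p).  The maximum cluster mass is compared to a
  permutation null built by shuffling the pairing of perf_diff against
  alignment (which preserves both marginals but destroys any joint
  structure), giving a single multiple-comparison-aware p-value.

The clustering half assigns datasets to APD regions: k-means on z-scored
axes, k chosen by the silhouette score, and out-of-sample assignment by
the nearest per-cluster mean MMCD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import binom
from sklearn.cluster import KMeans
from sklearn.metrics import balanced_accuracy_score, silhouette_score

__all__ = [
    "QuantileGrid",
    "ClusterTestResult",
    "APDClustering",
    "grid_binomial_test",
    "cluster_permutation_test",
    "fit_apd_clusters",
    "assign_by_mmcd",
    "balanced_accuracy",
]


@dataclass(frozen=True)
class QuantileGrid:
    """Binomial p-value map over pairs of marginal quantile thresholds."""

    alignment_thresholds: np.ndarray  # quantile levels, increasing
    perfdiff_thresholds: np.ndarray
    alignment_cutoffs: np.ndarray  # data-scale threshold values
    perfdiff_cutoffs: np.ndarray
    observed_counts: np.ndarray  # shape (n_a, n_p)
    null_probs: np.ndarray
    p_values: np.ndarray
    n_points: int
    quantile_method: str = "median_unbiased"


@dataclass(frozen=True)
class ClusterTestResult:
    observed_cluster_mass: float
    cluster_cells: tuple  # grid coordinates of the maximal cluster
    n_permutations: int
    p_value: float
    seed: int = 0
    cell_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("permutation p-value must lie in (0, 1]")


@dataclass(frozen=True)
class APDClustering:
    k: int
    centers: np.ndarray  # in original (alignment, perf_diff) units
    train_labels: np.ndarray
    silhouette_by_k: dict
    cluster_mmcd_mean_sd: Optional[dict] = None  # label -> (mean, sd)
    scale_mean: np.ndarray = field(default=None, repr=False)
    scale_std: np.ndarray = field(default=None, repr=False)


def _extract_xy(points) -> tuple[np.ndarray, np.ndarray]:
    """Accept APDPoint-likes (attributes) or (alignment, perf_diff) pairs."""
    first = points[0]
    if hasattr(first, "alignment"):
        a = np.array([p.alignment for p in points], dtype=float)
        d = np.array([p.perf_diff for p in points], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        a, d = arr[:, 0], arr[:, 1]
    return a, d


def grid_binomial_test(points, quantile_step: float = 0.05) -> QuantileGrid:
    """Exact one-sided binomial tests over a grid of quantile-threshold pairs.

    For each cell (q_a, q_p), the region is {alignment > Q_a(q_a) and
    perf_diff > Q_p(q_p)} with marginal quantiles Q estimated by the
    median-unbiased convention; the p-value is P(K ≤ observed) for
    K ~ Binomial(N, (1 − q_a)(1 − q_p)).
    """
    if len(points) < 10:
        raise ValueError(f"need at least 10 points, got {len(points)}")
    inv = round(1.0 / quantile_step)
    if abs(inv * quantile_step - 1.0) > 1e-9:
        raise ValueError("quantile_step must divide 1")
    a, d = _extract_xy(points)
    if np.ptp(a) == 0 or np.ptp(d) == 0:
        raise ValueError("constant alignment or perf_diff: quantiles degenerate")
    levels = np.arange(inv) * quantile_step  # 0, step, ..., 1-step
    a_cut = np.quantile(a, levels, method="median_unbiased")
    d_cut = np.quantile(d, levels, method="median_unbiased")
    # at level 0 the region must contain every point; a strict '>' against
    # the sample minimum would drop it
    a_cut[0] = -np.inf
    d_cut[0] = -np.inf
    counts = _region_counts(a, d, a_cut, d_cut)
    p0 = np.outer(1.0 - levels, 1.0 - levels)
    pvals = binom.cdf(counts, len(a), p0)
    return QuantileGrid(
        alignment_thresholds=levels,
        perfdiff_thresholds=levels,
        alignment_cutoffs=a_cut,
        perfdiff_cutoffs=d_cut,
        observed_counts=counts,
        null_probs=p0,
        p_values=pvals,
        n_points=len(a),
    )


def _region_counts(a: np.ndarray, d: np.ndarray,
                   a_cut: np.ndarray, d_cut: np.ndarray) -> np.ndarray:
    """Count points strictly above each (a_cut[i], d_cut[j]) pair."""
    A = a[:, None] > a_cut[None, :]  # (N, n_a)
    D = d[:, None] > d_cut[None, :]
    return (A.astype(np.int64).T @ D.astype(np.int64)).astype(np.int64)


def _max_cluster_mass(pvals: np.ndarray, cell_alpha: float):
    """Largest 4-connected cluster of sub-threshold cells, scored by Σ −log10 p."""
    sig = pvals < cell_alpha
    if not sig.any():
        return 0.0, ()
    labeled, n_lab = ndimage.label(sig)  # default structure = 4-connectivity
    mass_map = -np.log10(np.maximum(pvals, 1e-300))
    masses = ndimage.sum_labels(mass_map, labeled, index=np.arange(1, n_lab + 1))
    best = int(np.argmax(masses)) + 1
    cells = tuple(map(tuple, np.argwhere(labeled == best)))
    return float(masses[best - 1]), cells


def cluster_permutation_test(points, quantile_step: float = 0.05,
                             cell_alpha: float = 0.05,
                             n_permutations: int = 9999,
                             seed: int = 0) -> ClusterTestResult:
    """Cluster-based permutation test for the exclusion zone.

    The observed maximal cluster mass on the binomial p-value grid is
    compared against the null distribution obtained by permuting the
    pairing of perf_diff against alignment across points.  The marginal
    quantile cutoffs are unchanged by the permutation, so only the joint
    counts are recomputed.  p = (1 + #{null ≥ observed}) / (1 + B).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    grid = grid_binomial_test(points, quantile_step=quantile_step)
    obs_mass, cells = _max_cluster_mass(grid.p_values, cell_alpha)

    a, d = _extract_xy(points)
    n = len(a)
    rng = np.random.default_rng(seed)
    # precompute the binomial lower-tail per cell for every possible count
    flat_p0 = grid.null_probs.ravel()
    cdf_table = binom.cdf(np.arange(n + 1)[None, :], n, flat_p0[:, None])
    A = (a[:, None] > grid.alignment_cutoffs[None, :]).astype(np.int64)
    D = (d[:, None] > grid.perfdiff_cutoffs[None, :]).astype(np.int64)
    shape = grid.p_values.shape
    cell_idx = np.arange(flat_p0.size)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        counts = (A.T @ D[perm]).ravel()
        pv = cdf_table[cell_idx, counts].reshape(shape)
        mass, _ = _max_cluster_mass(pv, cell_alpha)
        if mass >= obs_mass:
            n_ge += 1
    p_value = (1 + n_ge) / (1 + n_permutations)
    return ClusterTestResult(
        observed_cluster_mass=obs_mass,
        cluster_cells=cells,
        n_permutations=n_permutations,
        p_value=p_value,
        seed=seed,
        cell_alpha=cell_alpha,
    )


def fit_apd_clusters(points, k_range: Sequence[int] = range(2, 11),
                     n_init: int = 100, seed: int = 0,
                     mmcd_values: Optional[Sequence[float]] = None) -> APDClustering:
    """K-means over z-scored APD coordinates with silhouette-selected k.

    For each k in ``k_range`` the best of ``n_init`` seeded initializations
    is kept; the k maximizing the mean silhouette score wins.  When
    ``mmcd_values`` are supplied (one per point), per-cluster MMCD means and
    sample standard deviations are recorded for later region assignment.
    """
    a, d = _extract_xy(points)
    X = np.column_stack([a, d])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate APD scatter: an axis is constant")
    Z = (X - mu) / sd
    k_range = [k for k in k_range]
    if len(points) < max(k_range) + 1:
        raise ValueError(f"need more than {max(k_range)} points")
    sil_by_k, fits = {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
        sil_by_k[k] = float(silhouette_score(Z, km.labels_))
        fits[k] = km
    best_k = max(sil_by_k, key=lambda k: (sil_by_k[k], -k))
    km = fits[best_k]
    centers = km.cluster_centers_ * sd + mu
    mmcd_stats = None
    if mmcd_values is not None:
        mmcd_values = np.asarray(mmcd_values, dtype=float)
        if mmcd_values.shape[0] != len(points):
            raise ValueError("one MMCD value per point required")
        mmcd_stats = {}
        for lab in range(best_k):
            vals = mmcd_values[km.labels_ == lab]
            sd_lab = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            mmcd_stats[lab] = (float(vals.mean()), sd_lab)
    return APDClustering(
        k=best_k,
        centers=centers,
        train_labels=km.labels_.copy(),
        silhouette_by_k=sil_by_k,
        cluster_mmcd_mean_sd=mmcd_stats,
        scale_mean=mu,
        scale_std=sd,
    )


def assign_by_mmcd(clustering: APDClustering, mmcd_value: float) -> int:
    """Label of the cluster whose mean MMCD is nearest to ``mmcd_value``.

    Exact distance ties go to the lowest cluster index.
    """
    if clustering.cluster_mmcd_mean_sd is None:
        raise ValueError("clustering has no per-cluster MMCD means")
    labels = sorted(clustering.cluster_mmcd_mean_sd)
    dists = [abs(clustering.cluster_mmcd_mean_sd[lab][0] - mmcd_value) for lab in labels]
    return labels[int(np.argmin(dists))]


def balanced_accuracy(true_labels: Sequence[int], pred_labels: Sequence[int]) -> float:
    """Unweighted mean of per-class recalls."""
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    if t.size == 0:
        raise ValueError("empty label vectors")
    return float(balanced_accuracy_score(t, p))
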