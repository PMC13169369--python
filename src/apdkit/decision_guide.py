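"""Decision simulations: value of another representation vs. value of more data.

Two practical questions for a modeler who has benchmarked a handful of
molecular representations on a dataset:

* **p_better** — given n evaluated models with performances m_1..m_n, how
  likely is it that one more representation beats the current best by at
  least a relative factor C, i.e. p(m_{n+1} > C · max(m_1..m_n))?
  Estimated by Monte Carlo over random subsets of a representation
  ensemble, tracking the mean pairwise alignment of each sampled subset so
  estimates can be grouped into low/mid/high-alignment regimes.

* **Data scaling** — does performance keep improving with more training
  data?  Train on 75–95% subsets (5% increments, 30 repeats each) and
  summarize with the Spearman rank correlation between training fraction
  and performance, with a percentile bootstrap 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ModelEnsembleRecord",
    "PBetterEstimate",
    "ScalingResult",
    "p_better_sim",
    "sweep_p_better",
    "scaling_analysis",
    "spearman_with_bootstrap",
]

DEFAULT_FRACTIONS = (0.75, 0.80, 0.85, 0.90, 0.95)


@dataclass(frozen=True)
class ModelEnsembleRecord:
    """Per-dataset performances and pairwise alignments of an ensemble."""

    dataset_id: str
    performances: np.ndarray  # per-representation MCC values
    alignment_matrix: np.ndarray  # symmetric, unit diagonal, in [0, 1]

    def __post_init__(self) -> None:
        perf = np.asarray(self.performances, dtype=float)
        A = np.asarray(self.alignment_matrix, dtype=float)
        if perf.ndim != 1 or perf.shape[0] < 4:
            raise ValueError("need at least 4 representations")
        if A.shape != (perf.shape[0], perf.shape[0]):
            raise ValueError("alignment matrix shape must match #representations")
        if np.max(np.abs(A - A.T)) > 1e-10:
            raise ValueError("alignment matrix must be symmetric")
        if np.max(np.abs(np.diag(A) - 1.0)) > 1e-10:
            raise ValueError("alignment matrix diagonal must be 1")
        object.__setattr__(self, "performances", perf)
        object.__setattr__(self, "alignment_matrix", A)

    @property
    def n_models(self) -> int:
        return self.performances.shape[0]


@dataclass(frozen=True)
class PBetterEstimate:
    n: int
    C: float  # multiplicative threshold, e.g. 1.10 for +10%
    probability: float
    reps: int
    std_error: float
    alignment_bin: str = "all"
    mean_alignment: float = float("nan")
    n_excluded: int = 0
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability outside [0, 1]")


@dataclass(frozen=True)
class ScalingResult:
    fractions: tuple
    performance_samples: np.ndarray  # shape (n_fractions, repeats)
    r_s: float
    ci_95: tuple[float, float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci_95
        if lo > hi:
            raise ValueError("CI lower bound exceeds upper bound")


def _subset_draws(rng: np.random.Generator, reps: int, n_models: int, n: int) -> np.ndarray:
    """(reps, n+1) index matrix: first n are the reference subset, last the new draw."""
    keys = rng.random((reps, n_models))
    return np.argsort(keys, axis=1)[:, : n + 1]


def _mean_pairwise_alignment(A: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """Mean off-diagonal alignment within each row of sampled model indices."""
    reps, n = subsets.shape
    sub = A[subsets[:, :, None], subsets[:, None, :]]  # (reps, n, n)
    total = sub.sum(axis=(1, 2)) - n  # subtract unit diagonal
    return total / (n * (n - 1))


def _bin_label(value: float, edges: tuple[float, float]) -> str:
    if value < edges[0]:
        return "low"
    if value < edges[1]:
        return "mid"
    return "high"


def p_better_sim(record: ModelEnsembleRecord, n: int, C: float,
                 reps: int = 10_000, seed: int = 0,
                 alignment_edges: Optional[tuple[float, float]] = None,
                 _draws: Optional[np.ndarray] = None) -> PBetterEstimate:
    """Monte-Carlo estimate of p(m_{n+1} > C · max of n sampled models).

    Each repetition samples ``n`` reference representations without
    replacement plus one additional one, and counts a success when the
    newcomer's performance exceeds ``C`` times the reference maximum.
    Repetitions whose reference maximum is ≤ 0 are excluded when ``C > 1``
    (a multiplicative threshold on a nonpositive best is ill-behaved);
    their count is reported.

    ``alignment_edges`` are data-scale cut points for the low/mid/high
    label of the mean within-subset alignment; when omitted the label is
    computed from terciles of the per-repetition means.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= record.n_models:
        raise ValueError(f"n={n} must be smaller than the ensemble size {record.n_models}")
    if C < 1.0:
        raise ValueError("C must be >= 1")
    rng = np.random.default_rng(seed)
    draws = _draws if _draws is not None else _subset_draws(rng, reps, record.n_models, n)
    reps = draws.shape[0]
    perf = record.performances
    ref = perf[draws[:, :n]]
    new = perf[draws[:, n]]
    ref_max = ref.max(axis=1)
    valid = np.ones(reps, dtype=bool)
    if C > 1.0:
        valid = ref_max > 0
    n_excluded = int((~valid).sum())
    successes = new[valid] > C * ref_max[valid]
    n_valid = int(valid.sum())
    p = float(successes.mean()) if n_valid else 0.0
    se = float(np.sqrt(p * (1 - p) / n_valid)) if n_valid else float("nan")
    mean_aligns = _mean_pairwise_alignment(record.alignment_matrix, draws[:, :n]) \
        if n > 1 else np.full(reps, np.nan)
    overall = float(np.nanmean(mean_aligns))
    if alignment_edges is None and n > 1:
        edges = tuple(np.quantile(mean_aligns, [1 / 3, 2 / 3]))
    else:
        edges = alignment_edges
    label = _bin_label(overall, edges) if (edges is not None and np.isfinite(overall)) else "all"
    return PBetterEstimate(
        n=n, C=C, probability=p, reps=n_valid, std_error=se,
        alignment_bin=label, mean_alignment=overall,
        n_excluded=n_excluded, dataset_id=record.dataset_id,
    )


def sweep_p_better(record: ModelEnsembleRecord,
                   n_range: Sequence[int] = range(3, 8),
                   C_range: Sequence[float] = (1.10, 1.20, 1.30, 1.40, 1.50),
                   reps: int = 10_000, seed: int = 0,
                   alignment_edges: Optional[tuple[float, float]] = None) -> list[PBetterEstimate]:
    """Full (n, C) grid of p_better estimates.

    For a fixed n all C values share the same random draws (common random
    numbers), so estimates are monotone nonincreasing in C up to the
    exclusion rule.
    """
    out = []
    for i, n in enumerate(n_range):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        draws = _subset_draws(rng, reps, record.n_models, n)
        for C in C_range:
            out.append(p_better_sim(record, n=n, C=C, reps=reps, seed=seed,
                                    alignment_edges=alignment_edges, _draws=draws))
    return out


def spearman_with_bootstrap(x: Sequence[float], y: Sequence[float],
                            n_boot: int = 1000, seed: int = 0) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation (average ranks for ties) with a percentile
    bootstrap 95% CI over paired resampling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    m = x.shape[0]
    if m < 3:
        raise ValueError("need at least 3 pairs")
    r_s = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_boot, m))
    bx, by = x[idx], y[idx]
    rx = stats.rankdata(bx, axis=1)
    ry = stats.rankdata(by, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boots = np.where(denom > 0, (rx * ry).sum(axis=1) / denom, 0.0)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return r_s, (float(lo), float(hi))


def scaling_analysis(train_fn: Callable[[float, int], float],
                     fractions: Sequence[float] = DEFAULT_FRACTIONS,
                     repeats: int = 30, seed: int = 0,
                     n_boot: int = 1000) -> ScalingResult:
    """Incremental data-collection simulation.

    ``train_fn(fraction, seed)`` must return a performance value for a model
    trained on that fraction of the data.  Each (fraction, repeat) cell gets
    a fresh derived seed.  The result is the Spearman correlation between
    fraction and performance over all fraction × repeat pairs, with a
    percentile bootstrap CI; constant performances yield r_s = 0 with the
    degeneracy flag set.
    """
    fractions = tuple(fractions)
    perf = np.empty((len(fractions), repeats))
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(fractions) * repeats) % (2**31)
    k = 0
    for i, f in enumerate(fractions):
        for j in range(repeats):
            perf[i, j] = train_fn(f, int(child_seeds[k]))
            k += 1
    x = np.repeat(fractions, repeats)
    y = perf.ravel()
    if np.ptp(y) == 0:
        return ScalingResult(fractions=fractions, performance_samples=perf,
                             r_s=0.0, ci_95=(0.0, 0.0), degenerate=True)
    r_s, ci = spearman_with_bootstrap(x, y, n_boot=n_boot, seed=seed)
    return ScalingResult(fractions=fractions, performance_samples=perf,
                         r_s=r_s, ci_95=ci)
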