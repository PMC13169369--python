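"""Linear centered kernel alignment (CKA) and the alignment–performance-gap bound.

Linear CKA measures how similarly two feature matrices ``X`` (n × p) and
``Z`` (n × q) embed the same n samples::

    align(X, Z) = ||X^T H Z||_F^2 / (||X^T H X||_F · ||Z^T H Z||_F)

where ``H = I − (1/n) 1 1^T`` is the centering matrix.  The value lies in
[0, 1], equals 1 when the centered matrices span the same geometry up to an
orthogonal transform and isotropic scaling, and 0 when the centered
cross-covariance vanishes.

For centered designs and a normalized response ``y``, the squared-residual
gap of the two ordinary-least-squares fits is bounded by the alignment::

    ||X W − y||² − ||Z V − y||²  ≤  rank X + rank Z − 2 · align(X, Z)

so high alignment forbids large performance gaps (the "exclusion zone").
This module provides the alignment, the minimum-norm OLS fits, numerical
ranks, and a randomized verification harness for the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureMatrix",
    "ResponseVector",
    "OLSFit",
    "AlignmentResult",
    "BoundCheck",
    "BoundExperimentSummary",
    "center_columns",
    "linear_cka",
    "ols_fit",
    "numeric_rank",
    "check_bound",
    "bound_experiment",
]

_CENTER_TOL_PER_N = 1e-8  # column sums must vanish within this × n


@dataclass(frozen=True)
class FeatureMatrix:
    """An n_samples × n_features real matrix with a fixed sample ordering.

    Parameters
    ----------
    values
        The matrix; rows are samples.
    sample_ids
        Ordered per-row identifiers.  Alignment between two matrices is only
        meaningful when both were computed on the same samples in the same
        order, so these are compared before any pairwise operation.
    centered
        True when every column has zero mean.
    """

    values: np.ndarray
    sample_ids: tuple
    centered: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("FeatureMatrix requires a 2-D array")
        if values.shape[0] < 2:
            raise ValueError("FeatureMatrix requires at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("FeatureMatrix entries must be finite")
        ids = tuple(self.sample_ids)
        if len(ids) != values.shape[0]:
            raise ValueError(
                f"got {len(ids)} sample ids for {values.shape[0]} rows"
            )
        if self.centered:
            col_sums = values.sum(axis=0)
            if np.any(np.abs(col_sums) > _CENTER_TOL_PER_N * values.shape[0]):
                raise ValueError("centered flag set but column sums are nonzero")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ResponseVector:
    """A response vector y; ``normalized`` asserts unit L2 norm."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(values)):
            raise ValueError("ResponseVector entries must be finite")
        if self.normalized and abs(np.linalg.norm(values) - 1.0) > 1e-10:
            raise ValueError("normalized flag set but L2 norm is not 1")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class OLSFit:
    """Minimum-norm least-squares solution and its squared residual norm."""

    coefficients: np.ndarray
    residual_sq_norm: float

    def __post_init__(self) -> None:
        if self.residual_sq_norm < 0:
            raise ValueError("residual_sq_norm must be nonnegative")


@dataclass(frozen=True)
class AlignmentResult:
    """A linear-CKA value for a pair of representation tags."""

    value: float
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        if not (-1e-10 <= self.value <= 1.0 + 1e-10):
            raise ValueError(f"alignment {self.value} outside [0, 1]")


@dataclass(frozen=True)
class BoundCheck:
    """One evaluation of the performance-gap bound.

    ``lhs`` is the signed residual gap ``||XW − y||² − ||ZV − y||²``;
    ``rhs`` is ``rank X + rank Z − 2·align(X, Z)``.
    """

    lhs: float
    rhs: float
    rank_x: int
    rank_z: int
    alignment: float
    holds: bool


@dataclass(frozen=True)
class BoundExperimentSummary:
    """Aggregate of a randomized bound-verification run."""

    n_trials: int
    n_violations: int
    slack_quantiles: dict = field(default_factory=dict)
    seed: int = 0


def center_columns(M: np.ndarray | FeatureMatrix, sample_ids: Sequence | None = None) -> FeatureMatrix:
    """Subtract each column's mean, i.e. apply the centering matrix H_n.

    Row order is preserved.  Idempotent: centering a centered matrix returns
    an identical matrix.
    """
    if isinstance(M, FeatureMatrix):
        if M.centered:
            return M
        values = M.values
        ids = M.sample_ids
    else:
        values = np.asarray(M, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        ids = tuple(sample_ids) if sample_ids is not None else tuple(range(values.shape[0]))
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 rows")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite entries")
    centered = values - values.mean(axis=0, keepdims=True)
    return FeatureMatrix(values=centered, sample_ids=ids, centered=True)


def _centered_values(M: FeatureMatrix) -> np.ndarray:
    return M.values if M.centered else center_columns(M).values


def linear_cka(
    X: FeatureMatrix,
    Z: FeatureMatrix,
    pair: tuple[str, str] = ("X", "Z"),
) -> AlignmentResult:
    """Linear CKA between two feature matrices on the same samples.

    Computed in feature space as
    ``||Xc^T Zc||_F^2 / (||Xc^T Xc||_F · ||Zc^T Zc||_F)`` with
    column-centered ``Xc``, ``Zc`` — algebraically identical to the
    HSIC form on double-centered Gram matrices but O(n·p·q) rather than
    O(n²·(p+q)).

    Raises
    ------
    ValueError
        If sample counts or orderings differ, or if either matrix is all-zero
        after centering (the alignment is then 0/0 and undefined).
    """
    if X.n_samples != Z.n_samples:
        raise ValueError(
            f"sample count mismatch: {X.n_samples} vs {Z.n_samples}"
        )
    if X.sample_ids != Z.sample_ids:
        raise ValueError("sample orderings differ between X and Z")
    Xc = _centered_values(X)
    Zc = _centered_values(Z)
    xx = np.linalg.norm(Xc.T @ Xc)
    zz = np.linalg.norm(Zc.T @ Zc)
    if xx == 0.0 or zz == 0.0:
        raise ValueError(
            "degenerate kernel: a matrix is all-zero after centering; "
            "linear CKA is undefined (0/0)"
        )
    xz = np.linalg.norm(Xc.T @ Zc)
    value = float(xz**2 / (xx * zz))
    value = min(value, 1.0 + 1e-10)
    return AlignmentResult(value=value, pair=tuple(pair))


def ols_fit(X: FeatureMatrix, y: ResponseVector) -> OLSFit:
    """Minimum-norm least squares of y on X.

    Uses the SVD-based solver, so rank-deficient designs get the
    pseudoinverse (minimum-norm) coefficient vector.  The residual is
    orthogonal to the column space of X.
    """
    Xv = X.values
    yv = y.values
    if Xv.shape[0] != yv.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {Xv.shape[0]} rows, y has {yv.shape[0]}"
        )
    coef, _, _, _ = np.linalg.lstsq(Xv, yv, rcond=None)
    resid = Xv @ coef - yv
    return OLSFit(coefficients=coef, residual_sq_norm=float(resid @ resid))


def numeric_rank(M: np.ndarray | FeatureMatrix) -> int:
    """Numerical rank: singular values above max(n, p)·eps·σ_max."""
    values = M.values if isinstance(M, FeatureMatrix) else np.asarray(M, dtype=float)
    if values.size == 0:
        raise ValueError("empty matrix has no rank")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite entries")
    if values.ndim == 1:
        values = values[:, None]
    return int(np.linalg.matrix_rank(values))


def _normalize_response(y: np.ndarray) -> ResponseVector:
    """Center y, then scale to unit L2 norm."""
    y = np.asarray(y, dtype=float).ravel()
    y = y - y.mean()
    nrm = np.linalg.norm(y)
    if nrm == 0.0:
        raise ValueError("response is constant; cannot normalize")
    return ResponseVector(values=y / nrm, normalized=True)


def check_bound(
    X: FeatureMatrix,
    Z: FeatureMatrix,
    y: ResponseVector | np.ndarray,
    tol: float = 1e-8,
) -> BoundCheck:
    """Evaluate both sides of the performance-gap bound for one instance.

    ``y`` is centered and scaled to unit L2 norm if not already flagged
    normalized.  ``lhs`` is signed (X's residual minus Z's), matching the
    one-sided statement of the bound.
    """
    if not isinstance(y, ResponseVector):
        y = _normalize_response(np.asarray(y))
    elif not y.normalized:
        y = _normalize_response(y.values)
    Xc = X if X.centered else center_columns(X)
    Zc = Z if Z.centered else center_columns(Z)
    fit_x = ols_fit(Xc, y)
    fit_z = ols_fit(Zc, y)
    align = linear_cka(Xc, Zc).value
    rank_x = numeric_rank(Xc)
    rank_z = numeric_rank(Zc)
    lhs = fit_x.residual_sq_norm - fit_z.residual_sq_norm
    rhs = rank_x + rank_z - 2.0 * align
    return BoundCheck(
        lhs=lhs,
        rhs=rhs,
        rank_x=rank_x,
        rank_z=rank_z,
        alignment=align,
        holds=bool(lhs <= rhs + tol),
    )


def bound_experiment(
    n_trials: int,
    n_range: tuple[int, int] = (10, 200),
    dim_range: tuple[int, int] = (1, 50),
    seed: int = 0,
    quantiles: Sequence[float] = (0.0, 0.05, 0.25, 0.5, 0.75, 0.95, 1.0),
) -> BoundExperimentSummary:
    """Randomized verification of the performance-gap bound.

    Each trial draws Gaussian X (n × p), Z (n × q) and y with
    n ~ U{n_range}, p, q ~ U{dim_range}, checks the bound in both
    orientations of the gap, and records the slack rhs − lhs of the
    as-drawn orientation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    slacks = np.empty(n_trials)
    n_violations = 0
    for t in range(n_trials):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        p = int(rng.integers(dim_range[0], dim_range[1] + 1))
        q = int(rng.integers(dim_range[0], dim_range[1] + 1))
        ids = tuple(range(n))
        X = center_columns(rng.standard_normal((n, p)), ids)
        Z = center_columns(rng.standard_normal((n, q)), ids)
        y = rng.standard_normal(n)
        chk = check_bound(X, Z, y)
        # the bound is symmetric in (X, Z); verify the swapped gap too
        swapped_holds = -chk.lhs <= chk.rhs + 1e-8
        if not (chk.holds and swapped_holds):
            n_violations += 1
        slacks[t] = chk.rhs - chk.lhs
    qs = {f"q{q:g}": float(np.quantile(slacks, q)) for q in quantiles}
    return BoundExperimentSummary(
        n_trials=n_trials, n_violations=n_violations, slack_quantiles=qs, seed=seed
    )
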