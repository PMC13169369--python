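"""MLP benchmarking: training, hidden-layer embeddings, MCC scoring, APD points.

Each molecular representation is scored with the same small predictive
model: a three-layer MLP (input → 128 → 128 → output, counting weight
layers), ReLU activations, trained with Adam for 30 epochs at learning
rate 1e-4 with L2 weight decay 5e-4 and batch size 1000.  Performance is
the Matthews correlation coefficient (MCC) on a held-out split.

For a pair of representations of the same dataset, the "APD point" is the
pair (alignment, |ΔMCC|): linear CKA between the two models'
final-hidden-layer embeddings on a shared evaluation set, against the
absolute MCC difference.  A scatter of such points over many datasets and
representation pairs is the object the exclusion-zone statistics operate on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .repr_align import FeatureMatrix, center_columns, linear_cka

__all__ = [
    "MLPConfig",
    "TrainedModel",
    "EmbeddingSet",
    "APDPoint",
    "train_mlp",
    "extract_embeddings",
    "mcc",
    "build_apd_point",
    "aggregate_apd",
    "envelope_violation_fraction",
    "train_test_apd_point",
]


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of the benchmark MLP.

    ``n_layers`` counts weight layers: 3 means two hidden layers of
    ``hidden_dim`` units plus the output layer, with the second hidden
    layer serving as the embedding source.
    """

    n_layers: int = 3
    hidden_dim: int = 128
    epochs: int = 30
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    batch_size: int = 1000
    activation: str = "relu"
    seed: int = 0
    scale_features: bool = True

    def __post_init__(self) -> None:
        for name in ("n_layers", "hidden_dim", "epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be positive, weight_decay nonnegative")


@dataclass(frozen=True)
class TrainedModel:
    """A fitted MLP plus the preprocessing bound to it."""

    estimator: MLPClassifier
    config: MLPConfig
    representation_tag: str = "repr"
    scaler: Optional[StandardScaler] = None
    input_dim: int = 0

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"feature width {X.shape[1]} does not match model input width {self.input_dim}"
            )
        return self.scaler.transform(X) if self.scaler is not None else X

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self._transform(X))


@dataclass(frozen=True)
class EmbeddingSet:
    """n × hidden_dim matrix of last-hidden-layer activations."""

    matrix: np.ndarray
    sample_ids: tuple
    representation_tag: str = "repr"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(m)):
            raise ValueError("embedding entries must be finite")
        if m.shape[0] != len(tuple(self.sample_ids)):
            raise ValueError("sample_ids length must match rows")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))

    def as_feature_matrix(self) -> FeatureMatrix:
        return center_columns(self.matrix, self.sample_ids)


@dataclass(frozen=True)
class APDPoint:
    """One (dataset, representation-pair) observation in APD space."""

    dataset_id: str
    pair: tuple[str, str]
    alignment: float
    perf_diff: float
    mcc_a: float
    mcc_b: float

    def __post_init__(self) -> None:
        if abs(self.perf_diff - abs(self.mcc_a - self.mcc_b)) > 1e-12:
            raise ValueError("perf_diff must equal |mcc_a - mcc_b|")
        if not (-1e-10 <= self.alignment <= 1 + 1e-10):
            raise ValueError("alignment outside [0, 1]")


def _is_binary_matrix(X: np.ndarray) -> bool:
    return np.all((X == 0) | (X == 1))


def train_mlp(features: FeatureMatrix | np.ndarray, labels: Sequence[int],
              config: MLPConfig = MLPConfig()) -> TrainedModel:
    """Train the benchmark MLP on one representation.

    Continuous features are standard-scaled (fit on the training data);
    binary fingerprint matrices are left unscaled.  Training is
    deterministic given ``config.seed``.
    """
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} samples but {y.shape[0]} labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")

    scaler = None
    if config.scale_features and not _is_binary_matrix(X):
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)

    n_hidden = config.n_layers - 1
    est = MLPClassifier(
        hidden_layer_sizes=(config.hidden_dim,) * n_hidden,
        activation=config.activation,
        solver="adam",
        alpha=config.weight_decay,
        batch_size=min(config.batch_size, X.shape[0]),
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        n_iter_no_change=config.epochs,  # no early stopping: fixed epoch count
        shuffle=True,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        est.fit(X, y)
    if not np.isfinite(est.loss_):
        raise RuntimeError(
            f"training diverged (loss={est.loss_}); check feature scaling / learning rate"
        )
    return TrainedModel(
        estimator=est, config=config, representation_tag="repr",
        scaler=scaler, input_dim=X.shape[1] if scaler is None else scaler.n_features_in_,
    )


def extract_embeddings(model: TrainedModel, features: FeatureMatrix | np.ndarray,
                       sample_ids: Sequence | None = None) -> EmbeddingSet:
    """Post-activation values of the model's last hidden layer.

    The forward pass is replayed through the fitted weight matrices, so two
    identical input rows always produce identical embedding rows.  Under
    ReLU every entry is nonnegative.
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        ids = features.sample_ids
    else:
        X = np.asarray(features, dtype=float)
        ids = tuple(sample_ids) if sample_ids is not None else tuple(range(X.shape[0]))
    H = model._transform(X)
    est = model.estimator
    for W, b in zip(est.coefs_[:-1], est.intercepts_[:-1]):
        H = H @ W + b
        if model.config.activation == "relu":
            np.maximum(H, 0.0, out=H)
        elif model.config.activation == "tanh":
            np.tanh(H, out=H)
        elif model.config.activation == "logistic":
            H = 1.0 / (1.0 + np.exp(-H))
    return EmbeddingSet(matrix=H, sample_ids=ids,
                        representation_tag=model.representation_tag)


def mcc(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(matthews_corrcoef(y_true, y_pred))


def build_apd_point(dataset_id: str, embA: EmbeddingSet, embB: EmbeddingSet,
                    mcc_a: float, mcc_b: float) -> APDPoint:
    """Assemble one APD point from two embedding sets on a shared evaluation set."""
    if embA.sample_ids != embB.sample_ids:
        raise ValueError("embedding sets were not computed on the same samples")
    align = linear_cka(
        embA.as_feature_matrix(), embB.as_feature_matrix(),
        pair=(embA.representation_tag, embB.representation_tag),
    )
    return APDPoint(
        dataset_id=dataset_id,
        pair=(embA.representation_tag, embB.representation_tag),
        alignment=align.value,
        perf_diff=abs(mcc_a - mcc_b),
        mcc_a=float(mcc_a),
        mcc_b=float(mcc_b),
    )


def aggregate_apd(points: Sequence[APDPoint], ddof: int = 1) -> pd.DataFrame:
    """Per-dataset mean and standard deviation of alignment and perf_diff.

    ``ddof=1`` (sample std) by default; a dataset with a single point gets
    std 0 by convention.
    """
    if not points:
        raise ValueError("no APD points to aggregate")
    df = pd.DataFrame(
        {
            "dataset_id": [p.dataset_id for p in points],
            "alignment": [p.alignment for p in points],
            "perf_diff": [p.perf_diff for p in points],
        }
    )

    def _std(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(x.std(ddof=ddof))

    out = df.groupby("dataset_id", sort=True).agg(
        alignment_mean=("alignment", "mean"),
        alignment_std=("alignment", _std),
        perf_diff_mean=("perf_diff", "mean"),
        perf_diff_std=("perf_diff", _std),
        n_pairs=("alignment", "size"),
    )
    return out.reset_index()


def envelope_violation_fraction(points: Sequence[APDPoint]) -> float:
    """Fraction of points whose performance gap exceeds 1 − alignment."""
    if not points:
        raise ValueError("no APD points")
    return float(np.mean([p.perf_diff > 1.0 - p.alignment for p in points]))


def train_test_apd_point(
    dataset_id: str,
    features_a: np.ndarray,
    features_b: np.ndarray,
    labels: Sequence[int],
    tag_a: str = "A",
    tag_b: str = "B",
    config: MLPConfig = MLPConfig(),
    test_size: float = 0.2,
) -> APDPoint:
    """End-to-end APD point from two representations of the same samples.

    Stratified ``test_size`` split (seeded from the config); one MLP per
    representation; MCC on the held-out split; alignment of the two models'
    embeddings extracted on that same held-out split.
    """
    y = np.asarray(labels, dtype=int)
    n = y.shape[0]
    idx_train, idx_test = train_test_split(
        np.arange(n), test_size=test_size, stratify=y, random_state=config.seed
    )
    mccs, embs = [], []
    for tag, feats in ((tag_a, features_a), (tag_b, features_b)):
        feats = np.asarray(feats, dtype=float)
        model = train_mlp(feats[idx_train], y[idx_train], config)
        mccs.append(mcc(y[idx_test], model.predict(feats[idx_test])))
        emb = extract_embeddings(model, feats[idx_test], sample_ids=idx_test)
        embs.append(EmbeddingSet(matrix=emb.matrix, sample_ids=emb.sample_ids,
                                 representation_tag=tag))
    return build_apd_point(dataset_id, embs[0], embs[1], mccs[0], mccs[1])
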