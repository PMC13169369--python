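"""Seeded generators for every stage of the APD pipeline.

These generators reproduce the statistical structure the analysis assumes —
binary fingerprint datasets with a tunable between-class margin, multiple
noisy views of one latent sample set with tunable mutual alignment, APD
scatters under an independence null or with a planted exclusion zone, and
noisy learning curves — so the full pipeline is exercisable and testable
without any external data.  Every generator is a pure function of its
config: the same config yields bit-identical output.

What they do *not* emulate: chemically valid structures (fingerprints are
prototype-plus-noise bit vectors, not molecules), the geometry of
pretrained featurizers, and the size/assay heterogeneity of real
benchmark collections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .chem_features import Fingerprint, MoleculeRecord, MolecularDataset
from .model_bench import APDPoint
from .repr_align import FeatureMatrix, center_columns

__all__ = [
    "FPGenConfig",
    "ReprGenConfig",
    "APDGenConfig",
    "gen_fp_dataset",
    "gen_representations",
    "gen_apd_points",
    "gen_apd_clusters",
    "gen_learning_curves",
    "gen_blobs",
]


@dataclass(frozen=True)
class FPGenConfig:
    """Binary fingerprint dataset with a tunable between-class Tanimoto margin.

    Two class prototypes share ``prototype_overlap`` of their set bits
    (overlap 1 ⇒ identical prototypes ⇒ zero margin; overlap 0 ⇒ disjoint
    prototypes ⇒ maximal margin).  Each record is its class prototype with
    independent bit flips at ``flip_prob``.
    """

    n_per_class: int = 50
    n_bits: int = 2048
    prototype_overlap: float = 0.5
    bits_per_prototype: int = 64
    flip_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prototype_overlap <= 1.0):
            raise ValueError("prototype_overlap must be in [0, 1]")
        if not (0.0 <= self.flip_prob < 1.0):
            raise ValueError("flip_prob must be in [0, 1)")
        if self.bits_per_prototype > self.n_bits:
            raise ValueError("bits_per_prototype exceeds n_bits")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


@dataclass(frozen=True)
class ReprGenConfig:
    """Multiple noisy linear views of one shared latent sample set."""

    n_samples: int = 200
    latent_dim: int = 8
    output_dims: tuple = (16, 16)
    noise_scales: tuple = (0.0, 0.0)
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.output_dims) != len(self.noise_scales) or len(self.output_dims) < 2:
            raise ValueError("output_dims and noise_scales must have equal length >= 2")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")


@dataclass(frozen=True)
class APDGenConfig:
    """Synthetic APD scatter, either independence-null or planted exclusion."""

    n_datasets: int = 200
    mode: str = "null"  # or "exclusion"
    exclusion_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 10:
            raise ValueError("n_datasets must be >= 10")
        if self.mode not in ("null", "exclusion"):
            raise ValueError("mode must be 'null' or 'exclusion'")
        if self.exclusion_strength <= 0:
            raise ValueError("exclusion_strength must be > 0")


def gen_fp_dataset(config: FPGenConfig) -> MolecularDataset:
    """Generate a balanced two-class fingerprint dataset.

    Expected MMCD decreases as ``prototype_overlap`` increases: with
    overlap 1 and no flips every fingerprint is identical (MMCD 0); with
    overlap 0 and no flips the classes' bit sets are disjoint (MMCD 1).
    """
    rng = np.random.default_rng(config.seed)
    k = config.bits_per_prototype
    n_shared = int(round(config.prototype_overlap * k))
    if 2 * k - n_shared > config.n_bits:
        raise ValueError("n_bits too small for two prototypes at this overlap")
    # choose shared bits plus disjoint remainders for each prototype
    pool = rng.permutation(config.n_bits)
    shared = pool[:n_shared]
    own_a = pool[n_shared: n_shared + (k - n_shared)]
    own_b = pool[n_shared + (k - n_shared): n_shared + 2 * (k - n_shared)]
    proto = np.zeros((2, config.n_bits), dtype=np.uint8)
    proto[0, shared] = 1
    proto[0, own_a] = 1
    proto[1, shared] = 1
    proto[1, own_b] = 1
    records = []
    for cls in (0, 1):
        flips = rng.random((config.n_per_class, config.n_bits)) < config.flip_prob
        bits = np.where(flips, 1 - proto[cls], proto[cls]).astype(np.uint8)
        for i in range(config.n_per_class):
            records.append(
                MoleculeRecord(
                    id=f"c{cls}_{i}",
                    label=cls,
                    fingerprint=Fingerprint(bits=bits[i], n_bits=config.n_bits),
                )
            )
    return MolecularDataset(records=tuple(records), dataset_id=f"synth_fp_{config.seed}")


def _orthonormal_mixing(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    """d_in × d_out matrix with orthonormal rows or columns as shape permits."""
    G = rng.standard_normal((max(d_in, d_out), min(d_in, d_out)))
    Q, _ = np.linalg.qr(G)
    return Q if d_in >= d_out else Q.T


def gen_representations(config: ReprGenConfig) -> tuple[list[FeatureMatrix], np.ndarray]:
    """Noisy orthogonal views r = L·M_r + σ_r·ε of a shared latent matrix L.

    With zero noise and square mixings all views are orthogonal transforms
    of each other, so their mutual linear CKA is 1; CKA decreases as the
    noise scales grow.  Labels come from a logistic rule on L with a
    ``label_noise`` fraction of random flips.
    """
    rng = np.random.default_rng(config.seed)
    L = rng.standard_normal((config.n_samples, config.latent_dim))
    ids = tuple(range(config.n_samples))
    reps = []
    for d_out, sigma in zip(config.output_dims, config.noise_scales):
        M = _orthonormal_mixing(rng, config.latent_dim, d_out)
        R = L @ M
        if sigma > 0:
            R = R + sigma * rng.standard_normal(R.shape)
        reps.append(FeatureMatrix(values=R, sample_ids=ids, centered=False))
    w = rng.standard_normal(config.latent_dim)
    p = 1.0 / (1.0 + np.exp(-L @ w))
    labels = (p > 0.5).astype(int)
    if config.label_noise > 0:
        flip = rng.random(config.n_samples) < config.label_noise
        labels = np.where(flip, 1 - labels, labels)
    return reps, labels


def gen_apd_points(config: APDGenConfig) -> list[APDPoint]:
    """Synthetic APD scatter.

    Null mode: alignment ~ U(0, 1) independent of perf_diff ~ U(0, 0.6).
    Exclusion mode: perf_diff ~ U(0, s·(1 − alignment)) truncated to [0, 2],
    so with strength s = 1 no point violates the 1 − alignment envelope.
    """
    rng = np.random.default_rng(config.seed)
    align = rng.uniform(0.0, 1.0, config.n_datasets)
    if config.mode == "null":
        diff = rng.uniform(0.0, 0.6, config.n_datasets)
    else:
        ceil = np.clip(config.exclusion_strength * (1.0 - align), 0.0, 2.0)
        diff = rng.uniform(0.0, 1.0, config.n_datasets) * ceil
    points = []
    for i in range(config.n_datasets):
        m = diff[i] / 2.0
        points.append(
            APDPoint(
                dataset_id=f"ds{i:04d}",
                pair=("A", "B"),
                alignment=float(align[i]),
                perf_diff=float(diff[i]),
                mcc_a=float(m),
                mcc_b=float(-m),
            )
        )
    return points


def gen_apd_clusters(
    centers: Sequence[tuple[float, float]] = ((0.15, 0.1), (0.75, 0.1), (0.15, 0.5)),
    n_per_cluster: int = 60,
    spread: float = 0.04,
    mmcd_means: Sequence[float] | None = (0.85, 0.55, 0.75),
    mmcd_sd: float = 0.03,
    seed: int = 0,
) -> tuple[list[APDPoint], np.ndarray, np.ndarray]:
    """Planted Gaussian clusters in APD space with per-cluster MMCD levels.

    Returns (points, true_labels, mmcd_values).  The default centers mimic
    the three populated APD regions — low-alignment/low-gap,
    high-alignment/low-gap, low-alignment/high-gap — with the
    high-alignment region carrying the lowest MMCD.
    """
    rng = np.random.default_rng(seed)
    points, labels, mmcds = [], [], []
    for lab, (ca, cd) in enumerate(centers):
        a = np.clip(rng.normal(ca, spread, n_per_cluster), 0.0, 1.0)
        d = np.clip(rng.normal(cd, spread, n_per_cluster), 0.0, 2.0)
        if mmcd_means is not None:
            mm = np.clip(rng.normal(mmcd_means[lab], mmcd_sd, n_per_cluster), 0.0, 1.0)
            mmcds.extend(mm)
        for i in range(n_per_cluster):
            points.append(
                APDPoint(
                    dataset_id=f"k{lab}_{i:03d}",
                    pair=("A", "B"),
                    alignment=float(a[i]),
                    perf_diff=float(d[i]),
                    mcc_a=float(d[i] / 2),
                    mcc_b=float(-d[i] / 2),
                )
            )
            labels.append(lab)
    return points, np.asarray(labels), np.asarray(mmcds, dtype=float)


def gen_learning_curves(base: float, slope: float, noise_sd: float,
                        seed: int = 0) -> Callable[[float, int], float]:
    """Performance oracle: performance(f) = base + slope·f + N(0, noise_sd²).

    The returned callable has the (fraction, seed) signature
    ``scaling_analysis`` expects; the noise draw is seeded per call from
    both the generator seed and the call seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    def oracle(fraction: float, call_seed: int) -> float:
        mean = base + slope * fraction
        if noise_sd == 0:
            return float(mean)
        rng = np.random.default_rng(np.random.SeedSequence([seed, int(call_seed)]))
        return float(mean + noise_sd * rng.standard_normal())

    return oracle


def gen_blobs(n: int = 5000, separation: float = 6.0, n_features: int = 2,
              seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Two well-separated Gaussian blobs: a linearly separable sanity dataset.

    Defaults give essentially non-overlapping classes (6 sigma between the
    means) at the benchmark's dataset-size cap of 5000 samples.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    mean = np.zeros(n_features)
    mean[0] = separation / 2.0
    X = np.vstack([
        rng.normal(0, 1.0, (half, n_features)) - mean,
        rng.normal(0, 1.0, (n - half, n_features)) + mean,
    ])
    y = np.r_[np.zeros(half, dtype=int), np.ones(n - half, dtype=int)]
    perm = rng.permutation(n)
    return X[perm], y[perm]
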