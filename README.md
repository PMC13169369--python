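# apdkit

Tools for analyzing the relationship between **representational alignment**
and **performance differences** of machine-learning models in molecular
property prediction.

When two molecular representations (fingerprints, descriptors, learned
embeddings) are benchmarked on the same binary classification dataset, how
different can their results be? `apdkit` implements an analysis built
around a simple observation: the more aligned two representations are, the
less their models can disagree. Each (dataset, representation-pair)
observation becomes a point in **APD space** — alignment on the x-axis,
absolute performance difference on the y-axis — and the high-alignment /
high-difference corner is an *exclusion zone* that stays empty.

The package is aimed at computational chemists and ML practitioners who
benchmark multiple representations and want principled answers to "should
I try another representation, or collect more data?"

## What's inside

* **`repr_align`** — linear centered kernel alignment between feature
  matrices `X`, `Z` on the same n samples,

      align(X, Z) = ‖XᵀHZ‖²_F / (‖XᵀHX‖_F · ‖ZᵀHZ‖_F),   H = I − (1/n)11ᵀ,

  minimum-norm least squares, numerical ranks, and a randomized harness
  verifying the performance-gap bound
  `‖XW − y‖² − ‖ZV − y‖² ≤ rank X + rank Z − 2·align(X, Z)`.
* **`chem_features`** — Morgan fingerprints (radius 2, 2048 bits, via
  RDKit), Tanimoto distances, dataset preparation (MW < 600 Da filter,
  5000-molecule cap), and the **MMCD** (mean minimum class distance): the
  per-compound nearest-opposite-class Tanimoto distance averaged over the
  dataset — a cheap margin statistic that predicts where a dataset lands
  in APD space.
* **`model_bench`** — the fixed benchmark MLP (two hidden layers of 128,
  ReLU, Adam, 30 epochs, lr 1e-4, weight decay 5e-4, batch 1000),
  final-hidden-layer embedding extraction, Matthews correlation
  coefficient scoring, and APD-point assembly/aggregation.
* **`apd_inference`** — exclusion-zone statistics: exact binomial tests on
  a grid of quantile-threshold pairs, and a cluster-based permutation test
  over 4-connected grids of significant cells; plus k-means clustering of
  APD space with silhouette-selected k and MMCD-based region assignment.
* **`decision_guide`** — `p_better`, the Monte-Carlo probability that one
  more representation beats the best of n by at least a factor C, and a
  data-scaling analysis (train on 75–95% subsets, Spearman correlation
  with bootstrap CI).
* **`synthetic_data`** — seeded generators for every stage (fingerprint
  datasets with tunable class margin, multi-view representations with
  tunable alignment, null/planted APD scatters, learning curves), so the
  whole pipeline runs without external data.
* **`cli`** — `apdkit simulate|mmcd|cka|bound-check|apd-test|cluster|pbetter|scaling`.

## Worked example

```python
import numpy as np
from apdkit import (FPGenConfig, APDGenConfig, gen_fp_dataset, gen_apd_points,
                    mmcd, cluster_permutation_test, center_columns, check_bound)

# 1. margin statistic on a synthetic fingerprint dataset
ds = gen_fp_dataset(FPGenConfig(n_per_class=50, prototype_overlap=0.2, seed=0))
res = mmcd(ds)
print(f"MMCD ({res.variant}) = {res.value:.3f}  [n_pos={res.n_pos}, n_neg={res.n_neg}]")

# 2. alignment bounds the performance gap
rng = np.random.default_rng(0)
ids = tuple(range(100))
X = center_columns(rng.standard_normal((100, 12)), ids)
Z = center_columns(rng.standard_normal((100, 8)), ids)
chk = check_bound(X, Z, rng.standard_normal(100))
print(f"align = {chk.alignment:.3f}; gap = {chk.lhs:.3f} <= "
      f"rank sum - 2*align = {chk.rhs:.3f}; holds = {chk.holds}")

# 3. exclusion-zone test on a planted scatter
pts = gen_apd_points(APDGenConfig(n_datasets=200, mode="exclusion", seed=1))
test = cluster_permutation_test(pts, n_permutations=999, seed=0)
print(f"cluster permutation p = {test.p_value:.4f} "
      f"(observed mass {test.observed_cluster_mass:.1f}, "
      f"{len(test.cluster_cells)} cells)")
```

Output:

```
MMCD (mean_of_min) = 0.892  [n_pos=50, n_neg=50]
align = 0.078; gap = -0.054 <= rank sum - 2*align = 19.843; holds = True
cluster permutation p = 0.0010 (observed mass 913.2, 230 cells)
```

Reading the numbers: the two synthetic classes share only 20% of their
prototype bits, so the nearest opposite-class compound is on average at
Tanimoto distance 0.89 — a wide margin. The two random feature matrices
are nearly unaligned (0.078), so the bound permits a large gap, yet the
observed residual gap is tiny and the inequality holds comfortably. The
planted scatter keeps every point below the `1 − alignment` envelope, and
the permutation test flags that upper-right vacancy at p = 0.001 (the
floor for 999 permutations is 1/1000).

The same analyses run from the shell:

```bash
apdkit simulate --kind apd-points --mode exclusion --n 200 --seed 1 --out pts.jsonl
apdkit apd-test --points pts.jsonl --n-permutations 999 --seed 0 --out result.json
```

## Layout

```
src/apdkit/        repr_align, chem_features, model_bench, apd_inference,
                   decision_guide, synthetic_data, io, cli
tests/             unit, property (hypothesis), and acceptance suites
scripts/           acceptance.py
docs/methods.md    models, assumptions, parameter choices, limitations
```
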