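# uff

Unsupervised feature filtering for feature-by-instance matrices (genes ×
samples and similar), built on the SVD-entropy of the singular-value
spectrum:

* **Exact ranking** — each feature is scored by the change in the matrix
  SVD-entropy when its row is removed (computed through a rank-one
  downdate of the N×N Gram matrix, so cost is independent of the feature
  count per removal). Features above mean + 1 SD form the selected
  *positive* group, features below mean − 1 SD the *negative* group.
* **Fast ranking** — a first-order eigenvalue perturbation
  (`c'_i = c_i − (V_iᵀf)²`) scores all M features with a single
  eigendecomposition, O(M·N²) total. A warning is raised when the matrix
  entropy exceeds 0.1 and the small-perturbation assumption is doubtful.
* **Applicability check** — entropy-like measures on squared scores (SE)
  and feature variances (VE); a dataset is judged suitable when
  `sqrt(SE·VE) < 0.8`.
* **Outlier detection** — each instance gets an outlier-degree (entropy
  decrease upon removing its column); instances above mean + 1 SD are
  flagged. A kth-nearest-neighbour distance ranking is included as a
  baseline.
* **Evaluation harness** — variance / per-feature-entropy / random
  selection baselines, repeated k-means, and a pair-counting Jaccard
  score against known labels.
* **Synthetic data** — seeded generators of planted matrices (dominant
  first principal component, cluster-informative features, PC1-aligned
  wide-noise features, injectable outlier instances) with full ground
  truth, used by the whole test suite.

## Matrix format

Tab-delimited text; first row holds instance ids, first column holds
feature ids, everything else numeric. Features in rows, instances in
columns; pass `--transpose` for files stored the other way. GEO series
matrices and TCGA downloads should be reduced to this plain TSV (strip
comment/metadata lines, keep the expression table) before use.

## CLI

```sh
uff simulate --output matrix.tsv --seed 1          # planted matrix + truth TSV
uff rank --input matrix.tsv --output scores.tsv --method exact
uff rank --input matrix.tsv --output scores.tsv --method fast   # warns if entropy > 0.1
uff applicability --input matrix.tsv               # SE, VE, combined, verdict
uff udo --input matrix.tsv --output outliers.tsv --knn 5
uff evaluate --input matrix.tsv --labels labels.tsv \
    --output eval.tsv --methods uff,variance,random --n-features 100 --k 3
```

Options shared across subcommands can also be set in a `key = value`
config file via `--config`; flags override it. All randomness is
controlled by `--seed`; outputs are byte-identical across repeat runs
(add `--timestamp` to record wall-clock time in headers).

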