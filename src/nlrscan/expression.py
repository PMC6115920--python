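"""Tissue-expression normalisation and expression-level clustering.

Normalisation is the median-of-ratios size-factor estimator: each tissue's
factor is the median, over genes expressed in every tissue, of that gene's
value divided by its geometric mean across tissues. K-means (Lloyd's
algorithm, Euclidean distance) then groups genes into expression classes;
with k = 3 the classes are labelled by descending centroid magnitude as
moderate-to-minimal, minimal-to-basal and basal-to-none expression.

K-means is implemented directly rather than delegated so that the seeding
semantics are exactly as documented: initial centroids are k distinct genes
chosen uniformly from the gene list *sorted by id*, making the result a
function of the data and seed only, never of row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEVEL_LABELS = ("moderate-to-minimal", "minimal-to-basal", "basal-to-none")


@dataclass
class ExpressionMatrix:
    """Genes x tissues nonnegative expression values."""

    gene_ids: list[str]
    tissue_ids: list[str]
    values: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tissue_ids)):
            raise ValueError("values shape must be (n_genes, n_tissues)")
        if np.any(self.values < 0):
            raise ValueError("expression values must be nonnegative")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if self.size_factors.shape != (len(self.tissue_ids),):
                raise ValueError("size_factors length must equal tissue count")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            gene_ids=[str(g) for g in df.index],
            tissue_ids=[str(t) for t in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.tissue_ids)


def size_factors(matrix: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios per-tissue size factors.

    Only genes with strictly positive values in every tissue enter the
    reference set. Raises (suggesting a pseudocount) when no gene qualifies.
    """
    v = matrix.values
    positive = np.all(v > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no gene is positive in every tissue; add a pseudocount before "
            "normalising"
        )
    ref = v[positive]
    geo = np.exp(np.mean(np.log(ref), axis=1, keepdims=True))
    return np.median(ref / geo, axis=0)


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each tissue column by its size factor."""
    f = size_factors(matrix)
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        tissue_ids=list(matrix.tissue_ids),
        values=matrix.values / f[None, :],
        size_factors=f,
    )


@dataclass
class KMeansResult:
    gene_ids: list[str]          # sorted by id, the order of ``assignments``
    assignments: np.ndarray
    centroids: np.ndarray
    inertia_trace: list[float]   # within-cluster sum of squares per iteration
    converged: bool


def kmeans_cluster(matrix: ExpressionMatrix, k: int = 3, max_iter: int = 1000,
                   seed: int = 0, n_init: int = 1) -> KMeansResult:
    """Lloyd's algorithm with seeded gene-row initialisation.

    Initial centroids are k distinct genes chosen uniformly at random
    (rows sorted by gene id first); an empty cluster is re-seeded to the
    point farthest from its centroid. The within-cluster sum of squares is
    non-increasing across iterations. ``n_init`` > 1 runs that many
    restarts (seeds derived deterministically from ``seed``) and keeps the
    solution with the lowest final within-cluster sum of squares.
    """
    if n_init > 1:
        rng = np.random.default_rng(seed)
        seeds = rng.integers(0, 2 ** 31, size=n_init)
        runs = [kmeans_cluster(matrix, k=k, max_iter=max_iter, seed=int(s))
                for s in seeds]
        return min(runs, key=lambda r: r.inertia_trace[-1])
    n = len(matrix.gene_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds gene count {n}")
    order = np.argsort(np.array(matrix.gene_ids, dtype=object))
    X = matrix.values[order]
    ids = [matrix.gene_ids[i] for i in order]

    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    assignments = np.full(n, -1)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        # re-seed empty clusters to the farthest points (one point each)
        used: set[int] = set()
        for c in range(k):
            if not np.any(new_assign == c):
                by_dist = np.argsort(-d2[np.arange(n), new_assign])
                far = next(int(i) for i in by_dist if int(i) not in used)
                used.add(far)
                new_assign[far] = c
        trace.append(float(d2[np.arange(n), new_assign].sum()))
        if np.array_equal(new_assign, assignments):
            converged = True
            break
        assignments = new_assign
        for c in range(k):
            centroids[c] = X[assignments == c].mean(axis=0)
    return KMeansResult(
        gene_ids=ids,
        assignments=assignments,
        centroids=centroids,
        inertia_trace=trace,
        converged=converged,
    )


def classify_expression_levels(result: KMeansResult) -> dict[int, str]:
    """Rank k=3 clusters by mean centroid magnitude and label by rank.

    Highest-expressed cluster -> "moderate-to-minimal", middle ->
    "minimal-to-basal", lowest -> "basal-to-none". Ties break by cluster
    index.
    """
    if result.centroids.shape[0] != len(LEVEL_LABELS):
        raise ValueError(f"expression-level labelling requires k={len(LEVEL_LABELS)}")
    means = result.centroids.mean(axis=1)
    ranked = sorted(range(len(means)), key=lambda c: (-means[c], c))
    return {c: LEVEL_LABELS[rank] for rank, c in enumerate(ranked)}
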