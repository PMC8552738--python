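"""Alpha and beta diversity.

Alpha diversity: bias-corrected Chao1 richness and the Shannon index, plus a
Kruskal-Wallis H test for differences between sample groups (caves, sites,
niches).  Beta diversity: Bray-Curtis dissimilarities, classical principal
coordinate analysis (PCoA), and UPGMA (average-linkage) clustering with a
newick export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as _skbio_alpha

from .tables import FeatureTable, RelAbundanceTable, TableError

__all__ = [
    "chao1",
    "shannon",
    "alpha_diversity_table",
    "kruskal_wallis",
    "bray_curtis",
    "PcoaResult",
    "pcoa",
    "Dendrogram",
    "upgma",
]


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the numbers of singletons and doubletons.  With no
    singletons the estimator reduces to the observed richness.
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        raise ValueError("all-zero count vector has no richness estimate")
    return float(_skbio_alpha.chao1(counts, bias_corrected=True))


def shannon(counts, log_base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over non-zero proportions.

    Natural log by default (the ecology convention); pass ``log_base`` to
    change the unit (e.g. 2 for bits).
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() <= 0:
        raise ValueError("need at least one positive count")
    base = np.e if log_base is None else log_base
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def alpha_diversity_table(t: FeatureTable) -> pd.DataFrame:
    """Chao1, Shannon, and observed richness for every sample."""
    rows = []
    for j, sid in enumerate(t.sample_ids):
        col = t.counts[:, j]
        rows.append(
            {
                "sample_id": sid,
                "observed": int((col > 0).sum()),
                "chao1": chao1(col),
                "shannon": shannon(col),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).

    Degenerate all-tied input (every observation identical) carries no
    evidence against the null, so it returns H = 0, p = 1 instead of NaN.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    split = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in split):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*split)
    return float(h), float(p)


def bray_curtis(t: FeatureTable | RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    d(u, v) = 1 - 2 * sum_i min(u_i, v_i) / (sum u + sum v), in [0, 1].
    """
    if isinstance(t, RelAbundanceTable):
        mat = t.proportions
    else:
        mat = t.counts
    samples = np.asarray(mat, dtype=float).T  # samples x features
    if samples.shape[0] < 2:
        raise ValueError("need at least two samples")
    zero = np.where(samples.sum(axis=1) == 0)[0]
    if len(zero) >= 2:
        bad = [t.sample_ids[j] for j in zero]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {bad}")
    d = pdist(samples, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=t.sample_ids)


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    explained: np.ndarray  # percent of positive-eigenvalue variance per axis

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Principal coordinate analysis by classical (Torgerson) scaling.

    Double-centers -d^2/2 and eigendecomposes.  Axes with non-positive
    eigenvalues (possible for non-Euclidean dissimilarities such as
    Bray-Curtis) are dropped, and explained variance is reported over the
    positive eigenvalues only, so the percentages sum to 100.
    """
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    dd = d.data
    b = -0.5 * dd**2
    b = b - b.mean(axis=0) - b.mean(axis=1)[:, np.newaxis] + b.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    eigvals, eigvecs = eigvals[pos], eigvecs[:, pos]
    coords = eigvecs * np.sqrt(eigvals)[np.newaxis, :]
    explained = 100.0 * eigvals / eigvals.sum()
    return PcoaResult(list(d.ids), coords, eigvals, explained)


@dataclass
class Dendrogram:
    """UPGMA tree: scipy-style merge list plus leaf ids.

    ``merges`` rows are (cluster_a, cluster_b, height, size); heights are
    half the between-cluster average distance (molecular-clock convention),
    so the leaf-to-leaf path length through the tree equals the cophenetic
    distance.
    """

    leaf_ids: list[str]
    merges: np.ndarray  # linkage matrix with halved heights

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        tree = sch.to_tree(self._scipy_linkage())

        def height(node) -> float:
            return 0.0 if node.is_leaf() else node.dist / 2.0

        def render(node, parent_h: float) -> str:
            bl = parent_h - height(node)
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{bl:.10g}"
            left = render(node.left, height(node))
            right = render(node.right, height(node))
            return f"({left},{right}):{bl:.10g}"

        h = height(tree)
        return f"({render(tree.left, h)},{render(tree.right, h)});"

    def _scipy_linkage(self) -> np.ndarray:
        link = self.merges.copy()
        link[:, 2] *= 2.0
        return link

    def cophenetic(self) -> np.ndarray:
        return squareform(sch.cophenet(self._scipy_linkage()))


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering of a distance matrix."""
    link = sch.linkage(squareform(d.data, checks=False), method="average")
    merges = link.copy()
    merges[:, 2] /= 2.0
    return Dendrogram(list(d.ids), merges)
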