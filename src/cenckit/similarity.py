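"""Sample-relationship analytics: Spearman matrix, PCA, hierarchical tree.

All three operate on an expression compendium, optionally restricted to a
gene panel (e.g. a combined differential-expression list), mirroring the
common QC triptych of bulk RNA-seq studies: a rank-correlation heat map,
principal-component scores, and an agglomerative sample tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .compendium import ExpressionCompendium
from .genesets import GeneSet


def _panel_matrix(compendium: ExpressionCompendium, gene_panel: GeneSet | None) -> pd.DataFrame:
    if gene_panel is None:
        return compendium.tpm
    keep = [g for g in compendium.gene_ids if g in gene_panel]
    if not keep:
        raise ValueError(f"gene panel {gene_panel.name!r} shares no genes with the matrix")
    return compendium.tpm.loc[keep]


@dataclass
class CorrelationMatrix:
    """Symmetric sample x sample rank-correlation matrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class PCAResult:
    """Per-sample principal-component scores and variance fractions."""

    scores: pd.DataFrame          # samples x components
    variance_ratio: np.ndarray

    def write(self, path: str | Path) -> None:
        out = self.scores.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def spearman_matrix(compendium: ExpressionCompendium,
                    gene_panel: GeneSet | None = None) -> CorrelationMatrix:
    """Pairwise Spearman correlation between samples over a gene panel.

    Average ranks are used for ties. Invariant under strictly monotone
    transforms of any sample, so TPM vs log-TPM makes no difference.
    """
    mat = _panel_matrix(compendium, gene_panel).to_numpy(float)
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    rho = stats.spearmanr(mat, axis=0).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-sample case to a scalar
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2
    ids = compendium.sample_ids
    return CorrelationMatrix(pd.DataFrame(rho, index=ids, columns=ids))


def pca_scores(compendium: ExpressionCompendium, gene_panel: GeneSet | None = None,
               n_components: int = 2) -> PCAResult:
    """Sample scores on the principal components of log2(TPM + 1).

    Genes (features) are centered, not variance-scaled. Component signs
    are fixed by making each component's largest-magnitude gene loading
    positive, so results are fully deterministic. A constant matrix yields
    all-zero scores and variance fractions (not an error).
    """
    mat = _panel_matrix(compendium, gene_panel)
    X = np.log2(mat.to_numpy(float).T + 1.0)  # samples x genes
    n_samples, n_genes = X.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if n_components > min(n_samples, n_genes):
        raise ValueError(f"n_components={n_components} exceeds min(samples, panel genes)")
    centered = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(centered) > 1e-12):
        scores = np.zeros((n_samples, n_components))
        ratios = np.zeros(n_components)
    else:
        model = PCA(n_components=n_components, svd_solver="full")
        scores = model.fit_transform(X)
        for j in range(n_components):
            load = model.components_[j]
            if load[np.argmax(np.abs(load))] < 0:
                model.components_[j] *= -1
                scores[:, j] *= -1
        ratios = model.explained_variance_ratio_
    cols = [f"PC{j+1}" for j in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=compendium.sample_ids, columns=cols),
        variance_ratio=np.asarray(ratios, float),
    )


# --------------------------------------------------------------------------
# agglomerative clustering with a documented deterministic tie-break


@dataclass
class ClusterTree:
    """Binary agglomerative merge tree over labelled items.

    ``merges`` is a list of (left, right, height) triples where left/right
    are nested tuples of item labels (leaves are plain strings). Heights
    are non-decreasing for average and complete linkage.
    """

    labels: list[str]
    merges: list[tuple]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignment after undoing the k-1 highest merges."""
        if not (1 <= k <= len(self.labels)):
            raise ValueError(f"k must be in [1, {len(self.labels)}]")
        clusters = [frozenset([l]) for l in self.labels]
        merged = {frozenset([l]): frozenset([l]) for l in self.labels}
        groups = {frozenset([l]) for l in self.labels}
        for left, right, _h in self.merges[: len(self.labels) - k]:
            a, b = _leafset(left), _leafset(right)
            groups.discard(a)
            groups.discard(b)
            groups.add(a | b)
        assignment = {}
        for i, g in enumerate(sorted(groups, key=lambda s: sorted(s)[0])):
            for label in g:
                assignment[label] = i
        return assignment

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        if not self.merges:
            return f"{self.labels[0]};" if self.labels else ";"
        heights: dict[frozenset, float] = {frozenset([l]): 0.0 for l in self.labels}
        newick: dict[frozenset, str] = {frozenset([l]): l for l in self.labels}
        node = None
        for left, right, h in self.merges:
            a, b = _leafset(left), _leafset(right)
            la, lb = h - heights[a], h - heights[b]
            node = a | b
            newick[node] = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g})"
            heights[node] = h
        return newick[node] + ";"


def _leafset(node) -> frozenset:
    if isinstance(node, str):
        return frozenset([node])
    out = frozenset()
    for child in node:
        out |= _leafset(child)
    return out


def _pairwise_distance(X: np.ndarray, metric: str) -> np.ndarray:
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    n = X.shape[0]
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))
    if metric == "correlation":
        # rank-correlation distance 1 - Spearman, matching the package's
        # correlation-heatmap context
        ranks = np.apply_along_axis(stats.rankdata, 1, X)
        rc = np.corrcoef(ranks)
        rc = np.atleast_2d(rc)
        return 1.0 - rc
    raise ValueError(f"metric must be 'euclidean' or 'correlation', got {metric!r}")


def hierarchical_cluster(matrix: pd.DataFrame, metric: str = "correlation",
                         linkage: str = "average") -> ClusterTree:
    """Agglomerative clustering of the rows of an items x features matrix.

    Average or complete linkage over euclidean or rank-correlation
    (1 - Spearman) distance. Deterministic: among equal-distance merge
    candidates, the pair whose (lexicographically smallest member) labels
    sort first is merged, so the tree is invariant under row reordering.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"linkage must be 'average' or 'complete', got {linkage!r}")
    labels = [str(l) for l in matrix.index]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    D = _pairwise_distance(matrix.to_numpy(float), metric)

    # active clusters: representative label -> (node, leaf indices, size)
    nodes: dict[str, tuple] = {labels[i]: (labels[i], [i], 1) for i in range(n)}
    dist: dict[tuple[str, str], float] = {}
    order = sorted(nodes)
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            dist[(a, b)] = float(D[nodes[a][1][0], nodes[b][1][0]])

    merges: list[tuple] = []
    while len(nodes) > 1:
        # smallest distance, ties broken by the sorted representative pair
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (ra, rb), h = best
        na, ia, sa = nodes.pop(ra)
        nb, ib, sb = nodes.pop(rb)
        merges.append((na, nb, h))
        rep = min(ra, rb)
        new_idx = ia + ib
        for key in [k for k in dist if ra in k or rb in k]:
            del dist[key]
        nodes[rep] = ((na, nb), new_idx, sa + sb)
        for rc, (nc, ic, sc) in nodes.items():
            if rc == rep:
                continue
            if linkage == "average":
                d = _linkage_distance_avg(D, new_idx, ic)
            else:
                d = _linkage_distance_max(D, new_idx, ic)
            dist[tuple(sorted((rep, rc)))] = d
    return ClusterTree(labels=sorted(labels), merges=merges)


def _linkage_distance_avg(D: np.ndarray, idx_a: list[int], idx_b: list[int]) -> float:
    return float(D[np.ix_(idx_a, idx_b)].mean())


def _linkage_distance_max(D: np.ndarray, idx_a: list[int], idx_b: list[int]) -> float:
    return float(D[np.ix_(idx_a, idx_b)].max())
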