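"""Hierarchical clustering of haplotypes and diplotypes.

Clustering uses city-block (Manhattan) genetic distance with complete
linkage. Diplotype clusters that are both common and depleted of
heterozygous sites are candidates for haplotypes under recent selection:
a sweeping haplotype rises in frequency, so carriers increasingly hold
two copies of it and their dosage vectors become homozygous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from anosurv.io import MISSING

log = logging.getLogger(__name__)


@dataclass
class DiplotypeRegion:
    """Per-sample dosage vectors (0/1/2) over a gene region.

    In haplotype mode the vectors are binary and per-vector
    heterozygosity is identically zero.
    """

    region_id: str
    ids: tuple[str, ...]
    vectors: np.ndarray  # (n, S)
    mode: str = "diplotype"  # or "haplotype"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D")
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("one vector per id required")
        if self.mode == "haplotype" and not np.isin(
            self.vectors[self.vectors != MISSING], (0, 1)
        ).all():
            raise ValueError("haplotype-mode vectors must be binary")

    def heterozygosity(self) -> np.ndarray:
        """Fraction of (non-missing) sites with dosage 1, per vector."""
        if self.mode == "haplotype":
            return np.zeros(self.vectors.shape[0])
        called = self.vectors != MISSING
        het = ((self.vectors == 1) & called).sum(axis=1)
        denom = np.maximum(called.sum(axis=1), 1)
        return het / denom


@dataclass
class ClusterTree:
    linkage: np.ndarray  # scipy (n-1, 4) merge table
    ids: tuple[str, ...]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, height: float) -> np.ndarray:
        """Cluster labels (1-based, scipy convention) at a height cutoff."""
        return hierarchy.fcluster(self.linkage, t=height, criterion="distance")

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.ids[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


@dataclass
class ClusterReport:
    label: int
    member_ids: tuple[str, ...]
    size: int
    frequency: float
    mean_heterozygosity: float
    shared_sites: tuple[int, ...]  # site indices fixed non-reference in the cluster
    exclusive_sites: tuple[int, ...]  # shared sites absent outside the cluster
    mean_copy_number: float | None
    selection_candidate: bool


def impute_to_mode(vectors: np.ndarray) -> tuple[np.ndarray, float]:
    """Replace missing entries by the per-site modal dosage (distance only)."""
    v = np.asarray(vectors).copy()
    miss = v == MISSING
    frac = float(miss.mean()) if v.size else 0.0
    if miss.any():
        for j in np.flatnonzero(miss.any(axis=0)):
            col = v[:, j]
            good = col[col != MISSING]
            mode = np.bincount(good, minlength=3).argmax() if good.size else 0
            col[col == MISSING] = mode
        log.info("imputed %.1f%% missing dosages to site mode", 100 * frac)
    return v, frac


def pairwise_cityblock(vectors: np.ndarray) -> np.ndarray:
    """Full city-block distance matrix: d(a,b) = sum_s |a_s - b_s|."""
    v = np.asarray(vectors, dtype=np.float64)
    if v.ndim != 2:
        raise ValueError("vectors must be 2-D (equal-length rows)")
    return squareform(pdist(v, metric="cityblock"))


def complete_linkage(distance: np.ndarray, ids: tuple[str, ...]) -> ClusterTree:
    """Agglomerative clustering with complete (maximum) linkage.

    The inter-cluster distance is the maximum pairwise member distance
    (Lance-Williams max update). Ties are broken deterministically by
    the smallest leaf index, so the dendrogram is invariant to input
    order up to that rule. Emits a scipy-format linkage matrix so the
    standard cutting/plotting tools apply.
    """
    D = np.asarray(distance, dtype=np.float64)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    work = D.copy()
    active: list[int] = list(range(n))  # row index in `work` per live cluster
    link_id = list(range(n))  # scipy node id per live cluster
    sizes = [1] * n
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best_d = np.inf
        best = (0, 1)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                d = work[active[ai], active[bi]]
                if d < best_d:
                    best_d = d
                    best = (ai, bi)
        ai, bi = best
        ra, rb = active[ai], active[bi]
        Z[step] = (link_id[ai], link_id[bi], best_d, sizes[ai] + sizes[bi])
        # complete-linkage update onto row ra
        np.maximum(work[ra], work[rb], out=work[ra])
        work[:, ra] = work[ra]
        work[ra, ra] = 0.0
        sizes[ai] += sizes[bi]
        link_id[ai] = n + step
        del active[bi], link_id[bi], sizes[bi]
    return ClusterTree(Z, tuple(ids))


def cluster_diplotypes(region: DiplotypeRegion) -> ClusterTree:
    v, _ = impute_to_mode(region.vectors)
    return complete_linkage(pairwise_cityblock(v), region.ids)


def cluster_report(
    tree: ClusterTree,
    region: DiplotypeRegion,
    cutoff: float | None = None,
    min_cluster_frac: float = 0.05,
    het_quantile: float = 0.25,
    copy_number: np.ndarray | None = None,
) -> list[ClusterReport]:
    """Cut the dendrogram and summarize common clusters.

    ``cutoff`` defaults to ``0.001 * site count`` (a per-site distance
    convention). Clusters with frequency >= ``min_cluster_frac`` are
    reported with size, frequency, mean heterozygosity, sites fixed
    non-reference within the cluster (and the subset exclusive to it),
    and mean region copy number when CNV state is supplied. Clusters
    whose mean heterozygosity falls below the ``het_quantile`` quantile
    of per-sample heterozygosity are flagged as selection candidates.
    """
    if cutoff is None:
        cutoff = 0.001 * region.vectors.shape[1]
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    labels = tree.cut(cutoff)
    het = region.heterozygosity()
    het_cut = float(np.quantile(het, het_quantile)) if het.size else 0.0
    n = len(region.ids)
    vec, _ = impute_to_mode(region.vectors)
    reports = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        freq = members.size / n
        if freq < min_cluster_frac:
            continue
        sub = vec[members]
        shared = np.flatnonzero((sub > 0).all(axis=0))
        outside = np.flatnonzero(labels != lab)
        if outside.size:
            absent_out = (vec[outside][:, shared] == 0).all(axis=0)
            exclusive = shared[absent_out]
        else:
            exclusive = shared
        mean_het = float(het[members].mean())
        reports.append(
            ClusterReport(
                label=int(lab),
                member_ids=tuple(region.ids[i] for i in members),
                size=int(members.size),
                frequency=freq,
                mean_heterozygosity=mean_het,
                shared_sites=tuple(int(s) for s in shared),
                exclusive_sites=tuple(int(s) for s in exclusive),
                mean_copy_number=(
                    float(np.mean(copy_number[members])) if copy_number is not None else None
                ),
                selection_candidate=mean_het <= het_cut,
            )
        )
    reports.sort(key=lambda r: -r.size)
    return reports
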