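"""Unsupervised hierarchical clustering of samples: centered-Pearson
dissimilarity, average-linkage (UPGMA) trees, newick export, and a
per-group branch-purity report."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from mirisk.datamodel import ClinicalAnnotation, ExpressionMatrix
from mirisk.errors import DissimilarityError, ValidationError


def pearson_dissimilarity(matrix: ExpressionMatrix) -> np.ndarray:
    """Sample-by-sample d(i,j) = 1 - r(i,j), r the Pearson correlation over
    probes; d in [0, 2], zero diagonal."""
    if matrix.n_samples < 2 or matrix.n_probes < 2:
        raise DissimilarityError("need >=2 samples and >=2 probes")
    x = matrix.values
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = [s for s, v in zip(matrix.sample_ids, sd) if v == 0]
        raise DissimilarityError(f"zero-variance samples: {bad}")
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - np.clip(r, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class Dendrogram:
    """UPGMA merge sequence in scipy linkage format plus the leaf ids."""

    linkage: np.ndarray         # (n-1) x 4 scipy linkage matrix
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.leaf_ids, (int(v) for v in labels)))

    def clade_leafsets(self) -> list[set[str]]:
        """Leaf-id set of every internal node, in merge order."""
        n = self.n_leaves
        sets: dict[int, set[str]] = {i: {self.leaf_ids[i]} for i in range(n)}
        out = []
        for k, (a, b, _, _) in enumerate(self.linkage):
            merged = sets[int(a)] | sets[int(b)]
            sets[n + k] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.leaf_ids[node.id]
            left = rec(node.left)
            right = rec(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.10g},{right}:{dr:.10g})"

        return rec(tree) + ";"


def average_linkage(d: np.ndarray, leaf_ids: Sequence[str]) -> Dendrogram:
    """UPGMA on a symmetric dissimilarity matrix.

    Leaves are pre-sorted lexicographically so tie-breaks in the merge order
    are deterministic regardless of input sample order.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or len(leaf_ids) != n:
        raise ValidationError("dissimilarity must be square and match leaf ids")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix must be symmetric")
    order = sorted(range(n), key=lambda i: str(leaf_ids[i]))
    d_sorted = d[np.ix_(order, order)]
    ids_sorted = [str(leaf_ids[i]) for i in order]
    z = hierarchy.linkage(squareform(d_sorted, checks=False), method="average")
    return Dendrogram(linkage=z, leaf_ids=ids_sorted)


def cluster_samples(matrix: ExpressionMatrix) -> Dendrogram:
    """Convenience: centered-Pearson dissimilarity + average linkage."""
    return average_linkage(pearson_dissimilarity(matrix), matrix.sample_ids)


@dataclass
class GroupBranchReport:
    group: str
    n_members: int
    pure_branch: bool           # members form a clade (or a single leaf)
    smallest_clade_size: int    # leaves in the smallest clade containing all members

    def describe(self) -> str:
        shape = "forms a pure sub-branch" if self.pure_branch else (
            f"spreads over a clade of {self.smallest_clade_size} leaves"
        )
        return f"{self.group} (n={self.n_members}): {shape}"


def cluster_purity_report(
    dendrogram: Dendrogram,
    annotations: Sequence[ClinicalAnnotation] | Mapping[str, str],
) -> list[GroupBranchReport]:
    """For each sample group, report whether its members form a connected
    sub-branch and the size of the smallest clade containing them all."""
    if isinstance(annotations, Mapping):
        by_id = {str(k): str(v) for k, v in annotations.items()}
    else:
        by_id = {a.sample_id: a.group.value for a in annotations}
    missing = [s for s in dendrogram.leaf_ids if s not in by_id]
    if missing:
        raise ValidationError(f"leaves without annotation: {missing}")
    clades = dendrogram.clade_leafsets()
    all_leaves = set(dendrogram.leaf_ids)
    reports = []
    for group in sorted(set(by_id[s] for s in dendrogram.leaf_ids)):
        members = {s for s in dendrogram.leaf_ids if by_id[s] == group}
        pure = len(members) == 1 or members in clades or members == all_leaves
        containing = [c for c in clades if members <= c] or [all_leaves]
        smallest = min(len(c) for c in containing) if len(members) > 1 else 1
        reports.append(
            GroupBranchReport(
                group=group,
                n_members=len(members),
                pure_branch=bool(pure),
                smallest_clade_size=smallest,
            )
        )
    return reports
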