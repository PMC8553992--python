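"""Module detection: Euclidean distances on correlation profiles,
agglomerative clustering, and the half-height dendrogram cut.

Each region's coactivity profile is its full row of the interregional
Pearson matrix (diagonal included). Regions are clustered on the Euclidean
distances between profiles; the dendrogram is cut at a fixed fraction
(default one half) of its maximal merge height, and every maximal cluster
fully merged strictly below the cut becomes a module. Leaves that never
merge below the cut are singleton modules ("isolates").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .coactivity import CorrelationMatrix
from .regions import RegionSet

SUPPORTED_LINKAGES = ("single", "complete", "average", "ward")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Euclidean distance matrix over region coactivity profiles."""

    regions: RegionSet
    D: pd.DataFrame

    def __post_init__(self):
        a = self.D.to_numpy()
        if not np.allclose(a, a.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(a), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (a < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history over regions.

    ``Z`` is the standard (n-1) x 4 linkage array: children indices, merge
    height, cluster size. ``labels`` gives the leaf order used to build it.
    """

    labels: tuple[str, ...]
    Z: np.ndarray
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def max_height(self) -> float:
        return float(self.Z[-1, 2])

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(a), int(b), float(h), int(s)) for a, b, h, s in self.Z
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Z, columns=["child_a", "child_b", "height", "size"]
        ).astype({"child_a": int, "child_b": int, "size": int})


@dataclass(frozen=True)
class ModulePartition:
    """Assignment of every region to exactly one module."""

    assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.assignment:
            raise ValueError("partition must cover at least one region")

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for m in self.assignment.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def members(self, module_id: int) -> list[str]:
        return [r for r, m in self.assignment.items() if m == module_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": list(self.assignment), "module_id": list(self.assignment.values())}
        )


def correlation_distance(cm: CorrelationMatrix) -> DistanceMatrix:
    """Euclidean distances between full correlation-matrix rows.

    Rows include the diagonal entries and the columns of both regions being
    compared; identical coactivity profiles yield distance 0.
    """
    if len(cm.regions) < 3:
        raise ValueError("need at least 3 regions to build a distance matrix")
    R = cm.R
    if R.isna().to_numpy().any():
        bad = sorted(R.columns[R.isna().any()].tolist())
        raise ValueError(
            f"correlation matrix has missing entries involving {bad}; "
            "drop incomplete regions before computing distances"
        )
    D = squareform(pdist(R.to_numpy(), metric="euclidean"))
    return DistanceMatrix(
        regions=cm.regions,
        D=pd.DataFrame(D, index=R.index, columns=R.columns),
    )


def hierarchical_cluster(dm: DistanceMatrix, linkage_method: str = "complete") -> LinkageTree:
    """Agglomerative clustering of the distance matrix.

    Leaves are processed in lexicographic label order so the tree is a pure
    function of the labelled distances, independent of input region order.
    """
    if linkage_method not in SUPPORTED_LINKAGES:
        raise ValueError(
            f"unsupported linkage {linkage_method!r}; choose one of {SUPPORTED_LINKAGES}"
        )
    order = sorted(dm.regions.names)
    D = dm.D.loc[order, order].to_numpy()
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    return LinkageTree(labels=tuple(order), Z=Z, method=linkage_method)


def cut_dendrogram(tree: LinkageTree, cut_fraction: float = 0.5) -> ModulePartition:
    """Cut the tree at ``cut_fraction`` x (maximal merge height).

    Merges at heights strictly below the cut join their clusters; a merge
    exactly at the cut height does not, so ties at the cut resolve the same
    way every run. ``cut_fraction = 1.0`` means cutting above the root and
    yields a single module. Module ids are assigned 1..m in order of each
    module's first member in leaf-label order.
    """
    if not (0.0 < cut_fraction <= 1.0):
        raise ValueError("cut_fraction must lie in (0, 1]")
    n = tree.n_leaves
    cut_height = cut_fraction * tree.max_height

    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, h, _size) in enumerate(tree.merges):
        if h < cut_height or cut_fraction >= 1.0:
            new = n + k
            parent[find(a)] = new
            parent[find(b)] = new

    roots: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for leaf, label in enumerate(tree.labels):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1
        assignment[label] = roots[r]
    return ModulePartition(assignment=assignment)


def count_isolates(p: ModulePartition) -> int:
    """Number of singleton modules (regions that never merged below the cut)."""
    return sum(1 for s in p.module_sizes.values() if s == 1)


def modules_from_correlation(
    cm: CorrelationMatrix,
    linkage_method: str = "complete",
    cut_fraction: float = 0.5,
) -> tuple[LinkageTree, ModulePartition]:
    """Correlation matrix -> distances -> tree -> half-height partition."""
    dm = correlation_distance(cm)
    tree = hierarchical_cluster(dm, linkage_method=linkage_method)
    if tree.max_height == 0:
        warnings.warn(
            "all merge heights are zero (identical coactivity profiles); "
            "the cut yields singletons"
        )
    return tree, cut_dendrogram(tree, cut_fraction=cut_fraction)
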