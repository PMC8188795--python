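"""Genetic and phenotypic distance matrices, NJ dendrograms, and
partition comparison.

Population-level distances use Nei's (1978) unbiased genetic distance;
individual-level distances use the allele-sharing distance
1 - shared/(2 * shared loci).  Neighbor-joining trees are built with
scikit-bio and written as Newick.  Trait matrices are standardized and
clustered hierarchically (Euclidean distance, average linkage by
default); partitions are compared with the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import TreeNode, nj

from .geno_io import MISSING, GenotypeMatrix
from .differentiation import _pop_inputs


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str                      # nei-population | allele-share-individual | euclidean-trait
    flags: list = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class PartitionComparison:
    ari: float
    contingency: pd.DataFrame


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def nei_distance(matrix: GenotypeMatrix, grouping: pd.Series) -> DistanceMatrix:
    """Nei's (1978) unbiased genetic distance between populations.

    D = -ln( Jxy / sqrt(Jx Jy) ) with J's averaged over loci and the
    within-population identities bias-corrected by
    (2n sum(p^2) - 1)/(2n - 1).  Zero cross-identity at every locus gives
    an infinite distance (flagged, never silently capped).
    """
    pops, n, p, h = _pop_inputs(matrix, grouping)
    s = len(pops)
    if s < 2:
        raise ValueError("need at least two populations")
    L = p.shape[1]
    vals = np.zeros((s, s))
    flags = []
    jx = np.zeros((s, L))
    for gi in range(s):
        for l in range(L):
            nn = 2 * n[gi, l]
            if nn <= 1:
                jx[gi, l] = np.nan
                continue
            jx[gi, l] = (nn * (p[gi, l] ** 2).sum() - 1) / (nn - 1)
    for i in range(s):
        for j in range(i + 1, s):
            jxy = (p[i] * p[j]).sum(axis=1)  # per locus
            ok = ~np.isnan(jx[i]) & ~np.isnan(jx[j])
            num = jxy[ok].mean()
            den = np.sqrt(jx[i][ok].mean() * jx[j][ok].mean())
            if num <= 0:
                d = np.inf
                flags.append(f"infinite distance: {pops[i]} vs {pops[j]}")
            else:
                d = -np.log(num / den)
                if d < 0:
                    flags.append(f"negative Nei distance floored: {pops[i]} vs {pops[j]}")
                    d = 0.0
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(list(pops), vals, "nei-population", flags)


def individual_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance between individuals:
    1 - (shared allele count)/(2 * shared loci)."""
    n, L = matrix.n_individuals, matrix.n_loci
    if n < 2:
        raise ValueError("need at least two individuals")
    calls = matrix.calls
    typed = calls[:, :, 0] != MISSING
    shared_loci = typed.astype(np.int32) @ typed.astype(np.int32).T
    shared = np.zeros((n, n))
    for l in range(L):
        a = calls[:, l, :]
        x1, x2 = a[:, 0][:, None], a[:, 1][:, None]
        y1, y2 = a[:, 0][None, :], a[:, 1][None, :]
        both = (x1 == y1) & (x2 == y2)
        one = (x1 == y1) | (x1 == y2) | (x2 == y1) | (x2 == y2)
        sc = np.where(both, 2, np.where(one, 1, 0)).astype(float)
        ok = typed[:, l]
        sc[~ok, :] = 0.0
        sc[:, ~ok] = 0.0
        shared += sc
    flags = []
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 1.0 - shared / (2.0 * shared_loci)
    if (shared_loci == 0).any():
        flags.append("pairs sharing zero typed loci are undefined (NaN)")
        vals[shared_loci == 0] = np.nan
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(list(matrix.individuals), vals, "allele-share-individual", flags)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted, branch lengths; negatives allowed)."""
    if len(dm.labels) < 3:
        raise ValueError("need at least three labels")
    if not np.isfinite(dm.values).all():
        raise ValueError(
            "distance matrix contains infinite/undefined entries; "
            "cap or drop those labels before building a tree"
        )
    sk = SkbioDM(dm.values, ids=[str(x) for x in dm.labels])
    return nj(sk)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Convert a scipy linkage matrix to a Newick string with heights as
    cumulative branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g})"
        heights[n + k] = h
        del nodes[a], nodes[b], heights[a], heights[b]
    (root,) = nodes.values()
    return root + ";"


@dataclass
class TraitDendrogram:
    linkage: np.ndarray
    labels: list[str]
    dropped_traits: list[str]

    def to_newick(self) -> str:
        return _linkage_to_newick(self.linkage, self.labels)

    def cut(self, k: int) -> pd.Series:
        return pd.Series(
            fcluster(self.linkage, k, criterion="maxclust"),
            index=self.labels, name="cluster",
        )


def trait_cluster(
    traits: pd.DataFrame,
    grouping: pd.Series | None = None,
    level: str = "individual",
    method: str = "average",
) -> TraitDendrogram:
    """Hierarchical clustering of a numeric trait matrix.

    Columns are standardized to zero mean / unit variance (constant columns
    are dropped with a note); population level aggregates trait means per
    population first.  Linkage: average (UPGMA) by default; single and
    complete also accepted.
    """
    if method not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {method!r}")
    X = traits.copy()
    if level == "population":
        if grouping is None:
            raise ValueError("population-level clustering needs a grouping")
        X = X.groupby(grouping.reindex(X.index)).mean()
    elif level != "individual":
        raise ValueError(f"unknown level {level!r}")
    if len(X) < 3:
        raise ValueError("need at least three items after aggregation")
    sd = X.std(ddof=0)
    dropped = list(X.columns[sd == 0])
    X = X.loc[:, sd > 0]
    X = (X - X.mean()) / X.std(ddof=0)
    Z = linkage(pdist(X.to_numpy()), method=method)
    return TraitDendrogram(Z, [str(i) for i in X.index], dropped)


# ---------------------------------------------------------------------------
# Partition comparison
# ---------------------------------------------------------------------------

def compare_partitions(labels_a: pd.Series, labels_b: pd.Series) -> PartitionComparison:
    """Adjusted Rand index between two labelings of the same items."""
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if set(a.index) != set(b.index):
        raise ValueError("partitions cover different item sets")
    b = b.reindex(a.index)
    ari = adjusted_rand_score(a.to_numpy(), b.to_numpy())
    tab = pd.crosstab(a, b)
    return PartitionComparison(float(ari), tab)
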