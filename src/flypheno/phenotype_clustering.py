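"""Genotype-level clustering of behavioral features + NMF components.

Genotype means of the sleep/activity features (morning anticipation excluded,
as it is highly correlated with the temporal NMF components) are joined with
the per-genotype component means, z-scored per column, and hierarchically
clustered with correlation distance and McQuitty (WPGMA) linkage.  The tree
is cut into a coarse 2-group partition and a finer 5-subgroup partition.
PCA on the same scaled matrix provides the scree fractions and per-feature
cor^2 diagnostics.  Leave-one-feature-out re-clustering quantifies subgroup
stability via best-match Jaccard similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .concordance import jaccard_sets, categorize_stability

#: features entering the genotype matrix (morning anticipation excluded)
CLUSTER_FEATURES = ("sleep_fraction_day", "sleep_fraction_night",
                    "latency_longest_bout", "mean_bout_length_night",
                    "n_bouts_night", "velocity_if_awake", "total_distance")


@dataclass
class Dendrogram:
    """Linkage result with leaf labels (scipy linkage matrix inside)."""

    Z: np.ndarray
    labels: list[str]
    distance_name: str
    linkage_name: str = "mcquitty"

    def cut(self, n_groups: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.Z, t=n_groups, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.Z)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def scale_columns(df: pd.DataFrame) -> pd.DataFrame:
    """z-score each column with sample (n-1) standard deviation."""
    sd = df.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance columns cannot be scaled: {list(zero.index)}")
    return (df - df.mean()) / sd


def assemble_features(feature_means: pd.DataFrame,
                      component_means: pd.DataFrame,
                      scale: bool = True) -> pd.DataFrame:
    """Genotype x (behavioral features + NMF components) matrix, z-scored.

    ``feature_means`` and ``component_means`` are indexed by genotype; the
    morning-anticipation column is dropped before joining.
    """
    missing_a = set(feature_means.index) - set(component_means.index)
    missing_b = set(component_means.index) - set(feature_means.index)
    if missing_a or missing_b:
        raise ValueError(f"genotype sets differ: only-features={sorted(missing_a)}, "
                         f"only-components={sorted(missing_b)}")
    feats = feature_means.drop(columns=["morning_anticipation"], errors="ignore")
    feats = feats[[c for c in feats.columns if c in CLUSTER_FEATURES]]
    joined = feats.join(component_means.loc[feats.index])
    if joined.isna().any().any():
        bad = joined.columns[joined.isna().any()].tolist()
        raise ValueError(f"missing cells in assembled matrix: {bad}")
    return scale_columns(joined) if scale else joined


def correlation_distance(values: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson correlation between rows."""
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 columns for correlation distance")
    if np.any(values.std(axis=1) == 0):
        raise ValueError("zero-variance row has undefined correlation")
    d = 1.0 - np.corrcoef(values)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def wpgma_linkage(dist: np.ndarray, labels: list[str],
                  distance_name: str = "correlation") -> Dendrogram:
    """McQuitty/WPGMA agglomeration of a square distance matrix.

    A merged cluster's distance to any other cluster is the plain average of
    its two constituents' distances (independent of cluster sizes).
    """
    dist = np.asarray(dist, dtype=float)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="weighted")
    return Dendrogram(Z=Z, labels=list(labels), distance_name=distance_name)


def cut_tree(dendrogram: Dendrogram, n_groups: int,
             name: str = "") -> dict[str, int]:
    """Partition the genotypes by cutting the dendrogram into n_groups."""
    if not 1 <= n_groups <= len(dendrogram.labels):
        raise ValueError("n_groups out of range")
    return dendrogram.cut(n_groups)


def cluster_genotypes(matrix: pd.DataFrame, n_groups: int = 2,
                      n_subgroups: int = 5) -> tuple[Dendrogram, dict, dict]:
    """Correlation-distance WPGMA clustering; returns (tree, groups, subgroups)."""
    dist = correlation_distance(matrix.to_numpy())
    tree = wpgma_linkage(dist, list(matrix.index))
    return tree, cut_tree(tree, n_groups), cut_tree(tree, n_subgroups)


@dataclass
class PCAResult:
    scores: pd.DataFrame           # genotype x PC
    loadings: pd.DataFrame         # feature x PC
    variance_fraction: np.ndarray
    cor2: pd.DataFrame             # feature x PC squared correlation


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Centered PCA of the (already scaled) genotype matrix.

    Variance fractions are squared singular values over total variance; cor^2
    is the squared Pearson correlation of each feature column with each PC
    score vector.
    """
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_pc = int(np.sum(s > 1e-12 * max(s[0], 1)))
    scores = U[:, :n_pc] * s[:n_pc]
    var_frac = (s[:n_pc] ** 2) / float(np.sum(s ** 2))
    pcs = [f"PC{j + 1}" for j in range(n_pc)]
    cor2 = np.zeros((X.shape[1], n_pc))
    for j in range(n_pc):
        sc = scores[:, j]
        if sc.std() == 0:
            continue
        for i in range(X.shape[1]):
            col = Xc[:, i]
            if col.std() == 0:
                continue
            cor2[i, j] = np.corrcoef(col, sc)[0, 1] ** 2
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=pcs),
        loadings=pd.DataFrame(Vt[:n_pc].T, index=matrix.columns, columns=pcs),
        variance_fraction=var_frac,
        cor2=pd.DataFrame(cor2, index=matrix.columns, columns=pcs))


def partition_groups(assignment: dict[str, int]) -> dict[int, set]:
    groups: dict[int, set] = {}
    for g, c in assignment.items():
        groups.setdefault(c, set()).add(g)
    return groups


def best_match_jaccard(reference: dict[str, int],
                       candidate: dict[str, int]) -> dict[int, float]:
    """For each reference subgroup, its best Jaccard against candidate groups."""
    ref = partition_groups(reference)
    cand = partition_groups(candidate)
    return {label: max(jaccard_sets(members, c) for c in cand.values())
            for label, members in ref.items()}


def stability_loo(raw_matrix: pd.DataFrame, reference: dict[str, int],
                  n_subgroups: int = 5) -> pd.DataFrame:
    """Leave-one-feature-out stability of the reference subgroups.

    For each dropped column the remaining matrix is re-scaled, re-clustered
    (correlation distance + WPGMA) and cut into ``n_subgroups``; each
    reference subgroup is scored by its best-match Jaccard.  Returns a tidy
    frame with one row per (dropped feature, reference subgroup) plus the
    stability category of each Jaccard value.
    """
    rows = []
    for col in raw_matrix.columns:
        sub = scale_columns(raw_matrix.drop(columns=[col]))
        dist = correlation_distance(sub.to_numpy())
        tree = wpgma_linkage(dist, list(sub.index))
        new = cut_tree(tree, n_subgroups)
        for label, j in best_match_jaccard(reference, new).items():
            rows.append({"dropped": col, "subgroup": label, "jaccard": j})
    df = pd.DataFrame(rows)
    df["category"] = categorize_stability(df["jaccard"].to_numpy())["category"]
    return df
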