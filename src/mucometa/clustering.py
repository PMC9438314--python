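"""Unsupervised two-way hierarchical clustering of the MFA table.

Both axes (KOs and samples) are clustered agglomeratively with correlation
distance (1 - Pearson) and average linkage — the defaults of the classic
gene-expression clustering tools this analysis style descends from.  The
trees are cut at a requested number of clusters (2 main sample clusters,
optionally 4 sub-clusters as a second cut of the same tree), the sample
clusters are tested against clinical variables, and KO clusters are scored
for pathway enrichment with the hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import DegenerateDataError, InvalidParameterError
from .mfa import MFATable
from .pathway import PathwayMap


@dataclass(frozen=True)
class ClusterAssignment:
    """Cluster labels and linkage trees for both axes of the MFA table."""

    sample_labels: pd.Series
    ko_labels: pd.Series
    sample_linkage: np.ndarray
    ko_linkage: np.ndarray

    def cut_samples(self, k: int) -> pd.Series:
        return pd.Series(
            hierarchy.fcluster(self.sample_linkage, t=k, criterion="maxclust"),
            index=self.sample_labels.index, name=f"sample_cluster_k{k}",
        )

    def cut_kos(self, k: int) -> pd.Series:
        return pd.Series(
            hierarchy.fcluster(self.ko_linkage, t=k, criterion="maxclust"),
            index=self.ko_labels.index, name=f"ko_cluster_k{k}",
        )


def _correlation_linkage(matrix: np.ndarray, axis_name: str,
                         method: str, metric: str) -> np.ndarray:
    if metric == "correlation":
        variances = matrix.var(axis=1)
        if (variances == 0).any():
            bad = int((variances == 0).sum())
            raise DegenerateDataError(
                f"{bad} constant {axis_name}(s): correlation distance undefined"
            )
    dists = pdist(matrix, metric=metric)
    if not np.isfinite(dists).all():
        raise DegenerateDataError(f"non-finite {axis_name} distances")
    return hierarchy.linkage(dists, method=method)


def hierarchical_cluster(table: MFATable, n_sample_clusters: int = 2,
                         n_ko_clusters: int = 2, metric: str = "correlation",
                         method: str = "average") -> ClusterAssignment:
    """Cluster KOs (rows) and samples (columns) of a log2-centred table.

    Cluster memberships are invariant to input row/column order up to label
    renaming (linkage depends only on the pairwise distances).
    """
    if table.values.shape[0] < 2 or table.values.shape[1] < 2:
        raise InvalidParameterError("need >= 2 KOs and >= 2 samples to cluster")
    if table.values.isna().to_numpy().any():
        raise InvalidParameterError("table contains missing values")
    # sort axes first so linkage (and hence labels) never depend on input order
    values = table.values.sort_index(axis=0).sort_index(axis=1)
    ko_link = _correlation_linkage(values.to_numpy(float), "KO row", method, metric)
    s_link = _correlation_linkage(values.to_numpy(float).T, "sample column",
                                  method, metric)
    sample_labels = pd.Series(
        hierarchy.fcluster(s_link, t=n_sample_clusters, criterion="maxclust"),
        index=values.columns, name="sample_cluster",
    )
    ko_labels = pd.Series(
        hierarchy.fcluster(ko_link, t=n_ko_clusters, criterion="maxclust"),
        index=values.index, name="ko_cluster",
    )
    return ClusterAssignment(sample_labels=sample_labels, ko_labels=ko_labels,
                             sample_linkage=s_link, ko_linkage=ko_link)


def cluster_clinical_association(assignment: ClusterAssignment,
                                 clinical: pd.DataFrame) -> pd.DataFrame:
    """Association of the two main sample clusters with clinical variables.

    Continuous variables (age, BMI, tumor size) use the two-sided rank-sum
    test; categorical ones (stage I/II vs III/IV, nodal status) use Fisher's
    exact test.  With more than two clusters, the two most populous are
    compared.
    """
    labels = assignment.sample_labels
    counts = labels.value_counts()
    if len(counts) < 2:
        raise DegenerateDataError("only one sample cluster: nothing to compare")
    main = counts.index[:2]
    a = labels.index[labels == main[0]]
    b = labels.index[labels == main[1]]
    rows = []
    for var in ("age", "bmi", "tumor_size_cm"):
        if var not in clinical.columns:
            continue
        x = clinical.loc[a, var].astype(float)
        y = clinical.loc[b, var].astype(float)
        if x.nunique() <= 1 and y.nunique() <= 1 and x.iloc[0] == y.iloc[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append((var, "rank-sum", p))
    binary = {}
    if "stage" in clinical.columns:
        binary["stage_III_IV"] = clinical["stage"].astype(str).isin(["III", "IV"])
    if "node_positive" in clinical.columns:
        binary["node_positive"] = clinical["node_positive"].astype(bool)
    for var, flags in binary.items():
        t = [[int(flags.loc[a].sum()), int((~flags.loc[a]).sum())],
             [int(flags.loc[b].sum()), int((~flags.loc[b]).sum())]]
        p = float(stats.fisher_exact(t, alternative="two-sided")[1])
        rows.append((var, "fisher", p))
    return pd.DataFrame(rows, columns=["variable", "test", "p_value"]).set_index("variable")


def ko_cluster_pathway_overlap(assignment: ClusterAssignment,
                               pmap: PathwayMap) -> pd.DataFrame:
    """Overlap counts and hypergeometric enrichment p per (KO cluster, pathway).

    The universe is the set of clustered KOs; for a cluster of size n and a
    pathway with K members in the universe, the p-value is the upper tail
    P[X >= overlap] of Hypergeometric(M=universe, K, n).
    """
    labels = assignment.ko_labels
    universe = set(labels.index)
    M = len(universe)
    rows = []
    for cluster in sorted(labels.unique()):
        members = set(labels.index[labels == cluster])
        n = len(members)
        for pid in sorted(pmap):
            in_universe = pmap[pid] & universe
            K = len(in_universe)
            overlap = len(in_universe & members)
            p = float(stats.hypergeom.sf(overlap - 1, M, K, n)) if K else float("nan")
            rows.append((cluster, pid, overlap, K, n, p))
    return pd.DataFrame(rows, columns=[
        "ko_cluster", "pathway_id", "overlap", "pathway_size_in_universe",
        "cluster_size", "hypergeom_p"])


def linkage_to_newick(linkage: np.ndarray, labels) -> str:
    """Serialise a scipy linkage tree to a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)
    labels = list(labels)

    def walk(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.get_left(), node.dist)
        right = walk(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.get_left(), tree.dist)},{walk(tree.get_right(), tree.dist)});"
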