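"""Two-way hierarchical clustering and its clinical/pathway associations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score, rand_score

import mucometa as mm
from mucometa.clustering import linkage_to_newick
from mucometa.errors import DegenerateDataError
from mucometa.mfa import MFATable


def _table(values: pd.DataFrame) -> MFATable:
    return MFATable(values=values,
                    total_reads=pd.Series(1, index=values.columns),
                    stage="log2centered")


@pytest.fixture()
def blocky_table():
    rng = np.random.default_rng(21)
    kos = [f"K{i}" for i in range(30)]
    cols = {}
    for i in range(10):
        shift = 2.0 if i < 5 else -2.0
        profile = np.concatenate([np.full(15, shift), np.full(15, -shift)])
        cols[f"s{i}"] = profile + rng.normal(0, 0.3, size=30)
    return _table(pd.DataFrame(cols, index=kos))


class TestHierarchicalCluster:
    def test_identical_pair_coclusters_against_outlier(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=20)
        values = pd.DataFrame({"s1": base, "s2": base + rng.normal(0, 0.01, 20),
                               "s3": -base},
                              index=[f"K{i}" for i in range(20)])
        asg = mm.hierarchical_cluster(_table(values), 2, 2)
        labels = asg.sample_labels
        assert labels["s1"] == labels["s2"] != labels["s3"]

    def test_column_permutation_leaves_memberships(self, blocky_table):
        asg = mm.hierarchical_cluster(blocky_table, 2, 2)
        rng = np.random.default_rng(0)
        perm_cols = list(rng.permutation(blocky_table.values.columns))
        perm_rows = list(rng.permutation(blocky_table.values.index))
        permuted = _table(blocky_table.values.loc[perm_rows, perm_cols])
        asg2 = mm.hierarchical_cluster(permuted, 2, 2)
        common = blocky_table.values.columns
        assert adjusted_rand_score(asg.sample_labels[common],
                                   asg2.sample_labels[common]) == 1.0
        rows = blocky_table.values.index
        assert adjusted_rand_score(asg.ko_labels[rows],
                                   asg2.ko_labels[rows]) == 1.0

    def test_recovers_planted_dominance_split(self, default_cohort,
                                              default_tables):
        """Two sample clusters track the planted community-dominance split
        (Rand index > 0.7 at default effect sizes)."""
        centered = mm.log2_center(mm.filter_prevalent(default_tables["norm"], 30))
        asg = mm.hierarchical_cluster(centered, 2, 2)
        w = default_cohort["truth"].mixing_weight_a
        planted = (w > w.median()).astype(int)
        ri = rand_score(planted.loc[asg.sample_labels.index],
                        asg.sample_labels)
        assert ri > 0.7

    def test_constant_table_rejected(self):
        values = pd.DataFrame(np.ones((4, 4)),
                              index=list("abcd"), columns=list("wxyz"))
        with pytest.raises(DegenerateDataError):
            mm.hierarchical_cluster(_table(values), 2, 2)

    def test_newick_export_parses(self, blocky_table):
        from io import StringIO

        from Bio import Phylo

        asg = mm.hierarchical_cluster(blocky_table, 2, 2)
        newick = linkage_to_newick(asg.sample_linkage,
                                   asg.sample_labels.index)
        tree = Phylo.read(StringIO(newick), "newick")
        leaves = {leaf.name for leaf in tree.get_terminals()}
        assert leaves == set(asg.sample_labels.index)


class TestClinicalAssociation:
    def _clinical(self, sizes, stages=None):
        n = len(sizes)
        return pd.DataFrame({
            "age": np.linspace(30, 60, n),
            "bmi": np.linspace(20, 30, n),
            "tumor_size_cm": sizes,
            "stage": stages if stages is not None else ["II"] * n,
            "node_positive": [False] * n,
        }, index=[f"s{i}" for i in range(n)])

    def test_identical_sizes_show_no_signal(self, blocky_table):
        asg = mm.hierarchical_cluster(blocky_table, 2, 2)
        clin = self._clinical([5.0] * 10)
        clin["age"] = 40.0
        clin["bmi"] = 25.0
        assoc = mm.cluster_clinical_association(asg, clin)
        assert assoc.loc["tumor_size_cm", "p_value"] > 0.9

    def test_perfect_stage_separation_hits_extreme_tail(self, blocky_table):
        asg = mm.hierarchical_cluster(blocky_table, 2, 2)
        labels = asg.sample_labels
        stages = ["III" if labels[f"s{i}"] == labels["s0"] else "I"
                  for i in range(10)]
        clin = self._clinical(np.linspace(2, 9, 10), stages)
        assoc = mm.cluster_clinical_association(asg, clin)
        n1 = int((labels == labels["s0"]).sum())
        n2 = 10 - n1
        # enumeration oracle: sum hypergeometric point masses <= observed
        support = np.arange(max(0, n1 - n2), n1 + 1)
        pmf = stats.hypergeom.pmf(support, 10, n1, n1)
        observed = stats.hypergeom.pmf(n1, 10, n1, n1)
        expected = float(pmf[pmf <= observed * (1 + 1e-7)].sum())
        assert assoc.loc["stage_III_IV", "p_value"] == pytest.approx(
            expected, rel=1e-6)

    def test_label_renaming_preserves_pvalues(self, blocky_table):
        asg = mm.hierarchical_cluster(blocky_table, 2, 2)
        clin = self._clinical(np.linspace(2, 9, 10))
        a = mm.cluster_clinical_association(asg, clin)
        relabeled = type(asg)(
            sample_labels=asg.sample_labels.map({1: 2, 2: 1}),
            ko_labels=asg.ko_labels, sample_linkage=asg.sample_linkage,
            ko_linkage=asg.ko_linkage)
        b = mm.cluster_clinical_association(relabeled, clin)
        pd.testing.assert_frame_equal(a, b)

    def test_tumor_size_association_detected_on_cohort(self, default_cohort,
                                                       default_tables):
        centered = mm.log2_center(mm.filter_prevalent(default_tables["norm"], 30))
        asg = mm.hierarchical_cluster(centered, 2, 2)
        assoc = mm.cluster_clinical_association(asg,
                                                default_cohort["clinical"])
        assert assoc.loc["tumor_size_cm", "p_value"] < 0.05

    def test_single_cluster_rejected(self, blocky_table):
        asg = mm.hierarchical_cluster(blocky_table, 2, 2)
        degenerate = type(asg)(
            sample_labels=pd.Series(1, index=asg.sample_labels.index),
            ko_labels=asg.ko_labels, sample_linkage=asg.sample_linkage,
            ko_linkage=asg.ko_linkage)
        clin = self._clinical(np.linspace(2, 9, 10))
        with pytest.raises(DegenerateDataError):
            mm.cluster_clinical_association(degenerate, clin)


class TestPathwayOverlap:
    def test_contained_pathway_scores_minimal_p(self, blocky_table):
        asg = mm.hierarchical_cluster(blocky_table, 2, 2)
        cluster1 = set(asg.ko_labels.index[asg.ko_labels == 1])
        pmap = mm.PathwayMap({"pw": frozenset(cluster1)})
        res = mm.ko_cluster_pathway_overlap(asg, pmap).set_index("ko_cluster")
        assert res.loc[1, "overlap"] == len(cluster1)
        assert res["hypergeom_p"].min() == res.loc[1, "hypergeom_p"]

    def test_disjoint_pathway_has_zero_overlap(self, blocky_table):
        asg = mm.hierarchical_cluster(blocky_table, 2, 2)
        pmap = mm.PathwayMap({"pw": frozenset({"Z1", "Z2"})})
        res = mm.ko_cluster_pathway_overlap(asg, pmap)
        assert (res["overlap"] == 0).all()

    def test_hypergeometric_p_matches_enumeration(self, blocky_table):
        """For small sets the tail probability equals brute-force counting of
        favourable draws with binomial coefficients."""
        asg = mm.hierarchical_cluster(blocky_table, 2, 2)
        pmap = mm.PathwayMap({"pw": frozenset(
            list(asg.ko_labels.index[:7]) + ["Zx"])})
        res = mm.ko_cluster_pathway_overlap(asg, pmap).set_index("ko_cluster")
        M = len(asg.ko_labels)
        K = 7  # pathway members inside the clustered universe
        for cluster, row in res.iterrows():
            n = int(row["cluster_size"])
            k_obs = int(row["overlap"])
            tail = sum(math.comb(K, x) * math.comb(M - K, n - x)
                       for x in range(k_obs, min(K, n) + 1)) / math.comb(M, n)
            assert row["hypergeom_p"] == pytest.approx(tail, rel=1e-9)
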