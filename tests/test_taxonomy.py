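"""Length x depth taxon quantification and pathway-representative taxa."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mucometa as mm
from mucometa.datatypes import CONTIG_COLUMNS
from mucometa.errors import DegenerateDataError, InvalidParameterError
from mucometa.taxonomy import lineage_at

LIN_A = "Bacteria;F1;C1;OrderA;FamA;GenA;SpA"
LIN_B = "Bacteria;F2;C2;OrderB;FamB;GenB;SpB"


def _frame(rows):
    return pd.DataFrame(rows, columns=CONTIG_COLUMNS)


class TestLineageParsing:
    def test_positional_rank_extraction(self):
        assert lineage_at(LIN_A, "order") == "OrderA"
        assert lineage_at(LIN_A, "species") == "SpA"

    @pytest.mark.parametrize("lineage", ["Bacteria;F1;C1;NA;FamA;GenA;SpA",
                                         "Bacteria;F1", None])
    def test_unassigned_pools_to_unclassified(self, lineage):
        assert lineage_at(lineage, "order") == "unclassified"


class TestTaxaAbundance:
    def test_lone_contig_gets_full_weight(self):
        frame = _frame([("s1", "c1", 2000, 3.0, LIN_A, "g1", None, 0)])
        otu = mm.taxa_abundance(frame, "order")
        assert otu.values.loc["OrderA", "s1"] == pytest.approx(1.0)

    def test_equal_mass_split(self):
        frame = _frame([
            ("s1", "c1", 2000, 3.0, LIN_A, "g1", None, 0),
            ("s1", "c2", 1000, 6.0, LIN_A, "g2", None, 0),
            ("s1", "c3", 4000, 3.0, LIN_B, "g3", None, 0),
        ])
        otu = mm.taxa_abundance(frame, "order")
        assert otu.values.loc["OrderA", "s1"] == pytest.approx(0.5)
        assert otu.values.loc["OrderB", "s1"] == pytest.approx(0.5)

    def test_columns_sum_to_one_on_synthetic_cohort(self, small_cohort):
        otu = mm.taxa_abundance(small_cohort["contigs"], "order")
        np.testing.assert_allclose(otu.values.sum(axis=0), 1.0, atol=1e-9)

    def test_coarser_rank_sums_child_ranks(self, small_cohort):
        orders = mm.taxa_abundance(small_cohort["contigs"], "order").values
        families = mm.taxa_abundance(small_cohort["contigs"], "family").values
        contigs = small_cohort["contigs"].drop_duplicates(
            subset=["sample_id", "contig_id"])
        fam_to_order = {lineage_at(l, "family"): lineage_at(l, "order")
                        for l in contigs["lineage"]}
        rolled = families.groupby(
            families.index.map(fam_to_order)).sum()
        pd.testing.assert_frame_equal(
            rolled.sort_index(), orders.sort_index(), atol=1e-12)

    def test_zero_weight_sample_rejected(self):
        frame = _frame([("s1", "c1", 2000, 0.0, LIN_A, "g1", None, 0)])
        with pytest.raises(DegenerateDataError, match="s1"):
            mm.taxa_abundance(frame, "order")


class TestDifferentialTaxa:
    def _groups(self, n=8):
        labels = ["LT"] * n + ["ST"] * n
        return pd.Series(labels, index=[f"s{i}" for i in range(2 * n)])

    def test_st_only_taxon_is_fisher_significant(self):
        # present in 6 of 8 ST samples, absent from LT: prevalence 6/16 < 50%
        # routes to Fisher, which is significant for the 0/8 vs 6/8 table
        n = 8
        cols = {f"s{i}": {"OrderX": 0.5 if i >= n and i < n + 6 else 0.0,
                          "OrderY": 1.0 if i < n else 0.5}
                for i in range(2 * n)}
        otu = mm.OTUTable(values=pd.DataFrame(cols), rank="order")
        res = mm.differential_taxa(otu, self._groups(n))
        assert res.loc["OrderX", "routing"] == "fisher"
        assert res.loc["OrderX", "selected"]
        assert res.loc["OrderX", "direction"] == "ST"

    def test_identical_profiles_not_selected(self):
        n = 8
        cols = {f"s{i}": {"OrderX": 0.4, "OrderY": 0.6} for i in range(2 * n)}
        otu = mm.OTUTable(values=pd.DataFrame(cols), rank="order")
        res = mm.differential_taxa(otu, self._groups(n))
        assert not res["selected"].any()

    def test_planted_order_skew_detected_across_seeds(self):
        """The community-B order comes out ST-directional in >= 90% of 20
        seeds at default effect sizes."""
        hits = 0
        for seed in range(20):
            params = mm.CohortParams(seed=seed, n_kos_per_community=200)
            contigs, clinical, _, truth = mm.generate_cohort(params)
            otu = mm.taxa_abundance(contigs, "order")
            groups = mm.assign_size_groups(clinical, 14)
            res = mm.differential_taxa(otu, groups)
            hits += (truth.order_b in res.index
                     and res.loc[truth.order_b, "direction"] == "ST")
        assert hits >= 18


class TestPathwayTaxaProfile:
    def test_single_encoding_contig_dominates(self):
        frame = _frame([
            ("s1", "c1", 2000, 3.0, LIN_A, "g1", "K1", 5),
            ("s1", "c2", 9000, 9.0, LIN_B, "g2", "K9", 5),
        ])
        profile = mm.pathway_taxa_profile(frame, {"K1"}, "order")
        assert profile.values.loc["OrderA", "s1"] == pytest.approx(1.0)

    def test_empty_pathway_rejected(self, small_cohort):
        with pytest.raises(InvalidParameterError):
            mm.pathway_taxa_profile(small_cohort["contigs"], set(), "order")

    def test_sample_without_pathway_contigs_gets_zero_column(self):
        frame = _frame([
            ("s1", "c1", 2000, 3.0, LIN_A, "g1", "K1", 5),
            ("s2", "c2", 2000, 3.0, LIN_B, "g2", "K9", 5),
        ])
        profile = mm.pathway_taxa_profile(frame, {"K1"}, "order")
        assert (profile.values["s2"] == 0).all()

    def test_subset_property_under_whole_sample_normalization(self,
                                                              small_cohort):
        """Pathway-restricted L*D mass never exceeds the taxon's total mass
        when both are normalised by the whole-sample denominator."""
        contigs = small_cohort["contigs"]
        truth = small_cohort["truth"]
        kos = truth.pathway_map[next(iter(truth.pathway_map))]
        whole = mm.taxa_abundance(contigs, "order").values
        uniq = contigs.drop_duplicates(subset=["sample_id", "contig_id"])
        totals = (uniq["length_bp"] * uniq["depth"]).groupby(
            uniq["sample_id"]).sum()
        hits = contigs[contigs["ko_id"].isin(kos)][
            ["sample_id", "contig_id"]].drop_duplicates()
        sel = uniq.merge(hits, on=["sample_id", "contig_id"])
        sel_mass = (sel["length_bp"] * sel["depth"]).groupby(
            [sel["lineage"].map(lambda l: lineage_at(l, "order")),
             sel["sample_id"]]).sum().unstack(fill_value=0.0).div(totals, axis=1)
        sel_mass = sel_mass.reindex(index=whole.index,
                                    columns=whole.columns, fill_value=0.0)
        assert ((sel_mass <= whole + 1e-12).all().all())

    def test_community_a_pathway_carried_by_planted_order(self,
                                                          default_cohort):
        truth = default_cohort["truth"]
        clinical = default_cohort["clinical"]
        pw_a = next(p for p in truth.pathway_map if p.startswith("pw_A"))
        profile = mm.pathway_taxa_profile(default_cohort["contigs"],
                                          truth.pathway_map[pw_a], "order")
        groups = mm.assign_size_groups(clinical, 14)
        lt = groups.index[groups == "LT"]
        lt_comp = profile.values.loc[:, lt].mean(axis=1)
        assert lt_comp.idxmax() == truth.order_a


class TestCorrelateTaxa:
    def test_proportional_taxon_has_unit_correlation(self):
        score = pd.Series({"s1": 1.0, "s2": 2.0, "s3": 3.0})
        values = pd.DataFrame({"s1": {"OrderA": 0.1, "OrderB": 0.5},
                               "s2": {"OrderA": 0.2, "OrderB": 0.5},
                               "s3": {"OrderA": 0.3, "OrderB": 0.5}})
        otu = mm.OTUTable(values=values, rank="order")
        res = mm.correlate_pathway_taxa(score, otu)
        assert res.loc["OrderA", "pearson_r"] == pytest.approx(1.0)
        assert not res.loc["OrderB", "defined"]

    def test_matches_closed_form_covariance(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(12)]
        score = pd.Series(rng.normal(size=12), index=samples)
        values = pd.DataFrame(rng.random((4, 12)),
                              index=[f"T{i}" for i in range(4)],
                              columns=samples)
        res = mm.correlate_pathway_taxa(score, mm.OTUTable(values, "order"))
        for taxon, row in values.iterrows():
            x, y = row.to_numpy(), score.to_numpy()
            r = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
            assert res.loc[taxon, "pearson_r"] == pytest.approx(r, abs=1e-12)
            assert res.loc[taxon, "pearson_p"] == pytest.approx(
                stats.pearsonr(x, y).pvalue, abs=1e-12)
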