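"""Taxon quantification from contig length x depth.

A contig of length L (bp) with mean read depth D carries roughly L*D bases
of read mass, so L*D summed over the contigs assigned to a taxon — divided
by the sample's total over all contigs — is the taxon's relative abundance.
The same weighting, restricted to contigs encoding a pathway's enzymes,
profiles the taxa that carry a pathway in each metagenome.

Lineages use a fixed 7-rank ';'-separated dialect (superkingdom..species)
with "NA" for unassigned ranks; anything unparseable at the requested rank
pools into "unclassified".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import RANKS
from .differential import differential_kos
from .errors import DegenerateDataError, InvalidParameterError
from .mfa import MFATable

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class OTUTable:
    """Taxon x sample matrix of relative abundances at one rank."""

    values: pd.DataFrame
    rank: str

    def __post_init__(self):
        if self.rank not in RANKS:
            raise InvalidParameterError(f"unknown rank {self.rank!r}")


def lineage_at(lineage: str, rank: str) -> str:
    """Extract the taxon at ``rank`` from a 7-rank lineage string."""
    if rank not in RANKS:
        raise InvalidParameterError(f"unknown rank {rank!r}; choose from {RANKS}")
    if not isinstance(lineage, str):
        return UNCLASSIFIED
    parts = lineage.split(";")
    idx = RANKS.index(rank)
    if idx >= len(parts):
        return UNCLASSIFIED
    name = parts[idx].strip()
    return name if name and name != "NA" else UNCLASSIFIED


def _contig_weights(contigs: pd.DataFrame) -> pd.DataFrame:
    """One row per (sample, contig) with its L*D weight and lineage."""
    uniq = contigs.drop_duplicates(subset=["sample_id", "contig_id"])
    return uniq.assign(weight=uniq["length_bp"].astype(float) * uniq["depth"].astype(float))


def taxa_abundance(contigs: pd.DataFrame, rank: str = "order") -> OTUTable:
    """Relative taxon abundances: sum of L*D per taxon over the sample total."""
    weights = _contig_weights(contigs)
    weights = weights.assign(
        taxon=[lineage_at(l, rank) for l in weights["lineage"]])
    totals = weights.groupby("sample_id")["weight"].sum()
    zero = totals.index[totals <= 0]
    if len(zero):
        raise DegenerateDataError(
            f"samples with zero total contig weight: {list(zero)}"
        )
    table = (
        weights.groupby(["taxon", "sample_id"])["weight"].sum()
        .unstack(fill_value=0.0)
        .div(totals, axis=1)
    )
    table.index.name = "taxon"
    return OTUTable(values=table.sort_index(), rank=rank)


def differential_taxa(otu: OTUTable, groups: pd.Series, alpha: float = 0.05,
                      rare_threshold: float = 0.5) -> pd.DataFrame:
    """Differentially abundant taxa between LT and ST groups.

    The same Fisher/Mann-Whitney machinery as for KOs, but routed by
    prevalence: taxa present in fewer than ``rare_threshold`` of the
    samples ("rare") are judged by Fisher's presence/absence test, the rest
    ("common") by the Mann-Whitney abundance test.  Direction follows the
    routed test (prevalence for rare, mean abundance for common).
    """
    used = groups.index[groups.isin(["LT", "ST"])]
    totals = pd.Series(1, index=used)  # placeholder; OTU values are relative
    table = MFATable(values=otu.values[used], total_reads=totals,
                     stage="normalized")
    both = differential_kos(table, groups, alpha=alpha)
    prevalence = (otu.values[used] > 0).sum(axis=1) / len(used)
    prevalence = prevalence.reindex(both.index)
    rare = prevalence < rare_threshold
    routed_p = both["fisher_p"].where(rare, both["mw_p"])
    selected = routed_p < alpha
    prev_dir = np.where(both["prevalence_LT"] > both["prevalence_ST"], "LT",
                        np.where(both["prevalence_ST"] > both["prevalence_LT"], "ST",
                                 np.where(both["mean_LT"] >= both["mean_ST"],
                                          "LT", "ST")))
    mean_dir = np.where(both["mean_LT"] >= both["mean_ST"], "LT", "ST")
    direction = np.where(selected, np.where(rare, prev_dir, mean_dir), None)
    out = both.drop(columns=["selected", "direction"]).assign(
        prevalence=prevalence, routing=np.where(rare, "fisher", "mann-whitney"),
        routed_p=routed_p, selected=selected, direction=direction,
    )
    out.index.name = "taxon"
    return out


def pathway_taxa_profile(contigs: pd.DataFrame, pathway_kos,
                         rank: str = "order") -> OTUTable:
    """Taxon composition of the contigs encoding a pathway's enzymes.

    Only contigs carrying >= 1 gene annotated with a pathway KO contribute;
    weights are L*D normalized within the selected subset per sample.
    Samples with no pathway-encoding contig get an all-zero column.
    """
    kos = set(pathway_kos)
    if not kos:
        raise InvalidParameterError("pathway KO set is empty")
    hits = contigs[contigs["ko_id"].isin(kos)]
    selected_ids = hits[["sample_id", "contig_id"]].drop_duplicates()
    selected = contigs.merge(selected_ids, on=["sample_id", "contig_id"])
    weights = _contig_weights(selected)
    weights = weights.assign(
        taxon=[lineage_at(l, rank) for l in weights["lineage"]])
    all_samples = pd.Index(sorted(contigs["sample_id"].unique()), name="sample_id")
    totals = weights.groupby("sample_id")["weight"].sum().reindex(all_samples)
    empty = totals.index[~(totals > 0)]
    if len(empty):
        logger.warning("samples with no pathway-encoding contigs: %s", list(empty))
    table = (
        weights.groupby(["taxon", "sample_id"])["weight"].sum()
        .unstack(fill_value=0.0)
        .reindex(columns=all_samples, fill_value=0.0)
    )
    table = table.div(totals.where(totals > 0, 1.0), axis=1).fillna(0.0)
    table.index.name = "taxon"
    return OTUTable(values=table.sort_index(), rank=rank)


def correlate_pathway_taxa(activity_scores: pd.Series,
                           profile: OTUTable) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each taxon's abundance against the
    pathway activity score across samples; constant taxa are flagged NaN."""
    common = activity_scores.index.intersection(profile.values.columns)
    if len(common) < 3:
        raise DegenerateDataError("need >= 3 samples for correlations")
    score = activity_scores.loc[common].to_numpy(float)
    if np.std(score) == 0:
        raise DegenerateDataError("activity score has zero variance")
    rows = []
    for taxon, ab in profile.values[common].iterrows():
        x = ab.to_numpy(float)
        if np.std(x) == 0:
            rows.append((taxon, float("nan"), float("nan"), False))
        else:
            r, p = stats.pearsonr(x, score)
            rows.append((taxon, float(r), float(p), True))
    return pd.DataFrame(rows, columns=["taxon", "pearson_r", "pearson_p",
                                       "defined"]).set_index("taxon")


def plot_composition(otu: OTUTable, ax=None, sample_order=None):
    """100% stacked-area plot of taxon composition across samples."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    values = otu.values
    if sample_order is not None:
        values = values[list(sample_order)]
    x = np.arange(values.shape[1])
    ax.stackplot(x, values.to_numpy(), labels=values.index)
    ax.set_xticks(x)
    ax.set_xticklabels(values.columns, rotation=90, fontsize=7)
    ax.set_ylabel(f"relative abundance ({otu.rank})")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, loc="upper right")
    return ax
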