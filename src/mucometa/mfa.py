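"""Metagenome Function Abundance (MFA) table construction and transforms.

The MFA table quantifies each molecular function (KO) in each metagenome as
the total number of sequencing reads covering genes annotated with that KO,
summed over all organisms in the sample.  Genes with no KO call contribute
nothing.  The table then goes through three stages:

``raw``           integer read counts per (KO, sample);
``normalized``    raw x 1e6 / total sequenced reads of the sample (reads per
                  million, RPM);
``log2centered``  log2(normalized + pseudocount), each KO row centred on its
                  median (the transform used ahead of hierarchical
                  clustering).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputIntegrityError, InvalidParameterError

STAGES = ("raw", "normalized", "log2centered")


@dataclass(frozen=True)
class MFATable:
    """KO x sample abundance matrix plus per-sample total read counts.

    ``values`` rows are KO ids, columns sample ids.  ``total_reads`` is the
    total number of sequenced reads per sample (the normalisation
    denominator, which includes reads on unannotated genes and unassembled
    reads; it is metadata, not recomputable from the table).
    """

    values: pd.DataFrame
    total_reads: pd.Series
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise InvalidParameterError(f"unknown MFA stage {self.stage!r}")
        missing = self.values.columns.difference(self.total_reads.index)
        if len(missing):
            raise InvalidParameterError(
                f"total_reads missing for samples: {list(missing)}"
            )

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def kos(self) -> pd.Index:
        return self.values.index

    def subset_kos(self, kos) -> "MFATable":
        return replace(self, values=self.values.loc[list(kos)])


def build_mfa(annotations: pd.DataFrame, total_reads: pd.Series | None = None) -> MFATable:
    """Build the raw MFA table from a per-gene contig-annotation frame.

    Cell (KO k, sample s) is the sum of ``read_count`` over all genes of
    sample s annotated with k.  Genes without a KO are ignored; samples with
    no annotated gene still appear as all-zero columns.

    Raises
    ------
    InputIntegrityError
        If a (sample_id, gene_id) pair occurs more than once — upstream gene
        calling assigns each gene id once per sample, so duplicates mean the
        input was concatenated incorrectly.
    """
    genes = annotations.dropna(subset=["gene_id"])
    dup = genes.duplicated(subset=["sample_id", "gene_id"])
    if dup.any():
        bad = genes.loc[dup, ["sample_id", "gene_id"]].iloc[0]
        raise InputIntegrityError(
            f"duplicate gene record: sample {bad.sample_id!r} gene {bad.gene_id!r}"
        )
    annotated = genes.dropna(subset=["ko_id"])
    values = (
        annotated.groupby(["ko_id", "sample_id"], sort=True)["read_count"]
        .sum()
        .unstack(fill_value=0)
    )
    all_samples = pd.Index(sorted(annotations["sample_id"].unique()), name="sample_id")
    values = values.reindex(columns=all_samples, fill_value=0).astype(int)
    values.index.name = "ko_id"
    if total_reads is None:
        # placeholder totals; normalize() requires real ones
        total_reads = pd.Series(np.nan, index=all_samples, name="total_reads")
    return MFATable(values=values, total_reads=total_reads.reindex(all_samples), stage="raw")


def normalize(table: MFATable, total_reads: pd.Series | None = None) -> MFATable:
    """Scale raw counts to reads per million sequenced reads (x 1e6 / total)."""
    if table.stage != "raw":
        raise InvalidParameterError(f"normalize expects a raw table, got {table.stage!r}")
    totals = (total_reads if total_reads is not None else table.total_reads)
    totals = totals.reindex(table.samples)
    bad = totals.index[(totals.isna()) | (totals <= 0)]
    if len(bad):
        raise InvalidParameterError(
            f"total_reads must be > 0 for every sample; offending samples: {list(bad)}"
        )
    values = table.values * (1e6 / totals)
    return MFATable(values=values, total_reads=totals.astype(int), stage="normalized")


def unnormalize(table: MFATable) -> MFATable:
    """Invert :func:`normalize` (x total_reads / 1e6), recovering raw counts."""
    if table.stage != "normalized":
        raise InvalidParameterError("unnormalize expects a normalized table")
    values = (table.values * (table.total_reads / 1e6)).round().astype(int)
    return MFATable(values=values, total_reads=table.total_reads, stage="raw")


def filter_prevalent(table: MFATable, min_samples: int = 30) -> MFATable:
    """Keep KOs found (nonzero) in at least ``min_samples`` samples."""
    if min_samples < 1:
        raise InvalidParameterError("min_samples must be >= 1")
    keep = (table.values > 0).sum(axis=1) >= min_samples
    return replace(table, values=table.values.loc[keep])


def log2_transform(table: MFATable, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(normalized + pseudocount) as a plain frame (no centring)."""
    if table.stage != "normalized":
        raise InvalidParameterError("log2 transform expects a normalized table")
    if pseudocount < 0:
        raise InvalidParameterError("pseudocount must be >= 0")
    if pseudocount == 0 and (table.values <= 0).to_numpy().any():
        raise DegenerateDataError(
            "pseudocount=0 requires strictly positive abundances"
        )
    return np.log2(table.values + pseudocount)


def log2_center(table: MFATable, pseudocount: float = 1.0, axis: str = "ko") -> MFATable:
    """log2-transform then median-centre each KO row (or each sample column).

    Median centring per KO is the heatmap convention (each function shown
    relative to its cohort-typical level); ``axis="sample"`` is offered since
    the choice is a convention, not a law.
    """
    logv = log2_transform(table, pseudocount)
    if axis == "ko":
        centered = logv.sub(logv.median(axis=1), axis=0)
    elif axis == "sample":
        centered = logv.sub(logv.median(axis=0), axis=1)
    else:
        raise InvalidParameterError(f"axis must be 'ko' or 'sample', got {axis!r}")
    return MFATable(values=centered, total_reads=table.total_reads, stage="log2centered")
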