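"""Core domain containers.

The on-disk/lingua-franca representation of annotated assemblies is a flat
per-gene table (one row per predicted gene, contig-level fields repeated; see
:mod:`mucometa.io`).  The dataclasses here give a typed object view used by
small fixtures and by user code that builds records by hand; conversion to the
flat frame is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .errors import InvalidParameterError

#: Column order of the flat per-gene contig-annotation table.
CONTIG_COLUMNS = [
    "sample_id",
    "contig_id",
    "length_bp",
    "depth",
    "lineage",
    "gene_id",
    "ko_id",
    "read_count",
]

#: Fixed seven-rank lineage dialect, ';'-separated, "NA" for unassigned ranks.
RANKS = ["superkingdom", "phylum", "class", "order", "family", "genus", "species"]

MIN_CONTIG_BP = 1000


@dataclass(frozen=True)
class GeneAnnotation:
    """One predicted gene on a contig with its (optional) KO call.

    ``ko_id`` is ``None`` for genes without a recognised molecular function;
    such genes carry no weight in the function-abundance table.
    """

    gene_id: str
    ko_id: Optional[str]
    read_count: int

    def __post_init__(self):
        if self.read_count < 0:
            raise InvalidParameterError(
                f"gene {self.gene_id}: read_count must be >= 0, got {self.read_count}"
            )


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig: length L (bp), mean read depth D, ranked lineage
    and the genes predicted on it."""

    sample_id: str
    contig_id: str
    length_bp: int
    depth: float
    lineage: str
    genes: Sequence[GeneAnnotation] = field(default_factory=tuple)

    def __post_init__(self):
        if self.length_bp < MIN_CONTIG_BP:
            raise InvalidParameterError(
                f"contig {self.contig_id}: length_bp must be >= {MIN_CONTIG_BP} "
                f"(short contigs are removed upstream), got {self.length_bp}"
            )
        if self.depth < 0:
            raise InvalidParameterError(
                f"contig {self.contig_id}: depth must be >= 0, got {self.depth}"
            )


def contigs_to_frame(contigs: Sequence[ContigRecord]) -> pd.DataFrame:
    """Flatten ContigRecord objects into the per-gene annotation table.

    Contigs without genes still contribute one row with gene fields set to NA
    so that taxonomy (which weighs whole contigs) sees them.
    """
    rows = []
    for c in contigs:
        if not c.genes:
            rows.append((c.sample_id, c.contig_id, c.length_bp, c.depth,
                         c.lineage, None, None, 0))
        for g in c.genes:
            rows.append((c.sample_id, c.contig_id, c.length_bp, c.depth,
                         c.lineage, g.gene_id, g.ko_id, g.read_count))
    return pd.DataFrame(rows, columns=CONTIG_COLUMNS)


def frame_to_contigs(frame: pd.DataFrame) -> list[ContigRecord]:
    """Inverse of :func:`contigs_to_frame` (gene order preserved per contig)."""
    out: list[ContigRecord] = []
    for (sample_id, contig_id), grp in frame.groupby(
        ["sample_id", "contig_id"], sort=False
    ):
        first = grp.iloc[0]
        genes = tuple(
            GeneAnnotation(row.gene_id,
                           None if pd.isna(row.ko_id) else row.ko_id,
                           int(row.read_count))
            for row in grp.itertuples()
            if not pd.isna(row.gene_id)
        )
        out.append(
            ContigRecord(sample_id, contig_id, int(first.length_bp),
                         float(first.depth), str(first.lineage), genes)
        )
    return out
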