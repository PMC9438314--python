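"""Readers and writers for the package's plain-text table dialects.

Everything is TSV/CSV so outputs diff cleanly and fixtures stay readable:

* contig-annotation TSV — one row per predicted gene (contig fields repeated),
  columns :data:`mucometa.datatypes.CONTIG_COLUMNS`; ``ko_id`` is ``NA`` for
  genes without a function call.
* clinical CSV — one row per patient.
* total-reads TSV — ``sample_id``, ``total_reads`` (sequenced reads per
  sample; the normalisation denominator).
* MFA TSV — KO rows x sample columns, first column ``ko_id``.
* two-column maps — ``pathway_id<TAB>ko_id`` and ``ko_id<TAB>family``.
"""

from __future__ import annotations

import os

import pandas as pd

from .datatypes import CONTIG_COLUMNS
from .errors import InputIntegrityError, MapParseError

CLINICAL_COLUMNS = [
    "patient_id", "age", "bmi", "stage", "tumor_size_cm",
    "node_positive", "rfs_months", "rfs_event",
]


def read_contig_table(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "contig_id": str,
                                               "gene_id": str, "ko_id": str})
    missing = [c for c in CONTIG_COLUMNS if c not in frame.columns]
    if missing:
        raise InputIntegrityError(f"contig table {path} lacks columns: {missing}")
    return frame[CONTIG_COLUMNS]


def write_contig_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame[CONTIG_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_clinical(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise InputIntegrityError(f"clinical table {path} lacks columns: {missing}")
    return frame.set_index("patient_id")


def write_clinical(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.reset_index().rename(columns={"index": "patient_id"}).to_csv(path, index=False)


def read_total_reads(path: str | os.PathLike) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "total_reads"} <= set(frame.columns):
        raise InputIntegrityError(f"{path}: expected columns sample_id, total_reads")
    return frame.set_index("sample_id")["total_reads"].astype(int)


def write_total_reads(total_reads: pd.Series, path: str | os.PathLike) -> None:
    total_reads.rename("total_reads").rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_matrix_tsv(path: str | os.PathLike, index_name: str = "ko_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis(index_name)


def write_matrix_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t")


def read_two_column_map(path: str | os.PathLike,
                        key_first: bool = True) -> dict[str, set[str]]:
    """Parse a two-column TSV into ``first -> {second}`` (or reversed).

    Blank lines and ``#`` comments are skipped; duplicate rows collapse.
    A line without exactly two tab-separated fields raises
    :class:`MapParseError` naming the line number.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise MapParseError(
                    f"{path}:{lineno}: expected two tab-separated fields, got {line!r}"
                )
            key, value = (fields if key_first else fields[::-1])
            mapping.setdefault(key.strip(), set()).add(value.strip())
    return mapping


def write_two_column_map(mapping: dict[str, set[str]], path: str | os.PathLike,
                         key_first: bool = True) -> None:
    with open(path, "w") as handle:
        for key in sorted(mapping):
            for value in sorted(mapping[key]):
                pair = (key, value) if key_first else (value, key)
                handle.write(f"{pair[0]}\t{pair[1]}\n")
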