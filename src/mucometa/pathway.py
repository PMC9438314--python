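"""Pathway-level annotation of differential KOs.

Three scores live here:

* **enrichment score** — for a pathway P and the two direction-specific
  differential KO sets, with pct_G = 100 * |P ∩ G| / |G|:

      score = (pct_ST - pct_LT) / (pct_ST + pct_LT)

  in [-1, +1]; positive means ST-enriched (the formula is written ST-first,
  and the sign convention is stated here because it matters).  Pathways are
  reported only when the overlap on the favoured side reaches the minimum
  KO count (defaults: 9 for LT-favouring, 4 for ST-favouring pathways).
* **activity score** — per sample, the mean of log2(normalized abundance +
  pseudocount) over the pathway's KOs; feeds the survival analysis.
* **CAZy summary** — counts of carbohydrate-active enzyme classes
  (GH/GT/PL/CE/CBM/AA) among each direction's KOs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .io import read_two_column_map, write_two_column_map
from .mfa import MFATable

CAZY_CLASSES = ["GH", "GT", "PL", "CE", "CBM", "AA"]


@dataclass(frozen=True)
class PathwayMap:
    """pathway_id -> non-empty KO set, with optional display names."""

    pathways: dict[str, frozenset[str]]
    names: dict[str, str] | None = None

    def __post_init__(self):
        empty = [p for p, kos in self.pathways.items() if not kos]
        if empty:
            raise InvalidParameterError(f"pathways with empty KO sets: {empty}")

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id]

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self):
        return len(self.pathways)

    def name_of(self, pathway_id: str) -> str:
        return (self.names or {}).get(pathway_id, pathway_id)


def load_pathway_map(path) -> PathwayMap:
    """Read a ``pathway_id<TAB>ko_id`` TSV (duplicates collapse)."""
    raw = read_two_column_map(path, key_first=True)
    return PathwayMap({p: frozenset(kos) for p, kos in raw.items()})


def save_pathway_map(pmap: PathwayMap, path) -> None:
    write_two_column_map({p: set(k) for p, k in pmap.pathways.items()}, path)


def load_cazy_map(path) -> dict[str, set[str]]:
    """Read a ``ko_id<TAB>cazy_family`` TSV into ko -> {families}."""
    return read_two_column_map(path, key_first=True)


def enrichment_scores(diff: pd.DataFrame, pmap: PathwayMap,
                      min_lt: int = 9, min_st: int = 4) -> pd.DataFrame:
    """Score every pathway's skew between the ST and LT differential KO sets.

    ``diff`` is the frame from :func:`mucometa.differential.differential_kos`;
    only selected KOs (non-null direction) participate.  Pathways with zero
    overlap on both sides are omitted; the remaining ones must meet the
    minimum overlap for their favoured direction.
    """
    lt_set = set(diff.index[diff["direction"] == "LT"])
    st_set = set(diff.index[diff["direction"] == "ST"])
    rows = []
    for pid in sorted(pmap):
        kos = pmap[pid]
        n_lt = len(kos & lt_set)
        n_st = len(kos & st_set)
        if n_lt == 0 and n_st == 0:
            continue
        pct_lt = 100.0 * n_lt / len(lt_set) if lt_set else 0.0
        pct_st = 100.0 * n_st / len(st_set) if st_set else 0.0
        score = (pct_st - pct_lt) / (pct_st + pct_lt)
        favored_ok = (n_st >= min_st) if score > 0 else (
            (n_lt >= min_lt) if score < 0 else (n_st >= min_st or n_lt >= min_lt))
        if not favored_ok:
            continue
        rows.append((pid, pmap.name_of(pid), n_st, n_lt, pct_st, pct_lt, score))
    out = pd.DataFrame(rows, columns=["pathway_id", "name", "n_ST_overlap",
                                      "n_LT_overlap", "pct_ST", "pct_LT", "score"])
    return out.sort_values("score", ascending=False).set_index("pathway_id")


def activity_score(table: MFATable, pathway_kos, pseudocount: float = 1.0,
                   pathway_id: str = "pathway") -> pd.Series:
    """Per-sample pathway activity: mean log2(normalized + pseudocount) over
    the pathway's KOs present in the table."""
    if table.stage != "normalized":
        raise InvalidParameterError("activity_score expects a normalized table")
    kos = table.kos.intersection(set(pathway_kos))
    if kos.empty:
        raise InvalidParameterError(
            f"no KO of pathway {pathway_id!r} appears in the abundance table"
        )
    logv = np.log2(table.values.loc[kos] + pseudocount)
    return logv.mean(axis=0).rename(f"activity_{pathway_id}")


def cazy_summary(diff: pd.DataFrame, cazy_map: dict[str, set[str]],
                 ec_map: dict[str, set[str]] | None = None) -> pd.DataFrame:
    """Tally CAZy classes per differential direction.

    Counts KOs (not families): a KO mapping to two GH families counts once
    for GH.  With ``ec_map`` (ko -> EC numbers), an extra ``glycosidase``
    row counts KOs with an EC 3.2.1.- annotation (O-/S-glycosyl hydrolases).
    """
    class_re = re.compile(r"^(GH|GT|PL|CE|CBM|AA)\d*$")
    rows = {}
    for direction in ("LT", "ST"):
        kos = diff.index[diff["direction"] == direction]
        counts = dict.fromkeys(CAZY_CLASSES, 0)
        glycosidases = 0
        for ko in kos:
            classes = set()
            for fam in cazy_map.get(ko, ()):
                m = class_re.match(fam)
                if m:
                    classes.add(m.group(1))
            for cls in classes:
                counts[cls] += 1
            if ec_map and any(ec.startswith("3.2.1.") for ec in ec_map.get(ko, ())):
                glycosidases += 1
        if ec_map is not None:
            counts["glycosidase"] = glycosidases
        rows[direction] = counts
    return pd.DataFrame(rows).rename_axis("cazy_class")
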