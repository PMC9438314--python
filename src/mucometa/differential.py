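"""Tumor-size groups and differentially abundant KOs.

Samples are sorted by tumor size; the k largest form the LT-group and the k
smallest the ST-group (k=14 by default).  Every KO found in at least one
sample is then tested two ways, without multiplicity adjustment:

* Fisher's exact test on the 2x2 presence/absence x group table, and
* a two-sided Mann-Whitney test on the normalized abundances.

A KO is differentially abundant when either p < alpha.  Direction follows a
presence-first rule: if Fisher is significant the KO is assigned to the
group where it is more prevalent; otherwise (Mann-Whitney significant) to
the group with the higher mean normalized abundance.  Benjamini-Hochberg
q-values are reported as extra columns for reference but play no role in
selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, InvalidParameterError
from .mfa import MFATable

logger = logging.getLogger(__name__)

LT, ST, UNASSIGNED = "LT", "ST", "unassigned"


def assign_size_groups(clinical: pd.DataFrame, k: int = 14) -> pd.Series:
    """Label the k largest tumors LT, the k smallest ST, the rest unassigned.

    Ties straddling rank k break deterministically by (size desc,
    patient_id asc) for LT and (size asc, patient_id asc) for ST, so labels
    do not depend on input row order.
    """
    n = len(clinical)
    if 2 * k > n:
        raise InvalidParameterError(f"2*k = {2 * k} exceeds cohort size {n}")
    order_lt = clinical.reset_index().sort_values(
        ["tumor_size_cm", "patient_id"], ascending=[False, True], kind="mergesort"
    )["patient_id"]
    order_st = clinical.reset_index().sort_values(
        ["tumor_size_cm", "patient_id"], ascending=[True, True], kind="mergesort"
    )["patient_id"]
    labels = pd.Series(UNASSIGNED, index=clinical.index, name="size_group")
    labels.loc[order_lt.iloc[:k]] = LT
    labels.loc[order_st.iloc[:k]] = ST
    if (labels == LT).sum() != k or (labels == ST).sum() != k:
        raise InvalidParameterError(
            "LT and ST assignments overlap; ties span more than the middle of "
            "the cohort (choose a smaller k)"
        )
    return labels


@lru_cache(maxsize=None)
def _fisher_p(a: int, b: int, n1: int, n2: int) -> float:
    """Two-sided Fisher exact p for table [[a, n1-a], [b, n2-b]]."""
    return float(stats.fisher_exact([[a, n1 - a], [b, n2 - b]],
                                    alternative="two-sided")[1])


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Mann-Whitney p for matrices x (r x n1), y (r x n2).

    Exact null when both groups have <= 12 observations and the row has no
    ties; normal approximation with tie correction otherwise.
    """
    r = x.shape[0]
    pvals = np.empty(r)
    combined = np.hstack([x, y])
    has_ties = np.array([len(np.unique(row)) < row.size for row in combined])
    small = x.shape[1] <= 12 and y.shape[1] <= 12
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows yield harmless warnings
        rows_exact = np.where(~has_ties)[0] if small else np.array([], dtype=int)
        rows_asymp = np.setdiff1d(np.arange(r), rows_exact)
        if rows_exact.size:
            res = stats.mannwhitneyu(x[rows_exact], y[rows_exact], axis=1,
                                     alternative="two-sided", method="exact")
            pvals[rows_exact] = np.atleast_1d(res.pvalue)
        if rows_asymp.size:
            res = stats.mannwhitneyu(x[rows_asymp], y[rows_asymp], axis=1,
                                     alternative="two-sided", method="asymptotic")
            pvals[rows_asymp] = np.atleast_1d(res.pvalue)
    # identical constant rows have an undefined statistic; no evidence => p=1
    const = (combined == combined[:, :1]).all(axis=1)
    pvals[const] = 1.0
    return np.clip(pvals, 0.0, 1.0)


def differential_kos(table: MFATable, groups: pd.Series,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Test every KO for differential abundance between LT and ST groups.

    Parameters
    ----------
    table : MFATable (normalized)
        Normalized abundances; presence/absence is nonzero entry.
    groups : Series
        Labels from :func:`assign_size_groups` (only LT/ST rows are used).
    alpha : float
        Unadjusted significance cutoff applied to either test.

    Returns
    -------
    DataFrame indexed by ko_id with columns fisher_p, mw_p, fisher_q, mw_q,
    prevalence_LT, prevalence_ST, mean_LT, mean_ST, selected, direction.
    ``direction`` is NA for unselected KOs.
    """
    if table.stage != "normalized":
        raise InvalidParameterError("differential_kos expects a normalized table")
    lt_samples = groups.index[groups == LT]
    st_samples = groups.index[groups == ST]
    if len(lt_samples) < 2 or len(st_samples) < 2:
        raise InvalidParameterError("each group needs at least 2 samples")
    sub = table.values
    present_any = (sub[lt_samples.union(st_samples)] > 0).any(axis=1)
    sub = sub.loc[present_any]
    if sub.empty:
        logger.warning("differential_kos: no KO present in either group")
        return _empty_diff_frame()

    xv = sub[lt_samples].to_numpy(float)
    yv = sub[st_samples].to_numpy(float)
    n1, n2 = xv.shape[1], yv.shape[1]
    prev_lt = (xv > 0).sum(axis=1)
    prev_st = (yv > 0).sum(axis=1)
    fisher_p = np.array([_fisher_p(int(a), int(b), n1, n2)
                         for a, b in zip(prev_lt, prev_st)])
    mw_p = _mannwhitney_p(xv, yv)
    mean_lt = xv.mean(axis=1)
    mean_st = yv.mean(axis=1)

    selected = (fisher_p < alpha) | (mw_p < alpha)
    direction = np.full(len(sub), None, dtype=object)
    fisher_sig = fisher_p < alpha
    # presence-first rule; equal prevalences under a significant Fisher fall
    # back to the mean difference (the rule's unstated corner case)
    prev_dir = np.where(prev_lt > prev_st, LT,
                        np.where(prev_st > prev_lt, ST,
                                 np.where(mean_lt >= mean_st, LT, ST)))
    mean_dir = np.where(mean_lt >= mean_st, LT, ST)
    direction[selected & fisher_sig] = prev_dir[selected & fisher_sig]
    direction[selected & ~fisher_sig] = mean_dir[selected & ~fisher_sig]

    out = pd.DataFrame({
        "fisher_p": fisher_p,
        "mw_p": mw_p,
        "fisher_q": multipletests(fisher_p, method="fdr_bh")[1],
        "mw_q": multipletests(mw_p, method="fdr_bh")[1],
        "prevalence_LT": prev_lt,
        "prevalence_ST": prev_st,
        "mean_LT": mean_lt,
        "mean_ST": mean_st,
        "selected": selected,
        "direction": direction,
    }, index=sub.index)
    return out


def _empty_diff_frame() -> pd.DataFrame:
    cols = ["fisher_p", "mw_p", "fisher_q", "mw_q", "prevalence_LT",
            "prevalence_ST", "mean_LT", "mean_ST", "selected", "direction"]
    return pd.DataFrame(columns=cols).rename_axis("ko_id")


@dataclass(frozen=True)
class RichnessResult:
    """Per-sample unique-KO counts and their clinical associations."""

    richness: pd.Series
    pearson_r: float
    pearson_p: float
    stage_wilcoxon_p: float  # richness in stage I/II vs III/IV

    def summary(self) -> str:
        return (
            f"Functional richness across {len(self.richness)} samples: "
            f"median {self.richness.median():.0f} unique KOs\n"
            f"  Pearson r vs tumor size: {self.pearson_r:.3f} (p = {self.pearson_p:.3g})\n"
            f"  Rank-sum p, stage I/II vs III/IV: {self.stage_wilcoxon_p:.3g}"
        )


def functional_richness(table: MFATable, clinical: pd.DataFrame) -> RichnessResult:
    """Unique-KO count per sample, its linear association with tumor size and
    its rank-sum comparison between early (I/II) and advanced (III/IV) stage."""
    if table.stage != "raw":
        raise InvalidParameterError("functional_richness expects a raw table")
    missing = table.samples.difference(clinical.index)
    if len(missing):
        raise InvalidParameterError(f"clinical table lacks samples: {list(missing)}")
    richness = (table.values > 0).sum(axis=0).rename("richness")
    sizes = clinical.loc[richness.index, "tumor_size_cm"].astype(float)
    if len(richness) < 3:
        raise DegenerateDataError("need >= 3 samples for a correlation")
    if richness.std() == 0 or sizes.std() == 0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r, p = stats.pearsonr(richness.to_numpy(float), sizes.to_numpy())
    stage = clinical.loc[richness.index, "stage"].astype(str)
    early = richness[stage.isin(["I", "II"])]
    late = richness[stage.isin(["III", "IV"])]
    if len(early) and len(late):
        stage_p = float(stats.mannwhitneyu(early, late,
                                           alternative="two-sided").pvalue)
    else:
        stage_p = float("nan")
    return RichnessResult(richness=richness, pearson_r=float(r),
                          pearson_p=float(p), stage_wilcoxon_p=stage_p)
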