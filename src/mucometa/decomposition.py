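"""Two-community decomposition of KO log-abundance densities.

The supervised comparison yields two direction-specific KO sets.  Each set's
log2 abundances define a normal curve (sample mean and sd) characterising
the molecular functions of one of the two co-existing microbial communities
(LT-dominant and ST-dominant).  Holding those curves fixed, the density of
*all* KO abundances in a sample group is modelled as a non-negative linear
combination of the two normal pdfs:

    density(x) ≈ coef_LT * N(x; mu_LT, sd_LT) + coef_ST * N(x; mu_ST, sd_ST)

The amplitudes are fitted by non-negative least squares of a kernel density
estimate on a regular grid against the two pdfs (a density mixture cannot
have negative component weights, and has no intercept).  Comparing each
amplitude between the LT and the ST sample group quantifies how strongly
each community dominates each group.

This is deliberately *not* an EM Gaussian-mixture fit: the curve parameters
come from the differential KOs, only the amplitudes are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .errors import CollinearityError, DegenerateDataError, InvalidParameterError
from .mfa import MFATable

__all__ = [
    "NormalCurve", "fit_group_normal", "TwoCommunityDecomposition",
    "DecompositionResults", "decompose_density", "dominance_report",
    "DominanceReport",
]


@dataclass(frozen=True)
class NormalCurve:
    """Normal density describing one community's KO log2-abundance profile."""

    mu: float
    sigma: float
    source: str = ""

    def __post_init__(self):
        if not np.isfinite(self.mu) or not np.isfinite(self.sigma) or self.sigma <= 0:
            raise InvalidParameterError(
                f"invalid normal curve: mu={self.mu}, sigma={self.sigma}"
            )

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return stats.norm.pdf(x, loc=self.mu, scale=self.sigma)


def fit_group_normal(log2_abundances, source: str = "") -> NormalCurve:
    """Fit a normal curve to a vector of log2 abundances.

    mu is the sample mean and sigma the sample sd (ddof=1).  Requires at
    least 3 finite values and nonzero variance.
    """
    x = np.asarray(log2_abundances, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise DegenerateDataError(
            f"need >= 3 finite values to fit a curve, got {x.size}"
        )
    sigma = float(x.std(ddof=1))
    if sigma == 0:
        raise DegenerateDataError("zero variance: cannot fit a normal curve")
    return NormalCurve(mu=float(x.mean()), sigma=sigma, source=source)


class TwoCommunityDecomposition:
    """Model: a group's KO log2-abundance density as a non-negative mixture
    of two fixed normal curves.

    Parameters
    ----------
    data : array-like or None
        Pooled log2 abundances of all KOs in the group (>= 10 values).  May
        be None when ``grid`` and ``density`` are supplied directly (e.g. a
        precomputed histogram density).
    curve_lt, curve_st : NormalCurve
        The community curves estimated from direction-specific KOs.
    grid_n : int
        Number of evaluation points of the density grid.
    bandwidth : str or float
        KDE bandwidth rule (default Silverman) or a scalar factor, passed to
        :class:`scipy.stats.gaussian_kde`.
    """

    def __init__(self, data, curve_lt: NormalCurve, curve_st: NormalCurve,
                 grid_n: int = 512, bandwidth="silverman",
                 grid: np.ndarray | None = None,
                 density: np.ndarray | None = None):
        if (abs(curve_lt.mu - curve_st.mu) < 1e-12
                and abs(curve_lt.sigma - curve_st.sigma) < 1e-12):
            raise CollinearityError(
                "the two community curves are identical; amplitudes are not identifiable"
            )
        self.curve_lt = curve_lt
        self.curve_st = curve_st
        self.grid_n = grid_n
        self.bandwidth = bandwidth
        if density is not None:
            if grid is None:
                raise InvalidParameterError("density requires an explicit grid")
            self.grid = np.asarray(grid, float)
            self.density = np.asarray(density, float)
            self.data = None
        else:
            x = np.asarray(data, float)
            x = x[np.isfinite(x)]
            if x.size < 10:
                raise DegenerateDataError(
                    f"need >= 10 abundance values to decompose, got {x.size}"
                )
            self.data = x
            pad = 3.0 * max(curve_lt.sigma, curve_st.sigma)
            self.grid = np.linspace(x.min() - pad, x.max() + pad, grid_n)
            kde = stats.gaussian_kde(x, bw_method=bandwidth)
            self.density = kde(self.grid)

    def fit(self) -> "DecompositionResults":
        design = np.column_stack([self.curve_lt.pdf(self.grid),
                                  self.curve_st.pdf(self.grid)])
        coefs, rnorm = nnls(design, self.density)
        resid = self.density - design @ coefs
        ss_tot = float(((self.density - self.density.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
        return DecompositionResults(
            model=self, coef_lt=float(coefs[0]), coef_st=float(coefs[1]),
            r_squared=r2, fitted=design @ coefs,
        )


@dataclass(frozen=True)
class DecompositionResults:
    """Fitted amplitudes of the two community curves for one sample group."""

    model: TwoCommunityDecomposition
    coef_lt: float
    coef_st: float
    r_squared: float
    fitted: np.ndarray

    @property
    def grid(self) -> np.ndarray:
        return self.model.grid

    @property
    def lt_fraction(self) -> float:
        """coef_LT / (coef_LT + coef_ST); NaN if both are zero."""
        total = self.coef_lt + self.coef_st
        return self.coef_lt / total if total > 0 else float("nan")

    def summary(self) -> str:
        m = self.model
        return (
            "Two-community density decomposition (NNLS)\n"
            f"  LT-abundant curve: N({m.curve_lt.mu:.3f}, {m.curve_lt.sigma:.3f}^2)"
            f"  amplitude = {self.coef_lt:.4f}\n"
            f"  ST-abundant curve: N({m.curve_st.mu:.3f}, {m.curve_st.sigma:.3f}^2)"
            f"  amplitude = {self.coef_st:.4f}\n"
            f"  LT fraction = {self.lt_fraction:.3f}   R^2 = {self.r_squared:.4f}"
        )

    def plot(self, ax=None, label: str = ""):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.model.density, label=f"{label} density".strip())
        ax.plot(self.grid, self.fitted, "--", label="fitted mixture")
        ax.plot(self.grid, self.coef_lt * self.model.curve_lt.pdf(self.grid),
                ":", label="LT component")
        ax.plot(self.grid, self.coef_st * self.model.curve_st.pdf(self.grid),
                ":", label="ST component")
        ax.set_xlabel("log2 normalized abundance")
        ax.set_ylabel("density")
        ax.legend()
        return ax


def decompose_density(all_log2_abundances, curve_lt: NormalCurve,
                      curve_st: NormalCurve, grid_n: int = 512,
                      bandwidth="silverman") -> DecompositionResults:
    """Functional one-shot wrapper around :class:`TwoCommunityDecomposition`."""
    return TwoCommunityDecomposition(
        all_log2_abundances, curve_lt, curve_st, grid_n=grid_n,
        bandwidth=bandwidth,
    ).fit()


@dataclass(frozen=True)
class DominanceReport:
    """Per-group decomposition fits and their cross-group amplitude ratios."""

    curve_lt: NormalCurve
    curve_st: NormalCurve
    fit_lt_group: DecompositionResults
    fit_st_group: DecompositionResults
    ratio_lt: float        # coef_LT in LT-group / coef_LT in ST-group
    ratio_st: float        # coef_ST in LT-group / coef_ST in ST-group
    diff_lt: float         # coef_LT difference (LT-group minus ST-group)
    diff_st: float

    def summary(self) -> str:
        return (
            "Community dominance report\n"
            f"  LT-abundant curve N({self.curve_lt.mu:.3f}, {self.curve_lt.sigma:.3f}^2), "
            f"ST-abundant curve N({self.curve_st.mu:.3f}, {self.curve_st.sigma:.3f}^2)\n"
            f"  LT-group: coef_LT={self.fit_lt_group.coef_lt:.4f} "
            f"coef_ST={self.fit_lt_group.coef_st:.4f} R^2={self.fit_lt_group.r_squared:.3f}\n"
            f"  ST-group: coef_LT={self.fit_st_group.coef_lt:.4f} "
            f"coef_ST={self.fit_st_group.coef_st:.4f} R^2={self.fit_st_group.r_squared:.3f}\n"
            f"  LT-community amplitude ratio (LT/ST group): {self.ratio_lt:.3f} "
            f"(difference {self.diff_lt:+.4f})\n"
            f"  ST-community amplitude ratio (LT/ST group): {self.ratio_st:.3f} "
            f"(difference {self.diff_st:+.4f})"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, fit in (("LT", self.fit_lt_group), ("ST", self.fit_st_group)):
            rows.append((group, fit.coef_lt, fit.coef_st, fit.r_squared,
                         self.curve_lt.mu, self.curve_lt.sigma,
                         self.curve_st.mu, self.curve_st.sigma))
        return pd.DataFrame(rows, columns=[
            "group", "coef_LT", "coef_ST", "r_squared",
            "mu_LT", "sigma_LT", "mu_ST", "sigma_ST"]).set_index("group")


def _group_values(table: MFATable, samples, kos=None,
                  pseudocount: float = 0.0) -> np.ndarray:
    """Pooled log2 abundances of (nonzero) entries for the given samples.

    Only KOs found (nonzero) in a sample contribute a value for that sample,
    matching 'all KOs found in the group'; zeros never reach the log, so the
    default pseudocount is 0 (a nonzero pseudocount would compress the low
    tail of the density)."""
    sub = table.values[list(samples)]
    if kos is not None:
        sub = sub.loc[sub.index.intersection(set(kos))]
    arr = sub.to_numpy(float)
    vals = arr[arr > 0]
    return np.log2(vals + pseudocount)


def dominance_report(groups: pd.Series, table: MFATable, diff: pd.DataFrame,
                     pseudocount: float = 0.0, grid_n: int = 512,
                     bandwidth="silverman") -> DominanceReport:
    """Full two-stage decomposition for a cohort.

    Stage 1: normal curves from the direction-specific differential KOs,
    each evaluated in its own group's samples (LT-abundant KOs in LT-group
    samples; ST-abundant in ST-group).  Stage 2: NNLS decomposition of each
    group's density of *all* KOs found in that group against the two fixed
    curves; amplitude ratios LT-group/ST-group are reported per curve.
    """
    if table.stage != "normalized":
        raise InvalidParameterError("dominance_report expects a normalized table")
    lt_samples = list(groups.index[groups == "LT"])
    st_samples = list(groups.index[groups == "ST"])
    if not lt_samples or not st_samples:
        raise InvalidParameterError("both LT and ST groups must be non-empty")
    lt_kos = diff.index[diff["direction"] == "LT"]
    st_kos = diff.index[diff["direction"] == "ST"]
    curve_lt = fit_group_normal(
        _group_values(table, lt_samples, lt_kos, pseudocount), source="LT-abundant")
    curve_st = fit_group_normal(
        _group_values(table, st_samples, st_kos, pseudocount), source="ST-abundant")
    fit_lt = decompose_density(_group_values(table, lt_samples, None, pseudocount),
                               curve_lt, curve_st, grid_n, bandwidth)
    fit_st = decompose_density(_group_values(table, st_samples, None, pseudocount),
                               curve_lt, curve_st, grid_n, bandwidth)

    def _ratio(a: float, b: float) -> float:
        return a / b if b > 0 else float("inf") if a > 0 else float("nan")

    return DominanceReport(
        curve_lt=curve_lt, curve_st=curve_st,
        fit_lt_group=fit_lt, fit_st_group=fit_st,
        ratio_lt=_ratio(fit_lt.coef_lt, fit_st.coef_lt),
        ratio_st=_ratio(fit_lt.coef_st, fit_st.coef_st),
        diff_lt=fit_lt.coef_lt - fit_st.coef_lt,
        diff_st=fit_lt.coef_st - fit_st.coef_st,
    )
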