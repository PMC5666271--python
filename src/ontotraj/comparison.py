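"""Wild-vs-domestic comparison of bivariate ontogenetic trajectories.

Per variable, the two forms' log-log SMA lines are compared with a gated
chain of tests:

1. *Common slope* — likelihood-ratio test of equal SMA slopes, referred to
   chi-square with 1 df.  The statistic is the Bartlett-corrected profile
   ``LR(b) = -sum_i (n_i - 2.5) ln(1 - r_i(b)^2)`` minimised over the
   candidate common slope b, where ``r_i(b)`` is the within-group
   correlation between residual scores ``y - b x`` and fitted-axis scores
   ``y + b x`` (zero in a group whose true slope is b).
2. *Common intercept* — if slopes are shared, a Wald test of equal
   elevations (mean residuals at the common slope), with the slope's
   sampling variance propagated through the group mean-x difference.
3. *Shift* — if slopes and intercepts are shared, a Wald test of equal
   mean fitted-axis scores, i.e. whether one form extends further along
   the shared trajectory than the other.

The first significant difference is then translated into the classical
heterochrony vocabulary, reading the wild form as ancestral: a larger
domestic slope is acceleration, a higher domestic intercept
pre-displacement, a domestic extension along the axis hypermorphosis
(together: peramorphosis, extended development); the three mirror cases
are deceleration, post-displacement and hypomorphosis (paedomorphosis,
truncated development).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .bivariate import BivarConfig, bonferroni_alpha, geometric_mean_size, sma_fit
from .io import common_variables
from .series import GrowthSeries

__all__ = [
    "HETEROCHRONY_LABELS", "PERAMORPH_LABELS", "PAEDOMORPH_LABELS",
    "label_process", "SlopeTest", "ElevationTest", "ShiftTest",
    "common_slope_test", "intercept_test", "shift_test",
    "classify_heterochrony", "PairComparison", "PairSummary", "PairResult",
    "compare_pair",
]

# ---------------------------------------------------------------------------
# heterochrony vocabulary

ACCELERATION = "acceleration"
DECELERATION = "deceleration"
HYPERMORPHOSIS = "hypermorphosis"
HYPOMORPHOSIS = "hypomorphosis"
PRE_DISPLACEMENT = "pre_displacement"
POST_DISPLACEMENT = "post_displacement"
NO_CHANGE = "no_change"

PERAMORPH_LABELS = frozenset({ACCELERATION, HYPERMORPHOSIS, PRE_DISPLACEMENT})
PAEDOMORPH_LABELS = frozenset({DECELERATION, HYPOMORPHOSIS, POST_DISPLACEMENT})
HETEROCHRONY_LABELS = tuple(sorted(PERAMORPH_LABELS | PAEDOMORPH_LABELS)) + (NO_CHANGE,)

#: Swapping the wild/domestic roles of the two series mirrors every label.
MIRROR_LABEL = {
    ACCELERATION: DECELERATION, DECELERATION: ACCELERATION,
    HYPERMORPHOSIS: HYPOMORPHOSIS, HYPOMORPHOSIS: HYPERMORPHOSIS,
    PRE_DISPLACEMENT: POST_DISPLACEMENT, POST_DISPLACEMENT: PRE_DISPLACEMENT,
    NO_CHANGE: NO_CHANGE,
}


def label_process(label: str) -> str:
    """Map a heterochrony label to its process (peramorphosis /
    paedomorphosis / none)."""
    if label in PERAMORPH_LABELS:
        return "peramorphosis"
    if label in PAEDOMORPH_LABELS:
        return "paedomorphosis"
    if label == NO_CHANGE:
        return "none"
    raise ValueError(f"unknown label {label!r}")


# ---------------------------------------------------------------------------
# group summaries

@dataclass(frozen=True)
class _Group:
    n: int
    mean_x: float
    mean_y: float
    sxx: float  # variances / covariance with ddof=1
    syy: float
    sxy: float

    @property
    def r(self) -> float:
        return self.sxy / np.sqrt(self.sxx * self.syy)

    @property
    def slope(self) -> float:
        sign = 1.0 if self.sxy >= 0 else -1.0
        return sign * np.sqrt(self.syy / self.sxx)


def _group(x: np.ndarray, y: np.ndarray) -> _Group:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("each group needs at least 3 observations")
    cov = np.cov(x, y, ddof=1)
    if cov[0, 0] == 0 or cov[1, 1] == 0:
        raise ValueError("zero variance within a group")
    return _Group(n, float(x.mean()), float(y.mean()),
                  float(cov[0, 0]), float(cov[1, 1]), float(cov[0, 1]))


def _res_fit_corr_sq(g: _Group, b: float) -> float:
    """Squared correlation between residual (y - b x) and fitted-axis
    (y + b x) scores within one group, from its moments."""
    var_res = g.syy - 2.0 * b * g.sxy + b * b * g.sxx
    var_fit = g.syy + 2.0 * b * g.sxy + b * b * g.sxx
    if var_res <= 0 or var_fit <= 0:
        return 0.0
    cov_rf = g.syy - b * b * g.sxx
    r2 = cov_rf * cov_rf / (var_res * var_fit)
    return min(r2, 1.0 - 1e-15)


def _lr_profile(groups: Sequence[_Group], b: float) -> float:
    return float(sum(-(g.n - 2.5) * np.log1p(-_res_fit_corr_sq(g, b))
                     for g in groups))


@dataclass(frozen=True)
class SlopeTest:
    statistic: float  # LR, chi-square 1 df
    pvalue: float
    common_slope: float
    slopes: tuple[float, float]  # (wild, domestic)


def common_slope_test(x_wild: np.ndarray, y_wild: np.ndarray,
                      x_domestic: np.ndarray, y_domestic: np.ndarray,
                      *, xtol: float = 1e-10) -> SlopeTest:
    """Likelihood-ratio test of a common SMA slope across the two forms.

    The common-slope estimate minimises the Bartlett-corrected LR profile;
    the search is bracketed around the two group slopes.  The statistic is
    the profile minimum, referred to chi-square with 1 df.  The common
    slope is returned regardless of the test outcome.
    """
    gw = _group(x_wild, y_wild)
    gd = _group(x_domestic, y_domestic)
    groups = (gw, gd)
    b_lo, b_hi = sorted((gw.slope, gd.slope))
    if np.isclose(b_lo, b_hi, rtol=0, atol=xtol):
        b_hat = 0.5 * (b_lo + b_hi)
    else:
        # widen the bracket: the profile minimum lies between the group
        # slopes for two groups, but guard against boundary effects
        pad = 0.25 * (b_hi - b_lo) + 1e-12
        res = optimize.minimize_scalar(
            lambda b: _lr_profile(groups, b),
            bounds=(b_lo - pad, b_hi + pad), method="bounded",
            options={"xatol": xtol})
        if not res.success:  # pragma: no cover - bounded Brent rarely fails
            raise RuntimeError(
                f"common-slope search failed to converge between slopes "
                f"{b_lo:.6g} and {b_hi:.6g}: {res.message}")
        b_hat = float(res.x)
    lr = max(0.0, _lr_profile(groups, b_hat))
    p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return SlopeTest(lr, p, b_hat, (gw.slope, gd.slope))


def _common_slope_var(groups: Sequence[_Group], b: float) -> float:
    """Sampling variance of the common-slope estimate, pooling the
    asymptotic per-group SMA slope variances b^2 (1-r^2)/(n-2)."""
    infos = []
    for g in groups:
        var_i = b * b * (1.0 - g.r ** 2) / (g.n - 2)
        if var_i <= 0:
            return 0.0
        infos.append(1.0 / var_i)
    return 1.0 / sum(infos)


@dataclass(frozen=True)
class ElevationTest:
    statistic: float  # Wald, chi-square 1 df
    pvalue: float
    higher_form: str | None  # "domestic" | "wild" | None
    elevations: tuple[float, float]  # (wild, domestic)


def intercept_test(x_wild: np.ndarray, y_wild: np.ndarray,
                   x_domestic: np.ndarray, y_domestic: np.ndarray,
                   common_slope: float) -> ElevationTest:
    """Wald test of equal elevations (y-intercepts) at a shared slope.

    The elevation of a group is the mean residual ``mean(y - b x)``; the
    variance of the difference adds the residual-mean variances and the
    common-slope variance propagated through the difference in mean x.
    """
    gw = _group(x_wild, y_wild)
    gd = _group(x_domestic, y_domestic)
    b = common_slope
    res_w = np.asarray(y_wild, float) - b * np.asarray(x_wild, float)
    res_d = np.asarray(y_domestic, float) - b * np.asarray(x_domestic, float)
    a_w, a_d = float(res_w.mean()), float(res_d.mean())
    var = (res_w.var(ddof=1) / gw.n + res_d.var(ddof=1) / gd.n
           + (gw.mean_x - gd.mean_x) ** 2 * _common_slope_var((gw, gd), b))
    diff = a_d - a_w
    if var == 0:
        stat = 0.0 if diff == 0 else np.inf
    else:
        stat = diff * diff / var
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    higher = None
    if diff > 0:
        higher = "domestic"
    elif diff < 0:
        higher = "wild"
    return ElevationTest(float(stat), p, higher, (a_w, a_d))


@dataclass(frozen=True)
class ShiftTest:
    statistic: float  # Wald, chi-square 1 df
    pvalue: float
    direction: str  # "domestic_extends" | "wild_extends" | "none"
    axis_means: tuple[float, float]  # (wild, domestic)


def shift_test(x_wild: np.ndarray, y_wild: np.ndarray,
               x_domestic: np.ndarray, y_domestic: np.ndarray,
               common_slope: float, *, alpha: float = 0.05) -> ShiftTest:
    """Wald test for displacement along the shared trajectory.

    Fitted-axis scores ``y + b x`` locate each specimen along the common
    line; a significant difference in their group means marks an
    extension (or truncation) of one form's trajectory relative to the
    other.  Direction is reported only when the test rejects at *alpha*.
    """
    gw = _group(x_wild, y_wild)
    gd = _group(x_domestic, y_domestic)
    b = common_slope
    f_w = np.asarray(y_wild, float) + b * np.asarray(x_wild, float)
    f_d = np.asarray(y_domestic, float) + b * np.asarray(x_domestic, float)
    m_w, m_d = float(f_w.mean()), float(f_d.mean())
    var = (f_w.var(ddof=1) / gw.n + f_d.var(ddof=1) / gd.n
           + (gw.mean_x - gd.mean_x) ** 2 * _common_slope_var((gw, gd), b))
    diff = m_d - m_w
    if var == 0:
        stat = 0.0 if diff == 0 else np.inf
    else:
        stat = diff * diff / var
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    direction = "none"
    if p < alpha:
        direction = "domestic_extends" if diff > 0 else "wild_extends"
    return ShiftTest(float(stat), p, direction, (m_w, m_d))


# ---------------------------------------------------------------------------
# classification

def classify_heterochrony(*, slope_significant: bool, wild_slope: float,
                          domestic_slope: float,
                          intercept_significant: bool = False,
                          domestic_intercept_higher: bool = False,
                          shift_direction: str = "none",
                          ) -> tuple[str, str]:
    """Decision tree mapping the gated test outcomes to a label.

    Order of precedence: slope difference (rate change) > intercept
    difference (onset change) > shift (offset change) > no change.  The
    wild form is read as the ancestral trajectory.  Returns
    ``(label, process)``.
    """
    if slope_significant:
        label = ACCELERATION if domestic_slope > wild_slope else DECELERATION
    elif intercept_significant:
        label = PRE_DISPLACEMENT if domestic_intercept_higher else POST_DISPLACEMENT
    elif shift_direction == "domestic_extends":
        label = HYPERMORPHOSIS
    elif shift_direction == "wild_extends":
        label = HYPOMORPHOSIS
    else:
        label = NO_CHANGE
    return label, label_process(label)


@dataclass
class PairComparison:
    """Gated comparison of one variable's trajectories within a pair.

    Later tests are absent (None) whenever an earlier test in the chain
    was significant — an intercept difference is only interpretable on a
    shared slope, a shift only on a shared line.
    """

    pair_id: str
    variable: str
    alpha: float
    slope_test: SlopeTest
    intercept_test: ElevationTest | None
    shift_test: ShiftTest | None
    label: str
    process: str

    @property
    def slope_significant(self) -> bool:
        return self.slope_test.pvalue < self.alpha

    @property
    def intercept_significant(self) -> bool:
        return (self.intercept_test is not None
                and self.intercept_test.pvalue < self.alpha)


@dataclass
class PairSummary:
    """Tallies of trajectory differences for one pair (one row of the
    study-wide comparison figure)."""

    pair_id: str
    n_variables: int
    n_slope_domestic_higher: int = 0
    n_slope_wild_higher: int = 0
    n_intercept_domestic_higher: int = 0
    n_intercept_wild_higher: int = 0
    n_shift_domestic: int = 0
    n_shift_wild: int = 0
    n_no_change: int = 0
    label_tallies: Counter = field(default_factory=Counter)

    @property
    def n_different_slopes(self) -> int:
        return self.n_slope_domestic_higher + self.n_slope_wild_higher

    @property
    def n_different_intercepts(self) -> int:
        return self.n_intercept_domestic_higher + self.n_intercept_wild_higher

    @property
    def n_shifts(self) -> int:
        return self.n_shift_domestic + self.n_shift_wild

    @property
    def n_heterochronic_events(self) -> int:
        """Variables whose label is not no_change."""
        return self.n_variables - self.n_no_change

    def to_dict(self) -> dict:
        return {
            "pair": self.pair_id,
            "n_variables": self.n_variables,
            "different_slopes_domestic_higher": self.n_slope_domestic_higher,
            "different_slopes_wild_higher": self.n_slope_wild_higher,
            "different_intercepts_domestic_higher": self.n_intercept_domestic_higher,
            "different_intercepts_wild_higher": self.n_intercept_wild_higher,
            "shift_domestic": self.n_shift_domestic,
            "shift_wild": self.n_shift_wild,
            "no_change": self.n_no_change,
            "heterochronic_events": self.n_heterochronic_events,
            "labels": dict(self.label_tallies),
        }


@dataclass
class PairResult:
    pair_id: str
    comparisons: list[PairComparison]
    summary: PairSummary

    def comparison(self, variable: str) -> PairComparison:
        for c in self.comparisons:
            if c.variable == variable:
                return c
        raise KeyError(variable)

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.comparisons:
            rows.append({
                "pair": c.pair_id, "variable": c.variable,
                "slope_wild": c.slope_test.slopes[0],
                "slope_domestic": c.slope_test.slopes[1],
                "common_slope": c.slope_test.common_slope,
                "slope_stat": c.slope_test.statistic,
                "slope_p": c.slope_test.pvalue,
                "intercept_stat": c.intercept_test.statistic if c.intercept_test else np.nan,
                "intercept_p": c.intercept_test.pvalue if c.intercept_test else np.nan,
                "shift_stat": c.shift_test.statistic if c.shift_test else np.nan,
                "shift_p": c.shift_test.pvalue if c.shift_test else np.nan,
                "shift_direction": c.shift_test.direction if c.shift_test else "",
                "label": c.label, "process": c.process,
            })
        return pd.DataFrame(rows)


def compare_variable(x_wild: np.ndarray, y_wild: np.ndarray,
                     x_domestic: np.ndarray, y_domestic: np.ndarray,
                     *, alpha: float, variable: str = "",
                     pair_id: str = "") -> PairComparison:
    """Run the gated slope -> intercept -> shift chain for one variable."""
    st = common_slope_test(x_wild, y_wild, x_domestic, y_domestic)
    et = None
    sht = None
    if st.pvalue >= alpha:
        et = intercept_test(x_wild, y_wild, x_domestic, y_domestic, st.common_slope)
        if et.pvalue >= alpha:
            sht = shift_test(x_wild, y_wild, x_domestic, y_domestic,
                             st.common_slope, alpha=alpha)
    label, process = classify_heterochrony(
        slope_significant=st.pvalue < alpha,
        wild_slope=st.slopes[0], domestic_slope=st.slopes[1],
        intercept_significant=et is not None and et.pvalue < alpha,
        domestic_intercept_higher=(et.higher_form == "domestic") if et else False,
        shift_direction=sht.direction if sht else "none")
    return PairComparison(pair_id=pair_id, variable=variable, alpha=alpha,
                          slope_test=st, intercept_test=et, shift_test=sht,
                          label=label, process=process)


def compare_pair(wild: GrowthSeries, domestic: GrowthSeries,
                 config: BivarConfig | None = None,
                 variables: Sequence[str] | None = None) -> PairResult:
    """Compare every common variable's trajectory between the two forms.

    Both forms use the same geometric-mean proxy set (their common
    variable set) so the size axes are commensurable.  All three tests run
    at the Bonferroni-corrected level ``alpha / n_common_variables``;
    *variables* optionally restricts which variables are compared without
    changing that correction.
    """
    config = config or BivarConfig()
    shared = common_variables(wild, domestic)
    alpha_corr = bonferroni_alpha(config.alpha, len(shared))
    proxy = list(config.proxy_set) if config.proxy_set is not None else shared
    targets = list(variables) if variables is not None else shared

    def _xy(series: GrowthSeries, var: str):
        size = geometric_mean_size(series, proxy)
        log_gm = dict(zip(size.specimen_ids, size.log10))
        col = series.column(var)
        pts = [(log_gm[s], np.log10(m))
               for s, m in zip(series.specimen_ids, col)
               if s in log_gm and not np.isnan(m)]
        x, y = map(np.asarray, zip(*pts))
        return x, y

    comparisons = []
    for var in targets:
        xw, yw = _xy(wild, var)
        xd, yd = _xy(domestic, var)
        comparisons.append(compare_variable(
            xw, yw, xd, yd, alpha=alpha_corr, variable=var,
            pair_id=wild.pair_id))

    summary = PairSummary(pair_id=wild.pair_id, n_variables=len(comparisons))
    for c in comparisons:
        summary.label_tallies[c.label] += 1
        if c.label == ACCELERATION:
            summary.n_slope_domestic_higher += 1
        elif c.label == DECELERATION:
            summary.n_slope_wild_higher += 1
        elif c.label == PRE_DISPLACEMENT:
            summary.n_intercept_domestic_higher += 1
        elif c.label == POST_DISPLACEMENT:
            summary.n_intercept_wild_higher += 1
        elif c.label == HYPERMORPHOSIS:
            summary.n_shift_domestic += 1
        elif c.label == HYPOMORPHOSIS:
            summary.n_shift_wild += 1
        else:
            summary.n_no_change += 1
    return PairResult(wild.pair_id, comparisons, summary)
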