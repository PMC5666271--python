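"""Bivariate allometry: SMA regressions of log10 measurements on log10 size.

Each variable is regressed on overall size, proxied by the geometric mean
(GM) of the measurement set, after base-10 log transformation of both axes
(the standard allometric power law, linear on log-log axes).  Lines are
fitted by standardized major axis (SMA), whose slope magnitude is
``sd(log y)/sd(log x)``; slopes are read as relative growth rates, so a
slope above 1 means the part outgrows overall size.  Deviation from
isometry (slope 1.0) is tested with the SMA F-test based on the
correlation between residual and fitted-axis scores, at a
Bonferroni-corrected level (0.05/14 = 0.0036 when all 14 variables are
fitted).  Normality of the size proxy is screened with Shapiro-Wilk,
advisory only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .series import GrowthSeries

__all__ = [
    "SizeVector", "NormalityCheck", "SMAFit", "BivarConfig",
    "geometric_mean_size", "shapiro_wilk", "sma_fit", "isometry_test",
    "bonferroni_alpha", "run_bivar",
]


@dataclass
class SizeVector:
    """Per-specimen geometric-mean size over a fixed proxy variable set."""

    values: np.ndarray
    proxy_variables: list[str]
    specimen_ids: list[str]
    excluded_specimens: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def log10(self) -> np.ndarray:
        return np.log10(self.values)


@dataclass(frozen=True)
class NormalityCheck:
    statistic: float  # Shapiro-Wilk W
    pvalue: float


@dataclass
class SMAFit:
    """Standardized major axis fit of log10 y on log10 x.

    ``slope`` is ``sign(r) * sd(y)/sd(x)``; ``intercept`` is
    ``mean(y) - slope*mean(x)``; ``slope_ci`` is the standard SMA interval
    derived from the F distribution of the correlation.  ``p_isometry``
    and ``trend`` are filled once the isometry test has been run at a
    given corrected alpha.
    """

    variable: str
    n: int
    slope: float
    intercept: float
    r: float
    slope_ci: tuple[float, float]
    p_isometry: float | None = None
    trend: str | None = None  # "+" | "=" | "−"
    x: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)


def geometric_mean_size(series: GrowthSeries,
                        proxy_set: Sequence[str] | None = None) -> SizeVector:
    """Geometric mean of the proxy variables, one value per specimen.

    The GM is ``(prod_k y_k)^(1/q)``, equivalently ``10^mean(log10 y)``;
    being an equal-weight average of logs it is isometric by construction
    and serves as the overall-size axis of every bivariate fit.  Specimens
    missing any proxy variable are excluded with a warning.
    """
    if proxy_set is None:
        proxy_set = series.present_variables(min_n=1)
    idx = [series.variable_names.index(v) for v in proxy_set]
    sub = series.measurements[:, idx]
    keep = ~np.isnan(sub).any(axis=1)
    excluded = [s for s, k in zip(series.specimen_ids, keep) if not k]
    if excluded:
        warnings.warn(
            f"{series.taxon_label} ({series.form}): {len(excluded)} specimen(s) "
            "missing a size-proxy variable were excluded from the geometric mean",
            stacklevel=2)
    values = sub[keep]
    if np.any(values <= 0):
        raise ValueError("geometric mean requires strictly positive measurements")
    gm = 10.0 ** np.log10(values).mean(axis=1)
    return SizeVector(gm, list(proxy_set),
                      [s for s, k in zip(series.specimen_ids, keep) if k],
                      excluded)


def shapiro_wilk(sizes: SizeVector | np.ndarray) -> NormalityCheck:
    """Shapiro-Wilk normality check of the size proxy (advisory)."""
    values = sizes.values if isinstance(sizes, SizeVector) else np.asarray(sizes, float)
    if len(values) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(values) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    res = stats.shapiro(values)
    return NormalityCheck(float(res.statistic), float(res.pvalue))


def sma_fit(x: np.ndarray, y: np.ndarray, *, ci_level: float = 0.95,
            variable: str = "", estimator: str = "sma") -> SMAFit:
    """Fit a line to (log10 x, log10 y) by standardized major axis.

    Parameters
    ----------
    x, y
        Already log-transformed coordinates (size proxy on x).
    ci_level
        Level of the slope confidence interval.
    estimator
        ``"sma"`` (default) or ``"ols"`` (sensitivity analysis only; the
        OLS slope is ``r * sd_y/sd_x``).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    if estimator == "sma":
        slope = sign * sy / sx
    elif estimator == "ols":
        slope = r * sy / sx
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    intercept = float(y.mean() - slope * x.mean())

    # SMA slope CI from the F distribution of the correlation:
    # B = F_{1,n-2}(level) * (1 - r^2)/(n - 2);
    # limits slope * (sqrt(B + 1) -/+ sqrt(B)).
    df = n - 2
    B = stats.f.ppf(ci_level, 1, df) * (1.0 - r * r) / df
    lo = slope * (np.sqrt(B + 1.0) - np.sqrt(B))
    hi = slope * (np.sqrt(B + 1.0) + np.sqrt(B))
    ci = (float(min(lo, hi)), float(max(lo, hi)))
    return SMAFit(variable=variable, n=n, slope=float(slope),
                  intercept=intercept, r=r, slope_ci=ci, x=x, y=y)


def isometry_test(fit: SMAFit, null_slope: float = 1.0) -> float:
    """Two-sided p-value of H0: SMA slope equals *null_slope*.

    Evaluates the correlation ``r_rf`` between residual scores
    ``y - b0*x`` and fitted-axis scores ``y + b0*x`` at the null slope;
    under H0 these are uncorrelated, and
    ``F = r_rf^2 (n-2)/(1 - r_rf^2)`` follows F(1, n-2).  Degenerate exact
    fits (zero residual variance at the null slope) give p = 1.
    """
    if fit.x is None or fit.y is None:
        raise ValueError("fit does not carry its data; refit with sma_fit")
    n = fit.n
    if n <= 3:
        raise ValueError("isometry test needs n > 3")
    res = fit.y - null_slope * fit.x
    axis = fit.y + null_slope * fit.x
    if res.std() == 0 or axis.std() == 0:
        return 1.0
    r_rf = float(np.corrcoef(res, axis)[0, 1])
    if abs(r_rf) >= 1.0:
        return 0.0
    F = r_rf * r_rf * (n - 2) / (1.0 - r_rf * r_rf)
    return float(stats.f.sf(F, 1, n - 2))


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Per-test level after Bonferroni correction over *n_tests* tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class BivarConfig:
    """Settings for the bivariate stage.

    alpha is the family-wise level; the per-test level divides it by the
    number of regressions actually fitted for the series (0.05/14 = 0.0036
    when all 14 variables are present).
    """

    alpha: float = 0.05
    ci_level: float = 0.95
    estimator: str = "sma"
    proxy_set: Sequence[str] | None = None
    check_normality: bool = True


def run_bivar(series: GrowthSeries, config: BivarConfig | None = None,
              variables: Sequence[str] | None = None) -> list[SMAFit]:
    """One SMA fit per variable against the geometric-mean size proxy.

    Per variable, the fit uses specimens with that variable and every
    proxy variable present.  Trends are classified at the Bonferroni
    level ``alpha / n_regressions``: '+' when the isometry test rejects
    with slope > 1, '−' when it rejects with slope < 1, '=' otherwise.
    """
    config = config or BivarConfig()
    if variables is None:
        variables = series.present_variables(min_n=3)
    proxy = list(config.proxy_set) if config.proxy_set is not None else list(variables)
    size = geometric_mean_size(series, proxy)
    if config.check_normality and len(size) >= 3:
        check = shapiro_wilk(size)
        if check.pvalue < 0.05:
            warnings.warn(
                f"{series.taxon_label} ({series.form}): geometric-mean size "
                f"deviates from normality (W={check.statistic:.3f}, "
                f"p={check.pvalue:.4f}); proceeding", stacklevel=2)
    log_gm = {s: v for s, v in zip(size.specimen_ids, size.log10)}
    alpha_corr = bonferroni_alpha(config.alpha, len(variables))
    fits = []
    for var in variables:
        col = series.column(var)
        pairs = [(log_gm[s], np.log10(m))
                 for s, m in zip(series.specimen_ids, col)
                 if s in log_gm and not np.isnan(m)]
        if len(pairs) < 4:
            warnings.warn(f"{series.taxon_label} ({series.form}): variable "
                          f"{var} has fewer than 4 usable specimens; skipped",
                          stacklevel=2)
            continue
        x, y = map(np.asarray, zip(*pairs))
        fit = sma_fit(x, y, ci_level=config.ci_level, variable=var,
                      estimator=config.estimator)
        fit.p_isometry = isometry_test(fit, 1.0)
        if fit.p_isometry >= alpha_corr:
            fit.trend = "="
        else:
            fit.trend = "+" if fit.slope > 1.0 else "−"
        fits.append(fit)
    return fits
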