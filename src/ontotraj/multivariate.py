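"""Multivariate allometry via the first eigenvector of the log-covariance.

Size is treated as a latent factor loading on all measurements at once: the
unit-scaled first eigenvector of the covariance matrix of log10-transformed
measurements gives one allometry coefficient per variable.  Under isometry
every element equals ``1/sqrt(p)`` (0.267 at p = 14); deviation of a
variable's element from that value measures its positive or negative
allometry.

Uncertainty is quantified by leave-one-out jackknifing of the eigenvector:
first-order (Tukey) pseudovalues ``n*theta - (n-1)*theta_(-i)`` yield a
bias-adjusted mean, a standard deviation and a Student-t confidence
interval per element.  Because extreme pseudovalues can inflate the
intervals, a trimmed variant removes the m largest and m smallest
pseudovalues per variable; the reported mode (untrimmed 'U' or trimmed 'T')
is the one with the lower average standard deviation, falling back to lower
average absolute bias on ties.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .series import GrowthSeries, MIN_SPECIMENS_HARD, MIN_SPECIMENS_RECOMMENDED
from .signs import ISOMETRIC, MISSING, NEGATIVE, POSITIVE, SignPattern

__all__ = [
    "MultivarConfig", "AllometryCoefficient", "PseudovalueMatrix",
    "MultivarResult", "isometry_value", "first_eigenvector",
    "jackknife_pseudovalues", "trim_pseudovalues", "jackknife_ci",
    "classify_signs", "run_multivar",
]

_EIG_TIE_RTOL = 1e-12


@dataclass
class MultivarConfig:
    """Settings for the multivariate stage.

    trim_m
        Number of extreme pseudovalues removed from each end of every
        per-variable column in the trimmed variant (default 1).
    ci_level
        Two-sided confidence level for the jackknife intervals.
    mode
        ``"untrimmed"`` / ``"trimmed"`` force one variant; ``"auto"``
        computes both and reports the better one.
    selection_criterion
        How ``auto`` chooses: ``"lower_mean_sd"``, ``"lower_mean_abs_bias"``
        or ``"either"`` (sd first, bias breaks ties, untrimmed on full tie).
    ci_multiplier
        ``"t"`` for the Student-t jackknife interval (default) or
        ``"two_sd"`` for a plain mean +/- 2*sd/sqrt(n') sensitivity variant.
    """

    trim_m: int = 1
    ci_level: float = 0.95
    mode: str = "auto"  # "untrimmed" | "trimmed" | "auto"
    selection_criterion: str = "either"
    ci_multiplier: str = "t"

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.trim_m < 0:
            raise ValueError("trim_m must be >= 0")
        if self.mode not in ("untrimmed", "trimmed", "auto"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.selection_criterion not in ("lower_mean_sd", "lower_mean_abs_bias", "either"):
            raise ValueError(f"unknown selection_criterion {self.selection_criterion!r}")
        if self.ci_multiplier not in ("t", "two_sd"):
            raise ValueError(f"unknown ci_multiplier {self.ci_multiplier!r}")


@dataclass
class AllometryCoefficient:
    """Jackknifed first-eigenvector element for one variable."""

    variable: str
    estimate_full: float
    jackknife_mean: float
    jackknife_sd: float
    bias: float
    ci_low: float
    ci_high: float
    sign: str | None = None  # "P" | "I" | "N"
    trimmed: bool = False

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


@dataclass
class PseudovalueMatrix:
    """Jackknife pseudovalues, one column per variable.

    For the untrimmed matrix row i derives from the leave-one-out sample
    excluding specimen i; after trimming, columns are trimmed independently
    so rows no longer align with specimens.
    """

    values: np.ndarray  # (n', p)
    variable_names: list[str]
    estimate_full: np.ndarray  # (p,) sign-aligned full-sample eigenvector
    trimmed_m: int = 0

    @property
    def n(self) -> int:
        return self.values.shape[0]


def isometry_value(p: int) -> float:
    """Hypothetical isometric eigenvector element, ``1/sqrt(p)``."""
    if p < 1:
        raise ValueError("p must be >= 1")
    return 1.0 / np.sqrt(p)


def _log_matrix(series: GrowthSeries, variables: Sequence[str] | None
                ) -> tuple[np.ndarray, list[str]]:
    variables = list(variables) if variables is not None else list(series.variable_names)
    X, _ = series.complete_cases(variables)
    if np.any(X <= 0):
        raise ValueError("measurements must be strictly positive for log transform")
    return np.log10(X), variables


def _principal_axis(Z: np.ndarray) -> np.ndarray:
    """Unit first eigenvector of the covariance of *Z* (rows = specimens),
    oriented so its element sum is positive."""
    n, p = Z.shape
    if n < 3:
        raise ValueError(f"need at least 3 complete specimens, got {n}")
    if p < 2:
        raise ValueError("need at least 2 variables")
    cov = np.cov(Z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    lead, second = eigvals[-1], eigvals[-2]
    scale = max(abs(lead), 1.0)
    if lead - second <= _EIG_TIE_RTOL * scale and second > _EIG_TIE_RTOL * scale:
        raise ValueError(
            "degenerate covariance: the two largest eigenvalues are tied; "
            "the first principal axis is not identified")
    v = eigvecs[:, -1]
    total = v.sum()
    if total < 0 or (total == 0 and v[np.argmax(np.abs(v))] < 0):
        v = -v
    return v


def first_eigenvector(series: GrowthSeries,
                      variables: Sequence[str] | None = None) -> np.ndarray:
    """Unit-scaled first eigenvector of the log10 covariance matrix.

    Uses complete cases over *variables* (default: all variables of the
    series).  The vector has Euclidean norm 1 and is oriented so its
    element sum is positive (all loadings positive for growth data).
    """
    Z, _ = _log_matrix(series, variables)
    return _principal_axis(Z)


def jackknife_pseudovalues(series: GrowthSeries,
                           variables: Sequence[str] | None = None
                           ) -> PseudovalueMatrix:
    """Leave-one-out pseudovalues of every eigenvector element.

    Row i is ``n*theta - (n-1)*theta_(-i)`` where ``theta`` is the
    sign-aligned full-sample eigenvector and ``theta_(-i)`` the eigenvector
    recomputed without specimen i, re-aligned to the full-sample vector by
    positive dot product before differencing (sign flips between rounds
    would otherwise corrupt the pseudovalues).
    """
    Z, varnames = _log_matrix(series, variables)
    n = Z.shape[0]
    if n < 4:
        raise ValueError(f"jackknife needs at least 4 complete specimens, got {n}")
    v_full = _principal_axis(Z)
    pv = np.empty_like(Z)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            v_i = _principal_axis(Z[mask])
        except (ValueError, np.linalg.LinAlgError) as exc:
            sid = series.specimen_ids[i] if i < len(series.specimen_ids) else str(i)
            raise ValueError(
                f"eigen-decomposition failed with specimen {sid!r} excluded: {exc}"
            ) from exc
        mask[i] = True
        if float(v_i @ v_full) < 0:
            v_i = -v_i
        pv[i] = n * v_full - (n - 1) * v_i
    return PseudovalueMatrix(pv, varnames, v_full)


def trim_pseudovalues(pv: PseudovalueMatrix, m: int) -> PseudovalueMatrix:
    """Remove the m largest and m smallest pseudovalues of every column.

    Trimming is per variable (each column on its own order statistics), so
    the rows of the result no longer correspond to specimens.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return PseudovalueMatrix(pv.values.copy(), list(pv.variable_names),
                                 pv.estimate_full.copy(), trimmed_m=0)
    n = pv.n
    if n - 2 * m < 3:
        raise ValueError(f"cannot trim m={m} from n={n}: fewer than 3 values would remain")
    trimmed = np.sort(pv.values, axis=0)[m:n - m]
    return PseudovalueMatrix(trimmed, list(pv.variable_names),
                             pv.estimate_full.copy(), trimmed_m=m)


def jackknife_ci(pv: PseudovalueMatrix, level: float = 0.95,
                 estimate_full: np.ndarray | None = None,
                 *, multiplier: str = "t") -> list[AllometryCoefficient]:
    """Per-variable mean, SD, bias and confidence interval of pseudovalues.

    The interval is ``mean +/- t_{n'-1,(1+level)/2} * sd / sqrt(n')`` with
    n' the (possibly trimmed) column length; ``multiplier="two_sd"``
    substitutes a plain factor 2 for the t quantile.  Bias is the signed
    difference ``jackknife_mean - estimate_full``.
    """
    if estimate_full is None:
        estimate_full = pv.estimate_full
    values = pv.values
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pseudovalues per column")
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    if multiplier == "t":
        tq = stats.t.ppf(0.5 * (1.0 + level), df=n - 1)
    elif multiplier == "two_sd":
        tq = 2.0
    else:
        raise ValueError(f"unknown multiplier {multiplier!r}")
    half = tq * sds / np.sqrt(n)
    coeffs = []
    for k, var in enumerate(pv.variable_names):
        coeffs.append(AllometryCoefficient(
            variable=var,
            estimate_full=float(estimate_full[k]),
            jackknife_mean=float(means[k]),
            jackknife_sd=float(sds[k]),
            bias=float(means[k] - estimate_full[k]),
            ci_low=float(means[k] - half[k]),
            ci_high=float(means[k] + half[k]),
            trimmed=pv.trimmed_m > 0,
        ))
    return coeffs


def classify_signs(coefficients: Sequence[AllometryCoefficient],
                   isometry: float, *, atol: float = 1e-9) -> SignPattern:
    """Assign P/I/N per variable from CI position versus the isometric value.

    A variable is isometric when its interval contains ``1/sqrt(p)``,
    positively allometric when the whole interval lies above it, negatively
    allometric when below.  *atol* guards degenerate zero-width intervals
    (noiseless data) against float round-off.  The ``sign`` field of each
    coefficient is set in place and the pattern returned in coefficient
    order.
    """
    symbols = []
    for c in coefficients:
        if c.ci_low > isometry + atol:
            c.sign = "P"
            symbols.append(POSITIVE)
        elif c.ci_high < isometry - atol:
            c.sign = "N"
            symbols.append(NEGATIVE)
        else:
            c.sign = "I"
            symbols.append(ISOMETRIC)
    return SignPattern(tuple(symbols))


@dataclass
class MultivarResult:
    """Full multivariate-allometry output for one series."""

    taxon_label: str
    form: str
    pair_id: str
    p: int
    isometry_value: float
    mode_used: str  # "U" | "T"
    coefficients_untrimmed: list[AllometryCoefficient]
    coefficients_trimmed: list[AllometryCoefficient] | None
    mean_sd_untrimmed: float
    mean_sd_trimmed: float | None
    mean_abs_bias_untrimmed: float
    mean_abs_bias_trimmed: float | None
    n_specimens: int = 0
    absent_variables: list[str] = field(default_factory=list)

    @property
    def coefficients(self) -> list[AllometryCoefficient]:
        """Coefficients of the reported (mode-selected) variant."""
        if self.mode_used == "T":
            assert self.coefficients_trimmed is not None
            return self.coefficients_trimmed
        return self.coefficients_untrimmed

    @property
    def variable_names(self) -> list[str]:
        return [c.variable for c in self.coefficients]

    def coefficient(self, variable: str) -> AllometryCoefficient:
        for c in self.coefficients:
            if c.variable == variable:
                return c
        raise KeyError(variable)

    @property
    def sign_pattern(self) -> SignPattern:
        mapping = {"P": POSITIVE, "I": ISOMETRIC, "N": NEGATIVE}
        return SignPattern(tuple(mapping[c.sign] for c in self.coefficients))

    def sign_string(self, variable_order: Sequence[str] | None = None) -> str:
        """Positional sign string over *variable_order* (default: the
        series' own variables), '?' where a variable was not analysed."""
        if variable_order is None:
            return self.sign_pattern.render()
        by_var = {c.variable: c for c in self.coefficients}
        mapping = {"P": POSITIVE, "I": ISOMETRIC, "N": NEGATIVE}
        return "".join(mapping[by_var[v].sign] if v in by_var else MISSING
                       for v in variable_order)

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.coefficients:
            rows.append({
                "taxon": self.taxon_label, "form": self.form, "pair": self.pair_id,
                "variable": c.variable, "estimate": c.estimate_full,
                "mean": c.jackknife_mean, "sd": c.jackknife_sd, "bias": c.bias,
                "ci_low": c.ci_low, "ci_high": c.ci_high, "sign": c.sign,
                "mode": self.mode_used,
            })
        return pd.DataFrame(rows)


def _summaries(coeffs: Sequence[AllometryCoefficient]) -> tuple[float, float]:
    sds = np.array([c.jackknife_sd for c in coeffs])
    biases = np.array([abs(c.bias) for c in coeffs])
    return float(sds.mean()), float(biases.mean())


def _lower(a: float, b: float, rtol: float = 1e-9, atol: float = 1e-12) -> int:
    """-1 if a < b, +1 if a > b, 0 on a numerical tie."""
    if np.isclose(a, b, rtol=rtol, atol=atol):
        return 0
    return -1 if a < b else 1


def _choose_mode(sd_u: float, sd_t: float, bias_u: float, bias_t: float,
                 criterion: str) -> str:
    if criterion == "lower_mean_sd":
        return "T" if _lower(sd_t, sd_u) < 0 else "U"
    if criterion == "lower_mean_abs_bias":
        return "T" if _lower(bias_t, bias_u) < 0 else "U"
    # "either": sd comparison takes precedence; bias breaks sd ties;
    # untrimmed on a full tie.
    sd_cmp = _lower(sd_t, sd_u)
    if sd_cmp != 0:
        return "T" if sd_cmp < 0 else "U"
    return "T" if _lower(bias_t, bias_u) < 0 else "U"


def run_multivar(series: GrowthSeries, config: MultivarConfig | None = None,
                 variables: Sequence[str] | None = None) -> MultivarResult:
    """Full multivariate stage for one series.

    Computes the full-sample eigenvector, its jackknife pseudovalues, both
    untrimmed and (m-)trimmed confidence intervals, selects the reported
    mode, and classifies every variable as P/I/N against ``1/sqrt(p)``
    where p is the number of variables actually analysed for this series.
    """
    config = config or MultivarConfig()
    if variables is None:
        variables = series.present_variables(min_n=1)
    pv = jackknife_pseudovalues(series, variables)
    n = pv.n
    if n < MIN_SPECIMENS_HARD:
        raise ValueError(
            f"{series.taxon_label} ({series.form}): {n} complete specimens is "
            f"below the floor of {MIN_SPECIMENS_HARD} for jackknife CIs")
    if n < MIN_SPECIMENS_RECOMMENDED:
        warnings.warn(
            f"{series.taxon_label} ({series.form}): jackknife CIs from only "
            f"{n} specimens are unreliable", stacklevel=2)

    coeffs_u = jackknife_ci(pv, config.ci_level, multiplier=config.ci_multiplier)
    sd_u, bias_u = _summaries(coeffs_u)

    coeffs_t = None
    sd_t = bias_t = None
    want_trimmed = config.mode in ("trimmed", "auto") and config.trim_m > 0
    if want_trimmed and n - 2 * config.trim_m >= 3:
        pv_t = trim_pseudovalues(pv, config.trim_m)
        coeffs_t = jackknife_ci(pv_t, config.ci_level, pv.estimate_full,
                                multiplier=config.ci_multiplier)
        sd_t, bias_t = _summaries(coeffs_t)
    elif config.mode == "trimmed":
        raise ValueError(
            f"cannot trim m={config.trim_m} pseudovalues from n={n}")

    if config.mode == "untrimmed":
        mode = "U"
    elif config.mode == "trimmed":
        mode = "T"
    elif coeffs_t is None:
        mode = "U"
    else:
        mode = _choose_mode(sd_u, sd_t, bias_u, bias_t, config.selection_criterion)

    p = len(pv.variable_names)
    iso = isometry_value(p)
    classify_signs(coeffs_u, iso)
    if coeffs_t is not None:
        classify_signs(coeffs_t, iso)

    return MultivarResult(
        taxon_label=series.taxon_label,
        form=series.form,
        pair_id=series.pair_id,
        p=p,
        isometry_value=iso,
        mode_used=mode,
        coefficients_untrimmed=coeffs_u,
        coefficients_trimmed=coeffs_t,
        mean_sd_untrimmed=sd_u,
        mean_sd_trimmed=sd_t,
        mean_abs_bias_untrimmed=bias_u,
        mean_abs_bias_trimmed=bias_t,
        n_specimens=n,
        absent_variables=list(series.absent_variables),
    )
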