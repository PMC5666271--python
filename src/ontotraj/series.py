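"""Growth-series containers and validation.

A :class:`GrowthSeries` holds the specimen-by-variable matrix of linear
measurements (in mm) for one form of one taxon, together with the metadata
needed to pair it with its wild or domesticated counterpart.  Measurements
must be strictly positive so that a log10 transform is defined; missing
values are carried as NaN and flagged per cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of the 14 skull measurement codes.  Sign strings and
#: all tabular outputs follow this order so that per-position symbols are
#: directly comparable across taxa.
CANONICAL_VARIABLES: tuple[str, ...] = (
    "CPL", "LN", "HM", "UPR", "LP", "BP", "LO",
    "ZB", "BB", "HO", "LD", "HD", "HC", "LPR",
)

WILD = "wild"
DOMESTIC = "domestic"
FORMS = (WILD, DOMESTIC)

#: Series with fewer specimens than this cannot enter jackknife CI
#: estimation at all.
MIN_SPECIMENS_HARD = 5
#: Below this many specimens jackknife CIs are computed but flagged as
#: unreliable (warning, not error).
MIN_SPECIMENS_RECOMMENDED = 10


def canonical_order(variables: Iterable[str]) -> list[str]:
    """Order *variables* canonically where they match the 14 standard codes,
    preserving input order for any non-standard names (appended after)."""
    variables = list(variables)
    upper = {v.upper(): v for v in variables}
    ordered = [upper[c] for c in CANONICAL_VARIABLES if c in upper]
    ordered += [v for v in variables if v.upper() not in CANONICAL_VARIABLES]
    return ordered


@dataclass(frozen=True)
class Finding:
    """One validation finding attached to a specimen/variable cell."""

    severity: str  # "error" | "warning"
    specimen_id: str | None
    variable: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - display helper
        loc = ",".join(x for x in (self.specimen_id, self.variable) if x)
        return f"[{self.severity}] {loc}: {self.message}" if loc else \
            f"[{self.severity}] {self.message}"


@dataclass
class ValidationReport:
    """Collection of findings; an error-free report is the precondition of
    every analysis stage."""

    findings: list[Finding] = field(default_factory=list)

    def add(self, severity: str, message: str, *, specimen_id: str | None = None,
            variable: str | None = None) -> None:
        self.findings.append(Finding(severity, specimen_id, variable, message))

    def extend(self, other: "ValidationReport") -> None:
        self.findings.extend(other.findings)

    @property
    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_errors(self) -> None:
        if self.errors:
            lines = "; ".join(str(f) for f in self.errors[:10])
            raise ValueError(f"validation failed with {len(self.errors)} error(s): {lines}")


@dataclass
class GrowthSeries:
    """Measurement matrix for one (taxon, form) ontogenetic series.

    Parameters
    ----------
    taxon_label
        Display name of the taxon (e.g. ``"Canis lupus familiaris"``).
    form
        Either ``"wild"`` or ``"domestic"``.
    pair_id
        Identifier shared by the two members of a wild-domestic pair.
    variable_names
        Measurement codes, unique, ordered; order is preserved in every
        downstream output.
    measurements
        ``(n_specimens, n_variables)`` float array, mm; NaN marks a missing
        cell.  Values must be strictly positive where present.
    specimen_ids
        Unique specimen identifiers, one per row.
    absent_variables
        Codes that the study protocol defines but that were not measurable
        for this taxon (e.g. dentary variables in forms whose dentaries were
        unavailable); rendered as ``?`` in sign tables.
    meta
        Free-form provenance (e.g. generating parameters of a synthetic
        series).
    """

    taxon_label: str
    form: str
    pair_id: str
    variable_names: list[str]
    measurements: np.ndarray
    specimen_ids: list[str]
    absent_variables: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.measurements = np.asarray(self.measurements, dtype=float)
        if self.measurements.ndim != 2:
            raise ValueError("measurements must be a 2-D specimen x variable array")
        n, p = self.measurements.shape
        if p != len(self.variable_names):
            raise ValueError(
                f"{p} measurement columns but {len(self.variable_names)} variable names")
        if n != len(self.specimen_ids):
            raise ValueError(
                f"{n} measurement rows but {len(self.specimen_ids)} specimen ids")
        if len(set(self.variable_names)) != len(self.variable_names):
            raise ValueError("variable_names must be unique")
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_specimens(self) -> int:
        return self.measurements.shape[0]

    @property
    def n_variables(self) -> int:
        return self.measurements.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.measurements)

    def column(self, variable: str) -> np.ndarray:
        return self.measurements[:, self.variable_names.index(variable)]

    # -- derived views --------------------------------------------------
    def subset(self, variables: Sequence[str]) -> "GrowthSeries":
        """Return a copy restricted to *variables* (order as given)."""
        idx = [self.variable_names.index(v) for v in variables]
        return dataclasses.replace(
            self,
            variable_names=list(variables),
            measurements=self.measurements[:, idx].copy(),
            specimen_ids=list(self.specimen_ids),
            absent_variables=[v for v in self.absent_variables if v in variables],
        )

    def complete_cases(self, variables: Sequence[str] | None = None
                       ) -> tuple[np.ndarray, list[str]]:
        """Matrix and specimen ids restricted to rows complete for
        *variables* (default: all variables of the series)."""
        if variables is None:
            variables = self.variable_names
        idx = [self.variable_names.index(v) for v in variables]
        sub = self.measurements[:, idx]
        keep = ~np.isnan(sub).any(axis=1)
        return sub[keep], [s for s, k in zip(self.specimen_ids, keep) if k]

    def present_variables(self, min_n: int = 1) -> list[str]:
        """Variables with at least *min_n* non-missing measurements."""
        counts = (~self.missing_mask).sum(axis=0)
        return [v for v, c in zip(self.variable_names, counts) if c >= min_n]

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame (specimen id index, one column per variable)."""
        return pd.DataFrame(self.measurements, index=pd.Index(self.specimen_ids, name="specimen_id"),
                            columns=self.variable_names)

    # -- validation -----------------------------------------------------
    def validate(self) -> ValidationReport:
        """Check log-transformability and structural invariants."""
        report = ValidationReport()
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            dupes = sorted({s for s in self.specimen_ids if self.specimen_ids.count(s) > 1})
            report.add("error", f"duplicate specimen id(s): {', '.join(dupes)}")
        values = self.measurements
        bad = np.asarray((values <= 0) & ~np.isnan(values)).nonzero()
        for i, j in zip(*bad):
            report.add("error", "non-positive measurement",
                       specimen_id=self.specimen_ids[i], variable=self.variable_names[j])
        inf = np.asarray(np.isinf(values)).nonzero()
        for i, j in zip(*inf):
            report.add("error", "non-finite measurement",
                       specimen_id=self.specimen_ids[i], variable=self.variable_names[j])
        n = self.n_specimens
        if n < MIN_SPECIMENS_HARD:
            report.add("warning",
                       f"only {n} specimens: below the floor of {MIN_SPECIMENS_HARD} "
                       "required for jackknife confidence intervals")
        elif n < MIN_SPECIMENS_RECOMMENDED:
            report.add("warning",
                       f"only {n} specimens: jackknife confidence intervals are "
                       f"unreliable below {MIN_SPECIMENS_RECOMMENDED}")
        return report
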