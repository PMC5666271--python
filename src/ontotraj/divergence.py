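"""Wild-vs-domestic divergence of multivariate allometry coefficients.

The divergence between two forms on one variable is the gap between their
jackknife confidence intervals: zero when the intervals intersect,
otherwise the distance between the nearer limits.  Summing the gaps over
the common variable set gives the "added change" of the pair, a
descriptive measure of how far the two ontogenetic trajectories have
drifted apart; the same sum taken per variable across pairs ranks the
measurements by how labile they are under domestication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .multivariate import MultivarResult
from .series import canonical_order

__all__ = [
    "interval_distance", "VariableDivergence", "PairDivergence",
    "pair_divergence", "DivergenceSummary", "divergence_summary",
]


def interval_distance(ci_a: tuple[float, float], ci_b: tuple[float, float]
                      ) -> tuple[float, bool]:
    """Gap between two closed intervals.

    Returns ``(distance, overlap)`` where distance is
    ``max(0, b.low - a.high, a.low - b.high)`` and overlap is True exactly
    when the intervals intersect (distance 0).
    """
    a_low, a_high = ci_a
    b_low, b_high = ci_b
    if a_low > a_high or b_low > b_high:
        raise ValueError("interval limits must satisfy low <= high")
    distance = max(0.0, b_low - a_high, a_low - b_high)
    return distance, distance == 0.0


@dataclass(frozen=True)
class VariableDivergence:
    variable: str
    distance: float
    overlap: bool
    sign_disagreement: bool
    wild_ci: tuple[float, float]
    domestic_ci: tuple[float, float]


@dataclass
class PairDivergence:
    """Per-variable CI gaps and their sum for one wild-domestic pair."""

    pair_id: str
    taxon_wild: str
    taxon_domestic: str
    variables: list[VariableDivergence] = field(default_factory=list)

    @property
    def added_change(self) -> float:
        return float(sum(v.distance for v in self.variables))

    @property
    def variable_names(self) -> list[str]:
        return [v.variable for v in self.variables]

    def distance(self, variable: str) -> float:
        for v in self.variables:
            if v.variable == variable:
                return v.distance
        raise KeyError(variable)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "pair": self.pair_id, "variable": v.variable,
            "distance": v.distance, "overlap": v.overlap,
            "sign_disagreement": v.sign_disagreement,
            "wild_ci_low": v.wild_ci[0], "wild_ci_high": v.wild_ci[1],
            "domestic_ci_low": v.domestic_ci[0], "domestic_ci_high": v.domestic_ci[1],
        } for v in self.variables]
        rows.append({"pair": self.pair_id, "variable": "added_change",
                     "distance": self.added_change, "overlap": None,
                     "sign_disagreement": None})
        return pd.DataFrame(rows)


def pair_divergence(wild: MultivarResult, domestic: MultivarResult
                    ) -> PairDivergence:
    """CI gaps between the mode-selected intervals of the two forms.

    Each form contributes the intervals of its own selected variant
    (untrimmed or trimmed).  Variables present in only one result are
    dropped with a warning; a variable can disagree in sign (e.g. P in one
    form, I in the other) while its gap is zero, which is flagged
    separately.  Symmetric in its arguments up to the wild/domestic
    labelling.
    """
    wild_vars = set(wild.variable_names)
    dom_vars = set(domestic.variable_names)
    shared = [v for v in canonical_order(wild.variable_names) if v in dom_vars]
    if wild_vars != dom_vars:
        dropped = sorted(wild_vars.symmetric_difference(dom_vars))
        warnings.warn(
            f"pair {wild.pair_id!r}: variable sets differ; restricting to "
            f"{len(shared)} shared variables (dropped: {dropped})", stacklevel=2)
    if not shared:
        raise ValueError(f"pair {wild.pair_id!r}: no shared variables")
    records = []
    for var in shared:
        cw = wild.coefficient(var)
        cd = domestic.coefficient(var)
        dist, overlap = interval_distance(cw.ci, cd.ci)
        records.append(VariableDivergence(
            variable=var, distance=dist, overlap=overlap,
            sign_disagreement=cw.sign != cd.sign,
            wild_ci=cw.ci, domestic_ci=cd.ci))
    return PairDivergence(
        pair_id=wild.pair_id, taxon_wild=wild.taxon_label,
        taxon_domestic=domestic.taxon_label, variables=records)


@dataclass
class DivergenceSummary:
    """Pairs-by-variables distance matrix with both marginal sums."""

    distances: pd.DataFrame  # index: pair_id; columns: variables; NaN = missing

    @property
    def added_change_per_pair(self) -> pd.Series:
        return self.distances.sum(axis=1, skipna=True).rename("added_change")

    @property
    def added_change_per_variable(self) -> pd.Series:
        return self.distances.sum(axis=0, skipna=True).rename("added_change")

    @property
    def ranking(self) -> list[str]:
        """Pair ids ordered from most to least diverged."""
        return list(self.added_change_per_pair.sort_values(ascending=False).index)

    @property
    def total(self) -> float:
        return float(np.nansum(self.distances.to_numpy()))

    def to_frame(self) -> pd.DataFrame:
        """Distance matrix with 'added_change' marginals appended."""
        table = self.distances.copy()
        table["added_change"] = self.added_change_per_pair
        margin = self.added_change_per_variable.copy()
        margin["added_change"] = self.total
        table.loc["added_change"] = margin
        table.index.name = "pair"
        return table


def divergence_summary(pairs: Sequence[PairDivergence]) -> DivergenceSummary:
    """Assemble per-pair divergences into the matrix-with-marginals view.

    Missing cells (variables absent from a pair) stay NaN and contribute
    nothing to either marginal sum.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    all_vars = canonical_order(
        dict.fromkeys(v for p in pairs for v in p.variable_names))
    matrix = pd.DataFrame(np.nan, index=[p.pair_id for p in pairs],
                          columns=all_vars)
    for p in pairs:
        for v in p.variables:
            matrix.loc[p.pair_id, v.variable] = v.distance
    return DivergenceSummary(matrix)
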