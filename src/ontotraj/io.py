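"""Reading and writing growth-series tables and stage results.

The input format is a wide CSV with one row per specimen: metadata columns
(specimen id, taxon, form, pair) followed by one column per measurement
variable (mm, decimal point '.').  Empty cells and ``NA`` are missing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .series import (
    CANONICAL_VARIABLES,
    FORMS,
    GrowthSeries,
    ValidationReport,
    canonical_order,
)

_ID_NAMES = ("specimen_id", "specimen", "id")
_TAXON_NAMES = ("taxon", "taxon_label", "species")
_FORM_NAMES = ("form",)
_PAIR_NAMES = ("pair", "pair_id")
_NA_STRINGS = {"", "na", "nan", "n/a", "?"}


def _find_column(columns: Sequence[str], candidates: Sequence[str], what: str) -> str:
    lower = {c.lower().strip(): c for c in columns}
    for cand in candidates:
        if cand in lower:
            return lower[cand]
    raise ValueError(f"no {what} column found (expected one of {candidates})")


def _parse_cell(raw: Any) -> tuple[float, str | None]:
    """Parse one measurement cell -> (value, error message or None)."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan, None
    text = str(raw).strip()
    if text.lower() in _NA_STRINGS:
        return np.nan, None
    try:
        value = float(text)
    except ValueError:
        return np.nan, f"non-numeric measurement {text!r}"
    if not np.isfinite(value):
        return np.nan, f"non-finite measurement {text!r}"
    if value <= 0:
        return np.nan, f"non-positive measurement {value!r}"
    return value, None


def read_growth_table(path: str | Path, *, sep: str = ",",
                      variables: Sequence[str] | None = None,
                      ) -> tuple[list[GrowthSeries], ValidationReport]:
    """Read a wide CSV of specimens and split it into one
    :class:`GrowthSeries` per (taxon, form).

    Parameters
    ----------
    path
        CSV file with header row.  Metadata columns are matched
        case-insensitively (``specimen_id``/``specimen``/``id``,
        ``taxon``/``species``, ``form``, ``pair``/``pair_id``); every other
        column is a measurement variable.
    sep
        Field separator (default comma).
    variables
        Optional restriction to a subset of measurement columns.

    Returns
    -------
    (series, report)
        Series in file order of first appearance; the report collects
        non-numeric / non-positive cells (errors) and structural problems.
        An error-free report is a precondition of every analysis stage.

    Notes
    -----
    Measurement columns whose codes match the 14 canonical skull codes are
    reordered canonically; unrecognised columns keep file order after them.
    A variable that is entirely missing within a series is dropped from that
    series and recorded in ``absent_variables`` (rendered ``?`` downstream).
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    report = ValidationReport()
    id_col = _find_column(raw.columns, _ID_NAMES, "specimen id")
    taxon_col = _find_column(raw.columns, _TAXON_NAMES, "taxon")
    form_col = _find_column(raw.columns, _FORM_NAMES, "form")
    pair_col = _find_column(raw.columns, _PAIR_NAMES, "pair")
    meta_cols = {id_col, taxon_col, form_col, pair_col}
    measure_cols = [c for c in raw.columns if c not in meta_cols]
    if variables is not None:
        wanted = {v.upper() for v in variables}
        measure_cols = [c for c in measure_cols if c.strip().upper() in wanted]
    if not measure_cols:
        raise ValueError("no measurement columns found")
    measure_cols = canonical_order([c.strip() for c in measure_cols])

    series_list: list[GrowthSeries] = []
    for (taxon, form), group in raw.groupby([taxon_col, form_col], sort=False):
        form_norm = str(form).strip().lower()
        if form_norm not in FORMS:
            report.add("error", f"unknown form {form!r} for taxon {taxon!r} "
                                f"(expected one of {FORMS})")
            continue
        pair_ids = {str(p).strip() for p in group[pair_col]}
        if len(pair_ids) > 1:
            report.add("error", f"taxon {taxon!r} ({form_norm}) maps to multiple "
                                f"pair ids: {sorted(pair_ids)}")
        pair_id = sorted(pair_ids)[0]
        specimen_ids = [str(s).strip() for s in group[id_col]]
        matrix = np.full((len(group), len(measure_cols)), np.nan)
        for i, (_, row) in enumerate(group.iterrows()):
            for j, col in enumerate(measure_cols):
                value, err = _parse_cell(row.get(col, ""))
                matrix[i, j] = value
                if err:
                    report.add("error", err, specimen_id=specimen_ids[i], variable=col)
        # drop all-missing columns into absent_variables
        present = ~np.isnan(matrix).all(axis=0)
        absent = [v for v, keep in zip(measure_cols, present) if not keep]
        kept = [v for v, keep in zip(measure_cols, present) if keep]
        series = GrowthSeries(
            taxon_label=str(taxon).strip(),
            form=form_norm,
            pair_id=pair_id,
            variable_names=kept,
            measurements=matrix[:, present],
            specimen_ids=specimen_ids,
            absent_variables=absent,
        )
        report.extend(series.validate())
        series_list.append(series)
    return series_list, report


def write_growth_table(series: Iterable[GrowthSeries], path: str | Path,
                       *, sep: str = ",") -> None:
    """Write series back to the wide CSV layout (round-trippable with
    :func:`read_growth_table` up to float formatting)."""
    frames = []
    for s in series:
        frame = s.to_frame().reset_index()
        frame.insert(1, "taxon", s.taxon_label)
        frame.insert(2, "form", s.form)
        frame.insert(3, "pair", s.pair_id)
        for v in s.absent_variables:
            frame[v] = np.nan
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    meta = ["specimen_id", "taxon", "form", "pair"]
    measures = canonical_order([c for c in table.columns if c not in meta])
    table = table[meta + measures]
    table.to_csv(path, sep=sep, index=False, float_format="%.17g")


def common_variables(wild: GrowthSeries, domestic: GrowthSeries,
                     *, min_n: int = 3) -> list[str]:
    """Variables usable in both members of a pair, canonical order.

    A variable qualifies when both forms have at least *min_n* non-missing
    measurements for it.  Raises ``ValueError`` on an empty intersection or
    when the two series do not share a pair id.
    """
    if wild.pair_id != domestic.pair_id:
        raise ValueError(
            f"series are not a pair: {wild.pair_id!r} vs {domestic.pair_id!r}")
    wild_ok = set(wild.present_variables(min_n))
    dom_ok = set(domestic.present_variables(min_n))
    shared = [v for v in canonical_order(wild.variable_names)
              if v in wild_ok and v in dom_ok]
    if not shared:
        raise ValueError(
            f"pair {wild.pair_id!r}: no variable has >= {min_n} measurements "
            "in both forms")
    return shared


def _to_serializable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_serializable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_serializable(v) for v in obj]
    return obj


def write_results(results: Any, path: str | Path, format: str = "tsv") -> None:
    """Serialise a stage output to TSV or JSON at full numeric precision.

    DataFrames (or objects exposing ``to_frame``) go to TSV; anything
    JSON-representable (dataclasses, dicts, lists, numpy scalars/arrays)
    goes to JSON.
    """
    path = Path(path)
    if format == "tsv":
        frame = results if isinstance(results, pd.DataFrame) else results.to_frame()
        frame.to_csv(path, sep="\t", index=isinstance(frame.index, pd.MultiIndex)
                     or frame.index.name is not None, float_format="%.17g")
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_to_serializable(results), fh, indent=2, allow_nan=True)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'json')")
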