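"""End-to-end orchestration: validate -> multivar -> divergence -> bivar ->
compare, plus rendering of the three study-style summary tables (per-form
sign table, pairs-by-variables added-change matrix, per-pair comparison
tallies)."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .bivariate import BivarConfig, SMAFit, run_bivar
from .comparison import PairResult, compare_pair
from .divergence import DivergenceSummary, PairDivergence, divergence_summary, pair_divergence
from .io import common_variables, read_growth_table, write_results
from .multivariate import MultivarConfig, MultivarResult, run_multivar
from .series import DOMESTIC, WILD, GrowthSeries, ValidationReport, canonical_order

__all__ = ["PipelineConfig", "PipelineBundle", "run_pipeline",
           "render_sign_table", "render_divergence_table",
           "render_comparison_summary"]

log = logging.getLogger("ontotraj")


@dataclass
class PipelineConfig:
    """Resolved settings for a pipeline run; serialisable as key=value
    text so every run can write the configuration it actually used."""

    alpha: float = 0.05
    ci_level: float = 0.95
    trim_mode: str = "auto"  # "auto" | "untrimmed" | "trimmed"
    trim_m: int = 1
    ci_multiplier: str = "t"
    sep: str = ","
    coefficient_decimals: int = 3
    pvalue_decimals: int = 4
    log_level: str = "INFO"

    def multivar(self) -> MultivarConfig:
        return MultivarConfig(trim_m=self.trim_m, ci_level=self.ci_level,
                              mode=self.trim_mode, ci_multiplier=self.ci_multiplier)

    def bivar(self) -> BivarConfig:
        return BivarConfig(alpha=self.alpha, ci_level=self.ci_level)

    # -- key=value (de)serialisation -----------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [f"{k}={v}" for k, v in dataclasses.asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            hint = str(types[key])
            if "int" in hint:
                kwargs[key] = int(value)
            elif "float" in hint:
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineBundle:
    """Everything a full run produces, at full numeric precision."""

    config: PipelineConfig
    series: list[GrowthSeries]
    report: ValidationReport
    multivar: dict[tuple[str, str], MultivarResult]  # (pair_id, form) -> result
    divergences: list[PairDivergence]
    divergence_summary: DivergenceSummary
    bivar: dict[tuple[str, str], list[SMAFit]]
    comparisons: dict[str, PairResult]  # pair_id -> result
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def pair_ids(self) -> list[str]:
        return sorted({s.pair_id for s in self.series})

    def sign_table(self) -> str:
        ordered = sorted(self.multivar.values(),
                         key=lambda r: (r.pair_id, r.form != WILD))
        return render_sign_table(ordered)

    def divergence_table(self) -> pd.DataFrame:
        return self.divergence_summary.to_frame()

    def comparison_summary(self) -> dict:
        return render_comparison_summary(list(self.comparisons.values()))


def render_sign_table(results: Sequence[MultivarResult],
                      variable_order: Sequence[str] | None = None) -> str:
    """Per-form sign table: one row per form with its positional sign
    string (missing variables as '?'), the U/T mode flag and P/I/N totals.
    Sign strings round-trip through ``parse_sign_string``."""
    if variable_order is None:
        seen: dict[str, None] = {}
        for r in results:
            for v in r.variable_names:
                seen.setdefault(v)
            for v in r.absent_variables:
                seen.setdefault(v)
        variable_order = canonical_order(seen)
    width = max((len(r.taxon_label) for r in results), default=10)
    header = f"{'form':<{width}}  mode  {'signs':<{len(variable_order)}}  totals"
    lines = [header]
    for r in results:
        signs = r.sign_string(variable_order)
        lines.append(f"{r.taxon_label:<{width}}  {r.mode_used:<4}  {signs}  "
                     f"{r.sign_pattern.totals_string}")
    return "\n".join(lines)


def render_divergence_table(summary: DivergenceSummary,
                            decimals: int = 3) -> str:
    """Added-change matrix (pairs x variables plus marginals) as TSV text,
    '?' for missing cells."""
    table = summary.to_frame().round(decimals)
    return table.to_csv(sep="\t", na_rep="?")


def render_comparison_summary(results: Sequence[PairResult]) -> dict:
    """Per-pair tallies of slope / intercept / shift differences."""
    return {r.pair_id: r.summary.to_dict() for r in results}


def _group_pairs(series: list[GrowthSeries]
                 ) -> dict[str, dict[str, GrowthSeries]]:
    pairs: dict[str, dict[str, GrowthSeries]] = {}
    for s in series:
        slot = pairs.setdefault(s.pair_id, {})
        if s.form in slot:
            raise ValueError(f"pair {s.pair_id!r} has two {s.form!r} series")
        slot[s.form] = s
    return pairs


def run_pipeline(source: str | Path | Sequence[GrowthSeries],
                 config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> PipelineBundle:
    """Run every stage over a growth table or pre-built series.

    Raises on validation errors or on pairs lacking one of the two forms.
    With *out_dir*, writes per-stage TSV/JSON outputs, the three rendered
    summaries and the resolved configuration next to them.
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if isinstance(source, (str, Path)):
        series, report = read_growth_table(source, sep=config.sep)
    else:
        series = list(source)
        report = ValidationReport()
        for s in series:
            report.extend(s.validate())
    report.raise_if_errors()
    timings["validate"] = time.perf_counter() - t0
    log.info("validated %d series (%d warnings)", len(series), len(report.warnings))

    pairs = _group_pairs(series)
    incomplete = [p for p, forms in pairs.items()
                  if WILD not in forms or DOMESTIC not in forms]
    if incomplete:
        raise ValueError(f"pairs lacking a wild or domestic series: {incomplete}")

    t0 = time.perf_counter()
    multivar: dict[tuple[str, str], MultivarResult] = {}
    for pair_id, forms in pairs.items():
        shared = common_variables(forms[WILD], forms[DOMESTIC])
        for form, s in forms.items():
            multivar[(pair_id, form)] = run_multivar(s, config.multivar(), shared)
    timings["multivar"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    divergences = [pair_divergence(multivar[(p, WILD)], multivar[(p, DOMESTIC)])
                   for p in sorted(pairs)]
    div_summary = divergence_summary(divergences)
    timings["divergence"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    bivar: dict[tuple[str, str], list[SMAFit]] = {}
    for pair_id, forms in pairs.items():
        shared = common_variables(forms[WILD], forms[DOMESTIC])
        bconf = config.bivar()
        bconf.proxy_set = shared
        for form, s in forms.items():
            bivar[(pair_id, form)] = run_bivar(s, bconf, shared)
    timings["bivar"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    comparisons = {p: compare_pair(forms[WILD], forms[DOMESTIC], config.bivar())
                   for p, forms in pairs.items()}
    timings["compare"] = time.perf_counter() - t0
    log.info("pipeline timings: %s",
             {k: f"{v:.2f}s" for k, v in timings.items()})

    bundle = PipelineBundle(config=config, series=series, report=report,
                            multivar=multivar, divergences=divergences,
                            divergence_summary=div_summary, bivar=bivar,
                            comparisons=comparisons, timings=timings)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: PipelineBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.config.to_file(out_dir / "config.txt")

    multivar_frame = pd.concat([r.to_frame() for r in bundle.multivar.values()],
                               ignore_index=True)
    write_results(multivar_frame, out_dir / "multivar.tsv", "tsv")

    (out_dir / "sign_table.txt").write_text(bundle.sign_table() + "\n",
                                            encoding="utf-8")
    (out_dir / "divergence.tsv").write_text(
        render_divergence_table(bundle.divergence_summary,
                                bundle.config.coefficient_decimals),
        encoding="utf-8")
    write_results(bundle.divergence_summary.to_frame(),
                  out_dir / "divergence_full.tsv", "tsv")

    bivar_rows = []
    for (pair_id, form), fits in bundle.bivar.items():
        for f in fits:
            bivar_rows.append({
                "pair": pair_id, "form": form, "variable": f.variable,
                "n": f.n, "slope": f.slope, "intercept": f.intercept,
                "r": f.r, "ci_low": f.slope_ci[0], "ci_high": f.slope_ci[1],
                "p_isometry": f.p_isometry, "trend": f.trend})
    write_results(pd.DataFrame(bivar_rows), out_dir / "bivar.tsv", "tsv")

    compare_frame = pd.concat([r.to_frame() for r in bundle.comparisons.values()],
                              ignore_index=True)
    write_results(compare_frame, out_dir / "comparisons.tsv", "tsv")

    with open(out_dir / "comparison_summary.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.comparison_summary(), fh, indent=2)
    log.info("wrote bundle to %s", out_dir)
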