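"""Synthetic growth series with known allometric structure.

Measurements follow the log-linear power-law growth model the pipeline
estimates: for latent size ``s`` of a specimen, variable k is

    log10 y_k = a_k + b_k * log10 s + eps_k,   eps_k ~ N(0, sigma_k^2)

with exponent ``b_k`` (1 = isometric), intercept ``a_k`` (log10 mm at
log10 s = 0) and independent lognormal measurement noise.  Latent sizes
are drawn log-uniformly over a range of at least 2x (growth series span
juveniles half the adult size or smaller), so log10 s has variance bounded
away from zero.  Scenario presets plant each heterochrony signature —
rate changes, intercept offsets and trajectory extensions — with effect
sizes large relative to the noise, providing ground truth for every
pipeline stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .series import CANONICAL_VARIABLES, DOMESTIC, GrowthSeries, WILD

__all__ = [
    "SyntheticSpec", "ScenarioPreset", "SCENARIO_NAMES", "generate_series",
    "scenario_preset", "generate_pair", "StudyFixture", "make_study_fixture",
    "DEFAULT_EXPONENTS", "DEFAULT_INTERCEPTS",
]

#: Default per-variable allometric exponents: positive allometry on the
#: facial/masticatory (splanchnocranial) measurements, negative on the
#: braincase and orbit (neurocranial), balanced to mean exactly 1 so the
#: geometric mean of all 14 variables is isometric to latent size.
DEFAULT_EXPONENTS: dict[str, float] = {
    "CPL": 1.05, "LN": 1.25, "HM": 1.15, "UPR": 1.10, "LP": 1.05,
    "BP": 0.90, "LO": 0.80, "ZB": 1.10, "BB": 0.70, "HO": 0.80,
    "LD": 1.10, "HD": 1.05, "HC": 1.20, "LPR": 0.75,
}

#: Default intercepts, log10 mm at log10 s = 0 (order-of-magnitude of
#: adult skull measurements).
DEFAULT_INTERCEPTS: dict[str, float] = {
    "CPL": 2.00, "LN": 1.55, "HM": 1.40, "UPR": 1.60, "LP": 1.70,
    "BP": 1.50, "LO": 1.35, "ZB": 1.80, "BB": 1.60, "HO": 1.40,
    "LD": 1.90, "HD": 1.30, "HC": 1.40, "LPR": 1.50,
}

SCENARIO_NAMES = (
    "acceleration", "deceleration", "pre_displacement", "post_displacement",
    "hypermorphosis", "hypomorphosis", "no_change", "isometric_null",
    "outlier_injection",
)


def _as_vector(value, variables: Sequence[str], name: str) -> np.ndarray:
    if isinstance(value, dict):
        return np.array([value[v] for v in variables], dtype=float)
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(len(variables), float(arr))
    if arr.shape != (len(variables),):
        raise ValueError(f"{name} must be scalar, dict or length-{len(variables)}")
    return arr


@dataclass
class SyntheticSpec:
    """Generating parameters for one form's growth series.

    size_range
        (s_min, s_max) of the latent size factor; the study design calls
        for at least a two-fold span (smallest specimens half the size of
        the largest or less).
    size_distribution
        ``"log_uniform"`` (default: log10 s uniform) or ``"uniform"``.
    shared_noise_sd
        Optional common size-error term added to every variable of a
        specimen (correlated noise); off by default.
    """

    form: str = WILD
    n: int = 80
    size_range: tuple[float, float] = (0.5, 2.0)
    exponents: object = 1.0  # scalar | dict | vector, per variable
    intercepts: object = None  # defaults to DEFAULT_INTERCEPTS
    noise_sd: object = 0.02
    size_distribution: str = "log_uniform"
    variable_names: tuple[str, ...] = CANONICAL_VARIABLES
    shared_noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        s_min, s_max = self.size_range
        if s_min <= 0 or s_max <= s_min:
            raise ValueError("size_range must satisfy 0 < s_min < s_max")
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.size_distribution not in ("log_uniform", "uniform"):
            raise ValueError(f"unknown size_distribution {self.size_distribution!r}")
        if self.intercepts is None:
            self.intercepts = {v: DEFAULT_INTERCEPTS.get(v, 1.5)
                               for v in self.variable_names}

    @property
    def exponent_vector(self) -> np.ndarray:
        return _as_vector(self.exponents, self.variable_names, "exponents")

    @property
    def intercept_vector(self) -> np.ndarray:
        return _as_vector(self.intercepts, self.variable_names, "intercepts")

    @property
    def noise_vector(self) -> np.ndarray:
        vec = _as_vector(self.noise_sd, self.variable_names, "noise_sd")
        if np.any(vec < 0):
            raise ValueError("noise_sd must be >= 0")
        return vec

    def with_changes(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


def generate_series(spec: SyntheticSpec, taxon_label: str = "synthetic",
                    pair_id: str = "pair01",
                    rng: np.random.Generator | None = None) -> GrowthSeries:
    """Draw one growth series from the power-law model of *spec*.

    Deterministic for a fixed ``spec.seed``; the generating parameters are
    recorded in the series metadata.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n
    s_min, s_max = spec.size_range
    if spec.size_distribution == "log_uniform":
        log_s = rng.uniform(np.log10(s_min), np.log10(s_max), size=n)
    else:
        log_s = np.log10(rng.uniform(s_min, s_max, size=n))
    b = spec.exponent_vector
    a = spec.intercept_vector
    sigma = spec.noise_vector
    eps = rng.standard_normal((n, len(b))) * sigma
    if spec.shared_noise_sd > 0:
        eps += rng.standard_normal((n, 1)) * spec.shared_noise_sd
    log_y = a + np.outer(log_s, b) + eps
    measurements = 10.0 ** log_y
    ids = [f"{pair_id}_{spec.form[0]}{i:03d}" for i in range(n)]
    return GrowthSeries(
        taxon_label=taxon_label, form=spec.form, pair_id=pair_id,
        variable_names=list(spec.variable_names), measurements=measurements,
        specimen_ids=ids,
        meta={"generator": "power_law", "spec": dataclasses.asdict(spec),
              "latent_log10_size": log_s.tolist()},
    )


@dataclass
class ScenarioPreset:
    """A wild/domestic spec pair with ground-truth labels.

    ``expected_labels`` names the variables whose heterochrony label is
    guaranteed by construction (effect sizes large relative to the noise
    at the preset n); untargeted variables are left unasserted because
    the geometric-mean proxy couples them weakly to the planted effect.
    """

    name: str
    wild: SyntheticSpec
    domestic: SyntheticSpec
    expected_labels: dict[str, str] = field(default_factory=dict)


# Effect sizes of the planted scenarios (log10 units or exponent units);
# chosen large against the default preset noise (sigma = 0.05, n = 80).
_RATE_EFFECT = 0.4        # exponent change for acceleration/deceleration
_INTERCEPT_EFFECT = 0.2   # log10 offset for pre/post-displacement
_EXTENSION_FACTOR = 2.0   # size-range shift for hyper/hypomorphosis
_OUTLIER_FACTOR = 3.0     # multiplicative error of the injected outlier


def scenario_preset(name: str, *, seed: int = 0, n: int = 80,
                    noise_sd: float = 0.05, target: str = "LN",
                    ) -> ScenarioPreset:
    """Build the named heterochrony scenario.

    All presets start from a shared isometric baseline (every exponent 1,
    default intercepts, log-uniform sizes over a four-fold range) and
    perturb only what the scenario requires: rate presets move the target
    variable's exponent, displacement presets its intercept, extension
    presets translate the domestic size range along the shared line, and
    ``outlier_injection`` corrupts one domestic specimen to exercise the
    trimmed jackknife.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    variables = CANONICAL_VARIABLES
    if target not in variables:
        raise ValueError(f"target {target!r} is not a canonical variable")
    seed = int(seed) % (2 ** 31)
    base = dict(n=n, size_range=(0.5, 2.0), exponents=1.0,
                noise_sd=noise_sd, variable_names=variables)
    wild = SyntheticSpec(form=WILD, seed=seed * 2 + 1, **base)
    domestic = SyntheticSpec(form=DOMESTIC, seed=seed * 2 + 2, **base)
    expected: dict[str, str] = {}
    k = variables.index(target)

    def _bump_exponent(delta: float) -> SyntheticSpec:
        b = np.ones(len(variables))
        b[k] += delta
        return domestic.with_changes(exponents=b)

    def _bump_intercept(delta: float) -> SyntheticSpec:
        a = np.array([DEFAULT_INTERCEPTS[v] for v in variables])
        a[k] += delta
        return domestic.with_changes(intercepts=a)

    if name == "acceleration":
        domestic = _bump_exponent(+_RATE_EFFECT)
        expected[target] = "acceleration"
    elif name == "deceleration":
        domestic = _bump_exponent(-_RATE_EFFECT)
        expected[target] = "deceleration"
    elif name == "pre_displacement":
        domestic = _bump_intercept(+_INTERCEPT_EFFECT)
        expected[target] = "pre_displacement"
    elif name == "post_displacement":
        domestic = _bump_intercept(-_INTERCEPT_EFFECT)
        expected[target] = "post_displacement"
    elif name == "hypermorphosis":
        lo, hi = domestic.size_range
        domestic = domestic.with_changes(
            size_range=(lo * _EXTENSION_FACTOR, hi * _EXTENSION_FACTOR))
        expected[target] = "hypermorphosis"
    elif name == "hypomorphosis":
        lo, hi = domestic.size_range
        domestic = domestic.with_changes(
            size_range=(lo / _EXTENSION_FACTOR, hi / _EXTENSION_FACTOR))
        expected[target] = "hypomorphosis"
    elif name == "no_change":
        expected[target] = "no_change"
    elif name == "isometric_null":
        for v in variables:
            expected[v] = "no_change"
    elif name == "outlier_injection":
        pass  # handled in generate_pair
    return ScenarioPreset(name=name, wild=wild, domestic=domestic,
                          expected_labels=expected)


def generate_pair(preset: ScenarioPreset | str, *, seed: int | None = None,
                  taxon: str = "synthetic", pair_id: str = "pair01",
                  ) -> tuple[GrowthSeries, GrowthSeries, dict[str, str]]:
    """Materialise a preset into (wild, domestic, expected labels)."""
    if isinstance(preset, str):
        preset = scenario_preset(preset, seed=seed or 0)
    elif seed is not None:
        preset = ScenarioPreset(
            preset.name,
            preset.wild.with_changes(seed=int(seed) % (2 ** 31) * 2 + 1),
            preset.domestic.with_changes(seed=int(seed) % (2 ** 31) * 2 + 2),
            dict(preset.expected_labels))
    wild = generate_series(preset.wild, f"{taxon} ({WILD})", pair_id)
    domestic = generate_series(preset.domestic, f"{taxon} ({DOMESTIC})", pair_id)
    if preset.name == "outlier_injection":
        # corrupt one domestic specimen by a gross multiplicative error on
        # every variable (a mismeasured or mislabelled specimen)
        domestic.measurements[0] *= _OUTLIER_FACTOR
        domestic.meta["injected_outlier"] = domestic.specimen_ids[0]
    return wild, domestic, dict(preset.expected_labels)


@dataclass
class StudyFixture:
    """Multi-pair dataset with planted ground truth."""

    series: list[GrowthSeries]
    truth: dict  # pair_id -> {"divergence_level": float, "exponents_*": ...}

    @property
    def pair_ids(self) -> list[str]:
        return sorted({s.pair_id for s in self.series})

    def pair(self, pair_id: str) -> tuple[GrowthSeries, GrowthSeries]:
        wild = next(s for s in self.series
                    if s.pair_id == pair_id and s.form == WILD)
        dom = next(s for s in self.series
                   if s.pair_id == pair_id and s.form == DOMESTIC)
        return wild, dom

    @property
    def planted_ranking(self) -> list[str]:
        """Pair ids ordered by planted divergence level, descending."""
        return sorted(self.truth, key=lambda p: -self.truth[p]["divergence_level"])


#: Zero-mean direction along which domestic exponent vectors are displaced
#: from the wild ones in the study fixture: facial variables speed up,
#: neurocranial variables slow down.
_DIVERGENCE_PATTERN: dict[str, float] = {
    "CPL": 0.5, "LN": 1.0, "HM": 0.5, "UPR": 1.0, "LP": -0.5,
    "BP": -0.5, "LO": -1.0, "ZB": 0.5, "BB": -1.0, "HO": -0.5,
    "LD": 0.5, "HD": -0.5, "HC": 1.0, "LPR": -1.0,
}


def make_study_fixture(n_pairs: int = 13, seed: int = 0, *,
                       n_per_form: int = 50, noise_sd: float = 0.02,
                       max_divergence: float = 0.4) -> StudyFixture:
    """Generate a study-shaped multi-pair dataset with planted divergences.

    Pair i receives a divergence level on a descending ladder from
    *max_divergence* to 0; its domestic exponent vector is the wild one
    displaced by level * pattern along a fixed zero-mean direction, so the
    planted added-change ordering across pairs is the ladder ordering.
    The truth dict records levels and generating vectors per pair.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    seed = int(seed) % (2 ** 31)
    variables = CANONICAL_VARIABLES
    pattern = np.array([_DIVERGENCE_PATTERN[v] for v in variables])
    levels = np.linspace(max_divergence, 0.0, n_pairs)
    series: list[GrowthSeries] = []
    truth: dict = {}
    for i, level in enumerate(levels):
        pair_id = f"pair{i + 1:02d}"
        b_wild = np.array([DEFAULT_EXPONENTS[v] for v in variables])
        b_dom = b_wild + level * pattern
        wild_spec = SyntheticSpec(
            form=WILD, n=n_per_form, exponents=b_wild, noise_sd=noise_sd,
            variable_names=variables, seed=(seed + 1000 * (i + 1)) % (2 ** 31))
        dom_spec = SyntheticSpec(
            form=DOMESTIC, n=n_per_form, exponents=b_dom, noise_sd=noise_sd,
            variable_names=variables, seed=(seed + 1000 * (i + 1) + 500) % (2 ** 31))
        series.append(generate_series(wild_spec, f"taxon{i + 1:02d} (wild)", pair_id))
        series.append(generate_series(dom_spec, f"taxon{i + 1:02d} (domestic)", pair_id))
        truth[pair_id] = {
            "divergence_level": float(level),
            "exponents_wild": b_wild.tolist(),
            "exponents_domestic": b_dom.tolist(),
        }
    return StudyFixture(series, truth)
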