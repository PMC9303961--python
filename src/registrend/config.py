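"""Scenario configuration for the synthetic registry generator.

A :class:`ScenarioConfig` fully determines a synthetic study: the stratum
grid (prefecture x diagnosis year x sex x 5-year age band), baseline
incidence and its log-linear trends, the histology and stage mixture models,
the two MAR missingness models (nonspecific histology coding, unknown or
missing stage), survival hazards and the person-year denominators.  The
default scenario emulates a three-prefecture Japanese lung-cancer registry
observed 1993-2015: roughly 60,000 expected cases, about 11% of cases coded
with a nonspecific morphology (8010/8046) and about 23.6% with unconfirmed
stage, declining over calendar time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

from .constants import ADC, HIST_GROUPS, LAC, OTHER_NSCLC, OTHER_UNSPEC, SEXES, SMC, SQC, STAGES


class ConfigError(ValueError):
    """Raised for an invalid or inconsistent scenario configuration."""


def default_age_bands(n: int = 18) -> tuple[str, ...]:
    """Five-year bands ``0-4`` ... ``85+`` (open-ended last band)."""
    bands = [f"{5 * i}-{5 * i + 4}" for i in range(n - 1)]
    bands.append(f"{5 * (n - 1)}+")
    return tuple(bands)


def age_to_band(age: int, bands: tuple[str, ...]) -> str:
    idx = min(int(age) // 5, len(bands) - 1)
    return bands[idx]


#: Baseline age-specific incidence (cases per 100,000 person-years) by sex.
#: Shaped like lung-cancer incidence: negligible below 40, rising steeply
#: with age; female rates roughly 40% of male.
_MALE_AGE_RATES = (
    0.1, 0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 4.0, 8.0,
    18.0, 40.0, 80.0, 150.0, 250.0, 380.0, 500.0, 600.0, 650.0,
)


@dataclass(frozen=True)
class MissingnessModel:
    """Logistic MAR model for one missingness indicator.

    The linear predictor is
    ``intercept + b_female*1[female] + b_age80*1[age>=80] + prefecture effect
    + b_year*(year - year0) + b_no_treatment*1[no primary treatment]
    + b_short_obs*1[obs < 1y]``.
    If ``target_rate`` is set, the intercept is re-solved at generation time
    so the population-average masking probability equals the target.
    """

    intercept: float = -2.0
    b_female: float = 0.0
    b_age80: float = 0.0
    prefecture_effects: dict = field(default_factory=dict)  # name -> log-odds
    b_year: float = 0.0
    year0: int = 1993
    b_no_treatment: float = 0.0
    b_short_obs: float = 0.0
    target_rate: Optional[float] = None
    # misuse knob: dependence on the *true* (masked) value makes the
    # mechanism MNAR; zero by default.
    mnar_effects: dict = field(default_factory=dict)  # true category -> log-odds


@dataclass(frozen=True)
class TrendSpec:
    """Piecewise log-linear multiplier on incidence for one series key.

    ``slope1``/``slope2`` are annual-percent-change-like values in percent;
    the multiplier is exp(b1*(t-t0)) up to ``change_year`` and continues with
    slope b2 afterwards, where b = ln(1 + slope/100).
    """

    slope1: float = 0.0
    slope2: Optional[float] = None
    change_year: Optional[int] = None


@dataclass(frozen=True)
class ScenarioConfig:
    prefectures: tuple[str, ...] = ("Yamagata", "Fukui", "Nagasaki")
    year_start: int = 1993
    year_end: int = 2015
    age_bands: tuple[str, ...] = field(default_factory=default_age_bands)
    sex_levels: tuple[str, ...] = SEXES
    #: person-years per (prefecture, year, sex, age-band) stratum
    m_population: float = 25_000.0
    #: per-sex multiplier on the age-rate schedule
    rate_scale: dict = field(default_factory=lambda: {"male": 1.0, "female": 0.42})
    #: per-sex age-band baseline rates, cases per 100,000 person-years
    base_rates: dict = field(default_factory=dict)
    #: (sex, histology) -> TrendSpec multiplier on incidence
    trend_spec: dict = field(default_factory=dict)
    #: per-sex softmax intercepts over the six histology groups
    histology_alpha: dict = field(default_factory=dict)
    #: per-group log-linear year slope of the histology mix (shared by sex)
    histology_beta: dict = field(default_factory=dict)
    #: per-histology softmax intercepts over the three stages
    stage_gamma: dict = field(default_factory=dict)
    #: per-stage year slope (stage shift) and age slope (per decade over 70)
    stage_delta_year: dict = field(
        default_factory=lambda: {"localized": 0.04, "regional": -0.02, "distant": 0.01}
    )
    stage_eps_age: dict = field(
        default_factory=lambda: {"localized": -0.08, "regional": 0.0, "distant": 0.08}
    )
    #: MAR models
    histology_missing: MissingnessModel = field(
        default_factory=lambda: MissingnessModel(
            b_female=0.25,
            b_age80=0.5,
            prefecture_effects={"Nagasaki": 0.4},
            b_no_treatment=0.6,
            b_short_obs=0.4,
            target_rate=0.110,
        )
    )
    stage_missing: MissingnessModel = field(
        default_factory=lambda: MissingnessModel(
            b_female=0.1,
            b_age80=0.6,
            prefecture_effects={"Nagasaki": 0.3},
            b_year=-0.05,
            b_no_treatment=0.5,
            target_rate=0.236,
        )
    )
    #: split of masked histology codes between 8010 and 8046 (true SMC cases
    #: are always coded 8010 because 8046 asserts non-small-cell)
    p_code_8046: float = 0.12
    #: split of masked stage labels between "unknown" and "missing"
    p_stage_unknown: float = 0.57
    #: per-stage exponential hazard (1/years), multiplied by histology factor
    survival_hazard_stage: dict = field(
        default_factory=lambda: {"localized": 0.08, "regional": 0.35, "distant": 1.2}
    )
    survival_hazard_hist: dict = field(
        default_factory=lambda: {SMC: 1.5, SQC: 1.0, ADC: 0.8, LAC: 1.2, OTHER_NSCLC: 1.0, OTHER_UNSPEC: 1.1}
    )
    censor_year: int = 2017
    #: probability a case is registered from a death certificate only
    dco_rate: float = 0.08
    #: Gini coefficient by prefecture (socioeconomic covariate stand-in)
    gini: dict = field(
        default_factory=lambda: {"Yamagata": 0.29, "Fukui": 0.27, "Nagasaki": 0.32}
    )
    seed: int = 20150101

    # ------------------------------------------------------------------
    def __post_init__(self):
        if not self.prefectures or not self.age_bands or not self.sex_levels:
            raise ConfigError("empty grid dimension (prefectures/age_bands/sexes)")
        if self.year_end < self.year_start:
            raise ConfigError("year_end precedes year_start")
        if self.m_population <= 0:
            raise ConfigError("person-years per stratum must be positive")
        for name, mm in (("histology", self.histology_missing), ("stage", self.stage_missing)):
            if mm.target_rate is not None and not (0.0 <= mm.target_rate <= 1.0):
                raise ConfigError(f"{name} missingness target outside [0, 1]")
        for h, f in self.survival_hazard_hist.items():
            if f <= 0:
                raise ConfigError(f"non-positive hazard factor for {h}")
        for s, hz in self.survival_hazard_stage.items():
            if hz <= 0:
                raise ConfigError(f"non-positive hazard for stage {s}")
        if not (0.0 <= self.p_code_8046 <= 1.0 and 0.0 <= self.p_stage_unknown <= 1.0):
            raise ConfigError("split probabilities must lie in [0, 1]")
        # populate derived defaults (frozen dataclass: use object.__setattr__)
        if not self.base_rates:
            rates = {}
            for sex in self.sex_levels:
                scale = self.rate_scale.get(sex, 1.0)
                sched = list(_MALE_AGE_RATES)[: len(self.age_bands)]
                while len(sched) < len(self.age_bands):
                    sched.append(sched[-1])
                rates[sex] = tuple(scale * r for r in sched)
            object.__setattr__(self, "base_rates", rates)
        if not self.histology_alpha:
            object.__setattr__(self, "histology_alpha", _default_hist_alpha())
        if not self.histology_beta:
            object.__setattr__(
                self,
                "histology_beta",
                {SMC: -0.010, SQC: -0.015, ADC: 0.015, LAC: -0.02, OTHER_NSCLC: 0.02, OTHER_UNSPEC: -0.005},
            )
        if not self.stage_gamma:
            object.__setattr__(self, "stage_gamma", _default_stage_gamma())

    # ------------------------------------------------------------------
    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.year_start, self.year_end + 1))

    def trend_multiplier(self, sex: str, histology: str, year: int) -> float:
        spec = self.trend_spec.get((sex, histology))
        if spec is None:
            return 1.0
        b1 = math.log1p(spec.slope1 / 100.0)
        t0 = self.year_start
        if spec.change_year is None or year <= spec.change_year:
            return math.exp(b1 * (year - t0))
        b2 = math.log1p((spec.slope2 or 0.0) / 100.0)
        return math.exp(b1 * (spec.change_year - t0) + b2 * (year - spec.change_year))

    def to_yaml(self, path) -> None:
        """Persist the scalar scenario settings (grid, calibration, seed)."""
        doc = {
            "prefectures": list(self.prefectures),
            "year_start": self.year_start,
            "year_end": self.year_end,
            "m_population": float(self.m_population),
            "rate_scale": dict(self.rate_scale),
            "p_code_8046": self.p_code_8046,
            "p_stage_unknown": self.p_stage_unknown,
            "censor_year": self.censor_year,
            "dco_rate": self.dco_rate,
            "gini": dict(self.gini),
            "histology_missing_target": self.histology_missing.target_rate,
            "stage_missing_target": self.stage_missing.target_rate,
            "trend_spec": {
                f"{sex}/{hist}": {
                    "slope1": ts.slope1, "slope2": ts.slope2, "change_year": ts.change_year,
                }
                for (sex, hist), ts in self.trend_spec.items()
            },
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        trend = {
            tuple(key.split("/", 1)): TrendSpec(**spec)
            for key, spec in (doc.pop("trend_spec", {}) or {}).items()
        }
        hist_target = doc.pop("histology_missing_target", None)
        stage_target = doc.pop("stage_missing_target", None)
        cfg = cls(
            prefectures=tuple(doc.pop("prefectures")),
            trend_spec=trend,
            **doc,
        )
        if hist_target is not None:
            cfg = replace(cfg, histology_missing=replace(cfg.histology_missing, target_rate=hist_target))
        if stage_target is not None:
            cfg = replace(cfg, stage_missing=replace(cfg.stage_missing, target_rate=stage_target))
        return cfg


def _default_hist_alpha() -> dict:
    """Softmax intercepts reproducing realistic per-sex histology mixes.

    Targets (over the six true groups): male roughly 11% SMC, 27% SQC,
    40% ADC, 3% LAC, 2% other NSCLC, 17% other/unspecified; female ADC-heavy.
    """
    male = {SMC: 0.11, SQC: 0.27, ADC: 0.40, LAC: 0.03, OTHER_NSCLC: 0.02, OTHER_UNSPEC: 0.17}
    female = {SMC: 0.05, SQC: 0.07, ADC: 0.65, LAC: 0.012, OTHER_NSCLC: 0.012, OTHER_UNSPEC: 0.206}
    return {
        "male": {h: math.log(male[h]) for h in HIST_GROUPS},
        "female": {h: math.log(female[h]) for h in HIST_GROUPS},
    }


def _default_stage_gamma() -> dict:
    """Per-histology stage-mix intercepts (observed-stage shares, Table-like)."""
    mix = {
        SMC: {"localized": 0.084, "regional": 0.335, "distant": 0.581},
        SQC: {"localized": 0.298, "regional": 0.431, "distant": 0.271},
        ADC: {"localized": 0.353, "regional": 0.284, "distant": 0.362},
        LAC: {"localized": 0.20, "regional": 0.28, "distant": 0.52},
        OTHER_NSCLC: {"localized": 0.22, "regional": 0.28, "distant": 0.50},
        OTHER_UNSPEC: {"localized": 0.22, "regional": 0.26, "distant": 0.52},
    }
    return {h: {s: math.log(mix[h][s]) for s in STAGES} for h in HIST_GROUPS}


def with_expected_cases(config: ScenarioConfig, n_cases: float) -> ScenarioConfig:
    """Rescale person-years so the scenario's expected case count is ``n_cases``."""
    from .synthetic import expected_case_count  # local import avoids a cycle

    current = expected_case_count(config)
    if current <= 0:
        raise ConfigError("scenario has zero expected cases; cannot rescale")
    return replace(config, m_population=config.m_population * n_cases / current)
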