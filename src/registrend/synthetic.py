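"""Synthetic population-based cancer-registry generator.

Case counts are Poisson given stratum person-years and a log-linear rate
surface; each case carries a true histology group, a true summary stage,
demographic/clinical covariates and exponential survival with
administrative censoring.  Two logistic missing-at-random models then mask
histology (replacing the code with nonspecific 8010 or 8046, which carry
candidate sets) and stage (labelled unknown or missing).  The pre-masking
values are returned in a separate truth table so downstream recovery tests
never peek at them by accident.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._rng import substream
from .config import ConfigError, MissingnessModel, ScenarioConfig, TrendSpec
from .constants import (
    CODE_CARCINOMA_NOS,
    CODE_NSC_CARCINOMA,
    HIST_GROUPS,
    SMC,
    STAGES,
)
from .recode import MorphologyMap, recode_histology, recode_stage

#: representative specific morphology code emitted for each true group
GROUP_CODES = {
    "SMC": 8041,
    "SQC": 8070,
    "ADC": 8140,
    "LAC": 8012,
    "other_NSCLC": 8560,
    "other_unspecified": 8000,
}

_YEAR_CENTER = 2004


def generate_population(config: ScenarioConfig) -> pd.DataFrame:
    """Person-year denominators, one positive entry per grid stratum."""
    idx = pd.MultiIndex.from_product(
        [config.prefectures, config.years, config.sex_levels, config.age_bands],
        names=["prefecture", "year", "sex", "age_band"],
    )
    pop = pd.DataFrame(index=idx).reset_index()
    pop["person_years"] = float(config.m_population)
    return pop


def _hist_mix(config: ScenarioConfig, sex: str, year: int) -> np.ndarray:
    a = np.array([config.histology_alpha[sex][h] for h in HIST_GROUPS])
    b = np.array([config.histology_beta[h] for h in HIST_GROUPS])
    t = year - _YEAR_CENTER
    logits = a + b * t
    p = np.exp(logits - logits.max())
    return p / p.sum()


def _intensity_table(config: ScenarioConfig) -> pd.DataFrame:
    """Expected case count per (prefecture, year, sex, age-band, histology)."""
    rows = []
    py = float(config.m_population)
    for sex in config.sex_levels:
        rates = np.asarray(config.base_rates[sex], dtype=float)
        for year in config.years:
            mix = _hist_mix(config, sex, year)
            tmult = np.array([config.trend_multiplier(sex, h, year) for h in HIST_GROUPS])
            lam_band_hist = np.outer(rates, mix * tmult) * py / 1e5  # bands x hist
            if lam_band_hist.sum(axis=1).max() > py:
                raise ConfigError("expected cases exceed person-years in a stratum")
            for pref in config.prefectures:
                rows.append((pref, sex, year, lam_band_hist))
    rec = []
    for pref, sex, year, lam in rows:
        for bi, band in enumerate(config.age_bands):
            for hi, h in enumerate(HIST_GROUPS):
                rec.append((pref, year, sex, band, h, lam[bi, hi]))
    return pd.DataFrame(rec, columns=["prefecture", "year", "sex", "age_band", "histology", "lam"])


def expected_case_count(config: ScenarioConfig) -> float:
    return float(_intensity_table(config)["lam"].sum())


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw; ``probs`` is (n, k) with rows summing to 1."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    return (u[:, None] > cum).sum(axis=1)


def _stage_probs(config: ScenarioConfig, hist: np.ndarray, year: np.ndarray, age: np.ndarray) -> np.ndarray:
    g = np.array([[config.stage_gamma[h][s] for s in STAGES] for h in HIST_GROUPS])
    order = {h: i for i, h in enumerate(HIST_GROUPS)}
    hidx = np.vectorize(order.get)(hist)
    logits = g[hidx]
    t = (year - _YEAR_CENTER)[:, None]
    a = ((age - 70.0) / 10.0)[:, None]
    logits = logits + t * np.array([config.stage_delta_year[s] for s in STAGES])
    logits = logits + a * np.array([config.stage_eps_age[s] for s in STAGES])
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def _missingness_probability(
    model: MissingnessModel,
    df: pd.DataFrame,
    true_values: pd.Series,
    eligible: np.ndarray | None = None,
) -> np.ndarray:
    """Per-case masking probability; ``eligible`` zeroes out cases whose true
    value no nonspecific code could represent (intercept calibration then
    targets the population-average rate including the ineligible zeros)."""
    eta = np.zeros(len(df))
    eta += model.b_female * (df["sex"].to_numpy() == "female")
    eta += model.b_age80 * (df["age_years"].to_numpy() >= 80)
    for pref, eff in model.prefecture_effects.items():
        eta += eff * (df["prefecture"].to_numpy() == pref)
    eta += model.b_year * (df["diag_year"].to_numpy() - model.year0)
    no_treat = ~(
        df["surgery"].to_numpy()
        | df["radiotherapy"].to_numpy()
        | df["chemotherapy"].to_numpy()
        | df["laparoscopy"].to_numpy()
    )
    eta += model.b_no_treatment * no_treat
    eta += model.b_short_obs * (df["obs_years"].to_numpy() < 1.0)
    for cat, eff in model.mnar_effects.items():
        eta += eff * (true_values.to_numpy() == cat)
    if eligible is None:
        eligible = np.ones(len(df))
    eligible = np.asarray(eligible, dtype=float)
    if model.target_rate is not None:
        if model.target_rate <= 0:
            return np.zeros(len(df))
        # solve the intercept so the average masking probability hits the target
        b0 = brentq(
            lambda b: (expit(eta + b) * eligible).mean() - model.target_rate, -30.0, 30.0
        )
    else:
        b0 = model.intercept
    if not np.isfinite(b0):
        return np.zeros(len(df))
    return expit(eta + b0)


def generate_registry(config: ScenarioConfig):
    """Generate (records, quality_table, truth) for one scenario.

    ``records`` is the masked registry (what an analyst would receive),
    already recoded: nonspecific codes carry candidate sets, masked stage is
    absent with an unknown/missing kind.  ``truth`` holds the pre-masking
    histology and stage keyed by case_id.
    """
    rng = substream(config.seed, "registry")
    intens = _intensity_table(config)
    counts = rng.poisson(intens["lam"].to_numpy())
    keep = counts > 0
    expanded = intens.loc[keep].reset_index(drop=True)
    reps = counts[keep]
    df = expanded.loc[expanded.index.repeat(reps)].reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise ConfigError("scenario produced zero cases")

    df = df.rename(columns={"year": "diag_year", "histology": "true_histology"})
    df = df.drop(columns=["lam"])

    # age uniform within band (top band 85-94)
    band_index = {b: i for i, b in enumerate(config.age_bands)}
    bi = df["age_band"].map(band_index).to_numpy()
    lo = 5 * bi
    width = np.where(bi == len(config.age_bands) - 1, 10, 5)
    df["age_years"] = lo + rng.integers(0, width, size=n)

    # true stage
    sp = _stage_probs(
        config,
        df["true_histology"].to_numpy(),
        df["diag_year"].to_numpy(dtype=float),
        df["age_years"].to_numpy(dtype=float),
    )
    df["true_stage"] = np.array(STAGES)[_draw_categorical(rng, sp)]

    # treatments and screening
    stage = df["true_stage"].to_numpy()
    hist = df["true_histology"].to_numpy()
    year = df["diag_year"].to_numpy()
    p_surg = np.select([stage == "localized", stage == "regional"], [0.70, 0.45], default=0.10)
    p_radio = np.select([stage == "localized", stage == "regional"], [0.10, 0.35], default=0.40)
    p_chemo = np.where(hist == SMC, 0.70, np.select([stage == "localized", stage == "regional"], [0.15, 0.45], default=0.60))
    df["surgery"] = rng.random(n) < p_surg
    df["radiotherapy"] = rng.random(n) < p_radio
    df["chemotherapy"] = rng.random(n) < p_chemo
    df["laparoscopy"] = rng.random(n) < 0.03
    p_screen = expit(-2.2 + 0.05 * (year - config.year_start) + 0.8 * (stage == "localized"))
    df["screening_detected"] = rng.random(n) < p_screen

    # survival: exponential hazard by stage x histology, censored administratively
    hz = (
        df["true_stage"].map(config.survival_hazard_stage).to_numpy()
        * df["true_histology"].map(config.survival_hazard_hist).to_numpy()
    )
    t_event = rng.exponential(1.0 / hz)
    c_admin = np.maximum(config.censor_year - year, 1).astype(float)
    dead = t_event <= c_admin
    obs = np.minimum(t_event, c_admin)

    # death-certificate-only registrations: no follow-up, improving over time
    p_dco = config.dco_rate * np.exp(-0.05 * (year - config.year_start)) / np.exp(-0.05 * 11)
    is_dco = rng.random(n) < np.clip(p_dco, 0, 1)
    obs = np.where(is_dco, 0.0, obs)
    dead = dead | is_dco
    df["obs_years"] = obs
    df["vital_status"] = np.where(dead, "dead", "alive")
    df["dco_flag"] = is_dco
    df["dcn_flag"] = is_dco | (rng.random(n) < 0.06)
    df["mv_flag"] = ~is_dco & (rng.random(n) < 0.78)

    df["case_id"] = [f"C{i:07d}" for i in range(n)]

    # quality covariates (empirical per prefecture-year) + Gini stand-in
    grp = df.groupby(["prefecture", "diag_year"])
    quality = grp.agg(
        dcn_pct=("dcn_flag", lambda s: 100.0 * s.mean()),
        dco_pct=("dco_flag", lambda s: 100.0 * s.mean()),
        mv_pct=("mv_flag", lambda s: 100.0 * s.mean()),
    ).reset_index()
    quality["gini"] = quality["prefecture"].map(config.gini) + 0.0005 * (
        quality["diag_year"] - _YEAR_CENTER
    )
    df = df.merge(quality, on=["prefecture", "diag_year"], how="left")

    # ---- masking ------------------------------------------------------
    # The nonspecific code is drawn first (8010 with probability 1-p_code_8046,
    # 8046 otherwise) and masking only goes through when the true group lies
    # in that code's candidate set (8010: any specific carcinoma group, i.e.
    # not other/unspecified; 8046 additionally excludes small-cell).  This
    # makes the observed code uninformative about the true group beyond the
    # candidate restriction — the missing-at-random structure the restricted
    # imputer assumes.  The calibration weight is the per-case probability
    # that the drawn code is admissible.
    truth_h = df["true_histology"].to_numpy()
    elig_8010 = truth_h != "other_unspecified"
    elig_8046 = elig_8010 & (truth_h != SMC)
    code_weight = (1 - config.p_code_8046) * elig_8010 + config.p_code_8046 * elig_8046
    p_hist = _missingness_probability(
        config.histology_missing, df, df["true_histology"], eligible=code_weight
    )
    p_stage = _missingness_probability(config.stage_missing, df, df["true_stage"])
    want_8046 = rng.random(n) < config.p_code_8046
    attempt = rng.random(n) < p_hist
    mask_hist = attempt & np.where(want_8046, elig_8046, elig_8010)
    mask_stage = rng.random(n) < p_stage

    # emitted morphology code: specific group code, or 8010/8046 when masked
    code = df["true_histology"].map(GROUP_CODES).to_numpy().copy()
    code = np.where(
        mask_hist, np.where(want_8046, CODE_NSC_CARCINOMA, CODE_CARCINOMA_NOS), code
    )
    df["morphology_code"] = code.astype(int)

    stage_raw = df["true_stage"].str.capitalize()
    kind_unknown = rng.random(n) < config.p_stage_unknown
    stage_raw = np.where(mask_stage, np.where(kind_unknown, "Unknown", ""), stage_raw)
    df["stage_raw"] = stage_raw

    truth = df[["case_id", "true_histology", "true_stage"]].copy()

    records = df.drop(columns=["true_histology", "true_stage"])
    records = recode_histology(records, MorphologyMap.default())
    records = recode_stage(records)
    col_order = [
        "case_id", "prefecture", "sex", "age_years", "age_band", "diag_year",
        "morphology_code", "histology_group", "histology_restriction",
        "stage", "stage_unknown_kind", "screening_detected",
        "surgery", "radiotherapy", "chemotherapy", "laparoscopy",
        "obs_years", "vital_status", "dco_flag", "dcn_flag", "mv_flag",
        "dcn_pct", "dco_pct", "mv_pct", "gini",
    ]
    records = records[col_order]
    return records, quality, truth


def inject_joinpoint_trend(
    config: ScenarioConfig,
    series_key: tuple[str, str],
    slope1: float,
    slope2: float | None = None,
    change_year: int | None = None,
) -> ScenarioConfig:
    """Return a config whose (sex, histology) incidence follows a piecewise
    log-linear trend: APC ``slope1`` (%) before ``change_year``, ``slope2``
    afterwards.  ``change_year`` must lie strictly inside the year range."""
    if change_year is not None and not (config.year_start < change_year < config.year_end):
        raise ConfigError("change_year must be strictly inside the year range")
    spec = dict(config.trend_spec)
    spec[tuple(series_key)] = TrendSpec(slope1=slope1, slope2=slope2, change_year=change_year)
    return replace(config, trend_spec=spec)
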