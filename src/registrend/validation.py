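"""Imputation validity and missingness diagnostics.

The survival check compares, within strata defined by diagnosis period,
sex, stage and histology, the follow-up of cases whose values were observed
against cases that were imputed into the stratum (majority-vote label over
the m completions), using the Kaplan-Meier log-rank test.  If the imputation
model is compatible with the data-generating mechanism, the two arms share
a survival distribution and the per-stratum rejection fraction stays near
the nominal level; masking that secretly depends on the masked value itself
inflates it.

Covariate/missingness associations are screened with Pearson chi-square
tests (categorical covariates) and Kruskal-Wallis rank-sum tests
(continuous covariates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .constants import DEFAULT_PERIODS
from .imputation import ImputedStack


class ValidationError(ValueError):
    pass


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate; columns time, survival."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("empty survival sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def logrank_compare(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank chi-square statistic (1 df) and p-value."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValidationError("log-rank comparison requires two non-empty groups")
    res = _ll_logrank(times_a, times_b, event_observed_A=np.asarray(events_a, dtype=bool),
                      event_observed_B=np.asarray(events_b, dtype=bool))
    return float(res.test_statistic), float(res.p_value)


@dataclass
class DiagnosticsReport:
    table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _period_of(year: int, periods) -> str:
    for lo, hi in periods:
        if lo <= year <= hi:
            return f"{lo}-{hi}"
    return "other"


def _majority_vote(stack: ImputedStack, col: str) -> pd.Series:
    votes = pd.concat([imp[col].astype(str) for imp in stack.imputations], axis=1)
    return votes.mode(axis=1)[0]


def validate_imputation(
    stack: ImputedStack,
    periods=DEFAULT_PERIODS,
    alpha: float = 0.05,
    min_arm: int = 10,
) -> DiagnosticsReport:
    """Stratified log-rank comparison of observed vs imputed-into-stratum cases.

    A case enters the "imputed" arm if any analysis value was masked; its
    stratum labels come from the majority-vote completion.  Strata with
    fewer than ``min_arm`` cases in either arm are skipped and counted.
    """
    orig = stack.original
    was_missing = orig["histology_group"].isna() | orig["stage"].isna()
    hist_label = orig["histology_group"].astype("string").copy()
    stage_label = orig["stage"].astype("string").copy()
    hist_label[hist_label.isna()] = _majority_vote(stack, "histology_group")[hist_label.isna()]
    stage_label[stage_label.isna()] = _majority_vote(stack, "stage")[stage_label.isna()]

    frame = pd.DataFrame(
        {
            "period": [_period_of(y, periods) for y in orig["diag_year"]],
            "sex": orig["sex"].astype(str),
            "stage": stage_label.astype(str),
            "histology": hist_label.astype(str),
            "time": orig["obs_years"].to_numpy(dtype=float),
            "event": orig["vital_status"].to_numpy() == "dead",
            "imputed": was_missing.to_numpy(),
        }
    )
    rows, skipped = [], 0
    for keys, sub in frame.groupby(["period", "sex", "stage", "histology"]):
        a = sub[~sub.imputed]
        b = sub[sub.imputed]
        if len(a) < min_arm or len(b) < min_arm:
            skipped += 1
            continue
        stat, p = logrank_compare(a.time, a.event, b.time, b.event)
        rows.append(
            {"period": keys[0], "sex": keys[1], "stage": keys[2], "histology": keys[3],
             "n_observed": len(a), "n_imputed": len(b), "statistic": stat, "p": p}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("p").reset_index(drop=True)
        mrank = np.arange(1, len(table) + 1)
        bh = np.minimum.accumulate((table["p"].to_numpy() * len(table) / mrank)[::-1])[::-1]
        table["p_bh"] = np.clip(bh, 0, 1)
    frac = float((table["p"] < alpha).mean()) if len(table) else np.nan
    return DiagnosticsReport(
        table=table,
        summary={"n_strata_tested": len(table), "n_strata_skipped": skipped,
                 "fraction_rejected": frac, "alpha": alpha},
    )


_CONTINUOUS = {"age_years", "obs_years", "dcn_pct", "dco_pct", "mv_pct", "gini", "diag_year"}


def missingness_diagnostics(records: pd.DataFrame, covariates) -> DiagnosticsReport:
    """Association tests between covariates and each missingness indicator."""
    indicators = {
        "histology_missing": records["histology_group"].isna().to_numpy(),
        "stage_missing": records["stage"].isna().to_numpy(),
    }
    rows = []
    for cov in covariates:
        values = records[cov]
        for ind_name, ind in indicators.items():
            if cov in _CONTINUOUS:
                groups = [values.to_numpy(dtype=float)[ind], values.to_numpy(dtype=float)[~ind]]
                stat, p = stats.kruskal(*groups)
                test = "kruskal-wallis"
                df = 1
            else:
                tab = pd.crosstab(values.astype(str), ind)
                stat, p, df, expected = stats.chi2_contingency(tab, correction=False)
                test = "chi-square"
                if (expected < 1).any():
                    # fall back to an exact test for sparse 2x2 tables
                    if tab.shape == (2, 2):
                        _, p = stats.fisher_exact(tab)
                        test = "fisher-exact"
            rows.append({"covariate": cov, "indicator": ind_name, "test": test,
                         "statistic": float(stat), "df": int(df), "p": float(p)})
    return DiagnosticsReport(table=pd.DataFrame(rows))


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a contingency table."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table, dtype=float), correction=False)
    return float(stat), float(p)
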