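"""Morphology/stage recoding and descriptive tabulation.

Raw registry rows carry an ICD-O morphology code and a free-text summary
stage.  Recoding maps the code to one of six histology groups, attaches a
candidate set instead of a group for the two nonspecific codes (8010:
carcinoma NOS, any group but other/unspecified; 8046: non-small-cell
carcinoma, additionally excluding small-cell), and normalizes stage to
localized/regional/distant with unknown and empty entries flagged as
missing values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .constants import (
    DEFAULT_PERIODS,
    HIST_GROUPS,
    STAGES,
    restriction_to_str,
)


class RecodeError(ValueError):
    pass


@dataclass(frozen=True)
class MorphologyMap:
    """Lookup from ICD-O morphology code to histology group or candidate set."""

    groups: dict = field(default_factory=dict)       # code -> group
    candidates: dict = field(default_factory=dict)   # code -> tuple of groups

    @classmethod
    def from_csv(cls, path) -> "MorphologyMap":
        df = pd.read_csv(path, dtype={"code": int, "group": "string", "candidates": "string"})
        groups, cands = {}, {}
        for row in df.itertuples(index=False):
            code = int(row.code)
            grp = None if pd.isna(row.group) or row.group == "" else str(row.group)
            cand = () if pd.isna(row.candidates) or row.candidates == "" else tuple(str(row.candidates).split("|"))
            if grp is not None and cand:
                raise RecodeError(f"code {code} maps to both a group and a candidate set")
            if grp is None and not cand:
                raise RecodeError(f"code {code} maps to neither a group nor a candidate set")
            if grp is not None:
                if grp not in HIST_GROUPS:
                    raise RecodeError(f"unknown histology group {grp!r} for code {code}")
                groups[code] = grp
            else:
                bad = set(cand) - set(HIST_GROUPS)
                if bad:
                    raise RecodeError(f"unknown groups in candidate set for {code}: {sorted(bad)}")
                cands[code] = cand
        return cls(groups=groups, candidates=cands)

    @classmethod
    def default(cls) -> "MorphologyMap":
        ref = importlib.resources.files("registrend.data").joinpath("morphology_map.csv")
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)


def recode_histology(records: pd.DataFrame, mmap: MorphologyMap | None = None) -> pd.DataFrame:
    """Fill ``histology_group`` / ``histology_restriction`` from morphology codes.

    Idempotent: re-running on recoded records reproduces the same columns.
    Raises :class:`RecodeError` listing every unmapped code.
    """
    mmap = mmap or MorphologyMap.default()
    out = records.copy()
    codes = out["morphology_code"].astype(int)
    known = set(mmap.groups) | set(mmap.candidates)
    unmapped = sorted(set(codes.unique()) - known)
    if unmapped:
        raise RecodeError(f"unmapped morphology codes: {unmapped}")
    group = codes.map(mmap.groups)
    restr = codes.map({c: restriction_to_str(v) for c, v in mmap.candidates.items()}).fillna("")
    out["histology_group"] = pd.array(group, dtype="string")
    out["histology_restriction"] = restr.astype(str)
    return out


_STAGE_ALIASES = {s.lower(): s for s in STAGES}


def recode_stage(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw stage strings to categories plus an unknown/missing kind."""
    out = records.copy()
    if "stage_raw" in out.columns:
        raw = out["stage_raw"].astype("string")
    else:
        # already-recoded input: reconstruct the raw vocabulary so a second
        # pass is a no-op (absent stage keeps its unknown/missing kind)
        raw = out["stage"].astype("string")
        if "stage_unknown_kind" in out.columns:
            unk = raw.isna() & (out["stage_unknown_kind"].astype(str) == "unknown")
            raw = raw.copy()
            raw[unk] = "Unknown"
    lowered = raw.str.strip().str.lower().fillna("")
    stage = lowered.map(_STAGE_ALIASES)
    kind = pd.Series("none", index=out.index, dtype="string")
    kind[lowered == "unknown"] = "unknown"
    kind[lowered == ""] = "missing"
    bad = lowered[~lowered.isin(list(_STAGE_ALIASES) + ["unknown", ""])]
    if len(bad):
        raise RecodeError(f"unrecognized stage strings: {sorted(bad.unique())}")
    out["stage"] = pd.array(stage, dtype="string")
    out["stage_unknown_kind"] = kind
    return out


# ----------------------------------------------------------------------
# Tabulation


@dataclass
class CaseTabulation:
    """Counts and row percentages by sex x diagnosis period x category."""

    margin: str
    periods: tuple[tuple[int, int], ...]
    table: pd.DataFrame  # columns: sex, period, category, count, pct

    def cell(self, sex: str, period: str, category: str) -> tuple[int, float]:
        t = self.table
        row = t[(t.sex == sex) & (t.period == period) & (t.category == category)]
        if row.empty:
            return 0, 0.0
        return int(row["count"].iloc[0]), float(row["pct"].iloc[0])


def _period_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def _histology_category(records: pd.DataFrame) -> pd.Series:
    cat = records["histology_group"].astype("string").copy()
    mask = cat.isna()
    cat[mask] = records.loc[mask, "morphology_code"].astype(int).astype(str)
    return cat


def _stage_category(records: pd.DataFrame) -> pd.Series:
    cat = records["stage"].astype("string").copy()
    mask = cat.isna()
    cat[mask] = records.loc[mask, "stage_unknown_kind"].astype(str)
    return cat


def tabulate_cases(
    records: pd.DataFrame,
    margin: str = "histology",
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS,
) -> CaseTabulation:
    """Tabulate recoded cases by sex and diagnosis period.

    ``margin`` is ``histology`` (six groups plus the 8010/8046 rows),
    ``stage`` (three stages plus unknown, missing, and their pooled
    ``unknown_missing`` row), or ``histology_x_stage``.  An ``overall``
    period column spanning all periods is always included.  Percentages are
    within (sex, period); the pooled unknown/missing row repeats its two
    parts and is excluded from the percentage base checksum.
    """
    yr = records["diag_year"].astype(int)
    edges = pd.IntervalIndex.from_tuples([(lo - 1, hi) for lo, hi in periods], closed="right")
    which = edges.get_indexer(yr)
    if (which < 0).any():
        bad = sorted(yr[which < 0].unique())
        raise RecodeError(f"diagnosis years outside all periods: {bad}")
    period = pd.Series([_period_label(*periods[i]) for i in which], index=records.index)

    if margin == "histology":
        cat = _histology_category(records)
    elif margin == "stage":
        cat = _stage_category(records)
    elif margin == "histology_x_stage":
        cat = _histology_category(records) + "/" + _stage_category(records)
    else:
        raise ValueError(f"unknown margin {margin!r}")

    df = pd.DataFrame({"sex": records["sex"].astype(str), "period": period, "category": cat.astype(str)})
    rows = []
    for per_label, sub in [("overall", df)] + [(p, df[df.period == p]) for p in sorted(df.period.unique())]:
        counts = sub.groupby(["sex", "category"], sort=True).size()
        totals = sub.groupby("sex").size()
        for (sex, category), n in counts.items():
            rows.append(
                {"sex": sex, "period": per_label, "category": category,
                 "count": int(n), "pct": 100.0 * n / totals[sex]}
            )
        if margin in ("stage", "histology_x_stage"):
            pooled = sub[sub.category.str.endswith(("unknown", "missing"))]
            key = pooled.groupby("sex").size() if margin == "stage" else None
            if margin == "stage":
                for sex, n in key.items():
                    rows.append(
                        {"sex": sex, "period": per_label, "category": "unknown_missing",
                         "count": int(n), "pct": 100.0 * n / totals[sex]}
                    )
    out = pd.DataFrame(rows)
    return CaseTabulation(margin=margin, periods=tuple(periods), table=out)
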