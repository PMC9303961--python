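"""Packaged descriptive-count fixture (histology- and stage-margin cases).

The bundled CSV holds published-style case counts for two sexes and four
diagnosis periods: eight histology rows (six specific groups plus the
nonspecific codes 8010 and 8046) and five stage rows (three stages plus
unknown and missing).  :func:`make_fixture_table1` expands each margin into
one pseudo-record per case so the tabulation arithmetic (shares, pooled
unknown/missing) can be checked by independent counting.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd


def _load_counts() -> pd.DataFrame:
    ref = importlib.resources.files("registrend.data").joinpath("table1_counts.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def make_fixture_table1() -> dict:
    """Return {'histology': records, 'stage': records} pseudo-record frames.

    Each frame has the columns tabulation needs (sex, diag_year,
    morphology_code, histology_group, stage, stage_unknown_kind); diag_year
    is the first year of the row's period, which places every case in the
    correct period bin.
    """
    counts = _load_counts()
    out = {}
    for variable, sub in counts.groupby("variable"):
        reps = sub["count"].to_numpy()
        df = sub.loc[sub.index.repeat(reps)].reset_index(drop=True)
        rec = pd.DataFrame({"sex": df["sex"].astype(str), "diag_year": df["period_start"].astype(int)})
        if variable == "histology":
            cat = df["category"].astype(str)
            nonspecific = cat.isin(["8010", "8046"])
            rec["morphology_code"] = np.where(nonspecific, cat, "0").astype(int)
            rec["histology_group"] = pd.array(np.where(nonspecific, pd.NA, cat), dtype="string")
            rec["stage"] = pd.array([pd.NA] * len(rec), dtype="string")
            rec["stage_unknown_kind"] = "missing"
        else:
            cat = df["category"].astype(str)
            absent = cat.isin(["unknown", "missing"])
            rec["morphology_code"] = 0
            rec["histology_group"] = pd.array([pd.NA] * len(rec), dtype="string")
            rec["stage"] = pd.array(np.where(absent, pd.NA, cat), dtype="string")
            rec["stage_unknown_kind"] = np.where(absent, cat, "none")
        out[variable] = rec
    return out


def fixture_totals() -> dict:
    counts = _load_counts()
    hist = counts[counts.variable == "histology"]
    return {
        sex: int(hist[hist.sex == sex]["count"].sum()) for sex in ("male", "female")
    } | {"total": int(hist["count"].sum())}
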