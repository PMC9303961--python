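"""Restricted fully-conditional-specification multiple imputation.

Histology and stage are imputed by chained equations: each sweep refits a
baseline-category multinomial logistic model for stage given covariates and
the current histology completion, redraws the absent stages, then does the
same for histology given covariates and the current stage completion.  The
restriction amendment constrains each draw to the record's candidate set
(8010: five of six groups, excluding other/unspecified; 8046: four of six,
additionally excluding small-cell) by zeroing the disallowed categories'
predicted probabilities and renormalizing before drawing.

:func:`rubin_pool` implements the combining rules for pooling any scalar
statistic across the m completed datasets: the point estimate is the
arithmetic mean, the total variance is the within-imputation mean variance
plus (1 + 1/m) times the between-imputation variance.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from ._rng import substream
from .constants import HIST_GROUPS, STAGES, restriction_from_str


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class ImputationSpec:
    m: int = 20
    n_cycles: int = 10
    #: continuous diagnosis-year term by default; "categorical-period" switches
    #: to indicator coding of the descriptive periods
    diag_year_treatment: str = "linear"
    #: how the candidate-set restriction is enforced for histology draws:
    #: "renormalize" zeroes the full model's disallowed probabilities;
    #: "refit" fits a separate conditional over each candidate set
    restriction_mode: str = "renormalize"
    covariates: tuple[str, ...] = (
        "prefecture", "diag_year", "age_years", "sex", "screening_detected",
        "surgery", "radiotherapy", "chemotherapy", "laparoscopy",
        "obs_years", "vital_status", "dcn_pct", "dco_pct", "mv_pct", "gini",
    )
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ImputationError("m must be at least 2")
        if self.n_cycles < 1:
            raise ImputationError("n_cycles must be at least 1")
        if not self.covariates:
            raise ImputationError("covariate list is empty")
        if self.restriction_mode not in ("renormalize", "refit"):
            raise ImputationError("restriction_mode must be 'renormalize' or 'refit'")


@dataclass
class ImputedStack:
    """m completed registry copies plus the original (masked) records."""

    original: pd.DataFrame
    imputations: list
    spec: ImputationSpec
    seed: int

    def __len__(self) -> int:
        return len(self.imputations)

    @property
    def provenance(self) -> dict:
        h = hashlib.sha256(repr(self.spec).encode()).hexdigest()[:16]
        return {"m": len(self.imputations), "seed": self.seed, "spec_hash": h}


@dataclass(frozen=True)
class PooledEstimate:
    point: float
    within: float
    between: float
    total: float
    m: int
    df: float
    infinite_df: bool = False


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Combine m estimates and their variances by the combining rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim != 1 or q.shape != u.shape or q.size < 2:
        raise ImputationError("need m >= 2 aligned estimates and variances")
    if (u < 0).any():
        raise ImputationError("negative variance")
    m = q.size
    qbar = q.mean()
    w = u.mean()
    b = q.var(ddof=1)
    t = w + (1 + 1 / m) * b
    if b == 0:
        return PooledEstimate(qbar, w, 0.0, t, m, np.inf, infinite_df=True)
    with np.errstate(over="ignore"):
        df = (m - 1) * (1 + w / ((1 + 1 / m) * b)) ** 2
    return PooledEstimate(qbar, w, b, t, m, df)


# ----------------------------------------------------------------------
# Conditional models

_TARGET_CATEGORIES = {"stage": STAGES, "histology": HIST_GROUPS}
_TARGET_COLUMN = {"stage": "stage", "histology": "histology_group"}


def _design_matrix(records: pd.DataFrame, spec: ImputationSpec, other_col: str | None,
                   other_cats: tuple[str, ...] | None) -> tuple[np.ndarray, list[str]]:
    cols, names = [], []

    def add(name, values):
        cols.append(np.asarray(values, dtype=float))
        names.append(name)

    cov = set(spec.covariates)
    if "prefecture" in cov:
        prefs = sorted(records["prefecture"].unique())
        for p in prefs[1:]:
            add(f"prefecture[{p}]", records["prefecture"].to_numpy() == p)
    if "diag_year" in cov:
        if spec.diag_year_treatment == "linear":
            add("diag_year", (records["diag_year"].to_numpy() - 2004) / 10.0)
        else:
            from .constants import DEFAULT_PERIODS

            yr = records["diag_year"].to_numpy()
            for lo, hi in DEFAULT_PERIODS[1:]:
                add(f"period[{lo}-{hi}]", (yr >= lo) & (yr <= hi))
    if "age_years" in cov:
        age = records["age_years"].to_numpy(dtype=float)
        add("age", (age - 70.0) / 10.0)
        add("age80", age >= 80)  # masking is elevated in the oldest patients
    if "sex" in cov:
        add("female", records["sex"].to_numpy() == "female")
    for flag in ("screening_detected", "surgery", "radiotherapy", "chemotherapy", "laparoscopy"):
        if flag in cov:
            add(flag, records[flag].to_numpy(dtype=bool))
    if "obs_years" in cov:
        add("obs_years", np.log1p(records["obs_years"].to_numpy(dtype=float)))
    if "vital_status" in cov:
        add("dead", records["vital_status"].to_numpy() == "dead")
    for q in ("dcn_pct", "dco_pct", "mv_pct"):
        if q in cov:
            add(q, records[q].to_numpy(dtype=float) / 100.0)
    if "gini" in cov:
        add("gini", records["gini"].to_numpy(dtype=float))
    if other_col is not None:
        other = records[other_col].astype("string").to_numpy()
        for c in other_cats[1:]:
            add(f"{other_col}[{c}]", other == c)
    if not cols:
        return np.empty((len(records), 0)), names
    X = np.column_stack(cols)
    return X, names


@dataclass
class FittedConditional:
    """Predicts category probabilities for the target's full category set."""

    categories: tuple[str, ...]
    feature_names: list[str]
    _model: object = None
    _marginal: np.ndarray | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._marginal is not None:
            return np.tile(self._marginal, (X.shape[0], 1))
        return self._model.predict_proba(X)


def fit_conditional(
    records: pd.DataFrame,
    target: str,
    spec: ImputationSpec,
    warm_cache: dict | None = None,
    categories: tuple[str, ...] | None = None,
) -> FittedConditional:
    """Fit the multinomial conditional for ``target`` on its observed rows.

    The other imputed variable enters as a predictor using its current
    completion.  With an empty covariate design (intercept only) the exact
    MLE — the observed category frequencies — is returned directly.
    ``warm_cache`` lets successive sweeps warm-start the lbfgs solver from
    the previous fit for the same target (the refitted data differ only in
    the redrawn completions, so few iterations are needed).
    """
    if target not in _TARGET_CATEGORIES:
        raise ImputationError(f"unknown target {target!r}")
    cats = tuple(categories) if categories is not None else tuple(_TARGET_CATEGORIES[target])
    col = _TARGET_COLUMN[target]
    other = "histology_group" if target == "stage" else "stage"
    other_cats = HIST_GROUPS if target == "stage" else STAGES
    use_other = not records[other].isna().any() and spec.covariates != ("intercept",)
    obs = records[records[col].notna()]
    if categories is not None:
        obs = obs[obs[col].astype(str).isin(cats)]
    y = obs[col].astype(str).to_numpy()
    present = set(np.unique(y))
    missing_cats = [c for c in cats if c not in present]
    if missing_cats:
        raise ImputationError(f"no observed records for categories {missing_cats}")
    X, names = _design_matrix(obs, spec, other if use_other else None,
                              other_cats if use_other else None)
    if X.shape[1] == 0:
        freq = np.array([(y == c).mean() for c in cats])
        return FittedConditional(cats, names, _marginal=freq)
    # constant (degenerate) columns make the design singular
    const = [nm for nm, v in zip(names, X.T) if np.ptp(v) == 0]
    if const:
        raise ImputationError(f"constant covariate column(s) in design: {const}")
    cache_key = (target, cats)
    model = None
    if warm_cache is not None:
        model = warm_cache.get(cache_key)
    if model is None:
        model = LogisticRegression(
            penalty=None, solver="lbfgs", max_iter=300, tol=1e-4, warm_start=True
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    if warm_cache is not None:
        warm_cache[cache_key] = model
    # reorder class axis to the canonical category order
    class_order = list(model.classes_)
    perm = [class_order.index(c) for c in cats]

    class _Wrapped:
        def predict_proba(self, Xq):
            return model.predict_proba(Xq)[:, perm]

    return FittedConditional(cats, names, _model=_Wrapped())


def restricted_draw(probabilities: np.ndarray, candidate_mask: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row with disallowed categories zeroed out.

    ``probabilities`` is (n, k); ``candidate_mask`` a boolean (n, k) with at
    least one True per row.  Rows whose allowed probabilities all vanish fall
    back to a uniform draw over the candidate set.
    """
    p = np.asarray(probabilities, dtype=float)
    mask = np.asarray(candidate_mask, dtype=bool)
    if p.ndim == 1:
        p = p[None, :]
        mask = mask[None, :]
    if not mask.any(axis=1).all():
        raise ImputationError("empty candidate set")
    p = np.where(mask, p, 0.0)
    tot = p.sum(axis=1, keepdims=True)
    degenerate = tot[:, 0] <= 0
    if degenerate.any():
        p[degenerate] = mask[degenerate].astype(float)
        tot = p.sum(axis=1, keepdims=True)
    p = p / tot
    u = rng.random(p.shape[0])
    cum = np.cumsum(p, axis=1)
    return (u[:, None] > cum).sum(axis=1)


def _candidate_masks(records: pd.DataFrame, target: str, rows: np.ndarray) -> np.ndarray:
    cats = _TARGET_CATEGORIES[target]
    if target == "stage":
        return np.ones((rows.sum(), len(cats)), dtype=bool)
    restr = records.loc[rows, "histology_restriction"].to_numpy()
    mask = np.zeros((len(restr), len(cats)), dtype=bool)
    cat_index = {c: i for i, c in enumerate(cats)}
    for i, s in enumerate(restr):
        allowed = restriction_from_str(s)
        if not allowed:
            raise ImputationError("record with absent histology has no candidate set")
        for c in allowed:
            mask[i, cat_index[c]] = True
    return mask


def impute_once(
    records: pd.DataFrame,
    spec: ImputationSpec,
    imputation_index: int = 0,
    warm_cache: dict | None = None,
) -> pd.DataFrame:
    """One completed copy of the registry (deterministic in seed and index)."""
    rng = substream(spec.seed, "imputation", imputation_index)
    out = records.copy()
    miss_stage = out["stage"].isna().to_numpy()
    miss_hist = out["histology_group"].isna().to_numpy()
    if not miss_stage.any() and not miss_hist.any():
        return out

    # initialize from observed marginal frequencies (restricted)
    for target, miss in (("stage", miss_stage), ("histology", miss_hist)):
        if not miss.any():
            continue
        col = _TARGET_COLUMN[target]
        cats = _TARGET_CATEGORIES[target]
        obs_vals = out.loc[~miss, col].astype(str).to_numpy()
        freq = np.array([(obs_vals == c).mean() for c in cats])
        cmask = _candidate_masks(out, target, miss)
        draws = restricted_draw(np.tile(freq, (miss.sum(), 1)), cmask, rng)
        out.loc[miss, col] = np.array(cats)[draws]

    for _cycle in range(spec.n_cycles):
        for target, miss in (("stage", miss_stage), ("histology", miss_hist)):
            if not miss.any():
                continue
            col = _TARGET_COLUMN[target]
            cats = _TARGET_CATEGORIES[target]
            fit_frame = out.copy()
            fit_frame.loc[miss, col] = pd.NA  # fit on originally-observed rows
            other = "histology_group" if target == "stage" else "stage"
            other_cats = HIST_GROUPS if target == "stage" else STAGES
            if target == "histology" and spec.restriction_mode == "refit":
                # one restricted-category conditional per distinct candidate set
                new_vals = pd.Series(index=out.index[miss], dtype="string")
                restr = out.loc[miss, "histology_restriction"]
                for rstr, idx in restr.groupby(restr).groups.items():
                    rcats = tuple(restriction_from_str(rstr))
                    sub_model = fit_conditional(
                        fit_frame, target, spec, warm_cache=warm_cache, categories=rcats
                    )
                    Xsub, _ = _design_matrix(out.loc[idx], spec, other, other_cats)
                    probs = sub_model.predict_proba(Xsub)
                    sub_rng_draws = restricted_draw(
                        probs, np.ones_like(probs, dtype=bool), rng
                    )
                    new_vals.loc[idx] = np.array(rcats)[sub_rng_draws]
                out.loc[miss, col] = new_vals
            else:
                model = fit_conditional(fit_frame, target, spec, warm_cache=warm_cache)
                Xmiss, _ = _design_matrix(out.loc[miss], spec, other, other_cats)
                probs = model.predict_proba(Xmiss)
                cmask = _candidate_masks(out, target, miss)
                draws = restricted_draw(probs, cmask, rng)
                out.loc[miss, col] = np.array(cats)[draws]
    return out


def multiple_impute(records: pd.DataFrame, spec: ImputationSpec) -> ImputedStack:
    """m completed copies from independent RNG substreams."""
    warm_cache: dict = {}
    imputations = [impute_once(records, spec, i, warm_cache=warm_cache) for i in range(spec.m)]
    return ImputedStack(original=records, imputations=imputations, spec=spec, seed=spec.seed)
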