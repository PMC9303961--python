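"""Restricted draws, chained-equation behaviour and the combining rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from registrend._rng import substream
from registrend.constants import HIST_GROUPS, SMC, STAGES
from registrend.imputation import (
    ImputationError,
    ImputationSpec,
    fit_conditional,
    impute_once,
    multiple_impute,
    restricted_draw,
    rubin_pool,
)


# ----------------------------------------------------------------------
# restricted_draw


def test_singleton_candidate_set_is_certain():
    rng = substream(0, "t")
    p = np.array([0.2, 0.2, 0.2, 0.2, 0.1, 0.1])
    mask = np.array([True, False, False, False, False, False])
    draws = [restricted_draw(p, mask, rng)[0] for _ in range(50)]
    assert set(draws) == {0}


def test_renormalization_spreads_uniformly_over_candidates():
    rng = substream(1, "t")
    n = 10_000
    p = np.tile(np.full(6, 1 / 6), (n, 1))
    mask = np.tile([False, True, True, True, True, False], (n, 1))
    draws = restricted_draw(p, mask, rng)
    freq = np.bincount(draws, minlength=6) / n
    assert freq[0] == 0 and freq[5] == 0
    np.testing.assert_allclose(freq[1:5], 0.25, atol=0.02)


def test_smc_never_drawn_under_8046_restriction():
    rng = substream(2, "t")
    n = 10_000
    smc_idx = HIST_GROUPS.index(SMC)
    p = np.tile(np.array([0.4, 0.2, 0.2, 0.1, 0.05, 0.05]), (n, 1))
    mask = np.ones((n, 6), dtype=bool)
    mask[:, smc_idx] = False
    mask[:, HIST_GROUPS.index("other_unspecified")] = False
    draws = restricted_draw(p, mask, rng)
    assert not (draws == smc_idx).any()


def test_zero_probability_candidates_fall_back_to_uniform():
    rng = substream(3, "t")
    p = np.array([0.5, 0.5, 0.0, 0.0])
    mask = np.array([False, False, True, True])
    draws = np.array([restricted_draw(p, mask, rng)[0] for _ in range(2000)])
    assert set(draws) <= {2, 3}
    assert abs((draws == 2).mean() - 0.5) < 0.05


def test_empty_candidate_set_raises():
    with pytest.raises(ImputationError):
        restricted_draw(np.array([1.0, 0.0]), np.array([False, False]), substream(4, "t"))


# ----------------------------------------------------------------------
# rubin_pool


def test_rubin_pool_matches_hand_computation():
    pe = rubin_pool([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
    assert pe.point == pytest.approx(2.0, abs=1e-12)
    assert pe.within == pytest.approx(1.0, abs=1e-12)
    assert pe.between == pytest.approx(1.0, abs=1e-12)
    assert pe.total == pytest.approx(7.0 / 3.0, abs=1e-12)
    assert pe.df == pytest.approx(2 * (1 + 1 / (4 / 3)) ** 2, abs=1e-9)


def test_identical_estimates_give_zero_between_variance_and_infinite_df():
    pe = rubin_pool([5.0] * 4, [0.04] * 4)
    assert pe.point == 5.0
    assert pe.between == 0.0
    assert pe.total == 0.04
    assert pe.infinite_df and np.isinf(pe.df)


def test_rubin_pool_rejects_degenerate_input():
    with pytest.raises(ImputationError):
        rubin_pool([1.0], [1.0])
    with pytest.raises(ImputationError):
        rubin_pool([1.0, 2.0], [1.0, -1.0])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    q=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30),
    seed=st.integers(0, 10_000),
)
def test_rubin_total_variance_dominates_within(q, seed):
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, 10, size=len(q))
    pe = rubin_pool(q, u)
    assert pe.total >= pe.within - 1e-9
    assert pe.total == pytest.approx(pe.within + (1 + 1 / pe.m) * pe.between, abs=1e-12 * max(1, abs(pe.total)))
    assert pe.point == pytest.approx(np.mean(q), rel=1e-12, abs=1e-12)


# ----------------------------------------------------------------------
# conditional models


def _toy_records(n, rng, signal=0.0):
    year = rng.integers(1993, 2016, n)
    female = rng.random(n) < 0.5
    logits = np.zeros((n, 3))
    logits[:, 1] = signal * female
    logits[:, 2] = -signal * female
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    stage = np.array(STAGES)[(rng.random(n)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)]
    hist = rng.choice(HIST_GROUPS, n)
    return pd.DataFrame(
        {
            "prefecture": rng.choice(["A", "B"], n),
            "sex": np.where(female, "female", "male"),
            "age_years": rng.integers(40, 90, n),
            "diag_year": year,
            "screening_detected": rng.random(n) < 0.2,
            "surgery": rng.random(n) < 0.5,
            "radiotherapy": rng.random(n) < 0.3,
            "chemotherapy": rng.random(n) < 0.4,
            "laparoscopy": rng.random(n) < 0.05,
            "obs_years": rng.exponential(2, n),
            "vital_status": np.where(rng.random(n) < 0.5, "dead", "alive"),
            "dcn_pct": rng.uniform(5, 25, n),
            "dco_pct": rng.uniform(2, 15, n),
            "mv_pct": rng.uniform(60, 90, n),
            "gini": rng.uniform(0.25, 0.35, n),
            "stage": pd.array(stage, dtype="string"),
            "histology_group": pd.array(hist, dtype="string"),
            "histology_restriction": "",
        }
    )


def test_intercept_only_model_returns_exact_frequencies():
    rng = np.random.default_rng(0)
    rec = _toy_records(2000, rng)
    spec = ImputationSpec(seed=0, covariates=("intercept",))
    fit = fit_conditional(rec, "stage", spec)
    probs = fit.predict_proba(np.empty((3, 0)))
    expected = [(rec["stage"] == s).mean() for s in STAGES]
    np.testing.assert_allclose(probs[0], expected, atol=1e-12)


def test_null_model_predicts_balanced_probabilities():
    rng = np.random.default_rng(1)
    rec = _toy_records(10_000, rng, signal=0.0)
    spec = ImputationSpec(seed=0)
    fit = fit_conditional(rec, "stage", spec)
    from registrend.imputation import _design_matrix

    X, _ = _design_matrix(rec, spec, "histology_group", HIST_GROUPS)
    probs = fit.predict_proba(X)
    np.testing.assert_allclose(probs.mean(axis=0), 1 / 3, atol=0.02)


def test_conditional_model_agrees_with_statsmodels_oracle():
    """Dual route: the lbfgs fit must match an independent MNLogit MLE."""
    smd = pytest.importorskip("statsmodels.discrete.discrete_model")
    rng = np.random.default_rng(2)
    rec = _toy_records(5000, rng, signal=0.8)
    spec = ImputationSpec(seed=0, covariates=("sex", "age_years"))
    fit = fit_conditional(rec, "stage", spec)
    from registrend.imputation import _design_matrix

    X, _ = _design_matrix(rec, spec, "histology_group", HIST_GROUPS)
    probs = fit.predict_proba(X)
    y = pd.Categorical(rec["stage"].astype(str), categories=STAGES).codes
    Xc = np.column_stack([np.ones(len(rec)), X])
    sm_fit = smd.MNLogit(y, Xc).fit(disp=0)
    sm_probs = sm_fit.predict(Xc)
    assert np.abs(probs - sm_probs).max() < 1e-3


def test_missing_category_raises():
    rng = np.random.default_rng(3)
    rec = _toy_records(500, rng)
    rec.loc[rec["stage"] == "distant", "stage"] = "regional"
    with pytest.raises(ImputationError, match="distant"):
        fit_conditional(rec, "stage", ImputationSpec(seed=0))


# ----------------------------------------------------------------------
# chained imputation


def test_zero_missing_input_is_returned_unchanged():
    rng = np.random.default_rng(4)
    rec = _toy_records(800, rng)
    out = impute_once(rec, ImputationSpec(seed=1, n_cycles=2), 0)
    pd.testing.assert_frame_equal(out, rec)


def test_stack_on_complete_data_has_zero_between_variance():
    rng = np.random.default_rng(5)
    rec = _toy_records(800, rng)
    stack = multiple_impute(rec, ImputationSpec(m=3, n_cycles=1, seed=2))
    shares = [float((imp["stage"] == "distant").mean()) for imp in stack.imputations]
    pe = rubin_pool(shares, [0.1] * 3)
    assert pe.between == 0.0


def test_imputation_completes_and_respects_restrictions(small_stack):
    records = small_stack.original
    masked = records["histology_group"].isna()
    allowed = records.loc[masked, "histology_restriction"].str.split("|")
    for imp in small_stack.imputations:
        assert imp["stage"].notna().all()
        assert imp["histology_group"].notna().all()
        drawn = imp.loc[masked, "histology_group"]
        ok = [g in a for g, a in zip(drawn, allowed)]
        assert all(ok)
        # every 8046 record imputed to a non-SMC group
        m8046 = records["morphology_code"] == 8046
        assert not (imp.loc[m8046, "histology_group"] == SMC).any()


def test_non_target_fields_unchanged_by_imputation(small_stack):
    records = small_stack.original
    imp = small_stack.imputations[0]
    untouched = [c for c in records.columns if c not in ("histology_group", "stage")]
    pd.testing.assert_frame_equal(imp[untouched], records[untouched])


def test_multiple_impute_is_deterministic(small_registry):
    records, _, _ = small_registry
    spec = ImputationSpec(m=2, n_cycles=1, seed=42)
    s1 = multiple_impute(records, spec)
    s2 = multiple_impute(records, spec)
    for a, b in zip(s1.imputations, s2.imputations):
        pd.testing.assert_frame_equal(a, b)
    # distinct substreams: the two imputations differ from each other
    assert not s1.imputations[0]["stage"].equals(s1.imputations[1]["stage"])


def test_spec_validation():
    with pytest.raises(ImputationError):
        ImputationSpec(m=1)
    with pytest.raises(ImputationError):
        ImputationSpec(n_cycles=0)
    with pytest.raises(ImputationError):
        ImputationSpec(covariates=())
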