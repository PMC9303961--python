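"""Direct standardization, gamma intervals, pooling and rate ratios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from registrend.imputation import ImputedStack, ImputationSpec
from registrend.rates import (
    RateError,
    StandardPopulation,
    asir,
    gamma_ci,
    irr_series,
    pooled_rate_series,
    single_rate_series,
)


def std2(w=(0.4, 0.6)):
    return StandardPopulation(name="toy", bands=("b0", "b1"), weights=np.array(w))


def test_single_band_rate_and_variance():
    std = StandardPopulation(name="one", bands=("b",), weights=np.array([1.0]))
    e = asir([10], [100_000], std)
    assert e.rate == pytest.approx(10.0, abs=1e-12)
    assert e.variance == pytest.approx(10.0, abs=1e-12)
    assert e.case_count == 10


def test_two_band_hand_computation():
    e = asir([5, 20], [50_000, 200_000], std2())
    # brute-force oracle: spreadsheet-style recomputation
    rate = 1e5 * (0.4 * 5 / 50_000 + 0.6 * 20 / 200_000)
    var = 1e10 * (0.4**2 * 5 / 50_000**2 + 0.6**2 * 20 / 200_000**2)
    assert e.rate == pytest.approx(rate, rel=1e-10)
    assert e.rate == pytest.approx(10.0, rel=1e-12)
    assert e.variance == pytest.approx(var, rel=1e-10)
    assert e.variance == pytest.approx(5.0, rel=1e-12)


def test_equal_crude_rates_standardize_to_crude():
    e = asir([10, 40], [100_000, 400_000], std2())
    assert e.rate == pytest.approx(10.0, rel=1e-12)


@pytest.mark.parametrize("d,n", [([-1, 2], [1e5, 1e5]), ([1, 2, 3], [1e5, 1e5])])
def test_invalid_inputs_raise(d, n):
    with pytest.raises(RateError):
        asir(d, n, std2())


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    d=st.lists(st.integers(0, 500), min_size=2, max_size=8),
    seed=st.integers(0, 9999),
    c=st.floats(0.5, 8.0),
)
def test_standardization_bounds_and_scale_equivariance(d, seed, c):
    rng = np.random.default_rng(seed)
    k = len(d)
    n = rng.uniform(1e4, 5e5, k)
    w = rng.uniform(0.1, 1.0, k)
    std = StandardPopulation.from_counts([f"b{i}" for i in range(k)], w)
    e = asir(d, n, std)
    crude = 1e5 * np.array(d) / n
    assert crude.min() - 1e-9 <= e.rate <= crude.max() + 1e-9
    halved = asir(d, 2 * n, std)
    assert halved.rate == pytest.approx(e.rate / 2, rel=1e-9)
    scaled = asir(np.array(d, dtype=float) * c, n * c, std)
    assert scaled.rate == pytest.approx(e.rate, rel=1e-9)
    assert scaled.variance == pytest.approx(e.variance / c, rel=1e-9)


def test_single_band_gamma_interval_matches_chi_square_oracle():
    std = StandardPopulation(name="one", bands=("b",), weights=np.array([1.0]))
    d, n = 10, 100_000
    e = asir([d], [n], std)
    lo, hi = gamma_ci(e, variant="tiwari")
    scale = 1e5 / n
    lo_oracle = scale * stats.chi2.ppf(0.025, 2 * d) / 2
    assert lo == pytest.approx(lo_oracle, rel=1e-10)
    # upper: adjustment z = scale for a single band (mean == max)
    z = scale
    X, v = e.rate, e.variance
    hi_oracle = stats.gamma.ppf(0.975, (X + z) ** 2 / (v + z**2), scale=(v + z**2) / (X + z))
    assert hi == pytest.approx(hi_oracle, rel=1e-10)
    lo_ff, hi_ff = gamma_ci(e, variant="fay-feuer")
    assert hi_ff == pytest.approx(hi, rel=1e-12)  # single band: mean == max


def test_zero_cases_lower_bound_is_zero():
    e = asir([0, 0], [1e5, 1e5], std2())
    lo, hi = gamma_ci(e)
    assert e.rate == 0.0
    assert lo == 0.0
    assert hi > 0.0


def test_tiwari_upper_bound_is_tighter_than_fay_feuer():
    std = std2((0.3, 0.7))
    e = asir([3, 12], [40_000, 90_000], std)
    _, hi_t = gamma_ci(e, variant="tiwari")
    _, hi_f = gamma_ci(e, variant="fay-feuer")
    assert hi_t < hi_f


def test_alpha_validation():
    e = asir([1], [1e5], StandardPopulation(name="one", bands=("b",), weights=np.array([1.0])))
    with pytest.raises(RateError):
        gamma_ci(e, alpha=1.5)


# ----------------------------------------------------------------------
# series-level behaviour


def _mini_population(years=(2000, 2001), bands=("b0", "b1")):
    rows = []
    for y in years:
        for s in ("male", "female"):
            for b in bands:
                rows.append({"prefecture": "P", "year": y, "sex": s, "age_band": b,
                             "person_years": 100_000.0})
    return pd.DataFrame(rows)


def _mini_records(n_per_cell=20, years=(2000, 2001), bands=("b0", "b1")):
    rows = []
    i = 0
    for y in years:
        for s in ("male", "female"):
            for b in bands:
                for _ in range(n_per_cell):
                    rows.append({"case_id": f"c{i}", "sex": s, "diag_year": y,
                                 "age_band": b, "histology_group": "ADC",
                                 "stage": "localized"})
                    i += 1
    df = pd.DataFrame(rows)
    df["histology_group"] = df["histology_group"].astype("string")
    df["stage"] = df["stage"].astype("string")
    return df


def test_pooled_series_with_identical_tables_equals_single_series():
    pop = _mini_population()
    rec = _mini_records()
    std = std2()
    stack = ImputedStack(original=rec, imputations=[rec.copy() for _ in range(3)],
                         spec=ImputationSpec(m=3, seed=0), seed=0)
    pooled, complete = pooled_rate_series(stack, pop, std, {"sex": "male"})
    single = single_rate_series(rec, pop, std, {"sex": "male"})
    np.testing.assert_allclose(pooled.rates, single.rates, rtol=1e-12)
    np.testing.assert_allclose(pooled.variances, single.variances, rtol=1e-12)
    np.testing.assert_allclose(complete.rates, single.rates, rtol=1e-12)


def test_pooled_point_is_mean_of_per_imputation_rates(small_stack, small_config):
    from registrend.synthetic import generate_population

    pop = generate_population(small_config)
    std = StandardPopulation.japan_1985()
    strat = {"sex": "male", "stage": "distant"}
    pooled, _ = pooled_rate_series(small_stack, pop, std, strat, years=(2000,))
    per = [
        single_rate_series(imp, pop, std, strat, years=(2000,)).rates[0]
        for imp in small_stack.imputations
    ]
    assert pooled.rates[0] == pytest.approx(np.mean(per), rel=1e-12)


def test_imputed_series_dominates_complete_case_series(small_stack, small_config):
    from registrend.synthetic import generate_population

    pop = generate_population(small_config)
    std = StandardPopulation.japan_1985()
    pooled, complete = pooled_rate_series(
        small_stack, pop, std, {"sex": "male", "histology_group": "ADC"}
    )
    assert (pooled.rates >= complete.rates - 1e-9).all()
    assert pooled.rates.sum() > complete.rates.sum()


def test_irr_identical_series_is_unity_with_covering_ci():
    pop = _mini_population()
    rec = _mini_records()
    std = std2()
    f = single_rate_series(rec, pop, std, {"sex": "female"})
    m = single_rate_series(rec, pop, std, {"sex": "male"})
    irr = irr_series(f, m)
    np.testing.assert_allclose(irr.irr, 1.0, rtol=1e-12)
    assert (irr.ci_low <= 1.0).all() and (irr.ci_high >= 1.0).all()


def test_irr_recovers_known_half_ratio():
    """Female counts at half the male counts give IRR 0.5 with a covering CI."""
    rng = np.random.default_rng(77)
    years = (2000, 2001, 2002, 2003, 2004)
    pop = _mini_population(years=years)
    rows = []
    i = 0
    for y in years:
        for b in ("b0", "b1"):
            n_m = rng.poisson(400)
            n_f = rng.poisson(200)
            for sex, n in (("male", n_m), ("female", n_f)):
                for _ in range(n):
                    rows.append({"case_id": f"c{i}", "sex": sex, "diag_year": y,
                                 "age_band": b, "histology_group": "ADC",
                                 "stage": "localized"})
                    i += 1
    rec = pd.DataFrame(rows)
    std = std2()
    f = single_rate_series(rec, pop, std, {"sex": "female"}, years=years)
    m = single_rate_series(rec, pop, std, {"sex": "male"}, years=years)
    irr = irr_series(f, m)
    covered = ((irr.ci_low <= 0.5) & (irr.ci_high >= 0.5)).mean()
    assert covered >= 0.8
    assert np.nanmean(irr.irr) == pytest.approx(0.5, abs=0.08)


def test_irr_mismatched_years_raises():
    pop = _mini_population()
    rec = _mini_records()
    std = std2()
    f = single_rate_series(rec, pop, std, {"sex": "female"}, years=(2000,))
    m = single_rate_series(rec, pop, std, {"sex": "male"}, years=(2000, 2001))
    with pytest.raises(RateError):
        irr_series(f, m)
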