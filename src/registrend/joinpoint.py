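"""Joinpoint (segmented log-linear) regression for annual rate series.

The model is continuous piecewise-linear in ln(rate) against calendar year,
fitted by weighted least squares with weights 1/SE(ln rate)^2.  Joinpoint
locations are found by exhaustive grid search over data years subject to
the 3-3-3 rule (at least three observations from a joinpoint to either end
of the series and between consecutive joinpoints).  The number of
joinpoints is chosen by sequential Monte Carlo permutation tests of
H0: k = k0 against H1: k = k_max, permuting the standardized residuals of
the null fit and comparing F ratios, with the overall level Bonferroni-split
across the test sequence.

Per-segment slopes b_i are reported as annual percent changes
APC_i = 100(e^{b_i} - 1); the average annual percent change over a period
is the segment-length-weighted slope average transformed the same way,
with a fixed-joinpoint delta-method confidence interval.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import substream


class JoinpointError(ValueError):
    pass


@dataclass
class TrendInput:
    years: np.ndarray
    rates: np.ndarray
    ses: np.ndarray
    zero_adjusted: bool = False

    @classmethod
    def from_arrays(cls, years, rates, ses) -> "TrendInput":
        years = np.asarray(years, dtype=float)
        rates = np.asarray(rates, dtype=float)
        ses = np.asarray(ses, dtype=float)
        if not (len(years) == len(rates) == len(ses)):
            raise JoinpointError("years, rates and SEs must have equal length")
        if (ses <= 0).any():
            raise JoinpointError("standard errors must be positive")
        zero_adjusted = False
        if (rates <= 0).any():
            pos = rates[rates > 0]
            if pos.size == 0:
                raise JoinpointError("all rates are zero; nothing to fit")
            rates = np.where(rates <= 0, pos.min() / 2.0, rates)
            zero_adjusted = True
        return cls(years=years, rates=rates, ses=ses, zero_adjusted=zero_adjusted)

    @property
    def log_rates(self) -> np.ndarray:
        return np.log(self.rates)

    @property
    def weights(self) -> np.ndarray:
        # delta method: SE(ln r) = SE(r)/r
        return (self.rates / self.ses) ** 2


@dataclass
class JoinpointModel:
    k: int
    taus: tuple[int, ...]
    years: np.ndarray
    beta: np.ndarray
    cov_beta: np.ndarray
    sse: float
    df_resid: int
    fitted_log: np.ndarray
    selection_pvalues: dict = field(default_factory=dict)

    @property
    def slopes(self) -> np.ndarray:
        """Per-segment slopes of ln(rate) per year."""
        b = [self.beta[1]]
        for j in range(self.k):
            b.append(b[-1] + self.beta[2 + j])
        return np.array(b)

    def slope_cov(self) -> np.ndarray:
        A = np.zeros((self.k + 1, len(self.beta)))
        A[:, 1] = 1.0
        for i in range(self.k + 1):
            for j in range(i):
                A[i, 2 + j] = 1.0
        return A @ self.cov_beta @ A.T

    @property
    def segments(self) -> list[tuple[float, float]]:
        bounds = [self.years.min(), *self.taus, self.years.max()]
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def _basis(years: np.ndarray, taus) -> np.ndarray:
    t = years - years.min()
    cols = [np.ones_like(t), t]
    for tau in taus:
        cols.append(np.maximum(years - tau, 0.0))
    return np.column_stack(cols)


def _admissible_tau_sets(years: np.ndarray, k: int) -> list[tuple[int, ...]]:
    n = len(years)
    if k == 0:
        return [()]
    positions = range(3, n - 3)  # >= 3 observations to either end
    sets = []
    for combo in itertools.combinations(positions, k):
        if all(combo[i + 1] - combo[i] >= 4 for i in range(k - 1)):  # >= 3 between
            sets.append(tuple(int(years[p]) for p in combo))
    return sets


def _wls(Xw: np.ndarray, yw: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    sse = float(resid @ resid)
    return beta, sse


def fit_segmented(inp: TrendInput, k: int, grid: int = 1) -> JoinpointModel:
    """Best k-joinpoint fit by exhaustive search over admissible integer taus.

    Ties in SSE break toward the lexicographically earliest tau vector.
    """
    if grid != 1:
        raise JoinpointError("only a 1-year grid is supported")
    years, y = inp.years, inp.log_rates
    w = inp.weights
    sw = np.sqrt(w)
    n = len(years)
    if n < 2 * 3 + 1 and k >= 1:
        raise JoinpointError(
            f"{k} joinpoint(s) need at least {3 * (k + 1) + k} points under the "
            "3-3-3 rule (three observations to either end and between joinpoints)"
        )
    tau_sets = _admissible_tau_sets(years, k)
    if not tau_sets:
        raise JoinpointError(
            f"no admissible joinpoint locations for k={k} on {n} points "
            "(3-3-3 rule: three observations to either end and between joinpoints)"
        )
    best = None
    for taus in tau_sets:
        X = _basis(years, taus)
        beta, sse = _wls(X * sw[:, None], y * sw)
        if best is None or sse < best[1] - 1e-12:
            best = (taus, sse, beta, X)
    taus, sse, beta, X = best
    df = n - (k + 2)
    Xw = X * sw[:, None]
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    sigma2 = sse / df if df > 0 else 0.0
    cov = sigma2 * xtx_inv
    fitted = X @ beta
    return JoinpointModel(
        k=k, taus=taus, years=years, beta=beta, cov_beta=cov,
        sse=sse, df_resid=df, fitted_log=fitted,
    )


def apc(model: JoinpointModel, alpha: float = 0.05) -> list[dict]:
    """Per-segment annual percent change with t-based confidence intervals."""
    b = model.slopes
    se = np.sqrt(np.clip(np.diag(model.slope_cov()), 0, None))
    tq = stats.t.ppf(1 - alpha / 2, model.df_resid) if model.df_resid > 0 else np.inf
    out = []
    for (s0, s1), bi, sei in zip(model.segments, b, se):
        out.append(
            {
                "period": (int(s0), int(s1)),
                "apc": 100.0 * np.expm1(bi),
                "ci_low": 100.0 * np.expm1(bi - tq * sei),
                "ci_high": 100.0 * np.expm1(bi + tq * sei),
                "slope": bi,
                "se": sei,
            }
        )
    return out


def aapc(model: JoinpointModel, period: tuple[int, int] | None = None, alpha: float = 0.05) -> dict:
    """Average annual percent change over ``period`` (default: full range).

    The weighted slope uses segment lengths inside the period; its variance
    comes from the WLS covariance of the segment slopes (joinpoint locations
    treated as fixed), and the CI uses normal quantiles.
    """
    y0, y1 = period if period is not None else (model.years.min(), model.years.max())
    if y0 < model.years.min() - 1e-9 or y1 > model.years.max() + 1e-9 or y1 <= y0:
        raise JoinpointError("AAPC period must lie within the fitted range")
    L = np.array([max(0.0, min(e, y1) - max(s, y0)) for s, e in model.segments])
    if L.sum() <= 0:
        raise JoinpointError("AAPC period overlaps no segment")
    a = L / L.sum()
    b = model.slopes
    wavg = float(a @ b)
    var = float(a @ model.slope_cov() @ a)
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(max(var, 0.0))
    return {
        "period": (int(y0), int(y1)),
        "aapc": 100.0 * np.expm1(wavg),
        "ci_low": 100.0 * np.expm1(wavg - z * se),
        "ci_high": 100.0 * np.expm1(wavg + z * se),
        "slope": wavg,
        "se": se,
    }


# ----------------------------------------------------------------------
# Permutation model selection


def _sse_matrix(Y: np.ndarray, Qs: list[np.ndarray]) -> np.ndarray:
    """Min SSE over candidate designs for each column of Y."""
    total = np.einsum("ij,ij->j", Y, Y)
    best = None
    for Q in Qs:
        proj = Q.T @ Y
        sse = total - np.einsum("ij,ij->j", proj, proj)
        best = sse if best is None else np.minimum(best, sse)
    return best


def _q_factors(years, sw, k) -> list[np.ndarray]:
    Qs = []
    for taus in _admissible_tau_sets(years, k):
        X = _basis(years, taus) * sw[:, None]
        Q, _ = np.linalg.qr(X)
        Qs.append(Q)
    return Qs


def permutation_select(
    inp: TrendInput,
    k_min: int = 0,
    k_max: int = 1,
    n_perm: int = 4500,
    alpha_overall: float = 0.05,
    seed: int | None = None,
) -> JoinpointModel:
    """Select the number of joinpoints by sequential permutation tests.

    Tests H0: k = k0 against H1: k = k_max for k0 = k_min, k_min+1, ...,
    each at level alpha_overall / (k_max - k0); the first non-rejected k0 is
    selected (k_max if every H0 is rejected).  The permutation p-value is
    (1 + #{F* >= F}) / (1 + n_perm) with standardized null-fit residuals
    shuffled and both models refitted (grid search included) per shuffle.
    """
    if seed is None:
        raise JoinpointError("a seed is required for reproducible permutation tests")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p-value")
    if k_max < k_min:
        raise JoinpointError("k_max must be >= k_min")
    rng = substream(seed, "joinpoint-permutation")
    years = inp.years
    sw = np.sqrt(inp.weights)
    yw = inp.log_rates * sw
    n = len(years)
    # verify admissibility up front (raises with the 3-3-3 message)
    fit_segmented(inp, k_max) if k_max > 0 else None

    q_cache = {k: _q_factors(years, sw, k) for k in range(k_min, k_max + 1)}
    pvalues: dict[int, float] = {}
    selected = k_max
    for k0 in range(k_min, k_max):
        df0, df1 = n - (k0 + 2), n - (k_max + 2)
        sse0 = float(_sse_matrix(yw[:, None], q_cache[k0])[0])
        sse1 = float(_sse_matrix(yw[:, None], q_cache[k_max])[0])
        f_obs = ((sse0 - sse1) / max(df0 - df1, 1)) / (sse1 / df1) if sse1 > 0 else np.inf
        # null fit for residual resampling
        null_model = fit_segmented(inp, k0)
        fitted_w = null_model.fitted_log * sw
        resid_w = yw - fitted_w
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)]).T
        Ystar = fitted_w[:, None] + resid_w[perm_idx]
        s0 = _sse_matrix(Ystar, q_cache[k0])
        s1 = _sse_matrix(Ystar, q_cache[k_max])
        with np.errstate(divide="ignore", invalid="ignore"):
            f_star = ((s0 - s1) / max(df0 - df1, 1)) / (s1 / df1)
        p = (1 + int(np.sum(f_star >= f_obs - 1e-12))) / (1 + n_perm)
        pvalues[k0] = p
        level = alpha_overall / (k_max - k0)
        if p > level:
            selected = k0
            break
    model = fit_segmented(inp, selected)
    model.selection_pvalues = pvalues
    return model
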