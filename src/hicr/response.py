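"""Response thresholds and the 50%-response temperature threshold.

The responder criterion is derived from spontaneous fluctuations of
unheated cells: their dF_max/F0 values are fitted with a Gaussian CDF
(erf form, least squares on the empirical CDF) and the threshold is
``dF_th = mu + 1.96 sigma``.  A heated cell responds when its heat-pulse
dF_max/F0 strictly exceeds dF_th.  The heat-sensitivity threshold
``dTth`` is the deltaT at which the response probability crosses 50%,
estimated by a two-parameter logistic fitted to the per-cell binary
outcomes by maximum likelihood (bootstrap CI), with an
isotonic-interpolation fallback when the MLE is degenerate.
"""

from __future__ import annotations

import logging
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .datatypes import FluctuationModel, ResponseCurve

log = logging.getLogger(__name__)

__all__ = [
    "fit_fluctuation_cdf",
    "threshold",
    "classify_responders",
    "response_curve",
    "estimate_dtth",
    "compare_groups",
]


def _gauss_cdf(x, mu, sigma):
    return 0.5 * (1.0 + special.erf((x - mu) / np.sqrt(2.0 * sigma**2)))


def fit_fluctuation_cdf(values) -> FluctuationModel:
    """Least-squares Gaussian-CDF fit to spontaneous dF_max/F0 values.

    The empirical cumulative probability (plotting position i/n at the
    i-th sorted value) is fitted with
    ``F(x) = 1/2 [1 + erf((x - mu) / sqrt(2 sigma^2))]``.
    Zero spread returns sigma = 0 with a warning.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < 10:
        raise ValueError(f"need >= 10 fluctuation values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("fluctuation values must be finite")
    if np.ptp(x) == 0:
        warnings.warn("zero spread in fluctuation values; sigma set to 0")
        return FluctuationModel(mu=float(x[0]), sigma=0.0, n_cells=x.size,
                                fit_rss=0.0, degenerate=True)
    ecdf = np.arange(1, x.size + 1) / x.size
    p0 = (float(x.mean()), float(x.std(ddof=1)))
    popt, _ = optimize.curve_fit(_gauss_cdf, x, ecdf, p0=p0, maxfev=5000)
    mu, sigma = float(popt[0]), abs(float(popt[1]))
    rss = float(np.sum((_gauss_cdf(x, mu, sigma) - ecdf) ** 2))
    return FluctuationModel(mu=mu, sigma=sigma, n_cells=x.size, fit_rss=rss)


def threshold(model: FluctuationModel) -> float:
    """Responder threshold dF_th = mu + 1.96 sigma."""
    return model.df_th


def classify_responders(dfmax_values, df_th: float) -> np.ndarray:
    """Responder flags: dF_max/F0 strictly above dF_th.

    Ties at the threshold are non-responders (strict inequality).
    """
    if not np.isfinite(df_th):
        raise ValueError("df_th must be finite")
    vals = np.asarray(dfmax_values, dtype=float)
    return vals > df_th


def response_curve(delta_t, responders, *, n_bins: int | None = None,
                   min_per_bin: int = 8) -> ResponseCurve:
    """Bin cells by deltaT and tabulate per-bin response probabilities.

    Default binning: equal-count quantile bins with at least
    ``min_per_bin`` cells each.
    """
    dt = np.asarray(delta_t, dtype=float)
    resp = np.asarray(responders, dtype=bool)
    if dt.size != resp.size or dt.size == 0:
        raise ValueError("delta_t and responders must be equal-length, non-empty")
    if np.unique(dt).size < 2:
        raise ValueError("all cells share one deltaT; need more spread to bin")
    if n_bins is None:
        n_bins = int(np.clip(dt.size // min_per_bin, 2, 10))
    edges = np.unique(np.quantile(dt, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:
        raise ValueError("deltaT values too concentrated for >= 2 bins")
    which = np.clip(np.searchsorted(edges, dt, side="right") - 1, 0, edges.size - 2)
    rows = []
    for b in range(edges.size - 1):
        sel = which == b
        if not sel.any():
            continue
        n = int(sel.sum())
        k = int(resp[sel].sum())
        rows.append({"deltaT_mid": float(dt[sel].mean()), "n": n, "k": k,
                     "p": k / n})
    bins = pd.DataFrame(rows)
    if len(bins) < 2:
        raise ValueError("fewer than 2 non-empty bins")
    return ResponseCurve(bins=bins)


def _logit2_init(dt: np.ndarray, resp: np.ndarray):
    """Plain two-parameter logistic MLE (starting values)."""
    import statsmodels.api as sm

    X = sm.add_constant(dt)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(resp.astype(float), X).fit(disp=0, maxiter=200)
    except Exception:
        return None
    b0, b1 = fit.params
    if not np.all(np.isfinite(fit.params)) or b1 <= 0 or abs(b1) > 1e3:
        return None
    return float(-b0 / b1), float(1.0 / b1)


# Spontaneous-response floor implied by the threshold rule: dF_th sits
# at the 97.5th percentile of the fitted fluctuation Gaussian, so ~2.5%
# of cells cross it without a heat-induced burst.
SPONT_FLOOR = 0.025


def _logistic_mle(dt: np.ndarray, resp: np.ndarray, floor: float = SPONT_FLOOR):
    """Floor-anchored logistic MLE; returns (midpoint, width, floor) or None.

    Model: p(deltaT) = c + (1 - c) / (1 + exp(-(deltaT - m)/w)) with the
    spontaneous floor ``c`` fixed at the rate the threshold construction
    implies.  The reported midpoint ``m`` is the 50% point of the
    heat-induced component; a plain two-parameter logistic absorbs the
    floor by widening and biases ``m`` low whenever a long stretch of
    the sampled deltaT range lies below the midpoint.
    """
    y = resp.astype(float)

    def nll(theta):
        m, logw = theta
        p = floor + (1.0 - floor) * special.expit((dt - m) / np.exp(logw))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))

    init2 = _logit2_init(dt, resp)
    if init2 is None:
        return None
    m0, w0 = init2
    res = optimize.minimize(nll, np.array([m0, np.log(max(w0, 1e-3))]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-9,
                                     "maxiter": 2000})
    if not (res.success and np.all(np.isfinite(res.x))):
        return None
    m, logw = res.x
    w = float(np.exp(logw))
    span = dt.max() - dt.min()
    if not np.isfinite(m) or w > 10.0 * span:
        return None
    return float(m), w, float(floor)


def _isotonic_crossing(dt: np.ndarray, resp: np.ndarray) -> float | None:
    """50% crossing of the isotonic (monotone) response estimate."""
    from sklearn.isotonic import IsotonicRegression

    order = np.argsort(dt)
    x, y = dt[order], resp[order].astype(float)
    p = IsotonicRegression(increasing=True, out_of_bounds="clip").fit_transform(x, y)
    above = p >= 0.5
    if not above.any() or above.all():
        return None
    i = int(np.argmax(above))
    x_lo = x[i - 1]
    x_hi = x[i]
    p_lo, p_hi = p[i - 1], p[i]
    if p_hi == p_lo:
        return float(0.5 * (x_lo + x_hi))
    return float(x_lo + (0.5 - p_lo) * (x_hi - x_lo) / (p_hi - p_lo))


def estimate_dtth(delta_t, responders, *, n_boot: int = 1000,
                  seed: int = 0, binning_kwargs: dict | None = None) -> ResponseCurve:
    """Estimate the 50%-response threshold dTth from per-cell outcomes.

    A two-parameter logistic ``p(deltaT) = 1/(1+exp(-(deltaT-m)/w))`` is
    fitted by maximum likelihood; ``dtth = m``.  The 95% CI comes from a
    nonparametric bootstrap over cells (seeded).  When the MLE fails
    (e.g. complete separation) the estimate falls back to isotonic
    regression with linear interpolation of the 50% crossing, flagged in
    ``method``.
    """
    dt = np.asarray(delta_t, dtype=float)
    resp = np.asarray(responders, dtype=bool)
    if dt.size != resp.size or dt.size == 0:
        raise ValueError("delta_t and responders must be equal-length, non-empty")
    if resp.all() or not resp.any():
        raise ValueError("need both responders and non-responders to locate dTth")

    curve = response_curve(dt, resp, **(binning_kwargs or {}))

    fit = _logistic_mle(dt, resp)
    floor = float("nan")
    if fit is not None:
        mid, width, floor = fit
        method = "logistic_mle"
    else:
        warnings.warn("logistic MLE failed (separation?); isotonic fallback")
        mid = _isotonic_crossing(dt, resp)
        width = float("nan")
        method = "isotonic_interpolation"
    if mid is None or not (dt.min() <= mid <= dt.max()):
        raise ValueError(
            f"dTth outside sampled range [{dt.min():g}, {dt.max():g}] degC")

    ci_low = ci_high = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng([seed, 777])
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, dt.size, dt.size)
            if resp[idx].all() or not resp[idx].any():
                continue
            bfit = _logistic_mle(dt[idx], resp[idx])
            m = bfit[0] if bfit is not None else _isotonic_crossing(dt[idx], resp[idx])
            if m is not None and np.isfinite(m):
                boots.append(m)
        if len(boots) >= max(20, n_boot // 5):
            ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        else:
            warnings.warn("too few successful bootstrap refits for a CI")

    curve.dtth = float(mid)
    curve.logistic_width = width
    curve.spont_floor = floor
    curve.ci_low = float(ci_low)
    curve.ci_high = float(ci_high)
    curve.method = method
    log.info("dTth = %.3g degC (%s), 95%% CI [%.3g, %.3g]", mid, method,
             ci_low, ci_high)
    return curve


# ---------------------------------------------------------------------------
# two-sample rank test


@lru_cache(maxsize=None)
def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of the Mann-Whitney U statistic.

    ``counts[u]`` is the number of arrangements of n1 + n2 distinct
    values giving U = u for the first sample; classic dynamic-programming
    recursion f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u).
    """
    if n1 == 0 or n2 == 0:
        return np.ones(1)
    a = _u_counts(n1 - 1, n2)
    b = _u_counts(n1, n2 - 1)
    out = np.zeros(n1 * n2 + 1)
    out[n2:n2 + a.size] += a
    out[: b.size] += b
    return out


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    counts = _u_counts(n1, n2)
    total = counts.sum()
    u_int = int(round(u))
    p_le = counts[: u_int + 1].sum() / total
    p_ge = counts[u_int:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def compare_groups(a, b, *, exact_max_n: int = 9):
    """Two-sided Mann-Whitney U test.

    Uses the exact permutation distribution (own enumeration) when both
    groups have at most ``exact_max_n`` observations and the pooled data
    are tie-free; otherwise the normal approximation with tie correction
    and continuity correction.  Returns (U of the first sample, p).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need >= 3 observations per group")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= exact_max_n and y.size <= exact_max_n and not has_ties:
        return u1, _exact_two_sided_p(u1, x.size, y.size)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
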