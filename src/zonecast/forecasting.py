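"""Quarterly time-series forecasting of zone outlet counts.

Non-seasonal ARIMA(p, d, q) models, optionally with a constant/drift, fitted
by exact maximum likelihood. The differencing degree d is chosen by repeated
KPSS tests, variance instability triggers a Box-Cox transform (Guerrero's
method for lambda), and (p, q) are selected over a grid p, q = 0..5 by the
small-sample-corrected AIC (AICc). Residual autocorrelation is screened with
a Ljung-Box test. Forecast accuracy is assessed by rolling-origin
cross-validation against an exponential-smoothing (ETS) benchmark, using RMSE
and the mean absolute scaled error

    MASE = mean_i |y_i - yhat_i| / ( (1/(T-1)) sum_{t=2..T} |y_t - y_{t-1}| )

whose denominator is the in-sample mean absolute first difference of the full
series (the one-step naive forecaster's average error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.stattools import kpss as _kpss

from ._arma import ArmaFit, fit_arma, _arma2ma
from .zones import count_in_zones

__all__ = [
    "QuarterlySeries",
    "ArimaModel",
    "ForecastResult",
    "ForecastEvaluation",
    "build_series",
    "kpss_difference",
    "maybe_boxcox",
    "fit_arima_grid",
    "auto_arima",
    "ljung_box",
    "forecast",
    "forecast_annual",
    "rolling_origin_cv",
    "ets_benchmark",
    "ArimaForecaster",
    "NaiveForecaster",
    "EtsForecaster",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class QuarterlySeries:
    """Chronologically ordered, equally spaced quarterly counts."""

    start_quarter: str
    values: np.ndarray
    missing_mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 3:
            raise ValueError("series must have at least 3 quarters")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.size, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.size != self.values.size:
            raise ValueError("missing_mask length mismatch")

    @property
    def quarters(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_quarter, periods=self.values.size, freq="Q")

    def __len__(self):
        return self.values.size


def build_series(snapshots: pd.DataFrame, zone_union, known_missing=()) -> QuarterlySeries:
    """Count outlets within the zone union per quarter; interpolate gaps.

    ``snapshots`` has columns x, y, quarter, label. Quarters listed in
    ``known_missing`` (by label) are treated as unobserved and filled by
    linear interpolation between the flanking observed counts; a missing
    quarter at either end of the series has no anchor and is rejected.
    """
    labels = (
        snapshots[["quarter", "label"]]
        .drop_duplicates()
        .sort_values("quarter")
        .set_index("quarter")["label"]
    )
    quarters = labels.index.to_numpy()
    if not np.array_equal(quarters, np.arange(quarters.min(), quarters.max() + 1)):
        raise ValueError("snapshot quarters are not consecutive")
    missing = {str(m) for m in known_missing}
    mask = labels.isin(missing).to_numpy()
    if mask[0] or mask[-1]:
        raise ValueError("missing quarter at a series endpoint has no interpolation anchor")
    counts = np.full(quarters.size, np.nan)
    for i, q in enumerate(quarters):
        if mask[i]:
            continue
        pts = snapshots.loc[snapshots["quarter"] == q, ["x", "y"]].to_numpy()
        counts[i] = count_in_zones(pts, zone_union)
    obs = ~mask
    counts[mask] = np.interp(quarters[mask], quarters[obs], counts[obs])
    return QuarterlySeries(labels.iloc[0], counts, mask)


def kpss_difference(values, alpha: float = 0.05, max_d: int = 2):
    """Smallest differencing degree at which KPSS accepts level stationarity.

    Uses the short (legacy) lag truncation ``4 * (n/100)^0.25``. Returns
    ``(d, differenced_values, stationary)``; ``stationary`` is False when even
    ``max_d`` differences still reject, in which case ``max_d`` is used with a
    warning. A (near-)constant series is stationary by construction and
    accepted without testing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for KPSS differencing (need >= 8)")
    crit_keys = {0.10: "10%", 0.05: "5%", 0.025: "2.5%", 0.01: "1%"}
    if alpha not in crit_keys:
        raise ValueError(f"alpha must be one of {sorted(crit_keys)}")
    for d in range(max_d + 1):
        xd = np.diff(x, n=d) if d else x
        if np.ptp(xd) < 1e-12 * max(1.0, np.abs(xd).max()):
            return d, xd, True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, _, _, crit = _kpss(xd, regression="c", nlags="legacy")
        if stat <= crit[crit_keys[alpha]]:
            return d, xd, True
    warnings.warn(f"series still non-stationary after {max_d} differences")
    return max_d, np.diff(x, n=max_d), False


def _guerrero_lambda(x: np.ndarray, block: int = 4) -> float:
    """Guerrero's variance-stabilising Box-Cox lambda.

    Splits the series into non-overlapping blocks (quarterly data: blocks of
    four), and picks the lambda minimising the coefficient of variation of
    ``sd_i / mean_i^(1 - lambda)`` across blocks.
    """
    n_blocks = len(x) // block
    xb = x[: n_blocks * block].reshape(n_blocks, block)
    means = xb.mean(axis=1)
    sds = xb.std(axis=1, ddof=1)

    def cv(lam):
        ratio = sds / means ** (1.0 - lam)
        m = ratio.mean()
        return ratio.std(ddof=1) / m if m > 0 else np.inf

    res = optimize.minimize_scalar(cv, bounds=(-1.0, 2.0), method="bounded")
    return float(res.x)


def _boxcox(x, lam):
    return np.log(x) if abs(lam) < 1e-12 else (x**lam - 1.0) / lam


def _inv_boxcox(y, lam):
    return np.exp(y) if abs(lam) < 1e-12 else np.maximum(lam * y + 1.0, 1e-12) ** (1.0 / lam)


def maybe_boxcox(values, sd_ratio_trigger: float = 2.0):
    """Box-Cox transform the series when its variance grows over time.

    The transform fires only when the standard deviation of the last third of
    the series exceeds that of the first third by more than
    ``sd_ratio_trigger``; lambda then comes from Guerrero's method. Series
    with non-positive values are shifted up before transforming and the shift
    recorded. Returns ``(transformed, lambda_or_None, shift)``.
    """
    x = np.asarray(values, dtype=float)
    third = max(len(x) // 3, 2)
    sd_first = np.std(x[:third], ddof=1)
    sd_last = np.std(x[-third:], ddof=1)
    if sd_first == 0 or sd_last / sd_first <= sd_ratio_trigger:
        return x, None, 0.0
    shift = 0.0
    if x.min() <= 0:
        shift = 1.0 - x.min()
        x = x + shift
    lam = _guerrero_lambda(x)
    return _boxcox(x, lam), lam, shift


@dataclass
class ArimaModel:
    """Selected ARIMA(p, d, q) model, optionally with constant/drift."""

    p: int
    d: int
    q: int
    include_drift: bool
    c: float
    phi: np.ndarray
    theta: np.ndarray
    sigma2: float
    aicc: float
    loglike: float
    boxcox_lambda: Optional[float] = None
    boxcox_shift: float = 0.0
    _fit: ArmaFit = field(default=None, repr=False)
    _values: np.ndarray = field(default=None, repr=False)  # modelling scale

    def __post_init__(self):
        if not (0 <= self.p <= 5 and 0 <= self.q <= 5 and 0 <= self.d <= 2):
            raise ValueError("order out of range")
        if not np.isfinite(self.aicc):
            raise ValueError("AICc must be finite")
        if self.p:
            # stationarity: all roots of 1 - phi_1 z - ... - phi_p z^p outside
            # the unit circle (small slack for optimizer boundary limits)
            roots = np.roots(np.r_[-np.asarray(self.phi)[::-1], 1.0])
            if np.any(np.abs(roots) <= 1.0 - 1e-6):
                raise ValueError("fitted AR polynomial is not stationary")

    @property
    def order(self):
        return (self.p, self.d, self.q)

    def residuals(self) -> np.ndarray:
        return self._fit.residuals()


def fit_arima_grid(values, d: int, p_max: int = 5, q_max: int = 5, **model_kwargs) -> ArimaModel:
    """Exact-MLE fit over the (p, q) grid; minimum-AICc model wins.

    The series is differenced ``d`` times and every ARMA(p, q) candidate is
    fitted with and without a constant (a constant on the differenced scale is
    drift; it is excluded for d = 2). AICc ties break to fewer parameters,
    then lower p, then lower q.
    """
    x = np.asarray(values, dtype=float)
    xd = np.diff(x, n=d) if d else x
    if xd.size < 3:
        raise ValueError("series too short to fit any model")
    best = None
    failures = []
    for p in range(p_max + 1):
        for q in range(q_max + 1):
            consts = (False, True) if d <= 1 else (False,)
            for const in consts:
                # candidates the sample cannot identify (AICc undefined) are
                # skipped, so short training sets in cross-validation still
                # select among the estimable orders
                if xd.size - (p + q + int(const) + 1) - 1 <= 0:
                    continue
                try:
                    f = fit_arma(xd, p, q, with_const=const)
                except Exception as err:  # non-convergent candidate: skip
                    failures.append(((p, d, q, const), str(err)))
                    continue
                if not np.isfinite(f.aicc):
                    continue
                key = (f.aicc, f.n_params, p, q)
                if best is None or key < best[0]:
                    best = (key, f)
    if best is None:
        raise RuntimeError(f"no ARIMA candidate converged; failures: {failures[:3]}")
    f = best[1]
    return ArimaModel(
        p=f.p,
        d=d,
        q=f.q,
        include_drift=f.with_const and d >= 1,
        c=f.mu,
        phi=f.phi,
        theta=f.theta,
        sigma2=f.sigma2,
        aicc=f.aicc,
        loglike=f.loglike,
        _fit=f,
        _values=x,
        **model_kwargs,
    )


def auto_arima(series: QuarterlySeries, alpha: float = 0.05, p_max: int = 5, q_max: int = 5) -> ArimaModel:
    """Full selection protocol: Box-Cox check, KPSS differencing, AICc grid."""
    y, lam, shift = maybe_boxcox(series.values)
    d, _, _ = kpss_difference(y, alpha=alpha)
    return fit_arima_grid(y, d, p_max, q_max, boxcox_lambda=lam, boxcox_shift=shift)


def ljung_box(model: ArimaModel, residuals=None):
    """Ljung-Box residual autocorrelation test.

    Lags = min(10, n // 5); degrees of freedom = lags - p - q, floored at one
    (with a warning when the floor binds). Returns (Q, p_value).
    """
    resid = model.residuals() if residuals is None else np.asarray(residuals, dtype=float)
    n = resid.size
    lags = max(min(10, n // 5), 1)
    if np.ptp(resid) < 1e-12 * max(1.0, np.abs(resid).max()):
        warnings.warn("constant residuals: Ljung-Box test degenerate")
        return np.nan, np.nan
    lb = acorr_ljungbox(resid, lags=[lags], model_df=0)
    q_stat = float(lb["lb_stat"].iloc[0])
    df = lags - model.p - model.q
    if df < 1:
        warnings.warn("lags <= p + q; using df = 1 for the Ljung-Box p-value")
        df = 1
    return q_stat, float(stats.chi2.sf(q_stat, df))


@dataclass
class ForecastResult:
    horizon: int
    mean: float
    lower95: float
    upper95: float

    def __post_init__(self):
        if not (self.lower95 <= self.mean <= self.upper95):
            raise ValueError("forecast interval does not bracket the mean")


def _predict_original_scale(model: ArimaModel, h: int):
    """Point forecasts and variances on the (possibly transformed) data scale."""
    means_d, _ = model._fit.predict_mean_var(h)
    x = model._values
    d = model.d
    mean = means_d
    if d == 2:
        mean = (x[-1] - x[-2]) + np.cumsum(mean)
    if d >= 1:
        mean = x[-1] + np.cumsum(mean)
    psi = _arma2ma(model.phi, model.theta, h)
    for _ in range(d):
        psi = np.cumsum(psi)
    var = model.sigma2 * np.cumsum(psi**2)
    return mean, var


def forecast(model: ArimaModel, h: int) -> list:
    """h-step forecasts with 95% Gaussian intervals on the original scale.

    When a Box-Cox transform was applied, the interval endpoints and the
    central value are back-transformed quantiles (no bias adjustment).
    """
    if h <= 0:
        raise ValueError("forecast horizon must be positive")
    mean, var = _predict_original_scale(model, h)
    se = np.sqrt(var)
    lo, hi = mean - _Z975 * se, mean + _Z975 * se
    if model.boxcox_lambda is not None:
        lam, shift = model.boxcox_lambda, model.boxcox_shift
        mean = _inv_boxcox(mean, lam) - shift
        lo = _inv_boxcox(lo, lam) - shift
        hi = _inv_boxcox(hi, lam) - shift
    return [
        ForecastResult(i + 1, float(mean[i]), float(lo[i]), float(hi[i])) for i in range(h)
    ]


def forecast_annual(series: QuarterlySeries, model: ArimaModel, horizon_year: int) -> pd.DataFrame:
    """Annual forecast table: the second-calendar-quarter value of each year."""
    last = series.quarters[-1]
    target = pd.Period(f"{horizon_year}Q2", freq="Q")
    h = (target - last).n
    if h <= 0:
        raise ValueError("horizon year not beyond the observed series")
    fcs = forecast(model, h)
    rows = []
    for i, fc in enumerate(fcs):
        period = last + i + 1
        if period.quarter == 2:
            rows.append((period.year, fc.mean, fc.lower95, fc.upper95))
    return pd.DataFrame(rows, columns=["year", "mean", "lower95", "upper95"])


@dataclass
class ForecastEvaluation:
    rmse: float
    mase: float
    n_forecasts: int
    per_horizon: pd.DataFrame
    details: pd.DataFrame = None  # origin, horizon, actual, predicted

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


class NaiveForecaster:
    """Forecasts equal to the last observed value (the MASE reference)."""

    def fit(self, values):
        self._last = float(values[-1])
        return self

    def predict(self, h: int) -> np.ndarray:
        return np.full(h, self._last)


class ArimaForecaster:
    """ARIMA forecaster for the CV harness: auto selection or a fixed order."""

    def __init__(self, order=None, drift=None, alpha=0.05, p_max=5, q_max=5):
        self.order = order
        self.drift = drift
        self.alpha = alpha
        self.p_max = p_max
        self.q_max = q_max

    def fit(self, values):
        values = np.asarray(values, dtype=float)
        if self.order is None:
            d, _, _ = kpss_difference(values, alpha=self.alpha)
            self._model = fit_arima_grid(values, d, self.p_max, self.q_max)
        else:
            p, d, q = self.order
            xd = np.diff(values, n=d) if d else values
            f = fit_arma(xd, p, q, with_const=bool(self.drift))
            self._model = ArimaModel(
                p=p, d=d, q=q, include_drift=bool(self.drift) and d >= 1,
                c=f.mu, phi=f.phi, theta=f.theta, sigma2=f.sigma2,
                aicc=f.aicc, loglike=f.loglike, _fit=f, _values=values,
            )
        return self

    def predict(self, h: int) -> np.ndarray:
        return np.array([fc.mean for fc in forecast(self._model, h)])


class EtsForecaster:
    """Error-trend exponential smoothing, AICc-selected (no seasonality)."""

    _CANDIDATES = (
        {"trend": None},
        {"trend": "add"},
        {"trend": "add", "damped_trend": True},
    )

    def fit(self, values):
        from statsmodels.tsa.exponential_smoothing.ets import ETSModel

        values = np.asarray(values, dtype=float)
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for kw in self._CANDIDATES:
                try:
                    res = ETSModel(values, error="add", **kw).fit(disp=False)
                except Exception:
                    continue
                if best is None or res.aicc < best.aicc:
                    best = res
        if best is None:
            raise RuntimeError("no ETS candidate converged")
        self._res = best
        return self

    def predict(self, h: int) -> np.ndarray:
        return np.asarray(self._res.forecast(h), dtype=float)


def rolling_origin_cv(
    series: QuarterlySeries, spec, min_train: int = 8, max_h: int = 8
) -> ForecastEvaluation:
    """Rolling-origin cross-validation with pooled error averaging.

    Every observation after the first ``min_train`` serves as a test point:
    for each origin t (training sizes min_train .. T-1) the forecaster is
    refitted on observations 1..t and scored at horizons 1..min(max_h, T-t).
    RMSE pools all (origin, horizon) errors; MASE divides the pooled mean
    absolute error by the full-series mean absolute first difference. A
    constant series leaves MASE undefined (NaN).
    """
    y = series.values
    T = y.size
    if T <= min_train:
        raise ValueError("series not longer than min_train")
    rows = []
    for t in range(min_train, T):
        fitted = spec.fit(y[:t])
        h = min(max_h, T - t)
        pred = np.asarray(fitted.predict(h), dtype=float)
        for i in range(h):
            rows.append((t, i + 1, y[t + i], pred[i]))
    df = pd.DataFrame(rows, columns=["origin", "horizon", "actual", "predicted"])
    err = df["actual"] - df["predicted"]
    rmse = float(np.sqrt(np.mean(err**2)))
    denom = np.mean(np.abs(np.diff(y)))
    if denom == 0:
        warnings.warn("constant series: MASE undefined")
        mase = np.nan
    else:
        mase = float(np.mean(np.abs(err)) / denom)
    per_h = (
        df.assign(sq=err**2, ab=err.abs())
        .groupby("horizon")
        .agg(rmse=("sq", lambda s: float(np.sqrt(s.mean()))), mae=("ab", "mean"), n=("ab", "size"))
        .reset_index()
    )
    return ForecastEvaluation(rmse=rmse, mase=mase, n_forecasts=len(df), per_horizon=per_h, details=df)


def ets_benchmark(series: QuarterlySeries, min_train: int = 8, max_h: int = 8) -> ForecastEvaluation:
    """ETS benchmark run through the identical CV harness."""
    return rolling_origin_cv(series, EtsForecaster(), min_train=min_train, max_h=max_h)
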