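"""Segmented interrupted-time-series analysis of monthly mean response times.

The monthly mean response time f(t) is modelled as a segmented linear trend
with a discontinuity at the intervention month t_pi, a winter indicator, and
serially correlated errors:

    f(t) = b0 + b1*t + b2*u(t - t_pi) + b3*(t - t_pi)*u(t - t_pi)
           + b4*I_winter(t) + e(t)

where u(x) = 1 for x >= 0 and 0 otherwise, I_winter is 1 for October-March,
b2 is the immediate level change at the intervention, b3 the change in slope,
and e(t) follows one of a small candidate set of stationary error processes
(white noise, MA(1), AR(1), seasonal MA at lag 12) selected by small-sample
corrected AIC. Estimation is exact Gaussian maximum likelihood via the
state-space (Kalman filter) representation, which also handles months that
are excluded from the fit (the intervention month, outlier months) as
missing observations without breaking the error process's timing.

Inference on b2 and b3 uses t-distributed statistics with n - k degrees of
freedom, n being the number of observed months and k the number of estimated
parameters. The counterfactual trajectory — the expected response time had
the intervention not happened — is b0 + b1*t + b4*I_winter(t).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .missions import response_time_minutes

__all__ = [
    "aggregate_monthly", "flag_excluded_months", "build_design",
    "InterruptedTimeSeriesRegressor", "fit_its", "select_error_model",
    "counterfactual", "plot_its",
]

WINTER_MONTHS = (10, 11, 12, 1, 2, 3)

#: Candidate error processes: label -> (ARIMA order, seasonal order, n extra params)
ERROR_SPECS = {
    "white": ((0, 0, 0), (0, 0, 0, 0)),
    "ma1": ((0, 0, 1), (0, 0, 0, 0)),
    "ar1": ((1, 0, 0), (0, 0, 0, 0)),
    "sma12": ((0, 0, 0), (0, 0, 1, 12)),
}

DESIGN_COLUMNS = ("intercept", "t", "step", "ramp", "winter")


def aggregate_monthly(missions: pd.DataFrame, study_start: str | None = None,
                      study_end: str | None = None) -> pd.DataFrame:
    """Aggregate mission response times into a monthly series.

    Returns one row per calendar month spanning the study window with
    columns ``t`` (0-based month index), ``calendar_month`` (Period),
    ``mean_response``, ``n_missions``, ``included`` and
    ``exclusion_reason``. Months with no missions keep a row with a missing
    mean and are flagged.
    """
    rt = response_time_minutes(missions)
    months = (missions["alarm_time"].dt.tz_convert("UTC")
              .dt.tz_localize(None).dt.to_period("M"))
    grouped = pd.DataFrame({"month": months, "rt": rt}).groupby("month")["rt"]
    agg = grouped.agg(["mean", "count"])
    start = pd.Period(study_start, freq="M") if study_start else agg.index.min()
    end = pd.Period(study_end, freq="M") if study_end else agg.index.max()
    full = pd.period_range(start, end, freq="M")
    agg = agg.reindex(full)
    series = pd.DataFrame({
        "t": np.arange(len(full)),
        "calendar_month": full,
        "mean_response": agg["mean"].to_numpy(),
        "n_missions": agg["count"].fillna(0).astype(int).to_numpy(),
    })
    series["included"] = series["mean_response"].notna()
    series["exclusion_reason"] = np.where(series["included"], "none", "empty month")
    return series


def flag_excluded_months(series: pd.DataFrame, tpi_month: str,
                         z_threshold: float = 3.0) -> pd.DataFrame:
    """Flag the intervention month and outlier months for exclusion.

    The intervention month itself is always dropped (the intervention was
    introduced mid-month). A month is an outlier when its mean lies more
    than ``z_threshold`` standard deviations from the mean of the remaining
    (non-intervention) months.
    """
    out = series.copy()
    tpi = pd.Period(tpi_month, freq="M")
    if not (out["calendar_month"] == tpi).any():
        raise ValueError(f"intervention month {tpi_month} outside study window")
    is_tpi = out["calendar_month"] == tpi
    out.loc[is_tpi & out["included"], "exclusion_reason"] = "intervention month"
    out.loc[is_tpi, "included"] = False

    # leave-one-out z: judge each month against the mean/SD of the others,
    # so an extreme month cannot mask itself by inflating the pooled SD
    inc = out["included"].to_numpy()
    x = out["mean_response"].to_numpy(float)
    n = int(inc.sum())
    if n > 2:
        s, ss = x[inc].sum(), (x[inc] ** 2).sum()
        for i in np.flatnonzero(inc):
            mu_i = (s - x[i]) / (n - 1)
            var_i = (ss - x[i] ** 2 - (n - 1) * mu_i ** 2) / (n - 2)
            if var_i <= 0:
                continue
            if abs(x[i] - mu_i) / np.sqrt(var_i) > z_threshold:
                out.loc[out.index[i], "exclusion_reason"] = "outlier"
                out.loc[out.index[i], "included"] = False
    return out


def build_design(t: np.ndarray, calendar_months: np.ndarray, tpi: int,
                 winter_months: tuple[int, ...] = WINTER_MONTHS,
                 validate_window: bool = True) -> np.ndarray:
    """Regressor matrix [1, t, step, ramp, winter] for month indices ``t``.

    ``tpi`` is the index of the (excluded) intervention month; the step is 1
    for t >= tpi and the ramp is (t - tpi) on that support, so the first
    included post month carries step 1 and ramp 1. ``validate_window`` is
    switched off when building rows for prediction at arbitrary months.
    """
    t = np.asarray(t, dtype=float)
    if validate_window and not (t.min() <= tpi <= t.max()):
        raise ValueError(f"tpi={tpi} outside the study window "
                         f"[{t.min():.0f}, {t.max():.0f}]")
    step = (t >= tpi).astype(float)
    ramp = (t - tpi) * step
    cal = np.asarray([m.month if isinstance(m, pd.Period) else int(m)
                      for m in np.asarray(calendar_months)])
    winter = np.isin(cal, winter_months).astype(float)
    X = np.column_stack([np.ones_like(t), t, step, ramp, winter])
    return X


class InterruptedTimeSeriesRegressor(BaseEstimator, RegressorMixin):
    """Segmented regression with a discontinuity and ARMA-family errors.

    Parameters
    ----------
    tpi : int
        0-based month index of the intervention month (excluded from data).
    error_spec : {"white", "ma1", "ar1", "sma12"}
        Error process. "white" reduces to ordinary least squares.
    winter_months : tuple of int
        Calendar months (1-12) forming the seasonal indicator.

    The estimator is fit on ``X`` of shape (n, 2) with columns
    ``[month_index, calendar_month_number]`` and ``y`` the monthly mean
    response times in minutes; rows are the *included* months and may have
    gaps in the month index — the likelihood treats the gaps as missing
    observations so the error process stays correctly aligned in time.

    Fitted attributes
    -----------------
    beta_ : ndarray (5,) — [b0, b1, b2, b3, b4]
    se_ : ndarray (5,) — standard errors of beta_
    pvalues_ : ndarray (5,) — two-sided t tests (df = n - k)
    theta_ : float — MA(1)/AR(1)/seasonal-MA coefficient (0 for white noise)
    sigma_ : float — innovation SD, minutes
    aicc_, r2_, llf_, nobs_, k_params_
    """

    def __init__(self, tpi: int = 24, error_spec: str = "ma1",
                 winter_months: tuple[int, ...] = WINTER_MONTHS,
                 maxiter: int = 500):
        self.tpi = tpi
        self.error_spec = error_spec
        self.winter_months = winter_months
        self.maxiter = maxiter

    # -- internal ---------------------------------------------------------

    def _validate_X(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: "
                             "[month_index, calendar_month_number]")
        t = X[:, 0]
        cal = X[:, 1].astype(int)
        if np.any((cal < 1) | (cal > 12)):
            raise ValueError("calendar month numbers must be in 1..12")
        return t, cal

    def fit(self, X, y):
        """Fit by exact Gaussian maximum likelihood."""
        from statsmodels.tsa.arima.model import ARIMA

        if self.error_spec not in ERROR_SPECS:
            raise ValueError(f"unknown error_spec {self.error_spec!r}; "
                             f"choose from {sorted(ERROR_SPECS)}")
        t, cal = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != t.shape[0]:
            raise ValueError("X and y lengths differ")
        n_obs = int(np.isfinite(y).sum())
        if n_obs < 10:
            raise ValueError(f"need >= 10 included months, got {n_obs}")

        # lay the observations on the full month grid; gaps become NaN
        t_int = t.astype(int)
        t_full = np.arange(t_int.min(), t_int.max() + 1)
        y_full = np.full(t_full.shape, np.nan)
        cal_full = self._calendar_on_grid(t_int, cal, t_full)
        y_full[t_int - t_int.min()] = y
        X_full = build_design(t_full, cal_full, self.tpi, self.winter_months)
        if np.linalg.matrix_rank(X_full[np.isfinite(y_full)]) < X_full.shape[1]:
            raise ValueError("design matrix is rank deficient on the "
                             "included months")

        order, seasonal = ERROR_SPECS[self.error_spec]
        if self.error_spec == "white":
            res = self._fit_ols(X_full, y_full)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = ARIMA(y_full, exog=X_full[:, 1:], order=order,
                              seasonal_order=seasonal, trend="c")
                res = model.fit(method_kwargs={"maxiter": self.maxiter})
                if not res.mle_retvals.get("converged", True):
                    # lbfgs can stop with precision loss near the invertibility
                    # boundary; Powell is slower but derivative-free and robust
                    res_retry = model.fit(
                        start_params=res.params,
                        method_kwargs={"maxiter": self.maxiter,
                                       "method": "powell"})
                    if res_retry.llf >= res.llf:
                        res = res_retry
            retvals = res.mle_retvals
            grad_ok = np.max(np.abs(retvals.get("gopt", [np.inf]))) < 0.1
            if not (retvals.get("converged", True) or grad_ok):
                raise RuntimeError(
                    f"maximum-likelihood fit did not converge: {retvals}")
        self._unpack(res, X_full, y_full, n_obs)
        self._t_grid_ = t_full
        self._cal_grid_ = cal_full
        return self

    @staticmethod
    def _calendar_on_grid(t_int, cal, t_full):
        """Extend calendar month numbers over grid gaps (months cycle)."""
        anchor_t, anchor_cal = t_int[0], cal[0]
        return ((anchor_cal - 1 + (t_full - anchor_t)) % 12) + 1

    def _fit_ols(self, X_full, y_full):
        import statsmodels.api as sm
        mask = np.isfinite(y_full)
        return sm.OLS(y_full[mask], X_full[mask]).fit()

    def _unpack(self, res, X_full, y_full, n_obs):
        if self.error_spec == "white":
            beta = np.asarray(res.params)
            se = np.asarray(res.bse)
            theta = 0.0
            sigma = float(np.sqrt(res.ssr / n_obs))  # ML variance estimate
            llf = float(res.llf)
            k = X_full.shape[1] + 1  # betas + variance
        else:
            p = np.asarray(res.params)
            # params: [const, exog betas..., arma coefs..., sigma2]
            beta = p[:5]
            theta = float(p[5])
            sigma = float(np.sqrt(p[-1]))
            llf = float(res.llf)
            k = len(p)
            # ML sigma^2 divides by n; rescale SEs by sqrt(n/(n-k)) so the
            # t tests carry the usual residual-df correction (as OLS does)
            se = np.asarray(res.bse)[:5] * np.sqrt(n_obs / (n_obs - k))
        self.result_ = res
        self.beta_ = beta
        self.se_ = se
        self.theta_ = theta
        self.sigma_ = sigma
        self.llf_ = llf
        self.nobs_ = n_obs
        self.k_params_ = k
        df = n_obs - k
        if df <= 0:
            raise ValueError(f"no residual degrees of freedom (n={n_obs}, k={k})")
        tstat = np.divide(beta, se, out=np.full(5, np.inf), where=se > 0)
        self.pvalues_ = 2.0 * stats.t.sf(np.abs(tstat), df)
        aic = 2.0 * k - 2.0 * llf
        if n_obs - k - 1 <= 0:
            raise ValueError(
                f"AICc undefined: n={n_obs} <= k+1={k + 1} parameters")
        self.aicc_ = aic + 2.0 * k * (k + 1) / (n_obs - k - 1)
        mask = np.isfinite(y_full)
        fitted = X_full[mask] @ beta
        resid = y_full[mask] - fitted
        sst = float(np.sum((y_full[mask] - y_full[mask].mean()) ** 2))
        self.r2_ = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else 1.0
        self.fitted_mean_ = fitted

    # -- public API -------------------------------------------------------

    def predict(self, X):
        """Deterministic model mean b0 + b1 t + b2 step + b3 ramp + b4 winter."""
        check_is_fitted(self, "beta_")
        t, cal = self._validate_X(X)
        return build_design(t, cal, self.tpi, self.winter_months,
                            validate_window=False) @ self.beta_

    def counterfactual(self, X):
        """Expected trajectory absent the intervention: b0 + b1 t + b4 winter."""
        check_is_fitted(self, "beta_")
        t, cal = self._validate_X(X)
        D = build_design(t, cal, self.tpi, self.winter_months,
                         validate_window=False)
        return D[:, [0, 1, 4]] @ self.beta_[[0, 1, 4]]

    def summary_dict(self) -> dict:
        check_is_fitted(self, "beta_")
        d = {f"beta{i}": float(b) for i, b in enumerate(self.beta_)}
        d.update({
            "se_beta2": float(self.se_[2]), "se_beta3": float(self.se_[3]),
            "p_beta2": float(self.pvalues_[2]), "p_beta3": float(self.pvalues_[3]),
            "p_beta4": float(self.pvalues_[4]),
            "ma_theta": self.theta_, "sigma": self.sigma_,
            "aicc": float(self.aicc_), "r2": float(self.r2_),
            "error_spec": self.error_spec, "tpi": self.tpi,
            "n_months": int(self.nobs_),
        })
        return d


def _series_to_Xy(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    inc = series[series["included"]]
    cal = np.asarray([m.month for m in inc["calendar_month"]])
    X = np.column_stack([inc["t"].to_numpy(float), cal])
    return X, inc["mean_response"].to_numpy(float)


def fit_its(series: pd.DataFrame, tpi: int,
            error_spec: str = "ma1") -> InterruptedTimeSeriesRegressor:
    """Fit the segmented model to the included months of a monthly series."""
    X, y = _series_to_Xy(series)
    return InterruptedTimeSeriesRegressor(tpi=tpi, error_spec=error_spec).fit(X, y)


def select_error_model(series: pd.DataFrame, tpi: int,
                       candidates: tuple[str, ...] = ("white", "ma1", "ar1", "sma12"),
                       ) -> InterruptedTimeSeriesRegressor:
    """Fit every candidate error process and keep the lowest AICc.

    Ties (within 1e-9) go to the model with fewer parameters, then to the
    earlier candidate in the list. If every candidate fails, raises with all
    the individual diagnostics.
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    fits: list[tuple[float, int, int, InterruptedTimeSeriesRegressor]] = []
    failures: list[str] = []
    for i, spec in enumerate(candidates):
        try:
            m = fit_its(series, tpi, error_spec=spec)
            fits.append((m.aicc_, m.k_params_, i, m))
        except Exception as exc:  # noqa: BLE001 — collect per-candidate diagnostics
            failures.append(f"{spec}: {exc}")
    if not fits:
        raise RuntimeError("all candidate error models failed:\n"
                           + "\n".join(failures))
    fits.sort(key=lambda f: (round(f[0], 9), f[1], f[2]))
    return fits[0][3]


def counterfactual(model: InterruptedTimeSeriesRegressor, t, calendar_months):
    """Counterfactual mean response time at month indices ``t``."""
    cal = np.asarray([m.month if isinstance(m, pd.Period) else int(m)
                      for m in np.asarray(calendar_months)])
    return model.counterfactual(np.column_stack([np.asarray(t, float), cal]))


def plot_its(series: pd.DataFrame, model: InterruptedTimeSeriesRegressor,
             path: str) -> None:
    """Observed monthly means, fitted segments, and counterfactual line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = series["t"].to_numpy(float)
    cal = np.asarray([m.month for m in series["calendar_month"]])
    X = np.column_stack([t, cal])
    fitted = model.predict(X)
    cf = model.counterfactual(X)
    inc = series["included"].to_numpy(bool)

    fig, ax = plt.subplots(figsize=(9, 5))
    ax.scatter(t[inc], series["mean_response"].to_numpy()[inc],
               s=22, color="black", label="monthly mean (included)")
    ax.scatter(t[~inc], series["mean_response"].to_numpy()[~inc],
               s=22, facecolors="none", edgecolors="grey", label="excluded month")
    pre = t < model.tpi
    ax.plot(t[pre], fitted[pre], color="tab:red", label="fitted trend")
    ax.plot(t[~pre], fitted[~pre], color="tab:red")
    ax.plot(t[~pre], cf[~pre], color="tab:blue", ls="--", label="counterfactual")
    ax.axvline(model.tpi, color="grey", ls=":", lw=1)
    ax.set_xlabel("month index")
    ax.set_ylabel("mean response time (min)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
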