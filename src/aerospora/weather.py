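"""Daily weather processing: wind speed, site seasonality models, anomalies.

Weather covariates (temperature, precipitation, wind speed) follow seasonal
cycles that depend on latitude, so raw values would be confounded with the
climatic and seasonal model terms.  Instead, each covariate is reduced to
its anomaly: the observed daily value minus the prediction of a
site-specific seasonality model (the CS4 structure — MAT quadratic fixed
effects, latitude-by-Fourier seasonality, and per-site random intercept and
seasonal slopes) fitted to the daily series by maximum likelihood.  A
positive temperature anomaly means the day was warmer than expected for
that site in that season.  Anomalies are then averaged over 1-day, 7-day or
30-day windows ending on the sampling date.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

DAYS_PER_YEAR = 365.0

WINDOWS = (1, 7, 30)


def wind_speed(u, v):
    """Euclidean wind speed sqrt(u^2 + v^2) from the eastward (u) and
    northward (v) components."""
    return np.hypot(u, v)


def add_wind_speed(weather: pd.DataFrame) -> pd.DataFrame:
    out = weather.copy()
    out["wind_speed"] = wind_speed(out["wind_u"], out["wind_v"])
    return out


def _fourier(doy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ang = 2.0 * np.pi * doy / DAYS_PER_YEAR
    return np.sin(ang), np.cos(ang)


@dataclass
class WeatherSeasonalityModel:
    """Fitted site-seasonality model for one weather variable.

    Holds the ML fixed effects and per-site BLUPs of the random intercept
    and seasonal slopes, enough to predict the expected value for any
    (site, day-of-year) among the fitted sites.
    """

    variable: str
    fixed_params: pd.Series
    site_effects: pd.DataFrame  # site x (intercept, sin, cos) BLUPs
    structure: str  # "CS4" or the "CS3" fallback
    loglik: float
    converged: bool

    def predict(self, sites: pd.DataFrame, site_ids, dates) -> np.ndarray:
        """Expected value per (site, date); raises for unknown sites."""
        site_ids = pd.Index(site_ids)
        unknown = set(site_ids) - set(self.site_effects.index)
        if unknown:
            raise KeyError(f"sites outside the fitted model: {sorted(unknown)[:5]}")
        meta = sites.set_index("site_id").loc[site_ids]
        doy = pd.DatetimeIndex(dates).dayofyear.to_numpy(dtype=float)
        s, c = _fourier(doy)
        mat = meta["mat"].to_numpy()
        lat = meta["latitude"].to_numpy()
        fp = self.fixed_params
        pred = (
            fp["intercept"]
            + fp["mat"] * mat
            + fp["mat2"] * mat**2
            + fp["lat_sin"] * lat * s
            + fp["lat_cos"] * lat * c
        )
        re = self.site_effects.loc[site_ids]
        pred = pred + re["intercept"].to_numpy()
        if self.structure == "CS4":
            pred = pred + re["sin"].to_numpy() * s + re["cos"].to_numpy() * c
        return pred


def fit_weather_seasonality(
    weather: pd.DataFrame, sites: pd.DataFrame, variable: str
) -> WeatherSeasonalityModel:
    """Fit the CS4 seasonality structure to one daily weather variable.

    Fixed effects: intercept, MAT, MAT^2, latitude x sin(2 pi d/365),
    latitude x cos(2 pi d/365).  Random effects per site: intercept plus
    both seasonal slopes with diagonal covariance, estimated by maximum
    likelihood.  Singular CS4 fits fall back to the CS3 structure (random
    intercept only) with a warning.
    """
    if variable == "wind_speed" and "wind_speed" not in weather.columns:
        weather = add_wind_speed(weather)
    df = weather.merge(sites[["site_id", "mat", "latitude"]], on="site_id")
    per_site_days = df.groupby("site_id")["date"].count()
    if (per_site_days < 365).any():
        raise ValueError("need at least one year of daily data per site")
    doy = pd.DatetimeIndex(df["date"]).dayofyear.to_numpy(dtype=float)
    s, c = _fourier(doy)
    df = df.assign(
        sin_d=s,
        cos_d=c,
        mat2=df["mat"] ** 2,
        lat_sin=df["latitude"] * s,
        lat_cos=df["latitude"] * c,
    )
    y = df[variable].to_numpy(dtype=float)
    exog = sm.add_constant(df[["mat", "mat2", "lat_sin", "lat_cos"]].to_numpy())

    structure = "CS4"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                y,
                exog,
                groups=df["site_id"].to_numpy(),
                exog_re=np.ones((len(df), 1)),
                exog_vc=_vc_design(df),
                use_sqrt=True,
            )
            fit = model.fit(reml=False, method="lbfgs", maxiter=400)
        singular = not np.all(np.isfinite(fit.params))
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        fit = None
    if singular:
        warnings.warn(f"CS4 fit for {variable} singular; falling back to CS3")
        structure = "CS3"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                y, exog, groups=df["site_id"].to_numpy(), exog_re=np.ones((len(df), 1))
            )
            fit = model.fit(reml=False, method="lbfgs", maxiter=400)

    fixed = pd.Series(
        fit.fe_params, index=["intercept", "mat", "mat2", "lat_sin", "lat_cos"]
    )
    site_ids = sorted(df["site_id"].unique())
    re_rows = []
    for sid in site_ids:
        re = fit.random_effects[sid]
        re = np.asarray(re, dtype=float).ravel()
        if structure == "CS4":
            # order: exog_re intercept, then vc terms (cos, sin alphabetical)
            re_rows.append([re[0], re[2], re[1]])
        else:
            re_rows.append([re[0], 0.0, 0.0])
    site_effects = pd.DataFrame(
        re_rows, index=pd.Index(site_ids, name="site_id"), columns=["intercept", "sin", "cos"]
    )
    return WeatherSeasonalityModel(
        variable=variable,
        fixed_params=fixed,
        site_effects=site_effects,
        structure=structure,
        loglik=float(fit.llf),
        converged=bool(getattr(fit, "converged", True)),
    )


def _vc_design(df: pd.DataFrame) -> dict:
    """Variance-component design: independent per-site sin and cos slopes."""
    groups = df["site_id"].unique()
    vc = {"cos": {}, "sin": {}}
    for g in groups:
        mask = (df["site_id"] == g).to_numpy()
        vc["sin"][g] = df.loc[mask, ["sin_d"]].to_numpy()
        vc["cos"][g] = df.loc[mask, ["cos_d"]].to_numpy()
    # statsmodels expects full-length design per group via VCSpec; use the
    # formula-free dict interface
    from statsmodels.regression.mixed_linear_model import VCSpec

    names = ["cos", "sin"]
    colnames = [[["cos_d"]] * len(groups), [["sin_d"]] * len(groups)]
    mats = []
    for name in names:
        mats.append([vc[name][g] for g in groups])
    return VCSpec(names, colnames, mats)


def compute_anomalies(
    weather: pd.DataFrame, sites: pd.DataFrame, model: WeatherSeasonalityModel
) -> pd.DataFrame:
    """observed - predicted for every site x day of the input series."""
    df = weather
    if model.variable == "wind_speed" and "wind_speed" not in df.columns:
        df = add_wind_speed(df)
    pred = model.predict(sites, df["site_id"], df["date"])
    return pd.DataFrame(
        {
            "site_id": df["site_id"].to_numpy(),
            "date": pd.to_datetime(df["date"]).to_numpy(),
            "variable": model.variable,
            "anomaly": df[model.variable].to_numpy(dtype=float) - pred,
        }
    )


def window_average(
    anomalies: pd.DataFrame, site_id: str, sample_date, window: int
) -> float:
    """Mean anomaly over the ``window`` days ending on the sampling date
    (inclusive, so window=1 is the sampling-day anomaly itself).

    Returns NaN with a warning when any day of the window is missing.
    """
    end = pd.Timestamp(sample_date)
    start = end - pd.Timedelta(days=window - 1)
    sub = anomalies[
        (anomalies["site_id"] == site_id)
        & (anomalies["date"] >= start)
        & (anomalies["date"] <= end)
    ]
    if len(sub) < window:
        warnings.warn(
            f"only {len(sub)}/{window} anomaly days available before "
            f"{end.date()} at {site_id}; returning NaN"
        )
        return float("nan")
    return float(sub["anomaly"].mean())


def anomaly_covariates(
    anomalies_by_var: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    windows=WINDOWS,
) -> pd.DataFrame:
    """Window-averaged anomaly covariates per sample.

    Returns one row per sample with columns ``{var}_{window}d`` for every
    variable and window, computed with rolling means over each site's daily
    series (windows end on the sampling date inclusive).
    """
    out = samples[["sample_id", "site_id", "date"]].copy()
    out["date"] = pd.to_datetime(out["date"])
    for var, anoms in anomalies_by_var.items():
        anoms = anoms.sort_values(["site_id", "date"])
        for w in windows:
            rolled = (
                anoms.set_index("date")
                .groupby("site_id")["anomaly"]
                .rolling(f"{w}D", min_periods=w)
                .mean()
                .rename(f"{var}_{w}d")
                .reset_index()
            )
            out = out.merge(rolled, on=["site_id", "date"], how="left")
    return out.set_index("sample_id")
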