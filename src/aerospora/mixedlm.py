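"""Climate/season/weather linear mixed models with AIC selection.

Four nested structures of climatic and seasonal variation are compared for
each response (log DNA amount, log richness + 1, CWM log spore volume,
log guild richness + 1):

* CS1 — null: site random intercept (plus log depth where relevant);
* CS2 — adds fixed MAT and MAT^2;
* CS3 — adds latitude-by-seasonality fixed effects, with seasonality the
  Fourier pair sin(2 pi d/365), cos(2 pi d/365) and latitude signed so the
  two hemispheres are automatically 6 months out of phase;
* CS4 — adds per-site random slopes on the seasonal terms.

On top of the best CS structure, four weather structures (W1-W4) add
anomaly covariates (temperature, precipitation, wind speed), each either
excluded or averaged over a 1-, 7- or 30-day window before sampling —
a 4^3 = 64-variant grid per W level.  All models are fitted by maximum
likelihood (not REML) so AIC is comparable across fixed-effect structures;
random-effect covariances are diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import VCSpec

DAYS_PER_YEAR = 365.0

WEATHER_COVARIATES = ("temp", "precip", "wind")
WEATHER_OPTIONS = ("excluded", "day", "week", "month")
WINDOW_DAYS = {"day": 1, "week": 7, "month": 30}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative structure of one candidate mixed model."""

    response: str
    cs_level: int = 1
    w_level: int = 0
    weather_inclusion: tuple = (("temp", "excluded"), ("precip", "excluded"), ("wind", "excluded"))
    include_log_depth: bool = True

    def __post_init__(self):
        if self.cs_level not in (1, 2, 3, 4):
            raise ValueError("cs_level must be 1..4")
        if self.w_level not in (0, 1, 2, 3, 4):
            raise ValueError("w_level must be 0 (none) .. 4")
        incl = dict(self.weather_inclusion)
        if set(incl) != set(WEATHER_COVARIATES):
            raise ValueError(f"weather_inclusion must cover {WEATHER_COVARIATES}")
        if any(v not in WEATHER_OPTIONS for v in incl.values()):
            raise ValueError(f"weather options are {WEATHER_OPTIONS}")
        if self.w_level == 0 and any(v != "excluded" for v in incl.values()):
            raise ValueError("w_level=0 requires all weather covariates excluded")

    @property
    def included_weather(self) -> list[tuple[str, int]]:
        """(covariate, window days) pairs actually included."""
        return [
            (cov, WINDOW_DAYS[opt])
            for cov, opt in self.weather_inclusion
            if opt != "excluded"
        ]

    def label(self) -> str:
        parts = [f"CS{self.cs_level}"]
        if self.w_level:
            incl = ",".join(f"{c}:{o}" for c, o in self.weather_inclusion if o != "excluded")
            parts.append(f"W{self.w_level}[{incl or 'null'}]")
        return "+".join(parts)


def enumerate_weather_grid(w_level: int, base: ModelSpec) -> list[ModelSpec]:
    """All 4^3 = 64 inclusion variants of the three weather covariates at
    one W level (including the all-excluded null)."""
    if w_level not in (1, 2, 3, 4):
        raise ValueError("w_level must be in 1..4")
    specs = []
    for opts in product(WEATHER_OPTIONS, repeat=len(WEATHER_COVARIATES)):
        incl = tuple(zip(WEATHER_COVARIATES, opts))
        level = w_level if any(o != "excluded" for o in opts) else w_level
        specs.append(
            ModelSpec(
                response=base.response,
                cs_level=base.cs_level,
                w_level=level,
                weather_inclusion=incl,
                include_log_depth=base.include_log_depth,
            )
        )
    return specs


def seasonal_columns(data: pd.DataFrame) -> pd.DataFrame:
    """Attach doy/sin/cos/lat-interaction columns derived from date and
    latitude."""
    out = data.copy()
    doy = pd.DatetimeIndex(pd.to_datetime(out["date"])).dayofyear.to_numpy(dtype=float)
    ang = 2.0 * np.pi * doy / DAYS_PER_YEAR
    out["sin_d"] = np.sin(ang)
    out["cos_d"] = np.cos(ang)
    out["lat_sin"] = out["latitude"] * out["sin_d"]
    out["lat_cos"] = out["latitude"] * out["cos_d"]
    out["mat2"] = out["mat"] ** 2
    return out


def build_design(spec: ModelSpec, data: pd.DataFrame):
    """Materialise the design for one spec.

    Returns ``(fixed, vc_columns, y, groups)`` where ``fixed`` is the
    fixed-effect DataFrame (with intercept), ``vc_columns`` maps variance-
    component names to design columns, and rows with missing values are
    dropped.  Requested anomaly windows missing from ``data`` raise a
    KeyError naming the column.
    """
    df = seasonal_columns(data)
    fixed_cols = []
    if spec.include_log_depth:
        fixed_cols.append("log_depth")
    if spec.cs_level >= 2:
        fixed_cols += ["mat", "mat2"]
    if spec.cs_level >= 3:
        fixed_cols += ["lat_sin", "lat_cos"]

    vc_columns: dict[str, list[str]] = {}
    if spec.cs_level >= 4:
        vc_columns["season_sin"] = ["sin_d"]
        vc_columns["season_cos"] = ["cos_d"]

    for cov, wdays in spec.included_weather:
        col = f"{cov}_{wdays}d"
        if col not in df.columns:
            raise KeyError(
                f"anomaly column {col!r} missing; precompute it with "
                "aerospora.weather.anomaly_covariates"
            )
        fixed_cols.append(col)
        if spec.w_level >= 2:
            df[f"{col}_x_mat"] = df[col] * df["mat"]
            df[f"{col}_x_mat2"] = df[col] * df["mat2"]
            fixed_cols += [f"{col}_x_mat", f"{col}_x_mat2"]
            vc_columns[f"site_{cov}"] = [col]
        if spec.w_level >= 3:
            df[f"{col}_x_latsin"] = df[col] * df["lat_sin"]
            df[f"{col}_x_latcos"] = df[col] * df["lat_cos"]
            fixed_cols += [f"{col}_x_latsin", f"{col}_x_latcos"]
        if spec.w_level >= 4:
            df[f"{col}_x_sin"] = df[col] * df["sin_d"]
            df[f"{col}_x_cos"] = df[col] * df["cos_d"]
            vc_columns[f"site_{cov}_sin"] = [f"{col}_x_sin"]
            vc_columns[f"site_{cov}_cos"] = [f"{col}_x_cos"]

    needed = [spec.response, *fixed_cols, "site_id", "sin_d", "cos_d"]
    needed += [c for cols in vc_columns.values() for c in cols]
    df = df.dropna(subset=[c for c in dict.fromkeys(needed)])
    fixed = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for c in fixed_cols:
        fixed[c] = df[c].to_numpy()
    return fixed, vc_columns, df[spec.response].to_numpy(dtype=float), df


@dataclass
class MixedFitResult:
    """ML fit of one candidate model."""

    spec: ModelSpec
    loglik: float
    n_params: int
    aic: float
    fixed_coefs: pd.Series
    re_variances: pd.Series
    converged: bool
    n_obs: int
    fixed_bse: pd.Series | None = field(default=None, repr=False)
    site_effects: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"Mixed model {self.spec.label()} for {self.spec.response!r}",
            f"  n obs {self.n_obs}   logLik {self.loglik:.3f}   "
            f"k {self.n_params}   AIC {self.aic:.2f}   converged {self.converged}",
            "  fixed effects:",
        ]
        lines += [f"    {k:<18s} {v:+.5f}" for k, v in self.fixed_coefs.items()]
        lines.append("  random-effect variances:")
        lines += [f"    {k:<18s} {v:.5f}" for k, v in self.re_variances.items()]
        return "\n".join(lines)


class SeasonalMixedModel:
    """One candidate mixed model (a ModelSpec bound to data).

    ``fit()`` estimates by maximum likelihood so that AIC comparisons
    across fixed-effect structures are valid; random-slope covariances are
    diagonal.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.fixed, self.vc_columns, self.y, self.frame = build_design(spec, data)

    def fit(self, maxiter: int = 300) -> MixedFitResult:
        groups = self.frame["site_id"].to_numpy()
        exog = self.fixed.to_numpy()
        exog_vc = None
        if self.vc_columns:
            exog_vc = _vcspec(self.frame, groups, self.vc_columns)
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(
                self.y, exog, groups=groups, exog_re=np.ones((len(self.y), 1)),
                exog_vc=exog_vc,
            )
            try:
                res = model.fit(reml=False, maxiter=maxiter)
                converged = (
                    bool(res.converged)
                    and np.all(np.isfinite(res.params))
                    and np.isfinite(res.llf)
                )
            except (np.linalg.LinAlgError, ValueError):
                res = None
                converged = False
        if res is None:
            nan = float("nan")
            return MixedFitResult(
                spec=self.spec, loglik=nan, n_params=0, aic=nan,
                fixed_coefs=pd.Series(dtype=float), re_variances=pd.Series(dtype=float),
                converged=False, n_obs=len(self.y),
            )
        fixed_coefs = pd.Series(res.fe_params, index=list(self.fixed.columns))
        re_vars = {"site_intercept": float(np.asarray(res.cov_re)[0, 0])}
        for i, name in enumerate(sorted(self.vc_columns)):
            re_vars[name] = float(res.vcomp[i])
        re_vars["residual"] = float(res.scale)
        k = len(fixed_coefs) + 1 + len(self.vc_columns) + 1  # + site var + resid var
        loglik = float(res.llf)
        try:
            site_effects = pd.DataFrame(
                {g: np.asarray(v, dtype=float).ravel() for g, v in res.random_effects.items()}
            ).T
        except ValueError:  # singular RE covariance: BLUPs unavailable
            site_effects = None
        return MixedFitResult(
            spec=self.spec,
            loglik=loglik,
            n_params=k,
            aic=-2.0 * loglik + 2.0 * k,
            fixed_coefs=fixed_coefs,
            re_variances=pd.Series(re_vars),
            converged=converged,
            n_obs=len(self.y),
            fixed_bse=pd.Series(
                np.asarray(res.bse_fe, dtype=float), index=list(self.fixed.columns)
            ),
            site_effects=site_effects,
        )


def _vcspec(frame: pd.DataFrame, groups: np.ndarray, vc_columns: dict) -> VCSpec:
    names = sorted(vc_columns)
    ug = pd.unique(groups)
    colnames, mats = [], []
    for name in names:
        cols = vc_columns[name]
        colnames.append([cols] * len(ug))
        mats.append([frame.loc[groups == g, cols].to_numpy() for g in ug])
    return VCSpec(names, colnames, mats)


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> MixedFitResult:
    """Build and fit one candidate model (convenience wrapper)."""
    return SeasonalMixedModel(spec, data).fit()


def select_by_aic(fits: list[MixedFitResult]) -> tuple[MixedFitResult, pd.DataFrame]:
    """Minimal-AIC fit among converged candidates.

    Ties break toward fewer parameters, then stable input order.  Returns
    the winner and a delta-AIC table.
    """
    converged = [f for f in fits if f.converged]
    dropped = len(fits) - len(converged)
    if dropped:
        warnings.warn(f"{dropped} non-converged candidates dropped from selection")
    if not converged:
        raise ValueError("no converged fits to select among")
    order = sorted(range(len(converged)), key=lambda i: (converged[i].aic, converged[i].n_params, i))
    best = converged[order[0]]
    table = pd.DataFrame(
        {
            "spec": [f.spec.label() for f in converged],
            "loglik": [f.loglik for f in converged],
            "k": [f.n_params for f in converged],
            "aic": [f.aic for f in converged],
        }
    )
    table["delta_aic"] = table["aic"] - best.aic
    return best, table.sort_values("aic", kind="stable").reset_index(drop=True)


def select_cs_level(response: str, data: pd.DataFrame, include_log_depth=True):
    """Fit CS1..CS4 and return (best fit, table)."""
    fits = [
        fit_lmm(ModelSpec(response=response, cs_level=lvl, include_log_depth=include_log_depth), data)
        for lvl in (1, 2, 3, 4)
    ]
    return select_by_aic(fits)


def select_weather_model(best_cs: ModelSpec, data: pd.DataFrame, w_levels=(1, 2, 3, 4)):
    """Holding the best CS structure, select among W levels x 64 grids."""
    fits = []
    for w in w_levels:
        for spec in enumerate_weather_grid(w, base=best_cs):
            fits.append(fit_lmm(spec, data))
    return select_by_aic(fits)


def predict_seasonal_curves(
    fit: MixedFitResult, zone_profiles: pd.DataFrame, n_days: int = 73
) -> pd.DataFrame:
    """Fixed-effects-only predictions over the year per climatic zone.

    ``zone_profiles`` carries one row per zone with representative ``mat``
    and ``latitude`` (Northern-Hemisphere convention).  Weather anomaly
    terms are evaluated at zero (a typical day).  Specs without seasonal
    terms yield flat curves.
    """
    days = np.linspace(0.0, DAYS_PER_YEAR, n_days, endpoint=False)
    ang = 2.0 * np.pi * days / DAYS_PER_YEAR
    coefs = fit.fixed_coefs
    rows = []
    for zp in zone_profiles.itertuples(index=False):
        pred = np.full(len(days), coefs.get("intercept", 0.0))
        if "log_depth" in coefs:
            pred += coefs["log_depth"] * getattr(zp, "log_depth", 0.0)
        if "mat" in coefs:
            pred += coefs["mat"] * zp.mat + coefs["mat2"] * zp.mat**2
        if "lat_sin" in coefs:
            pred += zp.latitude * (coefs["lat_sin"] * np.sin(ang) + coefs["lat_cos"] * np.cos(ang))
        rows.append(
            pd.DataFrame({"zone": zp.zone, "day": days, "prediction": pred})
        )
    return pd.concat(rows, ignore_index=True)


def simulate_cs_response(
    data: pd.DataFrame,
    cs_level: int,
    coefs: dict,
    site_sd: float = 0.3,
    season_slope_sd: float = 0.2,
    resid_sd: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Draw a response from a known CS-structure truth over ``data``'s design.

    ``coefs`` maps fixed-effect names (intercept, log_depth, mat, mat2,
    lat_sin, lat_cos) to true values; terms above ``cs_level`` are ignored.
    CS4 truth adds per-site random seasonal slopes with sd
    ``season_slope_sd``.  Used for model-recovery simulations.
    """
    rng = np.random.default_rng(seed)
    df = seasonal_columns(data)
    y = np.full(len(df), float(coefs.get("intercept", 0.0)))
    if "log_depth" in coefs and "log_depth" in df:
        y += coefs["log_depth"] * df["log_depth"].to_numpy()
    if cs_level >= 2:
        y += coefs.get("mat", 0.0) * df["mat"].to_numpy()
        y += coefs.get("mat2", 0.0) * df["mat2"].to_numpy()
    if cs_level >= 3:
        y += coefs.get("lat_sin", 0.0) * df["lat_sin"].to_numpy()
        y += coefs.get("lat_cos", 0.0) * df["lat_cos"].to_numpy()
    sites, idx = np.unique(df["site_id"], return_inverse=True)
    y += rng.normal(0.0, site_sd, len(sites))[idx]
    if cs_level >= 4:
        bs = rng.normal(0.0, season_slope_sd, len(sites))[idx]
        bc = rng.normal(0.0, season_slope_sd, len(sites))[idx]
        y += bs * df["sin_d"].to_numpy() + bc * df["cos_d"].to_numpy()
    return y + rng.normal(0.0, resid_sd, len(df))


def plot_seasonal_curves(curves: pd.DataFrame, ax=None):
    """Line plot of per-zone seasonal predictions (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for zone, sub in curves.groupby("zone"):
        ax.plot(sub["day"], sub["prediction"], label=str(zone))
    ax.set_xlabel("day of year")
    ax.set_ylabel("prediction")
    ax.legend()
    return ax
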