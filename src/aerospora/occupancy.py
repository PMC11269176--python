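"""Per-species probit occurrence models and climatic/seasonal response
metrics.

Each sufficiently common species (>= 50 occurrences by default) is fitted
with a Bayesian probit regression of presence/absence on the second-order
MAT polynomial, the latitude-by-Fourier seasonality interaction and log
sequencing depth, with a site random intercept.  Sampling uses the
Albert-Chib latent-variable Gibbs scheme: truncated-normal latent scores,
conjugate normal updates for the coefficients and site effects, and an
inverse-gamma update for the site-effect variance.  Convergence is
monitored with the Gelman-Rubin potential scale-reduction factor across
chains.

From each fit, derived metrics summarise the species' response: Tjur R^2
and AUC for discrimination; the share of linear-predictor variance carried
by the MAT polynomial versus the seasonal terms; climatic and seasonal
sensitivity (variance share times Tjur R^2); the optimal MAT (vertex of
the quadratic truncated to the observed MAT range); and the optimal day of
year (peak of the seasonal sinusoid, Northern-Hemisphere convention, with
a 182.5-day shift for Southern-Hemisphere interpretation).  Optima are
reported only where the matching sensitivity reaches 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.metrics import roc_auc_score

DAYS_PER_YEAR = 365.0

SENSITIVITY_THRESHOLD = 0.05

COEF_NAMES = ("intercept", "b_mat", "b_mat2", "b_latsin", "b_latcos", "b_logdepth")

#: published full MCMC schedule: 4 chains x 37,500 iterations, 12,500
#: burn-in, thinning 100 -> 250 draws per chain, 1,000 total
FULL_SCHEDULE = dict(n_chains=4, n_iter=37_500, burn_in=12_500, thin=100)


@dataclass(frozen=True)
class MCMCSchedule:
    """Chains/iterations/burn-in/thinning of the Gibbs sampler."""

    n_chains: int = 2
    n_iter: int = 1_500
    burn_in: int = 500
    thin: int = 5

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")

    @property
    def draws_per_chain(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.draws_per_chain


def published_schedule() -> MCMCSchedule:
    return MCMCSchedule(**FULL_SCHEDULE)


# ---------------------------------------------------------------------------
# design and species selection
# ---------------------------------------------------------------------------

def select_common_species(
    presence: pd.DataFrame, min_occurrences: int = 50
) -> list[str]:
    """Species with at least ``min_occurrences`` presences (inclusive)."""
    counts = presence.sum(axis=0)
    return [str(c) for c in presence.columns[counts >= min_occurrences]]


def occupancy_design(samples: pd.DataFrame, sites: pd.DataFrame, log_depth: pd.Series):
    """Fixed-effect design (intercept, MAT, MAT^2, lat sin, lat cos,
    centred log depth) plus site index per sample."""
    meta = samples.merge(sites[["site_id", "mat", "latitude"]], on="site_id")
    meta = meta.set_index("sample_id").loc[log_depth.index]
    doy = pd.DatetimeIndex(pd.to_datetime(meta["date"])).dayofyear.to_numpy(dtype=float)
    ang = 2.0 * np.pi * doy / DAYS_PER_YEAR
    ld = log_depth.to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(meta)),
            meta["mat"].to_numpy(),
            meta["mat"].to_numpy() ** 2,
            meta["latitude"].to_numpy() * np.sin(ang),
            meta["latitude"].to_numpy() * np.cos(ang),
            ld - np.nanmean(ld),
        ]
    )
    sites_idx, site_labels = pd.factorize(meta["site_id"])
    return X, sites_idx, list(site_labels), meta


# ---------------------------------------------------------------------------
# Albert-Chib Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass
class ProbitOccupancyResults:
    """Posterior summary of one species' probit occurrence model."""

    species_id: str
    coefs: pd.Series  # posterior means on the original covariate scale
    site_re_variance: float
    draws: np.ndarray = field(repr=False)  # (chains, draws, p + 1) coefs + log site var
    psrf: pd.Series | None = None
    converged: bool = True
    fitted_prob: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [f"Probit occurrence model: {self.species_id}"]
        sd = self.draws[..., : len(self.coefs)].reshape(-1, len(self.coefs)).std(axis=0)
        for i, (k, v) in enumerate(self.coefs.items()):
            line = f"  {k:<12s} {v:+.4f} (sd {sd[i]:.4f})"
            if self.psrf is not None:
                line += f"  PSRF {self.psrf.iloc[i]:.3f}"
            lines.append(line)
        lines.append(f"  site RE variance {self.site_re_variance:.4f}")
        return "\n".join(lines)


class ProbitOccupancyModel:
    """Bayesian probit occurrence model with a site random intercept.

    Priors: N(0, 2^2) on fixed effects of standardised covariates
    (transformed back to the input scale in the results) and a
    weakly-informative inverse-gamma(2, 0.1) on the site-effect variance
    (prior mean 0.1, letting the posterior concentrate near zero when the
    data carry no site structure).

    Parameters
    ----------
    y : binary presence vector.
    X : fixed-effect design including the leading intercept column.
    site_index : integer site id per observation.
    """

    prior_sd = 2.0
    ig_shape = 2.0
    ig_scale = 0.1

    def __init__(self, y, X, site_index, species_id: str = "species"):
        y = np.asarray(y, dtype=int)
        X = np.asarray(X, dtype=float)
        if y.min() == y.max():
            raise ValueError(
                f"{species_id}: all-present or all-absent pattern; cannot fit"
            )
        self.species_id = species_id
        self.y = y
        # standardise non-intercept columns for the prior scale
        self._mean = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._mean[0], self._sd[0] = 0.0, 1.0
        self._sd[self._sd == 0] = 1.0
        self.Xs = (X - self._mean) / self._sd
        self.site_index = np.asarray(site_index)
        self.n_sites = int(self.site_index.max()) + 1
        self._site_counts = np.bincount(self.site_index, minlength=self.n_sites)

    def fit(self, schedule: MCMCSchedule = MCMCSchedule(), seed: int = 0) -> ProbitOccupancyResults:
        p = self.Xs.shape[1]
        chains = []
        fitted = np.zeros(len(self.y))
        n_fit_draws = 0
        prec0 = np.eye(p) / self.prior_sd**2
        XtX = self.Xs.T @ self.Xs
        post_prec = XtX + prec0
        chol = np.linalg.cholesky(np.linalg.inv(post_prec))
        ss = np.random.SeedSequence(seed)
        for chain_seed in ss.spawn(schedule.n_chains):
            rng = np.random.default_rng(chain_seed)
            out, fsum, nf = self._run_chain(rng, schedule, post_prec, chol)
            chains.append(out)
            fitted += fsum
            n_fit_draws += nf
        draws = np.stack(chains)  # (chains, draws, p+1)
        coef_draws = draws[..., :p].reshape(-1, p)
        coefs_std = coef_draws.mean(axis=0)
        # back-transform to the original covariate scale
        coefs = coefs_std / self._sd
        coefs[0] = coefs_std[0] - np.sum(coefs_std[1:] * self._mean[1:] / self._sd[1:])
        psrf_vals = psrf(draws) if schedule.n_chains >= 2 else None
        return ProbitOccupancyResults(
            species_id=self.species_id,
            coefs=pd.Series(coefs, index=COEF_NAMES[: p]),
            site_re_variance=float(np.exp(draws[..., p]).mean()),
            draws=draws,
            psrf=psrf_vals,
            converged=bool(psrf_vals is None or (psrf_vals < 1.2).all()),
            fitted_prob=fitted / max(n_fit_draws, 1),
        )

    def _run_chain(self, rng, schedule, post_prec, chol):
        n, p = self.Xs.shape
        beta = np.zeros(p)
        alpha = np.zeros(self.n_sites)
        sigma2 = 0.5
        lo = np.where(self.y == 1, 0.0, -np.inf)
        hi = np.where(self.y == 1, np.inf, 0.0)
        keep = []
        fitted_sum = np.zeros(n)
        n_fit = 0
        for it in range(schedule.n_iter):
            eta = self.Xs @ beta + alpha[self.site_index]
            # latent truncated-normal scores via inverse-CDF
            a = ndtr(lo - eta)
            b = ndtr(hi - eta)
            u = rng.uniform(a, np.maximum(b, a + 1e-12))
            z = eta + ndtri(np.clip(u, 1e-12, 1 - 1e-12))
            # fixed effects: conjugate normal
            resid = z - alpha[self.site_index]
            mean = np.linalg.solve(post_prec, self.Xs.T @ resid)
            beta = mean + chol @ rng.standard_normal(p)
            # site effects: conjugate normal per site
            r2 = z - self.Xs @ beta
            ssum = np.bincount(self.site_index, weights=r2, minlength=self.n_sites)
            prec = self._site_counts + 1.0 / sigma2
            alpha = ssum / prec + rng.standard_normal(self.n_sites) / np.sqrt(prec)
            # site variance: inverse-gamma
            sigma2 = 1.0 / rng.gamma(
                self.ig_shape + 0.5 * self.n_sites,
                1.0 / (self.ig_scale + 0.5 * np.sum(alpha**2)),
            )
            if it >= schedule.burn_in and (it - schedule.burn_in) % schedule.thin == 0:
                keep.append(np.append(beta, np.log(sigma2)))
                fitted_sum += ndtr(self.Xs @ beta + alpha[self.site_index])
                n_fit += 1
        return np.array(keep), fitted_sum, n_fit


def psrf(draws: np.ndarray) -> pd.Series:
    """Gelman-Rubin potential scale-reduction factor per parameter.

    ``draws`` has shape (chains, iterations, parameters); needs >= 2
    chains.
    """
    if draws.ndim != 3 or draws.shape[0] < 2:
        raise ValueError("psrf needs draws shaped (chains >= 2, iters, params)")
    m, n, _ = draws.shape
    chain_means = draws.mean(axis=1)
    chain_vars = draws.var(axis=1, ddof=1)
    W = chain_vars.mean(axis=0)
    B = n * chain_means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(var_hat / W)
    names = [*COEF_NAMES[: draws.shape[2] - 1], "log_site_var"]
    return pd.Series(np.where(W > 0, r, 1.0), index=names[: draws.shape[2]])


# ---------------------------------------------------------------------------
# discrimination metrics
# ---------------------------------------------------------------------------

def tjur_r2(observed, predicted) -> float:
    """Mean predicted probability over presences minus mean over absences."""
    observed = np.asarray(observed, dtype=bool)
    predicted = np.asarray(predicted, dtype=float)
    if observed.all() or (~observed).all():
        raise ValueError("Tjur R^2 undefined with a single class")
    return float(predicted[observed].mean() - predicted[~observed].mean())


def auc(observed, predicted) -> float:
    """Probability a random presence outranks a random absence (ties 1/2)."""
    observed = np.asarray(observed, dtype=int)
    if observed.min() == observed.max():
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(observed, np.asarray(predicted, dtype=float)))


# ---------------------------------------------------------------------------
# variance partitioning and sensitivities
# ---------------------------------------------------------------------------

def variance_partition_fixed(
    coefs: pd.Series, X: np.ndarray, site_re_variance: float
) -> pd.Series:
    """Share of linear-predictor variance per predictor group.

    Groups: the MAT polynomial, the seasonal (latitude x Fourier) pair,
    log depth, and the site random effect (entering with its estimated
    variance).  Cross-group covariances are excluded; shares are
    normalised to sum to 1.
    """
    contrib = {
        "mat": X[:, 1] * coefs["b_mat"] + X[:, 2] * coefs["b_mat2"],
        "seasonal": X[:, 3] * coefs["b_latsin"] + X[:, 4] * coefs["b_latcos"],
        "log_depth": X[:, 5] * coefs["b_logdepth"],
    }
    variances = {k: float(np.var(v)) for k, v in contrib.items()}
    variances["site"] = max(float(site_re_variance), 0.0)
    total = sum(variances.values())
    if total == 0:
        return pd.Series({k: np.nan for k in variances})
    return pd.Series({k: v / total for k, v in variances.items()})


def sensitivities(shares: pd.Series, tjur: float) -> tuple[float, float]:
    """Climatic and seasonal sensitivity: variance share x Tjur R^2.

    Negative Tjur R^2 values floor the sensitivities at 0.
    """
    t = max(float(tjur), 0.0)
    return float(shares["mat"] * t), float(shares["seasonal"] * t)


def optimal_mat(coefs: pd.Series, mat_range: tuple, sensitivity: float) -> float:
    """MAT maximising the quadratic, truncated to the observed range.

    Undefined (NaN) below the 5% climatic-sensitivity rule.  With a convex
    quadratic (b_mat2 > 0) the better boundary wins.
    """
    if sensitivity < SENSITIVITY_THRESHOLD:
        return float("nan")
    lo, hi = float(mat_range[0]), float(mat_range[1])
    b1, b2 = float(coefs["b_mat"]), float(coefs["b_mat2"])
    quad = lambda m: b1 * m + b2 * m**2  # noqa: E731
    if b2 < 0:
        vertex = -b1 / (2.0 * b2)
        if lo <= vertex <= hi:
            return float(vertex)
    return float(lo if quad(lo) >= quad(hi) else hi)


SEASON_BINS = (
    ((12, 1, 2), "winter"),
    ((3, 4, 5), "spring"),
    ((6, 7, 8), "summer"),
    ((9, 10, 11), "autumn"),
)


def season_of_day(day: float) -> str:
    """Meteorological season (Northern-Hemisphere month windows) of a
    day-of-year."""
    month = pd.Timestamp("2001-01-01") + pd.Timedelta(days=float(day) % DAYS_PER_YEAR)
    for months, label in SEASON_BINS:
        if month.month in months:
            return label
    raise AssertionError("unreachable")


def optimal_day(
    coefs: pd.Series, sensitivity: float, hemisphere: str = "north"
) -> tuple[float, str]:
    """Day of year at which the seasonal sinusoid peaks, plus its season.

    The phase is computed under the Northern-Hemisphere convention
    (atan2 of the sin/cos coefficients; positive latitude scaling leaves
    the phase unchanged); Southern-Hemisphere interpretation adds 182.5
    days.  Undefined (NaN) below the 5% seasonal-sensitivity rule or when
    both coefficients vanish.
    """
    if sensitivity < SENSITIVITY_THRESHOLD:
        return float("nan"), ""
    bs, bc = float(coefs["b_latsin"]), float(coefs["b_latcos"])
    if bs == 0.0 and bc == 0.0:
        return float("nan"), ""
    theta = np.arctan2(bs, bc)
    day = (theta / (2.0 * np.pi) * DAYS_PER_YEAR) % DAYS_PER_YEAR
    if hemisphere == "south":
        day = (day + DAYS_PER_YEAR / 2.0) % DAYS_PER_YEAR
    return float(day), season_of_day(day)


# ---------------------------------------------------------------------------
# batteries
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMetrics:
    species_id: str
    tjur_r2: float
    auc: float
    climatic_sensitivity: float
    seasonal_sensitivity: float
    optimal_mat: float
    optimal_day: float
    season_bin: str


def species_metrics(
    presence: pd.DataFrame,
    samples: pd.DataFrame,
    sites: pd.DataFrame,
    log_depth: pd.Series,
    min_occurrences: int = 50,
    schedule: MCMCSchedule = MCMCSchedule(),
    seed: int = 0,
    species_subset=None,
) -> tuple[pd.DataFrame, dict]:
    """Fit every common species and derive its sensitivity metrics.

    Returns the metrics table and a dict of the underlying
    :class:`ProbitOccupancyResults` keyed by species.
    """
    X, site_idx, _, meta = occupancy_design(samples, sites, log_depth)
    presence = presence.loc[meta.index]
    common = select_common_species(presence, min_occurrences)
    if species_subset is not None:
        common = [s for s in common if s in set(species_subset)]
    mat_range = (meta["mat"].min(), meta["mat"].max())
    rows, fits = [], {}
    ss = np.random.SeedSequence(seed)
    for sp, sp_seed in zip(common, ss.spawn(len(common))):
        y = presence[sp].to_numpy(dtype=int)
        if y.min() == y.max():
            warnings.warn(f"{sp}: single-class pattern; excluded")
            continue
        model = ProbitOccupancyModel(y, X, site_idx, species_id=sp)
        res = model.fit(schedule=schedule, seed=sp_seed.generate_state(1)[0] % (2**31))
        fits[sp] = res
        t = tjur_r2(y, res.fitted_prob)
        a = auc(y, res.fitted_prob)
        shares = variance_partition_fixed(res.coefs, X, res.site_re_variance)
        cs, ses = sensitivities(shares, t)
        om = optimal_mat(res.coefs, mat_range, cs)
        od, bin_ = optimal_day(res.coefs, ses)
        rows.append(
            SensitivityMetrics(
                species_id=sp, tjur_r2=t, auc=a,
                climatic_sensitivity=cs, seasonal_sensitivity=ses,
                optimal_mat=om, optimal_day=od, season_bin=bin_,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]), fits


def order_summaries(
    metrics: pd.DataFrame, taxonomy: pd.DataFrame, min_species: int = 10
) -> pd.DataFrame:
    """Median/quartile/extreme sensitivities per order, restricted to
    orders represented by at least ``min_species`` analysed species."""
    order_of = taxonomy.set_index("otu_id")["order"]
    df = metrics.assign(order=metrics["species_id"].map(order_of))
    rows = []
    for order, sub in df.groupby("order"):
        if len(sub) < min_species:
            continue
        row = {"order": order, "n_species": len(sub)}
        for col in ("climatic_sensitivity", "seasonal_sensitivity"):
            q = sub[col].quantile([0.0, 0.25, 0.5, 0.75, 1.0])
            row.update(
                {
                    f"{col}_min": q[0.0], f"{col}_q1": q[0.25],
                    f"{col}_median": q[0.5], f"{col}_q3": q[0.75],
                    f"{col}_max": q[1.0],
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
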