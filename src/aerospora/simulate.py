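"""Seeded synthetic data generator for the full analysis pipeline.

Emulates a global air-sampling study: sites spanning both hemispheres with
40-year climate normals, daily weather with seasonal cycles and AR(1)
anomalies, a nested seven-rank taxonomy, species occurrence driven by a
probit model (MAT quadratic + latitude-dependent Fourier seasonality +
log sequencing depth + site effects), read counts with a spike-in column,
trait tables with realistic coverage gaps, and sparse cross-contamination
in negative controls.  All ground-truth parameters are recorded so that
every downstream estimator can be tested for recovery.

Species-level probit coefficients are drawn as a lambda-weighted mixture of
a tree-structured component (correlation equal to the taxonomy correlation
matrix) and an independent component, so that Pagel's lambda of each
coefficient equals ``lambda_target`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import RANKS, build_taxon_tree, taxonomy_to_correlation, write_newick

DAYS_PER_YEAR = 365.0

#: closed guild vocabulary (grouped trophic guilds)
GUILD_VOCABULARY = (
    "plant pathogen",
    "saprotroph",
    "wood saprotroph",
    "ectomycorrhizal",
    "ericoid mycorrhizal",
    "lichenized",
    "endophyte",
    "animal parasite",
    "mycoparasite",
)

#: climatic-zone thresholds on MAT (degC); configurable via SimConfig
ZONE_TROPICAL_MAT = 18.0
ZONE_POLAR_MAT = 3.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the published study design: ~40 sites on all
    continents, weekly 24-h samples over two years, ~300 species in a
    nested taxonomy, occurrence controlled by a site-climate quadratic and
    latitude-scaled seasonality, and 11% of negative controls carrying a
    few reads of common OTUs (the observed 89%-clean rate).
    """

    seed: int = 0
    n_sites: int = 40
    #: (phyla, classes/phylum, orders/class, families/order, genera/family,
    #: species/genus) under a single kingdom
    ranks_fanout: tuple = (2, 3, 5, 1, 2, 5)
    date_range: tuple = ("2021-01-01", "2022-12-31")
    sampling_interval_days: int = 7
    #: (log-mean, log-sd) of total reads per sample
    depth_distribution: tuple = (10.8, 0.6)
    spike_fraction_mean: float = 0.10
    #: sd of the (linear, quadratic) MAT occurrence coefficients
    beta_mat: tuple = (0.08, 0.003)
    #: probit-scale seasonal amplitude of a typical |latitude| = 60 site
    beta_season: float = 1.2
    #: Pagel's lambda of the species coefficient vectors, in [0, 1]
    lambda_target: float = 0.5
    #: sd of per-species-per-site random effects (probit scale)
    site_sigma: float = 0.5
    contamination_rate: float = 0.11
    #: matches the published study's negative-control count
    n_negative_controls: int = 99
    # -- weather structure --
    weather_ar1_rho: float = 0.7
    weather_anomaly_sd: float = 2.2
    #: seasonal temperature half-amplitude per degree of |latitude|
    season_amp_per_deg: float = 0.33
    # -- trait coverage (fraction of species with a database entry) --
    trait_species_coverage: float = 0.55
    #: fraction of covered species whose asexual / sexual entry is missing
    trait_stage_missing: tuple = (0.25, 0.25)
    # -- occurrence coefficient location parameters --
    intercept_mean: float = -1.0
    intercept_sd: float = 0.6
    beta_mat_mean: tuple = (0.24, -0.010)
    beta_logdepth_mean: float = 0.25
    beta_logdepth_sd: float = 0.10
    zone_tropical_mat: float = ZONE_TROPICAL_MAT
    zone_polar_mat: float = ZONE_POLAR_MAT

    @property
    def n_species(self) -> int:
        return int(np.prod(self.ranks_fanout))

    def __post_init__(self):
        if len(self.ranks_fanout) != 6:
            raise ValueError("ranks_fanout needs 6 entries (phyla..species)")
        if any(f < 1 for f in self.ranks_fanout):
            raise ValueError("every rank fanout must be >= 1")
        if not 0.0 <= self.lambda_target <= 1.0:
            raise ValueError("lambda_target must be in [0, 1]")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be in [0, 1]")
        for name in ("site_sigma", "beta_season", "weather_anomaly_sd", "season_amp_per_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        start, end = pd.Timestamp(self.date_range[0]), pd.Timestamp(self.date_range[1])
        if (end - start).days < 365:
            raise ValueError("date_range must span at least one year")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticDataset:
    """All generated tables plus the ground truth that produced them."""

    config: SimConfig
    sites: pd.DataFrame
    weather: pd.DataFrame
    taxonomy: pd.DataFrame
    truth: pd.DataFrame
    traits: pd.DataFrame
    samples: pd.DataFrame
    otu_table: pd.DataFrame
    negcontrols: pd.DataFrame

    def write(self, outdir) -> None:
        """Write all tables as CSV plus the taxonomy tree as Newick."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(outdir / "sites.csv", index=False)
        self.weather.to_csv(outdir / "weather.csv", index=False)
        self.taxonomy.to_csv(outdir / "taxonomy.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.traits.to_csv(outdir / "traits.csv", index=False)
        self.samples[["sample_id", "site_id", "date"]].to_csv(
            outdir / "samples.csv", index=False
        )
        if "latent_intensity" in self.samples.columns:
            self.samples[["sample_id", "latent_intensity"]].to_csv(
                outdir / "truth_samples.csv", index=False
            )
        self.otu_table.to_csv(outdir / "otu_table.csv")
        self.negcontrols.to_csv(outdir / "negcontrols.csv")
        write_newick(build_taxon_tree(self.taxonomy), outdir / "taxonomy.nwk")


def zone_label(mat, tropical_mat=ZONE_TROPICAL_MAT, polar_mat=ZONE_POLAR_MAT):
    """Climatic zone from MAT: >=18 tropical-subtropical, 3..18 temperate,
    <3 polar-continental."""
    mat = np.asarray(mat, dtype=float)
    out = np.where(
        mat >= tropical_mat,
        "tropical-subtropical",
        np.where(mat < polar_mat, "polar-continental", "temperate"),
    )
    return out if out.ndim else out.item()


def simulate_sites(config: SimConfig) -> pd.DataFrame:
    """Generate the site table with coordinates, climate normals and zones.

    Latitude magnitudes are stratified over [2, 70] degrees with alternating
    hemispheres, which guarantees that all three climatic zones are
    represented for any n_sites >= 4.  MAT decreases with |latitude| at
    ~0.47 degC per degree plus noise.
    """
    if config.n_sites < 4:
        raise ValueError("n_sites must be >= 4 (variance partitioning needs >= 4 sites)")
    rng = np.random.default_rng(_stream(config.seed, 1))
    n = config.n_sites
    mag = np.linspace(2.0, 70.0, n)
    sign = np.where(np.arange(n) % 3 == 2, -1.0, 1.0)  # NH-heavy, both hemispheres
    lat = np.clip(sign * (mag + rng.normal(0.0, 2.0, n)), -78.0, 78.0)
    lon = rng.uniform(-180.0, 180.0, n)
    mat = 27.0 - 0.47 * np.abs(lat) + rng.normal(0.0, 1.5, n)
    map_mm = np.exp(rng.normal(6.7, 0.6, n))  # median ~800 mm/yr
    mai = np.clip(map_mm / 1200.0 + rng.normal(0.0, 0.2, n), 0.02, None)
    wind = np.exp(rng.normal(1.2, 0.35, n))  # median ~3.3 m/s
    return pd.DataFrame(
        {
            "site_id": [f"S{i:03d}" for i in range(n)],
            "latitude": lat,
            "longitude": lon,
            "mat": mat,
            "map": map_mm,
            "mai": mai,
            "wind": wind,
            "zone": zone_label(mat, config.zone_tropical_mat, config.zone_polar_mat),
        }
    )


def _seasonal_phase(lat) -> np.ndarray:
    """Day of peak warmth: ~196 (mid-July) in the NH, shifted 182.5 days in
    the SH."""
    return np.where(np.asarray(lat) >= 0, 196.0, 196.0 - 182.5)


def simulate_weather(sites: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Daily weather per site: seasonal sinusoid + AR(1) anomalies.

    Temperature is the site MAT plus a latitude-scaled annual cosine (peak
    mid-summer in each hemisphere) plus a stationary AR(1) anomaly.
    Precipitation is gamma with a mild seasonal modulation; wind components
    carry a weak seasonal cycle.
    """
    if len(sites) == 0:
        raise ValueError("sites table is empty")
    dates = pd.date_range(config.date_range[0], config.date_range[1], freq="D")
    if len(dates) == 0:
        raise ValueError("empty date range")
    rng = np.random.default_rng(_stream(config.seed, 2))
    nd = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    frames = []
    for row in sites.itertuples(index=False):
        amp = config.season_amp_per_deg * abs(row.latitude)
        peak = _seasonal_phase(row.latitude)
        seasonal = amp * np.cos(2 * np.pi * (doy - peak) / DAYS_PER_YEAR)
        anom = _ar1(nd, config.weather_ar1_rho, config.weather_anomaly_sd, rng)
        temp = row.mat + seasonal + anom
        daily_precip = row.map / 365.0 / 1000.0  # m per day
        precip_season = 1.0 + 0.3 * np.sin(2 * np.pi * (doy - peak) / DAYS_PER_YEAR)
        precip = rng.gamma(0.6, np.maximum(daily_precip * precip_season, 1e-9) / 0.6)
        wind_season = 0.25 * row.wind * np.cos(2 * np.pi * (doy - peak + 91) / DAYS_PER_YEAR)
        u = row.wind * 0.6 + wind_season + rng.normal(0.0, 1.2, nd)
        v = row.wind * 0.3 - wind_season + rng.normal(0.0, 1.2, nd)
        frames.append(
            pd.DataFrame(
                {
                    "site_id": row.site_id,
                    "date": dates,
                    "temp": temp,
                    "precip": precip,
                    "wind_u": u,
                    "wind_v": v,
                    "true_temp_anomaly": anom,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _ar1(n, rho, sd, rng) -> np.ndarray:
    """Stationary AR(1) with marginal sd ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(max(1.0 - rho**2, 0.0)), n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t - 1]
    return x


def simulate_taxonomy(config: SimConfig) -> pd.DataFrame:
    """Fully nested seven-rank taxonomy under one kingdom.

    Every species has a complete lineage and no rank name is reused across
    parents, so every genus maps to exactly one family and so on.
    """
    fanout = config.ranks_fanout
    counters = [1] * 6
    rows = []

    def recurse(depth, lineage, otu_counter):
        if depth == 6:
            otu_id = f"OTU{otu_counter[0]:04d}"
            otu_counter[0] += 1
            rows.append([otu_id, "Fungi", *lineage])
            return
        for _ in range(fanout[depth]):
            name = f"{RANKS[depth + 1][0]}__{RANKS[depth + 1]}{counters[depth]:03d}"
            counters[depth] += 1
            recurse(depth + 1, lineage + [name], otu_counter)

    recurse(0, [], [1])
    return pd.DataFrame(rows, columns=["otu_id", *RANKS])


def _lambda_mixture(n_species, chol, lam, rng) -> np.ndarray:
    """Unit-variance draw with correlation lam * C between species."""
    tree_part = chol @ rng.normal(size=n_species)
    indep_part = rng.normal(size=n_species)
    return np.sqrt(lam) * tree_part + np.sqrt(1.0 - lam) * indep_part


def simulate_species_params(taxonomy: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Ground-truth probit coefficients, guilds and spore volumes per species.

    Each coefficient vector across species is an affine transform of a
    lambda_target-weighted mixture of a tree-structured and an independent
    unit-variance component, giving Pagel's lambda = lambda_target.  Guilds
    are assigned at family level (all members share the family's guild
    pool); spore volumes are log-normal with family-level means.
    """
    rng = np.random.default_rng(_stream(config.seed, 3))
    n = len(taxonomy)
    _, corr = taxonomy_to_correlation(taxonomy)
    # corr is PSD by construction; jitter for Cholesky stability
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n))
    lam = config.lambda_target
    draw = lambda: _lambda_mixture(n, chol, lam, rng)  # noqa: E731

    intercept = config.intercept_mean + config.intercept_sd * draw()
    b_mat = config.beta_mat_mean[0] + config.beta_mat[0] * draw()
    b_mat2 = config.beta_mat_mean[1] + config.beta_mat[1] * draw()
    seasonal_scale = config.beta_season / 60.0
    b_latsin = seasonal_scale * draw()
    b_latcos = seasonal_scale * draw()
    b_logdepth = config.beta_logdepth_mean + config.beta_logdepth_sd * draw()

    with np.errstate(divide="ignore", invalid="ignore"):
        opt_mat = np.where(b_mat2 < 0, -b_mat / (2.0 * b_mat2), np.nan)
    peak_day = (
        np.degrees(np.arctan2(b_latsin, b_latcos)) / 360.0 * DAYS_PER_YEAR
    ) % DAYS_PER_YEAR

    # family-level guild pools
    families = taxonomy["family"].unique()
    fam_guilds = {}
    for fam in families:
        k = 1 + rng.binomial(1, 0.4)
        fam_guilds[fam] = tuple(
            sorted(rng.choice(GUILD_VOCABULARY, size=k, replace=False))
        )
    guilds = [";".join(fam_guilds[f]) for f in taxonomy["family"]]

    fam_logvol_asex = {f: rng.normal(np.log(60.0), 1.0) for f in families}
    fam_logvol_sex = {f: rng.normal(np.log(200.0), 1.0) for f in families}
    asex = np.exp([rng.normal(fam_logvol_asex[f], 0.5) for f in taxonomy["family"]])
    sex = np.exp([rng.normal(fam_logvol_sex[f], 0.5) for f in taxonomy["family"]])

    return pd.DataFrame(
        {
            "species_id": taxonomy["otu_id"],
            "species": taxonomy["species"],
            "intercept": intercept,
            "b_mat": b_mat,
            "b_mat2": b_mat2,
            "b_latsin": b_latsin,
            "b_latcos": b_latcos,
            "b_logdepth": b_logdepth,
            "true_optimal_mat": opt_mat,
            "true_peak_day": peak_day,
            "guild": guilds,
            "asexual_volume": asex,
            "sexual_volume": sex,
        }
    )


def make_trait_table(taxonomy: pd.DataFrame, truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Trait database with coverage gaps.

    Only ``trait_species_coverage`` of species have an entry at all, and a
    further ``trait_stage_missing`` fraction of entries lack the asexual or
    sexual volume, mirroring the incompleteness of real spore-size
    compilations.  Guild entries follow the same species coverage.
    """
    rng = np.random.default_rng(_stream(config.seed, 4))
    n = len(truth)
    covered = rng.random(n) < config.trait_species_coverage
    miss_a = rng.random(n) < config.trait_stage_missing[0]
    miss_s = rng.random(n) < config.trait_stage_missing[1]
    tab = truth.loc[covered, ["species", "guild", "asexual_volume", "sexual_volume"]].copy()
    tab.loc[miss_a[covered], "asexual_volume"] = np.nan
    tab.loc[miss_s[covered], "sexual_volume"] = np.nan
    tab = tab.rename(columns={"guild": "guilds"})
    return tab.reset_index(drop=True)


def occurrence_probability(
    truth: pd.DataFrame, mat, lat, doy, log_depth_centered, site_effect=0.0
) -> np.ndarray:
    """Phi(linear predictor) for every species at one sample's covariates."""
    s = np.sin(2 * np.pi * doy / DAYS_PER_YEAR)
    c = np.cos(2 * np.pi * doy / DAYS_PER_YEAR)
    eta = (
        truth["intercept"].to_numpy()
        + truth["b_mat"].to_numpy() * mat
        + truth["b_mat2"].to_numpy() * mat**2
        + truth["b_latsin"].to_numpy() * lat * s
        + truth["b_latcos"].to_numpy() * lat * c
        + truth["b_logdepth"].to_numpy() * log_depth_centered
        + site_effect
    )
    return stats.norm.cdf(eta)


def simulate_samples(
    sites: pd.DataFrame,
    weather: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the OTU read table, sample metadata and negative controls.

    For each site x sampling date, species presence is Bernoulli with
    probit-linear predictor from the TruthRecord plus a per-species-site
    random effect; total depth is log-normal; reads of present species are
    multinomial with log-normal intensities.  The spike-in emulates a fixed
    amount of synthetic DNA: a sample's spike read share is
    S / (S + latent fungal intensity), with S calibrated so the average
    share matches ``spike_fraction_mean`` — so the non-spike/spike ratio
    tracks the latent fungal DNA amount, as it does on a sequencer.
    Negative controls are empty except for a ``contamination_rate`` share
    carrying Poisson(3) counts of a few of the 20 most prevalent OTUs.

    Returns ``(otu_table, samples, negcontrols)``; ``otu_table`` is indexed
    by sample_id with one column per OTU plus a ``SPIKE`` column, and
    ``samples`` carries the latent fungal intensity as generator truth.
    """
    rng = np.random.default_rng(_stream(config.seed, 5))
    dates = pd.date_range(
        config.date_range[0], config.date_range[1], freq=f"{config.sampling_interval_days}D"
    )
    n_species = len(truth)
    otu_ids = list(truth["species_id"])
    mu_ld = config.depth_distribution[0]

    site_effects = rng.normal(0.0, config.site_sigma, size=(len(sites), n_species))

    sample_rows, weight_rows, depths = [], [], []
    for si, site in enumerate(sites.itertuples(index=False)):
        for date in dates:
            sample_id = f"{site.site_id}_{date.date().isoformat()}"
            depth = max(int(np.round(rng.lognormal(*config.depth_distribution))), 100)
            p = occurrence_probability(
                truth,
                site.mat,
                site.latitude,
                float(date.dayofyear),
                np.log(depth) - mu_ld,
                site_effects[si],
            )
            present = rng.random(n_species) < p
            weights = np.where(present, rng.lognormal(0.0, 1.0, n_species), 0.0)
            sample_rows.append((sample_id, site.site_id, date.date().isoformat()))
            weight_rows.append(weights)
            depths.append(depth)

    weights = np.array(weight_rows) if weight_rows else np.empty((0, n_species))
    intensity = weights.sum(axis=1)
    spike_amount = _calibrate_spike(intensity, config.spike_fraction_mean)

    count_rows, sample_ids = [], []
    for (sample_id, _, _), w, depth, inten in zip(sample_rows, weights, depths, intensity):
        spike_share = spike_amount / (spike_amount + inten) if spike_amount > 0 else 0.0
        spike = int(np.round(depth * spike_share))
        fungal_total = depth - spike
        counts = np.zeros(n_species, dtype=np.int64)
        if inten > 0 and fungal_total > 0:
            counts = rng.multinomial(fungal_total, w / inten)
        sample_ids.append(sample_id)
        count_rows.append(np.append(counts, spike))

    otu_table = pd.DataFrame(
        np.array(count_rows, dtype=np.int64) if count_rows else np.empty((0, n_species + 1), int),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[*otu_ids, "SPIKE"],
    )
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "site_id", "date"])
    samples["latent_intensity"] = intensity

    negcontrols = _simulate_negative_controls(otu_table, config, rng)
    return otu_table, samples, negcontrols


def _calibrate_spike(intensity: np.ndarray, target_share: float) -> float:
    """Spike DNA amount S with mean_i S/(S + I_i) equal to the target share."""
    pos = intensity[intensity > 0]
    if len(pos) == 0 or target_share <= 0:
        return 0.0
    lo, hi = 1e-9 * pos.mean(), 1e6 * pos.mean()
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        share = float(np.mean(mid / (mid + intensity)))
        if share < target_share:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _simulate_negative_controls(otu_table, config, rng) -> pd.DataFrame:
    """Mostly-clean negative controls with sparse contamination.

    Contaminated controls carry Poisson(3) counts of 1-3 OTUs drawn from the
    20 most prevalent OTUs in the field samples.
    """
    otu_cols = [c for c in otu_table.columns if c != "SPIKE"]
    nc = config.n_negative_controls
    counts = np.zeros((nc, len(otu_cols)), dtype=np.int64)
    if len(otu_table) and otu_cols:
        prevalence = (otu_table[otu_cols] > 0).mean(axis=0)
        top = prevalence.sort_values(ascending=False).index[:20]
        top_pos = [otu_cols.index(o) for o in top]
        contaminated = rng.random(nc) < config.contamination_rate
        for i in np.flatnonzero(contaminated):
            k = rng.integers(1, min(4, len(top_pos) + 1))
            picks = rng.choice(top_pos, size=k, replace=False)
            counts[i, picks] = np.maximum(rng.poisson(3.0, size=k), 1)
    return pd.DataFrame(
        counts,
        index=pd.Index([f"NC{i:03d}" for i in range(nc)], name="sample_id"),
        columns=otu_cols,
    )


def generate(config: SimConfig) -> SyntheticDataset:
    """Run the full generator: sites, weather, taxonomy, truth, traits,
    samples, negative controls."""
    sites = simulate_sites(config)
    weather = simulate_weather(sites, config)
    taxonomy = simulate_taxonomy(config)
    truth = simulate_species_params(taxonomy, config)
    traits = make_trait_table(taxonomy, truth, config)
    otu_table, samples, negcontrols = simulate_samples(sites, weather, truth, config)
    return SyntheticDataset(
        config=config,
        sites=sites,
        weather=weather,
        taxonomy=taxonomy,
        truth=truth,
        traits=traits,
        samples=samples,
        otu_table=otu_table,
        negcontrols=negcontrols,
    )


def _stream(seed: int, offset: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=(offset,))
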