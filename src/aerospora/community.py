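"""Site-level community structure: prevalence profiles, dissimilarities,
NMDS ordination with covariate surfaces, and Whittaker variance
partitioning.

Multivariate analyses run at the site level: each taxon's abundance at a
site is its prevalence, the proportion of that site's samples containing
it.  Site-to-site distances are Bray-Curtis on prevalence vectors or
unweighted UniFrac on the equal-branch taxonomy tree.  The contribution of
geography versus climate to community dissimilarity is split into unique
and shared fractions from the three nested regressions (Whittaker's
partition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .phylo import RANKS, lineage_codes

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# prevalence and distances
# ---------------------------------------------------------------------------

def site_prevalence(otu_table: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-site prevalence profiles (sites x OTUs), sites with no samples
    omitted with a warning.  Adds an ``n_samples`` attribute column handled
    separately; returns a frame indexed by site_id."""
    meta = samples.set_index("sample_id").loc[otu_table.index]
    presence = (otu_table > 0).astype(float)
    grouped = presence.groupby(meta["site_id"])
    prev = grouped.mean()
    n = grouped.size()
    empty = set(samples["site_id"]) - set(prev.index)
    if empty:
        warnings.warn(f"sites with zero retained samples omitted: {sorted(empty)}")
    prev.insert(0, "n_samples", n)
    return prev


def _profile_matrix(profiles: pd.DataFrame) -> np.ndarray:
    cols = [c for c in profiles.columns if c != "n_samples"]
    return profiles[cols].to_numpy(dtype=float)


def bray_curtis(profiles: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between site prevalence profiles."""
    x = _profile_matrix(profiles)
    if len(x) < 2:
        raise ValueError("need at least two profiles")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn("all-zero profile pair; distance set to 0")
        d = np.nan_to_num(d, nan=0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def unifrac_taxonomic(profiles: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Unweighted UniFrac on the equal-branch-length taxonomy tree.

    Presence is prevalence > 0.  Every branch (one unit edge per taxonomic
    level below the kingdom root) is attributed to the sites containing at
    least one descendant OTU; the distance is the unshared branch length
    over the total branch length of the union.  Sites whose OTUs share no
    ranks below the kingdom are maximally distant (1).
    """
    otu_cols = [c for c in profiles.columns if c != "n_samples"]
    missing = set(otu_cols) - set(taxonomy["otu_id"])
    if missing:
        raise KeyError(f"OTUs missing from tree/taxonomy: {sorted(missing)[:5]}")
    tax = taxonomy.set_index("otu_id").loc[otu_cols].reset_index()
    codes = lineage_codes(tax)  # n_otus x 7 cumulative path codes
    presence = _profile_matrix(profiles) > 0

    # branch sets per site: the set of (rank, path-code) pairs present
    n_sites = presence.shape[0]
    branch_sets = []
    for s in range(n_sites):
        otus = presence[s]
        branches = set()
        for r in range(1, len(RANKS)):  # levels below the kingdom root
            branches.update((r, c) for c in np.unique(codes[otus, r]))
        branch_sets.append(branches)

    d = np.zeros((n_sites, n_sites))
    for i in range(n_sites):
        for j in range(i + 1, n_sites):
            union = branch_sets[i] | branch_sets[j]
            if not union:
                warnings.warn("two empty sites; UniFrac set to 0")
                continue
            shared = branch_sets[i] & branch_sets[j]
            d[i, j] = d[j, i] = (len(union) - len(shared)) / len(union)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Best NMDS configuration over random restarts."""

    coordinates: pd.DataFrame  # site x (axis1, axis2)
    stress: float  # Kruskal stress-1
    n_restarts: int
    seed: int


def nmds(dist: pd.DataFrame, k: int = 2, n_restarts: int = 8, seed: int = 0) -> OrdinationResult:
    """Non-metric multidimensional scaling of a site distance matrix.

    Kruskal stress-1 minimisation with isotonic regression (ties averaged,
    the primary treatment), best of ``n_restarts`` random starts,
    deterministic under a fixed seed.  Coordinates are centred.
    """
    d = dist.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if len(d) < 4:
        raise ValueError("need at least 4 points for NMDS")
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    coords = model.fit_transform(d)
    coords = coords - coords.mean(axis=0)
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=dist.index, columns=[f"axis{i+1}" for i in range(k)]
        ),
        stress=float(model.stress_),
        n_restarts=n_restarts,
        seed=seed,
    )


def surface_deviance(ordination: OrdinationResult, covariate: pd.Series) -> float:
    """Deviance explained by a smooth surface of a covariate over ordination
    space.

    Fits a thin-plate-type radial-basis expansion (with linear terms) of the
    covariate over the 2-D coordinates, ridge penalty chosen by generalised
    cross-validation, and returns 1 - RSS/TSS in [0, 1].
    """
    xy = ordination.coordinates.to_numpy()
    y = covariate.reindex(ordination.coordinates.index).to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("covariate must be defined for all ordinated sites")
    if np.ptp(y) == 0:
        warnings.warn("constant covariate; deviance explained is 0")
        return 0.0
    n = len(y)
    r2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    scale = np.median(r2[r2 > 0]) if np.any(r2 > 0) else 1.0
    r2s = r2 / scale
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(r2s > 0, 0.5 * r2s * np.log(r2s), 0.0)  # thin-plate kernel
    X = np.column_stack([np.ones(n), xy, K])
    tss = float(np.sum((y - y.mean()) ** 2))
    best = (np.inf, 0.0)
    for lam in 10.0 ** np.arange(-6, 5):
        P = np.zeros((X.shape[1], X.shape[1]))
        P[3:, 3:] = lam * np.eye(n)
        A = X.T @ X + P
        beta = np.linalg.solve(A, X.T @ y)
        H = X @ np.linalg.solve(A, X.T)
        resid = y - X @ beta
        rss = float(resid @ resid)
        edf = float(np.trace(H))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if gcv < best[0]:
            best = (gcv, 1.0 - rss / tss)
    return float(np.clip(best[1], 0.0, 1.0))


# ---------------------------------------------------------------------------
# Whittaker variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VariancePartition:
    """Unique/shared/unexplained fractions of community dissimilarity."""

    space_alone: float
    env_alone: float
    shared: float
    unexplained: float

    def as_tuple(self):
        return (self.space_alone, self.env_alone, self.shared, self.unexplained)


def whittaker_partition(r2_full: float, r2_geo: float, r2_env: float) -> VariancePartition:
    """Whittaker's arithmetic identity on the three nested R² values."""
    space = r2_full - r2_env
    env = r2_full - r2_geo
    shared = r2_geo + r2_env - r2_full
    return VariancePartition(space, env, shared, 1.0 - r2_full)


def _upper(d: pd.DataFrame) -> np.ndarray:
    a = d.to_numpy(dtype=float)
    iu = np.triu_indices_from(a, k=1)
    return a[iu]


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - resid @ resid / tss) if tss > 0 else 0.0


def variance_partition(
    d_comm: pd.DataFrame, d_geo: pd.DataFrame, d_env: pd.DataFrame
) -> VariancePartition:
    """Partition community dissimilarity into space/environment fractions.

    Unfolds the upper triangles and fits the three least-squares models
    (geo; env; geo+env), then applies Whittaker's identity.
    """
    if len(d_comm) < 4:
        raise ValueError("need at least 4 sites")
    if not (d_comm.shape == d_geo.shape == d_env.shape):
        raise ValueError("distance matrices must be aligned")
    y = _upper(d_comm)
    g = _upper(d_geo)
    e = _upper(d_env)
    return whittaker_partition(
        r2_full=_r2(y, np.column_stack([g, e])),
        r2_geo=_r2(y, g[:, None]),
        r2_env=_r2(y, e[:, None]),
    )


def haversine_distances(sites: pd.DataFrame) -> pd.DataFrame:
    """Great-circle distance matrix (km) from site coordinates."""
    lat = np.radians(sites["latitude"].to_numpy())
    lon = np.radians(sites["longitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    return pd.DataFrame(d, index=sites["site_id"], columns=sites["site_id"])


def climate_distance(sites: pd.DataFrame, variable: str = "mat") -> pd.DataFrame:
    """Absolute pairwise difference of a site climate normal."""
    v = sites[variable].to_numpy(dtype=float)
    d = np.abs(v[:, None] - v[None, :])
    return pd.DataFrame(d, index=sites["site_id"], columns=sites["site_id"])


# ---------------------------------------------------------------------------
# climatic-zone overlap and prevalent genera
# ---------------------------------------------------------------------------

VENN_CELLS = (
    "tropical_only", "temperate_only", "polar_only",
    "tropical_temperate", "tropical_polar", "temperate_polar", "all_three",
)

_ZONES = ("tropical-subtropical", "temperate", "polar-continental")


def zone_overlap(
    otu_table: pd.DataFrame,
    samples: pd.DataFrame,
    sites: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rank: str = "species",
) -> pd.Series:
    """Counts of taxa (at ``rank``) per cell of the three-zone Venn diagram.

    A taxon is attributed to every zone where at least one sample contains a
    member OTU.  The returned series also carries ``share_all_three``: the
    fraction of observed taxa present in all three zones.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    meta = samples.set_index("sample_id").loc[otu_table.index]
    zone_of_site = sites.set_index("site_id")["zone"]
    zones = meta["site_id"].map(zone_of_site)
    rank_of = taxonomy.set_index("otu_id")[rank]

    taxa_by_zone = {z: set() for z in _ZONES}
    for z in _ZONES:
        rows = otu_table.loc[(zones == z).to_numpy()]
        if len(rows):
            present_otus = rows.columns[(rows > 0).any(axis=0)]
            taxa_by_zone[z] = set(rank_of.reindex(present_otus).dropna())
    trop, temp, pol = (taxa_by_zone[z] for z in _ZONES)
    counts = {
        "tropical_only": len(trop - temp - pol),
        "temperate_only": len(temp - trop - pol),
        "polar_only": len(pol - trop - temp),
        "tropical_temperate": len((trop & temp) - pol),
        "tropical_polar": len((trop & pol) - temp),
        "temperate_polar": len((temp & pol) - trop),
        "all_three": len(trop & temp & pol),
    }
    total = len(trop | temp | pol)
    out = pd.Series(counts, name=rank)
    out["share_all_three"] = counts["all_three"] / total if total else 0.0
    return out


def top_prevalent_genera(
    otu_table: pd.DataFrame,
    samples: pd.DataFrame,
    taxonomy: pd.DataFrame,
    n: int = 10,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Genera ranked by the number of samples containing any member OTU.

    Ties are broken lexicographically on the genus name.  With ``sites``
    given, adds per-zone sample counts.
    """
    genus_of = taxonomy.set_index("otu_id")["genus"]
    presence = otu_table.drop(columns=["SPIKE"], errors="ignore") > 0
    genus_presence = presence.T.groupby(genus_of.reindex(presence.columns)).any().T
    counts = genus_presence.sum(axis=0)
    ranked = (
        counts.rename("n_samples")
        .reset_index()
        .rename(columns={"index": "genus"})
        .sort_values(["n_samples", "genus"], ascending=[False, True], kind="stable")
        .head(n)
        .reset_index(drop=True)
    )
    if sites is not None:
        meta = samples.set_index("sample_id").loc[otu_table.index]
        zones = meta["site_id"].map(sites.set_index("site_id")["zone"])
        for z in _ZONES:
            sub = genus_presence.loc[(zones == z).to_numpy()]
            ranked[z] = ranked["genus"].map(sub.sum(axis=0)).fillna(0).astype(int)
    return ranked
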