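"""Seasonality in community composition: the paired-Jaccard index.

For each site, pairs of samples are classified by their calendar-date gap:
at most 30 days apart is "same season", 90 +/- 15 days apart is "different
season".  The seasonality index is the mean Jaccard similarity of
same-season pairs minus that of different-season pairs, restricted to
pairs in which both samples contain at least five species.  Subtracting
the same-season mean controls for baseline turnover, isolating the pure
effect of season.  Regressed against site MAT, the index shows whether
colder sites have more seasonal communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

SAME_SEASON_MAX_DAYS = 30
DIFFERENT_SEASON_DAYS = (75, 105)


def jaccard_similarity(a: set, b: set) -> float:
    """|a & b| / |a | b|; defined as 0 for two empty sets (with warning)."""
    union = len(a | b)
    if union == 0:
        warnings.warn("Jaccard of two empty sets; defined as 0")
        return 0.0
    return len(a & b) / union


def classify_pair(date_i, date_j, circular: bool = False) -> str:
    """Classify a sample pair by date gap: same_season (<= 30 d),
    different_season (75-105 d), else neither.

    With ``circular=True`` the gap is the circular day-of-year difference
    (so cross-year anniversary pairs count as same season); the default is
    the plain calendar difference.
    """
    delta = abs((pd.Timestamp(date_i) - pd.Timestamp(date_j)).days)
    if circular:
        delta = delta % 365
        delta = min(delta, 365 - delta)
    if delta <= SAME_SEASON_MAX_DAYS:
        return "same_season"
    if DIFFERENT_SEASON_DAYS[0] <= delta <= DIFFERENT_SEASON_DAYS[1]:
        return "different_season"
    return "neither"


@dataclass
class SeasonalityIndexResult:
    """Per-site paired-Jaccard seasonality index."""

    site_id: str
    mean_jaccard_same: float
    mean_jaccard_diff: float
    index: float
    n_pairs_same: int
    n_pairs_diff: int


def site_seasonality_index(
    otu_table: pd.DataFrame,
    samples: pd.DataFrame,
    site_id: str,
    min_species: int = 5,
    circular: bool = False,
) -> SeasonalityIndexResult:
    """Seasonality index for one site.

    Only within-site pairs in which BOTH samples hold at least
    ``min_species`` present species enter the averages; the index is
    missing (NaN) if either pair class is empty.
    """
    meta = samples.set_index("sample_id")
    ids = [s for s in otu_table.index if meta.loc[s, "site_id"] == site_id]
    fungal = otu_table.drop(columns=["SPIKE"], errors="ignore")
    presence = {
        s: frozenset(fungal.columns[fungal.loc[s].to_numpy() > 0]) for s in ids
    }
    dates = {s: pd.Timestamp(meta.loc[s, "date"]) for s in ids}
    ids = sorted(ids, key=lambda s: dates[s])

    sims: dict[str, list] = {"same_season": [], "different_season": []}
    for a, b in combinations(ids, 2):
        if len(presence[a]) < min_species or len(presence[b]) < min_species:
            continue
        cls = classify_pair(dates[a], dates[b], circular=circular)
        if cls != "neither":
            sims[cls].append(jaccard_similarity(set(presence[a]), set(presence[b])))

    same = float(np.mean(sims["same_season"])) if sims["same_season"] else np.nan
    diff = float(np.mean(sims["different_season"])) if sims["different_season"] else np.nan
    return SeasonalityIndexResult(
        site_id=site_id,
        mean_jaccard_same=same,
        mean_jaccard_diff=diff,
        index=same - diff if np.isfinite(same) and np.isfinite(diff) else np.nan,
        n_pairs_same=len(sims["same_season"]),
        n_pairs_diff=len(sims["different_season"]),
    )


def seasonality_index_table(
    otu_table: pd.DataFrame,
    samples: pd.DataFrame,
    min_species: int = 5,
    circular: bool = False,
) -> pd.DataFrame:
    """Seasonality index for every site with samples in the table."""
    meta = samples.set_index("sample_id").loc[otu_table.index]
    rows = [
        site_seasonality_index(otu_table, samples, site, min_species, circular)
        for site in sorted(meta["site_id"].unique())
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def regress_index_on_mat(index_table: pd.DataFrame, sites: pd.DataFrame):
    """OLS of the seasonality index on site MAT.

    Returns ``(slope, intercept, p_value, r_squared)`` with a two-sided
    test on the slope; requires at least 3 sites with a defined index.
    """
    merged = index_table.merge(sites[["site_id", "mat"]], on="site_id").dropna(
        subset=["index", "mat"]
    )
    if len(merged) < 3:
        raise ValueError("need at least 3 sites with a defined index")
    X = sm.add_constant(merged["mat"].to_numpy())
    fit = sm.OLS(merged["index"].to_numpy(), X).fit()
    return (
        float(fit.params[1]),
        float(fit.params[0]),
        float(fit.pvalues[1]),
        float(fit.rsquared),
    )
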