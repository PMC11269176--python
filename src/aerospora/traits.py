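"""Spore-size backfilling, guild assignment and community-weighted means.

Trait databases cover only a fraction of molecularly identified species, so
missing spore volumes are backfilled hierarchically: the species-level
entry when present, else the mean over congeners with data, else the mean
of genus means within the family — never borrowing above family, where
trait conservatism breaks down.  Averages are taken on the log scale
(geometric means), consistent with the community-weighted mean being
defined on log volume.

Guild labels are borrowed the same way but as set unions: a species without
a database entry inherits every guild recorded for its congeners, else for
its family, and may therefore belong to several potential guilds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _trait_lineage(taxonomy: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Trait rows joined to genus/family through the species name."""
    lineage = taxonomy[["species", "genus", "family"]].drop_duplicates("species")
    return traits.merge(lineage, on="species", how="inner")


def backfill_spore_volume(
    taxonomy: pd.DataFrame, traits: pd.DataFrame, stage: str = "asexual"
) -> pd.DataFrame:
    """Per-OTU spore volume with provenance in {species, genus, family, missing}.

    Genus estimates are geometric means over congeners with data; family
    estimates are geometric means of the genus means (mean of genus means,
    not of pooled species).
    """
    col = {"asexual": "asexual_volume", "sexual": "sexual_volume"}[stage]
    db = _trait_lineage(taxonomy, traits).dropna(subset=[col])
    db = db.assign(logvol=np.log(db[col]))

    species_mean = db.groupby("species")["logvol"].mean()
    genus_mean = db.groupby("genus")["logvol"].mean()
    fam_of_genus = db.drop_duplicates("genus").set_index("genus")["family"]
    family_mean = genus_mean.groupby(fam_of_genus).mean()

    rows = []
    for row in taxonomy.itertuples(index=False):
        if row.species in species_mean.index:
            vol, prov = np.exp(species_mean[row.species]), "species"
        elif row.genus in genus_mean.index:
            vol, prov = np.exp(genus_mean[row.genus]), "genus"
        elif row.family in family_mean.index:
            vol, prov = np.exp(family_mean[row.family]), "family"
        else:
            vol, prov = np.nan, "missing"
        rows.append((row.otu_id, vol, prov))
    return pd.DataFrame(rows, columns=["otu_id", "volume", "provenance"])


def assign_guilds(taxonomy: pd.DataFrame, traits: pd.DataFrame) -> dict[str, frozenset]:
    """OTU -> set of potential guilds, borrowed by genus then family union."""
    db = _trait_lineage(taxonomy, traits).dropna(subset=["guilds"])
    split = db["guilds"].apply(lambda g: frozenset(s for s in str(g).split(";") if s))

    def union(series):
        return frozenset().union(*series) if len(series) else frozenset()

    by_species = split.groupby(db["species"]).apply(union)
    by_genus = split.groupby(db["genus"]).apply(union)
    by_family = split.groupby(db["family"]).apply(union)

    out = {}
    for row in taxonomy.itertuples(index=False):
        if row.species in by_species.index:
            out[row.otu_id] = by_species[row.species]
        elif row.genus in by_genus.index:
            out[row.otu_id] = by_genus[row.genus]
        elif row.family in by_family.index:
            out[row.otu_id] = by_family[row.family]
        else:
            out[row.otu_id] = frozenset()
    return out


def cwm_spore_size(
    presence: pd.DataFrame, backfill: pd.DataFrame, min_species: int = 10
) -> pd.Series:
    """Community-weighted mean log spore volume per sample.

    ``presence`` is a boolean samples x OTUs frame (reads > 0 after depth
    filtering).  The CWM is the unweighted mean of log volumes over present
    species with a non-missing volume; samples with fewer than
    ``min_species`` present species (counting all present species) are
    missing.
    """
    logvol = np.log(backfill.set_index("otu_id")["volume"])
    logvol = logvol.reindex(presence.columns)
    pres = presence.to_numpy(dtype=bool)
    lv = logvol.to_numpy()
    has_vol = np.isfinite(lv)
    contrib = np.where(has_vol, lv, 0.0)
    num = pres @ contrib
    cnt = pres @ has_vol.astype(float)
    with np.errstate(invalid="ignore"):
        cwm = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    richness = pres.sum(axis=1)
    cwm = np.where(richness >= min_species, cwm, np.nan)
    return pd.Series(cwm, index=presence.index, name="cwm")


def guild_richness(presence: pd.DataFrame, guild_map: dict[str, frozenset]) -> pd.DataFrame:
    """Per-sample count of present species carrying each guild.

    A species belonging to k guilds counts once in each of them.
    """
    guilds = sorted(set().union(*guild_map.values())) if guild_map else []
    member = np.zeros((len(presence.columns), len(guilds)))
    for i, otu in enumerate(presence.columns):
        for g in guild_map.get(otu, ()):  # pragma: no branch
            member[i, guilds.index(g)] = 1.0
    counts = presence.to_numpy(dtype=float) @ member
    return pd.DataFrame(counts.astype(int), index=presence.index, columns=guilds)


def provenance_tally(backfill: pd.DataFrame) -> pd.Series:
    """Count of OTUs per backfill provenance class."""
    return backfill["provenance"].value_counts().reindex(
        ["species", "genus", "family", "missing"], fill_value=0
    )
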