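"""Readers for the tabular input schema, with referential-integrity checks.

The schema matches the writers of :mod:`aerospora.simulate`: an OTU read
table (rows = samples, columns = OTU ids plus a ``SPIKE`` column), sample
metadata, site metadata with climate normals, daily weather, a seven-rank
taxonomy, a trait table and negative-control read vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .phylo import RANKS


class ValidationError(ValueError):
    """Raised when an input table violates the schema or referential
    integrity; the message names the offending rows."""


@dataclass
class Dataset:
    """In-memory bundle of all loaded inputs."""

    otu_table: pd.DataFrame
    samples: pd.DataFrame
    sites: pd.DataFrame
    weather: pd.DataFrame
    taxonomy: pd.DataFrame
    traits: pd.DataFrame
    negcontrols: pd.DataFrame


REQUIRED_COLUMNS = {
    "samples": ["sample_id", "site_id", "date"],
    "sites": ["site_id", "latitude", "longitude", "mat", "map", "mai", "wind", "zone"],
    "weather": ["site_id", "date", "temp", "precip", "wind_u", "wind_v"],
    "taxonomy": ["otu_id", *RANKS],
    "traits": ["species", "guilds", "asexual_volume", "sexual_volume"],
}


def read_inputs(indir) -> Dataset:
    """Load all CSV inputs from ``indir`` and validate them.

    Raises :class:`ValidationError` on missing columns, unknown site or OTU
    ids, or unparseable dates, listing the offending rows.
    """
    indir = Path(indir)
    otu_table = pd.read_csv(indir / "otu_table.csv", index_col="sample_id")
    samples = pd.read_csv(indir / "samples.csv")
    sites = pd.read_csv(indir / "sites.csv")
    weather = pd.read_csv(indir / "weather.csv")
    taxonomy = pd.read_csv(indir / "taxonomy.csv")
    traits = pd.read_csv(indir / "traits.csv")
    negcontrols = pd.read_csv(indir / "negcontrols.csv", index_col="sample_id")
    ds = Dataset(otu_table, samples, sites, weather, taxonomy, traits, negcontrols)
    validate(ds)
    return ds


def validate(ds: Dataset, spike_columns=("SPIKE",)) -> None:
    """Schema and referential-integrity validation of a loaded dataset."""
    problems = []
    for name, cols in REQUIRED_COLUMNS.items():
        tab = getattr(ds, name)
        missing = [c for c in cols if c not in tab.columns]
        if missing:
            problems.append(f"{name}.csv missing columns {missing}")
    if problems:
        raise ValidationError("; ".join(problems))

    known_sites = set(ds.sites["site_id"])
    bad = ds.samples.loc[~ds.samples["site_id"].isin(known_sites), "sample_id"]
    if len(bad):
        problems.append(f"samples referencing unknown sites: {list(bad[:10])}")

    try:
        pd.to_datetime(ds.samples["date"], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(ds.samples["date"], errors="coerce")
        bad = ds.samples.loc[parsed.isna(), "sample_id"]
        problems.append(f"unparseable dates in samples: {list(bad[:10])}")

    known_otus = set(ds.taxonomy["otu_id"])
    otu_cols = [c for c in ds.otu_table.columns if c not in spike_columns]
    unknown = [c for c in otu_cols if c not in known_otus]
    if unknown:
        problems.append(f"OTU columns absent from taxonomy: {unknown[:10]}")

    missing_samples = set(ds.otu_table.index) - set(ds.samples["sample_id"])
    if missing_samples:
        problems.append(
            f"otu_table rows without sample metadata: {sorted(missing_samples)[:10]}"
        )

    if problems:
        raise ValidationError("; ".join(problems))
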