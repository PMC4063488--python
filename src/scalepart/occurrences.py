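"""Occurrence-record input and quality filtering.

Records arrive as CSV with a species column and two coordinate columns
(``species,lon,lat`` or the Darwin-Core names ``decimalLongitude`` /
``decimalLatitude``).  The original coordinate *strings* are preserved
alongside the parsed floats because the precision filter judges recorded
precision — the number of digits written after the decimal separator — which
float parsing erases ("35.450" carries three recorded decimals even though
the float equals 35.45).

Filters never mutate records: each returns a subset of its input, so filters
are idempotent and commute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical record columns used throughout the pipeline.
RECORD_COLUMNS = ["species_id", "lon", "lat", "lon_text", "lat_text"]

_SPECIES_ALIASES = ("species_id", "species", "scientificName")
_LON_ALIASES = ("lon", "decimalLongitude", "longitude")
_LAT_ALIASES = ("lat", "decimalLatitude", "latitude")


@dataclass(frozen=True)
class SpeciesWhitelist:
    """An allowed-species filter (e.g. a regional breeding-bird list)."""

    allowed_ids: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.allowed_ids:
            raise ValueError("species whitelist must be non-empty")

    @classmethod
    def from_file(cls, path, label: str | None = None) -> "SpeciesWhitelist":
        """One species id per line; blank lines and '#' comments ignored."""
        with open(path) as fh:
            ids = frozenset(
                line.strip() for line in fh if line.strip() and not line.startswith("#")
            )
        return cls(allowed_ids=ids, label=label or str(path))


def _pick_column(columns, aliases, what: str) -> str:
    for a in aliases:
        if a in columns:
            return a
    raise ValueError(
        f"occurrence table lacks a {what} column (looked for {', '.join(aliases)})"
    )


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV, keeping coordinate strings alongside floats.

    Accepts ``species,lon,lat`` headers or Darwin-Core aliases.  Rows whose
    coordinates do not parse as finite numbers are dropped; the drop count is
    logged and stored in ``df.attrs["n_dropped"]``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    sp = _pick_column(raw.columns, _SPECIES_ALIASES, "species")
    lon = _pick_column(raw.columns, _LON_ALIASES, "longitude")
    lat = _pick_column(raw.columns, _LAT_ALIASES, "latitude")

    lon_num = pd.to_numeric(raw[lon].str.strip(), errors="coerce")
    lat_num = pd.to_numeric(raw[lat].str.strip(), errors="coerce")
    ok = np.isfinite(lon_num.to_numpy()) & np.isfinite(lat_num.to_numpy())
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with unparseable coordinates", path, n_dropped)

    out = pd.DataFrame(
        {
            "species_id": raw.loc[ok, sp].to_numpy(),
            "lon": lon_num[ok].to_numpy(dtype=float),
            "lat": lat_num[ok].to_numpy(dtype=float),
            "lon_text": raw.loc[ok, lon].str.strip().to_numpy(),
            "lat_text": raw.loc[ok, lat].str.strip().to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def write_occurrences(records: pd.DataFrame, path) -> None:
    """Write records as ``species,lon,lat`` CSV using the preserved text coordinates."""
    pd.DataFrame(
        {
            "species": records["species_id"],
            "lon": records["lon_text"],
            "lat": records["lat_text"],
        }
    ).to_csv(path, index=False)


def _n_decimals(text: str) -> int:
    """Digits recorded after the decimal separator; −1 if undefined.

    Scientific notation has no well-defined recorded decimal count and is
    treated as unparseable precision (filtered out).
    """
    t = text.strip()
    if "e" in t or "E" in t:
        return -1
    if "." not in t:
        return 0
    frac = t.split(".", 1)[1]
    if not frac.isdigit() and frac != "":
        return -1
    return len(frac)


def filter_precision(records: pd.DataFrame, min_decimals: int = 3) -> pd.DataFrame:
    """Keep records with at least ``min_decimals`` recorded decimal digits
    in *both* coordinates (geographic-accuracy control; default 3).
    """
    lon_ok = records["lon_text"].map(lambda t: _n_decimals(t) >= min_decimals)
    lat_ok = records["lat_text"].map(lambda t: _n_decimals(t) >= min_decimals)
    out = records.loc[np.asarray(lon_ok, dtype=bool) & np.asarray(lat_ok, dtype=bool)]
    logger.info(
        "precision filter (>=%d decimals): kept %d of %d records",
        min_decimals,
        len(out),
        len(records),
    )
    return out


def filter_whitelist(records: pd.DataFrame, whitelist: SpeciesWhitelist) -> pd.DataFrame:
    """Keep only records of whitelisted species (taxon-list filter)."""
    out = records.loc[records["species_id"].isin(whitelist.allowed_ids)]
    if len(records) and not len(out):
        logger.warning(
            "whitelist %r removed every record", whitelist.label or "<unnamed>"
        )
    return out
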