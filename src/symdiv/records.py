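"""Reading, validation, filtering and tabulation of association records.

One association record is one observation of a single Symbiodiniaceae
phylotype in one coral colony; different phylotypes in the same colony are
distinct records, repeated observations of the same phylotype in the same
colony are not. Records are carried as a pandas DataFrame with a fixed
column contract:

    host_species, phylotype            mandatory, non-empty strings
    is_pigv                            optional bool: potential intragenomic
                                       variant flag (uncodified ITS2 sequence
                                       treated as its own phylotype)
    depth_m, latitude, longitude       optional numerics (>= 0 / [-90, 90] /
                                       [-180, 180]); missing allowed
    colony_id, source_id               optional free-text provenance

Extra columns are preserved but ignored. Phylotype labels are matched
case-sensitively after whitespace trimming; no fuzzy reconciliation of
ITS2 nomenclature is attempted, to avoid silently merging distinct
phylotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .diversity import AssemblageCounts

log = logging.getLogger(__name__)

__all__ = [
    "RecordFormatError",
    "RecordSet",
    "read_records",
    "write_records",
    "read_traits",
    "filter_min_records",
    "exclude_pigv",
    "tabulate_assemblages",
    "species_ranges",
    "summarize",
]

REQUIRED_COLUMNS = ("host_species", "phylotype")
NUMERIC_COLUMNS = ("depth_m", "latitude", "longitude")
TEXT_COLUMNS = ("colony_id", "source_id")
ALL_COLUMNS = REQUIRED_COLUMNS + ("is_pigv",) + NUMERIC_COLUMNS + TEXT_COLUMNS

_NUMERIC_BOUNDS = {
    "depth_m": (0.0, float("inf")),
    "latitude": (-90.0, 90.0),
    "longitude": (-180.0, 180.0),
}
_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n", ""}


class RecordFormatError(ValueError):
    """Raised when an input table violates the record column contract."""


@dataclass(frozen=True)
class RecordSet:
    """An ordered collection of association records plus provenance.

    ``dropped_species`` lists species removed by the most recent filtering
    step, so sensitivity reruns (e.g. after P-IGV exclusion) can report
    what fell below the inclusion threshold.
    """

    df: pd.DataFrame
    provenance: str = ""
    dropped_species: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["host_species"].unique())

    def species_counts(self) -> pd.Series:
        """Total records N per host species."""
        return self.df.groupby("host_species").size().sort_index()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "RecordSet":
        """Normalize a raw DataFrame into the record contract.

        Fills absent optional columns, trims whitespace, and collapses
        duplicate (host_species, colony_id, phylotype) rows where a colony
        id is present -- repeated sampling of one phylotype within one
        colony is a single observation. Rows without a colony id are
        trusted as distinct observations.
        """
        df = df.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise RecordFormatError(f"missing mandatory column: {col!r}")
            df[col] = df[col].astype(str).str.strip()
            empty = df[col] == ""
            if empty.any():
                row = int(np.flatnonzero(empty.to_numpy())[0])
                raise RecordFormatError(f"empty {col!r} in data row {row + 1}")
        if "is_pigv" not in df.columns:
            df["is_pigv"] = False
        df["is_pigv"] = df["is_pigv"].astype(bool)
        for col in NUMERIC_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
            lo, hi = _NUMERIC_BOUNDS[col]
            bad = df[col].notna() & ((df[col] < lo) | (df[col] > hi))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise RecordFormatError(
                    f"{col} out of range [{lo}, {hi}] in data row {row + 1}"
                )
        for col in TEXT_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        has_colony = df["colony_id"].notna() & (df["colony_id"].astype(str) != "")
        dup = has_colony & df.duplicated(
            subset=["host_species", "colony_id", "phylotype"], keep="first"
        )
        if dup.any():
            log.warning(
                "collapsing %d duplicate (colony, phylotype) observation(s)",
                int(dup.sum()),
            )
            df = df[~dup]
        ordered = [c for c in ALL_COLUMNS if c in df.columns] + [
            c for c in df.columns if c not in ALL_COLUMNS
        ]
        return cls(df[ordered].reset_index(drop=True), provenance=provenance)


def read_records(path: str | Path, dialect: str = "tsv") -> RecordSet:
    """Read an association-record table from TSV or CSV.

    Raises :class:`RecordFormatError` naming the offending column when a
    mandatory column is absent, and naming the file line when a coordinate
    or depth cannot be parsed.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [str(c).strip() for c in raw.columns]
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise RecordFormatError(f"{path.name}: missing mandatory column: {col!r}")
    df = raw.copy()
    for col in NUMERIC_COLUMNS:
        if col in df.columns:
            text = df[col].str.strip()
            coerced = pd.to_numeric(text.replace({"": None, "NA": None, "nan": None}),
                                    errors="coerce")
            bad = coerced.isna() & text.ne("") & ~text.str.lower().isin({"na", "nan"})
            if bad.any():
                # +2: header line plus 1-based row numbering
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise RecordFormatError(
                    f"{path.name}: unparsable {col} value {text[bad].iloc[0]!r} "
                    f"on line {line}"
                )
            df[col] = coerced
    if "is_pigv" in df.columns:
        tokens = df["is_pigv"].str.strip().str.lower()
        unknown = ~tokens.isin(_TRUE_TOKENS | _FALSE_TOKENS)
        if unknown.any():
            line = int(np.flatnonzero(unknown.to_numpy())[0]) + 2
            raise RecordFormatError(
                f"{path.name}: unparsable is_pigv value "
                f"{df['is_pigv'][unknown].iloc[0]!r} on line {line}"
            )
        df["is_pigv"] = tokens.isin(_TRUE_TOKENS)
    for col in TEXT_COLUMNS:
        if col in df.columns:
            df[col] = df[col].replace({"": pd.NA})
    rs = RecordSet.from_dataframe(df, provenance=str(path))
    log.info("read %d association records from %s", len(rs), path)
    return rs


def write_records(rs: RecordSet, path: str | Path) -> None:
    """Write a normalized TSV dump of the record set."""
    rs.df.to_csv(path, sep="\t", index=False)


def read_traits(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read the per-species trait table (taxon-BRI and optional ranges).

    taxon-BRI is the published taxon-specific bleaching and mortality
    response index, a percentage in [0, 100]; it is consumed as an input,
    never derived here.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    df = pd.read_csv(path, sep=sep)
    if "host_species" not in df.columns:
        raise RecordFormatError("trait table missing mandatory column: 'host_species'")
    df["host_species"] = df["host_species"].astype(str).str.strip()
    for col in ("taxon_bri", "delta_depth", "delta_lat", "delta_long"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "taxon_bri" in df.columns:
        bad = df["taxon_bri"].notna() & (
            (df["taxon_bri"] < 0) | (df["taxon_bri"] > 100)
        )
        if bad.any():
            raise RecordFormatError("taxon_bri values must lie in [0, 100]")
    return df.set_index("host_species", verify_integrity=True)


def filter_min_records(rs: RecordSet, min_n: int = 15) -> RecordSet:
    """Retain only species with at least ``min_n`` association records.

    The default of 15 matches the smallest standard rarefaction depth;
    species below it cannot be rarefied to any standard depth and are
    excluded to minimize scarce-sampling artifacts.
    """
    if min_n < 1:
        raise ValueError("min_n must be a positive integer")
    counts = rs.species_counts()
    keep = set(counts.index[counts >= min_n])
    dropped = tuple(sorted(set(counts.index) - keep))
    if dropped:
        log.info("dropping %d species with < %d records", len(dropped), min_n)
    if not keep:
        log.warning("no species retained at min_n=%d", min_n)
    df = rs.df[rs.df["host_species"].isin(keep)].reset_index(drop=True)
    return RecordSet(df, provenance=rs.provenance, dropped_species=dropped)


def exclude_pigv(rs: RecordSet) -> RecordSet:
    """Drop records flagged as potential intragenomic variants.

    This is the sensitivity analysis that treats P-IGVs as true
    intragenomic variants of existing phylotypes rather than distinct
    phylotypes; re-apply :func:`filter_min_records` afterwards, since
    species may fall below the inclusion threshold.
    """
    flagged = rs.df["is_pigv"].to_numpy(dtype=bool)
    if flagged.any():
        log.info("excluding %d P-IGV record(s)", int(flagged.sum()))
    df = rs.df[~flagged].reset_index(drop=True)
    return RecordSet(df, provenance=rs.provenance, dropped_species=rs.dropped_species)


def tabulate_assemblages(rs: RecordSet) -> dict[str, AssemblageCounts]:
    """Per-species phylotype count vectors (N_i, N, P)."""
    if len(rs) == 0:
        raise ValueError("cannot tabulate an empty record set")
    out: dict[str, AssemblageCounts] = {}
    grouped = rs.df.groupby(["host_species", "phylotype"]).size()
    for species, sub in grouped.groupby(level=0):
        counts = {phylotype: int(n) for (_, phylotype), n in sub.items()}
        out[str(species)] = AssemblageCounts.from_mapping(counts)
    return out


def species_ranges(rs: RecordSet) -> pd.DataFrame:
    """Observed bathymetric/latitudinal/longitudinal range per species.

    Each range is max - min over that species' records bearing the field;
    species with fewer than two such records get a missing value. Records
    missing a field are simply omitted from that field's range.
    Longitudinal ranges are plain max - min with no antimeridian wrapping
    (a documented limitation).
    """
    pairs = {"depth_m": "delta_depth", "latitude": "delta_lat",
             "longitude": "delta_long"}
    rows = {}
    for species, sub in rs.df.groupby("host_species"):
        row = {}
        for col, out_col in pairs.items():
            vals = sub[col].dropna()
            row[out_col] = float(vals.max() - vals.min()) if len(vals) >= 2 else np.nan
        rows[str(species)] = row
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "host_species"
    return out


def summarize(rs: RecordSet) -> dict:
    """JSON-ready summary of a record set."""
    counts = rs.species_counts()
    return {
        "n_records": int(len(rs)),
        "n_species": int(counts.size),
        "n_phylotypes": int(rs.df["phylotype"].nunique()),
        "n_pigv_records": int(rs.df["is_pigv"].sum()),
        "median_records_per_species": float(counts.median()) if counts.size else None,
        "dropped_species": list(rs.dropped_species),
    }
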