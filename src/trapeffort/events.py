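"""Photo-record ingestion and event processing.

Turns raw camera-trap photographs into independent detection events,
applies species-guild exclusions, and builds the incidence matrices that
all richness analyses consume.

The central rule is the independence filter: photographs of the same
species at the same camera separated by more than a fixed interval
(30 minutes by default) are counted as separate detection events;
closer photographs are merged into one event.  The sampling unit for
richness analyses is one monitoring day — one calendar day of the whole
camera array.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GUILDS",
    "IncidenceMatrix",
    "UnclassifiedSpeciesError",
    "read_photo_records",
    "read_classification",
    "read_daily_matrix",
    "filter_independent",
    "apply_exclusions",
    "summarize_species",
    "species_summary_from_counts",
    "build_incidence",
]

GUILDS = ("resident_terrestrial", "arboreal", "transient")

#: required columns of a photo-record table
RECORD_COLUMNS = ("site_id", "species", "timestamp")

#: columns of an event table produced by :func:`filter_independent`
EVENT_COLUMNS = ("site_id", "species", "event_start", "n_photos")


class UnclassifiedSpeciesError(KeyError):
    """A species in the event table has no guild classification."""


@dataclass
class IncidenceMatrix:
    """Sampling-units x species occurrence structure.

    Parameters
    ----------
    counts : pandas.DataFrame
        Units x species table of nonnegative integers.  For day units the
        cell is the number of camera sites detecting the species that day;
        for site units it is the number of independent events at the site.
    unit_kind : {"day", "site"}
        What one row represents.
    max_count : int, optional
        Upper bound on cell values (e.g. the number of cameras for day
        units); validated if given.
    """

    counts: pd.DataFrame
    unit_kind: str
    max_count: int | None = None

    def __post_init__(self) -> None:
        if self.unit_kind not in ("day", "site"):
            raise ValueError(f"unit_kind must be 'day' or 'site', got {self.unit_kind!r}")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("incidence counts must be nonnegative")
        if self.max_count is not None and values.size and (values > self.max_count).any():
            bad = int(values.max())
            raise ValueError(
                f"incidence count {bad} exceeds the declared maximum {self.max_count}"
            )

    @property
    def unit_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def species(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_units(self) -> int:
        return len(self.counts.index)

    @property
    def n_species(self) -> int:
        return len(self.counts.columns)

    def binarized(self) -> np.ndarray:
        """Units x species boolean detection matrix (idempotent)."""
        return self.counts.to_numpy() > 0

    def occurrence_counts(self) -> pd.Series:
        """Number of sampling units in which each species occurs (D_i)."""
        return pd.Series(self.binarized().sum(axis=0), index=self.species, name="D_i")

    @property
    def s_obs(self) -> int:
        """Observed species richness (species occurring in >=1 unit)."""
        return int((self.occurrence_counts() > 0).sum())


def read_photo_records(
    source,
    *,
    site_col: str = "site_id",
    species_col: str = "species",
    time_col: str = "timestamp",
    timestamp_format: str | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited photo-record table into the canonical layout.

    Returns a DataFrame with columns ``site_id``, ``species``,
    ``timestamp`` sorted by (site, species, time).  An unparseable
    timestamp is a hard error naming the offending file row (1-based,
    counting the header line).
    """
    raw = pd.read_csv(source, sep=sep, dtype=str)
    missing = [c for c in (site_col, species_col, time_col) if c not in raw.columns]
    if missing:
        raise ValueError(f"photo-record table lacks required column(s): {missing}")
    extra = [c for c in raw.columns if c not in (site_col, species_col, time_col)]
    if extra:
        import warnings

        warnings.warn(f"ignoring unknown column(s) {extra}", stacklevel=2)
    records = raw.rename(
        columns={site_col: "site_id", species_col: "species", time_col: "timestamp"}
    )[list(RECORD_COLUMNS)]
    parsed = pd.to_datetime(records["timestamp"], format=timestamp_format, errors="coerce")
    if parsed.isna().any():
        # +2: one for the header line, one for 0- vs 1-based indexing
        rows = [int(i) + 2 for i in np.flatnonzero(parsed.isna().to_numpy())]
        raise ValueError(f"unparseable timestamp(s) at file row(s) {rows}")
    records["timestamp"] = parsed
    return records.sort_values(list(RECORD_COLUMNS), kind="mergesort").reset_index(drop=True)


def write_photo_records(records: pd.DataFrame, path) -> None:
    """Write records as CSV with ISO-8601 timestamps (lossless round-trip)."""
    out = records.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_classification(source, *, sep: str = ",") -> dict[str, str]:
    """Read a species,guild table into a classification mapping."""
    table = pd.read_csv(source, sep=sep, dtype=str)
    if not {"species", "guild"} <= set(table.columns):
        raise ValueError("classification table must have 'species' and 'guild' columns")
    bad = sorted(set(table["guild"]) - set(GUILDS))
    if bad:
        raise ValueError(f"unknown guild(s) {bad}; expected one of {GUILDS}")
    return dict(zip(table["species"], table["guild"]))


def read_daily_matrix(source, *, max_cameras: int = 19, sep: str | None = None) -> IncidenceMatrix:
    """Read a daily detection matrix (rows = days, columns = species).

    Each cell is the number of cameras that detected the species on that
    day; values above ``max_cameras`` are rejected.  A leading
    non-numeric column, if present, is used as the day label.
    """
    table = pd.read_csv(source, sep=sep, engine="python")
    first = table.columns[0]
    if not pd.api.types.is_numeric_dtype(table[first]) or first.lower() in ("day", "date", "unit"):
        table = table.set_index(first)
    if not all(pd.api.types.is_numeric_dtype(t) for t in table.dtypes):
        raise ValueError("daily matrix must be numeric apart from an optional day column")
    counts = table.astype(int)
    counts.index = pd.Index(counts.index, name="day")
    return IncidenceMatrix(counts=counts, unit_kind="day", max_count=max_cameras)


def filter_independent(
    records: pd.DataFrame,
    interval_minutes: float = 30.0,
    *,
    per_site: bool = True,
) -> pd.DataFrame:
    """Merge photographs into independent detection events.

    Within each (site, species) stream — or each species stream globally
    if ``per_site=False`` — a photograph starts a new event iff it falls
    strictly more than ``interval_minutes`` after the previous photograph
    of that stream (rolling gap rule).  A gap of exactly the interval
    does *not* start a new event.

    Returns an event table with columns ``site_id``, ``species``,
    ``event_start``, ``n_photos``.  The result is insensitive to the
    input row order.
    """
    if interval_minutes < 0:
        raise ValueError("interval_minutes must be nonnegative")
    if records.empty:
        return pd.DataFrame(columns=list(EVENT_COLUMNS))
    keys = ["site_id", "species"] if per_site else ["species"]
    recs = records.sort_values(keys + ["timestamp"], kind="mergesort").reset_index(drop=True)
    gap = recs.groupby(keys, sort=False)["timestamp"].diff()
    new_event = gap.isna() | (gap > pd.Timedelta(minutes=interval_minutes))
    event_id = new_event.cumsum()
    events = (
        recs.groupby(event_id)
        .agg(
            site_id=("site_id", "first"),
            species=("species", "first"),
            event_start=("timestamp", "first"),
            n_photos=("timestamp", "size"),
        )
        .reset_index(drop=True)
    )
    return events.sort_values(["site_id", "species", "event_start"], kind="mergesort").reset_index(
        drop=True
    )


def apply_exclusions(
    events: pd.DataFrame, classification: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict an event table to resident terrestrial species.

    Arboreal and transient species are removed.  Every species present in
    ``events`` must be classified; silent guessing is refused.

    Returns ``(resident_events, removal_log)`` where the log lists each
    removed species with its guild and event count.
    """
    present = pd.Index(sorted(set(events["species"])))
    unclassified = [s for s in present if s not in classification]
    if unclassified:
        raise UnclassifiedSpeciesError(f"species without guild classification: {unclassified}")
    bad = sorted({classification[s] for s in present} - set(GUILDS))
    if bad:
        raise ValueError(f"unknown guild(s) {bad}; expected one of {GUILDS}")
    guilds = events["species"].map(classification)
    keep = guilds == "resident_terrestrial"
    removed = events.loc[~keep]
    removal_log = (
        removed.assign(guild=guilds[~keep])
        .groupby(["species", "guild"], sort=True)
        .size()
        .rename("n_events")
        .reset_index()
    )
    return events.loc[keep].reset_index(drop=True), removal_log


def species_summary_from_counts(
    rp: Mapping[str, int] | pd.Series,
    ip: Mapping[str, int] | pd.Series,
    resident: Iterable[str],
) -> pd.DataFrame:
    """Build the per-species summary from photograph and event counts.

    Parameters
    ----------
    rp, ip : mapping species -> count
        Recorded photographs (RP) and independent photographs (IP).
    resident : iterable of species
        The resident terrestrial species (P2 is computed only for these).

    Returns a DataFrame indexed by species with columns ``rp``, ``ip``,
    ``p1``, ``p2``, ``resident``; ``p1`` is each species' percentage of
    all independent photographs, ``p2`` its percentage among resident
    species only (NaN for excluded species).  Percentages are kept at
    full precision; round at display time.
    """
    rp = pd.Series(rp, dtype=float)
    ip = pd.Series(ip, dtype=float).reindex(rp.index)
    if (ip > rp).any():
        raise ValueError("independent photographs cannot exceed recorded photographs")
    total_ip = float(ip.sum())
    if total_ip == 0:
        raise ValueError("no independent photographs: summary undefined")
    resident = pd.Index(resident)
    is_resident = rp.index.isin(resident)
    total_resident = float(ip[is_resident].sum())
    if is_resident.any() and total_resident == 0:
        raise ValueError("no independent photographs among resident species")
    summary = pd.DataFrame(
        {
            "rp": rp.astype(int),
            "ip": ip.astype(int),
            "p1": 100.0 * ip / total_ip,
            "p2": np.where(is_resident, 100.0 * ip / total_resident, np.nan),
            "resident": is_resident,
        }
    )
    summary.index.name = "species"
    return summary.sort_values("ip", ascending=False, kind="mergesort")


def summarize_species(all_events: pd.DataFrame, resident_events: pd.DataFrame) -> pd.DataFrame:
    """Per-species summary (RP, IP, P1, P2) from event tables.

    ``all_events`` is the full post-filter event table; ``resident_events``
    the subset retained by :func:`apply_exclusions`.
    """
    resident_species = set(resident_events["species"])
    if not resident_species <= set(all_events["species"]):
        raise ValueError("resident_events contains species absent from all_events")
    grouped = all_events.groupby("species")
    return species_summary_from_counts(
        rp=grouped["n_photos"].sum(),
        ip=grouped.size(),
        resident=sorted(resident_species),
    )


def build_incidence(
    events: pd.DataFrame,
    unit_kind: str,
    survey_span: tuple | None = None,
    *,
    sites: Iterable[str] | None = None,
) -> IncidenceMatrix:
    """Build an incidence matrix from an event table.

    For ``unit_kind="day"`` there is one unit per calendar day of
    ``survey_span`` (inclusive start/end dates; all-zero days are
    retained) and the cell counts the distinct sites detecting the
    species that day.  For ``unit_kind="site"`` there is one unit per
    site and the cell counts independent events.
    """
    if unit_kind == "day":
        if survey_span is None:
            raise ValueError("survey_span (start, end) is required for day units")
        start, end = (pd.Timestamp(t).normalize() for t in survey_span)
        days = pd.date_range(start, end, freq="D")
        species = pd.Index(sorted(set(events["species"])), name="species")
        counts = pd.DataFrame(0, index=days.date, columns=species)
        counts.index.name = "day"
        if not events.empty:
            event_day = events["event_start"].dt.normalize()
            if (event_day < start).any() or (event_day > end).any():
                raise ValueError("event outside the declared survey span")
            per_day = (
                events.assign(day=event_day.dt.date)
                .groupby(["day", "species"])["site_id"]
                .nunique()
            )
            for (day, sp), n in per_day.items():
                counts.at[day, sp] = int(n)
        n_sites = len(set(events["site_id"]) if sites is None else set(sites))
        return IncidenceMatrix(counts=counts, unit_kind="day", max_count=max(n_sites, 1))
    if unit_kind == "site":
        site_index = pd.Index(
            sorted(set(events["site_id"]) if sites is None else set(sites)), name="site_id"
        )
        counts = (
            events.groupby(["site_id", "species"])
            .size()
            .unstack(fill_value=0)
            .reindex(site_index, fill_value=0)
        )
        counts = counts[sorted(counts.columns)]
        return IncidenceMatrix(counts=counts, unit_kind="site")
    raise ValueError(f"unit_kind must be 'day' or 'site', got {unit_kind!r}")
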