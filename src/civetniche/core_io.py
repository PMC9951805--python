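"""Record types, CSV ingestion and the detection-independence filter.

The spatial and temporal analyses both start from camera-trap detection
records (site, species, timestamp).  Raw camera data contain bursts of
near-simultaneous triggers of the same animal; to avoid pseudo-replication
every downstream count uses *independent* detections, obtained by a greedy
per-(site, species) time filter: an event is kept iff it falls at least
``window`` minutes after the previously *kept* event of its group.

Dietary analyses start from scat records (a set of food-item categories per
scat) which are tabulated into a frequency-of-occurrence (FO) composition
table: FO of an item = number of scats containing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ConfigurationError",
    "DataError",
    "DetectionEvent",
    "DetectionTable",
    "ScatRecord",
    "CompositionTable",
    "read_detections",
    "read_scats",
    "read_composition",
    "filter_independent",
    "tabulate_composition",
]


class ConfigurationError(ValueError):
    """A problem with the requested schema/config, not with the data rows."""


class DataError(ValueError):
    """Malformed input rows; the message names the offending row numbers."""


@dataclass(frozen=True)
class DetectionEvent:
    """One camera-trap capture: where, who, when (minute precision)."""

    site_id: str
    species: str
    timestamp: datetime

    def __post_init__(self) -> None:
        if not self.site_id:
            raise DataError("site_id must be non-empty")
        if not self.species:
            raise DataError("species must be non-empty")


@dataclass(frozen=True)
class ScatRecord:
    """One scat: its id, the species it belongs to, items found in it."""

    scat_id: str
    species: str
    items: frozenset[str]

    def __post_init__(self) -> None:
        if not self.items:
            raise DataError(f"scat {self.scat_id!r}: item set must be non-empty")

    @classmethod
    def from_item_list(cls, scat_id: str, species: str, items: Sequence[str]) -> "ScatRecord":
        """Build from an ordered item list, rejecting duplicate labels."""
        if len(set(items)) != len(items):
            raise DataError(f"scat {scat_id!r}: duplicate item labels {sorted(items)}")
        return cls(scat_id=scat_id, species=species, items=frozenset(items))


class DetectionTable:
    """Ordered collection of detection events with filtering provenance.

    Parameters
    ----------
    events
        Detection events in any order; stored sorted by (site, species, time).
    filtered_window
        ``None`` for raw data; the window in minutes once
        :func:`filter_independent` has been applied.
    """

    def __init__(self, events: Iterable[DetectionEvent], filtered_window: float | None = None):
        self.events: list[DetectionEvent] = sorted(
            events, key=lambda e: (e.site_id, e.species, e.timestamp)
        )
        self.filtered_window = filtered_window

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def is_filtered(self) -> bool:
        return self.filtered_window is not None

    def species(self) -> list[str]:
        return sorted({e.species for e in self.events})

    def sites(self) -> list[str]:
        return sorted({e.site_id for e in self.events})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": [e.site_id for e in self.events],
                "species": [e.species for e in self.events],
                "timestamp": [e.timestamp for e in self.events],
            }
        )

    def times_for(self, species: str) -> list[datetime]:
        return [e.timestamp for e in self.events if e.species == species]


DEFAULT_DETECTION_SCHEMA: Mapping[str, str] = {
    "site": "site",
    "species": "species",
    "date": "date",
    "time": "time",
}


def _parse_timestamp(date_str: str, time_str: str) -> datetime:
    date = datetime.strptime(date_str.strip(), "%Y-%m-%d").date()
    t = datetime.strptime(time_str.strip(), "%H:%M").time()
    return datetime.combine(date, t)


def read_detections(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    skip_bad_rows: bool = False,
) -> DetectionTable:
    """Read detection events from a CSV with columns for site/species/date/time.

    ``schema`` maps the logical names ``site, species, date, time`` onto the
    file's column headers.  Extra columns are ignored.  Dates are ISO
    ``YYYY-MM-DD`` and times 24-h ``HH:MM``.

    Raises
    ------
    ConfigurationError
        If a mapped column is absent from the header.
    DataError
        If a row has an unparseable timestamp (unless ``skip_bad_rows``);
        the message carries 1-based data row numbers.
    """
    schema = dict(DEFAULT_DETECTION_SCHEMA if schema is None else schema)
    df = pd.read_csv(path, dtype=str)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )

    events: list[DetectionEvent] = []
    bad: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        try:
            ts = _parse_timestamp(rec[schema["date"]], rec[schema["time"]])
            events.append(
                DetectionEvent(
                    site_id=str(rec[schema["site"]]).strip(),
                    species=str(rec[schema["species"]]).strip(),
                    timestamp=ts,
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((i, str(exc)))
    if bad and not skip_bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad[:10])
        raise DataError(f"{path}: {len(bad)} malformed row(s): {detail}")
    return DetectionTable(events)


def filter_independent(table: DetectionTable, window_minutes: float = 30.0) -> DetectionTable:
    """Greedy independence filter within each (site, species) group.

    Events are processed in time order per group; the first event is always
    retained and each later event is retained iff it is at least
    ``window_minutes`` after the last *retained* event (an event exactly on
    the boundary is retained).  Groups at different sites or of different
    species never interact.  The filter is idempotent.
    """
    if window_minutes <= 0:
        raise ConfigurationError(f"independence window must be > 0, got {window_minutes}")
    window = timedelta(minutes=window_minutes)
    kept: list[DetectionEvent] = []
    groups: dict[tuple[str, str], list[DetectionEvent]] = {}
    for e in table.events:
        groups.setdefault((e.site_id, e.species), []).append(e)
    for group_events in groups.values():
        group_events.sort(key=lambda e: e.timestamp)
        last_kept: datetime | None = None
        for e in group_events:
            if last_kept is None or e.timestamp - last_kept >= window:
                kept.append(e)
                last_kept = e.timestamp
    return DetectionTable(kept, filtered_window=window_minutes)


def read_scats(path: str | Path) -> list[ScatRecord]:
    """Read scat records from CSV columns ``scat_id, species, items``.

    ``items`` is a semicolon-separated list of category labels found in that
    scat; duplicates within one scat are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["scat_id", "species", "items"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        items = [s.strip() for s in str(rec["items"]).split(";") if s.strip()]
        try:
            records.append(
                ScatRecord.from_item_list(str(rec["scat_id"]), str(rec["species"]), items)
            )
        except DataError as exc:
            raise DataError(f"{path}: row {i}: {exc}") from exc
    return records


def tabulate_composition(scats: Sequence[ScatRecord], species: str) -> pd.Series:
    """Frequency of occurrence per item: number of scats containing it.

    All records must belong to ``species``; the returned Series is indexed by
    item label, sorted, with integer FO counts.  Conservation law:
    ``result.sum() == sum(len(s.items) for s in scats)``.
    """
    if not scats:
        raise DataError("empty scat collection")
    wrong = [s.scat_id for s in scats if s.species != species]
    if wrong:
        raise DataError(f"records not belonging to {species!r}: {wrong[:5]}")
    counts: dict[str, int] = {}
    for s in scats:
        for item in s.items:
            counts[item] = counts.get(item, 0) + 1
    return pd.Series(counts, name=species).sort_index().astype(int)


class CompositionTable:
    """Food-item × species occurrence-count table (the diet analysis atom).

    Rows are food-item categories, each tagged with a coarse group
    (wild animal / domestic animal / plant / other); one integer FO column
    per species.
    """

    GROUPS = ("wild animal", "domestic animal", "plant", "other")

    def __init__(self, df: pd.DataFrame):
        if "item" in df.columns:
            df = df.set_index("item")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise DataError(f"duplicate item categories: {dupes}")
        if "group" not in df.columns:
            raise ConfigurationError("composition table needs a 'group' column")
        fo_cols = [c for c in df.columns if c != "group"]
        if not fo_cols:
            raise ConfigurationError("composition table needs at least one FO column")
        fo = df[fo_cols].apply(pd.to_numeric)
        if (fo < 0).any().any():
            raise DataError("FO counts must be >= 0")
        if not (fo == fo.round()).all().all():
            raise DataError("FO counts must be integers")
        self.df = df.copy()
        self.df[fo_cols] = fo.astype(int)
        self._fo_cols = fo_cols

    @property
    def species(self) -> list[str]:
        """FO column names, stripped of an optional ``fo_`` prefix."""
        return [c.removeprefix("fo_") for c in self._fo_cols]

    @property
    def items(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    def fo(self, species: str) -> pd.Series:
        """FO column for one species (accepts bare or ``fo_``-prefixed name)."""
        for col in self._fo_cols:
            if col == species or col.removeprefix("fo_") == species:
                return self.df[col].rename(species)
        raise ConfigurationError(
            f"species {species!r} not in table (have {self.species})"
        )

    @classmethod
    def from_columns(
        cls, columns: Mapping[str, pd.Series], groups: pd.Series | Mapping[str, str] | None = None
    ) -> "CompositionTable":
        """Assemble from per-species FO Series (e.g. ``tabulate_composition``
        output); absent items get FO 0, absent groups the tag 'other'."""
        df = pd.DataFrame(columns).fillna(0)
        if groups is None:
            df.insert(0, "group", "other")
        else:
            df.insert(0, "group", pd.Series(dict(groups)).reindex(df.index).fillna("other"))
        df.index.name = "item"
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="item")


def read_composition(path: str | Path) -> CompositionTable:
    """Read an item,group,fo_<species>... CSV into a :class:`CompositionTable`."""
    df = pd.read_csv(path)
    if "item" not in df.columns:
        raise ConfigurationError(f"{path}: missing 'item' column")
    return CompositionTable(df)
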