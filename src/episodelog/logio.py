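"""Search-log and demographic-panel data model with TSV readers/writers.

A search log is a flat table of queries: one row per query with the
anonymized user id, a minute-resolution local timestamp, the query text,
and the result clicks that followed (domain, click order, dwell seconds).
The canonical on-disk form is a tab-separated file with header
``user_id  timestamp  query_text  clicks`` where ``clicks`` is a
semicolon-joined list of ``domain|order|dwell`` triples (empty when the
query had no clicks). Timestamps are ISO-8601 to the minute and are
treated as already-local times: the day boundary used everywhere
downstream is local midnight.

In memory a :class:`SearchLog` wraps a :class:`pandas.DataFrame` (fast
vectorized path) while :meth:`SearchLog.iter_records` exposes the same
rows as :class:`QueryRecord` dataclasses for record-level code.
"""

from __future__ import annotations

import datetime as _dt
import gzip
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOG_COLUMNS = ["user_id", "timestamp", "query_text", "clicks"]
PANEL_COLUMNS = ["user_id", "gender", "age_bucket"]
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"

#: Ordered 5-year age buckets used by the demographic panel.
DEFAULT_AGE_BUCKETS = (
    "18-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65+",
)

GENDERS = ("female", "male", "unknown")


@dataclass(frozen=True)
class StudyWindow:
    """Half-open calendar interval ``[start, end)`` covering the study."""

    start: _dt.date
    end: _dt.date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start_date must precede end_date ({self.start} >= {self.end})")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days

    def contains(self, ts: _dt.datetime | _dt.date) -> bool:
        d = ts.date() if isinstance(ts, _dt.datetime) else ts
        return self.start <= d < self.end

    def day_index(self, day: _dt.date) -> int:
        """0-based index of a calendar day inside the window."""
        return (day - self.start).days

    def day(self, index: int) -> _dt.date:
        return self.start + _dt.timedelta(days=int(index))


#: Default window: 182 days starting December 2011 (the six-month study period).
DEFAULT_WINDOW = StudyWindow(_dt.date(2011, 12, 1), _dt.date(2011, 12, 1) + _dt.timedelta(days=182))


@dataclass(frozen=True)
class ClickRecord:
    domain: str
    click_order: int  # 1 = first click for the query
    dwell_seconds: int

    def __post_init__(self) -> None:
        if self.click_order < 1:
            raise ValueError("click_order must be a positive integer")
        if self.dwell_seconds < 0:
            raise ValueError("dwell_seconds must be non-negative")


@dataclass(frozen=True)
class QueryRecord:
    user_id: str
    timestamp: _dt.datetime
    query_text: str
    clicks: tuple[ClickRecord, ...] = ()

    def __post_init__(self) -> None:
        orders = [c.click_order for c in self.clicks]
        if len(set(orders)) != len(orders):
            raise ValueError("click_order must be unique within a query")


def encode_clicks(clicks: Iterable[ClickRecord]) -> str:
    return ";".join(f"{c.domain}|{c.click_order}|{c.dwell_seconds}" for c in clicks)


def decode_clicks(encoded: str) -> tuple[ClickRecord, ...]:
    """Parse a semicolon-joined ``domain|order|dwell`` list; raises ValueError on bad triples."""
    if not encoded:
        return ()
    out = []
    for part in encoded.split(";"):
        fields = part.split("|")
        if len(fields) != 3:
            raise ValueError(f"malformed click triple: {part!r}")
        domain, order, dwell = fields
        out.append(ClickRecord(domain=domain, click_order=int(order), dwell_seconds=int(dwell)))
    return tuple(out)


@dataclass
class SearchLog:
    """A collection of query rows plus the study window they live in.

    ``df`` always carries the four canonical columns; annotation stages
    (:func:`episodelog.lexicon.annotate`) append further columns
    (``msd_flag``, ``matched``, ``drug_names``, ``categories``) without
    changing the canonical ones.
    """

    df: pd.DataFrame
    window: StudyWindow = DEFAULT_WINDOW
    n_malformed: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in LOG_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"log frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def user_ids(self) -> np.ndarray:
        return self.df["user_id"].unique()

    @property
    def is_annotated(self) -> bool:
        return "msd_flag" in self.df.columns

    def require_annotated(self) -> None:
        if not self.is_annotated:
            raise ValueError("operation requires an annotated log (run lexicon.annotate first)")

    def iter_records(self) -> Iterator[QueryRecord]:
        for row in self.df.itertuples(index=False):
            yield QueryRecord(
                user_id=row.user_id,
                timestamp=row.timestamp.to_pydatetime(),
                query_text=row.query_text,
                clicks=decode_clicks(row.clicks),
            )

    @classmethod
    def from_records(cls, records: Iterable[QueryRecord], window: StudyWindow = DEFAULT_WINDOW) -> "SearchLog":
        rows = [
            (r.user_id, pd.Timestamp(r.timestamp), r.query_text, encode_clicks(r.clicks))
            for r in records
        ]
        df = pd.DataFrame(rows, columns=LOG_COLUMNS)
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        return cls(df=df, window=window)


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t", encoding="utf-8", newline="")
    return open(path, mode, encoding="utf-8", newline="")


def read_log(path: str | Path, dialect: str = "tsv", window: StudyWindow | None = None) -> SearchLog:
    """Read a TSV search log.

    Malformed rows (unparseable timestamp, bad click triple, negative
    dwell) are excluded and counted in ``SearchLog.n_malformed``; rows
    whose timestamp falls outside ``window`` are likewise flagged and
    excluded with a warning. An unreadable file raises.
    """
    if dialect != "tsv":
        raise ValueError(f"unknown log dialect: {dialect!r}")
    with _open_text(path, "r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"log file {path} missing columns: {missing}")
    df = df[LOG_COLUMNS]

    ts = pd.to_datetime(df["timestamp"], format=TIMESTAMP_FORMAT, errors="coerce")
    bad_ts = ts.isna()

    bad_clicks = np.zeros(len(df), dtype=bool)
    decoded_ok = {}
    for text in df.loc[~bad_ts, "clicks"].unique():
        try:
            decode_clicks(text)
            decoded_ok[text] = True
        except (ValueError, TypeError):
            decoded_ok[text] = False
    bad_clicks[~bad_ts.to_numpy()] = ~df.loc[~bad_ts, "clicks"].map(decoded_ok).to_numpy()

    malformed = bad_ts.to_numpy() | bad_clicks
    n_malformed = int(malformed.sum())
    if n_malformed:
        logger.warning("read_log: excluded %d malformed rows from %s", n_malformed, path)

    df = df.loc[~malformed].copy()
    df["timestamp"] = ts.loc[~malformed]

    if window is None:
        if len(df):
            first = df["timestamp"].min().date()
            last = df["timestamp"].max().date()
            window = StudyWindow(first, last + _dt.timedelta(days=1))
        else:
            window = DEFAULT_WINDOW
    else:
        days = df["timestamp"].dt.date
        outside = (days < window.start) | (days >= window.end)
        n_outside = int(outside.sum())
        if n_outside:
            logger.warning("read_log: excluded %d rows outside study window", n_outside)
            n_malformed += n_outside
            df = df.loc[~outside.to_numpy()].copy()

    df = df.reset_index(drop=True)
    return SearchLog(df=df, window=window, n_malformed=n_malformed)


def write_log(log: SearchLog, path: str | Path) -> None:
    """Write a log as canonical TSV: deterministic column order, rows sorted
    by (user_id, timestamp) with a stable sort, timestamps at minute resolution."""
    df = log.df.sort_values(["user_id", "timestamp"], kind="stable")
    out = pd.DataFrame(
        {
            "user_id": df["user_id"],
            "timestamp": df["timestamp"].dt.strftime(TIMESTAMP_FORMAT),
            "query_text": df["query_text"],
            "clicks": df["clicks"],
        }
    )
    with _open_text(path, "w") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def hash_user_ids(log: SearchLog, salt: str) -> SearchLog:
    """Replace user ids with salted hashes (16 hex chars).

    The mapping is deterministic in (salt, id) and checked to be injective
    on the observed ids; original ids do not appear in the output.
    """
    ids = log.df["user_id"].unique()
    mapping = {u: hashlib.sha256(f"{salt}:{u}".encode()).hexdigest()[:16] for u in ids}
    if len(set(mapping.values())) != len(mapping):
        raise RuntimeError("user-id hash collision; choose a different salt")
    df = log.df.copy()
    df["user_id"] = df["user_id"].map(mapping)
    return SearchLog(df=df, window=log.window, n_malformed=log.n_malformed)


def iter_user_days(log: SearchLog) -> Iterator[tuple[str, _dt.date, pd.DataFrame]]:
    """Yield ``(user_id, day, records)`` groups at local-midnight day boundaries.

    Days are emitted chronologically per user, and days with zero queries
    inside a user's active span (first to last query day) are emitted as
    empty groups, so lagged daily features measure calendar time.
    """
    df = log.df
    days = df["timestamp"].dt.normalize()
    for uid, g in df.groupby("user_id", sort=True):
        g_days = days.loc[g.index]
        first, last = g_days.min(), g_days.max()
        by_day = dict(tuple(g.groupby(g_days)))
        empty = g.iloc[0:0]
        day = first
        while day <= last:
            yield uid, day.date(), by_day.get(day, empty)
            day += pd.Timedelta(days=1)


def read_panel(path: str | Path, age_buckets: tuple[str, ...] = DEFAULT_AGE_BUCKETS) -> pd.DataFrame:
    with _open_text(path, "r") as fh:
        panel = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel file {path} missing columns: {missing}")
    bad_gender = ~panel["gender"].isin(GENDERS)
    bad_age = ~panel["age_bucket"].isin(age_buckets)
    bad = bad_gender | bad_age
    if bad.any():
        logger.warning("read_panel: excluded %d rows with unknown gender/age bucket", int(bad.sum()))
    return panel.loc[~bad, PANEL_COLUMNS].reset_index(drop=True)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    out = panel[PANEL_COLUMNS].sort_values("user_id", kind="stable")
    with _open_text(path, "w") as fh:
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")
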