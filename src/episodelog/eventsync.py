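"""Event-anchored analysis of query streams.

Queries are synchronized to each calendar day on which a user posted an
MSD query (the *anchor days*, offset zero). For a topical category the
likelihood-ratio curve at relative hourly bin t is::

    ratio(t) = [ n_cat(t) / n_all(t) ] / [ n_cat(total) / n_all(total) ]

i.e. the probability of the category among queries at offset t, divided
by its probability over the whole stream; 1 means no change. Offsets
are measured from anchor-day midnight, so day 0 spans [0 h, 24 h), and
queries near several anchors contribute to each anchor's window (set
``nearest_only=True`` for the alternative convention). The reported
curve is additionally smoothed with a centered 5-bin moving average
(partial windows at the ends), matching how such curves are usually
displayed.

Also provides hour-of-day / day-of-week profiles of MSD vs all other
queries with two-sample Kolmogorov-Smirnov comparisons.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lexicon import category_membership
from .logio import SearchLog

__all__ = [
    "SyncCurve", "anchor_days", "anchor_day_indices", "sync_category_likelihood",
    "peak_ratio", "temporal_profiles", "TemporalProfiles",
]


@dataclass
class SyncCurve:
    """Likelihood-ratio time series relative to anchor days."""

    category: str
    offsets_hours: np.ndarray    # bin start offsets, -window_days*24 .. window_days*24-1
    ratio_raw: np.ndarray        # NaN where the bin holds no queries
    ratio_smoothed: np.ndarray
    n_queries: np.ndarray        # all queries per bin
    n_category: np.ndarray
    baseline_share: float        # overall category probability
    smoothing_hours: int
    window_days: int

    def __post_init__(self) -> None:
        if len(self.offsets_hours) != len(self.ratio_raw):
            raise ValueError("bin arrays must align")
        if np.nanmin(self.ratio_raw, initial=0) < 0 or (self.n_queries < 0).any():
            raise ValueError("ratios and counts must be non-negative")
        if not (np.diff(self.offsets_hours) == (self.offsets_hours[1] - self.offsets_hours[0])).all():
            raise ValueError("bins must be contiguous")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_hours": self.offsets_hours,
                "ratio_raw": self.ratio_raw,
                "ratio_smoothed": self.ratio_smoothed,
                "n_queries": self.n_queries,
            }
        )


def anchor_days(log: SearchLog, user: str) -> tuple[_dt.date, ...]:
    """Distinct calendar days on which ``user`` posted an MSD query."""
    log.require_annotated()
    df = log.df
    sel = (df["user_id"] == user) & df["msd_flag"]
    days = df.loc[sel, "timestamp"].dt.normalize().drop_duplicates().sort_values()
    return tuple(d.date() for d in days)


def anchor_day_indices(log: SearchLog) -> dict[str, np.ndarray]:
    """Per user, sorted day indices (within the study window) with >= 1 MSD query."""
    log.require_annotated()
    df = log.df
    msd = df[df["msd_flag"]]
    day_idx = (msd["timestamp"].dt.normalize() - pd.Timestamp(log.window.start)).dt.days
    return {
        uid: np.unique(g.to_numpy())
        for uid, g in day_idx.groupby(msd["user_id"])
    }


def _smooth(raw: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average over the defined values; partial windows at
    the ends; bins that are themselves undefined stay undefined."""
    defined = np.isfinite(raw)
    kernel = np.ones(width)
    num = np.convolve(np.where(defined, raw, 0.0), kernel, mode="same")
    den = np.convolve(defined.astype(float), kernel, mode="same")
    out = np.full_like(raw, np.nan)
    ok = defined & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def sync_category_likelihood(
    log: SearchLog,
    category: str,
    anchors: dict[str, np.ndarray] | None = None,
    window_days: int = 7,
    bin_hours: int = 1,
    smooth_hours: int = 5,
    nearest_only: bool = False,
) -> SyncCurve:
    """Event-synchronized likelihood-ratio curve for one category.

    ``anchors`` maps user id to sorted anchor day indices (defaults to
    the annotated MSD days). Raises when there are no anchors or the
    category never occurs (unknown category).
    """
    log.require_annotated()
    if anchors is None:
        anchors = anchor_day_indices(log)
    anchors = {u: a for u, a in anchors.items() if len(a)}
    if not anchors:
        raise ValueError("no anchor days in log")

    df = log.df
    is_cat = category_membership(log, category)
    baseline = is_cat.sum() / len(df) if len(df) else 0.0
    if baseline == 0:
        raise ValueError(f"category {category!r} does not occur in the log")

    half = window_days * 24
    n_bins = 2 * half // bin_hours
    day_idx = (df["timestamp"].dt.normalize() - pd.Timestamp(log.window.start)).dt.days.to_numpy()
    q_hour = day_idx * 24 + df["timestamp"].dt.hour.to_numpy()

    total = np.zeros(n_bins, dtype=np.int64)
    n_cat = np.zeros(n_bins, dtype=np.int64)
    uid_arr = df["user_id"].to_numpy()
    order = np.argsort(uid_arr, kind="stable")
    sorted_uid = uid_arr[order]
    bounds = np.flatnonzero(np.r_[True, sorted_uid[1:] != sorted_uid[:-1], True])
    for i in range(len(bounds) - 1):
        rows = order[bounds[i]:bounds[i + 1]]
        a = anchors.get(sorted_uid[bounds[i]])
        if a is None or not len(a):
            continue
        qh = q_hour[rows]
        qc = is_cat[rows]
        if nearest_only:
            pos = np.searchsorted(a * 24, qh)
            cand_lo = np.clip(pos - 1, 0, len(a) - 1)
            cand_hi = np.clip(pos, 0, len(a) - 1)
            # nearest by distance to anchor-day midnight
            lo_d = np.abs(qh - a[cand_lo] * 24)
            hi_d = np.abs(qh - a[cand_hi] * 24)
            nearest = np.where(lo_d <= hi_d, a[cand_lo], a[cand_hi])
            rel = qh - nearest * 24
            keep = (rel >= -half) & (rel < half)
            bins = (rel[keep] + half) // bin_hours
            np.add.at(total, bins, 1)
            np.add.at(n_cat, bins, qc[keep])
        else:
            rel = qh[:, None] - (a * 24)[None, :]
            keep = (rel >= -half) & (rel < half)
            bins = ((rel + half) // bin_hours)[keep]
            np.add.at(total, bins, 1)
            np.add.at(n_cat, bins, np.broadcast_to(qc[:, None], rel.shape)[keep])

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, (n_cat / np.maximum(total, 1)) / baseline, np.nan)
    smoothed = _smooth(ratio, max(smooth_hours // bin_hours, 1))
    offsets = np.arange(-half, half, bin_hours)
    return SyncCurve(
        category=category,
        offsets_hours=offsets,
        ratio_raw=ratio,
        ratio_smoothed=smoothed,
        n_queries=total,
        n_category=n_cat,
        baseline_share=float(baseline),
        smoothing_hours=smooth_hours,
        window_days=window_days,
    )


def peak_ratio(
    curve: SyncCurve,
    search_range: tuple[float, float] | None = None,
    series: str = "smoothed",
) -> tuple[float, int]:
    """Maximum ratio and its offset (hours) within a relative-day interval.

    ``search_range`` is in days, half-open; ties resolve to the earliest
    offset. Raises when every bin in range is undefined.
    """
    vals = curve.ratio_smoothed if series == "smoothed" else curve.ratio_raw
    if search_range is None:
        mask = np.ones(len(vals), dtype=bool)
    else:
        lo, hi = search_range
        mask = (curve.offsets_hours >= lo * 24) & (curve.offsets_hours < hi * 24)
    vals = np.where(mask, vals, np.nan)
    if not np.isfinite(vals).any():
        raise ValueError("no defined bins in search range")
    best = np.nanargmax(vals)  # first occurrence wins ties
    return float(vals[best]), int(curve.offsets_hours[best])


@dataclass
class TemporalProfiles:
    hour_dist_msd: np.ndarray    # 24 bins, sums to 1
    hour_dist_other: np.ndarray
    hour_ks_p: float
    weekday_dist_msd: np.ndarray  # 7 bins (Mon..Sun), sums to 1
    weekday_dist_other: np.ndarray
    weekday_ks_p: float
    n_msd: int
    n_other: int


def temporal_profiles(log: SearchLog) -> TemporalProfiles:
    """Hour-of-day and day-of-week distributions for MSD vs other queries,
    with two-sample KS tests on the underlying per-query samples."""
    log.require_annotated()
    df = log.df
    msd = df["msd_flag"].to_numpy()
    if msd.all() or not msd.any():
        raise ValueError("both MSD and non-MSD queries are required")
    hours = df["timestamp"].dt.hour.to_numpy()
    dows = df["timestamp"].dt.dayofweek.to_numpy()
    h_m, h_o = hours[msd], hours[~msd]
    d_m, d_o = dows[msd], dows[~msd]
    hour_p = float(sps.ks_2samp(h_m, h_o).pvalue)
    dow_p = float(sps.ks_2samp(d_m, d_o).pvalue)

    def _dist(x: np.ndarray, k: int) -> np.ndarray:
        return np.bincount(x, minlength=k) / len(x)

    return TemporalProfiles(
        hour_dist_msd=_dist(h_m, 24),
        hour_dist_other=_dist(h_o, 24),
        hour_ks_p=hour_p,
        weekday_dist_msd=_dist(d_m, 7),
        weekday_dist_other=_dist(d_o, 7),
        weekday_ks_p=dow_p,
        n_msd=int(msd.sum()),
        n_other=int((~msd).sum()),
    )
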