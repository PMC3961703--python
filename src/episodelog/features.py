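"""Daily-activity feature vectors for next-day query prediction.

Each user-day is summarized by 132 base attributes: total queries,
number of distinct query topics, maximal queries in any hour, number of
active hours, count and fraction of queries in unusual hours (the
half-open wrap-around window 23:00-04:00), and 63 per-category query
counts plus their thresholded indicators. The full feature vector for a
day concatenates 15 copies of the base block — the current-day values,
13 trailing averages over the previous 2..14 calendar days, and a
divergence block (current value minus the mean over all previous
non-MSD days, zero when no such day exists) — plus a single day-of-week
attribute, for exactly 15 x 132 + 1 = 1981 attributes.

Empty days inside a user's active span (first to last query day) count
as zero-activity days in the trailing averages, so lags measure
calendar time, and each row's label says whether the user posts an MSD
(or, for the adult variant, adult-category) query on the following day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lexicon import CategoryLexicon, default_category_lexicon
from .logio import SearchLog

logger = logging.getLogger(__name__)

SCALAR_ATTRS = (
    "total_queries", "n_topics", "max_queries_per_hour",
    "active_hours", "unusual_count", "unusual_fraction",
)
N_BASE = 132
WINDOW_LAGS = tuple(range(2, 15))  # trailing-average windows (previous k days)
N_FEATURES = N_BASE * (1 + len(WINDOW_LAGS) + 1) + 1  # = 1981

UNUSUAL_START, UNUSUAL_END = 23, 4  # [23:00, 04:00) wrap-around


def base_attribute_names(categories: tuple[str, ...]) -> list[str]:
    if len(categories) != 63:
        raise ValueError("expected 63 categories")
    return (
        list(SCALAR_ATTRS)
        + [f"n_{c}" for c in categories]
        + [f"has_{c}" for c in categories]
    )


def feature_names(categories: tuple[str, ...]) -> list[str]:
    base = base_attribute_names(categories)
    names = [f"base_{a}" for a in base]
    for k in WINDOW_LAGS:
        names += [f"win{k}_{a}" for a in base]
    names += [f"div_{a}" for a in base]
    names.append("day_of_week")
    assert len(names) == N_FEATURES
    return names


def _is_unusual(hours: np.ndarray) -> np.ndarray:
    return (hours >= UNUSUAL_START) | (hours < UNUSUAL_END)


def daily_base(records: pd.DataFrame, categories: tuple[str, ...],
               threshold: int = 1) -> np.ndarray:
    """132-attribute summary of one user-day (annotated rows).

    An empty frame yields the all-zero base. Raises when the rows span
    more than one calendar day.
    """
    base = np.zeros(N_BASE, dtype=np.float64)
    n_cat = len(categories)
    if len(records):
        days = records["timestamp"].dt.normalize().unique()
        if len(days) > 1:
            raise ValueError("daily_base records must lie on one calendar day")
        hours = records["timestamp"].dt.hour.to_numpy()
        cat_index = {c: i for i, c in enumerate(categories)}
        counts = np.zeros(n_cat)
        topic_set = set()
        for joined in records["categories"]:
            if joined:
                for c in joined.split(";"):
                    counts[cat_index[c]] += 1
                    topic_set.add(c)
        total = len(records)
        unusual = int(_is_unusual(hours).sum())
        per_hour = np.bincount(hours, minlength=24)
        base[0] = total
        base[1] = len(topic_set)
        base[2] = per_hour.max()
        base[3] = (per_hour > 0).sum()
        base[4] = unusual
        base[5] = unusual / total
        base[6:6 + n_cat] = counts
        base[6 + n_cat:] = counts >= threshold
    return base


def feature_vector(history: np.ndarray, msd_flags: np.ndarray, day_index: int,
                   day_of_week: int) -> np.ndarray:
    """Assemble the 1981-attribute vector for one day of a user's history.

    ``history`` is the (n_days, 132) base matrix over the user's active
    span; ``msd_flags`` marks MSD-query days. Trailing window k uses the
    min(k, available) most recent prior days; the divergence block uses
    all prior non-MSD days and is zero when there are none.
    """
    if history.ndim != 2 or history.shape[1] != N_BASE:
        raise ValueError("history must be (n_days, 132)")
    if not 0 <= day_index < len(history):
        raise ValueError("day before the user's first active day (or past the last)")
    cur = history[day_index]
    blocks = [cur]
    for k in WINDOW_LAGS:
        lo = max(day_index - k, 0)
        prior = history[lo:day_index]
        blocks.append(prior.mean(axis=0) if len(prior) else np.zeros(N_BASE))
    prior_non_msd = history[:day_index][~msd_flags[:day_index].astype(bool)]
    div = cur - prior_non_msd.mean(axis=0) if len(prior_non_msd) else np.zeros(N_BASE)
    blocks.append(div)
    vec = np.concatenate(blocks + [[day_of_week]])
    assert len(vec) == N_FEATURES
    return vec


@dataclass
class LabeledDataset:
    """Per-(user, day) features with next-day labels and user-level folds."""

    X: np.ndarray           # (n_rows, 1981) float32
    y: np.ndarray           # bool: target query on day+1
    user_ids: np.ndarray
    day_index: np.ndarray   # day within the user's active span
    fold: np.ndarray
    columns: list[str]
    n_users: int
    label: str              # "msd" or a category name
    skipped_users: list[str]

    def __post_init__(self) -> None:
        if self.X.shape[1] != N_FEATURES:
            raise ValueError(f"feature dimension must be {N_FEATURES}")
        per_user_folds = pd.Series(self.fold).groupby(pd.Series(self.user_ids)).nunique()
        if (per_user_folds > 1).any():
            raise ValueError("a user's rows must share one fold id")

    def subset_users(self, users: np.ndarray) -> "LabeledDataset":
        mask = np.isin(self.user_ids, users)
        return LabeledDataset(
            X=self.X[mask], y=self.y[mask], user_ids=self.user_ids[mask],
            day_index=self.day_index[mask], fold=self.fold[mask], columns=self.columns,
            n_users=len(np.unique(self.user_ids[mask])), label=self.label,
            skipped_users=self.skipped_users,
        )


def _user_day_aggregates(log: SearchLog, users: set[str], cat_lex: CategoryLexicon,
                         threshold: int, label: str):
    """Vectorized per-(user, day) aggregation used by build_dataset."""
    df = log.df[log.df["user_id"].isin(users)]
    names = cat_lex.names
    cat_code = {c: i for i, c in enumerate(names)}
    day_idx = (df["timestamp"].dt.normalize() - pd.Timestamp(log.window.start)).dt.days
    hours = df["timestamp"].dt.hour
    key = pd.MultiIndex.from_arrays([df["user_id"], day_idx], names=["user_id", "day"])

    target = df["msd_flag"] if label == "msd" else df["categories"].str.contains(
        rf"(?:^|;){label}(?:;|$)", regex=True
    )
    agg = pd.DataFrame(
        {
            "total": 1,
            "unusual": _is_unusual(hours.to_numpy()),
            "target": target.to_numpy(),
            "msd": df["msd_flag"].to_numpy(),
        },
        index=key,
    ).groupby(level=[0, 1]).agg(
        total=("total", "size"), unusual=("unusual", "sum"),
        target=("target", "any"), msd=("msd", "any"),
    )
    hour_counts = pd.Series(1, index=pd.MultiIndex.from_arrays(
        [df["user_id"], day_idx, hours])).groupby(level=[0, 1, 2]).size()
    agg["max_per_hour"] = hour_counts.groupby(level=[0, 1]).max()
    agg["active_hours"] = hour_counts.groupby(level=[0, 1]).size()

    cats = df["categories"].str.split(";").explode()
    cats = cats[cats.notna() & (cats != "")]
    cat_rows = pd.DataFrame(
        {
            "user_id": df.loc[cats.index, "user_id"].to_numpy(),
            "day": day_idx.loc[cats.index].to_numpy(),
            "cat": cats.map(cat_code).to_numpy(),
        }
    )
    cat_counts = cat_rows.groupby(["user_id", "day", "cat"]).size()
    return agg, cat_counts


def build_dataset(
    log: SearchLog,
    population: set[str],
    folds: int = 5,
    seed: int = 0,
    label: str = "msd",
    threshold: int = 1,
    cat_lex: CategoryLexicon | None = None,
) -> LabeledDataset:
    """Construct the labeled per-(user, day) dataset for a population.

    One row per day of each user's active span except the last; the
    label marks a target query (MSD by default) on the following day.
    Users are randomly assigned whole to one of ``folds`` folds (seeded)
    and users with fewer than 2 active days are skipped with a warning.
    """
    log.require_annotated()
    if not population:
        raise ValueError("population is empty")
    cat_lex = cat_lex or default_category_lexicon()
    names = cat_lex.names
    n_cat = len(names)
    agg, cat_counts = _user_day_aggregates(log, set(population), cat_lex, threshold, label)

    users = sorted(set(agg.index.get_level_values(0)))
    rng = np.random.default_rng(seed)
    fold_of_user = dict(zip(users, rng.permutation(len(users)) % folds))
    agg_by_user = {u: g.droplevel(0) for u, g in agg.groupby(level=0, sort=False)}
    cc_by_user = {u: g.droplevel(0) for u, g in cat_counts.groupby(level=0, sort=False)}

    X_parts, y_parts, uid_parts, day_parts, fold_parts = [], [], [], [], []
    skipped: list[str] = []
    for uid in users:
        a = agg_by_user[uid]
        days = a.index.to_numpy()
        first, last = int(days.min()), int(days.max())
        span = last - first + 1
        if span < 2:
            skipped.append(uid)
            continue
        B = np.zeros((span, N_BASE))
        rows = days - first
        totals = a["total"].to_numpy(dtype=float)
        B[rows, 0] = totals
        B[rows, 2] = a["max_per_hour"].to_numpy(dtype=float)
        B[rows, 3] = a["active_hours"].to_numpy(dtype=float)
        B[rows, 4] = a["unusual"].to_numpy(dtype=float)
        B[rows, 5] = a["unusual"].to_numpy(dtype=float) / totals
        cc = cc_by_user.get(uid)
        if cc is not None:
            d_idx = cc.index.get_level_values(0).to_numpy() - first
            c_idx = cc.index.get_level_values(1).to_numpy()
            B[d_idx, 6 + c_idx] = cc.to_numpy(dtype=float)
        B[:, 6 + n_cat:6 + 2 * n_cat] = B[:, 6:6 + n_cat] >= threshold
        B[:, 1] = (B[:, 6:6 + n_cat] > 0).sum(axis=1)

        msd_flags = np.zeros(span, dtype=bool)
        msd_flags[rows] = a["msd"].to_numpy()
        target_flags = np.zeros(span, dtype=bool)
        target_flags[rows] = a["target"].to_numpy()

        # windows: trailing means via exclusive prefix sums
        csum = np.vstack([np.zeros(N_BASE), np.cumsum(B, axis=0)])
        t = np.arange(span)
        blocks = [B]
        for k in WINDOW_LAGS:
            lo = np.maximum(t - k, 0)
            denom = np.maximum(np.minimum(k, t), 1)[:, None]
            blocks.append((csum[t] - csum[lo]) / denom)
        non_msd = (~msd_flags)[:, None] * B
        c_non = np.vstack([np.zeros(N_BASE), np.cumsum(non_msd, axis=0)])
        n_non = np.concatenate([[0], np.cumsum(~msd_flags)])
        with np.errstate(invalid="ignore"):
            prior_mean = c_non[t] / np.maximum(n_non[t], 1)[:, None]
        div = np.where((n_non[t] > 0)[:, None], B - prior_mean, 0.0)
        blocks.append(div)

        start_dow = (log.window.start.weekday() + first) % 7
        dow = ((start_dow + t) % 7)[:, None].astype(float)
        F = np.hstack(blocks + [dow]).astype(np.float32)

        keep = t[:-1]  # last day has no next-day label
        X_parts.append(F[keep])
        y_parts.append(target_flags[keep + 1])
        uid_parts.append(np.full(len(keep), uid, dtype=object))
        day_parts.append(keep)
        fold_parts.append(np.full(len(keep), fold_of_user[uid], dtype=np.int8))

    if skipped:
        logger.warning("build_dataset: skipped %d users with < 2 active days", len(skipped))
    if not X_parts:
        raise ValueError("no usable users in population")
    return LabeledDataset(
        X=np.vstack(X_parts),
        y=np.concatenate(y_parts),
        user_ids=np.concatenate(uid_parts),
        day_index=np.concatenate(day_parts),
        fold=np.concatenate(fold_parts),
        columns=feature_names(names),
        n_users=len(users) - len(skipped),
        label=label,
        skipped_users=skipped,
    )
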