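"""Cohort construction and descriptive statistics.

Works on an annotated :class:`~episodelog.logio.SearchLog` (see
:func:`episodelog.lexicon.annotate`). Provides the user-level MSD
statistics, the population assignment (Recurring / Occasional /
LithiumOnly), query-rate contrasts on MSD vs other days, drug loyalty,
term-category summaries, first-click/long-dwell domain tables,
search-frequency bucket ratios, and the demographic comparison against
a panel.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .lexicon import tokenize, _contains_phrase
from .logio import SearchLog

logger = logging.getLogger(__name__)

RECURRING = "Recurring"
OCCASIONAL = "Occasional"
LITHIUM_ONLY = "LithiumOnly"
NONE_LABEL = "None"
POPULATION_LABELS = (RECURRING, OCCASIONAL, LITHIUM_ONLY, NONE_LABEL)


@dataclass(frozen=True)
class Thresholds:
    """Cohort thresholds; the inclusive defaults mirror the emulated study."""

    min_msd_queries: int = 5          # cohort membership: >= 5 MSD queries
    min_msd_days_recurring: int = 5   # Recurring: MSD queries on >= 5 days
    high_interest_queries: int = 10   # "high interest" drug-name query count
    dwell_min_seconds: float = 30.0   # satisfied ("long dwell") click
    survey_buckets: tuple[str, ...] = ("never", "once", "2-10", ">10")

    def __post_init__(self) -> None:
        if min(self.min_msd_queries, self.min_msd_days_recurring,
               self.high_interest_queries) < 1 or self.dwell_min_seconds <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class UserMsdStats:
    user_id: str
    n_msd_queries: int
    n_msd_days: int
    distinct_drugs: frozenset[str]
    matched_kinds: frozenset[str]  # subset of {"drug-name","lithium","stabilizer-phrase"}
    msd_query_dates: tuple[_dt.date, ...]
    queries_per_day_on_msd_days: float
    queries_per_day_on_other_days: float
    inter_msd_gaps: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (self.n_msd_days <= len(set(self.msd_query_dates)) <= self.n_msd_queries
                or self.n_msd_queries == 0):
            raise ValueError("inconsistent MSD day/query counts")


def user_msd_stats(log: SearchLog) -> dict[str, UserMsdStats]:
    """Per-user MSD statistics over the user's active span.

    Rates count all queries per calendar day; "other days" include
    zero-query days between the user's first and last query day, so the
    off-day rate reflects calendar time.
    """
    log.require_annotated()
    df = log.df
    day = df["timestamp"].dt.normalize()
    out: dict[str, UserMsdStats] = {}
    for uid, g in df.groupby("user_id", sort=True):
        g_day = day.loc[g.index]
        first, last = g_day.min(), g_day.max()
        span = (last - first).days + 1
        msd = g["msd_flag"].to_numpy()
        msd_dates_all = g_day[msd]
        msd_dates = pd.unique(msd_dates_all)
        n_msd_days = len(msd_dates)
        counts_by_day = g_day.value_counts()
        on_msd = counts_by_day.reindex(msd_dates).sum() if n_msd_days else 0
        total = len(g)
        n_other_days = span - n_msd_days
        rate_msd = on_msd / n_msd_days if n_msd_days else float("nan")
        rate_other = (total - on_msd) / n_other_days if n_other_days else float("nan")
        drugs = set()
        for names in g.loc[msd, "drug_names"]:
            if names:
                drugs.update(names.split(";"))
        kinds = set()
        for m in pd.unique(g.loc[msd, "matched"]):
            kinds.add("drug-name" if m not in ("lithium", "stabilizer-phrase") else m)
        msd_sorted = np.sort(msd_dates.astype("datetime64[D]"))
        gaps = tuple(int(x) for x in np.diff(msd_sorted).astype(int)) if n_msd_days > 1 else ()
        out[uid] = UserMsdStats(
            user_id=uid,
            n_msd_queries=int(msd.sum()),
            n_msd_days=n_msd_days,
            distinct_drugs=frozenset(drugs),
            matched_kinds=frozenset(kinds),
            msd_query_dates=tuple(pd.Timestamp(d).date() for d in msd_dates_all),
            queries_per_day_on_msd_days=float(rate_msd),
            queries_per_day_on_other_days=float(rate_other),
            inter_msd_gaps=gaps,
        )
    return out


def assign_population(stats: UserMsdStats, th: Thresholds | None = None) -> str:
    """Assign the mutually exclusive population label.

    Recurring: MSD queries on >= ``min_msd_days_recurring`` days.
    Occasional: a specific drug-name query, on fewer days.
    LithiumOnly: only bare lithium / stabilizer-phrase matches, < 5 days.
    """
    th = th or Thresholds()
    if stats.n_msd_queries == 0:
        return NONE_LABEL
    if stats.n_msd_days >= th.min_msd_days_recurring:
        return RECURRING
    if "drug-name" in stats.matched_kinds:
        return OCCASIONAL
    return LITHIUM_ONLY


def population_table(log: SearchLog, th: Thresholds | None = None) -> pd.DataFrame:
    th = th or Thresholds()
    stats = user_msd_stats(log)
    rows = [(u, assign_population(s, th), s.n_msd_queries, s.n_msd_days) for u, s in stats.items()]
    return pd.DataFrame(rows, columns=["user_id", "population", "n_msd_queries", "n_msd_days"])


def msd_cohort(log: SearchLog, th: Thresholds | None = None) -> set[str]:
    """Users with at least ``min_msd_queries`` MSD queries (inclusive)."""
    th = th or Thresholds()
    log.require_annotated()
    counts = log.df.loc[log.df["msd_flag"], "user_id"].value_counts()
    return set(counts.index[counts >= th.min_msd_queries])


@dataclass(frozen=True)
class RateContrast:
    mean_rate_msd_days: float
    mean_rate_other_days: float
    ratio: float
    sign_test_p: float
    n_users: int


def rate_contrast(stats: dict[str, UserMsdStats] | list[UserMsdStats]) -> RateContrast:
    """Queries/day on MSD days vs other days, paired sign test across users.

    Only users with both day types contribute; ties are discarded from
    the sign test (p = 1 when every pair ties).
    """
    values = stats.values() if isinstance(stats, dict) else stats
    pairs = [
        (s.queries_per_day_on_msd_days, s.queries_per_day_on_other_days)
        for s in values
        if np.isfinite(s.queries_per_day_on_msd_days) and np.isfinite(s.queries_per_day_on_other_days)
    ]
    if not pairs:
        raise ValueError("no users with both MSD days and other days")
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    n_pos = int((a > b).sum())
    n_neg = int((a < b).sum())
    p = sps.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue if n_pos + n_neg else 1.0
    mean_a, mean_b = float(a.mean()), float(b.mean())
    ratio = mean_a / mean_b if mean_b else float("nan")
    return RateContrast(mean_a, mean_b, ratio, float(p), len(pairs))


@dataclass(frozen=True)
class DrugLoyalty:
    query_level_fraction: float   # drug-name queries naming exactly one drug
    user_level_fraction: float    # drug-name users with one distinct drug
    high_interest_fraction: float  # same, users with >= high_interest_queries drug-name queries
    n_drug_queries: int
    n_drug_users: int
    n_high_interest_users: int

    @property
    def undefined(self) -> bool:
        return self.n_drug_queries == 0


def drug_loyalty(log: SearchLog, th: Thresholds | None = None) -> DrugLoyalty:
    th = th or Thresholds()
    log.require_annotated()
    df = log.df
    named = df[df["drug_names"] != ""]
    if not len(named):
        return DrugLoyalty(float("nan"), float("nan"), float("nan"), 0, 0, 0)
    n_names = named["drug_names"].str.count(";") + 1
    q_frac = float((n_names == 1).mean())
    per_user = named.groupby("user_id")["drug_names"].agg(
        lambda s: len(set(";".join(s).split(";")))
    )
    u_frac = float((per_user == 1).mean())
    q_counts = named.groupby("user_id").size()
    hi_users = q_counts.index[q_counts >= th.high_interest_queries]
    hi_frac = float((per_user.loc[hi_users] == 1).mean()) if len(hi_users) else float("nan")
    return DrugLoyalty(q_frac, u_frac, hi_frac, len(named), len(per_user), len(hi_users))


#: Default mutually exclusive MSD-query term buckets (side-effect,
#: drug-related, disease-related, other term families).
DEFAULT_TERM_BUCKETS: dict[str, tuple[str, ...]] = {
    "side_effects": ("mood", "effects", "side", "side effects", "weight", "effect"),
    "drug_related": ("mg", "long", "take", "dosage", "dose", "generic", "release",
                     "interaction", "gain"),
    "disease_related": ("cause", "bipolar", "depression", "high", "low", "treatment",
                        "anxiety", "symptoms"),
    "other": ("drug", "blood", "levels", "children", "use", "sod", "medication", "code",
              "sprinkles", "used", "taking", "loss", "time", "list", "normal", "test",
              "work", "help", "liver", "patient", "pain", "lab", "together"),
}


def term_category_summary(
    log: SearchLog,
    buckets: dict[str, tuple[str, ...]] | None = None,
    cohort_size: int | None = None,
) -> pd.DataFrame:
    """Per term bucket: users whose MSD queries mention a bucket term.

    A user counts at most once per bucket; percentages use
    ``cohort_size`` as the denominator (default: number of MSD-querying
    users in the log). Buckets must not share terms.
    """
    log.require_annotated()
    buckets = buckets or DEFAULT_TERM_BUCKETS
    seen: dict[str, str] = {}
    for name, terms in buckets.items():
        for t in terms:
            if t in seen and seen[t] != name:
                raise ValueError(f"term {t!r} appears in buckets {seen[t]!r} and {name!r}")
            seen[t] = name
    msd = log.df[log.df["msd_flag"]]
    if cohort_size is None:
        cohort_size = msd["user_id"].nunique()
    patterns = {name: [tuple(tokenize(t)) for t in terms] for name, terms in buckets.items()}
    hits: dict[str, set[str]] = {name: set() for name in buckets}
    for text, uid in zip(msd["query_text"], msd["user_id"]):
        tokens = tokenize(text)
        for name, pats in patterns.items():
            if uid not in hits[name] and any(_contains_phrase(tokens, p) for p in pats):
                hits[name].add(uid)
    rows = [
        (name, len(hits[name]), 100.0 * len(hits[name]) / cohort_size if cohort_size else 0.0)
        for name in buckets
    ]
    return pd.DataFrame(rows, columns=["category", "n_users", "pct_of_cohort"])


def click_domain_table(log: SearchLog, msd_only: bool = True,
                       th: Thresholds | None = None) -> pd.DataFrame:
    """Domains of satisfied first clicks, ranked by distinct users.

    One click per query (click_order = 1) with dwell >= the long-dwell
    threshold; ``avg_clicks_per_user`` = clicks / users.
    """
    th = th or Thresholds()
    df = log.df
    if msd_only:
        log.require_annotated()
        df = df[df["msd_flag"]]
    df = df[df["clicks"] != ""]
    if not len(df):
        return pd.DataFrame(columns=["domain", "n_users", "n_clicks", "avg_clicks_per_user"])
    first = df["clicks"].str.split(";").str[0].str.split("|", expand=True)
    first.columns = ["domain", "order", "dwell"]
    keep = (first["order"] == "1") & (first["dwell"].astype(float) >= th.dwell_min_seconds)
    sub = pd.DataFrame({"user_id": df.loc[keep.to_numpy(), "user_id"],
                        "domain": first.loc[keep, "domain"]})
    grouped = sub.groupby("domain").agg(
        n_users=("user_id", "nunique"), n_clicks=("user_id", "size")
    )
    grouped["avg_clicks_per_user"] = grouped["n_clicks"] / grouped["n_users"]
    grouped = grouped.sort_values(["n_users", "domain"], ascending=[False, True], kind="stable")
    return grouped.reset_index()


@dataclass(frozen=True)
class FrequencyRatios:
    ratio_mid: float   # (2-10 searches) / (single search)
    ratio_high: float  # (>10 searches) / (single search)
    rounded: tuple[float, float]

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.ratio_mid)


def frequency_ratios(bucket_counts: dict[str, int]) -> FrequencyRatios:
    """Ratios of repeated-search counts to single-search counts.

    ``bucket_counts`` uses the survey bucket labels; 'never' is ignored.
    Full precision is kept; ``rounded`` carries the 1-d.p. report values.
    """
    once = bucket_counts.get("once", 0)
    mid = bucket_counts.get("2-10", 0)
    high = bucket_counts.get(">10", 0)
    if once == 0:
        logger.warning("frequency_ratios: zero 'once' bucket; ratios undefined")
        return FrequencyRatios(float("nan"), float("nan"), (float("nan"), float("nan")))
    r_mid, r_high = mid / once, high / once
    return FrequencyRatios(r_mid, r_high, (round(r_mid, 1), round(r_high, 1)))


def msd_frequency_buckets(log: SearchLog, universe: set[str] | None = None,
                          th: Thresholds | None = None) -> dict[str, int]:
    """Bucket users by their number of MSD queries (never/once/2-10/>10)."""
    th = th or Thresholds()
    log.require_annotated()
    counts = log.df.loc[log.df["msd_flag"], "user_id"].value_counts()
    if universe is None:
        universe = set(log.df["user_id"])
    n_query_users = len(counts)
    return {
        "never": len(universe) - n_query_users,
        "once": int((counts == 1).sum()),
        "2-10": int(((counts >= 2) & (counts <= 10)).sum()),
        ">10": int((counts > 10).sum()),
    }


def two_proportion_test(count_a: int, n_a: int, count_b: int, n_b: int) -> tuple[float, float]:
    """Pooled two-proportion z test (two-sided). Returns (z, p)."""
    z, p = proportions_ztest([count_a, count_b], [n_a, n_b])
    return float(z), float(p)


@dataclass(frozen=True)
class DemographicComparison:
    female_frac_cohort: float
    female_frac_control: float
    z: float
    p_two_sided: float
    age_chi_square_p: float
    tornado: pd.DataFrame  # gender x age_bucket proportions for cohort and control
    n_cohort: int
    n_control: int


def demographic_comparison(panel: pd.DataFrame, cohort: set[str]) -> DemographicComparison:
    """Compare cohort vs rest-of-panel demographics.

    Female fractions use female/(female+male); the age comparison is a
    chi-square on the cohort-vs-control age-bucket count table.
    """
    in_cohort = panel["user_id"].isin(cohort)
    coh, ctl = panel[in_cohort], panel[~in_cohort]
    if not len(coh):
        raise ValueError("empty cohort in panel")
    if not len(ctl):
        raise ValueError("empty control group in panel")

    def _female(g: pd.DataFrame) -> tuple[int, int]:
        known = g[g["gender"].isin(("female", "male"))]
        return int((known["gender"] == "female").sum()), len(known)

    f_c, n_c = _female(coh)
    f_t, n_t = _female(ctl)
    if min(n_c, n_t) == 0:
        raise ValueError("no gendered panel rows in cohort or control")
    z, p = two_proportion_test(f_c, n_c, f_t, n_t)

    age_tab = pd.crosstab(panel["age_bucket"], in_cohort)
    age_tab = age_tab.loc[age_tab.sum(axis=1) > 0]
    if age_tab.shape[1] == 2 and age_tab.shape[0] > 1:
        age_p = float(sps.chi2_contingency(age_tab.to_numpy().T)[1])
    else:
        age_p = float("nan")

    rows = []
    for grp_name, grp in (("cohort", coh), ("control", ctl)):
        prop = grp.groupby(["gender", "age_bucket"]).size() / len(grp)
        for (g, a), v in prop.items():
            rows.append((grp_name, g, a, float(v)))
    tornado = pd.DataFrame(rows, columns=["group", "gender", "age_bucket", "proportion"])
    return DemographicComparison(
        female_frac_cohort=f_c / n_c,
        female_frac_control=f_t / n_t,
        z=z,
        p_two_sided=p,
        age_chi_square_p=age_p,
        tornado=tornado,
        n_cohort=len(coh),
        n_control=len(ctl),
    )
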