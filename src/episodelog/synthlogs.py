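"""Synthetic search-log generator with episodic behavioral structure.

Emulates, at configurable scale, the behavioral regularities reported
for searchers with intensive interest in mood-stabilizing drugs (MSD):

* four user populations — Recurring (MSD queries on >= 5 days),
  Occasional (specific drug name, < 5 days), Lithium Only (bare
  disambiguated "lithium", < 5 days) and Control (no MSD interest,
  occasional lithium-battery noise queries);
* episodic bursts: gamma-renewal episode onsets (mean gap 13 days,
  SD 11) lasting a few consecutive days, with a ~2x elevation of the
  daily query rate on episode days and per-day MSD-query emission on
  episode days only, so MSD-query days anchor real behavioral change;
* category-likelihood elevation around anchor days: morning-hour pulses
  in nutrition / business / adult query probability on days 0..+4 after
  an anchor (adult ramping linearly to its maximum at +4), calibrated so
  the configured multiplier equals the likelihood ratio measured against
  the stream's own average (see note below);
* morning/weekday bias of MSD queries, near-exclusive single-drug
  loyalty, lithium-battery noise, and gender/age panel marginals.

Calibration note: for each elevated category the off-pulse probability
is lowered so that the category's marginal share equals its mixture
weight. The event-synchronized likelihood ratio is (share at offset) /
(overall share), so without this the overall share would be inflated by
the elevated windows and the measured peak would undershoot the
configured multiplier. With it, the multiplier *is* the expected peak.

Query text is synthesized as "category keyword + filler tokens" from the
same lexicon the classifier uses, so topical classification recovers the
intended category by construction (no NLP realism is attempted).

All randomness flows from ``config.seed``: per-user substreams are
seeded by (seed, user index) and the global synthesis pass by
(seed, 2**20), so output is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lexicon import CategoryLexicon, DrugLexicon, default_category_lexicon, default_drug_lexicon
from .logio import DEFAULT_AGE_BUCKETS, DEFAULT_WINDOW, LOG_COLUMNS, SearchLog, StudyWindow

logger = logging.getLogger(__name__)

POPULATIONS = ("recurring", "occasional", "lithium_only", "control")

# Query "kinds" used internally during synthesis.
_REGULAR, _MSD, _MOOD_FIRST, _MOOD_OTHER, _COMORBID, _NOISE = range(6)

_MSD_DOMAINS = (
    "drugs.com", "en.wikipedia.org", "ehow.com", "wiki.answers.com",
    "answers.yahoo.com", "bipolar-disorder.emedtv.com", "webmd.com",
    "ncbi.nlm.nih.gov", "healthcentral.com", "bipolar.about.com",
)
_MSD_DOMAIN_WEIGHTS = np.array([0.22, 0.18, 0.10, 0.10, 0.09, 0.08, 0.07, 0.06, 0.05, 0.05])

_GENERIC_DOMAINS = tuple(f"portal{i:02d}.example.com" for i in range(20))

# Terms appended to MSD queries, drawn from the side-effect / drug /
# disease / other term families that dominate real MSD query text.
_MSD_TERMS = (
    "side effects", "side effects", "weight", "mood", "effects",
    "dosage", "dose", "mg", "generic", "interaction",
    "bipolar", "depression", "treatment", "symptoms",
    "blood levels", "medication", "sprinkles", "liver",
)

_MOOD_FIRST_TEMPLATES = (
    "i have severe depression", "i feel manic today", "my bipolar medication",
    "i think i have mood disorder", "my depression is worse",
)
_MOOD_OTHER_TEMPLATES = (
    "my wife bipolar treatment", "my husband has depression", "my son manic behavior",
    "my daughter depression help", "my spouse mood disorder",
)
_COMORBID_TEMPLATES = (
    "migraine relief", "seizure medication", "migraines every morning", "seizures at night",
)
_NOISE_TEMPLATES = (
    "lithium ion battery", "lithium battery charger", "lithium batteries bulk",
    "lithium mining stocks", "nirvana lithium lyrics",
)

# Filler tokens: consonant trigrams that match no lexicon keyword.
_FILLER_POOL = tuple(
    a + b + c
    for a, b, c in [
        ("z", "q", "v"), ("x", "r", "k"), ("v", "z", "p"), ("q", "m", "x"),
        ("z", "k", "r"), ("x", "v", "b"), ("q", "p", "z"), ("v", "r", "x"),
        ("z", "b", "q"), ("x", "k", "v"), ("q", "z", "m"), ("v", "p", "k"),
        ("z", "x", "r"), ("x", "q", "b"), ("q", "v", "z"), ("v", "k", "m"),
        ("z", "r", "p"), ("x", "z", "q"), ("q", "k", "v"), ("v", "x", "z"),
    ]
)


def _default_diurnal() -> tuple[float, ...]:
    # Typical web-usage shape: overnight trough, daytime plateau, evening peak.
    w = np.array([
        1.0, 0.6, 0.4, 0.3, 0.3, 0.5, 1.0, 2.0, 3.0, 3.6, 3.8, 3.8,
        3.8, 3.8, 3.8, 3.8, 4.0, 4.2, 4.5, 4.8, 4.8, 4.2, 3.0, 1.8,
    ])
    return tuple(w / w.sum())


def _default_msd_diurnal() -> tuple[float, ...]:
    # Same shape with extra morning mass (8am-11am), where MSD queries peak.
    w = np.array(_default_diurnal())
    w[7:12] *= 1.9
    return tuple(w / w.sum())


def _default_weekday() -> tuple[float, ...]:
    w = np.array([1.085] * 5 + [0.7875, 0.7875])
    return tuple(w / w.sum())


def _default_msd_weekday() -> tuple[float, ...]:
    w = np.array([1.15] * 5 + [0.625, 0.625])
    return tuple(w / w.sum())


def _default_mixture() -> dict[str, float]:
    lex = default_category_lexicon()
    names = lex.names
    elevated = {"nutrition": 0.02, "business": 0.02, "adult": 0.02, "health": 0.05}
    rest = [n for n in names if n not in elevated]
    p_rest = (1.0 - sum(elevated.values())) / len(rest)
    mix = {n: elevated.get(n, p_rest) for n in names}
    return mix


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Defaults encode the empirical anchors of the emulated study: mean
    base rate 8.7 queries/day, ~2x rate on episode days, episode
    recurrence 13 days (SD 11), category multipliers 3.30 / 2.29 / 2.24
    (nutrition / business / adult) with the adult elevation ramping to
    its peak 4 days after the anchor, 98% single-drug loyalty, and
    female fractions 53.04% (control) vs 57.06% (MSD users).
    """

    n_recurring: int = 500
    n_occasional: int = 300
    n_lithium_only: int = 300
    n_control: int = 400
    window: StudyWindow = DEFAULT_WINDOW
    base_rate_mean: float = 8.7      # mean of the lognormal over per-user queries/day
    base_rate_sigma: float = 0.5     # sigma of log(queries/day) across users
    episode_gap_mean: float = 13.0   # days between episode onsets
    episode_gap_sd: float = 11.0
    episode_duration_days: int = 3
    episode_rate_multiplier: float = 2.0
    msd_emission_prob: float = 0.8   # mean per episode day, before weekday tilt
    # emission probability by day-within-episode (last entry reused when the
    # episode is longer): the MSD query typically trails the behavioral onset
    msd_emission_profile: tuple[float, ...] = (0.4, 0.95, 1.0)
    episode_night_boost: float = 4.0  # x on 23:00-04:00 hour mass on episode days (sleep loss)
    msd_day_extra_queries: float = 0.3  # Poisson extra MSD queries beyond the first
    category_mixture: dict[str, float] = field(default_factory=_default_mixture)
    episode_category_multipliers: dict[str, float] = field(
        default_factory=lambda: {"nutrition": 3.30, "business": 2.29, "adult": 2.24}
    )
    adult_ramp_days: int = 4
    pulse_hours: tuple[int, ...] = (8, 9, 10, 11, 12)
    diurnal_profile: tuple[float, ...] = field(default_factory=_default_diurnal)
    msd_diurnal_profile: tuple[float, ...] = field(default_factory=_default_msd_diurnal)
    weekday_profile: tuple[float, ...] = field(default_factory=_default_weekday)
    msd_weekday_profile: tuple[float, ...] = field(default_factory=_default_msd_weekday)
    msd_emission_uniform: bool = False  # True: emission days independent of episodes (null mode)
    drug_loyalty: float = 0.98
    lithium_noise_rate: float = 2.0  # expected battery/metal lithium queries per control user
    click_probs: tuple[float, float, float] = (0.45, 0.40, 0.15)  # P(0/1/2 clicks)
    long_dwell_prob: float = 0.55
    female_frac_control: float = 0.5304
    female_frac_msd: float = 0.5706
    age_buckets: tuple[str, ...] = DEFAULT_AGE_BUCKETS
    age_dist_control: tuple[float, ...] = (0.13, 0.16, 0.15, 0.12, 0.10, 0.09, 0.08, 0.07, 0.05, 0.05)
    age_dist_msd: tuple[float, ...] = (0.12, 0.20, 0.18, 0.13, 0.10, 0.08, 0.07, 0.05, 0.04, 0.03)
    adult_user_sigma: float = 1.0  # log-sd of per-user adult-category affinity (mean 1)
    mood_mention_first_rate: float = 0.30  # P(an MSD user posts first-person mood queries)
    mood_mention_other_rate: float = 0.05
    comorbid_mention_rate: float = 0.12
    msd_term_rate: float = 0.5  # P(an MSD query carries a drug/side-effect term)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_recurring", "n_occasional", "n_lithium_only", "n_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("diurnal_profile", "msd_diurnal_profile"):
            vec = np.asarray(getattr(self, name))
            if len(vec) != 24 or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a 24-bin probability vector summing to 1")
        for name in ("weekday_profile", "msd_weekday_profile"):
            vec = np.asarray(getattr(self, name))
            if len(vec) != 7 or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a 7-bin probability vector summing to 1")
        mix = np.array(list(self.category_mixture.values()))
        if abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
            raise ValueError("category_mixture must be a probability vector summing to 1")
        if any(m < 0 for m in self.episode_category_multipliers.values()):
            raise ValueError("category multipliers must be >= 0")
        if self.episode_rate_multiplier < 1:
            raise ValueError("episode_rate_multiplier must be >= 1")
        ages_c, ages_m = np.asarray(self.age_dist_control), np.asarray(self.age_dist_msd)
        if len(ages_c) != len(self.age_buckets) or len(ages_m) != len(self.age_buckets):
            raise ValueError("age distributions must match age_buckets length")
        if abs(ages_c.sum() - 1) > 1e-9 or abs(ages_m.sum() - 1) > 1e-9:
            raise ValueError("age distributions must sum to 1")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` with every episode effect neutralized.

    Rate multiplier and all category multipliers become 1 and MSD-query
    emission is spread uniformly over the window (same expected number
    of MSD days), so downstream sync curves should be flat at 1 and
    next-day prediction should be at chance.
    """
    return config.replace(
        episode_rate_multiplier=1.0,
        episode_category_multipliers={c: 1.0 for c in config.episode_category_multipliers},
        episode_night_boost=1.0,
        msd_emission_uniform=True,
    )


def with_signal_strength(config: GeneratorConfig, strength: float) -> GeneratorConfig:
    """Scale every episode effect along one axis.

    ``strength=2`` reproduces the defaults; ``strength=1`` removes the
    behavioral signal (rate multiplier, night shift and category
    multipliers all 1, emission still episodic); larger values deepen
    the episode signature proportionally.
    """
    if strength < 1:
        raise ValueError("strength must be >= 1")
    f = strength - 1.0
    return config.replace(
        episode_rate_multiplier=1.0 + (config.episode_rate_multiplier - 1.0) * f,
        episode_night_boost=1.0 + (config.episode_night_boost - 1.0) * f,
        episode_category_multipliers={
            c: 1.0 + (m - 1.0) * f for c, m in config.episode_category_multipliers.items()
        },
    )


@dataclass
class GroundTruth:
    """Per-user generation record for evaluating downstream stages."""

    users: pd.DataFrame  # user_id, population, assigned_drug, loyal, gender, age_bucket, n_msd_days
    episode_days: dict[str, np.ndarray]
    msd_days: dict[str, np.ndarray]
    query_category: pd.Series  # intended category per log row ("" for non-topical queries)


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    return shape, mean / shape


def _episode_days(rng, cfg: GeneratorConfig, n_days: int) -> tuple[np.ndarray, np.ndarray]:
    """Episode days and each day's position within its episode (0-based)."""
    shape, scale = _gamma_params(cfg.episode_gap_mean, cfg.episode_gap_sd)
    starts = []
    t = rng.uniform(0, cfg.episode_gap_mean)
    while t < n_days:
        starts.append(int(t))
        t += max(1.0, rng.gamma(shape, scale))
    pos_of: dict[int, int] = {}
    for s in starts:
        for i in range(cfg.episode_duration_days):
            d = s + i
            if d < n_days:
                pos_of[d] = min(pos_of.get(d, i), i)
    days = np.array(sorted(pos_of), dtype=np.int64)
    pos = np.array([pos_of[d] for d in days], dtype=np.int64)
    return days, pos


def _choose_emission_days(rng, cfg, ep_days: np.ndarray, ep_pos: np.ndarray,
                          dows: np.ndarray, n_days: int, population: str) -> np.ndarray:
    """Pick MSD-emitting days. Episode-day based unless the null mode
    (uniform emission) is active; recurring users are topped up to >= 5."""
    wd = np.asarray(cfg.msd_weekday_profile) * 7.0  # relative weights, mean 1
    if cfg.msd_emission_uniform:
        dens = cfg.msd_emission_prob * len(ep_days) / max(n_days, 1) if population != "lithium_only" else 0.0
        if population == "lithium_only":
            k = int(rng.integers(1, 5))
        else:
            k = int(rng.binomial(n_days, min(dens, 1.0)))
            if population == "occasional":
                k = int(min(max(k, 1), 4))
            elif population == "recurring":
                k = max(k, 5)
        k = min(k, n_days)
        return np.sort(rng.choice(n_days, size=k, replace=False))

    if population == "lithium_only":
        k = int(rng.integers(1, 5))
        return np.sort(rng.choice(n_days, size=min(k, n_days), replace=False))

    if len(ep_days) == 0:
        ep_days = np.sort(rng.choice(n_days, size=min(5, n_days), replace=False))
        ep_pos = np.zeros(len(ep_days), dtype=np.int64)
    profile = np.asarray(cfg.msd_emission_profile)
    base_p = profile[np.minimum(ep_pos, len(profile) - 1)]
    base_p = base_p * cfg.msd_emission_prob / max(profile.mean(), 1e-9)
    tilt = wd[dows[ep_days]]
    p = np.clip(base_p * tilt / tilt.mean(), 0, 1)
    emit = ep_days[rng.random(len(ep_days)) < p]
    if population == "occasional":
        k = int(rng.integers(1, 5))
        k = min(k, len(ep_days))
        weights = tilt / tilt.sum()
        return np.sort(rng.choice(ep_days, size=k, replace=False, p=weights))
    # recurring: guarantee at least 5 emitting days
    target = min(5, len(ep_days))
    if len(emit) < target:
        pool = np.setdiff1d(ep_days, emit)
        extra = rng.choice(pool, size=target - len(emit), replace=False)
        emit = np.sort(np.concatenate([emit, extra]))
    return emit


def _user_stream(idx: int, population: str, cfg: GeneratorConfig, n_days: int,
                 start_dow: int, drug_names: tuple[str, ...]):
    """Draw one user's day structure and query skeleton (no text yet)."""
    rng = np.random.default_rng([cfg.seed % (2**31), idx])
    dows = (start_dow + np.arange(n_days)) % 7
    wd = np.asarray(cfg.weekday_profile) * 7.0

    mu = math.log(cfg.base_rate_mean) - cfg.base_rate_sigma**2 / 2
    lam = rng.lognormal(mu, cfg.base_rate_sigma)

    if population in ("recurring", "occasional"):
        ep_days, ep_pos = _episode_days(rng, cfg, n_days)
    else:
        ep_days = np.array([], dtype=np.int64)
        ep_pos = np.array([], dtype=np.int64)
    msd_days = (
        _choose_emission_days(rng, cfg, ep_days, ep_pos, dows, n_days, population)
        if population != "control"
        else np.array([], dtype=np.int64)
    )
    # ground-truth episode days always cover the emission days (for the
    # lithium-only and uniform-emission cases, which have no behavioral
    # episodes, the MSD days themselves are the recorded "episodes")
    ep_days_truth = np.union1d(ep_days, msd_days)
    if cfg.msd_emission_uniform:
        ep_days = msd_days  # behavioral effects are neutral in this mode anyway

    rate = lam * wd[dows]
    is_ep = np.zeros(n_days, dtype=bool)
    is_ep[ep_days] = True
    rate = np.where(is_ep, rate * cfg.episode_rate_multiplier, rate)
    counts = rng.poisson(rate)

    n_msd_q = np.zeros(n_days, dtype=np.int64)
    if len(msd_days):
        n_msd_q[msd_days] = 1 + rng.poisson(cfg.msd_day_extra_queries, size=len(msd_days))
        counts = np.maximum(counts, n_msd_q)  # MSD queries are part of the day's total

    total = int(counts.sum())
    q_day = np.repeat(np.arange(n_days), counts)
    # first n_msd_q queries of each day are the MSD ones
    day_starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    within = np.arange(total) - np.repeat(day_starts, counts)
    is_msd = within < np.repeat(n_msd_q, counts)

    kind = np.where(is_msd, _MSD, _REGULAR).astype(np.int8)

    # per-query drug assignment
    drug_a = drug_b = ""
    two_drug_pos = -1
    drug_idx = np.full(total, -1, dtype=np.int64)
    if population in ("recurring", "occasional"):
        a = int(rng.integers(len(drug_names)))
        drug_a = drug_names[a]
        loyal = rng.random() < cfg.drug_loyalty
        msd_pos = np.flatnonzero(is_msd)
        drug_idx[msd_pos] = 0
        if not loyal and len(msd_pos):
            b = int((a + 1 + rng.integers(len(drug_names) - 1)) % len(drug_names))
            drug_b = drug_names[b]
            drug_idx[msd_pos[rng.random(len(msd_pos)) < 0.4]] = 1
            two_drug_pos = int(rng.choice(msd_pos))
    elif population == "lithium_only":
        drug_a, loyal = "lithium", True
        drug_idx[np.flatnonzero(is_msd)] = 0
    else:
        loyal = True

    # extra queries: mood mentions / comorbid mentions / lithium-battery noise
    extra_day, extra_kind = [], []
    if population in ("recurring", "occasional", "lithium_only"):
        for rate_, k in (
            (cfg.mood_mention_first_rate, _MOOD_FIRST),
            (cfg.mood_mention_other_rate, _MOOD_OTHER),
            (cfg.comorbid_mention_rate, _COMORBID),
        ):
            if rng.random() < rate_:
                for d in rng.integers(0, n_days, size=rng.integers(1, 3)):
                    extra_day.append(int(d))
                    extra_kind.append(k)
    else:
        for d in rng.integers(0, n_days, size=rng.poisson(cfg.lithium_noise_rate)):
            extra_day.append(int(d))
            extra_kind.append(_NOISE)
    if extra_day:
        q_day = np.concatenate([q_day, np.array(extra_day, dtype=np.int64)])
        kind = np.concatenate([kind, np.array(extra_kind, dtype=np.int8)])
        drug_idx = np.concatenate([drug_idx, np.full(len(extra_day), -1, dtype=np.int64)])

    n_q = len(q_day)
    hours = rng.choice(24, size=n_q, p=np.asarray(cfg.diurnal_profile))
    # sleep-loss signature: episode-day activity shifts toward night hours
    if len(ep_days) and cfg.episode_night_boost != 1.0:
        night = np.array(cfg.diurnal_profile)
        night[[23, 0, 1, 2, 3]] *= cfg.episode_night_boost
        night /= night.sum()
        on_ep = np.isin(q_day, ep_days) & (kind == _REGULAR)
        n_ep_q = int(on_ep.sum())
        if n_ep_q:
            hours[on_ep] = rng.choice(24, size=n_ep_q, p=night)
    msd_mask = kind == _MSD
    n_m = int(msd_mask.sum())
    if n_m:
        hours[msd_mask] = rng.choice(24, size=n_m, p=np.asarray(cfg.msd_diurnal_profile))
    minutes = rng.integers(0, 60, size=n_q)

    # demographics
    if population in ("recurring", "occasional"):
        female_p, age_p = cfg.female_frac_msd, np.asarray(cfg.age_dist_msd)
    else:
        female_p, age_p = cfg.female_frac_control, np.asarray(cfg.age_dist_control)
    gender = "female" if rng.random() < female_p else "male"
    age_bucket = cfg.age_buckets[int(rng.choice(len(cfg.age_buckets), p=age_p))]
    adult_affinity = rng.lognormal(-cfg.adult_user_sigma**2 / 2, cfg.adult_user_sigma)

    return dict(
        day=q_day, hour=hours, minute=minutes, kind=kind, drug_idx=drug_idx,
        ep_days=ep_days_truth, msd_days=msd_days, drug_a=drug_a, drug_b=drug_b,
        two_drug_pos=two_drug_pos, loyal=loyal, gender=gender, age_bucket=age_bucket,
        adult_affinity=adult_affinity,
    )


def _elevation_multipliers(cfg: GeneratorConfig, cat: str, mult: float,
                           offsets: np.ndarray, pulse: np.ndarray) -> np.ndarray:
    """Explicit multiplier for in-window pulse-hour queries, NaN elsewhere."""
    ramp = cfg.adult_ramp_days
    in_win = (offsets >= 0) & (offsets <= ramp) & pulse
    m = np.full(len(offsets), np.nan)
    if cat == "adult":
        m[in_win] = 1.0 + (mult - 1.0) * offsets[in_win] / max(ramp, 1)
    else:
        m[in_win] = mult
    return m


def generate(config: GeneratorConfig,
             cat_lex: CategoryLexicon | None = None,
             drug_lex: DrugLexicon | None = None) -> tuple[SearchLog, pd.DataFrame, GroundTruth]:
    """Generate (SearchLog, panel table, GroundTruth) under ``config``.

    Deterministic under ``config.seed``. Raises if all population counts
    are zero.
    """
    cat_lex = cat_lex or default_category_lexicon()
    drug_lex = drug_lex or default_drug_lexicon()
    n_users = config.n_recurring + config.n_occasional + config.n_lithium_only + config.n_control
    if n_users == 0:
        raise ValueError("at least one population must have users")

    names = cat_lex.names
    mixture = np.array([config.category_mixture.get(n, 0.0) for n in names])
    gen_keywords = np.array([cat_lex.categories[n][0] for n in names], dtype=object)
    bad = [t for t in _FILLER_POOL if t in cat_lex.all_keyword_tokens]
    if bad:
        raise ValueError(f"filler tokens collide with lexicon keywords: {bad}")

    n_days = config.window.n_days
    start_dow = config.window.start.weekday()
    populations = (
        ["recurring"] * config.n_recurring
        + ["occasional"] * config.n_occasional
        + ["lithium_only"] * config.n_lithium_only
        + ["control"] * config.n_control
    )

    streams = []
    for idx, pop in enumerate(populations):
        streams.append(_user_stream(idx, pop, config, n_days, start_dow, drug_lex.msd_names))

    uid_strs = np.array([f"u{idx:05d}" for idx in range(n_users)], dtype=object)
    sizes = np.array([len(s["day"]) for s in streams])
    user_of_q = np.repeat(np.arange(n_users), sizes)
    day = np.concatenate([s["day"] for s in streams])
    hour = np.concatenate([s["hour"] for s in streams])
    minute = np.concatenate([s["minute"] for s in streams])
    kind = np.concatenate([s["kind"] for s in streams])
    drug_idx = np.concatenate([s["drug_idx"] for s in streams])

    # ---- offsets to the most recent anchor (MSD emission day) per query
    offsets = np.full(len(day), 10**6, dtype=np.int64)
    starts = np.concatenate([[0], np.cumsum(sizes)])
    for u, s in enumerate(streams):
        md = s["msd_days"]
        if not len(md):
            continue
        d = day[starts[u]:starts[u + 1]]
        pos = np.searchsorted(md, d, side="right") - 1
        off = np.where(pos >= 0, d - md[np.clip(pos, 0, None)], 10**6)
        offsets[starts[u]:starts[u + 1]] = off

    rng = np.random.default_rng([config.seed % (2**31), 2**20])
    pulse = np.isin(hour, np.asarray(config.pulse_hours, dtype=hour.dtype))
    regular = kind == _REGULAR
    n_reg = int(regular.sum())

    # ---- calibrated per-query probabilities for the elevated categories
    elev_names = [n for n in config.episode_category_multipliers if n in cat_lex.name_index]
    elev_prob = np.zeros((len(elev_names), len(day)))
    for j, cname in enumerate(elev_names):
        mult = config.episode_category_multipliers[cname]
        m = _elevation_multipliers(config, cname, mult, offsets, pulse)
        m_reg = m[regular]
        in_win = ~np.isnan(m_reg)
        s_win, k_win = np.nansum(m_reg), int(in_win.sum())
        baseline = (n_reg - s_win) / max(n_reg - k_win, 1) if n_reg else 1.0
        if baseline < 0.05:
            logger.warning("category %s elevation too dense; clamping baseline", cname)
            baseline = 0.05
        full = np.where(np.isnan(m), baseline, m)
        elev_prob[j] = mixture[cat_lex.name_index[cname]] * full
        if cname == "adult" and config.adult_user_sigma > 0:
            # stable per-user taste for adult content (mean-1 lognormal tilt)
            affinity = np.array([s["adult_affinity"] for s in streams])
            elev_prob[j] = elev_prob[j] * affinity[user_of_q]

    if len(elev_names):
        # keep per-query elevated mass bounded away from 1
        tot = elev_prob.sum(axis=0)
        over = tot > 0.9
        if over.any():
            elev_prob[:, over] *= 0.9 / tot[over]

    elev_idx = np.array([cat_lex.name_index[n] for n in elev_names])
    others = np.setdiff1d(np.arange(len(names)), elev_idx)
    p_others = mixture[others]
    cum_others = np.cumsum(p_others / p_others.sum())

    cat_of_q = np.full(len(day), -1, dtype=np.int64)
    u01 = rng.random(len(day))
    cum = np.cumsum(elev_prob, axis=0)  # (n_elev, n_q)
    chosen = np.full(len(day), -1, dtype=np.int64)
    prev = np.zeros(len(day))
    for j in range(len(elev_names)):
        hit = (chosen < 0) & (u01 < cum[j])
        chosen[hit] = elev_idx[j]
        prev = cum[j]
    rest = chosen < 0
    tail = np.clip((u01[rest] - prev[rest]) / np.clip(1.0 - prev[rest], 1e-12, None), 0, 1 - 1e-12)
    chosen[rest] = others[np.searchsorted(cum_others, tail, side="right")]
    cat_of_q[regular] = chosen[regular]

    # ---- text synthesis
    text = np.empty(len(day), dtype=object)
    n_fill = rng.integers(1, 3, size=len(day))
    f1 = np.array(_FILLER_POOL, dtype=object)[rng.integers(0, len(_FILLER_POOL), size=len(day))]
    f2 = np.array(_FILLER_POOL, dtype=object)[rng.integers(0, len(_FILLER_POOL), size=len(day))]
    reg_pos = np.flatnonzero(regular)
    kw = gen_keywords[cat_of_q[reg_pos]]
    fill = np.where(n_fill[reg_pos] == 1, f1[reg_pos], f1[reg_pos] + " " + f2[reg_pos])
    text[reg_pos] = kw + " " + fill

    msd_pos = np.flatnonzero(kind == _MSD)
    if len(msd_pos):
        drug_a = np.array([s["drug_a"] for s in streams], dtype=object)
        drug_b = np.array([s["drug_b"] for s in streams], dtype=object)
        u_m = user_of_q[msd_pos]
        base = np.where(drug_idx[msd_pos] == 1, drug_b[u_m], drug_a[u_m])
        terms = np.array(_MSD_TERMS, dtype=object)[rng.integers(0, len(_MSD_TERMS), size=len(msd_pos))]
        with_term = rng.random(len(msd_pos)) < config.msd_term_rate
        text[msd_pos] = np.where(with_term, base + " " + terms, base + " " + f1[msd_pos])
        # one explicit two-drug query per disloyal user
        for u, s in enumerate(streams):
            if s["two_drug_pos"] >= 0:
                text[starts[u] + s["two_drug_pos"]] = f"{s['drug_a']} vs {s['drug_b']}"

    for k, pool in ((_MOOD_FIRST, _MOOD_FIRST_TEMPLATES), (_MOOD_OTHER, _MOOD_OTHER_TEMPLATES),
                    (_COMORBID, _COMORBID_TEMPLATES), (_NOISE, _NOISE_TEMPLATES)):
        pos = np.flatnonzero(kind == k)
        if len(pos):
            text[pos] = np.array(pool, dtype=object)[rng.integers(0, len(pool), size=len(pos))]

    # ---- clicks
    n_clicks = rng.choice(3, size=len(day), p=np.asarray(config.click_probs))
    clicks = np.empty(len(day), dtype=object)
    is_msd_q = kind == _MSD
    doms = np.empty((len(day), 2), dtype=object)
    p_msd = _MSD_DOMAIN_WEIGHTS / _MSD_DOMAIN_WEIGHTS.sum()
    for col in range(2):
        doms[:, col] = np.array(_GENERIC_DOMAINS, dtype=object)[
            rng.integers(0, len(_GENERIC_DOMAINS), size=len(day))
        ]
        sel = np.flatnonzero(is_msd_q)
        doms[sel, col] = np.array(_MSD_DOMAINS, dtype=object)[
            rng.choice(len(_MSD_DOMAINS), size=len(sel), p=p_msd)
        ]
    long_dwell = rng.random((len(day), 2)) < config.long_dwell_prob
    dwell = np.where(
        long_dwell,
        np.clip(rng.lognormal(math.log(70), 0.5, size=(len(day), 2)), 30, 1800),
        rng.integers(2, 26, size=(len(day), 2)),
    ).astype(np.int64)
    clicks[n_clicks == 0] = ""
    one = n_clicks == 1
    clicks[one] = doms[one, 0] + "|1|" + dwell[one, 0].astype(str).astype(object)
    two = n_clicks == 2
    clicks[two] = (
        doms[two, 0] + "|1|" + dwell[two, 0].astype(str).astype(object)
        + ";" + doms[two, 1] + "|2|" + dwell[two, 1].astype(str).astype(object)
    )

    # ---- assemble the log
    ts = (
        np.datetime64(config.window.start, "m")
        + day * np.timedelta64(24 * 60, "m")
        + hour * np.timedelta64(60, "m")
        + minute * np.timedelta64(1, "m")
    )
    df = pd.DataFrame(
        {
            "user_id": uid_strs[user_of_q],
            "timestamp": pd.to_datetime(ts),
            "query_text": text,
            "clicks": clicks,
        }
    )
    order = np.lexsort((minute, hour, day, user_of_q))
    df = df.iloc[order].reset_index(drop=True)
    log = SearchLog(df=df[LOG_COLUMNS], window=config.window)

    intended = np.where(cat_of_q >= 0, np.array(names, dtype=object)[np.clip(cat_of_q, 0, None)], "")
    query_category = pd.Series(intended[order], index=df.index, name="intended_category")

    panel = pd.DataFrame(
        {
            "user_id": uid_strs,
            "gender": [s["gender"] for s in streams],
            "age_bucket": [s["age_bucket"] for s in streams],
        }
    )
    users = pd.DataFrame(
        {
            "user_id": uid_strs,
            "population": populations,
            "assigned_drug": [s["drug_a"] for s in streams],
            "second_drug": [s["drug_b"] for s in streams],
            "loyal": [s["loyal"] for s in streams],
            "gender": [s["gender"] for s in streams],
            "age_bucket": [s["age_bucket"] for s in streams],
            "n_msd_days": [len(s["msd_days"]) for s in streams],
        }
    )
    truth = GroundTruth(
        users=users,
        episode_days={u: s["ep_days"] for u, s in zip(uid_strs, streams)},
        msd_days={u: s["msd_days"] for u, s in zip(uid_strs, streams)},
        query_category=query_category,
    )
    return log, panel, truth
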