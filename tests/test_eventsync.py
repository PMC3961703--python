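import datetime as dt

import numpy as np
import pytest

from episodelog import cohort, eventsync, lexicon, synthlogs

from conftest import make_annotated


def test_anchor_days_distinct_and_empty():
    rows = [
        ("u1", "2011-12-05T08:00", "depakote", ""),
        ("u1", "2011-12-05T21:00", "depakote dose", ""),
        ("u1", "2011-12-09T10:00", "lithium dose", ""),
        ("u2", "2011-12-05T10:00", "weather", ""),
    ]
    log = make_annotated(rows)
    assert eventsync.anchor_days(log, "u1") == (dt.date(2011, 12, 5), dt.date(2011, 12, 9))
    assert eventsync.anchor_days(log, "u2") == ()
    idx = eventsync.anchor_day_indices(log)
    assert list(idx["u1"]) == [4, 8]  # window starts 2011-12-01


def _brute_force_curve(log, category, window_days=7):
    """Nested-loop counting oracle for the unsmoothed sync curve."""
    df = log.df
    half = window_days * 24
    start = np.datetime64(log.window.start)
    total = np.zeros(2 * half, dtype=int)
    ncat = np.zeros(2 * half, dtype=int)
    anchors = {}
    for row in df.itertuples(index=False):
        if row.msd_flag:
            d = (row.timestamp.to_datetime64().astype("datetime64[D]") - start).astype(int)
            anchors.setdefault(row.user_id, set()).add(int(d))
    n_cat_total = 0
    for row in df.itertuples(index=False):
        cats = set(row.categories.split(";")) if row.categories else set()
        n_cat_total += category in cats
        qh = (row.timestamp.to_datetime64().astype("datetime64[D]") - start).astype(int) * 24 \
            + row.timestamp.hour
        for a in anchors.get(row.user_id, ()):
            rel = int(qh) - a * 24
            if -half <= rel < half:
                total[rel + half] += 1
                ncat[rel + half] += category in cats
    baseline = n_cat_total / len(df)
    with np.errstate(invalid="ignore"):
        ratio = np.where(total > 0, (ncat / np.maximum(total, 1)) / baseline, np.nan)
    return total, ncat, ratio


def test_sync_curve_equals_bruteforce_oracle(small_annotated):
    alog, _, _ = small_annotated
    sub_users = list(alog.df["user_id"].unique())[:10]
    sub = alog.df[alog.df["user_id"].isin(sub_users)].reset_index(drop=True)
    slog = type(alog)(df=sub, window=alog.window)
    curve = eventsync.sync_category_likelihood(slog, "nutrition", smooth_hours=1)
    total, ncat, ratio = _brute_force_curve(slog, "nutrition")
    np.testing.assert_array_equal(curve.n_queries, total)
    np.testing.assert_array_equal(curve.n_category, ncat)
    np.testing.assert_allclose(curve.ratio_raw, ratio, equal_nan=True)


def test_sync_requires_anchors_and_known_category():
    log = make_annotated([("u1", "2011-12-05T10:00", "weather zkq", "")])
    with pytest.raises(ValueError):
        eventsync.sync_category_likelihood(log, "weather")  # no anchors
    log2 = make_annotated([
        ("u1", "2011-12-05T10:00", "depakote", ""),
        ("u1", "2011-12-05T11:00", "weather zkq", ""),
    ])
    with pytest.raises(ValueError):
        eventsync.sync_category_likelihood(log2, "no_such_category")


def test_smoothing_constant_curve_is_identity_and_oracle():
    raw = np.array([np.nan, 1.0, 1.0, 1.0, 1.0, 1.0, np.nan])
    sm = eventsync._smooth(raw, 5)
    assert np.isnan(sm[0]) and np.isnan(sm[-1])
    np.testing.assert_allclose(sm[1:-1], 1.0)
    rng = np.random.default_rng(0)
    raw = rng.random(50)
    sm = eventsync._smooth(raw, 5)
    # interior values equal the brute-force centered average
    for i in range(2, 48):
        assert sm[i] == pytest.approx(raw[i - 2:i + 3].mean(), abs=1e-12)
    # mass neutrality over fully covered interior bins
    interior = [raw[i - 2:i + 3].mean() for i in range(2, 48)]
    assert np.mean(sm[2:48]) == pytest.approx(np.mean(interior), abs=1e-9)


def test_peak_ratio_tie_and_single_bin_rules():
    offsets = np.arange(-24, 24)
    flat = np.ones(48)
    curve = eventsync.SyncCurve(
        category="c", offsets_hours=offsets, ratio_raw=flat, ratio_smoothed=flat,
        n_queries=np.ones(48, dtype=int), n_category=np.ones(48, dtype=int),
        baseline_share=0.5, smoothing_hours=5, window_days=1,
    )
    val, off = eventsync.peak_ratio(curve, search_range=(0, 1))
    assert (val, off) == (1.0, 0)  # tie -> earliest offset in range
    single = np.full(48, np.nan)
    single[30] = 2.5
    curve2 = eventsync.SyncCurve(
        category="c", offsets_hours=offsets, ratio_raw=single, ratio_smoothed=single,
        n_queries=np.ones(48, dtype=int), n_category=np.ones(48, dtype=int),
        baseline_share=0.5, smoothing_hours=1, window_days=1,
    )
    assert eventsync.peak_ratio(curve2) == (2.5, 6)
    with pytest.raises(ValueError):
        eventsync.peak_ratio(curve2, search_range=(-1, 0))


def test_adult_ramp_peaks_near_day_four():
    """With sparse single-day episodes, the adult elevation peaks +3..+5 days out."""
    cfg = synthlogs.GeneratorConfig(
        n_recurring=150, n_occasional=0, n_lithium_only=0, n_control=0,
        episode_duration_days=1, msd_emission_profile=(1.0,), msd_emission_prob=1.0,
        adult_user_sigma=0.0, seed=13,
    )
    log, _, _ = synthlogs.generate(cfg)
    alog = lexicon.annotate(log)
    curve = eventsync.sync_category_likelihood(alog, "adult")
    _, offset = eventsync.peak_ratio(curve, search_range=(0, 7))
    assert 3 * 24 <= offset <= 5 * 24 + 23


def test_constant_category_has_no_mean_structure(small_annotated):
    """A category generated at constant mixture probability is centred on
    ratio 1 (per-bin flatness needs larger cohorts; see the acceptance
    suite's null-calibration check)."""
    alog, _, _ = small_annotated
    curve = eventsync.sync_category_likelihood(alog, "weather")
    ok = np.isfinite(curve.ratio_raw)
    weighted_mean = np.average(curve.ratio_raw[ok], weights=curve.n_queries[ok])
    assert abs(weighted_mean - 1) < 0.05


def test_temporal_profiles_normalized_and_biased(small_annotated):
    alog, _, _ = small_annotated
    prof = eventsync.temporal_profiles(alog)
    assert prof.hour_dist_msd.sum() == pytest.approx(1.0, abs=1e-9)
    assert prof.hour_dist_other.sum() == pytest.approx(1.0, abs=1e-9)
    assert prof.weekday_dist_msd.sum() == pytest.approx(1.0, abs=1e-9)
    # designed morning bias: more MSD mass at 8-11h than other queries
    assert prof.hour_dist_msd[8:12].sum() > prof.hour_dist_other[8:12].sum()
    assert prof.hour_ks_p < 0.01
    # weekday bias: MSD weekday mass exceeds other queries'
    assert prof.weekday_dist_msd[:5].sum() > prof.weekday_dist_other[:5].sum()


def test_temporal_profiles_null_is_nonsignificant_mostly():
    hits = 0
    for seed in range(6):
        cfg = synthlogs.GeneratorConfig(
            n_recurring=15, n_occasional=0, n_lithium_only=0, n_control=0, seed=100 + seed,
            msd_diurnal_profile=synthlogs.GeneratorConfig().diurnal_profile,
            msd_weekday_profile=synthlogs.GeneratorConfig().weekday_profile,
            episode_night_boost=1.0,
        )
        log, _, _ = synthlogs.generate(cfg)
        prof = eventsync.temporal_profiles(lexicon.annotate(log))
        hits += prof.hour_ks_p > 0.05
    assert hits >= 4


def test_temporal_profiles_requires_both_groups():
    log = make_annotated([("u1", "2011-12-05T10:00", "weather zkq", "")])
    with pytest.raises(ValueError):
        eventsync.temporal_profiles(log)
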