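import numpy as np
import pandas as pd
import pytest

from episodelog import features, lexicon
from episodelog.features import N_BASE, N_FEATURES, WINDOW_LAGS

from conftest import make_annotated

CATS = lexicon.default_category_lexicon().names


def test_dimension_constants():
    assert N_BASE == 132
    assert N_FEATURES == 1981
    assert len(features.feature_names(CATS)) == 1981
    assert len(features.base_attribute_names(CATS)) == 132


def test_daily_base_unusual_hour_boundaries():
    rows = [
        ("u1", "2011-12-05T23:30", "weather zkq", ""),
        ("u1", "2011-12-05T03:59", "weather zkq", ""),
        ("u1", "2011-12-05T04:00", "weather zkq", ""),
    ]
    log = make_annotated(rows)
    base = features.daily_base(log.df, CATS)
    names = features.base_attribute_names(CATS)
    assert base[names.index("unusual_count")] == 2
    assert base[names.index("unusual_fraction")] == pytest.approx(2 / 3)


def test_daily_base_empty_day_is_zero():
    log = make_annotated([("u1", "2011-12-05T10:00", "weather zkq", "")])
    base = features.daily_base(log.df.iloc[0:0], CATS)
    assert (base == 0).all()


def test_daily_base_rejects_multi_day_records():
    rows = [("u1", "2011-12-05T10:00", "a", ""), ("u1", "2011-12-06T10:00", "b", "")]
    log = make_annotated(rows)
    with pytest.raises(ValueError):
        features.daily_base(log.df, CATS)


def test_daily_base_hand_computed_fixture():
    rows = (
        [("u1", f"2011-12-05T09:{m:02d}", "weather zkq", "") for m in range(4)]
        + [("u1", "2011-12-05T10:00", "music zkq", "")]
        + [("u1", "2011-12-05T10:30", "purchase flight tickets", "")]
        + [("u1", f"2011-12-05T23:{m:02d}", "depakote dose", "") for m in (5, 6)]
        + [("u1", "2011-12-05T03:00", "gym zkq", "")]
    )
    log = make_annotated(rows)
    base = features.daily_base(log.df, CATS)
    names = features.base_attribute_names(CATS)
    get = lambda a: base[names.index(a)]
    assert get("total_queries") == 9
    assert get("max_queries_per_hour") == 4
    assert get("active_hours") == 4  # hours 09, 10, 23, 03
    assert get("unusual_count") == 3  # two at 23h, one at 03h
    assert get("unusual_fraction") == pytest.approx(3 / 9)
    assert get("n_weather") == 4
    assert get("n_tourism") == 1 and get("n_commerce") == 1
    assert get("has_music") == 1 and get("has_adult") == 0
    # topics: weather, music, tourism, commerce, fitness (+ drug_related none)
    assert get("n_topics") == 5


def test_feature_vector_dimension_and_constancy():
    history = np.tile(np.arange(N_BASE, dtype=float), (6, 1))
    msd = np.zeros(6, dtype=bool)
    vec = features.feature_vector(history, msd, 5, day_of_week=2)
    assert vec.shape == (N_FEATURES,)
    # constant history: every window average equals the current value, divergence 0
    np.testing.assert_allclose(vec[:N_BASE], history[0])
    for j in range(len(WINDOW_LAGS)):
        np.testing.assert_allclose(vec[(1 + j) * N_BASE:(2 + j) * N_BASE], history[0])
    np.testing.assert_allclose(vec[-1 - N_BASE:-1], 0.0)
    assert vec[-1] == 2


def test_feature_vector_window3_hand_check():
    rng = np.random.default_rng(1)
    history = rng.random((5, N_BASE))
    msd = np.array([False, True, False, False, False])
    vec = features.feature_vector(history, msd, 4, day_of_week=0)
    w3 = vec[(1 + WINDOW_LAGS.index(3)) * N_BASE:(2 + WINDOW_LAGS.index(3)) * N_BASE]
    np.testing.assert_allclose(w3, history[1:4].mean(axis=0))
    # divergence excludes the MSD day 1
    div = vec[-1 - N_BASE:-1]
    np.testing.assert_allclose(div, history[4] - history[[0, 2, 3]].mean(axis=0))


def test_feature_vector_first_day_divergence_zero():
    history = np.random.default_rng(0).random((4, N_BASE))
    vec = features.feature_vector(history, np.zeros(4, bool), 0, day_of_week=6)
    np.testing.assert_allclose(vec[-1 - N_BASE:-1], 0.0)
    for j in range(len(WINDOW_LAGS)):  # no prior days -> zero windows
        np.testing.assert_allclose(vec[(1 + j) * N_BASE:(2 + j) * N_BASE], 0.0)


def test_feature_vector_windows_bounded_by_contributors():
    rng = np.random.default_rng(2)
    history = rng.random((10, N_BASE))
    vec = features.feature_vector(history, np.zeros(10, bool), 9, day_of_week=0)
    for j, k in enumerate(WINDOW_LAGS):
        win = vec[(1 + j) * N_BASE:(2 + j) * N_BASE]
        contrib = history[max(9 - k, 0):9]
        assert (win >= contrib.min(axis=0) - 1e-12).all()
        assert (win <= contrib.max(axis=0) + 1e-12).all()


def test_feature_vector_rejects_out_of_span_day():
    history = np.zeros((3, N_BASE))
    with pytest.raises(ValueError):
        features.feature_vector(history, np.zeros(3, bool), 3, 0)


def _tiny_dataset():
    rows = []
    for d in (1, 2, 3, 4, 5, 6, 7, 8, 9, 10):
        rows.append(("u1", f"2011-12-{d:02d}T10:00", "weather zkq", ""))
    rows.append(("u1", "2011-12-10T11:00", "depakote dose", ""))  # MSD on day 10 only
    rows += [("u2", f"2011-12-{d:02d}T12:00", "music zkq", "") for d in (3, 5)]
    return make_annotated(rows)


def test_build_dataset_label_shift_and_positive_count():
    log = _tiny_dataset()
    ds = features.build_dataset(log, {"u1", "u2"}, seed=0)
    u1 = ds.user_ids == "u1"
    # positive exactly on the row for day 9 (index 8 within span)
    assert ds.y[u1].sum() == 1
    assert ds.day_index[u1][ds.y[u1]].tolist() == [8]
    # u2 span is days 3..5 -> 2 rows, no positives
    assert (ds.user_ids == "u2").sum() == 2
    assert ds.X.shape[1] == N_FEATURES


def test_build_dataset_matches_daily_base_and_feature_vector():
    """Bulk construction agrees with the per-day reference implementation."""
    log = _tiny_dataset()
    ds = features.build_dataset(log, {"u1"}, seed=0)
    df = log.df[log.df["user_id"] == "u1"]
    day = df["timestamp"].dt.normalize()
    first = day.min()
    span = (day.max() - first).days + 1
    history = np.zeros((span, N_BASE))
    msd = np.zeros(span, bool)
    for d in range(span):
        sel = df[day == first + pd.Timedelta(days=d)]
        history[d] = features.daily_base(sel, CATS)
        msd[d] = bool(sel["msd_flag"].any()) if len(sel) else False
    for i in range(len(ds.X)):
        t = ds.day_index[i]
        dow = (first + pd.Timedelta(days=int(t))).weekday()
        expected = features.feature_vector(history, msd, int(t), dow)
        np.testing.assert_allclose(ds.X[i], expected.astype(np.float32), rtol=1e-5)


def test_build_dataset_fold_assignment_reproducible(small_annotated):
    alog, _, truth = small_annotated
    rec = set(truth.users.loc[truth.users["population"] == "recurring", "user_id"])
    ds1 = features.build_dataset(alog, rec, seed=7)
    ds2 = features.build_dataset(alog, rec, seed=7)
    np.testing.assert_array_equal(ds1.fold, ds2.fold)
    per_user = pd.Series(ds1.fold).groupby(pd.Series(ds1.user_ids)).nunique()
    assert (per_user == 1).all()
    assert set(np.unique(ds1.fold)) <= set(range(5))


def test_build_dataset_skips_single_day_users():
    log = make_annotated([("solo", "2011-12-05T10:00", "weather zkq", ""),
                          ("pair", "2011-12-05T10:00", "weather zkq", ""),
                          ("pair", "2011-12-06T10:00", "music zkq", "")])
    ds = features.build_dataset(log, {"solo", "pair"}, seed=0)
    assert ds.skipped_users == ["solo"]
    assert set(ds.user_ids) == {"pair"}
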