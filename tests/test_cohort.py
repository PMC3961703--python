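import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from episodelog import cohort, lexicon

from conftest import make_annotated


def _stats(**kw):
    defaults = dict(
        user_id="u", n_msd_queries=0, n_msd_days=0, distinct_drugs=frozenset(),
        matched_kinds=frozenset(), msd_query_dates=(), queries_per_day_on_msd_days=float("nan"),
        queries_per_day_on_other_days=float("nan"), inter_msd_gaps=(),
    )
    defaults.update(kw)
    return cohort.UserMsdStats(**defaults)


def test_assign_population_definitions():
    th = cohort.Thresholds()
    rec = _stats(n_msd_queries=8, n_msd_days=6, matched_kinds=frozenset({"drug-name"}),
                 msd_query_dates=tuple(range(8)))
    assert cohort.assign_population(rec, th) == cohort.RECURRING
    occ = _stats(n_msd_queries=3, n_msd_days=2, matched_kinds=frozenset({"drug-name", "lithium"}),
                 msd_query_dates=(1, 2, 2))
    assert cohort.assign_population(occ, th) == cohort.OCCASIONAL
    lith = _stats(n_msd_queries=3, n_msd_days=3, matched_kinds=frozenset({"lithium"}),
                  msd_query_dates=(1, 2, 3))
    assert cohort.assign_population(lith, th) == cohort.LITHIUM_ONLY
    assert cohort.assign_population(_stats(), th) == cohort.NONE_LABEL


def test_population_labels_partition(small_annotated):
    alog, _, _ = small_annotated
    pops = cohort.population_table(alog)
    assert pops["user_id"].is_unique
    with_msd = pops[pops["n_msd_queries"] > 0]
    assert set(with_msd["population"]) <= {cohort.RECURRING, cohort.OCCASIONAL,
                                           cohort.LITHIUM_ONLY}
    assert (pops.loc[pops["n_msd_queries"] == 0, "population"] == cohort.NONE_LABEL).all()


def test_msd_cohort_threshold_inclusive():
    rows = []
    for i in range(5):
        rows.append(("in5", f"2011-12-{5+i:02d}T10:00", "depakote dose", ""))
    for i in range(4):
        rows.append(("out4", f"2011-12-{5+i:02d}T10:00", "depakote dose", ""))
    log = make_annotated(rows)
    assert cohort.msd_cohort(log) == {"in5"}


def test_rate_contrast_hand_fixture():
    stats = {
        f"u{i}": _stats(user_id=f"u{i}", n_msd_queries=1, n_msd_days=1,
                        msd_query_dates=(None,),
                        queries_per_day_on_msd_days=a, queries_per_day_on_other_days=b)
        for i, (a, b) in enumerate([(10, 5), (8, 4), (6, 3)])
    }
    rc = cohort.rate_contrast(stats)
    assert (rc.mean_rate_msd_days, rc.mean_rate_other_days) == (8.0, 4.0)
    assert rc.ratio == 2.0


def test_rate_contrast_identical_rates_gives_p1():
    stats = {f"u{i}": _stats(queries_per_day_on_msd_days=5.0,
                             queries_per_day_on_other_days=5.0) for i in range(4)}
    assert cohort.rate_contrast(stats).sign_test_p == 1.0


def test_rate_contrast_requires_paired_users():
    with pytest.raises(ValueError):
        cohort.rate_contrast({"u": _stats()})


def test_user_msd_stats_invariant(small_annotated):
    alog, _, _ = small_annotated
    for s in cohort.user_msd_stats(alog).values():
        if s.n_msd_queries:
            assert s.n_msd_days <= len(set(s.msd_query_dates)) <= s.n_msd_queries


def test_drug_loyalty_all_single_drug():
    rows = [(f"u{i}", "2011-12-05T10:00", "depakote dose", "") for i in range(3)]
    res = cohort.drug_loyalty(make_annotated(rows))
    assert res.query_level_fraction == 1.0
    assert res.user_level_fraction == 1.0


def test_drug_loyalty_counts_multi_drug_queries():
    rows = [
        ("u1", "2011-12-05T10:00", "depakote vs valproate", ""),  # two drugs, one query
        ("u1", "2011-12-06T10:00", "depakote dose", ""),
        ("u2", "2011-12-05T10:00", "depakene info", ""),
    ]
    res = cohort.drug_loyalty(make_annotated(rows))
    assert res.query_level_fraction == pytest.approx(2 / 3)
    assert res.user_level_fraction == pytest.approx(1 / 2)  # u1 saw two distinct drugs
    assert res.n_drug_queries == 3


def test_term_category_summary_hand_fixture():
    rows = [
        ("u1", "2011-12-05T10:00", "depakote weight", ""),
        ("u2", "2011-12-05T10:00", "depakote weight gain", ""),
        ("u3", "2011-12-05T10:00", "depakote info", ""),
        ("u4", "2011-12-05T10:00", "lithium dosage", ""),
    ]
    table = cohort.term_category_summary(make_annotated(rows), cohort_size=4)
    row = table.set_index("category").loc["side_effects"]
    assert (row["n_users"], row["pct_of_cohort"]) == (2, 50.0)
    drug_rel = table.set_index("category").loc["drug_related"]
    assert drug_rel["n_users"] == 2  # "gain" and "dosage"


def test_term_category_summary_rejects_overlapping_buckets():
    with pytest.raises(ValueError):
        cohort.term_category_summary(
            make_annotated([("u1", "2011-12-05T10:00", "depakote", "")]),
            buckets={"a": ("weight",), "b": ("weight", "dose")},
        )


def test_term_summary_reproduces_reported_percentage():
    """n=5,391 of a 20,046-user cohort -> 26.89%."""
    assert round(100 * 5391 / 20046, 2) == 26.89


def test_click_domain_table_rule_composition():
    rows = [
        # first click fails dwell; second click is not first -> contributes nothing
        ("u1", "2011-12-05T10:00", "depakote", "a.com|1|10;b.com|2|120"),
        ("u1", "2011-12-05T11:00", "depakote", "drugs.com|1|45"),
        ("u2", "2011-12-05T10:00", "depakote", "drugs.com|1|31"),
        ("u2", "2011-12-06T10:00", "depakote", "drugs.com|1|200"),
        ("u3", "2011-12-05T10:00", "weather", "x.com|1|60"),  # not an MSD query
    ]
    table = cohort.click_domain_table(make_annotated(rows), msd_only=True)
    assert table["domain"].tolist() == ["drugs.com"]
    row = table.iloc[0]
    assert (row["n_users"], row["n_clicks"]) == (2, 3)
    assert row["avg_clicks_per_user"] == 1.5


def test_click_domain_table_matches_bruteforce(small_annotated):
    alog, _, _ = small_annotated
    th = cohort.Thresholds()
    table = cohort.click_domain_table(alog, msd_only=True, th=th)
    expected: dict[str, list] = {}
    for row in alog.df[alog.df["msd_flag"]].itertuples(index=False):
        if not row.clicks:
            continue
        for part in row.clicks.split(";"):
            dom, order, dwell = part.split("|")
            if order == "1" and float(dwell) >= th.dwell_min_seconds:
                expected.setdefault(dom, []).append(row.user_id)
    for _, row in table.iterrows():
        users = expected.pop(row["domain"])
        assert row["n_clicks"] == len(users)
        assert row["n_users"] == len(set(users))
    assert not expected
    # ranking invariant
    assert (table["n_users"].diff().dropna() <= 0).all()


def test_frequency_ratios_reported_and_degenerate():
    res = cohort.frequency_ratios({"once": 81, "2-10": 117, ">10": 16})
    assert res.rounded == (1.4, 0.2)
    flat = cohort.frequency_ratios({"once": 10, "2-10": 10, ">10": 10})
    assert flat.rounded == (1.0, 1.0)
    undef = cohort.frequency_ratios({"once": 0, "2-10": 5, ">10": 1})
    assert undef.undefined


def test_frequency_buckets_match_direct_counting(small_annotated):
    alog, _, _ = small_annotated
    buckets = cohort.msd_frequency_buckets(alog)
    counts = alog.df.loc[alog.df["msd_flag"], "user_id"].value_counts()
    assert buckets["once"] == (counts == 1).sum()
    assert buckets[">10"] == (counts > 10).sum()
    assert sum(buckets.values()) == alog.df["user_id"].nunique()


def test_two_proportion_test_reproduces_reported_values():
    """586/1027 vs 45,707/86,168 female: z=2.56, two-sided p=.010 (one-sided .005)."""
    z, p = cohort.two_proportion_test(586, 1027, 45707, 86168)
    # independent arithmetic oracle
    p1, p2 = 586 / 1027, 45707 / 86168
    pool = (586 + 45707) / (1027 + 86168)
    z_hand = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / 1027 + 1 / 86168))
    assert z == pytest.approx(z_hand)
    assert p == pytest.approx(2 * sps.norm.sf(abs(z_hand)))
    assert round(p, 3) == 0.010
    assert round(sps.norm.sf(abs(z_hand)), 3) == 0.005


def test_demographic_comparison_identical_distributions():
    panel = pd.DataFrame({
        "user_id": [f"u{i}" for i in range(40)],
        "gender": ["female", "male"] * 20,
        "age_bucket": ["25-29", "30-34"] * 20,
    })
    cohort_users = {f"u{i}" for i in range(20)}  # same 50/50 female split
    res = cohort.demographic_comparison(panel, cohort_users)
    assert res.z == pytest.approx(0.0)
    assert res.p_two_sided == pytest.approx(1.0)


def test_demographic_comparison_detects_configured_shift():
    rng = np.random.default_rng(0)
    n_c, n_t = 4 * 1027, 4 * 86168 // 10
    coh_g = np.where(rng.random(n_c) < 0.5706, "female", "male")
    ctl_g = np.where(rng.random(n_t) < 0.5304, "female", "male")
    panel = pd.DataFrame({
        "user_id": [f"c{i}" for i in range(n_c)] + [f"t{i}" for i in range(n_t)],
        "gender": np.concatenate([coh_g, ctl_g]),
        "age_bucket": ["25-29"] * (n_c + n_t),
    })
    res = cohort.demographic_comparison(panel, {f"c{i}" for i in range(n_c)})
    assert res.p_two_sided < 0.01
    assert res.female_frac_cohort > res.female_frac_control


def test_demographic_comparison_requires_cohort():
    panel = pd.DataFrame({"user_id": ["u1"], "gender": ["female"], "age_bucket": ["25-29"]})
    with pytest.raises(ValueError):
        cohort.demographic_comparison(panel, set())
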