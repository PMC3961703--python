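#!/usr/bin/env python
"""Characterize the MSD-querying cohort.

Annotates the simulated log with the query classifiers, then reproduces
the descriptive analyses: population assignment, first-person vs
other-person mood queries, comorbid-term ratio, MSD-day vs other-day
query rates, drug loyalty, common MSD query terms, satisfied-click
domains, search-frequency buckets, and the cohort-vs-control
demographic comparison. Tables land in results/cohort/.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from episodelog import cohort, lexicon
from episodelog.logio import read_log, read_panel

ap = argparse.ArgumentParser()
ap.add_argument("--sim", type=Path, default=Path("results/simulation"))
ap.add_argument("--out", type=Path, default=Path("results/cohort"))
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

log = read_log(args.sim / "log.tsv")
panel = read_panel(args.sim / "panel.tsv")
alog = lexicon.annotate(log)

pops = cohort.population_table(alog)
pops.to_csv(args.out / "populations.tsv", sep="\t", index=False)
print("populations:", pops["population"].value_counts().to_dict())

so = lexicon.self_other_ratio(alog)
print(f"first-person vs other-person mood queries: {so.n_first} vs {so.n_other} "
      f"(ratio {so.ratio:.1f}, chi-square p={so.chi_square_p:.2g})")
com = lexicon.comorbid_ratio(alog)
print(f"mood-term vs migraine/seizure users: {com.n_mood_users} vs "
      f"{com.n_comorbid_users} (ratio {com.ratio:.2f})")

stats = cohort.user_msd_stats(alog)
rc = cohort.rate_contrast(stats)
print(f"queries/day on MSD days {rc.mean_rate_msd_days:.1f} vs other days "
      f"{rc.mean_rate_other_days:.1f} (ratio {rc.ratio:.2f}, sign-test p={rc.sign_test_p:.2g})")

loyalty = cohort.drug_loyalty(alog)
print(f"single-drug: {100*loyalty.query_level_fraction:.2f}% of drug-name queries, "
      f"{100*loyalty.user_level_fraction:.2f}% of users, "
      f"{100*loyalty.high_interest_fraction:.1f}% of high-interest users")

table1 = cohort.term_category_summary(alog, cohort_size=len(cohort.msd_cohort(alog)))
table1.to_csv(args.out / "term_categories.tsv", sep="\t", index=False)
clicks = cohort.click_domain_table(alog, msd_only=True)
clicks.head(10).to_csv(args.out / "clicks_top10.tsv", sep="\t", index=False)
print("top clicked domain:", clicks.iloc[0].to_dict() if len(clicks) else "none")

freq = cohort.frequency_ratios(cohort.msd_frequency_buckets(alog))
print(f"repeat-search ratios (2-10 / once, >10 / once): {freq.rounded}")

demo = cohort.demographic_comparison(panel, cohort.msd_cohort(alog))
demo.tornado.to_csv(args.out / "demographics_tornado.tsv", sep="\t", index=False)
print(f"female fraction cohort {100*demo.female_frac_cohort:.2f}% vs control "
      f"{100*demo.female_frac_control:.2f}% (z={demo.z:.2f}, p={demo.p_two_sided:.3f})")

with open(args.out / "summary.json", "w") as fh:
    json.dump({
        "self_other_ratio": so.ratio, "comorbid_ratio": com.ratio,
        "rate_ratio": rc.ratio, "sign_test_p": rc.sign_test_p,
        "loyalty_query_pct": 100 * loyalty.query_level_fraction,
        "loyalty_user_pct": 100 * loyalty.user_level_fraction,
        "female_frac_cohort": demo.female_frac_cohort,
        "female_frac_control": demo.female_frac_control,
        "demographic_p": demo.p_two_sided,
    }, fh, indent=2, default=float)
print(f"tables in {args.out}/")
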