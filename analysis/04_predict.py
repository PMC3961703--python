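#!/usr/bin/env python
"""Predict next-day MSD queries from daily activity.

Builds the 1,981-attribute lagged daily feature vectors for the three
user populations (occasional and lithium-only subsampled to the
recurring population's size), trains decision trees under user-level
five-fold cross-validation, and reports pooled AUCs, the AUC contrast
between populations, the most-selected attributes, and the
adult-outcome variant. Results land in results/predict/.
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from episodelog import cohort, features, lexicon, predict
from episodelog.logio import read_log

ap = argparse.ArgumentParser()
ap.add_argument("--sim", type=Path, default=Path("results/simulation"))
ap.add_argument("--out", type=Path, default=Path("results/predict"))
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

alog = lexicon.annotate(read_log(args.sim / "log.tsv"))
pops = cohort.population_table(alog)
by_pop = dict(pops.groupby("population")["user_id"].apply(set))

results = {}
recurring = by_pop.get(cohort.RECURRING, set())
ds_rec = features.build_dataset(alog, recurring, seed=args.seed)
n_target = len(np.unique(ds_rec.user_ids))
payload = {}
for name in (cohort.RECURRING, cohort.OCCASIONAL, cohort.LITHIUM_ONLY):
    users = by_pop.get(name, set())
    if len(users) < 10:
        print(f"{name}: too few users ({len(users)}), skipped")
        continue
    ds = ds_rec if name == cohort.RECURRING else features.build_dataset(
        alog, users, seed=args.seed)
    if len(np.unique(ds.user_ids)) > n_target:
        ds = predict.subsample_to_match(ds, n_target, seed=args.seed)
    res = predict.cv_train_eval(ds, seed=args.seed, population=name)
    results[name] = res
    top = predict.top_attributes(res)
    print(f"{name:12s} pooled AUC {res.pooled_auc:.3f} "
          f"(per-fold mean {res.mean_fold_auc:.3f}, {res.n_users} users, "
          f"{res.n_rows} user-days)")
    print(f"{'':12s} top attributes: {', '.join(top[:6]) or '(none selected >2x)'}")
    payload[name] = {"pooled_auc": res.pooled_auc, "mean_fold_auc": res.mean_fold_auc,
                     "fold_aucs": res.fold_aucs, "n_users": res.n_users,
                     "top_attributes": top}

if cohort.RECURRING in results and cohort.LITHIUM_ONLY in results:
    p = predict.compare_auc(results[cohort.RECURRING], results[cohort.LITHIUM_ONLY],
                            seed=args.seed)
    print(f"recurring vs lithium-only AUC difference: bootstrap p={p:.4f}")
    payload["p_recurring_vs_lithium_only"] = p

adult = predict.adult_prediction_variant(alog, seed=args.seed)
print(f"adult-outcome variant: pooled AUC {adult.pooled_auc:.3f} "
      f"({adult.n_users} users with >=5 adult-query days)")
payload["adult_variant"] = {"pooled_auc": adult.pooled_auc, "n_users": adult.n_users}

with open(args.out / "prediction.json", "w") as fh:
    json.dump(payload, fh, indent=2, default=float)
print(f"results in {args.out}/")
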