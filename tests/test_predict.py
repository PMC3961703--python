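import numpy as np
import pandas as pd
import pytest

from episodelog import features, predict
from episodelog.features import N_FEATURES


def brute_force_auc(scores, labels):
    """O(n^2) pairwise oracle: P(positive > negative), ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_examples_and_oracle():
    assert predict.auc([0.9, 0.1], [1, 0]) == 1.0
    assert predict.auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
    rng = np.random.default_rng(0)
    scores = rng.choice([0.1, 0.3, 0.3, 0.8], size=20)
    labels = rng.random(20) < 0.4
    if labels.any() and not labels.all():
        assert predict.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))
    with pytest.raises(ValueError):
        predict.auc([0.1, 0.2], [1, 1])


def test_auc_oracle_on_larger_fixture():
    rng = np.random.default_rng(5)
    scores = rng.random(500)
    labels = scores + rng.normal(0, 0.5, 500) > 0.7
    assert predict.auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))


def _toy_dataset(n_users=20, days=30, separable=False, seed=0):
    rng = np.random.default_rng(seed)
    X, y, uids, dayi, fold = [], [], [], [], []
    for u in range(n_users):
        rows = rng.random((days, N_FEATURES)).astype(np.float32)
        lab = rng.random(days) < 0.3
        if separable:
            rows[:, 0] = lab.astype(np.float32)
        X.append(rows)
        y.append(lab)
        uids.append(np.full(days, f"u{u:03d}", dtype=object))
        dayi.append(np.arange(days))
        fold.append(np.full(days, u % 5, dtype=np.int8))
    return features.LabeledDataset(
        X=np.vstack(X), y=np.concatenate(y), user_ids=np.concatenate(uids),
        day_index=np.concatenate(dayi), fold=np.concatenate(fold),
        columns=[f"f{i}" for i in range(N_FEATURES - 1)] + ["day_of_week"],
        n_users=n_users, label="msd", skipped_users=[],
    )


def test_cv_perfectly_separable_dataset():
    ds = _toy_dataset(separable=True)
    res = predict.cv_train_eval(ds, tree_params={"max_features": None}, seed=0)
    assert res.pooled_auc == 1.0
    assert len(res.fold_aucs) == 5


def test_cv_null_labels_near_chance():
    aucs = []
    for seed in range(3):
        ds = _toy_dataset(n_users=30, days=40, seed=seed)
        aucs.append(predict.cv_train_eval(ds, seed=seed).pooled_auc)
    assert 0.4 < np.mean(aucs) < 0.6


def test_cv_fold_structure_and_no_leakage():
    ds = _toy_dataset(n_users=20)
    res = predict.cv_train_eval(ds, seed=1)
    # every user appears in exactly one test fold
    df = pd.DataFrame({"u": res.user_ids, "f": res.fold_of_rows})
    assert (df.groupby("u")["f"].nunique() == 1).all()
    assert res.n_rows == len(ds.X)
    # removing one user's rows from another fold's training data is the only
    # way it can influence scores; dropping a user entirely must leave the
    # scores of folds that never trained on it unchanged
    victim = "u000"  # fold 0
    keep = ds.user_ids != victim
    ds2 = features.LabeledDataset(
        X=ds.X[keep], y=ds.y[keep], user_ids=ds.user_ids[keep],
        day_index=ds.day_index[keep], fold=ds.fold[keep], columns=ds.columns,
        n_users=19, label="msd", skipped_users=[])
    res2 = predict.cv_train_eval(ds2, seed=1)
    mask2 = res2.fold_of_rows == 0
    mask1 = (res.fold_of_rows == 0) & (res.user_ids != victim)
    np.testing.assert_array_equal(res.scores[mask1], res2.scores[mask2])


def test_subsample_to_match():
    ds = _toy_dataset(n_users=20)
    same = predict.subsample_to_match(ds, 20, seed=0)
    assert set(same.user_ids) == set(ds.user_ids)
    sub1 = predict.subsample_to_match(ds, 5, seed=3)
    sub2 = predict.subsample_to_match(ds, 5, seed=3)
    assert set(sub1.user_ids) == set(sub2.user_ids)
    assert len(set(sub1.user_ids)) == 5
    # all rows of each chosen user retained
    for u in set(sub1.user_ids):
        assert (sub1.user_ids == u).sum() == (ds.user_ids == u).sum()
    with pytest.raises(ValueError):
        predict.subsample_to_match(ds, 21, seed=0)


def test_compare_auc_identical_results_gives_p1():
    ds = _toy_dataset(n_users=10, seed=2)
    res = predict.cv_train_eval(ds, seed=0)
    assert predict.compare_auc(res, res) == 1.0


def test_compare_auc_separates_signal_from_chance():
    strong = predict.cv_train_eval(_toy_dataset(n_users=30, separable=True, seed=0),
                                   tree_params={"max_features": None}, seed=0)
    weak = predict.cv_train_eval(_toy_dataset(n_users=30, seed=1), seed=0)
    p = predict.compare_auc(strong, weak, n_boot=200, seed=0)
    assert p < 0.01


def test_top_attributes_counting_rules():
    def tree(features_):
        return pd.DataFrame({"rank": range(len(features_)),
                             "depth": [0] * len(features_), "feature": features_})
    res = predict.cv_train_eval(_toy_dataset(n_users=10, seed=4), seed=0)
    res.trees = [tree(["root_attr", "twice_attr"]) for _ in range(5)]
    res.trees[0] = tree(["root_attr", "twice_attr"])
    res.trees[1] = tree(["root_attr", "twice_attr"])
    res.trees[2] = tree(["root_attr"])
    res.trees[3] = tree(["root_attr"])
    res.trees[4] = tree(["root_attr"])
    out = predict.top_attributes(res, min_count=3)
    assert out == ["root_attr"]  # selected 5x; twice_attr only 2x -> excluded
    deep = [tree([f"a{i}" for i in range(60)]) for _ in range(5)]
    res.trees = deep
    out = predict.top_attributes(res, max_levels=50, min_count=3)
    assert "a55" not in out and "a10" in out  # rank >= 50 never counted
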