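"""Next-day query prediction: trees, user-level CV, AUC, comparisons.

A decision tree is trained to predict whether a user posts an MSD (or
adult-category) query on the following day from the 1,981-attribute
daily feature vector. Cross-validation is five-fold *at the level of
users* — a user's rows never appear in both train and test — and
performance is the area under the ROC curve over pooled held-out
class-probability scores (per-fold AUCs are also kept, since pooling
vs averaging is a reporting choice).

Default tree parameters: ``min_samples_leaf=20``, ``max_depth=12`` and
``max_features='sqrt'`` (randomized split subspaces; at ~2,000 largely
redundant attributes this bounds training cost and acts as a mild
regularizer without changing which attribute families the trees use).

AUC differences between populations are tested with a user-stratified
bootstrap: users are resampled with replacement within each population
and the pooled-AUC difference re-measured.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .cohort import Thresholds
from .features import LabeledDataset, build_dataset
from .lexicon import CategoryLexicon, category_membership
from .logio import SearchLog

logger = logging.getLogger(__name__)

DEFAULT_TREE_PARAMS: dict = {
    "min_samples_leaf": 20,
    "max_depth": 12,
    "max_features": "sqrt",
}


def auc(scores, labels) -> float:
    """Area under the ROC curve: P(random positive outranks a random
    negative), ties counted 1/2. Raises when only one class is present."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, scores))


def subsample_to_match(dataset: LabeledDataset, target_n_users: int, seed: int = 0) -> LabeledDataset:
    """Random subset of exactly ``target_n_users`` users (all their rows kept)."""
    users = np.unique(dataset.user_ids)
    if len(users) < target_n_users:
        raise ValueError(f"population has {len(users)} users < target {target_n_users}")
    if len(users) == target_n_users:
        return dataset
    rng = np.random.default_rng(seed)
    chosen = rng.choice(users, size=target_n_users, replace=False)
    return dataset.subset_users(chosen)


def _tree_summary(tree: DecisionTreeClassifier, columns: list[str]) -> pd.DataFrame:
    """Internal nodes in level order: (rank, depth, feature name)."""
    t = tree.tree_
    rows = []
    queue = deque([(0, 0)])
    rank = 0
    while queue:
        node, depth = queue.popleft()
        if t.children_left[node] != t.children_right[node]:  # internal
            rows.append((rank, depth, columns[t.feature[node]]))
            queue.append((t.children_left[node], depth + 1))
            queue.append((t.children_right[node], depth + 1))
        rank += 1
    return pd.DataFrame(rows, columns=["rank", "depth", "feature"])


@dataclass
class PredictionResult:
    population: str
    fold_aucs: list[float]
    pooled_auc: float
    mean_fold_auc: float
    scores: np.ndarray
    labels: np.ndarray
    user_ids: np.ndarray
    fold_of_rows: np.ndarray
    trees: list[pd.DataFrame]
    n_users: int
    n_rows: int
    seed: int
    tree_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.pooled_auc <= 1:
            raise ValueError("AUC out of [0, 1]")


def cv_train_eval(
    dataset: LabeledDataset,
    tree_params: dict | None = None,
    seed: int = 0,
    population: str = "",
) -> PredictionResult:
    """User-level 5-fold CV of a decision tree; pooled held-out AUC.

    Test rows are scored with the tree's leaf class-probability. A fold
    whose training data is single-class is skipped with a warning.
    """
    params = dict(DEFAULT_TREE_PARAMS)
    params.update(tree_params or {})
    folds = sorted(np.unique(dataset.fold))
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("dataset labels are single-class")
    scores, labels, uids, fold_rows, fold_aucs, trees = [], [], [], [], [], []
    for f in folds:
        test = dataset.fold == f
        train = ~test
        y_tr = dataset.y[train]
        if y_tr.all() or not y_tr.any():
            logger.warning("fold %s skipped: single-class training data", f)
            continue
        clf = DecisionTreeClassifier(random_state=seed + int(f), **params)
        clf.fit(dataset.X[train], y_tr)
        pos_col = int(np.flatnonzero(clf.classes_)[0]) if clf.classes_[0] == False else 0
        proba = clf.predict_proba(dataset.X[test])
        s = proba[:, list(clf.classes_).index(True)]
        scores.append(s)
        labels.append(dataset.y[test])
        uids.append(dataset.user_ids[test])
        fold_rows.append(np.full(int(test.sum()), f))
        trees.append(_tree_summary(clf, dataset.columns))
        y_te = dataset.y[test]
        if 0 < y_te.sum() < len(y_te):
            fold_aucs.append(auc(s, y_te))
    if not scores:
        raise ValueError("no usable folds")
    scores = np.concatenate(scores)
    labels = np.concatenate(labels)
    uids = np.concatenate(uids)
    return PredictionResult(
        population=population,
        fold_aucs=fold_aucs,
        pooled_auc=auc(scores, labels),
        mean_fold_auc=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        scores=scores,
        labels=labels,
        user_ids=uids,
        fold_of_rows=np.concatenate(fold_rows),
        trees=trees,
        n_users=len(np.unique(uids)),
        n_rows=len(scores),
        seed=seed,
        tree_params=params,
    )


def _user_groups(result: PredictionResult) -> list[np.ndarray]:
    order = np.argsort(result.user_ids, kind="stable")
    uid = result.user_ids[order]
    bounds = np.flatnonzero(np.r_[True, uid[1:] != uid[:-1], True])
    return [order[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]


def _boot_auc(result: PredictionResult, groups: list[np.ndarray], rng) -> float | None:
    pick = rng.integers(0, len(groups), size=len(groups))
    rows = np.concatenate([groups[i] for i in pick])
    y = result.labels[rows]
    if y.all() or not y.any():
        return None
    return auc(result.scores[rows], y)


def compare_auc(result_a: PredictionResult, result_b: PredictionResult,
                n_boot: int = 500, seed: int = 0) -> float:
    """Two-sided p-value for the pooled-AUC difference via a
    user-stratified bootstrap (users resampled within each population)."""
    if (
        len(result_a.scores) == len(result_b.scores)
        and np.array_equal(np.sort(result_a.scores), np.sort(result_b.scores))
        and np.array_equal(np.sort(result_a.labels), np.sort(result_b.labels))
    ):
        return 1.0
    rng = np.random.default_rng(seed)
    ga, gb = _user_groups(result_a), _user_groups(result_b)
    diffs = []
    for _ in range(n_boot):
        aa = _boot_auc(result_a, ga, rng)
        bb = _boot_auc(result_b, gb, rng)
        if aa is None or bb is None:
            continue
        diffs.append(aa - bb)
    if not diffs:
        return float("nan")
    diffs = np.asarray(diffs)
    lo = (np.sum(diffs <= 0) + 1) / (len(diffs) + 1)
    hi = (np.sum(diffs >= 0) + 1) / (len(diffs) + 1)
    return float(min(1.0, 2 * min(lo, hi)))


def top_attributes(result: PredictionResult, max_levels: int = 50,
                   min_count: int = 3) -> list[str]:
    """Attributes splitting the top-``max_levels`` level-order nodes of the
    CV trees, kept when selected at least ``min_count`` times (the
    "more than twice" rule), ordered by count descending."""
    if not result.trees:
        raise ValueError("result carries no tree summaries")
    counter: Counter[str] = Counter()
    for tree in result.trees:
        top = tree[tree["rank"] < max_levels]
        counter.update(top["feature"])
    return [a for a, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
            if c >= min_count]


def adult_day_users(log: SearchLog, min_days: int = 5,
                    category: str = "adult") -> set[str]:
    """Users with adult-category queries on at least ``min_days`` days."""
    is_adult = category_membership(log, category)
    df = log.df[is_adult]
    days = df.groupby("user_id")["timestamp"].apply(lambda s: s.dt.normalize().nunique())
    return set(days.index[days >= min_days])


def adult_prediction_variant(
    log: SearchLog,
    th: Thresholds | None = None,
    folds: int = 5,
    seed: int = 0,
    tree_params: dict | None = None,
    cat_lex: CategoryLexicon | None = None,
) -> PredictionResult:
    """Same pipeline with adult-category queries as the outcome.

    Population: users with adult queries on >= 5 days; label: adult
    query on the following day.
    """
    th = th or Thresholds()
    users = adult_day_users(log, min_days=th.min_msd_days_recurring)
    if not users:
        raise ValueError("no users with enough adult-query days")
    dataset = build_dataset(log, users, folds=folds, seed=seed, label="adult", cat_lex=cat_lex)
    return cv_train_eval(dataset, tree_params=tree_params, seed=seed, population="adult_variant")
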