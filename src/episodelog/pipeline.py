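"""End-to-end orchestration of the study stages.

``run_all`` sequences: (optional) simulation -> annotation -> cohort
descriptives -> temporal profiles -> event-synchronized curves ->
demographics -> per-population next-day prediction (with the
occasional / lithium-only populations subsampled to the recurring
population's size) -> adult-outcome variant. Every stage's tables land
in the output directory as TSV/JSON, together with a manifest of seeds
and parameters sufficient to reproduce every number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as coh
from . import eventsync, features, predict
from .lexicon import annotate, comorbid_ratio, default_category_lexicon, self_other_ratio
from .logio import SearchLog, read_log, read_panel, write_log, write_panel
from .synthlogs import GeneratorConfig, generate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Either a generator config (simulation) or paths to real log/panel files."""

    generator: GeneratorConfig | None = None
    log_path: str | None = None
    panel_path: str | None = None
    thresholds: coh.Thresholds = field(default_factory=coh.Thresholds)
    sync_categories: tuple[str, ...] = ("nutrition", "business", "adult")
    sync_window_days: int = 7
    sync_smooth_hours: int = 5
    feature_threshold: int = 1
    folds: int = 5
    tree_params: dict | None = None
    seed: int = 0
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if self.generator is None and self.log_path is None:
            raise ValueError("config needs a generator config or a log path")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if hasattr(obj, "isoformat"):
        return obj.isoformat()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()
                if not isinstance(v, (pd.DataFrame, pd.Series))}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return None
    return obj


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the report bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    report: dict = {"stages": {}}
    t_start = time.time()

    def stage(name):
        logger.info("stage %-22s t=%.1fs", name, time.time() - t_start)

    try:
        if config.generator is not None:
            stage("simulate")
            log, panel, truth = generate(config.generator)
            write_log(log, out / "log.tsv")
            write_panel(panel, out / "panel.tsv")
            truth.users.to_csv(out / "ground_truth_users.tsv", sep="\t", index=False)
        else:
            stage("load")
            log = read_log(config.log_path)
            panel = read_panel(config.panel_path) if config.panel_path else None

        stage("classify")
        alog = annotate(log)

        stage("cohort")
        stats = coh.user_msd_stats(alog)
        pops = coh.population_table(alog, th)
        pops.to_csv(out / "populations.tsv", sep="\t", index=False)
        cohort_users = coh.msd_cohort(alog, th)
        so = self_other_ratio(alog)
        com = comorbid_ratio(alog)
        rates = coh.rate_contrast(stats)
        loyalty = coh.drug_loyalty(alog, th)
        table1 = coh.term_category_summary(alog, cohort_size=len(cohort_users) or None)
        table1.to_csv(out / "term_categories.tsv", sep="\t", index=False)
        clicks = coh.click_domain_table(alog, msd_only=True, th=th)
        clicks.head(10).to_csv(out / "clicks.tsv", sep="\t", index=False)
        freq = coh.frequency_ratios(coh.msd_frequency_buckets(alog, th=th))
        report["cohort"] = {
            "n_users": int(alog.df["user_id"].nunique()),
            "n_queries": len(alog.df),
            "cohort_size": len(cohort_users),
            "populations": pops["population"].value_counts().to_dict(),
            "self_other": _jsonable(so),
            "comorbid": _jsonable(com),
            "rate_contrast": _jsonable(rates),
            "drug_loyalty": _jsonable(loyalty),
            "frequency_ratios": _jsonable(freq),
        }

        stage("temporal")
        prof = eventsync.temporal_profiles(alog)
        report["temporal"] = {
            "hour_ks_p": prof.hour_ks_p,
            "weekday_ks_p": prof.weekday_ks_p,
            "n_msd": prof.n_msd,
        }

        stage("sync")
        report["sync_peaks"] = {}
        for cat in config.sync_categories:
            curve = eventsync.sync_category_likelihood(
                alog, cat, window_days=config.sync_window_days,
                smooth_hours=config.sync_smooth_hours,
            )
            curve.frame().to_csv(out / f"sync_{cat}.tsv", sep="\t", index=False)
            peak, offset = eventsync.peak_ratio(curve, search_range=(0, config.sync_window_days))
            raw_peak, _ = eventsync.peak_ratio(
                curve, search_range=(0, config.sync_window_days), series="raw")
            report["sync_peaks"][cat] = {
                "smoothed_peak": peak, "offset_hours": offset, "raw_peak": raw_peak,
            }

        if panel is not None:
            stage("demographics")
            demo = coh.demographic_comparison(panel, cohort_users)
            demo.tornado.to_csv(out / "demographics.tsv", sep="\t", index=False)
            report["demographics"] = {
                "female_frac_cohort": demo.female_frac_cohort,
                "female_frac_control": demo.female_frac_control,
                "z": demo.z, "p_two_sided": demo.p_two_sided,
                "age_chi_square_p": demo.age_chi_square_p,
            }

        stage("predict")
        by_pop = dict(pops.groupby("population")["user_id"].apply(set))
        recurring = by_pop.get(coh.RECURRING, set())
        report["prediction"] = {}
        results = {}
        if len(recurring) >= 10:
            ds_rec = features.build_dataset(
                alog, recurring, folds=config.folds, seed=config.seed,
                threshold=config.feature_threshold,
            )
            n_target = len(np.unique(ds_rec.user_ids))
            for name, users in (
                (coh.RECURRING, recurring),
                (coh.OCCASIONAL, by_pop.get(coh.OCCASIONAL, set())),
                (coh.LITHIUM_ONLY, by_pop.get(coh.LITHIUM_ONLY, set())),
            ):
                if len(users) < 10:
                    continue
                ds = ds_rec if name == coh.RECURRING else features.build_dataset(
                    alog, users, folds=config.folds, seed=config.seed,
                    threshold=config.feature_threshold,
                )
                if len(np.unique(ds.user_ids)) > n_target:
                    ds = predict.subsample_to_match(ds, n_target, seed=config.seed)
                try:
                    res = predict.cv_train_eval(
                        ds, tree_params=config.tree_params, seed=config.seed, population=name)
                except ValueError as exc:
                    logger.warning("prediction for %s skipped: %s", name, exc)
                    continue
                results[name] = res
                report["prediction"][name] = {
                    "pooled_auc": res.pooled_auc,
                    "mean_fold_auc": res.mean_fold_auc,
                    "fold_aucs": res.fold_aucs,
                    "n_users": res.n_users,
                    "n_rows": res.n_rows,
                    "top_attributes": predict.top_attributes(res),
                }
            if coh.RECURRING in results and coh.LITHIUM_ONLY in results:
                report["prediction"]["p_recurring_vs_lithium"] = predict.compare_auc(
                    results[coh.RECURRING], results[coh.LITHIUM_ONLY], seed=config.seed)
            try:
                adult = predict.adult_prediction_variant(
                    alog, th, folds=config.folds, seed=config.seed,
                    tree_params=config.tree_params,
                )
                report["prediction"]["adult_variant"] = {
                    "pooled_auc": adult.pooled_auc, "n_users": adult.n_users,
                }
            except ValueError as exc:
                logger.warning("adult variant skipped: %s", exc)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    report["manifest"] = {
        "seed": config.seed,
        "thresholds": _jsonable(th),
        "generator": _jsonable(config.generator) if config.generator else None,
        "sync": {"window_days": config.sync_window_days, "smooth_hours": config.sync_smooth_hours},
        "tree_params": config.tree_params or predict.DEFAULT_TREE_PARAMS,
        "folds": config.folds,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, default=str)
    return report
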