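"""End-to-end orchestration: encode → normalize-in-CV → rank → subset search
→ tune → cross-validate → independent test → post-hoc analyses.

The normalizer is always fit inside each training fold (and on the full
development set only for the final retrain), so no held-out information leaks
into scaling.  Every random step derives from one base seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoders import EncoderRegistry, default_registry, encode_all
from .evaluate import (EvalReport, cross_validate, independent_test,
                       probability_tpr_correlation, tpr_by_probability_bins)
from .modeling import FAMILIES, ModelSpec, TuneResult, tune_hyperparameters
from .selection import (DEFAULT_GRID, RankedFeatureList, SubsetSearchResult,
                        heuristic_subset_search, shadow_feature_ranking)
from .seqio import LabeledDataset, stratified_split

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of the full workflow; defaults follow the development protocol
    (5-fold CV in the subset search, 10-fold CV for tuning and evaluation)."""

    split_fraction: float = 0.8
    boruta_iter: int = 30
    boruta_alpha: float = 0.05
    boruta_trees: int = 300
    grid: tuple[int, ...] = DEFAULT_GRID
    search_cv_folds: int = 5
    search_repeats: int = 3
    tune_trials: int = 100
    tune_cv_folds: int = 10
    eval_cv_folds: int = 10
    eval_repeats: int = 1
    families: tuple[str, ...] = FAMILIES
    tune_families: tuple[str, ...] | None = None  # default: all families
    seed: int = 0


@dataclass
class PipelineResult:
    registry_hash: str
    ranking: RankedFeatureList
    search: SubsetSearchResult
    tuning: dict[str, TuneResult]
    cv_reports: dict[str, EvalReport]
    best_family: str
    test_report: EvalReport
    test_probabilities: np.ndarray
    tpr_bins: pd.DataFrame
    tpr_correlation: float
    dev: LabeledDataset
    test: LabeledDataset


def run_pipeline(dataset: LabeledDataset, registry: EncoderRegistry | None = None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the whole workflow on one labeled dataset and return all artifacts."""
    cfg = config or PipelineConfig()
    registry = registry or default_registry()
    dev, test = stratified_split(dataset, cfg.split_fraction, seed=cfg.seed)
    logger.info("split: %d development / %d test peptides", len(dev), len(test))

    m_dev = encode_all(dev, registry)
    logger.info("encoded development matrix: %d x %d", *m_dev.shape)

    ranking = shadow_feature_ranking(
        m_dev, dev.labels, n_iter=cfg.boruta_iter, alpha=cfg.boruta_alpha,
        seed=cfg.seed, n_estimators=cfg.boruta_trees)
    logger.info("ranking: %d confirmed features", ranking.n_confirmed())

    search = heuristic_subset_search(
        m_dev, dev.labels, ranking, grid=cfg.grid,
        cv_folds=cfg.search_cv_folds, repeats=cfg.search_repeats,
        seed=cfg.seed, families=cfg.families)
    logger.info("subset search: best N=%d (family %s, MCC %.3f)",
                search.best_n, search.best_family,
                search.best_mcc.loc[search.best_n])

    m_sel = m_dev[search.best_features]
    tuning: dict[str, TuneResult] = {}
    cv_reports: dict[str, EvalReport] = {}
    tune_fams = cfg.tune_families or cfg.families
    for fam in tune_fams:
        tuning[fam] = tune_hyperparameters(
            m_sel, dev.labels, fam, n_trials=cfg.tune_trials,
            cv_folds=cfg.tune_cv_folds, seed=cfg.seed)
        spec = ModelSpec(fam, tuning[fam].best_params, cfg.seed)
        cv_reports[fam] = cross_validate(
            m_sel, dev.labels, spec, k=cfg.eval_cv_folds,
            repeats=cfg.eval_repeats, seed=cfg.seed)
        logger.info("%s: tuned CV MCC %.3f, eval CV MCC %.3f",
                    fam, tuning[fam].best_score, cv_reports[fam].mcc)

    best_family = max(tune_fams, key=lambda f: cv_reports[f].mcc)
    best_spec = ModelSpec(best_family, tuning[best_family].best_params, cfg.seed)
    test_report, _model, test_p = independent_test(
        dev, test, best_spec, registry, search.best_features)
    logger.info("independent test (%s): MCC %.3f", best_family, test_report.mcc)

    tpr_bins = tpr_by_probability_bins(test.labels, test_p)
    tpr_corr = probability_tpr_correlation(tpr_bins)

    return PipelineResult(
        registry_hash=registry.hash(), ranking=ranking, search=search,
        tuning=tuning, cv_reports=cv_reports, best_family=best_family,
        test_report=test_report, test_probabilities=test_p,
        tpr_bins=tpr_bins, tpr_correlation=tpr_corr, dev=dev, test=test)
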