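"""Confusion-based metrics, CV and independent-test protocols, and post-hoc
analyses (probability calibration, residue-property stratification, class
composition propensities).

Metric definitions: Acc = (TP+TN)/n, Pre = TP/(TP+FP), Rec = TP/(TP+FN),
Sp = TN/(TN+FP), and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

A metric whose denominator is zero is reported as 0 with an explicit flag.
AUC is the rank-based (Mann-Whitney) area under the ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (RepeatedKFold, RepeatedStratifiedKFold,
                                     StratifiedKFold)

from .encoders import EncoderRegistry, encode_all
from .modeling import ModelSpec, TrainedModel, build_estimator, fit_final
from .preprocess import fit_quartile_scaler
from .seqio import LabeledDataset

__all__ = [
    "ConfusionCounts", "EvalReport", "compute_metrics", "compute_auc",
    "cross_validate", "independent_test", "tpr_by_probability_bins",
    "accuracy_by_residue_property", "composition_propensity",
    "PROPERTY_RESIDUES",
]

# Residue sets for the property-stratified accuracy analysis.  Hydrophilic and
# charged overlap by definition (E, D, R, K, H are both).
PROPERTY_RESIDUES = {
    "hydrophobic": set("VILMFWC"),
    "hydrophilic": set("RNDEQHKST"),
    "charged": set("EDRKH"),
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        t = np.asarray(y_true, int)
        p = np.asarray(y_pred, int)
        return cls(tp=int(((t == 1) & (p == 1)).sum()),
                   tn=int(((t == 0) & (p == 0)).sum()),
                   fp=int(((t == 0) & (p == 1)).sum()),
                   fn=int(((t == 1) & (p == 0)).sum()))

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class EvalReport:
    acc: float
    pre: float
    rec: float
    sp: float
    mcc: float
    auc: float | None = None
    counts: ConfusionCounts | None = None
    flags: list[str] = field(default_factory=list)
    per_fold: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {"Acc": self.acc, "Pre": self.pre, "Rec": self.rec,
             "Sp": self.sp, "MCC": self.mcc}
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def _safe_div(num: float, den: float, flag: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(flag)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> EvalReport:
    """Accuracy, precision, recall, specificity, and MCC from counts."""
    if c.n < 1:
        raise ValueError("at least one evaluated sample required")
    flags: list[str] = []
    acc = (c.tp + c.tn) / c.n
    pre = _safe_div(c.tp, c.tp + c.fp, "precision_undefined", flags)
    rec = _safe_div(c.tp, c.tp + c.fn, "recall_undefined", flags)
    sp = _safe_div(c.tn, c.tn + c.fp, "specificity_undefined", flags)
    denom = math.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = _safe_div(c.tp * c.tn - c.fp * c.fn, denom, "mcc_undefined", flags)
    return EvalReport(acc, pre, rec, sp, mcc, counts=c, flags=flags)


def compute_auc(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties get midranks."""
    y = np.asarray(y_true, int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, float)))


def cross_validate(m: pd.DataFrame, labels, spec: ModelSpec, k: int = 10,
                   repeats: int = 1, seed: int = 0) -> EvalReport:
    """(Repeated) stratified k-fold CV with per-fold scaler refit.

    Threshold metrics come from confusion counts pooled over all folds and
    repeats; AUC is the mean of the per-fold AUCs.  Deterministic given seed.
    """
    y = np.asarray(labels, int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k == len(y):  # leave-one-out: stratification is vacuous
        splitter = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    else:
        splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats,
                                           random_state=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    fold_aucs: list[float] = []
    per_fold: list[dict] = []
    for fold, (tr, te) in enumerate(splitter.split(m, y)):
        scaler = fit_quartile_scaler(m.iloc[tr])
        est = build_estimator(spec)
        est.fit(scaler.transform(m.iloc[tr]).to_numpy(), y[tr])
        proba = est.predict_proba(scaler.transform(m.iloc[te]).to_numpy())
        pos_col = list(est.classes_).index(1)
        p = proba[:, pos_col]
        pred = (p >= 0.5).astype(int)
        c = ConfusionCounts.from_predictions(y[te], pred)
        pooled = pooled + c
        rep = compute_metrics(c)
        if len(np.unique(y[te])) == 2:
            rep.auc = compute_auc(y[te], p)
            fold_aucs.append(rep.auc)
        per_fold.append({"fold": fold, **rep.as_dict()})
    out = compute_metrics(pooled)
    out.auc = float(np.mean(fold_aucs)) if fold_aucs else None
    out.per_fold = per_fold
    return out


def independent_test(dev: LabeledDataset, test: LabeledDataset,
                     spec: ModelSpec, registry: EncoderRegistry,
                     selected_features: list[str] | None = None,
                     ) -> tuple[EvalReport, TrainedModel, np.ndarray]:
    """Retrain on the full development set, evaluate once on the held-out set.

    Both datasets are encoded with the same registry; the scaler and model are
    fit on the development matrix only (optionally restricted to the selected
    features).  Returns the report, the trained model, and the test-set
    positive-class probabilities.
    """
    overlap = set(dev.ids) & set(test.ids)
    if overlap:
        raise ValueError(f"dev and test sets share ids: {sorted(overlap)[:5]}")
    m_dev = encode_all(dev, registry)
    m_test = encode_all(test, registry)
    if selected_features is not None:
        missing = set(selected_features) - set(m_dev.columns)
        if missing:
            raise ValueError(f"selected features absent from encoding: "
                             f"{sorted(missing)[:5]}")
        m_dev = m_dev[list(selected_features)]
        m_test = m_test[list(selected_features)]
    model = fit_final(m_dev, dev.labels, spec)
    p = model.predict_proba(m_test)
    pred = (p >= model.threshold).astype(int)
    report = compute_metrics(ConfusionCounts.from_predictions(test.labels, pred))
    if len(np.unique(test.labels)) == 2:
        report.auc = compute_auc(test.labels, p)
    return report, model, p


def tpr_by_probability_bins(y_true, probabilities,
                            bin_width: float = 0.1) -> pd.DataFrame:
    """Fraction of actual positives among sequences in each predicted-
    probability bin (the calibration-style analysis).

    Returns a frame with bin edges, midpoints, per-bin sequence counts and
    TPR (NaN for empty bins, flagged in the ``empty`` column).
    """
    y = np.asarray(y_true, int)
    p = np.asarray(probabilities, float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.arange(0, 1 + bin_width / 2, bin_width)
    edges[-1] = 1.0
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        rows.append({
            "bin_left": edges[b], "bin_right": edges[b + 1],
            "midpoint": (edges[b] + edges[b + 1]) / 2,
            "count": n,
            "tpr": (y[mask].sum() / n) if n else np.nan,
            "empty": n == 0,
        })
    out = pd.DataFrame(rows)
    assert out["count"].sum() == len(y)
    return out


def probability_tpr_correlation(report: pd.DataFrame) -> float:
    """Spearman rank correlation between bin midpoint and TPR (non-empty bins)."""
    ok = report[report["count"] > 0]
    return float(spearmanr(ok.midpoint, ok.tpr).statistic)


def accuracy_by_residue_property(dataset: LabeledDataset, predictions,
                                 prop: str, bin_width: float = 0.1) -> pd.DataFrame:
    """Mean prediction accuracy stratified by a residue-property ratio.

    For each peptide, ratio = (number of property residues)/L; peptides are
    binned by ratio and per-bin mean accuracy and counts are reported.
    """
    if prop not in PROPERTY_RESIDUES:
        raise ValueError(f"unknown property {prop!r}; "
                         f"choose from {sorted(PROPERTY_RESIDUES)}")
    residues = PROPERTY_RESIDUES[prop]
    pred = np.asarray(predictions, int)
    if len(pred) != len(dataset):
        raise ValueError("predictions must cover the dataset")
    ratios = np.array([sum(aa in residues for aa in p.sequence) / len(p)
                       for p in dataset.peptides])
    correct = (pred == dataset.labels).astype(float)
    edges = np.arange(0, 1 + bin_width / 2, bin_width)
    edges[-1] = 1.0
    idx = np.clip(np.digitize(ratios, edges[1:-1]), 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        rows.append({"bin_left": edges[b], "bin_right": edges[b + 1],
                     "midpoint": (edges[b] + edges[b + 1]) / 2,
                     "count": n,
                     "mean_accuracy": correct[mask].mean() if n else np.nan})
    out = pd.DataFrame(rows)
    assert out["count"].sum() == len(dataset)
    return out


def composition_propensity(dataset: LabeledDataset) -> dict[str, pd.DataFrame]:
    """Per-class mean residue and dipeptide compositions and their difference
    (positive minus negative), sorted by |difference| descending."""
    from .encoders import encode_aac, encode_dpc, _DIPEPTIDES
    from .scales import AA_LIST

    y = dataset.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")

    def table(encoder, names):
        vals = np.array([encoder(p) for p in dataset.peptides])
        mean_pos = vals[y == 1].mean(axis=0)
        mean_neg = vals[y == 0].mean(axis=0)
        df = pd.DataFrame({"mean_pos": mean_pos, "mean_neg": mean_neg,
                           "difference": mean_pos - mean_neg}, index=list(names))
        return df.reindex(df.difference.abs().sort_values(ascending=False).index)

    return {"AAC": table(encode_aac, AA_LIST),
            "DPC": table(encode_dpc, _DIPEPTIDES)}
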