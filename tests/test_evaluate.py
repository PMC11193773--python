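"""Evaluation metrics against brute-force oracles, CV/test protocols, and the
post-hoc analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from antiangio.evaluate import (ConfusionCounts, accuracy_by_residue_property,
                                composition_propensity, compute_auc,
                                compute_metrics, cross_validate,
                                independent_test, probability_tpr_correlation,
                                tpr_by_probability_bins)
from antiangio.encoders import default_registry
from antiangio.modeling import make_default_model
from antiangio.seqio import LabeledDataset, Peptide
from antiangio.synthdata import generate_feature_matrix, generate_peptide_dataset, \
    nterm15_config


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

def brute_force_metrics(tp, tn, fp, fn):
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return acc, pre, rec, sp, mcc


def test_balanced_random_case_is_mcc_zero():
    rep = compute_metrics(ConfusionCounts(25, 25, 25, 25))
    assert rep.mcc == 0.0 and rep.acc == 0.5


def test_perfect_predictor():
    rep = compute_metrics(ConfusionCounts(10, 12, 0, 0))
    assert rep.mcc == rep.acc == rep.pre == rep.rec == rep.sp == 1.0


def test_worked_mcc_example():
    rep = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
    assert rep.mcc == pytest.approx(10 / math.sqrt(600))


def test_metrics_match_brute_force_on_random_draws():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        y = rng.integers(0, 2, 30)
        p = rng.integers(0, 2, 30)
        c = ConfusionCounts.from_predictions(y, p)
        rep = compute_metrics(c)
        acc, pre, rec, sp, mcc = brute_force_metrics(c.tp, c.tn, c.fp, c.fn)
        assert (rep.acc, rep.pre, rep.rec, rep.sp) == (acc, pre, rec, sp)
        assert rep.mcc == pytest.approx(mcc, abs=1e-12)
        assert c.n == 30


def test_mcc_invariant_under_class_swap_and_rec_sp_exchange():
    rng = np.random.default_rng(1)
    for _ in range(200):
        tp, tn, fp, fn = rng.integers(0, 20, 4)
        if tp + tn + fp + fn == 0:
            continue
        a = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        b = compute_metrics(ConfusionCounts(tn, tp, fn, fp))
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
        assert a.rec == pytest.approx(b.sp) and a.sp == pytest.approx(b.rec)


def test_zero_denominator_flagged():
    rep = compute_metrics(ConfusionCounts(0, 5, 0, 5))
    assert rep.pre == 0.0 and "precision_undefined" in rep.flags


def test_negative_counts_error():
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 2)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def brute_force_auc(y, s):
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_examples():
    assert compute_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert compute_auc([1, 1, 0, 0], [0.9, 0.6, 0.4, 0.8]) == 0.75


def test_auc_random_scores_near_half():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 4000)
    s = rng.random(4000)
    assert abs(compute_auc(y, s) - 0.5) < 0.03


def test_auc_single_class_errors():
    with pytest.raises(ValueError):
        compute_auc([1, 1], [0.5, 0.6])


def test_auc_matches_brute_force_pair_counting_with_ties():
    rng = np.random.default_rng(3)
    for n in (4, 11, 25, 50):
        y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
        s = rng.integers(0, 5, n) / 4.0  # coarse grid forces ties
        assert compute_auc(y, s) == pytest.approx(brute_force_auc(y, s))


# ---------------------------------------------------------------------------
# CV and independent test
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def separable_matrix():
    return generate_feature_matrix(40, 4, 6, effect=6.0, seed=4)


def test_leave_one_out_fold_structure(separable_matrix):
    X, y, _ = separable_matrix
    keep = np.r_[np.flatnonzero(y == 1)[:5], np.flatnonzero(y == 0)[:5]]
    X10, y10 = X.iloc[keep], y[keep]
    rep = cross_validate(X10, y10, make_default_model("LDA"), k=10, seed=0)
    assert len(rep.per_fold) == 10
    assert rep.counts.n == 10


def test_pooled_counts_conserved_across_repeats(separable_matrix):
    X, y, _ = separable_matrix
    rep = cross_validate(X, y, make_default_model("LDA"), k=5, repeats=3, seed=0)
    assert rep.counts.n == len(y) * 3


def test_separable_data_gives_perfect_pooled_mcc(separable_matrix):
    X, y, _ = separable_matrix
    rep = cross_validate(X, y, make_default_model("SVM"), k=5, seed=0)
    assert rep.mcc == pytest.approx(1.0)
    assert rep.auc == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_peptide_sets():
    full = generate_peptide_dataset(nterm15_config(n_pos=30, n_neg=30, seed=7))
    from antiangio.seqio import stratified_split
    return stratified_split(full, 0.8, seed=7)


def test_independent_test_on_dev_copy_equals_training_metrics(small_peptide_sets):
    dev, _ = small_peptide_sets
    registry = default_registry().subset(["AAC", "GAAC"])
    clone = LabeledDataset("copy",
                           [Peptide(f"c_{p.id}", p.sequence) for p in dev.peptides],
                           dev.labels.copy())
    rep, model, _p = independent_test(dev, clone, make_default_model("LDA"),
                                      registry)
    from antiangio.encoders import encode_all
    m_dev = encode_all(dev, registry)
    train_pred = model.predict(m_dev)
    train_rep = compute_metrics(ConfusionCounts.from_predictions(dev.labels, train_pred))
    assert rep.acc == train_rep.acc and rep.mcc == train_rep.mcc


def test_independent_test_rejects_overlapping_ids(small_peptide_sets):
    dev, _ = small_peptide_sets
    with pytest.raises(ValueError, match="share ids"):
        independent_test(dev, dev, make_default_model("LDA"),
                         default_registry().subset(["AAC"]))


def test_independent_test_mcc_close_to_cv(small_peptide_sets):
    dev, test = small_peptide_sets
    registry = default_registry().subset(["AAC", "GAAC", "GDPC"])
    from antiangio.encoders import encode_all
    m_dev = encode_all(dev, registry)
    cv = cross_validate(m_dev, dev.labels, make_default_model("SVM"), k=5, seed=1)
    rep, _, _ = independent_test(dev, test, make_default_model("SVM"), registry)
    assert abs(rep.mcc - cv.mcc) <= 0.35  # strongly separated generator


# ---------------------------------------------------------------------------
# post-hoc analyses
# ---------------------------------------------------------------------------

def test_tpr_bins_top_bin_and_count_conservation():
    y = [1, 1, 0, 0, 1]
    p = [1.0, 0.97, 0.2, 0.05, 0.98]
    rep = tpr_by_probability_bins(y, p)
    assert rep["count"].sum() == 5
    assert rep.iloc[-1].tpr == 1.0
    assert rep[rep["count"] == 0].empty is False  # middle bins flagged empty


def test_tpr_bins_calibrated_scores_rank_correlate():
    rng = np.random.default_rng(8)
    p = rng.random(3000)
    y = (rng.random(3000) < p).astype(int)  # perfectly calibrated by design
    rep = tpr_by_probability_bins(y, p)
    assert probability_tpr_correlation(rep) > 0.9


def test_property_ratio_worked_examples():
    ds = LabeledDataset("x", [Peptide("a", "VILMFWC"), Peptide("b", "EDRKH"),
                              Peptide("c", "GGGG")], [1, 1, 0])
    pred = [1, 1, 0]
    hydro = accuracy_by_residue_property(ds, pred, "hydrophobic")
    assert hydro["count"].sum() == 3
    assert hydro.iloc[-1]["count"] == 1  # the all-hydrophobic peptide
    phil = accuracy_by_residue_property(ds, pred, "hydrophilic")
    assert phil.iloc[-1]["count"] == 1   # EDRKH is also fully hydrophilic
    charged = accuracy_by_residue_property(ds, pred, "charged")
    assert charged.iloc[-1]["count"] == 1
    assert charged.iloc[0]["count"] == 2  # VILMFWC and GGGG have ratio 0
    with pytest.raises(ValueError):
        accuracy_by_residue_property(ds, pred, "greasy")


def test_composition_propensity_contrast_and_null():
    ds = LabeledDataset("x", [Peptide("p1", "CCCC"), Peptide("p2", "CCCC"),
                              Peptide("n1", "AAAA"), Peptide("n2", "AAAA")],
                        [1, 1, 0, 0])
    out = composition_propensity(ds)
    aac = out["AAC"]
    assert aac.loc["C", "difference"] == 1.0
    assert aac.loc["A", "difference"] == -1.0
    same = LabeledDataset("y", [Peptide("a", "ACDE"), Peptide("b", "ACDE")], [1, 0])
    out2 = composition_propensity(same)
    assert (out2["AAC"]["difference"] == 0).all()
    assert (out2["DPC"]["difference"] == 0).all()


def test_composition_propensity_requires_both_classes():
    ds = LabeledDataset("z", [Peptide("a", "AC"), Peptide("b", "CD")], [1, 1])
    with pytest.raises(ValueError):
        composition_propensity(ds)
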