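"""Metric identities, brute-force oracles and the gender correlation."""

import numpy as np
import pytest

from trihinge.errors import ConfigError
from trihinge.evaluation import (
    aggregate_subjects,
    centroid_pre,
    confusion_counts,
    gender_correlation,
    region_metrics,
)


def test_perfect_prediction_scores_100():
    truth = np.array([0, 1, 1, 0, 1])
    assert region_metrics(truth, truth) == (100.0, 100.0, 100.0)


def test_direct_formula_evaluation():
    # TP=2, FP=1, FN=1
    pred = np.array([1, 1, 1, 0, 0])
    truth = np.array([1, 1, 0, 1, 0])
    p, r, f1 = region_metrics(pred, truth)
    assert p == pytest.approx(200 / 3, abs=0.01)
    assert r == pytest.approx(200 / 3, abs=0.01)
    assert f1 == pytest.approx(200 / 3, abs=0.01)


def test_empty_prediction_zero_recall_f1():
    pred = np.zeros(6)
    truth = np.array([1, 1, 0, 0, 0, 0])
    p, r, f1 = region_metrics(pred, truth)
    assert (p, r, f1) == (0.0, 0.0, 0.0)


def test_mask_excludes_vertices():
    pred = np.array([1, 1, 1, 1])
    truth = np.array([1, 1, 0, 0])
    mask = np.array([1, 1, 1, 0])
    assert confusion_counts(pred, truth, mask) == (2, 1, 0)


def test_f1_harmonic_mean_bounds(rng):
    for _ in range(50):
        tp, fp, fn = rng.integers(1, 100, size=3)
        p, r, f1 = region_metrics(
            np.repeat([1, 1, 0], [tp, fp, fn]), np.repeat([1, 0, 1], [tp, fp, fn])
        )
        assert min(p, r) - 1e-9 <= f1 <= max(p, r) + 1e-9


# ---------------------------------------------------------------------------
# PreE
# ---------------------------------------------------------------------------

def test_pre_zero_for_identical_sets(rng):
    pts = rng.normal(size=(5, 3))
    assert centroid_pre(pts, pts) == 0.0


def test_pre_345_triangle():
    assert centroid_pre([[3.0, 4.0, 0.0]], [[0.0, 0.0, 0.0]]) == pytest.approx(5.0)


def test_pre_matches_brute_force(rng):
    truth = rng.normal(size=(5, 3)) * 10
    pred = rng.normal(size=(7, 3)) * 10
    oracle = np.mean(
        [min(np.linalg.norm(t - p) for p in pred) for t in truth]
    )
    assert centroid_pre(pred, truth) == pytest.approx(oracle, abs=1e-12)


def test_pre_invariances(rng):
    truth = rng.normal(size=(4, 3))
    pred = rng.normal(size=(6, 3))
    base = centroid_pre(pred, truth)
    assert centroid_pre(pred[::-1], truth[rng.permutation(4)]) == pytest.approx(base)
    t = np.array([5.0, -2.0, 9.0])
    assert centroid_pre(pred + t, truth + t) == pytest.approx(base, abs=1e-9)


def test_pre_empty_sets():
    assert centroid_pre(np.zeros((0, 3)), [[0, 0, 0]]) == float("inf")
    with pytest.raises(ConfigError):
        centroid_pre([[0, 0, 0]], np.zeros((0, 3)))


def test_pre_symmetric_direction(rng):
    truth = rng.normal(size=(3, 3))
    pred = rng.normal(size=(5, 3))
    t2p = centroid_pre(pred, truth)
    sym = centroid_pre(pred, truth, direction="symmetric")
    p2t = np.mean([min(np.linalg.norm(t - p) for t in truth) for p in pred])
    assert sym == pytest.approx(0.5 * (t2p + p2t))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_single_subject_report_equals_record():
    rep = aggregate_subjects(
        [{"subject_id": "s0", "tp": 10, "fp": 5, "fn": 2, "lh_pre": 4.0, "rh_pre": 6.0}]
    )
    assert rep.precision == pytest.approx(100 * 10 / 15)
    assert rep.recall == pytest.approx(100 * 10 / 12)
    assert rep.lh_pre == 4.0 and rep.rh_pre == 6.0 and rep.mean_pre == 5.0


def test_macro_f1_is_mean_of_subject_f1():
    # two subjects with F1 60 and 70
    recs = [
        {"tp": 3, "fp": 2, "fn": 2},   # P=R=F1=60
        {"tp": 7, "fp": 3, "fn": 3},   # P=R=F1=70
    ]
    rep = aggregate_subjects(recs, aggregation="macro")
    assert rep.f1 == pytest.approx(65.0)


def test_micro_equals_pooled_recomputation(rng):
    arrays = []
    recs = []
    for _ in range(3):
        pred = (rng.random(200) > 0.6).astype(int)
        truth = (rng.random(200) > 0.7).astype(int)
        arrays.append((pred, truth))
        tp, fp, fn = confusion_counts(pred, truth)
        recs.append({"tp": tp, "fp": fp, "fn": fn})
    rep = aggregate_subjects(recs, aggregation="micro")
    pooled_pred = np.concatenate([a for a, _ in arrays])
    pooled_truth = np.concatenate([b for _, b in arrays])
    assert region_metrics(pooled_pred, pooled_truth) == (rep.precision, rep.recall, rep.f1)


def test_micro_equals_macro_for_identical_confusions():
    recs = [{"tp": 4, "fp": 2, "fn": 1}] * 4
    micro = aggregate_subjects(recs, "micro")
    macro = aggregate_subjects(recs, "macro")
    assert micro.f1 == pytest.approx(macro.f1)
    assert micro.precision == pytest.approx(macro.precision)


# ---------------------------------------------------------------------------
# gender correlation
# ---------------------------------------------------------------------------

def test_point_biserial_closed_form():
    # accuracy identical within gender groups; r from the closed form
    acc = np.array([60.0, 60.0, 60.0, 70.0, 70.0, 70.0])
    g = np.array([0, 0, 0, 1, 1, 1])
    r, p = gender_correlation(acc, g)
    n0 = n1 = 3
    n = 6
    s_pop = acc.std()  # population sd
    expected = np.sqrt(n0 * n1) / n * (70.0 - 60.0) / s_pop
    assert abs(r) == pytest.approx(expected, abs=1e-12)
    assert r > 0


def test_permutation_null_matches_t_based_p():
    rng = np.random.default_rng(3)
    acc = rng.normal(size=24)
    g = np.array([0, 1] * 12)
    acc[g == 1] += 1.0
    r, p = gender_correlation(acc, g)
    count = 0
    n_perm = 1000
    for _ in range(n_perm):
        rp, _ = gender_correlation(acc, rng.permutation(g))
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    p_emp = count / n_perm
    mc_err = 3 * np.sqrt(max(p * (1 - p), 1e-4) / n_perm)
    assert abs(p_emp - p) < mc_err + 0.01


def test_null_simulation_keeps_r_small():
    rng = np.random.default_rng(11)
    hits = 0
    for _ in range(100):
        acc = rng.normal(size=100)
        g = rng.permutation(np.repeat([0, 1], 50))
        r, _ = gender_correlation(acc, g)
        hits += abs(r) < 0.3
    assert hits >= 95


def test_gender_flip_negates_r():
    rng = np.random.default_rng(2)
    acc = rng.normal(size=20)
    g = np.array([0, 1] * 10)
    r1, p1 = gender_correlation(acc, g)
    r2, p2 = gender_correlation(acc, 1 - g)
    assert r2 == pytest.approx(-r1)
    assert p2 == pytest.approx(p1)


def test_gender_correlation_validation():
    with pytest.raises(ConfigError):
        gender_correlation([1.0, 2.0], [0, 1])
    with pytest.raises(ConfigError):
        gender_correlation([1.0, 2.0, 3.0], [0, 0, 0])
    with pytest.raises(ConfigError):
        gender_correlation([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
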