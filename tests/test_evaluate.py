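"""Metrics, Wilcoxon, splits, Shapley attribution, matching."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edemaeeg import evaluate as ev
from edemaeeg.core import FEATURE_NAMES, PatientRecord


def _rec(pid, label="none", age=50.0, sex="M", witnessed=True, ohca=True,
         t_eeg=18.0, t_edema=None):
    if label == "edema" and t_edema is None:
        t_edema = 30.0
    return PatientRecord(pid, age, sex, witnessed, ohca, label, t_eeg, t_edema)


def _cohort(n_edema, n_none, n_indet=0):
    cohort = [_rec(f"E{i}", "edema") for i in range(n_edema)]
    cohort += [_rec(f"N{i}", "none") for i in range(n_none)]
    cohort += [_rec(f"I{i}", "indeterminate") for i in range(n_indet)]
    return cohort


# --------------------------------------------------------------------------
# AUC / threshold metrics


def brute_force_auc(labels, scores):
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_worked_example():
    labels = [1, 1, 0, 0, 0]
    scores = [0.9, 0.4, 0.7, 0.6, 0.4]
    m = ev.compute_metrics(labels, scores)
    assert m["auc"] == pytest.approx(3.5 / 6)


def test_auc_matches_exhaustive_concordance_up_to_n200(rng):
    """Rank-based AUC equals pairwise counting, with heavy ties, n<=200."""
    from sklearn.metrics import roc_auc_score
    for n in (5, 20, 73, 200):
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 1)  # induce ties
        m = ev.compute_metrics(labels, scores)
        assert m["auc"] == pytest.approx(brute_force_auc(labels, scores),
                                         abs=1e-12)
        assert m["auc"] == pytest.approx(roc_auc_score(labels, scores),
                                         abs=1e-12)


def test_threshold_metrics():
    m = ev.compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
    assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0,
                 "auc": 1.0}
    m = ev.compute_metrics([1, 0, 1, 0], [0.49] * 4)
    assert m["sensitivity"] == 0.0 and m["specificity"] == 1.0
    m = ev.compute_metrics([1, 1], [0.9, 0.2])
    assert math.isnan(m["auc"])  # AUC undefined, threshold metrics intact
    assert m["sensitivity"] == 0.5


def test_threshold_partitions_into_two_classes(rng):
    p = rng.random(50)
    pred = (p >= 0.5).astype(int)
    assert set(pred) <= {0, 1}
    m = ev.compute_metrics(rng.integers(0, 2, 50), p)
    assert 0 <= m["accuracy"] <= 1


# --------------------------------------------------------------------------
# replication summaries


def test_summary_median_iqr():
    res = [ev.ReplicationResult(i, {"auc": v})
           for i, v in enumerate([0.7, 0.8, 0.9])]
    s = ev.summarize_replications(res)
    assert s["auc"]["median"] == pytest.approx(0.8)
    single = ev.summarize_replications([ev.ReplicationResult(1, {"auc": 0.6})])
    assert single["auc"]["median"] == single["auc"]["q1"] == 0.6


def test_summary_matches_sorted_array_oracle(rng):
    vals = rng.random(30)
    res = [ev.ReplicationResult(i, {"m": v}) for i, v in enumerate(vals)]
    s = ev.summarize_replications(res)["m"]
    v = np.sort(vals)

    def pct(q):  # linear-interpolation percentile on the sorted array
        h = (len(v) - 1) * q
        lo = int(math.floor(h))
        return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])

    assert s["median"] == pytest.approx(pct(0.5))
    assert s["q1"] == pytest.approx(pct(0.25))
    assert s["q3"] == pytest.approx(pct(0.75))


# --------------------------------------------------------------------------
# Wilcoxon signed-rank


def enumerate_wilcoxon_p(diffs):
    """Exact two-sided p by enumerating all sign patterns (midranks)."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    if n == 0:
        return 1.0
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, bit in zip(ranks, pattern) if bit)
          for pattern in itertools.product([0, 1], repeat=n)]
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


def test_wilcoxon_all_positive_n5():
    assert ev.wilcoxon_signed_rank([1, 2, 3, 4, 5]) == pytest.approx(2 / 32)


def test_wilcoxon_identical_series_and_antisymmetry(rng):
    a = rng.random(12)
    assert ev.compare_models(a, a) == 1.0
    b = rng.random(12)
    assert ev.compare_models(a, b) == pytest.approx(ev.compare_models(b, a))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.integers(-5, 5), min_size=1, max_size=10))
def test_wilcoxon_matches_exact_enumeration(diffs):
    got = ev.wilcoxon_signed_rank(diffs)
    want = enumerate_wilcoxon_p(diffs)
    assert got == pytest.approx(want, abs=1e-12)


def test_wilcoxon_matches_scipy_in_both_regimes(rng):
    from scipy.stats import wilcoxon as scipy_wilcoxon
    # exact regime, tie-free
    d = rng.standard_normal(12)
    assert ev.wilcoxon_signed_rank(d) == pytest.approx(
        scipy_wilcoxon(d, mode="exact").pvalue, abs=1e-12)
    # large-sample regime (normal approximation with tie correction)
    d = np.round(rng.standard_normal(60), 1)
    d = d[d != 0]
    assert ev.wilcoxon_signed_rank(d) == pytest.approx(
        scipy_wilcoxon(d, mode="approx", correction=False).pvalue, rel=1e-6)


# --------------------------------------------------------------------------
# split plans


def test_detection_splits_are_balanced_and_disjoint():
    cohort = _cohort(65, 59)
    plans = ev.make_detection_splits(cohort, 0.16, 30, seed=3)
    assert len(plans) == 30
    labels = {p.id: p.edema_label for p in cohort}
    for plan in plans:
        assert len(plan.test_ids) == 20
        assert len(plan.train_ids) == 104
        assert not set(plan.train_ids) & set(plan.test_ids)
        test_labels = [labels[i] for i in plan.test_ids]
        assert test_labels.count("edema") == 10
        assert test_labels.count("none") == 10
    # replications differ
    assert len({p.test_ids for p in plans}) > 1


def test_detection_splits_input_validation():
    cohort = _cohort(65, 59)
    with pytest.raises(ValueError):
        ev.make_detection_splits(cohort, 0.0)
    with pytest.raises(ValueError):
        ev.make_detection_splits(_cohort(3, 50), 0.16)  # class too small
    with pytest.raises(ValueError):
        ev.make_detection_splits(_cohort(5, 5, n_indet=2), 0.16)


def test_prediction_splits_keep_pairs_together():
    pairs = [ev.MatchedPair(f"E{i}", f"N{i}", 0.1) for i in range(19)]
    plans = ev.make_prediction_splits(pairs, 0.58, 30, seed=5)
    for plan in plans:
        assert len(plan.train_ids) == 22  # 11 pairs
        assert len(plan.test_ids) == 16   # 8 pairs
        for pair in pairs:
            in_train = pair.case_id in plan.train_ids
            assert (pair.referent_id in plan.train_ids) == in_train
    same = ev.make_prediction_splits(pairs, 0.58, 30, seed=5)
    assert [p.test_ids for p in same] == [p.test_ids for p in plans]
    with pytest.raises(ValueError):
        ev.make_prediction_splits(pairs[:1])


# --------------------------------------------------------------------------
# Shapley attribution


def _linear_predict(w, bias=0.0):
    w = np.asarray(w, dtype=float)

    def fn(x_flat):  # x_flat: (n, epochs, derivations*9)
        x = x_flat.reshape(x_flat.shape[0], x_flat.shape[1], -1, 9)
        return x.mean(axis=(1, 2)) @ w + bias

    return fn


def test_linear_model_efficiency_zero_weight_and_ranking(rng):
    w = np.zeros(9)
    w[2] = 3.0   # dominant: DeltaPower
    w[0] = -0.5  # minor: entropy
    # w[4] stays exactly zero: AlphaPower must attribute ~0
    fn = _linear_predict(w)
    samples = rng.standard_normal((6, 4, 3, 9))
    background = rng.standard_normal((4, 3, 9))
    signed = ev.attribute_features(fn, samples, background,
                                   n_coalition_samples=40, seed=1,
                                   aggregate=False)
    # efficiency: per-sample attributions sum to f(x) - f(background)
    fx = fn(samples.reshape(6, 4, -1))
    fb = fn(np.broadcast_to(background, samples.shape).reshape(6, 4, -1))
    assert np.allclose(signed.sum(axis=1), fx - fb, atol=1e-9)
    agg = ev.attribute_features(fn, samples, background,
                                n_coalition_samples=40, seed=1)
    assert agg[4] < 0.01                 # ignored feature
    assert np.argmax(agg) == 2           # dominant feature ranks first
    with pytest.raises(ValueError):
        ev.attribute_features(fn, samples, background, n_coalition_samples=5)


# --------------------------------------------------------------------------
# subgroup / relabeling


def test_subgroup_evaluation_matches_manual_filter(rng):
    records = [_rec(f"P{i}", ohca=bool(i % 2)) for i in range(20)]
    labels = rng.integers(0, 2, 20)
    probs = rng.random(20)
    full = ev.subgroup_evaluate(labels, probs, records, lambda r: True)
    assert full == ev.compute_metrics(labels, probs)
    ohca = ev.subgroup_evaluate(labels, probs, records, lambda r: r.ohca)
    keep = [i for i, r in enumerate(records) if r.ohca]
    assert ohca == ev.compute_metrics(labels[keep], probs[keep])
    assert ev.subgroup_evaluate(labels, probs, records, lambda r: False) is None


def test_relabel_indeterminate_policies():
    cohort = _cohort(65, 59, n_indet=25)
    assert len(cohort) == 149
    primary = ev.relabel_indeterminate(cohort, "exclude")
    assert len(primary) == 124
    secondary = ev.relabel_indeterminate(cohort, "as_none")
    assert len(secondary) == 149
    assert sum(r.edema_label == "none" for r in secondary) == 59 + 25
    clean = ev.relabel_indeterminate(_cohort(2, 2), "exclude")
    assert len(clean) == 4
    with pytest.raises(ValueError):
        ev.relabel_indeterminate(cohort, "bogus")


# --------------------------------------------------------------------------
# matching


def test_matching_prefers_dominating_referent():
    case = _rec("C1", "edema", age=50, sex="M", witnessed=True, t_eeg=18)
    good = _rec("R1", "none", age=51, sex="M", witnessed=True, t_eeg=19)
    bad = _rec("R2", "none", age=70, sex="F", witnessed=False, t_eeg=30)
    pairs = ev.match_referents([case], [good, bad])
    assert pairs[0].referent_id == "R1"
    dup = _rec("R3", "none", age=50, sex="M", witnessed=True, t_eeg=18)
    pairs = ev.match_referents([case], [dup, bad])
    assert pairs[0].distance == pytest.approx(0.0)


def test_matching_uses_each_referent_once(rng):
    cases = [_rec(f"C{i}", "edema", age=float(rng.uniform(30, 70)),
                  sex="M" if rng.random() < 0.6 else "F",
                  witnessed=bool(rng.random() < 0.5),
                  t_eeg=float(rng.uniform(10, 30))) for i in range(19)]
    pool = [_rec(f"R{i}", "none", age=float(rng.uniform(30, 70)),
                 sex="M" if rng.random() < 0.6 else "F",
                 witnessed=bool(rng.random() < 0.5),
                 t_eeg=float(rng.uniform(10, 30))) for i in range(59)]
    pairs = ev.match_referents(cases, pool, seed=11)
    assert len(pairs) == 19
    referents = [p.referent_id for p in pairs]
    assert len(set(referents)) == 19
    assert all(p.distance >= 0 for p in pairs)


def test_matching_pool_validation():
    cases = [_rec(f"C{i}", "edema") for i in range(3)]
    pool = [_rec("R0", "none")]
    with pytest.raises(ValueError):
        ev.match_referents(cases, pool)
    with pytest.raises(ValueError):
        ev.match_referents(cases, [_rec("X", "edema")] * 5)
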