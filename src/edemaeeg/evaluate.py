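"""Replicated balanced evaluation, model comparison, Shapley attribution,
subgroup/secondary analyses, and nearest-neighbor case-referent matching.

The evaluation harness mirrors a repeated train/test protocol: 30
class-balanced splits for detection (~16% of patients held out, equal class
counts in every test set), 58/42 pair-level splits for prediction, threshold
metrics at 0.5, Wilcoxon signed-rank comparison across paired replications,
and permutation-sampling Shapley attribution grouped to the nine named
features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import FEATURE_NAMES, PatientRecord

__all__ = [
    "SplitPlan",
    "ReplicationResult",
    "MatchedPair",
    "make_detection_splits",
    "compute_metrics",
    "summarize_replications",
    "wilcoxon_signed_rank",
    "compare_models",
    "attribute_features",
    "subgroup_evaluate",
    "relabel_indeterminate",
    "match_referents",
    "make_prediction_splits",
]


@dataclass
class SplitPlan:
    """One replication's train/test membership (patient ids)."""

    replication_index: int
    train_ids: Tuple[str, ...]
    test_ids: Tuple[str, ...]
    task: str = "detection"

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class ReplicationResult:
    """Test metrics (and optional attributions) of one trained split."""

    replication_index: int
    metrics: Dict[str, float]
    attributions: Optional[np.ndarray] = None  # (9,) mean |phi|
    config_echo: Dict[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class MatchedPair:
    """A case and its matched no-edema referent."""

    case_id: str
    referent_id: str
    distance: float


# --------------------------------------------------------------------------
# splits


def make_detection_splits(cohort: Sequence[PatientRecord],
                          test_fraction: float = 0.16, n_reps: int = 30,
                          seed: int = 0) -> List[SplitPlan]:
    """Class-balanced held-out test sets, redrawn per replication.

    The cohort must already be restricted to edema / no-edema labels.  Per
    replication ``round(test_fraction * N) / 2`` patients per class go to
    test; everyone else trains.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = {p.edema_label for p in cohort}
    if not labels <= {"edema", "none"}:
        raise ValueError("cohort must be restricted to edema/none labels")
    edema = sorted(p.id for p in cohort if p.edema_label == "edema")
    none = sorted(p.id for p in cohort if p.edema_label == "none")
    n_test = int(round(test_fraction * len(cohort)))
    per_class = max(n_test // 2, 1)
    if per_class > min(len(edema), len(none)):
        raise ValueError("a class is too small for a balanced test set")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(1, n_reps + 1):
        test = (list(rng.choice(edema, per_class, replace=False))
                + list(rng.choice(none, per_class, replace=False)))
        train = [p.id for p in cohort if p.id not in set(test)]
        plans.append(SplitPlan(rep, tuple(train), tuple(test), "detection"))
    return plans


def make_prediction_splits(pairs: Sequence[MatchedPair],
                           train_fraction: float = 0.58, n_reps: int = 30,
                           seed: int = 0) -> List[SplitPlan]:
    """Pair-level splits: a case and its referent always travel together."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched pairs")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * len(pairs)))
    n_train = min(max(n_train, 1), len(pairs) - 1)
    rng = np.random.default_rng(seed)
    plans = []
    idx = np.arange(len(pairs))
    for rep in range(1, n_reps + 1):
        chosen = set(rng.choice(idx, n_train, replace=False))
        train, test = [], []
        for i, pair in enumerate(pairs):
            (train if i in chosen else test).extend(
                [pair.case_id, pair.referent_id])
        plans.append(SplitPlan(rep, tuple(train), tuple(test), "prediction"))
    return plans


# --------------------------------------------------------------------------
# metrics


def _auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """Concordance probability; ties count one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined for single-class labels")
    # rank-based (equivalent to pairwise counting with tie = 1/2)
    from scipy.stats import rankdata
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0) \
        / (len(pos) * len(neg))
    return float(auc)


def compute_metrics(labels: Sequence[int], probabilities: Sequence[float],
                    threshold: float = 0.5) -> Dict[str, float]:
    """AUC (Mann-Whitney), accuracy, sensitivity, specificity at threshold.

    With single-class labels the threshold metrics are still returned and
    AUC is NaN (flagged, not raised, so subgroup analyses degrade gracefully).
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities differ in length")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    metrics = {
        "accuracy": (tp + tn) / len(y) if len(y) else math.nan,
        "sensitivity": tp / (tp + fn) if (tp + fn) else math.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else math.nan,
    }
    try:
        metrics["auc"] = _auc_mann_whitney(y, p)
    except ValueError:
        metrics["auc"] = math.nan
    return metrics


def summarize_replications(results: Sequence[ReplicationResult]
                           ) -> Dict[str, Dict[str, float]]:
    """Median and IQR (linear-interpolation percentiles) per metric."""
    if not results:
        raise ValueError("no replications to summarize")
    out: Dict[str, Dict[str, float]] = {}
    for key in results[0].metrics:
        vals = np.array([r.metrics[key] for r in results], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            out[key] = {"median": math.nan, "q1": math.nan, "q3": math.nan}
            continue
        out[key] = {
            "median": float(np.percentile(vals, 50)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        }
    return out


# --------------------------------------------------------------------------
# Wilcoxon signed-rank


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for W+ given doubled midranks (integers)."""
    ranks2 = ranks2.astype(int)
    total = int(ranks2.sum())
    # distribution of W+ (doubled scale) over all 2^n sign patterns, by DP
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2i = int(round(w2))
    p_le = dist[: w2i + 1].sum()
    p_ge = dist[w2i:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(diffs: Sequence[float],
                         exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences.

    Zero differences are dropped.  The null distribution is exact
    (dynamic-programming enumeration over sign patterns, midranks for tied
    magnitudes) for up to ``exact_max_n`` nonzero differences, and a
    tie-corrected normal approximation beyond that.  All differences zero
    gives p = 1.
    """
    from scipy.stats import rankdata
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return _exact_signed_rank_p(np.round(2 * ranks), 2 * w_pos)
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction
    _, counts = np.unique(ranks, return_counts=True)
    sigma2 -= (counts ** 3 - counts).sum() / 48.0
    if sigma2 <= 0:
        return 1.0
    z = (w_pos - mu) / math.sqrt(sigma2)
    from scipy.stats import norm
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def compare_models(metrics_a: Sequence[float], metrics_b: Sequence[float]
                   ) -> float:
    """Paired two-sided Wilcoxon signed-rank p across replications."""
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("metric series must be paired (equal length)")
    return wilcoxon_signed_rank(a - b)


# --------------------------------------------------------------------------
# Shapley attribution


def attribute_features(predict_fn: Callable[[np.ndarray], np.ndarray],
                       samples: np.ndarray, background: np.ndarray,
                       n_coalition_samples: int = 32,
                       seed: int = 0,
                       n_groups: int = len(FEATURE_NAMES),
                       aggregate: bool = True) -> np.ndarray:
    """Permutation-sampling Shapley values grouped to the named features.

    ``samples`` is (n, epochs, derivations, 9); the last axis indexes the
    feature groups.  ``background`` (epochs, derivations, 9) is the
    reference input (training-set feature means).  For each sample and each
    sampled permutation the marginal contribution of switching a feature
    group from background to sample values is accumulated; contributions
    telescope, so per-permutation attributions satisfy the efficiency
    property exactly.  Returns mean |phi| per feature over samples, or the
    signed per-sample (n, n_groups) attribution matrix when ``aggregate``
    is False.
    """
    if n_coalition_samples < 10:
        raise ValueError("n_coalition_samples must be >= 10")
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 3:
        samples = samples[None]
    n = samples.shape[0]
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, n_groups))
    for _ in range(n_coalition_samples):
        perm = rng.permutation(n_groups)
        # evaluate the chain background -> sample along the permutation,
        # batched over samples
        cur = np.broadcast_to(background, samples.shape).copy()
        prev = predict_fn(cur.reshape(n, samples.shape[1], -1))
        for g in perm:
            cur[..., g] = samples[..., g]
            nxt = predict_fn(cur.reshape(n, samples.shape[1], -1))
            phi[:, g] += nxt - prev
            prev = nxt
    phi /= n_coalition_samples
    if not aggregate:
        return phi
    return np.abs(phi).mean(axis=0)


# --------------------------------------------------------------------------
# subgroup / secondary analyses


def subgroup_evaluate(labels: Sequence[int], probabilities: Sequence[float],
                      records: Sequence[PatientRecord],
                      predicate: Callable[[PatientRecord], bool],
                      threshold: float = 0.5) -> Optional[Dict[str, float]]:
    """Threshold metrics restricted to test patients matching a predicate.

    Returns None for an empty subgroup; AUC is NaN when the subgroup is
    single-class.
    """
    keep = [i for i, r in enumerate(records) if predicate(r)]
    if not keep:
        return None
    y = np.asarray(labels)[keep]
    p = np.asarray(probabilities)[keep]
    return compute_metrics(y, p, threshold)


def relabel_indeterminate(cohort: Sequence[PatientRecord],
                          policy: str = "exclude") -> List[PatientRecord]:
    """Primary analysis drops indeterminate patients; secondary relabels
    them as no-edema."""
    if policy == "exclude":
        return [p for p in cohort if p.edema_label != "indeterminate"]
    if policy == "as_none":
        out = []
        for p in cohort:
            if p.edema_label == "indeterminate":
                out.append(PatientRecord(p.id, p.age, p.sex, p.witnessed,
                                         p.ohca, "none", p.t_eeg_start, None))
            else:
                out.append(p)
        return out
    raise ValueError(f"unknown policy {policy!r}")


# --------------------------------------------------------------------------
# case-referent matching


def _covariate_matrix(records: Sequence[PatientRecord],
                      covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov == "age":
            cols.append([r.age for r in records])
        elif cov == "sex":
            cols.append([1.0 if r.sex == "M" else 0.0 for r in records])
        elif cov == "witnessed":
            cols.append([1.0 if r.witnessed else 0.0 for r in records])
        elif cov == "t_eeg_start":
            cols.append([r.t_eeg_start for r in records])
        else:
            raise ValueError(f"unknown matching covariate {cov!r}")
    return np.asarray(cols, dtype=float).T


_BINARY_COVARIATES = {"sex", "witnessed"}


def match_referents(cases: Sequence[PatientRecord],
                    pool: Sequence[PatientRecord],
                    covariates: Sequence[str] = ("age", "sex", "witnessed",
                                                 "t_eeg_start"),
                    binary_penalty: float = 2.0,
                    seed: int = 0) -> List[MatchedPair]:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Continuous covariates are z-scored over cases + pool and compared by
    Euclidean distance; each mismatched binary covariate adds a fixed
    penalty (in standardized units, added to the squared distance before
    the square root).  Cases are processed in seeded random order.
    """
    if len(pool) < len(cases):
        raise ValueError("referent pool smaller than the case list")
    if any(r.edema_label != "none" for r in pool):
        raise ValueError("referent pool must contain only no-edema patients")
    everyone = list(cases) + list(pool)
    X = _covariate_matrix(everyone, covariates)
    is_binary = np.array([c in _BINARY_COVARIATES for c in covariates])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    Zc, Zp = Z[: len(cases)], Z[len(cases):]
    Xc, Xp = X[: len(cases)], X[len(cases):]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    used = np.zeros(len(pool), dtype=bool)
    pairs: List[MatchedPair] = []
    for ci in order:
        dz = Zc[ci] - Zp  # (pool, k)
        sq = np.where(is_binary, (Xc[ci] != Xp) * binary_penalty, dz ** 2)
        dist = np.sqrt(sq.sum(axis=1))
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if not np.isfinite(dist[j]):
            raise ValueError("referent pool exhausted")
        used[j] = True
        pairs.append(MatchedPair(cases[ci].id, pool[j].id, float(dist[j])))
    pairs.sort(key=lambda p: p.case_id)
    return pairs
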