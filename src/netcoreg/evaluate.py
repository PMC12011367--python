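"""Scoring of predicted regulatory and coordination networks against truth sets.

The confusion universe is the set of candidate TF x TG pairs actually offered
to the fitter, not all genes squared. In signed mode a predicted link counts
as a true positive only when both the pair and the sign match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score


@dataclass
class MetricSet:
    """Confusion counts and derived classification metrics over a declared universe."""

    tp: int
    fp: int
    tn: int
    fn: int
    aupr: float
    jaccard: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    sensitivity = recall

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.recall + self.specificity)

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "aupr": self.aupr,
            "jaccard": self.jaccard,
        }


def _pair(link) -> tuple:
    return tuple(link[:2])


def score_grn(
    predicted: set[tuple],
    truth: set[tuple],
    universe: set[tuple],
    signed: bool = False,
    scores: dict[tuple, float] | None = None,
) -> MetricSet:
    """Score predicted (TF, TG[, sign]) links against a truth set.

    ``universe`` holds unsigned (TF, TG) pairs. In signed mode both
    ``predicted`` and ``truth`` carry a third element in {-1, +1} and a
    correct pair with the wrong sign counts as a false positive (and the
    truth link stays a false negative). AUPR ranks predictions by
    ``scores`` (e.g. |c*|; unpredicted universe pairs score 0) against
    unsigned pair membership in truth.
    """
    if not universe:
        raise ValueError("empty universe")
    pred_pairs = {_pair(p) for p in predicted}
    truth_pairs = {_pair(t) for t in truth}
    if not pred_pairs <= universe:
        raise ValueError("predicted links fall outside the declared universe")
    if not truth_pairs <= universe:
        raise ValueError("truth links fall outside the declared universe")

    if signed:
        for name, ls in (("predicted", predicted), ("truth", truth)):
            if any(len(l) < 3 for l in ls):
                raise ValueError(f"signed mode requires (TF, TG, sign) tuples in {name}")
        tp = len(set(predicted) & set(truth))
    else:
        tp = len(pred_pairs & truth_pairs)
    fp = len(pred_pairs) - tp
    fn = len(truth_pairs) - tp
    tn = len(universe) - tp - fp - fn

    inter = len(set(predicted) & set(truth)) if signed else len(pred_pairs & truth_pairs)
    union = len(set(predicted) | set(truth)) if signed else len(pred_pairs | truth_pairs)
    jaccard = inter / union if union else 1.0

    ordered = sorted(universe)
    y_true = np.array([p in truth_pairs for p in ordered], dtype=int)
    if scores is None:
        scores = {p: 1.0 for p in pred_pairs}
    y_score = np.array([scores.get(p, 0.0) for p in ordered], dtype=float)
    aupr = float(average_precision_score(y_true, y_score)) if y_true.any() else 0.0

    return MetricSet(tp=tp, fp=fp, tn=tn, fn=fn, aupr=aupr, jaccard=jaccard)


def signed_average_aupr(
    predicted: set[tuple],
    truth: set[tuple],
    universe: set[tuple],
    scores: dict[tuple, float],
) -> float:
    """Mean of per-sign-class AUPRs (activator and repressor links as
    separate positive classes, each ranked by score)."""
    ordered = sorted(universe)
    pred_sign = {_pair(p): p[2] for p in predicted}
    auprs = []
    for sign in (+1, -1):
        y_true = np.array([( *p, sign) in truth for p in ordered], dtype=int)
        if not y_true.any():
            continue
        y_score = np.array(
            [scores.get(p, 0.0) if pred_sign.get(p) == sign else 0.0 for p in ordered]
        )
        auprs.append(average_precision_score(y_true, y_score))
    return float(np.mean(auprs)) if auprs else 0.0


def topk_ppi_validation(
    bbar: pd.DataFrame,
    eval_ppin: set[frozenset],
    k: int,
) -> float:
    """Percentage of the top-k |b_bar| TF-TF pairs present in an evaluation PPIN.

    Pairs are ranked by |b_bar| descending with lexicographic tie-breaking.
    If fewer than k pairs are available, all are used with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = bbar.copy()
    if len(df) < k:
        warnings.warn(
            f"k={k} exceeds available pairs ({len(df)}); using all pairs",
            UserWarning,
            stacklevel=2,
        )
        k = len(df)
    df["_abs"] = df["b_bar"].abs()
    df = df.sort_values(["_abs", "TF_i", "TF_j"], ascending=[False, True, True])
    top = df.head(k)
    hits = sum(frozenset((r.TF_i, r.TF_j)) in eval_ppin for r in top.itertuples(index=False))
    return 100.0 * hits / k


def grouped_fn_fp_analysis(
    bbar: pd.DataFrame,
    ppin_old: set[frozenset],
    ppin_new: set[frozenset],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare |b_bar| across pair groups defined by old/new PPIN membership.

    Groups: absent in both, present in both (TP), removed in the update (FP),
    discovered in the update (FN). Welch one-sided t-tests ask whether each
    annotated group has higher |b_bar| than the absent group (and TP > FP),
    with Benjamini-Hochberg adjustment. Empty groups skip their comparisons.
    """

    def group_of(pair: frozenset) -> str:
        in_old, in_new = pair in ppin_old, pair in ppin_new
        if in_old and in_new:
            return "present_both"
        if in_old:
            return "removed"
        if in_new:
            return "discovered"
        return "absent_both"

    df = bbar.copy()
    df["group"] = [
        group_of(frozenset((r.TF_i, r.TF_j))) for r in df.itertuples(index=False)
    ]
    df["_abs"] = df["b_bar"].abs()
    summary = (
        df.groupby("group")["_abs"]
        .agg(n="count", mean_abs_bbar="mean", median_abs_bbar="median")
        .reset_index()
    )

    comparisons = [
        ("present_both", "absent_both"),
        ("discovered", "absent_both"),
        ("removed", "absent_both"),
        ("present_both", "removed"),
    ]
    rows = []
    groups = {g: sub["_abs"].to_numpy() for g, sub in df.groupby("group")}
    for hi, lo in comparisons:
        a, b = groups.get(hi), groups.get(lo)
        if a is None or b is None or len(a) < 2 or len(b) < 2:
            rows.append((hi, lo, np.nan, np.nan, "skipped: empty or singleton group"))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        rows.append((hi, lo, float(t), float(p), ""))
    tests = pd.DataFrame(rows, columns=["group_hi", "group_lo", "t_stat", "p_value", "note"])
    valid = tests["p_value"].notna()
    padj = np.full(len(tests), np.nan)
    if valid.any():
        padj[valid.to_numpy()] = stats.false_discovery_control(
            tests.loc[valid, "p_value"].to_numpy(), method="bh"
        )
    tests["p_adj"] = padj
    return summary, tests
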