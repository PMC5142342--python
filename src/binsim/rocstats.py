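"""ROC/AUC scoring of how well each equation separates match from mismatch
pairs.

A pair of formulas is a *match* when their efficacy-class sets agree (by
default: share at least one class) and a *mismatch* otherwise.  Per
equation, the per-pair coefficients are min-max normalized over the full
pair population; dissimilarities are converted to similarities by
S = 1 - D^2.  An ROC curve sweeps the 100 lower-interval-limit thresholds of
[0, 1] with the rule "similarity >= threshold -> predicted match".  The
class imbalance (mismatch pairs vastly outnumber match pairs) is countered
by scoring each equation on bootstrap mismatch samples of exactly the match
class size, 20 replicates by default.

Summary statistics per equation: mean/sd AUC over replicates (trapezoid on
the threshold grid), the minimum Euclidean distance from the full-population
curve to the optimum point (0, 1), the recognition rate (balanced accuracy)
at that operating threshold, and Cohen's kappa at each replicate's own
minimum-distance threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import BinaryDataset, enumerate_pairs
from .measures import REGISTRY, evaluate_all_pairs

__all__ = [
    "PairLabeling",
    "ROCCurve",
    "label_pairs",
    "label_pairs_for_class",
    "normalize_minmax",
    "dissim_to_sim",
    "bootstrap_mismatch",
    "roc_curve",
    "auc",
    "min_distance",
    "recognition_rate",
    "cohen_kappa",
    "equation_similarity_scores",
    "rank_equations",
    "write_roc_points",
]


@dataclass
class PairLabeling:
    """Index sets (into the upper-triangle pair order) of the two classes."""

    match: np.ndarray
    mismatch: np.ndarray

    def __post_init__(self):
        if np.intersect1d(self.match, self.mismatch).size:
            raise ValueError("match and mismatch sets overlap")


def _label_matrix(dataset: BinaryDataset):
    """(N, C) one-hot label indicator and the ordered class list."""
    sets = dataset.label_sets()
    classes = sorted(set().union(*sets))
    idx = {code: k for k, code in enumerate(classes)}
    indicator = np.zeros((len(sets), len(classes)), dtype=np.int64)
    for row, codes in enumerate(sets):
        for code in codes:
            indicator[row, idx[code]] = 1
    return indicator, classes


def label_pairs(dataset: BinaryDataset, rule: str = "share") -> PairLabeling:
    """Split all pairs into match vs mismatch by their efficacy labels.

    ``rule="share"``: match iff the two label sets intersect (the sensible
    reading of "same efficacy" for multi-label formulas).
    ``rule="exact"``: match iff the label sets are identical.
    """
    ii, jj = enumerate_pairs(dataset)
    if rule == "share":
        indicator, _ = _label_matrix(dataset)
        shared = (indicator @ indicator.T)[ii, jj] > 0
    elif rule == "exact":
        sets = dataset.label_sets()
        codes, inverse = np.unique(
            np.array([",".join(sorted(s)) for s in sets]), return_inverse=True
        )
        shared = inverse[ii] == inverse[jj]
    else:
        raise ValueError(f"unknown match rule {rule!r}")
    return PairLabeling(np.flatnonzero(shared), np.flatnonzero(~shared))


def label_pairs_for_class(dataset: BinaryDataset,
                          class_code: str) -> PairLabeling:
    """Per-class labeling: match = both formulas carry the class; mismatch =
    exactly one does.  Pairs where neither formula carries the class are
    excluded from the analysis."""
    indicator, classes = _label_matrix(dataset)
    if class_code not in classes:
        raise KeyError(f"unknown efficacy class {class_code!r}")
    has = indicator[:, classes.index(class_code)].astype(bool)
    ii, jj = enumerate_pairs(dataset)
    both = has[ii] & has[jj]
    one = has[ii] ^ has[jj]
    return PairLabeling(np.flatnonzero(both), np.flatnonzero(one))


def normalize_minmax(scores: np.ndarray) -> np.ndarray:
    """Map finite scores linearly onto [0, 1]."""
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise ValueError("constant scores cannot be min-max normalized")
    return (scores - lo) / (hi - lo)


def dissim_to_sim(d_normalized: np.ndarray) -> np.ndarray:
    """Convert a normalized dissimilarity to a similarity via S = 1 - D^2."""
    d = np.asarray(d_normalized, dtype=np.float64)
    if (d < 0).any() or (d > 1).any():
        raise ValueError("normalized dissimilarity must lie in [0, 1]")
    return 1.0 - d ** 2


def bootstrap_mismatch(mismatch: np.ndarray, size: int, replicates: int = 20,
                       seed=None) -> list[np.ndarray]:
    """Draw ``replicates`` with-replacement samples of ``size`` mismatch
    indices, to balance the match/mismatch class sizes."""
    mismatch = np.asarray(mismatch)
    if mismatch.size == 0:
        raise ValueError("mismatch set is empty")
    if size < 1:
        raise ValueError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    return [rng.choice(mismatch, size=size, replace=True)
            for _ in range(replicates)]


@dataclass
class ROCCurve:
    """Threshold sweep rows plus the (0,0) and (1,1) closure points.

    ``rows`` columns: threshold, TP, FP, TN, FN, FPR, TPR, ordered by
    decreasing threshold (hence nondecreasing FPR/TPR).
    """

    rows: np.ndarray

    @property
    def fpr(self) -> np.ndarray:
        return self.rows[:, 5]

    @property
    def tpr(self) -> np.ndarray:
        return self.rows[:, 6]

    def points(self) -> np.ndarray:
        """(FPR, TPR) including the closure points, sorted by FPR then TPR."""
        pts = np.vstack([[0.0, 0.0], self.rows[:, 5:7], [1.0, 1.0]])
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        return pts[order]


def roc_curve(match_scores: np.ndarray, mismatch_scores: np.ndarray,
              n_thresholds: int = 100) -> ROCCurve:
    """Sweep the lower limits of ``n_thresholds`` equal intervals of [0, 1].

    A pair is predicted a match when its similarity is >= the threshold; TP
    and FN come from the match distribution, FP and TN from the mismatch
    distribution.
    """
    match_scores = np.asarray(match_scores, dtype=np.float64)
    mismatch_scores = np.asarray(mismatch_scores, dtype=np.float64)
    if match_scores.size == 0 or mismatch_scores.size == 0:
        raise ValueError("both score sets must be nonempty")
    for name, s in (("match", match_scores), ("mismatch", mismatch_scores)):
        if (s < 0).any() or (s > 1).any():
            raise ValueError(f"{name} scores must lie in [0, 1]")
    thresholds = np.arange(n_thresholds) / n_thresholds
    n_match, n_mismatch = match_scores.size, mismatch_scores.size
    # counts of scores >= t via sorted search
    match_sorted = np.sort(match_scores)
    mismatch_sorted = np.sort(mismatch_scores)
    tp = n_match - np.searchsorted(match_sorted, thresholds, side="left")
    fp = n_mismatch - np.searchsorted(mismatch_sorted, thresholds, side="left")
    fn = n_match - tp
    tn = n_mismatch - fp
    rows = np.column_stack([
        thresholds, tp, fp, tn, fn,
        fp / n_mismatch, tp / n_match,
    ])[::-1]  # decreasing threshold -> nondecreasing rates
    return ROCCurve(rows)


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area under the (FPR, TPR) curve."""
    pts = curve.points()
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def min_distance(curve: ROCCurve) -> float:
    """Minimum Euclidean distance from the threshold points to (0, 1)."""
    return float(np.sqrt(curve.fpr ** 2 + (1.0 - curve.tpr) ** 2).min())


def min_distance_threshold(curve: ROCCurve) -> tuple[float, np.ndarray]:
    """(threshold, confusion row) achieving the minimum distance to (0, 1)."""
    dist = np.sqrt(curve.fpr ** 2 + (1.0 - curve.tpr) ** 2)
    k = int(np.argmin(dist))
    return float(curve.rows[k, 0]), curve.rows[k, 1:5]


def recognition_rate(tp: float, fn: float, tn: float, fp: float) -> float:
    """Balanced accuracy: (TP/(TP+FN) + TN/(TN+FP)) / 2."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be nonempty")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def cohen_kappa(tp: float, fp: float, fn: float, tn: float) -> float:
    """Observed-vs-chance agreement of the binary confusion table."""
    total = tp + fp + fn + tn
    if total <= 0:
        raise ValueError("empty confusion table")
    p_o = (tp + tn) / total
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / total ** 2
    if p_e == 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1")
    return (p_o - p_e) / (1.0 - p_e)


def equation_similarity_scores(dataset: BinaryDataset,
                               eq_ids: list[int]) -> np.ndarray:
    """Per-pair similarity scores in [0, 1] for each equation.

    Coefficients are min-max normalized over the full pair population;
    dissimilarity equations are then converted by S = 1 - D^2.
    """
    coeffs = evaluate_all_pairs(dataset, eq_ids)
    if not coeffs.finite.all():
        bad = [eq for eq, ok in zip(eq_ids, coeffs.finite.all(axis=0)) if not ok]
        raise ValueError(f"non-finite coefficients for eq_ids {bad}; "
                         "run the reduction pipeline first")
    scores = np.empty_like(coeffs.values)
    for k, eq_id in enumerate(eq_ids):
        s = normalize_minmax(coeffs.values[:, k])
        if REGISTRY[eq_id].polarity == "D":
            s = dissim_to_sim(s)
        scores[:, k] = s
    return scores


def rank_equations(dataset: BinaryDataset, eq_ids: list[int],
                   replicates: int = 20, seed=0, match_rule: str = "share",
                   labeling: PairLabeling | None = None,
                   n_thresholds: int = 100) -> pd.DataFrame:
    """Score and rank equations by their match/mismatch separation.

    Returns a DataFrame (one row per equation, sorted by mean AUC
    descending) with columns: eq_id, name, polarity, uses_d, mean_auc,
    sd_auc, min_distance, recognition_rate, mean_kappa, sd_kappa and the
    rank columns auc_rank, min_distance_rank, kappa_rank.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if labeling is None:
        labeling = label_pairs(dataset, rule=match_rule)
    if labeling.match.size == 0:
        raise ValueError("no match pairs under the given labeling")
    if labeling.mismatch.size == 0:
        raise ValueError("no mismatch pairs under the given labeling")
    scores = equation_similarity_scores(dataset, eq_ids)
    samples = bootstrap_mismatch(labeling.mismatch, labeling.match.size,
                                 replicates, seed)
    records = []
    for k, eq_id in enumerate(eq_ids):
        s = scores[:, k]
        match_s = s[labeling.match]
        full_curve = roc_curve(match_s, s[labeling.mismatch], n_thresholds)
        _, (tp, fp, tn, fn) = min_distance_threshold(full_curve)
        aucs, kappas = [], []
        for sample in samples:
            curve = roc_curve(match_s, s[sample], n_thresholds)
            aucs.append(auc(curve))
            _, (rtp, rfp, rtn, rfn) = min_distance_threshold(curve)
            kappas.append(cohen_kappa(rtp, rfp, rfn, rtn))
        spec = REGISTRY[eq_id]
        records.append({
            "eq_id": eq_id,
            "name": spec.name,
            "polarity": spec.polarity,
            "uses_d": spec.uses_d,
            "mean_auc": float(np.mean(aucs)),
            "sd_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            "min_distance": min_distance(full_curve),
            "recognition_rate": recognition_rate(tp, fn, tn, fp),
            "mean_kappa": float(np.mean(kappas)),
            "sd_kappa": (float(np.std(kappas, ddof=1))
                         if len(kappas) > 1 else 0.0),
        })
    table = pd.DataFrame.from_records(records)
    table["auc_rank"] = table["mean_auc"].rank(ascending=False,
                                               method="min").astype(int)
    table["min_distance_rank"] = table["min_distance"].rank(
        ascending=True, method="min").astype(int)
    table["kappa_rank"] = table["mean_kappa"].rank(ascending=False,
                                                   method="min").astype(int)
    table = table.sort_values(
        ["mean_auc", "min_distance", "mean_kappa", "eq_id"],
        ascending=[False, True, False, True],
    ).reset_index(drop=True)
    return table


def write_roc_points(curve: ROCCurve, path, delimiter: str = ",") -> None:
    """Export (threshold, FPR, TPR) rows as delimited text."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["threshold", "fpr", "tpr"])
        for row in curve.rows:
            writer.writerow([f"{row[0]:.4f}", f"{row[5]:.10g}",
                             f"{row[6]:.10g}"])
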