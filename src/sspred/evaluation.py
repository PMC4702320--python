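"""ROC / precision-recall evaluation and the cross-validation driver.

ROC points are produced by sweeping every distinct score as a threshold
(positive call at score >= threshold, ties grouped on one vertex), the
area is the trapezoid over (FPR, TPR), and its standard error follows the
binormal-free formula of Hanley and McNeil,

    SE = sqrt[ (th(1-th) + (Np-1)(Q1-th^2) + (Nn-1)(Q2-th^2)) / (Np*Nn) ],
    Q1 = th/(2-th),  Q2 = 2 th^2/(1+th),

with Np true sites, Nn false sites and th the AUC.  PR curves interpolate
between achievable (TP, FP) points by increasing FP linearly with TP at
the local skew (FP_B-FP_A)/(TP_B-TP_A), the correction of Davis and
Goadrich that avoids the over-optimism of straight-line interpolation in
PR space; AUC-PR is the trapezoid over the interpolated curve.

AUC-ROC is exactly invariant to duplicating negatives (class skew), while
precision at fixed recall is not — the reason both curve families are
reported for imbalanced data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io import AlignedMotifSet
from .sae import SaeClassifier
from .baselines import Mm1Classifier, WmmClassifier

POSITIVE = "TSS"


def _as_binary(labels: Sequence) -> np.ndarray:
    y = np.asarray(list(labels), dtype=object)
    if y.dtype.kind in "biuf" or set(np.unique(y)) <= {0, 1, True, False}:
        return y.astype(int)
    return (y == POSITIVE).astype(int)


def confusion(
    scores: Sequence[float], labels: Sequence, threshold: float
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) with a positive call at score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels length mismatch")
    call = s >= threshold
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    tn = int(np.sum(~call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    return tp, fp, tn, fn


def _sweep(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (TP, FP) at each distinct threshold, descending scores."""
    order = np.argsort(-scores, kind="stable")
    s, yy = scores[order], y[order]
    tp = np.cumsum(yy == 1)
    fp = np.cumsum(yy == 0)
    # keep only the last index of each tied score block (ties grouped)
    last = np.r_[np.diff(s) != 0, True]
    return tp[last], fp[last]


@dataclass(frozen=True)
class RocResult:
    points: np.ndarray  # (k, 2) of (FPR, TPR), starting at (0, 0)
    theta: float
    se: float
    n_tss: int
    n_fss: int


def hanley_mcneil_se(theta: float, n_tss: int, n_fss: int) -> float:
    """Standard error of the AUC; tends to 0 as theta -> 1 at fixed n."""
    q1 = theta / (2.0 - theta)
    q2 = 2.0 * theta**2 / (1.0 + theta)
    var = (
        theta * (1.0 - theta)
        + (n_tss - 1) * (q1 - theta**2)
        + (n_fss - 1) * (q2 - theta**2)
    ) / (n_tss * n_fss)
    return math.sqrt(max(var, 0.0))


def roc(scores: Sequence[float], labels: Sequence) -> RocResult:
    """ROC curve, trapezoidal AUC and its Hanley-McNeil standard error."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one instance of each class")
    tp, fp = _sweep(s, y)
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    theta = float(np.trapezoid(tpr, fpr))
    return RocResult(
        points=np.column_stack([fpr, tpr]),
        theta=theta,
        se=hanley_mcneil_se(theta, n_pos, n_neg),
        n_tss=n_pos,
        n_fss=n_neg,
    )


def pr_interpolate(
    A: tuple[int, int], B: tuple[int, int], n_tss: int
) -> list[tuple[float, float]]:
    """Intermediate (recall, precision) points between achievable A and B.

    For x = 1 .. TP_B-TP_A-1 the interpolated counts are TP_A + x and
    FP_A + x * skew with skew = (FP_B-FP_A)/(TP_B-TP_A); recall = TP/n_tss
    and precision = TP/(TP+FP).
    """
    (tpa, fpa), (tpb, fpb) = A, B
    if tpb <= tpa or fpb < fpa:
        raise ValueError("need TP_A < TP_B and FP_A <= FP_B")
    skew = (fpb - fpa) / (tpb - tpa)
    out = []
    for x in range(1, tpb - tpa):
        tp = tpa + x
        fp = fpa + x * skew
        out.append((tp / n_tss, tp / (tp + fp)))
    return out


@dataclass(frozen=True)
class PrResult:
    points: np.ndarray  # (k, 2) of (recall, precision), interpolated
    auc_pr: float


def pr(scores: Sequence[float], labels: Sequence) -> PrResult:
    """Davis-Goadrich interpolated PR curve and its trapezoidal area.

    Achievable points come from the same threshold sweep as the ROC
    (ties grouped); consecutive points with a TP gap are filled with the
    skew-interpolated intermediates.  The curve is anchored at recall 0
    with the precision of the first achievable point before integration.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n_pos = int((y == 1).sum())
    if n_pos == 0:
        raise ValueError("PR curve needs at least one positive instance")
    tp, fp = _sweep(s, y)
    keep = tp > 0
    tp, fp = tp[keep], fp[keep]
    pts: list[tuple[float, float]] = []
    prev: tuple[int, int] | None = None
    for tpb, fpb in zip(tp.tolist(), fp.tolist()):
        if prev is not None and tpb > prev[0]:
            pts.extend(pr_interpolate(prev, (tpb, fpb), n_pos))
        pts.append((tpb / n_pos, tpb / (tpb + fpb)))
        prev = (tpb, fpb)
    curve = np.array(pts)
    anchored = np.vstack([[0.0, curve[0, 1]], curve])
    auc = float(np.trapezoid(anchored[:, 1], anchored[:, 0]))
    return PrResult(points=curve, auc_pr=auc)


@dataclass(frozen=True)
class CvResult:
    per_fold: tuple[dict, ...]  # sensitivity/specificity per held-out fold
    roc: RocResult  # pooled over concatenated held-out scores
    pr: PrResult
    epsilon: float | None


_METHODS: dict[str, Callable] = {
    "sae": lambda kw: SaeClassifier(**kw),
    "wmm": lambda kw: WmmClassifier(**kw),
    "mm1": lambda kw: Mm1Classifier(**kw),
}


def stratified_folds(
    n_tss: int, n_fss: int, k: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Shuffled per-class index folds with sizes differing by at most 1."""
    return (
        np.array_split(rng.permutation(n_tss), k),
        np.array_split(rng.permutation(n_fss), k),
    )


def cross_validate(
    tss: AlignedMotifSet,
    fss: AlignedMotifSet,
    k: int = 10,
    seed: int | None = None,
    method: str = "sae",
    **params,
) -> CvResult:
    """Stratified k-fold evaluation with pooled held-out ROC/PR curves.

    Per-fold sensitivity and specificity are measured at each fold model's
    own decision threshold (epsilon for SAE, 0 for the log-odds
    baselines); the pooled curves concatenate held-out scores across
    folds.  Deterministic under ``seed``.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    tss_folds, fss_folds = stratified_folds(tss.N, fss.N, k, rng)
    if any(f.size == 0 for f in tss_folds + fss_folds):
        raise ValueError("a fold has an empty class; reduce k")

    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    fold_stats = []
    epsilons = []
    for f in range(k):
        Xtr = [tss.motifs[i] for g in range(k) if g != f for i in tss_folds[g]]
        ytr = ["TSS"] * len(Xtr)
        nf = [fss.motifs[i] for g in range(k) if g != f for i in fss_folds[g]]
        Xtr += nf
        ytr += ["FSS"] * len(nf)
        kw = dict(params)
        if method == "sae":
            kw.setdefault("random_state", int(rng.integers(2**31 - 1)))
        clf = _METHODS[method](kw).fit(Xtr, ytr)

        Xte = [tss.motifs[i] for i in tss_folds[f]] + [
            fss.motifs[i] for i in fss_folds[f]
        ]
        yte = ["TSS"] * tss_folds[f].size + ["FSS"] * fss_folds[f].size
        pred = clf.predict(Xte)
        yb = np.array(yte) == "TSS"
        pb = np.array(pred) == "TSS"
        sens = float(np.mean(pb[yb]))
        spec = float(np.mean(~pb[~yb]))
        fold_stats.append({"fold": f, "sensitivity": sens, "specificity": spec})
        pooled_scores.append(clf.decision_function(Xte))
        pooled_labels.append(np.array(yte, dtype=object))
        if method == "sae":
            epsilons.append(clf.epsilon_)

    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    return CvResult(
        per_fold=tuple(fold_stats),
        roc=roc(scores, labels),
        pr=pr(scores, labels),
        epsilon=float(np.mean(epsilons)) if epsilons else None,
    )
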