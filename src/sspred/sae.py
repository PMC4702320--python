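"""Sum-of-absolute-error (SAE) donor splice-site classifier.

The model treats each base of an aligned motif as an indicator variable
and predicts it from every other position.  Given a training set, the
conditional probability of base ``s`` at position ``i`` given base ``t``
at position ``j`` is the count ratio

    p(s_i | t_j) = n_ij(s, t) / n_j(t)          (pseudocount 0)
                 = (n_ij(s, t) + a) / (n_j(t) + 4a)   (pseudocount a > 0).

The observed indicator of the test motif's own base at ``i`` is 1 and the
remaining three bases are 0, so the absolute prediction error at ``i``
summed over conditioning positions is

    SAE_i = 2 * sum_{j != i} (1 - p(s_i | t_j)),    in [0, 2(P-1)],

and over all positions SAE_ap = sum_i SAE_i, in [0, 2P(P-1)].  A true-site
motif is highly predictable under the true-site (TSS) model, so

    dSAE = SAE_ap^{TSS model} - SAE_ap^{FSS model}

is low for true sites: the decision rule is dSAE < eps -> TSS and
dSAE >= eps -> FSS.  The reported score is -dSAE, so that higher means
more TSS-like and the predicted class is score > -eps.

The threshold eps is estimated by drawing a stratified 60% sample,
splitting it into ten folds, and in each fold locating the score at which
held-out sensitivity equals specificity; eps is the mean of the ten
per-fold crossings.  Sensitivity and specificity are class-conditional
rates, so eps is invariant to the TSS:FSS ratio once the folds are fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .association import IndicatorCounts, _encode, count_indicators
from .io import BASE_TO_INDEX, AlignedMotifSet


@dataclass(frozen=True)
class ConditionalModel:
    """Class-conditional table p(s_i | t_j) for all ordered pairs i != j."""

    P: int
    cond: np.ndarray  # (P, P, 4, 4); cond[i, j, s, t] = p(s_i | t_j); NaN on i == j
    counts: IndicatorCounts
    pseudocount: float
    label: str | None = None


def fit_conditionals(
    motifs: AlignedMotifSet,
    pseudocount: float = 0.0,
    label: str | None = None,
) -> ConditionalModel:
    """Estimate p(s_i | t_j) from aligned motifs.

    With ``pseudocount`` 0 the estimate is the exact count ratio
    n_ij(s,t)/n_j(t); any base absent from some position then leaves a
    conditional undefined and a ``ValueError`` directs the caller to a
    positive pseudocount (Laplace-style: +a on joints, +4a on marginals).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = count_indicators(motifs)
    label = label if label is not None else motifs.label
    single = counts.single.astype(float)
    if pseudocount == 0 and (single == 0).any():
        j, t = np.argwhere(single == 0)[0]
        raise ValueError(
            f"base {'ATGC'[t]} never occurs at position {j}: p(.|{'ATGC'[t]}_{j}) "
            "is undefined with pseudocount 0; use pseudocount > 0"
        )
    denom = single[None, :, None, :] + 4 * pseudocount  # broadcast over (i, s)
    cond = (counts.joint + pseudocount) / denom
    idx = np.arange(counts.P)
    cond[idx, idx] = np.nan  # self-conditioning is not part of the model
    return ConditionalModel(
        P=counts.P, cond=cond, counts=counts, pseudocount=pseudocount, label=label
    )


def _codes(model_P: int, seq: str) -> np.ndarray:
    if len(seq) != model_P:
        raise ValueError(f"sequence length {len(seq)} != model P {model_P}")
    try:
        return np.array([BASE_TO_INDEX[b] for b in seq])
    except KeyError as e:
        raise ValueError(f"non-ACGT base {e} in {seq!r}") from None


def _gather(model: ConditionalModel, codes: np.ndarray) -> np.ndarray:
    """Matrix of p(s_i | t_j) for the motif's own bases; NaN on the diagonal."""
    return model.cond[
        np.arange(model.P)[:, None],
        np.arange(model.P)[None, :],
        codes[:, None],
        codes[None, :],
    ]


def sae_position(model: ConditionalModel, seq: str, i: int) -> float:
    """SAE at position ``i`` (0-based): 2 * sum_{j != i} (1 - p(s_i | t_j))."""
    codes = _codes(model.P, seq)
    row = _gather(model, codes)[i]
    row = np.delete(row, i)
    if np.isnan(row).any():
        raise ValueError(
            "undefined conditional encountered (pseudocount 0, unseen base); "
            "refit with pseudocount > 0"
        )
    return float(2.0 * np.sum(1.0 - row))


def sae_total(model: ConditionalModel, seq: str) -> float:
    """SAE over all positions: 2P(P-1) - 2 * sum_{i} sum_{j != i} p(s_i | t_j)."""
    codes = _codes(model.P, seq)
    g = _gather(model, codes)
    off = g[~np.eye(model.P, dtype=bool)]
    if np.isnan(off).any():
        raise ValueError(
            "undefined conditional encountered (pseudocount 0, unseen base); "
            "refit with pseudocount > 0"
        )
    P = model.P
    return float(2.0 * P * (P - 1) - 2.0 * off.sum())


@dataclass(frozen=True)
class ThresholdEstimate:
    """Per-fold sensitivity=specificity crossings and their mean."""

    per_fold: tuple[float, ...]
    epsilon: float
    seed: int | None
    fraction: float


def _crossing(dsae_tss: np.ndarray, dsae_fss: np.ndarray) -> float:
    """Threshold where held-out sensitivity equals specificity.

    Candidates are the midpoints between consecutive sorted unique pooled
    dSAE values; the candidate minimising |sensitivity - specificity| is
    retained (ties averaged).  Sensitivity counts TSS with dSAE < c,
    specificity FSS with dSAE >= c, matching the decision rule.
    """
    pooled = np.unique(np.concatenate([dsae_tss, dsae_fss]))
    if pooled.size == 1:
        return float(pooled[0])
    cands = (pooled[:-1] + pooled[1:]) / 2.0
    sens = np.mean(dsae_tss[None, :] < cands[:, None], axis=1)
    spec = np.mean(dsae_fss[None, :] >= cands[:, None], axis=1)
    diff = np.abs(sens - spec)
    tied = cands[diff == diff.min()]
    return float(tied.mean())


def estimate_threshold(
    tss: AlignedMotifSet,
    fss: AlignedMotifSet,
    fraction: float = 0.6,
    k: int = 10,
    seed: int | None = None,
    pseudocount: float = 0.0,
) -> ThresholdEstimate:
    """Estimate the decision threshold eps by the fold-wise crossing procedure.

    A stratified random ``fraction`` of each class is drawn, split into
    ``k`` folds with approximately equal class counts, and each fold is
    scored by models trained on the remaining folds; eps is the mean of
    the per-fold sensitivity=specificity crossings.  Fully reproducible
    from ``seed``.
    """
    if tss.P != fss.P:
        raise ValueError("TSS and FSS motif lengths differ")
    rng = np.random.default_rng(seed)

    def folds_of(mset: AlignedMotifSet) -> list[np.ndarray]:
        n_take = int(round(fraction * mset.N))
        idx = rng.permutation(mset.N)[:n_take]
        return np.array_split(idx, k)

    tss_folds, fss_folds = folds_of(tss), folds_of(fss)
    if any(f.size == 0 for f in tss_folds + fss_folds):
        raise ValueError(
            "a fold has an empty class; use fewer folds, a larger fraction, "
            "or more motifs"
        )
    per_fold = []
    for f in range(k):
        tr_t = [tss.motifs[i] for g in range(k) if g != f for i in tss_folds[g]]
        tr_f = [fss.motifs[i] for g in range(k) if g != f for i in fss_folds[g]]
        mt = fit_conditionals(AlignedMotifSet(tuple(tr_t)), pseudocount, "TSS")
        mf = fit_conditionals(AlignedMotifSet(tuple(tr_f)), pseudocount, "FSS")
        d_t = np.array(
            [sae_total(mt, tss.motifs[i]) - sae_total(mf, tss.motifs[i])
             for i in tss_folds[f]]
        )
        d_f = np.array(
            [sae_total(mt, fss.motifs[i]) - sae_total(mf, fss.motifs[i])
             for i in fss_folds[f]]
        )
        per_fold.append(_crossing(d_t, d_f))
    return ThresholdEstimate(
        per_fold=tuple(per_fold),
        epsilon=float(np.mean(per_fold)),
        seed=seed,
        fraction=fraction,
    )


class SaeClassifier(ClassifierMixin, BaseEstimator):
    """Donor splice-site classifier scoring candidate motifs by -dSAE.

    Parameters
    ----------
    pseudocount : float, default 0.0
        Laplace-style smoothing of the conditional tables.  0 gives the
        exact count-ratio estimates and raises when a base is unseen at
        some position; use a positive value for small training sets.
    epsilon : float or None, default None
        Decision threshold on dSAE.  If None it is estimated during
        ``fit`` by the fold-wise sensitivity=specificity procedure.
    threshold_fraction : float, default 0.6
        Fraction of the training data drawn for threshold estimation.
    threshold_folds : int, default 10
        Number of folds used for threshold estimation.
    random_state : int or None
        Seed for the threshold-estimation subsample and fold assignment.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels; ``"TSS"`` (or 1) is the positive class.
    tss_model_, fss_model_ : ConditionalModel
        Fitted class-conditional probability tables.
    epsilon_ : float
        Decision threshold actually used.
    threshold_estimate_ : ThresholdEstimate or None
        Per-fold detail when the threshold was estimated during fit.
    """

    def __init__(
        self,
        pseudocount: float = 0.0,
        epsilon: float | None = None,
        threshold_fraction: float = 0.6,
        threshold_folds: int = 10,
        random_state: int | None = None,
    ):
        self.pseudocount = pseudocount
        self.epsilon = epsilon
        self.threshold_fraction = threshold_fraction
        self.threshold_folds = threshold_folds
        self.random_state = random_state

    # -- label plumbing ----------------------------------------------------
    @staticmethod
    def _positive(classes: np.ndarray):
        cl = list(classes)
        if len(cl) != 2:
            raise ValueError(f"need exactly two classes, got {cl}")
        if "TSS" in cl:
            return "TSS"
        return max(cl)

    def _split(self, X, y) -> tuple[AlignedMotifSet, AlignedMotifSet]:
        X = np.asarray(list(X), dtype=object)
        y = np.asarray(list(y), dtype=object)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y.astype(str))
        ypos = np.unique(y)
        pos = self._positive(ypos)
        tss = AlignedMotifSet(tuple(str(m) for m in X[y == pos]), label="TSS")
        fss = AlignedMotifSet(tuple(str(m) for m in X[y != pos]), label="FSS")
        self._pos_label, self._neg_label = pos, [c for c in ypos if c != pos][0]
        return tss, fss

    # -- estimator API -----------------------------------------------------
    def fit(self, X: Sequence[str], y: Sequence) -> "SaeClassifier":
        """Fit TSS/FSS conditional tables and (optionally) estimate epsilon.

        ``X`` is a sequence of equal-length ACGT motif strings (the modeled
        core positions, GT excluded); ``y`` the class of each motif.
        """
        tss, fss = self._split(X, y)
        if tss.P != fss.P:
            raise ValueError("TSS and FSS motif lengths differ")
        self.tss_model_ = fit_conditionals(tss, self.pseudocount, "TSS")
        self.fss_model_ = fit_conditionals(fss, self.pseudocount, "FSS")
        if self.epsilon is not None:
            self.epsilon_ = float(self.epsilon)
            self.threshold_estimate_ = None
        else:
            self.threshold_estimate_ = estimate_threshold(
                tss,
                fss,
                fraction=self.threshold_fraction,
                k=self.threshold_folds,
                seed=self.random_state,
                pseudocount=self.pseudocount,
            )
            self.epsilon_ = self.threshold_estimate_.epsilon
        self.P_ = tss.P
        return self

    def dsae(self, X: Sequence[str]) -> np.ndarray:
        """dSAE = SAE_ap under the TSS model minus under the FSS model."""
        self._check_fitted()
        return np.array(
            [
                sae_total(self.tss_model_, s) - sae_total(self.fss_model_, s)
                for s in X
            ]
        )

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        """Score = -dSAE, so that higher means more TSS-like."""
        return -self.dsae(X)

    def predict(self, X: Sequence[str]) -> np.ndarray:
        """Apply the rule dSAE < epsilon -> TSS, dSAE >= epsilon -> FSS."""
        self._check_fitted()
        if self.epsilon_ is None:
            raise ValueError("no decision threshold set")
        d = self.dsae(X)
        return np.where(d < self.epsilon_, self._pos_label, self._neg_label)

    def _check_fitted(self) -> None:
        if not hasattr(self, "tss_model_"):
            raise ValueError("SaeClassifier is not fitted; call fit first")

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Persist counts, pseudocount and threshold as self-describing JSON."""
        self._check_fitted()

        def pack(m: ConditionalModel) -> dict:
            return {
                "N": m.counts.N,
                "single": m.counts.single.tolist(),
                "joint": m.counts.joint.tolist(),
            }

        blob = {
            "format": "sspred-sae-model",
            "version": 1,
            "P": self.P_,
            "pseudocount": self.pseudocount,
            "epsilon": self.epsilon_,
            "positive_label": str(self._pos_label),
            "negative_label": str(self._neg_label),
            "tss_counts": pack(self.tss_model_),
            "fss_counts": pack(self.fss_model_),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "SaeClassifier":
        blob = json.loads(Path(path).read_text())
        if blob.get("format") != "sspred-sae-model":
            raise ValueError(f"{path}: not an sspred SAE model file")
        clf = cls(pseudocount=blob["pseudocount"], epsilon=blob["epsilon"])

        def unpack(key: str, label: str) -> ConditionalModel:
            c = blob[key]
            counts = IndicatorCounts(
                N=c["N"],
                single=np.array(c["single"], dtype=np.int64),
                joint=np.array(c["joint"], dtype=np.int64),
            )
            a = blob["pseudocount"]
            single = counts.single.astype(float)
            denom = single[None, :, None, :] + 4 * a
            cond = (counts.joint + a) / denom
            idx = np.arange(counts.P)
            cond[idx, idx] = np.nan
            return ConditionalModel(
                P=counts.P, cond=cond, counts=counts, pseudocount=a, label=label
            )

        clf.tss_model_ = unpack("tss_counts", "TSS")
        clf.fss_model_ = unpack("fss_counts", "FSS")
        clf.P_ = blob["P"]
        clf.epsilon_ = blob["epsilon"]
        clf.threshold_estimate_ = None
        clf._pos_label = blob["positive_label"]
        clf._neg_label = blob["negative_label"]
        clf.classes_ = np.unique([clf._pos_label, clf._neg_label])
        return clf


# -- thin functional wrappers ---------------------------------------------

def dsae(clf: SaeClassifier, seq: str) -> float:
    """dSAE of one motif under a fitted classifier."""
    return float(clf.dsae([seq])[0])


def predict(clf: SaeClassifier, seq: str) -> tuple[str, float]:
    """(label, score) of one motif; score is -dSAE (higher = more TSS-like)."""
    label = clf.predict([seq])[0]
    return str(label), float(clf.decision_function([seq])[0])


def fit_sae(
    tss: AlignedMotifSet,
    fss: AlignedMotifSet,
    pseudocount: float = 0.0,
    epsilon: float | None = None,
    random_state: int | None = None,
) -> SaeClassifier:
    """Fit an SaeClassifier directly from labelled motif sets."""
    X = list(tss.motifs) + list(fss.motifs)
    y = ["TSS"] * tss.N + ["FSS"] * fss.N
    return SaeClassifier(
        pseudocount=pseudocount, epsilon=epsilon, random_state=random_state
    ).fit(X, y)
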