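"""Reference donor-site scorers: WMM and first-order Markov log-odds.

WMM (weighted matrix method) assumes independent positions: each class is
a product of per-position base distributions and the score of a motif is
the base-2 log-likelihood ratio

    score(x) = sum_i log2( p_i^TSS(x_i) / p_i^FSS(x_i) ).

MM1 adds adjacent-position dependence: a class is an inhomogeneous
first-order Markov chain with an initial distribution at position 1 and a
position-specific transition table at each subsequent position, scored as
the log2 chain-likelihood ratio.  Both are trained here on the same
TSS/FSS motif sets as the SAE model (the FSS model is the background), so
cross-tool score *values* are not comparable to other implementations —
only the ranking behaviour is.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .association import _encode
from .io import AlignedMotifSet


def _positional_probs(motifs: AlignedMotifSet, alpha: float) -> np.ndarray:
    """(P, 4) smoothed per-position base probabilities."""
    codes = _encode(motifs)
    N, P = codes.shape
    counts = np.zeros((P, 4))
    for b in range(4):
        counts[:, b] = (codes == b).sum(axis=0)
    if alpha == 0 and (counts == 0).any():
        raise ValueError("zero count with pseudocount 0; use alpha > 0")
    return (counts + alpha) / (N + 4 * alpha)


def _transition_probs(motifs: AlignedMotifSet, alpha: float) -> np.ndarray:
    """(P-1, 4, 4) smoothed transitions trans[i, a, b] = p(x_{i+1}=b | x_i=a)."""
    codes = _encode(motifs)
    N, P = codes.shape
    joint = np.zeros((P - 1, 4, 4))
    for i in range(P - 1):
        np.add.at(joint[i], (codes[:, i], codes[:, i + 1]), 1)
    row = joint.sum(axis=2, keepdims=True)
    if alpha == 0 and (joint == 0).any():
        raise ValueError("zero transition count with pseudocount 0; use alpha > 0")
    return (joint + alpha) / (row + 4 * alpha)


class _TwoClassScorer(ClassifierMixin, BaseEstimator):
    """Shared plumbing: split X/y into class motif sets, threshold at 0."""

    def _split(self, X, y) -> tuple[AlignedMotifSet, AlignedMotifSet]:
        X = np.asarray(list(X), dtype=object)
        y = np.asarray(list(y), dtype=object)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly two classes, got {list(classes)}")
        pos = "TSS" if "TSS" in classes else max(classes)
        self.classes_ = np.unique(y.astype(str))
        self._pos_label = pos
        self._neg_label = [c for c in classes if c != pos][0]
        tss = AlignedMotifSet(tuple(str(m) for m in X[y == pos]), label="TSS")
        fss = AlignedMotifSet(tuple(str(m) for m in X[y != pos]), label="FSS")
        if tss.P != fss.P:
            raise ValueError("class motif lengths differ")
        return tss, fss

    def predict(self, X: Sequence[str]) -> np.ndarray:
        s = self.decision_function(X)
        return np.where(s >= 0, self._pos_label, self._neg_label)


class WmmClassifier(_TwoClassScorer):
    """Position-independent log-odds scorer (weighted matrix method).

    ``alpha`` (default 0.5) is the Laplace pseudocount applied to both
    class matrices.  ``decision_function`` returns the summed per-position
    log2 odds of TSS over FSS.
    """

    def __init__(self, alpha: float = 0.5):
        self.alpha = alpha

    def fit(self, X: Sequence[str], y: Sequence) -> "WmmClassifier":
        tss, fss = self._split(X, y)
        self.tss_probs_ = _positional_probs(tss, self.alpha)
        self.fss_probs_ = _positional_probs(fss, self.alpha)
        self.P_ = tss.P
        return self

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        mset = AlignedMotifSet(tuple(str(s) for s in X))
        if mset.P != self.P_:
            raise ValueError(f"motif length {mset.P} != model P {self.P_}")
        codes = _encode(mset)
        pos = np.arange(self.P_)
        lt = np.log2(self.tss_probs_[pos, codes])
        lf = np.log2(self.fss_probs_[pos, codes])
        return (lt - lf).sum(axis=1)


class Mm1Classifier(_TwoClassScorer):
    """Inhomogeneous first-order Markov log-odds scorer."""

    def __init__(self, alpha: float = 0.5):
        self.alpha = alpha

    def fit(self, X: Sequence[str], y: Sequence) -> "Mm1Classifier":
        tss, fss = self._split(X, y)
        self.tss_initial_ = _positional_probs(tss, self.alpha)[0]
        self.fss_initial_ = _positional_probs(fss, self.alpha)[0]
        self.tss_trans_ = _transition_probs(tss, self.alpha)
        self.fss_trans_ = _transition_probs(fss, self.alpha)
        self.P_ = tss.P
        return self

    def _loglik(self, codes: np.ndarray, initial, trans) -> np.ndarray:
        ll = np.log2(initial[codes[:, 0]])
        for i in range(self.P_ - 1):
            ll = ll + np.log2(trans[i, codes[:, i], codes[:, i + 1]])
        return ll

    def decision_function(self, X: Sequence[str]) -> np.ndarray:
        mset = AlignedMotifSet(tuple(str(s) for s in X))
        if mset.P != self.P_:
            raise ValueError(f"motif length {mset.P} != model P {self.P_}")
        codes = _encode(mset)
        return self._loglik(codes, self.tss_initial_, self.tss_trans_) - self._loglik(
            codes, self.fss_initial_, self.fss_trans_
        )


# -- thin functional wrappers ---------------------------------------------

def _fit(cls, tss: AlignedMotifSet, fss: AlignedMotifSet, alpha: float):
    X = list(tss.motifs) + list(fss.motifs)
    y = ["TSS"] * tss.N + ["FSS"] * fss.N
    return cls(alpha=alpha).fit(X, y)


def fit_wmm(tss: AlignedMotifSet, fss: AlignedMotifSet, alpha: float = 0.5):
    return _fit(WmmClassifier, tss, fss, alpha)


def score_wmm(model: WmmClassifier, seq: str) -> float:
    return float(model.decision_function([seq])[0])


def fit_mm1(tss: AlignedMotifSet, fss: AlignedMotifSet, alpha: float = 0.5):
    return _fit(Mm1Classifier, tss, fss, alpha)


def score_mm1(model: Mm1Classifier, seq: str) -> float:
    return float(model.decision_function([seq])[0])
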