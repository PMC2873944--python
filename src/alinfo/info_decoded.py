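"""Decoding (confusion-matrix) lower bound on mutual information.

For populations whose pattern space is too large to enumerate, odors are
decoded from PN count vectors with a one-against-one ensemble of binary
linear support-vector machines (majority vote), and the mutual information
between the true and predicted odor labels is computed from the confusion
matrix:

    I(S; S_hat) = sum_{s, s'} P(s) P(s'|s) log2 [ P(s'|s) / P(s') ],

with ``P(s'|s)`` the row-normalized confusion matrix and ``P(s')`` its
prior-weighted column marginal.  By the data-processing inequality this
never exceeds the information carried by the responses themselves, so it is
a lower bound that can be pushed toward the truth with more training data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

from .circuit import CircuitParams, SpikeCountTable, run_ensemble
from .odors import OdorResponseMatrix

__all__ = [
    "PairwiseVoteDecoder",
    "ConfusionMatrix",
    "train_decoder",
    "evaluate_decoder",
    "mi_from_confusion",
    "decoded_mi_experiment",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of (true odor, predicted odor) pairs; rows are true labels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(c < 0):
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_per_class(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


class PairwiseVoteDecoder:
    """One-against-one linear-SVM odor decoder over raw count vectors.

    For K classes, K(K-1)/2 binary SVMs with a linear kernel are trained on
    all class pairs; a test vector is assigned the class with the most
    votes.  Vote ties are broken deterministically: ``tie_break='index'``
    picks the lowest class index (default), ``'margin'`` picks the larger
    summed signed decision margin.  Features are used raw (capped spike
    counts are already on a common scale); no standardization.
    """

    def __init__(self, C: float = 1.0, tie_break: str = "index"):
        if tie_break not in ("index", "margin"):
            raise ValueError("tie_break must be 'index' or 'margin'")
        self.C = C
        self.tie_break = tie_break

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PairwiseVoteDecoder":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        counts = {c: int((y == c).sum()) for c in self.classes_}
        empty = [c for c, n in counts.items() if n == 0]
        if empty:
            raise ValueError(f"classes without training data: {empty}")
        self.n_features_in_ = X.shape[1]
        self.estimators_ = {}
        for a, b in combinations(range(len(self.classes_)), 2):
            mask = (y == self.classes_[a]) | (y == self.classes_[b])
            clf = SVC(kernel="linear", C=self.C)
            clf.fit(X[mask], y[mask])
            self.estimators_[(a, b)] = clf
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got shape {X.shape}"
            )
        K = len(self.classes_)
        votes = np.zeros((len(X), K), dtype=np.int64)
        margins = np.zeros((len(X), K))
        for (a, b), clf in self.estimators_.items():
            # SVC orders its two classes ascending; decision > 0 favors the
            # second (larger-label) class.
            f = clf.decision_function(X)
            lo, hi = (a, b) if self.classes_[a] < self.classes_[b] else (b, a)
            votes[f > 0, hi] += 1
            votes[f <= 0, lo] += 1
            margins[:, hi] += f
            margins[:, lo] -= f
        if self.tie_break == "index":
            best = np.argmax(votes, axis=1)  # argmax takes the lowest index on ties
        else:
            score = votes + 1e-9 * np.tanh(margins)
            best = np.argmax(score, axis=1)
        return self.classes_[best]


def train_decoder(
    train: SpikeCountTable, C: float = 1.0, tie_break: str = "index"
) -> PairwiseVoteDecoder:
    """Fit the one-against-one linear-SVM decoder on a spike-count table."""
    return PairwiseVoteDecoder(C=C, tie_break=tie_break).fit(
        train.counts, train.odor_index
    )


def evaluate_decoder(
    decoder: PairwiseVoteDecoder, test: SpikeCountTable
) -> ConfusionMatrix:
    """Confusion matrix of the decoder on held-out trials."""
    if test.n_trials == 0:
        raise ValueError("empty test set")
    pred = decoder.predict(test.counts)
    n = int(max(test.odor_index.max(), pred.max())) + 1
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (test.odor_index, pred), 1)
    return ConfusionMatrix(counts)


def mi_from_confusion(
    matrix: ConfusionMatrix | np.ndarray, prior: np.ndarray | None = None
) -> float:
    """Plug-in MI (bits) of the (true, predicted) joint under the prior."""
    counts = matrix.counts if isinstance(matrix, ConfusionMatrix) else np.asarray(matrix)
    counts = np.asarray(counts, dtype=float)
    S = counts.shape[0]
    row_sums = counts.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("every true class needs at least one test trial")
    if prior is None:
        prior = np.full(S, 1.0 / S)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (S,) or abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < 0):
        raise ValueError("prior must be a probability vector over classes")
    p_cond = counts / row_sums[:, None]          # P(pred | true)
    joint = prior[:, None] * p_cond              # P(true, pred)
    p_pred = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(joint > 0, joint / (prior[:, None] * p_pred[None, :]), 1.0)
        info = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    return float(info.sum())


def decoded_mi_experiment(
    matrix: OdorResponseMatrix,
    params: CircuitParams,
    n_train: int = 200,
    n_test: int = 200,
    seed: int = 0,
    C: float = 1.0,
    tie_break: str = "index",
    return_confusion: bool = False,
):
    """Simulate, decode, and return the confusion-matrix MI in bits.

    ``n_train + n_test`` trials are simulated per odor; the first
    ``n_train`` of each odor's block train the decoder and the rest are
    held out.  With ``return_confusion=True`` the confusion matrix is
    returned alongside the MI.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    tab = run_ensemble(matrix, params, n_train + n_test, seed=seed)
    n_odors = matrix.n_odors
    train_mask = np.zeros(tab.n_trials, dtype=bool)
    for s in range(n_odors):
        idx = np.flatnonzero(tab.odor_index == s)
        train_mask[idx[:n_train]] = True
    train = SpikeCountTable(
        tab.counts[train_mask], tab.odor_index[train_mask],
        cap=tab.cap, t_bin=tab.t_bin, n_pn=tab.n_pn, seed_record=seed,
    )
    test = SpikeCountTable(
        tab.counts[~train_mask], tab.odor_index[~train_mask],
        cap=tab.cap, t_bin=tab.t_bin, n_pn=tab.n_pn, seed_record=seed,
    )
    decoder = train_decoder(train, C=C, tie_break=tie_break)
    confusion = evaluate_decoder(decoder, test)
    mi = mi_from_confusion(confusion)
    if return_confusion:
        return mi, confusion
    return mi
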