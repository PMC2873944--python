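"""Pairwise odor discrimination and the effect of lateral inhibition.

Inhibitory lateral input acts as adaptive gain control: its strength grows
with total ORN activity, so strongly driven (saturating) PN ensembles are
pushed back into the responsive range while weakly driven ones are barely
touched.  The analyses here quantify, for every odor pair, how switching
the lateral pathway off changes (a) held-out accuracy of a binary linear
SVM, (b) the separation between mean PN response vectors, and (c) trial-to-
trial response variability — and aggregate the pairs into outcome
categories.  A two-principal-component projection visualizes how inhibition
moves saturated response clusters away from the all-maximal corner of
response space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .circuit import CircuitParams, run_ensemble
from .odors import OdorResponseMatrix

__all__ = [
    "PairMetrics",
    "PairRecord",
    "PairProjection",
    "pair_metrics",
    "pair_classification_rate",
    "table1_summary",
    "pca_pair_view",
]


def _counts(x) -> np.ndarray:
    counts = getattr(x, "counts", x)
    return np.asarray(counts, dtype=float)


@dataclass(frozen=True)
class PairMetrics:
    """Separation and variability statistics for one odor pair.

    ``distance``: Euclidean distance between the two trial-mean PN count
    vectors (spikes per bin).  ``mean_variance``: average over the two
    odors of the mean Euclidean distance from each trial's response vector
    to its odor's trial mean.  ``mean_rate``: grand-mean PN firing rate in
    Hz over both odors.
    """

    distance: float
    mean_variance: float
    mean_rate: float


def pair_metrics(counts_a, counts_b, t_bin: float = 0.010) -> PairMetrics:
    """Distance / variability / rate statistics for a pair of odors."""
    a, b = _counts(counts_a), _counts(counts_b)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("count tables must be 2-D with matching PN dimension")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("count tables must be non-empty")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    distance = float(np.linalg.norm(mean_a - mean_b))
    spread = 0.5 * (
        float(np.linalg.norm(a - mean_a, axis=1).mean())
        + float(np.linalg.norm(b - mean_b, axis=1).mean())
    )
    rate = float(np.concatenate([a, b]).mean() / t_bin)
    return PairMetrics(distance=distance, mean_variance=spread, mean_rate=rate)


def pair_classification_rate(
    counts_a,
    counts_b,
    n_train: int = 200,
    n_test: int = 200,
    seed: int = 0,
    C: float = 1.0,
) -> float:
    """Held-out percent-correct of a binary linear SVM on one odor pair.

    Trials of each odor are shuffled with ``seed``; the first ``n_train``
    per odor train the classifier, the next ``n_test`` are scored.
    """
    a, b = _counts(counts_a), _counts(counts_b)
    if len(a) < n_train + n_test or len(b) < n_train + n_test:
        raise ValueError("not enough trials for the requested train/test split")
    rng = np.random.default_rng(seed)
    a = a[rng.permutation(len(a))]
    b = b[rng.permutation(len(b))]
    X_train = np.vstack([a[:n_train], b[:n_train]])
    y_train = np.repeat([0, 1], n_train)
    X_test = np.vstack([a[n_train : n_train + n_test], b[n_train : n_train + n_test]])
    y_test = np.repeat([0, 1], n_test)
    clf = SVC(kernel="linear", C=C).fit(X_train, y_train)
    return float((clf.predict(X_test) == y_test).mean() * 100.0)


@dataclass(frozen=True)
class PairRecord:
    """Effect of lateral inhibition on one odor pair.

    Percent-correct rates, distances, variabilities and mean rates with the
    inhibitory lateral pathway on vs off, plus the outcome category
    ``"<correct-rate direction>/dist-<up|down>-var-<up|down>"`` (or
    ``"no-change"`` when the held-out rates are exactly equal).
    """

    odor_a: int
    odor_b: int
    correct_with: float
    correct_without: float
    distance_with: float
    distance_without: float
    variance_with: float
    variance_without: float
    rate_with: float
    rate_without: float
    category: str


def _categorize(rec_with: PairMetrics, rec_without: PairMetrics,
                cr_with: float, cr_without: float) -> str:
    if cr_with == cr_without:
        return "no-change"
    direction = "increase" if cr_with > cr_without else "decrease"
    dist = "up" if rec_with.distance > rec_without.distance else "down"
    var = "down" if rec_with.mean_variance < rec_without.mean_variance else "up"
    return f"{direction}/dist-{dist}-var-{var}"


def table1_summary(
    matrix: OdorResponseMatrix,
    params: CircuitParams,
    seed: int = 0,
    n_metric_trials: int = 1000,
    n_train: int = 200,
    n_test: int = 200,
) -> tuple[list[PairRecord], pd.DataFrame]:
    """Categorize every odor pair by the effect of lateral inhibition.

    ``params`` carries the inhibitory operating point (typically peak i);
    the comparison condition is the same circuit with ``w_lat = 0``.
    Returns the per-pair records and an aggregate table with one row per
    category: share of pairs (%), mean rates, and mean effect sizes.
    """
    if matrix.n_odors < 2:
        raise ValueError("need at least two odors")
    if params.w_lat >= 0:
        raise ValueError("params.w_lat must be inhibitory (negative)")
    n_sim = max(n_metric_trials, n_train + n_test)
    tab_on = run_ensemble(matrix, params, n_sim, seed=seed)
    tab_off = run_ensemble(matrix, params.with_(w_lat=0.0), n_sim, seed=seed)
    per_odor_on = [tab_on.for_odor(s) for s in range(matrix.n_odors)]
    per_odor_off = [tab_off.for_odor(s) for s in range(matrix.n_odors)]

    records: list[PairRecord] = []
    for a in range(matrix.n_odors):
        for b in range(a + 1, matrix.n_odors):
            m_on = pair_metrics(per_odor_on[a], per_odor_on[b], t_bin=params.t_bin)
            m_off = pair_metrics(per_odor_off[a], per_odor_off[b], t_bin=params.t_bin)
            cr_on = pair_classification_rate(
                per_odor_on[a], per_odor_on[b], n_train, n_test, seed=seed
            )
            cr_off = pair_classification_rate(
                per_odor_off[a], per_odor_off[b], n_train, n_test, seed=seed
            )
            records.append(
                PairRecord(
                    odor_a=a,
                    odor_b=b,
                    correct_with=cr_on,
                    correct_without=cr_off,
                    distance_with=m_on.distance,
                    distance_without=m_off.distance,
                    variance_with=m_on.mean_variance,
                    variance_without=m_off.mean_variance,
                    rate_with=m_on.mean_rate,
                    rate_without=m_off.mean_rate,
                    category=_categorize(m_on, m_off, cr_on, cr_off),
                )
            )

    rows = []
    n_pairs = len(records)
    for cat in sorted({r.category for r in records}):
        sub = [r for r in records if r.category == cat]
        rows.append(
            {
                "category": cat,
                "ratio_pct": 100.0 * len(sub) / n_pairs,
                "rate_without_hz": np.mean([r.rate_without for r in sub]),
                "rate_with_hz": np.mean([r.rate_with for r in sub]),
                "d_rate_hz": np.mean([r.rate_with - r.rate_without for r in sub]),
                "d_correct_pct": np.mean(
                    [r.correct_with - r.correct_without for r in sub]
                ),
                "d_variance": np.mean(
                    [r.variance_with - r.variance_without for r in sub]
                ),
                "d_distance": np.mean(
                    [r.distance_with - r.distance_without for r in sub]
                ),
            }
        )
    return records, pd.DataFrame(rows)


@dataclass(frozen=True)
class PairProjection:
    """Two-PC view of one odor pair with and without lateral inhibition.

    Coordinates are projections of held-out trial responses onto the two
    leading principal components of the pooled (with + without) trial set.
    ``silent_point`` / ``max_point`` are the projected corners of response
    space where every PN is silent or firing at its maximal rate, and each
    condition's ``boundary`` is the fitted SVM hyperplane projected into
    the PC plane as ``(a1, a2, c)`` with ``a1*z1 + a2*z2 + c = 0``.
    """

    proj_a_with: np.ndarray
    proj_b_with: np.ndarray
    proj_a_without: np.ndarray
    proj_b_without: np.ndarray
    silent_point: np.ndarray
    max_point: np.ndarray
    boundary_with: tuple[float, float, float]
    boundary_without: tuple[float, float, float]
    explained_variance_ratio: np.ndarray


def pca_pair_view(
    counts_a_with,
    counts_b_with,
    counts_a_without,
    counts_b_without,
    max_count: float,
    train_fraction: float = 0.5,
    seed: int = 0,
    C: float = 1.0,
) -> PairProjection:
    """Project one odor pair's responses onto shared principal components.

    ``max_count`` is the expected bin count of a PN firing at its maximum
    rate (``r_max * t_bin``), defining the all-maximal reference corner.
    Both conditions share the PCA axes (fitted on the pooled trial set) so
    their geometry is directly comparable.
    """
    blocks = [
        _counts(x)
        for x in (counts_a_with, counts_b_with, counts_a_without, counts_b_without)
    ]
    if min(len(b) for b in blocks) < 2:
        raise ValueError("need at least two trials per odor and condition")
    pooled = np.vstack(blocks)
    if np.allclose(pooled.var(axis=0), 0.0):
        raise ValueError("zero-variance responses cannot be projected")
    pca = PCA(n_components=2).fit(pooled)

    def split(block):
        n_train = max(1, int(round(train_fraction * len(block))))
        return block[:n_train], block[n_train:] if len(block) > n_train else block

    def boundary(a, b):
        a_tr, _ = split(a)
        b_tr, _ = split(b)
        clf = SVC(kernel="linear", C=C).fit(
            np.vstack([a_tr, b_tr]), np.repeat([0, 1], [len(a_tr), len(b_tr)])
        )
        w = clf.coef_[0]
        coef2 = pca.components_ @ w
        c = float(w @ pca.mean_ + clf.intercept_[0])
        return (float(coef2[0]), float(coef2[1]), c)

    a_w, b_w, a_o, b_o = blocks
    n_units = pooled.shape[1]
    return PairProjection(
        proj_a_with=pca.transform(split(a_w)[1]),
        proj_b_with=pca.transform(split(b_w)[1]),
        proj_a_without=pca.transform(split(a_o)[1]),
        proj_b_without=pca.transform(split(b_o)[1]),
        silent_point=pca.transform(np.zeros((1, n_units)))[0],
        max_point=pca.transform(np.full((1, n_units), float(max_count)))[0],
        boundary_with=boundary(a_w, b_w),
        boundary_without=boundary(a_o, b_o),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
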