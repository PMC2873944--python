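"""Mapping mutual information over the circuit's two free parameters.

The analyses here sweep the intraglomerular transformation shape ``beta``
and the lateral strength ``w_lat``, locate the information maxima —
``peak i`` (concave transformation, inhibitory lateral input), ``peak e``
(convex, excitatory) and ``point n`` (best no-lateral-input model) — and
summarize how a chosen operating point reshapes the ORN-to-PN rate
transformation and the distribution of PN response magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .circuit import CircuitParams, run_ensemble
from .info_decoded import decoded_mi_experiment
from .info_exact import InfoResult, estimate_conditional, mutual_information_exact
from .odors import OdorResponseMatrix

__all__ = [
    "SweepGrid",
    "PeakReport",
    "TransformSummary",
    "sweep_mi",
    "find_peaks",
    "response_transform_summary",
    "threshold_experiment",
    "normalized_entropy",
    "DEFAULT_BETA_GRID",
    "DEFAULT_W_GRID",
]

# Default grids: beta spans concave through convex; the lateral grid is
# symmetric and scaled so its strongest inhibition roughly halves mean PN
# output on the default synthetic ensemble.
DEFAULT_BETA_GRID = (0.3, 0.5, 0.7, 1.0, 1.4, 2.0)
DEFAULT_W_GRID = (-2.0, -1.0, 0.0, 1.0, 2.0)


@dataclass(frozen=True)
class SweepGrid:
    """MI (bits) on a (beta, w_lat) grid; ``mi[i, j]`` is beta i, w j."""

    beta_values: tuple[float, ...]
    w_values: tuple[float, ...]
    mi: np.ndarray
    estimator: str
    info: tuple | None = None  # per-cell InfoResult rows when exact

    def __post_init__(self) -> None:
        mi = np.asarray(self.mi, dtype=float)
        if mi.shape != (len(self.beta_values), len(self.w_values)):
            raise ValueError("mi shape must be |beta_values| x |w_values|")
        if np.any(mi < -1e-12):
            raise ValueError("MI entries must be non-negative")
        object.__setattr__(self, "mi", mi)


@dataclass(frozen=True)
class PeakReport:
    """Region-restricted grid argmaxes of a sweep.

    ``peak_i``: (beta, w_lat, mi) best cell with beta < 1 and w_lat < 0.
    ``peak_e``: (beta, w_lat, mi) best cell with beta > 1 and w_lat > 0.
    ``point_n``: (beta, mi) best cell on the w_lat = 0 line.
    Ties are broken toward smaller |w_lat|, then smaller beta.
    """

    peak_i: tuple[float, float, float]
    peak_e: tuple[float, float, float]
    point_n: tuple[float, float]


def sweep_mi(
    matrix: OdorResponseMatrix,
    params: CircuitParams,
    beta_grid=DEFAULT_BETA_GRID,
    w_grid=DEFAULT_W_GRID,
    estimator: str = "exact",
    n_trials: int = 400,
    n_train: int = 200,
    n_test: int = 200,
    seed: int = 0,
    factorized: bool = True,
) -> SweepGrid:
    """MI at every (beta, w_lat) grid point.

    The same master seed is used at every cell (common random numbers), so
    the surface is not roughened by independent simulation noise.  The
    ``exact`` estimator uses plug-in enumeration over ``n_trials`` trials
    per odor; ``decoded`` uses the SVM confusion-matrix bound with
    ``n_train``/``n_test`` trials per odor.
    """
    beta_grid = tuple(float(b) for b in beta_grid)
    w_grid = tuple(float(w) for w in w_grid)
    if not beta_grid or not w_grid:
        raise ValueError("grids must be non-empty")
    if estimator not in ("exact", "decoded"):
        raise ValueError("estimator must be 'exact' or 'decoded'")
    mi = np.zeros((len(beta_grid), len(w_grid)))
    info_rows = []
    for i, b in enumerate(beta_grid):
        row = []
        for j, w in enumerate(w_grid):
            p = params.with_(beta=b, w_lat=w)
            if estimator == "exact":
                tab = run_ensemble(matrix, p, n_trials, seed=seed)
                res = mutual_information_exact(
                    estimate_conditional(tab, factorized=factorized)
                )
                mi[i, j] = res.mutual_information
                row.append(res)
            else:
                mi[i, j] = decoded_mi_experiment(
                    matrix, p, n_train=n_train, n_test=n_test, seed=seed
                )
        info_rows.append(tuple(row))
    info = tuple(info_rows) if estimator == "exact" else None
    return SweepGrid(beta_grid, w_grid, mi, estimator, info)


def _region_argmax(grid: SweepGrid, mask: np.ndarray) -> tuple[int, int]:
    if not mask.any():
        raise ValueError("requested region is absent from the grid")
    mi = np.where(mask, grid.mi, -np.inf)
    best = mi.max()
    cand = np.argwhere(mi == best)
    w = np.asarray(grid.w_values)
    beta = np.asarray(grid.beta_values)
    order = sorted(cand, key=lambda ij: (abs(w[ij[1]]), beta[ij[0]]))
    i, j = order[0]
    return int(i), int(j)


def find_peaks(grid: SweepGrid) -> PeakReport:
    """Locate peak i, peak e, and point n on a sweep grid.

    Requires the grid to cover the concave-inhibitory quadrant, the
    convex-excitatory quadrant, and the w_lat = 0 line.
    """
    beta = np.asarray(grid.beta_values)
    w = np.asarray(grid.w_values)
    bb, ww = np.meshgrid(beta, w, indexing="ij")
    i_i, j_i = _region_argmax(grid, (bb < 1) & (ww < 0))
    i_e, j_e = _region_argmax(grid, (bb > 1) & (ww > 0))
    i_n, j_n = _region_argmax(grid, ww == 0)
    return PeakReport(
        peak_i=(float(beta[i_i]), float(w[j_i]), float(grid.mi[i_i, j_i])),
        peak_e=(float(beta[i_e]), float(w[j_e]), float(grid.mi[i_e, j_e])),
        point_n=(float(beta[i_n]), float(grid.mi[i_n, j_n])),
    )


def normalized_entropy(values, n_bins: int = 20, lo: float = 0.0,
                       hi: float | None = None) -> float:
    """Entropy of the binned value distribution, normalized by log2(n_bins).

    Used as the flatness measure for response-magnitude histograms: 1 means
    perfectly uniform use of the dynamic range, 0 means a single bin.
    """
    values = np.asarray(values, dtype=float)
    if hi is None:
        hi = float(values.max()) or 1.0
    h, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = h / h.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0))
    return float(ent / np.log2(n_bins))


@dataclass(frozen=True)
class TransformSummary:
    """ORN-to-PN rate transformation and PN response histogram at one point.

    ``orn_rates`` / ``pn_rates`` pair every (glomerulus, odor) input rate
    with the trial-averaged PN output rate (Hz); ``fit_a``/``fit_b`` are the
    least-squares parameters of the saturating-exponential curve
    ``a * (1 - exp(-r/b))``; the histogram uses ``bin_width`` Hz bins over
    ``[0, r_max]``.  ``pn_rates_no_lateral`` is the companion with the
    lateral pathway removed (w_lat = 0).
    """

    orn_rates: np.ndarray
    pn_rates: np.ndarray
    pn_rates_no_lateral: np.ndarray
    fit_a: float
    fit_b: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    flatness: float = field(default=float("nan"))


def response_transform_summary(
    matrix: OdorResponseMatrix,
    params: CircuitParams,
    n_trials: int = 200,
    seed: int = 0,
    bin_width: float = 10.0,
) -> TransformSummary:
    """Measure the realized ORN->PN transformation at one parameter point."""
    def mean_rates(p: CircuitParams) -> np.ndarray:
        tab = run_ensemble(matrix, p, n_trials, seed=seed)
        # (odor, glomerulus) mean rate in Hz, averaged over trials and PNs
        out = np.empty((matrix.n_odors, matrix.n_receptors))
        for s in range(matrix.n_odors):
            block = tab.for_odor(s) / p.t_bin
            out[s] = block.reshape(len(block), matrix.n_receptors, p.n_pn).mean(
                axis=(0, 2)
            )
        return out

    pn = mean_rates(params)
    pn_off = mean_rates(params.with_(w_lat=0.0))
    orn = matrix.rates.T  # (odor, glomerulus)

    def satexp(r, a, b):
        return a * (1.0 - np.exp(-r / b))

    try:
        (fit_a, fit_b), _ = curve_fit(
            satexp, orn.ravel(), pn.ravel(),
            p0=(params.r_max, 50.0),
            bounds=([1e-6, 1e-6], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError:  # pragma: no cover - ill-conditioned degenerate data
        fit_a, fit_b = float("nan"), float("nan")
    edges = np.arange(0.0, params.r_max + bin_width, bin_width)
    # sampling noise can push a trial-mean past r_max; fold it into the top bin
    clipped = np.minimum(pn.ravel(), params.r_max)
    hist, _ = np.histogram(clipped, bins=edges)
    flat = normalized_entropy(clipped, n_bins=20, lo=0.0, hi=params.r_max)
    return TransformSummary(
        orn_rates=orn.ravel(),
        pn_rates=pn.ravel(),
        pn_rates_no_lateral=pn_off.ravel(),
        fit_a=float(fit_a),
        fit_b=float(fit_b),
        hist_counts=hist,
        hist_edges=edges,
        flatness=flat,
    )


def threshold_experiment(
    matrix: OdorResponseMatrix,
    params: CircuitParams,
    theta_grid,
    mode: str = "fixed-beta-curve",
    beta_grid=DEFAULT_BETA_GRID,
    w_grid=DEFAULT_W_GRID,
    estimator: str = "decoded",
    n_trials: int = 400,
    n_train: int = 200,
    n_test: int = 200,
    seed: int = 0,
):
    """Effect of a static PN firing threshold on mutual information.

    ``fixed-beta-curve`` returns MI over ``theta_grid`` with beta and w_lat
    held at ``params`` (a static-inhibition dose-response curve);
    ``full-grid-per-theta`` returns one (beta, w_lat) sweep per theta so the
    interplay of threshold and lateral input can be mapped.
    """
    theta_grid = [float(t) for t in theta_grid]
    if not theta_grid:
        raise ValueError("theta_grid must be non-empty")
    for t in theta_grid:
        if not 0 <= t < params.x_max:
            raise ValueError("theta values must satisfy 0 <= theta < x_max")
    if mode == "fixed-beta-curve":
        out = []
        for t in theta_grid:
            p = params.with_(theta=t)
            if estimator == "decoded":
                mi = decoded_mi_experiment(
                    matrix, p, n_train=n_train, n_test=n_test, seed=seed
                )
            else:
                tab = run_ensemble(matrix, p, n_trials, seed=seed)
                mi = mutual_information_exact(
                    estimate_conditional(tab)
                ).mutual_information
            out.append((t, float(mi)))
        return out
    if mode == "full-grid-per-theta":
        return [
            sweep_mi(
                matrix, params.with_(theta=t), beta_grid, w_grid,
                estimator=estimator, n_trials=n_trials,
                n_train=n_train, n_test=n_test, seed=seed,
            )
            for t in theta_grid
        ]
    raise ValueError("mode must be 'fixed-beta-curve' or 'full-grid-per-theta'")
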