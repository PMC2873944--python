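"""Plug-in mutual information between odors and PN spike-count patterns.

The response of the circuit to one presentation is the vector of capped PN
spike counts; its information about the odor ensemble is

    I = H - H_noise,
    H       = -sum_r P(r) log2 P(r),          P(r) = sum_s P(s) P(r|s)
    H_noise = sum_s P(s) [ -sum_r P(r|s) log2 P(r|s) ],

with the sums running over all (cap+1)**n_units activity patterns and a
uniform odor prior unless stated otherwise.  ``P(r|s)`` is the empirical
(plug-in) distribution over a finite number of simulated trials; no bias
correction is applied by default.

Because a joint table over patterns cannot be populated from a few hundred
trials, the default estimate factorizes ``P(r|s)`` into per-PN marginals
(conditional independence given the odor — exact for this circuit when LN
spiking noise is absent, an approximation otherwise).  Joint-table
estimation is kept for small instances and cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitParams, SpikeCountTable, run_ensemble
from .odors import OdorResponseMatrix

__all__ = [
    "ConditionalDistribution",
    "InfoResult",
    "estimate_conditional",
    "mutual_information_exact",
    "entropy_decomposition_curve",
    "entropy_bits",
]

DEFAULT_PATTERN_CEILING = 10_000_000


def entropy_bits(p: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Shannon entropy in bits; zero-probability terms contribute nothing."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    out = -terms.sum(axis=axis)
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class ConditionalDistribution:
    """Estimated P(response pattern | odor) from simulated trials.

    In factorized form ``tables`` is ``(S, n_units, cap+1)`` of per-PN
    marginals; in joint form it is ``(S, (cap+1)**n_units)`` over
    mixed-radix pattern indices (unit 0 most significant).
    """

    tables: np.ndarray
    cap: int
    n_units: int
    factorized: bool
    n_trials: np.ndarray  # per-odor trial counts

    def __post_init__(self) -> None:
        t = np.asarray(self.tables, dtype=float)
        if np.any(t < 0):
            raise ValueError("probabilities must be non-negative")
        sums = t.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each probability table must sum to 1")
        object.__setattr__(self, "tables", t)

    @property
    def n_odors(self) -> int:
        return self.tables.shape[0]

    @property
    def n_patterns(self) -> int:
        return (self.cap + 1) ** self.n_units


@dataclass(frozen=True)
class InfoResult:
    """Entropy decomposition of a response ensemble, in bits."""

    entropy: float
    noise_entropy: float

    @property
    def mutual_information(self) -> float:
        return self.entropy - self.noise_entropy


def estimate_conditional(
    table: SpikeCountTable,
    cap: int | None = None,
    factorized: bool = True,
) -> ConditionalDistribution:
    """Empirical per-odor response distribution from a spike-count table."""
    cap = table.cap if cap is None else cap
    n_odors = table.n_odors
    n_units = table.n_units
    n_trials = np.array([(table.odor_index == s).sum() for s in range(n_odors)])
    if np.any(n_trials == 0):
        missing = int(np.flatnonzero(n_trials == 0)[0])
        raise ValueError(f"odor {missing} has no trials")
    if factorized:
        out = np.zeros((n_odors, n_units, cap + 1))
        for s in range(n_odors):
            block = table.for_odor(s)
            for u in range(n_units):
                out[s, u] = np.bincount(block[:, u], minlength=cap + 1) / len(block)
    else:
        n_pat = (cap + 1) ** n_units
        if n_pat > DEFAULT_PATTERN_CEILING:
            raise ValueError(
                f"joint table over {n_pat} patterns exceeds the ceiling; "
                "use factorized estimation or the decoding estimator "
                "(info_decoded)"
            )
        radix = (cap + 1) ** np.arange(n_units - 1, -1, -1)
        out = np.zeros((n_odors, n_pat))
        for s in range(n_odors):
            block = table.for_odor(s)
            idx = block @ radix
            out[s] = np.bincount(idx, minlength=n_pat) / len(block)
    return ConditionalDistribution(
        tables=out,
        cap=cap,
        n_units=n_units,
        factorized=factorized,
        n_trials=n_trials,
    )


def _factorized_pattern_probs(marginals: np.ndarray) -> np.ndarray:
    """Probabilities of all patterns from per-unit marginals.

    ``marginals`` is ``(n_units, cap+1)``; returns ``((cap+1)**n_units,)``
    in mixed-radix order (unit 0 most significant).
    """
    out = np.ones(1)
    for m in marginals:
        out = np.multiply.outer(out, m).ravel()
    return out


def mutual_information_exact(
    cond: ConditionalDistribution,
    prior: np.ndarray | None = None,
    max_patterns: int = DEFAULT_PATTERN_CEILING,
) -> InfoResult:
    """Entropy, noise entropy, and MI by full pattern enumeration.

    The noise entropy of a factorized conditional is the prior-weighted sum
    of per-PN marginal entropies; the total entropy always requires
    enumerating the pattern mixture, which is refused above
    ``max_patterns`` (use the decoding estimator for larger populations).
    """
    S = cond.n_odors
    if prior is None:
        prior = np.full(S, 1.0 / S)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (S,) or abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < 0):
        raise ValueError("prior must be a probability vector over odors")
    if cond.n_patterns > max_patterns:
        raise ValueError(
            f"{cond.n_patterns} patterns exceed max_patterns={max_patterns}; "
            "use the decoding estimator (info_decoded) instead"
        )
    if cond.factorized:
        noise = float(
            prior @ entropy_bits(cond.tables, axis=-1).sum(axis=-1)
        )
        mix = np.zeros(cond.n_patterns)
        for s in range(S):
            if prior[s] > 0:
                mix += prior[s] * _factorized_pattern_probs(cond.tables[s])
        total = entropy_bits(mix)
    else:
        noise = float(prior @ entropy_bits(cond.tables, axis=-1))
        total = entropy_bits(prior @ cond.tables)
    return InfoResult(entropy=float(total), noise_entropy=noise)


def entropy_decomposition_curve(
    matrix: OdorResponseMatrix,
    params: CircuitParams,
    vary: str,
    grid,
    n_trials: int = 400,
    seed: int = 0,
    factorized: bool = True,
) -> list[InfoResult]:
    """Entropy / noise-entropy / MI along a 1-D parameter grid.

    ``vary`` is one of ``beta``, ``w_lat``, ``theta``; all other parameters
    are held fixed and the same master seed is reused at every grid point
    (common random numbers, so differences along the curve are not masked
    by simulation noise).
    """
    if vary not in ("beta", "w_lat", "theta"):
        raise ValueError("vary must be 'beta', 'w_lat' or 'theta'")
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    out = []
    for value in grid:
        p = params.with_(**{vary: value})
        tab = run_ensemble(matrix, p, n_trials, seed=seed)
        cond = estimate_conditional(tab, factorized=factorized)
        out.append(mutual_information_exact(cond))
    return out
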