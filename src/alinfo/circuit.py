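"""Stochastic simulation of the glomerular ORN -> (LN) -> PN circuit.

The model is a two-layer feed-forward network with a shared lateral pathway:

* Each glomerulus holds ``n_orn`` olfactory receptor neurons (ORNs) firing
  as independent Poisson processes at the odor-specific rate of that
  receptor type (rates are time-independent).
* Every spike feeds an exponential synaptic filter with time constant
  ``tau``; a neuron's "drive" is the filtered activity of its presynaptic
  population, averaged over that population so that population sizes set
  noise levels but not operating points.
* ``n_ln`` local neurons (LNs) each receive the mean filtered activity of
  *all* ORNs scaled by ``g_ln`` and fire Poisson spikes at a rate linear in
  that drive (floored at zero).
* Each projection neuron (PN) receives the mean filtered activity of its
  own glomerulus's ORNs times ``w_ff`` plus the mean filtered LN activity
  times the signed lateral strength ``w_lat`` (negative = inhibitory).
  Its firing rate follows a threshold-power-saturation nonlinearity
  (:func:`pn_rate`) and it emits Poisson spikes at that time-varying rate.

A trial is one stimulus presentation: filters warm up for ``t_warmup``
seconds, then PN spikes are counted in a single ``t_bin`` window and capped
at ``cap`` (a pattern-space ceiling for the entropy computations).

Only two parameters are swept in the information analyses: ``beta``, the
shape of the intraglomerular transformation (concave for ``beta < 1``,
convex for ``beta > 1``), and ``w_lat``, the lateral strength ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .odors import OdorResponseMatrix

__all__ = [
    "CircuitParams",
    "SpikeCountTable",
    "pn_rate",
    "filtered_drive",
    "exp_filter",
    "simulate_trial",
    "run_ensemble",
]

_TRIAL_CHUNK = 4096  # trials simulated per vectorized block (memory bound)


@dataclass(frozen=True)
class CircuitParams:
    """All model constants plus the two swept parameters.

    Units: times in seconds, rates in Hz, drives in units of the
    per-ORN-averaged filtered activity (a glomerulus driven at rate ``r``
    contributes a mean feed-forward drive of ``r * tau * w_ff``, so with the
    defaults PN saturation onsets near ``x_max / tau`` = 200 Hz of ORN
    input).
    """

    beta: float = 1.0          # intraglomerular transformation shape
    w_lat: float = 0.0         # lateral strength ratio (sign = valence)
    theta: float = 0.0         # PN input threshold
    x_max: float = 0.4         # PN saturation input
    r_max: float = 200.0       # maximum PN rate, Hz
    tau: float = 0.002         # synaptic time constant, s
    n_orn: int = 40            # ORNs per glomerulus
    n_pn: int = 1              # PNs per glomerulus
    n_ln: int = 10             # LN count
    g_ln: float = 400.0        # ORN->LN gain (drive units -> Hz)
    w_ff: float = 1.0          # ORN->PN weight, scale anchor
    dt: float = 2e-4           # simulation step, s
    t_warmup: float = 0.020    # filter warm-up before counting, s
    t_bin: float = 0.010       # spike-counting bin, s
    cap: int = 5               # spike-count ceiling per bin
    deterministic_ln: bool = False  # replace LN spiking by its expectation

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not (self.x_max > self.theta >= 0):
            raise ValueError("require x_max > theta >= 0")
        if self.r_max <= 0 or self.tau <= 0 or self.dt <= 0 or self.t_bin <= 0:
            raise ValueError("r_max, tau, dt, t_bin must be > 0")
        if self.t_warmup < 0 or self.g_ln < 0:
            raise ValueError("t_warmup and g_ln must be >= 0")
        if min(self.n_orn, self.n_pn, self.n_ln) < 1:
            raise ValueError("population sizes must be >= 1")
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        if self.dt > self.tau / 2:
            raise ValueError("dt must be <= tau/2 for the synaptic filter")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "CircuitParams":
        """A copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SpikeCountTable:
    """Per-trial capped PN spike-count vectors with stimulus labels.

    ``counts`` has one row per trial and one column per PN
    (``n_glomeruli * n_pn`` columns, glomerulus-major); every entry lies in
    ``{0, ..., cap}``.  ``seed_record`` keeps the master seed the ensemble
    was generated from.
    """

    counts: np.ndarray
    odor_index: np.ndarray
    cap: int
    t_bin: float
    n_pn: int
    seed_record: int | None = None
    odor_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        odor = np.asarray(self.odor_index, dtype=np.int64)
        if counts.ndim != 2 or odor.shape != (counts.shape[0],):
            raise ValueError("counts must be trials x PNs with one label per trial")
        if counts.size and (counts.min() < 0 or counts.max() > self.cap):
            raise ValueError(f"counts must lie in [0, cap={self.cap}]")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "odor_index", odor)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    @property
    def n_odors(self) -> int:
        return int(self.odor_index.max()) + 1 if self.odor_index.size else 0

    def for_odor(self, s: int) -> np.ndarray:
        return self.counts[self.odor_index == s]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, columns=[f"pn{i}" for i in range(self.n_units)]
        )
        df.insert(0, "odor", self.odor_index)
        return df


def pn_rate(input_strength, params: CircuitParams):
    """PN firing rate (Hz) from total synaptic input.

    Zero below ``theta``, ``r_max`` above ``x_max``, and in between
    ``r_max * ((x - theta)/(x_max - theta))**beta`` — strictly increasing,
    concave for ``beta < 1`` and convex for ``beta > 1``.  Accepts scalars
    or arrays.
    """
    x = np.asarray(input_strength, dtype=float)
    frac = np.clip((x - params.theta) / (params.x_max - params.theta), 0.0, 1.0)
    out = params.r_max * frac**params.beta
    return out if out.ndim else float(out)


def filtered_drive(spike_times: Sequence[float], tau: float, t: float) -> float:
    """Summed exponential synaptic kernel at time ``t``.

    Each past spike contributes ``exp(-(t - t_spike)/tau)``; spikes after
    ``t`` contribute nothing.
    """
    times = np.asarray(spike_times, dtype=float)
    times = times[times <= t]
    if times.size == 0:
        return 0.0
    return float(np.exp(-(t - times) / tau).sum())


def exp_filter(counts: np.ndarray, dt: float, tau: float, axis: int = 0) -> np.ndarray:
    """Discrete exponential synaptic filter of per-step spike counts.

    Implements ``x_t = exp(-dt/tau) * x_{t-1} + c * counts_t`` with
    ``c = tau * (1 - exp(-dt/tau)) / dt``, the step-averaged kernel value
    for a spike falling uniformly within its step.  With this convention the
    stationary mean of the filtered output of a rate-``r`` Poisson source is
    exactly ``r * tau`` (Campbell's theorem), independent of ``dt``.
    """
    decay = np.exp(-dt / tau)
    c = tau * (1.0 - decay) / dt
    return lfilter([c], [1.0, -decay], np.asarray(counts, dtype=float), axis=axis)


def _simulate_block(
    rates_hz: np.ndarray,
    params: CircuitParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one counting bin for a block of trials.

    ``rates_hz`` is ``(n_trials, n_glomeruli)`` of ORN rates (each trial may
    present a different odor).  Returns capped PN counts
    ``(n_trials, n_glomeruli * n_pn)``.
    """
    p = params
    n_trials, n_glom = rates_hz.shape
    steps_warm = int(round(p.t_warmup / p.dt))
    steps_bin = int(round(p.t_bin / p.dt))
    n_steps = steps_warm + steps_bin

    out = np.empty((n_trials, n_glom * p.n_pn), dtype=np.int64)
    for lo in range(0, n_trials, _TRIAL_CHUNK):
        hi = min(lo + _TRIAL_CHUNK, n_trials)
        block = hi - lo
        lam_orn = p.n_orn * rates_hz[lo:hi, None, :] * p.dt  # (block, 1, G)
        orn_counts = rng.poisson(np.broadcast_to(lam_orn, (block, n_steps, n_glom)))
        x = exp_filter(orn_counts / p.n_orn, p.dt, p.tau, axis=1)  # per-ORN mean

        ln_rate = np.maximum(p.g_ln * x.mean(axis=2), 0.0)  # (block, steps), Hz
        lam_ln = p.n_ln * ln_rate * p.dt
        ln_counts = lam_ln if p.deterministic_ln else rng.poisson(lam_ln)
        y = exp_filter(ln_counts / p.n_ln, p.dt, p.tau, axis=1)  # per-LN mean

        drive = p.w_ff * x + p.w_lat * y[:, :, None]
        rate_pn = pn_rate(drive, p)  # (block, steps, G)
        # Given the rate path, the bin count of each PN is Poisson with the
        # integrated intensity over the counting window.
        lam_bin = rate_pn[:, steps_warm:, :].sum(axis=1) * p.dt  # (block, G)
        counts = rng.poisson(np.repeat(lam_bin, p.n_pn, axis=1))
        out[lo:hi] = np.minimum(counts, p.cap)
    return out


def simulate_trial(
    odor_rates: Sequence[float],
    params: CircuitParams,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """One stimulus presentation; returns capped PN counts, one per PN.

    ``odor_rates`` holds the ORN firing rate (Hz) of each glomerulus's
    receptor type for the presented odor.
    """
    rates = np.asarray(odor_rates, dtype=float)
    if rates.ndim != 1:
        raise ValueError("odor_rates must be a 1-D vector over glomeruli")
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise ValueError("odor rates must be finite and >= 0")
    rng = np.random.default_rng(seed)
    return _simulate_block(rates[None, :], params, rng)[0]


def run_ensemble(
    matrix: OdorResponseMatrix,
    params: CircuitParams,
    n_trials: int,
    seed: int = 0,
) -> SpikeCountTable:
    """Simulate ``n_trials`` presentations of every odor in the matrix.

    Each odor gets an independent RNG substream spawned from the master
    seed, so the table is bitwise-reproducible and per-odor blocks do not
    share randomness.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rates = matrix.rates  # (G, S)
    n_glom, n_odors = rates.shape
    streams = np.random.SeedSequence(seed).spawn(n_odors)
    counts = np.empty((n_odors * n_trials, n_glom * params.n_pn), dtype=np.int64)
    odor_index = np.repeat(np.arange(n_odors), n_trials)
    for s in range(n_odors):
        rng = np.random.default_rng(streams[s])
        block = np.broadcast_to(rates[:, s], (n_trials, n_glom))
        counts[s * n_trials : (s + 1) * n_trials] = _simulate_block(
            block, params, rng
        )
    return SpikeCountTable(
        counts=counts,
        odor_index=odor_index,
        cap=params.cap,
        t_bin=params.t_bin,
        n_pn=params.n_pn,
        seed_record=seed,
        odor_labels=matrix.odor_labels,
    )
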