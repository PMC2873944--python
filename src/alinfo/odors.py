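"""ORN odor-response matrices: loading, synthesis, and glomerulus subsetting.

The stimulus ensemble for the antennal-lobe model is a matrix of mean
olfactory-receptor-neuron (ORN) firing rates, one row per receptor type
(equivalently, per glomerulus) and one column per odor.  Published
measurements of this kind cover 24 receptor types and ~110 odors and show a
characteristic shape: most responses sit at the weak end of the dynamic
range, with a minority of strong responses reaching a few hundred Hz.  When
no measured matrix is supplied, :func:`synthesize_orn_matrix` draws a
surrogate with that statistical signature from a truncated two-component
exponential mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OdorResponseMatrix",
    "load_orn_matrix",
    "synthesize_orn_matrix",
    "subset_glomeruli",
    "truncated_exponential_mean",
]


@dataclass(frozen=True)
class OdorResponseMatrix:
    """Mean ORN firing rates (Hz), receptor types x odors.

    Parameters
    ----------
    rates
        Non-negative, finite array of shape ``(n_receptors, n_odors)``.
    receptor_labels, odor_labels
        Row / column identifiers; defaulted to ``or0..`` / ``odor0..``.
    """

    rates: np.ndarray
    receptor_labels: tuple[str, ...] = field(default=())
    odor_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.ndim != 2:
            raise ValueError(f"rates must be 2-D, got shape {rates.shape}")
        if rates.shape[0] < 1:
            raise ValueError("need at least one receptor type")
        if rates.shape[1] < 2:
            raise ValueError(
                "need at least two odors (mutual information is undefined "
                "for a single stimulus)"
            )
        if not np.all(np.isfinite(rates)):
            i, j = np.argwhere(~np.isfinite(rates))[0]
            raise ValueError(f"non-finite rate at receptor {i}, odor {j}")
        if np.any(rates < 0):
            i, j = np.argwhere(rates < 0)[0]
            raise ValueError(
                f"negative rate {rates[i, j]:g} Hz at receptor {i}, odor {j}"
            )
        object.__setattr__(self, "rates", rates)
        rec = tuple(self.receptor_labels) or tuple(
            f"or{i}" for i in range(rates.shape[0])
        )
        odo = tuple(self.odor_labels) or tuple(
            f"odor{j}" for j in range(rates.shape[1])
        )
        if len(rec) != rates.shape[0]:
            raise ValueError("receptor_labels length mismatch")
        if len(odo) != rates.shape[1]:
            raise ValueError("odor_labels length mismatch")
        object.__setattr__(self, "receptor_labels", rec)
        object.__setattr__(self, "odor_labels", odo)

    @property
    def n_receptors(self) -> int:
        return self.rates.shape[0]

    @property
    def n_odors(self) -> int:
        return self.rates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rates,
            index=pd.Index(self.receptor_labels, name="receptor"),
            columns=list(self.odor_labels),
        )

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep)


def load_orn_matrix(path: str | Path, sep: str | None = None) -> OdorResponseMatrix:
    """Read an ORN rate matrix from a delimited text file.

    Layout: one header row of odor labels, one leading column of receptor
    labels, numeric body in Hz.  ``sep=None`` sniffs tab vs comma from the
    header line.

    Raises
    ------
    ValueError
        On a negative or non-numeric entry (named by receptor/odor label)
        or fewer than two odor columns.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need >= 2 odor columns, found {df.shape[1]}")
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & df.notna() | df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric entry {df.iat[i, j]!r} at receptor "
            f"{df.index[i]!r}, odor {df.columns[j]!r}"
        )
    neg = body.to_numpy() < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"{path}: negative rate {body.iat[i, j]:g} at receptor "
            f"{df.index[i]!r}, odor {df.columns[j]!r}"
        )
    return OdorResponseMatrix(
        body.to_numpy(dtype=float),
        tuple(str(x) for x in df.index),
        tuple(str(x) for x in df.columns),
    )


def _truncated_exponential(
    rng: np.random.Generator, scale: float, upper: float, size: int
) -> np.ndarray:
    # Inverse-CDF sampling of Exp(scale) conditioned on [0, upper]; keeps the
    # density continuous instead of piling clipped mass at the bound.
    if scale <= 0:
        return np.zeros(size)
    u = rng.random(size)
    cdf_upper = -np.expm1(-upper / scale)
    return -scale * np.log1p(-u * cdf_upper)


def truncated_exponential_mean(scale: float, upper: float) -> float:
    """Mean of an exponential with the given scale truncated to [0, upper]."""
    if scale <= 0:
        return 0.0
    z = -np.expm1(-upper / scale)  # P(X <= upper)
    return scale - upper * np.exp(-upper / scale) / z


def synthesize_orn_matrix(
    n_receptors: int = 24,
    n_odors: int = 110,
    weak_fraction: float = 0.85,
    weak_scale: float = 20.0,
    strong_scale: float = 120.0,
    max_rate: float = 300.0,
    seed: int | np.random.SeedSequence = 0,
) -> OdorResponseMatrix:
    """Draw a surrogate ORN rate matrix from a truncated exponential mixture.

    Each entry is independently weak (probability ``weak_fraction``,
    exponential mean ``weak_scale`` Hz) or strong (exponential mean
    ``strong_scale`` Hz), truncated to ``[0, max_rate]``.  The defaults mimic
    the measured 24-receptor x 110-odor ensemble, whose response histogram
    has its mode at the weak end of the dynamic range.
    """
    if n_receptors < 1:
        raise ValueError("n_receptors must be >= 1")
    if n_odors < 2:
        raise ValueError("n_odors must be >= 2")
    if not 0.0 <= weak_fraction <= 1.0:
        raise ValueError("weak_fraction must lie in [0, 1]")
    if weak_scale < 0 or strong_scale <= 0 or max_rate <= 0:
        raise ValueError("scales and max_rate must be positive")
    rng = np.random.default_rng(seed)
    n = n_receptors * n_odors
    weak = rng.random(n) < weak_fraction
    out = np.empty(n)
    out[weak] = _truncated_exponential(rng, weak_scale, max_rate, int(weak.sum()))
    out[~weak] = _truncated_exponential(
        rng, strong_scale, max_rate, int((~weak).sum())
    )
    return OdorResponseMatrix(out.reshape(n_receptors, n_odors))


def subset_glomeruli(
    matrix: OdorResponseMatrix, groups: Sequence[Sequence[int]]
) -> list[OdorResponseMatrix]:
    """Split a rate matrix into receptor (glomerulus) groups.

    ``groups`` is a list of disjoint receptor-index lists — e.g. 24 receptor
    types into three non-overlapping groups of eight for tractable exact MI.
    The odor axis is unchanged.
    """
    seen: set[int] = set()
    for g in groups:
        for idx in g:
            if not 0 <= idx < matrix.n_receptors:
                raise ValueError(f"receptor index {idx} out of range")
            if idx in seen:
                raise ValueError(f"receptor index {idx} appears in two groups")
            seen.add(idx)
    return [
        OdorResponseMatrix(
            matrix.rates[list(g), :],
            tuple(matrix.receptor_labels[i] for i in g),
            matrix.odor_labels,
        )
        for g in groups
    ]
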