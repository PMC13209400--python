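"""Pan-genome partition, rarefaction curves, and the openness fit.

Clusters are split into core (present in every genome), accessory
(present in at least two but not all) and unique (exactly one genome).
Pan/core rarefaction curves are built from random genome orderings and
summarised by the per-step median, and the pan curve is fitted with the
Heaps-style power law y = A * x**b; b < 1 diagnoses an open pan-genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit


@dataclass(frozen=True)
class PanPartition:
    """Core / accessory / unique split of the gene-cluster set."""

    core: frozenset[str]
    accessory: frozenset[str]
    unique: dict[str, frozenset[str]]  # genome_id -> cluster ids

    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def n_accessory(self) -> int:
        return len(self.accessory)

    @property
    def n_unique(self) -> int:
        return sum(len(v) for v in self.unique.values())

    @property
    def n_total(self) -> int:
        return self.n_core + self.n_accessory + self.n_unique

    def unique_of(self, genome_id: str) -> frozenset[str]:
        return self.unique.get(genome_id, frozenset())


@dataclass(frozen=True)
class RarefactionCurve:
    """Median pan/core sizes as genomes are added in random orders."""

    x: np.ndarray
    pan_median: np.ndarray
    core_median: np.ndarray
    n_permutations: int
    seed: int


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of y = A * x**b with the openness flag."""

    A: float
    b: float
    rss: float

    @property
    def open(self) -> bool:
        return self.b < 1.0


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[1] < 2:
        raise ValueError("presence matrix needs at least 2 genomes")
    values = matrix.to_numpy(dtype=bool)
    empty = np.flatnonzero(~values.any(axis=1))
    if empty.size:
        raise ValueError(
            f"presence matrix has all-absent row(s): {list(matrix.index[empty][:5])}"
        )


def partition(matrix: pd.DataFrame) -> PanPartition:
    """Partition clusters into core, accessory and unique sets."""
    _validate_matrix(matrix)
    values = matrix.to_numpy(dtype=bool)
    n_genomes = matrix.shape[1]
    counts = values.sum(axis=1)
    core = frozenset(matrix.index[counts == n_genomes])
    accessory = frozenset(matrix.index[(counts >= 2) & (counts < n_genomes)])
    unique: dict[str, frozenset[str]] = {}
    unique_mask = counts == 1
    if unique_mask.any():
        owner = values[unique_mask].argmax(axis=1)
        ids = matrix.index[unique_mask]
        for genome_pos in np.unique(owner):
            genome = matrix.columns[genome_pos]
            unique[genome] = frozenset(ids[owner == genome_pos])
    return PanPartition(core=core, accessory=accessory, unique=unique)


def rarefaction_curves(
    matrix: pd.DataFrame, n_permutations: int = 20, seed: int = 0
) -> RarefactionCurve:
    """Median pan/core curves over random genome addition orders.

    For each permutation of the genome columns the cumulative union
    (pan) and intersection (core) sizes are recorded at x = 1..N; the
    per-x median across permutations is returned.  The median of an even
    number of values is the mean of the two central ones.
    """
    _validate_matrix(matrix)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    values = matrix.to_numpy(dtype=bool)
    n_genomes = values.shape[1]
    rng = np.random.default_rng(seed)
    pan = np.empty((n_permutations, n_genomes), dtype=np.int64)
    core = np.empty((n_permutations, n_genomes), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n_genomes)
        cum_any = np.logical_or.accumulate(values[:, order], axis=1)
        cum_all = np.logical_and.accumulate(values[:, order], axis=1)
        pan[p] = cum_any.sum(axis=0)
        core[p] = cum_all.sum(axis=0)
    return RarefactionCurve(
        x=np.arange(1, n_genomes + 1),
        pan_median=np.median(pan, axis=0),
        core_median=np.median(core, axis=0),
        n_permutations=n_permutations,
        seed=seed,
    )


def fit_power_law(x, y) -> PowerLawFit:
    """Fit y = A * x**b by least squares on the original scale.

    Initialised by ordinary least squares in log-log space, then refined
    by a nonlinear pass (Levenberg-Marquardt) minimising squared error
    on the original scale, which avoids the bias of a pure log fit under
    additive noise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("power-law fit requires positive x and y")
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    a0, b0 = float(np.exp(intercept)), float(slope)
    try:
        with warnings.catch_warnings():
            # degenerate exact fits (e.g. constant y) cannot estimate a
            # covariance; the parameters themselves are still exact
            warnings.simplefilter("ignore", OptimizeWarning)
            (a_fit, b_fit), _ = curve_fit(
                lambda t, a, b: a * np.power(t, b), x, y, p0=(a0, b0), maxfev=10000
            )
    except RuntimeError:  # no convergence: keep the log-log estimate
        a_fit, b_fit = a0, b0
    rss = float(np.sum((y - a_fit * np.power(x, b_fit)) ** 2))
    return PowerLawFit(A=float(a_fit), b=float(b_fit), rss=rss)


def fit_pan_curve(curve: RarefactionCurve) -> PowerLawFit:
    """Convenience: fit the power law to a rarefaction pan curve."""
    return fit_power_law(curve.x, curve.pan_median)


def curve_frame(curve: RarefactionCurve) -> pd.DataFrame:
    """Tabular form of a rarefaction curve for TSV output."""
    return pd.DataFrame(
        {
            "n_genomes": curve.x,
            "pan_median": curve.pan_median,
            "core_median": curve.core_median,
        }
    )
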