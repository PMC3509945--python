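"""Four landscape-roughness measures and a fitness-permutation null report.

1. ``additive_deviation`` — roughness-to-slope ratio of the least-squares
   additive fit: RMS residual divided by the mean absolute per-locus
   coefficient.  0 for exactly additive landscapes.
2. ``rms_neighbor_difference`` — RMS fitness difference over all viable
   neighbor pairs (each unordered pair counted once).
3. ``peak_fraction`` — number of local maxima over number of viable
   genotypes.
4. ``mean_tree_distance`` — mean Hamming distance to the "tree component",
   the set of genotypes with at most one fitter neighbor (on which adaptive
   walks are deterministic).

Peak fraction and mean tree distance depend only on fitness ranks; the other
two scale linearly with fitness (the additive-deviation *ratio* is scale
invariant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import fsum, sqrt
from typing import Dict, Optional

import numpy as np

from .generators import permute_fitness
from .landscape import FitnessLandscape, hamming

MEASURES = (
    "additive_deviation",
    "rms_neighbor_difference",
    "peak_fraction",
    "mean_tree_distance",
)


class UnderdeterminedFitError(ValueError):
    """Too few genotypes (or a rank-deficient design) for the additive fit."""


class UndefinedMeasureError(ValueError):
    """The measure is undefined on this landscape (e.g. no neighbor pairs)."""


def additive_deviation(landscape: FitnessLandscape, log_fitness: bool = False) -> float:
    """Roughness-to-slope ratio r/s of the additive least-squares fit.

    Fits ``F(g) ~ a0 + sum_i a_i g_i`` over the viable genotypes; ``r`` is the
    RMS residual and ``s`` the mean absolute slope ``|a_i|``.  A flat fitted
    landscape (s = 0) returns ``inf`` with a warning.  With ``log_fitness``
    the fit is on ``log F`` (for multiplicative data).
    """
    genotypes = landscape.genotypes()
    n, L = len(genotypes), landscape.L
    if n < L + 2:
        raise UnderdeterminedFitError(
            f"need at least L + 2 = {L + 2} genotypes for the additive fit, have {n}"
        )
    X = np.empty((n, L + 1))
    X[:, 0] = 1.0
    X[:, 1:] = [[int(b) for b in g] for g in genotypes]
    y = np.array([landscape.fitness(g) for g in genotypes])
    if log_fitness:
        y = np.log(y)
    if np.linalg.matrix_rank(X) < L + 1:
        raise UnderdeterminedFitError("additive design matrix is rank deficient")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    residuals = y - X @ coef
    r = sqrt(float(np.mean(residuals ** 2)))
    s = float(np.mean(np.abs(coef[1:])))
    if s <= 1e-12 * float(np.mean(np.abs(y))):  # flat up to fp noise
        warnings.warn("flat additive fit (all slopes zero); r/s is infinite",
                      stacklevel=2)
        return float("inf")
    return r / s


def rms_neighbor_difference(landscape: FitnessLandscape) -> float:
    """RMS of F(g) - F(h) over all viable unordered neighbor pairs."""
    sq = []
    for g in landscape.genotypes():
        fg = landscape.fitness(g)
        for h in landscape.viable_neighbors(g):
            if g < h:  # each unordered pair once
                sq.append((fg - landscape.fitness(h)) ** 2)
    if not sq:
        raise UndefinedMeasureError("no viable neighbor pairs")
    return sqrt(fsum(sq) / len(sq))


def peak_fraction(landscape: FitnessLandscape) -> float:
    """Fraction of viable genotypes that are local maxima."""
    return len(landscape.peaks()) / len(landscape)


def mean_tree_distance(landscape: FitnessLandscape) -> float:
    """Mean Hamming distance from each genotype to the tree component
    T = {g : at most one fitter neighbor}; members of T contribute 0."""
    genotypes = landscape.genotypes()
    tree = [g for g in genotypes if len(landscape.fitter_neighbors(g)) <= 1]
    total = fsum(min(hamming(g, t) for t in tree) for g in genotypes)
    return total / len(genotypes)


@dataclass
class NullComparison:
    """Permutation-null summary for one measure.

    ``empirical_quantile`` is the fraction of permuted replicates whose
    measure is <= the observed value (descriptive, one-sided; no
    multiple-testing correction across measures)."""

    observed: float
    null_mean: float
    null_sd: float
    empirical_quantile: float
    n_permutations: int


@dataclass
class RoughnessReport:
    additive_deviation: float
    rms_neighbor_difference: float
    peak_fraction: float
    mean_tree_distance: float
    n_genotypes: int
    n_peaks: int
    null: Dict[str, NullComparison] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        return {m: getattr(self, m) for m in MEASURES}


def _all_measures(landscape: FitnessLandscape, log_fitness: bool) -> Dict[str, float]:
    return {
        "additive_deviation": additive_deviation(landscape, log_fitness=log_fitness),
        "rms_neighbor_difference": rms_neighbor_difference(landscape),
        "peak_fraction": peak_fraction(landscape),
        "mean_tree_distance": mean_tree_distance(landscape),
    }


def roughness_report(
    landscape: FitnessLandscape,
    n_permutations: int = 0,
    seed: int = 0,
    log_fitness: bool = False,
) -> RoughnessReport:
    """All four measures, plus (if requested) their distribution over
    fitness-permuted replicates and one-sided empirical quantiles."""
    observed = _all_measures(landscape, log_fitness)
    report = RoughnessReport(
        **observed,
        n_genotypes=len(landscape),
        n_peaks=len(landscape.peaks()),
    )
    if n_permutations <= 0:
        return report

    rng = np.random.default_rng(seed)
    null_values: Dict[str, list] = {m: [] for m in MEASURES}
    for _ in range(n_permutations):
        permuted = permute_fitness(landscape, seed=int(rng.integers(2 ** 63)))
        for m, v in _all_measures(permuted, log_fitness).items():
            null_values[m].append(v)
    for m in MEASURES:
        vals = np.array(null_values[m])
        report.null[m] = NullComparison(
            observed=observed[m],
            null_mean=float(np.mean(vals)),
            null_sd=float(np.std(vals)),
            empirical_quantile=float(np.mean(vals <= observed[m])),
            n_permutations=n_permutations,
        )
    return report
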