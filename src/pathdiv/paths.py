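"""Monotone-path machinery on the fitter-neighbor DAG.

Under strong-selection/weak-mutation (SSWM) dynamics a population performs an
adaptive walk: at each genotype one of the strictly fitter single-mutation
neighbors is fixed, chosen uniformly, until a local peak is reached.  The
realized trajectory is therefore a *monotone path* — fitness strictly
increases along it — and its occurrence probability is the product over all
non-terminal points of ``1 / (number of fitter neighbors)``.

This module enumerates and counts monotone paths, computes their SSWM
probabilities, the probability of reaching a given peak from each start, the
landscape-level peak-accessibility summary, and provides a seeded walk
sampler used as the simulation oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import fsum
from typing import Dict, List, Optional, Union

import numpy as np

from .landscape import FitnessLandscape, GenotypeNotFoundError, Peak

#: Default cap on the number of enumerated paths from one start.
DEFAULT_MAX_PATHS = 1_000_000


class PathOverflowError(RuntimeError):
    """Enumeration exceeded the configured path cap."""


class NonMonotonePathError(ValueError):
    """A path violated the strictly-increasing-fitness contract."""


class NotAPeakError(ValueError):
    """The requested terminal genotype is not a local peak."""


@dataclass(frozen=True)
class Path:
    """An ordered genotype sequence with unit-Hamming steps."""

    genotypes: tuple
    landscape: FitnessLandscape = field(compare=False)

    def __len__(self) -> int:
        return len(self.genotypes)

    def __iter__(self):
        return iter(self.genotypes)

    @property
    def start(self) -> str:
        return self.genotypes[0]

    @property
    def terminal(self) -> str:
        return self.genotypes[-1]

    def is_monotone(self) -> bool:
        fit = self.landscape.fitness
        steps = zip(self.genotypes, self.genotypes[1:])
        return all(
            fit(b) > fit(a) and sum(x != y for x, y in zip(a, b)) == 1
            for a, b in steps
        )


@dataclass
class PathEnsemble:
    """All monotone paths sharing one start and one terminal peak, with their
    SSWM occurrence probabilities."""

    start: str
    peak: Peak
    paths: List[Path]
    probabilities: List[float]

    def __len__(self) -> int:
        return len(self.paths)

    @property
    def total_probability(self) -> float:
        return fsum(self.probabilities)


def sswm_path_probability(path: Path) -> float:
    """Product over all points except the terminal one of
    ``1 / |fitter_neighbors|``; 1 for a length-1 path."""
    if not path.is_monotone():
        raise NonMonotonePathError(f"path {path.genotypes} is not monotone")
    prob = 1.0
    for g in path.genotypes[:-1]:
        prob /= len(path.landscape.fitter_neighbors(g))
    return prob


def enumerate_monotone_paths(
    landscape: FitnessLandscape,
    start: str,
    end: Optional[str] = None,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> List[PathEnsemble]:
    """Every maximal monotone path from ``start``, grouped by terminal peak.

    Depth-first traversal of the fitter-neighbor DAG, children visited in
    lexicographic order, so the path list is deterministic.  If ``end`` is
    given only the ensemble terminating there is returned (possibly empty
    list).  Raises :class:`PathOverflowError` when more than ``max_paths``
    maximal paths exist.
    """
    if start not in landscape:
        raise GenotypeNotFoundError(start)

    by_peak: Dict[str, List[tuple]] = {}
    probs_by_peak: Dict[str, List[float]] = {}
    n_found = 0

    # iterative DFS carrying (path-so-far, probability-so-far)
    stack = [((start,), 1.0)]
    while stack:
        prefix, prob = stack.pop()
        here = prefix[-1]
        fitter = sorted(landscape.fitter_neighbors(here))
        if not fitter:
            if end is None or here == end:
                n_found += 1
                if n_found > max_paths:
                    raise PathOverflowError(
                        f"more than {max_paths} monotone paths from {start!r}; "
                        "raise max_paths or use sample_sswm_walk"
                    )
                by_peak.setdefault(here, []).append(prefix)
                probs_by_peak.setdefault(here, []).append(prob)
            continue
        step = prob / len(fitter)
        # reversed so lexicographically smallest child is expanded first
        for child in reversed(fitter):
            stack.append((prefix + (child,), step))

    fmax = landscape.max_fitness()
    ensembles = []
    for peak_g in sorted(by_peak):
        peak = Peak(peak_g, landscape.fitness(peak_g),
                    is_global=(landscape.fitness(peak_g) == fmax))
        paths = [Path(p, landscape) for p in by_peak[peak_g]]
        ensembles.append(
            PathEnsemble(start=start, peak=peak, paths=paths,
                         probabilities=probs_by_peak[peak_g])
        )
    return ensembles


def _as_peak_genotype(landscape: FitnessLandscape, end: Union[str, Peak]) -> str:
    g = end.genotype if isinstance(end, Peak) else end
    if g not in landscape:
        raise GenotypeNotFoundError(g)
    if landscape.fitter_neighbors(g):
        raise NotAPeakError(f"{g!r} has fitter neighbors; not a peak")
    return g


def _by_increasing_fitness(landscape: FitnessLandscape) -> List[str]:
    return sorted(landscape.genotypes(), key=lambda g: (landscape.fitness(g), g))


def count_monotone_paths(
    landscape: FitnessLandscape, end: Union[str, Peak]
) -> Dict[str, int]:
    """Exact number of monotone paths from every genotype to the peak ``end``.

    Dynamic programming over genotypes in decreasing-fitness order with exact
    integer arithmetic (counts overflow 64 bits well below L = 20).
    """
    target = _as_peak_genotype(landscape, end)
    counts: Dict[str, int] = {}
    for g in reversed(_by_increasing_fitness(landscape)):
        if g == target:
            counts[g] = 1
        else:
            counts[g] = sum(counts[h] for h in landscape.fitter_neighbors(g))
    return counts


def reach_probability(
    landscape: FitnessLandscape, end: Union[str, Peak]
) -> Dict[str, float]:
    """Probability that an SSWM walk from each genotype terminates at ``end``:
    1 at ``end``, 0 at any other peak, otherwise the mean over fitter
    neighbors."""
    target = _as_peak_genotype(landscape, end)
    rho: Dict[str, float] = {}
    for g in reversed(_by_increasing_fitness(landscape)):
        if g == target:
            rho[g] = 1.0
            continue
        fitter = landscape.fitter_neighbors(g)
        rho[g] = fsum(rho[h] for h in fitter) / len(fitter) if fitter else 0.0
    return rho


@dataclass
class AccessibilityReport:
    """Landscape-level accessibility of the global peak.

    ``existence_accessibility`` is the fraction of genotypes with at least one
    monotone path to the global peak; ``mean_reach_probability`` averages the
    SSWM reach probability over genotypes.  With several tied global peaks the
    top-level numbers are absent and ``per_peak`` holds one pair per peak.
    """

    n_peaks: int
    n_global_peaks: int
    existence_accessibility: Optional[float]
    mean_reach_probability: Optional[float]
    per_peak: Dict[str, tuple]


def peak_accessibility(landscape: FitnessLandscape) -> AccessibilityReport:
    """Existence accessibility and mean SSWM reach probability of the global
    peak(s), averaged over all viable genotypes."""
    peaks = landscape.peaks()
    global_peaks = [p for p in peaks if p.is_global]
    n = len(landscape)

    per_peak: Dict[str, tuple] = {}
    for p in global_peaks:
        counts = count_monotone_paths(landscape, p.genotype)
        rho = reach_probability(landscape, p.genotype)
        exist = sum(1 for c in counts.values() if c > 0) / n
        mean_rho = fsum(rho.values()) / n
        per_peak[p.genotype] = (exist, mean_rho)

    if len(global_peaks) == 1:
        exist, mean_rho = per_peak[global_peaks[0].genotype]
    else:
        warnings.warn(
            f"{len(global_peaks)} genotypes tie for the global fitness "
            "maximum; reporting accessibility per peak", stacklevel=2
        )
        exist = mean_rho = None
    return AccessibilityReport(
        n_peaks=len(peaks),
        n_global_peaks=len(global_peaks),
        existence_accessibility=exist,
        mean_reach_probability=mean_rho,
        per_peak=per_peak,
    )


def sample_sswm_walk(
    landscape: FitnessLandscape,
    start: str,
    rng: Union[int, np.random.Generator],
) -> Path:
    """One random SSWM adaptive walk: from ``start``, repeatedly fix a
    uniformly chosen fitter neighbor until a peak is reached."""
    if start not in landscape:
        raise GenotypeNotFoundError(start)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    walk = [start]
    while True:
        fitter = sorted(landscape.fitter_neighbors(walk[-1]))
        if not fitter:
            return Path(tuple(walk), landscape)
        walk.append(fitter[rng.integers(len(fitter))])
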