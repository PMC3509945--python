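"""Path-divergence statistics: how similar are the monotone paths an
adaptive walk could take?

The inter-path distance between two paths is the symmetrized mean of minimum
Hamming distances from each point of one path to the other, divided by the
combined number of points.  The divergence of a path ensemble weights the
pairwise distances by the product of the paths' SSWM occurrence
probabilities; low divergence means the possible trajectories are few and/or
tightly clustered — i.e., evolution on that landscape is predictable.

Two ensemble modes are provided:

* ``raw`` — the plain weighted sum over unordered distinct pairs.
* ``normalized`` (default) — the weighted sum divided by the total pair
  weight, i.e. a probability-weighted *mean* pairwise distance.  This form is
  scale-free when the ensemble probabilities do not sum to one (ensembles
  conditioned on a single peak), so it is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import fsum
from typing import Dict, Tuple

import numpy as np

from .landscape import FitnessLandscape, hamming
from .paths import DEFAULT_MAX_PATHS, Path, PathEnsemble, enumerate_monotone_paths

MODES = ("raw", "normalized")
TARGETS = ("global-peak", "all-peaks")


def point_to_path_distance(x: str, p: Path) -> int:
    """Minimum Hamming distance from genotype ``x`` to any point of ``p``."""
    return min(hamming(x, y) for y in p.genotypes)


def inter_path_distance(p1: Path, p2: Path) -> float:
    """Symmetrized, length-normalized minimum-Hamming distance between two
    paths; 0 iff the paths visit identical point sets."""
    total = sum(point_to_path_distance(x, p2) for x in p1.genotypes)
    total += sum(point_to_path_distance(y, p1) for y in p2.genotypes)
    return total / (len(p1) + len(p2))


def _pairwise_distance_matrix(ensemble: PathEnsemble) -> np.ndarray:
    """All pairwise inter-path distances, vectorized.

    Works on an index encoding of the genotypes that appear in the ensemble:
    ``M[j, g]`` is the min Hamming distance from genotype ``g`` to path ``j``,
    and the per-pair point sums reduce to one matrix product with the binary
    membership matrix.
    """
    paths = ensemble.paths
    n = len(paths)
    genotypes = sorted({g for p in paths for g in p.genotypes})
    index = {g: i for i, g in enumerate(genotypes)}
    m = len(genotypes)

    codes = np.array([int(g, 2) for g in genotypes], dtype=np.int64)
    xor = codes[:, None] ^ codes[None, :]
    # popcount via uint8 view
    H = np.unpackbits(xor.astype(">u8").view(np.uint8).reshape(m, m, 8),
                      axis=-1).sum(axis=-1).astype(np.float64)

    membership = np.zeros((n, m))
    min_to_path = np.empty((n, m))
    lengths = np.empty(n)
    for j, p in enumerate(paths):
        idx = [index[g] for g in p.genotypes]
        membership[j, idx] = 1.0
        min_to_path[j] = H[:, idx].min(axis=1)
        lengths[j] = len(p)

    point_sums = membership @ min_to_path.T  # S[i, j] = sum_{x in p_i} d(x, p_j)
    return (point_sums + point_sums.T) / (lengths[:, None] + lengths[None, :])


@dataclass
class DivergenceResult:
    per_ensemble: Dict[Tuple[str, str], float]  # (start, peak) -> divergence
    mean_divergence: float
    normalization_mode: str
    n_ensembles: int


def ensemble_divergence(ensemble: PathEnsemble, mode: str = "normalized") -> float:
    """Probability-weighted divergence of one path ensemble.

    ``raw``: sum over unordered distinct pairs of ``P_i * P_j * d(p_i, p_j)``.
    ``normalized``: the same sum divided by the total pair weight
    ``sum P_i * P_j`` — a weighted mean pairwise distance.  Single-path
    ensembles have divergence 0 in both modes.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not ensemble.paths:
        raise ValueError("empty ensemble")
    if len(ensemble.paths) == 1:
        return 0.0

    P = np.asarray(ensemble.probabilities)
    D = _pairwise_distance_matrix(ensemble)
    weighted = 0.5 * (P @ D @ P)  # diag(D) = 0, so this is the i<j sum
    if mode == "raw":
        return float(weighted)
    pair_weight = 0.5 * (P.sum() ** 2 - (P ** 2).sum())
    return float(weighted / pair_weight)


def mean_path_divergence(
    landscape: FitnessLandscape,
    mode: str = "normalized",
    target: str = "global-peak",
    max_paths: int = DEFAULT_MAX_PATHS,
) -> DivergenceResult:
    """Mean divergence over the ensembles of monotone paths that start at
    every viable genotype and terminate at the target peak(s).

    Starts with no monotone path to the target are skipped (they measure
    inaccessibility, not divergence); the mean over contributing ensembles is
    unweighted.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}, got {target!r}")

    fmax = landscape.max_fitness()
    per_ensemble: Dict[Tuple[str, str], float] = {}
    for start in landscape.genotypes():
        ensembles = enumerate_monotone_paths(landscape, start, max_paths=max_paths)
        for ens in ensembles:
            if target == "global-peak" and ens.peak.fitness != fmax:
                continue
            per_ensemble[(start, ens.peak.genotype)] = ensemble_divergence(ens, mode)

    values = list(per_ensemble.values())
    mean = fsum(values) / len(values) if values else float("nan")
    return DivergenceResult(
        per_ensemble=per_ensemble,
        mean_divergence=mean,
        normalization_mode=mode,
        n_ensembles=len(values),
    )
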