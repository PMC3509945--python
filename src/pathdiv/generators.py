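"""Seeded model-landscape generators.

Three families:

* **noisy additive** — additive fitness (peak fitness minus summed
  exponential per-locus effects) perturbed multiplicatively by
  ``uniform(0,1)**k`` noise; ``k`` tunes ruggedness continuously from exactly
  additive (``k=0``) to heavily perturbed.  Genotypes whose perturbed fitness
  is not positive are nonviable and excluded.
* **uncorrelated** (house-of-cards) — i.i.d. uniform fitness on the full
  hypercube; the maximal-ruggedness null.
* **fitness permutation** — same genotype set, fitness values shuffled; the
  null used to test whether a landscape is smoother than chance.

All generators are pure functions of their parameters plus a seed
(numpy ``default_rng``, PCG64).  Random-stream discipline for the noisy
additive family: the ``L`` per-locus effects are drawn first, then one noise
variate per genotype in lexicographic genotype order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .landscape import EmptyLandscapeError, FitnessLandscape, MAX_LOCI


class GeneratorParameterError(ValueError):
    """Invalid generator parameters."""


class DegenerateLandscapeError(EmptyLandscapeError):
    """The viability filter removed every genotype."""


def all_genotypes(L: int):
    """All 2**L genotype strings of length L in lexicographic order."""
    return ("".join(bits) for bits in itertools.product("01", repeat=L))


@dataclass
class NoisyAdditiveParams:
    """Parameters of the noisy-additive landscape family.

    ``effect_mean`` is the *mean* (not the rate) of the exponential
    distribution of per-locus fitness effects; it defaults to ``0.5/L`` so the
    expected all-zeros pre-noise fitness is ``peak_fitness/2`` and most
    genotypes pass the viability filter.  ``noise_power`` is the exponent
    ``k`` applied to the per-genotype uniform noise draws.
    """

    L: int
    peak_fitness: float = 1.0
    effect_mean: Optional[float] = None  # defaults to 0.5 / L
    noise_power: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.L <= MAX_LOCI):
            raise GeneratorParameterError(f"L must be in [1, {MAX_LOCI}], got {self.L}")
        if self.effect_mean is None:
            self.effect_mean = 0.5 / self.L
        if not self.peak_fitness > 0:
            raise GeneratorParameterError("peak_fitness must be > 0")
        if not self.effect_mean > 0:
            raise GeneratorParameterError("effect_mean must be > 0")
        if self.noise_power < 0:
            raise GeneratorParameterError("noise_power must be >= 0")


def generate_noisy_additive(params: NoisyAdditiveParams) -> FitnessLandscape:
    """Build one noisy-additive landscape.

    Pre-noise fitness of genotype ``g`` is
    ``peak_fitness - sum of effects at loci where g is 0`` (the all-ones
    genotype is the additive peak).  Every genotype — including the all-ones
    peak — is then multiplied by an independent ``uniform(0,1)**k`` factor, so
    for ``k > 0`` the all-ones genotype need not remain the global peak.
    Genotypes with non-positive perturbed fitness are excluded.
    """
    rng = np.random.default_rng(params.seed)
    effects = rng.exponential(params.effect_mean, size=params.L)
    genotypes = list(all_genotypes(params.L))
    noise = rng.random(size=len(genotypes)) ** params.noise_power

    entries: Dict[str, float] = {}
    for g, u in zip(genotypes, noise):
        pre = params.peak_fitness - sum(
            e for bit, e in zip(g, effects) if bit == "0"
        )
        f = pre * u
        if f > 0.0:
            entries[g] = f
    if not entries:
        raise DegenerateLandscapeError(
            "viability filter removed every genotype; "
            "lower effect_mean or noise_power"
        )
    meta = {
        "model": "noisy-additive",
        "L": params.L,
        "peak_fitness": params.peak_fitness,
        "effect_mean": params.effect_mean,
        "noise_power": params.noise_power,
        "seed": params.seed,
        "effects": effects.tolist(),
        "rng": "numpy default_rng (PCG64)",
    }
    return FitnessLandscape(entries, metadata=meta)


def generate_additive(L: int, seed: int = 0, peak_fitness: float = 1.0,
                      effect_mean: Optional[float] = None) -> FitnessLandscape:
    """Exactly additive landscape: the ``noise_power = 0`` limit."""
    return generate_noisy_additive(
        NoisyAdditiveParams(L=L, peak_fitness=peak_fitness,
                            effect_mean=effect_mean, noise_power=0.0, seed=seed)
    )


def generate_uncorrelated(L: int, seed: int = 0) -> FitnessLandscape:
    """Full hypercube with i.i.d. Uniform(0, 1] fitness (house of cards)."""
    if not (1 <= L <= 12):
        raise GeneratorParameterError(f"L must be in [1, 12], got {L}")
    rng = np.random.default_rng(seed)
    genotypes = list(all_genotypes(L))
    values = 1.0 - rng.random(size=len(genotypes))  # (0, 1]: fitness must be > 0
    entries = dict(zip(genotypes, values))
    meta = {"model": "uncorrelated", "L": L, "seed": seed,
            "rng": "numpy default_rng (PCG64)"}
    return FitnessLandscape(entries, metadata=meta)


def permute_fitness(landscape: FitnessLandscape, seed: int = 0) -> FitnessLandscape:
    """Uniformly random permutation of the fitness values over the same
    genotype set; conserves the fitness multiset exactly."""
    rng = np.random.default_rng(seed)
    genotypes = landscape.genotypes()
    values = np.array([landscape.fitness(g) for g in genotypes])
    permuted = values[rng.permutation(len(values))]
    meta = dict(landscape.metadata)
    meta.update({"permuted": True, "permutation_seed": seed})
    return FitnessLandscape(dict(zip(genotypes, permuted)), metadata=meta)
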