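"""Genotype/fitness-landscape data model and TSV I/O.

A genotype is a fixed-length string over the alphabet ``{0, 1}``; the set of
genotypes of length ``L`` forms the vertices of the L-dimensional hypercube.
A :class:`FitnessLandscape` is a *partial* map from genotypes to strictly
positive fitness values: genotypes absent from the map are nonviable and are
removed from the mutational graph entirely (paths may not traverse them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Set

logger = logging.getLogger(__name__)

#: Hard cap on the number of loci accepted anywhere in the package.
MAX_LOCI = 25

ALPHABET = frozenset("01")


class LandscapeError(Exception):
    """Base class for landscape-related failures."""


class LandscapeFormatError(LandscapeError):
    """Malformed genotype-fitness table (bad symbols, ragged lengths, ...)."""


class DuplicateGenotypeError(LandscapeFormatError):
    """The same genotype appears twice with conflicting fitness."""


class EmptyLandscapeError(LandscapeError):
    """No viable genotype survives parsing/filtering."""


class GenotypeNotFoundError(LandscapeError, KeyError):
    """A genotype was queried that is not part of the landscape."""


def validate_genotype(genotype: str, L: Optional[int] = None) -> str:
    """Check alphabet and (optionally) length; return the genotype unchanged."""
    if not genotype or not set(genotype) <= ALPHABET:
        raise LandscapeFormatError(
            f"genotype {genotype!r} is not a non-empty string over {{0,1}}"
        )
    if len(genotype) > MAX_LOCI:
        raise LandscapeFormatError(
            f"genotype {genotype!r} has {len(genotype)} loci; hard cap is {MAX_LOCI}"
        )
    if L is not None and len(genotype) != L:
        raise LandscapeFormatError(
            f"genotype {genotype!r} has length {len(genotype)}, expected {L}"
        )
    return genotype


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length genotype strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class Peak:
    """A genotype with no strictly fitter viable neighbor."""

    genotype: str
    fitness: float
    is_global: bool


class FitnessLandscape:
    """Partial map genotype -> positive fitness over ``L`` binary loci.

    Parameters
    ----------
    entries:
        Mapping from genotype strings (all the same length, alphabet ``{0,1}``)
        to finite, strictly positive fitness values.
    metadata:
        Free-form provenance (generator parameters, source file, ...).
    """

    def __init__(self, entries: Mapping[str, float], metadata: Optional[dict] = None):
        if not entries:
            raise EmptyLandscapeError("a landscape needs at least one genotype")
        genotypes = list(entries)
        L = len(genotypes[0])
        table: Dict[str, float] = {}
        for g, f in entries.items():
            validate_genotype(g, L)
            f = float(f)
            if not (f > 0.0) or f != f or f == float("inf"):
                raise LandscapeError(
                    f"fitness of {g!r} must be finite and > 0, got {f!r}"
                )
            table[g] = f
        self._fitness = table
        self.L = L
        self.metadata = dict(metadata or {})

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._fitness)

    def __contains__(self, genotype: str) -> bool:
        return genotype in self._fitness

    def __iter__(self) -> Iterator[str]:
        return iter(self.genotypes())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FitnessLandscape):
            return NotImplemented
        return self._fitness == other._fitness

    def __repr__(self) -> str:
        return f"FitnessLandscape(L={self.L}, n={len(self)})"

    # -- queries -------------------------------------------------------------

    def genotypes(self) -> List[str]:
        """All viable genotypes in lexicographic order."""
        return sorted(self._fitness)

    def fitness(self, genotype: str) -> float:
        try:
            return self._fitness[genotype]
        except KeyError:
            raise GenotypeNotFoundError(genotype) from None

    def items(self):
        return self._fitness.items()

    def max_fitness(self) -> float:
        return max(self._fitness.values())

    def viable_neighbors(self, genotype: str) -> Set[str]:
        """Viable genotypes at Hamming distance exactly 1 from ``genotype``."""
        if genotype not in self._fitness:
            raise GenotypeNotFoundError(genotype)
        out = set()
        for i in range(self.L):
            flipped = genotype[:i] + ("1" if genotype[i] == "0" else "0") + genotype[i + 1 :]
            if flipped in self._fitness:
                out.add(flipped)
        return out

    def fitter_neighbors(self, genotype: str) -> Set[str]:
        """Viable neighbors with *strictly* greater fitness (ties are neutral,
        hence not beneficial, and are excluded)."""
        f = self.fitness(genotype)
        return {h for h in self.viable_neighbors(genotype) if self._fitness[h] > f}

    def is_peak(self, genotype: str) -> bool:
        return not self.fitter_neighbors(genotype)

    def peaks(self) -> List[Peak]:
        """All local fitness maxima, sorted by descending fitness then genotype."""
        fmax = self.max_fitness()
        found = [
            Peak(g, f, is_global=(f == fmax))
            for g, f in self._fitness.items()
            if self.is_peak(g)
        ]
        found.sort(key=lambda p: (-p.fitness, p.genotype))
        return found

    def global_peaks(self) -> List[Peak]:
        return [p for p in self.peaks() if p.is_global]


# Module-level aliases matching the functional surface.

def viable_neighbors(landscape: FitnessLandscape, genotype: str) -> Set[str]:
    return landscape.viable_neighbors(genotype)


def fitter_neighbors(landscape: FitnessLandscape, genotype: str) -> Set[str]:
    return landscape.fitter_neighbors(genotype)


def find_peaks(landscape: FitnessLandscape) -> List[Peak]:
    return landscape.peaks()


# -- file I/O ----------------------------------------------------------------

def load_landscape(
    path,
    delimiter: str = "\t",
) -> FitnessLandscape:
    """Load a genotype-fitness table.

    Expected format: optional ``#`` comment lines, an optional header row
    (``genotype<delim>fitness``), then one ``genotype<delim>fitness`` row per
    genotype.  Rows whose fitness is non-numeric or ``<= 0`` are dropped (the
    viability filter) with a logged count.
    """
    rows: List[tuple] = []
    dropped = 0
    seen_any = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise LandscapeFormatError(
                    f"{path}:{lineno}: expected 2 {delimiter!r}-separated fields"
                )
            g, val = parts[0].strip(), parts[1].strip()
            if not seen_any and g.lower() == "genotype":
                seen_any = True
                continue  # header row
            seen_any = True
            validate_genotype(g)
            try:
                f = float(val)
            except ValueError:
                dropped += 1
                continue
            if not f > 0.0:
                dropped += 1
                continue
            rows.append((g, f, lineno))

    if dropped:
        logger.info("%s: dropped %d nonviable/non-numeric rows", path, dropped)
    if not rows:
        raise EmptyLandscapeError(f"{path}: no viable genotypes")

    L = len(rows[0][0])
    entries: Dict[str, float] = {}
    for g, f, lineno in rows:
        if len(g) != L:
            raise LandscapeFormatError(
                f"{path}:{lineno}: genotype length {len(g)} != {L}"
            )
        if g in entries and entries[g] != f:
            raise DuplicateGenotypeError(
                f"{path}:{lineno}: duplicate genotype {g!r} with conflicting fitness"
            )
        entries[g] = f
    return FitnessLandscape(
        entries, metadata={"source": str(path), "dropped_rows": dropped}
    )


def save_landscape(landscape: FitnessLandscape, path, delimiter: str = "\t",
                   header_comments: Iterable[str] = ()) -> None:
    """Write the canonical table: header row, genotypes sorted lexicographically,
    fitness at full (round-trippable) precision."""
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write(f"genotype{delimiter}fitness\n")
        for g in landscape.genotypes():
            fh.write(f"{g}{delimiter}{landscape.fitness(g)!r}\n")
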