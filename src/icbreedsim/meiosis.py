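"""Mendelian machinery: gametes with recombination, crossing, selfing, DH.

Meiosis follows the Haldane (no chiasma interference) model: the crossover
count on a chromosome of genetic length G Morgans is Poisson(G), crossover
positions are uniform on the map, and the starting haplotype is chosen at
random. No obligate crossover is imposed.

Populations are stored as dense int8 arrays of shape ``(n, 2, L)`` (line,
haplotype, locus) and all operations are batched; a thin :class:`Line`
wrapper exposes the single-individual API. The batched gamete kernel is
numba-compiled: for each gamete it walks loci left to right, toggling the
source haplotype at each crossover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .founders import FounderPopulation, GeneticMap

__all__ = [
    "Line",
    "Population",
    "gametes",
    "make_gamete",
    "cross",
    "self_line",
    "make_dh",
]


@njit(cache=True)
def _gamete_kernel(haps, parent_idx, start, cuts, offsets, out):  # pragma: no cover
    m, L = out.shape
    for g in range(m):
        h = start[g]
        p = offsets[g]
        end = offsets[g + 1]
        pg = parent_idx[g]
        for j in range(L):
            while p < end and cuts[p] <= j:
                h = 1 - h
                p += 1
            out[g, j] = haps[pg, h, j]


def gametes(
    haps: np.ndarray,
    parent_idx: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Draw one recombinant gamete per entry of ``parent_idx``.

    ``haps`` has shape (n, 2, L); the result has shape (len(parent_idx), L).
    ``out`` may be a preallocated int8 array (a view is fine) of that shape.
    """
    parent_idx = np.ascontiguousarray(parent_idx, dtype=np.int64)
    m = parent_idx.size
    L = gmap.positions.size
    k = rng.poisson(gmap.length, m)
    xo = rng.uniform(0.0, gmap.length, int(k.sum()))
    gid = np.repeat(np.arange(m), k)
    order = np.lexsort((xo, gid))
    # map each crossover to the index of the first locus to its right
    cuts = np.searchsorted(gmap.positions, xo[order], side="left").astype(np.int64)
    offsets = np.zeros(m + 1, dtype=np.int64)
    np.cumsum(k, out=offsets[1:])
    start = rng.integers(0, 2, m).astype(np.int8)
    if out is None:
        out = np.empty((m, L), dtype=np.int8)
    if m:
        _gamete_kernel(np.ascontiguousarray(haps), parent_idx, start, cuts, offsets, out)
    return out


@dataclass
class Line:
    """One diploid individual: a pair of binary haplotypes plus pedigree tags."""

    hap0: np.ndarray
    hap1: np.ndarray
    crop: str = ""
    family: int = -1
    generation: str = ""

    def __post_init__(self) -> None:
        self.hap0 = np.asarray(self.hap0, dtype=np.int8)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        if self.hap0.shape != self.hap1.shape:
            raise ValueError("haplotypes must have equal length")

    @property
    def n_loci(self) -> int:
        return self.hap0.size

    def dosage(self) -> np.ndarray:
        return (self.hap0 + self.hap1).astype(np.int8)

    def heterozygosity(self) -> float:
        return float((self.hap0 != self.hap1).mean())

    def is_homozygous(self) -> bool:
        return bool((self.hap0 == self.hap1).all())

    def as_array(self) -> np.ndarray:
        return np.stack([self.hap0, self.hap1])[None, :, :]


@dataclass
class Population:
    """A batch of lines of one crop: haplotypes ``(n, 2, L)`` + family ids."""

    haps: np.ndarray
    crop: str = ""
    family: np.ndarray = field(default=None)  # type: ignore[assignment]
    generation: str = ""

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.ndim != 3 or self.haps.shape[1] != 2:
            raise ValueError("haps must have shape (n, 2, L)")
        if self.family is None:
            self.family = np.full(self.size, -1, dtype=np.int64)
        else:
            self.family = np.asarray(self.family, dtype=np.int64)
        if self.family.size != self.size:
            raise ValueError("family ids must match population size")

    @property
    def size(self) -> int:
        return self.haps.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haps.shape[2]

    def dosages(self) -> np.ndarray:
        return self.haps.sum(axis=1, dtype=np.int16).astype(np.int8)

    def heterozygosity(self) -> np.ndarray:
        """Per-line fraction of heterozygous loci."""
        return (self.haps[:, 0, :] != self.haps[:, 1, :]).mean(axis=1)

    def subset(self, idx: np.ndarray) -> "Population":
        idx = np.asarray(idx)
        return Population(
            haps=self.haps[idx],
            crop=self.crop,
            family=self.family[idx],
            generation=self.generation,
        )

    def line(self, i: int) -> Line:
        return Line(
            self.haps[i, 0], self.haps[i, 1],
            crop=self.crop, family=int(self.family[i]), generation=self.generation,
        )

    @classmethod
    def from_founders(cls, founders: FounderPopulation) -> "Population":
        return cls(
            haps=founders.as_diploid().copy(),
            crop=founders.spec.crop,
            family=np.arange(founders.n_founders),
            generation="founder",
        )

    # -- batched reproduction -------------------------------------------------

    def cross_pairs(
        self,
        pairs: np.ndarray,
        n_progeny_per_pair: int,
        gmap: GeneticMap,
        rng: np.random.Generator,
        generation: str = "S0",
    ) -> "Population":
        """Make ``n_progeny_per_pair`` progeny for each (mother, father) index
        pair; progeny of pair ``j`` carry family id ``j``."""
        pairs = np.asarray(pairs, dtype=np.int64)
        mothers = np.repeat(pairs[:, 0], n_progeny_per_pair)
        fathers = np.repeat(pairs[:, 1], n_progeny_per_pair)
        haps = np.empty((mothers.size, 2, self.n_loci), dtype=np.int8)
        gametes(self.haps, mothers, gmap, rng, out=haps[:, 0, :])
        gametes(self.haps, fathers, gmap, rng, out=haps[:, 1, :])
        fam = np.repeat(np.arange(pairs.shape[0]), n_progeny_per_pair)
        return Population(
            haps=haps, crop=self.crop, family=fam, generation=generation,
        )

    def self_batch(
        self,
        parent_idx: np.ndarray,
        gmap: GeneticMap,
        rng: np.random.Generator,
        generation: str = "",
    ) -> "Population":
        """One selfed progeny per entry of ``parent_idx`` (entries may repeat)."""
        parent_idx = np.asarray(parent_idx, dtype=np.int64)
        haps = np.empty((parent_idx.size, 2, self.n_loci), dtype=np.int8)
        gametes(self.haps, parent_idx, gmap, rng, out=haps[:, 0, :])
        gametes(self.haps, parent_idx, gmap, rng, out=haps[:, 1, :])
        return Population(
            haps=haps, crop=self.crop,
            family=self.family[parent_idx], generation=generation,
        )

    def dh_batch(
        self,
        parent_idx: np.ndarray,
        gmap: GeneticMap,
        rng: np.random.Generator,
        generation: str = "DH0",
    ) -> "Population":
        """One doubled-haploid line (a single gamete doubled) per entry."""
        parent_idx = np.asarray(parent_idx, dtype=np.int64)
        haps = np.empty((parent_idx.size, 2, self.n_loci), dtype=np.int8)
        gametes(self.haps, parent_idx, gmap, rng, out=haps[:, 0, :])
        haps[:, 1, :] = haps[:, 0, :]
        return Population(
            haps=haps, crop=self.crop,
            family=self.family[parent_idx], generation=generation,
        )


def make_gamete(parent: Line, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a single parent."""
    return gametes(parent.as_array(), np.zeros(1, dtype=np.int64), gmap, rng)[0]


def cross(
    p1: Line, p2: Line, n_progeny: int, gmap: GeneticMap, rng: np.random.Generator
) -> list[Line]:
    """Cross two lines of the same crop; no interspecific hybrids exist here."""
    if p1.crop != p2.crop:
        raise ValueError(f"cannot cross {p1.crop!r} with {p2.crop!r}")
    haps = np.concatenate([p1.as_array(), p2.as_array()])
    g0 = gametes(haps, np.zeros(n_progeny, dtype=np.int64), gmap, rng)
    g1 = gametes(haps, np.ones(n_progeny, dtype=np.int64), gmap, rng)
    return [
        Line(g0[i], g1[i], crop=p1.crop, family=p1.family, generation="S0")
        for i in range(n_progeny)
    ]


def self_line(parent: Line, gmap: GeneticMap, rng: np.random.Generator) -> Line:
    """One selfed progeny: two independent gametes of the same parent."""
    haps = parent.as_array()
    z = np.zeros(1, dtype=np.int64)
    return Line(
        gametes(haps, z, gmap, rng)[0],
        gametes(haps, z, gmap, rng)[0],
        crop=parent.crop,
        family=parent.family,
        generation="self",
    )


def make_dh(
    parent: Line, n_lines: int, gmap: GeneticMap, rng: np.random.Generator
) -> list[Line]:
    """Doubled haploids: each line is one independent gamete duplicated."""
    g = gametes(parent.as_array(), np.zeros(n_lines, dtype=np.int64), gmap, rng)
    return [
        Line(g[i], g[i].copy(), crop=parent.crop, family=parent.family, generation="DH0")
        for i in range(n_lines)
    ]
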