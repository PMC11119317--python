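"""Founder genome simulation.

Each hypothetical crop (a faba-bean-like legume and a triticale-like cereal)
is collapsed to a single diploid chromosome carrying a few thousand biallelic
segregating sites. Founders are fully homozygous inbred lines: standing
variation is between founders, never within one. Allele frequencies at each
site are drawn from a U-shaped Beta(0.5, 0.5) spectrum, mimicking the excess
of rare and common variants left by drift, and any column that comes out
monomorphic among the sampled founders is redrawn so that every site truly
segregates.

Recombination downstream operates on the genetic map (Morgans); physical
lengths in basepairs are carried as metadata only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GenomeSpec",
    "GeneticMap",
    "FounderPopulation",
    "simulate_founder_haplotypes",
    "simulate_founder_haplotypes_coalescent",
    "designate_qtl",
    "save_founders",
    "load_founders",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one crop's (single-chromosome) genome.

    Attributes
    ----------
    crop:
        Identifier of the component crop (e.g. ``"faba_bean"``).
    physical_length_bp:
        Physical chromosome length in basepairs; metadata only.
    genetic_length_m:
        Genetic map length in Morgans; recombination operates on this scale.
    n_sites:
        Number of segregating sites simulated.
    n_qtl:
        Number of sites later designated as trait QTL (``<= n_sites``).
    """

    crop: str
    physical_length_bp: float
    genetic_length_m: float = 1.0
    n_sites: int = 2000
    n_qtl: int = 1000
    n_chromosomes: int = 1

    def __post_init__(self) -> None:
        if self.n_chromosomes != 1:
            raise ValueError("each crop genome is modelled as one chromosome")
        if self.physical_length_bp <= 0 or self.genetic_length_m <= 0:
            raise ValueError("chromosome lengths must be positive")
        if not 0 < self.n_qtl <= self.n_sites:
            raise ValueError("need 0 < n_qtl <= n_sites")

    @classmethod
    def faba_bean(cls, **kw) -> "GenomeSpec":
        return cls(crop="faba_bean", physical_length_bp=1.1e9, **kw)

    @classmethod
    def triticale(cls, **kw) -> "GenomeSpec":
        return cls(crop="triticale", physical_length_bp=9.9e8, **kw)


@dataclass(frozen=True)
class GeneticMap:
    """Sorted locus positions (Morgans) on a chromosome of given map length."""

    positions: np.ndarray
    length: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 1 or pos.size == 0:
            raise ValueError("positions must be a non-empty 1-D array")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if pos[0] < 0 or pos[-1] > self.length:
            raise ValueError("positions must lie within [0, length]")

    def subset(self, indices: np.ndarray) -> "GeneticMap":
        return GeneticMap(self.positions[np.asarray(indices)], self.length)


@dataclass
class FounderPopulation:
    """Haplotypes of one crop's founder panel.

    ``haplotypes`` has shape ``(2 * n_founders, n_sites)`` with rows
    ``2i, 2i+1`` belonging to founder ``i``; founders are homozygous so the
    two rows of each founder are identical.
    """

    haplotypes: np.ndarray
    gmap: GeneticMap
    spec: GenomeSpec

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def dosages(self) -> np.ndarray:
        """Per-founder reference-allele dosage matrix, shape (n_founders, n_sites)."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def as_diploid(self) -> np.ndarray:
        """Haplotypes reshaped to (n_founders, 2, n_sites)."""
        n = self.n_founders
        return self.haplotypes.reshape(n, 2, self.n_sites)

    def validate(self) -> None:
        h = self.haplotypes
        if h.ndim != 2 or h.shape[0] % 2:
            raise ValueError("haplotype matrix must have an even number of rows")
        if not np.isin(h, (0, 1)).all():
            raise ValueError("haplotypes must be binary")
        if (h[0::2] != h[1::2]).any():
            raise ValueError("founders must be fully homozygous")
        freq = h.mean(axis=0)
        if np.any((freq == 0) | (freq == 1)):
            raise ValueError("every site must be polymorphic among founders")
        if self.gmap.positions.size != self.n_sites:
            raise ValueError("genetic map does not match site count")


def simulate_founder_haplotypes(
    spec: GenomeSpec,
    seed: int | np.random.Generator,
    n_founders: int = 100,
    max_redraws: int = 100,
) -> FounderPopulation:
    """Simulate a panel of homozygous founders for one crop.

    Site allele frequencies are drawn from Beta(0.5, 0.5); each founder's
    (homozygous) genotype at a site is a Bernoulli draw at that frequency.
    Columns that come out monomorphic are redrawn (fresh frequency and fresh
    genotypes) until all sites segregate, or ``max_redraws`` rounds are
    exhausted, which signals a degenerate spec (e.g. too few founders).
    """
    rng = np.random.default_rng(seed)
    L = spec.n_sites
    geno = np.empty((n_founders, L), dtype=np.int8)
    todo = np.arange(L)
    for _ in range(max_redraws):
        p = rng.beta(0.5, 0.5, size=todo.size)
        geno[:, todo] = (rng.random((n_founders, todo.size)) < p).astype(np.int8)
        freq = geno[:, todo].mean(axis=0)
        todo = todo[(freq == 0) | (freq == 1)]
        if todo.size == 0:
            break
    else:
        raise RuntimeError(
            f"could not make all {L} sites polymorphic in {max_redraws} rounds"
        )
    haps = np.repeat(geno, 2, axis=0)

    pos = np.sort(rng.uniform(0.0, spec.genetic_length_m, L))
    while np.any(np.diff(pos) <= 0):  # pragma: no cover - prob. ~0 with float64
        pos = np.sort(rng.uniform(0.0, spec.genetic_length_m, L))
    gmap = GeneticMap(pos, spec.genetic_length_m)

    pop = FounderPopulation(haplotypes=haps, gmap=gmap, spec=spec)
    pop.validate()
    return pop


def simulate_founder_haplotypes_coalescent(
    spec: GenomeSpec,
    seed: int | np.random.Generator,
    n_founders: int = 100,
    population_size: float = 1000.0,
    max_redraws: int = 5,
) -> FounderPopulation:
    """Simulate founders from a neutral coalescent with recombination.

    One haploid genome per founder is generated with msprime on a uniform
    recombination map spanning the chromosome's physical length and scaled
    to its genetic length, overlaid with binary mutations, and doubled into
    a fully homozygous individual. Exactly ``n_sites`` polymorphic sites are
    kept (uniform downsample). Compared to the Beta-spectrum generator this
    carries the linkage disequilibrium and rare-allele-rich site-frequency
    spectrum that drift leaves in a finite population, which matters for how
    costly early candidate-number bottlenecks are.
    """
    import msprime

    rng = np.random.default_rng(seed)
    rec_rate = spec.genetic_length_m / spec.physical_length_bp
    # target ~30% more segregating sites than needed, E[S] = theta * H(n-1)
    harmonic = np.sum(1.0 / np.arange(1, n_founders))
    mu = 1.3 * spec.n_sites / (4 * population_size * harmonic * spec.physical_length_bp)
    for _ in range(max_redraws):
        ms_seed = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=n_founders,
            ploidy=1,
            population_size=population_size,
            sequence_length=spec.physical_length_bp,
            recombination_rate=rec_rate,
            random_seed=ms_seed,
        )
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            random_seed=ms_seed,
            model=msprime.BinaryMutationModel(),
        )
        geno = mts.genotype_matrix().T.astype(np.int8)  # founders x sites
        freq = geno.mean(axis=0)
        poly = np.flatnonzero((freq > 0) & (freq < 1))
        if poly.size >= spec.n_sites:
            keep = np.sort(rng.choice(poly, size=spec.n_sites, replace=False))
            geno = geno[:, keep]
            pos_bp = mts.sites_position[keep]
            break
        mu *= 2.0  # not enough variation: thicken the mutation layer
    else:
        raise RuntimeError(
            f"coalescent simulation yielded fewer than {spec.n_sites} polymorphic sites"
        )
    pos = pos_bp / spec.physical_length_bp * spec.genetic_length_m
    # distinct integer basepair positions map to distinct genetic positions
    gmap = GeneticMap(pos, spec.genetic_length_m)
    pop = FounderPopulation(
        haplotypes=np.repeat(geno, 2, axis=0), gmap=gmap, spec=spec
    )
    pop.validate()
    return pop


def designate_qtl(
    pop: FounderPopulation, n_qtl: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample ``n_qtl`` distinct QTL site indices uniformly, returned sorted."""
    if n_qtl > pop.n_sites:
        raise ValueError(f"n_qtl={n_qtl} exceeds available sites ({pop.n_sites})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pop.n_sites, size=n_qtl, replace=False)
    return np.sort(idx)


def save_founders(pop: FounderPopulation, prefix: str | Path) -> None:
    """Write haplotypes (CSV of 0/1, one row per haplotype) plus a locus-map
    sidecar (site index, genetic position in Morgans)."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".haplotypes.csv"), pop.haplotypes, fmt="%d", delimiter=",")
    L = pop.n_sites
    sidecar = np.column_stack([np.arange(L), pop.gmap.positions])
    np.savetxt(
        prefix.with_suffix(".loci.csv"),
        sidecar,
        fmt=("%d", "%.10f"),
        delimiter=",",
        header="site_index,position_morgan",
        comments="",
    )
    spec_line = ",".join(
        f"{f.name}={getattr(pop.spec, f.name)}" for f in dataclasses.fields(pop.spec)
    )
    prefix.with_suffix(".spec.txt").write_text(spec_line + "\n")


def load_founders(prefix: str | Path) -> FounderPopulation:
    prefix = Path(prefix)
    haps = np.loadtxt(prefix.with_suffix(".haplotypes.csv"), delimiter=",", dtype=np.int8)
    loci = np.loadtxt(prefix.with_suffix(".loci.csv"), delimiter=",", skiprows=1)
    fields = dict(
        kv.split("=", 1)
        for kv in prefix.with_suffix(".spec.txt").read_text().strip().split(",")
    )
    spec = GenomeSpec(
        crop=fields["crop"],
        physical_length_bp=float(fields["physical_length_bp"]),
        genetic_length_m=float(fields["genetic_length_m"]),
        n_sites=int(fields["n_sites"]),
        n_qtl=int(fields["n_qtl"]),
    )
    gmap = GeneticMap(loci[:, 1], spec.genetic_length_m)
    return FounderPopulation(haplotypes=haps, gmap=gmap, spec=spec)
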