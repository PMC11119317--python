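"""Correlated monocrop/intercrop trait architecture and phenotype model.

Both traits of a crop — monocrop (MC) performance in pure stand and
intercrop (IC) performance in mixture — are purely additive and controlled
by the same set of biallelic QTL. Reference-allele effects for the two
traits are drawn jointly from a bivariate standard normal whose correlation
is fixed at the target genetic correlation R, so selection on the MC trait
improves the IC trait only through that correlation (indirect selection).

Effects are affinely rescaled against the founder panel so that founder
genetic values (GVs) have mean 0 and variance 1 per trait; heritability and
all gain trajectories are then expressed on that common founder scale.

The GV of an intercrop combination is the arithmetic mean of its two
components' IC GVs, g = (g_f + g_t) / 2. Phenotypes add a single normal
environmental deviate with entry-mean variance sigma_e^2 / r, where
sigma_e^2 = (1 - h^2) sigma_a^2 / h^2 and r is the number of plot
replications at the trial stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .founders import FounderPopulation

__all__ = [
    "TraitArchitecture",
    "PhenotypeSettings",
    "sample_correlated_effects",
    "scale_architecture",
    "genetic_value",
    "ic_combination_gv",
    "environmental_variance",
    "phenotype",
]

TRAITS = ("MC", "IC")


@dataclass
class TraitArchitecture:
    """Paired MC/IC additive QTL effects for one crop.

    ``offset_mc`` / ``offset_ic`` shift GVs so the founder mean is zero after
    :func:`scale_architecture`; raw (unscaled) architectures have offset 0.
    """

    qtl_indices: np.ndarray
    effects_mc: np.ndarray
    effects_ic: np.ndarray
    target_correlation: float
    offset_mc: float = 0.0
    offset_ic: float = 0.0
    scaled: bool = False

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=np.int64)
        self.effects_mc = np.asarray(self.effects_mc, dtype=np.float64)
        self.effects_ic = np.asarray(self.effects_ic, dtype=np.float64)
        if not (
            self.qtl_indices.shape == self.effects_mc.shape == self.effects_ic.shape
        ):
            raise ValueError("QTL indices and both effect vectors must align")

    @property
    def n_qtl(self) -> int:
        return self.qtl_indices.size

    def effects(self, trait: str) -> np.ndarray:
        if trait == "MC":
            return self.effects_mc
        if trait == "IC":
            return self.effects_ic
        raise ValueError(f"unknown trait {trait!r}")

    def offset(self, trait: str) -> float:
        return self.offset_mc if trait == "MC" else self.offset_ic


@dataclass(frozen=True)
class PhenotypeSettings:
    """Noise model of one trial stage: heritability h2 and r replications.

    ``h2 == 1`` is accepted as an exact noiseless test mode (sigma_e^2 = 0);
    otherwise 0 < h2 < 1 is required. ``sigma_a2`` is the additive variance
    of the founder population, which the effect scaling fixes at 1.
    """

    h2: float
    r: int = 1
    sigma_a2: float = 1.0

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("need at least one replication")
        if not 0 < self.h2 <= 1:
            raise ValueError("heritability must satisfy 0 < h2 <= 1")

    @property
    def sigma_e2(self) -> float:
        if self.h2 == 1.0:
            return 0.0
        return environmental_variance(self.h2, self.sigma_a2)

    @property
    def noise_sd(self) -> float:
        """Standard deviation of the entry-mean environmental deviate."""
        return float(np.sqrt(self.sigma_e2 / self.r))


def sample_correlated_effects(
    n_qtl: int, R: float, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-QTL (MC, IC) effect pairs from a bivariate standard normal
    with correlation R.

    R = 1 duplicates the MC effects exactly (degenerate test mode); any other
    |R| >= 1 is rejected.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n_qtl)
    if R == 1.0:
        return a, a.copy()
    if abs(R) >= 1.0:
        raise ValueError("genetic correlation must satisfy |R| < 1 (or R == 1)")
    b = R * a + np.sqrt(1.0 - R * R) * rng.standard_normal(n_qtl)
    return a, b


def genetic_values_at_qtl(
    qtl_dosages: np.ndarray, effects: np.ndarray, offset: float = 0.0
) -> np.ndarray:
    """GVs from a dosage matrix already restricted to the QTL columns."""
    return qtl_dosages.astype(np.float64) @ effects - offset


@njit(cache=True)
def _gv_kernel(haps, qtl, eff, offset, out):  # pragma: no cover
    n = haps.shape[0]
    for i in range(n):
        s = 0.0
        for k in range(qtl.size):
            j = qtl[k]
            d = haps[i, 0, j] + haps[i, 1, j]
            if d:
                s += d * eff[k]
        out[i] = s - offset


def genetic_values_from_haps(
    haps: np.ndarray, arch: "TraitArchitecture", trait: str
) -> np.ndarray:
    """GVs straight from an (n, 2, L) haplotype array, without materializing
    the dosage matrix (hot path of the breeding-scheme engine)."""
    out = np.empty(haps.shape[0], dtype=np.float64)
    _gv_kernel(haps, arch.qtl_indices, arch.effects(trait), arch.offset(trait), out)
    return out


def scale_architecture(
    arch: TraitArchitecture, founders: FounderPopulation
) -> TraitArchitecture:
    """Rescale effects so founder GVs have mean 0 and variance 1 per trait.

    The rescaling is affine per trait (divide effects by the founder GV
    standard deviation, then subtract the resulting mean), so the MC-IC
    correlation structure is untouched.
    """
    qtl_dos = founders.dosages()[:, arch.qtl_indices]
    new = {}
    for trait in TRAITS:
        raw = genetic_values_at_qtl(qtl_dos, arch.effects(trait))
        sd = raw.std()
        if sd == 0:
            raise ValueError(f"founder {trait} genetic variance is zero")
        eff = arch.effects(trait) / sd
        new[trait] = (eff, float(np.mean(qtl_dos @ eff)))
    return replace(
        arch,
        effects_mc=new["MC"][0],
        effects_ic=new["IC"][0],
        offset_mc=new["MC"][1],
        offset_ic=new["IC"][1],
        scaled=True,
    )


def fix_founder_correlation(
    arch: TraitArchitecture, founders: FounderPopulation
) -> TraitArchitecture:
    """Adjust the IC effects so the *realized* founder GV correlation equals
    the target R exactly.

    Sampling effect pairs from a bivariate normal fixes the correlation only
    in expectation; across 100 founders the realized GV correlation then
    scatters with a standard error near 0.1. Following the design intent of
    fixing the genetic correlation, the IC effect vector is replaced by the
    combination R * a + sqrt(1 - R^2) * w of the MC effects ``a`` and the
    component ``w`` of the sampled IC effects orthogonal to the MC GVs in
    founder space (both standardized on founder GVs). The MC effects are
    untouched.
    """
    R = arch.target_correlation
    if not -1.0 < R < 1.0 and R != 1.0:
        raise ValueError("target correlation must satisfy |R| < 1 (or R == 1)")
    qtl_dos = founders.dosages()[:, arch.qtl_indices].astype(np.float64)
    u = qtl_dos @ arch.effects_mc
    v = qtl_dos @ arch.effects_ic
    su = u.std()
    if su == 0:
        raise ValueError("founder MC genetic variance is zero")
    a = arch.effects_mc / su
    u = u / su
    if R == 1.0:  # degenerate test mode: traits coincide
        return replace(arch, effects_ic=arch.effects_mc.copy())
    r_uv = float(np.corrcoef(u, v)[0, 1])
    w_eff = arch.effects_ic / v.std() - r_uv * a
    w = qtl_dos @ w_eff
    sw = w.std()
    if sw == 0:
        raise ValueError("IC effects are collinear with MC effects in founder space")
    eff_ic = R * a + np.sqrt(1.0 - R * R) * w_eff / sw
    return replace(arch, effects_ic=eff_ic)


def genetic_value(
    genotype: np.ndarray, arch: TraitArchitecture, trait: str = "MC"
) -> np.ndarray | float:
    """Additive GV of one genotype (1-D dosage vector over all sites) or a
    stack of genotypes (2-D, one row each)."""
    g = np.asarray(genotype)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("dosages must be 0, 1 or 2")
    gv = genetic_values_at_qtl(g[..., arch.qtl_indices], arch.effects(trait), arch.offset(trait))
    return float(gv) if g.ndim == 1 else gv


def ic_combination_gv(g_f, g_t):
    """GV of an intercrop combination: mean of the two components' IC GVs."""
    return (np.asarray(g_f) + np.asarray(g_t)) / 2.0


def environmental_variance(h2: float, sigma_a2: float = 1.0) -> float:
    """sigma_e^2 = (1 - h2) * sigma_a2 / h2 for a single unreplicated plot."""
    if not 0 < h2 < 1:
        raise ValueError("heritability must satisfy 0 < h2 < 1")
    if sigma_a2 <= 0:
        raise ValueError("additive variance must be positive")
    return (1.0 - h2) * sigma_a2 / h2


def phenotype(
    gv: np.ndarray | float, settings: PhenotypeSettings, rng: np.random.Generator
) -> np.ndarray | float:
    """Entry-mean phenotype: GV plus one Normal(0, sigma_e^2 / r) deviate."""
    g = np.asarray(gv, dtype=np.float64)
    if settings.noise_sd == 0.0:
        return g.copy()
    return g + rng.normal(0.0, settings.noise_sd, size=g.shape)
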