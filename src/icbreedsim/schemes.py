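"""Stage machinery of the two line-breeding schemes and their intercrop variants.

Both schemes run three yield-trial stages per breeding cycle under a fixed
phenotyping budget that is identical for every variant:

* PYT (preliminary): 784 single-replicate plots,
* AYT (advanced): 144 entries in 2 replicates (288 plots),
* EYT (elite): 36 entries in 4 replicates (144 plots).

In monocrop (MC) mode a plot holds one line of one crop, so PYT hosts 392
faba-bean plus 392 triticale lines; in intercrop (IC) mode a plot holds one
faba-bean x triticale combination, so the same budgets host 28 x 28 = 784,
12 x 12 = 144 and 6 x 6 = 36 combinations. The "switch stage" is the first
stage run in IC mode; every stage from there on, and the EYT always, is IC.

Line development differs between the schemes. DH: each of the 14 S0 plants
yields doubled-haploid lines directly, without selection. Ear/pod-to-row
(EPR): each S0 is selfed to a family nursery and advanced S1 to S4 under
within-family visual selection on the MC trait at h2 = 0.1, keeping the top
8% each generation; the same 8% rule at S4 advances the PYT entrants, so
the nursery holds 350 plants per family when 28 advance (MC scenarios, 392
total) and 25 when 2 advance (IC testing from the PYT, 28 total).

IC-mode selection scores a line by the mean phenotype of all combinations it
appears in — an empirical general mixing ability — and truncation-selects
per crop. Ties are broken by stable entry order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .founders import GeneticMap
from .meiosis import Population
from .traits import (
    PhenotypeSettings,
    TraitArchitecture,
    genetic_values_from_haps,
    ic_combination_gv,
    phenotype,
)

__all__ = [
    "STAGES",
    "StagePlan",
    "SchemeConfig",
    "CropContext",
    "ICCombination",
    "ICSet",
    "MCEntries",
    "StageResult",
    "build_stage_plans",
    "epr_fixation",
    "dh_production",
    "form_ic_combinations",
    "run_stage",
    "recycle_parents",
]

STAGES = ("PYT", "AYT", "EYT")

# Per-crop entry counts at each stage and the per-crop count advanced out of
# it, for MC and IC testing modes. The plot budget is the invariant.
_PLOTS = {"PYT": 784, "AYT": 288, "EYT": 144}
_REPS = {"PYT": 1, "AYT": 2, "EYT": 4}
_LINES_PER_CROP = {
    "MC": {"PYT": 392, "AYT": 72, "EYT": 6},
    "IC": {"PYT": 28, "AYT": 12, "EYT": 6},
}


@dataclass(frozen=True)
class StagePlan:
    """One trial stage: testing mode, entry count, replications, selected."""

    stage: str
    mode: str
    n_entries: int
    n_reps: int
    n_select_per_crop: int | None

    @property
    def n_plots(self) -> int:
        return self.n_entries * self.n_reps

    def lines_per_crop(self) -> int:
        return _LINES_PER_CROP[self.mode][self.stage]


def build_stage_plans(switch_stage: str) -> tuple[StagePlan, ...]:
    """Stage plans for a given switch stage (first IC-tested stage).

    The EYT is always IC mode: genetic progress is measured on the 36 elite
    combinations in every scheme.
    """
    if switch_stage not in STAGES:
        raise ValueError(f"switch stage must be one of {STAGES}")
    switch_i = STAGES.index(switch_stage)
    plans = []
    for i, stage in enumerate(STAGES):
        mode = "IC" if i >= switch_i or stage == "EYT" else "MC"
        per_crop = _LINES_PER_CROP[mode][stage]
        n_entries = per_crop * per_crop if mode == "IC" else 2 * per_crop
        n_reps = _REPS[stage]
        if stage == "EYT":
            n_select = None
        else:
            next_stage = STAGES[i + 1]
            next_mode = "IC" if i + 1 >= switch_i or next_stage == "EYT" else "MC"
            n_select = _LINES_PER_CROP[next_mode][next_stage]
        plan = StagePlan(stage, mode, n_entries, n_reps, n_select)
        if plan.n_plots != _PLOTS[stage]:
            raise AssertionError("stage plan violates the plot budget")
        plans.append(plan)
    return tuple(plans)


@dataclass(frozen=True)
class SchemeConfig:
    """Full parameterization of one breeding scheme variant."""

    method: str  # "DH" or "EPR"
    switch_stage: str  # first IC-tested stage
    n_crosses: int = 14
    n_founder_parents: int = 14
    epr_selfing_generations: int = 4
    visual_h2: float = 0.1
    advancement_fraction: float = 0.08  # visual within-family selection rate
    recycle_from: str = "EYT"  # parent pool: EYT entrants or AYT entrants
    ic_selection: str = "mixing_ability"  # or "combination": top combo plots
    stage_plans: tuple[StagePlan, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.method not in ("DH", "EPR"):
            raise ValueError("method must be 'DH' or 'EPR'")
        if self.recycle_from not in ("AYT", "EYT"):
            raise ValueError("recycle_from must be 'AYT' or 'EYT'")
        if self.stage_plans is None:
            object.__setattr__(self, "stage_plans", build_stage_plans(self.switch_stage))

    @property
    def lines_per_family_to_pyt(self) -> int:
        """Fixation output per S0 family: 28 when the PYT is MC-tested
        (392 lines per crop), 2 when IC testing starts at the PYT (28 lines)."""
        return self.stage_plans[0].lines_per_crop() // self.n_crosses

    @property
    def nursery_size_per_family(self) -> int:
        """EPR family-nursery size, scaled so that the within-family visual
        advancement is always ``advancement_fraction`` (8%): 350 plants when
        28 advance per family, 25 when 2 advance."""
        return round(self.lines_per_family_to_pyt / self.advancement_fraction)

    def plan(self, stage: str) -> StagePlan:
        return self.stage_plans[STAGES.index(stage)]


@dataclass
class CropContext:
    """One crop's genetic map and (scaled) trait architecture, with the QTL
    indices expressed on the loci carried by the populations in play."""

    gmap: GeneticMap
    arch: TraitArchitecture

    def gv(self, pop: Population, trait: str) -> np.ndarray:
        return genetic_values_from_haps(pop.haps, self.arch, trait)


# ---------------------------------------------------------------------------
# line development (fixation)
# ---------------------------------------------------------------------------


def _top_k_per_family(scores: np.ndarray, n_families: int, k: int) -> np.ndarray:
    """Indices of the k best scores within each equal-sized family block;
    stable order breaks ties. ``scores`` is ordered family-major."""
    per_fam = scores.size // n_families
    if k > per_fam:
        raise ValueError("selection count exceeds family size")
    blocks = scores.reshape(n_families, per_fam)
    order = np.argsort(-blocks, axis=1, kind="stable")[:, :k]
    return (order + per_fam * np.arange(n_families)[:, None]).ravel()


def epr_fixation(
    s0: Population,
    config: SchemeConfig,
    ctx: CropContext,
    rng: np.random.Generator,
) -> Population:
    """Ear/pod-to-row fixation: self S0 plants to S4 family nurseries under
    within-family visual selection, then advance the PYT entrants.

    Each of the 14 S0 plants founds one family. Selfing the S0 fills a
    nursery of ``nursery_size_per_family`` S1 plants; at S1, S2 and S3 the
    top 8% per family (visual MC phenotype at ``visual_h2``) are selfed
    onward, refilling the nursery; at S4 the same 8% rule advances the
    ``lines_per_family_to_pyt`` PYT entrants.
    """
    n_fam = config.n_crosses
    if s0.size != n_fam:
        raise ValueError(f"expected {n_fam} S0 plants, got {s0.size}")
    nursery = config.nursery_size_per_family
    keep = config.lines_per_family_to_pyt  # 8% of the nursery
    settings = PhenotypeSettings(h2=config.visual_h2, r=1)

    # S0 -> S1: each single S0 plant fills its family nursery
    parent_idx = np.repeat(np.arange(n_fam), nursery)
    pop = s0.self_batch(parent_idx, ctx.gmap, rng, generation="S1")

    for gen in range(2, config.epr_selfing_generations + 1):
        scores = phenotype(ctx.gv(pop, "MC"), settings, rng)
        kept = _top_k_per_family(scores, n_fam, keep)
        # each kept plant contributes ~nursery/keep selfed progeny
        reps = int(np.ceil(nursery / keep))
        parent_idx = np.repeat(kept.reshape(n_fam, keep), reps, axis=1)[:, :nursery].ravel()
        pop = pop.self_batch(parent_idx, ctx.gmap, rng, generation=f"S{gen}")

    scores = phenotype(ctx.gv(pop, "MC"), settings, rng)
    advanced = _top_k_per_family(scores, n_fam, config.lines_per_family_to_pyt)
    return pop.subset(advanced)


def dh_production(
    s0: Population,
    lines_per_family: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> Population:
    """Doubled-haploid line development: every S0 plant yields
    ``lines_per_family`` fully homozygous DH0 lines, without selection."""
    parent_idx = np.repeat(np.arange(s0.size), lines_per_family)
    return s0.dh_batch(parent_idx, gmap, rng)


# ---------------------------------------------------------------------------
# trial stages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCombination:
    """A single faba-bean x triticale entry of an IC trial."""

    fb_index: int
    tr_index: int
    gv_ic: float
    phenotype: float | None = None


@dataclass
class ICSet:
    """Full factorial of IC combinations between two line sets.

    ``gv_matrix[i, j]`` is the combination GV of faba-bean line i with
    triticale line j, the mean of their component IC GVs.
    """

    gv_f: np.ndarray  # IC GVs of the faba-bean lines
    gv_t: np.ndarray  # IC GVs of the triticale lines

    @property
    def n_combinations(self) -> int:
        return self.gv_f.size * self.gv_t.size

    @property
    def gv_matrix(self) -> np.ndarray:
        return ic_combination_gv(self.gv_f[:, None], self.gv_t[None, :])


@dataclass
class MCEntries:
    """Monocrop-stage candidates: per crop, the MC GVs of its lines."""

    gv: dict[str, np.ndarray]


def form_ic_combinations(gv_ic_f: np.ndarray, gv_ic_t: np.ndarray) -> ICSet:
    """All |fb| x |tr| pairings of two line sets, with combination GVs."""
    gv_f = np.asarray(gv_ic_f, dtype=float)
    gv_t = np.asarray(gv_ic_t, dtype=float)
    if gv_f.size == 0 or gv_t.size == 0:
        raise ValueError("both crops need at least one line")
    return ICSet(gv_f=gv_f, gv_t=gv_t)


@dataclass
class StageResult:
    """Outcome of one trial stage."""

    plan: StagePlan
    selected: dict[str, np.ndarray]  # crop -> indices into the stage entries
    scores: dict[str, np.ndarray]  # crop -> per-line selection score
    n_plots: int
    mean_gv: float  # mean true GV of the tested entries (IC: combinations)
    var_gv: float  # variance (ddof=1) of the tested entries' true GVs
    phenotypes: np.ndarray | None = None


def _top_k_stable(scores: np.ndarray, k: int) -> np.ndarray:
    return np.argsort(-scores, kind="stable")[:k]


def _lines_of_top_combinations(phen: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Walk combination plots best-first, collecting up to k distinct lines
    per crop (alternative IC selection rule)."""
    order = np.argsort(-phen, axis=None, kind="stable")
    rows, cols = np.unravel_index(order, phen.shape)
    sel_f: list[int] = []
    sel_t: list[int] = []
    for i, j in zip(rows, cols):
        if len(sel_f) < k and i not in sel_f:
            sel_f.append(int(i))
        if len(sel_t) < k and j not in sel_t:
            sel_t.append(int(j))
        if len(sel_f) == k and len(sel_t) == k:
            break
    return np.array(sel_f), np.array(sel_t)


def run_stage(
    entries: MCEntries | ICSet,
    plan: StagePlan,
    settings: PhenotypeSettings,
    rng: np.random.Generator,
    crops: tuple[str, str] = ("faba_bean", "triticale"),
    ic_selection: str = "mixing_ability",
) -> StageResult:
    """Phenotype one trial stage and truncation-select per crop.

    MC mode: each line is phenotyped on its MC trait with entry-mean noise
    variance sigma_e^2 / r and the top ``n_select_per_crop`` per crop advance.
    IC mode: each combination is phenotyped on its combination GV (one noise
    draw per combination plot-mean); a line's score is the mean phenotype
    over all its combinations and the top ``n_select_per_crop`` per crop
    advance. The EYT phenotypes its 36 combinations but selects nothing
    within the cycle.
    """
    if settings.r != plan.n_reps:
        raise ValueError("phenotype settings must use the stage's replication")
    if isinstance(entries, MCEntries):
        if plan.mode != "MC":
            raise ValueError("MC entries supplied to an IC-mode stage")
        sizes = {c: entries.gv[c].size for c in crops}
        if sum(sizes.values()) != plan.n_entries:
            raise ValueError(
                f"{plan.stage}: {sum(sizes.values())} entries != budget {plan.n_entries}"
            )
        gv_all = np.concatenate([entries.gv[c] for c in crops])
        scores, selected = {}, {}
        phen_all = []
        for c in crops:
            phen = phenotype(entries.gv[c], settings, rng)
            scores[c] = phen
            phen_all.append(phen)
            if plan.n_select_per_crop is not None:
                selected[c] = _top_k_stable(phen, plan.n_select_per_crop)
        return StageResult(
            plan=plan,
            selected=selected,
            scores=scores,
            n_plots=plan.n_plots,
            mean_gv=float(gv_all.mean()),
            var_gv=float(gv_all.var(ddof=1)),
            phenotypes=np.concatenate(phen_all),
        )

    if plan.mode != "IC":
        raise ValueError("IC entries supplied to an MC-mode stage")
    if entries.n_combinations != plan.n_entries:
        raise ValueError(
            f"{plan.stage}: {entries.n_combinations} combinations != budget {plan.n_entries}"
        )
    gv = entries.gv_matrix
    phen = phenotype(gv, settings, rng)
    scores = {crops[0]: phen.mean(axis=1), crops[1]: phen.mean(axis=0)}
    selected = {}
    if plan.n_select_per_crop is not None:
        if ic_selection == "mixing_ability":
            selected = {
                c: _top_k_stable(scores[c], plan.n_select_per_crop) for c in crops
            }
        elif ic_selection == "combination":
            selected = _lines_of_top_combinations(phen, plan.n_select_per_crop)
            selected = dict(zip(crops, selected))
        else:
            raise ValueError(f"unknown IC selection rule {ic_selection!r}")
    return StageResult(
        plan=plan,
        selected=selected,
        scores=scores,
        n_plots=plan.n_plots,
        mean_gv=float(gv.mean()),
        var_gv=float(gv.var(ddof=1)),
        phenotypes=phen,
    )


def recycle_parents(
    n_available: int, n_crosses: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_crosses`` within-crop parent pairs from a survivor pool.

    Each pair is two distinct survivors drawn uniformly; distinct crosses may
    repeat the same pair (the pool can be as small as 12 lines).
    """
    if n_available < 2:
        raise ValueError("need at least two distinct parents to recycle")
    pairs = np.empty((n_crosses, 2), dtype=np.int64)
    for i in range(n_crosses):
        pairs[i] = rng.choice(n_available, size=2, replace=False)
    return pairs
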