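"""Scenario runner: multi-cycle, multi-replicate breeding simulations.

A scenario fixes the line-development method (DH or EPR), the switch stage
(PYT, AYT or EYT), the trait heritability h2 and the MC-IC genetic
correlation R. Each replicate independently simulates founder genomes and
trait architectures for both crops and then runs ``n_cycles`` breeding
cycles; genetic progress is recorded as the mean and variance of the true
IC GVs of the 36 combinations tested at the EYT each cycle.

Replicate seeds are derived from ``(base_seed, scenario key, replicate)``
through :class:`numpy.random.SeedSequence`, so results are independent of
execution order and worker count.

By default the engine carries only the 1000 QTL columns of each genome
through the breeding machinery. Because meiosis depends only on map
positions and non-QTL sites never feed selection or measurement, this is an
exact-equivalence restriction, not an approximation; full-genome bookkeeping
is available with ``restrict_to_qtl=False``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .founders import (
    FounderPopulation,
    GenomeSpec,
    designate_qtl,
    simulate_founder_haplotypes,
    simulate_founder_haplotypes_coalescent,
)
from .meiosis import Population
from .schemes import (
    CropContext,
    MCEntries,
    SchemeConfig,
    StageResult,
    dh_production,
    epr_fixation,
    form_ic_combinations,
    recycle_parents,
    run_stage,
)
from .traits import (
    PhenotypeSettings,
    TraitArchitecture,
    fix_founder_correlation,
    sample_correlated_effects,
    scale_architecture,
)

__all__ = [
    "CROPS",
    "ScenarioConfig",
    "Trajectory",
    "ConvergenceResult",
    "CycleState",
    "init_replicate",
    "run_cycle",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "detect_convergence",
    "summarize_grid",
]

CROPS = ("faba_bean", "triticale")

_METHODS = ("DH", "EPR")
_SWITCHES = ("PYT", "AYT", "EYT")


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the scenario grid."""

    method: str
    switch_stage: str
    h2: float
    R: float
    n_cycles: int = 20
    n_replicates: int = 100
    base_seed: int = 0
    n_founders: int = 100
    n_sites: int = 2000
    n_qtl: int = 1000
    genetic_length_m: float = 1.0
    visual_h2: float = 0.1
    recycle_from: str = "EYT"
    ic_selection: str = "mixing_ability"
    founder_backend: str = "coalescent"  # or "beta": Beta(0.5, 0.5) spectrum
    restrict_to_qtl: bool = True
    noiseless: bool = False  # test mode: every phenotype equals its GV

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("need at least one breeding cycle")

    @property
    def label(self) -> str:
        return f"{self.method}_{self.switch_stage}_h{self.h2:g}_R{self.R:g}"

    def scheme(self) -> SchemeConfig:
        return SchemeConfig(
            method=self.method,
            switch_stage=self.switch_stage,
            visual_h2=1.0 if self.noiseless else self.visual_h2,
            recycle_from=self.recycle_from,
            ic_selection=self.ic_selection,
        )

    def genome_specs(self) -> dict[str, GenomeSpec]:
        kw = dict(
            genetic_length_m=self.genetic_length_m,
            n_sites=self.n_sites,
            n_qtl=self.n_qtl,
        )
        return {
            "faba_bean": GenomeSpec.faba_bean(**kw),
            "triticale": GenomeSpec.triticale(**kw),
        }

    def stage_settings(self, n_reps: int) -> PhenotypeSettings:
        h2 = 1.0 if self.noiseless else self.h2
        return PhenotypeSettings(h2=h2, r=n_reps)

    def replicate_seed(self, replicate: int) -> np.random.SeedSequence:
        """Seed for one replicate, derived from (base_seed, replicate) only.

        Scenarios run with the same base seed share founder histories,
        trait architectures and cycle-1 parents replicate-by-replicate
        (common random numbers), so scheme contrasts are paired on the
        founder history and are not blurred by it. Streams diverge as soon
        as the schemes consume randomness differently.
        """
        return np.random.SeedSequence((int(self.base_seed), int(replicate)))


@dataclass
class ConvergenceResult:
    converged: bool
    cycle: int | None
    threshold: float = 0.005


@dataclass
class Trajectory:
    """Per-replicate, per-cycle EYT records of one scenario."""

    config: ScenarioConfig
    data: pd.DataFrame  # columns: replicate, cycle, mean_ic_gv, var_ic_gv

    def mean_trajectory(self) -> np.ndarray:
        """Replicate-averaged mean IC GV per cycle (cycle order)."""
        return (
            self.data.groupby("cycle")["mean_ic_gv"].mean().sort_index().to_numpy()
        )

    def mean_variance_trajectory(self) -> np.ndarray:
        return (
            self.data.groupby("cycle")["var_ic_gv"].mean().sort_index().to_numpy()
        )

    @property
    def n_replicates(self) -> int:
        return self.data["replicate"].nunique()

    def convergence(self, threshold: float = 0.005) -> ConvergenceResult:
        return detect_convergence(self.mean_trajectory(), threshold)


@dataclass
class CycleState:
    """Carry-over between breeding cycles of one replicate."""

    contexts: dict[str, CropContext]
    parent_pops: dict[str, Population]
    parent_pairs: dict[str, np.ndarray]
    rng: np.random.Generator


def _build_crop(
    spec: GenomeSpec,
    R: float,
    restrict: bool,
    rng: np.random.Generator,
    backend: str = "coalescent",
) -> tuple[CropContext, Population]:
    if backend == "coalescent":
        founders = simulate_founder_haplotypes_coalescent(spec, rng, n_founders=100)
    elif backend == "beta":
        founders = simulate_founder_haplotypes(spec, rng, n_founders=100)
    else:
        raise ValueError(f"unknown founder backend {backend!r}")
    qtl = designate_qtl(founders, spec.n_qtl, rng)
    eff_mc, eff_ic = sample_correlated_effects(spec.n_qtl, R, rng)
    arch = TraitArchitecture(qtl, eff_mc, eff_ic, target_correlation=R)
    arch = scale_architecture(fix_founder_correlation(arch, founders), founders)
    if restrict:
        founders = FounderPopulation(
            haplotypes=founders.haplotypes[:, qtl],
            gmap=founders.gmap.subset(qtl),
            spec=spec,
        )
        arch = replace(arch, qtl_indices=np.arange(qtl.size))
    ctx = CropContext(gmap=founders.gmap, arch=arch)
    return ctx, Population.from_founders(founders)


def init_replicate(config: ScenarioConfig, seed) -> CycleState:
    """Simulate founders and architectures and pick the cycle-1 parents."""
    rng = np.random.default_rng(seed)
    scheme = config.scheme()
    contexts: dict[str, CropContext] = {}
    pops: dict[str, Population] = {}
    pairs: dict[str, np.ndarray] = {}
    for crop, spec in config.genome_specs().items():
        ctx, pop = _build_crop(
            spec, config.R, config.restrict_to_qtl, rng, config.founder_backend
        )
        parents = rng.choice(pop.size, size=scheme.n_founder_parents, replace=False)
        pool = pop.subset(parents)
        contexts[crop] = ctx
        pops[crop] = pool
        pairs[crop] = recycle_parents(pool.size, scheme.n_crosses, rng)
    return CycleState(contexts=contexts, parent_pops=pops, parent_pairs=pairs, rng=rng)


def run_cycle(
    state: CycleState,
    config: ScenarioConfig,
    cycle_index: int = 0,
    selection_log: list | None = None,
) -> tuple[CycleState, dict[str, float]]:
    """One breeding cycle: cross, fix lines, run PYT/AYT/EYT, recycle parents.

    Returns the next state and the cycle record (EYT mean and variance of
    the 36 combination IC GVs, plus the per-stage plot counts). If
    ``selection_log`` is a list, one row per stage entry (cycle, stage,
    mode, crop, line index, family, score, selected flag) is appended.
    """
    scheme = config.scheme()
    rng = state.rng
    record: dict[str, float] = {}

    # crossing + fixation, per crop
    entrants: dict[str, Population] = {}
    for crop in CROPS:
        ctx = state.contexts[crop]
        s0 = state.parent_pops[crop].cross_pairs(
            state.parent_pairs[crop], 1, ctx.gmap, rng
        )
        if scheme.method == "DH":
            fixed = dh_production(s0, scheme.lines_per_family_to_pyt, ctx.gmap, rng)
        else:
            fixed = epr_fixation(s0, scheme, ctx, rng)
        entrants[crop] = fixed

    pools = {crop: entrants[crop] for crop in CROPS}
    recycle_pool: dict[str, Population] | None = None

    for plan in scheme.stage_plans:
        settings = config.stage_settings(plan.n_reps)
        if plan.mode == "MC":
            entries = MCEntries(
                gv={c: state.contexts[c].gv(pools[c], "MC") for c in CROPS}
            )
        else:
            entries = form_ic_combinations(
                state.contexts["faba_bean"].gv(pools["faba_bean"], "IC"),
                state.contexts["triticale"].gv(pools["triticale"], "IC"),
            )
        result: StageResult = run_stage(
            entries, plan, settings, rng, crops=CROPS,
            ic_selection=scheme.ic_selection,
        )
        record[f"plots_{plan.stage}"] = result.n_plots
        if selection_log is not None:
            for crop in CROPS:
                chosen = (
                    set(result.selected[crop].tolist())
                    if crop in result.selected
                    else set()
                )
                for i, score in enumerate(result.scores[crop]):
                    selection_log.append(
                        dict(
                            cycle=cycle_index,
                            stage=plan.stage,
                            mode=plan.mode,
                            crop=crop,
                            line=i,
                            family=int(pools[crop].family[i]),
                            score=float(score),
                            selected=i in chosen,
                        )
                    )
        if plan.stage == "AYT":
            recycle_pool = dict(pools)  # lines that made it to the AYT
        if plan.stage == "EYT":
            if config.recycle_from == "EYT":
                recycle_pool = dict(pools)
            record["mean_ic_gv"] = result.mean_gv
            record["var_ic_gv"] = result.var_gv
            record["n_eyt_combinations"] = result.plan.n_entries
        else:
            pools = {c: pools[c].subset(result.selected[c]) for c in CROPS}

    assert recycle_pool is not None
    next_pops, next_pairs = {}, {}
    for crop in CROPS:
        pool = recycle_pool[crop]
        next_pops[crop] = pool
        next_pairs[crop] = recycle_parents(pool.size, scheme.n_crosses, rng)
    next_state = CycleState(
        contexts=state.contexts,
        parent_pops=next_pops,
        parent_pairs=next_pairs,
        rng=rng,
    )
    return next_state, record


def run_replicate(
    config: ScenarioConfig, replicate: int, selection_log: list | None = None
) -> pd.DataFrame:
    """All cycles of one independent replicate."""
    state = init_replicate(config, config.replicate_seed(replicate))
    rows = []
    for cycle in range(1, config.n_cycles + 1):
        state, record = run_cycle(state, config, cycle, selection_log)
        record.update(replicate=replicate, cycle=cycle)
        rows.append(record)
    return pd.DataFrame(rows)


def run_scenario(config: ScenarioConfig, n_jobs: int = 1) -> Trajectory:
    """Run all replicates of a scenario (embarrassingly parallel)."""
    frames = Parallel(n_jobs=n_jobs)(
        delayed(run_replicate)(config, rep) for rep in range(config.n_replicates)
    )
    data = pd.concat(frames, ignore_index=True)
    return Trajectory(config=config, data=data)


def detect_convergence(
    mean_trajectory: np.ndarray, threshold: float = 0.005
) -> ConvergenceResult:
    """First cycle whose increment over the previous cycle falls below the
    threshold, on the replicate-averaged trajectory (first-hit rule)."""
    m = np.asarray(mean_trajectory, dtype=float)
    if m.size < 2:
        raise ValueError("need at least two cycles to assess convergence")
    small = np.abs(np.diff(m)) < threshold
    if small.any():
        return ConvergenceResult(True, int(np.argmax(small)) + 2, threshold)
    return ConvergenceResult(False, None, threshold)


def _early_gain(m: np.ndarray, n_early: int = 5) -> float:
    n = min(n_early, m.size)
    return float((m[n - 1] - m[0]) / (n - 1))


def summarize_grid(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Comparison table over scenarios: asymptotic mean IC GV (final-cycle
    replicate mean), convergence cycle and early-cycle gain rate."""
    rows = []
    for traj in trajectories:
        m = traj.mean_trajectory()
        conv = traj.convergence()
        c = traj.config
        rows.append(
            dict(
                method=c.method,
                switch_stage=c.switch_stage,
                h2=c.h2,
                R=c.R,
                n_replicates=traj.n_replicates,
                n_cycles=c.n_cycles,
                asymptotic_mean_ic_gv=float(m[-1]),
                convergence_cycle=conv.cycle,
                early_gain_rate=_early_gain(m),
            )
        )
    return pd.DataFrame(rows)


def grid_configs(
    methods=("DH", "EPR"),
    switch_stages=("PYT", "AYT", "EYT"),
    h2_values=(0.3, 0.5, 0.9),
    R_values=(0.3, 0.5, 0.9),
    **kw,
) -> list[ScenarioConfig]:
    """The full scenario grid (2 methods x 3 switches x 3 h2 x 3 R = 54)."""
    return [
        ScenarioConfig(method=m, switch_stage=s, h2=h, R=r, **kw)
        for m, s, h, r in itertools.product(methods, switch_stages, h2_values, R_values)
    ]


def run_grid(configs: list[ScenarioConfig], n_jobs: int = 1) -> list[Trajectory]:
    return [run_scenario(c, n_jobs=n_jobs) for c in configs]


def comparison_configs(
    base_seed: int = 0,
    n_replicates: int = 20,
    n_cycles: int = 15,
    h2: float = 0.5,
    **kw,
) -> list[ScenarioConfig]:
    """Scaled-down scenario set behind the headline scheme comparisons.

    Covers, at one representative heritability, every (method, R, switch)
    cell needed to compare switch stages within each method at low, moderate
    and high MC-IC correlation, and to compare the two methods on matched
    scenarios. Default problem size is 20 replicates x 15 cycles, where the
    qualitative orderings are already stable.
    """
    cells = [
        ("DH", 0.3, "PYT"), ("DH", 0.3, "EYT"),
        ("DH", 0.9, "PYT"), ("DH", 0.9, "AYT"), ("DH", 0.9, "EYT"),
        ("EPR", 0.3, "PYT"), ("EPR", 0.3, "EYT"),
        ("EPR", 0.5, "PYT"), ("EPR", 0.5, "AYT"), ("EPR", 0.5, "EYT"),
        ("EPR", 0.9, "PYT"), ("EPR", 0.9, "AYT"), ("EPR", 0.9, "EYT"),
    ]
    return [
        ScenarioConfig(
            method=m, switch_stage=s, h2=h2, R=r,
            n_cycles=n_cycles, n_replicates=n_replicates, base_seed=base_seed,
            **kw,
        )
        for m, r, s in cells
    ]
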