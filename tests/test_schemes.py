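import numpy as np
import pytest

from icbreedsim.founders import GeneticMap
from icbreedsim.meiosis import Population
from icbreedsim.schemes import (
    CropContext,
    MCEntries,
    SchemeConfig,
    build_stage_plans,
    dh_production,
    epr_fixation,
    form_ic_combinations,
    recycle_parents,
    run_stage,
    _top_k_per_family,
)
from icbreedsim.traits import PhenotypeSettings, TraitArchitecture


@pytest.fixture
def toy_ctx(small_founders, small_arch):
    return CropContext(gmap=small_founders.gmap, arch=small_arch)


def s0_population(founders, rng, n=14):
    pop = Population.from_founders(founders)
    pairs = np.column_stack([rng.choice(pop.size, n), rng.choice(pop.size, n)])
    return pop.cross_pairs(pairs, 1, founders.gmap, rng)


class TestStagePlans:
    @pytest.mark.parametrize("switch", ["PYT", "AYT", "EYT"])
    def test_plot_budget_identical_across_schemes(self, switch):
        plans = build_stage_plans(switch)
        assert [p.n_plots for p in plans] == [784, 288, 144]

    def test_switch_stage_partitions_modes(self):
        assert [p.mode for p in build_stage_plans("PYT")] == ["IC", "IC", "IC"]
        assert [p.mode for p in build_stage_plans("AYT")] == ["MC", "IC", "IC"]
        assert [p.mode for p in build_stage_plans("EYT")] == ["MC", "MC", "IC"]

    def test_entry_counts_and_replications(self):
        pyt, ayt, eyt = build_stage_plans("PYT")
        assert (pyt.n_entries, pyt.n_reps) == (784, 1)  # 28 x 28 combinations
        assert (ayt.n_entries, ayt.n_reps) == (144, 2)  # 12 x 12 combinations
        assert (eyt.n_entries, eyt.n_reps) == (36, 4)  # 6 x 6 combinations
        mc_pyt = build_stage_plans("EYT")[0]
        assert mc_pyt.lines_per_crop() == 392  # 784 single-rep plots, 2 crops

    def test_selection_counts_feed_next_stage(self):
        # MC PYT feeds 12 lines/crop when the AYT is IC, 72 when it stays MC
        assert build_stage_plans("AYT")[0].n_select_per_crop == 12
        assert build_stage_plans("EYT")[0].n_select_per_crop == 72
        assert build_stage_plans("PYT")[1].n_select_per_crop == 6
        assert build_stage_plans("PYT")[2].n_select_per_crop is None

    def test_scheme_config_fixation_output(self):
        assert SchemeConfig("DH", "PYT").lines_per_family_to_pyt == 2
        assert SchemeConfig("DH", "AYT").lines_per_family_to_pyt == 28
        assert SchemeConfig("EPR", "EYT").lines_per_family_to_pyt == 28


class TestICCombinations:
    @pytest.mark.parametrize("nf,nt,total", [(28, 28, 784), (12, 12, 144), (6, 6, 36)])
    def test_full_factorial_counts(self, nf, nt, total, rng):
        ic = form_ic_combinations(rng.normal(size=nf), rng.normal(size=nt))
        assert ic.n_combinations == total
        assert ic.gv_matrix.shape == (nf, nt)

    def test_combination_gv_is_component_mean(self, rng):
        gf, gt = rng.normal(size=4), rng.normal(size=3)
        ic = form_ic_combinations(gf, gt)
        for i in range(4):
            for j in range(3):
                assert ic.gv_matrix[i, j] == (gf[i] + gt[j]) / 2

    def test_empty_line_set_rejected(self):
        with pytest.raises(ValueError):
            form_ic_combinations(np.array([]), np.array([1.0]))


class TestRunStage:
    def test_mc_noiseless_selection_equals_topk_oracle(self, rng):
        plan = build_stage_plans("EYT")[0]  # MC PYT, 392/crop, select 72
        gv = {c: rng.normal(size=392) for c in ("faba_bean", "triticale")}
        res = run_stage(
            MCEntries(gv=gv), plan, PhenotypeSettings(h2=1.0, r=1), rng
        )
        for c, g in gv.items():
            oracle = np.argsort(-g, kind="stable")[:72]
            assert (np.sort(res.selected[c]) == np.sort(oracle)).all()
        assert res.n_plots == 784

    def test_ic_noiseless_selection_equals_row_mean_oracle(self, rng):
        plan = build_stage_plans("PYT")[1]  # IC AYT: 12 x 12, select 6
        gf, gt = rng.normal(size=12), rng.normal(size=12)
        res = run_stage(
            form_ic_combinations(gf, gt), plan, PhenotypeSettings(h2=1.0, r=2), rng
        )
        gv = (gf[:, None] + gt[None, :]) / 2
        fb_oracle = np.argsort(-gv.mean(axis=1), kind="stable")[:6]
        tr_oracle = np.argsort(-gv.mean(axis=0), kind="stable")[:6]
        assert (np.sort(res.selected["faba_bean"]) == np.sort(fb_oracle)).all()
        assert (np.sort(res.selected["triticale"]) == np.sort(tr_oracle)).all()

    def test_budget_mismatch_rejected(self, rng):
        plan = build_stage_plans("EYT")[0]
        gv = {c: rng.normal(size=100) for c in ("faba_bean", "triticale")}
        with pytest.raises(ValueError):
            run_stage(MCEntries(gv=gv), plan, PhenotypeSettings(h2=1.0, r=1), rng)

    def test_replication_mismatch_rejected(self, rng):
        plan = build_stage_plans("PYT")[2]
        ic = form_ic_combinations(np.zeros(6), np.zeros(6))
        with pytest.raises(ValueError):
            run_stage(ic, plan, PhenotypeSettings(h2=0.5, r=1), rng)

    def test_selection_raises_mean_gv_noiseless(self, rng):
        plan = build_stage_plans("EYT")[0]
        gv = {c: rng.normal(size=392) for c in ("faba_bean", "triticale")}
        res = run_stage(MCEntries(gv=gv), plan, PhenotypeSettings(h2=1.0, r=1), rng)
        for c in gv:
            assert gv[c][res.selected[c]].mean() >= gv[c].mean()

    def test_selection_raises_mean_gv_in_expectation_under_noise(self):
        # directional response to truncation selection on a correlated
        # phenotype, averaged over seeded runs
        plan = build_stage_plans("EYT")[0]
        gains = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gv = {c: rng.normal(size=392) for c in ("faba_bean", "triticale")}
            res = run_stage(MCEntries(gv=gv), plan, PhenotypeSettings(h2=0.3, r=1), rng)
            gains.append(
                np.mean([gv[c][res.selected[c]].mean() - gv[c].mean() for c in gv])
            )
        assert np.mean(gains) > 0


class TestFixation:
    def test_dh_counts_and_homozygosity(self, small_founders, rng):
        s0 = s0_population(small_founders, rng)
        dh392 = dh_production(s0, 28, small_founders.gmap, rng)
        dh28 = dh_production(s0, 2, small_founders.gmap, rng)
        assert dh392.size == 392
        assert dh28.size == 28
        assert (dh392.heterozygosity() == 0).all()
        assert np.bincount(dh28.family).tolist() == [2] * 14

    def test_epr_advances_eight_percent(self, small_founders, toy_ctx, rng):
        s0 = s0_population(small_founders, rng)
        ic_cfg = SchemeConfig("EPR", "PYT")  # IC at PYT: 2 per family
        mc_cfg = SchemeConfig("EPR", "AYT")  # MC at PYT: 28 per family
        assert epr_fixation(s0, ic_cfg, toy_ctx, rng).size == 28
        advanced = epr_fixation(s0, mc_cfg, toy_ctx, rng)
        assert advanced.size == 392
        assert np.bincount(advanced.family).tolist() == [28] * 14
        assert advanced.generation == "S4"

    def test_epr_s4_residual_heterozygosity_near_one_sixteenth(
        self, small_founders, toy_ctx, rng
    ):
        s0 = s0_population(small_founders, rng)
        f1_het = s0.heterozygosity().mean()
        s4 = epr_fixation(s0, SchemeConfig("EPR", "AYT"), toy_ctx, rng)
        ratio = s4.heterozygosity().mean() / f1_het
        assert 0.02 < ratio < 0.15  # around (1/2)^4 = 0.0625

    def test_epr_wrong_s0_count_rejected(self, small_founders, toy_ctx, rng):
        s0 = s0_population(small_founders, rng, n=10)
        with pytest.raises(ValueError):
            epr_fixation(s0, SchemeConfig("EPR", "AYT"), toy_ctx, rng)

    def test_top_k_per_family_is_sort_oracle(self, rng):
        scores = rng.normal(size=6 * 10)
        picked = _top_k_per_family(scores, 6, 3)
        for fam in range(6):
            block = scores[fam * 10 : (fam + 1) * 10]
            expect = set(np.argsort(-block, kind="stable")[:3] + fam * 10)
            got = set(picked[fam * 3 : (fam + 1) * 3].tolist())
            assert got == expect

    def test_epr_visual_preselection_beats_dh(self, small_founders, toy_ctx):
        # four rounds of within-family visual selection should leave EPR
        # lines with higher mean MC GV than unselected DH lines
        diffs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            s0 = s0_population(small_founders, rng)
            epr = epr_fixation(s0, SchemeConfig("EPR", "AYT"), toy_ctx, rng)
            dh = dh_production(s0, 28, small_founders.gmap, rng)
            diffs.append(
                toy_ctx.gv(epr, "MC").mean() - toy_ctx.gv(dh, "MC").mean()
            )
        assert np.mean(diffs) > 0


class TestRecycling:
    def test_pair_structure(self, rng):
        pairs = recycle_parents(72, 14, rng)
        assert pairs.shape == (14, 2)
        assert (pairs[:, 0] != pairs[:, 1]).all()
        assert pairs.min() >= 0 and pairs.max() < 72

    def test_small_pool_allows_repeated_pairs(self):
        rng = np.random.default_rng(0)
        pairs = recycle_parents(12, 14, rng)
        assert pairs.max() < 12
        assert (pairs[:, 0] != pairs[:, 1]).all()

    def test_deterministic_given_seed(self):
        a = recycle_parents(12, 14, np.random.default_rng(3))
        b = recycle_parents(12, 14, np.random.default_rng(3))
        assert (a == b).all()

    def test_too_few_parents_rejected(self, rng):
        with pytest.raises(ValueError):
            recycle_parents(1, 14, rng)
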