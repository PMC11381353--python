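import math
import warnings
from dataclasses import replace

import numpy as np
import pytest

from wormsrna.de import ExclusiveSets, Thresholds, call_de, exclusive_sets, run_contrasts
from wormsrna.simulate import (
    SimConfig,
    build_class_membership,
    evaluate_recovery,
    scaled_config,
    simulate_dataset,
)


class TestDeterminismAndShape:
    def test_same_seed_reproduces_exactly(self):
        cfg = scaled_config(21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1, s1, d1, _ = simulate_dataset(cfg)
            m2, s2, d2, _ = simulate_dataset(cfg)
        assert np.array_equal(m1.counts, m2.counts)
        assert s1.records.equals(s2.records)
        assert [x.sample_id for x in d1] == [x.sample_id for x in d2]

    def test_different_seeds_differ(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1, _, _, _ = simulate_dataset(scaled_config(1))
            m2, _, _, _ = simulate_dataset(scaled_config(2))
        assert not np.array_equal(m1.counts, m2.counts)

    def test_matrix_dimensions(self):
        cfg = scaled_config(0, stages=("L4",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mrna, _, designs, _ = simulate_dataset(cfg)
        # 500 simulated genes + alg-3, alg-4, rpl-32; 4 conditions x 2 replicates
        assert mrna.counts.shape == (503, 8)
        assert len([d for d in designs if d.assay == "mRNA"]) == 8

    def test_replicate_counts_per_stage(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, _, designs, _ = simulate_dataset(scaled_config(0))
        l4 = [d for d in designs if d.stage == "L4" and d.assay == "mRNA"]
        adult = [d for d in designs if d.stage == "adult" and d.assay == "mRNA"]
        assert len(l4) == 4 * 2
        assert len(adult) == 4 * 3


class TestClassMembership:
    def test_realized_sizes_exact(self):
        cfg = scaled_config(0)
        _, membership = build_class_membership(cfg)
        for name, size in cfg.class_sizes.items():
            assert len(membership[name]) == size

    def test_alg34_groups_nest_inside_sperm(self):
        cfg = scaled_config(0)
        _, membership = build_class_membership(cfg)
        sperm = membership["sperm"]
        for name in ("alg34_neg", "alg34_pos", "alg34_other"):
            assert membership[name] <= sperm

    def test_infeasible_overlap_rejected_before_sampling(self):
        cfg = replace(
            scaled_config(0),
            class_overlaps={**scaled_config(0).class_overlaps, ("oogenesis", "sperm"): 500},
        )
        with pytest.raises(ValueError, match="infeasible"):
            build_class_membership(cfg)

    def test_mir35_family_has_eight_members(self):
        _, membership = build_class_membership(scaled_config(0))
        assert membership["mir35_family"] == {f"mir-{i}" for i in range(35, 43)}


class TestPlantedStructure:
    def test_sperm_switch_directionality(self, sim_dataset):
        _, _, _, truth = sim_dataset
        sperm = truth.class_membership["sperm"]
        assert sperm <= truth.planted_down["combined:L4"]
        assert sperm <= truth.planted_up["combined:adult"]
        assert not truth.planted_up["heat_only:L4"]
        assert not truth.planted_down["mutation_only:L4"]

    def test_mir35_and_rpl32_stable_across_conditions(self, sim_dataset):
        mrna, srna, designs, truth = sim_dataset
        # rpl-32 mRNA: compare mean counts across the four L4 conditions
        row = mrna.gene_row("rpl-32")
        l4_cols = [j for j, s in enumerate(mrna.sample_ids) if "_L4_" in s]
        vals = row[l4_cols]
        assert vals.std() / vals.mean() < 0.25
        # mir-35-family small-RNA totals: condition-independent up to noise
        fam = truth.class_membership["mir35_family"]
        sub = srna.records[srna.records["gene_id"].isin(fam)]
        per_lib = sub.groupby("sample_id")["weight"].sum()
        assert per_lib.std() / per_lib.mean() < 0.1

    def test_null_config_produces_empty_exclusive_sets(self):
        """No planted effects + no depletion -> exclusive sets almost always empty."""
        empty_runs = 0
        n_runs = 10
        for seed in range(n_runs):
            cfg = scaled_config(seed, effect_matrix={}, stages=("L4",))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mrna, _, designs, _ = simulate_dataset(cfg)
                de = run_contrasts(mrna, designs)
            calls = {k: call_de(v) for k, v in de.items()}
            excl = exclusive_sets(calls["heat_only"], calls["mutation_only"], calls["combined"])
            if not excl.up_exclusive and not excl.down_exclusive:
                empty_runs += 1
        assert empty_runs >= 0.8 * n_runs


class TestEvaluateRecovery:
    def _truth(self, sim_dataset):
        return sim_dataset[3]

    def test_perfect_recovery(self, sim_dataset):
        truth = self._truth(sim_dataset)
        down = truth.planted_down["combined:L4"]
        called = ExclusiveSets(up_exclusive=set(), down_exclusive=set(down))
        scores = evaluate_recovery(called, truth)
        assert scores["precision_down"] == 1.0
        assert scores["recall_down"] == 1.0

    def test_empty_call_convention(self, sim_dataset):
        truth = self._truth(sim_dataset)
        called = ExclusiveSets(up_exclusive=set(), down_exclusive=set())
        scores = evaluate_recovery(called, truth)
        assert scores["recall_down"] == 0.0
        assert math.isnan(scores["precision_down"])

    def test_half_overlap(self, sim_dataset):
        truth = self._truth(sim_dataset)
        planted = sorted(truth.planted_down["combined:L4"])
        called = set(planted[: len(planted) // 2]) | {"bogus-1", "bogus-2"}
        scores = evaluate_recovery(
            ExclusiveSets(up_exclusive=set(), down_exclusive=called), truth
        )
        expected_p = (len(planted) // 2) / len(called)
        assert scores["precision_down"] == pytest.approx(expected_p)
        assert scores["recall_down"] == pytest.approx((len(planted) // 2) / len(planted))


class TestDepletionStructure:
    def test_22g_depletion_ratio_near_planted_single_seed(self, sim_dataset):
        from wormsrna.taxonomy import (
            ClassificationConfig, SmallRNAClass, count_class_per_gene,
            count_family_per_library,
        )

        _, srna, designs, truth = sim_dataset
        sperm = truth.class_membership["sperm"]
        cm = count_class_per_gene(srna, ClassificationConfig(), SmallRNAClass.TWENTYTWO_G)
        fam = count_family_per_library(srna, truth.class_membership["mir35_family"])
        idx = [i for i, g in enumerate(cm.gene_ids) if g in sperm]

        def norm_mean(genotype):
            vals = [
                cm.counts[idx, j].sum() / fam[s]
                for j, s in enumerate(cm.sample_ids)
                if s.startswith(f"{genotype}_20_L4")
            ]
            return np.mean(vals)

        ratio = norm_mean("mut16") / norm_mean("WT")
        assert ratio == pytest.approx(truth.depletion.d22_mut16, rel=0.25)

    def test_26g_depleted_only_under_mutant_heat(self, sim_dataset):
        from wormsrna.taxonomy import ClassificationConfig, SmallRNAClass, count_class_per_gene

        _, srna, _, truth = sim_dataset
        sperm = truth.class_membership["sperm"]
        cm = count_class_per_gene(srna, ClassificationConfig(), SmallRNAClass.TWENTYSIX_G)
        idx = [i for i, g in enumerate(cm.gene_ids) if g in sperm]

        def mean_for(prefix):
            cols = [j for j, s in enumerate(cm.sample_ids) if s.startswith(prefix) and "_L4_" in s]
            return cm.counts[idx][:, cols].sum() / len(cols)

        wt20, wt25 = mean_for("WT_20"), mean_for("WT_25")
        mut20, mut25 = mean_for("mut16_20"), mean_for("mut16_25")
        assert mut25 / mut20 < 0.5          # severe loss only in mutant + heat
        assert 0.7 < wt25 / wt20 < 1.3      # heat alone leaves 26G pools intact
        assert 0.7 < mut20 / wt20 < 1.3     # mutation alone too
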