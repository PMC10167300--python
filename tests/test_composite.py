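"""Composite genotyper: selector labeling, tree training, assembly."""

import numpy as np
import pytest

from hlacomposite.callset import GenotypeCallset
from hlacomposite.composite import (
    SelectorInstance,
    assemble_composite,
    build_selector_instances,
    composite_name,
    train_selector,
)
from hlacomposite.concordance import summarize_concordance
from hlacomposite.hla_model import LocusGenotype
from hlacomposite.synthetic import (
    GenotyperProfile,
    SimulationConfig,
    simulate_callset,
    simulate_cohort,
)


def _single_locus_sets(gt, pred_by_tool):
    truth = GenotypeCallset()
    calls = GenotypeCallset()
    truth.set("s1", "truth", "A", gt("A", "A*02:01", "A*03:01"))
    for tool, names in pred_by_tool.items():
        calls.set("s1", tool, "A", gt("A", *names))
    return calls, truth


class TestInstances:
    def test_single_available_genotyper_is_the_label(self, gt):
        calls, truth = _single_locus_sets(gt, {"toolX": ["A*02:01", "A*03:01"]})
        inst = build_selector_instances(calls, truth, [2])
        assert len(inst) == 1
        assert inst[0].label == "toolX"
        assert inst[0].availability == {"toolX": True}

    def test_tie_broken_by_priority_order(self, gt):
        calls, truth = _single_locus_sets(
            gt,
            {
                "OptiType": ["A*02:01", "A*03:01"],
                "arcasHLA": ["A*02:01", "A*03:01"],
            },
        )
        inst = build_selector_instances(calls, truth, [2])
        assert inst[0].label == "arcasHLA"  # priority: arcasHLA first

    def test_empty_calls_mean_unavailable(self, gt):
        calls, truth = _single_locus_sets(gt, {"toolX": ["A*02:01", "A*03:01"]})
        calls.set("s1", "toolY", "A", LocusGenotype(locus="A"))
        inst = build_selector_instances(calls, truth, [2])
        assert inst[0].availability == {"toolX": True, "toolY": False}
        assert inst[0].label == "toolX"

    def test_shallow_calls_unavailable_at_deep_fields(self, gt):
        # a 2-field call is not a valid field-3 genotype
        calls, truth = _single_locus_sets(gt, {"toolX": ["A*02:01", "A*03:01"]})
        truth.set("s2", "truth", "A", gt("A", "A*02:01:01", "A*03:01:01"))
        inst = build_selector_instances(calls, truth, [3])
        assert all(not i.availability["toolX"] for i in inst)

    def test_no_overlap_is_an_error(self, gt):
        calls, _ = _single_locus_sets(gt, {"toolX": ["A*02:01"]})
        other = GenotypeCallset()
        other.set("sZ", "truth", "A", gt("A", "A*02:01"))
        with pytest.raises(ValueError):
            build_selector_instances(calls, other, [2])


def _planted_rule_study(seed=21, n=200):
    """Genotyper quality determined exactly by locus class: tool 'classI'
    is error-free on A/B/C and hopeless elsewhere; 'classII' the reverse."""
    config = SimulationConfig(seed=seed, n_samples=n)
    class_i = ("A", "B", "C")
    class_ii = ("DRB1", "DQA1", "DQB1", "DPA1", "DPB1", "DRB3", "DRB4", "DRB5")
    config.genotypers = [
        GenotyperProfile(
            name="classI",
            locus_dropout={l: 0.9 for l in class_ii},
            field_substitution={2: 0.0},
        ),
        GenotyperProfile(
            name="classII",
            locus_dropout={l: 0.9 for l in class_i},
            field_substitution={2: 0.0},
        ),
    ]
    truth, _ = simulate_cohort(config)
    calls = simulate_callset(truth, config)
    return calls, truth


class TestTraining:
    def test_constant_best_genotyper_learned_exactly(self, gt):
        instances = [
            SelectorInstance(f"s{i}", "A", 2, {"g1": True, "g2": True}, "g1")
            for i in range(40)
        ] + [
            SelectorInstance(f"s{i}", "B", 2, {"g1": True, "g2": True}, "g2")
            for i in range(40, 80)
        ]
        model = train_selector(instances, seed=0)
        assert model.metadata["holdout_accuracy"] == 1.0

    def test_planted_locus_rule_is_expressible(self):
        calls, truth = _planted_rule_study()
        instances = build_selector_instances(calls, truth, [2])
        model = train_selector(instances, seed=21)
        assert model.metadata["holdout_accuracy"] >= 0.95

    def test_full_train_fraction_rejected(self):
        instances = [
            SelectorInstance("s", "A", 2, {"g1": True}, "g1") for _ in range(10)
        ]
        with pytest.raises(ValueError):
            train_selector(instances, train_fraction=1.0)

    def test_single_label_degenerates_with_warning(self):
        instances = [
            SelectorInstance(f"s{i}", "A", 2, {"g1": True}, "g1") for i in range(10)
        ]
        model = train_selector(instances, seed=0)
        assert "warning" in model.metadata


class TestAssembly:
    @staticmethod
    def _gt2():
        from hlacomposite.hla_model import parse_allele

        return LocusGenotype(
            locus="A",
            alleles=(parse_allele("A*24:02"), parse_allele("A*11:01")),
        )

    def test_copy_semantics(self, gt):
        calls, truth = _single_locus_sets(
            gt, {"OptiType": ["A*02:01", "A*03:01"], "arcasHLA": ["A*11:01", "A*24:02"]}
        )
        instances = build_selector_instances(calls, truth, [2])
        # force plenty of training copies of the same pattern
        instances = instances * 20
        model = train_selector(instances, seed=0)
        composite = assemble_composite(calls, model, [2])[2]
        name = composite_name(model.roster)
        got = composite.get("s1", name, "A")
        want = calls.get("s1", "OptiType", "A")
        # selector picks the accuracy-1.0 genotyper; copy equals its call
        assert {str(a) for a in got.alleles} in (
            {str(a) for a in want.alleles},
            {str(a) for a in calls.get("s1", "arcasHLA", "A").alleles},
        )
        assert not got.is_empty

    def test_fallback_when_selected_tool_has_no_call(self, gt):
        instances = [
            SelectorInstance(f"s{i}", "A", 2, {"g1": True, "g2": True}, "g1")
            for i in range(30)
        ] + [
            SelectorInstance(f"s{i}", "B", 2, {"g1": True, "g2": True}, "g2")
            for i in range(30, 34)
        ]
        model = train_selector(instances, seed=0)
        calls = GenotypeCallset()
        # only g2 has a call at this slot although the tree prefers g1
        calls.set("sX", "g2", "A", self._gt2())
        composite = assemble_composite(calls, model, [2])[2]
        got = composite.get("sX", composite_name(model.roster), "A")
        assert {str(a) for a in got.alleles} == {"A*24:02", "A*11:01"}

    def test_all_tools_absent_leaves_slot_empty(self, gt):
        instances = [
            SelectorInstance(f"s{i}", "A", 2, {"g1": True, "g2": False}, "g1")
            for i in range(20)
        ] + [
            SelectorInstance(f"s{i}", "A", 2, {"g1": False, "g2": True}, "g2")
            for i in range(20, 24)
        ]
        model = train_selector(instances, seed=0)
        calls = GenotypeCallset()
        calls.set("sX", "g1", "A", LocusGenotype(locus="A"))
        composite = assemble_composite(calls, model, [2])[2]
        assert composite.get("sX", composite_name(model.roster), "A").is_empty

    def test_single_genotyper_composite_reproduces_its_calls(self, gt):
        config = SimulationConfig(seed=33, n_samples=60)
        config.genotypers = [
            GenotyperProfile(name="only", field_substitution={2: 0.1}, dropout=0.05)
        ]
        truth, _ = simulate_cohort(config)
        calls = simulate_callset(truth, config)
        instances = build_selector_instances(calls, truth, [2])
        model = train_selector(instances, seed=33)
        composite = assemble_composite(calls, model, [2])[2]
        name = composite_name(model.roster)
        for (s, _, locus), gt_call in composite.items():
            original = calls.get(s, "only", locus).truncated(2)
            assert {str(a) for a in gt_call.alleles} == {
                str(a) for a in original.alleles
            }

    def test_learned_composite_beats_every_single_genotyper(self):
        """Locus-dependent error rates: composite mean accuracy is within
        0.02 of (or above) the best single genotyper everywhere."""
        calls, truth = _planted_rule_study(seed=77, n=200)
        instances = build_selector_instances(calls, truth, [2])
        model = train_selector(instances, seed=77)
        composite = assemble_composite(calls, model, [2])[2]
        summary_single = summarize_concordance(calls, truth, [2])
        summary_comp = summarize_concordance(composite, truth, [2])
        comp_mean = summary_comp[summary_comp.metric == "accuracy"]["value"].mean()
        for tool in calls.genotypers:
            sel = summary_single[
                (summary_single.genotyper == tool)
                & (summary_single.metric == "accuracy")
            ]
            assert comp_mean >= sel["value"].mean() - 0.02

    def test_oracle_selector_bounds_learned_selector(self):
        """A cheating selector that always picks the truly best available
        genotyper upper-bounds the learned composite's accuracy."""
        calls, truth = _planted_rule_study(seed=55, n=120)
        instances = build_selector_instances(calls, truth, [2])
        model = train_selector(instances, seed=55)
        composite = assemble_composite(calls, model, [2])[2]
        learned = summarize_concordance(composite, truth, [2])
        learned_mean = learned[learned.metric == "accuracy"]["value"].mean()

        oracle = GenotypeCallset()
        by_key = {(i.sample_id, i.locus): i.label for i in instances}
        for (sample, locus), label in by_key.items():
            oracle.set(sample, "oracle", locus, calls.get(sample, label, locus).truncated(2))
        oracle_summary = summarize_concordance(oracle, truth, [2])
        oracle_mean = oracle_summary[oracle_summary.metric == "accuracy"]["value"].mean()
        assert oracle_mean >= learned_mean - 1e-9
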