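import logging

import numpy as np
import pandas as pd
import pytest

import stimulon as st
from stimulon.classify import (Thresholds, apply_discard_rules,
                               assemble_affected_set, assign_groups,
                               box_activity, mutant_background_table)
from stimulon.genome import GeneFeature, OperonModel, PromoterBox

from conftest import de_table, make_annotation


def _de(wt_fc, nod_fc, tts_fc, genes=("lead",), p=1e-6):
    """Three genistein contrasts with identical FCs per gene."""
    n = len(genes)
    mk = lambda fc: de_table(list(genes), [fc] * n, [p] * n)  # noqa: E731
    return {("WT", True): mk(wt_fc), ("nodD1", True): mk(nod_fc),
            ("ttsI", True): mk(tts_fc)}


def _linked_box(box_type="NB", gene="lead"):
    return PromoterBox("bx", box_type, "r1", 100, 145, "+",
                       downstream_gene=gene, offset_start=-146,
                       offset_end=-101)


def _ann_one_gene(gene="lead"):
    return make_annotation([GeneFeature(gene, "r1", 246, 845, "+")])


class TestBoxActivity:
    def test_nb_epistasis_active(self):
        """Induced in WT and ttsI-, not nodD1-: the NB is active."""
        call = box_activity(_linked_box("NB"), _ann_one_gene(),
                            _de(8.2, 1.0, 8.0))
        assert call.call == "active"
        assert call.induced == {"WT": True, "nodD1": False, "ttsI": True}

    def test_nb_weak_band_is_weakly_active(self):
        call = box_activity(_linked_box("NB"), _ann_one_gene(),
                            _de(2.5, 1.0, 2.4))
        assert call.call == "weakly_active"

    def test_nb_induced_in_nodD1_is_non_functional(self):
        call = box_activity(_linked_box("NB"), _ann_one_gene(),
                            _de(8.0, 8.0, 8.0))
        assert call.call == "non_functional"
        assert "nodD1" in call.reason

    def test_tb_epistasis_active(self):
        call = box_activity(_linked_box("TB"), _ann_one_gene(),
                            _de(8.0, 1.0, 1.0))
        assert call.call == "active"

    def test_tb_still_induced_without_ttsI_is_non_functional(self):
        """The decoy pattern: induction survives the ttsI knockout."""
        call = box_activity(_linked_box("TB"), _ann_one_gene(),
                            _de(8.0, 1.0, 7.5))
        assert call.call == "non_functional"
        assert call.reason == "ttsI_independent_induction"

    def test_silent_gene_is_non_functional(self):
        call = box_activity(_linked_box("NB"), _ann_one_gene(),
                            _de(1.1, 1.0, 0.9))
        assert call.call == "non_functional"
        assert call.reason == "not_induced"

    def test_no_downstream_gene_not_testable(self):
        box = PromoterBox("bx", "NB", "r1", 100, 145, "+")
        call = box_activity(box, _ann_one_gene(), _de(8.0, 1.0, 8.0))
        assert call.call == "not_testable"
        assert call.reason == "no_downstream_gene"

    def test_low_coverage_not_testable(self):
        de = _de(8.0, 1.0, 8.0)
        for tab in de.values():
            tab["mean_norm_baseline"] = 0.5
            tab["mean_norm_treatment"] = 4.0
        call = box_activity(_linked_box("NB"), _ann_one_gene(), de)
        assert call.call == "not_testable"
        assert call.reason == "low_reads"

    def test_missing_ttsI_contrast_fails_loudly(self):
        de = _de(8.0, 1.0, 8.0)
        del de[("ttsI", True)]
        with pytest.raises(ValueError, match="ttsI"):
            box_activity(_linked_box("TB"), _ann_one_gene(), de)

    def test_syrm_box_has_no_epistasis_rule(self):
        with pytest.raises(ValueError, match="SyrM"):
            box_activity(_linked_box("SyrM"), _ann_one_gene(),
                         _de(8.0, 1.0, 8.0))

    def test_majority_rule_rescues_sub_threshold_lead(self):
        """Half the operon induced speaks for the unit when the lead fails."""
        genes = ("lead", "m2", "m3")
        ann = make_annotation([
            GeneFeature("lead", "r1", 246, 845, "+", operon="op"),
            GeneFeature("m2", "r1", 900, 1400, "+", operon="op"),
            GeneFeature("m3", "r1", 1450, 1900, "+", operon="op")])
        ann.operons["op"] = OperonModel("op", genes, "+")
        de = {("WT", True): de_table(genes, [1.4, 8.0, 8.0], [1e-6] * 3),
              ("nodD1", True): de_table(genes, [1.0, 1.0, 1.0], [0.9] * 3),
              ("ttsI", True): de_table(genes, [1.2, 7.0, 7.5], [1e-6] * 3)}
        call = box_activity(_linked_box("NB"), ann, de)
        assert call.call == "active"
        assert call.regulon == genes


class TestAffectedSet:
    def _operon_ann(self):
        ann = make_annotation([
            GeneFeature("gA", "r1", 246, 845, "+", operon="op"),
            GeneFeature("gB", "r1", 900, 1400, "+", operon="op"),
            GeneFeature("gC", "r1", 3000, 3500, "+"),
            GeneFeature("gD", "r1", 5000, 5600, "+")])
        ann.operons["op"] = OperonModel("op", ("gA", "gB"), "+")
        return ann

    def test_three_inclusion_routes(self):
        ann = self._operon_ann()
        genes = ["gA", "gB", "gC", "gD"]
        de = {("WT", True): de_table(genes, [8.0, 1.8, 2.1, 2.5],
                                     [1e-6, 0.2, 0.01, 0.01])}
        box = PromoterBox("tb1", "TB", "r1", 2800, 2827, "+",
                          downstream_gene="gC", mismatches=0)
        got = assemble_affected_set(de, ann, [box])
        assert got.loc["gA", "route"] == "direct_DEG"
        assert got.loc["gB", "route"] == "operon_rescue"     # FC 1.8 rescued
        assert got.loc["gC", "route"] == "conserved_box_rescue"  # FC 2.1
        assert "gD" not in got.index   # FC 2.5, no box, no DEG operon

    def test_mismatched_box_does_not_rescue(self):
        ann = self._operon_ann()
        genes = ["gA", "gB", "gC", "gD"]
        de = {("WT", True): de_table(genes, [8.0, 1.8, 2.1, 2.5],
                                     [1e-6, 0.2, 0.01, 0.01])}
        box = PromoterBox("tb1", "TB", "r1", 2800, 2827, "+",
                          downstream_gene="gC", mismatches=1)
        got = assemble_affected_set(de, ann, [box])
        assert "gC" not in got.index


class TestDiscardRules:
    def test_opposed_and_identical_copy_discarded(self):
        ann = make_annotation([
            GeneFeature("gBox", "r1", 1001, 1600, "+"),    # NB-controlled
            GeneFeature("gOpp", "r1", 2500, 3100, "-"),    # antisense to NB2
            GeneFeature("gCopy", "r1", 5001, 5600, "+"),   # identical copy
            GeneFeature("gFree", "r1", 7001, 7600, "+")])
        # make gCopy sequence-identical to gBox
        seq = ann.sequences["r1"]
        ann.sequences["r1"] = seq[:5000] + seq[1000:1600] + seq[5600:]
        boxes = [
            PromoterBox("nb1", "NB", "r1", 800, 845, "+",
                        downstream_gene="gBox"),
            PromoterBox("nb2", "NB", "r1", 2301, 2346, "+", opposed=True,
                        opposed_gene="gOpp")]
        affected = pd.DataFrame(
            {"route": ["direct_DEG"] * 4},
            index=pd.Index(["gBox", "gOpp", "gCopy", "gFree"], name="gene"))
        retained, log = apply_discard_rules(affected, ann, boxes)
        assert set(retained.index) == {"gBox", "gFree"}
        assert log.loc["gOpp", "reason"] == "opposed_to_NB"
        assert log.loc["gCopy", "reason"] == "identical_copy"
        assert log.loc["gCopy", "of"] == "gBox"


class TestAssignGroups:
    def test_groups_and_dependence_flags(self):
        genes = ["gNB", "gTB", "gNod", "gAll"]
        ann = make_annotation([
            GeneFeature("gNB", "r1", 1001, 1600, "+"),
            GeneFeature("gTB", "r1", 3001, 3600, "+"),
            GeneFeature("gNod", "r1", 5001, 5600, "+"),
            GeneFeature("gAll", "r1", 7001, 7600, "+")])
        de = {
            ("WT", True): de_table(genes, [8, 8, 6, 6], [1e-6] * 4),
            ("nodD1", True): de_table(genes, [1, 1, 1, 5], [0.9, 0.9, 0.9,
                                                            1e-6]),
            ("ttsI", True): de_table(genes, [8, 1, 6, 6], [1e-6, 0.9, 1e-6,
                                                           1e-6]),
        }
        nb = PromoterBox("nb1", "NB", "r1", 800, 845, "+",
                         downstream_gene="gNB")
        tb = PromoterBox("tb1", "TB", "r1", 2800, 2827, "+",
                         downstream_gene="gTB")
        calls = [box_activity(nb, ann, de), box_activity(tb, ann, de)]
        retained = pd.DataFrame({"route": ["direct_DEG"] * 4},
                                index=pd.Index(genes, name="gene"))
        got = assign_groups(retained, calls, [nb, tb], de, ann)
        assert got.loc["gNB", "group"] == "NB"
        assert got.loc["gTB", "group"] == "TB"
        assert got.loc["gNod", "group"] == "other"
        assert got.loc["gNod", "nodD1_dependent"] == True   # noqa: E712
        assert got.loc["gNod", "ttsI_dependent"] == False   # noqa: E712
        # DEG in all three strains: independent of both regulators
        assert got.loc["gAll", "nodD1_dependent"] == False  # noqa: E712
        assert got.loc["gAll", "ttsI_dependent"] == False   # noqa: E712

    def test_conflicting_claims_resolved_by_proximity(self, caplog):
        genes = ["gX"]
        ann = make_annotation([GeneFeature("gX", "r1", 1001, 1600, "+")])
        de = _de(8.0, 1.0, 1.0, genes=("gX",))
        # TB rule matches (WT only); NB needs ttsI too -> force via two calls
        nb = PromoterBox("nb1", "NB", "r1", 500, 545, "+",
                         downstream_gene="gX")
        tb = PromoterBox("tb1", "TB", "r1", 900, 927, "+",
                         downstream_gene="gX")
        de_nb = _de(8.0, 1.0, 8.0, genes=("gX",))
        calls = [box_activity(nb, ann, de_nb), box_activity(tb, ann, de)]
        assert {c.call for c in calls} == {"active"}
        retained = pd.DataFrame({"route": ["direct_DEG"]},
                                index=pd.Index(genes, name="gene"))
        with caplog.at_level(logging.WARNING):
            got = assign_groups(retained, calls, [nb, tb], de, ann)
        assert got.loc["gX", "group"] == "TB"   # tb1 ends nearer the gene
        assert "claimed by both" in caplog.text

    def test_every_gene_has_group_or_discard_reason(
            self, default_classification):
        res = default_classification
        grouped = set(res.assignments.index)
        discarded = set(res.discards.index)
        assert grouped | discarded == set(res.affected.index)
        assert grouped & discarded == set()


class TestMutantBackground:
    def test_fbpA_pattern_is_reported_separately(self, default_sim,
                                                 default_de,
                                                 default_classification):
        _, truth, _ = default_sim
        planted = set(
            truth.genes.index[truth.genes["regulon_class"]
                              == "mutant_background"])
        got = set(default_classification.mutant_background.index)
        assert planted <= got
        # and those genes are not in the three groups
        assert planted.isdisjoint(set(default_classification.assignments.index))

    def test_empty_without_mutant_nogen_contrasts(self):
        de = _de(8.0, 1.0, 8.0)
        assert mutant_background_table(de).empty


class TestEndToEndRecovery:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_planted_box_calls_recovered(self, seed):
        """Active and non-functional plants (effects >= 5x) are called
        correctly; no-downstream plants come back not testable."""
        ann, truth, cm = st.simulate(st.SimulationConfig(), seed=seed)
        de = st.run_de(cm)
        res = st.classify(ann, de)
        calls = {c.box_id: c.call for c in res.box_calls}
        for bid, row in truth.boxes.iterrows():
            if row["type"] not in ("NB", "TB"):
                continue
            if row["functionality"] == "active":
                assert calls[bid] == "active", bid
            elif row["functionality"] == "non-functional":
                assert calls[bid] == "non_functional", bid
            elif row["functionality"] == "no-downstream-gene":
                assert calls[bid] == "not_testable", bid

    def test_dropping_ttsI_libraries_fails_loudly(self):
        ann, truth, cm = st.simulate(st.SimulationConfig(), seed=14)
        keep = [l for l in cm.counts.columns if not l.startswith("ttsI")]
        cm2 = st.CountMatrix(counts=cm.counts[keep],
                             design=cm.design.loc[keep])
        de = st.run_de(cm2)
        with pytest.raises(ValueError, match="ttsI"):
            st.classify(ann, de)


class TestVenn:
    def test_identical_sets_fill_triple_cell(self):
        sets = {s: {"a", "b", "c"} for s in ("WT", "nodD1", "ttsI")}
        cells = st.venn_partition(sets)
        assert cells["WT&nodD1&ttsI"] == 3
        assert sum(cells.values()) == 3

    def test_disjoint_sets_fill_singleton_cells(self):
        sets = {"WT": {"a"}, "nodD1": {"b", "c"}, "ttsI": {"d"}}
        cells = st.venn_partition(sets)
        assert (cells["WT_only"], cells["nodD1_only"],
                cells["ttsI_only"]) == (1, 2, 1)
        assert sum(cells.values()) == 4

    def test_random_sets_match_bruteforce(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(50):
            sets = {s: set(rng.choice(universe, rng.integers(0, 40),
                                      replace=False))
                    for s in ("WT", "nodD1", "ttsI")}
            cells = st.venn_partition(sets)
            # oracle: classify every union member by its membership triple
            expect = dict.fromkeys(cells, 0)
            names = {(1, 0, 0): "WT_only", (0, 1, 0): "nodD1_only",
                     (0, 0, 1): "ttsI_only", (1, 1, 0): "WT&nodD1",
                     (1, 0, 1): "WT&ttsI", (0, 1, 1): "nodD1&ttsI",
                     (1, 1, 1): "WT&nodD1&ttsI"}
            for g in set().union(*sets.values()):
                key = tuple(int(g in sets[s])
                            for s in ("WT", "nodD1", "ttsI"))
                expect[names[key]] += 1
            assert cells == expect
            st.report.check_venn(cells, sets)
            for s in sets:
                assert st.venn_strain_total(cells, s) == len(sets[s])
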