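import numpy as np
import pandas as pd
import pytest

import stimulon as st
from stimulon.genome import GeneFeature, GenomeAnnotation, Replicon
from stimulon.motifs import default_patterns, scan
from stimulon.simulate import (SimulationConfig, TruthTable, boxless_design,
                               cell_effects, make_library_specs,
                               simulate_counts, simulate_genome,
                               tts_box_design)


class TestSimulateGenome:
    def test_same_seed_gives_identical_outputs(self, tmp_path):
        for tag in ("a", "b"):
            ann, truth, cm = st.simulate(SimulationConfig(), seed=5)
            d = tmp_path / tag
            d.mkdir()
            st.write_annotation(ann, d / "g.gff3", d / "g.fasta")
            truth.write(d / "tg.tsv", d / "tb.tsv")
            cm.counts.to_csv(d / "c.tsv", sep="\t")
        for name in ("g.gff3", "g.fasta", "tg.tsv", "tb.tsv", "c.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_planted_box_census_matches_config(self, default_sim):
        ann, truth, _ = default_sim
        census = truth.boxes.groupby(["type", "functionality"]).size()
        assert census[("NB", "active")] == 11
        assert census[("NB", "weakly-active")] == 1
        assert census[("NB", "non-functional")] == 1
        assert census[("NB", "no-downstream-gene")] == 2
        assert census[("TB", "active")] == 11
        assert census[("TB", "non-functional")] == 7   # 1 decoy + 6 broken
        assert truth.boxes[truth.boxes["type"] == "NB"].shape[0] == 15
        assert truth.boxes[truth.boxes["type"] == "TB"].shape[0] == 18

    def test_annotation_is_internally_consistent(self, default_sim):
        ann, truth, _ = default_sim
        ann.validate()
        assert len(ann.replicons) == 7
        # every non-desert box links back to its planted lead gene
        for bid, row in truth.boxes.iterrows():
            if not isinstance(row["downstream_gene"], str) or \
                    not row["downstream_gene"]:
                continue
            linked = st.link_box_to_gene(ann, ann.boxes[bid])
            assert linked.downstream_gene == row["downstream_gene"]

    def test_planted_functional_boxes_pass_scanner(self, default_sim):
        """Exact plants are found at budget 0; broken cores never match."""
        ann, truth, _ = default_sim
        pats = default_patterns()
        for bid, row in truth.boxes.iterrows():
            box = ann.boxes[bid]
            pat = pats.patterns[row["type"]]
            region = ann.sequences[box.replicon][box.start - 1:box.end]
            target = region if box.strand == "+" else st.revcomp(region)
            hits = scan(target, pat, 0, strands="+")
            if row["core_corrupted"]:
                assert hits == [], bid
                # still no hit with a generous budget: the core is mandatory
                assert scan(target, pat, 3, strands="+") == [], bid
            else:
                assert [(h.start, h.mismatches) for h in hits] == [(1, 0)], bid

    def test_duplicate_copy_is_sequence_identical(self, default_sim):
        ann, truth, _ = default_sim
        dup = truth.genes[truth.genes["duplicate_of"].astype(str) != ""]
        dup = dup[dup["duplicate_of"].notna()]
        assert len(dup) == 1
        copy_id = dup.index[0]
        template = dup["duplicate_of"].iloc[0]
        assert ann.gene_sequence(copy_id) == ann.gene_sequence(template)

    def test_infeasible_packing_raises(self):
        cfg = SimulationConfig(
            replicons=(("chromosome", 3000, "chromosome"),))
        with pytest.raises(ValueError, match="infeasible packing"):
            simulate_genome(cfg, seed=0)

    def test_operons_are_contiguous_same_strand(self, default_sim):
        ann, _, _ = default_sim
        for op in ann.operons.values():
            strands = {ann.genes[g].strand for g in op.gene_ids}
            assert len(strands) == 1
            starts = [ann.genes[g].start for g in op.gene_ids]
            assert starts == sorted(starts, reverse=op.strand == "-")


class TestLibraryDesign:
    def test_full_three_by_two_design(self):
        specs = make_library_specs(SimulationConfig(), seed=1)
        cells = {(s.strain, s.genistein) for s in specs}
        assert cells == {(s, g) for s in ("WT", "nodD1", "ttsI")
                         for g in (True, False)}
        assert len(specs) == 12
        assert all(s.depth_factor > 0 for s in specs)

    def test_depth_factors_within_configured_range(self):
        cfg = SimulationConfig(depth_range=(0.7, 1.4))
        specs = make_library_specs(cfg, seed=2)
        assert all(0.7 <= s.depth_factor <= 1.4 for s in specs)


def _single_gene_truth(n, baseline, eff_wt_gen=1.0):
    ann = GenomeAnnotation()
    ann.replicons["r1"] = Replicon("r1", 1200 * (n + 1))
    rows = []
    for i in range(n):
        g = f"g{i}"
        ann.genes[g] = GeneFeature(g, "r1", 1200 * i + 1, 1200 * i + 1000,
                                   "+")
        eff = {f"eff_{s}_{c}": 1.0 for s in ("WT", "nodD1", "ttsI")
               for c in ("gen", "nogen")}
        eff["eff_WT_gen"] = eff_wt_gen
        rows.append({"gene": g, "baseline": baseline, **eff})
    return ann, TruthTable(genes=pd.DataFrame(rows).set_index("gene"),
                           boxes=pd.DataFrame())


class TestSimulateCounts:
    def test_null_model_mean(self):
        """dispersion 0, equal depths, no effects: mean = baseline*len/1kb."""
        ann, truth = _single_gene_truth(300, baseline=150.0)
        specs = make_library_specs(SimulationConfig(depth_range=(1.0, 1.0)),
                                   seed=4)
        cm = simulate_counts(ann, truth, specs, seed=5, dispersion=0.0)
        expected = 150.0  # baseline 150 x 1000/1000 x depth 1
        means = cm.counts.mean(axis=1)
        # Poisson error of the mean over 12 libraries, 300 genes
        assert abs(means.mean() - expected) < 1.0
        assert np.all(np.abs(means - expected) < 5 * np.sqrt(expected / 12))

    def test_negative_binomial_moments(self):
        """Marginal mean/variance match the NB parameterization (1e4 draws)."""
        ann, truth = _single_gene_truth(10000, baseline=200.0)
        specs = make_library_specs(SimulationConfig(depth_range=(1.0, 1.0)),
                                   seed=6)
        d = 0.1
        cm = simulate_counts(ann, truth, specs, seed=7, dispersion=d)
        col = cm.counts["WT_nogen_r1"].values.astype(float)
        mu = 200.0
        assert abs(col.mean() - mu) / mu < 0.02
        var_expected = mu + d * mu ** 2
        assert abs(col.var() - var_expected) / var_expected < 0.1

    def test_nb_class_realized_fold_change(self):
        """Planted 8x induction realizes a WT fold change in [5, 13]."""
        ann, truth = _single_gene_truth(1000, baseline=250.0, eff_wt_gen=8.0)
        specs = make_library_specs(SimulationConfig(depth_range=(1.0, 1.0)),
                                   seed=8)
        cm = simulate_counts(ann, truth, specs, seed=9, dispersion=0.05)
        sf = pd.Series(1.0, index=cm.counts.columns)
        treat = cm.counts[["WT_gen_r1", "WT_gen_r2"]].mean(axis=1)
        base = cm.counts[["WT_nogen_r1", "WT_nogen_r2"]].mean(axis=1)
        fc = (treat + 0.5) / (base + 0.5)
        assert 5.0 < fc.mean() < 13.0
        assert (fc > 3.0).mean() > 0.97   # nearly all pass the DEG cutoff

    def test_tb_class_silent_in_ttsI_knockout(self, default_sim):
        """TB-class genes show no induction in the ttsI knockout cell.

        Judged against the planted depth factors so the check isolates the
        generator (no effect planted in ttsI+genistein for the TB class).
        """
        _, truth, cm = default_sim
        tb_genes = truth.genes.index[truth.genes["regulon_class"] == "TB"]
        norm = cm.counts.div(cm.design["depth_factor"], axis=1)
        treat = norm.loc[tb_genes, ["ttsI_gen_r1", "ttsI_gen_r2"]].mean(axis=1)
        base = norm.loc[tb_genes, ["WT_nogen_r1", "WT_nogen_r2"]].mean(axis=1)
        l2 = np.log2((treat + 0.5) / (base + 0.5))
        ci = 1.96 * l2.std() / np.sqrt(len(l2))
        assert abs(l2.mean()) < max(ci, 0.15)   # CI covers no-change

    def test_cell_effect_patterns(self):
        nb = cell_effects("NB", 8.0)
        assert nb[("WT", True)] == nb[("ttsI", True)] == 8.0
        assert nb[("nodD1", True)] == 1.0 and nb[("WT", False)] == 1.0
        tb = cell_effects("TB", 8.0)
        assert tb[("WT", True)] == 8.0
        assert tb[("ttsI", True)] == 1.0
        mb = cell_effects("mutant_background", 0.2)
        assert mb[("nodD1", False)] == mb[("ttsI", True)] == 0.2
        assert mb[("WT", True)] == 1.0
        with pytest.raises(ValueError):
            cell_effects("nonsense", 2.0)

    def test_invalid_effect_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(induction=0.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(down_factor=1.5).validate()


class TestFocusedDesigns:
    def test_tts_design_census(self):
        _, truth = simulate_genome(tts_box_design(), seed=3)
        tb = truth.boxes[truth.boxes["type"] == "TB"]
        assert len(tb) == 18
        assert (tb["functionality"] == "active").sum() == 11
        assert truth.boxes[truth.boxes["type"] == "NB"].empty

    def test_boxless_design_census(self):
        _, truth = simulate_genome(boxless_design(), seed=3)
        classes = truth.genes["regulon_class"].value_counts()
        assert classes.get("nodD1_dep", 0) == 17
        assert classes.get("nodD1_ttsI_dep", 0) == 7
        assert classes.get("independent_up", 0) == 4
        assert classes.get("independent_down", 0) == 2
        assert truth.boxes.empty
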