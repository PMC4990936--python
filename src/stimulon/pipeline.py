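"""End-to-end orchestration: simulate/load -> DE -> scan -> classify -> report.

Every output file starts with a comment line carrying the config hash and
seed, so a run directory is self-describing and a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

from . import de as de_mod
from . import motifs, simulate as sim_mod
from .classify import classify
from .config import PipelineConfig
from .genome import (infer_operons, read_annotation, read_boxes,
                     write_annotation, write_boxes)
from .qpcr import concordance, fold_changes_from_table, read_ct_table
from .report import StimulonReport, summarize

logger = logging.getLogger(__name__)


def _header(config: PipelineConfig) -> str:
    return f"# stimulon config={config.config_hash()} seed={config.seed}\n"


def run(config: PipelineConfig) -> StimulonReport:
    """Run every configured stage in order; returns the final report.

    Any stage failure propagates with the stage name prepended.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    th = config.make_thresholds()

    # ---- stage: inputs (simulate or load) --------------------------------
    stage = "simulate" if config.simulate is not None else "load"
    try:
        if config.simulate is not None:
            sim_cfg = config.make_simulation_config()
            ann, truth = sim_mod.simulate_genome(sim_cfg, config.seed)
            specs = sim_mod.make_library_specs(sim_cfg, config.seed + 1)
            cm = sim_mod.simulate_counts(ann, truth, specs, config.seed + 2,
                                         dispersion=sim_cfg.dispersion)
            write_annotation(ann, outdir / "genome.gff3",
                             outdir / "genome.fasta")
            write_boxes(ann.boxes, outdir / "boxes.tsv")
            truth.write(outdir / "truth_genes.tsv", outdir / "truth_boxes.tsv",
                        header=header)
            with open(outdir / "counts.tsv", "w") as fh:
                fh.write(header)
                cm.counts.to_csv(fh, sep="\t", index_label="gene")
            with open(outdir / "libraries.tsv", "w") as fh:
                fh.write(header)
                cm.design.to_csv(fh, sep="\t", index_label="library")
        else:
            ann = read_annotation(config.gff3, config.fasta)
            ann.boxes = read_boxes(config.boxes)
            cm = de_mod.read_counts(config.counts, config.design)
        infer_operons(ann, max_gap=config.operon_gap)
    except Exception as err:
        raise RuntimeError(f"stage {stage} failed: {err}") from err

    # ---- stage: differential expression ----------------------------------
    try:
        de = de_mod.run_de(cm, fc_threshold=th.fc, alpha=th.alpha)
        de_mod.write_contrast_tables(de, outdir, header=header)
    except Exception as err:
        raise RuntimeError(f"stage de failed: {err}") from err

    # ---- stage: motif scan ------------------------------------------------
    try:
        patterns = (motifs.read_pattern_file(config.patterns)
                    if config.patterns else motifs.default_patterns())
        candidates = []
        for pid, pat in patterns.patterns.items():
            budget = min(patterns.budgets.get(pid, config.mismatch_budget),
                         config.mismatch_budget)
            candidates.extend(motifs.scan_upstream(
                ann, pat, window=config.upstream_window,
                max_mismatches=budget))
        with open(outdir / "scan_candidates.tsv", "w") as fh:
            fh.write(header)
            fh.write("id\ttype\treplicon\tstart\tend\tstrand"
                     "\tdownstream_gene\toffset_start\toffset_end"
                     "\tmismatches\n")
            for b in candidates:
                fh.write("\t".join(map(str, (
                    b.id, b.box_type, b.replicon, b.start, b.end, b.strand,
                    b.downstream_gene or "", b.offset_start, b.offset_end,
                    b.mismatches))) + "\n")
    except Exception as err:
        raise RuntimeError(f"stage scan failed: {err}") from err

    # ---- stage: classification -------------------------------------------
    try:
        result = classify(ann, de, th)
        with open(outdir / "box_calls.tsv", "w") as fh:
            fh.write(header)
            result.box_call_frame().to_csv(fh, sep="\t")
        with open(outdir / "assignments.tsv", "w") as fh:
            fh.write(header)
            result.assignments.to_csv(fh, sep="\t")
        with open(outdir / "discards.tsv", "w") as fh:
            fh.write(header)
            result.discards.to_csv(fh, sep="\t")
    except Exception as err:
        raise RuntimeError(f"stage classify failed: {err}") from err

    # ---- stage: qPCR (optional) ------------------------------------------
    qpcr_meta = {}
    if config.qpcr:
        try:
            ct = read_ct_table(config.qpcr)
            conditions = sorted(ct["condition"].unique())
            if len(conditions) != 2:
                raise ValueError("qPCR table must hold exactly 2 conditions")
            control, treated = conditions  # alphabetical: control first
            fcs = fold_changes_from_table(ct, treated=treated,
                                          control=control)
            with open(outdir / "qpcr_fold_changes.tsv", "w") as fh:
                fh.write(header)
                fcs.to_csv(fh, sep="\t")
            shared = set(fcs.index) & set(de[("WT", True)].index)
            if len(shared) >= 3:
                coef, table = concordance(fcs, de[("WT", True)])
                qpcr_meta["qpcr_rnaseq_pearson_r"] = round(coef, 4)
                with open(outdir / "qpcr_concordance.tsv", "w") as fh:
                    fh.write(header)
                    table.to_csv(fh, sep="\t")
        except Exception as err:
            raise RuntimeError(f"stage qpcr failed: {err}") from err

    # ---- stage: report ----------------------------------------------------
    try:
        meta = {"seed": config.seed, "config": config.config_hash(),
                **qpcr_meta}
        rep = summarize(de, result, ann, meta=meta)
        rep.to_json(outdir / "report.json")
    except Exception as err:
        raise RuntimeError(f"stage report failed: {err}") from err
    return rep
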