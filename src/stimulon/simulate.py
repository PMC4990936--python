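"""Synthetic genome + RNA-seq count generator with planted regulon structure.

The generator emulates, at desk scale, a flavonoid-induction experiment on a
7-replicon rhizobial genome: 12 libraries = 3 strains (wild type, nodD1-,
ttsI-) x 2 conditions (+/- genistein) x 2 biological replicates.  It plants
nod boxes (NB), tts boxes (TB) and SyrM boxes upstream of operon leads, with
configurable numbers of functional, weakly functional and broken boxes, plus
boxless genistein-responsive genes, and emits a machine-readable truth table
so every downstream stage can be scored against the planted structure.

Planted induction patterns per regulon class (effect applied to the mean):

=================  =====================================================
class              cells with effect != 1
=================  =====================================================
NB / nodD1_dep     WT+gen and ttsI+gen (NodD1-dependent induction)
TB / nodD1_ttsI_dep  WT+gen only (needs both NodD1 and TtsI)
SyrM               WT+gen, plus ttsI+gen when TtsI-independent (default)
independent_up     all three strains +gen
independent_down   all three strains +gen (factor < 1)
mutant_background  all four mutant cells, +/- genistein (factor < 1)
background         none
=================  =====================================================

Counts are negative-binomial in mean-dispersion form:
mean = baseline x effect x gene_length/1kb x library depth;
var = mean + dispersion x mean^2 (dispersion 0 recovers Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motifs
from .de import CountMatrix
from .genome import (GenomeAnnotation, GeneFeature, OperonModel, PromoterBox,
                     Replicon, revcomp)

STRAINS = ("WT", "nodD1", "ttsI")
CELLS = [(s, g) for s in STRAINS for g in (False, True)]

UP_CLASSES = {"NB", "TB", "SyrM", "nodD1_dep", "nodD1_ttsI_dep",
              "independent_up"}
DOWN_CLASSES = {"independent_down", "mutant_background"}


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library of the 3 x 2 x replicates design."""

    id: str
    strain: str
    genistein: bool
    replicate: int
    depth_factor: float = 1.0

    def __post_init__(self):
        if self.depth_factor <= 0:
            raise ValueError("depth factor must be > 0")


DEFAULT_REPLICONS = (
    ("chromosome", 70000, "chromosome"),
    ("pSfHH103e", 36000, "plasmid"),
    ("pSfHH103d", 70000, "plasmid"),   # pSym analogue: carries the boxes
    ("pSfHH103c", 18000, "plasmid"),
    ("pSfHH103b", 10000, "plasmid"),
    ("pSfHH103a1", 7000, "plasmid"),
    ("pSfHH103a2", 9000, "plasmid"),
)


@dataclass
class SimulationConfig:
    """Planted design of the synthetic genome and count matrix.

    Defaults mirror the reduced-scale study design: 7 replicons (~200 kb),
    15 NB (11 active, 1 weak, 1 silent, 1 without a downstream gene, 1
    opposed to its nearest gene), 18 TB (11 active, 1 TtsI-independent
    decoy, 6 with a corrupted CGN2AG core), one standalone SyrM operon plus
    a SyrM box on the decoy operon, and 30 boxless responsive genes of which
    24 are NodD1-dependent (7 of those also TtsI-dependent).
    """

    replicons: tuple = DEFAULT_REPLICONS
    n_background_genes: int = 180
    # nod boxes
    nb_active: int = 11
    nb_weak: int = 1
    nb_silent: int = 1
    nb_no_gene: int = 1
    nb_opposed: int = 1
    # tts boxes
    tb_active: int = 11
    tb_decoy: int = 1
    tb_broken: int = 6
    # SyrM
    syrm_operons: int = 1
    attach_syrm_to_decoy: bool = True
    syrm_ttsI_independent: bool = True
    # boxless responsive genes
    boxless_nodD1: int = 17
    boxless_nodD1_ttsI: int = 7
    boxless_independent_up: int = 4
    boxless_independent_down: int = 2
    n_mutant_background: int = 1
    n_duplicate_copy: int = 1
    plant_operon_rescue: bool = True
    # effect sizes
    induction: float = 8.0
    weak_induction: float = 2.5
    rescue_member_induction: float = 1.8
    down_factor: float = 0.125
    mutant_background_factor: float = 0.15
    # expression levels
    baseline_range: tuple = (200.0, 500.0)
    background_log_mean: float = 4.4
    background_log_sigma: float = 1.0
    dispersion: float = 0.05
    replicates: int = 2
    depth_range: tuple = (0.7, 1.4)
    # layout
    gene_length_range: tuple = (250, 500)
    intra_gap_range: tuple = (20, 100)
    inter_gap_range: tuple = (250, 400)
    box_offset_range: tuple = (60, 160)
    operon_size_range: tuple = (1, 3)
    box_mismatches: int = 0
    link_distance: int = 1000

    def validate(self) -> None:
        if self.induction < 1 or self.weak_induction < 1:
            raise ValueError("induction factors for up classes must be >= 1")
        if not (0 < self.down_factor <= 1):
            raise ValueError("down factors must be in (0, 1]")
        if not (0 < self.mutant_background_factor <= 1):
            raise ValueError("mutant background factor must be in (0, 1]")
        if self.replicates < 2:
            raise ValueError("design requires >= 2 replicates per cell")


def tts_box_design(**overrides) -> SimulationConfig:
    """The 18-TB functional-verification design.

    11 TB-preceded operons induced only in the wild type, one decoy operon
    that stays induced in the ttsI mutant, six never-induced operons; no
    other planted structure.
    """
    cfg = SimulationConfig(
        nb_active=0, nb_weak=0, nb_silent=0, nb_no_gene=0, nb_opposed=0,
        tb_active=11, tb_decoy=1, tb_broken=6,
        syrm_operons=0, attach_syrm_to_decoy=False,
        boxless_nodD1=0, boxless_nodD1_ttsI=0,
        boxless_independent_up=0, boxless_independent_down=0,
        n_mutant_background=0, n_duplicate_copy=0,
        plant_operon_rescue=False, n_background_genes=120)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def boxless_design(**overrides) -> SimulationConfig:
    """The 30-gene boxless design: 24 NodD1-dependent (7 also
    TtsI-dependent), 4 regulator-independent up, 2 down."""
    cfg = SimulationConfig(
        nb_active=0, nb_weak=0, nb_silent=0, nb_no_gene=0, nb_opposed=0,
        tb_active=0, tb_decoy=0, tb_broken=0,
        syrm_operons=0, attach_syrm_to_decoy=False,
        boxless_nodD1=17, boxless_nodD1_ttsI=7,
        boxless_independent_up=4, boxless_independent_down=2,
        n_mutant_background=0, n_duplicate_copy=0,
        plant_operon_rescue=False, n_background_genes=120)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class TruthTable:
    """Planted truth: per-box functionality, per-gene class and effects."""

    genes: pd.DataFrame   # index gene id
    boxes: pd.DataFrame   # index box id

    def write(self, genes_path: str | Path, boxes_path: str | Path,
              header: str = "") -> None:
        for path, frame, label in ((genes_path, self.genes, "gene"),
                                   (boxes_path, self.boxes, "box")):
            with open(path, "w") as fh:
                if header:
                    fh.write(header)
                frame.to_csv(fh, sep="\t", index_label=label)

    @classmethod
    def read(cls, genes_path: str | Path, boxes_path: str | Path
             ) -> "TruthTable":
        return cls(
            genes=pd.read_csv(genes_path, sep="\t", index_col=0, comment="#"),
            boxes=pd.read_csv(boxes_path, sep="\t", index_col=0, comment="#"))


def cell_effects(regulon_class: str, factor: float,
                 syrm_ttsI_independent: bool = True) -> dict:
    """Planted per-cell expression effect for one gene."""
    eff = {cell: 1.0 for cell in CELLS}
    if regulon_class in ("NB", "nodD1_dep"):
        eff[("WT", True)] = eff[("ttsI", True)] = factor
    elif regulon_class in ("TB", "nodD1_ttsI_dep"):
        eff[("WT", True)] = factor
    elif regulon_class == "SyrM":
        eff[("WT", True)] = factor
        if syrm_ttsI_independent:
            eff[("ttsI", True)] = factor
    elif regulon_class in ("independent_up", "independent_down"):
        for s in STRAINS:
            eff[(s, True)] = factor
    elif regulon_class == "mutant_background":
        for s in ("nodD1", "ttsI"):
            eff[(s, True)] = eff[(s, False)] = factor
    elif regulon_class not in ("background", "silent"):
        raise ValueError(f"unknown regulon class {regulon_class!r}")
    return eff


# ---------------------------------------------------------------------------
# Unit plans
# ---------------------------------------------------------------------------

@dataclass
class _GenePlan:
    regulon_class: str
    factor: float


@dataclass
class _UnitPlan:
    uid: str
    genes: list
    strand: str = "+"
    box_type: str | None = None          # "NB" | "TB" | "SyrM"
    box_functionality: str | None = None
    corrupt_core: bool = False
    syrm_extra: bool = False             # extra SyrM box further upstream
    desert: bool = False                 # box with no downstream gene
    opposed: bool = False                # nearest gene is antisense
    duplicate_of: str | None = None      # uid of template unit
    replicon: str | None = None


def _build_unit_plans(cfg: SimulationConfig,
                      rng: np.random.Generator) -> list:
    plans: list[_UnitPlan] = []
    lo, hi = cfg.operon_size_range

    def operon_size() -> int:
        return int(rng.integers(lo, hi + 1))

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    k = 0

    def uid(prefix):
        nonlocal k
        k += 1
        return f"{prefix}{k}"

    for i in range(cfg.nb_active):
        n = operon_size()
        strand = "+" if i == 0 else rand_strand()  # unit 0: duplicate template
        genes = [_GenePlan("NB", cfg.induction) for _ in range(n)]
        if i == 0 and cfg.plant_operon_rescue:
            if n < 2:
                genes.append(_GenePlan("NB", cfg.induction))
            genes[-1] = _GenePlan("NB", cfg.rescue_member_induction)
        plans.append(_UnitPlan(uid("NBu"), genes, strand, box_type="NB",
                               box_functionality="active"))
    for _ in range(cfg.nb_weak):
        plans.append(_UnitPlan(uid("NBu"), [_GenePlan("NB",
                                                      cfg.weak_induction)],
                               rand_strand(), box_type="NB",
                               box_functionality="weakly-active"))
    for _ in range(cfg.nb_silent):
        plans.append(_UnitPlan(uid("NBu"),
                               [_GenePlan("silent", 1.0)],
                               rand_strand(), box_type="NB",
                               box_functionality="non-functional"))
    for _ in range(cfg.nb_no_gene):
        plans.append(_UnitPlan(uid("NBu"), [], "+", box_type="NB",
                               box_functionality="no-downstream-gene",
                               desert=True))
    for _ in range(cfg.nb_opposed):
        plans.append(_UnitPlan(uid("NBu"),
                               [_GenePlan("independent_up", cfg.induction)],
                               "+", box_type="NB",
                               box_functionality="no-downstream-gene",
                               opposed=True))
    for _ in range(cfg.tb_active):
        plans.append(_UnitPlan(
            uid("TBu"),
            [_GenePlan("TB", cfg.induction) for _ in range(operon_size())],
            rand_strand(), box_type="TB", box_functionality="active"))
    for _ in range(cfg.tb_decoy):
        plans.append(_UnitPlan(
            uid("TBu"),
            [_GenePlan("SyrM", cfg.induction) for _ in range(operon_size())],
            rand_strand(), box_type="TB", box_functionality="non-functional",
            syrm_extra=cfg.attach_syrm_to_decoy))
    for _ in range(cfg.tb_broken):
        plans.append(_UnitPlan(
            uid("TBu"),
            [_GenePlan("silent", 1.0) for _ in range(operon_size())],
            rand_strand(), box_type="TB",
            box_functionality="non-functional", corrupt_core=True))
    for _ in range(cfg.syrm_operons):
        plans.append(_UnitPlan(
            uid("SBu"),
            [_GenePlan("SyrM", cfg.induction) for _ in range(operon_size())],
            rand_strand(), box_type="SyrM", box_functionality="active"))
    for cls, count, factor in (
            ("nodD1_dep", cfg.boxless_nodD1, cfg.induction),
            ("nodD1_ttsI_dep", cfg.boxless_nodD1_ttsI, cfg.induction),
            ("independent_up", cfg.boxless_independent_up, cfg.induction),
            ("independent_down", cfg.boxless_independent_down,
             cfg.down_factor),
            ("mutant_background", cfg.n_mutant_background,
             cfg.mutant_background_factor)):
        for _ in range(count):
            plans.append(_UnitPlan(uid("Gu"), [_GenePlan(cls, factor)],
                                   rand_strand()))
    if cfg.n_duplicate_copy and cfg.nb_active:
        template_uid = plans[0].uid
        for _ in range(cfg.n_duplicate_copy):
            plans.append(_UnitPlan(uid("Du"),
                                   [_GenePlan("nodD1_dep", cfg.induction)],
                                   "+", duplicate_of=template_uid))
    for _ in range(cfg.n_background_genes):
        plans.append(_UnitPlan(uid("Bu"), [_GenePlan("background", 1.0)],
                               rand_strand()))
    return plans


def _replicon_preference(unit, order: list, remaining: dict) -> list:
    """Replicon order to try for one unit: boxes on the pSym analogue,
    responsive singles on the chromosome, background balanced by room."""
    box_pref = [r for r in ("pSfHH103d", "pSfHH103c", "pSfHH103e",
                            "chromosome") if r in remaining]
    gene_pref = [r for r in ("chromosome", "pSfHH103e", "pSfHH103d")
                 if r in remaining]
    if unit.box_type:
        return box_pref + [r for r in order if r not in box_pref]
    if unit.uid.startswith("Bu"):
        return sorted(order, key=lambda r: -remaining[r])
    return gene_pref + [r for r in order if r not in gene_pref]


# ---------------------------------------------------------------------------
# simulate_genome
# ---------------------------------------------------------------------------

def simulate_genome(cfg: SimulationConfig | None = None, seed: int = 0
                    ) -> tuple[GenomeAnnotation, TruthTable]:
    """Build the planted genome.  Deterministic given (config, seed)."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    patterns = motifs.default_patterns()

    plans = _build_unit_plans(cfg, rng)

    ann = GenomeAnnotation()
    for rid, length, kind in cfg.replicons:
        ann.replicons[rid] = Replicon(id=rid, length=length, kind=kind)

    cursors = {rid: 150 for rid, _, _ in cfg.replicons}
    gene_rows = []          # truth rows
    box_rows = []
    box_inserts = []        # (replicon, start, end, strand, instance)
    gene_counter = 0
    unit_lead: dict[str, str] = {}     # uid -> lead gene id
    unit_genes: dict[str, list] = {}

    glo, ghi = cfg.gene_length_range
    ilo, ihi = cfg.intra_gap_range
    plo, phi = cfg.inter_gap_range
    blo, bhi = cfg.box_offset_range

    order = [rid for rid, _, _ in cfg.replicons]
    for unit in plans:
        pattern = patterns.patterns[unit.box_type] if unit.box_type else None
        boxlen = pattern.length if pattern else 0
        offd = int(rng.integers(blo, bhi + 1)) if pattern else 0
        pre = int(rng.integers(plo, phi + 1))
        syrm_pat = patterns.patterns["SyrM"]
        soff = int(rng.integers(200, 241)) if unit.syrm_extra else 0
        opp_gap = int(rng.integers(60, 121)) if unit.opposed else 0

        if unit.duplicate_of:
            # identical-copy plant: same length as the template lead gene
            glens = [ann.genes[unit_lead[unit.duplicate_of]].length]
        else:
            glens = [int(rng.integers(glo, ghi + 1)) for _ in unit.genes]
        gaps = [int(rng.integers(ilo, ihi + 1))
                for _ in range(max(0, len(unit.genes) - 1))]

        # exact footprint of this unit, then pick the first replicon with room
        span = sum(glens) + sum(gaps)
        if unit.desert:
            footprint = pre + boxlen + cfg.link_distance + 250
        elif unit.opposed:
            footprint = pre + boxlen + opp_gap + span
        elif unit.strand == "+":
            need = pre
            if pattern:
                need = max(need, offd + boxlen + 20)
            if unit.syrm_extra:
                need = max(need, soff + syrm_pat.length + 20)
            footprint = need + span
        else:
            ext = max(offd + boxlen if pattern else 0,
                      soff + syrm_pat.length if unit.syrm_extra else 0)
            footprint = pre + span + ext
        remaining = {rid: ann.replicons[rid].length - cursors[rid] - 200
                     for rid in order}
        for rid in _replicon_preference(unit, order, remaining):
            if remaining[rid] >= footprint:
                unit.replicon = rid
                break
        else:
            raise ValueError(
                "infeasible packing: planted genes and boxes exceed the "
                "configured replicon lengths")
        cursor = cursors[rid]
        length = ann.replicons[rid].length

        placed: list[GeneFeature] = []
        boxes_here: list[tuple] = []   # (type, start, end, functionality)

        if unit.desert:
            bstart = cursor + pre
            bend = bstart + boxlen - 1
            boxes_here.append((unit.box_type, bstart, bend, "+"))
            cursor = bend + cfg.link_distance + 250
        elif unit.opposed:
            bstart = cursor + pre
            bend = bstart + boxlen - 1
            boxes_here.append((unit.box_type, bstart, bend, "+"))
            gstart = bend + opp_gap + 1
            gend = gstart + glens[0] - 1
            gene_counter += 1
            placed.append(GeneFeature(
                id=f"g{gene_counter:04d}", replicon=rid, start=gstart,
                end=gend, strand="-", operon=unit.uid))
            cursor = gend
        elif unit.strand == "+":
            need = pre
            if pattern:
                need = max(need, offd + boxlen + 20)
            if unit.syrm_extra:
                need = max(need, soff + syrm_pat.length + 20)
            lead_start = cursor + need
            pos = lead_start
            for j, L in enumerate(glens):
                gene_counter += 1
                placed.append(GeneFeature(
                    id=f"g{gene_counter:04d}", replicon=rid, start=pos,
                    end=pos + L - 1, strand="+", operon=unit.uid))
                pos += L + (gaps[j] if j < len(gaps) else 0)
            if pattern:
                bend = lead_start - offd
                boxes_here.append((unit.box_type, bend - boxlen + 1, bend,
                                   "+"))
            if unit.syrm_extra:
                send = lead_start - soff
                boxes_here.append(("SyrM", send - syrm_pat.length + 1, send,
                                   "+"))
            cursor = placed[-1].end
        else:  # minus strand: lead is the rightmost gene, box to its right
            pos = cursor + pre
            for j, L in enumerate(glens):
                gene_counter += 1
                placed.append(GeneFeature(
                    id=f"g{gene_counter:04d}", replicon=rid, start=pos,
                    end=pos + L - 1, strand="-", operon=unit.uid))
                pos += L + (gaps[j] if j < len(gaps) else 0)
            lead_end = placed[-1].end
            cursor = lead_end
            if pattern:
                bstart = lead_end + offd
                boxes_here.append((unit.box_type, bstart,
                                   bstart + boxlen - 1, "-"))
                cursor = max(cursor, bstart + boxlen - 1)
            if unit.syrm_extra:
                sstart = lead_end + soff
                boxes_here.append(("SyrM", sstart,
                                   sstart + syrm_pat.length - 1, "-"))
                cursor = max(cursor, sstart + syrm_pat.length - 1)
            placed = placed[::-1]   # transcription order

        if cursor > length - 200:
            raise ValueError(
                f"infeasible packing: replicon {rid} overflows at unit "
                f"{unit.uid}")
        cursors[rid] = cursor

        # register genes
        for g, plan in zip(placed, unit.genes):
            ann.genes[g.id] = g
            if plan.regulon_class == "background":
                baseline = float(np.clip(rng.lognormal(
                    cfg.background_log_mean, cfg.background_log_sigma),
                    5.0, 2000.0))
            else:
                baseline = float(rng.uniform(*cfg.baseline_range))
            eff = cell_effects(plan.regulon_class, plan.factor,
                               cfg.syrm_ttsI_independent)
            row = {"gene": g.id, "regulon_class": plan.regulon_class,
                   "factor": plan.factor, "baseline": baseline,
                   "unit": unit.uid, "replicon": rid,
                   "duplicate_of": ""}
            for (s, gen), e in eff.items():
                row[f"eff_{s}_{'gen' if gen else 'nogen'}"] = e
            gene_rows.append(row)
        if placed:
            ann.operons[unit.uid] = OperonModel(
                id=unit.uid, gene_ids=tuple(g.id for g in placed),
                strand=placed[0].strand)
            unit_lead[unit.uid] = placed[0].id
        unit_genes[unit.uid] = [g.id for g in placed]

        # register boxes
        for btype, bstart, bend, bstrand in boxes_here:
            pat = patterns.patterns[btype]
            n_box = sum(1 for r in box_rows if r["type"] == btype) + 1
            bid = {"NB": "NB", "TB": "TB", "SyrM": "SB"}[btype] + str(n_box)
            downstream = unit_lead.get(unit.uid, "")
            if unit.desert or unit.opposed:
                downstream = ""
            functionality = (unit.box_functionality if btype == unit.box_type
                             else "active")
            box_rows.append({
                "box": bid, "type": btype, "replicon": rid, "start": bstart,
                "end": bend, "strand": bstrand, "downstream_gene": downstream,
                "functionality": functionality,
                "core_corrupted": unit.corrupt_core and btype == "TB",
                "mismatches": 0 if not (unit.corrupt_core and btype == "TB")
                              else 2,
                "unit": unit.uid})
            mism = cfg.box_mismatches if btype == unit.box_type else 0
            inst = motifs.instantiate(
                pat, rng, mismatches=mism,
                corrupt_core=unit.corrupt_core and btype == "TB")
            box_inserts.append((rid, bstart, bend, bstrand, inst))
            ann.boxes[bid] = PromoterBox(
                id=bid, box_type=btype, replicon=rid, start=bstart, end=bend,
                strand=bstrand, downstream_gene=downstream or None,
                mismatches=mism)

    # ---- sequences -------------------------------------------------------
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for rid, rep in ann.replicons.items():
        idx = rng.integers(0, 4, size=rep.length)
        ann.sequences[rid] = alphabet[idx].tobytes().decode("ascii")
    for rid, bstart, bend, bstrand, inst in box_inserts:
        seq = ann.sequences[rid]
        written = inst if bstrand == "+" else revcomp(inst)
        ann.sequences[rid] = seq[:bstart - 1] + written + seq[bend:]

    # duplicate copies: identical sequence to the template unit's lead gene
    truth_genes = pd.DataFrame(gene_rows).set_index("gene")
    for unit in plans:
        if unit.duplicate_of and unit_genes.get(unit.uid):
            template = unit_lead[unit.duplicate_of]
            copy_id = unit_genes[unit.uid][0]
            tmpl_seq = ann.gene_sequence(template)
            g = ann.genes[copy_id]
            seq = ann.sequences[g.replicon]
            ann.sequences[g.replicon] = (seq[:g.start - 1] + tmpl_seq
                                         + seq[g.end:])
            truth_genes.loc[copy_id, "duplicate_of"] = template

    ann.validate()
    truth_boxes = (pd.DataFrame(box_rows).set_index("box")
                   if box_rows else
                   pd.DataFrame(columns=["type", "replicon", "start", "end",
                                         "strand", "downstream_gene",
                                         "functionality", "core_corrupted",
                                         "mismatches", "unit"]))
    return ann, TruthTable(genes=truth_genes, boxes=truth_boxes)


# ---------------------------------------------------------------------------
# simulate_counts
# ---------------------------------------------------------------------------

def make_library_specs(cfg: SimulationConfig, seed: int) -> list[LibrarySpec]:
    """The 3 strains x 2 conditions x replicates design with random depths."""
    rng = np.random.default_rng(seed)
    lo, hi = cfg.depth_range
    specs = []
    for strain in STRAINS:
        for gen in (False, True):
            for rep in range(1, cfg.replicates + 1):
                depth = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                specs.append(LibrarySpec(
                    id=f"{strain}_{'gen' if gen else 'nogen'}_r{rep}",
                    strain=strain, genistein=gen, replicate=rep,
                    depth_factor=depth))
    return specs


def design_frame(specs: list[LibrarySpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"library": s.id, "strain": s.strain, "genistein": s.genistein,
          "replicate": s.replicate, "depth_factor": s.depth_factor}
         for s in specs]).set_index("library")


def simulate_counts(ann: GenomeAnnotation, truth: TruthTable,
                    specs: list[LibrarySpec], seed: int,
                    dispersion: float | None = None) -> CountMatrix:
    """Draw the genes x libraries count matrix.

    mean(g, lib) = baseline(g) x effect(g, cell) x length(g)/1kb x depth;
    negative binomial with var = mean + dispersion * mean^2.
    """
    rng = np.random.default_rng(seed)
    if dispersion is None:
        dispersion = 0.05
    genes = [g.id for g in ann.sorted_genes()]
    lengths = np.array([ann.genes[g].length for g in genes], dtype=float)
    baseline = truth.genes.loc[genes, "baseline"].values.astype(float)

    counts = np.zeros((len(genes), len(specs)), dtype=np.int64)
    for j, spec in enumerate(specs):
        col = f"eff_{spec.strain}_{'gen' if spec.genistein else 'nogen'}"
        eff = truth.genes.loc[genes, col].values.astype(float)
        mu = baseline * eff * lengths / 1000.0 * spec.depth_factor
        if dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            counts[:, j] = rng.poisson(lam)
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                         columns=[s.id for s in specs])
    return CountMatrix(counts=frame, design=design_frame(specs))


def simulate(cfg: SimulationConfig | None = None, seed: int = 0
             ) -> tuple[GenomeAnnotation, TruthTable, CountMatrix]:
    """Genome + truth + counts in one call (seed split internally)."""
    cfg = cfg or SimulationConfig()
    ann, truth = simulate_genome(cfg, seed)
    specs = make_library_specs(cfg, seed + 1)
    cm = simulate_counts(ann, truth, specs, seed + 2,
                         dispersion=cfg.dispersion)
    return ann, truth, cm
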