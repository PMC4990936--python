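"""Multi-replicon genome model: replicons, genes, operons and promoter boxes.

Coordinates are 1-based inclusive (GFF3 convention) throughout.  Offsets of
promoter elements are given relative to the first base of the start codon of
the downstream gene: -1 is the base immediately 5' of the translation start,
so a 66-bp box whose 3' end lies 62 bp upstream spans offsets -127..-62.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTMRWSYKVHDBNacgtmrwsykvhdbn",
                            "TGCAKYWSRMBDHVNtgcakywsrmbdhvn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Replicon:
    """One chromosome or plasmid."""

    id: str
    length: int
    kind: str = "plasmid"  # {"chromosome", "plasmid"}

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"replicon {self.id}: length must be >= 1")
        if self.kind not in ("chromosome", "plasmid"):
            raise ValueError(f"replicon {self.id}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene on a replicon."""

    id: str
    replicon: str
    start: int
    end: int
    strand: str
    operon: str | None = None
    product: str = ""

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"gene {self.id}: invalid coordinates "
                             f"{self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def translation_start(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class OperonModel:
    """A transcription unit: >=1 contiguous same-strand genes.

    ``gene_ids`` are in transcription order; the first entry is the lead
    gene (the one whose promoter any upstream box acts on).
    """

    id: str
    gene_ids: tuple[str, ...]
    strand: str

    def __post_init__(self):
        if len(self.gene_ids) < 1:
            raise ValueError(f"operon {self.id}: needs >= 1 gene")

    @property
    def lead_gene(self) -> str:
        return self.gene_ids[0]


@dataclass
class PromoterBox:
    """One candidate regulatory box (nod box, tts box or SyrM box).

    ``offset_start``/``offset_end`` are filled once the box is linked to a
    downstream gene; both are negative, ``offset_end`` being the distance of
    the box 3' end from the translation start (-62 means the box ends 62 bp
    upstream of the start codon).
    """

    id: str
    box_type: str  # {"NB", "TB", "SyrM"} or a pattern id
    replicon: str
    start: int
    end: int
    strand: str
    downstream_gene: str | None = None
    offset_start: int | None = None
    offset_end: int | None = None
    opposed: bool = False
    opposed_gene: str | None = None
    mismatches: int = 0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"box {self.id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"box {self.id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Replicons, genes, operons, boxes and the per-replicon sequences."""

    replicons: dict[str, Replicon] = field(default_factory=dict)
    genes: dict[str, GeneFeature] = field(default_factory=dict)
    operons: dict[str, OperonModel] = field(default_factory=dict)
    boxes: dict[str, PromoterBox] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for g in self.genes.values():
            if g.replicon not in self.replicons:
                raise ValueError(f"gene {g.id}: unknown replicon {g.replicon}")
            if g.end > self.replicons[g.replicon].length:
                raise ValueError(
                    f"gene {g.id}: end {g.end} exceeds replicon "
                    f"{g.replicon} length {self.replicons[g.replicon].length}")
        for b in self.boxes.values():
            if b.replicon not in self.replicons:
                raise ValueError(f"box {b.id}: unknown replicon {b.replicon}")
            if b.end > self.replicons[b.replicon].length:
                raise ValueError(f"box {b.id}: end exceeds replicon length")
        for op in self.operons.values():
            for gid in op.gene_ids:
                if gid not in self.genes:
                    raise ValueError(f"operon {op.id}: unknown gene {gid}")
        for rid, seq in self.sequences.items():
            if rid in self.replicons and len(seq) != self.replicons[rid].length:
                raise ValueError(f"sequence length mismatch for {rid}")

    def genes_on(self, replicon: str) -> list[GeneFeature]:
        """Genes of one replicon sorted by start coordinate."""
        return sorted((g for g in self.genes.values() if g.replicon == replicon),
                      key=lambda g: (g.start, g.end, g.id))

    def sorted_genes(self) -> list[GeneFeature]:
        out: list[GeneFeature] = []
        for rid in self.replicons:
            out.extend(self.genes_on(rid))
        return out

    def gene_sequence(self, gene_id: str) -> str:
        """Strand-aware nucleotide sequence of a gene."""
        g = self.genes[gene_id]
        raw = self.sequences[g.replicon][g.start - 1:g.end]
        return raw if g.strand == "+" else revcomp(raw)

    def operon_of(self, gene_id: str) -> OperonModel | None:
        g = self.genes[gene_id]
        if g.operon is not None and g.operon in self.operons:
            return self.operons[g.operon]
        return None


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_annotation(gff3_path: str | Path, fasta_path: str | Path,
                    operon_attribute: str = "operon_id") -> GenomeAnnotation:
    """Read a GFF3 + FASTA pair into a :class:`GenomeAnnotation`.

    Gene features are taken from GFF3 records of type ``gene`` (falling back
    to ``CDS`` where no gene features exist); replicon lengths come from the
    FASTA sequences.  A replicon's kind is taken from a ``region`` feature's
    ``kind`` attribute when present, else guessed from its id.

    Raises ``ValueError`` for a GFF3 seqid missing from the FASTA or a gene
    whose coordinates fall outside its replicon.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no sequences in {fasta_path}")

    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    kinds: dict[str, str] = {}
    for feat in db.features_of_type("region"):
        if "kind" in feat.attributes:
            kinds[feat.seqid] = feat.attributes["kind"][0]

    replicons = {
        rid: Replicon(
            id=rid, length=len(seq),
            kind=kinds.get(rid, "chromosome" if "chrom" in rid.lower()
                           else "plasmid"))
        for rid, seq in sequences.items()
    }

    feature_types = ["gene"]
    if not any(True for _ in db.features_of_type("gene")):
        feature_types = ["CDS"]

    genes: dict[str, GeneFeature] = {}
    for feat in db.features_of_type(feature_types):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if feat.seqid not in replicons:
            raise ValueError(
                f"gene {gid}: seqid {feat.seqid} not present in FASTA")
        gene = GeneFeature(
            id=gid, replicon=feat.seqid, start=feat.start, end=feat.end,
            strand=feat.strand,
            operon=feat.attributes.get(operon_attribute, [None])[0],
            product=feat.attributes.get("product", [""])[0])
        if gene.end > replicons[feat.seqid].length:
            raise ValueError(
                f"gene {gid}: end {gene.end} outside replicon {feat.seqid} "
                f"(length {replicons[feat.seqid].length})")
        if gid in genes:
            raise ValueError(f"duplicate gene id {gid}")
        genes[gid] = gene

    ann = GenomeAnnotation(replicons=replicons, genes=genes,
                           sequences=sequences)
    _rebuild_operons_from_tags(ann)
    ann.validate()
    return ann


def _rebuild_operons_from_tags(ann: GenomeAnnotation) -> None:
    """Group genes sharing an operon tag into OperonModel records."""
    by_tag: dict[str, list[GeneFeature]] = {}
    for g in ann.sorted_genes():
        if g.operon:
            by_tag.setdefault(g.operon, []).append(g)
    for tag, members in by_tag.items():
        strand = members[0].strand
        ordered = sorted(members, key=lambda g: g.start,
                         reverse=(strand == "-"))
        ann.operons[tag] = OperonModel(
            id=tag, gene_ids=tuple(g.id for g in ordered), strand=strand)


def write_annotation(ann: GenomeAnnotation, gff3_path: str | Path,
                     fasta_path: str | Path,
                     operon_attribute: str = "operon_id") -> None:
    """Write genes (and region pragmas) as GFF3 and sequences as FASTA."""
    gff3_path, fasta_path = Path(gff3_path), Path(fasta_path)
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, rep in ann.replicons.items():
            fh.write(f"##sequence-region {rid} 1 {rep.length}\n")
        for rid, rep in ann.replicons.items():
            fh.write("\t".join([
                rid, "stimulon", "region", "1", str(rep.length), ".", "+",
                ".", f"ID=region:{rid};kind={rep.kind}"]) + "\n")
        for g in ann.sorted_genes():
            attrs = [f"ID={g.id}"]
            if g.operon:
                attrs.append(f"{operon_attribute}={g.operon}")
            if g.product:
                attrs.append(f"product={g.product}")
            fh.write("\t".join([
                g.replicon, "stimulon", "gene", str(g.start), str(g.end),
                ".", g.strand, ".", ";".join(attrs)]) + "\n")
    records = [SeqRecord(Seq(seq), id=rid, description="")
               for rid, seq in ann.sequences.items()]
    SeqIO.write(records, str(fasta_path), "fasta")


BOX_TSV_COLUMNS = ("id", "type", "replicon", "start", "end", "strand",
                   "downstream_gene", "mismatches")


def write_boxes(boxes: list[PromoterBox] | dict[str, PromoterBox],
                path: str | Path) -> None:
    """Write promoter boxes as a TSV (7 core columns + mismatches)."""
    if isinstance(boxes, dict):
        boxes = list(boxes.values())
    with open(path, "w") as fh:
        fh.write("\t".join(BOX_TSV_COLUMNS) + "\n")
        for b in boxes:
            fh.write("\t".join([
                b.id, b.box_type, b.replicon, str(b.start), str(b.end),
                b.strand, b.downstream_gene or "", str(b.mismatches)]) + "\n")


def read_boxes(path: str | Path) -> dict[str, PromoterBox]:
    boxes: dict[str, PromoterBox] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            row = dict(zip(header, line.split("\t")))
            box = PromoterBox(
                id=row["id"], box_type=row["type"], replicon=row["replicon"],
                start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"],
                downstream_gene=row.get("downstream_gene") or None,
                mismatches=int(row.get("mismatches") or 0))
            boxes[box.id] = box
    return boxes


# ---------------------------------------------------------------------------
# Operon inference
# ---------------------------------------------------------------------------

def infer_operons(ann: GenomeAnnotation, max_gap: int = 200) -> GenomeAnnotation:
    """Group consecutive same-strand genes with intergenic gap <= max_gap.

    Pre-existing operon tags always win: tagged genes keep their operon and
    break inference runs.  Returns the same annotation with ``operons``
    filled and untagged genes assigned inferred operon ids.
    """
    counter = 0
    for rid in ann.replicons:
        genes = ann.genes_on(rid)
        run: list[GeneFeature] = []

        def flush(run):
            nonlocal counter
            if not run:
                return
            counter += 1
            op_id = f"opn_{rid}_{counter}"
            strand = run[0].strand
            ordered = sorted(run, key=lambda g: g.start,
                             reverse=(strand == "-"))
            ann.operons[op_id] = OperonModel(
                id=op_id, gene_ids=tuple(g.id for g in ordered),
                strand=strand)
            for g in run:
                ann.genes[g.id] = replace(g, operon=op_id)

        for g in genes:
            if g.operon is not None:
                flush(run)
                run = []
                continue
            if run and (g.strand != run[-1].strand
                        or g.start - run[-1].end - 1 > max_gap):
                flush(run)
                run = []
            run.append(g)
        flush(run)
    _rebuild_operons_from_tags(ann)
    return ann


# ---------------------------------------------------------------------------
# Upstream windows and box -> gene linking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UpstreamWindow:
    """The sequence 5' of a gene's translation start, on the gene's strand.

    Position ``i`` (1-based) of ``seq`` has offset ``start_offset + i - 1``;
    the last base has offset -1.  ``genomic_start``/``genomic_end`` bound the
    window on the forward genomic strand.
    """

    gene_id: str
    seq: str
    start_offset: int
    genomic_start: int
    genomic_end: int
    strand: str

    def genomic_position(self, window_pos: int) -> int:
        """Forward-strand genomic coordinate of window position (1-based)."""
        if self.strand == "+":
            return self.genomic_start + window_pos - 1
        return self.genomic_end - window_pos + 1


def upstream_window(ann: GenomeAnnotation, gene_id: str,
                    window: int) -> UpstreamWindow:
    """Extract the ``window`` bases 5' of a gene's start codon.

    Reverse-complemented for minus-strand genes; truncated at the replicon
    edge (the far end of the window shrinks).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if gene_id not in ann.genes:
        raise KeyError(f"unknown gene id {gene_id!r}")
    g = ann.genes[gene_id]
    seq = ann.sequences[g.replicon]
    if g.strand == "+":
        gs = max(1, g.start - window)
        ge = g.start - 1
        sub = seq[gs - 1:ge] if ge >= gs else ""
    else:
        gs = g.end + 1
        ge = min(len(seq), g.end + window)
        sub = revcomp(seq[gs - 1:ge]) if ge >= gs else ""
    return UpstreamWindow(gene_id=gene_id, seq=sub, start_offset=-len(sub),
                          genomic_start=gs, genomic_end=max(gs - 1, ge),
                          strand=g.strand)


def link_box_to_gene(ann: GenomeAnnotation, box: PromoterBox,
                     max_distance: int = 1000) -> PromoterBox:
    """Attach a promoter box to the nearest downstream gene on its strand.

    The downstream gene is the nearest gene whose translation start lies 3'
    of the box on the box strand, within ``max_distance`` bp.  If the nearest
    such gene is antisense to the box, the box is flagged ``opposed`` (and
    left unlinked); if no gene lies within reach the box keeps
    ``downstream_gene=None``.
    """
    candidates: list[tuple[int, GeneFeature]] = []
    for g in ann.genes_on(box.replicon):
        if box.strand == "+":
            dist = g.translation_start - box.end
        else:
            dist = box.start - g.translation_start
        if 0 < dist <= max_distance:
            candidates.append((dist, g))
    box = replace_box(box, downstream_gene=None, offset_start=None,
                      offset_end=None, opposed=False, opposed_gene=None)
    if not candidates:
        return box
    candidates.sort(key=lambda t: (t[0], t[1].id))
    dist, nearest = candidates[0]
    if nearest.strand != box.strand:
        box.opposed = True
        box.opposed_gene = nearest.id
        return box
    box.downstream_gene = nearest.id
    box.offset_end = -dist
    box.offset_start = -dist - box.length + 1
    return box


def replace_box(box: PromoterBox, **kw) -> PromoterBox:
    """Shallow copy of a PromoterBox with fields replaced."""
    from dataclasses import asdict
    d = asdict(box)
    d.update(kw)
    return PromoterBox(**d)
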