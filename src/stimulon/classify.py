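"""Knockout-epistasis classification of promoter boxes and gene groups.

A box is judged by the genistein-induction pattern of its downstream
transcription unit across the three genetic backgrounds:

* nod box (NB, NodD1-bound): active iff the unit is induced in the wild
  type AND the ttsI mutant but NOT in the nodD1 mutant.
* tts box (TB, TtsI-bound; TtsI itself is NB-driven): active iff the unit
  is induced in the wild type but in NEITHER mutant.

A box matching the epistasis sign pattern whose wild-type fold change sits
in the weak band [weak_fc, fc) is called weakly active; a box whose unit is
induced in a pattern inconsistent with its type (e.g. a TB whose genes stay
induced without TtsI) is non-functional; a box without a downstream gene,
or whose unit is below the baseline coverage floor, is not testable.

Every genistein-affected gene then lands in exactly one of three groups —
NB-controlled, TB-controlled, or "other" — or carries a discard reason
(antisense to a nod box, or an identical copy of a box-controlled gene).
Group-other genes get NodD1/TtsI dependence flags from the DEG pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomeAnnotation, PromoterBox, link_box_to_gene

logger = logging.getLogger(__name__)

GENISTEIN_CONTRASTS = (("WT", True), ("nodD1", True), ("ttsI", True))


@dataclass
class Thresholds:
    """Decision thresholds for box calls and group assembly."""

    fc: float = 3.0
    alpha: float = 0.05
    weak_fc: float = 2.0
    rescue_fc: float = 2.0
    coverage_floor: float = 10.0
    link_distance: int = 1000
    require_p: bool = True   # whether box-level "induced" also needs p < alpha

    def validate(self) -> None:
        if not (self.fc > self.weak_fc > 1):
            raise ValueError("need fc > weak_fc > 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class BoxFunctionalCall:
    box_id: str
    box_type: str
    call: str                 # active | weakly_active | non_functional | not_testable
    reason: str = ""
    lead_gene: str | None = None
    regulon: tuple[str, ...] = ()
    induced: dict = field(default_factory=dict)       # strain -> bool
    lead_fc: dict = field(default_factory=dict)       # strain -> float


def _require_contrasts(de: dict, box_type: str) -> None:
    missing = [s for (s, g) in GENISTEIN_CONTRASTS if (s, g) not in de]
    if missing:
        raise ValueError(
            f"{box_type} box activity requires the genistein contrasts for "
            f"all three strains; missing: {', '.join(missing)}")


def _unit_induced(de: dict, strain: str, genes: tuple[str, ...], lead: str,
                  fc_level: float, th: Thresholds) -> bool:
    """Lead gene up-induced, or a majority of the operon members are."""
    tab = de[(strain, True)]

    def up(g: str) -> bool:
        if g not in tab.index:
            return False
        row = tab.loc[g]
        ok = row["fc"] >= fc_level
        if th.require_p:
            ok = ok and row["p"] < th.alpha
        return bool(ok)

    if up(lead):
        return True
    members = [g for g in genes if g in tab.index]
    if len(members) >= 2:
        n_up = sum(up(g) for g in members)
        return n_up * 2 >= len(members)
    return False


def box_activity(box: PromoterBox, ann: GenomeAnnotation, de: dict,
                 thresholds: Thresholds | None = None) -> BoxFunctionalCall:
    """Call one NB or TB functional / weak / non-functional / not testable."""
    th = thresholds or Thresholds()
    th.validate()
    if box.box_type not in ("NB", "TB"):
        raise ValueError(
            f"no epistasis rule for box type {box.box_type!r}; only NB and "
            f"TB boxes are testable")
    _require_contrasts(de, box.box_type)

    if box.downstream_gene is None:
        reason = "opposed_gene" if box.opposed else "no_downstream_gene"
        return BoxFunctionalCall(box.id, box.box_type, "not_testable",
                                 reason=reason)
    lead = box.downstream_gene
    operon = ann.operon_of(lead)
    regulon = operon.gene_ids if operon else (lead,)

    wt_tab = de[("WT", True)]
    if lead not in wt_tab.index:
        return BoxFunctionalCall(box.id, box.box_type, "not_testable",
                                 reason="no_expression_data", lead_gene=lead)
    baseline_mean = float(wt_tab.loc[lead, "mean_norm_baseline"])
    treat_mean = float(wt_tab.loc[lead, "mean_norm_treatment"])
    if max(baseline_mean, treat_mean) < th.coverage_floor:
        return BoxFunctionalCall(box.id, box.box_type, "not_testable",
                                 reason="low_reads", lead_gene=lead,
                                 regulon=regulon)

    lead_fc = {s: float(de[(s, True)].loc[lead, "fc"])
               if lead in de[(s, True)].index else float("nan")
               for s, _ in GENISTEIN_CONTRASTS}
    strong = {s: _unit_induced(de, s, regulon, lead, th.fc, th)
              for s, _ in GENISTEIN_CONTRASTS}
    weak = {s: _unit_induced(de, s, regulon, lead, th.weak_fc, th)
            for s, _ in GENISTEIN_CONTRASTS}

    if box.box_type == "NB":
        pattern_strong = strong["WT"] and strong["ttsI"] and not strong["nodD1"]
        pattern_weak = weak["WT"] and weak["ttsI"] and not weak["nodD1"]
        inconsistent = "nodD1_independent_induction" if strong["nodD1"] else \
                       ("ttsI_dependent_induction"
                        if strong["WT"] and not strong["ttsI"] else "")
    else:  # TB
        pattern_strong = (strong["WT"] and not strong["nodD1"]
                          and not strong["ttsI"])
        pattern_weak = (weak["WT"] and not weak["nodD1"] and not weak["ttsI"])
        inconsistent = "ttsI_independent_induction" if strong["ttsI"] else \
                       ("nodD1_independent_induction"
                        if strong["nodD1"] else "")

    common = dict(lead_gene=lead, regulon=regulon, induced=strong,
                  lead_fc=lead_fc)
    if pattern_strong:
        return BoxFunctionalCall(box.id, box.box_type, "active", **common)
    if pattern_weak and lead_fc["WT"] < th.fc:
        return BoxFunctionalCall(box.id, box.box_type, "weakly_active",
                                 reason="low_efficiency", **common)
    if strong["WT"] and inconsistent:
        return BoxFunctionalCall(box.id, box.box_type, "non_functional",
                                 reason=inconsistent, **common)
    return BoxFunctionalCall(box.id, box.box_type, "non_functional",
                             reason="not_induced", **common)


# ---------------------------------------------------------------------------
# Affected-set assembly
# ---------------------------------------------------------------------------

def assemble_affected_set(de: dict, ann: GenomeAnnotation,
                          boxes: list[PromoterBox],
                          thresholds: Thresholds | None = None
                          ) -> pd.DataFrame:
    """Union of direct WT DEGs, operon-rescued and box-rescued genes.

    Routes: ``direct_DEG`` (genome-wide call in WT+genistein),
    ``operon_rescue`` (non-DEG member of an operon holding >=1 direct DEG),
    ``conserved_box_rescue`` (gene directly preceded by a 0-mismatch box
    whose wild-type fold change reaches the rescue threshold).
    """
    th = thresholds or Thresholds()
    wt = de[("WT", True)]
    routes: dict[str, str] = {}
    for g in wt.index[wt["call"]]:
        routes[g] = "direct_DEG"
    # operon rescue
    for op in ann.operons.values():
        if any(g in routes and routes[g] == "direct_DEG"
               for g in op.gene_ids):
            for g in op.gene_ids:
                routes.setdefault(g, "operon_rescue")
    # conserved-box rescue
    for box in boxes:
        if box.mismatches != 0 or box.downstream_gene is None:
            continue
        g = box.downstream_gene
        if g in routes or g not in wt.index:
            continue
        if float(wt.loc[g, "fc"]) >= th.rescue_fc:
            routes[g] = "conserved_box_rescue"
    return pd.DataFrame(
        {"route": pd.Series(routes, dtype="object")}).rename_axis("gene")


def apply_discard_rules(affected: pd.DataFrame, ann: GenomeAnnotation,
                        boxes: list[PromoterBox]
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes antisense to a nod box and duplicate identical copies.

    Returns (retained frame, discard log with reasons).
    """
    discards: list[dict] = []
    drop: set[str] = set()

    opposed = {b.opposed_gene for b in boxes
               if b.box_type == "NB" and b.opposed and b.opposed_gene}
    for g in affected.index:
        if g in opposed:
            drop.add(g)
            discards.append({"gene": g, "reason": "opposed_to_NB"})

    # identical copies: keep the box-linked copy, discard the rest
    box_linked: set[str] = set()
    for b in boxes:
        if b.downstream_gene:
            box_linked.add(b.downstream_gene)
            op = ann.operon_of(b.downstream_gene)
            if op:
                box_linked.update(op.gene_ids)
    by_seq: dict[str, list[str]] = {}
    for g in affected.index:
        if g in drop or g not in ann.genes:
            continue
        try:
            by_seq.setdefault(ann.gene_sequence(g), []).append(g)
        except KeyError:
            continue
    for seq, members in by_seq.items():
        if len(members) < 2:
            continue
        kept = [g for g in members if g in box_linked]
        if not kept:
            continue
        for g in members:
            if g not in box_linked:
                drop.add(g)
                discards.append({"gene": g, "reason": "identical_copy",
                                 "of": kept[0]})

    retained = affected.drop(index=[g for g in drop if g in affected.index])
    log = (pd.DataFrame(discards).set_index("gene") if discards
           else pd.DataFrame(columns=["reason", "of"]).rename_axis("gene"))
    return retained, log


# ---------------------------------------------------------------------------
# Group assignment
# ---------------------------------------------------------------------------

def _box_gene_distance(box: PromoterBox, ann: GenomeAnnotation,
                       gene_id: str) -> int:
    g = ann.genes[gene_id]
    if box.strand == "+":
        return abs(g.translation_start - box.end)
    return abs(box.start - g.translation_start)


def assign_groups(retained: pd.DataFrame, box_calls: list[BoxFunctionalCall],
                  boxes: list[PromoterBox], de: dict, ann: GenomeAnnotation,
                  syrm_boxes: list[PromoterBox] | None = None
                  ) -> pd.DataFrame:
    """Assign every retained gene to group NB / TB / other.

    NB regulons of active and weakly active nod boxes claim their genes;
    TB regulons of active tts boxes claim theirs; everything else is group
    "other" with NodD1/TtsI dependence flags (defined for direct DEGs only:
    dependent on a regulator iff the gene is a DEG in the wild type but not
    in that regulator's knockout).  A gene claimed by both an NB and a TB
    goes to the nearer box, with a logged conflict warning.
    """
    box_by_id = {b.id: b for b in boxes}
    claims: dict[str, list[tuple[str, str]]] = {}   # gene -> [(group, box_id)]
    for call in box_calls:
        if call.box_type == "NB" and call.call in ("active", "weakly_active"):
            group = "NB"
        elif call.box_type == "TB" and call.call == "active":
            group = "TB"
        else:
            continue
        for g in call.regulon:
            claims.setdefault(g, []).append((group, call.box_id))

    degs = {s: set(de[(s, True)].index[de[(s, True)]["call"]])
            for s, _ in GENISTEIN_CONTRASTS}
    syrm_upstream: set[str] = set()
    for b in (syrm_boxes or []):
        if b.downstream_gene:
            op = ann.operon_of(b.downstream_gene)
            syrm_upstream.update(op.gene_ids if op else (b.downstream_gene,))

    rows = []
    for g in retained.index:
        route = retained.loc[g, "route"]
        claimed = claims.get(g, [])
        groups = {grp for grp, _ in claimed}
        if len(groups) > 1:
            nearest = min(claimed, key=lambda c: _box_gene_distance(
                box_by_id[c[1]], ann, g))
            logger.warning("gene %s claimed by both an active NB and an "
                           "active TB; assigned to nearer box %s", g,
                           nearest[1])
            group, box_id = nearest
        elif claimed:
            group, box_id = claimed[0]
        else:
            group, box_id = "other", ""
        nod_dep = tts_dep = pd.NA
        if group == "other" and g in degs["WT"]:
            nod_dep = g not in degs["nodD1"]
            tts_dep = g not in degs["ttsI"]
        rows.append({"gene": g, "group": group, "box": box_id,
                     "route": route, "nodD1_dependent": nod_dep,
                     "ttsI_dependent": tts_dep,
                     "syrm_box_upstream": g in syrm_upstream})
    return pd.DataFrame(rows).set_index("gene")


def mutant_background_table(de: dict, thresholds: Thresholds | None = None
                            ) -> pd.DataFrame:
    """Genes differentially expressed in both mutants without genistein.

    The fbpA pattern: expression altered in the nodD1 and ttsI backgrounds
    regardless of the flavonoid; reported separately from the three groups.
    """
    keys = [("nodD1", False), ("ttsI", False)]
    if not all(k in de for k in keys):
        return pd.DataFrame(columns=["log2fc_nodD1", "log2fc_ttsI",
                                     "direction"]).rename_axis("gene")
    a, b = de[keys[0]], de[keys[1]]
    genes = sorted(set(a.index[a["call"]]) & set(b.index[b["call"]]))
    rows = []
    for g in genes:
        if a.loc[g, "direction"] != b.loc[g, "direction"]:
            continue
        rows.append({"gene": g, "log2fc_nodD1": a.loc[g, "log2fc"],
                     "log2fc_ttsI": b.loc[g, "log2fc"],
                     "direction": a.loc[g, "direction"]})
    return (pd.DataFrame(rows).set_index("gene") if rows
            else pd.DataFrame(columns=["log2fc_nodD1", "log2fc_ttsI",
                                       "direction"]).rename_axis("gene"))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    box_calls: list[BoxFunctionalCall]
    boxes: list[PromoterBox]          # after (re)linking
    affected: pd.DataFrame
    retained: pd.DataFrame
    discards: pd.DataFrame
    assignments: pd.DataFrame
    mutant_background: pd.DataFrame

    def box_call_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.box_calls:
            rows.append({
                "box": c.box_id, "type": c.box_type, "call": c.call,
                "reason": c.reason, "lead_gene": c.lead_gene or "",
                "regulon": ",".join(c.regulon),
                **{f"induced_{s}": c.induced.get(s, "")
                   for s in ("WT", "nodD1", "ttsI")},
                **{f"fc_{s}": c.lead_fc.get(s, "")
                   for s in ("WT", "nodD1", "ttsI")}})
        return (pd.DataFrame(rows).set_index("box") if rows
                else pd.DataFrame(columns=["type", "call"]).rename_axis("box"))

    def n_active(self, box_type: str,
                 include_weak: bool = False) -> int:
        ok = ("active", "weakly_active") if include_weak else ("active",)
        return sum(1 for c in self.box_calls
                   if c.box_type == box_type and c.call in ok)


def classify(ann: GenomeAnnotation, de: dict,
             thresholds: Thresholds | None = None,
             relink: bool = True) -> ClassificationResult:
    """Full classification pass over an annotated genome and DE results."""
    th = thresholds or Thresholds()
    th.validate()
    boxes = list(ann.boxes.values())
    if relink:
        boxes = [link_box_to_gene(ann, b, th.link_distance) for b in boxes]
    nb_tb = [b for b in boxes if b.box_type in ("NB", "TB")]
    syrm = [b for b in boxes if b.box_type == "SyrM"]

    box_calls = [box_activity(b, ann, de, th) for b in nb_tb]
    affected = assemble_affected_set(de, ann, boxes, th)
    retained, discards = apply_discard_rules(affected, ann, boxes)
    assignments = assign_groups(retained, box_calls, nb_tb, de, ann,
                                syrm_boxes=syrm)
    return ClassificationResult(
        box_calls=box_calls, boxes=boxes, affected=affected,
        retained=retained, discards=discards, assignments=assignments,
        mutant_background=mutant_background_table(de, th))
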