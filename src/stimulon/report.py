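"""Stimulon summary report: Venn partition, replicon tables, group totals.

The Venn partition decomposes the three strains' DEG sets into the seven
disjoint cells (each strain alone, each pair, all three); strain totals are
recovered by summing the cells containing that strain, and the report
asserts that internal consistency before serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .classify import ClassificationResult
from .genome import GenomeAnnotation

STRAINS = ("WT", "nodD1", "ttsI")

VENN_CELLS = ("WT_only", "nodD1_only", "ttsI_only", "WT&nodD1", "WT&ttsI",
              "nodD1&ttsI", "WT&nodD1&ttsI")


def venn_partition(sets: dict[str, set]) -> dict[str, int]:
    """Disjoint 7-cell partition of three labelled sets."""
    wt, nod, tts = (set(sets.get(s, set())) for s in STRAINS)
    return {
        "WT_only": len(wt - nod - tts),
        "nodD1_only": len(nod - wt - tts),
        "ttsI_only": len(tts - wt - nod),
        "WT&nodD1": len((wt & nod) - tts),
        "WT&ttsI": len((wt & tts) - nod),
        "nodD1&ttsI": len((nod & tts) - wt),
        "WT&nodD1&ttsI": len(wt & nod & tts),
    }


def venn_strain_total(cells: dict[str, int], strain: str) -> int:
    """Sum of the Venn cells containing one strain."""
    return sum(n for name, n in cells.items()
               if strain in name.replace("_only", "").split("&"))


def check_venn(cells: dict[str, int], sets: dict[str, set]) -> None:
    """Cells must be disjoint and sum to the union."""
    union = set().union(*sets.values()) if sets else set()
    if sum(cells.values()) != len(union):
        raise AssertionError("Venn cells do not sum to the union")
    for s in sets:
        if venn_strain_total(cells, s) != len(sets[s]):
            raise AssertionError(f"Venn cells for {s} do not sum to |{s}|")


def percent_of_genome(n: int, n_cds: int, digits: int = 2) -> float:
    """Share of the genome's coding sequences, as a rounded percentage."""
    return round(100.0 * n / n_cds, digits)


def direction_counts(table: pd.DataFrame) -> dict[str, int]:
    """Up/down split of the called DEGs in one contrast table."""
    called = table[table["call"]]
    up = int((called["direction"] == "up").sum())
    return {"up": up, "down": len(called) - up, "total": len(called)}


def replicon_distribution(de: dict, ann: GenomeAnnotation) -> dict:
    """Per-strain, per-replicon up/down DEG counts (+genistein cells)."""
    out: dict[str, dict[str, dict[str, int]]] = {}
    for (strain, gen), tab in de.items():
        if not gen:
            continue
        table: dict[str, dict[str, int]] = {
            rid: {"up": 0, "down": 0} for rid in ann.replicons}
        called = tab[tab["call"]]
        for g in called.index:
            if g not in ann.genes:
                continue
            rid = ann.genes[g].replicon
            table[rid][called.loc[g, "direction"]] += 1
        out[strain] = table
    return out


def group_counts(assignments: pd.DataFrame) -> dict[str, int]:
    counts = assignments["group"].value_counts().to_dict()
    return {g: int(counts.get(g, 0)) for g in ("NB", "TB", "other")}


@dataclass
class StimulonReport:
    """Machine-readable end-to-end summary of one analysis run."""

    venn: dict[str, int]
    strain_totals: dict[str, int]
    direction: dict[str, dict[str, int]]
    replicon_counts: dict
    box_calls: dict[str, dict[str, int]]    # box type -> call -> n
    groups: dict[str, int]
    n_affected: int
    n_discarded: int
    n_retained: int
    dependence: dict[str, int]
    mutant_background: list[str]
    meta: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        for s, total in self.strain_totals.items():
            if venn_strain_total(self.venn, s) != total:
                raise AssertionError(
                    f"Venn cells for {s} do not sum to the strain total")
        if self.n_affected - self.n_discarded != self.n_retained:
            raise AssertionError("affected - discarded != retained")
        if sum(self.groups.values()) != self.n_retained:
            raise AssertionError("group sizes do not sum to retained genes")

    def to_json(self, path: str | Path | None = None) -> str:
        self.check_consistency()
        payload = {
            "venn": self.venn, "strain_totals": self.strain_totals,
            "direction": self.direction,
            "replicon_counts": self.replicon_counts,
            "box_calls": self.box_calls, "groups": self.groups,
            "n_affected": self.n_affected, "n_discarded": self.n_discarded,
            "n_retained": self.n_retained, "dependence": self.dependence,
            "mutant_background": self.mutant_background, "meta": self.meta,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def summarize(de: dict, result: ClassificationResult, ann: GenomeAnnotation,
              meta: dict | None = None) -> StimulonReport:
    """Assemble the full report from DE results and the classification."""
    sets = {s: set(de[(s, True)].index[de[(s, True)]["call"]])
            for s in STRAINS if (s, True) in de}
    cells = venn_partition(sets)
    check_venn(cells, sets)

    box_calls: dict[str, dict[str, int]] = {}
    for c in result.box_calls:
        box_calls.setdefault(c.box_type, {})
        box_calls[c.box_type][c.call] = box_calls[c.box_type].get(c.call, 0) + 1

    assignments = result.assignments
    other = assignments[assignments["group"] == "other"]
    dependence = {
        "nodD1_dependent": int((other["nodD1_dependent"] == True).sum()),  # noqa: E712
        "ttsI_dependent": int((other["ttsI_dependent"] == True).sum()),  # noqa: E712
        "independent": int(((other["nodD1_dependent"] == False)
                            & (other["ttsI_dependent"] == False)).sum()),  # noqa: E712
    }
    report = StimulonReport(
        venn=cells,
        strain_totals={s: len(sets[s]) for s in sets},
        direction={s: direction_counts(de[(s, True)]) for s in sets},
        replicon_counts=replicon_distribution(de, ann),
        box_calls=box_calls,
        groups=group_counts(assignments),
        n_affected=len(result.affected),
        n_discarded=len(result.discards),
        n_retained=len(result.retained),
        dependence=dependence,
        mutant_background=list(result.mutant_background.index),
        meta=meta or {},
    )
    report.check_consistency()
    return report
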