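"""Degenerate promoter-motif patterns and fuzznuc-style scanning.

Patterns are literal IUPAC blocks separated by fixed-length N spacers, e.g.
``ATCN9GATN7ATCN6ATCGATN6AAT`` (the classic nod-box consensus: 46 bp, 18
informative positions).  N spacers constrain length only and never count
towards mismatches.  A pattern may carry a mandatory core sub-pattern (the
tts-box ``CGN2AG`` core): windows that mismatch inside the core are rejected
regardless of the overall mismatch budget.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeAnnotation, PromoterBox, revcomp, upstream_window

# Consensus strings for the two box families with a published consensus.
NB_CONSENSUS = "ATCN9GATN7ATCN6ATCGATN6AAT"
TB_CONSENSUS = "GTCAGN5CGN2AGN10TA"
TB_CORE = "CGN2AG"

# The SyrM-box consensus (defined for S. meliloti) is not distributed with
# this package; SYRM_SYNTHETIC is a synthetic stand-in pattern used by the
# simulator and demos.  Its 66-bp span matches the length of reported SyrM
# boxes; its literal content is arbitrary.
SYRM_SYNTHETIC = "GATCN4TTGCN8AATCN28GCTAN6TTCG"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_TOKEN = re.compile(r"N(\d+)|([ACGTRYSWKMBDHVN])", re.IGNORECASE)


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """A parsed degenerate pattern."""

    id: str
    text: str
    segments: tuple[tuple[str, object], ...]  # ("lit", str) | ("spacer", int)
    expanded: str          # pattern as a flat string, spacers as N runs
    core: str | None = None
    core_span: tuple[int, int] | None = None  # 0-based [start, end) in expanded

    @property
    def length(self) -> int:
        return len(self.expanded)

    @property
    def informative_positions(self) -> int:
        return sum(1 for c in self.expanded if c != "N")


def _expand(text: str) -> tuple[tuple[tuple[str, object], ...], str]:
    segments: list[tuple[str, object]] = []
    expanded: list[str] = []
    pos = 0
    lit: list[str] = []

    def flush_literal():
        if lit:
            segments.append(("lit", "".join(lit)))
            lit.clear()

    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise PatternError(
                f"malformed pattern at position {pos + 1}: {text[pos:]!r}")
        if m.group(1) is not None:
            n = int(m.group(1))
            if n < 1:
                raise PatternError(f"zero-length spacer at position {pos + 1}")
            flush_literal()
            segments.append(("spacer", n))
            expanded.append("N" * n)
        else:
            base = m.group(2).upper()
            lit.append(base)
            expanded.append(base)
        pos = m.end()
    flush_literal()
    if not any(kind == "lit" for kind, _ in segments):
        raise PatternError("pattern has no literal block")
    return tuple(segments), "".join(expanded)


def parse_pattern(text: str, id: str | None = None,
                  core: str | None = None) -> MotifPattern:
    """Parse pattern text of the form LITERAL (N<count> LITERAL)*.

    ``core`` optionally names a mandatory sub-pattern; it must occur (as
    pattern text) within the full pattern.
    """
    segments, expanded = _expand(text)
    core_span = None
    if core is not None:
        _, core_exp = _expand(core)
        idx = expanded.find(core_exp)
        if idx < 0:
            raise PatternError(f"core {core!r} not found within {text!r}")
        core_span = (idx, idx + len(core_exp))
    return MotifPattern(id=id or text, text=text, segments=segments,
                        expanded=expanded, core=core, core_span=core_span)


@dataclass(frozen=True)
class MotifHit:
    """One pattern occurrence (1-based inclusive coordinates)."""

    pattern_id: str
    sequence_id: str
    start: int
    end: int
    strand: str
    mismatches: int


def _mismatch_profile(seq: str, pattern: MotifPattern) -> np.ndarray:
    """Per-window mismatch counts over informative positions (forward)."""
    L = pattern.length
    n_win = len(seq) - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int32)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    mism = np.zeros(n_win, dtype=np.int32)
    for i, c in enumerate(pattern.expanded):
        if c == "N":
            continue
        allowed = np.frombuffer(IUPAC[c].encode("ascii"), dtype=np.uint8)
        mism += ~np.isin(arr[i:i + n_win], allowed)
    return mism


def _core_violations(seq: str, pattern: MotifPattern) -> np.ndarray | None:
    if pattern.core_span is None:
        return None
    lo, hi = pattern.core_span
    L = pattern.length
    n_win = len(seq) - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=bool)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    viol = np.zeros(n_win, dtype=bool)
    for i in range(lo, hi):
        c = pattern.expanded[i]
        if c == "N":
            continue
        allowed = np.frombuffer(IUPAC[c].encode("ascii"), dtype=np.uint8)
        viol |= ~np.isin(arr[i:i + n_win], allowed)
    return viol


def scan(seq: str, pattern: MotifPattern, max_mismatches: int = 0,
         strands: str = "+-", sequence_id: str = "seq") -> list[MotifHit]:
    """Report every window matching the pattern within the mismatch budget.

    N spacer positions match anything; the reverse strand is scanned against
    the reverse complement, hit coordinates mapped back to the forward
    strand.  Hits are sorted by start position, '+' strand first on ties.
    A sequence shorter than the pattern yields an empty list.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    L = pattern.length
    hits: list[MotifHit] = []
    for strand in strands:
        target = seq if strand == "+" else revcomp(seq)
        mism = _mismatch_profile(target, pattern)
        viol = _core_violations(target, pattern)
        for i in np.nonzero(mism <= max_mismatches)[0]:
            if viol is not None and viol[i]:
                continue
            if strand == "+":
                start = int(i) + 1
            else:
                start = len(seq) - int(i) - L + 1
            hits.append(MotifHit(pattern_id=pattern.id,
                                 sequence_id=sequence_id, start=start,
                                 end=start + L - 1, strand=strand,
                                 mismatches=int(mism[i])))
    hits.sort(key=lambda h: (h.start, h.strand != "+"))
    return hits


def scan_upstream(ann: GenomeAnnotation, pattern: MotifPattern, window: int,
                  max_mismatches: int = 0) -> list[PromoterBox]:
    """Scan each gene's upstream window for the pattern.

    Only the gene's own strand is searched (the upstream window is already
    strand-oriented).  Hits become :class:`PromoterBox` candidates typed by
    the pattern id, with offsets relative to the translation start.
    """
    if window < pattern.length:
        raise ValueError("window must be >= pattern length")
    candidates: list[PromoterBox] = []
    for g in ann.sorted_genes():
        uw = upstream_window(ann, g.id, window)
        if len(uw.seq) < pattern.length:
            continue
        for hit in scan(uw.seq, pattern, max_mismatches, strands="+",
                        sequence_id=g.id):
            off_start = uw.start_offset + hit.start - 1
            off_end = uw.start_offset + hit.end - 1
            gpos = sorted((uw.genomic_position(hit.start),
                           uw.genomic_position(hit.end)))
            candidates.append(PromoterBox(
                id=f"{pattern.id}:{g.id}:{off_start}",
                box_type=pattern.id, replicon=g.replicon,
                start=gpos[0], end=gpos[1], strand=g.strand,
                downstream_gene=g.id, offset_start=off_start,
                offset_end=off_end, mismatches=hit.mismatches))
    return candidates


# ---------------------------------------------------------------------------
# Pattern files and sequence instantiation
# ---------------------------------------------------------------------------

@dataclass
class PatternSet:
    """Patterns loaded from a pattern TSV (id, pattern, core, budget)."""

    patterns: dict[str, MotifPattern] = field(default_factory=dict)
    budgets: dict[str, int] = field(default_factory=dict)


def default_patterns() -> PatternSet:
    ps = PatternSet()
    ps.patterns["NB"] = parse_pattern(NB_CONSENSUS, id="NB")
    ps.budgets["NB"] = 1
    ps.patterns["TB"] = parse_pattern(TB_CONSENSUS, id="TB", core=TB_CORE)
    ps.budgets["TB"] = 1
    ps.patterns["SyrM"] = parse_pattern(SYRM_SYNTHETIC, id="SyrM")
    ps.budgets["SyrM"] = 1
    return ps


def read_pattern_file(path: str | Path) -> PatternSet:
    """Read a TSV of (id, pattern, core, budget); core/budget may be blank."""
    ps = PatternSet()
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
            core = row.get("core") or None
            pid = row["id"]
            ps.patterns[pid] = parse_pattern(row["pattern"], id=pid, core=core)
            ps.budgets[pid] = int(row.get("budget") or 0)
    return ps


def write_pattern_file(ps: PatternSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tpattern\tcore\tbudget\n")
        for pid, pat in ps.patterns.items():
            fh.write(f"{pid}\t{pat.text}\t{pat.core or ''}"
                     f"\t{ps.budgets.get(pid, 0)}\n")


def instantiate(pattern: MotifPattern, rng: np.random.Generator,
                mismatches: int = 0, corrupt_core: bool = False) -> str:
    """Draw one concrete sequence realizing the pattern.

    N positions are filled uniformly; degenerate literals pick a member of
    their base set.  ``mismatches`` informative positions outside the core
    are then corrupted; ``corrupt_core`` additionally breaks two core
    positions (used to plant non-functional tts boxes).
    """
    bases = []
    for c in pattern.expanded:
        choices = IUPAC[c]
        bases.append(choices[rng.integers(len(choices))])
    core_lo, core_hi = pattern.core_span or (0, 0)
    informative = [i for i, c in enumerate(pattern.expanded) if c != "N"]
    outside_core = [i for i in informative if not (core_lo <= i < core_hi)]
    if mismatches:
        for i in rng.choice(len(outside_core),
                            size=min(mismatches, len(outside_core)),
                            replace=False):
            pos = outside_core[int(i)]
            others = [b for b in "ACGT" if b not in IUPAC[pattern.expanded[pos]]]
            bases[pos] = others[rng.integers(len(others))]
    if corrupt_core:
        core_informative = [i for i in informative if core_lo <= i < core_hi]
        if not core_informative:
            raise PatternError("pattern has no core to corrupt")
        for i in rng.choice(len(core_informative),
                            size=min(2, len(core_informative)), replace=False):
            pos = core_informative[int(i)]
            others = [b for b in "ACGT" if b not in IUPAC[pattern.expanded[pos]]]
            bases[pos] = others[rng.integers(len(others))]
    return "".join(bases)
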