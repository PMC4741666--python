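"""Exact-match scanning for splicing enhancer/silencer factor binding motifs.

The packaged table holds experimentally characterized target sequences per
factor (exact matches only, no degenerate scoring — the point of an
experimentally-assessed motif set is that a hit is a literal binding
sequence).  Grading of gain/loss events follows the published criteria:
gaining an exonic binding site for the strong silencer hnRNP A1 is severe,
gaining a site for any other exonic silencer is mild, and losing an exonic
enhancer site is neutral because enhancer motifs are redundant in exons.
Combinations the criteria do not cover (intronic changes, exonic enhancer
gains, silencer losses) default to neutral and are configurable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

from .genome_variant import GeneModel, SequencePair
from .splice_scoring import Severity

HNRNP_A1 = "hnRNP A1"


class MotifRole(str, Enum):
    enhancer = "enhancer"
    silencer = "silencer"


class Region(str, Enum):
    exonic = "exonic"
    intronic = "intronic"


class ChangeKind(str, Enum):
    gained = "gained"
    lost = "lost"


@dataclass(frozen=True)
class SREMotif:
    factor: str
    motif: str
    role: MotifRole

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError(f"motif {self.motif!r} shorter than 4 nt")


@dataclass(frozen=True)
class MotifHit:
    factor: str
    motif: str
    role: MotifRole
    region: Region
    position: int


@dataclass
class SREChangeEvent:
    change: ChangeKind
    factor: str
    role: MotifRole
    region: Region
    position: int           # WT pre-mRNA frame (insertions collapse onto the edit start)
    motif: str
    grade: Severity


def load_motif_table(path: str | Path | None = None) -> list[SREMotif]:
    if path is None:
        path = resources.files("splicetriage.data") / "sre_motifs.tsv"
    motifs = []
    with open(str(path), newline="") as fh:
        rows = (line for line in fh if not line.startswith("#"))
        for row in csv.DictReader(rows, delimiter="\t"):
            motifs.append(SREMotif(row["factor"], row["motif"].upper(),
                                   MotifRole(row["role"])))
    if not any(m.factor == HNRNP_A1 and m.role is MotifRole.silencer for m in motifs):
        raise ValueError("motif table must contain at least one hnRNP A1 silencer motif")
    return motifs


def _find_all(sequence: str, motif: str, lo: int = 0, hi: int | None = None) -> list[int]:
    hi = len(sequence) if hi is None else hi
    out, start = [], lo
    while True:
        i = sequence.find(motif, start, hi + len(motif) - 1)
        if i == -1 or i >= hi:
            return out
        out.append(i)
        start = i + 1


def scan_motifs(table: list[SREMotif], sequence: str,
                region_of) -> list[MotifHit]:
    """Every exact occurrence of every motif, labeled with factor, role and
    region.  ``region_of(pos)`` maps a coordinate to exonic/intronic; a motif
    straddling a boundary takes the region of its 5'-most base."""
    hits = []
    for m in table:
        for pos in _find_all(sequence, m.motif):
            hits.append(MotifHit(m.factor, m.motif, m.role, region_of(pos), pos))
    return hits


def grade_sre_event(change: ChangeKind, factor: str, role: MotifRole,
                    region: Region) -> Severity:
    """Pure severity function over the published criteria (iii)-(iv)."""
    if change is ChangeKind.gained and role is MotifRole.silencer and region is Region.exonic:
        return Severity.severe if factor == HNRNP_A1 else Severity.mild
    return Severity.neutral


def model_region_of(model: GeneModel):
    def region_of(pos: int) -> Region:
        return Region.exonic if model.is_exonic(pos) else Region.intronic
    return region_of


def _mut_region_of(pair: SequencePair):
    exons = pair.mut_exons

    def region_of(pos: int) -> Region:
        return Region.exonic if any(s <= pos < e for s, e in exons) else Region.intronic
    return region_of


def diff_motifs(table: list[SREMotif], pair: SequencePair, model: GeneModel,
                window: int = 100) -> list[SREChangeEvent]:
    """Motif gains/losses between WT and mutant around the edit.

    Hits are keyed by (factor, motif, position) with mutant positions
    projected back through the edit into the WT frame, so an indel shifting
    downstream coordinates does not turn every downstream hit into a
    spurious gain+loss pair.
    """
    if pair.wt_premrna == pair.mut_premrna:
        return []
    estart, eend, delta = pair.edit_start, pair.edit_end, pair.delta
    max_len = max(len(m.motif) for m in table)
    lo = max(0, estart - window - max_len)
    hi = min(len(pair.wt_premrna), eend + window + max_len)
    mut_hi = min(len(pair.mut_premrna), eend + delta + window + max_len)

    wt_region = model_region_of(model)
    mut_region = _mut_region_of(pair)

    wt_hits: dict[tuple, MotifHit] = {}
    mut_hits: dict[tuple, MotifHit] = {}
    for m in table:
        for pos in _find_all(pair.wt_premrna, m.motif, lo, hi):
            wt_hits[(m.factor, m.motif, pos)] = MotifHit(
                m.factor, m.motif, m.role, wt_region(pos), pos)
        for q in _find_all(pair.mut_premrna, m.motif, lo, mut_hi):
            if q <= estart:
                p = q
            elif q >= estart + len(pair.inserted):
                p = q - delta
            else:
                p = estart
            mut_hits[(m.factor, m.motif, p)] = MotifHit(
                m.factor, m.motif, m.role, mut_region(q), p)

    events = []
    for key in sorted(set(mut_hits) - set(wt_hits)):
        h = mut_hits[key]
        events.append(SREChangeEvent(ChangeKind.gained, h.factor, h.role, h.region,
                                     h.position, h.motif,
                                     grade_sre_event(ChangeKind.gained, h.factor,
                                                     h.role, h.region)))
    for key in sorted(set(wt_hits) - set(mut_hits)):
        h = wt_hits[key]
        events.append(SREChangeEvent(ChangeKind.lost, h.factor, h.role, h.region,
                                     h.position, h.motif,
                                     grade_sre_event(ChangeKind.lost, h.factor,
                                                     h.role, h.region)))
    return events
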