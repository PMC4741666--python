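"""Gain/loss detection for mRNA nuclear-export regulatory elements.

An informational channel: element changes are reported alongside the
severity verdicts but never enter the consensus, because no severity rule is
defined for them — they exist to investigate discrepancies (e.g. a predicted
benign variant whose protein is nonetheless absent).  Scanning runs on the
mature mRNA (export elements act on the spliced transcript).  The packaged
element table is an explicitly synthetic placeholder; point ``table_path``
at a real collection to scan one.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

from .genome_variant import SequencePair
from .sre_scan import ChangeKind, _find_all

ELEMENT_NAMES = {"eIF4E-SE", "CJE", "CAR", "PRE", "CTE", "SSCR", "other"}


class ExportEffect(str, Enum):
    facilitates = "facilitates"
    obstructs = "obstructs"


@dataclass(frozen=True)
class ExportElement:
    name: str
    motif: str
    effect: ExportEffect

    def __post_init__(self) -> None:
        if self.name not in ELEMENT_NAMES:
            raise ValueError(f"unknown export element name {self.name!r}")


@dataclass(frozen=True)
class ExportChange:
    change: ChangeKind
    element: ExportElement
    position: int       # WT mature-mRNA frame


def load_export_table(path: str | Path | None = None) -> list[ExportElement]:
    if path is None:
        path = resources.files("splicetriage.data") / "export_elements.synthetic.tsv"
    out = []
    with open(str(path), newline="") as fh:
        rows = (line for line in fh if not line.startswith("#"))
        for row in csv.DictReader(rows, delimiter="\t"):
            out.append(ExportElement(row["name"], row["motif"].upper(),
                                     ExportEffect(row["effect"])))
    if not out:
        raise ValueError("export element table is empty")
    return out


def _mature_edit(wt: str, mut: str) -> tuple[int, int, int]:
    """Edit extent (start, end, delta) between two matures that differ only
    locally, found as the common prefix/suffix split."""
    i = 0
    while i < min(len(wt), len(mut)) and wt[i] == mut[i]:
        i += 1
    j = 0
    while (j < min(len(wt), len(mut)) - i
           and wt[len(wt) - 1 - j] == mut[len(mut) - 1 - j]):
        j += 1
    return i, len(wt) - j, len(mut) - len(wt)


def diff_export_elements(table: list[ExportElement],
                         pair: SequencePair) -> list[ExportChange]:
    """Symmetric difference of element hits between WT and mutant mature
    mRNA, with mutant positions projected back through the edit."""
    wt, mut = pair.wt_mature, pair.mut_mature
    if wt == mut:
        return []
    estart, eend, delta = _mature_edit(wt, mut)
    ins_len = (eend - estart) + delta

    wt_hits: set[tuple[str, str, int]] = set()
    mut_hits: set[tuple[str, str, int]] = set()
    by_key = {}
    for el in table:
        by_key[(el.name, el.motif)] = el
        for p in _find_all(wt, el.motif):
            wt_hits.add((el.name, el.motif, p))
        for q in _find_all(mut, el.motif):
            if q <= estart:
                p = q
            elif q >= estart + ins_len:
                p = q - delta
            else:
                p = estart
            mut_hits.add((el.name, el.motif, p))

    changes = []
    for name, motif, p in sorted(mut_hits - wt_hits):
        changes.append(ExportChange(ChangeKind.gained, by_key[(name, motif)], p))
    for name, motif, p in sorted(wt_hits - mut_hits):
        changes.append(ExportChange(ChangeKind.lost, by_key[(name, motif)], p))
    return changes
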