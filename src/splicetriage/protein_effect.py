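"""Protein-channel severity verdicts.

Most of this channel is rule-forced: nonsense and frameshift variants are
severe outright; in-frame insertions/deletions are capped at mild even when
an external predictor calls them damaging (they add or remove a few residues
without changing the reading frame); synonymous and splice-site variants
have no protein channel at all.  Missense verdicts come from an external
predictor adapter when verdict rows are supplied (dangerous -> severe,
neutral -> neutral, binary — the adapters' confidence is carried but unused
by default), and otherwise from a transparent physicochemical surrogate
(Grantham distance thresholding).  A variant touching a special protein
region (e.g. a nuclear localization signal) escalates missense/stop-loss
verdicts to severe: NLS disruption mislocalizes the protein regardless of
the substitution's chemistry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

from .genome_variant import (
    GeneModel,
    SequencePair,
    SpliceTriageError,
    VariantClass,
)
from .splice_scoring import Severity


class ProteinLabel(str, Enum):
    severe = "severe"
    mild = "mild"
    neutral = "neutral"
    not_applicable = "not_applicable"


class VerdictSource(str, Enum):
    rule = "rule"
    surrogate = "surrogate"
    adapter_consensus = "adapter:consensus"
    adapter_indel = "adapter:indel"


@dataclass
class ProteinVerdict:
    label: ProteinLabel
    confidence: float
    source: VerdictSource
    rationale: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


VALID_TOOLS = {"consensus_missense", "indel_nonsense"}
VALID_CALLS = {"dangerous", "neutral", "disease", "benign"}
_DAMAGING = {"dangerous", "disease"}


@dataclass(frozen=True)
class ExternalVerdictRow:
    hgvs_c: str
    tool: str
    call: str
    confidence: float

    def __post_init__(self) -> None:
        if self.tool not in VALID_TOOLS:
            raise SpliceTriageError(f"unknown tool {self.tool!r}")
        if self.call not in VALID_CALLS:
            raise SpliceTriageError(f"unknown call {self.call!r}")
        if not 0.0 <= self.confidence <= 1.0:
            raise SpliceTriageError(f"confidence {self.confidence} outside [0, 1]")


_grantham: dict[tuple[str, str], float] = {}


def grantham_distance(wt_aa: str, mut_aa: str) -> float:
    """Physicochemical substitution distance (packaged table, 0 on identity)."""
    if not _grantham:
        path = resources.files("splicetriage.data") / "grantham_distance.tsv"
        with open(str(path), newline="") as fh:
            rows = (line for line in fh if not line.startswith("#"))
            for row in csv.DictReader(rows, delimiter="\t"):
                _grantham[(row["wt_aa"], row["mut_aa"])] = float(row["distance"])
    return _grantham[(wt_aa, mut_aa)]


_MAX_GRANTHAM = 215.0


def surrogate_missense_score(wt_aa: str, mut_aa: str,
                             threshold: float = 100.0) -> ProteinVerdict:
    """Deterministic missense verdict from Grantham distance.

    Distances at/above ``threshold`` (default 100, the conventional
    radical-substitution cutoff) are severe, below it neutral; the scaled
    distance doubles as the confidence."""
    if wt_aa == mut_aa:
        return ProteinVerdict(ProteinLabel.neutral, 0.0, VerdictSource.surrogate,
                              "identical residue")
    d = grantham_distance(wt_aa, mut_aa)
    label = ProteinLabel.severe if d >= threshold else ProteinLabel.neutral
    return ProteinVerdict(label, min(d / _MAX_GRANTHAM, 1.0), VerdictSource.surrogate,
                          f"Grantham distance {d:.0f} vs threshold {threshold:.0f}")


def _first_difference(wt: str, mut: str) -> int:
    i = 0
    while i < min(len(wt), len(mut)) and wt[i] == mut[i]:
        i += 1
    return i


def nls_overlap_rule(model: GeneModel, pair: SequencePair) -> bool:
    """True when the variant changes or truncates any residue of a special
    protein region (1-based inclusive AA spans); truncation upstream of a
    region counts because the region is lost."""
    if not model.special_regions or pair.wt_protein == pair.mut_protein:
        return False
    wt, mut = pair.wt_protein, pair.mut_protein
    i0 = _first_difference(wt, mut)  # 0-based first altered residue
    point_change = len(wt) == len(mut) and wt[i0 + 1 :] == mut[i0 + 1 :]
    for _, aa_start, aa_end in model.special_regions:
        if point_change:
            if aa_start - 1 <= i0 <= aa_end - 1:
                return True
        elif i0 <= aa_end - 1:
            # divergence or truncation at/before the region's end alters it
            return True
    return False


def assess_protein(vclass: VariantClass, pair: SequencePair, model: GeneModel,
                   external: list[ExternalVerdictRow] | None = None,
                   surrogate_threshold: float = 100.0) -> ProteinVerdict:
    """Protein-channel verdict for one classified variant."""
    if vclass in (VariantClass.synonymous, VariantClass.splice_site):
        return ProteinVerdict(ProteinLabel.not_applicable, 1.0, VerdictSource.rule,
                              "no protein channel for this class")
    if vclass in (VariantClass.nonsense, VariantClass.frameshift):
        return ProteinVerdict(ProteinLabel.severe, 1.0, VerdictSource.rule,
                              f"{vclass.value} variants are severe by rule")
    if vclass is VariantClass.inframe_indel:
        return ProteinVerdict(ProteinLabel.mild, 1.0, VerdictSource.rule,
                              "in-frame indel capped at mild (reading frame preserved)")
    if vclass is VariantClass.stop_loss:
        if nls_overlap_rule(model, pair):
            return ProteinVerdict(ProteinLabel.severe, 1.0, VerdictSource.rule,
                                  "stop-loss extension disrupts a special region")
        return ProteinVerdict(ProteinLabel.mild, 1.0, VerdictSource.rule,
                              "stop-loss extension outside special regions")

    # missense
    verdict: ProteinVerdict | None = None
    if external:
        rows = [r for r in external if r.tool == "consensus_missense"]
        if rows:
            row = rows[0]
            label = ProteinLabel.severe if row.call in _DAMAGING else ProteinLabel.neutral
            verdict = ProteinVerdict(label, row.confidence, VerdictSource.adapter_consensus,
                                     f"external call {row.call!r}")
    if verdict is None:
        i0 = _first_difference(pair.wt_protein, pair.mut_protein)
        wt_aa = pair.wt_protein[i0] if i0 < len(pair.wt_protein) else "X"
        mut_aa = pair.mut_protein[i0] if i0 < len(pair.mut_protein) else "X"
        verdict = surrogate_missense_score(wt_aa, mut_aa, surrogate_threshold)
    if nls_overlap_rule(model, pair) and verdict.label is not ProteinLabel.severe:
        verdict = ProteinVerdict(ProteinLabel.severe, 1.0, VerdictSource.rule,
                                 "variant alters a special protein region")
    return verdict


def read_external_verdicts(path: str | Path) -> tuple[list[ExternalVerdictRow], list[dict]]:
    """Read an external-predictor verdict TSV (hgvs_c, tool, call, confidence).

    Unknown tool/call labels go to the rejects list; duplicate (hgvs_c, tool)
    pairs are an error."""
    rows: list[ExternalVerdictRow] = []
    rejects: list[dict] = []
    seen: set[tuple[str, str]] = set()
    dupes: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {"hgvs_c", "tool", "call", "confidence"} - set(reader.fieldnames or [])
        if missing:
            raise SpliceTriageError(f"{path}: missing column(s) {sorted(missing)}")
        for idx, raw in enumerate(reader, start=2):
            try:
                row = ExternalVerdictRow(raw["hgvs_c"].strip(), raw["tool"].strip(),
                                         raw["call"].strip(), float(raw["confidence"]))
            except (SpliceTriageError, ValueError) as exc:
                rejects.append({"line": idx, "error": str(exc), **raw})
                continue
            key = (row.hgvs_c, row.tool)
            if key in seen:
                dupes.append(key)
            seen.add(key)
            rows.append(row)
    if dupes:
        raise SpliceTriageError(f"duplicate (hgvs_c, tool) rows: {sorted(set(dupes))}")
    return rows, rejects


def protein_label_to_severity(label: ProteinLabel) -> Severity | None:
    """Map a protein label onto the common severity scale (None = no channel)."""
    if label is ProteinLabel.not_applicable:
        return None
    return Severity(label.value)
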