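"""Gene models, HGVS c. parsing, variant application and consequence classes.

Coordinate conventions
----------------------
Externally everything is HGVS cDNA: 1-based, inclusive, ``c.1`` is the A of
the start codon, intronic positions are exon-edge offsets (``c.438-1``,
``c.1347+1``).  Internally every sequence index is 0-based half-open on the
pre-mRNA (transcript sense strand).  The conversion lives only in
:func:`parse_hgvs_c` / :func:`serialize_hgvs` and
:meth:`GeneModel.cdna_to_premrna`, so no other module does coordinate
arithmetic.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

STOP_CODONS = {"TAA", "TAG", "TGA"}


class SpliceTriageError(Exception):
    """Base class for pipeline errors."""


class HgvsParseError(SpliceTriageError):
    pass


class HgvsValidationError(SpliceTriageError):
    pass


class ReferenceMismatchError(SpliceTriageError):
    pass


class FormatError(SpliceTriageError):
    pass


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Transcript-centric gene model on the sense strand.

    ``exons`` are half-open intervals on ``pre_mrna``; they must be sorted,
    non-overlapping, and concatenate to the mature mRNA.  ``cds_start`` /
    ``cds_end`` are 1-based inclusive positions *in the mature mRNA* of the
    first base of the start codon and the last base of the stop codon, so the
    HGVS coordinate ``c.N`` maps to mature position ``cds_start + N - 1``.
    ``special_regions`` holds protein spans with dedicated severity rules,
    e.g. a nuclear localization signal (for BAP1 the NLS is residues
    717-722; its disruption retains the protein in the cytoplasm).
    """

    gene_id: str
    pre_mrna: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    protein_length: int
    special_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pre_mrna = self.pre_mrna.upper()
        self.exons = [tuple(e) for e in self.exons]
        self.special_regions = [tuple(r) for r in self.special_regions]

    # -- derived sequences ---------------------------------------------------

    @property
    def mature_mrna(self) -> str:
        return "".join(self.pre_mrna[s:e] for s, e in self.exons)

    @property
    def cds(self) -> str:
        return self.mature_mrna[self.cds_start - 1 : self.cds_end]

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate()).rstrip("*")

    # -- boundaries ----------------------------------------------------------

    @property
    def donor_boundaries(self) -> list[int]:
        """Pre-mRNA index of the first intronic base after each internal exon."""
        return [e for (_, e) in self.exons[:-1]]

    @property
    def acceptor_boundaries(self) -> list[int]:
        """Pre-mRNA index of the first exonic base of each internal exon."""
        return [s for (s, _) in self.exons[1:]]

    def internal_boundaries(self) -> list[int]:
        return sorted(self.donor_boundaries + self.acceptor_boundaries)

    def is_exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    # -- coordinate mapping --------------------------------------------------

    def mature_to_premrna(self, m0: int) -> int:
        """0-based mature index -> 0-based pre-mRNA index."""
        off = 0
        for s, e in self.exons:
            if m0 < off + (e - s):
                return s + (m0 - off)
            off += e - s
        raise IndexError(f"mature position {m0} outside transcript")

    def cdna_to_premrna(self, pos: int, offset: int = 0) -> int:
        """HGVS c. position (+ intron offset) -> 0-based pre-mRNA index."""
        if pos < 1:
            raise HgvsValidationError(f"cDNA position must be >= 1, got {pos}")
        m0 = self.cds_start - 1 + pos - 1
        p = self.mature_to_premrna(m0)
        if offset == 0:
            return p
        q = p + offset
        if not 0 <= q < len(self.pre_mrna):
            raise HgvsValidationError(f"intronic offset {offset} at c.{pos} leaves the transcript")
        if self.is_exonic(q):
            raise HgvsValidationError(f"c.{pos}{offset:+d} does not land in an intron")
        return q

    # -- validation & I/O ----------------------------------------------------

    def validate(self) -> None:
        prev = 0
        for s, e in self.exons:
            if not (prev <= s < e <= len(self.pre_mrna)):
                raise FormatError(f"exon {(s, e)} out of order or out of bounds")
            prev = e
        cds = self.cds
        if len(cds) % 3 != 0:
            raise FormatError(f"CDS length {len(cds)} not a multiple of 3")
        prot = str(Seq(cds).translate())
        if not prot.endswith("*") or "*" in prot[:-1]:
            raise FormatError("CDS does not translate to a clean open reading frame")
        if len(prot) - 1 != self.protein_length:
            raise FormatError(
                f"protein_length {self.protein_length} != translated length {len(prot) - 1}"
            )

    @classmethod
    def from_files(cls, fasta_path: str | Path, model_path: str | Path) -> "GeneModel":
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
        raw = yaml.safe_load(Path(model_path).read_text())
        model = cls(
            gene_id=raw.get("gene_id", record.id),
            pre_mrna=str(record.seq),
            exons=[tuple(e) for e in raw["exons"]],
            cds_start=int(raw["cds_start"]),
            cds_end=int(raw["cds_end"]),
            protein_length=int(raw["protein_length"]),
            special_regions=[tuple(r) for r in raw.get("special_regions", [])],
        )
        model.validate()
        return model

    def to_files(self, fasta_path: str | Path, model_path: str | Path) -> None:
        Path(fasta_path).write_text(f">{self.gene_id}\n{self.pre_mrna}\n")
        Path(model_path).write_text(
            yaml.safe_dump(
                {
                    "gene_id": self.gene_id,
                    "exons": [list(e) for e in self.exons],
                    "cds_start": self.cds_start,
                    "cds_end": self.cds_end,
                    "protein_length": self.protein_length,
                    "special_regions": [list(r) for r in self.special_regions],
                },
                sort_keys=False,
            )
        )


# ---------------------------------------------------------------------------
# Variant descriptors
# ---------------------------------------------------------------------------

class VariantKind(str, Enum):
    substitution = "substitution"
    deletion = "deletion"
    insertion = "insertion"
    delins = "delins"
    duplication = "duplication"


class VariantClass(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    synonymous = "synonymous"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    splice_site = "splice_site"
    stop_loss = "stop_loss"


@dataclass(frozen=True)
class VariantDescriptor:
    """A parsed HGVS c. variant.

    ``intron_offset_*`` are 0 for exonic coordinates; ``ref_allele`` may be
    empty for insertions and for deletions/duplications given only by length
    (``stated_length`` then records that length until it is resolved against
    a gene model).
    """

    raw_hgvs: str = field(compare=False)
    kind: VariantKind
    cdna_start: int
    cdna_end: int
    intron_offset_start: int = 0
    intron_offset_end: int = 0
    ref_allele: str = ""
    alt_allele: str = ""
    stated_length: int | None = field(default=None, compare=False)

    @property
    def is_intronic(self) -> bool:
        return self.intron_offset_start != 0 or self.intron_offset_end != 0

    def net_length_change(self) -> int | None:
        """len(alt) - len(ref) where determinable without a gene model."""
        if self.kind is VariantKind.substitution:
            return 0
        if self.kind is VariantKind.insertion:
            return len(self.alt_allele)
        ref_len = len(self.ref_allele) or self.stated_length
        if ref_len is None and not self.is_intronic:
            ref_len = self.cdna_end - self.cdna_start + 1
        if self.kind is VariantKind.deletion:
            return None if ref_len is None else -ref_len
        if self.kind is VariantKind.duplication:
            return None if ref_len is None else ref_len
        if self.kind is VariantKind.delins:
            return None if ref_len is None else len(self.alt_allele) - ref_len
        return None


_POS = r"(\d+)([+-]\d+)?"
_HGVS_RE = re.compile(
    rf"^c\.{_POS}(?:_{_POS})?"
    r"(?:"
    r"(?P<ref>[ACGT])>(?P<alt>[ACGT])"      # substitution
    r"|delins(?P<delins>[ACGT]+)"            # delins (before del so it wins)
    r"|del(?P<del>[ACGT]+|\d+)?"             # deletion
    r"|ins(?P<ins>[ACGT]+)"                  # insertion
    r"|dup(?P<dup>[ACGT]+|\d+)?"             # duplication
    r")$"
)


def _length_arg(arg: str | None) -> tuple[str, int | None]:
    """A trailing del/dup argument is either the deleted sequence or a length."""
    if not arg:
        return "", None
    if arg.isdigit():
        return "", int(arg)
    return arg, len(arg)


def parse_hgvs_c(hgvs: str) -> VariantDescriptor:
    """Parse an HGVS cDNA string (substitution, del, ins, delins, dup)."""
    text = hgvs.strip().replace("–", "-").replace("−", "-").replace(" ", "")
    if not text.startswith("c."):
        raise HgvsParseError(f"{hgvs!r}: expected a 'c.' prefix")
    m = _HGVS_RE.match(text)
    if m is None:
        raise HgvsParseError(f"{hgvs!r}: unrecognized HGVS cDNA syntax")
    p1, o1, p2, o2 = m.group(1), m.group(2), m.group(3), m.group(4)
    start, off1 = int(p1), int(o1) if o1 else 0
    if p2 is not None:
        end, off2 = int(p2), int(o2) if o2 else 0
    else:
        end, off2 = start, off1
    if (start, off1) > (end, off2):
        raise HgvsValidationError(f"{hgvs!r}: start position after end position")
    span = end - start + 1 if off1 == 0 and off2 == 0 else None

    if m.group("ref") is not None:
        if p2 is not None:
            raise HgvsParseError(f"{hgvs!r}: a substitution takes a single position")
        if m.group("ref") == m.group("alt"):
            raise HgvsValidationError(f"{hgvs!r}: reference equals alternate ({m.group('ref')})")
        return VariantDescriptor(text, VariantKind.substitution, start, end, off1, off2,
                                 m.group("ref"), m.group("alt"))
    if m.group("delins") is not None:
        return VariantDescriptor(text, VariantKind.delins, start, end, off1, off2,
                                 "", m.group("delins"))
    if m.group("ins") is not None:
        if p2 is None:
            raise HgvsParseError(f"{hgvs!r}: insertion needs two flanking positions")
        return VariantDescriptor(text, VariantKind.insertion, start, end, off1, off2,
                                 "", m.group("ins"))
    if "dup" in text[text.index(".") :]:
        ref, stated = _length_arg(m.group("dup"))
        kind = VariantKind.duplication
    else:
        ref, stated = _length_arg(m.group("del"))
        kind = VariantKind.deletion
    if stated is not None and span is not None and stated != span:
        raise HgvsValidationError(
            f"{hgvs!r}: stated {kind.value} length {stated} != span {span}")
    return VariantDescriptor(text, kind, start, end, off1, off2, ref, "",
                             stated_length=stated)


def _fmt_pos(pos: int, off: int) -> str:
    return f"{pos}{off:+d}" if off else str(pos)


def serialize_hgvs(v: VariantDescriptor) -> str:
    """Normalized HGVS string; ``parse_hgvs_c(serialize_hgvs(v)) == v``."""
    a = _fmt_pos(v.cdna_start, v.intron_offset_start)
    b = _fmt_pos(v.cdna_end, v.intron_offset_end)
    single = (v.cdna_start, v.intron_offset_start) == (v.cdna_end, v.intron_offset_end)
    span = a if single else f"{a}_{b}"
    if v.kind is VariantKind.substitution:
        return f"c.{span}{v.ref_allele}>{v.alt_allele}"
    if v.kind is VariantKind.insertion:
        return f"c.{span}ins{v.alt_allele}"
    if v.kind is VariantKind.delins:
        return f"c.{span}delins{v.alt_allele}"
    suffix = v.ref_allele or (str(v.stated_length) if v.stated_length else "")
    if v.kind is VariantKind.deletion:
        return f"c.{span}del{suffix}"
    return f"c.{span}dup{suffix}"


# ---------------------------------------------------------------------------
# Variant application
# ---------------------------------------------------------------------------

@dataclass
class SequencePair:
    """WT and mutant sequences at every level, plus the pre-mRNA edit extent.

    ``edit_start``/``edit_end`` delimit (half-open, WT pre-mRNA coordinates)
    the bases removed by the edit; ``inserted`` is what replaced them, so the
    mutant pre-mRNA length is ``len(wt) - (edit_end - edit_start) +
    len(inserted)``.
    """

    wt_premrna: str
    mut_premrna: str
    wt_cds: str
    mut_cds: str
    wt_protein: str
    mut_protein: str
    edit_start: int
    edit_end: int
    inserted: str
    wt_mature: str
    mut_mature: str
    mut_exons: list[tuple[int, int]]

    @property
    def delta(self) -> int:
        return len(self.inserted) - (self.edit_end - self.edit_start)


def project_through_edit(x: int, edit_start: int, edit_end: int, delta: int) -> int | None:
    """Map a WT pre-mRNA coordinate into the mutant; None if it was deleted."""
    if x <= edit_start:
        return x
    if x >= edit_end:
        return x + delta
    return None


def _project_boundary(x: int, edit_start: int, edit_end: int, delta: int) -> int:
    if x <= edit_start:
        return x
    if x >= edit_end:
        return x + delta
    return edit_start


def apply_variant(model: GeneModel, v: VariantDescriptor) -> SequencePair:
    """Apply a parsed variant to the pre-mRNA and re-splice with the WT exon
    structure (exon boundaries are projected through the edit; splicing-level
    consequences are assessed separately by the splice-scoring channel)."""
    wt = model.pre_mrna
    p1 = model.cdna_to_premrna(v.cdna_start, v.intron_offset_start)
    p2 = model.cdna_to_premrna(v.cdna_end, v.intron_offset_end)
    if p2 < p1:
        raise HgvsValidationError(f"{v.raw_hgvs}: end precedes start on the transcript")

    if v.kind is VariantKind.substitution:
        estart, eend, inserted = p1, p2 + 1, v.alt_allele
        found = wt[p1 : p2 + 1]
        if v.ref_allele and found != v.ref_allele:
            raise ReferenceMismatchError(
                f"{v.raw_hgvs}: expected {v.ref_allele} at c.{v.cdna_start}, found {found}")
    elif v.kind is VariantKind.deletion:
        estart, eend, inserted = p1, p2 + 1, ""
        found = wt[p1 : p2 + 1]
        if v.ref_allele and found != v.ref_allele:
            raise ReferenceMismatchError(
                f"{v.raw_hgvs}: expected deletion of {v.ref_allele}, found {found}")
        if v.stated_length is not None and len(found) != v.stated_length:
            raise HgvsValidationError(
                f"{v.raw_hgvs}: stated length {v.stated_length} != spanned {len(found)}")
    elif v.kind is VariantKind.delins:
        estart, eend, inserted = p1, p2 + 1, v.alt_allele
    elif v.kind is VariantKind.insertion:
        # insert between the two flanking positions, i.e. after p1
        estart = eend = p1 + 1
        inserted = v.alt_allele
    elif v.kind is VariantKind.duplication:
        found = wt[p1 : p2 + 1]
        if v.ref_allele and found != v.ref_allele:
            raise ReferenceMismatchError(
                f"{v.raw_hgvs}: expected duplication of {v.ref_allele}, found {found}")
        estart = eend = p2 + 1
        inserted = found
    else:  # pragma: no cover
        raise HgvsValidationError(f"unsupported variant kind {v.kind}")

    mut = wt[:estart] + inserted + wt[eend:]
    delta = len(inserted) - (eend - estart)
    mut_exons = []
    for s, e in model.exons:
        s2 = _project_boundary(s, estart, eend, delta)
        e2 = _project_boundary(e, estart, eend, delta)
        if e2 > s2:
            mut_exons.append((s2, e2))
    mut_mature = "".join(mut[s:e] for s, e in mut_exons)

    wt_mature = model.mature_mrna
    wt_cds = model.cds

    # CDS start in the mutant: project the pre-mRNA position of c.1
    cds_start_pre = model.mature_to_premrna(model.cds_start - 1)
    cds_start_mut_pre = project_through_edit(cds_start_pre, estart, eend, delta)
    mut_cds, mut_protein = "", ""
    if cds_start_mut_pre is not None:
        m0 = 0
        for s, e in mut_exons:
            if s <= cds_start_mut_pre < e:
                m0 += cds_start_mut_pre - s
                break
            m0 += e - s
        tail = mut_mature[m0:]
        tail = tail[: len(tail) // 3 * 3]
        prot = str(Seq(tail).translate())
        stop = prot.find("*")
        if stop == -1:
            mut_cds, mut_protein = tail, prot
        else:
            mut_cds, mut_protein = tail[: 3 * (stop + 1)], prot[:stop]

    return SequencePair(
        wt_premrna=wt,
        mut_premrna=mut,
        wt_cds=wt_cds,
        mut_cds=mut_cds,
        wt_protein=str(Seq(wt_cds).translate()).rstrip("*"),
        mut_protein=mut_protein,
        edit_start=estart,
        edit_end=eend,
        inserted=inserted,
        wt_mature=wt_mature,
        mut_mature=mut_mature,
        mut_exons=mut_exons,
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_variant(model: GeneModel, v: VariantDescriptor, pair: SequencePair) -> VariantClass:
    """Assign exactly one consequence class.

    Any variant with a nonzero intron offset, or whose edited span crosses an
    exon/intron boundary, is a splice-site variant.  Exonic variants are
    classified by protein comparison; length-changing coding edits are
    frameshift iff the net length change is not a multiple of 3.
    """
    if v.is_intronic:
        return VariantClass.splice_site
    for b in model.internal_boundaries():
        if pair.edit_start < b < pair.edit_end:
            return VariantClass.splice_site

    wt_p, mut_p = pair.wt_protein, pair.mut_protein
    if wt_p == mut_p:
        return VariantClass.synonymous
    if v.kind is not VariantKind.substitution:
        delta = pair.delta
        return VariantClass.frameshift if delta % 3 != 0 else VariantClass.inframe_indel
    if len(mut_p) < len(wt_p) and wt_p.startswith(mut_p):
        return VariantClass.nonsense
    if len(mut_p) > len(wt_p) and mut_p.startswith(wt_p):
        return VariantClass.stop_loss
    return VariantClass.missense


def is_start_loss(v: VariantDescriptor) -> bool:
    """True when the edit touches the start codon (c.1-3); such variants are
    reported in the missense class with a warning."""
    return not v.is_intronic and v.cdna_start <= 3 and v.cdna_end >= 1


def protein_hgvs(pair: SequencePair) -> str:
    """p.-style annotation from the WT/mutant protein comparison."""
    wt, mut = pair.wt_protein, pair.mut_protein
    if wt == mut:
        return "p.="
    i = 0
    while i < min(len(wt), len(mut)) and wt[i] == mut[i]:
        i += 1
    if i >= len(wt):  # stop-loss: WT is a proper prefix
        return f"*{len(wt) + 1}{seq3(mut[i])}"
    if i >= len(mut):  # mutant is a proper prefix: truncation at residue i+1
        if pair.delta % 3 != 0:
            return f"{seq3(wt[i])}{i + 1}fs*1"  # frameshift with immediate stop
        return f"{seq3(wt[i])}{i + 1}*"
    if len(wt) == len(mut) and wt[i + 1 :] == mut[i + 1 :]:
        return f"{seq3(wt[i])}{i + 1}{seq3(mut[i])}"
    if pair.delta % 3 != 0:
        # frameshift: everything from residue i+1 diverges; the new stop sits
        # at new-frame position k counting the first altered residue as 1
        k = len(mut) - i + 1
        tail = f"fs*{k}" if pair.mut_cds.endswith(tuple(STOP_CODONS)) else "fs*?"
        return f"{seq3(wt[i])}{i + 1}{tail}"
    d = len(wt) - len(mut)
    if d > 0 and wt[i + d :] == mut[i:]:  # in-frame deletion of wt[i:i+d]
        if d == 1:
            return f"{seq3(wt[i])}{i + 1}del"
        return f"{seq3(wt[i])}{i + 1}_{seq3(wt[i + d - 1])}{i + d}del"
    if d < 0 and mut[i - d :] == wt[i:]:
        return f"{seq3(wt[i - 1])}{i}_{seq3(wt[i])}{i + 1}ins{''.join(seq3(a) for a in mut[i : i - d])}"
    # in-frame replacement: swap the segment between common prefix and suffix
    j = 0
    while (j < min(len(wt), len(mut)) - i
           and wt[len(wt) - 1 - j] == mut[len(mut) - 1 - j]):
        j += 1
    ins = "".join(seq3(a) for a in mut[i : len(mut) - j])
    return f"{seq3(wt[i])}{i + 1}_{seq3(wt[len(wt) - j - 1])}{len(wt) - j}delins{ins}"


# ---------------------------------------------------------------------------
# Mutation tables
# ---------------------------------------------------------------------------

def read_mutation_table(path: str | Path) -> tuple[list[tuple[str, VariantDescriptor]], list[dict]]:
    """Read a COSMIC-like TSV (columns: gene, hgvs_c[, hgvs_p, source]).

    Rows that fail to parse are collected into a rejects list (never silently
    dropped); a missing mandatory column raises :class:`FormatError`.
    """
    records: list[tuple[str, VariantDescriptor]] = []
    rejects: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, no header")
        missing = {"gene", "hgvs_c"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {sorted(missing)}")
        for idx, row in enumerate(reader, start=2):
            gene = (row.get("gene") or "").strip()
            hgvs = (row.get("hgvs_c") or "").strip()
            try:
                if not hgvs:
                    raise HgvsParseError("empty hgvs_c (protein-only records are rejected)")
                records.append((gene, parse_hgvs_c(hgvs)))
            except SpliceTriageError as exc:
                rejects.append({"line": idx, "gene": gene, "hgvs_c": hgvs, "error": str(exc)})
    return records, rejects


def write_rejects(rejects: list[dict], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["line", "gene", "hgvs_c", "error"],
                                delimiter="\t")
        writer.writeheader()
        writer.writerows(rejects)
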