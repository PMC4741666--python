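"""HGVS parsing, variant application, classification, protein annotation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicetriage.genome_variant import (
    FormatError,
    HgvsParseError,
    HgvsValidationError,
    ReferenceMismatchError,
    VariantClass,
    VariantDescriptor,
    VariantKind,
    apply_variant,
    classify_variant,
    parse_hgvs_c,
    protein_hgvs,
    read_mutation_table,
    serialize_hgvs,
)

# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("hgvs,kind,start,end,off1,off2,ref,alt", [
    ("c.438-1G>A", VariantKind.substitution, 438, 438, -1, -1, "G", "A"),
    ("c.1347+1G>T", VariantKind.substitution, 1347, 1347, 1, 1, "G", "T"),
    ("c.2054A>T", VariantKind.substitution, 2054, 2054, 0, 0, "A", "T"),
    ("c.2703delT", VariantKind.deletion, 2703, 2703, 0, 0, "T", ""),
    ("c.21_32del12", VariantKind.deletion, 21, 32, 0, 0, "", ""),
    ("c.3773_3779+9del16", VariantKind.deletion, 3773, 3779, 0, 9, "", ""),
    ("c.76_77insAGC", VariantKind.insertion, 76, 77, 0, 0, "", "AGC"),
    ("c.10_12dup", VariantKind.duplication, 10, 12, 0, 0, "", ""),
    ("c.5_7delinsTT", VariantKind.delins, 5, 7, 0, 0, "", "TT"),
])
def test_parse_hgvs_fields(hgvs, kind, start, end, off1, off2, ref, alt):
    v = parse_hgvs_c(hgvs)
    assert v.kind is kind
    assert (v.cdna_start, v.cdna_end) == (start, end)
    assert (v.intron_offset_start, v.intron_offset_end) == (off1, off2)
    assert (v.ref_allele, v.alt_allele) == (ref, alt)


def test_parse_stated_deletion_length():
    v = parse_hgvs_c("c.21_32del12")
    assert v.stated_length == 12
    with pytest.raises(HgvsValidationError):
        parse_hgvs_c("c.21_32del11")  # span is 12


def test_parse_unicode_minus_and_spaces():
    # database exports often carry en-dashes and spacing
    v = parse_hgvs_c("c.438–1G > A")
    assert (v.cdna_start, v.intron_offset_start) == (438, -1)


@pytest.mark.parametrize("bad,exc", [
    ("c.5A>A", HgvsValidationError),           # identity substitution
    ("c.abcG>A", HgvsParseError),
    ("g.100A>T", HgvsParseError),
    ("p.Glu685Val", HgvsParseError),           # protein-only is rejected
    ("c.100_99del", HgvsValidationError),      # reversed span
    ("c.10insA", HgvsParseError),              # insertion needs two positions
])
def test_parse_errors(bad, exc):
    with pytest.raises(exc):
        parse_hgvs_c(bad)


_pos = st.integers(min_value=1, max_value=5000)
_offset = st.one_of(st.just(0), st.integers(min_value=-50, max_value=50).filter(lambda x: x != 0))
_seq = st.text(alphabet="ACGT", min_size=1, max_size=8)


@st.composite
def descriptors(draw):
    kind = draw(st.sampled_from(list(VariantKind)))
    start = draw(_pos)
    off = draw(_offset)
    if kind is VariantKind.substitution:
        ref = draw(st.sampled_from("ACGT"))
        alt = draw(st.sampled_from([b for b in "ACGT" if b != ref]))
        return VariantDescriptor("", kind, start, start, off, off, ref, alt)
    if kind is VariantKind.insertion:
        return VariantDescriptor("", kind, start, start + 1, 0, 0, "",
                                 draw(_seq))
    if kind is VariantKind.delins:
        span = draw(st.integers(1, 6))
        return VariantDescriptor("", kind, start, start + span - 1, 0, 0, "",
                                 draw(_seq))
    ref = draw(_seq)
    return VariantDescriptor("", kind, start, start + len(ref) - 1, 0, 0, ref, "",
                             stated_length=len(ref))


@given(descriptors())
@settings(max_examples=300, deadline=None)
def test_parse_serialize_round_trip(desc):
    assert parse_hgvs_c(serialize_hgvs(desc)) == desc


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def test_start_codon_substitution_forces_valine(toy_model):
    pair = apply_variant(toy_model, parse_hgvs_c("c.1A>G"))
    assert pair.mut_cds.startswith("GTG")
    assert pair.mut_protein.startswith("V")


def test_stop_loss_extends_translation(toy_model):
    # stop codon TGA at c.88-90; c.88T>G turns it into GGA (Gly)
    pair = apply_variant(toy_model, parse_hgvs_c("c.88T>G"))
    assert len(pair.mut_protein) > len(pair.wt_protein)
    assert pair.mut_protein[:29] == pair.wt_protein
    assert pair.mut_protein[29] == "G"


def test_inframe_deletion_shortens_by_four(toy_model):
    pair = apply_variant(toy_model, parse_hgvs_c("c.4_15del12"))
    assert len(pair.wt_protein) - len(pair.mut_protein) == 4


def test_reference_mismatch_is_hard_error(toy_model):
    with pytest.raises(ReferenceMismatchError) as err:
        apply_variant(toy_model, parse_hgvs_c("c.1C>G"))  # c.1 is A
    assert "expected C" in str(err.value) and "found A" in str(err.value)


def test_apply_length_accounting(toy_model, rng):
    """len(mut) - len(wt) always equals insertion length - deletion length."""
    for _ in range(200):
        style = rng.integers(3)
        # deletions stay inside exon 1 (c.1-45): a pure-exonic span crossing
        # the junction is not a contiguous pre-mRNA deletion
        c = int(rng.integers(4, 38)) if style == 0 else int(rng.integers(4, 80))
        if style == 0:
            k = int(rng.integers(1, 7))
            v = VariantDescriptor("", VariantKind.deletion, c, c + k - 1, 0, 0, "", "",
                                  stated_length=k)
            expected = -k
        elif style == 1:
            ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 7))))
            v = VariantDescriptor("", VariantKind.insertion, c, c + 1, 0, 0, "", ins)
            expected = len(ins)
        else:
            ref = toy_model.cds[c - 1]
            alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
            v = VariantDescriptor("", VariantKind.substitution, c, c, 0, 0, ref, alt)
            expected = 0
        pair = apply_variant(toy_model, v)
        assert len(pair.mut_premrna) - len(pair.wt_premrna) == expected


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _classify(model, hgvs):
    v = parse_hgvs_c(hgvs)
    return classify_variant(model, v, apply_variant(model, v))


@pytest.mark.parametrize("hgvs,expected", [
    ("c.58G>T", VariantClass.nonsense),        # codon 20 GAG -> TAG
    ("c.44A>T", VariantClass.missense),        # codon 15 GAA -> GTA (Glu15Val)
    ("c.30C>T", VariantClass.synonymous),      # codon 10 AGC -> AGT (Ser)
    ("c.4_15del12", VariantClass.inframe_indel),
    ("c.4delG", VariantClass.frameshift),
    ("c.45+1G>A", VariantClass.splice_site),   # canonical donor position
    ("c.46-2A>T", VariantClass.splice_site),
    ("c.44_45+4del", VariantClass.splice_site),  # deletion spans the boundary
    ("c.88T>G", VariantClass.stop_loss),
])
def test_classify_examples(toy_model, hgvs, expected):
    assert _classify(toy_model, hgvs) is expected


def test_frame_rule_exhaustive_small_indels(toy_model):
    """Exonic coding indels: frameshift iff net length change mod 3 != 0."""
    for k in range(1, 7):
        d = VariantDescriptor("", VariantKind.deletion, 10, 10 + k - 1, 0, 0, "", "",
                              stated_length=k)
        ins = VariantDescriptor("", VariantKind.insertion, 10, 11, 0, 0, "", "A" * k)
        for v, net in ((d, -k), (ins, k)):
            cls = classify_variant(toy_model, v, apply_variant(toy_model, v))
            if net % 3 != 0:
                assert cls is VariantClass.frameshift, (k, v.kind)
            else:
                assert cls is VariantClass.inframe_indel, (k, v.kind)


# ---------------------------------------------------------------------------
# protein annotation
# ---------------------------------------------------------------------------

def test_protein_hgvs_formats(toy_model):
    cases = {
        "c.44A>T": "Glu15Val",
        "c.58G>T": "Glu20*",
        "c.30C>T": "p.=",
        "c.88T>G": "*30Gly",
    }
    for hgvs, expected in cases.items():
        pair = apply_variant(toy_model, parse_hgvs_c(hgvs))
        assert protein_hgvs(pair) == expected


def _oracle_frameshift_annotation(model, c_del):
    """Independent re-translation: delete one base from the mature cDNA and
    translate codon-by-codon with a plain table."""
    from Bio.Seq import Seq

    mature = model.mature_mrna
    cds_off = model.cds_start - 1
    mut = mature[: cds_off + c_del - 1] + mature[cds_off + c_del :]
    tail = mut[cds_off:]
    prot = ""
    for i in range(0, len(tail) - 2, 3):
        aa = str(Seq(tail[i : i + 3]).translate())
        if aa == "*":
            prot += "*"
            break
        prot += aa
    wt = model.protein
    i0 = 0
    while i0 < min(len(wt), len(prot)) and wt[i0] == prot[i0]:
        i0 += 1
    stopped = prot.endswith("*")
    body = prot.rstrip("*")
    k = len(body) - i0 + 1
    from Bio.SeqUtils import seq3
    return f"{seq3(wt[i0])}{i0 + 1}fs*{k if stopped else '?'}"


def test_frameshift_annotation_matches_retranslation_oracle(syn_model, rng):
    cds_len = 3 * (syn_model.protein_length + 1)
    n_checked = 0
    for _ in range(1000):
        c = int(rng.integers(4, cds_len - 6))
        v = VariantDescriptor("", VariantKind.deletion, c, c, 0, 0, "", "",
                              stated_length=1)
        pair = apply_variant(syn_model, v)
        cls = classify_variant(syn_model, v, pair)
        if cls is not VariantClass.frameshift:
            continue  # the deletion may be silent at the protein level
        assert protein_hgvs(pair) == _oracle_frameshift_annotation(syn_model, c)
        n_checked += 1
    assert n_checked > 900


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

def test_read_mutation_table_counts(tmp_path):
    p = tmp_path / "muts.tsv"
    p.write_text("gene\thgvs_c\nG1\tc.100A>T\nG1\tc.broken\nG1\tc.5delA\n")
    records, rejects = read_mutation_table(p)
    assert len(records) == 2 and len(rejects) == 1
    assert rejects[0]["hgvs_c"] == "c.broken"


def test_read_mutation_table_empty_and_missing_column(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("gene\thgvs_c\n")
    records, rejects = read_mutation_table(p)
    assert records == [] and rejects == []
    q = tmp_path / "nocol.tsv"
    q.write_text("gene\tprotein\nG1\tp.Glu2Lys\n")
    with pytest.raises(FormatError):
        read_mutation_table(q)


def test_row_count_conservation(tmp_path):
    rows = "".join(f"G1\tc.{i}A>T\n" for i in range(10, 393))
    p = tmp_path / "big.tsv"
    p.write_text("gene\thgvs_c\n" + rows)
    records, rejects = read_mutation_table(p)
    assert len(records) + len(rejects) == 383
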