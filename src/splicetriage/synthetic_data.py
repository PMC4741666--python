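"""Synthetic gene models and mutation sets with certified ground truth.

The generator emulates the shape of a curated somatic-mutation extract for a
tumour-suppressor transcript: a multi-exon gene whose natural splice sites
are strong under the packaged matrices, a mutation table whose class
composition follows the published BAP1-like mix (missense 45%, frameshift
26%, nonsense 11%, splice-site 10%, synonymous 5%, in-frame indel 3%), and
per-variant ground-truth severity labels.  A configurable fraction of
variants is *planted*: the edit is engineered (against pre-primed sequence
contexts, by rejection sampling against the package's own scorers) to
produce a specific splicing-level event — an hnRNP A1 exonic silencer gain,
another-silencer gain, a cryptic donor/acceptor creation, or a natural-site
degradation.  Every variant's intended class and planted grade are recorded
first and generation fails loudly if the realized outcome disagrees, so the
truth table is certified, not assumed.

Ground truth is written to a separate TSV that the pipeline never reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .config import PipelineConfig, Thresholds
from .consensus import Channel, ChannelVerdict, combine_channel, combine_overall
from .genome_variant import (
    GeneModel,
    SequencePair,
    VariantClass,
    VariantDescriptor,
    VariantKind,
    apply_variant,
    classify_variant,
    serialize_hgvs,
)
from .protein_effect import (
    ExternalVerdictRow,
    ProteinLabel,
    assess_protein,
    protein_label_to_severity,
)
from .splice_scoring import (
    Severity,
    SiteKind,
    SpliceEventKind,
    default_pwms,
    diff_splice_sites,
)
from .sre_scan import diff_motifs, load_motif_table

_CODONS = ["".join(c) for c in __import__("itertools").product("ACGT", repeat=3)]
_CODON_AA = {c: str(Seq(c).translate()) for c in _CODONS}
_SENSE_CODONS = [c for c in _CODONS if _CODON_AA[c] != "*"]

BAP1_LIKE_MIX = {
    VariantClass.missense: 0.45,
    VariantClass.frameshift: 0.26,
    VariantClass.nonsense: 0.11,
    VariantClass.splice_site: 0.10,
    VariantClass.synonymous: 0.05,
    VariantClass.inframe_indel: 0.03,
}

# primed exonic contexts: (name, WT 8- or 23-mer, edit offset, alt base,
# required CDS frame offset of the context start)
_PRIME_A1 = ("sre_gain_a1", "TAGGGCTG", 5, "A", 1)       # -> TAGGGA, Leu->Met missense
_PRIME_OTHER = ("sre_gain_other", "TGGGGCCA", 5, "G", 1)  # -> TGGGGG, Pro->Ala missense
_PRIME_DONOR = ("cryptic_donor", "CAGGAAAGT", 4, "T", 0)  # -> CAGGTAAGT, Glu->Val missense
_PRIME_ACCEPTOR = ("cryptic_acceptor", "TTTTTTTTTTTTTTTTCCATGCT", 19, "G", 0)
#   -> ...CCAG|GCT, Met->Arg missense
_PRIMES = {p[0]: p for p in (_PRIME_A1, _PRIME_OTHER, _PRIME_DONOR, _PRIME_ACCEPTOR)}


@dataclass
class SimulationConfig:
    seed: int = 0
    gene_id: str = "SYNGENE1"
    # defaults approximate a BAP1-scale transcript (~730 codons, many exons)
    n_exons: int = 12
    exon_length_range: tuple[int, int] = (150, 260)
    intron_length_range: tuple[int, int] = (250, 450)
    utr5_length: int = 30
    utr3_length: int = 30
    n_variants: int = 200
    class_mix: dict[VariantClass, float] = field(
        default_factory=lambda: dict(BAP1_LIKE_MIX))
    # probability that a missense-budget variant is built as each planted
    # splicing event (the remainder are plain missense edits)
    planted_event_rates: dict[str, float] = field(default_factory=lambda: {
        "sre_gain_a1": 0.05,
        "sre_gain_other": 0.05,
        "cryptic_donor": 0.05,
        "cryptic_acceptor": 0.05,
        "natural_weakening_mild": 0.05,
    })
    missense_dangerous_rate: float = 0.61   # fraction of missense planted damaging
    concordance: float = 1.0                # external-verdict agreement with truth
    with_nls: bool = True                   # plant an NLS-like special region
    min_site_score: float = 0.85            # natural-site strength target
    unambiguous_margin: float = 0.05

    def __post_init__(self) -> None:
        self.class_mix = {VariantClass(k): float(v) for k, v in self.class_mix.items()}
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix sums to {total}, expected 1")
        if self.intron_length_range[0] < 60:
            raise ValueError("introns must be at least 60 nt for the scan windows")


@dataclass
class GroundTruthRow:
    gene: str
    hgvs_c: str
    variant_class: VariantClass
    planted: str                      # planted event name or "none"
    splicing_truth: Severity
    protein_truth: str                # ProteinLabel value
    consensus_truth: Severity
    margin: float
    unambiguous: bool


# ---------------------------------------------------------------------------
# Gene generation
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=[0.27, 0.23, 0.23, 0.27]))


def _sample_from_pwm(rng: np.random.Generator, freqs: np.ndarray,
                     positions: slice) -> str:
    out = []
    for row in freqs[positions]:
        out.append("ACGT"[rng.choice(4, p=row / row.sum())])
    return "".join(out)


def generate_gene(config: SimulationConfig,
                  rng: np.random.Generator | None = None) -> GeneModel:
    """A multi-exon gene whose natural splice sites score >= the configured
    strength and whose CDS is a clean open reading frame, with primed exonic
    contexts reserved for planted variants."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pwms = default_pwms()
    donor_pwm, acceptor_pwm = pwms[SiteKind.donor], pwms[SiteKind.acceptor]

    for _attempt in range(50):
        exon_lens = [int(rng.integers(*config.exon_length_range))
                     for _ in range(config.n_exons)]
        mature_len = sum(exon_lens)
        cds_len = mature_len - config.utr5_length - config.utr3_length
        cds_len -= cds_len % 3
        if cds_len < 120:
            continue
        n_codons = cds_len // 3
        codons = ["ATG"] + [str(rng.choice(_SENSE_CODONS))
                            for _ in range(n_codons - 2)]
        codons.append(str(rng.choice(["TAA", "TAG", "TGA"])))
        # avoid internal ATG being the only start issue: fine; avoid internal stops: by construction
        utr3_len = mature_len - config.utr5_length - cds_len
        mature = (_random_bases(rng, config.utr5_length) + "".join(codons)
                  + _random_bases(rng, utr3_len))

        # junction placement first: the exon-side flank is dictated by the
        # CDS, so nudge each junction to a position where a consensus-ended
        # intron reaches the target strength
        boundaries_m = np.cumsum(exon_lens)[:-1]  # nominal junction offsets
        adjusted: list[int] = []
        feasible = True
        for k, b0 in enumerate(boundaries_m):
            found = None
            for db in sorted(range(-40, 41), key=abs):
                b = int(b0) + db
                lo_limit = (adjusted[-1] + 60) if adjusted else 60
                if b < lo_limit or b > mature_len - 60 * (len(boundaries_m) - k):
                    continue
                d = donor_pwm.score(mature[b - 3 : b] + "GTAAGT")
                a = acceptor_pwm.score("TTTTTTTTTTTTTTTTCCAG" + mature[b : b + 3])
                if (d >= config.min_site_score + 0.02
                        and a >= config.min_site_score + 0.02):
                    found = b
                    break
            if found is None:
                feasible = False
                break
            adjusted.append(found)
        if not feasible:
            continue

        # plant primed contexts into coding exonic sequence, clear of the
        # junction windows; each planted type is capped by the slots that fit
        mature_list = list(mature)
        prime_positions: dict[str, list[int]] = {name: [] for name in _PRIMES}
        needed = _planted_budget(config)
        reserved: list[tuple[int, int]] = []
        for name, count in needed.items():
            if name == "natural_weakening_mild":
                continue
            _, ctx, _off, _alt, frame = _PRIMES[name]
            for _ in range(count):
                pos = _find_prime_slot(rng, mature, len(ctx), frame,
                                       config.utr5_length, cds_len,
                                       adjusted, reserved)
                if pos is None:
                    break
                mature_list[pos : pos + len(ctx)] = ctx
                reserved.append((pos, pos + len(ctx)))
                prime_positions[name].append(pos)
        mature = "".join(mature_list)
        cds = mature[config.utr5_length : config.utr5_length + cds_len]
        prot = str(Seq(cds).translate())
        if "*" in prot[:-1] or not prot.endswith("*"):
            continue

        introns = []
        for k, b in enumerate(adjusted):
            L = int(rng.integers(*config.intron_length_range))
            exon_left = mature[b - 3 : b]
            exon_right = mature[b : b + 3]
            donor6 = _strong_donor6(rng, donor_pwm, exon_left,
                                    config.min_site_score) or "GTAAGT"
            acceptor20 = _strong_acceptor20(rng, acceptor_pwm, exon_right,
                                            config.min_site_score) \
                or "TTTTTTTTTTTTTTTTCCAG"
            mid = _random_bases(rng, L - 26)
            introns.append(donor6 + mid + acceptor20)

        exon_lens = [b - a for a, b in zip([0] + adjusted, adjusted + [mature_len])]
        pre, exons, cursor = [], [], 0
        m_prev = 0
        for k, el in enumerate(exon_lens):
            exon_seq = mature[m_prev : m_prev + el]
            exons.append((cursor, cursor + el))
            pre.append(exon_seq)
            cursor += el
            m_prev += el
            if k < len(exon_lens) - 1:
                pre.append(introns[k])
                cursor += len(introns[k])
        pre_mrna = "".join(pre)

        protein_length = cds_len // 3 - 1
        special = []
        if config.with_nls and protein_length > 20:
            special = [("NLS", protein_length - 12, protein_length - 7)]
        model = GeneModel(
            gene_id=config.gene_id, pre_mrna=pre_mrna, exons=exons,
            cds_start=config.utr5_length + 1,
            cds_end=config.utr5_length + cds_len,
            protein_length=protein_length, special_regions=special)
        model.validate()
        model._prime_positions = {  # mature offsets; consumed by generate_variants
            name: list(v) for name, v in prime_positions.items()}
        return model
    raise ValueError("could not generate a gene under these length constraints")


def _planted_budget(config: SimulationConfig) -> dict[str, int]:
    n_missense = int(round(config.n_variants
                           * config.class_mix.get(VariantClass.missense, 0.0)))
    return {name: int(round(rate * n_missense))
            for name, rate in config.planted_event_rates.items()}


def _find_prime_slot(rng, mature, ctx_len, frame, utr5, cds_len, boundaries_m,
                     reserved):
    """A CDS slot for a primed context: in frame, inside one exon, clear of
    junction windows and of other primed slots."""
    for _ in range(300):
        o = int(rng.integers(6, cds_len - ctx_len - 6))
        if o % 3 != frame:
            continue
        pos = utr5 + o
        if any(pos < b + 30 and pos + ctx_len > b - 30 for b in boundaries_m):
            continue
        if any(pos < e + 6 and pos + ctx_len > s - 6 for s, e in reserved):
            continue
        return pos
    return None


def _strong_donor6(rng, pwm, exon_left: str, target: float) -> str | None:
    for _ in range(300):
        intron6 = "GT" + _sample_from_pwm(rng, pwm.freqs, slice(5, 9))
        if pwm.score(exon_left + intron6) >= target:
            return intron6
    return None


def _strong_acceptor20(rng, pwm, exon_right: str, target: float) -> str | None:
    for _ in range(300):
        intron20 = _sample_from_pwm(rng, pwm.freqs, slice(0, 18)) + "AG"
        if pwm.score(intron20 + exon_right) >= target:
            return intron20
    return None


# ---------------------------------------------------------------------------
# Variant generation
# ---------------------------------------------------------------------------

class _Coord:
    """cDNA coordinate bookkeeping for one gene model."""

    def __init__(self, model: GeneModel):
        self.model = model
        self.pre_to_mature = {}
        m = 0
        for s, e in model.exons:
            for p in range(s, e):
                self.pre_to_mature[p] = m
                m += 1
        self.mature_to_pre = {m: p for p, m in self.pre_to_mature.items()}

    def c_of_premrna(self, p: int) -> int:
        return self.pre_to_mature[p] - (self.model.cds_start - 1) + 1

    def c_of_cds_offset(self, o: int) -> int:
        return o + 1

    def contiguous(self, o: int, k: int) -> bool:
        """True when CDS offsets o..o+k-1 are contiguous on the pre-mRNA
        (the span does not straddle an exon junction)."""
        cds0 = self.model.cds_start - 1
        pre = self.mature_to_pre
        return pre[cds0 + o + k - 1] - pre[cds0 + o] == k - 1


def _substitution(coord: _Coord, o: int, ref: str, alt: str) -> VariantDescriptor:
    c = coord.c_of_cds_offset(o)
    return VariantDescriptor(f"c.{c}{ref}>{alt}", VariantKind.substitution,
                             c, c, 0, 0, ref, alt)


def _certify(model, coord, desc, cfg: PipelineConfig, external_call,
             motif_table) -> tuple[VariantClass, Severity, ProteinLabel, Severity, float]:
    """Run the grading channels on one variant and measure the threshold margin."""
    pair = apply_variant(model, desc)
    vclass = classify_variant(model, desc, pair)

    t = cfg.thresholds
    splice_events = diff_splice_sites(model, pair, t, cfg.splice_window)
    sre_events = diff_motifs(motif_table, pair, model, cfg.sre_window)
    splicing = combine_channel(Channel.splicing, splice_events + sre_events)

    external = None
    if external_call is not None and vclass is VariantClass.missense:
        external = [ExternalVerdictRow(serialize_hgvs(desc), "consensus_missense",
                                       external_call, 0.9)]
    pv = assess_protein(vclass, pair, model, external, cfg.surrogate_threshold)
    protein = ChannelVerdict(Channel.protein, protein_label_to_severity(pv.label))
    overall = combine_overall(splicing, protein)

    margin = _splice_margin(model, pair, t, cfg.splice_window)
    return vclass, splicing.severity, pv.label, overall.severity, margin


def _splice_margin(model, pair: SequencePair, t: Thresholds, window: int) -> float:
    """Distance of every candidate score difference from the decision
    boundaries (reporting gate and severity thresholds)."""
    loose = dataclasses.replace(t, reporting_delta=1e-9)
    margin = 1.0
    for ev in diff_splice_sites(model, pair, loose, window):
        dists = [abs(abs(ev.delta) - t.reporting_delta)]
        if ev.event in (SpliceEventKind.natural_weakened, SpliceEventKind.natural_lost):
            dists += [abs((ev.wt_score - ev.mut_score) - t.severe_drop),
                      abs(ev.mut_score - t.severe_floor)]
        elif ev.event in (SpliceEventKind.cryptic_strengthened,
                          SpliceEventKind.site_created):
            dists.append(abs(ev.mut_score - t.cryptic_severe))
        margin = min(margin, min(dists))
    return margin


def generate_variants(model: GeneModel, config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      pipeline_config: PipelineConfig | None = None,
                      ) -> tuple[list[dict], list[GroundTruthRow]]:
    """Mutation records (gene, hgvs_c) plus certified ground truth.

    Class counts follow a multinomial draw from ``class_mix``; a share of the
    missense budget is spent on planted splicing events.  Every variant is
    pushed through the grading channels at generation time; the realized
    class must equal the intended one and a planted event's grade must match
    its design, otherwise generation aborts.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cfg = pipeline_config or PipelineConfig()
    motif_table = load_motif_table(cfg.motif_table)
    coord = _Coord(model)
    cds = model.cds
    cds_len = len(cds)
    utr5 = model.cds_start - 1
    prime_positions = dict(getattr(model, "_prime_positions", {}) or {})

    classes = sorted(config.class_mix, key=lambda c: c.value)
    probs = np.array([config.class_mix[c] for c in classes])
    counts = rng.multinomial(config.n_variants, probs / probs.sum())
    budget = dict(zip(classes, counts))

    planted_queue: list[str] = []
    needed = _planted_budget(config)
    for name, count in needed.items():
        avail = count if name == "natural_weakening_mild" else len(
            prime_positions.get(name, []))
        planted_queue += [name] * min(count, avail,
                                      budget.get(VariantClass.missense, 0)
                                      - len(planted_queue))

    records: list[dict] = []
    truth: list[GroundTruthRow] = []
    used_hgvs: set[str] = set()

    def emit(desc: VariantDescriptor, intended: VariantClass, planted: str,
             external_call: str | None, expect_grade: Severity | None = None,
             strict: bool = True) -> bool:
        hgvs = serialize_hgvs(desc)
        if hgvs in used_hgvs:
            return False
        vclass, spl, prot, overall, margin = _certify(
            model, coord, desc, cfg, external_call, motif_table)
        if vclass is not intended:
            if planted != "none" and strict:
                raise AssertionError(
                    f"planted {planted} variant {hgvs} realized class {vclass}, "
                    f"intended {intended}")
            return False
        if expect_grade is not None and spl is not expect_grade:
            if strict:
                raise AssertionError(
                    f"planted {planted} variant {hgvs} realized splicing {spl}, "
                    f"designed {expect_grade}")
            return False
        if planted == "none" and intended in (VariantClass.missense,
                                              VariantClass.synonymous,
                                              VariantClass.nonsense,
                                              VariantClass.inframe_indel,
                                              VariantClass.frameshift):
            # plain variants should carry no splicing signal; retry if the
            # edit accidentally lands on a scoring-relevant context
            if spl is not Severity.neutral:
                return False
        used_hgvs.add(hgvs)
        records.append({"gene": model.gene_id, "hgvs_c": hgvs})
        truth.append(GroundTruthRow(
            gene=model.gene_id, hgvs_c=hgvs, variant_class=vclass,
            planted=planted, splicing_truth=spl, protein_truth=prot.value,
            consensus_truth=overall,
            margin=margin, unambiguous=margin >= config.unambiguous_margin))
        return True

    def missense_call() -> str:
        return ("dangerous" if rng.random() < config.missense_dangerous_rate
                else "neutral")

    # --- planted variants (spend missense budget) --------------------------
    for name in planted_queue:
        call = missense_call()
        if name == "natural_weakening_mild":
            # searched (not primed): the same edit can graze another scoring
            # window, so a mismatch skips the plant instead of aborting
            desc, grade = _plant_natural_weakening(model, coord, rng, cfg)
            if desc is None:
                continue
            ok = emit(desc, VariantClass.missense, name, call, expect_grade=grade,
                      strict=False)
        else:
            pos = prime_positions[name].pop()
            _, ctx, off, alt, _frame = _PRIMES[name]
            o = (pos - utr5) + off
            desc = _substitution(coord, o, cds[o], alt)
            ok = emit(desc, VariantClass.missense, name, call,
                      expect_grade=Severity.severe if name != "sre_gain_other"
                      else Severity.mild)
        if ok:
            budget[VariantClass.missense] -= 1

    # --- plain variants per class ------------------------------------------
    # nonsense sites are scarce relative to their budget, so enumerate the
    # full pool once and draw without replacement
    nonsense_pool = []
    for o in range(3, cds_len - 3):
        ci, w = divmod(o, 3)
        codon = cds[3 * ci : 3 * ci + 3]
        if _CODON_AA[codon] == "*":
            continue
        for alt in "ACGT":
            if alt != codon[w] and _CODON_AA[codon[:w] + alt + codon[w + 1 :]] == "*":
                nonsense_pool.append((o, alt))
    nonsense_iter = iter([nonsense_pool[i]
                          for i in rng.permutation(len(nonsense_pool))])

    def _pop_nonsense():
        for o, alt in nonsense_iter:
            return _substitution(coord, o, cds[o], alt)
        raise AssertionError("nonsense substitution pool exhausted")

    makers = {
        VariantClass.missense: lambda: _make_missense(cds, coord, rng),
        VariantClass.synonymous: lambda: _make_synonymous(cds, coord, rng),
        VariantClass.nonsense: _pop_nonsense,
        VariantClass.frameshift: lambda: _make_frameshift(cds, coord, rng),
        VariantClass.inframe_indel: lambda: _make_inframe(cds, coord, rng),
        VariantClass.splice_site: lambda: _make_splice_site(model, coord, rng),
    }
    for vclass in classes:
        attempts = 0
        while budget[vclass] > 0:
            attempts += 1
            if attempts > budget[vclass] * 200 + 2000:
                raise AssertionError(f"cannot fill budget for {vclass}")
            desc = makers[vclass]()
            if desc is None:
                continue
            call = missense_call() if vclass is VariantClass.missense else (
                "dangerous" if vclass in (VariantClass.nonsense,
                                          VariantClass.frameshift,
                                          VariantClass.inframe_indel) else None)
            if emit(desc, vclass, "none", call):
                budget[vclass] -= 1
    return records, truth


def _coding_offset(rng, cds_len: int, width: int = 1) -> int:
    # keep clear of start and stop codons
    return int(rng.integers(3, cds_len - 3 - width))


def _make_missense(cds, coord, rng) -> VariantDescriptor | None:
    o = _coding_offset(rng, len(cds))
    ci, within = divmod(o, 3)
    codon = cds[3 * ci : 3 * ci + 3]
    alts = [b for b in "ACGT" if b != codon[within]]
    rng.shuffle(alts)
    for alt in alts:
        new = codon[:within] + alt + codon[within + 1 :]
        if _CODON_AA[new] not in ("*", _CODON_AA[codon]):
            return _substitution(coord, o, codon[within], alt)
    return None


def _make_synonymous(cds, coord, rng) -> VariantDescriptor | None:
    o = _coding_offset(rng, len(cds))
    ci, within = divmod(o, 3)
    codon = cds[3 * ci : 3 * ci + 3]
    alts = [b for b in "ACGT" if b != codon[within]]
    rng.shuffle(alts)
    for alt in alts:
        new = codon[:within] + alt + codon[within + 1 :]
        if _CODON_AA[new] == _CODON_AA[codon] and _CODON_AA[new] != "*":
            return _substitution(coord, o, codon[within], alt)
    return None


def _make_frameshift(cds, coord, rng) -> VariantDescriptor | None:
    o = _coding_offset(rng, len(cds), width=2)
    if not coord.contiguous(o, 3):
        return None
    c = coord.c_of_cds_offset(o)
    choice = int(rng.integers(3))
    if choice == 0:      # 1-nt deletion
        return VariantDescriptor(f"c.{c}del", VariantKind.deletion, c, c, 0, 0,
                                 cds[o], "")
    if choice == 1:      # 2-nt deletion
        return VariantDescriptor(f"c.{c}_{c+1}del", VariantKind.deletion, c, c + 1,
                                 0, 0, cds[o : o + 2], "")
    ins = "".join(rng.choice(list("ACGT"), size=1))
    return VariantDescriptor(f"c.{c}_{c+1}ins{ins}", VariantKind.insertion,
                             c, c + 1, 0, 0, "", ins)


def _make_inframe(cds, coord, rng) -> VariantDescriptor | None:
    # full-codon deletion or insertion so the frame is untouched
    n_codons = len(cds) // 3
    ci = int(rng.integers(2, n_codons - 2))
    o = 3 * ci
    if not coord.contiguous(max(o - 1, 0), 8):
        return None
    c = coord.c_of_cds_offset(o)
    if rng.random() < 0.5:
        k = int(rng.choice([3, 6]))
        if o + k >= len(cds) - 3:
            k = 3
        return VariantDescriptor(f"c.{c}_{c+k-1}del", VariantKind.deletion,
                                 c, c + k - 1, 0, 0, cds[o : o + k], "")
    ins = str(rng.choice(_SENSE_CODONS))
    return VariantDescriptor(f"c.{c-1}_{c}ins{ins}", VariantKind.insertion,
                             c - 1, c, 0, 0, "", ins)


def _make_splice_site(model: GeneModel, coord, rng) -> VariantDescriptor | None:
    """Canonical-position substitutions and boundary-spanning deletions."""
    junction = int(rng.integers(len(model.exons) - 1))
    donor_b = model.donor_boundaries[junction]      # first intronic base
    acceptor_b = model.acceptor_boundaries[junction]  # first exonic base of next exon
    pre = model.pre_mrna
    style = rng.random()
    if style < 0.35:    # donor +1/+2
        off = int(rng.integers(1, 3))
        p = donor_b + off - 1
        n_c = coord.c_of_premrna(donor_b - 1)
        ref = pre[p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return VariantDescriptor(f"c.{n_c}+{off}{ref}>{alt}", VariantKind.substitution,
                                 n_c, n_c, off, off, ref, alt)
    if style < 0.70:    # acceptor -1/-2
        off = int(rng.integers(1, 3))
        p = acceptor_b - off
        m_c = coord.c_of_premrna(acceptor_b)
        ref = pre[p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return VariantDescriptor(f"c.{m_c}-{off}{ref}>{alt}", VariantKind.substitution,
                                 m_c, m_c, -off, -off, ref, alt)
    if style < 0.80:    # intronic window position (donor +3..+6 / acceptor -20..-3)
        if rng.random() < 0.5:
            off = int(rng.integers(3, 7))
            p = donor_b + off - 1
            n_c = coord.c_of_premrna(donor_b - 1)
            ref = pre[p]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            return VariantDescriptor(f"c.{n_c}+{off}{ref}>{alt}",
                                     VariantKind.substitution, n_c, n_c, off, off,
                                     ref, alt)
        off = int(rng.integers(3, 21))
        p = acceptor_b - off
        m_c = coord.c_of_premrna(acceptor_b)
        ref = pre[p]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return VariantDescriptor(f"c.{m_c}-{off}{ref}>{alt}", VariantKind.substitution,
                                 m_c, m_c, -off, -off, ref, alt)
    # boundary-spanning deletion: last 2 exonic + first 4 intronic bases
    n_c = coord.c_of_premrna(donor_b - 1)
    ref = pre[donor_b - 2 : donor_b + 4]
    return VariantDescriptor(f"c.{n_c-1}_{n_c}+4del", VariantKind.deletion,
                             n_c - 1, n_c, 0, 4, ref, "")


def _plant_natural_weakening(model, coord, rng, cfg: PipelineConfig):
    """Search donor windows for a single exonic substitution whose mutant
    score lands in the mild band (reported but not severe)."""
    pwm = default_pwms()[SiteKind.donor]
    t = cfg.thresholds
    junctions = list(range(len(model.exons) - 1))
    rng.shuffle(junctions)
    pre = model.pre_mrna
    for j in junctions:
        b = model.donor_boundaries[j]
        window = pre[b - 3 : b + 6]
        wt_score = pwm.score(window)
        for i in range(3):  # exonic window positions -3..-1 (keep class exonic)
            for alt in "ACGT":
                if alt == window[i]:
                    continue
                mut_window = window[:i] + alt + window[i + 1 :]
                s = pwm.score(mut_window)
                drop = wt_score - s
                if (t.reporting_delta + 0.03 < drop < t.severe_drop - 0.03
                        and s > t.severe_floor + 0.03):
                    p = b - 3 + i
                    o = coord.pre_to_mature[p] - (model.cds_start - 1)
                    if o < 3:
                        continue
                    ci, within = divmod(o, 3)
                    cds = model.cds
                    codon = cds[3 * ci : 3 * ci + 3]
                    new = codon[:within] + alt + codon[within + 1 :]
                    if _CODON_AA[new] in ("*", _CODON_AA[codon]):
                        continue
                    return _substitution(coord, o, window[i], alt), Severity.mild
    return None, None


# ---------------------------------------------------------------------------
# External verdicts & fixture orchestration
# ---------------------------------------------------------------------------

def generate_external_verdicts(truth: list[GroundTruthRow],
                               config: SimulationConfig,
                               rng: np.random.Generator | None = None
                               ) -> list[ExternalVerdictRow]:
    """Adapter-style verdict rows consistent with the planted protein truth
    at the configured concordance rate (flips are recorded deviations, used
    to exercise discordance handling)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    rows: list[ExternalVerdictRow] = []
    for row in truth:
        if row.variant_class is VariantClass.missense:
            call = "dangerous" if row.protein_truth == ProteinLabel.severe.value \
                else "neutral"
            if rng.random() > config.concordance:
                call = "neutral" if call == "dangerous" else "dangerous"
            rows.append(ExternalVerdictRow(row.hgvs_c, "consensus_missense", call,
                                           round(float(rng.uniform(0.6, 1.0)), 3)))
        elif row.variant_class in (VariantClass.nonsense, VariantClass.frameshift,
                                   VariantClass.inframe_indel):
            # indel/nonsense predictor always calls these damaging; the
            # in-frame exception must cap them at mild downstream
            rows.append(ExternalVerdictRow(row.hgvs_c, "indel_nonsense", "disease",
                                           round(float(rng.uniform(0.6, 1.0)), 3)))
    return rows


def write_fixture_set(outdir: str | Path, config: SimulationConfig,
                      pipeline_config: PipelineConfig | None = None) -> dict[str, Path]:
    """Generate and write the full fixture set; byte-identical per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    model = generate_gene(config, rng)
    records, truth = generate_variants(model, config, rng, pipeline_config)
    verdicts = generate_external_verdicts(truth, config, rng)

    paths = {
        "fasta": outdir / f"{config.gene_id}.fa",
        "model": outdir / f"{config.gene_id}.model.yaml",
        "mutations": outdir / "mutations.tsv",
        "truth": outdir / "ground_truth.tsv",
        "verdicts": outdir / "external_verdicts.tsv",
    }
    model.to_files(paths["fasta"], paths["model"])
    with open(paths["mutations"], "w") as fh:
        fh.write("gene\thgvs_c\n")
        for r in records:
            fh.write(f"{r['gene']}\t{r['hgvs_c']}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("gene\thgvs_c\tvariant_class\tplanted\tsplicing_truth\t"
                 "protein_truth\tconsensus_truth\tmargin\tunambiguous\n")
        for row in truth:
            fh.write(f"{row.gene}\t{row.hgvs_c}\t{row.variant_class.value}\t"
                     f"{row.planted}\t{row.splicing_truth.value}\t{row.protein_truth}\t"
                     f"{row.consensus_truth.value}\t{row.margin:.4f}\t"
                     f"{int(row.unambiguous)}\n")
    with open(paths["verdicts"], "w") as fh:
        fh.write("hgvs_c\ttool\tcall\tconfidence\n")
        for v in verdicts:
            fh.write(f"{v.hgvs_c}\t{v.tool}\t{v.call}\t{v.confidence}\n")
    return paths
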