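# Methods

## The problem

Tumour-suppressor genes such as *BAP1*, *PBRM1* and *SETD2* in clear-cell
renal cell carcinoma accumulate hundreds of distinct cDNA-level mutations,
most with unknown molecular effect. This package triages each mutation into
**severe / mild / neutral** on two channels and combines them:

1. a **splicing channel** — does the edit weaken or destroy a natural splice
   site, strengthen or create a cryptic one, or gain/lose a splicing
   regulatory element (SRE)?
2. a **protein channel** — does the edit truncate, frameshift, or damage the
   protein directly?

The final verdict is the worst channel verdict (max-severity consensus).

## Splice-site strength model

Each site kind is scored by a position-frequency matrix over a fixed window:
donor 9-mer (exonic −3..−1, intronic +1..+6), acceptor 23-mer (intronic
−20..−1 covering the polypyrimidine tract and YAG, exonic +1..+3). These are
the standard splice-site footprints. A window lacking the invariant
canonical dinucleotide (GT at the intron start, AG at the intron end) scores
exactly 0: the dinucleotide is chemically mandatory, and a soft PWM penalty
would leave unspliceable "sites" with misleadingly high scores. Windows that
carry it are scored by total log-odds against a background composition
(A/T 0.27, C/G 0.23) and mapped through a logistic onto [0, 1], calibrated
from the matrix itself so that the consensus window scores ≈0.99 and a
background-typical dinucleotide-bearing window ≈0.01. Frequencies are
smoothed with a pseudocount of 0.5 per cell (treating the packaged
proportions as n=100 observations) so every probability is positive.

The scorer is deliberately a plain PWM: deterministic, monotone in
per-position log-odds, testable against a closed-form oracle, and pluggable
(the matrices are plain-text data files; a trained model can be substituted
behind the same interface). It reproduces the *ordering* semantics that the
grading rules need; it is not a re-implementation of any specific trained
predictor.

### Event detection

WT and mutant pre-mRNA are scanned within ±200 nt of the edit (configurable;
events farther away are impossible for a local edit, and the window bounds
runtime). Mutant window positions are projected back through the edit so
indels do not misalign natural boundaries. Events:

- `natural_weakened` / `natural_lost` — a gene-model boundary scores lower
  in the mutant (lost when the mutant score falls below 0.1, e.g. the
  canonical dinucleotide itself is destroyed);
- `site_created` / `cryptic_strengthened` — a non-natural position scores
  higher (created when the WT score was below 0.2);
- `site_destroyed` — a non-natural position scores lower (graded neutral:
  losing a site that was never used has no predicted consequence).

Only events with |Δscore| > 0.2 are reported. Strengthening of an
already-natural site is not emitted: no grading rule exists for it and a
stronger natural site does not change the predicted splicing outcome.

### Grading

- Natural-site weakening is **severe** if the score drops by ≥ 0.4, or
  crosses from ≥ 0.4 to < 0.4; otherwise **mild** (so 0.39 → 0.30 is mild).
  A literal reading of "final score below 0.4 ⇒ severe" would contradict
  that mild example; the crossing formulation is the only reading consistent
  with both clauses, and is what this package implements.
- Cryptic strengthening/creation is **severe** if the mutant score exceeds
  0.4 (strictly), otherwise **mild**.

## SRE channel

Exact string matching against a curated table of experimentally
characterized factor binding motifs (hnRNP A1 UAGGGA/UAGGGU-class silencer
sites, an hnRNP H G-run, a PTB pyrimidine silencer, SRSF1/Tra2β/SRSF5
enhancer-class sites; DNA alphabet, provenance per row, user-replaceable).
Exact matching mirrors the philosophy of experimentally-assessed motif
collections — a hit is a literal binding sequence, not a profile score.
Gains/losses are the symmetric difference of scans within ±100 nt of the
edit, with positions projected through the edit. Grading: exonic gain of an
hnRNP A1 silencer site is **severe** (a strong silencer whose creation can
cause exon skipping); exonic gain of any other silencer is **mild**; loss of
an exonic enhancer is **neutral** (enhancer motifs are redundant in exons).
All other combinations — intronic events, enhancer gains, silencer losses —
default to **neutral**; no rule is defined for them and the default is
configurable. A motif straddling a boundary takes the region of its 5′-most
base (deterministic tie-break).

## Protein channel

Rule-forced verdicts: nonsense and frameshift → **severe**; in-frame indels
→ **mild**, capping any external "damaging" call (they add or remove a few
residues without changing the frame); synonymous and splice-site variants →
**not applicable** (no protein channel; reported as "−"). Missense verdicts
come from an external-predictor adapter table when provided (binary
dangerous→severe / neutral→neutral; the confidence column is carried but
unused), else from a built-in surrogate: Grantham physicochemical distance,
recomputed from the published composition/polarity/volume formula and
shipped as a packaged table, thresholded at 100 (the conventional
radical-substitution cutoff). The surrogate is a transparent stand-alone
scorer labeled by `source`, not an emulation of any consensus web tool.

A variant that changes or truncates a residue of a special protein region
(e.g. a nuclear localization signal — for BAP1 the NLS spans residues
717–722 and its disruption retains the protein in the cytoplasm) escalates
missense and stop-loss verdicts to severe. Stop-loss variants (the single
class with no published protein rule) are severe iff the extension disrupts
a special region, else mild; in summaries they are folded into the missense
row (configurable), since the published taxonomy has no stop-loss row.

`not_applicable` is treated as channel *absence*, not as a neutral vote, so
it never dilutes the consensus.

## Export-element channel (informational)

Gain/loss of mRNA nuclear-export elements (eIF4E-SE, CJE, CAR, PRE, CTE,
SSCR) is scanned on the mature mRNA by the same symmetric-difference logic
and reported per variant, but never enters the consensus — no severity rule
exists for these events; they serve discrepancy investigation. The packaged
element table is an explicitly synthetic placeholder (the real element
collections are not redistributable); users point `export_table` at a real
collection to make this channel meaningful.

## Synthetic data generator

The generator emulates a curated somatic-mutation extract for one
transcript, with certified per-variant ground truth:

- **Gene**: 12 exons of 150–260 nt (a BAP1-scale transcript, ≈730 codons),
  introns 250–450 nt, 30 nt UTRs, stop-free ORF by construction, an
  NLS-like special region near the C-terminus. Each junction is nudged
  (≤40 nt) to a position where the exonic flank admits a strong site, then
  intron ends are sampled from the PWMs until the full window scores ≥ 0.85.
- **Variants**: class counts are a multinomial draw from the published
  BAP1-like mix (missense .45, frameshift .26, nonsense .11, splice-site
  .10, synonymous .05, in-frame indel .03). Substitutions are engineered at
  the codon level (missense/nonsense/synonymous by construction); indels
  avoid junction-straddling spans; splice-site variants mix canonical ±1/±2
  substitutions, other window positions, and boundary-spanning deletions.
- **Planted events**: 5% of the missense budget per event type is spent on
  engineered splicing events, built against *primed* sequence contexts
  written into the WT gene (a TAGGGC→TAGGGA hnRNP A1 gain, a TGGGGC→TGGGGG
  other-silencer gain, a CAGGAAAGT→CAGGTAAGT cryptic donor creation, a
  CCAT→CCAG cryptic acceptor creation after a planted pyrimidine tract) plus
  a searched natural-donor mild weakening. Primed contexts are frame-placed
  so neither WT nor mutant gains a stop codon. The planted budget is capped
  by the exonic slots that fit.
- **Certification**: every candidate variant is pushed through the grading
  channels at generation time. The intended class must equal the realized
  class and a primed event's grade must match its design (hard failure
  otherwise); plain variants that accidentally touch a scoring context are
  re-drawn. The recorded ground truth is therefore certified, not assumed.
  Per-variant a **margin** is recorded — the smallest distance of any
  candidate score difference from a decision boundary (reporting gate or
  severity threshold); variants with margin ≥ 0.05 form the "unambiguous"
  subset used for exact recovery checks. The searched mild-weakening plant
  is skipped (not aborted) when its edit grazes another scoring window.
- **External verdicts**: missense calls agree with the planted protein truth
  at a configurable concordance (default 1.0); nonsense/frameshift/in-frame
  rows always carry a damaging call, which exercises the in-frame cap.
- Determinism: one `numpy` generator seeded from the config; fixture files
  are byte-identical per seed.

What the generator does **not** emulate: mutation recurrence/clonality,
multi-isoform genes, genomic strand handling, branch points and RNA
secondary structure, real predictor noise. Passing the recovery checks shows
the pipeline is internally consistent and implements the grading rules
exactly — not that the PWM or motif table matches any particular trained
predictor on real genes.

## Numerical and design choices

- Coordinates: HGVS 1-based inclusive cDNA externally; 0-based half-open
  pre-mRNA internally; conversion confined to the parser/serializer and
  `GeneModel.cdna_to_premrna`.
- Reference-allele mismatches are hard errors (a silent mismatch corrupts
  every downstream channel); protein-only records are rejected (the splicing
  channel needs nucleotide context).
- Threshold ties: drop ≥ 0.4 is severe; cryptic final > 0.4 (strict) is
  severe; the 0.2 reporting gate is strict (> 0.2).
- Ambiguous bases (N) contribute background log-odds (zero) per position.
- Start-loss variants classify as missense with a `start_loss` warning flag.
- Variants whose cDNA span is exonic but crosses a junction (not a
  contiguous pre-mRNA edit) are validation errors.
- Percentages in summaries are recomputed from counts and rounded half-up to
  integers.
- Problem sizes: the acceptance script runs one 1,000-variant study on one
  BAP1-scale gene; the test suite uses the same scale for end-to-end checks
  and smaller fixtures elsewhere. These sizes give every class double-digit
  counts while keeping a full run in seconds.

## Known limitations

- The PWM scorer shares only the 0–1 scale and ordering semantics with
  trained splice-site predictors; absolute scores on real sequences will
  differ, so the 0.4/0.2 thresholds should be recalibrated if the scorer is
  swapped.
- The SRE table is deliberately compact; a fuller motif collection will
  find more (and more overlapping) events. Competition and proximity
  effects among factors are not modeled.
- Single-transcript model: no isoform selection, no liftover, no 5′UTR/3′UTR
  HGVS notation (`c.-n` / `c.*n`).
- The consensus is rule-based and unweighted by design; it is not a
  calibrated pathogenicity probability.
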