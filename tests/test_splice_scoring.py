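"""PWM scoring oracle checks, event grading rules, and WT/mutant diffs."""

from __future__ import annotations

import math

import numpy as np
import pytest

from splicetriage.config import Thresholds
from splicetriage.genome_variant import apply_variant, parse_hgvs_c
from splicetriage.splice_scoring import (
    Severity,
    SiteKind,
    SpliceEventKind,
    default_pwms,
    diff_splice_sites,
    grade_splice_event,
    scan_sites,
    score_window,
)

BASES = "ACGT"


def oracle_score(pwm, window: str) -> float:
    """Independent re-computation: canonical-dinucleotide gate, then plain
    log-odds sum scaled by the logistic whose endpoints are derived from the
    matrix itself (consensus ~0.99, dinucleotide-bearing background ~0.01)."""
    canon = pwm.canonical_positions
    for i, base in canon.items():
        if window[i] != base:
            return 0.0
    x = sum(math.log(pwm.freqs[i][BASES.index(b)] / pwm.background[BASES.index(b)])
            for i, b in enumerate(window))
    hi = sum(max(math.log(pwm.freqs[i][j] / pwm.background[j]) for j in range(4))
             for i in range(pwm.window_length))
    lo = 0.0
    for i in range(pwm.window_length):
        if i in canon:
            lo += max(math.log(pwm.freqs[i][j] / pwm.background[j]) for j in range(4))
        else:
            lo += sum(pwm.background[j]
                      * math.log(pwm.freqs[i][j] / pwm.background[j])
                      for j in range(4))
    mid = (hi + lo) / 2
    a = math.log(99.0) / (hi - mid)
    return 1.0 / (1.0 + math.exp(-a * (x - mid)))


@pytest.mark.parametrize("kind", [SiteKind.donor, SiteKind.acceptor])
def test_score_window_matches_brute_force_oracle(kind, rng):
    pwm = default_pwms()[kind]
    for _ in range(1000):
        window = "".join(rng.choice(list(BASES), size=pwm.window_length))
        assert abs(score_window(pwm, window) - oracle_score(pwm, window)) < 1e-9


@pytest.mark.parametrize("kind", [SiteKind.donor, SiteKind.acceptor])
def test_consensus_dominates_single_substitutions(kind):
    pwm = default_pwms()[kind]
    consensus = pwm.consensus
    s0 = score_window(pwm, consensus)
    assert s0 > 0.98
    for i in range(len(consensus)):
        for b in BASES:
            if b != consensus[i]:
                neighbour = consensus[:i] + b + consensus[i + 1 :]
                assert score_window(pwm, neighbour) <= s0


def test_degenerate_windows(rng):
    pwm = default_pwms()[SiteKind.donor]
    assert score_window(pwm, "AAAAAAAAA") < 0.1
    assert score_window(pwm, "NNNGTNNNN") <= 1.0  # N policy: background
    with pytest.raises(ValueError):
        score_window(pwm, "GT")
    for _ in range(50):
        w = "".join(rng.choice(list(BASES), size=9))
        assert 0.0 <= score_window(pwm, w) <= 1.0


# ---------------------------------------------------------------------------
# grading rules
# ---------------------------------------------------------------------------

def _oracle_natural(wt, mut):
    # severe iff the drop is at least 0.4 OR the score falls from >= 0.4 to
    # below 0.4; a small deviation (0.39 -> 0.30) stays mild
    return Severity.severe if (wt - mut >= 0.4 or (wt >= 0.4 and mut < 0.4)) \
        else Severity.mild


def _oracle_cryptic(wt, mut):
    return Severity.severe if mut > 0.4 else Severity.mild


def test_grade_grid_matches_closed_form_rules():
    grid = np.round(np.arange(0.0, 1.0001, 0.01), 2)
    for wt in grid:
        for mut in grid:
            assert grade_splice_event(SpliceEventKind.natural_weakened, wt, mut) \
                is _oracle_natural(wt, mut)
            assert grade_splice_event(SpliceEventKind.site_created, wt, mut) \
                is _oracle_cryptic(wt, mut)


@pytest.mark.parametrize("event,wt,mut,expected", [
    (SpliceEventKind.natural_weakened, 0.85, 0.30, Severity.severe),
    (SpliceEventKind.natural_weakened, 0.39, 0.30, Severity.mild),
    (SpliceEventKind.cryptic_strengthened, 0.10, 0.55, Severity.severe),
    (SpliceEventKind.cryptic_strengthened, 0.05, 0.35, Severity.mild),
    (SpliceEventKind.site_destroyed, 0.50, 0.00, Severity.neutral),
])
def test_grade_examples(event, wt, mut, expected):
    assert grade_splice_event(event, wt, mut) is expected


def test_cryptic_grade_monotone_in_mutant_score():
    seen_severe = False
    for mut in np.arange(0.0, 1.001, 0.005):
        g = grade_splice_event(SpliceEventKind.cryptic_strengthened, 0.1, float(mut))
        if g is Severity.severe:
            seen_severe = True
        assert not (seen_severe and g is Severity.mild)


# ---------------------------------------------------------------------------
# scanning and diffing
# ---------------------------------------------------------------------------

def test_scan_finds_all_natural_sites(syn_model):
    pwms = default_pwms()
    donors = scan_sites(pwms[SiteKind.donor], syn_model.pre_mrna, 0.4, syn_model)
    acceptors = scan_sites(pwms[SiteKind.acceptor], syn_model.pre_mrna, 0.4, syn_model)
    found_d = {s.position for s in donors if s.is_natural}
    found_a = {s.position for s in acceptors if s.is_natural}
    assert found_d == set(syn_model.donor_boundaries)
    assert found_a == set(syn_model.acceptor_boundaries)
    assert all(s.score >= 0.4 for s in donors + acceptors)


def test_scan_short_sequence_is_empty():
    pwm = default_pwms()[SiteKind.acceptor]
    assert scan_sites(pwm, "ACGT") == []


def test_diff_identity_edit_emits_nothing(toy_model):
    pair = apply_variant(toy_model, parse_hgvs_c("c.30C>T"))
    pair.mut_premrna = pair.wt_premrna
    assert diff_splice_sites(toy_model, pair) == []


def test_donor_plus_one_disruption_is_lost_and_severe(toy_model):
    pair = apply_variant(toy_model, parse_hgvs_c("c.45+1G>A"))
    events = diff_splice_sites(toy_model, pair)
    lost = [e for e in events if e.event is SpliceEventKind.natural_lost
            and e.kind is SiteKind.donor]
    assert lost and lost[0].grade is Severity.severe
    assert lost[0].mut_score == 0.0


def test_acceptor_minus_one_disruption_is_lost_and_severe(toy_model):
    pair = apply_variant(toy_model, parse_hgvs_c("c.46-1G>A"))
    events = diff_splice_sites(toy_model, pair)
    lost = [e for e in events if e.event is SpliceEventKind.natural_lost
            and e.kind is SiteKind.acceptor]
    assert lost and lost[0].grade is Severity.severe


def test_all_emitted_events_exceed_reporting_gate(toy_model):
    for hgvs in ["c.45+1G>A", "c.45+5G>A", "c.44A>T", "c.4delG"]:
        pair = apply_variant(toy_model, parse_hgvs_c(hgvs))
        for e in diff_splice_sites(toy_model, pair):
            assert abs(e.delta) > Thresholds().reporting_delta


def test_distant_variant_changes_nothing(syn_model):
    # an exonic edit > 200 nt from any junction, chosen not to touch a motif
    pair = apply_variant(syn_model, parse_hgvs_c("c.30C>T")
                         if syn_model.cds[29] == "C" else
                         parse_hgvs_c(f"c.30{syn_model.cds[29]}>"
                                      f"{'C' if syn_model.cds[29] != 'C' else 'G'}"))
    for e in diff_splice_sites(syn_model, pair):
        assert abs(e.delta) > 0.2  # whatever is emitted respects the gate
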