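"""Combining channel verdicts into the final severity.

Severity is a total order (severe > mild > neutral) and aggregation at both
levels is a max: a channel is as severe as its worst event, and the overall
verdict is as severe as its worst channel.  This restates the published
aggregation: severe if any tool says severe; mild if some tool says mild and
none severe; neutral when no tool reports an alteration.  A channel with no
events is neutral; a not-applicable channel is ignored entirely (it is
absence of a channel, not a neutral vote), so classes whose protein column
prints "-" are decided by the splicing channel alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .genome_variant import SpliceTriageError
from .splice_scoring import Severity

_RANK = {Severity.neutral: 0, Severity.mild: 1, Severity.severe: 2}


class Channel(str, Enum):
    splicing = "splicing"
    protein = "protein"


@dataclass
class ChannelVerdict:
    channel: Channel
    severity: Severity | None           # None = not applicable
    contributing_events: list = field(default_factory=list)

    @property
    def applicable(self) -> bool:
        return self.severity is not None


@dataclass
class ConsensusVerdict:
    severity: Severity
    basis: list[tuple[Channel, Severity]]


def combine_channel(channel: Channel, events: list) -> ChannelVerdict:
    """Worst grade over a channel's events; no events means neutral."""
    grades = [e.grade for e in events]
    severity = max(grades, key=_RANK.get, default=Severity.neutral)
    return ChannelVerdict(channel=channel, severity=severity,
                          contributing_events=list(events))


def combine_overall(splicing: ChannelVerdict, protein: ChannelVerdict) -> ConsensusVerdict:
    """Final severity: max over applicable channels."""
    applicable = [(v.channel, v.severity) for v in (splicing, protein) if v.applicable]
    if not applicable:
        raise SpliceTriageError("no assessable channel: both verdicts not applicable")
    severity = max((s for _, s in applicable), key=_RANK.get)
    return ConsensusVerdict(severity=severity, basis=applicable)
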