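"""Greedy reconstruction of the event set behind an observed karyotype.

Starting from the observed clone, the algorithm repeatedly "undoes" the
simplest applicable event, moving the state toward the normal karyotype
(46,XX / 46,XY).  Each undo removes one abnormality token (monotone
progress, hence termination); whole-chromosome gains and losses adjust
the modal count by one.  If the state cannot be reduced to normal with
the configured vocabulary, or two equal-rank opposite events compete for
the same chromosome, the reconstruction is flagged ambiguous and the
karyotype is excluded from downstream statistics.

The default vocabulary has 11 event kinds.  The exact list is a
documented modelling assumption (see docs/methods.md): whole-chromosome
gain; whole-chromosome loss; reciprocal translocation; terminal
deletion; interstitial deletion; tandem duplication; isochromosome;
paracentric inversion; pericentric inversion; derivative-resolved
translocation; three-break rearrangement.  A three-break rearrangement
is decomposed into two two-break translocations sharing a band.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .aberrations import (
    DELETION,
    DUPLICATION,
    GAIN,
    INVERSION,
    ISOCHROMOSOME,
    LOSS,
    TRANSLOCATION,
    Aberration,
)
from .iscn import NORMAL_MODAL_COUNT, Der, ParsedKaryotype, Token


@dataclass(frozen=True)
class EventKind:
    """One vocabulary entry: a name and a simplicity rank (lower = undone first)."""

    name: str
    rank: int


DEFAULT_VOCABULARY: tuple[EventKind, ...] = (
    EventKind("whole-chromosome gain", 0),
    EventKind("whole-chromosome loss", 0),
    EventKind("reciprocal translocation", 1),
    EventKind("terminal deletion", 2),
    EventKind("interstitial deletion", 2),
    EventKind("tandem duplication", 2),
    EventKind("isochromosome", 3),
    EventKind("paracentric inversion", 4),
    EventKind("pericentric inversion", 4),
    EventKind("derivative-resolved translocation", 5),
    EventKind("three-break rearrangement", 5),
)

_RANKS = {k.name: k.rank for k in DEFAULT_VOCABULARY}


def classify_token(token: Token) -> str:
    """Vocabulary entry name for a parsed token."""
    if isinstance(token, Der):
        return "derivative-resolved translocation"
    if token.kind == GAIN:
        return "whole-chromosome gain"
    if token.kind == LOSS:
        return "whole-chromosome loss"
    if token.kind == TRANSLOCATION:
        return (
            "reciprocal translocation"
            if len(token.loci) == 2
            else "three-break rearrangement"
        )
    if token.kind == DELETION:
        return "terminal deletion" if len(token.loci) == 1 else "interstitial deletion"
    if token.kind == DUPLICATION:
        return "tandem duplication"
    if token.kind == ISOCHROMOSOME:
        return "isochromosome"
    if token.kind == INVERSION:
        arms = {b.arm for b in token.loci}
        return "paracentric inversion" if len(arms) == 1 else "pericentric inversion"
    raise ValueError(f"token outside the vocabulary: {token}")


@dataclass
class Reconstruction:
    """Outcome of the greedy undo loop for one karyotype."""

    events: list[Aberration] = field(default_factory=list)
    ambiguous: bool = False
    steps: list[str] = field(default_factory=list)

    @property
    def aberration_ids(self) -> frozenset[str]:
        return frozenset(e.canonical_id for e in self.events)


def _decompose_three_break(token: Aberration) -> list[Aberration]:
    """Split an n-break (n>=3) translocation into band-sharing two-break ones."""
    loci = token.loci
    parts = []
    for a, b in zip(loci, loci[1:]):
        parts.append(Aberration(TRANSLOCATION, (a, b)))
    return parts


def reconstruct(
    parsed: ParsedKaryotype, ranks: dict[str, int] | None = None
) -> Reconstruction:
    """Greedily undo events until the normal karyotype is reached.

    Requires a valid, well-defined parse.  The event multiset replayed
    forward from 46,XX/XY reproduces the observed abnormality tokens
    (soundness is asserted in the test suite).
    """
    if not parsed.valid or not parsed.well_defined:
        raise ValueError("reconstruction requires a valid, well-defined karyotype")
    ranks = ranks or _RANKS
    rec = Reconstruction()
    remaining: list[Token] = list(parsed.tokens)
    count = parsed.modal_count

    # gain and loss of one chromosome competing at equal rank: the undo
    # order is not determined and the pair could equally be a net no-op
    gained = {t.loci[0] for t in remaining if isinstance(t, Aberration) and t.kind == GAIN}
    lost = {t.loci[0] for t in remaining if isinstance(t, Aberration) and t.kind == LOSS}
    if gained & lost:
        rec.ambiguous = True

    seen_der_events: set[str] = set()
    while remaining:
        remaining.sort(key=lambda t: (ranks[classify_token(t)], str(t)))
        token = remaining.pop(0)
        rec.steps.append(f"undo {classify_token(token)}: {token}")
        if isinstance(token, Der):
            for t in token.translocations:
                if t.canonical_id not in seen_der_events and not any(
                    e.canonical_id == t.canonical_id for e in rec.events
                ):
                    rec.events.append(t)
                    seen_der_events.add(t.canonical_id)
        elif token.kind == GAIN:
            rec.events.append(token)
            count -= 1
        elif token.kind == LOSS:
            rec.events.append(token)
            count += 1
        elif token.kind == TRANSLOCATION and len(token.loci) > 2:
            rec.events.extend(_decompose_three_break(token))
        else:
            rec.events.append(token)

    if count != NORMAL_MODAL_COUNT:
        rec.ambiguous = True  # not reducible to the normal modal count
    return rec


def replay(events, sex: str = "XX") -> tuple[int, Counter]:
    """Apply events forward to the normal karyotype.

    Returns the resulting modal count and the multiset of abnormality
    token ids.  Used to assert reconstruction soundness.
    """
    count = NORMAL_MODAL_COUNT
    tokens: Counter = Counter()
    for e in events:
        if e.kind == GAIN:
            count += 1
        elif e.kind == LOSS:
            count -= 1
        tokens[e.canonical_id] += 1
    return count, tokens
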