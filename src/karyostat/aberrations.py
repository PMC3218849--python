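"""Aberration objects and canonical ISCN-style identifiers.

An aberration is identified by its causing event kind and the chromosomal
locations it involves; two aberrations are equal iff their canonical ids
are equal.  Canonical ids follow ISCN conventions: ``+8`` (gain),
``-7`` (loss), ``t(9;22)(q34;q11)`` (translocation, chromosomes ordered
numerically with X and Y last), ``del(5)(q13q33)``, ``dup(1)(q21q32)``,
``i(17)(q10)``, ``inv(3)(p21q26)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .bands import CytoBand, chromosome_sort_key

# Event kind labels.  GAIN/LOSS carry a bare chromosome locus; the rest
# carry band loci.  DER_TRANSLOCATION shares the translocation id space:
# a derivative chromosome written as der(22)t(9;22)(q34;q11) names the
# same underlying event as the plain translocation token.
GAIN = "gain"
LOSS = "loss"
TRANSLOCATION = "translocation"
DELETION = "deletion"
DUPLICATION = "duplication"
ISOCHROMOSOME = "isochromosome"
INVERSION = "inversion"

_KINDS_WHOLE = {GAIN, LOSS}
_KINDS_BANDED = {TRANSLOCATION, DELETION, DUPLICATION, ISOCHROMOSOME, INVERSION}


@dataclass(frozen=True)
class Aberration:
    """A reconstructed chromosomal event.

    ``loci`` is a tuple of chromosome labels (gain/loss) or CytoBands
    (everything else).  Identity, hashing and ordering all reduce to
    ``canonical_id``.
    """

    kind: str
    loci: tuple
    canonical_id: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "canonical_id", canonical_id(self.kind, self.loci))
        # normalise locus order to match the id (translocation symmetry)
        if self.kind == TRANSLOCATION:
            object.__setattr__(
                self,
                "loci",
                tuple(sorted(self.loci, key=lambda b: chromosome_sort_key(b.chromosome))),
            )

    @property
    def chromosomes(self) -> tuple[str, ...]:
        if self.kind in _KINDS_WHOLE:
            return (self.loci[0],)
        return tuple(b.chromosome for b in self.loci)

    def __eq__(self, other) -> bool:
        return isinstance(other, Aberration) and self.canonical_id == other.canonical_id

    def __hash__(self) -> int:
        return hash(self.canonical_id)

    def __str__(self) -> str:
        return self.canonical_id


def canonical_id(kind: str, loci) -> str:
    """Deterministic, order-normalised id for (kind, loci).

    Raises ``ValueError`` on arity mismatches (malformed aberrations).
    """
    loci = tuple(loci)
    if kind in _KINDS_WHOLE:
        if len(loci) != 1 or not isinstance(loci[0], str):
            raise ValueError(f"{kind} takes exactly one bare chromosome locus")
        chromosome_sort_key(loci[0])  # validates the label
        return ("+" if kind == GAIN else "-") + loci[0]
    if not all(isinstance(b, CytoBand) for b in loci):
        raise ValueError(f"{kind} loci must be CytoBands")
    if kind == TRANSLOCATION:
        if len(loci) < 2:
            raise ValueError("translocation needs at least two loci")
        if len({b.chromosome for b in loci}) != len(loci):
            raise ValueError("translocation loci must be on distinct chromosomes")
        ordered = sorted(loci, key=lambda b: chromosome_sort_key(b.chromosome))
        chroms = ";".join(b.chromosome for b in ordered)
        bands = ";".join(f"{b.arm}{b.band}" for b in ordered)
        return f"t({chroms})({bands})"
    if kind == DELETION:
        if len(loci) not in (1, 2):
            raise ValueError("deletion takes one (terminal) or two (interstitial) loci")
        return _one_chrom_id("del", loci)
    if kind == DUPLICATION:
        if len(loci) != 2:
            raise ValueError("duplication takes two loci")
        return _one_chrom_id("dup", loci)
    if kind == ISOCHROMOSOME:
        if len(loci) != 1 or not loci[0].is_centromeric:
            raise ValueError("isochromosome takes one centromeric (p10/q10) locus")
        return _one_chrom_id("i", loci)
    if kind == INVERSION:
        if len(loci) != 2:
            raise ValueError("inversion takes two loci")
        return _one_chrom_id("inv", loci)
    raise ValueError(f"unknown aberration kind: {kind!r}")


def _one_chrom_id(prefix: str, loci: tuple[CytoBand, ...]) -> str:
    chrom = loci[0].chromosome
    if any(b.chromosome != chrom for b in loci):
        raise ValueError(f"{prefix} loci must share one chromosome")
    ordered = sorted(loci, key=lambda b: (b.arm, b.band))
    bands = "".join(f"{b.arm}{b.band}" for b in ordered)
    return f"{prefix}({chrom})({bands})"


def gain(chrom: str) -> Aberration:
    return Aberration(GAIN, (chrom,))


def loss(chrom: str) -> Aberration:
    return Aberration(LOSS, (chrom,))


def translocation(*loci: str | CytoBand) -> Aberration:
    bands = tuple(b if isinstance(b, CytoBand) else CytoBand.parse(b) for b in loci)
    return Aberration(TRANSLOCATION, bands)


_ID_GAIN_LOSS = re.compile(r"^([+-])(\d{1,2}|[XY])$")
_ID_TRANSLOC = re.compile(r"^t\(([^)]+)\)\(([^)]+)\)$")


def kind_of_id(canonical: str) -> str:
    """Coarse kind of a canonical id: 'gain', 'loss' or 'other'.

    Used for the gain/loss dichotomy readout on co-occurrence networks.
    """
    m = _ID_GAIN_LOSS.match(canonical)
    if m:
        return GAIN if m.group(1) == "+" else LOSS
    return "other"


def parse_canonical(canonical: str) -> Aberration:
    """Rebuild an Aberration from its canonical id (supported vocabulary)."""
    m = _ID_GAIN_LOSS.match(canonical)
    if m:
        return Aberration(GAIN if m.group(1) == "+" else LOSS, (m.group(2),))
    m = _ID_TRANSLOC.match(canonical)
    if m:
        chroms = m.group(1).split(";")
        bands = m.group(2).split(";")
        if len(chroms) != len(bands):
            raise ValueError(f"malformed translocation id: {canonical!r}")
        loci = tuple(CytoBand(c, b[0], b[1:]) for c, b in zip(chroms, bands))
        return Aberration(TRANSLOCATION, loci)
    m = re.match(r"^(del|dup|i|inv)\((\d{1,2}|[XY])\)\(([^)]+)\)$", canonical)
    if m:
        prefix, chrom, bandstr = m.groups()
        loci = tuple(
            CytoBand(chrom, arm, num)
            for arm, num in re.findall(r"([pq])(\d+)", bandstr)
        )
        kind = {"del": DELETION, "dup": DUPLICATION, "i": ISOCHROMOSOME, "inv": INVERSION}[prefix]
        return Aberration(kind, loci)
    raise ValueError(f"cannot parse canonical id: {canonical!r}")
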