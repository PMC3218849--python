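"""Parser and renderer for a defined ISCN subset.

The subset covers: modal chromosome count (ranges take the first value),
sex designation, whole-chromosome gains/losses (``+8``/``-7``),
translocations ``t(9;22)(q34;q11)``, deletions ``del(5)(q13q33)``,
duplications ``dup(1)(q21q32)``, isochromosomes ``i(17)(q10)``,
inversions ``inv(3)(p21q26)``, and derivative chromosomes composed of
listed translocations ``der(22)t(9;22)(q34;q11)``.

Anything else — uncertainty markers (``?``), marker chromosomes
(``mar``), incomplete karyotypes (``inc``), material of unknown origin
(``add``), or any unrecognised token — flags the karyotype as not
well-defined.  A malformed modal count invalidates the record outright.
No parse failure raises: every defect is encoded in flags so the
filtering cascade can report exclusion counts.
"""

from __future__ import annotations

import re
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
from .bands import CytoBand, chromosome_sort_key

NORMAL_MODAL_COUNT = 46

_CHROM = r"(?:\d{1,2}|[XY])"
_BAND = r"[pq]\d+(?:\.\d+)?"

_RE_MODAL = re.compile(r"^(\d{1,3})(?:[-~](\d{1,3}))?$")
_RE_SEX = re.compile(r"^[XY]{1,4}$")
_RE_GAIN_LOSS = re.compile(rf"^([+-])({_CHROM})$")
_RE_T = re.compile(rf"^t\(({_CHROM}(?:;{_CHROM})+)\)\((({_BAND})(?:;{_BAND})+)\)$")
_RE_ONE = re.compile(rf"^(del|dup|inv|i)\(({_CHROM})\)\(((?:{_BAND}){{1,2}})\)$")
_RE_DER = re.compile(rf"^der\(({_CHROM})\)((?:t\([^()]*\)\([^()]*\))+)$")
_RE_T_PART = re.compile(r"t\([^()]*\)\([^()]*\)")


@dataclass(frozen=True)
class Der:
    """A derivative chromosome written as a composition of translocations."""

    chromosome: str
    translocations: tuple[Aberration, ...]

    def __str__(self) -> str:
        return f"der({self.chromosome})" + "".join(
            t.canonical_id for t in self.translocations
        )


Token = Aberration | Der


@dataclass
class ParsedKaryotype:
    """Skeleton returned by :func:`parse_iscn` for a single-clone string."""

    iscn: str
    modal_count: int | None = None
    sex: str | None = None
    tokens: list[Token] = field(default_factory=list)
    valid: bool = True
    well_defined: bool = True
    bad_tokens: list[str] = field(default_factory=list)


@dataclass
class Karyotype:
    """One clone's parsed record with selection/validity flags.

    ``aberrations`` holds canonical ids with binary presence (a set);
    an invalid record carries an empty set.
    """

    record_id: str
    case_id: str
    clone_index: int
    iscn: str
    modal_count: int | None
    tumor_class: str
    category: str
    selected: bool
    valid: bool
    well_defined: bool
    aberrations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.valid and self.aberrations:
            raise ValueError("invalid karyotype must carry no aberrations")


def parse_iscn(iscn: str) -> ParsedKaryotype:
    """Parse one single-clone ISCN string into a karyotype skeleton.

    Multiclonal splitting happens upstream; this function sees one clone.
    """
    parsed = ParsedKaryotype(iscn=iscn)
    parts = [p.strip() for p in iscn.strip().split(",")]
    if len(parts) < 2:
        parsed.valid = False
        parsed.well_defined = False
        return parsed

    m = _RE_MODAL.match(parts[0])
    if m is None:
        parsed.valid = False
        parsed.well_defined = False
        return parsed
    parsed.modal_count = int(m.group(1))  # ranges take the first value

    if _RE_SEX.match(parts[1]):
        parsed.sex = parts[1]
    else:
        parsed.well_defined = False
        parsed.bad_tokens.append(parts[1])

    for raw in parts[2:]:
        if "?" in raw:
            parsed.well_defined = False
            parsed.bad_tokens.append(raw)
            continue
        token = _parse_token(raw)
        if token is None:
            parsed.well_defined = False
            parsed.bad_tokens.append(raw)
        else:
            parsed.tokens.append(token)
    return parsed


def _parse_token(raw: str) -> Token | None:
    m = _RE_GAIN_LOSS.match(raw)
    if m:
        sign, chrom = m.groups()
        return Aberration(GAIN if sign == "+" else LOSS, (chrom,))
    m = _RE_T.match(raw)
    if m:
        return _build_translocation(m.group(1), m.group(2))
    m = _RE_ONE.match(raw)
    if m:
        prefix, chrom, bandstr = m.groups()
        loci = tuple(
            CytoBand(chrom, arm, num)
            for arm, num in re.findall(r"([pq])(\d+(?:\.\d+)?)", bandstr)
        )
        kind = {
            "del": DELETION,
            "dup": DUPLICATION,
            "inv": INVERSION,
            "i": ISOCHROMOSOME,
        }[prefix]
        try:
            return Aberration(kind, loci)
        except ValueError:
            return None
    m = _RE_DER.match(raw)
    if m:
        chrom, rest = m.groups()
        translocs = []
        for part in _RE_T_PART.findall(rest):
            token = _parse_token(part)
            if not isinstance(token, Aberration) or token.kind != TRANSLOCATION:
                return None
            translocs.append(token)
        if not translocs or chrom not in {
            c for t in translocs for c in t.chromosomes
        }:
            return None
        return Der(chrom, tuple(translocs))
    return None


def _build_translocation(chroms: str, bands: str) -> Aberration | None:
    chrom_list = chroms.split(";")
    band_list = bands.split(";")
    if len(chrom_list) != len(band_list):
        return None
    try:
        loci = tuple(
            CytoBand(c, b[0], b[1:]) for c, b in zip(chrom_list, band_list)
        )
        return Aberration(TRANSLOCATION, loci)
    except ValueError:
        return None


def _token_sort_key(token: Token):
    chrom = token.chromosome if isinstance(token, Der) else token.chromosomes[0]
    return (chromosome_sort_key(chrom), str(token))


def render_iscn(modal_count: int, sex: str, tokens) -> str:
    """Render a karyotype string the subset parser round-trips exactly."""
    parts = [str(modal_count), sex]
    parts.extend(str(t) for t in sorted(tokens, key=_token_sort_key))
    return ",".join(parts)


__all__ = [
    "NORMAL_MODAL_COUNT",
    "Der",
    "Karyotype",
    "ParsedKaryotype",
    "parse_iscn",
    "render_iscn",
]
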