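"""Cytogenetic band model: chromosomes, arms and dot-free band labels.

A :class:`CytoBand` names a single band on a chromosome arm (``9q34``).
A :class:`CytobandModel` holds, per chromosome, the ordered band ladder
from pter to qter; it is the reference used to decide whether a CGH
segment spans the centromere.  The special bands ``p10`` and ``q10``
flank the centromere on every chromosome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")

_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}

_BAND_RE = re.compile(r"^(?P<chrom>\d{1,2}|[XY])(?P<arm>[pq])(?P<band>\d+(?:\.\d+)?)$")


def chromosome_sort_key(chrom: str) -> int:
    """Numeric ordering of chromosome labels with X and Y last."""
    try:
        return _CHROM_ORDER[chrom]
    except KeyError:
        raise ValueError(f"unknown chromosome label: {chrom!r}") from None


@dataclass(frozen=True, order=True)
class CytoBand:
    """One band, e.g. ``CytoBand('9', 'q', '34')`` rendered as ``9q34``.

    Sub-band suffixes are truncated on construction (``q34.1`` -> ``q34``)
    because aberration identity is band-level.  ``p10``/``q10`` denote the
    centromeric band of the respective arm.
    """

    chromosome: str
    arm: str
    band: str

    def __post_init__(self) -> None:
        if self.chromosome not in _CHROM_ORDER:
            raise ValueError(f"unknown chromosome label: {self.chromosome!r}")
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if "." in self.band:
            object.__setattr__(self, "band", self.band.split(".", 1)[0])
        if not self.band.isdigit():
            raise ValueError(f"malformed band label: {self.band!r}")

    @classmethod
    def parse(cls, text: str) -> "CytoBand":
        m = _BAND_RE.match(text)
        if m is None:
            raise ValueError(f"cannot parse band locus: {text!r}")
        return cls(m.group("chrom"), m.group("arm"), m.group("band"))

    @property
    def is_centromeric(self) -> bool:
        return self.band == "10"

    def __str__(self) -> str:
        return f"{self.chromosome}{self.arm}{self.band}"


class CytobandModel:
    """Ordered band ladders per chromosome (pter -> qter).

    Band order on the p arm runs from high band numbers down to ``p10``
    at the centromere, then ``q10`` up to qter on the q arm, mirroring
    the physical layout encoded in UCSC cytoband tables.
    """

    def __init__(self, ladders: dict[str, list[CytoBand]]):
        self._ladders = ladders
        self._index: dict[str, dict[tuple[str, str], int]] = {
            chrom: {(b.arm, b.band): i for i, b in enumerate(bands)}
            for chrom, bands in ladders.items()
        }

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._ladders, key=chromosome_sort_key)

    def bands(self, chrom: str) -> list[CytoBand]:
        return list(self._ladders[chrom])

    def position(self, band: CytoBand) -> int:
        """Rank of the band on its chromosome's pter->qter ladder."""
        try:
            return self._index[band.chromosome][(band.arm, band.band)]
        except KeyError:
            raise KeyError(
                f"band {band} not present in the cytoband model"
            ) from None

    def interval(self, start: CytoBand, end: CytoBand) -> list[CytoBand]:
        """Inclusive band range between two bands of the same chromosome."""
        if start.chromosome != end.chromosome:
            raise ValueError("interval endpoints on different chromosomes")
        i, j = self.position(start), self.position(end)
        if i > j:
            i, j = j, i
        return self._ladders[start.chromosome][i : j + 1]

    def spans_centromere(self, start: CytoBand, end: CytoBand) -> bool:
        """True iff the inclusive band interval touches both arms."""
        arms = {b.arm for b in self.interval(start, end)}
        return arms == {"p", "q"}

    @classmethod
    def from_ucsc(cls, path: str) -> "CytobandModel":
        """Load from a UCSC-style cytoband TSV (chrom, start, end, name, stain).

        Sub-bands are truncated to band level and consecutive duplicates
        collapsed, preserving the file's pter->qter order.  ``p10``/``q10``
        centromeric bands are inserted if the file lacks them (UCSC tables
        mark the centromere with 'acen' stained sub-bands named p11/q11).
        """
        ladders: dict[str, list[CytoBand]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                chrom = fields[0].removeprefix("chr")
                if chrom not in _CHROM_ORDER:
                    continue
                name = fields[3]
                band = CytoBand(chrom, name[0], name[1:])
                ladder = ladders.setdefault(chrom, [])
                if not ladder or ladder[-1] != band:
                    ladder.append(band)
        for chrom, ladder in ladders.items():
            if not any(b.is_centromeric for b in ladder):
                k = next(i for i, b in enumerate(ladder) if b.arm == "q")
                ladder[k:k] = [CytoBand(chrom, "p", "10"), CytoBand(chrom, "q", "10")]
        return cls(ladders)


def default_cytoband_model() -> CytobandModel:
    """A synthetic band-level ladder for all 24 chromosomes.

    Each chromosome gets p bands 15..11 plus p10, then q10 and q bands
    11..15, 21..26.  Only arm membership and pter->qter order are ever
    consumed by the callers (centromere-spanning tests), so a uniform
    synthetic ladder is sufficient and keeps the package self-contained.
    """
    ladders: dict[str, list[CytoBand]] = {}
    p_names = ["15", "14", "13", "12", "11", "10"]
    q_names = ["10", "11", "12", "13", "14", "15", "21", "22", "23", "24", "25", "26"]
    for chrom in CHROMOSOMES:
        ladders[chrom] = [CytoBand(chrom, "p", b) for b in p_names] + [
            CytoBand(chrom, "q", b) for b in q_names
        ]
    return CytobandModel(ladders)
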