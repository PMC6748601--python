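"""IMGT coordinate system for antibody variable domains.

The IMGT unique numbering assigns every variable-domain residue a position in
1..128; loops longer than the allotted range carry insertion letters around
the CDR3 apex (positions 111/112).  The junction reading order is

    ... 110, 111, 111A, 111B, ..., 112B, 112A, 112, 113 ...

i.e. insertions ascend after 111 but *descend* into 112, so that residues are
added symmetrically from both ends of the loop.  :class:`ImgtPosition`
implements that total order; :class:`RegionScheme` carries the CDR/framework
boundaries and drives region extraction.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .io import NumberedChain

__all__ = [
    "ImgtPosition",
    "RegionScheme",
    "IMGT_SCHEME",
    "compare",
    "extract_cdrs",
    "junction_positions",
]


@functools.total_ordering
@dataclass(frozen=True)
class ImgtPosition:
    """A numeric IMGT position with an optional insertion letter.

    Positions order by number; within one number, insertion codes ascend
    after the bare position everywhere except at 112, where they descend and
    precede it (the IMGT CDR3 symmetric-gap convention).
    """

    number: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.number <= 128):
            raise ValueError(f"IMGT position number out of range 1-128: {self.number}")
        if self.insertion and not (
            len(self.insertion) == 1 and "A" <= self.insertion <= "Z"
        ):
            raise ValueError(f"insertion code must be a single A-Z letter: {self.insertion!r}")

    @classmethod
    def parse(cls, text: str) -> "ImgtPosition":
        """Parse ``"111"`` or ``"111A"`` into a position."""
        text = text.strip()
        if text and text[-1].isalpha():
            return cls(int(text[:-1]), text[-1].upper())
        return cls(int(text))

    @property
    def sort_key(self) -> tuple[int, int, int]:
        # At 112 insertions come first, in reverse alphabetical order.
        if self.number == 112:
            if self.insertion:
                return (112, 0, 255 - ord(self.insertion))
            return (112, 1, 0)
        if self.insertion:
            return (self.number, 1, ord(self.insertion))
        return (self.number, 0, 0)

    def __lt__(self, other: "ImgtPosition") -> bool:
        if not isinstance(other, ImgtPosition):
            return NotImplemented
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return f"{self.number}{self.insertion}"

    def __repr__(self) -> str:
        return f"ImgtPosition({self})"


def compare(a: ImgtPosition, b: ImgtPosition) -> int:
    """Three-way comparison under the IMGT total order (-1, 0 or +1)."""
    if a.sort_key < b.sort_key:
        return -1
    if a.sort_key > b.sort_key:
        return 1
    return 0


@dataclass(frozen=True)
class RegionScheme:
    """CDR boundaries (inclusive IMGT position ranges); frameworks are the
    complement.  Defaults follow the IMGT standard definition."""

    cdr1: tuple[int, int] = (27, 38)
    cdr2: tuple[int, int] = (56, 65)
    cdr3: tuple[int, int] = (105, 117)

    def __post_init__(self) -> None:
        ranges = [self.cdr1, self.cdr2, self.cdr3]
        for lo, hi in ranges:
            if lo > hi:
                raise ValueError(f"empty CDR range {lo}-{hi}")
        for (_, hi), (lo, _) in zip(ranges, ranges[1:]):
            if hi >= lo:
                raise ValueError("CDR ranges must be disjoint and ordered")

    def region_of(self, pos: ImgtPosition) -> str:
        """Map a position to one of fw1, cdr1, fw2, cdr2, fw3, cdr3, fw4."""
        n = pos.number
        if n < self.cdr1[0]:
            return "fw1"
        if n <= self.cdr1[1]:
            return "cdr1"
        if n < self.cdr2[0]:
            return "fw2"
        if n <= self.cdr2[1]:
            return "cdr2"
        if n < self.cdr3[0]:
            return "fw3"
        if n <= self.cdr3[1]:
            return "cdr3"
        return "fw4"

    @property
    def region_names(self) -> tuple[str, ...]:
        return ("fw1", "cdr1", "fw2", "cdr2", "fw3", "cdr3", "fw4")


IMGT_SCHEME = RegionScheme()


def extract_cdrs(
    chain: "NumberedChain | Mapping[ImgtPosition, str]",
    scheme: RegionScheme = IMGT_SCHEME,
) -> tuple[str, str, str]:
    """Return (cdr1, cdr2, cdr3) residue strings in IMGT reading order.

    Accepts a :class:`~abmatch.io.NumberedChain` or a bare position->residue
    mapping; keys are re-sorted, so input ordering never matters.
    """
    residues = getattr(chain, "residues", chain)
    parts: dict[str, list[str]] = {"cdr1": [], "cdr2": [], "cdr3": []}
    for pos in sorted(residues, key=lambda p: p.sort_key):
        region = scheme.region_of(pos)
        if region in parts:
            parts[region].append(residues[pos])
    return ("".join(parts["cdr1"]), "".join(parts["cdr2"]), "".join(parts["cdr3"]))


def extract_regions(
    chain: "NumberedChain | Mapping[ImgtPosition, str]",
    scheme: RegionScheme = IMGT_SCHEME,
) -> dict[str, str]:
    """Split a chain into all seven regions (fw1..fw4, cdr1..cdr3)."""
    residues = getattr(chain, "residues", chain)
    out: dict[str, list[str]] = {name: [] for name in scheme.region_names}
    for pos in sorted(residues, key=lambda p: p.sort_key):
        out[scheme.region_of(pos)].append(residues[pos])
    return {name: "".join(chars) for name, chars in out.items()}


@functools.lru_cache(maxsize=64)
def junction_positions(length: int) -> tuple[ImgtPosition, ...]:
    """IMGT positions occupied by a CDR3 of the given length, in reading order.

    The CDR3 range 105-117 holds 13 positions.  Shorter loops vacate the apex
    symmetrically (the left arm 105-111 keeps one more residue when the length
    is odd); longer loops insert 112A, 111A, 112B, 111B, ... alternating,
    starting on the 112 side.
    """
    if length < 1:
        raise ValueError("CDR3 length must be >= 1")
    left = [ImgtPosition(n) for n in range(105, 112)]   # 105..111
    right = [ImgtPosition(n) for n in range(112, 118)]  # 112..117
    if length <= 13:
        n_left = (length + 1) // 2
        n_right = length // 2
        return tuple(left[:n_left] + right[len(right) - n_right:])
    extra = length - 13
    ins_112 = (extra + 1) // 2
    ins_111 = extra // 2
    mid = [ImgtPosition(111, chr(ord("A") + i)) for i in range(ins_111)]
    mid += [ImgtPosition(112, chr(ord("A") + i)) for i in reversed(range(ins_112))]
    return tuple(left + mid + right)


def sort_positions(positions: Iterable[ImgtPosition]) -> list[ImgtPosition]:
    """Stable sort under the IMGT total order."""
    return sorted(positions, key=lambda p: p.sort_key)
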