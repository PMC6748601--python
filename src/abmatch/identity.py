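"""Sequence-identity metrics over IMGT-numbered antibody chains.

The metric counts a match wherever an IMGT position is occupied in both the
query and the template with the same residue, then averages the two
normalisations m/Lq and m/Lt (lengths = occupied-position counts).  Averaging
both directions penalises substring relationships: a query that is a perfect
prefix of a longer template scores (1 + Lq/Lt)/2 < 1 rather than 1.

No similarity matrix and no gapped alignment are involved — the shared IMGT
coordinate system *is* the alignment, and the measure is identity, not
similarity.  The unknown-residue placeholder 'X' never scores a match, not
even against another 'X' (conservative: an unread residue is never evidence
of convergence).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from fractions import Fraction
from typing import Optional

from .io import NumberedChain


class Mode(str, Enum):
    """The three comparison modes."""

    FULL_CHAIN = "full_chain"
    CDR_TRIPLET = "cdr_triplet"
    CDRH3 = "cdrh3"


@dataclass(frozen=True)
class IdentityScore:
    """Outcome of one pairwise comparison.

    ``value`` is exactly (m/Lq + m/Lt)/2; the integer counts are retained so
    exact arithmetic (tie-breaking, display rounding) never goes through
    floating point.
    """

    value: float
    matches: int
    len_query: int
    len_template: int
    mode: Mode

    def __post_init__(self) -> None:
        if self.len_query < 1 or self.len_template < 1:
            raise ValueError("lengths must be >= 1")
        if not (0 <= self.matches <= min(self.len_query, self.len_template)):
            raise ValueError("matches out of range")

    @classmethod
    def from_counts(
        cls, matches: int, len_query: int, len_template: int, mode: Mode
    ) -> "IdentityScore":
        if len_query < 1 or len_template < 1:
            raise ValueError("lengths must be >= 1")
        value = (matches / len_query + matches / len_template) / 2
        return cls(value, matches, len_query, len_template, mode)

    @property
    def exact(self) -> Fraction:
        """The score as an exact rational number."""
        return (
            Fraction(self.matches, self.len_query)
            + Fraction(self.matches, self.len_template)
        ) / 2


def positional_identity(query: NumberedChain, template: NumberedChain) -> IdentityScore:
    """Symmetric full-chain identity over shared IMGT positions.

    Symmetric in its arguments; both chains must be non-empty and of the
    same chain type.
    """
    if query.chain != template.chain:
        raise ValueError(
            f"chain-type mismatch: {query.chain.value} vs {template.chain.value}"
        )
    q, t = query.residues, template.residues
    if not q or not t:
        raise ValueError("empty chain")
    # iterate the smaller map for speed; the count is symmetric
    if len(q) > len(t):
        q, t = t, q
    m = sum(1 for pos, aa in q.items() if aa != "X" and t.get(pos) == aa)
    return IdentityScore.from_counts(m, len(query), len(template), Mode.FULL_CHAIN)


def _string_identity(q: str, t: str, mode: Mode) -> IdentityScore:
    m = sum(1 for a, b in zip(q, t) if a == b and a != "X")
    return IdentityScore.from_counts(m, len(q), len(t), mode)


def cdr_triplet_identity(
    query_cdrs: tuple[str, str, str], template_cdrs: tuple[str, str, str]
) -> Optional[IdentityScore]:
    """Identity over concatenated CDR1+2+3, or None when not comparable.

    Comparable only when all three loop lengths match; with equal lengths the
    position-wise count reduces to a character-wise one over the
    concatenation.
    """
    if any(len(a) != len(b) for a, b in zip(query_cdrs, template_cdrs)):
        return None
    q = "".join(query_cdrs)
    t = "".join(template_cdrs)
    if not q:
        return None
    return _string_identity(q, t, Mode.CDR_TRIPLET)


def cdrh3_identity(query_cdrh3: str, template_cdrh3: str) -> Optional[IdentityScore]:
    """CDR-H3 identity, or None when loop lengths differ.

    A value of 1.0 is a perfect match."""
    if len(query_cdrh3) != len(template_cdrh3) or not query_cdrh3:
        return None
    return _string_identity(query_cdrh3, template_cdrh3, Mode.CDRH3)


def percent_display(score: "IdentityScore | float") -> int:
    """Integer percent, rounded half-up (0.975 -> 98), monotone in value.

    Given a full score the rounding is done on the exact fraction; bare
    floats go through their shortest decimal representation first so that
    binary representation error cannot flip a .5 boundary."""
    if isinstance(score, IdentityScore):
        pct = score.exact * 100
        # floor(pct + 1/2) = half-up for non-negative rationals
        return int(pct + Fraction(1, 2))
    d = Decimal(repr(float(score))) * 100
    return int(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
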