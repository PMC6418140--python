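"""Hairpin secondary-structure geometry.

Parses dot-bracket structures into pair tables and derives the duplex
quantities (mismatches, asymmetric bulges, 3' overhangs, paired fractions)
that the confidence rules are judged on.

Coordinates are 0-based, half-open, always 5'->3' on the precursor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .errors import (
    InvalidDuplexError,
    NotADuplexError,
    StructureFormatError,
    TruncatedPrecursorError,
)

_RNA_ALPHABET = frozenset("ACGU")

MIN_MATURE_LEN = 18
MAX_MATURE_LEN = 30


@dataclass(frozen=True)
class Interval:
    """Half-open interval [start, end) on precursor coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def expanded(self, up: int, down: int, limit: int | None = None) -> "Interval":
        """Windowed interval: `up` nt toward 5', `down` nt toward 3'."""
        start = max(0, self.start - up)
        end = self.end + down
        if limit is not None:
            end = min(end, limit)
        return Interval(start, end)


@dataclass(frozen=True)
class Precursor:
    """Candidate hairpin precursor with externally computed structure/MFE."""

    id: str
    sequence: str
    structure: str
    mfe: float
    n_genome_hits: int = 1

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(self.sequence) != len(self.structure):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"structure length {len(self.structure)}"
            )
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-RNA characters {sorted(bad)}")
        if self.mfe > 0:
            raise ValueError(f"{self.id}: mfe must be <= 0, got {self.mfe}")
        if self.n_genome_hits < 1:
            raise ValueError(f"{self.id}: n_genome_hits must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DuplexProfile:
    """Geometry of the mature/star duplex.

    ``mismatches`` counts opposed unpaired bases (the symmetric part of each
    internal loop, min(a, b)); the asymmetric remainder |a - b| is recorded
    as one bulge on the longer strand.  3' overhang unpaired ends are
    excluded from mismatch/bulge accounting.
    """

    mismatches: int
    bulges: Tuple[Tuple[str, int], ...]
    overhang_mature_3p: int
    overhang_star_3p: int
    paired_fraction_mature: float
    paired_fraction_star: float


def parse_dotbracket(structure: str) -> List[int]:
    """Parse a dot-bracket string into a pair table.

    Returns ``partner`` with ``partner[i]`` the paired index of position
    ``i`` or -1 when unpaired.

    Raises
    ------
    StructureFormatError
        On an illegal character (at its index) or unbalanced brackets (at
        the index of the unmatched bracket).
    """
    partner = [-1] * len(structure)
    stack: List[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureFormatError("unmatched ')'", i)
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        elif ch != ".":
            raise StructureFormatError(f"illegal character {ch!r}", i)
    if stack:
        raise StructureFormatError("unclosed '('", stack[0])
    return partner


def _nearest_paired(partner: Sequence[int], pos: int, step: int, lo: int, hi: int) -> int:
    """Scan from pos in direction `step` (within [lo, hi)) to a paired base."""
    i = pos
    while lo <= i < hi:
        if partner[i] != -1:
            return i
        i += step
    raise NotADuplexError(f"no paired base inward of position {pos}")


def infer_star_coords(partner: Sequence[int], mature: Interval) -> Interval:
    """Infer the star interval from a canonical 2-nt 3'-overhang duplex.

    star.start is the partner of mature position ``end - 3`` and star.end
    is the partner of ``mature.start`` plus 3 (the star's own 2-nt 3'
    overhang); when a referenced base is unpaired the nearest paired base
    toward the stem interior stands in for it.  The formula is symmetric:
    it holds whether the mature sits on the 5' or the 3' arm.
    """
    n = len(partner)
    if mature.end > n:
        raise TruncatedPrecursorError(
            f"mature interval {mature} exceeds precursor length {n}"
        )
    # mature must sit on a single arm: no position may pair inside mature
    for i in range(mature.start, mature.end):
        j = partner[i]
        if j != -1 and mature.start <= j < mature.end:
            raise NotADuplexError(
                f"mature interval {mature} spans the loop (position {i} "
                f"pairs with {j} inside the interval)"
            )
    _arm_is_five_prime(partner, mature)  # raises if mature has no pairs
    a_3p = _nearest_paired(partner, mature.end - 3, -1, mature.start, mature.end)
    a_5p = _nearest_paired(partner, mature.start, +1, mature.start, mature.end)
    star_start = partner[a_3p]
    star_end = partner[a_5p] + 3
    if star_start < 0 or star_end > n:
        raise TruncatedPrecursorError(
            f"star interval [{star_start}, {star_end}) exceeds precursor bounds"
        )
    if star_start >= star_end:
        raise NotADuplexError("degenerate star interval")
    star = Interval(star_start, star_end)
    if star.overlaps(mature):
        raise NotADuplexError("inferred star overlaps mature (loop-spanning duplex)")
    return star


def _arm_is_five_prime(partner: Sequence[int], mature: Interval) -> bool:
    """True when the mature interval lies on the 5' arm (partners are 3')."""
    for i in range(mature.start, mature.end):
        if partner[i] != -1:
            return partner[i] > i
    raise NotADuplexError(f"mature interval {mature} has no paired bases")


def duplex_profile(
    partner: Sequence[int],
    sequence: str,
    mature: Interval,
    star: Interval,
) -> DuplexProfile:
    """Compute mismatch/bulge/overhang geometry of a mature:star duplex.

    Walks consecutive paired mature positions; in each gap the opposed
    unpaired counts (a on mature, b on star) contribute min(a, b)
    mismatches and, when asymmetric, one bulge of size |a - b| on the
    longer strand.
    """
    if mature.overlaps(star):
        raise InvalidDuplexError(f"mature {mature} and star {star} overlap")
    paired_mature = [
        i
        for i in range(mature.start, mature.end)
        if partner[i] != -1 and star.start <= partner[i] < star.end
    ]
    if not paired_mature:
        raise InvalidDuplexError("no mature position pairs into the star interval")

    mismatches = 0
    bulges: List[Tuple[str, int]] = []
    for prev, cur in zip(paired_mature, paired_mature[1:]):
        a = cur - prev - 1  # unpaired mature bases in the gap
        b = partner[prev] - partner[cur] - 1  # opposing star bases
        mismatches += min(a, b)
        if a != b:
            arm = "mature" if a > b else "star"
            bulges.append((arm, abs(a - b)))

    overhang_mature = (mature.end - 1) - paired_mature[-1]
    overhang_star = (star.end - 1) - partner[paired_mature[0]]
    n_paired = len(paired_mature)
    return DuplexProfile(
        mismatches=mismatches,
        bulges=tuple(bulges),
        overhang_mature_3p=overhang_mature,
        overhang_star_3p=overhang_star,
        paired_fraction_mature=n_paired / len(mature),
        paired_fraction_star=n_paired / len(star),
    )


def mfe_per_nt(precursor: Precursor) -> float:
    """Folding free energy per nucleotide (kcal/mol/nt)."""
    return precursor.mfe / len(precursor)
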