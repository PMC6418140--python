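"""Read-stack evidence metrics.

Everything the confidence rules need from the aligned small-RNA reads:
exact arm counts, excision fraction, 5' homogeneity, library detection and
arm dominance.  A read belongs to an arm iff its full span lies within the
arm interval extended by ``window_up`` nt at the 5' side and
``window_down`` nt at the 3' side; reads contained in both windowed arms
are assigned to the mature arm.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import UndefinedEvidenceError
from .hairpin import Interval

DEFAULT_WINDOW_UP = 2
DEFAULT_WINDOW_DOWN = 5


@dataclass(frozen=True)
class AlignedRead:
    """A distinct read aligned to a precursor, with its collapsed count."""

    sequence: str
    start: int
    count: int
    library_id: str
    mismatch_positions: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"read count must be >= 1, got {self.count}")
        object.__setattr__(
            self, "sequence", self.sequence.upper().replace("T", "U")
        )
        object.__setattr__(
            self, "mismatch_positions", tuple(sorted(self.mismatch_positions))
        )

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def is_exact(self) -> bool:
        return not self.mismatch_positions


@dataclass
class ReadStack:
    """All aligned reads on one precursor, across libraries."""

    precursor_id: str
    reads: List[AlignedRead] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.reads)

    @property
    def library_ids(self) -> List[str]:
        return sorted({r.library_id for r in self.reads})

    def with_mismatches_computed(self, precursor_sequence: str) -> "ReadStack":
        """Recompute mismatch positions of every read against the precursor."""
        reads = []
        for r in self.reads:
            mm = mismatches_to_precursor(r, precursor_sequence)
            reads.append(
                AlignedRead(r.sequence, r.start, r.count, r.library_id, tuple(mm))
            )
        return ReadStack(self.precursor_id, reads)


def mismatches_to_precursor(read: AlignedRead, precursor_sequence: str) -> List[int]:
    """Read-relative positions where the read differs from the precursor.

    Positions hanging off the precursor end count as mismatches.
    """
    out = []
    for i, base in enumerate(read.sequence):
        pos = read.start + i
        if pos >= len(precursor_sequence) or precursor_sequence[pos] != base:
            out.append(i)
    return out


@dataclass(frozen=True)
class EvidenceSummary:
    """Aggregated read-stack evidence for one mature/star assignment."""

    arm_exact_reads_mature: int
    arm_exact_reads_star: int
    excision_fraction: float
    five_prime_homogeneity_mature: Optional[float]
    five_prime_homogeneity_star: Optional[float]
    libraries_detected: int
    dominance: float


def _on_arm(read: AlignedRead, windowed: Interval) -> bool:
    return windowed.contains(read.start, read.end)


def assign_arm(
    read: AlignedRead,
    mature_w: Interval,
    star_w: Optional[Interval],
) -> Optional[str]:
    """'mature' / 'star' / None; mature wins when both windows contain."""
    if _on_arm(read, mature_w):
        return "mature"
    if star_w is not None and _on_arm(read, star_w):
        return "star"
    return None


def arm_exact_counts(
    stack: ReadStack, mature: Interval, star: Optional[Interval]
) -> Tuple[int, int]:
    """Counts of mismatch-free reads starting exactly at each arm's 5' end
    and fully contained in the arm interval."""
    m = s = 0
    for r in stack.reads:
        if not r.is_exact:
            continue
        if r.start == mature.start and mature.contains(r.start, r.end):
            m += r.count
        elif star is not None and r.start == star.start and star.contains(r.start, r.end):
            s += r.count
    return m, s


def excision_fraction(
    stack: ReadStack,
    mature: Interval,
    star: Optional[Interval],
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> float:
    """Fraction of read counts falling inside the windowed mature or star."""
    total = stack.total_count
    if total == 0:
        raise UndefinedEvidenceError(f"{stack.precursor_id}: no reads")
    mature_w = mature.expanded(window_up, window_down)
    star_w = star.expanded(window_up, window_down) if star is not None else None
    inside = sum(
        r.count for r in stack.reads if assign_arm(r, mature_w, star_w) is not None
    )
    return inside / total


def five_prime_homogeneity(
    stack: ReadStack,
    arm: Interval,
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> float:
    """Fraction of windowed-arm counts sharing the modal 5' start.

    Modal-start ties break to the leftmost (5'-most) start.  Raises
    :class:`UndefinedEvidenceError` when no read is assigned to the arm.
    """
    arm_w = arm.expanded(window_up, window_down)
    starts: Counter = Counter()
    for r in stack.reads:
        if _on_arm(r, arm_w):
            starts[r.start] += r.count
    if not starts:
        raise UndefinedEvidenceError("no reads assigned to arm")
    total = sum(starts.values())
    best = max(starts.values())
    modal = min(s for s, c in starts.items() if c == best)
    return starts[modal] / total


def libraries_detected(
    stack: ReadStack,
    mature: Interval,
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> int:
    """Number of distinct libraries with >= 1 windowed mature-arm read."""
    mature_w = mature.expanded(window_up, window_down)
    return len({r.library_id for r in stack.reads if _on_arm(r, mature_w)})


def dominance(
    stack: ReadStack,
    mature: Interval,
    star: Optional[Interval],
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> float:
    """Mature-arm counts over total counts."""
    total = stack.total_count
    if total == 0:
        raise UndefinedEvidenceError(f"{stack.precursor_id}: no reads")
    mature_w = mature.expanded(window_up, window_down)
    star_w = star.expanded(window_up, window_down) if star is not None else None
    m = sum(r.count for r in stack.reads if assign_arm(r, mature_w, star_w) == "mature")
    return m / total


def summarize_evidence(
    stack: ReadStack,
    mature: Interval,
    star: Optional[Interval],
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
) -> EvidenceSummary:
    """Compute the full evidence summary the classifier consumes.

    Metrics that are undefined on an empty arm come back as None (the
    classifier treats them as rule failures rather than pipeline errors).
    """
    exact_m, exact_s = arm_exact_counts(stack, mature, star)
    try:
        exc = excision_fraction(stack, mature, star, window_up, window_down)
        dom = dominance(stack, mature, star, window_up, window_down)
    except UndefinedEvidenceError:
        exc = 0.0
        dom = 0.0
    try:
        homo_m: Optional[float] = five_prime_homogeneity(
            stack, mature, window_up, window_down
        )
    except UndefinedEvidenceError:
        homo_m = None
    homo_s: Optional[float] = None
    if star is not None:
        try:
            homo_s = five_prime_homogeneity(stack, star, window_up, window_down)
        except UndefinedEvidenceError:
            homo_s = None
    return EvidenceSummary(
        arm_exact_reads_mature=exact_m,
        arm_exact_reads_star=exact_s,
        excision_fraction=exc,
        five_prime_homogeneity_mature=homo_m,
        five_prime_homogeneity_star=homo_s,
        libraries_detected=libraries_detected(stack, mature, window_up, window_down),
        dominance=dom,
    )
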