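"""Conserved/novel assignment and isomiR calling.

Conservation is decided by ungapped mismatch distance to a known mature
set (<= 2 mismatches = conserved); novel matures are clustered into
families by single-linkage at the same distance.  isomiRs are read-level
variants of a mature/star reference: 5' shifts up to 4 nt, at most one
internal mismatch, retained when abundant enough relative to their
reference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import UndefinedReferenceError
from .evidence import AlignedRead, ReadStack
from .hairpin import Interval, Precursor

INF = float("inf")

ISOMIR_TYPES = (
    "5p_deletion",
    "5p_extension",
    "3p_deletion",
    "3p_extension",
    "3p_nontemplated",
    "polymorphic",
)


@dataclass(frozen=True)
class ConservationCall:
    status: str  # "conserved" | "novel"
    best_match_id: Optional[str]
    mismatches: Optional[int]
    family: Optional[str] = None


@dataclass(frozen=True)
class IsomiR:
    sequence: str
    start: int
    count: int
    reference: str  # "mature" | "star"
    shift5p: int
    type: str
    secondary_3p: Optional[str]
    seed_polymorphic: bool
    abundance_fraction: float


def mature_distance(a: str, b: str, max_slide: int = 2) -> float:
    """Ungapped mismatch distance between two mature sequences.

    Equal lengths compare position-wise.  Lengths differing by up to
    ``max_slide`` nt slide the shorter sequence along the longer one, and
    the overhanging bases count as mismatches.  Larger length differences
    are incomparable (infinite distance).  Symmetric by construction.
    """
    a, b = a.upper().replace("T", "U"), b.upper().replace("T", "U")
    if len(a) > len(b):
        a, b = b, a
    diff = len(b) - len(a)
    if diff > max_slide:
        return INF
    best = INF
    for off in range(diff + 1):
        mm = diff + sum(1 for i, ch in enumerate(a) if ch != b[off + i])
        best = min(best, mm)
    return best


def match_known(
    mature_seq: str,
    known: Sequence[Tuple[str, str]],
    max_mm: int = 2,
) -> ConservationCall:
    """Best ungapped match against the known mature set.

    Ties break to the first id in input order; an empty known set yields a
    novel call.
    """
    best_id: Optional[str] = None
    best_mm = INF
    for kid, kseq in known:
        d = mature_distance(mature_seq, kseq)
        if d < best_mm:
            best_mm, best_id = d, kid
    if best_id is not None and best_mm <= max_mm:
        return ConservationCall("conserved", best_id, int(best_mm))
    return ConservationCall("novel", None, None)


_FAMILY_RE = re.compile(r"mir[-]?(\d+)", re.IGNORECASE)


def family_from_name(known_id: str) -> str:
    """miRBase-style name token to family, e.g. 'ath-miR156a' -> 'MIR156'."""
    m = _FAMILY_RE.search(known_id)
    if m:
        return f"MIR{m.group(1)}"
    return known_id


def assign_families(
    ids: Sequence[str],
    sequences: Sequence[str],
    calls: Sequence[ConservationCall],
    abundances: Sequence[float],
    species_prefix: str = "Jcu",
    max_mm: int = 2,
) -> List[ConservationCall]:
    """Attach family names to conservation calls.

    Conserved matures inherit the known family; novel matures are grouped
    by single-linkage clustering at mismatch distance <= ``max_mm``, and
    families are numbered by descending total abundance (ties by the
    lexicographically smallest member sequence).
    """
    out: List[Optional[ConservationCall]] = [None] * len(calls)
    novel_idx = []
    for i, call in enumerate(calls):
        if call.status == "conserved":
            fam = f"{species_prefix}-{family_from_name(call.best_match_id)}"
            out[i] = ConservationCall(call.status, call.best_match_id, call.mismatches, fam)
        else:
            novel_idx.append(i)

    # union-find single-linkage over pairwise distances
    parent = {i: i for i in novel_idx}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ai in range(len(novel_idx)):
        for bi in range(ai + 1, len(novel_idx)):
            i, j = novel_idx[ai], novel_idx[bi]
            if mature_distance(sequences[i], sequences[j]) <= max_mm:
                parent[find(i)] = find(j)

    clusters: Dict[int, List[int]] = {}
    for i in novel_idx:
        clusters.setdefault(find(i), []).append(i)
    ordered = sorted(
        clusters.values(),
        key=lambda members: (
            -sum(abundances[i] for i in members),
            min(sequences[i] for i in members),
        ),
    )
    for rank, members in enumerate(ordered, start=1):
        fam = f"{species_prefix}-nMIR{rank:03d}"
        for i in members:
            call = calls[i]
            out[i] = ConservationCall(call.status, call.best_match_id, call.mismatches, fam)
    return [c for c in out if c is not None]


def _internal_mismatches(
    read_seq: str, start: int, precursor_seq: str
) -> Tuple[List[int], int]:
    """(internal mismatch positions, number of trailing 3' mismatches).

    A maximal run of mismatches at the read's 3' end is treated as a
    nontemplated addition, not as internal mismatches.
    """
    mm = []
    for i, base in enumerate(read_seq):
        pos = start + i
        if pos >= len(precursor_seq) or precursor_seq[pos] != base:
            mm.append(i)
    trailing = 0
    n = len(read_seq)
    while mm and mm[-1] == n - 1 - trailing:
        mm.pop()
        trailing += 1
    return mm, trailing


def call_isomirs(
    stack: ReadStack,
    precursor: Precursor,
    mature: Interval,
    star: Optional[Interval] = None,
    min_count: int = 100,
    max_shift: int = 4,
    min_frac: float = 0.5,
    min_reads: int = 10000,
    min_len: int = 18,
    max_len: int = 26,
) -> List[IsomiR]:
    """Detect and type isomiRs on one precursor.

    Candidate reads (pooled across libraries) must differ from the
    mature/star reference, carry at most one internal mismatch, fall in
    the 18-26 nt range, start within ``max_shift`` nt of a reference 5'
    end, and total at least ``min_count`` reads.  A candidate is retained
    when its count reaches ``min_frac`` of its reference count or exceeds
    ``min_reads``.  Typing is 5'-first; a concurrent 3' difference is kept
    as a secondary tag.
    """
    seq = precursor.sequence
    refs: Dict[str, Tuple[int, int, str]] = {
        "mature": (mature.start, mature.end, seq[mature.start : mature.end])
    }
    if star is not None:
        refs["star"] = (star.start, star.end, seq[star.start : star.end])

    # pool counts per distinct (sequence, start)
    pooled: Dict[Tuple[str, int], int] = {}
    for r in stack.reads:
        key = (r.sequence, r.start)
        pooled[key] = pooled.get(key, 0) + r.count

    ref_counts = {
        name: pooled.get((rseq, rstart), 0)
        for name, (rstart, _rend, rseq) in refs.items()
    }

    out: List[IsomiR] = []
    for (rseq, rstart), count in sorted(pooled.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if not (min_len <= len(rseq) <= max_len):
            continue
        if any(rseq == ref[2] and rstart == ref[0] for ref in refs.values()):
            continue  # the reference itself
        internal_mm, trailing = _internal_mismatches(rseq, rstart, seq)
        if len(internal_mm) > 1:
            continue
        # nearest reference arm by |5' shift|, ties to mature
        best_ref, best_shift = None, None
        for name in ("mature", "star"):
            if name not in refs:
                continue
            shift = rstart - refs[name][0]
            if abs(shift) <= max_shift and (
                best_shift is None or abs(shift) < abs(best_shift)
            ):
                best_ref, best_shift = name, shift
        if best_ref is None:
            continue
        if count < min_count:
            continue
        ref_count = ref_counts[best_ref]
        if ref_count == 0:
            raise UndefinedReferenceError(
                f"{stack.precursor_id}: reference {best_ref} has zero exact reads"
            )
        if not (count >= min_frac * ref_count or count > min_reads):
            continue
        ref_end = refs[best_ref][1]
        read_end = rstart + len(rseq)
        three_p = _type_3p(read_end, ref_end, trailing)
        if best_shift != 0:
            itype = "5p_deletion" if best_shift > 0 else "5p_extension"
            secondary = three_p
        elif three_p is not None:
            itype, secondary = three_p, None
        elif internal_mm:
            itype, secondary = "polymorphic", None
        else:
            continue  # same ends, templated, no mismatch: identical to ref
        seed_poly = any(1 <= i <= 8 for i in internal_mm)  # read pos 2-9, 1-based
        out.append(
            IsomiR(
                sequence=rseq,
                start=rstart,
                count=count,
                reference=best_ref,
                shift5p=best_shift,
                type=itype,
                secondary_3p=secondary,
                seed_polymorphic=seed_poly,
                abundance_fraction=count / ref_count,
            )
        )
    return out


def _type_3p(read_end: int, ref_end: int, trailing_mm: int) -> Optional[str]:
    if trailing_mm > 0:
        return "3p_nontemplated"
    if read_end > ref_end:
        return "3p_extension"
    if read_end < ref_end:
        return "3p_deletion"
    return None
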