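"""Independent brute-force reference implementations used by the tests.

These deliberately re-derive each quantity with a different algorithm
than the package (innermost-pair elimination instead of a stack,
per-read predicate loops instead of pooled counters, textbook step-up
instead of vectorized BH) so the two routes can be compared.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple


# -- dot-bracket ------------------------------------------------------------

def parse_dotbracket_oracle(structure: str) -> List[int]:
    """Innermost-pair elimination: repeatedly pair a '(' directly followed
    (ignoring dots) by a ')'."""
    chars = list(structure)
    for i, ch in enumerate(chars):
        if ch not in "().":
            raise ValueError(f"illegal at {i}")
    partner = [-1] * len(chars)
    changed = True
    while changed:
        changed = False
        open_idx = None
        for i, ch in enumerate(chars):
            if ch == "(":
                open_idx = i
            elif ch == ")":
                if open_idx is None:
                    raise ValueError(f"unmatched at {i}")
                partner[open_idx] = i
                partner[i] = open_idx
                chars[open_idx] = chars[i] = "."
                changed = True
                break
    if "(" in chars or ")" in chars:
        raise ValueError("unbalanced")
    return partner


def enumerate_dotbrackets(max_len: int):
    """All valid dot-bracket strings of length <= max_len."""
    def rec(prefix: str, open_count: int, remaining: int):
        if open_count == 0:
            yield prefix
        if remaining == 0:
            return
        yield from rec(prefix + ".", open_count, remaining - 1)
        yield from rec(prefix + "(", open_count + 1, remaining - 1)
        if open_count > 0:
            yield from rec(prefix + ")", open_count - 1, remaining - 1)

    for s in rec("", 0, max_len):
        yield s


# -- duplex profile ---------------------------------------------------------

def duplex_profile_oracle(
    partner: Sequence[int],
    mature: Tuple[int, int],
    star: Tuple[int, int],
) -> dict:
    """Explicit alignment-column walk of the duplex.

    Builds the ladder of paired rungs, then counts, for every internal
    loop between rungs, the opposed unpaired runs on each strand.
    """
    ms, me = mature
    ss, se = star
    rungs = [
        (i, partner[i])
        for i in range(ms, me)
        if partner[i] != -1 and ss <= partner[i] < se
    ]
    assert rungs, "no duplex rungs"
    mismatches = 0
    bulges = []
    for (i1, j1), (i2, j2) in zip(rungs, rungs[1:]):
        gap_m = [k for k in range(i1 + 1, i2)]
        gap_s = [k for k in range(j2 + 1, j1)]
        a, b = len(gap_m), len(gap_s)
        mismatches += min(a, b)
        if a > b:
            bulges.append(("mature", a - b))
        elif b > a:
            bulges.append(("star", b - a))
    return {
        "mismatches": mismatches,
        "bulges": tuple(bulges),
        "overhang_mature_3p": (me - 1) - rungs[-1][0],
        "overhang_star_3p": (se - 1) - rungs[0][1],
        "paired_fraction_mature": len(rungs) / (me - ms),
        "paired_fraction_star": len(rungs) / (se - ss),
    }


# -- read-stack metrics -----------------------------------------------------

def _within(start: int, end: int, lo: int, hi: int) -> bool:
    return lo <= start and end <= hi


def stack_metrics_oracle(
    reads: List[Tuple[str, int, int, str, int]],
    mature: Tuple[int, int],
    star: Optional[Tuple[int, int]],
    window_up: int = 2,
    window_down: int = 5,
) -> dict:
    """Per-read predicate evaluation of every evidence metric.

    ``reads``: (sequence, start, count, library_id, n_mismatches).
    """
    ms, me = mature
    mw = (max(0, ms - window_up), me + window_down)
    sw = (max(0, star[0] - window_up), star[1] + window_down) if star else None
    total = sum(c for _s, _p, c, _l, _m in reads)
    exact_m = exact_s = 0
    on_m = on_s = 0
    m_starts: Dict[int, int] = {}
    s_starts: Dict[int, int] = {}
    libs = set()
    for seq, start, count, lib, n_mm in reads:
        end = start + len(seq)
        if n_mm == 0 and start == ms and _within(start, end, ms, me):
            exact_m += count
        if star and n_mm == 0 and start == star[0] and _within(start, end, *star):
            exact_s += count
        in_m = _within(start, end, *mw)
        in_s = sw is not None and _within(start, end, *sw)
        if in_m:
            on_m += count
            m_starts[start] = m_starts.get(start, 0) + count
            libs.add(lib)
        elif in_s:
            on_s += count
            s_starts[start] = s_starts.get(start, 0) + count

    def modal_frac(starts: Dict[int, int]) -> Optional[float]:
        if not starts:
            return None
        best = max(starts.values())
        modal = min(s for s, c in starts.items() if c == best)
        return starts[modal] / sum(starts.values())

    return {
        "arm_exact_mature": exact_m,
        "arm_exact_star": exact_s,
        "excision_fraction": (on_m + on_s) / total if total else None,
        "dominance": on_m / total if total else None,
        "homogeneity_mature": modal_frac(m_starts),
        "homogeneity_star": modal_frac(s_starts),
        "libraries_detected": len(libs),
    }


# -- isomiR predicate -------------------------------------------------------

def isomir_oracle(
    pooled_reads: Dict[Tuple[str, int], int],
    precursor_seq: str,
    mature: Tuple[int, int],
    star: Optional[Tuple[int, int]],
    min_count: int = 100,
    max_shift: int = 4,
    min_frac: float = 0.5,
    min_reads: int = 10000,
) -> Dict[Tuple[str, int], dict]:
    """Evaluate the retention + typing rules read by read."""
    refs = {"mature": mature}
    if star:
        refs["star"] = star
    ref_seq = {k: precursor_seq[v[0] : v[1]] for k, v in refs.items()}
    ref_count = {
        k: pooled_reads.get((ref_seq[k], refs[k][0]), 0) for k in refs
    }
    out = {}
    for (seq, start), count in pooled_reads.items():
        if not 18 <= len(seq) <= 26:
            continue
        if any(seq == ref_seq[k] and start == refs[k][0] for k in refs):
            continue
        mm = [
            i
            for i, b in enumerate(seq)
            if start + i >= len(precursor_seq) or precursor_seq[start + i] != b
        ]
        trailing = 0
        while mm and mm[-1] == len(seq) - 1 - trailing:
            mm.pop()
            trailing += 1
        if len(mm) > 1:
            continue
        best = None
        for name in ("mature", "star"):
            if name not in refs:
                continue
            shift = start - refs[name][0]
            if abs(shift) <= max_shift and (best is None or abs(shift) < abs(best[1])):
                best = (name, shift)
        if best is None or count < min_count:
            continue
        name, shift = best
        if ref_count[name] == 0:
            out[(seq, start)] = {"error": "undefined-reference"}
            continue
        if not (count >= min_frac * ref_count[name] or count > min_reads):
            continue
        ref_end = refs[name][1]
        end = start + len(seq)
        if trailing > 0:
            three = "3p_nontemplated"
        elif end > ref_end:
            three = "3p_extension"
        elif end < ref_end:
            three = "3p_deletion"
        else:
            three = None
        if shift != 0:
            itype = "5p_deletion" if shift > 0 else "5p_extension"
        elif three is not None:
            itype = three
        elif mm:
            itype = "polymorphic"
        else:
            continue
        out[(seq, start)] = {
            "reference": name,
            "shift5p": shift,
            "type": itype,
            "seed_polymorphic": any(1 <= i <= 8 for i in mm),
        }
    return out


# -- homology ---------------------------------------------------------------

def hamming_scan_oracle(query: str, known_seq: str) -> float:
    """Slide the shorter sequence along the longer; overhang = mismatch."""
    a, b = query, known_seq
    if len(a) > len(b):
        a, b = b, a
    d = len(b) - len(a)
    if d > 2:
        return float("inf")
    best = float("inf")
    for off in range(d + 1):
        mm = d + sum(1 for i in range(len(a)) if a[i] != b[off + i])
        best = min(best, mm)
    return best


# -- statistics -------------------------------------------------------------

def bh_oracle(pvalues: Sequence[float]) -> List[float]:
    """Textbook step-up: padj_(i) = min_{j >= i} min(1, m p_(j) / j)."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    out = [0.0] * m
    for rank_pos, i in enumerate(indexed, start=1):
        candidates = []
        for later_pos in range(rank_pos, m + 1):
            j = indexed[later_pos - 1]
            candidates.append(min(1.0, m * pvalues[j] / later_pos))
        out[i] = min(candidates)
    return out
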