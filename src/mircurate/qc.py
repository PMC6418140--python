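"""Read QC (adapter trimming + clean-read filters) and composition stats.

Filters are applied in a fixed order -- low quality, N content,
homopolymer, length -- and each removed read is counted under its first
triggering reason only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from .errors import FastqFormatError

Q_OFFSET = 33


@dataclass(frozen=True)
class QCParams:
    max_low_quality_fraction: float = 0.20
    quality_threshold: int = 30  # bases below Q30 count as low quality
    max_n_fraction: float = 0.10
    min_len: int = 18
    max_len: int = 30
    homopolymer_fraction: float = 0.9
    adapter: Optional[str] = None
    min_adapter_overlap: int = 6

    def __post_init__(self) -> None:
        for name in ("max_low_quality_fraction", "max_n_fraction", "homopolymer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass
class QCStats:
    total: int = 0
    kept: int = 0
    removed: Counter = field(default_factory=Counter)  # reason -> count


@dataclass(frozen=True)
class FastqRead:
    id: str
    sequence: str
    quality: str


def parse_fastq(lines: Iterable[str]) -> Iterator[FastqRead]:
    buf: List[str] = []
    idx = 0
    for line in lines:
        line = line.rstrip("\n")
        buf.append(line)
        if len(buf) == 4:
            header, seq, plus, qual = buf
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqFormatError("malformed record header", idx)
            if len(seq) != len(qual):
                raise FastqFormatError("sequence/quality length mismatch", idx)
            yield FastqRead(header[1:].split()[0], seq.upper(), qual)
            buf = []
            idx += 1
    if buf:
        raise FastqFormatError("truncated record at end of file", idx)


def trim_adapter(sequence: str, quality: str, adapter: str, min_overlap: int = 6) -> Tuple[str, str]:
    """Remove a 3' adapter: leftmost full occurrence, else the longest
    read-suffix / adapter-prefix overlap of >= min_overlap nt."""
    pos = sequence.find(adapter)
    if pos != -1:
        return sequence[:pos], quality[:pos]
    for k in range(min(len(adapter), len(sequence)), min_overlap - 1, -1):
        if sequence.endswith(adapter[:k]):
            return sequence[:-k], quality[:-k]
    return sequence, quality


def _filter_reason(seq: str, qual: str, p: QCParams) -> Optional[str]:
    n = len(seq)
    if n == 0:
        return "length"
    low_q = sum(1 for c in qual if ord(c) - Q_OFFSET < p.quality_threshold)
    if low_q / n > p.max_low_quality_fraction:
        return "low_quality"
    if seq.count("N") / n > p.max_n_fraction:
        return "n_content"
    if max(seq.count(b) for b in "ACGTU") / n >= p.homopolymer_fraction:
        return "homopolymer"
    if n < p.min_len or n > p.max_len:
        return "length"
    return None


def read_qc(reads: Iterable[FastqRead], p: QCParams = QCParams()) -> Tuple[List[FastqRead], QCStats]:
    """Adapter-trim then filter; returns clean reads and removal stats."""
    stats = QCStats()
    clean: List[FastqRead] = []
    for r in reads:
        stats.total += 1
        seq, qual = r.sequence, r.quality
        if p.adapter:
            seq, qual = trim_adapter(seq, qual, p.adapter.upper(), p.min_adapter_overlap)
        reason = _filter_reason(seq, qual, p)
        if reason is None:
            stats.kept += 1
            clean.append(FastqRead(r.id, seq, qual))
        else:
            stats.removed[reason] += 1
    return clean, stats


@dataclass
class CompositionSummary:
    length_histogram: Dict[int, int]
    first_base_matrix: Dict[Tuple[int, str], int]


def composition_stats(matures: Iterable[str]) -> CompositionSummary:
    """Length histogram and (length, first base) counts over mature sequences."""
    hist: Counter = Counter()
    matrix: Counter = Counter()
    for seq in matures:
        seq = seq.upper().replace("T", "U")
        if not seq:
            continue
        hist[len(seq)] += 1
        matrix[(len(seq), seq[0])] += 1
    return CompositionSummary(dict(hist), dict(matrix))
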