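"""Readers and writers for the plain-text interchange formats.

Canonical fixture formats are TSV; FASTA is read via Biopython.  The
precursor structure sidecar is a 3-line-per-record file
(id / dot-bracket / ``mfe=<float>``).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError
from .evidence import AlignedRead, ReadStack
from .expression import CountMatrix, SampleSheet
from .hairpin import Precursor

PRECURSOR_COLUMNS = ["id", "sequence", "structure", "mfe", "n_genome_hits"]
STACK_COLUMNS = ["precursor_id", "library_id", "start", "read_sequence", "count"]


def read_precursors_tsv(path: str | Path) -> List[Precursor]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(PRECURSOR_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing precursor columns {sorted(missing)}")
    return [
        Precursor(
            id=row.id,
            sequence=row.sequence,
            structure=row.structure,
            mfe=float(row.mfe),
            n_genome_hits=int(row.n_genome_hits),
        )
        for row in df.itertuples()
    ]


def write_precursors_tsv(precursors: Iterable[Precursor], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": p.id,
                "sequence": p.sequence,
                "structure": p.structure,
                "mfe": p.mfe,
                "n_genome_hits": p.n_genome_hits,
            }
            for p in precursors
        ],
        columns=PRECURSOR_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_precursors_fasta(
    fasta_path: str | Path, structure_path: str | Path
) -> List[Precursor]:
    """FASTA plus 3-line-per-record structure sidecar (id / structure / mfe=x)."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    lines = Path(structure_path).read_text().splitlines()
    if len(lines) % 3 != 0:
        raise ConfigError(f"{structure_path}: expected 3 lines per record")
    for i in range(0, len(lines), 3):
        pid = lines[i].lstrip(">").strip()
        structure = lines[i + 1].strip()
        m = re.match(r"mfe=(-?\d+(?:\.\d+)?)", lines[i + 2].strip())
        if not m:
            raise ConfigError(f"{structure_path}: bad mfe line for {pid!r}")
        if pid not in seqs:
            raise ConfigError(f"{structure_path}: {pid!r} not in FASTA")
        out.append(
            Precursor(id=pid, sequence=seqs[pid], structure=structure, mfe=float(m.group(1)))
        )
    return out


def read_stacks_tsv(path: str | Path) -> Dict[str, ReadStack]:
    df = pd.read_csv(path, sep="\t", dtype={"precursor_id": str, "library_id": str})
    missing = set(STACK_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing stack columns {sorted(missing)}")
    stacks: Dict[str, ReadStack] = {}
    for row in df.itertuples():
        stack = stacks.setdefault(row.precursor_id, ReadStack(row.precursor_id))
        stack.reads.append(
            AlignedRead(
                sequence=row.read_sequence,
                start=int(row.start),
                count=int(row.count),
                library_id=row.library_id,
            )
        )
    return stacks


def write_stacks_tsv(stacks: Iterable[ReadStack], path: str | Path) -> None:
    rows = [
        {
            "precursor_id": s.precursor_id,
            "library_id": r.library_id,
            "start": r.start,
            "read_sequence": r.sequence,
            "count": r.count,
        }
        for s in stacks
        for r in s.reads
    ]
    pd.DataFrame(rows, columns=STACK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_known_matures(path: str | Path) -> List[Tuple[str, str]]:
    """miRBase-style mature FASTA -> [(id, sequence)] in file order."""
    return [
        (rec.id, str(rec.seq).upper().replace("T", "U"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    if "sample_id" not in df.columns:
        raise ConfigError(f"{path}: missing sample_id column")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t")


def read_count_matrix(counts_path: str | Path, sheet_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    return CountMatrix(counts, read_sample_sheet(sheet_path))
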