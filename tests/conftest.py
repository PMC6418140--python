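import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mircurate.expression import CountMatrix, SampleSheet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def sheet_3v3():
    samples = ["Young1", "Young2", "Young3", "Intermediate1", "Intermediate2",
               "Intermediate3", "Mature1", "Mature2", "Mature3"]
    stages = ["young"] * 3 + ["intermediate"] * 3 + ["mature"] * 3
    return SampleSheet(
        pd.DataFrame(
            {
                "stage": stages,
                "replicate": [1, 2, 3] * 3,
                "genome_mapped_reads": 1_000_000,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )


def make_count_matrix(counts: np.ndarray, sheet: SampleSheet) -> CountMatrix:
    return CountMatrix(
        pd.DataFrame(
            counts,
            index=[f"mir{i:04d}" for i in range(len(counts))],
            columns=list(sheet.table.index)[: counts.shape[1]],
        ),
        sheet,
    )


@pytest.fixture
def two_stage_sheet():
    samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
    return SampleSheet(
        pd.DataFrame(
            {
                "stage": ["young"] * 3 + ["mature"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
                "genome_mapped_reads": 1_000_000,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
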