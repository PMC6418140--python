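"""Quantification, TPM normalization and differential expression.

The differential test is a deliberately simple negative-binomial Wald
test (median-of-ratios normalization, pooled method-of-moments
dispersion): it mirrors the shape of a DESeq2 analysis but makes no claim
of numerical equivalence with it.  Significance is |log2FC| > 1 with
BH-adjusted p < 0.05.

TPM here follows the small-RNA convention: reads mapped to the miRNA
x 1e6 / reads mapped to the genome for that sample (note the denominator
is genome-mapped, not miRNA-mapped, reads).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .evidence import ReadStack
from .hairpin import Interval

LOG2FC_THRESHOLD = 1.0
ALPHA_FDR = 0.05
_PSEUDOCOUNT = 0.5  # display-only, for fold changes of zero-mean groups
_MIN_DISPERSION = 1e-8

STAGES = ("young", "intermediate", "mature")
CONTRASTS = (("intermediate", "young"), ("mature", "intermediate"), ("mature", "young"))


@dataclass
class SampleSheet:
    """Sample metadata: stage, replicate and genome-mapped totals."""

    table: pd.DataFrame  # index: sample_id; columns: stage, replicate, genome_mapped_reads

    def __post_init__(self) -> None:
        required = {"stage", "replicate", "genome_mapped_reads"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParameterError(f"sample sheet missing columns: {sorted(missing)}")
        if (self.table["genome_mapped_reads"] <= 0).any():
            raise ParameterError("genome_mapped_reads must be > 0 for every sample")

    def samples_for_stage(self, stage: str) -> List[str]:
        return list(self.table.index[self.table["stage"] == stage])


@dataclass
class CountMatrix:
    """miRNA x sample read counts plus the sample sheet."""

    counts: pd.DataFrame  # rows: miRNA ids, columns: sample ids
    samples: SampleSheet

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ParameterError("counts must be non-negative")
        extra = set(self.counts.columns) - set(self.samples.table.index)
        if extra:
            raise ParameterError(f"samples missing from sheet: {sorted(extra)}")


def quantify(
    stack: ReadStack,
    mature: Interval,
    window_up: int = 2,
    window_down: int = 5,
    max_mm: int = 1,
) -> Dict[str, int]:
    """Per-library counts of reads inside the windowed mature interval.

    A read counts when its full span lies within [start - window_up,
    end + window_down) and it has at most ``max_mm`` mismatches.
    """
    window = mature.expanded(window_up, window_down)
    out: Dict[str, int] = {}
    for r in stack.reads:
        if len(r.mismatch_positions) <= max_mm and window.contains(r.start, r.end):
            out[r.library_id] = out.get(r.library_id, 0) + r.count
    return out


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """counts x 1e6 / genome-mapped reads, per sample."""
    gm = cm.samples.table.loc[cm.counts.columns, "genome_mapped_reads"].astype(float)
    return cm.counts * 1e6 / gm


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric mean reference).

    Rows with any zero are excluded from the reference; if none remain the
    factors fall back to total-count ratios.  Factors are rescaled to
    geometric mean 1.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logs = np.log(mat[positive])
        ref = logs.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logs - ref, axis=0))
    else:
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ParameterError("cannot compute size factors: empty sample")
        factors = totals / np.exp(np.mean(np.log(totals)))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


@dataclass(frozen=True)
class DEResult:
    mirna_id: str
    contrast: str  # e.g. "mature/young"
    log2fc: float
    p: float
    padj: float
    significant: bool
    base_mean: float


def _moment_dispersion(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion, floored at 1e-8.

    Per gene and group with mean m and variance v, alpha-hat =
    (v - m) / m^2; estimates are pooled by averaging across both groups
    of every gene with positive mean.  Pooling across genes keeps the
    3-replicate estimate stable enough for a calibrated Wald test.
    """
    estimates = []
    for mat in (a, b):
        m = mat.mean(axis=1)
        v = mat.var(axis=1, ddof=1)
        ok = m > 0
        estimates.append((v[ok] - m[ok]) / (m[ok] ** 2))
    pooled = np.concatenate(estimates)
    if pooled.size == 0:
        return _MIN_DISPERSION
    return max(float(pooled.mean()), _MIN_DISPERSION)


def nb_test(
    cm: CountMatrix,
    stage_a: str,
    stage_b: str,
    factors: Optional[pd.Series] = None,
) -> List[DEResult]:
    """Wald test of stage_a vs stage_b on NB counts.

    log2FC is log2(mean_a / mean_b) of size-factor-normalized counts; the
    Wald statistic uses the delta-method variance of the log fold change
    under NB(mean, dispersion) with a moment dispersion pooled across
    genes, referred to the standard normal.
    """
    cols_a = cm.samples.samples_for_stage(stage_a)
    cols_b = cm.samples.samples_for_stage(stage_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ParameterError(
            f"need >= 2 replicates per stage ({stage_a}: {len(cols_a)}, "
            f"{stage_b}: {len(cols_b)})"
        )
    if factors is None:
        factors = size_factors(cm.counts)
    norm = cm.counts / factors
    a = norm[cols_a].to_numpy(dtype=float)
    b = norm[cols_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]

    log2fc = np.zeros(len(norm))
    pvals = np.ones(len(norm))
    base_mean = norm.to_numpy().mean(axis=1)
    disp = _moment_dispersion(a, b)
    for i in range(len(norm)):
        mu_a, mu_b = a[i].mean(), b[i].mean()
        if mu_a == 0 and mu_b == 0:
            continue  # all-zero row: p = 1, log2fc = 0
        if mu_a == 0 or mu_b == 0:
            log2fc[i] = np.log2((mu_a + _PSEUDOCOUNT) / (mu_b + _PSEUDOCOUNT))
            mu_a_t, mu_b_t = mu_a + _PSEUDOCOUNT, mu_b + _PSEUDOCOUNT
        else:
            log2fc[i] = np.log2(mu_a / mu_b)
            mu_a_t, mu_b_t = mu_a, mu_b
        # Var(log mu-hat) ~ (1/mu + disp) / n  (delta method on NB mean)
        var_log = (1.0 / mu_a_t + disp) / n_a + (1.0 / mu_b_t + disp) / n_b
        se_log2 = np.sqrt(var_log) / np.log(2)
        wald = log2fc[i] / se_log2
        pvals[i] = 2.0 * stats.norm.sf(abs(wald))

    padj = bh_adjust(pvals)
    contrast = f"{stage_a}/{stage_b}"
    return [
        DEResult(
            mirna_id=str(idx),
            contrast=contrast,
            log2fc=float(log2fc[i]),
            p=float(pvals[i]),
            padj=float(padj[i]),
            significant=bool(abs(log2fc[i]) > LOG2FC_THRESHOLD and padj[i] < ALPHA_FDR),
            base_mean=float(base_mean[i]),
        )
        for i, idx in enumerate(norm.index)
    ]


def de_all_contrasts(cm: CountMatrix) -> pd.DataFrame:
    """All three pairwise stage contrasts as one tidy frame.

    A miRNA is flagged differentially expressed when significant in at
    least one contrast.
    """
    frames = []
    for a, b in CONTRASTS:
        res = nb_test(cm, a, b)
        frames.append(pd.DataFrame([r.__dict__ for r in res]))
    return pd.concat(frames, ignore_index=True)


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    ddct_value = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_value))
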