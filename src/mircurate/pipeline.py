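"""End-to-end orchestration: fixtures in, curated miRNA reports out.

The pipeline is a pure function of (inputs, config): no randomness, stable
iteration order, deterministic output bytes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import io as mio
from .classify import (
    CATEGORY_HIGH,
    CATEGORY_REJECTED,
    CATEGORY_VERY_HIGH,
    ConfidenceCall,
    Thresholds,
    classify,
    evaluate_rules,
)
from .errors import ConfigError, MircurateError, UndefinedReferenceError
from .evidence import ReadStack, summarize_evidence
from .expression import CountMatrix, SampleSheet, de_all_contrasts, quantify, tpm
from .hairpin import Interval, Precursor, duplex_profile, parse_dotbracket, infer_star_coords
from .homology import assign_families, call_isomirs, match_known
from .qc import composition_stats

log = logging.getLogger("mircurate")


@dataclass
class CandidateResult:
    precursor: Precursor
    mature: Optional[Interval]
    star: Optional[Interval]
    call: Optional[ConfidenceCall]
    note: str = ""

    @property
    def category(self) -> str:
        return self.call.category if self.call else CATEGORY_REJECTED

    @property
    def mature_sequence(self) -> Optional[str]:
        if self.mature is None:
            return None
        return self.precursor.sequence[self.mature.start : self.mature.end]


def infer_mature_interval(stack: ReadStack) -> Optional[Interval]:
    """Most abundant pooled read position (exact reads preferred)."""
    pooled: Dict[Tuple[int, str, bool], int] = {}
    for r in stack.reads:
        key = (r.start, r.sequence, r.is_exact)
        pooled[key] = pooled.get(key, 0) + r.count
    if not pooled:
        return None
    # exact reads first, then highest count, then leftmost start
    (start, seq, _exact), _count = max(
        pooled.items(), key=lambda kv: (kv[0][2], kv[1], -kv[0][0])
    )
    return Interval(start, start + len(seq))


def infer_star_from_reads(
    stack: ReadStack, mature: Interval, anchor: Interval
) -> Optional[Interval]:
    """Modal read on the star arm (overlapping the structure-predicted
    star, clear of the mature), or None when the star is unsupported."""
    pooled: Dict[Tuple[int, str, bool], int] = {}
    for r in stack.reads:
        read_iv = Interval(r.start, r.end)
        if read_iv.overlaps(mature) or not read_iv.overlaps(anchor):
            continue
        if not (18 <= len(r.sequence) <= 30):
            continue
        key = (r.start, r.sequence, r.is_exact)
        pooled[key] = pooled.get(key, 0) + r.count
    if not pooled:
        return None
    (start, seq, _exact), _count = max(
        pooled.items(), key=lambda kv: (kv[0][2], kv[1], -kv[0][0])
    )
    return Interval(start, start + len(seq))


def classify_candidate(
    precursor: Precursor,
    stack: Optional[ReadStack],
    thresholds: Thresholds,
    window_up: int = 2,
    window_down: int = 5,
) -> CandidateResult:
    """Run geometry + evidence + rules for one candidate precursor.

    The mature interval is the tallest read stack; the star interval comes
    from star-arm reads when any exist (so the observed duplex overhangs
    are judged on evidence), falling back to the structure-predicted star
    of a canonical duplex when the star arm is read-free.
    """
    try:
        pt = parse_dotbracket(precursor.structure)
    except MircurateError as e:
        return CandidateResult(precursor, None, None, None, note=f"bad structure: {e}")
    if stack is None or not stack.reads:
        return CandidateResult(precursor, None, None, None, note="no reads")
    stack = stack.with_mismatches_computed(precursor.sequence)
    mature = infer_mature_interval(stack)
    if mature is None or not (18 <= len(mature) <= 30):
        return CandidateResult(precursor, mature, None, None, note="no mature-length read")
    try:
        anchor = infer_star_coords(pt, mature)
    except MircurateError as e:
        return CandidateResult(precursor, mature, None, None, note=f"no duplex: {e}")
    star_read = infer_star_from_reads(stack, mature, anchor)
    star, star_present = anchor, False
    profile = None
    if star_read is not None:
        try:
            profile = duplex_profile(pt, precursor.sequence, mature, star_read)
            star, star_present = star_read, True
        except MircurateError:
            profile = None
    if profile is None:
        try:
            profile = duplex_profile(pt, precursor.sequence, mature, anchor)
        except MircurateError as e:
            return CandidateResult(precursor, mature, None, None, note=f"no duplex: {e}")
    evidence = summarize_evidence(stack, mature, star, window_up, window_down)
    report = evaluate_rules(profile, evidence, precursor, star_present, thresholds)
    call = classify(report, thresholds)
    return CandidateResult(precursor, mature, star, call)


def _classification_row(res: CandidateResult) -> Dict[str, object]:
    row: Dict[str, object] = {
        "precursor_id": res.precursor.id,
        "mature_start": res.mature.start if res.mature else None,
        "mature_end": res.mature.end if res.mature else None,
        "mature_sequence": res.mature_sequence,
        "star_start": res.star.start if res.star else None,
        "star_end": res.star.end if res.star else None,
        "category": res.category,
        "note": res.note,
    }
    if res.call:
        for name, verdict in res.call.report.rules().items():
            row[f"{name}_pass"] = verdict.passed
            row[f"{name}_observed"] = str(verdict.observed)
        row["paired_fraction_ok"] = res.call.report.paired_fraction_ok.passed
        row["rescue_applied"] = res.call.report.rescue_applied
        row["star_present"] = res.call.report.star_present
        row["warnings"] = "; ".join(res.call.warnings)
    return row


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    if not isinstance(config, dict):
        config = load_config(config)
    inputs = config.get("inputs", {})
    for key in ("precursors", "stacks", "samples"):
        if key not in inputs:
            raise ConfigError(f"config missing inputs.{key}")
        if not Path(inputs[key]).exists():
            raise ConfigError(f"input file not found: {inputs[key]}")
    out_dir = Path(config.get("output_dir", "mircurate_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    thresholds = Thresholds(**config.get("thresholds", {}))
    quant_cfg = config.get("quantifier", {})
    window_up = int(quant_cfg.get("window_up", 2))
    window_down = int(quant_cfg.get("window_down", 5))
    max_mm = int(quant_cfg.get("max_mm", 1))
    isomir_cfg = config.get("isomir", {})
    species_prefix = config.get("species_prefix", "Jcu")

    log.info("loading inputs")
    precursors = mio.read_precursors_tsv(inputs["precursors"])
    stacks = mio.read_stacks_tsv(inputs["stacks"])
    samples = mio.read_sample_sheet(inputs["samples"])
    known = (
        mio.read_known_matures(inputs["known_matures"])
        if inputs.get("known_matures") and Path(inputs["known_matures"]).exists()
        else []
    )

    log.info("classifying %d candidates", len(precursors))
    results = [
        classify_candidate(p, stacks.get(p.id), thresholds, window_up, window_down)
        for p in precursors
    ]
    class_df = pd.DataFrame([_classification_row(r) for r in results])
    class_df.to_csv(out_dir / "classification.tsv", sep="\t", index=False)

    hc = [r for r in results if r.category in (CATEGORY_HIGH, CATEGORY_VERY_HIGH)]

    log.info("homology for %d HC miRNAs", len(hc))
    hc_ids = [r.precursor.id for r in hc]
    hc_seqs = [r.mature_sequence or "" for r in hc]
    calls = [match_known(seq, known) for seq in hc_seqs]
    abundances = []
    for r in hc:
        stack = stacks[r.precursor.id].with_mismatches_computed(r.precursor.sequence)
        counts = quantify(stack, r.mature, window_up, window_down, max_mm)
        abundances.append(float(sum(counts.values())))
    calls = assign_families(hc_ids, hc_seqs, calls, abundances, species_prefix)
    homology_df = pd.DataFrame(
        {
            "precursor_id": hc_ids,
            "mature_sequence": hc_seqs,
            "status": [c.status for c in calls],
            "best_match_id": [c.best_match_id for c in calls],
            "mismatches": [c.mismatches for c in calls],
            "family": [c.family for c in calls],
        }
    )
    homology_df.to_csv(out_dir / "homology.tsv", sep="\t", index=False)

    log.info("isomiRs")
    isomir_rows = []
    for r in hc:
        stack = stacks[r.precursor.id].with_mismatches_computed(r.precursor.sequence)
        try:
            isomirs = call_isomirs(stack, r.precursor, r.mature, r.star, **isomir_cfg)
        except UndefinedReferenceError:
            continue
        for iso in isomirs:
            isomir_rows.append({"precursor_id": r.precursor.id, **dataclasses.asdict(iso)})
    isomir_df = pd.DataFrame(
        isomir_rows,
        columns=[
            "precursor_id", "sequence", "start", "count", "reference", "shift5p",
            "type", "secondary_3p", "seed_polymorphic", "abundance_fraction",
        ],
    )
    isomir_df.to_csv(out_dir / "isomirs.tsv", sep="\t", index=False)

    log.info("quantification")
    sample_ids = list(samples.table.index)
    count_rows = {}
    for r in hc:
        stack = stacks[r.precursor.id].with_mismatches_computed(r.precursor.sequence)
        by_lib = quantify(stack, r.mature, window_up, window_down, max_mm)
        count_rows[r.precursor.id] = [int(by_lib.get(s, 0)) for s in sample_ids]
    counts_df = pd.DataFrame.from_dict(count_rows, orient="index", columns=sample_ids)
    counts_df.index.name = "mirna_id"
    counts_df.to_csv(out_dir / "counts.tsv", sep="\t")
    cm = CountMatrix(counts_df, samples)
    tpm_df = tpm(cm)
    tpm_df.to_csv(out_dir / "tpm.tsv", sep="\t")

    de_df = pd.DataFrame()
    n_de = 0
    stage_counts = samples.table["stage"].value_counts()
    de_possible = len(counts_df) > 0 and all(
        stage_counts.get(s, 0) >= 2 for s in ("young", "intermediate", "mature")
    )
    if de_possible:
        log.info("differential expression")
        de_df = de_all_contrasts(cm)
        n_de = int(de_df[de_df["significant"]]["mirna_id"].nunique())
    de_df.to_csv(out_dir / "de.tsv", sep="\t", index=False)

    comp = composition_stats([s for s in hc_seqs if s])
    pd.DataFrame(
        sorted(comp.length_histogram.items()), columns=["length", "count"]
    ).to_csv(out_dir / "composition_lengths.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(l, b, c) for (l, b), c in sorted(comp.first_base_matrix.items())],
        columns=["length", "first_base", "count"],
    ).to_csv(out_dir / "composition_first_base.tsv", sep="\t", index=False)

    summary = {
        "n_candidates": len(results),
        "n_high_confidence": len(hc),
        "n_very_high_confidence": sum(
            1 for r in results if r.category == CATEGORY_VERY_HIGH
        ),
        "n_rejected": sum(1 for r in results if r.category == CATEGORY_REJECTED),
        "n_conserved": sum(1 for c in calls if c.status == "conserved"),
        "n_novel": sum(1 for c in calls if c.status == "novel"),
        "n_isomirs": len(isomir_rows),
        "n_differentially_expressed": n_de,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "thresholds.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(thresholds), fh, sort_keys=True)
    return summary
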