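"""Synthetic hairpins, read stacks and multi-sample experiments.

Everything is generated from an explicit ``numpy.random.Generator`` so
fixtures are reproducible byte-for-byte.  Synthetic MFE is a
deterministic function of the structure (``-energy_scale * n_pairs``),
not a thermodynamic quantity: the confidence rules only need a number
with controllable sign and magnitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .evidence import AlignedRead, ReadStack
from .expression import CountMatrix, SampleSheet, STAGES
from .hairpin import Interval, Precursor

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_BASES = "ACGU"

DEFAULT_LENGTH_MIX = {21: 0.55, 24: 0.20, 22: 0.10, 20: 0.08, 23: 0.05, 19: 0.02}
# U-dominant starts at 20-22 nt, C preferred at 24 nt
DEFAULT_FIRST_BASE_BIAS = {
    19: {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25},
    20: {"A": 0.15, "C": 0.10, "G": 0.15, "U": 0.60},
    21: {"A": 0.15, "C": 0.08, "G": 0.12, "U": 0.65},
    22: {"A": 0.15, "C": 0.10, "G": 0.15, "U": 0.60},
    23: {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25},
    24: {"A": 0.20, "C": 0.45, "G": 0.15, "U": 0.20},
}


@dataclass
class TruthRecord:
    """Ground truth for one synthetic precursor."""

    precursor: Precursor
    mature: Interval
    star: Interval
    planted_category: str
    planted_rule_violations: Tuple[str, ...] = ()
    planted_isomirs: Tuple[Tuple[str, int, float], ...] = ()
    planted_log2fc: Dict[str, float] = field(default_factory=dict)
    first_base: str = "U"
    length_class: int = 21


def _rand_seq(rng: np.random.Generator, n: int, first_base: Optional[str] = None) -> str:
    seq = "".join(rng.choice(list(_BASES), size=n)) if n else ""
    if first_base and n:
        seq = first_base + seq[1:]
    return seq


def make_hairpin(
    mature_len: int = 22,
    mismatches: int = 0,
    bulges: Sequence[Tuple[str, int]] = (),
    overhangs: int = 2,
    flank: int = 10,
    loop: int = 8,
    seed: int = 0,
    energy_scale: float = 1.0,
    first_base: Optional[str] = None,
    precursor_id: str = "synth",
    n_genome_hits: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Precursor, Interval, Interval]:
    """Construct a hairpin whose duplex geometry is exactly as requested.

    The mature sits on the 5' arm.  Mismatches and bulges are spread along
    the stem with at least one base pair between consecutive defects, so
    ``duplex_profile`` on the product reproduces the request verbatim.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if loop < 3:
        raise ParameterError("loop must be >= 3 nt")
    for arm, size in bulges:
        if arm not in ("mature", "star") or size < 1:
            raise ParameterError(f"bad bulge spec ({arm}, {size})")
    bulge_mature = sum(s for a, s in bulges if a == "mature")
    bulge_star = sum(s for a, s in bulges if a == "star")
    n_pairs = mature_len - overhangs - mismatches - bulge_mature
    n_events = mismatches + len(bulges)
    if n_pairs < n_events + 1 or n_pairs < 2:
        raise ParameterError(
            f"infeasible stem: {n_pairs} pairs for {n_events} defects "
            f"(mature_len={mature_len}, overhangs={overhangs})"
        )

    # interleave defects between pairs: tokens P / M / (bulge, arm, size)
    events: List[object] = ["M"] * mismatches + [("B", arm, size) for arm, size in bulges]
    tokens: List[object] = []
    gaps = n_pairs - 1
    positions = [max(1, round((i + 1) * gaps / (n_events + 1))) for i in range(n_events)]
    ev = 0
    for p in range(n_pairs):
        tokens.append("P")
        while ev < n_events and positions[ev] == p + 1 and p < n_pairs - 1:
            tokens.append(events[ev])
            ev += 1

    # build both arms 5'->3'
    m_struct, m_seq = [], []
    s_struct_rev, s_seq_rev = [], []  # star 3'->5' (reversed at the end)
    for tok in tokens:
        if tok == "P":
            base = rng.choice(list(_BASES))
            m_struct.append("(")
            m_seq.append(base)
            s_struct_rev.append(")")
            s_seq_rev.append(_COMPLEMENT[base])
        elif tok == "M":
            base = rng.choice(list(_BASES))
            m_struct.append(".")
            m_seq.append(base)
            s_struct_rev.append(".")
            s_seq_rev.append(base)  # identical bases cannot pair
        else:
            _tag, arm, size = tok
            filler = _rand_seq(rng, size)
            if arm == "mature":
                m_struct.extend("." * size)
                m_seq.extend(filler)
            else:
                s_struct_rev.extend("." * size)
                s_seq_rev.extend(filler)

    m_struct.extend("." * overhangs)
    m_seq.extend(_rand_seq(rng, overhangs))
    star_tail_struct = "." * overhangs
    star_tail_seq = _rand_seq(rng, overhangs)

    structure = (
        "." * flank
        + "".join(m_struct)
        + "." * loop
        + "".join(reversed(s_struct_rev))
        + star_tail_struct
        + "." * flank
    )
    sequence = (
        _rand_seq(rng, flank)
        + "".join(m_seq)
        + _rand_seq(rng, loop)
        + "".join(reversed(s_seq_rev))
        + star_tail_seq
        + _rand_seq(rng, flank)
    )
    if first_base:
        sequence = sequence[:flank] + first_base + sequence[flank + 1 :]

    mature = Interval(flank, flank + mature_len)
    star_len = n_pairs + mismatches + bulge_star + overhangs
    star_start = flank + mature_len + loop
    star = Interval(star_start, star_start + star_len)
    mfe = -round(energy_scale * n_pairs, 2)
    precursor = Precursor(
        id=precursor_id,
        sequence=sequence,
        structure=structure,
        mfe=mfe,
        n_genome_hits=n_genome_hits,
    )
    return precursor, mature, star


def _arm_archetypes(
    precursor: Precursor, arm: Interval, n_shift_variants: int = 2
) -> List[Tuple[str, int]]:
    """(sequence, start) archetypes on an arm: modal exact read first,
    then 5'-shifted templated variants that stay inside the quantifier
    window."""
    seq = precursor.sequence
    out = [(seq[arm.start : arm.end], arm.start)]
    for shift in (1, 2, -1, -2)[:n_shift_variants]:
        start = arm.start + shift
        if start < max(0, arm.start - 2):
            continue
        s = seq[start : arm.end]
        if 18 <= len(s) <= 30:
            out.append((s, start))
    return out


def _outside_archetypes(
    precursor: Precursor, mature: Interval, n: int = 6
) -> List[Tuple[str, int]]:
    """Loop-spanning reads contained in neither windowed arm.

    Several distinct positions so that off-arm mass never concentrates in
    a single read stack taller than the mature one.
    """
    out = []
    for i in range(n):
        start = max(0, mature.end - 5 - i)
        end = min(start + 21, len(precursor))
        out.append((precursor.sequence[start:end], start))
    return out


def _plan_reads(
    precursor: Precursor,
    mature: Interval,
    star: Optional[Interval],
    library_id: str,
    plan: Dict[str, int],
) -> List[AlignedRead]:
    """Reads for one library from an archetype count plan.

    Plan keys: mature_modal, mature_shift, star_modal, star_shift,
    outside, isomir (a +3-nt 5'-shifted mature variant).  Shift counts
    split over two 5'-shift variants per arm.
    """
    seq = precursor.sequence
    reads: List[AlignedRead] = []

    def add(rseq: str, start: int, count: int) -> None:
        if count > 0 and rseq:
            reads.append(AlignedRead(rseq, start, count, library_id))

    m_arch = _arm_archetypes(precursor, mature)
    add(*m_arch[0], plan.get("mature_modal", 0))
    for arch in m_arch[1:]:
        add(*arch, plan.get("mature_shift", 0) // max(1, len(m_arch) - 1))
    if star is not None:
        s_arch = _arm_archetypes(precursor, star)
        add(*s_arch[0], plan.get("star_modal", 0))
        for arch in s_arch[1:]:
            add(*arch, plan.get("star_shift", 0) // max(1, len(s_arch) - 1))
    outside = _outside_archetypes(precursor, mature)
    for arch in outside:
        add(*arch, plan.get("outside", 0) // len(outside))
    add(seq[mature.start + 3 : mature.end], mature.start + 3, plan.get("isomir", 0))
    return reads


def build_stack(
    precursor: Precursor,
    mature: Interval,
    star: Optional[Interval],
    per_library: Dict[str, int],
    n_libraries: int = 3,
    library_prefix: str = "lib",
) -> ReadStack:
    """Deterministic stack: the same archetype plan in every library."""
    plans = {
        f"{library_prefix}{i + 1}": per_library for i in range(n_libraries)
    }
    return build_stack_multi(precursor, mature, star, plans)


def build_stack_multi(
    precursor: Precursor,
    mature: Interval,
    star: Optional[Interval],
    plans: Dict[str, Dict[str, int]],
) -> ReadStack:
    """Deterministic stack from an explicit per-library archetype plan."""
    reads: List[AlignedRead] = []
    for lib, plan in plans.items():
        reads.extend(_plan_reads(precursor, mature, star, lib, plan))
    return ReadStack(precursor.id, reads).with_mismatches_computed(precursor.sequence)


def simulate_stack(
    precursor: Precursor,
    mature: Interval,
    star: Optional[Interval],
    depth: int = 1000,
    excision: float = 0.9,
    homogeneity: float = 0.9,
    star_fraction: float = 0.2,
    n_libraries: int = 3,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    library_prefix: str = "lib",
) -> ReadStack:
    """Random stack: multinomial counts per library over read archetypes.

    Expected windowed fraction is ``excision``; expected modal-5' share on
    each arm is ``homogeneity``; ``star_fraction`` of windowed reads sit
    on the star arm.
    """
    for name, v in (("excision", excision), ("homogeneity", homogeneity),
                    ("star_fraction", star_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {v}")
    if rng is None:
        rng = np.random.default_rng(seed)

    archetypes: List[Tuple[str, int, float]] = []
    m_arch = _arm_archetypes(precursor, mature)
    s_arch = _arm_archetypes(precursor, star) if star is not None else []
    star_p = star_fraction if s_arch else 0.0
    for arch_list, arm_p in ((m_arch, excision * (1 - star_p)), (s_arch, excision * star_p)):
        if not arch_list:
            continue
        seq0, start0 = arch_list[0]
        archetypes.append((seq0, start0, arm_p * homogeneity))
        rest = arch_list[1:]
        for seq_i, start_i in rest:
            archetypes.append((seq_i, start_i, arm_p * (1 - homogeneity) / len(rest)))
    outside = _outside_archetypes(precursor, mature)
    for out_seq, out_start in outside:
        archetypes.append((out_seq, out_start, (1.0 - excision) / len(outside)))

    probs = np.array([p for _s, _t, p in archetypes])
    probs = probs / probs.sum()
    reads: List[AlignedRead] = []
    for lib_i in range(n_libraries):
        lib = f"{library_prefix}{lib_i + 1}"
        counts = rng.multinomial(depth, probs)
        for (seq, start, _p), c in zip(archetypes, counts):
            if c > 0:
                reads.append(AlignedRead(seq, start, int(c), lib))
    return ReadStack(precursor.id, reads).with_mismatches_computed(precursor.sequence)


# ---------------------------------------------------------------------------
# planted-category batches for classifier recovery


_SCENARIOS: List[Tuple[str, Tuple[str, ...]]] = [
    ("very_high_confidence", ()),
    ("very_high_confidence", ("r2",)),  # one structural violation, rescued by r4
    ("high_confidence", ("r5",)),
    ("high_confidence", ("r6",)),
    ("high_confidence", ("r7",)),
    ("high_confidence", ("r3", "r5")),  # rescued, but evidence rule fails
    ("rejected", ("r1", "r2")),
    ("rejected", ("r2", "r4")),
    ("rejected", ("r3", "r4")),
]


def _planted_hairpin_kwargs(violations: Tuple[str, ...]) -> dict:
    v = set(violations)
    return dict(
        mature_len=22,
        mismatches=6 if "r2" in v else 2,
        bulges=(("mature", 4),) if "r3" in v else (),
        overhangs=0 if "r1" in v else 2,
        energy_scale=0.3 if "r7" in v else 1.6,
        n_genome_hits=30 if "hits" in v else 1,
    )


def _planted_plan(violations: Tuple[str, ...]) -> Dict[str, int]:
    """Per-library archetype counts that fail exactly `violations` among
    the evidence rules, with wide margins elsewhere."""
    v = set(violations)
    plan = {
        "mature_modal": 180,
        "mature_shift": 10,
        "star_modal": 60,
        "star_shift": 6,
        "outside": 20,
    }
    if "r4" in v:
        plan["outside"] = 700  # excision ~ 0.27
    if "r5" in v:
        plan["star_modal"] = 1  # 3 pooled exact star reads, star still detected
        plan["star_shift"] = 0
    if "r6" in v:
        # modal share ~ 0.25 on the mature arm
        plan["mature_modal"] = 60
        plan["mature_shift"] = 180
    return plan


def planted_candidate(
    category: str,
    violations: Tuple[str, ...],
    seed: int,
    precursor_id: str = "synth",
) -> Tuple[TruthRecord, ReadStack]:
    """One precursor + stack engineered to fail exactly `violations`.

    Every other rule passes with a wide margin, so classification is
    deterministic.
    """
    rng = np.random.default_rng(seed)
    precursor, mature, star = make_hairpin(
        precursor_id=precursor_id, rng=rng, **_planted_hairpin_kwargs(violations)
    )
    stack = build_stack(precursor, mature, star, _planted_plan(violations), n_libraries=3)
    truth = TruthRecord(
        precursor=precursor,
        mature=mature,
        star=star,
        planted_category=category,
        planted_rule_violations=violations,
    )
    return truth, stack


def simulate_classification_batch(
    n: int, seed: int = 0, library_prefix: str = "synth"
) -> List[Tuple[TruthRecord, ReadStack]]:
    """Cycle through planted scenarios to build a labeled batch of size n."""
    out = []
    for i in range(n):
        category, violations = _SCENARIOS[i % len(_SCENARIOS)]
        out.append(
            planted_candidate(category, violations, seed=seed + i, precursor_id=f"syn{i:04d}")
        )
    return out


# ---------------------------------------------------------------------------
# multi-sample experiment


def _draw_nb(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def simulate_experiment(
    n_mirnas: int = 50,
    stage_means: float = 200.0,
    dispersions: float = 0.1,
    planted_de_fraction: float = 0.2,
    planted_lfc: float = 2.0,
    length_mix: Optional[Dict[int, float]] = None,
    first_base_bias: Optional[Dict[int, Dict[str, float]]] = None,
    n_replicates: int = 3,
    genome_mapped_reads: int = 2_000_000,
    seed: int = 0,
) -> Tuple[CountMatrix, List[dict]]:
    """3-stage x n-replicate count matrix with planted fold changes.

    Counts are NB(mean, dispersion) per stage.  A ``planted_de_fraction``
    of miRNAs change monotonically from young to mature by ``planted_lfc``
    log2 units (alternating up/down).  Mature lengths and first bases are
    drawn from the configured mixtures and recorded in the truth records.
    """
    length_mix = dict(length_mix or DEFAULT_LENGTH_MIX)
    first_base_bias = first_base_bias or DEFAULT_FIRST_BASE_BIAS
    if abs(sum(length_mix.values()) - 1.0) > 1e-6:
        raise ParameterError("length_mix must sum to 1")
    for length, bias in first_base_bias.items():
        if abs(sum(bias.values()) - 1.0) > 1e-6:
            raise ParameterError(f"first_base_bias[{length}] must sum to 1")
    rng = np.random.default_rng(seed)

    sample_ids, stages = [], []
    for stage in STAGES:
        for rep in range(1, n_replicates + 1):
            sample_ids.append(f"{stage.capitalize()}{rep}")
            stages.append(stage)

    n_de = int(round(planted_de_fraction * n_mirnas))
    lengths = rng.choice(
        list(length_mix), size=n_mirnas, p=list(length_mix.values())
    )
    counts = np.zeros((n_mirnas, len(sample_ids)), dtype=int)
    truths: List[dict] = []
    for i in range(n_mirnas):
        base = stage_means if np.isscalar(stage_means) else stage_means[i]
        de = i < n_de
        direction = 1 if i % 2 == 0 else -1
        lfc_y_to_m = direction * planted_lfc if de else 0.0
        stage_mu = {
            "young": base,
            "intermediate": base * 2 ** (lfc_y_to_m / 2),
            "mature": base * 2 ** lfc_y_to_m,
        }
        for j, (sid, stage) in enumerate(zip(sample_ids, stages)):
            counts[i, j] = _draw_nb(rng, stage_mu[stage], dispersions, 1)[0]
        length = int(lengths[i])
        bias = first_base_bias.get(length, {"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25})
        first = rng.choice(list(bias), p=list(bias.values()))
        truths.append(
            {
                "mirna_id": f"mir{i:04d}",
                "planted_de": de,
                "planted_log2fc_m_vs_y": lfc_y_to_m,
                "length": length,
                "first_base": str(first),
                "mature_sequence": _rand_seq(rng, length, first_base=str(first)),
            }
        )

    sheet = SampleSheet(
        pd.DataFrame(
            {
                "stage": stages,
                "replicate": [int(s[-1]) for s in sample_ids],
                "genome_mapped_reads": genome_mapped_reads,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    cm = CountMatrix(
        pd.DataFrame(
            counts, index=[t["mirna_id"] for t in truths], columns=sample_ids
        ),
        sheet,
    )
    return cm, truths


# ---------------------------------------------------------------------------
# on-disk fixture bundle


def write_fixture_bundle(
    out_dir: str | Path,
    n_precursors: int = 24,
    seed: int = 0,
    n_replicates: int = 3,
    planted_lfc: float = 2.0,
    de_every: int = 4,
    isomir_every: int = 3,
    conserved_every: int = 2,
    genome_mapped_reads: int = 2_000_000,
) -> dict:
    """Write a complete, deterministic fixture bundle the pipeline consumes.

    Produces precursors.tsv, stacks.tsv, samples.tsv, known_matures.fasta,
    truth.json and config.yaml under ``out_dir``.  Libraries are the nine
    stage/replicate samples; every ``de_every``-th precursor scales its
    read counts across stages by ``planted_lfc`` log2 units (alternating
    direction), every ``isomir_every``-th plants a retained 5'-shift
    isomiR, and every ``conserved_every``-th planted-HC mature is copied
    into the known-mature FASTA.
    """
    from . import io as mio  # local import to avoid a cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    sample_ids = [
        f"{stage.capitalize()}{rep}"
        for stage in STAGES
        for rep in range(1, n_replicates + 1)
    ]
    stage_of = {
        sid: stage
        for stage in STAGES
        for rep in range(1, n_replicates + 1)
        for sid in [f"{stage.capitalize()}{rep}"]
    }
    stage_index = {"young": 0, "intermediate": 1, "mature": 2}

    precursors, stacks, truths, known = [], [], [], []
    for i in range(n_precursors):
        category, violations = _SCENARIOS[i % len(_SCENARIOS)]
        pid = f"fix{i:04d}"
        precursor, mature, star = make_hairpin(
            precursor_id=pid, rng=rng, **_planted_hairpin_kwargs(violations)
        )
        plan = _planted_plan(violations)
        plant_isomir = (
            isomir_every > 0
            and i % isomir_every == 0
            and "r6" not in violations
            and category != "rejected"
        )
        if plant_isomir:
            plan = {**plan, "isomir": plan["mature_modal"] * 3 // 5}
        de = de_every > 0 and i % de_every == 0 and category != "rejected"
        direction = 1 if (i // de_every) % 2 == 0 else -1
        lfc = direction * planted_lfc if de else 0.0
        plans = {}
        for sid in sample_ids:
            scale = 2.0 ** (lfc * stage_index[stage_of[sid]] / 2.0)
            plans[sid] = {k: int(round(v * scale)) for k, v in plan.items()}
        stack = build_stack_multi(precursor, mature, star, plans)
        precursors.append(precursor)
        stacks.append(stack)

        mature_seq = precursor.sequence[mature.start : mature.end]
        conserved = (
            conserved_every > 0
            and i % conserved_every == 0
            and category != "rejected"
        )
        known_id = None
        if conserved:
            known_id = f"ath-miR{156 + i}a"
            known.append((known_id, mature_seq))
        truths.append(
            {
                "precursor_id": pid,
                "planted_category": category,
                "planted_rule_violations": list(violations),
                "mature": [mature.start, mature.end],
                "star": [star.start, star.end],
                "mature_sequence": mature_seq,
                "planted_de": de,
                "planted_log2fc_m_vs_y": lfc,
                "planted_isomir": (
                    {"type": "5p_deletion", "shift5p": 3} if plant_isomir else None
                ),
                "planted_conserved": conserved,
                "known_id": known_id,
            }
        )

    # decoy known matures that match nothing
    for d in range(3):
        known.append((f"ath-miR{9000 + d}", _rand_seq(rng, 21)))

    mio.write_precursors_tsv(precursors, out_dir / "precursors.tsv")
    mio.write_stacks_tsv(stacks, out_dir / "stacks.tsv")
    sheet = pd.DataFrame(
        {
            "stage": [stage_of[s] for s in sample_ids],
            "replicate": [int(s[-1]) for s in sample_ids],
            "genome_mapped_reads": genome_mapped_reads,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    sheet.to_csv(out_dir / "samples.tsv", sep="\t")
    with open(out_dir / "known_matures.fasta", "w") as fh:
        for kid, seq in known:
            fh.write(f">{kid}\n{seq}\n")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=2, sort_keys=True)
        fh.write("\n")

    config = {
        "inputs": {
            "precursors": str(out_dir / "precursors.tsv"),
            "stacks": str(out_dir / "stacks.tsv"),
            "samples": str(out_dir / "samples.tsv"),
            "known_matures": str(out_dir / "known_matures.fasta"),
        },
        "output_dir": str(out_dir / "out"),
    }
    import yaml

    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config
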