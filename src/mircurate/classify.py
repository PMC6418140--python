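"""Confidence classification of candidate miRNAs.

Seven curation rules over duplex geometry, read evidence and folding
energy, with a rescue clause: a candidate that slightly violates exactly
one of the structural rules (r1-r3) is still accepted when precise
excision (r4) is demonstrated.  Candidates passing r1-r3 are
high-confidence; adding the evidence rules r5-r7 yields
very-high-confidence.

Boundary semantics follow the rule text exactly: "at least 10" is >=,
"more than 75%" is strict >, "< -0.2" is strict <, "four or fewer" is <=.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional

from .evidence import EvidenceSummary
from .hairpin import DuplexProfile, Precursor, mfe_per_nt

CATEGORY_REJECTED = "rejected"
CATEGORY_HIGH = "high_confidence"
CATEGORY_VERY_HIGH = "very_high_confidence"

STRUCTURAL_RULES = ("r1", "r2", "r3")
EVIDENCE_RULES = ("r5", "r6", "r7")


@dataclass(frozen=True)
class Thresholds:
    """All tunable rule boundaries; defaults follow the printed rules."""

    max_mismatches: int = 4
    max_bulges: int = 1
    max_bulge_size: int = 2  # exclusive bound: every bulge size must be < this
    min_overhang: int = 2
    min_excision: float = 0.75  # strict >
    min_paired_fraction: float = 0.60
    min_arm_exact_reads: int = 10
    min_5p_homogeneity: float = 0.50
    max_mfe_per_nt: float = -0.2  # strict <
    min_libraries: int = 2
    max_genome_hits: int = 15
    # policy switches (not thresholds): see module docs
    require_paired_fraction: bool = False
    require_excision_for_hc: bool = False
    # canonical duplexes have exactly 2-nt 3' overhangs; set False to accept
    # any overhang >= min_overhang (the monotone variant of rule 1)
    overhang_exact: bool = True

    def __post_init__(self) -> None:
        for name in ("min_excision", "min_paired_fraction", "min_5p_homogeneity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "max_mismatches",
            "max_bulges",
            "max_bulge_size",
            "min_overhang",
            "min_arm_exact_reads",
            "min_libraries",
            "max_genome_hits",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RuleVerdict:
    passed: bool
    observed: object
    note: str = ""


@dataclass(frozen=True)
class RuleReport:
    """Per-rule verdicts plus the observed values they were judged on."""

    r1_overhang: RuleVerdict
    r2_mismatches: RuleVerdict
    r3_bulges: RuleVerdict
    r4_excision: RuleVerdict
    r5_arm_reads: RuleVerdict
    r6_homogeneity: RuleVerdict
    r7_mfe: RuleVerdict
    paired_fraction_ok: RuleVerdict
    candidate_ok: RuleVerdict
    star_present: bool
    libraries_detected: int
    rescue_applied: bool = False

    def rules(self) -> Dict[str, RuleVerdict]:
        return {
            "r1": self.r1_overhang,
            "r2": self.r2_mismatches,
            "r3": self.r3_bulges,
            "r4": self.r4_excision,
            "r5": self.r5_arm_reads,
            "r6": self.r6_homogeneity,
            "r7": self.r7_mfe,
        }


@dataclass(frozen=True)
class ConfidenceCall:
    category: str
    report: RuleReport
    warnings: tuple = ()


def evaluate_rules(
    profile: DuplexProfile,
    evidence: EvidenceSummary,
    precursor: Precursor,
    star_present: bool,
    t: Thresholds = Thresholds(),
) -> RuleReport:
    """Judge every rule; degenerate inputs become failed rules, not errors."""
    if star_present:
        overhangs = (profile.overhang_mature_3p, profile.overhang_star_3p)
        if t.overhang_exact:
            ok = all(o == t.min_overhang for o in overhangs)
        else:
            ok = all(o >= t.min_overhang for o in overhangs)
        r1 = RuleVerdict(passed=ok, observed=overhangs, note="duplex 3' overhangs")
    else:
        r1 = RuleVerdict(
            passed=evidence.libraries_detected >= t.min_libraries,
            observed=evidence.libraries_detected,
            note="star absent: multiple-library fallback",
        )
    r2 = RuleVerdict(
        passed=profile.mismatches <= t.max_mismatches, observed=profile.mismatches
    )
    bulge_sizes = [size for _arm, size in profile.bulges]
    r3 = RuleVerdict(
        passed=len(profile.bulges) <= t.max_bulges
        and all(size < t.max_bulge_size for size in bulge_sizes),
        observed=tuple(profile.bulges),
    )
    r4 = RuleVerdict(
        passed=evidence.excision_fraction > t.min_excision,
        observed=evidence.excision_fraction,
    )
    arm_reads = (evidence.arm_exact_reads_mature, evidence.arm_exact_reads_star)
    r5 = RuleVerdict(
        passed=all(c >= t.min_arm_exact_reads for c in arm_reads), observed=arm_reads
    )
    homos = (
        evidence.five_prime_homogeneity_mature,
        evidence.five_prime_homogeneity_star,
    )
    # absence of arm reads fails the homogeneity rule by convention
    r6 = RuleVerdict(
        passed=all(h is not None and h >= t.min_5p_homogeneity for h in homos),
        observed=homos,
    )
    mpn = mfe_per_nt(precursor)
    r7 = RuleVerdict(passed=mpn < t.max_mfe_per_nt, observed=mpn)
    pf = (profile.paired_fraction_mature, profile.paired_fraction_star)
    paired_ok = RuleVerdict(
        passed=all(f >= t.min_paired_fraction for f in pf), observed=pf
    )
    cand_ok = RuleVerdict(
        passed=precursor.n_genome_hits <= t.max_genome_hits,
        observed=precursor.n_genome_hits,
        note="genome multi-mapping filter",
    )
    return RuleReport(
        r1_overhang=r1,
        r2_mismatches=r2,
        r3_bulges=r3,
        r4_excision=r4,
        r5_arm_reads=r5,
        r6_homogeneity=r6,
        r7_mfe=r7,
        paired_fraction_ok=paired_ok,
        candidate_ok=cand_ok,
        star_present=star_present,
        libraries_detected=evidence.libraries_detected,
    )


def classify(report: RuleReport, t: Thresholds = Thresholds()) -> ConfidenceCall:
    """Turn a rule report into a confidence call.

    high_confidence: all of r1-r3 pass, or exactly one of r1-r3 fails and
    r4 (precise excision) rescues it.  very_high_confidence additionally
    requires r5-r7.  The 60%-paired check and r4-for-clean-candidates are
    policy switches off by default (reported as warnings instead).
    """
    rules = report.rules()
    warnings = []
    if not report.candidate_ok.passed:
        return ConfidenceCall(CATEGORY_REJECTED, report, ("genome multi-mapping",))
    structural_failures = [r for r in STRUCTURAL_RULES if not rules[r].passed]
    rescue = False
    if not structural_failures:
        hc = True
        if not rules["r4"].passed:
            if t.require_excision_for_hc:
                hc = False
            else:
                warnings.append("imprecise excision (r4) on otherwise clean candidate")
    elif len(structural_failures) == 1 and rules["r4"].passed:
        hc = True
        rescue = True
    else:
        hc = False
    if hc and t.require_paired_fraction and not report.paired_fraction_ok.passed:
        hc = False
    if not report.paired_fraction_ok.passed:
        warnings.append("paired fraction below 60%")
    report = dataclasses.replace(report, rescue_applied=rescue)
    if not hc:
        return ConfidenceCall(CATEGORY_REJECTED, report, tuple(warnings))
    vhc = all(rules[r].passed for r in EVIDENCE_RULES)
    category = CATEGORY_VERY_HIGH if vhc else CATEGORY_HIGH
    return ConfidenceCall(category, report, tuple(warnings))
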