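import dataclasses

import pytest

from mircurate.classify import (
    CATEGORY_HIGH,
    CATEGORY_REJECTED,
    CATEGORY_VERY_HIGH,
    Thresholds,
    classify,
    evaluate_rules,
)
from mircurate.evidence import EvidenceSummary
from mircurate.hairpin import DuplexProfile, Precursor


def good_profile(**overrides):
    base = dict(
        mismatches=2,
        bulges=(),
        overhang_mature_3p=2,
        overhang_star_3p=2,
        paired_fraction_mature=0.9,
        paired_fraction_star=0.9,
    )
    base.update(overrides)
    return DuplexProfile(**base)


def good_evidence(**overrides):
    base = dict(
        arm_exact_reads_mature=200,
        arm_exact_reads_star=50,
        excision_fraction=0.95,
        five_prime_homogeneity_mature=0.9,
        five_prime_homogeneity_star=0.9,
        libraries_detected=9,
        dominance=0.8,
    )
    base.update(overrides)
    return EvidenceSummary(**base)


def good_precursor(mfe=-30.0, length=100, hits=1):
    return Precursor("p", "A" * length, "." * length, mfe, n_genome_hits=hits)


def call_for(profile=None, evidence=None, precursor=None, star_present=True, t=None):
    t = t or Thresholds()
    report = evaluate_rules(
        profile or good_profile(),
        evidence or good_evidence(),
        precursor or good_precursor(),
        star_present,
        t,
    )
    return classify(report, t)


class TestRuleBoundaries:
    """Printed boundary semantics, one rule violated at a time."""

    def test_all_pass_is_very_high(self):
        assert call_for().category == CATEGORY_VERY_HIGH

    def test_mismatches_5_fails_r2_only(self):
        c = call_for(profile=good_profile(mismatches=5))
        assert not c.report.r2_mismatches.passed
        assert c.report.r1_overhang.passed and c.report.r3_bulges.passed

    def test_mismatches_4_passes_r2(self):
        c = call_for(profile=good_profile(mismatches=4))
        assert c.report.r2_mismatches.passed
        assert c.category == CATEGORY_VERY_HIGH

    def test_arm_reads_9_fails_r5(self):
        c = call_for(evidence=good_evidence(arm_exact_reads_star=9))
        assert not c.report.r5_arm_reads.passed
        assert c.category == CATEGORY_HIGH

    def test_arm_reads_10_passes_r5(self):
        c = call_for(evidence=good_evidence(arm_exact_reads_star=10))
        assert c.report.r5_arm_reads.passed

    def test_homogeneity_049_fails_r6(self):
        c = call_for(evidence=good_evidence(five_prime_homogeneity_mature=0.49))
        assert not c.report.r6_homogeneity.passed
        assert c.category == CATEGORY_HIGH

    def test_homogeneity_050_passes_r6(self):
        c = call_for(evidence=good_evidence(five_prime_homogeneity_star=0.50))
        assert c.report.r6_homogeneity.passed

    def test_mfe_per_nt_minus_019_fails_r7(self):
        c = call_for(precursor=good_precursor(mfe=-19.0, length=100))
        assert not c.report.r7_mfe.passed
        assert c.category == CATEGORY_HIGH

    def test_mfe_per_nt_exactly_minus_02_fails_r7(self):
        # strict <: the boundary itself fails
        c = call_for(precursor=good_precursor(mfe=-20.0, length=100))
        assert not c.report.r7_mfe.passed

    def test_excision_exactly_075_fails_r4(self):
        c = call_for(evidence=good_evidence(excision_fraction=0.75))
        assert not c.report.r4_excision.passed

    def test_excision_above_075_passes_r4(self):
        c = call_for(evidence=good_evidence(excision_fraction=0.7501))
        assert c.report.r4_excision.passed

    def test_overhang_not_two_fails_r1(self):
        c = call_for(profile=good_profile(overhang_star_3p=1))
        assert not c.report.r1_overhang.passed

    def test_missing_homogeneity_fails_r6(self):
        c = call_for(evidence=good_evidence(five_prime_homogeneity_star=None))
        assert not c.report.r6_homogeneity.passed


class TestStarAbsentFallback:
    def test_multiple_libraries_rescues_r1(self):
        c = call_for(star_present=False)
        assert c.report.r1_overhang.passed
        assert "fallback" in c.report.r1_overhang.note

    def test_single_library_fails_r1(self):
        c = call_for(evidence=good_evidence(libraries_detected=1), star_present=False)
        assert not c.report.r1_overhang.passed


class TestRescueLogic:
    def test_one_structural_failure_rescued_by_excision(self):
        c = call_for(profile=good_profile(mismatches=6))
        assert c.category == CATEGORY_VERY_HIGH
        assert c.report.rescue_applied

    def test_rescued_without_evidence_rules_is_high(self):
        c = call_for(
            profile=good_profile(mismatches=6),
            evidence=good_evidence(arm_exact_reads_star=0),
        )
        assert c.category == CATEGORY_HIGH
        assert c.report.rescue_applied

    def test_two_structural_failures_rejected_despite_excision(self):
        c = call_for(profile=good_profile(mismatches=6, bulges=(("mature", 3),)))
        assert c.category == CATEGORY_REJECTED

    def test_one_failure_without_excision_rejected(self):
        c = call_for(
            profile=good_profile(mismatches=6),
            evidence=good_evidence(excision_fraction=0.5),
        )
        assert c.category == CATEGORY_REJECTED

    def test_clean_candidate_with_poor_excision_is_high_with_warning(self):
        c = call_for(evidence=good_evidence(excision_fraction=0.5))
        assert c.category in (CATEGORY_HIGH, CATEGORY_VERY_HIGH)
        assert any("excision" in w for w in c.warnings)

    def test_require_excision_policy_demotes(self):
        t = Thresholds(require_excision_for_hc=True)
        c = call_for(evidence=good_evidence(excision_fraction=0.5), t=t)
        assert c.category == CATEGORY_REJECTED


class TestBulgeRule:
    def test_one_size_one_bulge_passes(self):
        c = call_for(profile=good_profile(bulges=(("star", 1),)))
        assert c.report.r3_bulges.passed

    def test_size_two_bulge_fails_default(self):
        # "less than two bases in the bulge": size 2 is out at the default
        c = call_for(profile=good_profile(bulges=(("star", 2),)))
        assert not c.report.r3_bulges.passed

    def test_size_two_bulge_passes_with_relaxed_bound(self):
        t = Thresholds(max_bulge_size=3)
        c = call_for(profile=good_profile(bulges=(("star", 2),)), t=t)
        assert c.report.r3_bulges.passed

    def test_two_bulges_fail(self):
        c = call_for(profile=good_profile(bulges=(("star", 1), ("mature", 1))))
        assert not c.report.r3_bulges.passed


class TestGenomeHits:
    def test_over_limit_rejected(self):
        c = call_for(precursor=good_precursor(hits=16))
        assert c.category == CATEGORY_REJECTED

    def test_at_limit_kept(self):
        c = call_for(precursor=good_precursor(hits=15))
        assert c.category == CATEGORY_VERY_HIGH


class TestPairedFractionPolicy:
    def test_reported_not_gating_by_default(self):
        c = call_for(profile=good_profile(paired_fraction_mature=0.5))
        assert not c.report.paired_fraction_ok.passed
        assert c.category == CATEGORY_VERY_HIGH
        assert any("paired" in w for w in c.warnings)

    def test_gates_when_required(self):
        t = Thresholds(require_paired_fraction=True)
        c = call_for(profile=good_profile(paired_fraction_mature=0.5), t=t)
        assert c.category == CATEGORY_REJECTED


_RANK = {CATEGORY_REJECTED: 0, CATEGORY_HIGH: 1, CATEGORY_VERY_HIGH: 2}

# (field, relax_delta) -- a relaxed threshold must never demote, a
# tightened one must never promote
THRESHOLD_DIRECTIONS = [
    ("max_mismatches", +2),
    ("max_bulges", +1),
    ("max_bulge_size", +2),
    ("min_overhang", -1),
    ("min_excision", -0.2),
    ("min_paired_fraction", -0.2),
    ("min_arm_exact_reads", -5),
    ("min_5p_homogeneity", -0.2),
    ("max_mfe_per_nt", +0.1),
    ("min_libraries", -1),
    ("max_genome_hits", +10),
]


def _mixed_candidates():
    """A spread of profiles/evidence hitting many boundary regions."""
    out = []
    for mm in (0, 4, 5, 6):
        for exc in (0.5, 0.76, 0.95):
            for arm in (0, 9, 10, 200):
                out.append(
                    (
                        good_profile(mismatches=mm, overhang_star_3p=2),
                        good_evidence(excision_fraction=exc, arm_exact_reads_star=arm),
                        good_precursor(),
                    )
                )
    out.append((good_profile(bulges=(("star", 2),)), good_evidence(), good_precursor()))
    out.append((good_profile(overhang_mature_3p=1), good_evidence(), good_precursor(hits=14)))
    out.append((good_profile(), good_evidence(libraries_detected=1), good_precursor(mfe=-19)))
    return out


class TestMonotonicity:
    @pytest.mark.parametrize("field,delta", THRESHOLD_DIRECTIONS)
    def test_relax_never_demotes_tighten_never_promotes(self, field, delta):
        # min_overhang only has a monotone direction in its >= variant
        base = Thresholds(
            require_paired_fraction=True,
            require_excision_for_hc=False,
            overhang_exact=(field != "min_overhang"),
        )
        relaxed = dataclasses.replace(base, **{field: getattr(base, field) + delta})
        tightened = dataclasses.replace(base, **{field: getattr(base, field) - delta})
        for profile, evidence, precursor in _mixed_candidates():
            for star_present in (True, False):
                args = (profile, evidence, precursor, star_present)
                r_base = _RANK[classify(evaluate_rules(*args, base), base).category]
                r_relaxed = _RANK[
                    classify(evaluate_rules(*args, relaxed), relaxed).category
                ]
                r_tight = _RANK[
                    classify(evaluate_rules(*args, tightened), tightened).category
                ]
                assert r_relaxed >= r_base, (field, "relax demoted")
                assert r_tight <= r_base, (field, "tighten promoted")


class TestBatchRecovery:
    def test_planted_batch_small(self):
        from mircurate.evidence import summarize_evidence
        from mircurate.hairpin import duplex_profile, parse_dotbracket
        from mircurate.simulate import simulate_classification_batch

        for truth, stack in simulate_classification_batch(36, seed=11):
            pt = parse_dotbracket(truth.precursor.structure)
            prof = duplex_profile(pt, truth.precursor.sequence, truth.mature, truth.star)
            ev = summarize_evidence(stack, truth.mature, truth.star)
            star_w = truth.star.expanded(2, 5)
            star_present = any(star_w.contains(r.start, r.end) for r in stack.reads)
            call = classify(evaluate_rules(prof, ev, truth.precursor, star_present, Thresholds()))
            assert call.category == truth.planted_category, truth.planted_rule_violations

    def test_vhc_subset_of_hc(self):
        from mircurate.evidence import summarize_evidence
        from mircurate.hairpin import duplex_profile, parse_dotbracket
        from mircurate.simulate import simulate_classification_batch

        cats = []
        for truth, stack in simulate_classification_batch(27, seed=4):
            pt = parse_dotbracket(truth.precursor.structure)
            prof = duplex_profile(pt, truth.precursor.sequence, truth.mature, truth.star)
            ev = summarize_evidence(stack, truth.mature, truth.star)
            call = classify(evaluate_rules(prof, ev, truth.precursor, True, Thresholds()))
            cats.append(call.category)
        assert cats.count(CATEGORY_VERY_HIGH) <= cats.count(CATEGORY_VERY_HIGH) + cats.count(CATEGORY_HIGH)
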