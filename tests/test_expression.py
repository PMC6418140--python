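import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_count_matrix
from oracles import bh_oracle

from mircurate.errors import ParameterError
from mircurate.evidence import AlignedRead, ReadStack
from mircurate.expression import (
    CountMatrix,
    SampleSheet,
    bh_adjust,
    ddct,
    de_all_contrasts,
    nb_test,
    quantify,
    size_factors,
    tpm,
)
from mircurate.hairpin import Interval
from mircurate.simulate import make_hairpin

PRE, MATURE, STAR = make_hairpin(seed=33)
SEQ = PRE.sequence


def _read(start, length, count, lib="s1", mm=()):
    return AlignedRead(SEQ[start : start + length], start, count, lib, mm)


class TestQuantify:
    def test_exact_reads_counted(self):
        s = ReadStack(PRE.id, [_read(MATURE.start, len(MATURE), 100)])
        assert quantify(s, MATURE) == {"s1": 100}

    def test_two_mismatches_excluded(self):
        r = AlignedRead(SEQ[MATURE.start : MATURE.end], MATURE.start, 10, "s1", (3, 7))
        assert quantify(ReadStack(PRE.id, [r]), MATURE) == {}

    def test_one_mismatch_included(self):
        r = AlignedRead(SEQ[MATURE.start : MATURE.end], MATURE.start, 10, "s1", (3,))
        assert quantify(ReadStack(PRE.id, [r]), MATURE) == {"s1": 10}

    def test_three_nt_upstream_excluded(self):
        s = ReadStack(PRE.id, [_read(MATURE.start - 3, len(MATURE), 10)])
        assert quantify(s, MATURE) == {}

    def test_two_nt_upstream_included(self):
        s = ReadStack(PRE.id, [_read(MATURE.start - 2, len(MATURE), 10)])
        assert quantify(s, MATURE) == {"s1": 10}

    def test_per_library_split(self):
        s = ReadStack(
            PRE.id,
            [
                _read(MATURE.start, len(MATURE), 10, lib="a"),
                _read(MATURE.start, len(MATURE), 20, lib="b"),
            ],
        )
        assert quantify(s, MATURE) == {"a": 10, "b": 20}


class TestTpm:
    def test_formula(self, two_stage_sheet):
        cm = make_count_matrix(np.full((1, 6), 100), two_stage_sheet)
        assert tpm(cm).iloc[0, 0] == pytest.approx(100.0)

    def test_zero_count(self, two_stage_sheet):
        cm = make_count_matrix(np.zeros((2, 6), dtype=int), two_stage_sheet)
        assert (tpm(cm).values == 0).all()

    def test_scale_invariance(self, two_stage_sheet):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(20, 6))
        cm1 = make_count_matrix(counts, two_stage_sheet)
        doubled_sheet = SampleSheet(
            two_stage_sheet.table.assign(
                genome_mapped_reads=two_stage_sheet.table.genome_mapped_reads * 2
            )
        )
        cm2 = CountMatrix(cm1.counts * 2, doubled_sheet)
        pd.testing.assert_frame_equal(tpm(cm1), tpm(cm2))

    def test_column_sum_conservation(self, two_stage_sheet):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 500, size=(30, 6))
        cm = make_count_matrix(counts, two_stage_sheet)
        t = tpm(cm)
        gm = two_stage_sheet.table["genome_mapped_reads"]
        for col in t.columns:
            assert t[col].sum() == pytest.approx(1e6 * counts_sum(cm, col) / gm[col])


def counts_sum(cm, col):
    return cm.counts[col].sum()


class TestSizeFactors:
    def test_identical_samples_unit_factors(self, two_stage_sheet):
        counts = np.tile(np.arange(1, 11).reshape(-1, 1), (1, 6))
        f = size_factors(make_count_matrix(counts, two_stage_sheet).counts)
        assert np.allclose(f, 1.0)

    def test_doubled_sample_factor_ratio_two(self, two_stage_sheet):
        base = np.arange(1, 11).reshape(-1, 1)
        counts = np.hstack([np.tile(base, (1, 3)), np.tile(base * 2, (1, 3))])
        f = size_factors(make_count_matrix(counts, two_stage_sheet).counts)
        assert f.iloc[3] / f.iloc[0] == pytest.approx(2.0)

    def test_geometric_mean_one(self, two_stage_sheet):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 1000, size=(50, 6))
        f = size_factors(make_count_matrix(counts, two_stage_sheet).counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_fallback_to_totals_without_positive_row(self):
        # 3x3 toy with a zero in every row; hand-computed total-count ratios
        counts = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [2, 4, 0]], columns=["a", "b", "c"]
        )
        f = size_factors(counts)
        totals = np.array([4.0, 6.0, 8.0])
        expected = totals / np.exp(np.mean(np.log(totals)))
        assert np.allclose(f, expected)


class TestBH:
    def test_matches_oracle_exhaustively_for_small_inputs(self):
        grid = [0.001, 0.01, 0.04, 0.2, 0.5, 1.0]
        for n in range(1, 5):
            for ps in itertools.product(grid, repeat=n):
                assert np.allclose(bh_adjust(list(ps)), bh_oracle(list(ps)))

    def test_six_value_permutations(self):
        base = [0.001, 0.008, 0.039, 0.041, 0.27, 0.9]
        for perm in itertools.permutations(base):
            assert np.allclose(bh_adjust(list(perm)), bh_oracle(list(perm)))

    def test_monotone_in_raw_p_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_empty(self):
        assert bh_adjust([]).size == 0


class TestNbTest:
    def test_identical_stage_means_zero_lfc(self, two_stage_sheet):
        counts = np.tile(np.array([[100], [200]]), (1, 6))
        res = nb_test(make_count_matrix(counts, two_stage_sheet), "young", "mature")
        assert all(r.log2fc == 0 for r in res)
        assert all(r.p == 1.0 for r in res)

    def test_all_zero_row(self, two_stage_sheet):
        counts = np.zeros((3, 6), dtype=int)
        counts[0] = [10, 12, 9, 50, 48, 52]
        res = nb_test(make_count_matrix(counts, two_stage_sheet), "young", "mature")
        assert res[1].p == 1.0 and res[1].log2fc == 0.0

    def test_antisymmetry_of_contrast_direction(self, two_stage_sheet):
        rng = np.random.default_rng(2)
        counts = rng.integers(10, 500, size=(30, 6))
        cm = make_count_matrix(counts, two_stage_sheet)
        fwd = nb_test(cm, "mature", "young")
        rev = nb_test(cm, "young", "mature")
        for a, b in zip(fwd, rev):
            assert a.log2fc == pytest.approx(-b.log2fc)
            assert a.p == pytest.approx(b.p)

    def test_invariant_to_replicate_relabeling(self, two_stage_sheet):
        rng = np.random.default_rng(3)
        counts = rng.integers(10, 500, size=(20, 6))
        cm1 = make_count_matrix(counts, two_stage_sheet)
        shuffled = counts[:, [2, 0, 1, 4, 5, 3]]  # permute within stages
        cm2 = make_count_matrix(shuffled, two_stage_sheet)
        r1 = nb_test(cm1, "young", "mature")
        r2 = nb_test(cm2, "young", "mature")
        for a, b in zip(r1, r2):
            assert a.p == pytest.approx(b.p)
            assert a.log2fc == pytest.approx(b.log2fc)

    def test_requires_two_replicates(self):
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "stage": ["young", "mature", "mature"],
                    "replicate": [1, 1, 2],
                    "genome_mapped_reads": 1000,
                },
                index=pd.Index(["a", "b", "c"], name="sample_id"),
            )
        )
        cm = CountMatrix(
            pd.DataFrame([[1, 2, 3]], columns=["a", "b", "c"], index=["m"]), sheet
        )
        with pytest.raises(ParameterError):
            nb_test(cm, "young", "mature")

    def test_strong_effect_detected(self, two_stage_sheet):
        rng = np.random.default_rng(4)
        null = rng.poisson(200, size=(50, 6))
        eff = np.hstack([rng.poisson(100, size=(5, 3)), rng.poisson(1600, size=(5, 3))])
        cm = make_count_matrix(np.vstack([null, eff]), two_stage_sheet)
        res = nb_test(cm, "young", "mature")
        assert all(r.significant for r in res[50:])


class TestDeAllContrasts:
    def test_three_contrasts_present(self, sheet_3v3):
        rng = np.random.default_rng(6)
        counts = rng.integers(10, 400, size=(10, 9))
        df = de_all_contrasts(make_count_matrix(counts, sheet_3v3))
        assert set(df["contrast"]) == {
            "intermediate/young",
            "mature/intermediate",
            "mature/young",
        }
        assert len(df) == 30


class TestDdct:
    def test_one_cycle_halves(self):
        assert ddct(25, 20, 24, 20) == pytest.approx(0.5)

    def test_zero_is_unity(self):
        assert ddct(24, 20, 24, 20) == pytest.approx(1.0)

    @given(
        a=st.floats(10, 35),
        b=st.floats(10, 35),
        c=st.floats(10, 35),
        d=st.floats(10, 35),
    )
    def test_closed_form(self, a, b, c, d):
        assert ddct(a, b, c, d) == pytest.approx(2 ** -((a - b) - (c - d)))
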