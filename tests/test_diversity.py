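"""Diversity/divergence estimators against worked values and brute-force
oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from relictpop.diversity import (
    dxy_windows,
    fst_windows,
    het_fis,
    pi_windows,
    relatedness_ajk,
    summarize,
)
from tests import oracles
from tests.conftest import make_cohort, random_cohort

WHOLE = 10**9  # one window spanning everything


def pooled(windows):
    num = sum(w.n_diffs for w in windows)
    den = sum(w.n_comps for w in windows)
    return num / den if den else math.nan


class TestPi:
    def test_worked_toy(self):
        # 2 diploids, 10 fully-called sites, one site 0/0 vs 1/1
        d = np.zeros((2, 10), dtype=np.int8)
        d[1, 3] = 2
        m = make_cohort(d, groups={"s0": "g", "s1": "g"})
        (w,) = pi_windows(m, "g", window_bp=WHOLE)
        assert (w.n_diffs, w.n_comps) == (4, 60)
        assert w.value == pytest.approx(4 / 60)

    def test_identical_homozygous_is_zero(self):
        m = make_cohort(np.full((4, 8), 2, dtype=np.int8),
                        groups={f"s{i}": "g" for i in range(4)})
        (w,) = pi_windows(m, "g", window_bp=WHOLE)
        assert w.value == 0.0

    @pytest.mark.parametrize("missing", [0.0, 0.2])
    def test_oracle_equality(self, rng, missing):
        for _ in range(10):
            m = random_cohort(rng, 6, 200, missing_rate=missing,
                              groups={f"s{i}": "g" for i in range(6)})
            (w,) = pi_windows(m, "g", window_bp=WHOLE)
            assert w.value == pytest.approx(oracles.pooled_pi(m.dosages), abs=1e-12)

    def test_undefined_window_is_nan_not_zero(self):
        d = np.full((2, 3), -1, dtype=np.int8)
        m = make_cohort(d, groups={"s0": "g", "s1": "g"})
        (w,) = pi_windows(m, "g", window_bp=WHOLE)
        assert math.isnan(w.value)
        assert w.n_comps == 0

    def test_ref_alt_swap_invariance(self, rng):
        m = random_cohort(rng, 5, 100, groups={f"s{i}": "g" for i in range(5)})
        swapped = make_cohort(
            np.where(m.dosages >= 0, 2 - m.dosages, -1),
            positions=m.positions(),
            groups={f"s{i}": "g" for i in range(5)},
        )
        assert pooled(pi_windows(m, "g", WHOLE)) == pytest.approx(
            pooled(pi_windows(swapped, "g", WHOLE)), abs=1e-12
        )

    def test_adding_invariant_sites_lowers_pi(self, rng):
        groups = {f"s{i}": "g" for i in range(5)}
        m = random_cohort(rng, 5, 50, groups=groups)
        base = pooled(pi_windows(m, "g", WHOLE))
        padded = make_cohort(
            np.concatenate([m.dosages, np.zeros((5, 50), dtype=np.int8)], axis=1),
            positions=np.concatenate([m.positions(), m.positions().max() + np.arange(1, 51)]),
            groups=groups,
        )
        assert pooled(pi_windows(padded, "g", WHOLE)) < base

    def test_window_tiling_anchored_at_one(self):
        groups = {"s0": "g", "s1": "g"}
        d = np.array([[0, 1], [2, 1]], dtype=np.int8)
        m = make_cohort(d, positions=[500, 15_000], groups=groups)
        wins = pi_windows(m, "g", window_bp=10_000)
        assert [(w.start, w.end) for w in wins] == [(1, 10_001), (10_001, 20_001)]
        assert wins[1].partial


class TestDxy:
    def test_worked_toy(self):
        d = np.zeros((2, 10), dtype=np.int8)
        d[1, :] = 0
        d[1, 0] = 2  # pop B diploid 1/1 at one site
        m = make_cohort(d, groups={"s0": "A", "s1": "B"})
        (w,) = dxy_windows(m, "A", "B", window_bp=WHOLE)
        assert (w.n_diffs, w.n_comps) == (4, 40)
        assert w.value == pytest.approx(0.1)

    def test_monomorphic_identical_groups(self):
        m = make_cohort(np.zeros((4, 6), dtype=np.int8),
                        groups={"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        (w,) = dxy_windows(m, "A", "B", window_bp=WHOLE)
        assert w.value == 0.0

    def test_symmetry(self, rng):
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        for _ in range(5):
            m = random_cohort(rng, 6, 100, missing_rate=0.15, groups=groups)
            assert pooled(dxy_windows(m, "A", "B", WHOLE)) == pytest.approx(
                pooled(dxy_windows(m, "B", "A", WHOLE)), abs=1e-12
            )

    def test_oracle_equality(self, rng):
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(7)}
        for _ in range(8):
            m = random_cohort(rng, 7, 150, missing_rate=0.2, groups=groups)
            got = pooled(dxy_windows(m, "A", "B", WHOLE))
            want = oracles.pooled_dxy(m.dosages[:3], m.dosages[3:])
            assert got == pytest.approx(want, abs=1e-12)

    def test_disjoint_groups_required(self, rng):
        m = random_cohort(rng, 4, 10, groups={f"s{i}": "A" for i in range(4)})
        with pytest.raises(ValueError, match="disjoint"):
            dxy_windows(m, ["s0", "s1"], ["s1", "s2"])


class TestFst:
    def test_fixed_difference_is_one(self):
        d = np.array([[0, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8)
        m = make_cohort(d, groups={"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        (w,) = fst_windows(m, "A", "B", window_bp=WHOLE)
        assert w.value == pytest.approx(1.0)

    def test_oracle_equality(self, rng):
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(9)}
        for _ in range(8):
            m = random_cohort(rng, 9, 120, missing_rate=0.15, groups=groups)
            (w,) = fst_windows(m, "A", "B", window_bp=WHOLE)
            want = oracles.pooled_fst(m.dosages[:4], m.dosages[4:])
            assert w.value == pytest.approx(want, abs=1e-12)

    def test_invariant_sites_contribute_zero(self, rng):
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        m = random_cohort(rng, 6, 60, groups=groups)
        (w1,) = fst_windows(m, "A", "B", window_bp=WHOLE)
        padded = make_cohort(
            np.concatenate([m.dosages, np.zeros((6, 40), dtype=np.int8)], axis=1),
            positions=np.concatenate([m.positions(), m.positions().max() + np.arange(1, 41)]),
            groups=groups,
        )
        (w2,) = fst_windows(padded, "A", "B", window_bp=WHOLE)
        assert w1.value == pytest.approx(w2.value, abs=1e-12)

    def test_hudson_flag(self, rng):
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        m = random_cohort(rng, 6, 80, groups=groups)
        (w,) = fst_windows(m, "A", "B", window_bp=WHOLE, estimator="hudson")
        assert -1.0 <= w.value <= 1.0

    def test_all_invariant_undefined(self):
        m = make_cohort(np.zeros((4, 5), dtype=np.int8),
                        groups={"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        (w,) = fst_windows(m, "A", "B", window_bp=WHOLE)
        assert math.isnan(w.value)


class TestHetFis:
    def test_two_heterozygotes(self):
        m = make_cohort([[1], [1]])
        r0, r1 = het_fis(m)
        for r in (r0, r1):
            assert r.obs_hom == 0
            assert r.exp_hom == pytest.approx(1 / 3)
            assert r.fis == pytest.approx(-0.5)
            assert r.he == 1.0

    def test_fully_homozygous_polymorphic(self):
        m = make_cohort([[0, 0], [2, 2]])
        for r in het_fis(m):
            assert r.he == 0.0
            assert r.fis == pytest.approx(1.0)

    def test_oracle_equality(self, rng):
        for _ in range(6):
            m = random_cohort(rng, 8, 100, missing_rate=0.2)
            reports = het_fis(m)
            for i, r in enumerate(reports):
                obs, exp, n_called = oracles.fis_individual(m.dosages, i)
                assert r.obs_hom == obs
                assert r.exp_hom == pytest.approx(exp, abs=1e-10)
                assert r.n_called == n_called
                if n_called != exp:
                    assert r.fis == pytest.approx((obs - exp) / (n_called - exp), abs=1e-10)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            het_fis(make_cohort([[1]]))


class TestRelatedness:
    def test_double_het_term_zero(self):
        m = make_cohort([[1], [1]])
        (pair,) = relatedness_ajk(m)
        assert pair.ajk == pytest.approx(0.0)

    def test_shared_homalt_term_two(self):
        # cohort frequency p = 0.5 with two 1/1 and two 0/0 individuals
        m = make_cohort([[2], [2], [0], [0]])
        pairs = {(p.sample_j, p.sample_k): p.ajk for p in relatedness_ajk(m)}
        assert pairs[("s0", "s1")] == pytest.approx(2.0)

    def test_oracle_equality(self, rng):
        for _ in range(5):
            m = random_cohort(rng, 7, 120, missing_rate=0.2)
            for p in relatedness_ajk(m):
                j = m.samples.index(p.sample_j)
                k = m.samples.index(p.sample_k)
                want = oracles.ajk_pair(m.dosages, j, k)
                assert p.ajk == pytest.approx(want, abs=1e-10)

    def test_duplicate_sample_ranks_highest(self, rng):
        m = random_cohort(rng, 6, 300)
        dup = make_cohort(
            np.concatenate([m.dosages, m.dosages[:1]], axis=0),
            positions=m.positions(),
            sample_names=[f"s{i}" for i in range(6)] + ["clone"],
        )
        pairs = relatedness_ajk(dup)
        best = max(pairs, key=lambda p: p.ajk)
        assert {best.sample_j, best.sample_k} == {"s0", "clone"}


class TestSummarize:
    def _win(self, diffs, comps):
        from relictpop.diversity import DiversityWindow

        return DiversityWindow("A01", 1, 10_001, 1, diffs, comps,
                               diffs / comps if comps else math.nan, "pi")

    def test_single_window_equals_value(self):
        df = summarize([self._win(3, 30)])
        genome = df[df.chrom == "genome"].iloc[0]
        assert genome.pooled == pytest.approx(0.1)
        assert genome.window_mean == pytest.approx(0.1)

    def test_hand_arithmetic(self):
        df = summarize([self._win(1, 10), self._win(3, 10)])
        g = df[df.chrom == "genome"].iloc[0]
        assert g.pooled == pytest.approx(0.2)
        assert g.window_mean == pytest.approx(0.2)
        df2 = summarize([self._win(1, 10), self._win(3, 30)])
        g2 = df2[df2.chrom == "genome"].iloc[0]
        assert g2.pooled == pytest.approx(0.1)
        assert g2.window_mean == pytest.approx(0.1)

    def test_pooled_invariant_under_window_size(self, rng):
        groups = {f"s{i}": "g" for i in range(4)}
        m = random_cohort(rng, 4, 200, groups=groups)
        p1 = pooled(pi_windows(m, "g", window_bp=1000))
        p2 = pooled(pi_windows(m, "g", window_bp=WHOLE))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_nan_windows_excluded_from_mean(self):
        df = summarize([self._win(1, 10), self._win(0, 0)])
        g = df[df.chrom == "genome"].iloc[0]
        assert g.n_defined == 1
        assert g.window_mean == pytest.approx(0.1)
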