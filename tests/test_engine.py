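"""Two-sided plumbus construction, combination, and exact moments."""

from __future__ import annotations

import numpy as np
import pytest
from numpy.testing import assert_allclose

from coloctx import (
    Annotation,
    ContextAwareMarkovChain,
    GenomeContext,
    brute_force,
    combine,
    finalize,
    moments,
    nstep,
    stationary,
)
from coloctx.engine import (
    bases_interval_plumbus,
    gap_plumbus,
    identity_plumbus,
    overlap_interval_plumbus,
)

from conftest import random_tiny_instance

T_DEMO = np.array([[0.8, 0.2], [0.3, 0.7]])


def _single_class(L, T=T_DEMO, label="bg"):
    chain = ContextAwareMarkovChain({label: T})
    ctx = GenomeContext.single_class({"chr1": L}, label=label)
    return chain, ctx


class TestGapPlumbus:
    def test_empty_span_is_identity(self):
        chain, ctx = _single_class(10)
        p = gap_plumbus(chain, ctx, "chr1", 3, 3)
        assert_allclose(p.psi, np.eye(2))
        assert_allclose(p.mu, 0)
        assert_allclose(p.var, 0)

    def test_single_class_span_is_nstep(self):
        chain, ctx = _single_class(10)
        p = gap_plumbus(chain, ctx, "chr1", 2, 7)
        assert_allclose(p.psi, nstep(T_DEMO, 5), atol=1e-12)

    def test_two_class_span_is_matrix_product(self):
        TA = np.array([[0.6, 0.4], [0.1, 0.9]])
        TB = np.array([[0.7, 0.3], [0.5, 0.5]])
        chain = ContextAwareMarkovChain({"A": TA, "B": TB})
        ctx = GenomeContext(
            starts={"chr1": np.array([0, 2])}, labels={"chr1": ["A", "B"]}, lengths={"chr1": 5}
        )
        p = gap_plumbus(chain, ctx, "chr1", 0, 5)
        expect = np.linalg.matrix_power(TA, 2) @ np.linalg.matrix_power(TB, 3)
        assert_allclose(p.psi, expect, atol=1e-12)


class TestOverlapPlumbus:
    def test_length_one_interval(self):
        chain, ctx = _single_class(10)
        p = overlap_interval_plumbus(chain, ctx, "chr1", 4, 5)
        for x in (0, 1):
            for y in (0, 1):
                assert p.mu[x, y] == pytest.approx(y)
                assert p.var[x, y] == pytest.approx(0.0)
                assert p.psi[x, y] == pytest.approx(T_DEMO[x, y])

    def test_length_two_conditional_mean(self):
        # z(0) = 0.8*0.8 = 0.64, psi(0->0) = 0.70, mu = 1 - 0.64/0.70
        chain, ctx = _single_class(10)
        p = overlap_interval_plumbus(chain, ctx, "chr1", 4, 6)
        mu = 1 - 0.64 / 0.70
        assert p.mu[0, 0] == pytest.approx(mu, abs=1e-10)
        assert p.var[0, 0] == pytest.approx(mu * (1 - mu), abs=1e-10)

    def test_final_state_one_forces_overlap(self):
        chain, ctx = _single_class(12)
        p = overlap_interval_plumbus(chain, ctx, "chr1", 2, 9)
        assert_allclose(p.mu[:, 1], 1.0)
        assert_allclose(p.var[:, 1], 0.0)


class TestBasesPlumbus:
    def test_length_one_base_case(self):
        chain, ctx = _single_class(10)
        p = bases_interval_plumbus(chain, ctx, "chr1", 4, 5)
        assert_allclose(p.mu, [[0, 1], [0, 1]])
        assert_allclose(p.var, 0)

    def test_length_two_matches_enumeration(self):
        # condition on (x, y); sum over the single inner state m
        chain, ctx = _single_class(10)
        p = bases_interval_plumbus(chain, ctx, "chr1", 4, 6)
        T = T_DEMO
        for x in (0, 1):
            for y in (0, 1):
                w = np.array([T[x, m] * T[m, y] for m in (0, 1)])
                psi = w.sum()
                w = w / psi
                vals = np.array([0 + y, 1 + y], dtype=float)
                mean = w @ vals
                var = w @ (vals - mean) ** 2
                assert p.psi[x, y] == pytest.approx(psi, abs=1e-12)
                assert p.mu[x, y] == pytest.approx(mean, abs=1e-12)
                assert p.var[x, y] == pytest.approx(var, abs=1e-12)

    def test_doubling_equals_left_fold(self):
        chain, ctx = _single_class(10)
        ladder = bases_interval_plumbus(chain, ctx, "chr1", 2, 7)  # length 5
        single = bases_interval_plumbus(chain, ctx, "chr1", 2, 3)
        acc = single
        for k in range(3, 7):
            acc = combine(acc, bases_interval_plumbus(chain, ctx, "chr1", k, k + 1))
        assert_allclose(ladder.mu, acc.mu, atol=1e-10)
        assert_allclose(ladder.var, acc.var, atol=1e-10)
        assert_allclose(ladder.psi, acc.psi, atol=1e-10)


class TestCombine:
    def test_identity_element(self):
        chain, ctx = _single_class(10)
        p = overlap_interval_plumbus(chain, ctx, "chr1", 2, 6)
        q = combine(p, identity_plumbus(start=6))
        assert_allclose(q.mu, p.mu, atol=1e-14)
        assert_allclose(q.var, p.var, atol=1e-14)
        assert_allclose(q.psi, p.psi, atol=1e-14)

    def test_associativity_on_random_chains(self, rng):
        for _ in range(20):
            T = rng.uniform(0.05, 0.95, (2, 2))
            T /= T.sum(1, keepdims=True)
            chain, ctx = _single_class(12, T)
            p1 = bases_interval_plumbus(chain, ctx, "chr1", 0, 3)
            p2 = gap_plumbus(chain, ctx, "chr1", 3, 7)
            p3 = bases_interval_plumbus(chain, ctx, "chr1", 7, 12)
            left = combine(combine(p1, p2), p3)
            right = combine(p1, combine(p2, p3))
            assert_allclose(left.mu, right.mu, atol=1e-10)
            assert_allclose(left.var, right.var, atol=1e-10)
            assert_allclose(left.psi, right.psi, atol=1e-10)

    def test_non_adjacent_spans_rejected(self):
        chain, ctx = _single_class(10)
        p = gap_plumbus(chain, ctx, "chr1", 0, 3)
        q = gap_plumbus(chain, ctx, "chr1", 5, 8)
        with pytest.raises(Exception, match="adjacent"):
            combine(p, q)

    def test_three_positions_match_enumeration(self):
        # v = number of covered bases over a 3-position chromosome
        chain, ctx = _single_class(3)
        full = bases_interval_plumbus(chain, ctx, "chr1", 0, 3)
        T = T_DEMO
        for x in (0, 1):
            acc = {}  # y -> list of (prob, value)
            for s0 in (0, 1):
                for s1 in (0, 1):
                    for s2 in (0, 1):
                        pr = T[x, s0] * T[s0, s1] * T[s1, s2]
                        acc.setdefault(s2, []).append((pr, s0 + s1 + s2))
            for y, items in acc.items():
                psi = sum(p for p, _ in items)
                mean = sum(p * v for p, v in items) / psi
                var = sum(p * (v - mean) ** 2 for p, v in items) / psi
                assert full.psi[x, y] == pytest.approx(psi, abs=1e-12)
                assert full.mu[x, y] == pytest.approx(mean, abs=1e-12)
                assert full.var[x, y] == pytest.approx(var, abs=1e-12)


class TestFinalize:
    def test_single_position_bernoulli(self):
        T = np.array([[0.9, 0.1], [0.5, 0.5]])
        chain, ctx = _single_class(1, T)
        full = overlap_interval_plumbus(chain, ctx, "chr1", 0, 1)
        mean, var = finalize(full, stationary(T))
        assert mean == pytest.approx(1 / 6, abs=1e-12)
        assert var == pytest.approx(5 / 36, abs=1e-12)

    def test_constant_statistic_has_zero_variance(self):
        p = identity_plumbus()
        p.mu = np.full((2, 2), 3.0)
        p.psi = np.array([[0.5, 0.5], [0.2, 0.8]])
        mean, var = finalize(p, np.array([0.4, 0.6]))
        assert mean == pytest.approx(3.0)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_unnormalized_init_rejected(self):
        chain, ctx = _single_class(3)
        full = bases_interval_plumbus(chain, ctx, "chr1", 0, 3)
        with pytest.raises(Exception, match="sum"):
            finalize(full, np.array([0.5, 0.6]))

    def test_small_chromosome_matches_enumeration(self):
        chain, ctx = _single_class(12)
        R = Annotation({"chr1": np.array([[2, 4], [7, 9]])}, {"chr1": 12})
        mom = moments(chain, ctx, R, "overlaps")
        bf = brute_force(chain, ctx, R, "overlaps")
        assert mom.mean == pytest.approx(bf.mean(), abs=1e-9)
        assert mom.variance == pytest.approx(bf.variance(), abs=1e-9)


class TestMoments:
    def test_identical_chromosomes_double(self):
        T = np.array([[0.9, 0.1], [0.4, 0.6]])
        chain = ContextAwareMarkovChain({"bg": T})
        iv = np.array([[2, 5], [8, 9]])
        one = moments(
            chain,
            GenomeContext.single_class({"a": 12}, label="bg"),
            Annotation({"a": iv}, {"a": 12}),
            "bases",
        )
        two = moments(
            chain,
            GenomeContext.single_class({"a": 12, "b": 12}, label="bg"),
            Annotation({"a": iv, "b": iv.copy()}, {"a": 12, "b": 12}),
            "bases",
        )
        assert two.mean == pytest.approx(2 * one.mean, abs=1e-12)
        assert two.variance == pytest.approx(2 * one.variance, abs=1e-12)

    def test_stationary_bases_mean(self):
        # at stationarity every position is covered with probability pi_1
        T = np.array([[0.9, 0.1], [0.5, 0.5]])
        chain, ctx = _single_class(40, T)
        R = Annotation({"chr1": np.array([[3, 9], [20, 24]])}, {"chr1": 40})
        mom = moments(chain, ctx, R, "bases")
        assert mom.mean == pytest.approx(10 / 6, abs=1e-10)

    def test_empty_reference(self):
        chain, ctx = _single_class(10)
        R = Annotation({"chr1": np.empty((0, 2), int)}, {"chr1": 10})
        mom = moments(chain, ctx, R, "overlaps")
        assert mom.mean == 0.0
        assert mom.variance == 0.0

    @pytest.mark.parametrize("statistic", ["overlaps", "bases"])
    def test_matches_brute_force_on_random_instances(self, statistic):
        rng = np.random.default_rng(42 if statistic == "overlaps" else 43)
        checked = 0
        for _ in range(40):
            chain, ctx, R = random_tiny_instance(rng)
            bf = brute_force(chain, ctx, R, statistic)
            mom = moments(chain, ctx, R, statistic)
            assert mom.mean == pytest.approx(bf.mean(), abs=1e-9)
            assert mom.variance == pytest.approx(bf.variance(), abs=1e-9)
            assert mom.variance >= 0.0
            checked += 1
        assert checked == 40

    def test_combine_counter_scales_linearly_for_overlaps(self):
        chain = None
        counts = []
        sizes = [50, 200, 800]
        for n in sizes:
            L = 20_000
            starts = np.arange(n) * (L // n)
            R = Annotation({"chr1": np.column_stack([starts, starts + 5])}, {"chr1": L})
            chain, ctx = _single_class(L)
            mom = moments(chain, ctx, R, "overlaps")
            counts.append(mom.combine_calls)
        slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_bases_counter_exceeds_overlaps_by_log_factor(self):
        chain, ctx = _single_class(20_000)
        starts = np.arange(100) * 150
        R = Annotation({"chr1": np.column_stack([starts, starts + 64])}, {"chr1": 20_000})
        mk = moments(chain, ctx, R, "overlaps")
        mb = moments(chain, ctx, R, "bases")
        # t = 64 = 2^6: one ladder term per interval plus ladder construction
        assert mb.combine_calls > mk.combine_calls
        assert mb.combine_calls <= mk.combine_calls * np.log2(64) + 64
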