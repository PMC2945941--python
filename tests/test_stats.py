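import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctxbias as cb
from ctxbias.align_io import AlignmentBlock
from ctxbias.stats import (
    PatternStatistic,
    TotalBiasStatistic,
    _central_ci,
    _sample_multiplicities,
    bh_fdr,
    bootstrap_ci,
    bootstrap_values,
    compare_total_bias,
    empirical_pvalues,
    median_total_bias_by_sample_size,
)


def brute_force_bh(p):
    """Step-up definition applied literally (independent oracle)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        q[i] = min(best, 1.0)
    return q


class TestBhFdr:
    def test_worked_example(self):
        got = bh_fdr([0.001, 0.01, 0.02, 0.8])
        assert got == pytest.approx([0.004, 0.02, 0.8 / 30, 0.8], rel=1e-12)

    def test_flat_case(self):
        got = bh_fdr([0.3] * 5)
        assert got == pytest.approx([0.3] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_empty(self):
        assert bh_fdr([]).size == 0

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force(self, p):
        assert bh_fdr(p) == pytest.approx(brute_force_bh(p), rel=1e-12)

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            assert bh_fdr(p) == pytest.approx(brute_force_bh(list(p)), rel=1e-12)


class TestEmpiricalPvalues:
    def test_add_one_formula(self):
        # real value above every pooled null: 10 controls x 100 values -> 1/1001
        real = {"CG->TG": 5.0}
        controls = [
            {f"{a}->{d}": 0.1 for a, d in _all_pairs(100)} for _ in range(10)
        ]
        p = empirical_pvalues(real, controls, pooling="per_length")
        assert p["CG->TG"] == pytest.approx(1 / 1001)

    def test_rank_bottom_case(self):
        real = {"CG->TG": 0.0}
        controls = [{"AA->AC": 0.2, "AC->AA": -0.3}]
        p = empirical_pvalues(real, controls)
        assert p["CG->TG"] == 1.0

    def test_per_pattern_pooling(self):
        real = {"CG->TG": 1.0}
        controls = [{"CG->TG": 0.5}, {"CG->TG": 2.0}, {"CG->TG": 0.1}]
        p = empirical_pvalues(real, controls, pooling="per_pattern")
        assert p["CG->TG"] == pytest.approx((1 + 1) / (1 + 3))

    def test_empty_controls_error(self):
        with pytest.raises(ValueError):
            empirical_pvalues({"CG->TG": 1.0}, [])

    def test_lengths_pooled_separately(self):
        real = {"CG->TG": 0.5, "CAG->CTG": 0.5}
        controls = [{"AA->AT": 0.9, "AAA->ATA": 0.1}]
        p = empirical_pvalues(real, controls)
        assert p["CG->TG"] == pytest.approx(2 / 2)
        assert p["CAG->CTG"] == pytest.approx(1 / 2)


def _all_pairs(n):
    out = []
    for i in range(n):
        a = "ACGT"[i % 4] + "ACGT"[(i // 4) % 4]
        d = "ACGT"[(i // 16) % 4] + "ACGT"[(i // 64) % 4]
        out.append((a, d))
    return out


class TestSampling:
    def test_reaches_target_keeping_last_block_whole(self):
        rng = np.random.default_rng(0)
        columns = np.array([100, 250, 60])
        for _ in range(20):
            mult = _sample_multiplicities(rng, columns, 1000)
            total = int((mult * columns).sum())
            # reaches the target, overshooting by at most one whole block
            assert 1000 <= total < 1000 + columns.max()

    def test_deterministic(self):
        cols = np.array([50, 70, 90])
        a = _sample_multiplicities(np.random.default_rng(1), cols, 500)
        b = _sample_multiplicities(np.random.default_rng(1), cols, 500)
        assert np.array_equal(a, b)


class TestBootstrapCi:
    def _blocks(self, seed=13, length=100_000):
        return cb.simulate_blocks(
            length, seed=seed, rules=[cb.ContextRule("C", "T", "CG", 0, 8.0)],
            block_length=5_000,
        )

    def test_reproducible_bit_for_bit(self):
        blocks = self._blocks()
        stat = PatternStatistic.for_keys(["CG->TG"])
        a = bootstrap_ci(blocks, stat, n_boot=100, seed=5)
        b = bootstrap_ci(blocks, stat, n_boot=100, seed=5)
        ka = a["rho:CG->TG"]
        kb = b["rho:CG->TG"]
        assert (ka.ci_low, ka.ci_high, ka.se) == (kb.ci_low, kb.ci_high, kb.se)

    def test_identical_blocks_zero_width_ci(self):
        block = AlignmentBlock("b", "CACGCATTGACCAGTA" * 20, "CATGCATTGACCAGTA" * 20)
        blocks = [AlignmentBlock(f"b{i}", block.ancestor, block.descendant) for i in range(4)]
        res = bootstrap_ci(blocks, PatternStatistic.for_keys(["CG->TG"]), n_boot=100, seed=1)
        s = res["rho:CG->TG"]
        assert s.ci_low == s.ci_high == s.point

    def test_ci_bounds_are_order_statistics(self):
        blocks = self._blocks(seed=17, length=50_000)
        stat = PatternStatistic.for_keys(["CG->TG"], kinds=("rho",))
        n_boot = 200
        values = bootstrap_values(blocks, stat, n_boot=n_boot, seed=3)["rho:CG->TG"]
        res = bootstrap_ci(blocks, stat, n_boot=n_boot, seed=3)["rho:CG->TG"]
        ordered = np.sort([v for v in values if v is not None])
        k = int(np.floor(0.025 * n_boot))  # order stats 26/975 for n_boot=1000
        assert res.ci_low == ordered[k]
        assert res.ci_high == ordered[n_boot - 1 - k]

    def test_middle_950_indices(self):
        lo, hi = _central_ci(np.arange(1000, dtype=float), 1000)
        assert (lo, hi) == (25.0, 974.0)  # 26th and 975th smallest

    def test_undefined_statistic_flagged(self):
        blocks = [
            AlignmentBlock("a", "ACAC" * 50, "ACAC" * 50),
            AlignmentBlock("b", "AGAG" * 50, "AGAG" * 50),
        ]
        res = bootstrap_ci(
            blocks, PatternStatistic.for_keys(["TT->TT"], kinds=("rho",)),
            n_boot=50, seed=2,
        )
        s = res["rho:TT->TT"]
        assert s.undefined_ci
        assert s.ci_low is None and s.point is None

    def test_preconditions(self):
        blocks = self._blocks(length=20_000)
        with pytest.raises(ValueError):
            bootstrap_ci(blocks[:1], PatternStatistic.for_keys(["CG->TG"]), 100, 0)
        with pytest.raises(ValueError):
            bootstrap_ci(blocks, PatternStatistic.for_keys(["CG->TG"]), n_boot=1, seed=0)


class TestCompareTotalBias:
    def test_identical_datasets_t_zero_p_one(self):
        blocks = [
            AlignmentBlock(f"b{i}", "CACGCATTGACCAGTA" * 20, "CATGCATTGACCAGTA" * 20)
            for i in range(4)
        ]
        res = compare_total_bias(
            blocks, blocks, [2], columns_per_sample=1000, n_resamples=50, seed=3
        )
        assert res[2].t_statistic == 0.0
        assert res[2].p_value == 1.0

    def test_power_against_injected_bias(self):
        biased = cb.simulate_blocks(
            300_000, seed=31, rules=[cb.ContextRule("C", "T", "CG", 0, 10.0)]
        )
        plain = cb.simulate_blocks(300_000, seed=32)
        res = compare_total_bias(
            biased, plain, [2], columns_per_sample=300_000, n_resamples=200, seed=7
        )
        assert res[2].p_value < 0.01
        assert res[2].mean_a > res[2].mean_b

    def test_extreme_reuse_warns(self):
        blocks = [AlignmentBlock("b1", "ACGT" * 10, "ACGT" * 10),
                  AlignmentBlock("b2", "TGCA" * 10, "TGCA" * 10)]
        with pytest.warns(UserWarning, match="100x"):
            compare_total_bias(
                blocks, blocks, [1], columns_per_sample=100_000,
                n_resamples=10, seed=0,
            )

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            compare_total_bias([], [], [2])


class TestMedianBySampleSize:
    def test_small_samples_inflated(self):
        blocks = cb.simulate_blocks(400_000, seed=41, block_length=1_000)
        med = median_total_bias_by_sample_size(
            blocks, [2_000, 400_000], L=2, n_samples=10, seed=5
        )
        assert med[2_000] > med[400_000]
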