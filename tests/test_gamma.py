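"""Fuzzy and crisp Goodman-Kruskal gamma: oracles, invariants, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stagetrends import (
    ExpressionMatrix,
    GammaParams,
    StageDesign,
    fdr_adjust,
    fuzzy_pair_masses,
    gamma_statistic,
    permutation_pvalue,
    screen_genes,
    strict_order_degree,
)


def crisp_gamma_oracle(x, y):
    """Classical Goodman-Kruskal gamma by direct pair counting."""
    c = d = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            sx = np.sign(x[j] - x[i])
            sy = np.sign(y[j] - y[i])
            if sx * sy > 0:
                c += 1
            elif sx * sy < 0:
                d += 1
    return (c - d) / (c + d) if c + d else float("nan"), c, d


def fuzzy_masses_oracle(x, y, r_x, r_y):
    """Naive double-loop fuzzy concordance/discordance masses (each unordered
    pair credited in both reading directions)."""
    c = d = 0.0
    n = len(x)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ox = strict_order_degree(x[i], x[j], r_x)
            c += 2 * min(ox, strict_order_degree(y[i], y[j], r_y))
            d += 2 * min(ox, strict_order_degree(y[j], y[i], r_y))
    return c, d


class TestStrictOrderDegree:
    @pytest.mark.parametrize(
        "a,b,r,expected",
        [
            (1.0, 2.0, 0.0, 1.0),
            (2.0, 1.0, 0.0, 0.0),
            (1.0, 1.0, 0.0, 0.0),
            (0.0, 0.05, 0.1, 0.5),
            (0.0, 0.2, 0.1, 1.0),
            (0.2, 0.0, 0.1, 0.0),
        ],
    )
    def test_ramp(self, a, b, r, expected):
        assert strict_order_degree(a, b, r) == pytest.approx(expected)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            strict_order_degree(0.0, 1.0, -0.1)


class TestFuzzyPairMasses:
    def test_perfectly_concordant_counts_both_orders(self):
        c, d = fuzzy_pair_masses([1, 2, 3, 4], [1, 2, 3, 4], 0.0, 0.0)
        assert (c, d) == (12.0, 0.0)

    def test_one_discordant_unordered_pair(self):
        # pairs of x=[1,3,2,4] vs y=[1,2,3,4]: only (3,2)/(2,3) is discordant
        c, d = fuzzy_pair_masses([1, 3, 2, 4], [1, 2, 3, 4], 0.0, 0.0)
        assert (c, d) == (10.0, 2.0)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_double_loop_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(2, 16))
        x = rng.normal(size=n)
        y = rng.integers(1, 5, size=n).astype(float)
        r_x = float(rng.uniform(0, 0.8))
        r_y = float(rng.choice([0.0, rng.uniform(0, 0.5)]))
        c, d = fuzzy_pair_masses(x, y, r_x, r_y)
        co, do = fuzzy_masses_oracle(x, y, r_x, r_y)
        assert c == pytest.approx(co, abs=1e-12)
        assert d == pytest.approx(do, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fuzzy_pair_masses([1, 2], [1, 2, 3], 0.0, 0.0)


class TestGammaStatistic:
    def test_monotone_gene_has_gamma_one(self):
        y = np.array([1, 1, 2, 2, 3, 3], dtype=float)
        x = np.arange(6, dtype=float)
        g, c, d = gamma_statistic(x, y, GammaParams(r_fraction=0.0))
        assert g == pytest.approx(1.0)
        assert d == 0.0

    def test_constant_gene_is_undefined(self):
        g, c, d = gamma_statistic(np.ones(6), [1, 1, 2, 2, 3, 3], GammaParams())
        assert np.isnan(g)
        assert c + d == 0.0

    def test_antisymmetry_under_negation(self, rng):
        y = np.repeat([1.0, 2, 3, 4, 5, 6], 3)
        x = rng.normal(size=18) + 0.3 * y
        g_fwd, *_ = gamma_statistic(x, y, GammaParams())
        g_neg, *_ = gamma_statistic(-x, y, GammaParams())
        assert g_neg == pytest.approx(-g_fwd, abs=1e-12)

    def test_crisp_equals_classical_oracle(self):
        params = GammaParams(r_fraction=0.0)
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 25))
            x = rng.normal(size=n)
            y = rng.integers(1, 6, size=n).astype(float)
            if np.unique(y).size < 2:
                continue
            g, *_ = gamma_statistic(x, y, params)
            g_oracle, *_ = crisp_gamma_oracle(x, y)
            if np.isnan(g_oracle):
                assert np.isnan(g)
            else:
                assert g == pytest.approx(g_oracle, abs=1e-12)

    def test_invariant_to_monotone_recoding_of_stages(self, rng):
        x = rng.normal(size=12)
        y = np.repeat([1.0, 2, 3, 4], 3)
        g1, *_ = gamma_statistic(x, y, GammaParams())
        g2, *_ = gamma_statistic(x, 10 * y, GammaParams())
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_single_stage_rejected(self):
        with pytest.raises(ValueError):
            gamma_statistic(np.arange(4.0), np.ones(4), GammaParams())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.0, 0.5))
    def test_gamma_bounded(self, seed, r_fraction):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = np.repeat([1.0, 2.0], 5)
        g, *_ = gamma_statistic(x, y, GammaParams(r_fraction=r_fraction))
        if not np.isnan(g):
            assert -1.0 - 1e-12 <= g <= 1.0 + 1e-12

    def test_fuzzy_converges_to_crisp_for_tie_free_x(self, rng):
        x = rng.normal(size=12)
        y = np.repeat([1.0, 2, 3, 4], 3)
        g_crisp, *_ = gamma_statistic(x, y, GammaParams(r_fraction=0.0))
        g_small, *_ = gamma_statistic(x, y, GammaParams(r_fraction=1e-10))
        assert g_small == pytest.approx(g_crisp, abs=1e-6)


class TestPermutationPvalue:
    def test_addone_floor(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1.0, 2, 3, 4], 3)
        x = np.arange(12, dtype=float)  # perfectly monotone
        p = permutation_pvalue(x, y, GammaParams(n_permutations=1000), rng)
        assert p >= 1 / 1001
        assert p < 0.01

    def test_undefined_gamma_propagates(self):
        rng = np.random.default_rng(0)
        p = permutation_pvalue(np.ones(6), np.repeat([1.0, 2, 3], 2), GammaParams(), rng)
        assert np.isnan(p)

    def test_monotone_gene_significant_across_seeds(self):
        # 4 stages x 3, x monotone in y: small p in virtually every rerun
        y = np.repeat([1.0, 2, 3, 4], 3)
        x = np.arange(12, dtype=float)
        params = GammaParams(n_permutations=500)
        small = sum(
            permutation_pvalue(x, y, params, np.random.default_rng(s)) < 0.01
            for s in range(40)
        )
        assert small >= 39

    def test_null_pvalues_super_uniform(self):
        # stage-independent genes: empirical CDF at 0.05 within MC error
        y = np.repeat(np.arange(1.0, 7.0), 3)
        params = GammaParams(n_permutations=200)
        rng = np.random.default_rng(11)
        ps = [
            permutation_pvalue(rng.normal(size=18), y, params, rng) for _ in range(150)
        ]
        frac = np.mean(np.asarray(ps) <= 0.05)
        mc_se = np.sqrt(0.05 * 0.95 / 150)
        assert frac <= 0.05 + 3 * mc_se


class TestFdrAdjust:
    def test_flat_pvector_fixed_point(self):
        q = fdr_adjust(np.full(10, 0.01))
        assert np.allclose(q, 0.01)

    def test_hand_computed_two_values(self):
        q = fdr_adjust([0.001, 0.5], m_total=2)
        assert q == pytest.approx([0.002, 0.5])

    def test_platform_total_inflates_q(self):
        q_small = fdr_adjust([0.001, 0.02], m_total=2)
        q_big = fdr_adjust([0.001, 0.02], m_total=20)
        assert np.all(q_big >= q_small)
        assert q_big[0] == pytest.approx(0.001 * 20 / 1)

    def test_matches_statsmodels_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0.001, 1.0, size=40)
        q = fdr_adjust(p)
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0.001, 1.0, size=50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [-0.1]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            fdr_adjust(bad)

    def test_rejects_m_smaller_than_n(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.1, 0.2, 0.3], m_total=2)


class TestScreenGenes:
    def test_injected_monotone_gene_selected(self, six_stage_design, rng):
        sample_ids = six_stage_design.sample_ids
        codes = six_stage_design.codes_for(sample_ids)
        values = rng.normal(5.0, 1.0, size=(6, 18))
        values[0] = codes * 2.0 + rng.normal(0, 0.1, size=18)  # strong trend
        expr = ExpressionMatrix([f"G{i}" for i in range(6)], sample_ids, values)
        res = screen_genes(expr, six_stage_design, GammaParams(n_permutations=300, seed=3))
        assert bool(res.loc[res.gene_id == "G0", "selected"].iloc[0])
        assert res.loc[res.gene_id == "G0", "direction"].iloc[0] == "up"

    def test_impossible_threshold_selects_nothing(self, small_matrix, six_stage_design):
        res = screen_genes(
            small_matrix,
            six_stage_design,
            GammaParams(gamma_threshold=1.1, n_permutations=50, seed=1),
        )
        assert not res["selected"].any()

    def test_constant_gene_flagged_not_selected(self, six_stage_design, rng):
        sample_ids = six_stage_design.sample_ids
        values = rng.normal(size=(2, 18))
        values[1] = 3.14
        expr = ExpressionMatrix(["A", "B"], sample_ids, values)
        res = screen_genes(expr, six_stage_design, GammaParams(n_permutations=50, seed=0))
        row = res.set_index("gene_id").loc["B"]
        assert np.isnan(row["gamma"]) and np.isnan(row["p_perm"])
        assert row["direction"] == "undefined" and not row["selected"]

    def test_deterministic_given_seed(self, small_matrix, six_stage_design):
        params = GammaParams(n_permutations=100, seed=9)
        r1 = screen_genes(small_matrix, six_stage_design, params)
        r2 = screen_genes(small_matrix, six_stage_design, params)
        pd.testing.assert_frame_equal(r1, r2)

    def test_misaligned_inputs_rejected(self, small_matrix, six_stage_design):
        shuffled = small_matrix.subset_samples(small_matrix.sample_ids[::-1])
        with pytest.raises(ValueError):
            screen_genes(shuffled, six_stage_design, GammaParams(n_permutations=10))
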