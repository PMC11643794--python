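"""ASCA contracts: exact partition, orthogonality, SCA ranks, permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oxispec as ox
from oxispec.asca import (
    EFFECT_NAMES,
    UnbalancedDesignError,
    ZeroEffectError,
)
from oxispec.synthetic import DesignSpec, simulate_effect_injection

from conftest import brute_force_anova_ssq


def random_balanced_case(n_time, n_temp, n_mat, n_rep, seed):
    spec = DesignSpec(
        time_levels=tuple(range(n_time)),
        temperature_levels=tuple(10 + 5 * i for i in range(n_temp)),
        material_levels=tuple(f"M{i}" for i in range(n_mat)),
        n_replicates=n_rep,
    )
    design = ox.generate_design(spec)
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(len(design), 7))
    return design, X


class TestDecompose:
    def test_identical_rows_give_all_zero_terms(self, small_design):
        X = np.tile(np.arange(5.0), (len(small_design), 1))
        d = ox.decompose(X, small_design)
        for m in d.effects.values():
            assert np.allclose(m, 0.0)
        assert np.allclose(d.residual, 0.0)

    def test_two_by_two_toy_hand_values(self):
        # temp x mat toy, one channel: cells (10,A)=1 (10,B)=2 (25,A)=3 (25,B)=4
        spec = DesignSpec(time_levels=(15,), temperature_levels=(10, 25),
                          material_levels=("A", "B"), n_replicates=1)
        design = ox.generate_design(spec)
        key = {(10, "A"): 1.0, (10, "B"): 2.0, (25, "A"): 3.0, (25, "B"): 4.0}
        y = np.array([[key[(r.temperature, r.material)]] for r in design.itertuples()])
        d = ox.decompose(y, design)
        temp_sign = np.where(design["temperature"] == 10, -1.0, 1.0)
        mat_sign = np.where(design["material"] == "A", -0.5, 0.5)
        assert np.allclose(d.effects["temp"].ravel(), temp_sign)
        assert np.allclose(d.effects["mat"].ravel(), mat_sign)
        assert np.allclose(d.effects["temp:mat"], 0.0)
        assert np.allclose(d.residual, 0.0)

    @given(
        n_time=st.integers(2, 3), n_temp=st.integers(2, 3),
        n_mat=st.integers(2, 3), n_rep=st.integers(1, 2),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=20, deadline=None)
    def test_partition_exact_orthogonal_additive(self, n_time, n_temp, n_mat, n_rep, seed):
        design, X = random_balanced_case(n_time, n_temp, n_mat, n_rep, seed)
        d = ox.decompose(X, design)
        # reconstruction identity
        assert np.allclose(d.reconstruct(), X, rtol=1e-8, atol=1e-10)
        # pairwise orthogonality of all terms (balanced design)
        terms = list(d.effects.values()) + [d.residual]
        for i in range(len(terms)):
            for j in range(i + 1, len(terms)):
                assert abs(np.sum(terms[i] * terms[j])) < 1e-8
        # SSQ additivity
        assert sum(d.ssq.values()) == pytest.approx(d.total_ssq, rel=1e-8)

    def test_effect_ranks_bounded_by_design_dof(self):
        design, X = random_balanced_case(3, 2, 3, 2, seed=4)
        d = ox.decompose(X, design)
        dof = {"time": 2, "temp": 1, "mat": 2,
               "time:temp": 2, "temp:mat": 2, "mat:time": 4}
        for name, m in d.effects.items():
            assert np.linalg.matrix_rank(m, tol=1e-8) <= dof[name]

    def test_univariate_matches_brute_force_anova(self):
        design, X = random_balanced_case(3, 2, 3, 2, seed=12)
        y = X[:, 0]
        d = ox.decompose(y[:, None], design)
        oracle = brute_force_anova_ssq(y, design)
        for name in list(EFFECT_NAMES) + ["residual"]:
            assert d.ssq[name] == pytest.approx(oracle[name], rel=1e-10, abs=1e-12)

    def test_unbalanced_design_rejected(self, small_design):
        design = small_design.iloc[:-1]
        X = np.zeros((len(design), 3))
        with pytest.raises(UnbalancedDesignError):
            ox.decompose(X, design)


class TestEffectPercentages:
    def test_sum_to_100(self, preprocessed):
        design, _, pre = preprocessed
        pct = ox.effect_percentages(ox.decompose(pre, design))
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-8)

    def test_pure_single_factor_signal_takes_all(self, small_design):
        # signal depends on temperature only, noise-free
        sig = np.where(small_design["temperature"] == 25, 1.0, -1.0)
        X = np.outer(sig, np.ones(4))
        pct = ox.effect_percentages(ox.decompose(X, small_design))
        assert pct["temp"] == pytest.approx(100.0, abs=1e-8)
        for name in EFFECT_NAMES:
            if name != "temp":
                assert pct[name] == pytest.approx(0.0, abs=1e-8)

    def test_injected_four_to_one_ratio_recovered(self):
        design = ox.generate_design()
        X = simulate_effect_injection(
            design, shares={"time": 0.8, "temp": 0.2}, noise_sd=0.002, seed=5
        )
        pct = ox.effect_percentages(ox.decompose(X, design))
        assert pct["time"] / pct["temp"] == pytest.approx(4.0, rel=0.2)

    def test_constant_matrix_undefined(self, small_design):
        X = np.ones((len(small_design), 3))
        with pytest.raises(ZeroDivisionError):
            ox.effect_percentages(ox.decompose(X, small_design))


class TestSca:
    def test_two_level_effect_has_one_component_at_100pct(self, preprocessed):
        design, _, pre = preprocessed
        d = ox.decompose(pre, design)
        res = ox.sca(d.effects["temp"], d.residual, "temp")
        assert res.n_components == 1
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_nine_level_time_effect_has_eight_components(self, preprocessed):
        design, _, pre = preprocessed
        d = ox.decompose(pre, design)
        assert ox.sca(d.effects["time"], d.residual, "time").n_components == 8

    def test_rank_one_matrix_recovers_direction(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=12)
        v = rng.normal(size=30)
        res = ox.sca(np.outer(u, v), np.zeros((12, 30)))
        assert res.n_components == 1
        cos = abs(res.loadings[0] @ v / np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(res.variance_fraction, [1.0])

    def test_loadings_orthonormal_and_fractions_sum_to_one(self, preprocessed):
        design, _, pre = preprocessed
        d = ox.decompose(pre, design)
        res = ox.sca(d.effects["mat:time"], d.residual)
        gram = res.loadings @ res.loadings.T
        assert np.allclose(gram, np.eye(res.n_components), atol=1e-10)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_spider_scores_are_augmented_projection(self, preprocessed):
        design, _, pre = preprocessed
        d = ox.decompose(pre, design)
        res = ox.sca(d.effects["temp"], d.residual, "temp")
        expected = (d.effects["temp"] + d.residual) @ res.loadings.T
        assert np.allclose(res.spider_scores, expected)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ZeroEffectError):
            ox.sca(np.zeros((4, 5)), np.zeros((4, 5)))


class TestPermutationTest:
    def test_observed_ssq_matches_decompose(self, preprocessed):
        design, _, pre = preprocessed
        d = ox.decompose(pre, design)
        for name in EFFECT_NAMES:
            r = ox.permutation_test(pre, design, name, B=3, seed=0)
            assert r.observed_ssq == pytest.approx(d.ssq[name], rel=1e-8)

    def test_strong_effect_hits_floor(self, preprocessed):
        design, _, pre = preprocessed
        r = ox.permutation_test(pre, design, "temp", B=200, seed=1)
        assert r.p_value == 1 / 200

    def test_constant_matrix_gives_p_one(self, small_design):
        # dyadic values center to exact zeros, making every permutation a tie
        X = np.tile(np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0]), (len(small_design), 1))
        r = ox.permutation_test(X, small_design, "temp", B=50, seed=0)
        assert r.p_value == 1.0

    def test_deterministic_given_seed(self, preprocessed):
        design, _, pre = preprocessed
        a = ox.permutation_test(pre, design, "mat", B=25, seed=9)
        b = ox.permutation_test(pre, design, "mat", B=25, seed=9)
        assert np.array_equal(a.permuted_ssq, b.permuted_ssq)
        assert a.p_value == b.p_value

    def test_p_value_bounds(self, small_design):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(len(small_design), 5))
        r = ox.permutation_test(X, small_design, "time", B=40, seed=3)
        assert 1 / 40 <= r.p_value <= 1.0

    def test_unknown_effect_rejected(self, preprocessed):
        design, _, pre = preprocessed
        with pytest.raises(ValueError):
            ox.permutation_test(pre, design, "light", B=10, seed=0)


def test_effects_table_shape(preprocessed):
    design, _, pre = preprocessed
    table = ox.effects_table(pre, design, B=20, seed=0)
    assert list(table["effect"]) == list(EFFECT_NAMES) + ["residual"]
    assert table["effect_pct"].sum() == pytest.approx(100.0, abs=1e-8)
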