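import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pinedemog import (
    ProjectionModel,
    TRANSITIONS,
    build_life_table,
    build_matrix,
    eigen_analysis,
    elasticity_matrix,
    growth_rate,
    printed_life_table,
    reproductive_value,
    sensitivity_matrix,
    signif,
    stable_structure,
    structural_sensitivities,
)
from conftest import loop_lambda

survivals_strategy = st.lists(
    st.floats(min_value=1e-3, max_value=1.0), min_size=5, max_size=5
)
fecundity_strategy = st.floats(min_value=1e-2, max_value=500.0)


def loop_model(survivals, fecundity):
    A = np.zeros((6, 6))
    A[np.arange(1, 6), np.arange(5)] = survivals
    A[0, 5] = fecundity
    return ProjectionModel(tuple("S" + str(i) for i in range(1, 7)), A)


@pytest.fixture
def cyclic_model():
    return loop_model([1.0] * 5, 1.0)


class TestBuildMatrix:
    def test_published_matrix_entries(self, printed_model):
        nonzero = sorted(printed_model.A[printed_model.A > 0])
        assert nonzero == pytest.approx([0.091, 0.15, 0.50, 0.54, 0.66, 69.45])
        assert np.count_nonzero(printed_model.A) == 6

    def test_unit_life_table_gives_cyclic_permutation(self):
        lt = build_life_table([1.0] * 6)
        model = build_matrix(lt)
        assert model.A == pytest.approx(np.roll(np.eye(6), 1, axis=0))

    def test_wrong_stage_count_rejected(self):
        lt = build_life_table([10, 5, 2], stage_labels=["a", "b", "c"])
        with pytest.raises(ValueError, match="6 stages"):
            build_matrix(lt)

    def test_broken_loop_rejected(self):
        lt = build_life_table([10, 5, 2, 1, 0.5, 0.0])
        with pytest.raises(ValueError, match="single loop"):
            build_matrix(lt)

    def test_negative_entry_rejected(self):
        A = np.zeros((6, 6))
        A[np.arange(1, 6), np.arange(5)] = [0.5, 0.5, 0.5, 0.5, -0.1]
        A[0, 5] = 10.0
        with pytest.raises(ValueError, match="non-negative"):
            ProjectionModel(tuple("abcdef"), A)

    def test_off_loop_entry_rejected(self):
        A = np.roll(np.eye(6), 1, axis=0)
        A[2, 4] = 0.3
        with pytest.raises(ValueError, match="single loop"):
            ProjectionModel(tuple("abcdef"), A)


class TestGrowthRate:
    def test_published_rate(self, printed_model):
        assert round(growth_rate(printed_model), 2) == 0.74

    def test_cyclic_permutation_is_stationary(self, cyclic_model):
        assert growth_rate(cyclic_model) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(survivals_strategy, fecundity_strategy)
    def test_matches_closed_form(self, survivals, fecundity):
        model = loop_model(survivals, fecundity)
        assert growth_rate(model) == pytest.approx(
            loop_lambda(fecundity, survivals), rel=1e-9
        )

    def test_six_step_projection_multiplies_by_loop_product(self, printed_model):
        """One full trip around the loop scales any stage vector by F·∏g."""
        product = printed_model.fecundity * np.prod(printed_model.survivals)
        A6 = np.linalg.matrix_power(printed_model.A, 6)
        assert A6 == pytest.approx(product * np.eye(6), rel=1e-12)


class TestStableStructure:
    def test_published_distribution(self, printed_model):
        w = stable_structure(printed_model)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        # published: (0.80, 0.097, 0.071, 0.014, 0.0096, 0.0085); the 2nd
        # and 6th entries recompute one unit higher in the last figure
        assert round(w[0], 2) == 0.80
        assert signif(w[2], 2) == 0.071
        assert signif(w[3], 2) == 0.014
        assert signif(w[4], 2) == 0.0096
        assert w[1] == pytest.approx(0.097, abs=1e-3)
        assert w[5] == pytest.approx(0.0085, abs=1e-4)

    def test_cyclic_model_is_uniform(self, cyclic_model):
        assert stable_structure(cyclic_model) == pytest.approx([1 / 6] * 6)

    @settings(max_examples=50, derandomize=True)
    @given(survivals_strategy, fecundity_strategy)
    def test_loop_recursion(self, survivals, fecundity):
        """w_{i+1} = w_i · g_i / λ down the loop."""
        model = loop_model(survivals, fecundity)
        w = stable_structure(model)
        lam = growth_rate(model)
        for i in range(5):
            assert w[i + 1] == pytest.approx(w[i] * survivals[i] / lam, rel=1e-8)


class TestReproductiveValue:
    def test_scaled_to_first_entry(self, printed_model):
        v = reproductive_value(printed_model)
        assert v[0] == 1.0
        assert np.all(v > 0)

    def test_left_eigen_equation(self, printed_model):
        v = reproductive_value(printed_model)
        lam = growth_rate(printed_model)
        assert v @ printed_model.A == pytest.approx(lam * v, rel=1e-9)


class TestSensitivityElasticity:
    def test_most_sensitive_transitions(self, printed_model):
        """The two smallest survivals (into L1 and into L3) dominate."""
        sens = structural_sensitivities(printed_model)
        ranked = sorted(sens, key=sens.get, reverse=True)
        assert ranked[:2] == ["E->L1", "L2->L3"]
        # the smallest survival always carries the largest sensitivity
        smallest = TRANSITIONS[int(np.argmin(printed_model.survivals))]
        assert ranked[0] == smallest

    @settings(max_examples=50, derandomize=True)
    @given(survivals_strategy, fecundity_strategy)
    def test_structural_sensitivity_closed_form(self, survivals, fecundity):
        """dλ/da = λ/(6a) for every loop entry a, from λ⁶ = F·∏g."""
        model = loop_model(survivals, fecundity)
        lam = loop_lambda(fecundity, survivals)
        sens = structural_sensitivities(model)
        for param, (i, j) in (
            (p, model.entry_index(p)) for p in sens
        ):
            a = model.A[i, j]
            assert sens[param] == pytest.approx(lam / (6 * a), rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(survivals_strategy, fecundity_strategy)
    def test_loop_elasticities_are_one_sixth(self, survivals, fecundity):
        model = loop_model(survivals, fecundity)
        E = elasticity_matrix(model)
        structural = E[model.A > 0]
        assert structural == pytest.approx([1 / 6] * 6, rel=1e-9)
        assert E.sum() == pytest.approx(1.0, rel=1e-9)
        assert np.all(E[model.A == 0] == 0)

    def test_sensitivity_matrix_is_rank_one_outer_product(self, printed_model):
        S = sensitivity_matrix(printed_model)
        w = stable_structure(printed_model)
        v = reproductive_value(printed_model)
        assert S == pytest.approx(np.outer(v, w) / (v @ w), rel=1e-12)


class TestEigenAnalysis:
    def test_internally_consistent(self, printed_model):
        eig = eigen_analysis(printed_model)
        assert eig.lambda_ == growth_rate(printed_model)
        assert eig.lambda_annual == pytest.approx(eig.lambda_**6, rel=1e-12)
        # per-year rate equals the loop product F·∏g
        assert eig.lambda_annual == pytest.approx(
            printed_model.fecundity * np.prod(printed_model.survivals), rel=1e-9
        )
        assert eig.w.sum() == pytest.approx(1.0)
        assert eig.v[0] == 1.0
        assert eig.E6.sum() == pytest.approx(1.0, rel=1e-9)
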