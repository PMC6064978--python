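"""Constraint expansion, free-parameter counting, contrasts, and the
equivalence of the different ways to encode the same model."""

import numpy as np
import pytest

from pfcompare import (
    ConfigurationError,
    DomainError,
    FitOptions,
    ModelSpec,
    ParamConstraint,
    PFParams,
    SpecificationError,
    count_free_params,
    exp_decay_learning,
    expand_parameters,
    fit_model,
    generate_contrasts,
    simulate_observer,
)
from pfcompare.simulate import ExperimentDesign

from conftest import GUESS, LAPSE, fixed, make_spec


class TestExpandParameters:
    def test_sum_difference_matrix(self):
        # theta = (2, 1) under the sum/difference matrix gives slopes (3, 1),
        # whose recoding as sum and difference is (4, 2).
        con = ParamConstraint.from_matrix([[1, 1], [1, -1]])
        beta = con.expand(np.array([2.0, 1.0]), 2)
        np.testing.assert_allclose(beta, [3.0, 1.0])
        np.testing.assert_allclose(np.array([[1, 1], [1, -1]]) @ beta, [4.0, 2.0])

    def test_single_row_matrix_equalizes(self):
        con = ParamConstraint.from_matrix([[1, 1]])
        np.testing.assert_allclose(con.expand(np.array([1.5]), 2), [1.5, 1.5])

    def test_constrained_shares_one_value(self):
        con = ParamConstraint.constrained()
        np.testing.assert_allclose(con.expand(np.array([0.7]), 3), [0.7, 0.7, 0.7])

    def test_fixed_scalar_broadcasts(self):
        con = ParamConstraint.fixed(0.02)
        np.testing.assert_allclose(con.expand(np.empty(0), 4), [0.02] * 4)

    def test_exp_decay_learning_curve(self):
        # alpha_s = a + b exp(-r (s-1)); at the first session alpha = a + b.
        mapper = exp_decay_learning(10)
        con = ParamConstraint.custom(mapper, [0.5, 2.0, 0.3])
        alphas = con.expand(np.array([0.5, 2.0, 0.3]), 10)
        assert alphas[0] == pytest.approx(2.5)
        np.testing.assert_allclose(
            alphas, 0.5 + 2.0 * np.exp(-0.3 * np.arange(10)), rtol=1e-12
        )

    def test_custom_fixed_entries_come_from_theta_init(self):
        mapper = exp_decay_learning(5)
        con = ParamConstraint.custom(mapper, [1.0, 2.0, 0.0], [True, True, False])
        alphas = con.expand(np.array([1.0, 2.0]), 5)  # rate pinned at 0
        np.testing.assert_allclose(alphas, 3.0)

    def test_theta_length_mismatch_rejected(self):
        spec = make_spec("u", "u")
        with pytest.raises(SpecificationError):
            expand_parameters(spec, np.zeros(3))

    def test_custom_wrong_length_rejected(self):
        con = ParamConstraint.custom(lambda t: np.ones(3), [1.0])
        with pytest.raises(SpecificationError):
            con.validate(5)

    def test_full_spec_expansion_layout(self):
        spec = make_spec("u", "c")
        native = expand_parameters(spec, np.array([-0.5, 0.5, 1.2]))
        np.testing.assert_allclose(native[0], [-0.5, 0.5])   # alpha
        np.testing.assert_allclose(native[1], [1.2, 1.2])    # beta
        np.testing.assert_allclose(native[2], [GUESS] * 2)
        np.testing.assert_allclose(native[3], [LAPSE] * 2)


class TestCountFreeParams:
    @pytest.mark.parametrize(
        "alpha_mode, beta_mode, n_cond, expected",
        [
            ("u", "u", 1, 2),  # one-condition fuller model
            ("f", "u", 1, 1),  # one-condition lesser model: df difference 1
            ("f", "u", 2, 2),  # '0 alpha 2 beta'
            ("f", "c", 2, 1),  # '0 alpha 1 beta'
            ("u", "u", 2, 4),
            ("f", "f", 2, 0),  # fully fixed model is legal
        ],
    )
    def test_grid_counts(self, alpha_mode, beta_mode, n_cond, expected):
        assert count_free_params(make_spec(alpha_mode, beta_mode, n_cond)) == expected

    def test_matrix_counts_rows(self):
        spec = ModelSpec(
            "logistic", 2,
            alpha=fixed(0.0),
            beta=ParamConstraint.from_matrix([[1, 1], [1, -1]]),
            gamma=fixed(GUESS), lambda_=fixed(LAPSE),
        )
        assert count_free_params(spec) == 2

    def test_custom_counts_free_flags(self):
        con = ParamConstraint.custom(exp_decay_learning(10), [0, 2, 0.5], [True, True, False])
        spec = ModelSpec("logistic", 10, alpha=con, beta=fixed(1.0),
                         gamma=fixed(GUESS), lambda_=fixed(LAPSE))
        assert count_free_params(spec) == 2


class TestContrasts:
    def test_polynomial_four_conditions_matches_classic_table(self):
        cm = generate_contrasts(4, "polynomial")
        np.testing.assert_allclose(cm.rows[0], [1, 1, 1, 1])
        np.testing.assert_allclose(cm.rows[1], [-3, -1, 1, 3])

    def test_polynomial_two_conditions_is_sum_and_difference(self):
        # The linear row equals the sum/difference matrix's difference row up
        # to an overall sign (contrast rows are defined up to sign; the
        # increasing-trend convention used here gives [-1, 1]).
        cm = generate_contrasts(2, "polynomial")
        np.testing.assert_allclose(cm.rows[0], [1, 1])
        np.testing.assert_allclose(np.abs(cm.rows[1]), [1, 1])
        assert cm.rows[1] @ np.ones(2) == 0

    @pytest.mark.parametrize("kind", ["polynomial", "helmert"])
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_rows_orthogonal_and_zero_sum(self, kind, n):
        rows = generate_contrasts(n, kind).rows
        assert rows.shape == (n, n)
        for i in range(1, n):
            assert abs(rows[i].sum()) < 1e-9
            for j in range(i + 1, n):
                assert abs(rows[i] @ rows[j]) < 1e-9

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_periodic_full_rank_with_intercept(self, n):
        rows = generate_contrasts(n, "periodic").rows
        assert rows.shape == (n, n)
        assert np.linalg.matrix_rank(rows) == n
        np.testing.assert_allclose(rows[0], np.ones(n))

    def test_bad_inputs(self):
        with pytest.raises(ConfigurationError):
            generate_contrasts(4, "fourier-ish")
        with pytest.raises(DomainError):
            generate_contrasts(1, "polynomial")


class TestEncodingEquivalence:
    """The same model written three ways must fit identically."""

    @pytest.fixture
    def data(self):
        design = ExperimentDesign.uniform(n_conditions=2)
        truth = [PFParams(0.0, 1.4, GUESS, LAPSE), PFParams(0.0, 0.8, GUESS, LAPSE)]
        return simulate_observer(design, "logistic", truth, seed=42)

    def _fit(self, data, beta_con):
        spec = ModelSpec("logistic", 2, alpha=fixed(0.0), beta=beta_con,
                         gamma=fixed(GUESS), lambda_=fixed(LAPSE))
        return fit_model(data, spec, FitOptions(seed=3, n_restarts=2))

    def test_constrained_matrix_and_custom_agree(self, data):
        by_label = self._fit(data, ParamConstraint.constrained())
        by_matrix = self._fit(data, ParamConstraint.from_matrix([[1, 1]]))
        by_custom = self._fit(
            data, ParamConstraint.custom(lambda t: np.full(2, t[0]), [1.0])
        )
        assert by_label.k_free == by_matrix.k_free == by_custom.k_free == 1
        assert by_matrix.log_likelihood == pytest.approx(by_label.log_likelihood, abs=1e-6)
        assert by_custom.log_likelihood == pytest.approx(by_label.log_likelihood, abs=1e-6)

    def test_identity_matrix_matches_unconstrained(self, data):
        by_label = self._fit(data, ParamConstraint.unconstrained())
        by_matrix = self._fit(data, ParamConstraint.from_matrix(np.eye(2)))
        assert by_label.k_free == by_matrix.k_free == 2
        assert by_matrix.log_likelihood == pytest.approx(by_label.log_likelihood, abs=1e-6)
        np.testing.assert_allclose(
            by_matrix.native_params[1], by_label.native_params[1], atol=1e-4
        )

    def test_matrix_round_trip_recovers_scaled_theta(self):
        # Applying M to the reconstructed natives returns (M M^T) theta.
        M = np.array([[1.0, 1.0], [1.0, -1.0]])
        con = ParamConstraint.from_matrix(M)
        theta = np.array([2.0, 1.0])
        native = con.expand(theta, 2)
        np.testing.assert_allclose(M @ native, (M @ M.T) @ theta)
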