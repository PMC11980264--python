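"""Cross-basis assembly against brute-force oracles."""

import numpy as np
import pytest

from thermolag.basis import BasisSpec, eval_basis, place_knots
from thermolag.crossbasis import (
    CrossBasisSpec,
    build_crossbasis,
    prediction_rows,
    spec_from_history,
)
from thermolag.exposure import ExposureHistory


def brute_force_crossbasis(history, spec):
    """Triple loop: design[i,(j,k)] = sum_l B_j(x_il) C_k(l)."""
    n, L = history.matrix.shape
    out = np.zeros((n, spec.df_var * spec.df_lag))
    lag_b = eval_basis(spec.lag_basis, np.arange(1, L + 1, dtype=float))
    for i in range(n):
        var_b = eval_basis(spec.var_basis, history.matrix[i])
        for j in range(spec.df_var):
            for k in range(spec.df_lag):
                acc = 0.0
                for l in range(L):
                    acc += var_b[l, j] * lag_b[l, k]
                out[i, j * spec.df_lag + k] = acc
    return out


def random_history(rng, n, weeks, period="prenatal"):
    # ExposureHistory enforces the fixed period lengths; use a raw container
    mat = rng.normal(10, 4, (n, weeks))

    class Tiny:
        matrix = mat
        n_weeks = weeks
        subjects = np.arange(n)

    return Tiny()


def tiny_spec(mat, weeks, df_var, df_lag):
    var_b = place_knots(mat.ravel(), df_var)
    lag_b = place_knots(np.arange(1, weeks + 1, dtype=float), df_lag)
    return CrossBasisSpec(var_b, lag_b, weeks)


class TestBuildCrossbasis:
    def test_default_dfs_give_six_columns(self, toy_history):
        spec = spec_from_history(toy_history, df_var=2, df_lag=3)
        cb = build_crossbasis(toy_history, spec)
        assert cb.design.shape == (4, 6)
        assert cb.column_index == [(j, k) for j in range(2) for k in range(3)]

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_triple_loop_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 6)
        weeks = rng.integers(4, 7)
        df_var = rng.integers(1, 4)
        df_lag = rng.integers(1, 4)
        hist = random_history(rng, n, weeks)
        spec = tiny_spec(hist.matrix, weeks, df_var, df_lag)
        cb = build_crossbasis(hist, spec)
        assert np.abs(cb.design - brute_force_crossbasis(hist, spec)).max() < 1e-10

    def test_two_week_linear_case_hand_computed(self):
        mat = np.array([[3.0, 8.0]])

        class Tiny:
            matrix = mat
            n_weeks = 2
            subjects = np.array([0])

        var_b = BasisSpec("linear", 1, (), (0.0, 10.0))  # centred at 5
        lag_b = place_knots(np.array([1.0, 2.0]), 1)  # centred at 1.5
        spec = CrossBasisSpec(var_b, lag_b, 2)
        cb = build_crossbasis(Tiny(), spec)
        # sum_l (x_l - 5) * (l - 1.5) = (3-5)(-0.5) + (8-5)(0.5) = 2.5
        assert cb.design[0, 0] == pytest.approx(2.5)

    def test_duplicated_rows_duplicate_design(self, toy_history):
        spec = spec_from_history(toy_history)
        doubled = ExposureHistory(
            np.r_[toy_history.subjects, toy_history.subjects],
            np.r_[toy_history.matrix, toy_history.matrix],
            "tmean",
            "prenatal",
        )
        cb1 = build_crossbasis(toy_history, spec)
        cb2 = build_crossbasis(doubled, spec)
        assert np.array_equal(cb2.design[:4], cb1.design)
        assert np.array_equal(cb2.design[4:], cb1.design)

    def test_mismatched_weeks_rejected(self, toy_history):
        spec = spec_from_history(toy_history)
        bad = ExposureHistory(
            np.arange(2), np.full((2, 91), 10.0), "tmean", "postnatal"
        )
        with pytest.raises(ValueError, match="weeks"):
            build_crossbasis(bad, spec)


class TestPredictionRows:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.hist = random_history(rng, 4, 6)
        self.spec = tiny_spec(self.hist.matrix, 6, 2, 3)

    def test_reference_contrast_is_zero(self):
        rows = prediction_rows(self.spec, 11.0, 11.0)
        assert np.all(rows == 0.0)

    def test_linear_var_basis_scales_linearly(self):
        spec = CrossBasisSpec(
            BasisSpec("linear", 1, (), (0.0, 20.0)), self.spec.lag_basis, 6
        )
        r1 = prediction_rows(spec, 12.0, 10.0)
        r2 = prediction_rows(spec, 14.0, 10.0)
        assert np.allclose(r2, 2.0 * r1)

    def test_single_lag_matches_kronecker_oracle(self):
        rows = prediction_rows(self.spec, 14.0, 10.0, lags=[3])
        db = (
            eval_basis(self.spec.var_basis, [14.0])
            - eval_basis(self.spec.var_basis, [10.0])
        )[0]
        c3 = eval_basis(self.spec.lag_basis, [3.0])[0]
        assert np.allclose(rows[0], np.kron(db, c3))

    def test_sum_over_lags_equals_cumulative_row(self):
        all_rows = prediction_rows(self.spec, 14.0, 10.0)
        assert np.allclose(
            all_rows.sum(axis=0),
            sum(prediction_rows(self.spec, 14.0, 10.0, [l])[0] for l in range(1, 7)),
        )

    def test_extrapolation_warns_not_errors(self):
        lo, hi = self.spec.var_basis.boundary_knots
        with pytest.warns(UserWarning, match="outside the boundary"):
            prediction_rows(self.spec, hi + 5.0, 0.5 * (lo + hi))

    def test_lags_outside_range_rejected(self):
        with pytest.raises(ValueError, match="1..6"):
            prediction_rows(self.spec, 12.0, 10.0, lags=[7])
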