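"""Relative-risk estimation, cumulative contrasts, window detection,
percent-change conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermolag.basis import BasisSpec
from thermolag.crossbasis import CrossBasisSpec, prediction_rows
from thermolag.effects import (
    EffectEstimate,
    cumulative_effect,
    find_windows,
    lag_effects,
    rr_to_percent,
)
from thermolag.model import FittedDlnm


def linear_fit(beta, var=0.0025, weeks=6):
    """One-block fit with a 1x1 cross-basis (linear var, linear lag)."""
    spec = CrossBasisSpec(
        BasisSpec("linear", 1, (), (0.0, 20.0)),
        BasisSpec("linear", 1, (), (1.0, float(weeks))),
        weeks,
    )
    fit = FittedDlnm(
        params=np.array([0.0, beta]),
        names=["intercept", "blk[v1l1]"],
        vcov=np.diag([0.0, var]),
        dispersion=1.0,
        loglik_poisson=0.0,
        n=100,
        blocks={"intercept": slice(0, 1), "blk": slice(1, 2)},
    )
    return fit, spec


class TestLagEffects:
    def test_reference_contrast_gives_unit_rr_and_degenerate_ci(self, fitted_main):
        _, res = fitted_main
        spec = res["specs"]["temp_post"]
        ests = lag_effects(res["fit"], spec, "temp_post", 11.0, 11.0)
        assert all(e.rr == 1.0 and e.ci_low == 1.0 and e.ci_high == 1.0 for e in ests)

    def test_linear_block_hand_computation(self):
        # beta = 0.1 on the var x lag column; at lag where C(l)=1 a +2 degree
        # contrast gives log-RR = 0.1 * 2 * C(l)
        fit, spec = linear_fit(0.1)
        ests = lag_effects(fit, spec, "blk", 12.0, 10.0)
        c = np.arange(1, 7) - 3.5  # lag basis centred at midpoint
        for e, cl in zip(ests, c):
            assert e.log_rr == pytest.approx(0.2 * cl)
        # beta * dx * C(l) on the exp scale, e.g. lag 6 where C = 2.5
        assert ests[5].rr == pytest.approx(np.exp(0.2 * 2.5))

    def test_rr_below_one_counts_as_reduction(self):
        fit, spec = linear_fit(-0.1)
        e = lag_effects(fit, spec, "blk", 12.0, 10.0, lags=[6])[0]
        assert e.rr < 1
        assert rr_to_percent(e.rr).direction == "reduction"

    def test_unknown_block_rejected(self, fitted_main):
        _, res = fitted_main
        with pytest.raises(KeyError, match="nope"):
            lag_effects(res["fit"], res["specs"]["temp_post"], "nope", 12.0, 10.0)


class TestCumulativeEffect:
    def test_single_lag_range_equals_lag_effect(self, fitted_main):
        _, res = fitted_main
        spec = res["specs"]["temp_post"]
        lag = lag_effects(res["fit"], spec, "temp_post", 16.0, 11.0, lags=[7])[0]
        cum = cumulative_effect(res["fit"], spec, "temp_post", 16.0, 11.0, [7])
        assert cum.log_rr == pytest.approx(lag.log_rr)
        assert cum.se_log_rr == pytest.approx(lag.se_log_rr)

    def test_point_estimate_is_product_of_lag_rrs(self, fitted_main):
        _, res = fitted_main
        spec = res["specs"]["temp_post"]
        lags = list(range(4, 16))
        ests = lag_effects(res["fit"], spec, "temp_post", 16.0, 11.0, lags=lags)
        cum = cumulative_effect(res["fit"], spec, "temp_post", 16.0, 11.0, lags)
        assert cum.rr == pytest.approx(np.prod([e.rr for e in ests]), rel=1e-10)

    def test_additive_over_disjoint_lag_sets(self, fitted_main):
        _, res = fitted_main
        spec = res["specs"]["temp_post"]
        args = (res["fit"], spec, "temp_post", 16.0, 11.0)
        a = cumulative_effect(*args, range(1, 11))
        b = cumulative_effect(*args, range(11, 31))
        ab = cumulative_effect(*args, range(1, 31))
        assert ab.log_rr == pytest.approx(a.log_rr + b.log_rr, rel=1e-10)

    def test_ci_matches_monte_carlo_oracle(self, fitted_main):
        # sample beta ~ N(beta_hat, Sigma); percentile CI of the cumulative
        # RR must match the delta-method CI within 2% relative
        _, res = fitted_main
        fit = res["fit"]
        spec = res["specs"]["temp_post"]
        lags = np.arange(5, 25)
        cum = cumulative_effect(fit, spec, "temp_post", 16.0, 11.0, lags)
        rows = prediction_rows(spec, 16.0, 11.0, lags).sum(axis=0)
        rng = np.random.default_rng(2024)
        draws = rng.multivariate_normal(
            fit.block_params("temp_post"), fit.block_vcov("temp_post"), size=10_000
        )
        mc = np.exp(draws @ rows)
        lo, hi = np.percentile(mc, [2.5, 97.5])
        assert cum.ci_low == pytest.approx(lo, rel=0.02)
        assert cum.ci_high == pytest.approx(hi, rel=0.02)

    def test_variance_uses_full_covariance_not_sum_of_variances(self, fitted_main):
        _, res = fitted_main
        spec = res["specs"]["temp_post"]
        lags = list(range(5, 25))
        ests = lag_effects(res["fit"], spec, "temp_post", 16.0, 11.0, lags=lags)
        cum = cumulative_effect(res["fit"], spec, "temp_post", 16.0, 11.0, lags)
        naive = np.sqrt(sum(e.se_log_rr**2 for e in ests))
        assert cum.se_log_rr != pytest.approx(naive, rel=1e-3)


def pattern(bits, log_rrs=None):
    """EffectEstimates over consecutive lags; bit=1 -> significant."""
    out = []
    for i, b in enumerate(bits):
        lr = (log_rrs[i] if log_rrs else -0.1) if b else 0.0
        se = 0.01 if b else 1.0
        out.append(EffectEstimate(lr, se, lag=i + 1))
    return out


class TestFindWindows:
    def test_no_significant_lag_gives_empty_list(self):
        assert find_windows(pattern([0, 0, 0, 0])) == []

    def test_run_length_oracle_pattern(self):
        # 0,1,1,1,0,1,0 -> single window weeks 2-4, isolated week 6 dropped
        wins = find_windows(pattern([0, 1, 1, 1, 0, 1, 0]))
        assert [(w.start_week, w.end_week) for w in wins] == [(2, 4)]

    def test_sign_flip_splits_run(self):
        bits = [0, 1, 1, 1, 1, 0]
        lrs = [0, -0.1, -0.1, 0.1, 0.1, 0]
        wins = find_windows(pattern(bits, lrs))
        assert [(w.start_week, w.end_week, w.direction) for w in wins] == [
            (2, 3, "deleterious"),
            (4, 5, "protective"),
        ]

    def test_single_significant_week_is_not_a_window(self):
        assert find_windows(pattern([0, 1, 0])) == []

    def test_windows_annotated_with_cumulative(self):
        calls = []

        def cum(lags):
            calls.append(tuple(lags))
            return EffectEstimate(-0.2, 0.05)

        wins = find_windows(pattern([1, 1, 1]), cumulative_fn=cum)
        assert calls == [(1, 2, 3)]
        assert wins[0].cumulative.rr == pytest.approx(np.exp(-0.2))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.booleans(), min_size=1, max_size=15), st.integers(1, 5))
    def test_invariant_to_nonsignificant_padding(self, bits, pad):
        base = find_windows(pattern([int(b) for b in bits]))
        padded = find_windows(pattern([0] * pad + [int(b) for b in bits] + [0] * pad))
        assert [(w.end_week - w.start_week, w.direction) for w in padded] == [
            (w.end_week - w.start_week, w.direction) for w in base
        ]
        assert [w.start_week - pad for w in padded] == [w.start_week for w in base]


class TestRrToPercent:
    @pytest.mark.parametrize(
        "rr,value,direction",
        [
            (0.968, 3.2, "reduction"),
            (1.033, 3.3, "increase"),
            (0.852, 14.8, "reduction"),
            (1.0, 0.0, "none"),
        ],
    )
    def test_conversion(self, rr, value, direction):
        pct = rr_to_percent(rr)
        assert pct.value == pytest.approx(value)
        assert pct.direction == direction

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            rr_to_percent(0.0)
        with pytest.raises(ValueError):
            rr_to_percent(-2.0)
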