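import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import approx_fprime

from riskrank import pt_model, task_model
from riskrank.pt_model import PTParams, choice_prob_right, sev, utility, weight


class TestUtility:
    @pytest.mark.parametrize(
        "x, params, expected",
        [
            (2, PTParams(rho_plus=0.5), math.sqrt(2)),
            (-2, PTParams(rho_minus=-0.5, lam=2.0), -2 * math.sqrt(2)),
            (0, PTParams(), 0.0),
            (3, PTParams(), 3.0),
            (-3, PTParams(lam=2.0), -6.0),
        ],
    )
    def test_closed_forms(self, x, params, expected):
        assert utility(x, params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("rho_p, rho_m", [(0.0, 0.0), (0.4, -0.3), (-0.6, 0.7)])
    def test_lambda_is_loss_gain_ratio_at_unit_outcome(self, rho_p, rho_m):
        # at |x| = 1 the curvature exponents drop out and lam is exactly the
        # loss/gain steepness ratio
        p = PTParams(rho_plus=rho_p, rho_minus=rho_m, lam=2.987)
        assert abs(utility(-1, p)) / utility(1, p) == pytest.approx(2.987)

    @given(
        rho=st.floats(-0.9, 0.9),
        lam=st.floats(0.1, 10),
    )
    @settings(deadline=None, derandomize=True)
    def test_sign_preserving_and_increasing(self, rho, lam):
        p = PTParams(rho_plus=rho, rho_minus=rho, lam=lam)
        vals = [utility(x, p) for x in (-3, -2, -1, 0, 1, 2, 3)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert vals[3] == 0.0

    def test_invalid_params_signalled(self):
        with pytest.raises(ValueError):
            PTParams(lam=-1.0)
        with pytest.raises(ValueError):
            PTParams(rho_plus=1.0)
        with pytest.raises(ValueError):
            PTParams(mu=float("nan"))


class TestWeight:
    @pytest.mark.parametrize(
        "p, alpha, expected",
        [
            (1.0, 0.7, 1.0),
            (1.0, 3.0, 1.0),
            (0.25, 1.0, 0.25),
            (math.exp(-1), 0.6, math.exp(-1)),
            (math.exp(-1), 2.5, math.exp(-1)),
        ],
    )
    def test_fixed_points_and_identity(self, p, alpha, expected):
        assert weight(p, alpha) == pytest.approx(expected, rel=1e-12)

    def test_invalid_probability_signalled(self):
        with pytest.raises(ValueError):
            weight(0.0, 1.0)
        with pytest.raises(ValueError):
            weight(1.2, 1.0)
        with pytest.raises(ValueError):
            weight(0.5, 0.0)

    @given(alpha=st.floats(0.1, 4.0))
    @settings(deadline=None, derandomize=True)
    def test_monotone_and_crosses_identity_only_at_fixed_points(self, alpha):
        grid = np.linspace(0.01, 1.0, 200)
        w = weight(grid, alpha)
        assert np.all(np.diff(w) > 0)
        # sign of w(p) - p flips only around p = 1/e
        diff = w - grid
        inv = 1 / math.e
        below = grid < inv - 1e-9
        above = (grid > inv + 1e-9) & (grid < 1 - 1e-9)
        if alpha < 1:  # inverted-S: overweight small p, underweight large p
            assert np.all(diff[below] > 0) and np.all(diff[above] < 0)
        elif alpha > 1:  # S-shape
            assert np.all(diff[below] < 0) and np.all(diff[above] > 0)


class TestSEVAndChoice:
    def test_sev_reduces_to_ev_at_neutral_params(self):
        neutral = PTParams()
        for lot in [(1, 1.0), (2, 0.25), (-3, 0.5), (3, 0.75)]:
            assert sev(lot, neutral) == pytest.approx(task_model.expected_value(lot))

    def test_sev_loss_scaling(self):
        p = PTParams(lam=3.0, rho_minus=0.0, alpha_minus=1.0)
        assert sev((-3, 0.5), p) == pytest.approx(-4.5)

    def test_equal_ev_tradeoff_is_coin_flip_for_neutral_agent(self):
        # the task's canonical example: 50% of 1 token vs 25% of 2 tokens
        pair = ((1, 0.50), (2, 0.25))
        assert choice_prob_right(pair, PTParams(mu=5.0)) == pytest.approx(0.5)

    def test_identical_lotteries_give_sigmoid_of_side_bias(self):
        from scipy.special import expit

        pair = ((2, 0.75), (2, 0.75))
        p = PTParams(rho_plus=0.3, alpha_plus=1.4, mu=8.0, x0=0.7)
        assert choice_prob_right(pair, p) == pytest.approx(float(expit(0.7)))

    @given(
        rho=st.floats(-0.8, 0.8),
        lam=st.floats(0.2, 8),
        alpha=st.floats(0.2, 3),
        mu=st.floats(0.0, 10),
        x0=st.floats(-2, 2),
        xl=st.sampled_from([-3, -2, -1, 1, 2, 3]),
        xr=st.sampled_from([-3, -2, -1, 1, 2, 3]),
        pl=st.sampled_from([0.25, 0.5, 0.75, 1.0]),
        pr=st.sampled_from([0.25, 0.5, 0.75, 1.0]),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_left_right_symmetry(self, rho, lam, alpha, mu, x0, xl, xr, pl, pr):
        # swapping sides and negating the side bias must flip the choice prob
        params = PTParams(
            rho_plus=rho, rho_minus=-rho, lam=lam,
            alpha_plus=alpha, alpha_minus=alpha, mu=mu, x0=x0,
        )
        pair = ((xl, pl), (xr, pr))
        swapped = ((xr, pr), (xl, pl))
        p1 = choice_prob_right(pair, params)
        p2 = choice_prob_right(swapped, params.replace(x0=-x0))
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)

    def test_overflow_safe(self):
        p = PTParams(mu=25.0, lam=15.0, x0=10.0)
        prob = choice_prob_right(((-3, 1.0), (3, 1.0)), p)
        assert prob == pytest.approx(1.0)


class TestNLL:
    def test_single_balanced_trial_is_ln2(self):
        import pandas as pd

        trials = pd.DataFrame(
            {
                "left_outcome": [1], "left_prob": [0.5],
                "right_outcome": [2], "right_prob": [0.25],
                "choice": ["right"],
            }
        )
        nll = pt_model.negative_log_likelihood(trials, PTParams(mu=5.0))
        assert nll == pytest.approx(math.log(2))
        # additivity over n identical trials
        rep = pd.concat([trials] * 7, ignore_index=True)
        assert pt_model.negative_log_likelihood(rep, PTParams(mu=5.0)) == pytest.approx(
            7 * math.log(2)
        )

    def test_empty_trials_signalled(self):
        import pandas as pd

        with pytest.raises(ValueError):
            pt_model.negative_log_likelihood(pd.DataFrame(columns=["choice"]), PTParams())

    def test_true_params_beat_perturbed_on_large_sample(self, battery, typical_params):
        # law of large numbers: the generating parameters (approximately)
        # minimize the NLL, so any single-parameter perturbation raises it
        trials = task_model.simulate_choices(typical_params, battery, 5000, seed=4)
        nll_true = pt_model.negative_log_likelihood(trials, typical_params)
        for name in pt_model.PARAM_NAMES[:5]:
            perturbed = typical_params.replace(
                **{name: getattr(typical_params, name) + 0.3}
            )
            assert nll_true <= pt_model.negative_log_likelihood(trials, perturbed)

    def test_analytic_gradient_matches_numeric(self, battery, typical_params):
        trials = task_model.simulate_choices(typical_params, battery, 400, seed=9)
        xl, pl, xr, pr, cr = pt_model.trials_to_arrays(trials)
        rng = np.random.default_rng(3)
        for _ in range(4):
            vec = np.array(
                [
                    rng.uniform(-0.7, 0.7), rng.uniform(-0.7, 0.7),
                    rng.uniform(0.3, 5), rng.uniform(0.3, 3),
                    rng.uniform(0.3, 3), rng.uniform(0.2, 4), rng.uniform(-1, 1),
                ]
            )
            _, g = pt_model.nll_and_grad_arrays(vec, xl, pl, xr, pr, cr)
            gn = approx_fprime(
                vec, lambda v: pt_model.nll_arrays(v, xl, pl, xr, pr, cr), 1e-7
            )
            assert np.allclose(g, gn, rtol=1e-3, atol=1e-4)
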