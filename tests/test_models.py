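"""The four decay models: closed forms, calculus identities, inversion."""

import json

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from tdrp.models import (
    RateModelKind,
    RateModelParams,
    average_rate,
    cumulative_substitutions,
    ex_max_substitutions,
    instantaneous_rate,
    invert_time,
)

KINDS = list(RateModelKind)


def random_params(kind, rng):
    alpha = 10.0 ** rng.uniform(-4, 1)
    beta = rng.uniform(0.05, 0.95) if kind.is_power_law else 10.0 ** rng.uniform(-3, 0.5)
    k = 10.0 ** rng.uniform(-6, -2) if kind.has_offset else 0.0
    return RateModelParams(kind=kind, alpha=alpha, beta=beta, k=k)


class TestClosedForms:
    @pytest.mark.parametrize(
        "kind,kw,t,expected",
        [
            ("PL", dict(alpha=2, beta=0.5), 4.0, 1.0),
            ("VEX", dict(alpha=1, beta=0.1, k=0.5), 0.0, 1.5),
            ("EX", dict(alpha=3, beta=0.2), 200.0, pytest.approx(0, abs=1e-15)),
        ],
    )
    def test_instantaneous_rate(self, kind, kw, t, expected):
        assert instantaneous_rate(RateModelParams(kind, **kw), t) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kind,kw,t,expected",
        [
            ("EX", dict(alpha=1, beta=1), 1.0, 1 - np.exp(-1)),
            ("PL", dict(alpha=0.4, beta=0.5), 6.25, 2.0),
        ],
    )
    def test_cumulative(self, kind, kw, t, expected):
        assert cumulative_substitutions(RateModelParams(kind, **kw), t) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("kind", KINDS)
    def test_cumulative_starts_at_origin(self, kind, rng):
        p = random_params(kind, rng)
        assert cumulative_substitutions(p, 0.0) == 0.0

    def test_average_rate_power_law(self):
        p = RateModelParams("PL", alpha=1.5e-4, beta=0.6)
        assert average_rate(p, 10.0) == pytest.approx(9.4196e-5, rel=1e-3)

    @pytest.mark.parametrize("kind", KINDS)
    def test_average_rate_is_cumulative_over_t(self, kind, rng):
        p = random_params(kind, rng)
        t = 10.0 ** rng.uniform(-2, 2, size=20)
        np.testing.assert_allclose(
            average_rate(p, t) * t, cumulative_substitutions(p, t), rtol=1e-14
        )

    def test_vpl_average_rate_tends_to_k(self):
        p = RateModelParams("VPL", alpha=0.3, beta=0.7, k=0.01)
        assert average_rate(p, 1e9) == pytest.approx(p.k, rel=1e-2)


class TestCalculusIdentities:
    @pytest.mark.parametrize("kind", KINDS)
    def test_cumulative_matches_quadrature(self, kind, rng):
        """s(t) equals the integral of the instantaneous rate from 0 to t."""
        for _ in range(25):
            p = random_params(kind, rng)
            t = 10.0 ** rng.uniform(-2, 2)
            val, _ = quad(
                lambda u: instantaneous_rate(p, u) if u > 0 else 0.0, 0, t,
                limit=400, epsabs=0.0, epsrel=1e-11,
            )
            assert cumulative_substitutions(p, t) == pytest.approx(val, rel=1e-8)

    @pytest.mark.parametrize("kind", KINDS)
    def test_rate_is_derivative_of_cumulative(self, kind, rng):
        p = random_params(kind, rng)
        grid = np.linspace(0.5, 50, 25)
        h = 1e-6
        num = (
            cumulative_substitutions(p, grid + h) - cumulative_substitutions(p, grid - h)
        ) / (2 * h)
        np.testing.assert_allclose(num, instantaneous_rate(p, grid), rtol=1e-6)

    @pytest.mark.parametrize("kind", KINDS)
    def test_monotonicity_and_ordering(self, kind, rng):
        """Rate decays, substitutions accumulate, and the running mean of a
        decaying rate always exceeds the current rate."""
        p = random_params(kind, rng)
        grid = 10.0 ** np.linspace(-2, 2, 50)
        r = instantaneous_rate(p, grid)
        s = cumulative_substitutions(p, grid)
        rb = average_rate(p, grid)
        assert np.all(np.diff(r) < 0)
        assert np.all(np.diff(s) > 0)
        assert np.all(np.diff(rb) < 0)
        assert np.all(r <= rb * (1 + 1e-12))

    def test_pl_log_average_rate_is_affine(self, rng):
        p = random_params(RateModelKind.PL, rng)
        grid = 10.0 ** np.linspace(-1, 2, 10)
        slope = np.diff(np.log(average_rate(p, grid))) / np.diff(np.log(grid))
        np.testing.assert_allclose(slope, -p.beta, rtol=1e-10)


class TestInversion:
    @pytest.mark.parametrize(
        "kind,kw,s,expected",
        [
            ("PL", dict(alpha=0.4, beta=0.5), 2.0, 6.25),
            ("EX", dict(alpha=1, beta=1), 1 - np.exp(-1), 1.0),
        ],
    )
    def test_closed_forms(self, kind, kw, s, expected):
        assert invert_time(RateModelParams(kind, **kw), s) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("kind", KINDS)
    def test_zero_substitutions_is_time_zero(self, kind, rng):
        assert invert_time(random_params(kind, rng), 0.0) == 0.0

    @pytest.mark.parametrize("kind", KINDS)
    def test_round_trip(self, kind, rng):
        for _ in range(25):
            p = random_params(kind, rng)
            t = 10.0 ** rng.uniform(-2, 2)
            if kind is RateModelKind.EX:
                # near saturation s carries no time information; stay in the
                # numerically invertible regime
                t = min(t, 15.0 / p.beta)
            t_back = invert_time(p, cumulative_substitutions(p, t))
            assert abs(t_back - t) <= 1e-8 * max(t, 1.0)

    def test_vex_against_brentq_oracle(self, rng):
        """The vectorized bisection agrees with an independently bracketed
        scipy Brent solve."""
        for _ in range(20):
            p = random_params(RateModelKind.VEX, rng)
            t_true = 10.0 ** rng.uniform(-1, 2)
            s = cumulative_substitutions(p, t_true)
            oracle = brentq(
                lambda u: cumulative_substitutions(p, u) - s, 0, 10 * t_true + 1,
                xtol=1e-12, rtol=1e-14,
            )
            assert invert_time(p, s) == pytest.approx(oracle, rel=1e-8, abs=1e-10)

    def test_ex_unreachable_raises(self):
        p = RateModelParams("EX", alpha=1, beta=1)
        assert ex_max_substitutions(p) == 1.0
        with pytest.raises(ValueError, match="saturates"):
            invert_time(p, 1.0)

    def test_negative_substitutions_rejected(self):
        with pytest.raises(ValueError):
            invert_time(RateModelParams("PL", alpha=1, beta=0.5), -0.1)


class TestValidationAndUnits:
    def test_power_law_singular_at_zero(self):
        with pytest.raises(ValueError):
            instantaneous_rate(RateModelParams("PL", alpha=1, beta=0.5), 0.0)

    @pytest.mark.parametrize("bad", [dict(alpha=-1, beta=0.5), dict(alpha=1, beta=-0.5),
                                     dict(alpha=np.nan, beta=0.5), dict(alpha=1, beta=0.5, k=-1)])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            RateModelParams("VPL", **bad)

    def test_power_law_beta_must_be_below_one(self):
        with pytest.raises(ValueError, match="beta"):
            RateModelParams("PL", alpha=1, beta=1.2)

    def test_ex_ignores_k(self):
        assert RateModelParams("EX", alpha=1, beta=1, k=0.3).k == 0.0

    @pytest.mark.parametrize("kind", KINDS)
    def test_unit_conversion_preserves_curves(self, kind, rng):
        """A model re-expressed in years predicts the same physical rate and
        the same substitutions at the same physical time."""
        p = random_params(kind, rng)  # Myr units
        py = p.to_unit("year")
        t_myr = 10.0 ** rng.uniform(-1, 2, size=5)
        np.testing.assert_allclose(
            instantaneous_rate(py, t_myr * 1e6) * 1e6, instantaneous_rate(p, t_myr), rtol=1e-12
        )
        np.testing.assert_allclose(
            cumulative_substitutions(py, t_myr * 1e6), cumulative_substitutions(p, t_myr),
            rtol=1e-12,
        )
        back = py.to_unit("Myr")
        assert back.alpha == pytest.approx(p.alpha, rel=1e-14)
        assert back.beta == pytest.approx(p.beta, rel=1e-14)

    @pytest.mark.parametrize("kind", KINDS)
    def test_json_round_trip_exact(self, kind, rng):
        p = random_params(kind, rng)
        q = RateModelParams.from_json(p.to_json())
        assert (q.alpha, q.beta, q.k, q.kind, q.time_unit) == (
            p.alpha, p.beta, p.k, p.kind, p.time_unit
        )
        assert json.loads(p.to_json())["kind"] == kind.value


class TestPropertyBased:
    """Hypothesis sweeps over the valid parameter space."""

    from hypothesis import given, settings, strategies as st

    kind_st = st.sampled_from(list(RateModelKind))
    t_st = st.floats(min_value=1e-2, max_value=1e2)

    @staticmethod
    def _params(kind, a_exp, b_frac, k_exp):
        beta = 0.05 + 0.9 * b_frac if kind.is_power_law else 10.0 ** (-3 + 3.5 * b_frac)
        k = 10.0 ** (-6 + 4 * k_exp) if kind.has_offset else 0.0
        return RateModelParams(kind=kind, alpha=10.0 ** a_exp, beta=beta, k=k)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(kind=kind_st, a_exp=st.floats(-4, 1), b_frac=st.floats(0, 1),
           k_exp=st.floats(0, 1), t1=t_st, t2=t_st)
    def test_decay_and_accumulation_everywhere(self, kind, a_exp, b_frac, k_exp, t1, t2):
        p = self._params(kind, a_exp, b_frac, k_exp)
        lo, hi = sorted((t1, t2))
        if hi <= lo:
            return
        assert instantaneous_rate(p, hi) <= instantaneous_rate(p, lo)
        assert cumulative_substitutions(p, hi) >= cumulative_substitutions(p, lo)
        assert average_rate(p, hi) <= average_rate(p, lo) * (1 + 1e-12)
        # current rate never exceeds the average of its own past
        assert instantaneous_rate(p, hi) <= average_rate(p, hi) * (1 + 1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(kind=kind_st, a_exp=st.floats(-4, 1), b_frac=st.floats(0, 1),
           k_exp=st.floats(0, 1), t=t_st)
    def test_inversion_is_a_left_inverse(self, kind, a_exp, b_frac, k_exp, t):
        p = self._params(kind, a_exp, b_frac, k_exp)
        if kind is RateModelKind.EX:
            t = min(t, 15.0 / p.beta)
        s = cumulative_substitutions(p, t)
        assert abs(invert_time(p, s) - t) <= 1e-8 * max(t, 1.0)
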