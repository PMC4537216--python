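"""The piecewise curve, the error-scaled cost and the DE fitter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from profilefit.profile_model import (
    DEConfig,
    PiecewiseParams,
    cost,
    evaluate_piecewise,
    fit_profile_de,
    fit_profiles,
    good_fit_mask,
    summarize_timescales,
)
from profilefit.synthetic import SyntheticConfig, sample_true_profiles


def random_params(rng, t0=3.0, span=333.0):
    t = rng.uniform(0, span / 4, size=4)
    a = rng.uniform(0, 2, size=3)
    return PiecewiseParams(t0, *t, *a)


class TestEvaluatePiecewise:
    def test_initial_and_terminal_plateaus(self, rng):
        for _ in range(50):
            p = random_params(rng)
            assert evaluate_piecewise(p, p.t0) == p.A1
            t_end = p.t0 + p.t1 + p.t2 + p.t3 + p.t4
            assert evaluate_piecewise(p, t_end + 1.0) == p.A3

    def test_ramp_midpoint_interpolates(self):
        # ramp from A1=0 at 4 h to A2=2 at 6 h: midpoint 5 h -> 1.0
        p = PiecewiseParams(3.0, 1.0, 2.0, 0.0, 0.0, 0.0, 2.0, 2.0)
        assert evaluate_piecewise(p, 5.0) == pytest.approx(1.0)

    def test_closed_form_at_knots_and_midpoints(self, rng):
        """Plateau and ramp values match the closed form for random draws."""

        def closed_form(p, t):
            k1 = p.t0 + p.t1
            k2, k3, k4 = k1 + p.t2, k1 + p.t2 + p.t3, k1 + p.t2 + p.t3 + p.t4
            if t <= k1:
                return p.A1
            if t < k2:
                return p.A1 + (p.A2 - p.A1) * (t - k1) / p.t2
            if t <= k3:
                return p.A2
            if t < k4:
                return p.A2 + (p.A3 - p.A2) * (t - k3) / p.t4
            return p.A3

        for _ in range(200):
            p = random_params(rng)
            knots = [p.t0, *(p.t0 + np.cumsum([p.t1, p.t2, p.t3, p.t4]))]
            pts = list(knots) + [(a + b) / 2 for a, b in zip(knots[:-1], knots[1:])]
            for t in pts:
                assert evaluate_piecewise(p, t) == closed_form(p, t)

    def test_continuity_at_knots(self, rng):
        eps = 1e-9
        for _ in range(50):
            p = random_params(rng)
            for k in p.knots:
                left = evaluate_piecewise(p, max(k - eps, p.t0))
                right = evaluate_piecewise(p, k + eps)
                assert abs(left - right) < 1e-6 * (1 + abs(right))

    def test_before_origin_rejected(self, transient_params):
        with pytest.raises(ValueError):
            evaluate_piecewise(transient_params, 2.0)

    def test_zero_duration_ramp_is_a_jump(self):
        p = PiecewiseParams(3.0, 1.0, 0.0, 1.0, 0.0, 0.0, 2.0, 2.0)
        assert evaluate_piecewise(p, 4.0) == 0.0  # boundary goes to plateau A1
        assert evaluate_piecewise(p, 4.0 + 1e-9) == 2.0

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            PiecewiseParams(3.0, -1.0, 0, 0, 0, 1, 1, 1)


class TestCost:
    def test_perfect_fit_zero(self, transient_params, grid):
        d = evaluate_piecewise(transient_params, grid)
        sigma = np.full_like(d, 0.1)
        assert cost(transient_params, d, sigma, grid) == 0.0

    def test_hand_arithmetic(self):
        # single point: d=2, s=1, sigma=1 -> F=1
        p = PiecewiseParams(0.0, 0, 0, 0, 0, 1.0, 1.0, 1.0)
        assert cost(p, [2.0], [1.0], [0.0]) == pytest.approx(1.0)
        # d=(1,2), s=(0,0), sigma=(1,2) -> 1 + 1 = 2
        p0 = PiecewiseParams(0.0, 0, 0, 0, 0, 0.0, 0.0, 0.0)
        assert cost(p0, [1.0, 2.0], [1.0, 2.0], [0.0, 1.0]) == pytest.approx(2.0)

    def test_term_by_term_oracle(self, rng, grid):
        for _ in range(50):
            p = random_params(rng)
            d = rng.uniform(0, 2, size=grid.size)
            sigma = rng.uniform(0.05, 0.5, size=grid.size)
            s = evaluate_piecewise(p, grid)
            expected = sum((dj - sj) ** 2 / sg**2 for dj, sj, sg in zip(d, s, sigma))
            assert cost(p, d, sigma, grid) == pytest.approx(expected, abs=1e-12, rel=1e-12)

    def test_joint_rescaling_invariance(self, rng, grid):
        p = random_params(rng)
        d = rng.uniform(0.1, 2, size=grid.size)
        sigma = rng.uniform(0.05, 0.5, size=grid.size)
        base = cost(p, d, sigma, grid)
        c = 7.3
        scaled = PiecewiseParams(p.t0, p.t1, p.t2, p.t3, p.t4, c * p.A1, c * p.A2, c * p.A3)
        assert cost(scaled, c * d, c * sigma, grid) == pytest.approx(base, rel=1e-9)

    def test_nonpositive_sigma_rejected(self, transient_params, grid):
        d = np.ones(grid.size)
        with pytest.raises(ValueError):
            cost(transient_params, d, np.zeros(grid.size), grid)


class TestDEFitter:
    def test_flat_data_recovers_constant(self, grid):
        d = np.full(grid.size, 0.8)
        sigma = np.full(grid.size, 0.01)
        ens = fit_profile_de(d, sigma, grid, DEConfig(seed=1, restarts=5))
        best = ens.best
        for a in (best.A1, best.A2, best.A3):
            assert abs(a - 0.8) < 1e-3 * 0.8

    def test_best_cost_trace_non_increasing(self, grid, rng):
        d = rng.uniform(0.2, 1.0, size=grid.size)
        sigma = np.full(grid.size, 0.05)
        ens = fit_profile_de(d, sigma, grid, DEConfig(seed=3, restarts=5))
        assert np.all(np.diff(ens.best_cost_trace) <= 0)

    def test_seeded_fit_is_bit_reproducible(self, grid, rng):
        d = rng.uniform(0.2, 1.0, size=grid.size)
        sigma = np.full(grid.size, 0.05)
        a = fit_profile_de(d, sigma, grid, DEConfig(seed=9, restarts=4))
        b = fit_profile_de(d, sigma, grid, DEConfig(seed=9, restarts=4))
        assert np.array_equal(a.params, b.params)
        assert np.array_equal(a.costs, b.costs)

    def test_noiseless_identifiable_quantities_recovered(self, grid):
        """On noiseless grid-anchored profiles t1, total change time, A1 and
        A3 are pinned down even when t2..t4 individually are degenerate."""
        cfg = SyntheticConfig(n_genes=12, seed=5)
        params, cats = sample_true_profiles(cfg)
        d = np.array([evaluate_piecewise(p, grid) for p in params])
        sigma = np.maximum(1e-6, 0.01 * d.mean(axis=1))[:, None] * np.ones_like(d)
        ensembles = fit_profiles(d, sigma, grid, DEConfig(seed=2))
        for p_true, cat, ens in zip(params, cats, ensembles):
            s = ens.curves()[0]
            assert np.allclose(s, evaluate_piecewise(p_true, grid), atol=1e-6)
            if cat == "flat":
                continue
            best = ens.best
            assert best.A1 == pytest.approx(p_true.A1, rel=0.05, abs=0.02)
            assert best.A3 == pytest.approx(p_true.A3, rel=0.05, abs=0.02)

    def test_ensemble_sorted_by_cost(self, grid, rng):
        d = rng.uniform(0.2, 1.0, size=grid.size)
        sigma = np.full(grid.size, 0.05)
        ens = fit_profile_de(d, sigma, grid, DEConfig(seed=4, restarts=3))
        assert np.all(np.diff(ens.costs) >= 0)
        assert len(ens) == 3 * 15

    def test_nonfinite_data_rejected(self, grid):
        d = np.full(grid.size, np.nan)
        with pytest.raises(ValueError):
            fit_profile_de(d, np.ones(grid.size), grid, DEConfig(seed=0))


class TestGoodFitMask:
    def test_exact_member_kept_and_2sigma_rejected(self, grid, transient_params):
        d = np.asarray(evaluate_piecewise(transient_params, grid))
        sigma = np.full(grid.size, 0.1)
        ens = fit_profile_de(d, sigma, grid, DEConfig(seed=0, restarts=2, max_iter=50))
        # inject a perfect member and an always-2-sigma member
        ens.params[0] = transient_params.as_array()
        shifted = np.asarray(evaluate_piecewise(transient_params, grid)) + 2 * sigma
        mask = good_fit_mask(ens, d, sigma)
        assert mask[0]
        dev = np.abs(ens.curves() - d[None, :]) / sigma[None, :]
        assert np.all(mask == (dev.mean(axis=1) <= 1.0 + 1e-12))

    def test_boundary_mean_deviation_inclusive(self, grid):
        # deviations (0, 2) sigma over 2 points -> mean exactly 1 -> kept
        times = np.array([0.0, 1.0])
        d = np.array([1.0, 1.0])
        sigma = np.array([0.5, 0.5])
        ens = fit_profile_de(d, sigma, times, DEConfig(seed=0, restarts=1, max_iter=10))
        member = PiecewiseParams(0.0, 0, 1.0, 0, 0, 1.0, 2.0, 2.0)  # s=(1, 2)
        ens.params[0] = member.as_array()
        assert good_fit_mask(ens, d, sigma)[0]


class TestTimescales:
    def test_uniform_members_give_point_estimate(self, grid):
        d = np.full(grid.size, 1.0)
        sigma = np.full(grid.size, 0.5)
        ens = fit_profile_de(d, sigma, grid, DEConfig(seed=0, restarts=1, max_iter=10))
        ens.params[:, 0] = 5.0  # force t1=5 for every member
        out = summarize_timescales([ens], d[None, :], sigma[None, :])
        assert out["t1"][0] == pytest.approx(5.0)

    def test_flat_genes_excluded(self, grid):
        d = np.full(grid.size, 1.0)
        sigma = np.full(grid.size, 0.5)
        ens = fit_profile_de(d, sigma, grid, DEConfig(seed=0, restarts=1, max_iter=10))
        out = summarize_timescales([ens], d[None, :], sigma[None, :],
                                   exclude=np.array([True]))
        assert out["t1"].size == 0


@settings(max_examples=30, deadline=None)
@given(
    t=st.lists(st.floats(0, 80, allow_nan=False), min_size=4, max_size=4),
    a=st.lists(st.floats(0, 3, allow_nan=False), min_size=3, max_size=3),
    query=st.floats(3, 400, allow_nan=False),
)
def test_piecewise_output_bounded_by_amplitudes(t, a, query):
    """The curve never leaves the interval spanned by its amplitudes."""
    p = PiecewiseParams(3.0, *t, *a)
    val = evaluate_piecewise(p, query)
    assert min(a) - 1e-9 <= val <= max(a) + 1e-9
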