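"""Boundary recursion: printed-value reproduction, conservation, MC oracle."""

import numpy as np
import pytest
from scipy.stats import norm

from seqtrial import (
    LookSchedule,
    SpendingSpec,
    compute_boundaries,
    crossing_probabilities,
    solve_power_drift,
)


def _mc_crossing(boundaries, drift, n_paths=400_000, seed=2024):
    """Monte-Carlo oracle: simulate the joint normal path on the score scale."""
    rng = np.random.default_rng(seed)
    fr = np.asarray(boundaries.schedule.fractions)
    dt = np.diff(np.concatenate(([0.0], fr)))
    inc = rng.standard_normal((n_paths, fr.size)) * np.sqrt(dt) + drift * dt
    s = np.cumsum(inc, axis=1)
    z = s / np.sqrt(fr)
    eff = np.zeros(fr.size)
    fut = np.zeros(fr.size)
    alive = np.ones(n_paths, dtype=bool)
    for k in range(fr.size):
        up = alive & (z[:, k] >= boundaries.efficacy_z[k])
        if k == fr.size - 1:
            down = alive & ~up
        else:
            down = alive & (z[:, k] <= boundaries.futility_z[k]) & ~up
        eff[k] = up.mean()
        fut[k] = down.mean()
        alive &= ~(up | down)
    return eff, fut


class TestBoundaryReproduction:
    def test_single_look_is_fixed_sample(self):
        bd = compute_boundaries(
            LookSchedule([1.0]), SpendingSpec(0.05, 3.0), SpendingSpec(0.10, 3.0)
        )
        assert bd.efficacy_p[0] == pytest.approx(0.05, abs=1e-9)

    def test_three_look_efficacy_p_90(self, boundaries_90):
        """Nominal efficacy p-values of the recommended 3-look design."""
        rounded = [round(p, 3) for p in boundaries_90.efficacy_p]
        assert rounded == [0.002, 0.014, 0.046]

    def test_three_look_futility_p_90(self, boundaries_90):
        assert [round(p, 3) for p in boundaries_90.futility_p[:2]] == [0.830, 0.298]

    def test_three_look_futility_p_80(self, boundaries_80):
        assert [round(p, 3) for p in boundaries_80.futility_p[:2]] == [0.835, 0.312]

    def test_futility_meets_efficacy_at_final_look(self, boundaries_90):
        assert boundaries_90.futility_z[-1] == boundaries_90.efficacy_z[-1]
        for k in range(boundaries_90.n_looks - 1):
            assert boundaries_90.futility_z[k] < boundaries_90.efficacy_z[k]

    def test_nominal_p_increases_across_looks(self, boundaries_90):
        assert np.all(np.diff(boundaries_90.efficacy_p) > 0)

    def test_higher_rho_is_more_conservative_early(self, three_looks):
        first_p = []
        for rho in (1.0, 2.0, 3.0, 4.0):
            bd = compute_boundaries(
                three_looks, SpendingSpec(0.05, rho), SpendingSpec(0.10, 3.0)
            )
            first_p.append(bd.efficacy_p[0])
        assert np.all(np.diff(first_p) < 0)

    def test_infeasible_spending_rejected(self, three_looks):
        with pytest.raises(ValueError):
            solve_power_drift(
                three_looks, SpendingSpec(0.6, 3.0), SpendingSpec(0.5, 3.0)
            )


class TestCrossingProbabilities:
    def test_efficacy_total_is_alpha_under_null(self, boundaries_90):
        """Ignoring futility (non-binding construction), efficacy spends alpha."""
        # recompute crossing with futility pushed out of the way
        from dataclasses import replace

        unbounded = replace(
            boundaries_90,
            futility_z=tuple([-30.0] * (boundaries_90.n_looks - 1))
            + (boundaries_90.efficacy_z[-1],),
        )
        cp = crossing_probabilities(unbounded, 0.0)
        assert cp.total_efficacy == pytest.approx(0.05, abs=2e-6)

    def test_power_attained_at_design_drift(self, boundaries_90, boundaries_80):
        assert crossing_probabilities(
            boundaries_90, boundaries_90.drift
        ).total_efficacy == pytest.approx(0.90, abs=2e-6)
        assert crossing_probabilities(
            boundaries_80, boundaries_80.drift
        ).total_efficacy == pytest.approx(0.80, abs=2e-6)

    def test_probabilities_conserve_mass(self, boundaries_90):
        for drift in (0.0, 1.5, boundaries_90.drift):
            cp = crossing_probabilities(boundaries_90, drift)
            assert cp.total_efficacy + cp.total_futility == pytest.approx(1.0, abs=1e-9)

    def test_beta_spent_under_design_drift(self, boundaries_90):
        cp = crossing_probabilities(boundaries_90, boundaries_90.drift)
        assert cp.total_futility == pytest.approx(0.10, abs=2e-6)

    @pytest.mark.parametrize("drift_kind", ["null", "design"])
    def test_recursion_matches_monte_carlo(self, boundaries_90, drift_kind):
        """First-passage recursion vs simulation of the correlated normal path."""
        drift = 0.0 if drift_kind == "null" else boundaries_90.drift
        cp = crossing_probabilities(boundaries_90, drift)
        eff_mc, fut_mc = _mc_crossing(boundaries_90, drift)
        n = 400_000
        for k in range(boundaries_90.n_looks):
            for exact, mc in ((cp.efficacy[k], eff_mc[k]), (cp.futility[k], fut_mc[k])):
                se = np.sqrt(max(mc * (1 - mc), 1e-12) / n)
                assert abs(exact - mc) < 3 * se + 1e-4

    def test_five_look_design_against_monte_carlo(self):
        sched = LookSchedule([0.2, 0.4, 0.6, 0.8, 1.0])
        bd = compute_boundaries(sched, SpendingSpec(0.05, 2.0), SpendingSpec(0.15, 2.0))
        cp = crossing_probabilities(bd, bd.drift)
        eff_mc, _ = _mc_crossing(bd, bd.drift, n_paths=300_000, seed=7)
        assert cp.total_efficacy == pytest.approx(0.85, abs=2e-6)
        se = np.sqrt(0.85 * 0.15 / 300_000)
        assert abs(eff_mc.sum() - 0.85) < 3 * se + 1e-4


class TestOneInterimVariant:
    def test_printed_first_look_level(self):
        """A single interim at t=0.5 with rho=3 yields nominal p 0.006."""
        bd = compute_boundaries(
            LookSchedule([0.5, 1.0]), SpendingSpec(0.05, 3.0), SpendingSpec(0.10, 3.0)
        )
        assert round(bd.efficacy_p[0], 3) == 0.006
        # final look spends the rest; slightly below the single-test level
        assert 0.045 < bd.efficacy_p[1] < 0.05

    def test_futility_level_documented_value(self):
        """Beta-spending at t=0.5 under the 90%-power drift gives ~0.56.

        (The corresponding published one-interim futility threshold of
        0.716 is not reproducible by rho in {2, 3} beta-spending; the
        package reports the spending-consistent value.)
        """
        bd = compute_boundaries(
            LookSchedule([0.5, 1.0]), SpendingSpec(0.05, 3.0), SpendingSpec(0.10, 3.0)
        )
        assert 0.4 < bd.futility_p[0] < 0.7


class TestLookSchedule:
    def test_rejects_bad_schedules(self):
        for bad in ([], [0.5, 0.5, 1.0], [0.7, 0.3, 1.0], [0.5, 0.9]):
            with pytest.raises(ValueError):
                LookSchedule(bad)
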