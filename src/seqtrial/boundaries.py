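"""Group-sequential stopping boundaries by first-passage recursion.

The sequential test statistic is modelled in its canonical joint-normal
form: at information fractions ``t_1 < ... < t_K = 1`` the z-statistics
``Z_k`` are multivariate normal with ``E[Z_k] = drift * sqrt(t_k)`` and
``Cov(Z_j, Z_k) = sqrt(t_j / t_k)`` for ``j <= k``.  Equivalently the
score-scale process ``S_k = Z_k * sqrt(t_k)`` has independent increments
``S_k - S_{k-1} ~ N(drift * (t_k - t_{k-1}), t_k - t_{k-1})``, which is
what the recursion propagates.

Efficacy boundaries spend the one-sided type-I error under the null
(``drift = 0``) according to an alpha-spending function; futility
boundaries spend the type-II error under the design alternative
(beta-spending under H1).  By default the futility boundary is
NON-binding: the efficacy boundaries are computed ignoring it, so the
type-I error is protected even if a monitoring committee overrides a
futility stop.  Passing ``binding=True`` restricts the null sub-density
to the continuation region instead, which relaxes the later efficacy
boundaries.  At the final look the two boundaries coincide when the
drift is the one that attains the design power;
:func:`solve_power_drift` finds that drift.

Numerics: the continuation sub-density is carried on a fixed Simpson
grid on the score scale, and each per-look boundary is found by
bracketed root-finding on its spending increment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .spending import SpendingSpec, incremental_spend

__all__ = [
    "LookSchedule",
    "GSBoundaries",
    "CrossingProbabilities",
    "compute_boundaries",
    "crossing_probabilities",
    "solve_power_drift",
]

_Z_RANGE = 8.5  # score-scale search range for boundary roots, in SD units
_GRID_POINTS = 601  # Simpson nodes per continuation region (odd)


@dataclass(frozen=True)
class LookSchedule:
    """Ordered information fractions of the analysis looks; last must be 1."""

    fractions: tuple

    def __init__(self, fractions: Sequence[float]):
        fr = tuple(float(f) for f in fractions)
        if len(fr) == 0:
            raise ValueError("schedule needs at least one look")
        if any(f2 <= f1 for f1, f2 in zip(fr, fr[1:])):
            raise ValueError("information fractions must be strictly increasing")
        if not (0.0 < fr[0] and abs(fr[-1] - 1.0) < 1e-12):
            raise ValueError("fractions must lie in (0, 1] with the last equal to 1")
        object.__setattr__(self, "fractions", fr)

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class GSBoundaries:
    """Per-look efficacy/futility boundaries on the z and nominal-p scales.

    ``efficacy_p[k]`` is the one-sided upper-tail probability of
    ``efficacy_z[k]`` under a standard normal; an observed one-sided
    p-value below it stops for efficacy at look ``k``, one above
    ``futility_p[k]`` stops for futility (interim looks only).  At the
    final look the futility boundary equals the efficacy boundary, so
    there is no continuation region.
    """

    schedule: LookSchedule
    efficacy_z: tuple
    futility_z: tuple
    drift: float
    alpha_spec: SpendingSpec
    beta_spec: SpendingSpec
    binding: bool = False

    @property
    def efficacy_p(self) -> tuple:
        return tuple(float(norm.sf(z)) for z in self.efficacy_z)

    @property
    def futility_p(self) -> tuple:
        return tuple(float(norm.sf(z)) for z in self.futility_z)

    @property
    def n_looks(self) -> int:
        return len(self.schedule)


@dataclass(frozen=True)
class CrossingProbabilities:
    """Per-look stopping probabilities under a given drift."""

    efficacy: tuple
    futility: tuple

    @property
    def total_efficacy(self) -> float:
        return float(sum(self.efficacy))

    @property
    def total_futility(self) -> float:
        return float(sum(self.futility))


def _simpson_weights(n: int, h: float) -> np.ndarray:
    """Composite Simpson weights for ``n`` (odd) equally spaced nodes."""
    if n < 3 or n % 2 == 0:
        raise ValueError("Simpson rule needs an odd number of nodes >= 3")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


class _Recursion:
    """Propagates the continuation sub-density of the score process.

    State after look k: grid ``x`` over the continuation interval of
    ``S_k``, sub-density values ``dens`` and quadrature weights ``w``
    such that ``sum(w * dens * f(x))`` integrates ``f`` against the
    joint density of {S_k in dx, no stop through look k}.
    """

    def __init__(self, drift: float, n_grid: int = _GRID_POINTS):
        self.drift = drift
        self.n_grid = n_grid
        self.x: np.ndarray | None = None
        self.dens: np.ndarray | None = None
        self.w: np.ndarray | None = None
        self.t_prev = 0.0

    def upper_crossing(self, t: float, z_bound: float) -> float:
        """P(first crossing above ``z_bound`` at information ``t``)."""
        s_bound = z_bound * np.sqrt(t)
        dt = t - self.t_prev
        mu = self.drift * dt
        sd = np.sqrt(dt)
        if self.x is None:
            return float(norm.sf((s_bound - mu) / sd))
        tail = norm.sf((s_bound - self.x - mu) / sd)
        return float(np.sum(self.w * self.dens * tail))

    def lower_crossing(self, t: float, z_bound: float) -> float:
        s_bound = z_bound * np.sqrt(t)
        dt = t - self.t_prev
        mu = self.drift * dt
        sd = np.sqrt(dt)
        if self.x is None:
            return float(norm.cdf((s_bound - mu) / sd))
        tail = norm.cdf((s_bound - self.x - mu) / sd)
        return float(np.sum(self.w * self.dens * tail))

    def step(self, t: float, z_lower: float, z_upper: float) -> None:
        """Advance to look at ``t`` with continuation region (z_lower, z_upper)."""
        lo = z_lower * np.sqrt(t)
        hi = z_upper * np.sqrt(t)
        if hi <= lo:
            raise ValueError("empty continuation region")
        x_new = np.linspace(lo, hi, self.n_grid)
        h = x_new[1] - x_new[0]
        dt = t - self.t_prev
        mu = self.drift * dt
        sd = np.sqrt(dt)
        if self.x is None:
            dens_new = norm.pdf(x_new, loc=mu, scale=sd)
        else:
            kernel = norm.pdf((x_new[:, None] - self.x[None, :] - mu) / sd) / sd
            dens_new = kernel @ (self.w * self.dens)
        self.x = x_new
        self.dens = dens_new
        self.w = _simpson_weights(self.n_grid, h)
        self.t_prev = t


def _solve_boundaries(
    fractions: Sequence[float],
    alpha_inc: np.ndarray,
    beta_inc: np.ndarray,
    drift: float,
    binding: bool,
    n_grid: int,
    stop_on_infeasible: bool,
):
    """Look-by-look boundary solve; returns (eff_z, fut_z, final_gap).

    ``final_gap`` is ``eff_z[-1] - fut_z[-1]`` (zero when the drift
    attains the design power exactly).  If an interim continuation
    region closes and ``stop_on_infeasible`` is False the negative gap
    at that look is returned for use by the drift root-finder.
    """
    rec_h0 = _Recursion(0.0, n_grid)
    rec_h1 = _Recursion(drift, n_grid)
    eff_z: list[float] = []
    fut_z: list[float] = []
    n_looks = len(fractions)
    for k, t in enumerate(fractions):
        e_k = float(alpha_inc[k])
        f_k = float(beta_inc[k])

        def eff_gap(z: float) -> float:
            return rec_h0.upper_crossing(t, z) - e_k

        def fut_gap(z: float) -> float:
            return rec_h1.lower_crossing(t, z) - f_k

        # If the mass still in play is below the requested increment the
        # continuation region has effectively closed (can happen while the
        # drift root-finder probes extreme drifts).
        if eff_gap(-_Z_RANGE) <= 0.0 or fut_gap(_Z_RANGE) <= 0.0:
            if stop_on_infeasible:
                raise ValueError(
                    f"infeasible design: continuation region closed before "
                    f"look {k + 1}"
                )
            return eff_z, fut_z, -1.0
        u_k = brentq(eff_gap, -_Z_RANGE, _Z_RANGE, xtol=1e-10, rtol=1e-14)
        l_k = brentq(fut_gap, -_Z_RANGE, _Z_RANGE, xtol=1e-10, rtol=1e-14)

        eff_z.append(float(u_k))
        fut_z.append(float(l_k))
        if k == n_looks - 1:
            return eff_z, fut_z, float(u_k - l_k)
        if l_k >= u_k:
            if stop_on_infeasible:
                raise ValueError(
                    f"infeasible design: futility boundary {l_k:.4f} is not "
                    f"below efficacy boundary {u_k:.4f} at interim look {k + 1}"
                )
            return eff_z, fut_z, float(u_k - l_k)
        lower = l_k if binding else -_Z_RANGE
        rec_h0.step(t, lower, u_k)
        rec_h1.step(t, l_k, u_k)
    raise AssertionError("unreachable")


@lru_cache(maxsize=256)
def _solve_power_drift_cached(
    fractions: tuple,
    alpha: float,
    rho_eff: float,
    beta: float,
    rho_fut: float,
    binding: bool,
    n_grid: int,
) -> float:
    alpha_inc = incremental_spend(fractions, SpendingSpec(alpha, rho_eff))
    beta_inc = incremental_spend(fractions, SpendingSpec(beta, rho_fut))

    def gap(drift: float) -> float:
        _, _, g = _solve_boundaries(
            fractions, alpha_inc, beta_inc, drift, binding, n_grid, False
        )
        return g

    # small drift -> futility bounds far below efficacy (positive gap);
    # large drift -> region closes (negative gap)
    lo, hi = 0.1, 8.0
    return float(brentq(gap, lo, hi, xtol=1e-10, rtol=1e-14))


def solve_power_drift(
    schedule: LookSchedule,
    alpha_spec: SpendingSpec,
    beta_spec: SpendingSpec,
    binding: bool = False,
    n_grid: int = _GRID_POINTS,
) -> float:
    """Drift (expected z at full information) attaining power 1 - beta.

    Solves for the drift at which the final-look futility boundary from
    beta-spending meets the final-look efficacy boundary from
    alpha-spending, i.e. the design alternative for which the trial has
    exactly the target power.
    """
    if alpha_spec.total_error + beta_spec.total_error >= 1.0:
        raise ValueError("alpha + beta must be below 1")
    return _solve_power_drift_cached(
        schedule.fractions,
        alpha_spec.total_error,
        alpha_spec.exponent,
        beta_spec.total_error,
        beta_spec.exponent,
        binding,
        n_grid,
    )


def compute_boundaries(
    schedule: LookSchedule,
    alpha_spec: SpendingSpec,
    beta_spec: SpendingSpec,
    drift: float | None = None,
    binding: bool = False,
    n_grid: int = _GRID_POINTS,
) -> GSBoundaries:
    """Efficacy and futility boundaries for a spending design.

    If ``drift`` is omitted it is solved so the design attains power
    ``1 - beta_spec.total_error`` (the usual case).  At the final look
    the futility boundary is set equal to the efficacy boundary; with
    the solved drift the two agree anyway (to root-finder tolerance).
    """
    if drift is None:
        drift = solve_power_drift(schedule, alpha_spec, beta_spec, binding, n_grid)
    if drift < 0:
        raise ValueError("drift must be non-negative")
    alpha_inc = incremental_spend(schedule.fractions, alpha_spec)
    beta_inc = incremental_spend(schedule.fractions, beta_spec)
    eff_z, fut_z, _ = _solve_boundaries(
        schedule.fractions, alpha_inc, beta_inc, drift, binding, n_grid, True
    )
    fut_z[-1] = eff_z[-1]  # no continuation region at the final look
    return GSBoundaries(
        schedule=schedule,
        efficacy_z=tuple(eff_z),
        futility_z=tuple(fut_z),
        drift=float(drift),
        alpha_spec=alpha_spec,
        beta_spec=beta_spec,
        binding=binding,
    )


def crossing_probabilities(
    boundaries: GSBoundaries,
    drift: float,
    n_grid: int = _GRID_POINTS,
) -> CrossingProbabilities:
    """Per-look efficacy/futility stopping probabilities under ``drift``.

    The futility boundary is honored at every interim (binding
    evaluation), matching how the boundaries were constructed; the final
    look splits all remaining probability between the two decisions.
    """
    fractions = boundaries.schedule.fractions
    rec = _Recursion(drift, n_grid)
    eff: list[float] = []
    fut: list[float] = []
    n_looks = len(fractions)
    for k, t in enumerate(fractions):
        u = boundaries.efficacy_z[k]
        l = boundaries.futility_z[k]
        p_eff = rec.upper_crossing(t, u)
        if k == n_looks - 1:
            p_fut = max(0.0, (1.0 - sum(eff) - sum(fut)) - p_eff)
        else:
            p_fut = rec.lower_crossing(t, l)
        eff.append(p_eff)
        fut.append(p_fut)
        if k < n_looks - 1:
            rec.step(t, l, u)
    return CrossingProbabilities(efficacy=tuple(eff), futility=tuple(fut))
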