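"""Sample sizes for two-arm binomial comparisons, fixed and group-sequential.

The comparison is a one-sided two-proportion z-test with unpooled
variance.  Writing ``q = 1 - p`` and allocation ratio ``r = n2 / n1``
(control : treatment = 1 : r), the statistical information carried by
``(n1, n2)`` is

    I(n1, n2) = 1 / (p0*q0/n1 + p1*q1/n2),

and the expected z-statistic at full information (the drift) is
``|p1 - p0| * sqrt(I)``.  The fixed-sample solver inverts the usual
closed form; the group-sequential solver asks the boundary module for
the drift at which the spending design attains its target power, turns
that drift into a maximum information, converts information to per-arm
sizes at the allocation ratio, and rounds up.

For mortality endpoints (benefit = a *decrease* in the event rate) the
design is mapped to the canonical increasing-effect scale internally;
sample sizes are unchanged because the unpooled variance is symmetric
under complementing both rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from .boundaries import (
    GSBoundaries,
    LookSchedule,
    compute_boundaries,
    crossing_probabilities,
    solve_power_drift,
)
from .spending import SpendingSpec

__all__ = [
    "DesignInput",
    "SampleSizeResult",
    "fixed_sample_size",
    "group_sequential_sample_size",
    "inflate_for_dropout",
]

_CEIL_FUZZ = 1e-9  # guards ceil() against float noise at integer solutions


@dataclass(frozen=True)
class DesignInput:
    """Full parameterization of one two-arm binomial design.

    ``allocation`` is (control, treatment), e.g. (1, 2) enrolls two
    treatment patients per control.  ``direction`` states whether a
    larger treatment-arm probability is the benefit ("increase", e.g.
    discharge by day 15) or a smaller one ("decrease", e.g. 30-day
    mortality).
    """

    p0: float
    p1: float
    alpha: float = 0.05
    power: float = 0.90
    allocation: tuple = (1, 1)
    schedule: LookSchedule | None = None
    rho_eff: float = 3.0
    rho_fut: float = 3.0
    direction: Literal["increase", "decrease"] = "increase"
    binding: bool = False

    def __post_init__(self) -> None:
        for name in ("p0", "p1"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {p}")
        if self.p0 == self.p1:
            raise ValueError("p0 and p1 must differ (zero effect size)")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")
        if not 0.5 < self.power < 1.0:
            raise ValueError("power must be in (0.5, 1)")
        if len(self.allocation) != 2 or min(self.allocation) <= 0:
            raise ValueError("allocation must be a positive (control, treatment) pair")
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")

    @property
    def ratio(self) -> float:
        """Treatment-per-control allocation ratio r = n2/n1."""
        return self.allocation[1] / self.allocation[0]

    @property
    def delta(self) -> float:
        return abs(self.p1 - self.p0)

    @property
    def unit_variance(self) -> float:
        """Variance of the difference at one control patient: p0q0 + p1q1/r."""
        return self.p0 * (1 - self.p0) + self.p1 * (1 - self.p1) / self.ratio

    def alpha_spec(self) -> SpendingSpec:
        return SpendingSpec(self.alpha, self.rho_eff)

    def beta_spec(self) -> SpendingSpec:
        return SpendingSpec(1.0 - self.power, self.rho_fut)


@dataclass(frozen=True)
class SampleSizeResult:
    """Per-arm sizes, look-wise enrollment and attained power."""

    n1: int
    n2: int
    per_look_enrollment: tuple  # ((n1_k, n2_k) cumulative at each look)
    attained_power: float
    design: DesignInput
    boundaries: GSBoundaries | None = None
    inflation_fraction: float = 0.0

    @property
    def total(self) -> int:
        return self.n1 + self.n2


def _ceil(x: float) -> int:
    return int(math.ceil(x - _CEIL_FUZZ))


def _per_look(design: DesignInput, n1: int, n2: int) -> tuple:
    if design.schedule is None:
        return ((n1, n2),)
    return tuple(
        (_ceil(f * n1), _ceil(f * n2)) for f in design.schedule.fractions
    )


def fixed_sample_size(design: DesignInput) -> SampleSizeResult:
    """Smallest per-arm sizes meeting power with a single analysis.

    Solves ``(z_alpha + z_power)^2 * unit_variance / n1 <= delta^2`` and
    takes the per-arm ceiling (``n2 = r * n1``).  Any look schedule on
    the design is ignored.
    """
    from scipy.stats import norm

    z = norm.isf(design.alpha) + norm.isf(1.0 - design.power)
    n1_cont = z**2 * design.unit_variance / design.delta**2
    n1 = _ceil(n1_cont)
    n2 = _ceil(design.ratio * n1)
    fixed = replace(design, schedule=None)
    drift = design.delta * math.sqrt(_information(design, n1, n2))
    power = float(norm.sf(norm.isf(design.alpha) - drift))
    return SampleSizeResult(
        n1=n1,
        n2=n2,
        per_look_enrollment=((n1, n2),),
        attained_power=power,
        design=fixed,
    )


def _information(design: DesignInput, n1: float, n2: float) -> float:
    return 1.0 / (
        design.p0 * (1 - design.p0) / n1 + design.p1 * (1 - design.p1) / n2
    )


def group_sequential_sample_size(design: DesignInput) -> SampleSizeResult:
    """Per-arm sizes for a spending design with interim looks.

    The maximum information comes from the drift solved by the boundary
    recursion (``I_max = (drift / delta)^2``); per-arm sizes are the
    ceiling of the continuous solution at the allocation ratio, and
    look-wise cumulative enrollment is the ceiling of the schedule
    fraction of each arm.  ``attained_power`` re-evaluates the crossing
    probabilities at the integer sizes.
    """
    if design.schedule is None:
        raise ValueError("design has no look schedule; use fixed_sample_size")
    a_spec, b_spec = design.alpha_spec(), design.beta_spec()
    drift_star = solve_power_drift(
        design.schedule, a_spec, b_spec, binding=design.binding
    )
    i_max = (drift_star / design.delta) ** 2
    n1_cont = i_max * design.unit_variance
    n1 = _ceil(n1_cont)
    n2 = _ceil(design.ratio * n1)  # keeps n2 = ratio * n1 at integer ratios
    boundaries = compute_boundaries(
        design.schedule, a_spec, b_spec, drift=drift_star, binding=design.binding
    )
    drift_n = design.delta * math.sqrt(_information(design, n1, n2))
    power = crossing_probabilities(boundaries, drift_n).total_efficacy
    return SampleSizeResult(
        n1=n1,
        n2=n2,
        per_look_enrollment=_per_look(design, n1, n2),
        attained_power=float(power),
        design=design,
        boundaries=boundaries,
    )


def inflate_for_dropout(
    result: SampleSizeResult, fraction: float = 0.05
) -> SampleSizeResult:
    """Inflate the total by ``(1 + fraction)``, preserving the arm ratio.

    The inflated total is the ceiling of ``total * (1 + fraction)``; the
    treatment arm gets the ceiling of its ratio share and the control
    arm the remainder, so e.g. a 243-patient 1:2 design at 5% becomes
    256 = 85 + 171.
    """
    if fraction < 0:
        raise ValueError("dropout fraction must be >= 0")
    if fraction == 0:
        return result
    total_new = _ceil(result.total * (1.0 + fraction))
    r = result.design.ratio
    n2_new = _ceil(total_new * r / (1.0 + r))
    n1_new = total_new - n2_new
    return SampleSizeResult(
        n1=n1_new,
        n2=n2_new,
        per_look_enrollment=_per_look(result.design, n1_new, n2_new),
        attained_power=result.attained_power,
        design=result.design,
        boundaries=result.boundaries,
        inflation_fraction=fraction,
    )
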