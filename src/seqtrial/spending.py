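"""Power-family (Kim-DeMets) error-spending functions.

A spending function allocates a total one-sided error probability (a
type-I error alpha, or a type-II error beta for futility) across the
interim looks of a group-sequential trial as a non-decreasing function of
the information fraction ``t``.  The power family spends

    f(t) = total_error * t ** rho,      0 <= t <= 1,

so ``rho`` controls how conservative early looks are: larger exponents
push almost all the error to the end of the trial.  ``rho = 1`` is the
linear (Pocock-like) spender; ``rho = 3`` concentrates spending late and
is the default used by the trial designs in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["SpendingSpec", "cumulative_spend", "incremental_spend"]


@dataclass(frozen=True)
class SpendingSpec:
    """Total one-sided error and power-family exponent.

    Parameters
    ----------
    total_error:
        The total probability to be spent over the whole trial
        (e.g. 0.05 for efficacy, 0.10 for futility at 90% power).
        Must lie strictly inside (0, 1).
    exponent:
        The power-family exponent rho (> 0).
    """

    total_error: float
    exponent: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.total_error < 1.0:
            raise ValueError(
                f"total_error must be in (0, 1), got {self.total_error}"
            )
        if self.exponent <= 0.0:
            raise ValueError(f"exponent must be > 0, got {self.exponent}")


def cumulative_spend(t, spec: SpendingSpec):
    """Cumulative error spent by information fraction ``t``.

    Accepts a scalar or array-like ``t`` in [0, 1] and returns
    ``total_error * t**exponent`` with matching shape.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0) or np.any(t_arr > 1.0):
        raise ValueError("information fraction must lie in [0, 1]")
    out = spec.total_error * t_arr**spec.exponent
    return out.item() if np.isscalar(t) or t_arr.ndim == 0 else out


def incremental_spend(schedule: Sequence[float], spec: SpendingSpec) -> np.ndarray:
    """Per-look spending increments over an ordered look schedule.

    ``schedule`` must be strictly increasing with final element 1; the
    returned non-negative increments sum to ``spec.total_error``.
    """
    sched = np.asarray(schedule, dtype=float)
    if sched.ndim != 1 or sched.size == 0:
        raise ValueError("schedule must be a non-empty 1-d sequence")
    if np.any(np.diff(sched) <= 0.0):
        raise ValueError("schedule must be strictly increasing")
    if not np.isclose(sched[-1], 1.0):
        raise ValueError("last information fraction must be 1")
    cum = cumulative_spend(sched, spec)
    return np.diff(np.concatenate(([0.0], np.atleast_1d(cum))))
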