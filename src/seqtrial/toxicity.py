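"""Continuous sequential toxicity monitoring for a single treatment arm.

The monitor watches the cumulative count of pre-adjudicated toxicity
events (binary flags, e.g. CTCAE grade > 2 judged related to the drug)
after every evaluated treatment-arm patient and stops the trial when the
count reaches a stopping boundary ``b(n)``, a non-decreasing step
function of the number of subjects observed.

The package ships a reference boundary for a monitored toxicity
probability of 25% at stated level 0.01 (loaded by
:func:`load_reference_boundary`); it stops, for instance, at 2 toxic
events among the first 5 subjects.  :func:`construct_boundary` builds
boundaries from first principles for other parameterizations, and
:func:`boundary_crossing_probability` is an exact dynamic-programming
evaluation of the probability that i.i.d. Bernoulli toxicities ever
reach a given boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np
from scipy.stats import binom

__all__ = [
    "ToxicityBoundary",
    "ToxicityDecision",
    "load_reference_boundary",
    "monitor_toxicity",
    "construct_boundary",
    "boundary_crossing_probability",
]


@dataclass(frozen=True)
class ToxicityBoundary:
    """Step-function stopping boundary for cumulative toxicity counts.

    ``change_points`` is an ordered tuple of ``(n, b)`` pairs: from ``n``
    subjects onward (until the next change point) the trial stops when
    the toxicity count reaches ``b``.  Below the first change point no
    stopping is possible.
    """

    change_points: tuple
    p_tox: float
    alpha_tox: float
    rule: str = "fixture"

    def __post_init__(self) -> None:
        ns = [n for n, _ in self.change_points]
        bs = [b for _, b in self.change_points]
        if not ns:
            raise ValueError("boundary needs at least one change point")
        if any(n2 <= n1 for n1, n2 in zip(ns, ns[1:])):
            raise ValueError("change-point n values must be strictly increasing")
        if any(b2 < b1 for b1, b2 in zip(bs, bs[1:])):
            raise ValueError("stop counts must be non-decreasing")
        if any(b > n for n, b in self.change_points):
            raise ValueError("stop count may not exceed subjects observed")

    @property
    def n_max(self) -> int:
        return self.change_points[-1][0]

    def value_at(self, n_observed: int) -> int | None:
        """Stop count at ``n_observed``; None if no stopping is possible yet."""
        if n_observed > self.n_max:
            raise ValueError(
                f"n_observed={n_observed} exceeds monitored maximum {self.n_max}"
            )
        b = None
        for n, bound in self.change_points:
            if n <= n_observed:
                b = bound
            else:
                break
        return b

    def as_array(self) -> np.ndarray:
        """Boundary per n = 1..n_max; entries with no stopping hold n+1."""
        unreachable = np.arange(2, self.n_max + 2)  # value n+1 at index n-1
        step = np.zeros(self.n_max, dtype=np.int64)
        for n, bound in self.change_points:
            step[n - 1 :] = bound
        return np.where(step > 0, step, unreachable)


@dataclass(frozen=True)
class ToxicityDecision:
    decision: Literal["stop", "continue"]
    n_observed: int
    n_toxic: int
    boundary_value: int | None

    @property
    def stop(self) -> bool:
        return self.decision == "stop"


def load_reference_boundary() -> ToxicityBoundary:
    """Packaged abbreviated boundary for p_tox = 0.25 at stated level 0.01."""
    path = resources.files("seqtrial.data") / "toxicity_boundary_p25.csv"
    with path.open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    points = tuple((int(n), int(b)) for n, b in rows[1:])
    return ToxicityBoundary(points, p_tox=0.25, alpha_tox=0.01, rule="fixture")


def monitor_toxicity(
    n_observed: int, n_toxic: int, boundary: ToxicityBoundary
) -> ToxicityDecision:
    """Stop/continue decision after ``n_observed`` evaluated subjects."""
    if n_toxic < 0 or n_observed < 0:
        raise ValueError("counts must be non-negative")
    if n_toxic > n_observed:
        raise ValueError(
            f"n_toxic={n_toxic} cannot exceed n_observed={n_observed}"
        )
    b = boundary.value_at(n_observed)  # raises beyond n_max
    stop = b is not None and n_toxic >= b
    return ToxicityDecision(
        decision="stop" if stop else "continue",
        n_observed=n_observed,
        n_toxic=n_toxic,
        boundary_value=b,
    )


def _pointwise_boundary(p_tox: float, level: float, n_max: int) -> np.ndarray:
    """b(n) = smallest k with P(Bin(n, p_tox) >= k) <= level, per n."""
    ns = np.arange(1, n_max + 1)
    b = np.empty(n_max, dtype=np.int64)
    for i, n in enumerate(ns):
        ks = np.arange(0, n + 2)
        tails = binom.sf(ks - 1, n, p_tox)  # P(X >= k)
        ok = np.nonzero(tails <= level)[0]
        b[i] = ks[ok[0]] if ok.size else n + 1
    return np.maximum.accumulate(b)  # enforce monotone non-decreasing


def _pocock_boundary(p_tox: float, alpha_tox: float, n_max: int) -> np.ndarray:
    """Constant-nominal-level boundary calibrated to an overall level.

    The attainable per-test levels form the discrete set of binomial
    upper-tail probabilities, over which the overall crossing
    probability is monotone; binary search picks the largest attainable
    level whose exact overall crossing probability under ``p_tox`` does
    not exceed ``alpha_tox`` (conservative side of the discreteness).
    """
    tails = set()
    for n in range(1, n_max + 1):
        ks = np.arange(1, n + 1)
        tails.update(np.round(binom.sf(ks - 1, n, p_tox), 15).tolist())
    candidates = np.array(sorted(t for t in tails if t > 0.0))

    def crossing(level: float) -> float:
        arr = _pointwise_boundary(p_tox, level, n_max)
        points = _array_to_change_points(arr)
        if not points:
            return 0.0
        bnd = ToxicityBoundary(points, p_tox, alpha_tox, rule="pocock")
        return boundary_crossing_probability(bnd, p_tox)

    lo, hi = 0, len(candidates) - 1
    if crossing(candidates[lo]) > alpha_tox:
        raise ValueError(
            "no attainable stopping boundary below n_max at this level"
        )
    best = lo
    while lo <= hi:
        mid = (lo + hi) // 2
        if crossing(candidates[mid]) <= alpha_tox:
            best = mid
            lo = mid + 1
        else:
            hi = mid - 1
    return _pointwise_boundary(p_tox, candidates[best], n_max)


def _array_to_change_points(b: np.ndarray) -> tuple:
    points = []
    prev = None
    for n, bound in enumerate(b, start=1):
        if bound > n:  # unreachable: no stopping at this n
            continue
        if prev is None or bound != prev:
            points.append((n, int(bound)))
            prev = int(bound)
    return tuple(points)


def construct_boundary(
    p_tox: float,
    alpha_tox: float,
    n_max: int,
    rule: Literal["pointwise", "pocock"] = "pointwise",
) -> ToxicityBoundary:
    """Build a stopping boundary from first principles.

    ``pointwise``: stop when the exact binomial upper-tail probability
    ``P(X >= k | n, p_tox)`` drops to ``alpha_tox`` or below, test by
    test (no multiplicity adjustment across looks).

    ``pocock``: a constant per-test nominal level is calibrated by
    bisection so that the *overall* probability (under Bernoulli
    ``p_tox`` toxicity) of ever crossing by ``n_max`` equals
    ``alpha_tox``; the exact crossing probability comes from
    :func:`boundary_crossing_probability`.
    """
    if not 0.0 < p_tox < 1.0:
        raise ValueError("p_tox must be in (0, 1)")
    if not 0.0 < alpha_tox < 1.0:
        raise ValueError("alpha_tox must be in (0, 1)")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if rule == "pointwise":
        arr = _pointwise_boundary(p_tox, alpha_tox, n_max)
    elif rule == "pocock":
        arr = _pocock_boundary(p_tox, alpha_tox, n_max)
    else:
        raise ValueError(
            f"unknown rule {rule!r}; supported: 'pointwise', 'pocock'"
        )
    points = _array_to_change_points(arr)
    if not points:
        # level so small that no count up to n_max can ever stop
        raise ValueError(
            "no attainable stopping boundary below n_max at this level"
        )
    return ToxicityBoundary(points, p_tox, alpha_tox, rule=rule)


def boundary_crossing_probability(
    boundary: ToxicityBoundary, p: float
) -> float:
    """Exact P(toxicity count ever reaches the boundary by n_max).

    Dynamic programming over (subjects observed, current count) states of
    paths that have not yet stopped; toxicities are i.i.d. Bernoulli(p).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    b = boundary.as_array()
    n_max = boundary.n_max
    alive = np.zeros(n_max + 2)
    alive[0] = 1.0
    stopped = 0.0
    for n in range(1, n_max + 1):
        new = np.zeros_like(alive)
        new[1:] = alive[:-1] * p
        new[:-1] += alive[:-1] * (1 - p)
        bound = b[n - 1]
        if bound <= n:
            stopped += new[bound:].sum()
            new[bound:] = 0.0
        alive = new
    return float(stopped)
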