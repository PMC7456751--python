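"""Interim and final efficacy testing for stratified two-arm binary data.

The test statistic is a one-sided z for the difference in response
proportions, oriented so that treatment benefit is positive: for a
response endpoint (benefit = higher rate) ``z`` is positive when the
treatment arm responds more; for a mortality endpoint (benefit = lower
rate) the sign is flipped.  Variances are unpooled.

With stratified randomization the statistic is formed within each
stratum and pooled.  The default pooling is inverse-variance weighting
of the per-stratum risk differences; a Cochran-Mantel-Haenszel-style
count pooling is available as an alternative.  Strata too sparse to
contribute a variance at an interim can be merged into a neighbor by
canonical index order before testing.

Look-wise decisions compare the observed one-sided p-value with the
nominal boundary p-values of a :class:`~seqtrial.boundaries.GSBoundaries`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm

from .boundaries import GSBoundaries

__all__ = [
    "StratumCounts",
    "TestResult",
    "unstratified_z",
    "stratified_z",
    "merge_sparse_strata",
    "decide_at_look",
]


@dataclass(frozen=True)
class StratumCounts:
    """Per-stratum 2x2 summaries: arrays aligned by stratum.

    ``n1/x1`` are control-arm sizes and successes, ``n2/x2`` treatment.
    """

    n1: np.ndarray
    x1: np.ndarray
    n2: np.ndarray
    x2: np.ndarray

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=np.int64) for a in (self.n1, self.x1, self.n2, self.x2)]
        n1, x1, n2, x2 = arrays
        if not (n1.shape == x1.shape == n2.shape == x2.shape):
            raise ValueError("count arrays must share one shape")
        if np.any(x1 > n1) or np.any(x2 > n2):
            raise ValueError("successes cannot exceed arm sizes")
        if min(a.min(initial=0) for a in arrays) < 0:
            raise ValueError("counts must be non-negative")
        for name, arr in zip(("n1", "x1", "n2", "x2"), arrays):
            object.__setattr__(self, name, arr)

    @property
    def n_strata(self) -> int:
        return int(np.atleast_1d(self.n1).size)

    @classmethod
    def single(cls, n1: int, x1: int, n2: int, x2: int) -> "StratumCounts":
        return cls(np.array([n1]), np.array([x1]), np.array([n2]), np.array([x2]))


@dataclass(frozen=True)
class TestResult:
    z: float
    p_one_sided: float
    estimate: float  # pooled treatment-minus-control difference, benefit-oriented
    per_stratum_z: tuple = ()
    weights: tuple = ()


def _direction_sign(direction: str) -> float:
    if direction == "increase":
        return 1.0
    if direction == "decrease":
        return -1.0
    raise ValueError("direction must be 'increase' or 'decrease'")


def unstratified_z(
    counts: StratumCounts, direction: Literal["increase", "decrease"] = "increase"
) -> TestResult:
    """One-sided unpooled-variance z for a single 2x2 table."""
    if counts.n_strata != 1:
        raise ValueError("unstratified_z expects a single stratum")
    return stratified_z(counts, direction=direction)


def _variance(p1, n1, p2, n2):
    """Unpooled variance of the risk difference."""
    return p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2


def stratified_z(
    counts: StratumCounts,
    weighting: Literal["inverse_variance", "null_variance", "cmh"] = "inverse_variance",
    direction: Literal["increase", "decrease"] = "increase",
) -> TestResult:
    """Pooled one-sided z across strata.

    ``inverse_variance`` weights each stratum's risk difference by the
    reciprocal of its unpooled variance; variances use the shrunk
    proportions ``(x + 0.5)/(n + 1)`` whenever an arm is degenerate
    (all successes or all failures), which keeps every populated
    stratum informative.  With one stratum this reduces exactly to the
    ordinary unpooled two-proportion z.

    ``null_variance`` estimates each stratum's variance at the pooled
    within-stratum proportion, ``p_bar*(1-p_bar)*(1/n1 + 1/n2)``.
    Because the pooled proportion is nearly uncorrelated with the risk
    difference, this weighting stays calibrated when strata are thin
    (a handful of patients per arm at an interim), where unpooled
    weights are anti-conservative; it is the scheme the trial
    simulator uses.

    ``cmh`` pools counts against the hypergeometric null variance
    (Cochran-Mantel-Haenszel).
    """
    sign = _direction_sign(direction)
    n1 = np.atleast_1d(counts.n1).astype(float)
    x1 = np.atleast_1d(counts.x1).astype(float)
    n2 = np.atleast_1d(counts.n2).astype(float)
    x2 = np.atleast_1d(counts.x2).astype(float)
    ok = (n1 >= 1) & (n2 >= 1)
    if not np.any(ok):
        raise ValueError("no stratum has patients in both arms")
    n1, x1, n2, x2 = n1[ok], x1[ok], n2[ok], x2[ok]

    p1, p2 = x1 / n1, x2 / n2
    diff = p2 - p1

    if weighting in ("inverse_variance", "null_variance"):
        if weighting == "inverse_variance":
            var = _variance(p1, n1, p2, n2)
        else:
            pbar = (x1 + x2) / (n1 + n2)
            var = pbar * (1 - pbar) * (1.0 / n1 + 1.0 / n2)
        degenerate = var <= 0.0
        if np.all(degenerate):
            warnings.warn("zero variance in every stratum; z defined by "
                          "shrunk-proportion variances")
        if np.any(degenerate):
            # shrink proportions (x+0.5)/(n+1) for the variance only, so
            # degenerate arms (0% or 100%) stay informative
            if weighting == "inverse_variance":
                p1s = (x1 + 0.5) / (n1 + 1.0)
                p2s = (x2 + 0.5) / (n2 + 1.0)
                var_s = _variance(p1s, n1, p2s, n2)
            else:
                pbs = (x1 + x2 + 0.5) / (n1 + n2 + 1.0)
                var_s = pbs * (1 - pbs) * (1.0 / n1 + 1.0 / n2)
            var = np.where(degenerate, var_s, var)
        w = 1.0 / var
        est = float(np.sum(w * diff) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
        z = sign * est / se
        per_z = sign * diff / np.sqrt(var)
        weights = w / np.sum(w)
    elif weighting == "cmh":
        n = n1 + n2
        x = x1 + x2
        expected = n2 * x / n
        null_var = n1 * n2 * x * (n - x) / (n**2 * (n - 1.0).clip(min=1.0))
        total_var = float(np.sum(null_var))
        if total_var <= 0.0:
            warnings.warn("zero variance in every cell; z defined as 0")
            z = 0.0
        else:
            z = sign * float(np.sum(x2 - expected)) / np.sqrt(total_var)
        est = sign * float(np.sum((x2 - expected)) / np.sum(n1 * n2 / n))
        per_z = np.where(null_var > 0, sign * (x2 - expected) / np.sqrt(null_var.clip(min=1e-300)), 0.0)
        weights = null_var / max(total_var, 1e-300)
        z = float(z)
        return TestResult(
            z=z,
            p_one_sided=float(norm.sf(z)),
            estimate=est,
            per_stratum_z=tuple(per_z.tolist()),
            weights=tuple(weights.tolist()),
        )
    else:
        raise ValueError(
            "weighting must be 'inverse_variance', 'null_variance' or 'cmh'"
        )

    if not np.isfinite(z):
        warnings.warn("zero variance in every cell; z defined as 0")
        z = 0.0
        per_z = np.zeros_like(diff)
    return TestResult(
        z=float(z),
        p_one_sided=float(norm.sf(z)),
        estimate=float(sign * est),
        per_stratum_z=tuple(np.atleast_1d(per_z).tolist()),
        weights=tuple(np.atleast_1d(weights).tolist()),
    )


def merge_sparse_strata(counts: StratumCounts, min_per_arm: int = 2) -> StratumCounts:
    """Merge strata with fewer than ``min_per_arm`` patients in either arm.

    Sparse strata are folded into the nearest (by canonical index)
    adequately filled stratum; if none is adequate everything collapses
    into one stratum.  Used at interim looks where early enrollment
    leaves cells too thin to carry their own variance.
    """
    n1 = np.atleast_1d(counts.n1)
    x1 = np.atleast_1d(counts.x1)
    n2 = np.atleast_1d(counts.n2)
    x2 = np.atleast_1d(counts.x2)
    adequate = (n1 >= min_per_arm) & (n2 >= min_per_arm)
    if np.all(adequate):
        return counts
    if not np.any(adequate):
        return StratumCounts(
            np.array([n1.sum()]), np.array([x1.sum()]),
            np.array([n2.sum()]), np.array([x2.sum()]),
        )
    targets = np.nonzero(adequate)[0]
    dest = np.arange(n1.size)
    for i in np.nonzero(~adequate)[0]:
        dest[i] = targets[np.argmin(np.abs(targets - i))]
    m1 = np.bincount(dest, weights=n1, minlength=n1.size)[targets]
    mx1 = np.bincount(dest, weights=x1, minlength=n1.size)[targets]
    m2 = np.bincount(dest, weights=n2, minlength=n1.size)[targets]
    mx2 = np.bincount(dest, weights=x2, minlength=n1.size)[targets]
    return StratumCounts(
        m1.astype(np.int64), mx1.astype(np.int64),
        m2.astype(np.int64), mx2.astype(np.int64),
    )


def decide_at_look(
    result: TestResult, look: int, boundaries: GSBoundaries
) -> str:
    """Decision at ``look`` (0-based): compare p with the nominal bounds.

    Interim looks return 'stop-efficacy', 'stop-futility' or 'continue';
    the final look returns 'reject' or 'accept'.
    """
    k = look
    n_looks = boundaries.n_looks
    if not 0 <= k < n_looks:
        raise ValueError(f"look must be in 0..{n_looks - 1}")
    p = result.p_one_sided
    final = k == n_looks - 1
    if p < boundaries.efficacy_p[k]:
        return "reject" if final else "stop-efficacy"
    if final:
        return "accept"
    if p > boundaries.futility_p[k]:
        return "stop-futility"
    return "continue"
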