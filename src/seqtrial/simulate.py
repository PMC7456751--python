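"""Patient-level Monte-Carlo simulation of the group-sequential designs.

Each replicate enrolls a synthetic patient stream (stratum membership
drawn from a prevalence mix, binary outcomes drawn per arm, optional
independent Bernoulli toxicity flags on the treatment arm), randomizes
it with the stratified permuted-block scheme, monitors toxicity after
every evaluated treatment patient, evaluates the stratified z-statistic
at each look's cumulative enrollment and applies the boundary decision.
Aggregating replicates yields the design's operating characteristics --
empirical power or type-I error, stopping distribution over looks,
toxicity-stop rate and expected enrollment -- with Monte-Carlo standard
errors.

Outcomes are treated as available at evaluation time: the 15-day /
30-day windows define the endpoint, not the simulated timeline, so
operating characteristics do not depend on calendar time.  All
randomness descends from ``(seed, replicate, stratum)`` spawn keys, so a
configuration and seed fully determine the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .analysis import StratumCounts, decide_at_look, merge_sparse_strata, stratified_z
from .samplesize import SampleSizeResult
from .stratification import (
    N_HIGH_RISK_STRATA,
    N_INTERMEDIATE_STRATA,
    _block_stream,
)
from .toxicity import ToxicityBoundary

__all__ = [
    "SimulationConfig",
    "PatientStream",
    "TrialOutcome",
    "OperatingCharacteristics",
    "simulate_patients",
    "run_single_trial",
    "estimate_operating_characteristics",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Design plus ground truth for a simulation study.

    ``sample_size`` carries the design, boundaries and per-look
    enrollment.  ``p_control``/``p_treatment`` are the true event
    probabilities (scalars, or one value per stratum).  ``stratum_mix``
    is the enrollment prevalence over the risk group's strata (uniform
    by default).  ``toxicity_rate`` of None disables toxicity
    monitoring (the high-risk design).
    """

    sample_size: SampleSizeResult
    p_control: float | tuple
    p_treatment: float | tuple
    risk_group: Literal["intermediate", "high"] = "intermediate"
    stratum_mix: tuple | None = None
    toxicity_rate: float | None = None
    toxicity_boundary: ToxicityBoundary | None = None
    weighting: Literal["inverse_variance", "null_variance", "cmh"] = "null_variance"
    min_per_arm_for_stratum: int = 2
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for p in np.atleast_1d(self.p_control).tolist() + np.atleast_1d(
            self.p_treatment
        ).tolist():
            if not 0.0 <= p <= 1.0:
                raise ValueError("true rates must lie in [0, 1]")
        if self.toxicity_rate is not None and not 0.0 <= self.toxicity_rate <= 1.0:
            raise ValueError("toxicity_rate must lie in [0, 1]")
        if self.sample_size.boundaries is None:
            raise ValueError("sample_size must carry group-sequential boundaries")

    @property
    def n_strata(self) -> int:
        if self.stratum_mix is not None:
            return len(self.stratum_mix)
        return (
            N_INTERMEDIATE_STRATA
            if self.risk_group == "intermediate"
            else N_HIGH_RISK_STRATA
        )

    def mix(self) -> np.ndarray:
        if self.stratum_mix is None:
            return np.full(self.n_strata, 1.0 / self.n_strata)
        m = np.asarray(self.stratum_mix, dtype=float)
        if abs(m.sum() - 1.0) > 1e-9 or np.any(m < 0):
            raise ValueError("stratum_mix must be a probability vector")
        return m

    def rate(self, which: str) -> np.ndarray:
        p = self.p_control if which == "control" else self.p_treatment
        arr = np.broadcast_to(np.asarray(p, dtype=float), (self.n_strata,))
        return arr


@dataclass(frozen=True)
class PatientStream:
    """One replicate's synthetic patients, in enrollment order."""

    stratum: np.ndarray  # canonical stratum index per patient
    u_outcome: np.ndarray  # uniforms resolved against the assigned arm's rate
    u_toxicity: np.ndarray


@dataclass(frozen=True)
class TrialOutcome:
    stop_look: int  # 0-based look index, or -1 for a toxicity stop
    decision: str  # stop-efficacy | stop-futility | toxicity-stop | reject | accept
    n_enrolled: int
    z_at_looks: tuple

    @property
    def rejected(self) -> bool:
        return self.decision in ("stop-efficacy", "reject")


@dataclass(frozen=True)
class OperatingCharacteristics:
    n_reps: int
    efficacy_rejection_rate: float
    futility_stop_rate: float
    toxicity_stop_rate: float
    stop_distribution: tuple  # over looks (toxicity stops fold into their look)
    expected_n: float
    se_rejection: float
    se_futility: float
    se_toxicity: float
    se_expected_n: float
    seed: int = 0


def simulate_patients(config: SimulationConfig, rng: np.random.Generator) -> PatientStream:
    """Draw one enrollment-ordered synthetic patient stream."""
    n_total = config.sample_size.total
    strata = rng.choice(config.n_strata, size=n_total, p=config.mix())
    return PatientStream(
        stratum=strata,
        u_outcome=rng.random(n_total),
        u_toxicity=rng.random(n_total),
    )


def _randomize_stream(
    stream: PatientStream, ratio: tuple, rng_key: list
) -> np.ndarray:
    """Arm per patient (0 control / 1 treatment) via per-stratum blocks."""
    arms = np.empty(stream.stratum.size, dtype=np.int64)
    for s in np.unique(stream.stratum):
        idx = np.nonzero(stream.stratum == s)[0]
        rng = np.random.default_rng(rng_key + [int(s)])
        a, _, _ = _block_stream(rng, ratio, idx.size)
        arms[idx] = a
    return arms


def run_single_trial(
    config: SimulationConfig, rep_seed: int | list
) -> TrialOutcome:
    """Enroll, randomize, monitor and decide one simulated trial."""
    key = [rep_seed] if np.isscalar(rep_seed) else list(rep_seed)
    rng = np.random.default_rng(key)
    stream = simulate_patients(config, rng)
    design = config.sample_size.design
    allocation = tuple(int(a) for a in design.allocation)
    arms = _randomize_stream(stream, allocation, key + [10_007])

    p_ctl = config.rate("control")[stream.stratum]
    p_trt = config.rate("treatment")[stream.stratum]
    outcome = np.where(
        arms == 1, stream.u_outcome < p_trt, stream.u_outcome < p_ctl
    ).astype(np.int64)

    # continuous toxicity monitoring on evaluated treatment patients
    tox_stop_at = None  # overall enrollment position (1-based) of the stop
    if config.toxicity_rate is not None and config.toxicity_boundary is not None:
        trt_pos = np.nonzero(arms == 1)[0]
        tox = (stream.u_toxicity[trt_pos] < config.toxicity_rate).astype(np.int64)
        bnd = config.toxicity_boundary.as_array()
        m = min(trt_pos.size, bnd.size)
        crossed = np.nonzero(tox[:m].cumsum() >= bnd[:m])[0]
        if crossed.size:
            tox_stop_at = int(trt_pos[crossed[0]]) + 1

    boundaries = config.sample_size.boundaries
    look_totals = [n1k + n2k for n1k, n2k in config.sample_size.per_look_enrollment]
    n_strata = config.n_strata
    zs: list[float] = []
    for k, m_k in enumerate(look_totals):
        if tox_stop_at is not None and tox_stop_at <= m_k:
            return TrialOutcome(
                stop_look=k,
                decision="toxicity-stop",
                n_enrolled=tox_stop_at,
                z_at_looks=tuple(zs),
            )
        sl = slice(0, m_k)
        st = stream.stratum[sl]
        arm = arms[sl]
        out = outcome[sl]
        n1 = np.bincount(st[arm == 0], minlength=n_strata)
        x1 = np.bincount(st[arm == 0], weights=out[arm == 0], minlength=n_strata)
        n2 = np.bincount(st[arm == 1], minlength=n_strata)
        x2 = np.bincount(st[arm == 1], weights=out[arm == 1], minlength=n_strata)
        keep = (n1 + n2) > 0
        counts = StratumCounts(
            n1[keep], x1[keep].astype(np.int64), n2[keep], x2[keep].astype(np.int64)
        )
        counts = merge_sparse_strata(counts, config.min_per_arm_for_stratum)
        result = stratified_z(
            counts, weighting=config.weighting, direction=design.direction
        )
        zs.append(result.z)
        decision = decide_at_look(result, k, boundaries)
        if decision != "continue":
            return TrialOutcome(
                stop_look=k,
                decision=decision,
                n_enrolled=m_k,
                z_at_looks=tuple(zs),
            )
    raise AssertionError("final look must decide")


def estimate_operating_characteristics(
    config: SimulationConfig,
) -> OperatingCharacteristics:
    """Monte-Carlo operating characteristics over ``config.n_reps`` trials."""
    n_looks = len(config.sample_size.per_look_enrollment)
    reject = np.zeros(config.n_reps, dtype=bool)
    futility = np.zeros(config.n_reps, dtype=bool)
    toxicity = np.zeros(config.n_reps, dtype=bool)
    stop_look = np.zeros(config.n_reps, dtype=np.int64)
    enrolled = np.zeros(config.n_reps, dtype=np.int64)
    for rep in range(config.n_reps):
        res = run_single_trial(config, [config.seed, rep])
        reject[rep] = res.rejected
        futility[rep] = res.decision == "stop-futility"
        toxicity[rep] = res.decision == "toxicity-stop"
        stop_look[rep] = res.stop_look
        enrolled[rep] = res.n_enrolled
    n = config.n_reps

    def rate_se(x: np.ndarray) -> tuple:
        r = float(x.mean())
        return r, float(np.sqrt(r * (1.0 - r) / n))

    rr, se_r = rate_se(reject)
    fr, se_f = rate_se(futility)
    tr, se_t = rate_se(toxicity)
    dist = np.bincount(stop_look, minlength=n_looks) / n
    return OperatingCharacteristics(
        n_reps=n,
        efficacy_rejection_rate=rr,
        futility_stop_rate=fr,
        toxicity_stop_rate=tr,
        stop_distribution=tuple(dist.tolist()),
        expected_n=float(enrolled.mean()),
        se_rejection=se_r,
        se_futility=se_f,
        se_toxicity=se_t,
        se_expected_n=float(enrolled.std(ddof=1) / np.sqrt(n)),
        seed=config.seed,
    )
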