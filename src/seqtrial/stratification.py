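"""Risk-group classification, stratum assignment and blocked randomization.

Patients are staged on the WHO ordinal scale of clinical status
(1 = no limitation of activities ... 8 = death).  Stages 3-5
(hospitalized, up to non-invasive ventilation / high-flow oxygen) form
the intermediate-risk group; stages 6-7 (invasive ventilation, with or
without additional organ support) form the high-risk group.  Stages 1-2
are low risk and stage 8 is not randomizable.

Intermediate-risk strata cross four factors -- stage group (3-4 vs 5,
i.e. non-ICU vs ICU), age (< 60 vs >= 60), sex, and presence of at least
one cardiovascular risk factor (obesity, hypertension or diabetes) --
giving 16 strata.  High-risk strata drop the stage factor and use an
age cutoff of 65, giving 8 strata.  Stratum indices follow the fixed
canonical order (stage group, age, sex, cvd) with the level order shown
in the module constants, so assignments are reproducible.

Randomization is Zelen-style stratified permuted blocks with an
independent block stream per stratum: 1:1 allocation draws each block's
size uniformly from {4, 6}; 1:2 allocation uses fixed blocks of 6
(2 control + 4 treatment), since a 1:2 split does not fit a block of 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "PatientProfile",
    "StratumId",
    "Assignment",
    "classify_risk_group",
    "assign_stratum",
    "stratum_labels",
    "zelen_randomize",
    "N_INTERMEDIATE_STRATA",
    "N_HIGH_RISK_STRATA",
]

N_INTERMEDIATE_STRATA = 16
N_HIGH_RISK_STRATA = 8

_STAGE_LEVELS = ("3-4", "5")
_AGE_LEVELS = ("<cut", ">=cut")
_SEX_LEVELS = ("M", "F")
_CVD_LEVELS = ("no", "yes")

INTERMEDIATE_AGE_CUTOFF = 60
HIGH_RISK_AGE_CUTOFF = 65


@dataclass(frozen=True)
class PatientProfile:
    who_stage: int
    age: float
    sex: Literal["M", "F"]
    cvd_risk: bool

    def __post_init__(self) -> None:
        if self.who_stage not in range(1, 9):
            raise ValueError(f"who_stage must be 1..8, got {self.who_stage}")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")


@dataclass(frozen=True)
class StratumId:
    risk_group: str
    index: int
    factor_levels: tuple


@dataclass(frozen=True)
class Assignment:
    patient: int | str
    arm: Literal["control", "treatment"]
    stratum: StratumId
    block: int
    position: int
    seed: int


def classify_risk_group(who_stage: int) -> str:
    """Map a WHO stage to its trial risk group.

    Returns 'low' (stages 1-2), 'intermediate' (3-5), 'high' (6-7) or
    'dead' (stage 8, not randomizable).
    """
    if who_stage not in range(1, 9):
        raise ValueError(f"who_stage must be 1..8, got {who_stage}")
    if who_stage <= 2:
        return "low"
    if who_stage <= 5:
        return "intermediate"
    if who_stage <= 7:
        return "high"
    return "dead"


def assign_stratum(profile: PatientProfile) -> StratumId:
    """Stratum of an eligible (intermediate- or high-risk) patient.

    Intermediate: (stage 3-4 vs 5) x (age < 60 vs >= 60) x sex x cvd,
    16 cells.  High: (age < 65 vs >= 65) x sex x cvd, 8 cells; stage
    6 vs 7 is deliberately not a factor.  Index = canonical mixed-radix
    order over those factor tuples.
    """
    group = classify_risk_group(profile.who_stage)
    if group == "low":
        raise ValueError("low-risk patients (stages 1-2) are not eligible")
    if group == "dead":
        raise ValueError("stage 8 is not randomizable")
    sex_i = _SEX_LEVELS.index(profile.sex)
    cvd_i = int(profile.cvd_risk)
    if group == "intermediate":
        stage_i = 0 if profile.who_stage in (3, 4) else 1
        age_i = int(profile.age >= INTERMEDIATE_AGE_CUTOFF)
        index = ((stage_i * 2 + age_i) * 2 + sex_i) * 2 + cvd_i
        levels = (
            _STAGE_LEVELS[stage_i],
            f"age{_AGE_LEVELS[age_i].replace('cut', str(INTERMEDIATE_AGE_CUTOFF))}",
            _SEX_LEVELS[sex_i],
            f"cvd-{_CVD_LEVELS[cvd_i]}",
        )
    else:
        age_i = int(profile.age >= HIGH_RISK_AGE_CUTOFF)
        index = (age_i * 2 + sex_i) * 2 + cvd_i
        levels = (
            f"age{_AGE_LEVELS[age_i].replace('cut', str(HIGH_RISK_AGE_CUTOFF))}",
            _SEX_LEVELS[sex_i],
            f"cvd-{_CVD_LEVELS[cvd_i]}",
        )
    return StratumId(risk_group=group, index=index, factor_levels=levels)


def stratum_labels(risk_group: str) -> list:
    """Canonical factor-level tuples for all strata of a risk group."""
    if risk_group == "intermediate":
        return [
            (s, a, x, c)
            for s in _STAGE_LEVELS
            for a in ("age<60", "age>=60")
            for x in _SEX_LEVELS
            for c in ("cvd-no", "cvd-yes")
        ]
    if risk_group == "high":
        return [
            (a, x, c)
            for a in ("age<65", "age>=65")
            for x in _SEX_LEVELS
            for c in ("cvd-no", "cvd-yes")
        ]
    raise ValueError("risk_group must be 'intermediate' or 'high'")


def _block_stream(
    rng: np.random.Generator, ratio: tuple, n_needed: int
) -> tuple:
    """Arm labels and (block, position) bookkeeping for one stratum."""
    arms: list[int] = []  # 0 = control, 1 = treatment
    blocks: list[int] = []
    positions: list[int] = []
    a, b = ratio
    block_no = 0
    while len(arms) < n_needed:
        if ratio == (1, 1):
            size = int(rng.choice([4, 6]))
        else:  # (1, 2)
            size = 6
        per_unit = size // (a + b)
        block = np.array([0] * (a * per_unit) + [1] * (b * per_unit))
        rng.shuffle(block)
        arms.extend(block.tolist())
        blocks.extend([block_no] * size)
        positions.extend(range(size))
        block_no += 1
    return arms[:n_needed], blocks[:n_needed], positions[:n_needed]


def zelen_randomize(
    patients: Sequence[PatientProfile],
    ratio: tuple = (1, 1),
    seed: int = 0,
    ids: Sequence | None = None,
) -> list:
    """Randomize an enrollment-ordered patient list to control/treatment.

    All patients must belong to the same risk group.  Each stratum has
    its own permuted-block stream, seeded from ``(seed, stratum index)``
    so assignments are reproducible and independent of how patients are
    interleaved across strata.  Returns one :class:`Assignment` per
    patient, in enrollment order.
    """
    if tuple(ratio) not in ((1, 1), (1, 2)):
        raise ValueError("supported allocation ratios: (1, 1) and (1, 2)")
    ratio = tuple(ratio)
    if ids is None:
        ids = list(range(len(patients)))
    strata = [assign_stratum(p) for p in patients]
    groups = {s.risk_group for s in strata}
    if len(groups) > 1:
        raise ValueError(f"patients span multiple risk groups: {sorted(groups)}")
    per_stratum: dict = {}
    for s in strata:
        per_stratum[s.index] = per_stratum.get(s.index, 0) + 1
    streams = {}
    for idx, count in per_stratum.items():
        rng = np.random.default_rng([seed, idx])
        streams[idx] = _block_stream(rng, ratio, count)
    cursor = {idx: 0 for idx in per_stratum}
    out = []
    for pid, stratum in zip(ids, strata):
        i = cursor[stratum.index]
        cursor[stratum.index] += 1
        arms, blocks, positions = streams[stratum.index]
        out.append(
            Assignment(
                patient=pid,
                arm="treatment" if arms[i] else "control",
                stratum=stratum,
                block=blocks[i],
                position=positions[i],
                seed=seed,
            )
        )
    return out
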