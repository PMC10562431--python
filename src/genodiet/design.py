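"""Arm assignment and energy prescription for the genotype-guided diet trial.

Randomization is 1:1 within (responder class, sex) strata using permuted
blocks whose sizes shrink late in enrolment (females 6 then 4; males 4 then
2).  Inside each block the allocation is adjusted by a biased coin so that the
running mean-BMI difference between arms in the stratum stays near zero, while
exact within-block balance is preserved.

Energy prescriptions start from Mifflin-St Jeor resting energy expenditure,
apply an activity factor, subtract a fixed daily deficit (default 750 kcal)
and snap to the meal-plan tier grid 1400..2800 kcal/day in 200 kcal steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .scoring import ResponderClass

__all__ = [
    "Sex",
    "DietArm",
    "Participant",
    "Assignment",
    "RandomizationConfig",
    "ENERGY_TIERS",
    "mifflin_st_jeor",
    "prescribe_energy",
    "is_concordant",
    "randomize_cohort",
]


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class DietArm(str, Enum):
    HIGH_FAT = "high_fat"
    HIGH_CARB = "high_carb"

    @property
    def macro_targets(self) -> dict[str, float]:
        """Percent of energy from (carbohydrate, fat, protein); sums to 100."""
        if self is DietArm.HIGH_CARB:
            return {"carb": 65.0, "fat": 20.0, "protein": 15.0}
        return {"carb": 45.0, "fat": 40.0, "protein": 15.0}


#: Meal plans exist in 200 kcal increments from 1400 to 2800 kcal/day.
ENERGY_TIERS: tuple[int, ...] = tuple(range(1400, 2801, 200))


@dataclass(frozen=True)
class Participant:
    subject_id: str
    sex: Sex
    race: str
    age: float
    weight: float  # kg
    height: float  # cm
    bmi: float  # kg/m^2
    responder_class: ResponderClass
    fasting_glucose: float = float("nan")  # mg/dL
    fasting_insulin: float = float("nan")  # uU/mL


@dataclass(frozen=True)
class Assignment:
    subject_id: str
    arm: DietArm
    stratum: tuple[str, str]  # (responder_class, sex)
    block_index: int
    concordant: bool
    energy_tier: int


@dataclass(frozen=True)
class RandomizationConfig:
    """Knobs for the stratified blocked randomization and prescription.

    ``switch_fraction`` is the fraction of a stratum's enrolment after which
    the block size drops from the early to the late size; the trial's actual
    switch point was chosen mid-study and is not public, so it is a parameter.
    """

    female_block_sizes: tuple[int, int] = (6, 4)
    male_block_sizes: tuple[int, int] = (4, 2)
    switch_fraction: float = 0.5
    bmi_tolerance: float = 1.5  # kg/m^2
    biased_coin_p: float = 0.8
    activity_factor: float = 1.4
    deficit_kcal: float = 750.0


def mifflin_st_jeor(sex: Sex, weight: float, height: float, age: float) -> float:
    """Resting energy expenditure (kcal/day), Mifflin-St Jeor equations.

    male:   10 W + 6.25 H - 5 A + 5
    female: 10 W + 6.25 H - 5 A - 161
    with W in kg, H in cm, A in years.
    """
    if weight <= 0 or height <= 0 or age <= 0:
        raise ValueError("weight, height and age must be positive")
    base = 10.0 * weight + 6.25 * height - 5.0 * age
    return base + (5.0 if Sex(sex) is Sex.MALE else -161.0)


def prescribe_energy(
    rmr: float, activity_factor: float = 1.4, deficit: float = 750.0
) -> int:
    """Snap (rmr * activity_factor - deficit) to the nearest meal-plan tier.

    Ties round up (favouring adequacy); results are clamped to [1400, 2800].
    """
    if rmr <= 0:
        raise ValueError("rmr must be positive")
    if activity_factor < 1:
        raise ValueError("activity_factor must be >= 1")
    target = rmr * activity_factor - deficit
    best = ENERGY_TIERS[0]
    best_dist = abs(target - best)
    for tier in ENERGY_TIERS[1:]:
        d = abs(target - tier)
        if d < best_dist or (d == best_dist and tier > best):
            best, best_dist = tier, d
    return best


def is_concordant(responder_class: ResponderClass, arm: DietArm) -> bool:
    """A diet is genotype-concordant when it matches the responder class."""
    responder_class = ResponderClass(responder_class)
    if not responder_class.eligible:
        raise ValueError(f"class {responder_class.value} is not randomizable")
    return (responder_class, DietArm(arm)) in (
        (ResponderClass.FAT_RESPONDER, DietArm.HIGH_FAT),
        (ResponderClass.CARB_RESPONDER, DietArm.HIGH_CARB),
    )


@dataclass
class _StratumState:
    """Running allocation state for one (class, sex) stratum."""

    n_total: int
    cfg: RandomizationConfig
    sizes: tuple[int, int]
    assigned: int = 0
    block_index: int = -1
    slots: dict = field(default_factory=dict)  # arm -> remaining slots in block
    bmi_sum: dict = field(default_factory=lambda: {a: 0.0 for a in DietArm})
    bmi_n: dict = field(default_factory=lambda: {a: 0 for a in DietArm})

    def _open_block(self) -> None:
        early, late = self.sizes
        size = early if self.assigned < self.cfg.switch_fraction * self.n_total else late
        self.block_index += 1
        self.slots = {DietArm.HIGH_FAT: size // 2, DietArm.HIGH_CARB: size // 2}

    def assign(self, bmi: float, rng: np.random.Generator) -> tuple[DietArm, int]:
        if not self.slots or all(v == 0 for v in self.slots.values()):
            self._open_block()
        open_arms = [a for a, v in self.slots.items() if v > 0]
        if len(open_arms) == 1:
            arm = open_arms[0]
        else:
            arm = self._choose(bmi, rng)
        self.slots[arm] -= 1
        self.assigned += 1
        self.bmi_sum[arm] += bmi
        self.bmi_n[arm] += 1
        return arm, self.block_index

    def _choose(self, bmi: float, rng: np.random.Generator) -> DietArm:
        means = {
            a: (self.bmi_sum[a] / self.bmi_n[a]) if self.bmi_n[a] else None
            for a in DietArm
        }
        if means[DietArm.HIGH_FAT] is None or means[DietArm.HIGH_CARB] is None:
            return DietArm(rng.choice([a.value for a in DietArm]))
        diff = means[DietArm.HIGH_FAT] - means[DietArm.HIGH_CARB]
        # the balancing arm is the one whose running mean moves toward the other
        if diff == 0:
            return DietArm(rng.choice([a.value for a in DietArm]))
        lighter = DietArm.HIGH_FAT if diff < 0 else DietArm.HIGH_CARB
        heavier = DietArm.HIGH_CARB if diff < 0 else DietArm.HIGH_FAT
        balancing = lighter if bmi > (means[lighter] + means[heavier]) / 2 else heavier
        if abs(diff) > self.cfg.bmi_tolerance:
            return balancing
        return balancing if rng.random() < self.cfg.biased_coin_p else (
            DietArm.HIGH_FAT if balancing is DietArm.HIGH_CARB else DietArm.HIGH_CARB
        )


def randomize_cohort(
    participants: Sequence[Participant],
    seed: int,
    cfg: RandomizationConfig | None = None,
) -> list[Assignment]:
    """Assign eligible participants 1:1 within (responder class, sex) strata.

    Deterministic given (participants order, seed, cfg).  Raises on BOTH /
    NEITHER responder classes; returns an empty list for an empty cohort.
    """
    cfg = cfg or RandomizationConfig()
    rng = np.random.default_rng(seed)
    for p in participants:
        if not ResponderClass(p.responder_class).eligible:
            raise ValueError(
                f"subject {p.subject_id}: class {p.responder_class} is not randomizable"
            )
    strata: dict[tuple[str, str], _StratumState] = {}
    totals: dict[tuple[str, str], int] = {}
    for p in participants:
        key = (ResponderClass(p.responder_class).value, Sex(p.sex).value)
        totals[key] = totals.get(key, 0) + 1
    out: list[Assignment] = []
    for p in participants:
        key = (ResponderClass(p.responder_class).value, Sex(p.sex).value)
        if key not in strata:
            sizes = (
                cfg.female_block_sizes if Sex(p.sex) is Sex.FEMALE else cfg.male_block_sizes
            )
            strata[key] = _StratumState(n_total=totals[key], cfg=cfg, sizes=sizes)
        arm, block = strata[key].assign(p.bmi, rng)
        rmr = mifflin_st_jeor(p.sex, p.weight, p.height, p.age)
        tier = prescribe_energy(rmr, cfg.activity_factor, cfg.deficit_kcal)
        out.append(
            Assignment(
                subject_id=p.subject_id,
                arm=arm,
                stratum=key,
                block_index=block,
                concordant=is_concordant(p.responder_class, arm),
                energy_tier=tier,
            )
        )
    return out
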