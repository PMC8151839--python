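"""Individual-animal state and the five-class life-stage machine.

An animal progresses CALF -> HEIFER_I -> HEIFER_II -> HEIFER_III -> COW,
never backwards; within COW it alternates between lactating and dry.  The
class is a pure function of age, reproductive state and parity, so
:func:`transition_class` is total and idempotent.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields

__all__ = [
    "AnimalClass",
    "CowState",
    "AnimalState",
    "CULL_REASONS",
    "transition_class",
    "dry_off_check",
]


class AnimalClass(enum.Enum):
    CALF = "calf"
    HEIFER_I = "heifer_1"
    HEIFER_II = "heifer_2"
    HEIFER_III = "heifer_3"
    COW = "cow"


#: Forward-only ordering of the life stages.
_CLASS_ORDER = {
    AnimalClass.CALF: 0,
    AnimalClass.HEIFER_I: 1,
    AnimalClass.HEIFER_II: 2,
    AnimalClass.HEIFER_III: 3,
    AnimalClass.COW: 4,
}


class CowState(enum.Enum):
    LACTATING = "lactating"
    DRY = "dry"


CULL_REASONS = (
    "low_production",
    "lameness",
    "injury",
    "mastitis",
    "disease",
    "udder",
    "unknown",
    "reproduction_failure",
    "sold",
)


@dataclass(slots=True)
class AnimalState:
    """One simulated animal.

    Day-valued fields are expressed on the simulation-day axis (0-based from
    the run's start date; negative ``birth_day`` means the animal was born
    before the run started).
    """

    id: int
    sex: str = "F"
    birth_day: int = 0
    animal_class: AnimalClass = AnimalClass.CALF
    cow_state: CowState | None = None

    bw: float = 40.0                 # kg, full body weight
    mature_bw: float = 680.0         # kg, full mature body weight
    birth_bw: float = 40.0           # kg
    parity: int = 0
    dim: int = 0                     # days in milk (current lactation)
    days_in_pregnancy: int = 0       # 0 = open
    gestation_length: int = 0        # drawn at conception; 0 while open
    expected_calf_bw: float = 0.0    # drawn at conception, drives conceptus mass
    breeding_day: int = -1           # next scheduled service day (-1 = none)
    services: int = 0                # services this breeding sequence
    last_calving_day: int | None = None

    weaning_day: int = 56            # age (days) at which milk feeding ends
    target_adg: float = 0.0          # kg/d, current growth target
    rho: float = 1.0                 # feed-efficiency multiplier on expected DMI
    expected_dmi: float = 0.0        # kg DM/d, from the assigned ration
    simulated_dmi: float = 0.0       # rho * expected_dmi
    pen_id: str = ""

    alive: bool = True
    cull_day: int | None = None
    cull_reason: str | None = None
    pre_drawn_exit_day: int | None = None

    def age(self, sim_day: int) -> int:
        return sim_day - self.birth_day

    @property
    def pregnant(self) -> bool:
        return self.days_in_pregnancy > 0

    @property
    def lactating(self) -> bool:
        return self.cow_state is CowState.LACTATING

    def validate(self) -> None:
        if self.bw <= 0:
            raise ValueError(f"animal {self.id}: BW must be > 0, got {self.bw}")
        if self.pregnant and self.days_in_pregnancy > self.gestation_length:
            raise ValueError(
                f"animal {self.id}: days_in_pregnancy {self.days_in_pregnancy} exceeds "
                f"gestation length {self.gestation_length}"
            )
        if self.dim < 0 or self.parity < 0:
            raise ValueError(f"animal {self.id}: DIM and parity must be >= 0")
        if self.cull_reason is not None and self.cull_reason not in CULL_REASONS:
            raise ValueError(f"animal {self.id}: unknown cull reason {self.cull_reason!r}")

    def copy(self) -> "AnimalState":
        return AnimalState(**{f.name: getattr(self, f.name) for f in fields(self)})


def transition_class(
    animal: AnimalState,
    sim_day: int,
    *,
    breeding_start_age: int,
    pre_fresh_period: int,
) -> AnimalClass:
    """Life stage implied by the animal's current state.

    CALF until weaning day; HEIFER_I until entry into the breeding period;
    HEIFER_II until within ``pre_fresh_period`` days of expected calving;
    HEIFER_III until first calving; COW thereafter (absorbing).
    """
    if animal.parity >= 1:
        return AnimalClass.COW
    age = animal.age(sim_day)
    if age < animal.weaning_day:
        return AnimalClass.CALF
    if (
        animal.pregnant
        and animal.days_in_pregnancy >= animal.gestation_length - pre_fresh_period
    ):
        return AnimalClass.HEIFER_III
    if age < breeding_start_age:
        return AnimalClass.HEIFER_I
    return AnimalClass.HEIFER_II


def advance_class(animal: AnimalState, new_class: AnimalClass) -> None:
    """Apply a transition, rejecting any backward move."""
    if _CLASS_ORDER[new_class] < _CLASS_ORDER[animal.animal_class]:
        raise ValueError(
            f"animal {animal.id}: invalid transition "
            f"{animal.animal_class.value} -> {new_class.value}"
        )
    animal.animal_class = new_class


def dry_off_check(cow: AnimalState, dry_off_day: int) -> CowState:
    """Cow substate: dry once a pregnant cow reaches ``dry_off_day`` days pregnant.

    Open cows stay lactating regardless of days in milk (the end of lactation
    is tied to pregnancy stage, not DIM).
    """
    if cow.cow_state is None:
        raise ValueError(f"animal {cow.id} is not a cow")
    if cow.pregnant and cow.days_in_pregnancy >= dry_off_day:
        return CowState.DRY
    return cow.cow_state
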