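"""Monte Carlo life-cycle events and the deterministic growth equations.

Covers birth, estrus scheduling, breeding, pregnancy (with check-day loss),
conceptus mass and growth, lactation-driven body-weight change, milestone
growth targets, the Wood lactation curve, and culling.

Growth-equation conventions
---------------------------
* Total conceptus mass uses the multiplicative grouping
  ``(0.0148*GL - 2.408) * CBW`` (GL gestation length in days, CBW calf birth
  weight in kg).  The alternative literal grouping ``0.0148*GL - 2.408*CBW``
  produces a negative mass for all realistic inputs and is retained only
  behind the ``literal=True`` flag for inspection.
* Daily conceptus growth is ``3*W*(t-50)^2 / (GL-50)^3`` for day ``t`` in
  (50, GL]; zero before day 51.  This is the unique grouping of the cubic
  growth curve whose integral over the gestation recovers the total mass W.
* Lactation tissue change is ``(s/m) * exp(1 - DIM/m) * (DIM/m - 1)`` with
  (s, m) = (20, 65) for primiparous and (40, 70) for multiparous cows:
  mobilisation in early lactation, repletion after DIM = m, integrating to
  ~zero over a complete lactation.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING

from .animals import AnimalClass, AnimalState, CowState
from .constants import SHRUNK_BW_FACTOR
from .rng import BoundedDistribution, RandomStreams, bernoulli_event, draw_bounded

if TYPE_CHECKING:
    from .config import HerdConfig, ProtocolConfig, ReproProtocolConfig

__all__ = [
    "conceptus_weight_total",
    "conceptus_growth",
    "lactation_bw_change",
    "wood_milk",
    "target_adg",
    "daily_bw_update",
    "simulate_birth",
    "schedule_estrus",
    "breed",
    "pregnancy_update",
    "cull_update",
]


# ---------------------------------------------------------------------------
# Deterministic growth / production equations
# ---------------------------------------------------------------------------


def conceptus_weight_total(gestation_length: float, calf_birth_bw: float,
                           literal: bool = False) -> float:
    """Total conceptus mass (kg) deposited over a pregnancy."""
    if gestation_length <= 50:
        raise ValueError(f"gestation length must exceed 50 d, got {gestation_length}")
    if literal:
        return 0.0148 * gestation_length - 2.408 * calf_birth_bw
    total = (0.0148 * gestation_length - 2.408) * calf_birth_bw
    if calf_birth_bw > 0 and total <= 0:
        raise ValueError(
            f"non-positive conceptus mass ({total:.2f} kg) for GL={gestation_length}, "
            f"CBW={calf_birth_bw}; inputs outside the equation's valid range"
        )
    return total


def conceptus_growth(days_in_pregnancy: float, gestation_length: float,
                     total_weight: float) -> float:
    """Daily conceptus growth (kg/d); zero before day 51 of pregnancy."""
    if gestation_length <= 50:
        raise ValueError(f"gestation length must exceed 50 d, got {gestation_length}")
    t = days_in_pregnancy
    if t > gestation_length:
        raise ValueError(f"days in pregnancy {t} exceeds gestation length {gestation_length}")
    if t <= 50:
        return 0.0
    return 3.0 * total_weight * (t - 50.0) ** 2 / (gestation_length - 50.0) ** 3


def lactation_bw_change(dim: int, parity: int, lactating: bool = True) -> float:
    """Lactation-driven daily body-tissue change (kg/d); 0 for dry cows."""
    if not lactating:
        return 0.0
    scale, midpoint = (20.0, 65.0) if parity == 1 else (40.0, 70.0)
    e = math.exp(1.0 - dim / midpoint)
    return (scale / midpoint) * e * (dim / midpoint - 1.0)


def wood_milk(dim: int, a: float, b: float, c: float) -> float:
    """Wood lactation curve: milk (kg/d) = a * DIM^b * exp(-c * DIM)."""
    if a < 0 or b < 0 or c < 0:
        raise ValueError(f"Wood curve parameters must be >= 0, got a={a}, b={b}, c={c}")
    if dim < 1:
        raise ValueError(f"DIM must be >= 1 for a lactating cow, got {dim}")
    return a * dim ** b * math.exp(-c * dim)


# ---------------------------------------------------------------------------
# Growth targets and the daily body-weight update
# ---------------------------------------------------------------------------


def _milestone_bw(animal: AnimalState, fraction: float) -> float:
    """Full BW corresponding to a fraction of mature *shrunk* BW."""
    return fraction * (SHRUNK_BW_FACTOR * animal.mature_bw) / SHRUNK_BW_FACTOR


def target_adg(animal: AnimalState, sim_day: int, herd: "HerdConfig") -> float:
    """Linear average-daily-gain target toward the next body-weight milestone.

    Milestones (fractions of mature shrunk BW): 55% at first pregnancy, 82%
    at first calving, 92% at the end of the first lactation, 100% by the end
    of the second lactation.  Pre-weaning calves grow at the configured
    constant target.  Gain targets never go negative.
    """
    m = herd.bw_milestones
    if animal.animal_class is AnimalClass.CALF:
        return herd.calf_target_adg

    if animal.parity == 0:
        if animal.pregnant:
            # heifer II/III: reach 82% at the upcoming calving
            days = animal.gestation_length - animal.days_in_pregnancy
            target = _milestone_bw(animal, m["first_calving"])
        else:
            # heifer I/II: reach 55% at the planned first conception
            if animal.breeding_day > sim_day:
                days = animal.breeding_day - sim_day
            else:
                days = (animal.birth_day + herd.heifer_repro_cull_age) - sim_day
            target = _milestone_bw(animal, m["first_pregnancy"])
    elif animal.parity == 1:
        days = (animal.last_calving_day or sim_day) + herd.estimated_lactation_length - sim_day
        target = _milestone_bw(animal, m["end_first_lactation"])
    elif animal.parity == 2:
        days = (animal.last_calving_day or sim_day) + herd.estimated_lactation_length - sim_day
        target = _milestone_bw(animal, m["end_second_lactation"])
    else:
        return 0.0

    if days <= 0:
        return 0.0
    return max(0.0, (target - animal.bw) / days)


def daily_bw_update(animal: AnimalState, adg: float, conceptus_delta: float,
                    lactation_delta: float) -> float:
    """Apply one day of body-weight change; returns the new BW (kg)."""
    new_bw = animal.bw + adg + conceptus_delta + lactation_delta
    if new_bw <= 0:
        raise ValueError(
            f"animal {animal.id}: body weight update would reach {new_bw:.2f} kg"
        )
    animal.bw = new_bw
    return new_bw


# ---------------------------------------------------------------------------
# Stochastic life events
# ---------------------------------------------------------------------------


def simulate_birth(dam: AnimalState, herd: "HerdConfig", streams: RandomStreams,
                   sim_day: int, calf_id: int) -> AnimalState | None:
    """Outcome of a calving: a retained female calf, or None.

    Draws (in fixed order on the lifecycle stream): stillbirth, calf sex,
    keep-female decision.  Male calves are sold at birth and never
    instantiated; body-weight draws come from the bodyweight stream.
    """
    if bernoulli_event(herd.stillbirth_probability, streams.lifecycle):
        return None
    female = bernoulli_event(herd.female_calf_probability, streams.lifecycle)
    if not female:
        return None
    if not bernoulli_event(herd.keep_female_calf_rate, streams.lifecycle):
        return None
    birth_bw = draw_bounded(herd.calf_birth_bw, streams.bodyweight)
    mature_bw = draw_bounded(herd.mature_bw, streams.bodyweight)
    return AnimalState(
        id=calf_id,
        sex="F",
        birth_day=sim_day,
        animal_class=AnimalClass.CALF,
        bw=birth_bw,
        birth_bw=birth_bw,
        mature_bw=mature_bw,
        weaning_day=herd.weaning_day,
        target_adg=herd.calf_target_adg,
        pen_id="calf",
    )


def schedule_estrus(animal: AnimalState, protocol: "ProtocolConfig",
                    repro: "ReproProtocolConfig", streams: RandomStreams,
                    current_day: int, first_service: bool = False,
                    max_cycles: int = 60) -> int:
    """Next breeding day under the configured reproduction protocol.

    * timed_ai: fixed protocol schedule, no draws consumed.
    * estrus_detection: cycle lengths drawn until an estrus is detected.
    * synch_estrus_detection: synchronized (fixed-day) first service, then
      detected estrus for re-services.
    """
    if protocol.protocol == "timed_ai":
        return current_day + protocol.tai_service_interval
    if protocol.protocol == "synch_estrus_detection" and first_service:
        return current_day + protocol.synch_first_service_delay
    day = current_day
    for _ in range(max_cycles):
        day += round(draw_bounded(repro.estrous_cycle, streams.lifecycle))
        if bernoulli_event(protocol.estrus_detection_probability, streams.lifecycle):
            return day
    # No detected estrus within the horizon: report a far-future day; the
    # reproduction-failure cull rule removes such animals first.
    return day


def breed(animal: AnimalState, protocol: "ProtocolConfig",
          repro: "ReproProtocolConfig", calf_bw_dist: BoundedDistribution,
          streams: RandomStreams, sim_day: int) -> bool:
    """Service the animal; on conception start the pregnancy clock.

    A successful conception draws the gestation length and the expected calf
    birth weight (the latter drives conceptus mass); a failed service
    reschedules the next estrus per the protocol.
    """
    animal.services += 1
    if bernoulli_event(protocol.conception_probability, streams.lifecycle):
        animal.days_in_pregnancy = 1
        animal.gestation_length = round(draw_bounded(repro.gestation_length,
                                                     streams.bodyweight))
        animal.expected_calf_bw = draw_bounded(calf_bw_dist, streams.bodyweight)
        animal.breeding_day = -1
        return True
    animal.breeding_day = schedule_estrus(animal, protocol, repro, streams, sim_day)
    return False


def pregnancy_update(animal: AnimalState, protocol: "ProtocolConfig",
                     repro: "ReproProtocolConfig", streams: RandomStreams,
                     sim_day: int) -> str:
    """One day of pregnancy: advance the clock, apply check-day loss.

    Returns "pregnant", "aborted" or "term" (ready to calve).  Loss is drawn
    only at the configured pregnancy-check days, with the per-check
    probability derived from the total loss rate; an aborted animal re-enters
    the breeding sequence immediately.
    """
    animal.days_in_pregnancy += 1
    if animal.days_in_pregnancy >= animal.gestation_length:
        return "term"
    if animal.days_in_pregnancy in repro.pregnancy_check_days:
        if bernoulli_event(repro.per_check_loss, streams.lifecycle):
            animal.days_in_pregnancy = 0
            animal.gestation_length = 0
            animal.expected_calf_bw = 0.0
            animal.breeding_day = schedule_estrus(animal, protocol, repro,
                                                  streams, sim_day)
            return "aborted"
    return "pregnant"


def cull_update(animal: AnimalState, herd: "HerdConfig", streams: RandomStreams,
                sim_day: int) -> str | None:
    """Reproduction-failure rules plus stochastic health/production culls.

    Health hazards apply to cows (one total-hazard draw per cow-day; the
    reason is resolved by a second draw only when a cull fires, keeping the
    per-day draw count constant).  Returns the cull reason or None.
    """
    if animal.parity == 0:
        if (not animal.pregnant
                and animal.age(sim_day) > herd.heifer_repro_cull_age):
            return "reproduction_failure"
        return None

    if not animal.pregnant and animal.dim > herd.cow_repro_cull_dim:
        return "reproduction_failure"

    hazards = herd.culling.daily_hazards
    total = sum(hazards.values())
    if total <= 0:
        return None
    u = streams.culling.random()
    if u >= total:
        return None
    # resolve the reason by position within the stacked hazard
    acc = 0.0
    for reason, h in hazards.items():
        acc += h
        if u < acc:
            return reason
    return "unknown"
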