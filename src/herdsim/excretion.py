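"""Daily manure excretion and enteric methane per animal class.

Class-specific submodels:

* Calves — manure and solids scale linearly with body weight (ASABE-style
  per-unit-mass coefficients); enteric CH4 from the metabolic-BW energy
  relation ``(0.013 * BW^0.75 * 4.184) / 0.05565`` g/d.
* Heifers — ASABE-style manure/TS/VS on body weight; enteric CH4 from a
  linear intake relation in L/d converted to g/d at 0.662 g/L.
* Lactating cows — excretion (manure, total solids, urine, fecal water,
  volatile solids split degradable/non-degradable, N) as linear functions of
  the efficiency-adjusted simulated DMI; enteric CH4 from a three-way model
  switch (intake regression with milk terms, Mitscherlich saturating curve,
  or IPCC Tier 2 on dietary gross energy).
* Dry cows — ASABE-style manure on body weight; enteric CH4 always from the
  Mitscherlich model (the intake-regression model carries milk-production
  terms that make it unsuitable for dry cows).

Empirical linear predictions are clamped at zero when extreme inputs would
drive them negative.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .animals import AnimalClass, AnimalState
from .constants import (
    ASABE_BW_COEFFICIENTS,
    ASH_FRACTION_DEFAULT,
    CH4_G_PER_L,
    CH4_MJ_PER_G,
    GE_MJ_PER_KG,
    HEIFER_CH4_L_PER_D,
    IPCC_YM_PERCENT,
    LACTATING_EXCRETION,
    MILLS_MIT3,
    MJ_PER_MCAL,
    NEL_TO_ME,
    NIU_US,
)

__all__ = [
    "EntericModel",
    "ExcretionRecord",
    "DietComposition",
    "calf_manure",
    "calf_methane",
    "heifer_excretion",
    "lactating_excretion",
    "dry_cow_excretion",
    "enteric_methane",
    "aggregate_excretion",
]


class EntericModel(enum.Enum):
    NIU_US = "niu"
    MILLS_MIT3 = "mills"
    IPCC_TIER2 = "ipcc"


@dataclass(frozen=True)
class DietComposition:
    """DM-basis fractions of the assigned diet needed by the enteric models."""

    cp: float = 0.16          # crude protein fraction of DM
    fat: float = 0.035
    nel_mcal_per_kg: float = 1.55
    ash: float = ASH_FRACTION_DEFAULT

    def gross_energy_mj_per_kg(self) -> float:
        """Dietary GE from proximate composition (MJ/kg DM)."""
        carb = max(0.0, 1.0 - self.cp - self.fat - self.ash)
        return (GE_MJ_PER_KG["cp"] * self.cp
                + GE_MJ_PER_KG["fat"] * self.fat
                + GE_MJ_PER_KG["carbohydrate"] * carb)


@dataclass
class ExcretionRecord:
    """One animal-day of manure and enteric methane."""

    manure: float = 0.0          # kg as-excreted/d
    total_solids: float = 0.0    # kg DM/d
    volatile_solids: float = 0.0  # kg/d
    vs_degradable: float = 0.0
    vs_nondegradable: float = 0.0
    urine: float = 0.0           # kg/d
    fecal_water: float = 0.0     # kg/d
    manure_n: float = 0.0        # g/d
    enteric_ch4: float = 0.0     # g/d

    def validate(self) -> None:
        for name in ("manure", "total_solids", "volatile_solids", "urine",
                     "fecal_water", "manure_n", "enteric_ch4"):
            if getattr(self, name) < 0:
                raise ValueError(f"excretion {name} must be >= 0")
        if self.total_solids > self.manure + 1e-9:
            raise ValueError("total solids cannot exceed manure mass")
        if abs(self.vs_degradable + self.vs_nondegradable - self.volatile_solids) > 1e-9:
            raise ValueError("VS partition must sum to total VS")


def _clamp0(x: float) -> float:
    return x if x > 0.0 else 0.0


# ---------------------------------------------------------------------------
# Class submodels
# ---------------------------------------------------------------------------


def calf_manure(bw: float) -> tuple[float, float]:
    """Calf daily manure and total solids (kg), linear in body weight."""
    c = ASABE_BW_COEFFICIENTS["calf"]
    return c["manure"] * bw, c["ts"] * bw


def calf_methane(bw: float) -> float:
    """Calf enteric CH4 (g/d) = (0.013 * BW^0.75 * 4.184) / 0.05565."""
    if bw < 0:
        raise ValueError(f"body weight must be >= 0, got {bw}")
    return 0.013 * bw ** 0.75 * MJ_PER_MCAL / CH4_MJ_PER_G


def heifer_excretion(bw: float, dmi: float) -> ExcretionRecord:
    """Heifer manure on BW; enteric CH4 linear in DMI (L/d -> g/d at 0.662 g/L)."""
    c = ASABE_BW_COEFFICIENTS["heifer"]
    ts = c["ts"] * bw
    vs = c["vs"] * bw
    ch4_l = _clamp0(HEIFER_CH4_L_PER_D["intercept"] + HEIFER_CH4_L_PER_D["slope"] * dmi)
    rec = ExcretionRecord(
        manure=c["manure"] * bw,
        total_solids=ts,
        volatile_solids=vs,
        vs_degradable=0.5 * vs,
        vs_nondegradable=0.5 * vs,
        manure_n=c["n_g"] * bw,
        enteric_ch4=ch4_l * CH4_G_PER_L,
    )
    rec.validate()
    return rec


def lactating_excretion(dmi: float) -> ExcretionRecord:
    """Lactating-cow excretion, all linear in the simulated (rho-adjusted) DMI."""
    c = LACTATING_EXCRETION
    manure = _clamp0(c["manure_slope"] * dmi + c["manure_intercept"])
    ts = _clamp0(c["ts_slope"] * dmi + c["ts_intercept"])
    urine = _clamp0(c["urine_slope"] * dmi + c["urine_intercept"])
    vs = c["vs_of_ts"] * ts
    deg = c["vs_degradable_fraction"] * vs
    rec = ExcretionRecord(
        manure=manure,
        total_solids=min(ts, manure),
        volatile_solids=vs,
        vs_degradable=deg,
        vs_nondegradable=vs - deg,
        urine=urine,
        fecal_water=_clamp0(manure - urine - ts),
        manure_n=_clamp0(c["n_slope"] * dmi + c["n_intercept"]),
    )
    rec.validate()
    return rec


def dry_cow_excretion(bw: float, dmi: float,
                      diet: DietComposition | None = None) -> ExcretionRecord:
    """Dry-cow manure on BW; enteric CH4 always from the Mitscherlich model."""
    c = ASABE_BW_COEFFICIENTS["dry"]
    vs = c["vs"] * bw
    rec = ExcretionRecord(
        manure=c["manure"] * bw,
        total_solids=c["ts"] * bw,
        volatile_solids=vs,
        vs_degradable=0.5 * vs,
        vs_nondegradable=0.5 * vs,
        manure_n=c["n_g"] * bw,
        enteric_ch4=_mills_ch4(dmi, diet or DietComposition()),
    )
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Enteric methane switch for lactating cows
# ---------------------------------------------------------------------------


def _mills_ch4(dmi: float, diet: DietComposition) -> float:
    """Mitscherlich saturating CH4 (g/d) from metabolisable-energy intake."""
    me_mj = dmi * diet.nel_mcal_per_kg * NEL_TO_ME * MJ_PER_MCAL
    a = MILLS_MIT3["asymptote_mj"]
    ch4_mj = a - a * math.exp(-MILLS_MIT3["rate_per_mj"] * me_mj)
    return ch4_mj / CH4_MJ_PER_G


def enteric_methane(dmi: float, milk: float, milk_fat_pct: float,
                    diet: DietComposition | None,
                    choice: EntericModel) -> float:
    """Lactating-cow enteric CH4 (g/d) under the selected model."""
    if choice is EntericModel.NIU_US:
        fat_yield = milk * milk_fat_pct / 100.0
        return _clamp0(NIU_US["intercept"] + NIU_US["dmi_slope"] * dmi
                       + NIU_US["fat_yield_slope"] * fat_yield)
    if choice is EntericModel.MILLS_MIT3:
        return _mills_ch4(dmi, diet or DietComposition())
    if choice is EntericModel.IPCC_TIER2:
        if diet is None:
            raise ValueError("IPCC Tier 2 requires the diet composition for gross energy")
        ge_mj = diet.gross_energy_mj_per_kg() * dmi
        return ge_mj * (IPCC_YM_PERCENT / 100.0) / CH4_MJ_PER_G
    raise ValueError(f"unknown enteric model {choice!r}")


def animal_excretion(animal: AnimalState, milk: float, milk_fat_pct: float,
                     diet: DietComposition | None,
                     choice: EntericModel) -> ExcretionRecord:
    """Dispatch to the class submodel for one alive animal-day."""
    cls = animal.animal_class
    if cls is AnimalClass.CALF:
        manure, ts = calf_manure(animal.bw)
        c = ASABE_BW_COEFFICIENTS["calf"]
        vs = c["vs"] * animal.bw
        return ExcretionRecord(manure=manure, total_solids=ts,
                               volatile_solids=vs, vs_degradable=0.5 * vs,
                               vs_nondegradable=0.5 * vs,
                               manure_n=c["n_g"] * animal.bw,
                               enteric_ch4=calf_methane(animal.bw))
    if cls in (AnimalClass.HEIFER_I, AnimalClass.HEIFER_II, AnimalClass.HEIFER_III):
        return heifer_excretion(animal.bw, animal.simulated_dmi)
    # cow
    if animal.lactating:
        rec = lactating_excretion(animal.simulated_dmi)
        rec.enteric_ch4 = enteric_methane(animal.simulated_dmi, milk,
                                          milk_fat_pct, diet, choice)
        return rec
    return dry_cow_excretion(animal.bw, animal.simulated_dmi, diet)


def aggregate_excretion(
    records: Iterable[tuple[AnimalState, ExcretionRecord]],
) -> dict[str, dict[str, float]]:
    """Exact sums of every excretion component by animal class and by pen."""
    totals: dict[str, dict[str, float]] = {}
    fields = ("manure", "total_solids", "volatile_solids", "urine",
              "fecal_water", "manure_n", "enteric_ch4")

    def _add(bucket: str, rec: ExcretionRecord) -> None:
        slot = totals.setdefault(bucket, {f: 0.0 for f in fields})
        for f in fields:
            slot[f] += getattr(rec, f)

    for animal, rec in records:
        _add("herd", rec)
        _add(f"class:{animal.animal_class.value}", rec)
        if animal.pen_id:
            _add(f"pen:{animal.pen_id}", rec)
    return totals
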