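"""Nutrient requirements, calf feeding, pen averaging and ration formulation.

Requirements follow the NRC (2001) dairy structure — additive maintenance,
growth, pregnancy and lactation terms in net-energy (NEl), metabolisable
protein (MP), Ca and P currencies, with the class-specific dry matter intake
(DMI) prediction — implemented as documented equations with the book's
functional forms:

* maintenance NEl  = 0.080 * BW^0.75                       (metabolic BW scaling)
* lactation NEl/kg = 0.0929*fat% + 0.0547*protein% + 0.0395*lactose%
* pregnancy NEl    = ((0.00318*d - 0.0352) * (CBW/45)) / 0.218  for d > 190
* lactating DMI    = (0.372*FCM + 0.0968*BW^0.75) * (1 - exp(-0.192*(WOL+3.67)))

The least-cost ration is a nonlinear program solved by sequential quadratic
programming (SLSQP): minimise feed cost subject to nutrient supplies meeting
the pen requirement, total DM fixed at the predicted intake, dietary NDF in
[25, 40]% of DM, forage NDF >= 19% of DM, fat <= 7% of DM and per-feed
inclusion caps.  If the solver fails within its iteration limit the
estimated milk is stepped down 0.5 kg and the formulation re-entered
(requirements never increase across retries) up to a bounded number of
times before a hard infeasibility error naming the binding constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .animals import AnimalClass, AnimalState
from .config import FeedLibraryEntry, RationConfig
from .constants import CALF_FEED_ENERGY, MILK_DM_FRACTION, PER_KG_MILK

__all__ = [
    "NutrientRequirements",
    "Ration",
    "InfeasibleRationError",
    "calf_milk_intake",
    "starter_intake",
    "calf_allowable_gain",
    "requirements",
    "expected_dmi",
    "pen_average",
    "formulate_ration",
    "assign_ration",
]

# Diet composition constraints, % of dietary DM.
NDF_MIN_PCT = 25.0
NDF_MAX_PCT = 40.0
FORAGE_NDF_MIN_PCT = 19.0
FAT_MAX_PCT = 7.0


@dataclass(frozen=True)
class NutrientRequirements:
    ne: float             # Mcal NEl/d
    mp: float             # g/d
    ca: float             # g/d
    p: float              # g/d
    expected_dmi: float   # kg DM/d
    estimated_milk: float = 0.0  # kg/d

    def validate(self) -> None:
        for name in ("ne", "mp", "ca", "p", "expected_dmi"):
            if getattr(self, name) < 0:
                raise ValueError(f"requirement {name} must be >= 0")

    def scaled(self, factor: float) -> "NutrientRequirements":
        return NutrientRequirements(self.ne * factor, self.mp * factor,
                                    self.ca * factor, self.p * factor,
                                    self.expected_dmi, self.estimated_milk)

    def with_milk_reduced(self, kg: float) -> "NutrientRequirements":
        """Requirements after lowering the milk estimate by ``kg`` (never < 0 milk)."""
        kg = min(kg, self.estimated_milk)
        return NutrientRequirements(
            ne=max(0.0, self.ne - kg * PER_KG_MILK["nel_mcal"]),
            mp=max(0.0, self.mp - kg * PER_KG_MILK["mp_g"]),
            ca=max(0.0, self.ca - kg * PER_KG_MILK["ca_g"]),
            p=max(0.0, self.p - kg * PER_KG_MILK["p_g"]),
            expected_dmi=self.expected_dmi,
            estimated_milk=self.estimated_milk - kg,
        )


class InfeasibleRationError(RuntimeError):
    """Raised when no feasible ration exists after all milk reductions."""


@dataclass
class Ration:
    """An optimised pen ration: kg DM of each feed per head per day."""

    feed_names: tuple[str, ...]
    amounts: np.ndarray           # kg DM/d per feed
    cost: float                   # $/head/d
    dmi: float                    # total kg DM/d
    supplied: dict[str, float]    # ne, mp, ca, p, ndf_pct, forage_ndf_pct, fat_pct
    milk_reductions: int = 0
    iterations: int = 0
    converged: bool = True

    @property
    def composition(self) -> dict[str, float]:
        """Per-feed fraction of dietary DM."""
        total = self.amounts.sum()
        if total <= 0:
            return {name: 0.0 for name in self.feed_names}
        return dict(zip(self.feed_names, self.amounts / total))

    def diet_fraction(self, key: str, feeds: Sequence[FeedLibraryEntry]) -> float:
        """DM-weighted mean of a feed attribute expressed as a fraction."""
        total = self.amounts.sum()
        if total <= 0:
            return 0.0
        pct = sum(a * getattr(f, key) for a, f in zip(self.amounts, feeds))
        return pct / total / 100.0


# ---------------------------------------------------------------------------
# Calf feeding
# ---------------------------------------------------------------------------


def calf_milk_intake(birth_bw: float, age: int, weaning_day: int,
                     weaning_period: int) -> float:
    """Daily milk / milk-replacer allowance (kg as-fed).

    10% of birth weight until the weaning ramp starts, then a linear ramp to
    zero ending at the weaning day.
    """
    base = 0.10 * birth_bw
    ramp_start = weaning_day - weaning_period
    if age < ramp_start:
        return base
    if age >= weaning_day:
        return 0.0
    return base * (weaning_day - age) / weaning_period


def starter_intake(bw: float) -> float:
    """Calf starter intake (kg/d) from the broken-line regression on BW.

    Two linear segments meeting at 69.365 kg; the raw line crosses zero near
    50 kg, below which intake is clamped at 0.
    """
    if bw <= 0:
        raise ValueError(f"body weight must be > 0, got {bw}")
    if bw <= 69.365:
        raw = -0.24783 + 0.0049567 * bw
    else:
        raw = -6.2263 + 0.091145 * bw
    return max(0.0, raw)


def calf_allowable_gain(milk_dm: float, starter_dm: float, bw: float) -> float:
    """Energy- and protein-allowable daily gain (kg/d); the minimum governs.

    NRC (2001) calf-chapter style: ME intake above maintenance converted to
    retained energy (k_g = 0.57) and inverted through the retained-energy
    requirement per kg gain; protein-allowable gain from digestible protein
    above maintenance at 180 g net protein per kg gain.  Negative values
    (intake below maintenance) are returned as energy-deficit losses.
    """
    if milk_dm < 0 or starter_dm < 0:
        raise ValueError("intakes must be >= 0")
    mbw = bw ** 0.75
    mei = (milk_dm * CALF_FEED_ENERGY["milk_me_mcal_per_kg_dm"]
           + starter_dm * CALF_FEED_ENERGY["starter_me_mcal_per_kg_dm"])
    me_maint = 0.10 * mbw
    surplus = mei - me_maint
    if surplus <= 0:
        # linearised tissue-energy loss (~5 Mcal mobilised per kg BW)
        gain_energy = surplus / 5.0
    else:
        gain_energy = (surplus * 0.57 / (0.0557 * mbw)) ** (1.0 / 1.097)
    cp_g = 1000.0 * (milk_dm * CALF_FEED_ENERGY["milk_cp_fraction"]
                     + starter_dm * CALF_FEED_ENERGY["starter_cp_fraction"])
    protein_surplus = 0.70 * cp_g - 3.0 * mbw
    gain_protein = protein_surplus / 180.0
    return min(gain_energy, gain_protein)


# ---------------------------------------------------------------------------
# Requirements and intake prediction
# ---------------------------------------------------------------------------


def expected_dmi(animal: AnimalState, milk: float, milk_fat_pct: float) -> float:
    """Predicted (expected) dry matter intake, kg DM/d, by animal class."""
    cls = animal.animal_class
    if cls is AnimalClass.CALF:
        milk_kg = calf_milk_intake(animal.birth_bw, 0, animal.weaning_day, 1)
        return milk_kg * MILK_DM_FRACTION + starter_intake(animal.bw)
    if cls is AnimalClass.COW:
        if animal.lactating:
            fcm = milk * (0.4 + 0.15 * milk_fat_pct)
            wol = animal.dim / 7.0
            ramp = 1.0 - math.exp(-0.192 * (wol + 3.67))
            return (0.372 * fcm + 0.0968 * animal.bw ** 0.75) * ramp
        return 0.0185 * animal.bw
    # heifers: allometric intake on metabolic BW
    return 0.0965 * animal.bw ** 0.75


def requirements(animal: AnimalState, milk: float, herd_cfg, adg: float) -> NutrientRequirements:
    """Daily NEl, MP, Ca and P requirement for one heifer or cow.

    Additive NRC-style terms: maintenance on metabolic BW, growth scaled by
    the target ADG, pregnancy beyond day 190 of gestation, and lactation per
    kg of milk at the herd's fat and protein tests.
    """
    mbw = animal.bw ** 0.75
    fat, prot = herd_cfg.milk_fat_pct, herd_cfg.milk_protein_pct

    ne = 0.080 * mbw
    mp = 3.8 * mbw
    ca = 0.031 * animal.bw
    p = 0.028 * animal.bw

    if adg > 0:
        ne += adg * (2.0 + 0.004 * animal.bw)   # energy per kg gain rises with BW
        mp += adg * 280.0
        ca += adg * 14.0
        p += adg * 7.5

    d = animal.days_in_pregnancy
    if d > 190:
        cbw = animal.expected_calf_bw or 42.0
        ne += (0.00318 * d - 0.0352) * (cbw / 45.0) / 0.218
        mp += 0.69 * (d - 190)
        ca += 12.0
        p += 6.0

    if milk > 0:
        nel_per_kg = 0.0929 * fat + 0.0547 * prot + 0.0395 * 4.85
        ne += milk * nel_per_kg
        mp += milk * prot * 10.0 / 0.67
        ca += milk * 3.2
        p += milk * 1.9

    dmi = expected_dmi(animal, milk, fat)
    req = NutrientRequirements(ne=ne, mp=mp, ca=ca, p=p,
                               expected_dmi=dmi, estimated_milk=milk)
    req.validate()
    return req


def pen_average(reqs: Sequence[NutrientRequirements],
                lead_factor: float = 1.0) -> NutrientRequirements:
    """Arithmetic pen mean of each nutrient, then scaled by the lead factor.

    The lead factor (>= 1) formulates above the mean so the diet covers a
    larger share of the pen; it scales nutrients, not intake.
    """
    if not reqs:
        raise ValueError("cannot average an empty pen")
    if lead_factor < 1.0:
        raise ValueError(f"lead factor must be >= 1, got {lead_factor}")
    n = len(reqs)
    mean = NutrientRequirements(
        ne=sum(r.ne for r in reqs) / n,
        mp=sum(r.mp for r in reqs) / n,
        ca=sum(r.ca for r in reqs) / n,
        p=sum(r.p for r in reqs) / n,
        expected_dmi=sum(r.expected_dmi for r in reqs) / n,
        estimated_milk=sum(r.estimated_milk for r in reqs) / n,
    )
    return replace(mean.scaled(lead_factor),
                   expected_dmi=mean.expected_dmi,
                   estimated_milk=mean.estimated_milk)


# ---------------------------------------------------------------------------
# Least-cost formulation (SLSQP)
# ---------------------------------------------------------------------------


def _solve_once(req: NutrientRequirements, feeds: Sequence[FeedLibraryEntry],
                cfg: RationConfig, x0: np.ndarray | None):
    n = len(feeds)
    prices = np.array([f.price for f in feeds])
    nel = np.array([f.nel for f in feeds])
    mp = np.array([f.mp for f in feeds])
    ca = np.array([f.ca * 10.0 for f in feeds])   # % DM -> g/kg DM
    p_ = np.array([f.p * 10.0 for f in feeds])
    ndf = np.array([f.ndf for f in feeds])
    fndf = np.array([f.ndf if f.forage else 0.0 for f in feeds])
    fat = np.array([f.fat for f in feeds])
    dmi = req.expected_dmi

    bounds = [(0.0, min(f.max_inclusion, dmi)) for f in feeds]
    constraints = [
        {"type": "eq", "fun": lambda x: x.sum() - dmi, "jac": lambda x: np.ones(n)},
        {"type": "ineq", "fun": lambda x: nel @ x - req.ne, "jac": lambda x: nel},
        {"type": "ineq", "fun": lambda x: mp @ x - req.mp, "jac": lambda x: mp},
        {"type": "ineq", "fun": lambda x: ca @ x - req.ca, "jac": lambda x: ca},
        {"type": "ineq", "fun": lambda x: p_ @ x - req.p, "jac": lambda x: p_},
        {"type": "ineq", "fun": lambda x: ndf @ x / 100.0 - NDF_MIN_PCT / 100.0 * dmi,
         "jac": lambda x: ndf / 100.0},
        {"type": "ineq", "fun": lambda x: NDF_MAX_PCT / 100.0 * dmi - ndf @ x / 100.0,
         "jac": lambda x: -ndf / 100.0},
        {"type": "ineq", "fun": lambda x: fndf @ x / 100.0 - FORAGE_NDF_MIN_PCT / 100.0 * dmi,
         "jac": lambda x: fndf / 100.0},
        {"type": "ineq", "fun": lambda x: FAT_MAX_PCT / 100.0 * dmi - fat @ x / 100.0,
         "jac": lambda x: -fat / 100.0},
    ]
    if x0 is None:
        x0 = np.minimum(np.full(n, dmi / n), [b[1] for b in bounds])
    res = minimize(lambda x: prices @ x, x0, jac=lambda x: prices,
                   method="SLSQP", bounds=bounds, constraints=constraints,
                   options={"maxiter": cfg.solver_maxiter, "ftol": cfg.solver_tol})
    return res


def _constraint_report(x: np.ndarray, req: NutrientRequirements,
                       feeds: Sequence[FeedLibraryEntry],
                       rtol: float = 1e-6) -> list[str]:
    """Names of constraints violated beyond the relative tolerance."""
    dmi = req.expected_dmi
    total = x.sum()
    supplied = _supplies(x, feeds)
    scale = max(dmi, 1.0)
    bad = []
    if abs(total - dmi) > rtol * scale:
        bad.append(f"total DM ({total:.3f} != {dmi:.3f} kg)")
    for key, need in (("ne", req.ne), ("mp", req.mp), ("ca", req.ca), ("p", req.p)):
        if supplied[key] < need * (1.0 - rtol) - rtol:
            bad.append(f"{key} ({supplied[key]:.2f} < {need:.2f})")
    if supplied["ndf_pct"] < NDF_MIN_PCT * (1 - rtol) - 1e-9:
        bad.append(f"NDF >= {NDF_MIN_PCT}% ({supplied['ndf_pct']:.2f}%)")
    if supplied["ndf_pct"] > NDF_MAX_PCT * (1 + rtol) + 1e-9:
        bad.append(f"NDF <= {NDF_MAX_PCT}% ({supplied['ndf_pct']:.2f}%)")
    if supplied["forage_ndf_pct"] < FORAGE_NDF_MIN_PCT * (1 - rtol) - 1e-9:
        bad.append(f"forage NDF >= {FORAGE_NDF_MIN_PCT}% ({supplied['forage_ndf_pct']:.2f}%)")
    if supplied["fat_pct"] > FAT_MAX_PCT * (1 + rtol) + 1e-9:
        bad.append(f"fat <= {FAT_MAX_PCT}% ({supplied['fat_pct']:.2f}%)")
    return bad


def _supplies(x: np.ndarray, feeds: Sequence[FeedLibraryEntry]) -> dict[str, float]:
    total = x.sum()
    ne = sum(a * f.nel for a, f in zip(x, feeds))
    mp = sum(a * f.mp for a, f in zip(x, feeds))
    ca = sum(a * f.ca * 10 for a, f in zip(x, feeds))
    p = sum(a * f.p * 10 for a, f in zip(x, feeds))
    ndf = sum(a * f.ndf for a, f in zip(x, feeds)) / total if total else 0.0
    fndf = sum(a * f.ndf for a, f in zip(x, feeds) if f.forage) / total if total else 0.0
    fat = sum(a * f.fat for a, f in zip(x, feeds)) / total if total else 0.0
    return {"ne": ne, "mp": mp, "ca": ca, "p": p,
            "ndf_pct": ndf, "forage_ndf_pct": fndf, "fat_pct": fat}


def formulate_ration(req: NutrientRequirements, feeds: Sequence[FeedLibraryEntry],
                     cfg: RationConfig | None = None,
                     x0: np.ndarray | None = None) -> Ration:
    """Least-cost ration for a pen requirement (see module docstring)."""
    if not feeds:
        raise ValueError("feed library is empty")
    cfg = cfg or RationConfig()
    current = req
    for reduction in range(cfg.max_milk_reductions + 1):
        res = _solve_once(current, feeds, cfg, x0)
        x = np.maximum(res.x, 0.0)
        violated = _constraint_report(x, current, feeds)
        if res.success and not violated:
            supplied = _supplies(x, feeds)
            return Ration(
                feed_names=tuple(f.name for f in feeds),
                amounts=x,
                cost=float(np.array([f.price for f in feeds]) @ x),
                dmi=float(current.expected_dmi),
                supplied=supplied,
                milk_reductions=reduction,
                iterations=int(res.nit),
            )
        if current.estimated_milk <= 0:
            break
        current = current.with_milk_reduced(cfg.milk_step_kg)
    raise InfeasibleRationError(
        "no feasible ration after "
        f"{cfg.max_milk_reductions} milk reductions; binding constraints: "
        + "; ".join(violated or ["solver did not converge"])
    )


def assign_ration(ration: Ration, animals: Sequence[AnimalState],
                  predicted_dmi: Sequence[float]) -> float:
    """Apply a pen ration to its members; returns the pen's simulated total.

    Each member's expected intake is its own predicted DMI (the pen mean of
    these equals the ration's DM total, so a pen of identical animals gets
    exactly the ration DMI); the simulated intake applies the animal's
    feed-efficiency multiplier.  Diet composition is the pen ration for all
    members.
    """
    if not ration.converged:
        raise ValueError("cannot assign a non-converged ration")
    total = 0.0
    for animal, dmi in zip(animals, predicted_dmi):
        animal.expected_dmi = dmi
        animal.simulated_dmi = animal.rho * dmi
        animal.pen_id = animal.pen_id  # composition travels with the pen record
        total += animal.simulated_dmi
    return total
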