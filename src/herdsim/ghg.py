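"""Greenhouse-gas accounting: lagoon CH4, manure N2O and CO2-equivalents.

Manure-derived emissions use the IPCC Tier 2 anaerobic-lagoon form: lagoon
CH4 is volatile solids times the maximum methane-producing capacity (B0),
methane density and the methane conversion factor (MCF); direct N2O is
excreted N times an emission factor and the 44/28 N2O-N to N2O mass ratio.
CO2-equivalents use 100-yr GWPs of 30 (CH4) and 298 (N2O), applied in
consistent mass units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["GWPFactors", "LagoonParameters", "lagoon_ch4", "manure_n2o",
           "co2_equivalents", "scenario_ghg_summary"]


@dataclass(frozen=True)
class GWPFactors:
    ch4: float = 30.0
    n2o: float = 298.0

    def validate(self) -> None:
        if self.ch4 <= 0 or self.n2o <= 0:
            raise ValueError("GWP factors must be > 0")


@dataclass(frozen=True)
class LagoonParameters:
    """North-American uncovered anaerobic lagoon, IPCC Tier 2 defaults."""

    b0: float = 0.24            # m^3 CH4 / kg VS
    mcf: float = 0.71           # methane conversion factor, fraction
    ch4_density: float = 0.662  # kg/m^3 at 25 degC
    n2o_ef: float = 0.002       # kg N2O-N per kg excreted N
    n2o_mass_ratio: float = 44.0 / 28.0

    def validate(self) -> None:
        if not 0.0 <= self.mcf <= 1.0:
            raise ValueError(f"MCF must be in [0, 1], got {self.mcf}")
        if self.n2o_ef < 0 or self.b0 < 0 or self.ch4_density <= 0:
            raise ValueError("lagoon parameters must be non-negative")


def lagoon_ch4(vs_mass: float, params: LagoonParameters = LagoonParameters()) -> float:
    """Lagoon CH4 mass from volatile solids (same mass unit as the input)."""
    if vs_mass < 0:
        raise ValueError(f"VS mass must be >= 0, got {vs_mass}")
    return vs_mass * params.b0 * params.ch4_density * params.mcf


def manure_n2o(n_mass: float, params: LagoonParameters = LagoonParameters()) -> float:
    """Direct N2O mass from excreted manure N (same mass unit as the input)."""
    if n_mass < 0:
        raise ValueError(f"N mass must be >= 0, got {n_mass}")
    return n_mass * params.n2o_ef * params.n2o_mass_ratio


def co2_equivalents(ch4_mass: float, n2o_mass: float,
                    factors: GWPFactors = GWPFactors()) -> float:
    """CO2-eq = CH4 x GWP_CH4 + N2O x GWP_N2O (inputs in one common mass unit)."""
    if ch4_mass < 0 or n2o_mass < 0:
        raise ValueError("gas masses must be >= 0")
    return ch4_mass * factors.ch4 + n2o_mass * factors.n2o


def scenario_ghg_summary(
    annual_totals: Mapping[str, Mapping[str, float]],
    baseline: str = "Baseline",
    lagoon: LagoonParameters = LagoonParameters(),
    factors: GWPFactors = GWPFactors(),
) -> pd.DataFrame:
    """Annual GHG table for a set of common-seed scenarios.

    ``annual_totals`` maps scenario label -> totals in tonnes with keys
    ``milk_t``, ``simulated_intake_t``, ``enteric_ch4_t``, ``vs_t``, ``n_t``.
    Returns one row per scenario: component CH4/N2O masses, their CO2-eq,
    the total CO2-eq and the percent reduction relative to the baseline.
    """
    if baseline not in annual_totals:
        raise ValueError(f"baseline scenario {baseline!r} missing from results")
    lagoon.validate()
    factors.validate()

    rows = []
    for label, totals in annual_totals.items():
        enteric = totals["enteric_ch4_t"]
        lag = lagoon_ch4(totals["vs_t"], lagoon)
        n2o = manure_n2o(totals["n_t"], lagoon)
        total = co2_equivalents(enteric + lag, n2o, factors)
        rows.append({
            "scenario": label,
            "milk_t": totals["milk_t"],
            "simulated_intake_t": totals["simulated_intake_t"],
            "enteric_ch4_t": enteric,
            "enteric_co2eq_t": enteric * factors.ch4,
            "manure_vs_t": totals["vs_t"],
            "lagoon_ch4_t": lag,
            "lagoon_co2eq_t": lag * factors.ch4,
            "manure_n_t": totals["n_t"],
            "n2o_t": n2o,
            "n2o_co2eq_t": n2o * factors.n2o,
            "total_co2eq_t": total,
        })
    df = pd.DataFrame(rows).set_index("scenario")
    base_total = df.loc[baseline, "total_co2eq_t"]
    df["co2eq_reduction_pct"] = 100.0 * (1.0 - df["total_co2eq_t"] / base_total)
    base_intake = df.loc[baseline, "simulated_intake_t"]
    df["intake_reduction_pct"] = 100.0 * (1.0 - df["simulated_intake_t"] / base_intake)
    return df
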