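"""Shared physical constants and empirical-model coefficient tables.

All emission and excretion submodels are linear or saturating empirical
equations whose coefficients live here, in one place, so they can be
corrected or re-parameterised without touching the model code.

Provenance notes
----------------
The coefficient *forms* follow the sources the simulator is built around
(ASABE D384.2 manure characterisation; Boadi & Wittenberg's intake-methane
regression for growing cattle; Nennich et al. (2005) lactating-cow excretion
equations; Niu et al. (2018) intake-based enteric model; Mills et al. (2003)
Mitscherlich saturating model; IPCC (2006/2019) Tier 2).  The numeric values
are documented reconstructions calibrated to typical Holstein magnitudes
(e.g. ~25 kg DMI, ~400 g/d enteric CH4, ~68 kg/d manure for a lactating cow);
they are package defaults, not transcriptions, and every downstream summary
that matters scientifically is a within-run ratio that is insensitive to the
absolute levels.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------

#: Energy density of methane, MJ/g.  (55.65 kJ/g; the same constant appears
#: as the divisor 0.05565 in the calf methane equation.)
CH4_MJ_PER_G = 0.05565

#: Density of methane at 25 degC, g/L (equivalently kg/m^3).
CH4_G_PER_L = 0.662

#: Mcal -> MJ.
MJ_PER_MCAL = 4.184

#: Shrunk body weight as a fraction of full body weight.
SHRUNK_BW_FACTOR = 0.96

#: Dry matter fraction of whole milk / reconstituted milk replacer fed to calves.
MILK_DM_FRACTION = 0.125

# ---------------------------------------------------------------------------
# Manure excretion coefficients (per kg of body weight per day)
# ---------------------------------------------------------------------------
# ASABE D384.2-style "per unit animal mass" characterisation for the classes
# whose excretion is body-weight driven.  Units: kg/d per kg BW for manure,
# total solids (TS) and volatile solids (VS); g/d per kg BW for nitrogen.

ASABE_BW_COEFFICIENTS = {
    # class:        manure,  total_solids, volatile_solids, nitrogen_g
    "calf":   {"manure": 0.030, "ts": 0.0033, "vs": 0.0028, "n_g": 0.15},
    "heifer": {"manure": 0.046, "ts": 0.0053, "vs": 0.0045, "n_g": 0.23},
    "dry":    {"manure": 0.038, "ts": 0.0048, "vs": 0.0041, "n_g": 0.20},
}

# ---------------------------------------------------------------------------
# Lactating-cow excretion: linear equations in dry matter intake (kg DM/d)
# (Nennich et al. 2005 functional form: prediction from DMI).
# ---------------------------------------------------------------------------

LACTATING_EXCRETION = {
    "manure_slope": 2.63,      # kg manure / kg DMI
    "manure_intercept": 9.4,   # kg/d
    "ts_slope": 0.356,         # kg TS / kg DMI
    "ts_intercept": 0.0,       # kg/d
    "urine_slope": 1.15,       # kg urine / kg DMI
    "urine_intercept": -10.0,  # kg/d (clamped at 0)
    "n_slope": 12.9,           # g N / kg DMI
    "n_intercept": 113.5,      # g/d
    "vs_of_ts": 0.85,          # organic fraction of total solids
    "vs_degradable_fraction": 0.56,
}

# ---------------------------------------------------------------------------
# Enteric methane models
# ---------------------------------------------------------------------------

#: Heifer enteric methane (Boadi & Wittenberg form): CH4 (L/d) = a + b * DMI.
HEIFER_CH4_L_PER_D = {"intercept": 17.77, "slope": 42.79}

#: Lactating-cow regression (Niu et al. 2018 US-model form): intake plus
#: milk-production terms.  CH4 (g/d) = b0 + b1*DMI + b2*milk_fat_yield(kg/d).
NIU_US = {"intercept": 12.0, "dmi_slope": 14.0, "fat_yield_slope": 20.0}

#: Mitscherlich saturating model (Mills et al. 2003 "Mit3" form):
#: CH4 (MJ/d) = a - a * exp(-c * MEI) with MEI metabolisable energy intake (MJ/d).
MILLS_MIT3 = {"asymptote_mj": 45.98, "rate_per_mj": 0.003}

#: NEl -> ME conversion used to build metabolisable-energy intake for the
#: Mitscherlich model (NRC-style efficiency of ME use for lactation ~0.64).
NEL_TO_ME = 1.0 / 0.64

#: IPCC Tier 2: CH4 conversion factor Ym (% of gross energy intake).
IPCC_YM_PERCENT = 6.5

#: Gross energy of feed fractions, MJ/kg (protein, fat, carbohydrate) used to
#: compute dietary GE from composition; ash assumed fraction of DM.
GE_MJ_PER_KG = {"cp": 23.85, "fat": 39.33, "carbohydrate": 17.5}
ASH_FRACTION_DEFAULT = 0.08

# ---------------------------------------------------------------------------
# Calf feeding energetics (NRC 2001 calf-chapter style)
# ---------------------------------------------------------------------------

CALF_FEED_ENERGY = {
    "milk_me_mcal_per_kg_dm": 4.7,     # whole milk / milk replacer DM
    "starter_me_mcal_per_kg_dm": 3.1,
    "milk_cp_fraction": 0.24,
    "starter_cp_fraction": 0.20,
}

# ---------------------------------------------------------------------------
# Marginal nutrient cost of one kg of milk (used by the ration-formulation
# fallback that steps estimated milk down 0.5 kg at a time).
# ---------------------------------------------------------------------------

PER_KG_MILK = {
    "nel_mcal": 0.715,  # at ~3.8% fat, ~3.1% true protein
    "mp_g": 46.3,       # 31 g true protein / 0.67 MP efficiency
    "ca_g": 3.2,
    "p_g": 1.9,
}
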