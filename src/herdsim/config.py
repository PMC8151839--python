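"""Tiered configuration: simulation, herd, reproduction, efficiency, feeds.

Configuration is structured YAML read from up to three tiers (farm ->
module -> detail); later (deeper) files override earlier ones key-by-key.
Every key has a documented default; defaults that fill in for omitted keys
are logged so two runs can never silently differ in an unspecified input.

The feed library is a CSV with one row per feed (composition per kg DM).
The packaged fixture library covers the five ration feeds of the case study
plus the two calf feeds; its values are NRC (2001)-style reconstructions
documented in the file header.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .rng import BoundedDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "HerdConfig",
    "ProtocolConfig",
    "ReproProtocolConfig",
    "EfficiencyConfig",
    "CullingConfig",
    "RationConfig",
    "FeedLibraryEntry",
    "FullConfig",
    "load_config",
    "load_feed_library",
    "default_config_paths",
    "default_feed_library_path",
]


class ConfigError(ValueError):
    """A missing required key or an out-of-range configuration value."""


# ---------------------------------------------------------------------------
# Dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    start_date: date
    end_date: date
    random_seed: int = 17
    ration_interval: int = 3
    output_dir: Path = Path("output")
    weather: Sequence[float] | None = None  # optional daily temperature (degC)

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    def validate(self) -> None:
        if self.end_date <= self.start_date:
            raise ConfigError(
                f"simulation.end_date ({self.end_date}) must be after "
                f"start_date ({self.start_date})"
            )
        if self.ration_interval < 1:
            raise ConfigError(
                f"simulation.ration_interval must be >= 1, got {self.ration_interval}"
            )


@dataclass(frozen=True)
class ProtocolConfig:
    """Reproduction protocol for one animal group (heifers or cows)."""

    protocol: str = "estrus_detection"  # estrus_detection | synch_estrus_detection | timed_ai
    breeding_start: int = 400           # heifers: age (d); cows: DIM (voluntary waiting period)
    conception_probability: float = 0.45
    estrus_detection_probability: float = 0.60
    synch_first_service_delay: int = 10  # synch protocols: days to synchronized 1st service
    tai_service_interval: int = 42       # timed-AI: fixed re-service interval (d)

    def validate(self, label: str) -> None:
        if self.protocol not in ("estrus_detection", "synch_estrus_detection", "timed_ai"):
            raise ConfigError(
                f"reproduction.{label}.protocol must be one of estrus_detection, "
                f"synch_estrus_detection, timed_ai; got {self.protocol!r}"
            )
        for key in ("conception_probability", "estrus_detection_probability"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"reproduction.{label}.{key} must be in [0, 1], got {v}")
        if self.breeding_start <= 0:
            raise ConfigError(f"reproduction.{label}.breeding_start must be > 0")


@dataclass(frozen=True)
class ReproProtocolConfig:
    heifer: ProtocolConfig = field(default_factory=lambda: ProtocolConfig(
        breeding_start=400, conception_probability=0.55,
        estrus_detection_probability=0.65))
    cow: ProtocolConfig = field(default_factory=lambda: ProtocolConfig(
        breeding_start=60, conception_probability=0.40,
        estrus_detection_probability=0.60))
    estrous_cycle: BoundedDistribution = field(
        default_factory=lambda: BoundedDistribution(21.0, 2.0, 18.0, 25.0))
    gestation_length: BoundedDistribution = field(
        default_factory=lambda: BoundedDistribution(279.0, 5.0, 266.0, 294.0))
    pregnancy_check_days: tuple[int, ...] = (35, 90, 180)
    pregnancy_loss_rate: float = 0.12

    def validate(self) -> None:
        self.heifer.validate("heifer")
        self.cow.validate("cow")
        if list(self.pregnancy_check_days) != sorted(set(self.pregnancy_check_days)):
            raise ConfigError(
                "reproduction.pregnancy_check_days must be strictly increasing, "
                f"got {self.pregnancy_check_days}"
            )
        if not 0.0 <= self.pregnancy_loss_rate <= 1.0:
            raise ConfigError(
                f"reproduction.pregnancy_loss_rate must be in [0, 1], "
                f"got {self.pregnancy_loss_rate}"
            )

    @property
    def per_check_loss(self) -> float:
        """Per-check loss probability q with (1-q)^k = 1 - total loss rate."""
        k = max(len(self.pregnancy_check_days), 1)
        return 1.0 - (1.0 - self.pregnancy_loss_rate) ** (1.0 / k)


@dataclass(frozen=True)
class CullingConfig:
    """Annual per-reason health/production culling probabilities (cows).

    Applied as daily hazards (annual/365).  Reproduction-failure culls are
    rule-based, not drawn: open heifers past ``heifer_repro_cull_age`` and
    open cows past ``cow_repro_cull_dim`` leave the herd deterministically.
    """

    annual_probabilities: Mapping[str, float] = field(default_factory=lambda: {
        "low_production": 0.060,
        "lameness": 0.045,
        "injury": 0.074,
        "mastitis": 0.054,
        "disease": 0.000,
        "udder": 0.017,
        "unknown": 0.038,
    })

    def validate(self) -> None:
        for reason, p in self.annual_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"culling.{reason} must be in [0, 1], got {p}")

    @property
    def daily_hazards(self) -> dict[str, float]:
        return {r: p / 365.0 for r, p in self.annual_probabilities.items()}


@dataclass(frozen=True)
class EfficiencyConfig:
    """Distribution of the per-animal feed-efficiency multiplier rho.

    rho scales the model-predicted (expected) DMI into the simulated DMI;
    rho < 1 is a more efficient animal (negative residual feed intake).
    """

    mean: float = 1.0
    sd: float = 0.06
    lower: float = 0.7
    upper: float = 1.3
    scenario: str = "Baseline"

    SCENARIO_MEANS = {"Baseline": 1.00, "High": 0.94, "VeryHigh": 0.88}

    @classmethod
    def from_scenario(cls, scenario: str, sd: float = 0.06) -> "EfficiencyConfig":
        try:
            mean = cls.SCENARIO_MEANS[scenario]
        except KeyError:
            raise ConfigError(
                f"unknown efficiency scenario {scenario!r}; "
                f"expected one of {sorted(cls.SCENARIO_MEANS)}"
            ) from None
        return cls(mean=mean, sd=sd, scenario=scenario)

    def validate(self) -> None:
        if not 0.0 < self.lower <= self.mean <= self.upper:
            raise ConfigError(
                f"efficiency bounds must satisfy 0 < lower <= mean <= upper, "
                f"got lower={self.lower}, mean={self.mean}, upper={self.upper}"
            )
        if self.sd < 0:
            raise ConfigError(f"efficiency.sd must be >= 0, got {self.sd}")

    @property
    def distribution(self) -> BoundedDistribution:
        return BoundedDistribution(self.mean, self.sd, self.lower, self.upper)


@dataclass(frozen=True)
class RationConfig:
    lead_factor: float = 1.0
    max_milk_reductions: int = 20
    milk_step_kg: float = 0.5
    solver_tol: float = 1e-8
    solver_maxiter: int = 100

    def validate(self) -> None:
        if self.lead_factor < 1.0:
            raise ConfigError(f"ration.lead_factor must be >= 1, got {self.lead_factor}")
        if self.max_milk_reductions < 0:
            raise ConfigError("ration.max_milk_reductions must be >= 0")


@dataclass(frozen=True)
class HerdConfig:
    target_lactating_cows: int = 200
    dry_fraction: float = 0.15          # expected dry share of the cow herd
    breed: str = "Holstein"

    mature_bw: BoundedDistribution = field(
        default_factory=lambda: BoundedDistribution(680.0, 55.0, 520.0, 820.0))
    calf_birth_bw: BoundedDistribution = field(
        default_factory=lambda: BoundedDistribution(42.0, 4.0, 30.0, 55.0))

    weaning_day: int = 56
    weaning_period: int = 14
    keep_female_calf_rate: float = 1.0
    stillbirth_probability: float = 0.06
    female_calf_probability: float = 0.5
    pre_fresh_period: int = 30          # transition period before expected calving
    dry_off_day: int = 220              # days in pregnancy at dry-off
    heifer_repro_cull_age: int = 700    # open heifers older than this are culled
    cow_repro_cull_dim: int = 400       # open cows past this DIM are culled

    milk_fat_pct: float = 3.8
    milk_protein_pct: float = 3.1
    # Wood lactation-curve parameters (a, b, c) per parity group
    lactation_curve: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "primiparous": (17.5, 0.22, 0.0030),
            "multiparous": (21.5, 0.22, 0.0034),
        })
    estimated_lactation_length: int = 340  # planning horizon for growth milestones

    calf_target_adg: float = 0.8        # kg/d pre-weaning growth target
    bw_milestones: Mapping[str, float] = field(default_factory=lambda: {
        "first_pregnancy": 0.55,        # fraction of mature shrunk BW
        "first_calving": 0.82,
        "end_first_lactation": 0.92,
        "end_second_lactation": 1.00,
    })

    n_lactating_pens: int = 3           # DIM-tercile pens for lactating cows
    culling: CullingConfig = field(default_factory=CullingConfig)
    use_pre_drawn_exit: bool = False    # optional pre-drawn longevity at birth

    @property
    def target_total_cows(self) -> int:
        return round(self.target_lactating_cows / (1.0 - self.dry_fraction))

    def default_starting_counts(self) -> dict[str, int]:
        """Steady-state-shaped starting class counts for the cow target.

        The ratios approximate the standing stock implied by the default
        reproduction and culling parameters when all female calves are kept.
        """
        cows = self.target_total_cows
        return {
            "cow": cows,
            "heifer_3": max(2, round(0.04 * cows)),
            "heifer_2": round(0.36 * cows),
            "heifer_1": round(0.40 * cows),
            "calf": round(0.07 * cows),
        }

    def validate(self) -> None:
        for key in ("keep_female_calf_rate", "stillbirth_probability",
                    "female_calf_probability", "dry_fraction"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"herd.{key} must be in [0, 1], got {v}")
        if self.weaning_day <= 0:
            raise ConfigError(f"herd.weaning_day must be > 0, got {self.weaning_day}")
        if self.weaning_period <= 0 or self.weaning_period > self.weaning_day:
            raise ConfigError(
                f"herd.weaning_period must be in (0, weaning_day], got {self.weaning_period}"
            )
        if self.target_lactating_cows <= 0:
            raise ConfigError("herd.target_lactating_cows must be > 0")
        if self.dry_off_day <= 0:
            raise ConfigError("herd.dry_off_day must be > 0")
        for group, params in self.lactation_curve.items():
            if any(p < 0 for p in params):
                raise ConfigError(
                    f"herd.lactation_curve.{group} parameters must be >= 0, got {params}"
                )
        self.culling.validate()

    def wood_params(self, parity: int) -> tuple[float, float, float]:
        key = "primiparous" if parity <= 1 else "multiparous"
        return tuple(self.lactation_curve[key])


@dataclass(frozen=True)
class FeedLibraryEntry:
    """One feed: price and composition per kg of dry matter."""

    name: str
    price: float          # $/kg DM
    dm: float             # DM fraction of as-fed
    nel: float            # Mcal NEl/kg DM
    mp: float             # g metabolisable protein/kg DM
    cp: float             # crude protein, % of DM
    ndf: float            # % of DM
    forage: bool          # contributes forage NDF iff True
    fat: float            # % of DM
    ca: float             # % of DM
    p: float              # % of DM
    starch: float         # % of DM
    max_inclusion: float  # kg DM/d (inf = unconstrained)

    def validate(self) -> None:
        for key in ("nel", "mp", "cp", "ndf", "fat", "ca", "p", "starch"):
            if getattr(self, key) < 0:
                raise ConfigError(f"feed {self.name!r}: {key} must be >= 0")
        if self.ndf > 100:
            raise ConfigError(f"feed {self.name!r}: NDF must be <= 100% DM, got {self.ndf}")
        if self.price < 0:
            raise ConfigError(f"feed {self.name!r}: price must be >= 0")
        if not 0 < self.dm <= 1:
            raise ConfigError(f"feed {self.name!r}: DM fraction must be in (0, 1]")


@dataclass(frozen=True)
class FullConfig:
    simulation: SimulationConfig
    herd: HerdConfig
    reproduction: ReproProtocolConfig
    efficiency: EfficiencyConfig
    ration: RationConfig
    feeds: tuple[FeedLibraryEntry, ...]
    enteric_model: str = "niu"

    def validate(self) -> None:
        self.simulation.validate()
        self.herd.validate()
        self.reproduction.validate()
        self.efficiency.validate()
        self.ration.validate()
        for feed in self.feeds:
            feed.validate()
        if self.enteric_model not in ("niu", "mills", "ipcc"):
            raise ConfigError(
                f"enteric_model must be one of niu, mills, ipcc; got {self.enteric_model!r}"
            )

    def with_scenario(self, scenario: str) -> "FullConfig":
        return replace(self, efficiency=EfficiencyConfig.from_scenario(
            scenario, sd=self.efficiency.sd))


# ---------------------------------------------------------------------------
# YAML tier loading
# ---------------------------------------------------------------------------


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def _require(mapping: Mapping, key: str, context: str) -> Any:
    if key not in mapping:
        raise ConfigError(f"missing required key {context}.{key}")
    return mapping[key]


def _dist(raw: Mapping | None, default: BoundedDistribution, context: str) -> BoundedDistribution:
    if raw is None:
        logger.debug("config default used for %s: %s", context, default)
        return default
    try:
        return BoundedDistribution(
            float(raw.get("mean", default.mean)),
            float(raw.get("sd", default.sd)),
            float(raw.get("lower", default.lower)),
            float(raw.get("upper", default.upper)),
        )
    except ValueError as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def _parse_date(value: Any, context: str) -> date:
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError as exc:
        raise ConfigError(f"{context} must be an ISO date, got {value!r}") from exc


def _build(cls, raw: Mapping, context: str, **converted: Any):
    """Construct a (frozen) config dataclass from raw keys + pre-converted ones."""
    import dataclasses

    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = dict(converted)
    for key, value in raw.items():
        if key in converted:
            continue
        if key not in names:
            raise ConfigError(f"unknown key {context}.{key}")
        kwargs[key] = value
    defaults_used = names - set(kwargs)
    if defaults_used:
        logger.debug("config defaults used for %s: %s", context, sorted(defaults_used))
    return cls(**kwargs)


def load_config(
    paths: Sequence[str | Path],
    feed_library: str | Path | None = None,
) -> FullConfig:
    """Read tiered YAML files (later files override earlier) plus the feed CSV.

    Raises :class:`ConfigError` for missing files, missing required keys and
    out-of-range values, naming the offending key.
    """
    merged: dict = {}
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"configuration file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"configuration file {path} must contain a mapping")
        merged = _deep_merge(merged, raw)
    return config_from_mapping(merged, feed_library=feed_library)


def config_from_mapping(
    merged: Mapping,
    feed_library: str | Path | None = None,
) -> FullConfig:
    sim_raw = dict(merged.get("simulation", {}))
    start = _parse_date(sim_raw.pop("start_date", "2020-01-01"), "simulation.start_date")
    end = _parse_date(sim_raw.pop("end_date", "2020-12-31"), "simulation.end_date")
    out_dir = Path(sim_raw.pop("output_dir", "output"))
    simulation = _build(SimulationConfig, sim_raw, "simulation",
                        start_date=start, end_date=end, output_dir=out_dir)

    herd_raw = dict(merged.get("herd", {}))
    mature = _dist(herd_raw.pop("mature_bw", None), HerdConfig().mature_bw, "herd.mature_bw")
    calf = _dist(herd_raw.pop("calf_birth_bw", None), HerdConfig().calf_birth_bw,
                 "herd.calf_birth_bw")
    lact_raw = herd_raw.pop("lactation_curve", None)
    if lact_raw is None:
        lact = HerdConfig().lactation_curve
    else:
        lact = {
            group: (float(p["a"]), float(p["b"]), float(p["c"]))
            if isinstance(p, Mapping) else tuple(float(x) for x in p)
            for group, p in lact_raw.items()
        }
    cull_raw = herd_raw.pop("culling", None)
    if cull_raw is None:
        culling = CullingConfig()
    else:
        probs = dict(CullingConfig().annual_probabilities)
        probs.update({k: float(v) for k, v in cull_raw.items()})
        culling = CullingConfig(annual_probabilities=probs)
    herd = _build(HerdConfig, herd_raw, "herd",
                  mature_bw=mature, calf_birth_bw=calf,
                  lactation_curve=lact, culling=culling)

    repro_raw = dict(merged.get("reproduction", {}))
    defaults = ReproProtocolConfig()
    heifer = _build(ProtocolConfig, repro_raw.pop("heifer", {}) or {},
                    "reproduction.heifer") if "heifer" in repro_raw else defaults.heifer
    cow = _build(ProtocolConfig, repro_raw.pop("cow", {}) or {},
                 "reproduction.cow") if "cow" in repro_raw else defaults.cow
    cycle = _dist(repro_raw.pop("estrous_cycle", None), defaults.estrous_cycle,
                  "reproduction.estrous_cycle")
    gl = _dist(repro_raw.pop("gestation_length", None), defaults.gestation_length,
               "reproduction.gestation_length")
    checks = tuple(repro_raw.pop("pregnancy_check_days", defaults.pregnancy_check_days))
    reproduction = _build(ReproProtocolConfig, repro_raw, "reproduction",
                          heifer=heifer, cow=cow, estrous_cycle=cycle,
                          gestation_length=gl, pregnancy_check_days=checks)

    eff_raw = dict(merged.get("efficiency", {}))
    if "scenario" in eff_raw and "mean" not in eff_raw:
        efficiency = EfficiencyConfig.from_scenario(
            eff_raw["scenario"], sd=float(eff_raw.get("sd", 0.06)))
    else:
        efficiency = _build(EfficiencyConfig, eff_raw, "efficiency")

    ration = _build(RationConfig, dict(merged.get("ration", {})), "ration")
    enteric = str(merged.get("enteric_model", "niu"))

    feeds = load_feed_library(feed_library or default_feed_library_path())

    cfg = FullConfig(simulation=simulation, herd=herd, reproduction=reproduction,
                     efficiency=efficiency, ration=ration, feeds=feeds,
                     enteric_model=enteric)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Feed library
# ---------------------------------------------------------------------------

_FEED_COLUMNS = ["name", "price", "dm", "nel", "mp", "cp", "ndf", "forage",
                 "fat", "ca", "p", "starch", "max_inclusion"]


def load_feed_library(path: str | Path) -> tuple[FeedLibraryEntry, ...]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"feed library not found: {path}")
    df = pd.read_csv(path, comment="#")
    missing = set(_FEED_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"feed library {path} missing columns: {sorted(missing)}")
    feeds = []
    for row in df.itertuples(index=False):
        max_inc = float(row.max_inclusion)
        feeds.append(FeedLibraryEntry(
            name=str(row.name), price=float(row.price), dm=float(row.dm),
            nel=float(row.nel), mp=float(row.mp), cp=float(row.cp),
            ndf=float(row.ndf), forage=bool(int(row.forage)), fat=float(row.fat),
            ca=float(row.ca), p=float(row.p), starch=float(row.starch),
            max_inclusion=math.inf if max_inc < 0 else max_inc,
        ))
    for feed in feeds:
        feed.validate()
    return tuple(feeds)


def _data_path(name: str) -> Path:
    return Path(resources.files("herdsim").joinpath("data", name))  # type: ignore[arg-type]


def default_feed_library_path() -> Path:
    return _data_path("feed_library.csv")


def default_config_paths() -> list[Path]:
    """The packaged three-tier fixture configuration (farm, herd, animal)."""
    return [_data_path("farm.yaml"), _data_path("herd.yaml"), _data_path("animal.yaml")]


def default_config() -> FullConfig:
    return load_config(default_config_paths())
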