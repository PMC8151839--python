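"""Output CSVs and SQLite persistence of simulated herds.

The daily tables are plain CSVs that round-trip bit-exactly through pandas
(floats are written at full shortest-round-trip precision).  Herd state is
stored in SQLite with one row per animal plus the replacement-market table,
so an initialization run can be built once and reused across scenarios.
"""

from __future__ import annotations

import sqlite3
from dataclasses import fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .animals import AnimalClass, AnimalState, CowState
from .engine import InitializationHerd, MarketEntry, ScenarioResult

__all__ = [
    "write_daily_outputs",
    "read_daily_outputs",
    "persist_herd",
    "load_herd",
    "persist_initialization",
    "load_initialization",
]


# ---------------------------------------------------------------------------
# CSV outputs
# ---------------------------------------------------------------------------


def write_daily_outputs(result: ScenarioResult, outdir: str | Path) -> dict[str, Path]:
    """Write the daily herd table, the ration log and the annual summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    daily = outdir / f"daily_{result.label}.csv"
    result.daily.to_csv(daily, index=False)
    paths["daily"] = daily

    rations = outdir / f"rations_{result.label}.csv"
    pd.DataFrame(result.ration_log).to_csv(rations, index=False)
    paths["rations"] = rations

    annual = outdir / f"annual_{result.label}.csv"
    pd.DataFrame([result.annual]).to_csv(annual, index=False)
    paths["annual"] = annual
    return paths


def read_daily_outputs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# SQLite persistence
# ---------------------------------------------------------------------------

_ANIMAL_FIELDS = [f.name for f in fields(AnimalState)]


def _animal_row(a: AnimalState) -> tuple:
    row = []
    for name in _ANIMAL_FIELDS:
        v = getattr(a, name)
        if isinstance(v, (AnimalClass, CowState)):
            v = v.value
        elif isinstance(v, bool):
            v = int(v)
        row.append(v)
    return tuple(row)


def _animal_from_row(row: Sequence) -> AnimalState:
    data = dict(zip(_ANIMAL_FIELDS, row))
    data["animal_class"] = AnimalClass(data["animal_class"])
    data["cow_state"] = CowState(data["cow_state"]) if data["cow_state"] else None
    data["alive"] = bool(data["alive"])
    return AnimalState(**data)


def persist_herd(animals: Iterable[AnimalState], path: str | Path) -> None:
    """Store animals in SQLite; ``load_herd`` reproduces every field exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.exists():
        path.unlink()
    with sqlite3.connect(path) as con:
        cols = ", ".join(_ANIMAL_FIELDS)
        marks = ", ".join("?" * len(_ANIMAL_FIELDS))
        con.execute(f"CREATE TABLE animals ({cols})")
        con.executemany(f"INSERT INTO animals VALUES ({marks})",
                        [_animal_row(a) for a in animals])


def load_herd(path: str | Path) -> list[AnimalState]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"herd database not found: {path}")
    try:
        with sqlite3.connect(path) as con:
            rows = con.execute(
                f"SELECT {', '.join(_ANIMAL_FIELDS)} FROM animals").fetchall()
    except sqlite3.DatabaseError as exc:
        raise ValueError(f"corrupt herd database {path}: {exc}") from exc
    return [_animal_from_row(r) for r in rows]


_MARKET_FIELDS = [f.name for f in fields(MarketEntry)]


def persist_initialization(init: InitializationHerd, path: str | Path) -> None:
    """Store the full initialization pool: animals, market, metadata."""
    persist_herd(init.animals, path)
    with sqlite3.connect(Path(path)) as con:
        cols = ", ".join(_MARKET_FIELDS)
        marks = ", ".join("?" * len(_MARKET_FIELDS))
        con.execute(f"CREATE TABLE market ({cols})")
        con.executemany(
            f"INSERT INTO market VALUES ({marks})",
            [tuple(getattr(m, f) for f in _MARKET_FIELDS) for m in init.market])
        con.execute("CREATE TABLE meta (n_days INTEGER, n_founders INTEGER)")
        con.execute("INSERT INTO meta VALUES (?, ?)", (init.n_days, init.n_founders))


def load_initialization(path: str | Path) -> InitializationHerd:
    animals = load_herd(path)
    with sqlite3.connect(Path(path)) as con:
        market_rows = con.execute(
            f"SELECT {', '.join(_MARKET_FIELDS)} FROM market").fetchall()
        n_days, n_founders = con.execute(
            "SELECT n_days, n_founders FROM meta").fetchone()
    market = [MarketEntry(**dict(zip(_MARKET_FIELDS, r))) for r in market_rows]
    return InitializationHerd(animals=animals, market=market,
                              n_days=n_days, n_founders=n_founders)
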