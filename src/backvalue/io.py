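"""File formats: CSV for tabular data, JSON/YAML for config and plans.

All writers produce plain-text files with documented headers; readers
validate required columns (naming any missing one), check record-level
invariants (naming the offending row), and preserve unknown columns.
``write(read(x))`` is value-identical for every format.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .config import SimulationConfig
from .equity import AgeDeprivationMatrix
from .errors import InputError
from .standardise import StandardisedRate
from .star import Disinvestment, FrontierPoint, Intervention, ReallocationPlan

EPISODE_COLUMNS = [
    "patient_id", "age", "sex", "practice_id", "imd_decile",
    "fiscal_year", "event_class", "intervention_id",
]
REGISTER_COLUMNS = [
    "practice_id", "age_band", "sex", "imd_decile", "count",
    "deprivation_score",
]
PORTFOLIO_COLUMNS = [
    "id", "name", "n_treated", "fixed_cost", "variable_cost_per_person",
    "qaly_per_person", "evidence_category", "provider",
]
RATE_COLUMNS = [
    "unit_id", "rate", "ci_low", "ci_high", "n_events", "denominator",
    "ci_method",
]


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s): {missing}")


def _row_error(path, df_index: int, msg: str) -> InputError:
    # +2: one for the header line, one for 1-based numbering
    return InputError(f"{path}, line {df_index + 2}: {msg}")


# --------------------------------------------------------------------------
# episodes / registers


def write_episodes(episodes: pd.DataFrame, path) -> None:
    episodes.to_csv(path, index=False)


def _first_bad(mask: pd.Series) -> int:
    return int(mask.idxmax())


def read_episodes(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip",
                     dtype={"intervention_id": str, "patient_id": str})
    _require(df, EPISODE_COLUMNS, path)
    bad = ~df["imd_decile"].between(1, 10)
    if bad.any():
        i = _first_bad(bad)
        raise _row_error(path, i, f"imd_decile {df.at[i, 'imd_decile']} "
                                  "outside 1..10")
    bad = df["age"] < 18
    if bad.any():
        i = _first_bad(bad)
        raise _row_error(path, i, f"age {df.at[i, 'age']} below 18")
    bad = ~df["sex"].isin(["F", "M"])
    if bad.any():
        i = _first_bad(bad)
        raise _row_error(path, i, f"sex must be F or M, got {df.at[i, 'sex']!r}")
    bad = ~df["event_class"].isin(["attendance", "procedure"])
    if bad.any():
        i = _first_bad(bad)
        raise _row_error(path, i,
                         f"bad event_class {df.at[i, 'event_class']!r}")
    return df


def write_registers(registers: pd.DataFrame, path) -> None:
    registers.to_csv(path, index=False)


def read_registers(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require(df, REGISTER_COLUMNS, path)
    bad = df["count"] < 0
    if bad.any():
        i = _first_bad(bad)
        raise _row_error(path, i, f"count: negative value {df.at[i, 'count']}")
    bad = ~df["imd_decile"].between(1, 10)
    if bad.any():
        i = _first_bad(bad)
        raise _row_error(path, i, f"imd_decile {df.at[i, 'imd_decile']} "
                                  "outside 1..10")
    return df


# --------------------------------------------------------------------------
# portfolio


def write_portfolio(portfolio: Sequence[Intervention], path) -> None:
    pd.DataFrame([asdict(iv) for iv in portfolio])[PORTFOLIO_COLUMNS].to_csv(
        path, index=False
    )


def read_portfolio(path) -> list[Intervention]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require(df, [c for c in PORTFOLIO_COLUMNS if c != "provider"], path)
    out = []
    for i, row in df.iterrows():
        for col in ("n_treated", "fixed_cost", "variable_cost_per_person"):
            if float(row[col]) < 0:
                raise _row_error(path, i, f"{col}: negative value {row[col]}")
        try:
            out.append(Intervention(
                id=str(row["id"]), name=str(row["name"]),
                n_treated=float(row["n_treated"]),
                fixed_cost=float(row["fixed_cost"]),
                variable_cost_per_person=float(row["variable_cost_per_person"]),
                qaly_per_person=float(row["qaly_per_person"]),
                evidence_category=str(row["evidence_category"]),
                provider=(str(row["provider"]) or None)
                if "provider" in df.columns else None,
            ))
        except InputError as exc:
            raise _row_error(path, i, str(exc)) from exc
    return out


# --------------------------------------------------------------------------
# rates / frontier / matrix

def write_rates(rates: Sequence[StandardisedRate], path,
                years: Sequence[str] | None = None) -> None:
    df = pd.DataFrame([asdict(r) for r in rates])[RATE_COLUMNS]
    df["years"] = ";".join(years or [])
    df.to_csv(path, index=False)


def read_rates(path) -> list[StandardisedRate]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    _require(df, RATE_COLUMNS, path)
    return [
        StandardisedRate(
            unit_id=str(r["unit_id"]), rate=float(r["rate"]),
            ci_low=float(r["ci_low"]), ci_high=float(r["ci_high"]),
            n_events=int(r["n_events"]), denominator=float(r["denominator"]),
            ci_method=str(r["ci_method"]),
        )
        for _, r in df.iterrows()
    ]


def write_frontier(points: Sequence[FrontierPoint], path) -> None:
    pd.DataFrame([asdict(p) for p in points]).to_csv(path, index=False)


def write_matrix(matrix: AgeDeprivationMatrix, path) -> None:
    matrix.cells.rename_axis("age_band").to_csv(path)


# --------------------------------------------------------------------------
# plan / config

def write_plan(plan: ReallocationPlan, path) -> None:
    payload = {
        "budget_mode": plan.budget_mode,
        "envelope": plan.envelope,
        "disinvestments": [asdict(d) for d in plan.disinvestments],
        "reinvestments": [asdict(iv) for iv in plan.reinvestments],
    }
    path = Path(path)
    text = (yaml.safe_dump(payload, sort_keys=False)
            if path.suffix in (".yaml", ".yml")
            else json.dumps(payload, indent=2))
    path.write_text(text)


def read_plan(path) -> ReallocationPlan:
    path = Path(path)
    raw = (yaml.safe_load(path.read_text())
           if path.suffix in (".yaml", ".yml")
           else json.loads(path.read_text()))
    return ReallocationPlan(
        disinvestments=tuple(Disinvestment(**d)
                             for d in raw.get("disinvestments", [])),
        reinvestments=tuple(Intervention(**iv)
                            for iv in raw.get("reinvestments", [])),
        budget_mode=raw.get("budget_mode", "released_only"),
        envelope=raw.get("envelope"),
    )


def write_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    payload = config.model_dump(mode="json")
    text = (yaml.safe_dump(payload, sort_keys=False)
            if path.suffix in (".yaml", ".yml")
            else json.dumps(payload, indent=2))
    path.write_text(text)


def read_config(path) -> SimulationConfig:
    path = Path(path)
    raw = (yaml.safe_load(path.read_text())
           if path.suffix in (".yaml", ".yml")
           else json.loads(path.read_text()))
    return SimulationConfig(**raw)
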