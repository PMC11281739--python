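"""End-to-end pipeline: simulate -> standardise -> variation -> equity ->
value reallocation, with file outputs, a combined JSON report and a run
manifest carrying content checksums for every written file.

All randomness flows from the single configured seed; the same config run
twice produces byte-identical data outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__, equity, io, star, synth, variation
from .config import SimulationConfig
from .errors import BackValueError

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    esp_version: str
    ci_method: str
    package_version: str
    started: str
    finished: str = ""
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> {sha256, rows}
    failed_stage: str | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: RunManifest, path: Path, rows: int | None = None) -> None:
    manifest.outputs[path.name] = {"sha256": _sha256(path), "rows": rows}


def run_pipeline(config: SimulationConfig | str | Path, out_dir) -> RunManifest:
    """Run every stage in order, writing all outputs under ``out_dir``.

    Stage outputs: the synthetic CSVs, per-practice and per-decile rate
    CSVs, the age-deprivation matrix, the frontier CSV, and ``report.json``
    with the headline quantities (fold variation, deprivation correlation,
    decile gradient, modal-age gap, baseline and post-plan portfolio
    summaries).  Any stage failure aborts with the stage name and cause.
    """
    if not isinstance(config, SimulationConfig):
        config = io.read_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        seed=config.seed,
        esp_version="ESP2013",
        ci_method="wilson (crude) / dobson (standardised)",
        package_version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    stage = "simulate"
    try:
        registers = synth.generate_registers(config)
        episodes = synth.generate_episodes(config, registers)
        io.write_registers(registers, out / "registers.csv")
        io.write_episodes(episodes, out / "episodes.csv")
        io.write_config(config, out / "config.json")
        _record(manifest, out / "registers.csv", len(registers))
        _record(manifest, out / "episodes.csv", len(episodes))
        _record(manifest, out / "config.json")
        log.info("simulate: %d practices, %d episodes",
                 config.n_practices, len(episodes))

        stage = "variation"
        rates = variation.practice_rates(episodes, registers)
        fold = variation.fold_variation(rates)
        corr = variation.deprivation_correlation(rates, registers)
        io.write_rates(rates, out / "practice_rates.csv", config.years)
        _record(manifest, out / "practice_rates.csv", len(rates))
        log.info("variation: fold=%.2f over %d practices (%d zero-rate "
                 "excluded)", fold.fold_variation, fold.n_units,
                 len(fold.excluded_units))

        stage = "equity"
        dec_rates = equity.decile_rates(episodes, registers)
        first = equity.first_procedure_per_patient(episodes)
        matrix = equity.age_deprivation_matrix(first)
        io.write_rates(dec_rates, out / "decile_rates.csv", config.years)
        io.write_matrix(matrix, out / "age_deprivation_matrix.csv")
        _record(manifest, out / "decile_rates.csv", len(dec_rates))
        _record(manifest, out / "age_deprivation_matrix.csv",
                len(matrix.cells))
        gradient = dec_rates[0].rate / dec_rates[-1].rate \
            if dec_rates[-1].rate > 0 else float("nan")
        log.info("equity: decile-1/decile-10 rate ratio %.2f", gradient)

        stage = "star"
        baseline = synth.synthetic_baseline_portfolio()
        reinvest = synth.generate_portfolio(config)
        plan = star.default_reallocation_plan(reinvest)
        base_summary = star.portfolio_summary(baseline)
        new_portfolio, post_summary, deltas = star.apply_reallocation(
            baseline, plan
        )
        frontier = star.build_frontier(
            [star.value_triangle(iv) for iv in new_portfolio],
            categories={iv.id: iv.evidence_category for iv in new_portfolio},
        )
        io.write_portfolio(baseline, out / "portfolio_baseline.csv")
        io.write_portfolio(new_portfolio, out / "portfolio_post_plan.csv")
        io.write_plan(plan, out / "plan.json")
        io.write_frontier(frontier, out / "frontier.csv")
        for name, n in (("portfolio_baseline.csv", len(baseline)),
                        ("portfolio_post_plan.csv", len(new_portfolio)),
                        ("plan.json", None), ("frontier.csv", len(frontier))):
            _record(manifest, out / name, n)
        log.info("star: %.0f -> %.0f QALYs (%.0f%% change)",
                 deltas["qaly_before"], deltas["qaly_after"],
                 deltas["qaly_change_pct"])

        stage = "report"
        report = {
            "fold_variation": {
                "fold": fold.fold_variation,
                "n_practices": fold.n_units,
                "min_rate": fold.min_rate,
                "max_rate": fold.max_rate,
                "excluded_units": list(fold.excluded_units),
            },
            "deprivation_correlation": {
                "coefficient": corr.coefficient,
                "method": corr.method,
            },
            "decile_gradient": {
                "ratio_decile1_decile10": gradient,
                "rates_per_10000": {r.unit_id: r.rate for r in dec_rates},
            },
            "modal_age": {
                "by_group": {str(k): v for k, v in matrix.modal_band.items()},
                "gap_decades": matrix.modal_gap_decades(),
            },
            "portfolio": {
                "baseline": asdict(base_summary),
                "post_plan": asdict(post_summary),
                "deltas": deltas,
            },
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        _record(manifest, out / "report.json")
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.finished = datetime.now(timezone.utc).isoformat()
        (out / "manifest.json").write_text(
            json.dumps(asdict(manifest), indent=2)
        )
        raise BackValueError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2))
    return manifest
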