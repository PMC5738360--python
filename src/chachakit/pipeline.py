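"""Reproducible generate -> fit -> report runs driven by a JSON config.

A :class:`RunConfig` holds optional stage blocks (grid, dose-response series,
dox titration, qPCR, reversibility pulse); :func:`run_pipeline` executes every
present stage, writing CSV tables, fit JSONs and a plain-text log (package
versions, seed, per-stage timing) into the output directory. Every stochastic
stage draws its seed from the config; when no seed is given one is generated
from OS entropy and echoed in the log and the run metadata, so any run can be
replayed exactly.
"""

from __future__ import annotations

import json
import platform
import secrets
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .dynamics import Schedule, simulate_chacha
from .fitting import fit_dox_hill, fit_hill_dose_response, fit_steady_state_model
from .io import write_measurement_table, write_qpcr_plate
from .params import (
    ChaChaRateParams,
    DoseResponseParams,
    DoxInductionParams,
    ParamsBase,
    SteadyStateParams,
)
from .qpcr import analyze_plate
from .synthetic_data import (
    NoiseModel,
    generate_dose_response,
    generate_dox_induction,
    generate_grid_dataset,
    generate_qpcr_plate,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NoiseBlock(_Block):
    kind: str = "multiplicative-lognormal"
    cv_or_sd: float = 0.10


class GridBlock(_Block):
    truth: SteadyStateParams
    adaptor_levels: list[float]
    ligand_doses: list[float]
    replicates: int = 3


class DoseResponseBlock(_Block):
    truth: DoseResponseParams
    doses: list[float]
    replicates: int = 3


class DoxBlock(_Block):
    truth: DoxInductionParams
    dox_levels: list[float]
    replicates: int = 3


class QpcrBlock(_Block):
    true_rel_expression: dict[str, dict[str, float]]
    reference_sample: str
    gapdh_ct: float = 20.0
    noise_sd: float = 0.0
    dropout_rel_threshold: Optional[float] = None
    replicates: int = 3
    housekeeping: str = "GAPDH"


class PulseBlock(_Block):
    rates: ChaChaRateParams
    ligand_level: float
    pulse_start: float = 0.0
    pulse_end: float = 24.0
    followup_hours: float = 144.0


class RunConfig(ParamsBase):
    """One-file description of a pipeline run; round-trips losslessly."""

    seed: Optional[int] = None
    outdir: str = "runs/run"
    log_level: str = "INFO"
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    grid: Optional[GridBlock] = None
    dose_response_hm3d: Optional[DoseResponseBlock] = None
    dose_response_nmbr: Optional[DoseResponseBlock] = None
    dox: Optional[DoxBlock] = None
    qpcr: Optional[QpcrBlock] = None
    pulse: Optional[PulseBlock] = None


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.load(path)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute every configured stage; returns artifact paths and summaries."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if config.seed is not None else secrets.randbelow(2**31)
    log_lines = [
        f"chachakit {__version__} | python {platform.python_version()} | "
        f"numpy {np.__version__} | pandas {pd.__version__}",
        f"seed {seed}" + (" (generated)" if config.seed is None else ""),
    ]
    artifacts: dict[str, object] = {"seed": seed, "outdir": str(outdir)}

    def noise_for(offset: int) -> NoiseModel:
        return NoiseModel(
            kind=config.noise.kind, cv_or_sd=config.noise.cv_or_sd,
            seed=(seed + offset) % 2**31,
        )

    def stage(name: str, fn):
        t0 = time.perf_counter()
        fn()
        log_lines.append(f"stage {name}: {time.perf_counter() - t0:.2f}s")

    if config.grid is not None:
        def _grid(b=config.grid):
            data = generate_grid_dataset(
                b.truth, b.adaptor_levels, b.ligand_doses, b.replicates, noise_for(0)
            )
            write_measurement_table(data, outdir / "grid.csv", kind="grid")
            fit = fit_steady_state_model(data)
            fit.save(outdir / "grid_fit.json")
            artifacts["grid_fit"] = fit
        stage("grid", _grid)

    for label, block, offset in (
        ("dose_response_hm3d", config.dose_response_hm3d, 1),
        ("dose_response_nmbr", config.dose_response_nmbr, 2),
    ):
        if block is None:
            continue

        def _dose(b=block, label=label, offset=offset):
            data = generate_dose_response(b.truth, b.doses, b.replicates, noise_for(offset))
            write_measurement_table(data, outdir / f"{label}.csv", kind="dose")
            fit = fit_hill_dose_response(data)
            fit.save(outdir / f"{label}_fit.json")
            artifacts[f"{label}_fit"] = fit
        stage(label, _dose)

    if config.dox is not None:
        def _dox(b=config.dox):
            data = generate_dox_induction(b.truth, b.dox_levels, b.replicates, noise_for(3))
            write_measurement_table(data, outdir / "dox.csv", kind="dox")
            fit = fit_dox_hill(data)
            fit.save(outdir / "dox_fit.json")
            artifacts["dox_fit"] = fit
        stage("dox", _dox)

    if config.qpcr is not None:
        def _qpcr(b=config.qpcr):
            plate = generate_qpcr_plate(
                b.true_rel_expression, b.gapdh_ct, b.noise_sd,
                b.dropout_rel_threshold, b.replicates, seed=(seed + 4) % 2**31,
                housekeeping=b.housekeeping,
            )
            write_qpcr_plate(plate, outdir / "qpcr_plate.csv")
            result = analyze_plate(plate, b.reference_sample, b.housekeeping)
            result.to_csv(outdir / "qpcr_expression.csv", index=False)
            artifacts["qpcr_expression"] = result
        stage("qpcr", _qpcr)

    if config.pulse is not None:
        def _pulse(b=config.pulse):
            sched = Schedule.pulse(b.ligand_level, b.pulse_start, b.pulse_end)
            traj = simulate_chacha(
                b.rates, sched, (b.pulse_start, b.pulse_end + b.followup_hours),
                n_points=2000,
            )
            traj.to_csv(outdir / "pulse_trajectory.csv")
            g = traj["G"]
            ipk = int(np.argmax(g))
            summary = {
                "peak_time_h": float(traj.times[ipk]),
                "pulse_end_h": b.pulse_end,
                "peak_gfp": float(g[ipk]),
                "terminal_gfp": float(g[-1]),
                "terminal_over_peak": float(g[-1] / g[ipk]),
            }
            (outdir / "pulse_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
            artifacts["pulse_summary"] = summary
        stage("pulse", _pulse)

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    (outdir / "run_metadata.json").write_text(
        json.dumps({"seed": seed, "version": __version__}, indent=2) + "\n"
    )
    return artifacts
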