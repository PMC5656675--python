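"""Stage runner chaining the kinetics pipeline through file handoffs."""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

from . import __version__
from .config import RunConfig
from .kinetics import (
    ObservableModel,
    RateParameters,
    fit_multiexponential,
    fit_pseudo_first_order,
    select_kobs1,
)
from .io import read_kobs_table, read_trace_csv, write_kobs_table, write_trace_csv
from .synthetic import gen_trace_series

log = logging.getLogger("proppinlab")


def _stage_synth_traces(config: RunConfig, outdir: Path) -> list[Path]:
    params = RateParameters(config.k_on, config.k_off, config.k_oli, config.k_dis)
    traces, truth = gen_trace_series(
        params,
        config.concentrations_mM,
        ObservableModel(),
        noise_sd=config.noise_sd,
        replicates=config.replicates,
        seed=config.seed,
        duration=config.duration_s,
        n_points=config.n_points,
        accessible_fraction=config.accessible_fraction,
        protein_conc=config.protein_uM,
    )
    paths = []
    for i, trace in enumerate(traces):
        path = outdir / f"trace_{i:03d}.csv"
        write_trace_csv(trace, path)
        paths.append(path)
    truth.write(outdir / "traces_truth.json")
    return paths


def _stage_fit_traces(config: RunConfig, outdir: Path) -> Path:
    points = []
    for path in sorted(outdir.glob("trace_*.csv")):
        trace = read_trace_csv(path)
        fit = fit_multiexponential(trace, n_phases=config.n_phases)
        points.append(select_kobs1(fit, trace.condition))
    if not points:
        raise FileNotFoundError(f"no trace_*.csv files in {outdir}")
    out = outdir / "kobs.csv"
    write_kobs_table(points, out)
    return out


def _stage_pfo_fit(config: RunConfig, outdir: Path) -> Path:
    points = read_kobs_table(outdir / "kobs.csv")
    fit = fit_pseudo_first_order(points)
    out = outdir / "pfo_fit.json"
    out.write_text(
        json.dumps(
            {
                "k_on_per_mM_s": fit.k_on,
                "k_on_se": fit.k_on_se,
                "k_off_app_per_s": fit.k_off_app,
                "k_off_app_se": fit.k_off_app_se,
                "r_squared": fit.r_squared,
                "n_points": fit.n_points,
                "weighted": fit.weighted,
                "negative_intercept": fit.negative_intercept,
            },
            indent=2,
        )
        + "\n"
    )
    return out


STAGES = {
    "synth-traces": _stage_synth_traces,
    "fit-traces": _stage_fit_traces,
    "pfo-fit": _stage_pfo_fit,
}


def run_pipeline(config: RunConfig, stages: list[str]) -> int:
    """Execute stages in order with file handoffs in config.output_dir.

    Returns 0 on success, 1 on any stage failure; unknown stage names
    raise immediately with the list of valid stages.
    """
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(
                f"unknown stage {stage!r}; valid stages: {sorted(STAGES)}"
            )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write_resolved(outdir / "resolved_config.yaml")
    log.info("proppinlab %s, seed %d", __version__, config.seed)
    for stage in stages:
        started = time.perf_counter()
        try:
            STAGES[stage](config, outdir)
        except Exception:
            log.exception("stage %s failed", stage)
            return 1
        log.info("stage %s finished in %.2f s", stage, time.perf_counter() - started)
    return 0
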