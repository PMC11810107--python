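"""Pipeline driver: simulate (or load) tables, then stage, project,
estimate turnover and infer growth, writing results with provenance."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth, staging, trajectory, turnover
from .io import RunConfig, read_bulk, read_cells, read_tracks, write_table
from .simulate import simulate_bulk, simulate_k48_experiment, simulate_tracks

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("sizeflux")


class PipelineError(RuntimeError):
    pass


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_sizeflux_tag", None) for h in log.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler()
        h._sizeflux_tag = "stderr"
        log.addHandler(h)
    logfile = outdir / "pipeline.log"
    for h in list(log.handlers):
        if getattr(h, "_sizeflux_tag", None) == "file":
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile, mode="w")
    fh._sizeflux_tag = "file"
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)


def run_pipeline(
    config: RunConfig,
    outdir,
    cells_path=None,
    tracks_path=None,
    bulk_path=None,
    stages=("simulate", "stage", "trajectory", "turnover", "growth", "tracks"),
) -> dict:
    """Execute the requested stages and write result tables to ``outdir``.

    Inputs are either loaded from the given paths or generated by the
    simulator under ``config.sim``. Any stage error aborts the run with a
    :class:`PipelineError` naming the stage; a missing CFZ arm only skips
    the turnover stage with a logged warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    prov = config.provenance()
    results: dict = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        write_table(df, outdir / f"{name}.csv", prov)
        results[name] = df

    # ------------------------------------------------------------------ inputs
    try:
        if cells_path is not None:
            cells = read_cells(cells_path)
        elif "simulate" in stages:
            log.info("simulating snapshot arms: %s", ", ".join(config.conditions))
            cells = simulate_k48_experiment(
                config.sim, config.conditions, treat_h=config.treat_h
            )
        else:
            cells = None
        if tracks_path is not None:
            tracks = {"loaded": read_tracks(tracks_path)}
        elif "simulate" in stages and "tracks" in stages:
            tracks = {
                c: simulate_tracks(config.sim, c, config.n_tracks)
                for c in config.conditions
            }
        else:
            tracks = None
        if bulk_path is not None:
            bulk = {"loaded": read_bulk(bulk_path)}
        elif "simulate" in stages and "growth" in stages:
            bulk = {
                c: simulate_bulk(config.sim, c, config.bulk_timepoints)
                for c in config.conditions
            }
        else:
            bulk = None
    except Exception as e:
        raise PipelineError(f"input stage failed: {e}") from e
    if cells is not None and cells_path is not None:
        emit("cells", cells)
    elif cells is not None:
        emit("cells", cells)

    # ------------------------------------------------------------------ staging
    if "stage" in stages and cells is not None:
        try:
            thresholds = staging.detect_thresholds(cells)
            cells = staging.assign_stage(cells, thresholds)
            emit(
                "stage_thresholds",
                pd.DataFrame(
                    [
                        {
                            "dna_2n_upper": thresholds.dna_2n_upper,
                            "dna_4n_lower": thresholds.dna_4n_lower,
                            "geminin_log_cut": thresholds.geminin_log_cut,
                        }
                    ]
                ),
            )
            emit("cells_staged", cells)
            log.info("staged %d cells", len(cells))
        except Exception as e:
            raise PipelineError(f"staging stage failed: {e}") from e

    # --------------------------------------------------------------- trajectory
    if "trajectory" in stages and cells is not None:
        try:
            reference = cells[cells["condition"] == "control"]
            if len(reference) < 2000:
                reference = cells
            curve = trajectory.fit_ridge(
                reference,
                n_grid=config.trajectory_grid,
                density_floor=config.trajectory_density_floor,
            )
            cells = trajectory.project_cells(curve, cells)
            emit(
                "trajectory_curve",
                pd.DataFrame(
                    {
                        "dna": curve.points[:, 0],
                        "log_geminin": curve.points[:, 1],
                        "ell": curve.ell,
                    }
                ),
            )
            emit("cells_projected", cells)
        except Exception as e:
            raise PipelineError(f"trajectory stage failed: {e}") from e

    # ----------------------------------------------------------------- turnover
    if "turnover" in stages and cells is not None:
        if "cfz_flag" not in cells.columns or cells["cfz_flag"].nunique() < 2:
            log.warning("turnover skipped: no paired +/-CFZ wells in the input")
        else:
            try:
                rows = []
                per_condition: dict[str, list] = {}
                for cond, sub in cells.groupby("condition"):
                    res = turnover.delta_k48(
                        sub, per_stage="stage" in cells.columns,
                        centre=config.turnover_centre,
                    )
                    per_condition[cond] = res
                    rows.extend(
                        {
                            "condition": r.condition,
                            "stage": r.stage,
                            "delta_k48": r.delta_k48,
                            "ci_low": r.ci_low,
                            "ci_high": r.ci_high,
                            "n_pairs": r.n_pairs,
                            "median_size": r.median_size,
                        }
                        for r in res
                    )
                emit("turnover", pd.DataFrame(rows))
                if "control" in per_condition and len(per_condition) > 1:
                    srows = []
                    rng = np.random.default_rng(config.sim.seed)
                    for cond, res in per_condition.items():
                        if cond == "control":
                            continue
                        fit = turnover.scaling_analysis(
                            per_condition["control"], res, n_boot=config.n_boot, rng=rng
                        )
                        srows.append(
                            {
                                "condition": cond,
                                "fold_delta": fit.fold_delta,
                                "fold_size": fit.fold_size,
                                "excess_ratio": fit.excess_ratio,
                                "superlinear_p": fit.superlinear_p,
                            }
                        )
                    emit("scaling", pd.DataFrame(srows))
            except Exception as e:
                raise PipelineError(f"turnover stage failed: {e}") from e

    # ------------------------------------------------------------------- growth
    if "growth" in stages and bulk is not None:
        try:
            rows = []
            for cond, b in bulk.items():
                fit = growth.fit_cycle_length(b)
                nu = growth.bulk_growth_rate(b)
                emit(f"bulk_{cond.replace('/', '_')}", nu)
                rows.append(
                    {
                        "condition": cond,
                        "alpha_per_h": fit.alpha,
                        "tau_h": fit.tau,
                        "alpha_ci_low": fit.alpha_ci[0],
                        "alpha_ci_high": fit.alpha_ci[1],
                        "mean_nu": float(np.mean(nu["nu"])),
                        "diagnostic": fit.diagnostic,
                    }
                )
            emit("growth_fits", pd.DataFrame(rows))
        except Exception as e:
            raise PipelineError(f"growth stage failed: {e}") from e

    # ------------------------------------------------------------------- tracks
    if "tracks" in stages and tracks is not None:
        try:
            rows = []
            for cond, tr in tracks.items():
                emit(f"tracks_{cond.replace('/', '_')}", tr)
                rates = growth.tracks_growth_table(
                    tr, config.smooth_window, config.trim_frames
                )
                durs = growth.phase_durations(tr)
                rows.append(
                    {
                        "condition": cond,
                        "mean_growth_rate": float(rates["growth_rate"].mean()),
                        "g1_mean_h": durs["g1_mean"],
                        "cycle_mean_h": durs["cycle_mean"],
                        "n_tracks": durs["n_tracks"],
                        "n_excluded": len(rates.attrs.get("excluded", [])),
                    }
                )
                aligned = growth.align_tracks(tr, anchor="birth")
                emit(f"aligned_birth_{cond.replace('/', '_')}", aligned)
            emit("track_summary", pd.DataFrame(rows))
        except Exception as e:
            raise PipelineError(f"tracks stage failed: {e}") from e

    log.info("pipeline complete: %s", ", ".join(sorted(results)))
    return results
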