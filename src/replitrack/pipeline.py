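"""End-to-end orchestration: simulate -> detect -> classify -> summarize.

`run_pipeline` executes a whole scenario deterministically for a seed and
returns (and optionally writes) per-cell tables plus a population summary
with seeded bootstrap confidence intervals.  Every analysis threshold is
echoed verbatim into the summary for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import events as ev
from . import fileio, speed as sp, timeline
from .detect import detect_cell_foci
from .scenarios import ScenarioParams, get_scenario
from .simulate import iter_population

logger = logging.getLogger("replitrack")

__all__ = ["RunConfig", "run_pipeline", "analyze_cell", "bootstrap_ci"]


@dataclass
class RunConfig:
    """Analysis configuration (scenario + every detection/classification knob)."""

    scenario: str = "WT"
    n_cells: int = 100
    rng_seed: int = 1
    # detection
    max_candidates: int = 3
    n_foci_max: int = 2
    sigma_range: tuple[float, float] = (1.0, 3.0)
    snr_min: float = 0.25
    width_rule: str = "both"
    seed_min_sigma: float = 5.0
    # windows / classification
    gap_frames: int = 1
    ratio_threshold: float = 1.5
    tau_boundary: float = 0.5
    k_streak: float = 1.5
    d_min_px: int = 5
    arrival_frac: float = 0.1
    d_max_coloc_nm: float = 250.0
    max_link_nm: float = 500.0
    w_div_nm: float = 400.0
    d_split_nm: float = 300.0
    # reporting
    n_bootstrap: int = 1000
    scenario_overrides: dict = field(default_factory=dict)

    def scenario_params(self) -> ScenarioParams:
        return get_scenario(self.scenario, **self.scenario_overrides)

    def threshold_echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["sigma_range"] = list(self.sigma_range)
        return d


def _detect(cell, channel, cfg: RunConfig) -> pd.DataFrame:
    return detect_cell_foci(
        cell, channel, max_candidates=cfg.max_candidates,
        n_foci_max=cfg.n_foci_max, sigma_range=cfg.sigma_range,
        snr_min=cfg.snr_min, width_rule=cfg.width_rule,
        seed_min_sigma=cfg.seed_min_sigma,
    )


def analyze_cell(cell, params: ScenarioParams, cfg: RunConfig) -> dict:
    """Run the full per-cell analysis chain; returns per-cell records.

    The returned dict contains the foci tables per channel plus (depending
    on scenario) window, patterns, split events, segregation record, steps
    and locus measurements.  ``excluded`` is True when no replication
    window could be found.
    """
    out: dict = {"cell_id": cell.cell_id, "excluded": False}
    primary = "locus" if params.locus_position_mb is not None else "dnaN"
    foci = {ch: _detect(cell, ch, cfg) for ch in cell.images}
    out["foci"] = foci

    if params.locus_position_mb is not None:
        L = sp.length_at_split(foci["locus"], cell, d_split_nm=cfg.d_split_nm)
        out["length_at_split"] = L
        out["alpha_fit"] = sp.estimate_alpha(
            np.arange(cell.n_frames) * cell.frame_interval, cell.lengths_um)
        return out

    win = timeline.detect_replication_window(foci[primary], gap_frames=cfg.gap_frames)
    if win is None:
        out["excluded"] = True
        return out
    out["window"] = win
    patterns = ev.frame_patterns(foci[primary], win, cfg.ratio_threshold)
    out["patterns"] = patterns

    if params.fast_frame:
        tracked = ev.link_tracks(foci[primary], cell.pixel_size, cfg.max_link_nm)
        out["steps"] = ev.step_sizes(tracked, cell, cfg.w_div_nm)
        return out

    out["early"] = ev.detect_early_splitting(
        patterns, win, cell.frame_interval, cell=cell, foci=foci[primary],
        tau_boundary=cfg.tau_boundary, k_streak=cfg.k_streak,
        d_min_px=cfg.d_min_px)
    out["late"] = ev.detect_late_splitting(
        patterns, win, cell.frame_interval, tau_boundary=cfg.tau_boundary)
    out["similar_rel"] = ev.similar_foci_duration(patterns, win)
    out["two_bright_early"] = ev.two_bright_early_flag(patterns, cfg.tau_boundary)
    out["any_two_foci"] = ev.any_two_foci_flag(patterns)

    if "parB" in cell.images:
        dim_class = "with_dim" if out["early"] is not None else "without_dim"
        out["segregation"] = ev.segregation_time(
            win, foci["parB"], cell, dim_class, arrival_frac=cfg.arrival_frac)

    if "ssb" in cell.images:
        frac, n = ev.conditional_coloc_fraction(
            foci[primary], foci["ssb"], patterns, cell.pixel_size,
            cfg.d_max_coloc_nm)
        out["coloc_qualifies"] = n > 0
        out["coloc_hit"] = bool(n > 0 and frac >= 1.0)
    return out


def bootstrap_ci(values, rng: np.random.Generator, n_boot: int = 1000,
                 stat=np.mean) -> tuple[float, float]:
    """Seeded percentile bootstrap 95% CI of ``stat`` over cell-level values."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if len(v) == 0:
        return float("nan"), float("nan")
    reps = np.array([stat(rng.choice(v, size=len(v), replace=True))
                     for _ in range(n_boot)])
    return float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5))


def _mean_sd_ci(values, rng, n_boot, prefix: str, summary: dict) -> None:
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    summary[f"{prefix}_n"] = int(len(v))
    if len(v) == 0:
        summary[f"{prefix}_mean"] = float("nan")
        summary[f"{prefix}_sd"] = float("nan")
        summary[f"{prefix}_ci95"] = [float("nan"), float("nan")]
        return
    summary[f"{prefix}_mean"] = float(np.mean(v))
    summary[f"{prefix}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    summary[f"{prefix}_ci95"] = list(bootstrap_ci(v, rng, n_boot))


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None,
                 save_images: bool = False) -> dict:
    """Execute the scenario in ``cfg`` end to end and summarize it.

    Deterministic for a fixed config: identical configs produce
    byte-identical summary JSON files.
    """
    params = cfg.scenario_params()
    rng_boot = np.random.default_rng(cfg.rng_seed + 1)

    records = []
    foci_tables = []
    step_tables = []
    for cell, truth in iter_population(params, cfg.n_cells, cfg.rng_seed):
        try:
            rec = analyze_cell(cell, params, cfg)
        except Exception as exc:  # abort naming the stage and cell
            raise RuntimeError(
                f"analysis failed for cell {cell.cell_id}: {exc}") from exc
        rec["truth"] = truth
        for ch, df in rec.get("foci", {}).items():
            foci_tables.append(df)
        if "steps" in rec:
            step_tables.append(rec["steps"])
        if save_images and outdir is not None:
            fileio.save_cell(cell, Path(outdir) / "cells")
        records.append(rec)

    summary: dict = {
        "scenario": params.name,
        "n_cells": cfg.n_cells,
        "rng_seed": cfg.rng_seed,
        "thresholds": cfg.threshold_echo(),
    }

    analyzed = [r for r in records if not r["excluded"]]
    summary["n_excluded"] = sum(r["excluded"] for r in records)

    if params.locus_position_mb is not None:
        lengths = [r["length_at_split"] for r in records
                   if r.get("length_at_split") is not None]
        summary["locus_position_mb"] = params.locus_position_mb
        summary["detection_fraction"] = len(lengths) / len(records)
        _mean_sd_ci(lengths, rng_boot, cfg.n_bootstrap, "length_at_split", summary)
        _mean_sd_ci([r["alpha_fit"] for r in records], rng_boot,
                    cfg.n_bootstrap, "alpha", summary)
    elif params.fast_frame:
        steps = pd.concat(step_tables, ignore_index=True) if step_tables else \
            pd.DataFrame(columns=fileio.STEP_COLUMNS)
        for loc in ("at_division_site", "away"):
            v = steps.loc[steps["location_class"] == loc, "step_nm"]
            key = "step_at_site" if loc == "at_division_site" else "step_away"
            summary[f"{key}_n"] = int(len(v))
            summary[f"{key}_mean_nm"] = float(v.mean()) if len(v) else float("nan")
    else:
        n = len(analyzed)
        early = [r["early"] is not None for r in analyzed]
        late = [r["late"] is not None for r in analyzed]
        summary["early_split_fraction"] = float(np.mean(early)) if n else float("nan")
        summary["late_split_fraction"] = float(np.mean(late)) if n else float("nan")
        summary["two_bright_early_fraction"] = (
            float(np.mean([r["two_bright_early"] for r in analyzed])) if n else float("nan"))
        summary["any_two_foci_fraction"] = (
            float(np.mean([r["any_two_foci"] for r in analyzed])) if n else float("nan"))
        _mean_sd_ci([r["late"].duration for r in analyzed if r["late"] is not None],
                    rng_boot, cfg.n_bootstrap, "late_duration", summary)
        _mean_sd_ci([r["late"].first_onset_tau for r in analyzed if r["late"] is not None],
                    rng_boot, cfg.n_bootstrap, "late_first_onset_tau", summary)
        _mean_sd_ci([r["similar_rel"] for r in analyzed], rng_boot,
                    cfg.n_bootstrap, "similar_rel_duration", summary)
        segs = [r.get("segregation") for r in analyzed]
        segs = [s for s in segs if s is not None]
        if segs:
            _mean_sd_ci([s.T_seg for s in segs if s.dim_class == "with_dim"],
                        rng_boot, cfg.n_bootstrap, "seg_time_with_dim", summary)
            _mean_sd_ci([s.T_seg for s in segs if s.dim_class == "without_dim"],
                        rng_boot, cfg.n_bootstrap, "seg_time_without_dim", summary)
        quals = [r for r in analyzed if r.get("coloc_qualifies")]
        if quals:
            hits = [r["coloc_hit"] for r in quals]
            summary["coloc_conditional_fraction"] = float(np.mean(hits))
            summary["coloc_n_cells"] = len(quals)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if foci_tables:
            fileio.write_table(outdir / "foci.csv",
                               pd.concat(foci_tables, ignore_index=True),
                               fileio.FOCI_COLUMNS, "foci")
        event_rows = []
        for r in records:
            for key in ("early", "late"):
                e = r.get(key)
                if e is not None:
                    event_rows.append(dataclasses.asdict(e))
        if event_rows:
            fileio.write_table(outdir / "events.csv", pd.DataFrame(event_rows),
                               fileio.EVENT_COLUMNS, "events")
        seg_rows = [dataclasses.asdict(r["segregation"]) for r in records
                    if r.get("segregation") is not None]
        if seg_rows:
            fileio.write_table(outdir / "segregation.csv", pd.DataFrame(seg_rows),
                               fileio.SEGREGATION_COLUMNS, "segregation")
        if step_tables:
            fileio.write_table(outdir / "steps.csv",
                               pd.concat(step_tables, ignore_index=True),
                               fileio.STEP_COLUMNS, "steps")
        params.to_yaml(outdir / "scenario.yaml")
        fileio.write_summary(outdir / "summary.json", summary)
        logger.info("wrote pipeline outputs to %s", outdir)

    summary["_records"] = records   # in-memory only; not serialized
    return summary
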