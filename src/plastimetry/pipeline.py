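"""End-to-end pipeline: simulate -> calcium / spines / morph -> stats -> report.

Stages run in dependency order; a failure in one stage is recorded in the run
report and stops only the stages that depend on it. All outputs are
deterministic given (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import calcium, groupstats, io, morphometry, spines as spines_mod
from .errors import ConfigurationError
from .synthetic import (
    DEFAULT_OVERRIDES,
    MorphSimParams,
    SpineSimParams,
    StudyDesign,
    TraceSimParams,
    simulate_study,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Run-wide options; unknown keys in ``from_dict`` are rejected."""

    out_dir: str = "plastimetry_run"
    seed: int = 0
    threshold_multiple: float = 3.0
    min_duration_frames: int = 1
    baseline_method: str = "mad"
    tolerance_um: float = 1.0
    min_spines: int = 8
    max_spines: int = 15
    sholl_r_start: float = 5.0
    sholl_r_step: float = 5.0
    alpha: float = 0.05
    posthoc_adjust: str | None = None
    n_groups_animals: int = 4
    n_fovs_per_animal: int = 2
    use_default_group_effects: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.threshold_multiple <= 0:
            raise ConfigurationError("threshold_multiple must be > 0")
        if cfg.min_duration_frames < 1:
            raise ConfigurationError("min_duration_frames must be >= 1")
        if cfg.tolerance_um < 0:
            raise ConfigurationError("tolerance_um must be >= 0")
        if cfg.min_spines > cfg.max_spines:
            raise ConfigurationError("min_spines must be <= max_spines")
        if cfg.sholl_r_step <= 0:
            raise ConfigurationError("sholl_r_step must be > 0")
        if not 0 < cfg.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        return cfg


@dataclass
class RunReport:
    """Per-stage file inventory, warnings, and the exact config echo."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[str],
               status: str = "ok", error: str | None = None,
               warnings: list[str] | None = None) -> None:
        self.stages[stage] = {
            "status": status,
            "outputs": outputs,
            "error": error,
            "warnings": warnings or [],
        }

    def to_dict(self) -> dict:
        return {"version": self.version, "config": self.config,
                "stages": self.stages}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full simulated-study pipeline and write all result tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))

    design = StudyDesign(
        n_animals_per_group=config.n_groups_animals,
        n_fovs_per_animal=config.n_fovs_per_animal,
        base_trace=TraceSimParams(),
        base_spine=SpineSimParams(),
        base_morph=MorphSimParams(),
        overrides=DEFAULT_OVERRIDES if config.use_default_group_effects else {},
    )

    # --- simulate -----------------------------------------------------------
    try:
        bundle = simulate_study(design, seed=config.seed)
        sim_files = []
        for rec in bundle.recordings:
            p = out / f"traces_{rec.fov_id}.csv"
            io.write_traces(rec, p)
            sim_files += [str(p), str(p.with_suffix(".meta.json"))]
        for s1, s2 in bundle.spine_pairs:
            p = out / f"spines_{s1.animal_id}.csv"
            io.write_spines([s1, s2], p)
            sim_files.append(str(p))
        for tree in bundle.trees:
            p = out / f"{tree.cell_id}.swc"
            morphometry.write_swc(tree, p)
            cp = out / f"{tree.cell_id}_contour.csv"
            morphometry.write_contour(tree.soma_contour, cp)
            sim_files += [str(p), str(cp)]
        p = out / "measurements.csv"
        io.write_table(bundle.measurements.sort_values(
            ["measure", "group", "unit_id"]).reset_index(drop=True), p)
        sim_files.append(str(p))
        report.record("simulate", sim_files)
    except Exception as exc:  # noqa: BLE001 - report and stop downstream
        logger.exception("simulate stage failed")
        report.record("simulate", [], status="failed", error=str(exc))
        return report

    # --- calcium ------------------------------------------------------------
    try:
        roi_tabs, files = [], []
        for rec in bundle.recordings:
            roi_tab, tr_tab, sync = calcium.summarize_fov(
                rec, config.threshold_multiple, config.min_duration_frames,
                baseline_method=config.baseline_method)
            roi_tab["mean_corr"] = sync.mean_corr
            roi_tabs.append(roi_tab)
            p = out / f"transients_{rec.fov_id}.csv"
            io.write_table(tr_tab, p)
            files.append(str(p))
            p = out / f"corr_{rec.fov_id}.csv"
            io.write_corr_matrix(sync.corr_matrix, p)
            files.append(str(p))
        p = out / "calcium_per_roi.csv"
        io.write_table(pd.concat(roi_tabs, ignore_index=True), p)
        files.append(str(p))
        report.record("calcium", files)
    except Exception as exc:  # noqa: BLE001
        logger.exception("calcium stage failed")
        report.record("calcium", [], status="failed", error=str(exc))

    # --- spines -------------------------------------------------------------
    try:
        rows, files, stage_warnings = [], [], []
        for s1, s2 in bundle.spine_pairs:
            f1, f2 = spines_mod.select_shafts(
                s1, config.min_spines, config.max_spines, companion=s2)
            if not f1.shafts:
                stage_warnings.append(
                    f"{s1.animal_id}: shaft filter removed every shaft")
                continue
            match = spines_mod.match_spines(f1, f2, config.tolerance_um)
            summ = spines_mod.turnover_metrics(match, f1, f2)
            rows.append({
                "animal_id": s1.animal_id, "group": s1.group,
                "density_s1_per_um": summ.density_s1,
                "density_s2_per_um": summ.density_s2,
                "formation_pct": summ.formation_pct,
                "elimination_pct": summ.elimination_pct,
                "turnover_pct": summ.turnover_pct,
                "n_s1": summ.n_s1, "n_s2": summ.n_s2,
            })
        p = out / "spine_turnover.csv"
        io.write_table(pd.DataFrame(rows), p)
        files.append(str(p))
        report.record("spines", files, warnings=stage_warnings)
    except Exception as exc:  # noqa: BLE001
        logger.exception("spine stage failed")
        report.record("spines", [], status="failed", error=str(exc))

    # --- morphometry --------------------------------------------------------
    try:
        rows, sholl_rows, files = [], [], []
        for tree in bundle.trees:
            prof = morphometry.sholl(tree, config.sholl_r_start,
                                     config.sholl_r_step)
            rows.append({
                "cell_id": tree.cell_id, "group": tree.group,
                "soma_area_um2": morphometry.soma_area(tree.soma_contour),
                "total_length_um": morphometry.total_length(tree),
                "branch_count": morphometry.branch_count(tree),
            })
            for r, ix, al in zip(prof.radii_um, prof.intersections,
                                 prof.annulus_length_um):
                sholl_rows.append({
                    "cell_id": tree.cell_id, "group": tree.group,
                    "radius_um": float(r), "intersections": int(ix),
                    "annulus_length_um": float(al),
                })
        p = out / "morphometry.csv"
        io.write_table(pd.DataFrame(rows), p)
        files.append(str(p))
        p = out / "sholl_profiles.csv"
        io.write_table(pd.DataFrame(sholl_rows), p)
        files.append(str(p))
        report.record("morph", files)
    except Exception as exc:  # noqa: BLE001
        logger.exception("morph stage failed")
        report.record("morph", [], status="failed", error=str(exc))

    # --- statistics ---------------------------------------------------------
    try:
        results, files = {}, []
        for measure in sorted(bundle.measurements["measure"].unique()):
            tidy = io.tidy_from_measurements(bundle.measurements, measure)
            try:
                res = groupstats.auto_compare(tidy, alpha=config.alpha,
                                              adjust=config.posthoc_adjust)
                results[measure] = {
                    "test": res.test_name,
                    "statistic": res.statistic,
                    "df": list(res.df),
                    "p_value": res.p_value,
                    "posthoc": res.posthoc,
                    "normality": res.normality_decision,
                }
            except Exception as exc:  # noqa: BLE001 - keep other endpoints
                results[measure] = {"error": str(exc)}
        p = out / "group_stats.json"
        io.write_json(results, p)
        files.append(str(p))
        report.record("stats", files)
    except Exception as exc:  # noqa: BLE001
        logger.exception("stats stage failed")
        report.record("stats", [], status="failed", error=str(exc))

    io.write_json(report.to_dict(), out / "run_report.json")
    return report
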