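"""End-to-end orchestration: simulate or load a cohort, score the three
diet-quality indices at baseline, build outcomes, fit the survey-series
models, and write the output bundle (scores, exposures, selection flow,
baseline descriptives, odds-ratio grids, manifest)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ahei import compute_sodium_deciles, score_ahei_frame
from .covariates import fill_missing_covariates, impute_education
from .exposure import assign_quintiles, assignments_to_series
from .heifa import score_heifa_frame
from .mds import compute_mds_reference, score_mds_frame
from .models import describe_baseline, run_survey_series
from .outcomes import build_enduring_status, select_analysis_sample
from .records import validate_intake_frame
from .simulate import CohortData, SimulationConfig, generate_cohort

log = logging.getLogger("dietscore")

INDEX_NAMES = ("HEIFA-2013", "MDS", "AHEI-2010")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: either a simulation config or input paths."""

    out_dir: str
    seed: int = 0
    simulation: SimulationConfig | None = None
    intake_path: str | None = None
    reports_path: str | None = None
    covariates_path: str | None = None
    deaths_path: str | None = None
    indices: tuple[str, ...] = INDEX_NAMES
    outcomes: tuple[str, ...] = (
        "DM", "CHD", "HT", "asthma", "cancer_nonskin", "dep_anx", "multimorbidity", "mortality",
    )
    waves: tuple[int, ...] = (4, 5, 6, 7, 8)
    fill_direction: str = "as-stated"

    def __post_init__(self) -> None:
        unknown = set(self.indices) - set(INDEX_NAMES)
        if unknown:
            raise ValueError(f"unknown indices: {sorted(unknown)}")


def score_indices(
    intake: pd.DataFrame, indices=INDEX_NAMES
) -> tuple[pd.DataFrame, dict]:
    """Score every requested index over a wide intake table.

    Returns (long scores table, reference statistics dict).  The MDS median
    reference and AHEI sodium deciles are computed from the same table, as
    both are sample-dependent.
    """
    validate_intake_frame(intake)
    idx = intake["participant_id"].astype(str)
    frames = []
    references: dict = {}
    if "HEIFA-2013" in indices:
        heifa = score_heifa_frame(intake)
        heifa.insert(0, "participant_id", idx)
        heifa.insert(1, "index", "HEIFA-2013")
        frames.append(heifa)
    if "MDS" in indices:
        ref = compute_mds_reference(intake)
        mds = score_mds_frame(intake, ref)
        mds.insert(0, "participant_id", idx)
        mds.insert(1, "index", "MDS")
        frames.append(mds)
        references["mds_medians"] = ref.as_dict()
    if "AHEI-2010" in indices:
        ref = compute_sodium_deciles(intake)
        ahei = score_ahei_frame(intake, ref)
        ahei.insert(0, "participant_id", idx)
        ahei.insert(1, "index", "AHEI-2010")
        frames.append(ahei)
        references["sodium_deciles"] = ref.as_dict()
    scores = pd.concat(frames, ignore_index=True)
    return scores, references


def _load_cohort(config: RunConfig) -> CohortData:
    if config.simulation is not None:
        return generate_cohort(config.simulation)
    raise NotImplementedError(
        "loading a real cohort requires intake/reports/covariates paths; "
        "use analyze() with explicit frames"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis and write the output bundle to ``out_dir``.

    Per-cell model failures are summarised, never fatal.  Returns a summary
    dict (paths, sample-flow counts, failed-cell count).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict:
    cohort = _load_cohort(config)
    log.info("cohort ready: n=%d", len(cohort.intake))

    status = build_enduring_status(cohort.reports, cohort.deaths, cohort.responded)
    sample, flow = select_analysis_sample(status, cohort.ffq_complete)
    log.info("analysis sample: %s", flow)

    intake = cohort.intake[cohort.intake["participant_id"].isin(sample)].reset_index(drop=True)
    scores, references = score_indices(intake, config.indices)

    exposures = {}
    for index_name in config.indices:
        totals = scores.loc[scores["index"] == index_name].set_index("participant_id")["total"]
        exposures[index_name] = assign_quintiles(totals)

    panel = impute_education(cohort.covariates)
    panel, fill_log = fill_missing_covariates(panel, direction=config.fill_direction)

    baseline_panel = panel[panel["wave"] == 3].drop(columns=["wave"])
    first_index = config.indices[0]
    descriptives = describe_baseline(
        assignments_to_series(exposures[first_index]), baseline_panel
    )

    results = run_survey_series(
        status,
        panel,
        exposures,
        cohort.deaths,
        sample,
        outcomes_to_run=config.outcomes,
        waves=config.waves,
    )
    ncd_grid = results[results["outcome"] != "mortality"]
    mortality_grid = results[results["outcome"] == "mortality"]
    failed = int((~results["converged"]).sum())

    scores.to_csv(out / "scores.csv", index=False)
    exposure_rows = [
        {
            "index": index_name,
            "participant_id": a.participant_id,
            "quintile": a.quintile,
            "collapsed_category": a.collapsed_category,
        }
        for index_name, assigns in exposures.items()
        for a in assigns
    ]
    pd.DataFrame(exposure_rows).to_csv(out / "exposures.csv", index=False)
    (out / "selection_flow.json").write_text(json.dumps(flow, indent=2))
    descriptives.to_csv(out / "baseline_descriptives.csv", index=False)
    ncd_grid.to_csv(out / "ncd_or_table.csv", index=False)
    mortality_grid.to_csv(out / "mortality_or_table.csv", index=False)
    render_or_table(ncd_grid).to_csv(out / "ncd_or_table_rendered.csv")
    (out / "references.json").write_text(json.dumps(references, indent=2))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "simulation": cohort.config.as_dict() if config.simulation is not None else None,
        "simulation_hash": cohort.config.content_hash() if config.simulation is not None else None,
        "indices": list(config.indices),
        "outcomes": list(config.outcomes),
        "waves": list(config.waves),
        "fill_direction": config.fill_direction,
        "n_eligible": flow["eligible"],
        "failed_cells": failed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("wrote output bundle to %s (%d non-converged cells)", out, failed)
    return {"out_dir": str(out), "flow": flow, "failed_cells": failed, "manifest": manifest}


def render_or_table(grid: pd.DataFrame) -> pd.DataFrame:
    """Render the long results grid as 'OR (low-high)' cells with a
    significance marker, one row per outcome/index/model, waves as columns."""
    grid = grid[grid["contrast"].isin(["Q5 vs Q1", "Q4+5 vs Q1"])].copy()

    def _cell(r):
        if not np.isfinite(r["odds_ratio"]):
            return "inestimable"
        star = " *" if (r["ci_low"] > 1.0 or r["ci_high"] < 1.0) else ""
        return f"{r['odds_ratio']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f}){star}"

    grid["cell"] = grid.apply(_cell, axis=1)
    grid["model"] = np.where(grid["adjusted"], "multivariate", "univariate")
    wide = grid.pivot_table(
        index=["outcome", "index", "model"],
        columns="wave",
        values="cell",
        aggfunc="first",
    )
    wide.columns = [f"S{w}" for w in wide.columns]
    return wide
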