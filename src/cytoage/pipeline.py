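"""End-to-end orchestration: simulate -> summarize -> screen -> fit ->
centiles/VPC, with every output reproducible from config + seed alone.

Stage seeds are derived from the master seed by a fixed splitting rule
(``stage_seed = (master_seed * 1009 + stage_index) % 2**31``) so stages can
be re-run independently and the full pipeline is byte-identical across
runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centiles import percentile_curves, plot_centiles, vpc
from .mixed import (MixedFit, fit_all_models, fit_model, make_grouped_data,
                    select_model)
from .simulate import (DEFAULT_LIMITS, CohortConfig, apply_quantification_limits,
                       default_panel, generate_cohort, panel_from_yaml,
                       panel_to_yaml, simulate_concentrations,
                       write_observations_csv, write_subjects_csv)
from .tobit import screen_covariates, summarize_concentrations

__all__ = ["PipelineConfig", "run_pipeline", "render_tables", "stage_seed"]

log = logging.getLogger("cytoage")

_STAGES = ("simulate", "summarize", "screen", "fit", "centiles_vpc")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (master_seed * 1009 + _STAGES.index(stage)) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full run."""

    seed: int = 1
    n_subjects: int = 271
    panel_path: Optional[str] = None        # None -> built-in reference panel
    covariates: List[str] = field(default_factory=lambda: ["age", "weight_z",
                                                           "sex", "vitd"])
    model_ids: List[str] = field(default_factory=lambda: ["M2_exponential"])
    quad_nodes: int = 21
    n_starts: int = 5
    vpc_replicates: int = 200
    vpc_bins: int = 6
    make_plots: bool = False
    shared_eta: bool = False
    fit_strata: Optional[List[List[str]]] = None  # [[cytokine, condition], ...]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: PipelineConfig, out_dir) -> Dict[str, Path]:
    """Run all five stages, writing the report bundle into ``out_dir``.

    Returns a mapping of artifact name -> path.  A stage failure aborts
    with the stage name; artifacts written before the failure persist.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    artifacts: Dict[str, Path] = {"config": out / "config_resolved.yaml"}
    log_lines = [f"cytoage {__version__}", f"master seed {config.seed}"]
    t0 = time.time()

    stage = "simulate"
    try:
        panel = (default_panel() if config.panel_path is None
                 else panel_from_yaml(config.panel_path))
        subjects = generate_cohort(config.n_subjects, stage_seed(config.seed, stage))
        latent = simulate_concentrations(subjects, panel,
                                         stage_seed(config.seed, stage) + 1,
                                         shared_eta=config.shared_eta)
        observations = apply_quantification_limits(latent)
        write_subjects_csv(subjects, out / "subjects.csv")
        write_observations_csv(observations, out / "observations.csv")
        panel_to_yaml(panel, out / "panel_resolved.yaml")
        artifacts["subjects"] = out / "subjects.csv"
        artifacts["observations"] = out / "observations.csv"
        log_lines.append(f"simulate: {len(subjects)} subjects, "
                         f"{len(observations)} observations "
                         f"(seed {stage_seed(config.seed, stage)})")

        stage = "summarize"
        summary = summarize_concentrations(observations)
        summary.to_csv(out / "summary_table.csv", index=False)
        artifacts["summary_table"] = out / "summary_table.csv"
        log_lines.append(f"summarize: {len(summary)} strata")

        stage = "screen"
        assoc = screen_covariates(observations, subjects, config.covariates)
        assoc.to_csv(out / "associations.csv", index=False,
                     float_format="%.6g")
        artifacts["associations"] = out / "associations.csv"
        log_lines.append(f"screen: {int((~assoc['skipped']).sum())} fits, "
                         f"{int(assoc['skipped'].sum())} skipped")

        stage = "fit"
        if config.fit_strata is None:
            strata = [(cy, co) for (cy, co), e in sorted(panel.items())
                      if e.quantifiable]
        else:
            strata = [tuple(s) for s in config.fit_strata]
        fit_seed = stage_seed(config.seed, stage)
        table_rows = []
        chosen_fits: Dict[Tuple[str, str], MixedFit] = {}
        for cytokine, condition in strata:
            data = make_grouped_data(observations, subjects, cytokine, condition)
            if data.n_censored == data.n_obs:
                log_lines.append(f"fit: {cytokine}/{condition} skipped "
                                 "(fully censored)")
                continue
            fits = fit_all_models(data, model_ids=config.model_ids,
                                  n_nodes=config.quad_nodes,
                                  n_starts=config.n_starts, seed=fit_seed,
                                  cytokine=cytokine, condition=condition)
            if not fits:
                log_lines.append(f"fit: {cytokine}/{condition} FAILED")
                continue
            if len(fits) > 1:
                chosen_id, _ = select_model(fits)
            else:
                chosen_id = next(iter(fits))
            for mid, f in fits.items():
                f.to_json(out / f"fit_{cytokine}_{condition}_{mid}.json")
            f = fits[chosen_id]
            chosen_fits[(cytokine, condition)] = f
            table_rows.append({
                "cytokine": cytokine, "condition": condition,
                "model_id": chosen_id,
                "value_infancy": round(f.value_infancy, 4),
                "value_12y": round(f.value_12y, 4),
                "change_12y": f.change_12y,
                "iiv_cv": round(f.iiv_cv, 2),
                "ruv_cv": round(f.ruv_cv, 2),
                "loglik": round(f.loglik, 4), "aic": round(f.aic, 4),
                "converged": f.converged,
            })
        table3 = pd.DataFrame(table_rows)
        table3.to_csv(out / "table3_analogue.csv", index=False)
        artifacts["table3_analogue"] = out / "table3_analogue.csv"
        log_lines.append(f"fit: {len(chosen_fits)} strata fitted "
                         f"(seed {fit_seed})")

        stage = "centiles_vpc"
        cent_seed = stage_seed(config.seed, stage)
        cent_frames, vpc_frames = [], []
        for k, ((cytokine, condition), f) in enumerate(sorted(chosen_fits.items())):
            for basis in ("between_subject", "total"):
                curve = percentile_curves(f, basis=basis)
                cent_frames.append(curve.to_frame(cytokine, condition))
            stratum_obs = observations[(observations["cytokine"] == cytokine)
                                       & (observations["condition"] == condition)]
            v = vpc(f, stratum_obs, subjects, n_replicates=config.vpc_replicates,
                    n_bins=config.vpc_bins, seed=cent_seed + k)
            vf = v.to_frame()
            vf.insert(0, "cytokine", cytokine)
            vf.insert(1, "condition", condition)
            vpc_frames.append(vf)
            if config.make_plots:
                curve = percentile_curves(f)
                plot_centiles(curve, out / f"centiles_{cytokine}_{condition}.png",
                              cytokine, condition, stratum_obs, subjects)
        if cent_frames:
            pd.concat(cent_frames, ignore_index=True).to_csv(
                out / "centiles.csv", index=False, float_format="%.6g")
            pd.concat(vpc_frames, ignore_index=True).to_csv(
                out / "vpc.csv", index=False, float_format="%.6g")
            artifacts["centiles"] = out / "centiles.csv"
            artifacts["vpc"] = out / "vpc.csv"
        log_lines.append(f"centiles_vpc: {len(chosen_fits)} strata "
                         f"(seed {cent_seed})")
    except Exception as exc:
        log_lines.append(f"FAILED at stage {stage}: {exc!r}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log_lines.append(f"completed in {time.time() - t0:.1f} s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    artifacts["run_log"] = out / "run.log"
    return artifacts


def render_tables(out_dir) -> Path:
    """Render the report bundle into a single markdown report.

    Produces a censoring-aware summary table (with "<LLOQ"-style tokens),
    an association matrix (signed % per unit for significant fits, blank
    for non-significant, "X" where >50% of rows were censored and no
    regression was attempted), and the fitted age-model table.
    """
    out = Path(out_dir)
    needed = ["summary_table.csv", "associations.csv", "table3_analogue.csv"]
    missing = [n for n in needed if not (out / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline outputs: {missing}")

    summary = pd.read_csv(out / "summary_table.csv")
    assoc = pd.read_csv(out / "associations.csv")
    table3 = pd.read_csv(out / "table3_analogue.csv")

    lines = ["# Synthetic cohort report", ""]
    lines += ["## Concentration summary (per cytokine x condition)", ""]
    cols = ["cytokine", "condition", "n_below_lloq", "pct_below_lloq",
            "n_above_uloq", "median", "min", "max", "p25", "p75"]
    lines += _markdown_table(summary[cols])

    lines += ["", "## Covariate associations (% change per unit; "
              "blank = not significant, X = >50% censored)", ""]
    matrix = _association_matrix(assoc)
    matrix.to_csv(out / "figure2_matrix.csv")
    lines += _markdown_table(matrix.reset_index())

    lines += ["", "## Fitted age models", ""]
    if not table3.empty:
        lines += _markdown_table(table3[["cytokine", "condition", "model_id",
                                         "value_infancy", "value_12y",
                                         "change_12y", "iiv_cv", "ruv_cv"]])
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report


def _association_matrix(assoc: pd.DataFrame) -> pd.DataFrame:
    def cell(row) -> str:
        if row["skipped"]:
            return "X"
        if not bool(row["significant"]):
            return ""
        return f"{row['pct_change_per_unit']:+.0f}%"

    if assoc.empty:
        return pd.DataFrame()
    assoc = assoc.copy()
    assoc["cell"] = assoc.apply(cell, axis=1)
    return assoc.pivot_table(index=["condition", "cytokine"],
                             columns="covariate", values="cell",
                             aggfunc="first").fillna("")


def _markdown_table(df: pd.DataFrame) -> List[str]:
    if df.empty:
        return ["(empty)"]
    header = "| " + " | ".join(str(c) for c in df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = ["| " + " | ".join(str(v) for v in rec) + " |"
            for rec in df.itertuples(index=False)]
    return [header, sep] + rows
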