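"""End-to-end orchestration: data -> cohort -> instruments -> diagnostics -> estimates.

`run_pipeline` wires the stages together, writes every report table as
comma-separated text under the configured output directory, and records a
manifest (seed, config hash, package version) so that identical configs
produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balance import balance_frame, balance_table
from .cohort import (
    ExclusionRules,
    apply_exclusions,
    attach_outcome,
    filter_bmi_range,
    filter_low_dose_amitriptyline,
    select_index_prescriptions,
)
from .estimators import (
    fe_tsls,
    first_stage_diagnostics,
    hausman_dwh,
    ols_cluster,
    ps_match_rd,
    tsls,
    year_controls,
)
from .instruments import InstrumentSpec, build_instrument
from .simulate import COVARIATES, SimulationConfig, generate_population, read_tables

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "summarize_incidence"]

_INSTRUMENT_SPECS = {
    "Z1": InstrumentSpec(1, "most_recent"),
    "count3": InstrumentSpec(3, "count"),
    "ind7": InstrumentSpec(7, "indicators"),
}


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    contrast: str = "tca-ssri"
    instruments: list = field(default_factory=lambda: ["Z1", "ind7"])
    estimators: list = field(default_factory=lambda: ["ols", "iv1", "iv7"])
    window_days: int = 91
    amitriptyline_threshold: float | None = None
    linked_only: bool = False
    drop_prior_self_harm: bool = False
    output_dir: str = "results/pipeline"
    seed: int = 0

    def validate(self):
        if self.simulation is None and self.input_dir is None:
            raise ValueError("either a SimulationConfig or an input directory is required")
        if not self.instruments or not self.estimators:
            raise ValueError("at least one instrument spec and one estimator are required")
        unknown = set(self.instruments) - set(_INSTRUMENT_SPECS)
        if unknown:
            raise ValueError(f"unknown instrument spec(s): {sorted(unknown)}")

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("output_dir")  # a location, not an analytic parameter
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def summarize_incidence(cohort):
    """(events, n, rate per 100) of the attached outcome."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    events = int(cohort["Y"].sum())
    n = len(cohort)
    return events, n, 100.0 * events / n


def _estimate_stage(name, cohort, contrast):
    yv = cohort["Y"].to_numpy(np.float64)
    xv = cohort["X"].to_numpy(np.float64)
    ctrl = year_controls(cohort["index_year"]).to_numpy()
    clusters = cohort["physician_id"].to_numpy()
    if name == "ols":
        return ols_cluster(yv, xv, ctrl, clusters, name="ols"), None
    if name in ("iv1", "iv7", "fe-iv"):
        cols = ["Z1"] if name in ("iv1", "fe-iv") else [f"Z_ind7_{j}" for j in range(1, 8)]
        Z = cohort[cols].to_numpy(np.float64)
        if name == "fe-iv":
            return fe_tsls(yv, xv, Z, ctrl, clusters, name="fe-iv"), None
        est, fs = tsls(yv, xv, Z, ctrl, clusters, name=name)
        stat, p = hausman_dwh(yv, xv, Z, ctrl, clusters)
        est.diagnostics.update({"hausman_stat": stat, "hausman_p": p})
        return est, fs
    if name == "psm":
        covs = [c for c in COVARIATES if c != "bmi_over_25"]
        sub = cohort.dropna(subset=covs)
        return ps_match_rd(
            sub["Y"].to_numpy(np.float64), sub["X"].to_numpy(np.int64), sub[covs].to_numpy(np.float64)
        ), None
    raise ValueError(f"unknown estimator {name!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the report bundle as a dict of frames.

    Writes attrition, balance, first-stage and estimate tables plus a
    machine-readable summary and a run manifest under ``config.output_dir``.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        if config.simulation is not None:
            prescriptions, patients, outcomes, truth = generate_population(config.simulation)
        else:
            prescriptions, patients, outcomes, truth = read_tables(config.input_dir)

        stage = "bmi_filter"
        patients, n_bmi = filter_bmi_range(patients)

        stage = "cohort"
        candidates, record_log = select_index_prescriptions(prescriptions, patients)
        rules = ExclusionRules(contrast=config.contrast)
        cohort, attrition = apply_exclusions(candidates, patients, prescriptions, rules)
        if config.amitriptyline_threshold is not None:
            cohort, n_lowdose, _ = filter_low_dose_amitriptyline(
                cohort, prescriptions, config.amitriptyline_threshold
            )
            attrition.record("low_dose_amitriptyline", n_lowdose)

        stage = "outcome"
        cohort, outcome_info = attach_outcome(
            cohort,
            outcomes,
            window_days=config.window_days,
            drop_prior_self_harm=config.drop_prior_self_harm,
            linked_only=config.linked_only,
        )
        if config.linked_only:
            attrition.record("unlinked_practice", outcome_info["n_unlinked_dropped"])
        if config.drop_prior_self_harm:
            attrition.record("prior_self_harm_admission", outcome_info["n_prior_self_harm_dropped"])

        stage = "instruments"
        coverage_rows = []
        for key in config.instruments:
            spec = _INSTRUMENT_SPECS[key]
            cohort, (loss, pct) = build_instrument(cohort, prescriptions, spec, config.contrast)
            coverage_rows.append({"instrument": key, "rows_lost": loss, "pct_lost": round(pct, 1)})
            attrition.record(f"insufficient_history_{key}", loss)

        stage = "balance"
        rows, summary = balance_table(cohort, instrument_col="Z1", exposure_col="X")
        bal = balance_frame(rows, summary)

        stage = "first_stage"
        ctrl = year_controls(cohort["index_year"]).to_numpy()
        fs_rows = []
        for key in config.instruments:
            cols = _INSTRUMENT_SPECS[key].columns
            fs = first_stage_diagnostics(
                cohort["X"].to_numpy(np.float64),
                cohort[cols].to_numpy(np.float64),
                ctrl,
                cohort["physician_id"].to_numpy(),
            )
            fs_rows.append(
                {
                    "instrument": key,
                    "first_stage_rd_per_100": fs.first_stage_rd,
                    "partial_f": fs.partial_f,
                    "partial_r2": fs.partial_r2,
                    "n": fs.n,
                    "n_clusters": fs.n_clusters,
                }
            )

        stage = "estimate"
        est_rows = []
        for name in config.estimators:
            est, _ = _estimate_stage(name, cohort, config.contrast)
            est_rows.append(
                {
                    "estimator": est.name,
                    "rd_per_100": round(est.rd_per_100, 2),
                    "ci_low": round(est.ci_low, 2),
                    "ci_high": round(est.ci_high, 2),
                    "n": est.n,
                    "n_clusters": est.n_clusters,
                    "hausman_p": round(est.diagnostics["hausman_p"], 2)
                    if "hausman_p" in est.diagnostics
                    else np.nan,
                }
            )
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} (cohort rows so far: "
            f"{len(cohort) if 'cohort' in dir() else 'n/a'}): {exc}"
        ) from exc

    events, n, rate = summarize_incidence(cohort)
    bundle = {
        "attrition": attrition.as_frame(),
        "record_log": pd.DataFrame([record_log]),
        "coverage": pd.DataFrame(coverage_rows),
        "balance": bal,
        "first_stage": pd.DataFrame(fs_rows),
        "estimates": pd.DataFrame(est_rows),
        "cohort": cohort,
    }
    summary_json = {
        "cohort_n": len(cohort),
        "attrition_final": attrition.final_remaining,
        "events": events,
        "incidence_per_100": round(rate, 2),
        "bmi_set_missing": n_bmi,
        "outcome_info": outcome_info,
        "mahalanobis_exposure": summary.d_exposure,
        "mahalanobis_instrument": summary.d_instrument,
        "mahalanobis_reduction_pct": summary.reduction_pct,
        "estimates": est_rows,
        "first_stage": fs_rows,
    }
    manifest = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "prefiv_version": __version__,
        "n_prescriptions": len(prescriptions),
        "n_patients": len(patients),
    }
    for key in ("attrition", "record_log", "coverage", "balance", "first_stage", "estimates"):
        bundle[key].to_csv(outdir / f"{key}.csv", index=False, float_format="%.6g")
    (outdir / "summary.json").write_text(json.dumps(summary_json, indent=2, sort_keys=True, default=float))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: n=%d, %d events", len(cohort), events)
    return bundle
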