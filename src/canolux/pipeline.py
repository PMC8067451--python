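"""End-to-end orchestration: simulate → segment → fit → light → traits → stats.

``run_pipeline`` executes the enabled stages in order on one output
directory, writing the standard CSV artefacts at each stage and a versioned,
machine-readable ``report.json`` at the end.  A fixed seed makes the whole
run — images, tables and report — byte-identical across invocations.

The stages communicate through files with frozen column names, so any stage
can also be run standalone (or from the command line) on externally produced
inputs:

======================  =====================================================
stage                   artefacts
======================  =====================================================
simulate                ``treatments.csv``, ``images/`` + ``manifest.csv``,
                        ``physiology.csv``, ``harvest.csv``, ``truth.csv``
segment                 ``pcs_long.csv``
fit                     ``sigmoid_fits.csv``, ``pcs_daily.csv``
light                   ``incident_light.csv``
traits                  ``traits.csv``
stats                   ``regression_report.csv``, ``report.json``
======================  =====================================================
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth, imaging, light, stats, synthetic, traits

__all__ = ["RunConfig", "run_pipeline", "fit_trajectories", "REPORT_SCHEMA_VERSION"]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: Trait-table responses analysed in the stats stage.
TRAIT_RESPONSES = (
    "pcs_at_harvest_cm2", "total_incident_mol", "dry_weight_g",
    "leaf_area_cm2", "lue_g_mol", "sla_cm2_g", "overlap_ratio",
)
#: Physiology responses analysed in the stats stage.
PHYSIOLOGY_RESPONSES = ("cci", "aci", "phipsii", "assimilation")

ALL_STAGES = ("simulate", "segment", "fit", "light", "traits", "stats")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``use_truth_pcs`` bypasses image segmentation and feeds the generator's
    sampled PCS table straight into the growth-model stage — used both for
    speed and to isolate segmentation error.  Harvest days default to 27
    (mizuna) and 28 (lettuce) days after seeding.
    """

    out_dir: str | Path = "canolux_run"
    seed: int = 42
    stages: tuple[str, ...] = ALL_STAGES
    photoperiod_h: float = 16.0
    harvest_days: dict[str, int] = field(
        default_factory=lambda: {"mizuna": 27, "lettuce": 28}
    )
    early_days: dict[str, int] = field(
        default_factory=lambda: {"mizuna": 8, "lettuce": 10}
    )
    alpha: float = 0.05
    segmentation_method: str = "otsu"
    fixed_threshold: float | None = None
    min_object_px: int = 25
    use_truth_pcs: bool = False
    experiment: synthetic.SyntheticExperiment | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def fit_trajectories(
    pcs_long: pd.DataFrame, harvest_days: dict[str, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the logistic per experimental unit and build the daily PCS table.

    Returns ``(sigmoid_fits, pcs_daily)`` dataframes.
    """
    fit_rows, daily_rows = [], []
    keys = ["species", "ppfd", "block"]
    for (sp, ppfd, block), grp in pcs_long.groupby(keys, sort=True):
        grp = grp.sort_values("day")
        traj = growth.PCSTrajectory(
            species=sp, ppfd=ppfd, block=int(block),
            days=grp["day"].to_numpy(dtype=float),
            pcs=grp["pcs_cm2_per_plant"].to_numpy(dtype=float),
        )
        fit = growth.fit_sigmoid(traj)
        fit_rows.append({
            "species": sp, "ppfd": ppfd, "block": int(block),
            "a_cm2": fit.a, "x0_day": fit.x0, "b_day": fit.b,
            "r_squared": fit.r_squared, "residual_sd_cm2": fit.residual_sd,
            "converged": fit.converged, "n_points": fit.n_points,
        })
        hday = harvest_days[sp]
        series = growth.predict_daily(fit, hday)
        for d, v in zip(series.days, series.pcs):
            daily_rows.append({
                "species": sp, "ppfd": ppfd, "block": int(block),
                "day": int(d), "pcs_cm2_per_plant": float(v),
            })
    return pd.DataFrame(fit_rows), pd.DataFrame(daily_rows)


def _integrate_all(pcs_daily: pd.DataFrame,
                   treatments: pd.DataFrame) -> pd.DataFrame:
    dli_by_ppfd = {
        row.ppfd_umol_m2_s: light.LightTreatment(
            ppfd=row.ppfd_umol_m2_s, photoperiod_h=row.photoperiod_h
        )
        for row in treatments.itertuples(index=False)
    }
    rows = []
    for (sp, ppfd, block), grp in pcs_daily.groupby(
        ["species", "ppfd", "block"], sort=True
    ):
        grp = grp.sort_values("day")
        fit_stub = growth.SigmoidFit(1, 0, 1, 1, 0, True, 4)  # carrier only
        series = growth.DailyPCSSeries(
            days=grp["day"].to_numpy(dtype=int),
            pcs=grp["pcs_cm2_per_plant"].to_numpy(dtype=float),
            source_fit=fit_stub,
        )
        result = light.integrate_incident_light(series, dli_by_ppfd[ppfd])
        rows.append({
            "species": sp, "ppfd": ppfd, "block": int(block),
            "total_incident_mol": result.total_incident,
            "dli_mol_m2_d": result.dli,
            "harvest_day": result.harvest_day,
        })
    return pd.DataFrame(rows)


def _stats_stage(trait_table: pd.DataFrame, physiology: pd.DataFrame,
                 pcs_daily: pd.DataFrame, config: RunConfig) -> dict:
    reg_rows, regressions = [], {}
    for df, responses in ((trait_table, TRAIT_RESPONSES),
                          (physiology, PHYSIOLOGY_RESPONSES)):
        enough_ppfds = df.groupby("species")["ppfd"].nunique().min() >= 3
        if not enough_ppfds:
            log.warning("skipping regressions: < 3 PPFD levels per species")
            continue
        for response in responses:
            if response not in df.columns:
                continue
            spec = stats.RegressionSpec(response=response, alpha=config.alpha)
            res = stats.fit_species_ppfd_model(df, spec)
            regressions[response] = {
                "coefficients": res.coefficients,
                "p_values": res.p_values,
                "interaction_dropped": res.interaction_dropped,
                "r_squared": res.r_squared,
                "n": res.n,
            }
            reg_rows.append({
                "response": response,
                **{f"coef_{k}": v for k, v in res.coefficients.items()},
                **{f"p_{k}": v for k, v in res.p_values.items()},
                "interaction_dropped": res.interaction_dropped,
                "r_squared": res.r_squared,
                "n": res.n,
            })

    correlations = {}
    for sp, early_day in config.early_days.items():
        early = pcs_daily[(pcs_daily["species"] == sp)
                          & (pcs_daily["day"] == early_day)]
        dw = trait_table[trait_table["species"] == sp]
        merged = early.merge(dw, on=["species", "ppfd", "block"])
        if len(merged) >= 3:
            r, p = stats.early_pcs_correlation(
                merged["pcs_cm2_per_plant"], merged["dry_weight_g"]
            )
            correlations[sp] = {"early_day": early_day, "r": r, "p": p,
                                "n": len(merged)}
    return {"regressions": regressions,
            "early_pcs_dw_correlation": correlations,
            "report_table": pd.DataFrame(reg_rows)}


def _recovery_diagnostics(truth: pd.DataFrame, fits: pd.DataFrame,
                          trait_table: pd.DataFrame) -> dict:
    keys = ["species", "ppfd", "block"]
    m = truth.merge(fits, on=keys).merge(
        trait_table[keys + ["lue_g_mol"]], on=keys
    )
    rel = lambda est, tru: float(np.max(np.abs(est - tru) / np.abs(tru)))
    return {
        "max_rel_err_a": rel(m["a_cm2"], m["true_a_cm2"]),
        "max_rel_err_x0": rel(m["x0_day"], m["true_x0_day"]),
        "max_rel_err_b": rel(m["b_day"], m["true_b_day"]),
        "max_rel_err_lue": rel(m["lue_g_mol"], m["true_lue_g_mol"]),
        "median_r_squared": float(m["r_squared"].median()),
        "n_units": int(len(m)),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return (and write) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "seed": config.seed, "stages": {}}
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            log.info("stage=%s out=%s", stage, out)
            experiment = config.experiment or synthetic.SyntheticExperiment(
                treatments=light.default_treatments(config.photoperiod_h),
                # no point rendering images that will be bypassed
                write_images=not config.use_truth_pcs,
            )
            synthetic.generate_experiment(experiment, out, seed=config.seed)
            report["stages"]["simulate"] = {
                "n_units": (len(experiment.treatments) * experiment.n_blocks
                            * len(experiment.species)),
                "write_images": experiment.write_images,
            }

        if "segment" in config.stages:
            stage = "segment"
            log.info("stage=%s", stage)
            if config.use_truth_pcs:
                pcs_long = pd.read_csv(out / "pcs_truth_long.csv")
                report["stages"]["segment"] = {"bypassed_with_truth": True,
                                               "n_images": 0}
            else:
                pcs_long = imaging.segment_manifest(
                    out / "manifest.csv",
                    method=config.segmentation_method,
                    fixed_threshold=config.fixed_threshold,
                    min_object_px=config.min_object_px,
                )
                report["stages"]["segment"] = {"bypassed_with_truth": False,
                                               "n_images": len(pcs_long)}
            pcs_long.to_csv(out / "pcs_long.csv", index=False)

        if "fit" in config.stages:
            stage = "fit"
            log.info("stage=%s", stage)
            pcs_long = pd.read_csv(out / "pcs_long.csv")
            fits, daily = fit_trajectories(pcs_long, config.harvest_days)
            fits.to_csv(out / "sigmoid_fits.csv", index=False)
            daily.to_csv(out / "pcs_daily.csv", index=False)
            bad = fits[~fits["converged"]]
            for row in bad.itertuples(index=False):
                log.warning("unconverged fit: %s %s block %s",
                            row.species, row.ppfd, row.block)
            report["stages"]["fit"] = {
                "n_fits": len(fits),
                "n_unconverged": int((~fits["converged"]).sum()),
                "median_r_squared": float(fits["r_squared"].median()),
            }

        if "light" in config.stages:
            stage = "light"
            log.info("stage=%s", stage)
            daily = pd.read_csv(out / "pcs_daily.csv")
            treatments = pd.read_csv(out / "treatments.csv")
            incident = _integrate_all(daily, treatments)
            incident.to_csv(out / "incident_light.csv", index=False)
            report["stages"]["light"] = {"n_units": len(incident)}

        if "traits" in config.stages:
            stage = "traits"
            log.info("stage=%s", stage)
            harvest = pd.read_csv(out / "harvest.csv")
            incident = pd.read_csv(out / "incident_light.csv")
            fits = pd.read_csv(out / "sigmoid_fits.csv")
            pcs_h = fits[["species", "ppfd", "block"]].copy()
            pcs_h["pcs_at_harvest_cm2"] = [
                float(growth.sigmoid(config.harvest_days[r.species],
                                     r.a_cm2, r.x0_day, r.b_day))
                for r in fits.itertuples(index=False)
            ]
            trait_table = traits.build_trait_table(
                harvest, incident[["species", "ppfd", "block",
                                   "total_incident_mol"]], pcs_h,
            )
            trait_table.to_csv(out / "traits.csv", index=False)
            report["stages"]["traits"] = {"n_records": len(trait_table)}

        if "stats" in config.stages:
            stage = "stats"
            log.info("stage=%s", stage)
            trait_table = pd.read_csv(out / "traits.csv")
            physiology = pd.read_csv(out / "physiology.csv")
            daily = pd.read_csv(out / "pcs_daily.csv")
            st = _stats_stage(trait_table, physiology, daily, config)
            st["report_table"].to_csv(out / "regression_report.csv",
                                      index=False)
            report["stages"]["stats"] = {
                "n_regressions": len(st["regressions"]),
            }
            report["regressions"] = st["regressions"]
            report["early_pcs_dw_correlation"] = st["early_pcs_dw_correlation"]

            truth_path = out / "truth.csv"
            if truth_path.exists() and (out / "sigmoid_fits.csv").exists():
                report["recovery"] = _recovery_diagnostics(
                    pd.read_csv(truth_path),
                    pd.read_csv(out / "sigmoid_fits.csv"),
                    trait_table,
                )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
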