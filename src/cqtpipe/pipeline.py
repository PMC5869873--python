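"""End-to-end orchestration: ECG processing -> central tendency/categorical ->
NCA -> exposure-response -> effect simulation, with all report tables written
to the output directory and a plain-text run log recording seeds, library
versions and every dropped or flagged record."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, categorical, central_tendency, ecg_core, effect_simulation
from . import exposure_response as er
from . import io as pio
from . import pk_nca
from .config import PipelineConfig
from .errors import CqtPipeError


@dataclass
class PipelineResult:
    points: pd.DataFrame
    exponents: pd.DataFrame
    deltas: pd.DataFrame
    central: pd.DataFrame
    flags: pd.DataFrame
    incidence: pd.DataFrame
    nca: pd.DataFrame
    nca_summary: pd.DataFrame
    cqt_fits: list
    final_fit: er.CqtModelFit
    hr_fit: er.CqtModelFit | None
    bootstrap: dict | None
    covariate_screen: dict | None
    simulation: effect_simulation.SimulationSummary
    sim_summary_table: pd.DataFrame
    paths: dict = field(default_factory=dict)


def build_cqt_dataset(
    deltas: pd.DataFrame, pk: pd.DataFrame, metric: str = "QTcI",
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge change-from-baseline records with the time-matched parent
    concentration to form the exposure-response dataset."""
    conc = pk[pk["analyte"] == "parent"][["subject_id", "day", "time_h", "conc_nM"]]
    d = deltas.loc[deltas["metric"] == metric,
                   ["subject_id", "day", "time_h", "delta"]]
    merged = d.merge(conc, on=["subject_id", "day", "time_h"], how="inner")
    out = merged.rename(columns={"delta": "value"})[
        ["subject_id", "day", "time_h", "conc_nM", "value"]
    ]
    if covariates is not None:
        out = out.merge(covariates, on="subject_id", how="left")
    return out


def build_hr_dataset(values: pd.DataFrame, pk: pd.DataFrame) -> pd.DataFrame:
    """Heart-rate observations across all days; drug-free records carry conc 0."""
    hr = values[values["metric"] == "HR"].copy()
    conc = pk[pk["analyte"] == "parent"][["subject_id", "day", "time_h", "conc_nM"]]
    merged = hr.merge(conc, on=["subject_id", "day", "time_h"], how="left")
    merged["conc_nM"] = merged["conc_nM"].fillna(0.0)
    merged.loc[merged["day"] == -1, "conc_nM"] = 0.0
    return merged[["subject_id", "day", "time_h", "conc_nM", "value"]]


def apply_evaluability(
    deltas: pd.DataFrame, dosing_days: dict | None, min_days: int, day: int = 10
) -> tuple[pd.DataFrame, list]:
    """Drop steady-state-day records of subjects with insufficient dosing.

    ``dosing_days`` maps subject_id to consecutive dosing days completed
    before the steady-state day; subjects absent from the map are assumed
    compliant.
    """
    if not dosing_days:
        return deltas, []
    bad = [s for s, nd in dosing_days.items() if nd < min_days]
    kept = deltas[~((deltas["day"] == day) & (deltas["subject_id"].isin(bad)))]
    return kept, bad


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage on the configured inputs and write the report bundle."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg):
        log_lines.append(msg)

    note(f"cqtpipe {__version__}; numpy {np.__version__}; pandas {pd.__version__}")
    note(f"seeds: bootstrap={config.bootstrap_seed} simulation={config.sim_seed}")

    try:
        ecg = pio.read_ecg_csv(config.ecg_csv)
        pk = pio.read_pk_csv(config.pk_csv)
    except CqtPipeError as exc:
        raise CqtPipeError(f"[input] {exc}") from exc
    covariates = None
    if config.truth_csv:
        truth = pio.read_truth_csv(config.truth_csv)
        covariates = pio.truth_covariates(truth)

    # --- ECG core -----------------------------------------------------------
    try:
        exponents = ecg_core.estimate_exponents(ecg)
        points = ecg_core.average_replicates_frame(ecg)
        points = ecg_core.apply_corrections(points, exponents,
                                            include_bazett=config.include_bazett)
        metrics = list(config.correction_methods) + ["HR", "PR", "QRS"]
        if config.include_bazett and "QTcB" not in metrics:
            metrics.insert(2, "QTcB")
        values = ecg_core.to_long_metrics(points, metrics)
        deltas = ecg_core.time_matched_delta(values)
        if config.drop_predose_delta_day1:
            n0 = len(deltas)
            deltas = deltas[~((deltas["day"] == 1) & (deltas["time_h"] == 0.0))]
            note(f"dropped {n0 - len(deltas)} Day-1 predose delta records (drug-free)")
    except CqtPipeError as exc:
        raise CqtPipeError(f"[ecg_core] {exc}") from exc
    note(f"ECG: {points['subject_id'].nunique()} subjects, {len(points)} averaged points")

    # --- central tendency and categorical ----------------------------------
    try:
        central = central_tendency.fit_repeated_measures(deltas)
    except CqtPipeError as exc:
        raise CqtPipeError(f"[central_tendency] {exc}") from exc
    try:
        flags = categorical.flag_observations(values, deltas, config.thresholds,
                                              qtc_metrics=tuple(config.correction_methods))
        incidence = categorical.tabulate(flags)
    except CqtPipeError as exc:
        raise CqtPipeError(f"[categorical] {exc}") from exc

    # --- NCA ----------------------------------------------------------------
    try:
        nca = pk_nca.run_nca(pk)
        nca_summary = pk_nca.summarize_nca(nca)
    except CqtPipeError as exc:
        raise CqtPipeError(f"[pk_nca] {exc}") from exc

    # --- exposure-response --------------------------------------------------
    try:
        cqt = build_cqt_dataset(deltas, pk, metric=config.correction_methods[0],
                                covariates=covariates)
        final_fit, cqt_fits = er.fit_hierarchy(cqt, alpha=config.selection_alpha)
        note(f"C-QT model selected: {final_fit.form} ({final_fit.message})")
        screen = None
        if covariates is not None and len(covariates.columns) > 1:
            cov_names = tuple(c for c in ("sex", "bmi", "ecog") if c in cqt.columns)
            screen = er.screen_covariates(cqt, form=final_fit.form,
                                          covariates=cov_names,
                                          alpha=config.covariate_alpha)
            note(f"covariates retained: {screen['retained']} "
                 f"(skipped constant: {screen['skipped']})")
        boot = None
        if config.run_bootstrap:
            boot = er.bootstrap_cqt(cqt, final_fit.form, B=config.bootstrap_b,
                                    seed=config.bootstrap_seed)
            note(f"bootstrap: {boot['n_success']} ok, {boot['n_failed']} failed")
        hr_obs = build_hr_dataset(values, pk)
        hr_fit, _ = er.fit_hr_model(hr_obs)
        note(f"HR model selected: {hr_fit.form}; intercept "
             f"{hr_fit.theta['intercept']:.2f} bpm")
    except CqtPipeError as exc:
        raise CqtPipeError(f"[exposure_response] {exc}") from exc

    # --- effect simulation --------------------------------------------------
    try:
        draws, sim = effect_simulation.simulate_population(
            final_fit, config.reference_conc_nM, n=config.sim_n, seed=config.sim_seed
        )
        sim_table = pd.DataFrame([{
            "metric": f"d{config.correction_methods[0]}",
            **{k: getattr(sim, k) for k in (
                "n_simulated", "median", "mean", "sd", "cv_pct", "min",
                "p5", "p95", "max", "pct_gt_30", "pct_gt_60", "reference_conc_nM")},
        }])
    except CqtPipeError as exc:
        raise CqtPipeError(f"[effect_simulation] {exc}") from exc

    # --- write bundle -------------------------------------------------------
    paths = {}
    paths["exponents"] = pio.write_table(exponents, out_dir / "qtci_exponents.csv")
    paths["points"] = pio.write_table(points, out_dir / "corrected_ecg.csv")
    paths["deltas"] = pio.write_table(deltas, out_dir / "deltas.csv")
    paths["central"] = pio.write_table(central, out_dir / "central_tendency.csv")
    paths["flags"] = pio.write_table(flags, out_dir / "categorical_flags.csv")
    paths["incidence"] = pio.write_table(incidence, out_dir / "categorical_incidence.csv")
    paths["nca"] = pio.write_table(nca, out_dir / "nca_subjects.csv")
    paths["nca_summary"] = pio.write_table(nca_summary, out_dir / "nca_summary.csv")
    paths["simulation"] = pio.write_table(sim_table, out_dir / "effect_simulation.csv")
    if boot is not None and boot["band"] is not None:
        paths["bootstrap"] = pio.write_table(
            boot["parameters"].reset_index(names="parameter"),
            out_dir / "bootstrap_parameters.csv")
        paths["bootstrap_band"] = pio.write_table(boot["band"], out_dir / "bootstrap_band.csv")
    fit_json = {
        "form": final_fit.form,
        "theta": final_fit.theta,
        "omega": final_fit.omega,
        "sigma": final_fit.sigma,
        "se": final_fit.se,
        "se_pct": final_fit.se_pct,
        "ofv": final_fit.ofv,
        "n_subjects": final_fit.n_subjects,
        "n_obs": final_fit.n_obs,
    }
    (out_dir / "cqt_fit.json").write_text(json.dumps(fit_json, indent=2, default=float))
    paths["fit_json"] = out_dir / "cqt_fit.json"
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    paths["run_log"] = out_dir / "run.log"

    return PipelineResult(
        points=points, exponents=exponents, deltas=deltas, central=central,
        flags=flags, incidence=incidence, nca=nca, nca_summary=nca_summary,
        cqt_fits=cqt_fits, final_fit=final_fit, hr_fit=hr_fit, bootstrap=boot,
        covariate_screen=screen, simulation=sim, sim_summary_table=sim_table,
        paths=paths,
    )
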