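"""End-to-end orchestration: fit every model, derive thermodynamics, and
write report tables.

The pipeline consumes direct- or gravimetric-schema CSVs (see
:mod:`thermosol.io`); when no input files are given it generates a synthetic
study from the bundled ABN401 reference parameters, which makes
``run_full_pipeline`` usable as a self-contained demonstration and as a
determinism check (same config + seed → byte-identical JSON).

Stages:

1. per-solvent Apelblat / van't Hoff / λh fits;
2. per-composition fits plus the Jouyban–Acree van't Hoff surface for the
   binary mixture;
3. Yalkowsky log-linear predictions over the composition grid, scored
   against the data;
4. ideal solubility and activity coefficients;
5. van't Hoff thermodynamic decomposition (ΔH°, ΔG°, ΔS° at Thm) per
   solvent and per composition, then enthalpy–entropy compensation across
   the mixture;
6. anti-solvent composition selection from the fitted mixture surface.

A stage that fails is recorded in the report's ``failures`` manifest with
the stage name and offending input; the remaining stages still run and
partial results are still written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import refdata
from ._utils import GAS_CONSTANT
from .exceptions import ThermosolError
from .io import (
    grid_from_frame,
    read_direct_csv,
    read_gravimetric_csv,
    series_from_frame,
    write_json_records,
)
from .models import (
    MixtureGrid,
    TemperatureSeries,
    eval_yalkowsky,
    fit_apelblat,
    fit_bkm,
    fit_javh,
    fit_vanthoff,
    mrd_abs,
    select_antisolvent_composition,
)
from .synthetic import GeneratorSpec, generate_mixture_grid, generate_temperature_series
from .thermo import (
    compensation_analysis,
    harmonic_mean_temperature,
    ideal_solubility,
    vanthoff_thermo,
)

__all__ = ["RunConfig", "run_full_pipeline"]

log = logging.getLogger("thermosol.pipeline")

VERSION = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    ``series_csv`` / ``grid_csv`` point at input data (``gravimetric=True``
    switches the reader); leave both ``None`` to run on synthetic data
    generated from the bundled ABN401 reference parameters with
    ``noise_cv`` multiplicative noise. ``thm`` is either the string
    ``"auto"`` (harmonic mean of the data temperatures) or a fixed kelvin
    value. ``max_solvent_fraction`` caps the solvent-to-anti-solvent ratio
    in the precipitation-design stage.
    """

    series_csv: str | None = None
    grid_csv: str | None = None
    gravimetric: bool = False
    thm: str | float = "auto"
    output_dir: str | None = None
    seed: int = 0
    noise_cv: float = 0.03
    max_solvent_fraction: float = 0.2
    design_temperature: float = 298.15
    round_decimals: int = 6
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Hash of the scientific configuration; excludes output location and
        logging so that identical analyses hash identically."""
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("output_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class _Report:
    provenance: dict
    pure_solvent_fits: list = field(default_factory=list)
    mixture_fits: list = field(default_factory=list)
    yalkowsky: dict = field(default_factory=dict)
    activity: list = field(default_factory=list)
    thermo: list = field(default_factory=list)
    compensation: dict = field(default_factory=dict)
    antisolvent_design: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)


def _synthetic_inputs(config: RunConfig):
    """Series for every reference solvent + the reference mixture grid."""
    series = {}
    for i, solvent in enumerate(refdata.solvent_ids()):
        spec = GeneratorSpec(
            model="vanthoff",
            params=refdata.vanthoff_params(solvent),
            noise_cv=config.noise_cv,
            seed=config.seed + i,
            solvent_id=solvent,
        )
        series[solvent] = generate_temperature_series(spec)
    grid_spec = GeneratorSpec(
        model="javh",
        params=refdata.javh_params(),
        noise_cv=config.noise_cv,
        seed=config.seed + 1000,
    )
    return series, generate_mixture_grid(grid_spec)


def _load_inputs(config: RunConfig):
    read = read_gravimetric_csv if config.gravimetric else read_direct_csv
    series, grid = {}, None
    if config.series_csv is not None:
        df = read(config.series_csv)
        for solvent in df["solvent_id"].unique():
            series[solvent] = series_from_frame(df, solvent)
    if config.grid_csv is not None:
        grid = grid_from_frame(read(config.grid_csv))
    return series, grid


def _thm_for(config: RunConfig, temperatures: np.ndarray) -> float:
    if config.thm == "auto":
        return harmonic_mean_temperature(temperatures)
    return float(config.thm)


def _fit_record(solvent_id, model, params, quality, **extra) -> dict:
    return {
        "solvent_id": solvent_id,
        "model": model,
        "params": asdict(params),
        "mrd_percent": quality.mrd_percent,
        "mrd_abs_percent": quality.mrd_abs_percent,
        "rmsd": quality.rmsd,
        "n": quality.n_points,
        **extra,
    }


def _grid_column(grid: MixtureGrid, w2: float) -> TemperatureSeries:
    mask = np.isclose(grid.w2, w2)
    order = np.argsort(grid.temperatures[mask])
    return TemperatureSeries(
        solvent_id=f"w2={w2:g}",
        temperatures=grid.temperatures[mask][order],
        x=grid.x[mask][order],
    )


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report as a plain dict; if
    ``config.output_dir`` is set, also write CSV tables and ``report.json``."""
    logging.basicConfig(level=config.log_level)
    fusion = refdata.fusion_properties()
    report = _Report(
        provenance={
            "seed": config.seed,
            "version": VERSION,
            "config_hash": config.config_hash(),
            "gas_constant_J_molK": GAS_CONSTANT,
        }
    )

    if config.series_csv is None and config.grid_csv is None:
        series_by_solvent, grid = _synthetic_inputs(config)
        report.provenance["inputs"] = "synthetic (bundled ABN401 reference parameters)"
    else:
        series_by_solvent, grid = _load_inputs(config)
        report.provenance["inputs"] = "user CSV"

    # -- stage 1: per-solvent fits -------------------------------------
    mixture_thermo = []
    for solvent, series in series_by_solvent.items():
        for model, fitter in (
            ("apelblat", fit_apelblat),
            ("vanthoff", fit_vanthoff),
            ("bkm", lambda s: fit_bkm(s, Tm=fusion.Tfus)),
        ):
            try:
                params, quality = fitter(series)
                report.pure_solvent_fits.append(
                    _fit_record(solvent, model, params, quality)
                )
                log.info(
                    "fit %s/%s: n=%d rmsd=%.3g", solvent, model, quality.n_points,
                    quality.rmsd,
                )
            except ThermosolError as err:
                report.failures.append(
                    {"stage": "pure_solvent_fits", "solvent_id": solvent,
                     "model": model, "error": str(err)}
                )

        # -- stage 4/5 for pure solvents: activity + thermodynamics ----
        try:
            thm = _thm_for(config, series.temperatures)
            tres = vanthoff_thermo(series, thm)
            report.thermo.append(
                {"solvent_id": solvent, "w2": None, "dH_J_mol": tres.dH,
                 "dG_J_mol": tres.dG, "dS_J_molK": tres.dS, "Thm_K": tres.Thm}
            )
            for T, xe in zip(series.temperatures, series.x):
                xidl = ideal_solubility(fusion, T)
                report.activity.append(
                    {"solvent_id": solvent, "T_K": float(T), "x_ideal": float(xidl),
                     "x_exp": float(xe), "gamma": float(xidl / xe)}
                )
        except ThermosolError as err:
            report.failures.append(
                {"stage": "thermo", "solvent_id": solvent, "error": str(err)}
            )

    # -- stages 2-6 for the binary mixture -----------------------------
    javh_fit = None
    if grid is not None:
        compositions = np.unique(grid.w2)
        for w2 in compositions:
            column = _grid_column(grid, w2)
            for model, fitter in (
                ("apelblat", fit_apelblat),
                ("vanthoff", fit_vanthoff),
                ("bkm", lambda s: fit_bkm(s, Tm=fusion.Tfus)),
            ):
                try:
                    params, quality = fitter(column)
                    report.mixture_fits.append(
                        _fit_record(None, model, params, quality, w2=float(w2))
                    )
                except ThermosolError as err:
                    report.failures.append(
                        {"stage": "mixture_fits", "w2": float(w2), "model": model,
                         "error": str(err)}
                    )
            try:
                thm = _thm_for(config, column.temperatures)
                tres = vanthoff_thermo(column, thm)
                rec = {"solvent_id": None, "w2": float(w2), "dH_J_mol": tres.dH,
                       "dG_J_mol": tres.dG, "dS_J_molK": tres.dS, "Thm_K": tres.Thm}
                report.thermo.append(rec)
                mixture_thermo.append(tres)
            except ThermosolError as err:
                report.failures.append(
                    {"stage": "thermo", "w2": float(w2), "error": str(err)}
                )

        try:
            javh_params, javh_quality = fit_javh(grid)
            javh_fit = javh_params
            report.mixture_fits.append(
                _fit_record(None, "javh", javh_params, javh_quality, w2=None)
            )
            log.info("fit javh: n=%d mrd_abs=%.3g%%", javh_quality.n_points,
                     javh_quality.mrd_abs_percent)
        except ThermosolError as err:
            report.failures.append({"stage": "javh", "error": str(err)})

        # Yalkowsky predictions from the grid's own pure-solvent endpoints
        try:
            report.yalkowsky = _yalkowsky_stage(grid)
        except ThermosolError as err:
            report.failures.append({"stage": "yalkowsky", "error": str(err)})

        try:
            slope, intercept = compensation_analysis(mixture_thermo)
            report.compensation = {"slope": slope, "intercept": intercept,
                                   "n": len(mixture_thermo)}
        except ThermosolError as err:
            report.failures.append({"stage": "compensation", "error": str(err)})

        if javh_fit is not None:
            try:
                w2_star, x_pred = select_antisolvent_composition(
                    javh_fit, config.design_temperature,
                    config.max_solvent_fraction,
                )
                report.antisolvent_design = {
                    "w2_star": w2_star, "predicted_x": x_pred,
                    "T_K": config.design_temperature,
                    "max_solvent_fraction": config.max_solvent_fraction,
                }
            except ThermosolError as err:
                report.failures.append({"stage": "antisolvent_design",
                                        "error": str(err)})

    out = {
        "provenance": report.provenance,
        "pure_solvent_fits": report.pure_solvent_fits,
        "mixture_fits": report.mixture_fits,
        "yalkowsky": report.yalkowsky,
        "activity": report.activity,
        "thermo": report.thermo,
        "compensation": report.compensation,
        "antisolvent_design": report.antisolvent_design,
        "failures": report.failures,
    }
    if config.output_dir is not None:
        _write_outputs(out, config)
    return out


def _yalkowsky_stage(grid: MixtureGrid) -> dict:
    """Log-linear predictions over the grid from its w2 = 0 / w2 = 1 columns."""
    compositions = np.unique(grid.w2)
    if not (np.isclose(compositions, 0.0).any() and np.isclose(compositions, 1.0).any()):
        raise ThermosolError("Yalkowsky stage needs both pure-solvent endpoints")
    end0 = _grid_column(grid, 0.0)
    end1 = _grid_column(grid, 1.0)
    lnx0 = dict(zip(end0.temperatures, np.log(end0.x)))
    lnx1 = dict(zip(end1.temperatures, np.log(end1.x)))
    rows, by_T = [], {}
    for T in sorted(lnx0):
        if T not in lnx1:
            continue
        mask = np.isclose(grid.temperatures, T)
        w2s = grid.w2[mask]
        lnx_pred = eval_yalkowsky(lnx0[T], lnx1[T], w2s)
        for w2, v in zip(w2s, np.atleast_1d(lnx_pred)):
            rows.append({"w2": float(w2), "T_K": float(T), "lnx_pred": float(v)})
        by_T[float(T)] = mrd_abs(grid.x[mask], np.exp(np.atleast_1d(lnx_pred)))
    overall = float(np.mean(list(by_T.values()))) if by_T else float("nan")
    return {"rows": rows, "mrd_abs_percent_by_T": by_T,
            "mrd_abs_percent_overall": overall}


def _write_outputs(report: dict, config: RunConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_json_records(outdir / "report.json", report, report["provenance"])

    def _flat(records):
        rows = []
        for r in records:
            row = {k: v for k, v in r.items() if k != "params"}
            for name, value in r.get("params", {}).items():
                row[f"param_{name}"] = value
            rows.append(row)
        return pd.DataFrame(rows)

    if report["pure_solvent_fits"]:
        _flat(report["pure_solvent_fits"]).to_csv(
            outdir / "pure_solvent_fits.csv", index=False
        )
    if report["mixture_fits"]:
        _flat(report["mixture_fits"]).to_csv(outdir / "mixture_fits.csv", index=False)
    if report["yalkowsky"]:
        pd.DataFrame(report["yalkowsky"]["rows"]).to_csv(
            outdir / "yalkowsky.csv", index=False
        )
    if report["activity"]:
        pd.DataFrame(report["activity"]).to_csv(outdir / "activity.csv", index=False)
    if report["thermo"]:
        pd.DataFrame(report["thermo"]).to_csv(outdir / "thermo.csv", index=False)
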