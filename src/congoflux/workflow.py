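"""End-to-end pipeline: chamber series → fluxes → summaries → basin table.

``run_pipeline`` chains the stages on whatever inputs are supplied —
chamber series and flux panels always; stream vials and isotope pairs
when present (skipped with a log note otherwise) — writing one CSV per
stage plus a provenance JSON (config hash, seed, package version) so a
rerun with the same inputs and config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chamber import compute_flux
from .dissolved import headspace_to_dissolved, saturation_ratio
from .fluxstats import TransformSpec, fit_geometric_mean_model
from .isotopes import classify_endmember, reduction_projection, two_source_mixing
from .tables import (
    CHAMBER_SERIES_SCHEMA,
    ISOTOPE_PAIR_SCHEMA,
    PANEL_SCHEMA,
    SUMMARY_SCHEMA,
    VIAL_SCHEMA,
    PipelineConfig,
    pairs_from_table,
    read_table,
    series_from_table,
    vials_from_table,
    write_table,
)
from .units import nmol_to_annual
from .upscale import TypeEstimate, basin_weighted_mean, swamp_composite

log = logging.getLogger("congoflux")


def choose_transform(values: np.ndarray, method: str = "auto") -> TransformSpec:
    """Resolve the log-transform strategy for a flux panel.

    ``auto`` picks log_positive for all-positive panels, negate_log for
    all-negative (uptake) panels, and shifted_log otherwise with
    c = |min| + 10% of the flux range — an explicit, logged choice since
    no transform of mixed-sign data is canonical.
    """
    v = np.asarray(values, dtype=float)
    if method != "auto":
        if method == "shifted_log":
            return TransformSpec("shifted_log", shift=_auto_shift(v))
        return TransformSpec(method)
    if np.all(v > 0):
        return TransformSpec("log_positive")
    if np.all(v < 0):
        return TransformSpec("negate_log")
    spec = TransformSpec("shifted_log", shift=_auto_shift(v))
    log.info("mixed-sign panel: shifted_log with c = %.6g", spec.shift)
    return spec


def _auto_shift(v: np.ndarray) -> float:
    rng = float(v.max() - v.min())
    return float(abs(v.min()) + 0.1 * (rng if rng > 0 else max(abs(v.min()), 1.0)))


def summarize_panel(
    panel: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Geometric-mean summary per forest type (swamp split by inundation).

    Fluxes are converted to kg element ha⁻¹ yr⁻¹ when the panel declares
    nmol units and the config asks for annual units.  Returns one row
    per (species, forest type, inundation regime) with the
    back-transformed point estimate and 95% CI.
    """
    df = panel.copy()
    if "species" not in df.columns:
        df["species"] = "N2O"
    if "inundated" not in df.columns:
        df["inundated"] = False
    df["inundated"] = df["inundated"].fillna(False).astype(bool)
    units = df["units"].iloc[0] if "units" in df.columns else "nmol_m2_s"
    if units == "nmol_m2_s" and config.units == "kg_ha_yr":
        df["flux"] = [nmol_to_annual(f, s) for f, s in zip(df["flux"], df["species"])]
        units = "kg_ha_yr"
    rows = []
    group_cols = ["species", "forest_type", "inundated"]
    for (species, ftype, inundated), grp in df.groupby(group_cols, sort=True):
        transform = choose_transform(
            grp["flux"].to_numpy(), config.transforms.get(species, "auto")
        )
        res = fit_geometric_mean_model(grp, transform)
        rows.append(
            {
                "species": species,
                "forest_type": ftype,
                "inundated": inundated,
                "point": res.geometric_mean,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "transform": transform.method,
                "n_obs": res.n_obs,
                "n_chambers": res.n_chambers,
                "n_dates": res.n_dates,
                "units": units,
            }
        )
    return pd.DataFrame(rows)


def upscale_summaries(
    summaries: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> pd.DataFrame:
    """Basin-wide coverage-weighted flux per species from a summary table."""
    summaries = summaries.copy()
    if "species" not in summaries.columns:
        summaries["species"] = "N2O"
    rows = []
    for species, grp in summaries.groupby("species"):
        est = {}
        swamp_parts = {}
        for _, row in grp.iterrows():
            te = TypeEstimate(
                forest_type=row["forest_type"],
                point=float(row["point"]),
                ci_low=float(row["ci_low"]),
                ci_high=float(row["ci_high"]),
            )
            inund = bool(row["inundated"]) if "inundated" in row and not pd.isna(row["inundated"]) else False
            if row["forest_type"] == "swamp":
                swamp_parts[inund] = te
            else:
                est[row["forest_type"]] = te
        if len(swamp_parts) == 2:
            est["swamp"] = swamp_composite(
                swamp_parts[True], swamp_parts[False], config.weights.inundated_fraction
            )
        elif len(swamp_parts) == 1:
            est["swamp"] = next(iter(swamp_parts.values()))
        basin = basin_weighted_mean(est, config.weights)
        rows.append(
            {
                "species": species,
                "point": basin.point,
                "ci_low": basin.ci_low,
                "ci_high": basin.ci_high,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    inputs: dict[str, str | Path],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Execute the available stages and write per-stage CSVs.

    ``inputs`` maps stage names to file paths: "series" (chamber time
    series), "panel" (flux panel), "vials" (stream vials), "pairs"
    (isotope pairs).  Returns {stage: output path}.  A stage whose input
    is absent is skipped with a log note; any stage error aborts with
    the stage name in the message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    report: list[str] = []

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    if "series" in inputs:
        def _flux():
            df, errors = read_table(inputs["series"], CHAMBER_SERIES_SCHEMA)
            report.extend(f"series line {e.line}: {e.message}" for e in errors)
            rows = []
            for series in series_from_table(df):
                est = compute_flux(series, config.geometry)
                rows.append(
                    {
                        "chamber_id": est.chamber_id,
                        "species": est.species,
                        "flux_nmol_m2_s": est.flux,
                        "slope_nmol_mol_s": est.slope,
                        "r_squared": est.r_squared,
                        "n_points": est.n_points,
                        "qc_pass": est.qc_pass,
                        "retained": est.retained,
                    }
                )
            path = out_dir / "fluxes.csv"
            write_table(pd.DataFrame(rows), path)
            return path

        written["fluxes"] = _stage("flux-compute", _flux)
    else:
        log.info("no chamber series input: flux stage skipped")

    if "vials" in inputs:
        def _dissolved():
            df, errors = read_table(inputs["vials"], VIAL_SCHEMA)
            report.extend(f"vials line {e.line}: {e.message}" for e in errors)
            rows = []
            for vial in vials_from_table(df):
                res = headspace_to_dissolved(vial, config.solubility[vial.species])
                rows.append(
                    {
                        "species": vial.species,
                        "concentration_mol_L": res.concentration_molar,
                        "concentration_ug_L": res.concentration_mass,
                        "saturation_ratio": saturation_ratio(
                            res.concentration_mass,
                            vial.species,
                            vial.equilibration_temperature,
                            config.atm_ppb[vial.species],
                            config.solubility[vial.species],
                        ),
                    }
                )
            path = out_dir / "dissolved.csv"
            write_table(pd.DataFrame(rows), path)
            return path

        written["dissolved"] = _stage("dissolved", _dissolved)
    else:
        log.info("no stream vial input: dissolved stage skipped")

    if "pairs" in inputs:
        def _isotopes():
            df, errors = read_table(inputs["pairs"], ISOTOPE_PAIR_SCHEMA)
            report.extend(f"pairs line {e.line}: {e.message}" for e in errors)
            rows = []
            for pair in pairs_from_table(df):
                sig = two_source_mixing(pair)
                row = {
                    "chamber_id": sig.chamber_id,
                    "delta_n2o_ppb": sig.delta_n2o,
                    "d15n_flux": sig.d15n_flux,
                    "d18o_flux": sig.d18o_flux,
                    "sp_flux": sig.sp_flux,
                    "valid": sig.valid,
                    "reason": sig.reason,
                }
                if sig.valid:
                    progress, residual = reduction_projection(
                        (sig.d15n_flux, sig.d18o_flux)
                    )
                    row["reduction_progress"] = progress
                    row["reduction_residual"] = residual
                    row["endmember"] = classify_endmember(
                        (sig.d15n_flux, sig.d18o_flux), config.endmember_boxes
                    )
                rows.append(row)
            path = out_dir / "signatures.csv"
            write_table(pd.DataFrame(rows), path)
            return path

        written["signatures"] = _stage("isotopes", _isotopes)
    else:
        log.info("no isotope pair input: isotope stage skipped")

    if "panel" in inputs:
        def _summarize():
            df, errors = read_table(inputs["panel"], PANEL_SCHEMA)
            report.extend(f"panel line {e.line}: {e.message}" for e in errors)
            summaries = summarize_panel(df, config)
            path = out_dir / "summaries.csv"
            write_table(summaries, path)
            return path, summaries

        path, summaries = _stage("summarize", _summarize)
        written["summaries"] = path

        present = set(summaries["forest_type"])
        if present >= {"lowland", "swamp", "montane"}:
            def _upscale():
                basin = upscale_summaries(summaries, config)
                path = out_dir / "basin.csv"
                write_table(basin, path)
                return path

            written["basin"] = _stage("upscale", _upscale)
        else:
            log.info(
                "panel covers %s only: basin upscaling needs all three forest types, skipped",
                sorted(present),
            )
    elif "summaries" in inputs:
        def _upscale_file():
            df, errors = read_table(inputs["summaries"], SUMMARY_SCHEMA)
            report.extend(f"summaries line {e.line}: {e.message}" for e in errors)
            basin = upscale_summaries(df, config)
            path = out_dir / "basin.csv"
            write_table(basin, path)
            return path

        written["basin"] = _stage("upscale", _upscale_file)
    else:
        log.info("no panel or summaries input: summarize/upscale stages skipped")

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "inputs": {k: str(v) for k, v in sorted(inputs.items())},
        "row_errors": report,
    }
    prov_path = out_dir / "provenance.json"
    prov_path.write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    written["provenance"] = prov_path
    return written
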