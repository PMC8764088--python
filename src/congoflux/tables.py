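"""Delimited-table readers/writers with schema validation, and YAML config.

All files are comma-delimited UTF-8 text with dot decimals and ISO-8601
dates; gas mole fractions are always nmol mol⁻¹ (ppb).  Readers validate
the header (order-free), coerce types, and collect row-level failures
into an error report with line numbers instead of aborting on the first
bad row; a missing required column is a file-level schema error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chamber import ChamberGeometry, DEFAULT_GEOMETRY, HeadspaceSeries
from .dissolved import DEFAULT_ATM_PPB, DEFAULT_SOLUBILITY, SolubilityParams, VialSample
from .isotopes import DEFAULT_ENDMEMBER_BOXES, EndmemberBoxes, IsotopePair
from .upscale import CoverageWeights


class SchemaError(ValueError):
    """Header does not match the expected schema."""


@dataclass(frozen=True)
class Column:
    name: str
    kind: str = "float"  # float | str | bool
    required: bool = True
    minimum: float | None = None


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[Column, ...]

    def required_names(self) -> list[str]:
        return [c.name for c in self.columns if c.required]


CHAMBER_SERIES_SCHEMA = TableSchema(
    "chamber_series",
    (
        Column("chamber_id", "str"),
        Column("species", "str"),
        Column("time_min", "float", minimum=0.0),
        Column("mole_fraction_ppb", "float", minimum=0.0),
        Column("temp_C", "float"),
        Column("pressure_atm", "float", required=False, minimum=0.0),
    ),
)

VIAL_SCHEMA = TableSchema(
    "vials",
    (
        Column("species", "str"),
        Column("water_ml", "float", minimum=0.0),
        Column("headspace_ml", "float", minimum=0.0),
        Column("temp_C", "float"),
        Column("pressure_atm", "float", required=False, minimum=0.0),
        Column("x_hs_ppb", "float", minimum=0.0),
        Column("x_init_ppb", "float", required=False, minimum=0.0),
    ),
)

ISOTOPE_PAIR_SCHEMA = TableSchema(
    "isotope_pairs",
    (
        Column("chamber_id", "str"),
        Column("c_start", "float", minimum=0.0),
        Column("c_end", "float", minimum=0.0),
        Column("d15n_start", "float"),
        Column("d15n_end", "float"),
        Column("d18o_start", "float"),
        Column("d18o_end", "float"),
        Column("d15n_alpha_start", "float", required=False),
        Column("d15n_alpha_end", "float", required=False),
        Column("d15n_beta_start", "float", required=False),
        Column("d15n_beta_end", "float", required=False),
    ),
)

PANEL_SCHEMA = TableSchema(
    "flux_panel",
    (
        Column("site", "str"),
        Column("forest_type", "str"),
        Column("plot", "str", required=False),
        Column("chamber_id", "str"),
        Column("date", "str"),
        Column("flux", "float"),
        Column("soil_temperature", "float", required=False),
        Column("wfps", "float", required=False),
        Column("vwc", "float", required=False),
        Column("inundated", "bool", required=False),
        Column("units", "str", required=False),
        Column("species", "str", required=False),
    ),
)

SUMMARY_SCHEMA = TableSchema(
    "summaries",
    (
        Column("forest_type", "str"),
        Column("species", "str", required=False),
        Column("point", "float"),
        Column("ci_low", "float"),
        Column("ci_high", "float"),
        Column("inundated", "bool", required=False),
    ),
)


def _parse_float(s):
    try:
        return float(s)
    except (TypeError, ValueError):
        return float("nan")


@dataclass
class RowError:
    line: int  # 1-based file line number (header = line 1)
    message: str


def read_table(path: str | Path, schema: TableSchema) -> tuple[pd.DataFrame, list[RowError]]:
    """Read and validate a delimited table against ``schema``.

    Returns the valid rows (typed) and a report of per-row failures;
    raises :class:`SchemaError` if required columns are missing.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in schema.required_names() if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing} for {schema.name}")
    errors: list[RowError] = []
    out: dict[str, list] = {}
    keep = np.ones(len(raw), dtype=bool)
    for col in schema.columns:
        if col.name not in raw.columns:
            continue
        values = raw[col.name]
        if col.kind == "str":
            out[col.name] = values.astype(str)
            continue
        if col.kind == "bool":
            mapped = values.str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
            bad = values.notna() & mapped.isna()
            for i in np.flatnonzero(bad.to_numpy()):
                errors.append(RowError(i + 2, f"{col.name}: unparseable boolean {values.iloc[i]!r}"))
            keep &= ~bad.to_numpy()
            out[col.name] = mapped
            continue
        # Python float() is an exact shortest-repr parser; pandas' fast
        # to_numeric path is lossy in the last ulp and breaks round-trips.
        nums = values.map(_parse_float)
        bad = values.notna() & nums.isna()
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append(RowError(i + 2, f"{col.name}: unparseable number {values.iloc[i]!r}"))
        if col.minimum is not None:
            neg = nums.notna() & (nums < col.minimum)
            for i in np.flatnonzero(neg.to_numpy()):
                errors.append(
                    RowError(i + 2, f"{col.name}: value {nums.iloc[i]} below minimum {col.minimum}")
                )
            bad = bad | neg
        keep &= ~bad.to_numpy()
        out[col.name] = nums
    df = pd.DataFrame(out)[[c.name for c in schema.columns if c.name in raw.columns]]
    return df[keep].reset_index(drop=True), errors


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# table <-> domain-object conversion


def series_from_table(df: pd.DataFrame) -> list[HeadspaceSeries]:
    """Group a chamber-series table into one HeadspaceSeries per (chamber, species)."""
    out = []
    for (chamber_id, species), grp in df.groupby(["chamber_id", "species"], sort=False):
        grp = grp.sort_values("time_min")
        pressure = float(grp["pressure_atm"].iloc[0]) if "pressure_atm" in grp else 1.0
        out.append(
            HeadspaceSeries(
                chamber_id=str(chamber_id),
                species=str(species),
                times=tuple(grp["time_min"]),
                mole_fractions=tuple(grp["mole_fraction_ppb"]),
                temperatures=tuple(grp["temp_C"] + 273.15),
                pressure=pressure,
            )
        )
    return out


def _num_or(row: pd.Series, name: str, default: float) -> float:
    value = row.get(name, default)
    if pd.isna(value):
        return default
    return float(value)


def vials_from_table(df: pd.DataFrame) -> list[VialSample]:
    out = []
    for _, row in df.iterrows():
        out.append(
            VialSample(
                species=str(row["species"]),
                water_volume=float(row["water_ml"]),
                headspace_volume=float(row["headspace_ml"]),
                equilibration_temperature=float(row["temp_C"]) + 273.15,
                headspace_mole_fraction=float(row["x_hs_ppb"]),
                lab_pressure=_num_or(row, "pressure_atm", 1.0),
                initial_headspace_mole_fraction=_num_or(row, "x_init_ppb", 0.0),
            )
        )
    return out


def pairs_from_table(df: pd.DataFrame) -> list[IsotopePair]:
    def opt(row, name):
        if name in row and pd.notna(row[name]):
            return float(row[name])
        return None

    out = []
    for _, row in df.iterrows():
        out.append(
            IsotopePair(
                chamber_id=str(row["chamber_id"]),
                c_start=float(row["c_start"]),
                c_end=float(row["c_end"]),
                d15n_start=float(row["d15n_start"]),
                d15n_end=float(row["d15n_end"]),
                d18o_start=float(row["d18o_start"]),
                d18o_end=float(row["d18o_end"]),
                d15n_alpha_start=opt(row, "d15n_alpha_start"),
                d15n_alpha_end=opt(row, "d15n_alpha_end"),
                d15n_beta_start=opt(row, "d15n_beta_start"),
                d15n_beta_end=opt(row, "d15n_beta_end"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PipelineConfig:
    """Bundled defaults for a full pipeline run; all fields YAML-overridable."""

    geometry: ChamberGeometry = DEFAULT_GEOMETRY
    solubility: dict[str, SolubilityParams] = field(
        default_factory=lambda: dict(DEFAULT_SOLUBILITY)
    )
    atm_ppb: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ATM_PPB))
    transforms: dict[str, str] = field(
        default_factory=lambda: {"CH4": "auto", "N2O": "auto"}
    )
    weights: CoverageWeights = CoverageWeights()
    endmember_boxes: EndmemberBoxes = field(
        default_factory=lambda: EndmemberBoxes(dict(DEFAULT_ENDMEMBER_BOXES))
    )
    units: str = "kg_ha_yr"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        kwargs = {}
        if "geometry" in raw:
            g = raw["geometry"]
            if "d" in g or "diameter" in g:
                kwargs["geometry"] = ChamberGeometry.from_cylinder(
                    float(g.get("d", g.get("diameter"))), float(g.get("h", g.get("height")))
                )
            else:
                kwargs["geometry"] = ChamberGeometry(
                    volume=float(g["volume"]), area=float(g["area"]), kind=g.get("kind", "static")
                )
        if "solubility" in raw:
            kwargs["solubility"] = {
                sp: SolubilityParams(sp, float(v["kH_298"]), float(v["vant_hoff"]))
                for sp, v in raw["solubility"].items()
            }
        if "atm_ppb" in raw:
            kwargs["atm_ppb"] = {k: float(v) for k, v in raw["atm_ppb"].items()}
        if "transforms" in raw:
            kwargs["transforms"] = dict(raw["transforms"])
        if "weights" in raw:
            w = raw["weights"]
            kwargs["weights"] = CoverageWeights(
                lowland=float(w.get("lowland", 0.906)),
                swamp=float(w.get("swamp", 0.068)),
                montane=float(w.get("montane", 0.026)),
                inundated_fraction=float(w.get("inundated_fraction", 0.5)),
            )
        if "endmember_boxes" in raw:
            kwargs["endmember_boxes"] = EndmemberBoxes(
                {k: tuple(map(float, v)) for k, v in raw["endmember_boxes"].items()}
            )
        if "units" in raw:
            kwargs["units"] = str(raw["units"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return replace(cfg, **kwargs)

    def digest(self) -> str:
        blob = json.dumps(
            {
                "geometry": [self.geometry.volume, self.geometry.area, self.geometry.kind],
                "solubility": {
                    k: [v.kH_298, v.vant_hoff] for k, v in sorted(self.solubility.items())
                },
                "atm_ppb": dict(sorted(self.atm_ppb.items())),
                "transforms": dict(sorted(self.transforms.items())),
                "weights": [
                    self.weights.lowland,
                    self.weights.swamp,
                    self.weights.montane,
                    self.weights.inundated_fraction,
                ],
                "endmember_boxes": {
                    k: list(v) for k, v in sorted(self.endmember_boxes.boxes.items())
                },
                "units": self.units,
                "seed": self.seed,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
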