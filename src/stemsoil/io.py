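"""Table readers/writers, configuration handling and run manifests.

CSV dialect: comma-separated, UTF-8, '.' decimal separator, mandatory
header row.  Inputs must NOT use thousands separators (Austrian-style
"385.000" notation is rejected by the numeric parser as three-decimal
values would be — write plain integers).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, SchemaError

SOIL_COLUMNS = [
    "site",
    "survey_year",
    "distance_cm",
    "horizon_top_cm",
    "horizon_bottom_cm",
    "ph_h2o",
    "ca_exch_mg_g",
    "mg_exch_mg_g",
    "c_mg_g",
    "n_mg_g",
    "s_mg_g",
    "bulk_density_g_cm3",
]
OPTIONAL_SOIL_COLUMNS = ["stone_fraction", "replicate"]

GRID_COLUMNS = ["x_cm", "y_cm", "ph_h2o"]

FLUX_COLUMNS = ["year", "tf_s", "sf_s"]
OPTIONAL_FLUX_COLUMNS = ["tf_water", "sf_water"]


def _read_table(
    path: str | Path,
    required: Sequence[str],
    optional: Sequence[str],
    string_cols: Sequence[str] = (),
) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in (*required, *optional)]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}")
    for col in df.columns:
        if col in string_cols:
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            lines = [int(i) + 2 for i in df.index[bad][:5]]
            raise SchemaError(
                f"{path}: unparseable numeric in column {col!r} at line(s) {lines}"
            )
        df[col] = numeric
    return df


def read_soil_table(path: str | Path) -> pd.DataFrame:
    """Read a tidy soil-sample table (one row per sampled horizon)."""
    return _read_table(path, SOIL_COLUMNS, OPTIONAL_SOIL_COLUMNS, string_cols=("site",))


def write_soil_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_grid_table(path: str | Path) -> pd.DataFrame:
    """Read a grid pH table (x_cm, y_cm, ph_h2o; stem at the origin)."""
    return _read_table(path, GRID_COLUMNS, ())


def write_grid_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_flux_table(path: str | Path) -> pd.DataFrame:
    """Read an annual deposition table (year, tf_s, sf_s[, tf_water, sf_water])."""
    return _read_table(path, FLUX_COLUMNS, OPTIONAL_FLUX_COLUMNS)


# -- configuration ---------------------------------------------------------

#: Allowed configuration keys per section (fail-fast on anything else).
CONFIG_SCHEMA: Mapping[str, set | None] = {
    "seed": None,
    "stand": {
        "crown_projection_area_m2",
        "stem_radius_cm",
        "base_delay_years",
        "columns",
        "flux_table",
    },
    "scenario": {
        "load_1983",
        "input_2013",
        "output_2013",
        "delay_years",
        "start_year",
        "anchor_year",
        "horizon_year",
        "input_after_anchor",
        "output_after_anchor",
        "column_distance_cm",
    },
    "sweep": {"loads", "column_distance_cm"},
    "synthetic": {"survey", "deposition", "grid"},
    "tables": {"soil", "grid"},
    "analysis": {
        "variable",
        "element",
        "survey_year",
        "idw_power",
        "extent_cm",
        "spacing_cm",
    },
}

_COLUMN_KEYS = {
    "distance_cm",
    "routing_fraction",
    "infiltration_area_m2",
    "water_time_factor",
    "delay_years",
}

_SYNTH_SUBSECTIONS = {"survey", "deposition", "grid"}
_GRID_KEYS = {"extent_cm", "spacing_cm", "year"}
_DEPOSITION_KEYS = {"seed", "noise_sd"}


def validate_config(cfg: Mapping) -> None:
    """Reject unknown sections/keys; nested synthetic sections included."""
    if not isinstance(cfg, Mapping):
        raise ConfigError("config root must be a mapping")
    for key, value in cfg.items():
        if key not in CONFIG_SCHEMA:
            raise ConfigError(f"unknown config section {key!r}")
        allowed = CONFIG_SCHEMA[key]
        if allowed is None:
            continue
        if not isinstance(value, Mapping):
            raise ConfigError(f"config section {key!r} must be a mapping")
        bad = set(value) - allowed
        if bad:
            raise ConfigError(f"unknown key(s) {sorted(bad)} in section {key!r}")
    stand = cfg.get("stand", {})
    for col in stand.get("columns", []) or []:
        bad = set(col) - _COLUMN_KEYS
        if bad:
            raise ConfigError(f"unknown column key(s) {sorted(bad)}")
    synth = cfg.get("synthetic", {})
    if "grid" in synth:
        bad = set(synth["grid"]) - _GRID_KEYS
        if bad:
            raise ConfigError(f"unknown key(s) {sorted(bad)} in synthetic.grid")
    if "deposition" in synth:
        bad = set(synth["deposition"]) - _DEPOSITION_KEYS
        if bad:
            raise ConfigError(f"unknown key(s) {sorted(bad)} in synthetic.deposition")


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def config_digest(cfg: Mapping) -> str:
    """Stable SHA-256 digest of a configuration mapping."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run (what ran, on what, producing what)."""

    command: str
    config_hash: str
    seed: int | None
    input_files: list[str] = field(default_factory=list)
    output_files: list[str] = field(default_factory=list)
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
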