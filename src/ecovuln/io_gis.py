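"""File formats and run configuration.

The canonical raster exchange format is the ESRI ASCII grid (``.asc``):
a six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by row-major values, top row first.  It is
human-readable and round-trips bit-exactly when written with full float
repr, which the tests rely on.  Station tables are CSV with columns
``x, y, value``.  The run configuration is YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core_model import ClassificationScheme, GridSpec, RasterLayer
from .errors import FormatError, ValidationError
from .interpolation import IdwParams, StationSet

__all__ = [
    "read_stations",
    "write_stations",
    "read_raster",
    "write_raster",
    "IndicatorSpec",
    "RunConfig",
    "load_config",
]

GROUPS = ("exposure", "sensitivity", "adaptation")
POLARITIES = ("direct", "inverse")


def read_stations(path: str | Path, name: str | None = None) -> StationSet:
    """Read a station CSV (header ``x,y,value``) into a StationSet."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no stations (empty file)")
    missing = {"x", "y", "value"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: no stations")
    for col in ("x", "y", "value"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2  # 1-based, after header
            raise FormatError(f"{path}: non-numeric {col!r} at line {row}")
        df[col] = numeric
    dup = df.duplicated(subset=["x", "y"])
    if dup.any():
        row = int(dup.idxmax())
        raise FormatError(
            f"{path}: duplicated coordinates ({df.x[row]}, {df.y[row]}) at line {row + 2}"
        )
    return StationSet(
        name or path.stem, df["x"].to_numpy(), df["y"].to_numpy(), df["value"].to_numpy()
    )


def write_stations(stations: StationSet, path: str | Path) -> None:
    pd.DataFrame({"x": stations.x, "y": stations.y, "value": stations.values}).to_csv(
        path, index=False
    )


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_raster(path: str | Path, name: str | None = None) -> RasterLayer:
    """Read an ESRI ASCII grid; sentinel cells become NaN in memory."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise FormatError(f"{path}: bad header line {line!r}")
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: header missing {key!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    tokens = " ".join(lines[i:]).split()
    try:
        flat = np.array(tokens, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: unreadable data block: {exc}")
    if flat.size != nrows * ncols:
        raise FormatError(
            f"{path}: expected {nrows * ncols} values ({nrows}x{ncols}), got {flat.size}"
        )
    values = flat.reshape(nrows, ncols)
    values[values == nodata] = np.nan
    grid = GridSpec(
        nrows,
        ncols,
        header.get("xllcorner", 0.0),
        header.get("yllcorner", 0.0),
        header["cellsize"],
        nodata,
    )
    return RasterLayer(grid, name or path.stem, values)


def write_raster(layer: RasterLayer, path: str | Path) -> None:
    """Write an ESRI ASCII grid with full-precision floats."""
    g = layer.grid
    vals = np.where(layer.valid_mask, layer.values, g.nodata_value)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_origin!r}\n")
        fh.write(f"yllcorner {g.y_origin!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {g.nodata_value!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


@dataclass
class IndicatorSpec:
    """One indicator's source and role in the two index systems."""

    name: str
    source: str  # "stations" | "raster"
    path: str
    group: str  # exposure | sensitivity | adaptation
    polarity: str = "direct"  # direct | inverse


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    indicators: list[IndicatorSpec]
    grid: GridSpec
    idw: IdwParams = field(default_factory=IdwParams)
    retention_threshold: float = 0.80
    scheme: ClassificationScheme = field(default_factory=ClassificationScheme)
    seed: int = 0
    outdir: str = "results"
    mask_path: str | None = None  # optional validity-mask raster
    province_path: str | None = None

    @property
    def indicator_names(self) -> list[str]:
        return [ind.name for ind in self.indicators]

    def group_members(self, group: str) -> list[str]:
        return [ind.name for ind in self.indicators if ind.group == group]


def _validate(cfg: RunConfig, base: Path) -> list[str]:
    problems: list[str] = []
    names = cfg.indicator_names
    if len(set(names)) != len(names):
        problems.append("duplicate indicator names")
    for ind in cfg.indicators:
        if ind.group not in GROUPS:
            problems.append(f"indicator {ind.name!r}: unknown group {ind.group!r}")
        if ind.polarity not in POLARITIES:
            problems.append(f"indicator {ind.name!r}: unknown polarity {ind.polarity!r}")
        if ind.source not in ("stations", "raster"):
            problems.append(f"indicator {ind.name!r}: unknown source {ind.source!r}")
        if not (base / ind.path).exists():
            problems.append(f"indicator {ind.name!r}: file not found: {ind.path}")
    if not cfg.indicators:
        problems.append("no indicators configured")
    if not (0.0 < cfg.retention_threshold <= 1.0):
        problems.append(
            f"retention threshold must be in (0, 1], got {cfg.retention_threshold}"
        )
    for attr in ("mask_path", "province_path"):
        p = getattr(cfg, attr)
        if p is not None and not (base / p).exists():
            problems.append(f"{attr}: file not found: {p}")
    return problems


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Validation is total: every problem is collected and reported at
    once, so a valid config never fails downstream for structural
    reasons.  Relative paths are resolved against the config file's
    directory.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")

    try:
        g = raw["grid"]
        grid = GridSpec(
            int(g["n_rows"]),
            int(g["n_cols"]),
            float(g.get("x_origin", 0.0)),
            float(g.get("y_origin", 0.0)),
            float(g.get("cell_size", 1000.0)),
            float(g.get("nodata_value", -9999.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: grid definition missing {exc}")

    indicators = [
        IndicatorSpec(
            name=str(item["name"]),
            source=str(item.get("source", "raster")),
            path=str(item["path"]),
            group=str(item.get("group", "")),
            polarity=str(item.get("polarity", "direct")),
        )
        for item in raw.get("indicators", [])
    ]
    idw_raw = raw.get("idw", {})
    neighbors = idw_raw.get("neighbors", 12)
    cfg = RunConfig(
        indicators=indicators,
        grid=grid,
        idw=IdwParams(
            power=float(idw_raw.get("power", 2.0)),
            neighbors=None if neighbors in (None, "all") else int(neighbors),
        ),
        retention_threshold=float(raw.get("retention_threshold", 0.80)),
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "results")),
        mask_path=raw.get("mask"),
        province_path=raw.get("provinces"),
    )
    base = path.parent
    problems = _validate(cfg, base)
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    # resolve paths relative to the config file
    for ind in cfg.indicators:
        ind.path = str(base / ind.path)
    if cfg.mask_path:
        cfg.mask_path = str(base / cfg.mask_path)
    if cfg.province_path:
        cfg.province_path = str(base / cfg.province_path)
    return cfg
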