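"""Seeded generator of a synthetic country with the statistical
structure the vulnerability analysis assumes.

The generator emulates the inventory a national assessment draws on,
without any real geography:

* **Climate** (4 indicators) — sparse stations sampled noiselessly from
  smooth Gaussian random fields carrying a planted north–south gradient
  (the south more vulnerable), to be gridded by IDW.
* **Socio-economic** (4) — province-constant layers from provincial
  statistics, with one small extreme-density province (a "Littoral-like"
  economic capital two orders of magnitude denser than the rest).
* **Thematic** (4) — continuous fields at a finer native resolution
  (exercising bilinear resampling); the NDVI-like greenness layer is
  negatively coupled to density (dense provinces have less vegetation).
* **Hazard** (3) — patchy blob-shaped frequency layers with a mild
  southern bias.

Everything flows from one seed: identical config + seed give
byte-identical outputs.  A ground-truth table records the planted
gradient and per-province parameters so recovery tests can score the
pipeline against what was actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .core_model import GridSpec, RasterLayer
from .errors import StructuralError
from .interpolation import StationSet

__all__ = ["SyntheticConfig", "gaussian_field", "make_country", "CountryBundle"]

CLIMATE = ("temperature", "rainfall", "humidity", "sunlight")
SOCIO = ("population", "density", "gdp", "houses")
THEMATIC = ("ndvi", "elevation", "slope", "carbon")
HAZARD = ("flood", "drought", "fire")

#: Indicator -> additive-system component, in canonical column order.
DEFAULT_GROUPS = {
    **{name: "exposure" for name in CLIMATE},
    "flood": "exposure",
    "drought": "exposure",
    **{name: "sensitivity" for name in ("population", "density", "houses") + THEMATIC[:4]},
    "gdp": "adaptation",
    "fire": "adaptation",
}
DEFAULT_GROUPS["carbon"] = "sensitivity"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic country.

    ``gradient_strength`` is the fraction of each climate field's
    variance carried by the planted north–south linear trend (0 = pure
    smooth noise, 1 = pure trend).
    """

    seed: int = 0
    n_rows: int = 100
    n_cols: int = 80
    cell_size: float = 1000.0  # meters; 1-km analysis cells
    n_provinces: int = 12
    n_stations: int = 30
    smoothing_radius: float = 10.0  # Gaussian sigma, in cells
    gradient_strength: float = 0.7
    hazard_blobs: int = 8
    hazard_radius: float = 6.0  # cells
    extreme_area_fraction: float = 0.01
    extreme_density_multiplier: float = 200.0
    fine_factor: int = 2  # thematic native resolution refinement

    def __post_init__(self) -> None:
        if not (0.0 <= self.gradient_strength <= 1.0):
            raise StructuralError("gradient_strength must be in [0, 1]")
        for attr in ("n_rows", "n_cols", "n_provinces", "n_stations", "hazard_blobs", "fine_factor"):
            if getattr(self, attr) < 1:
                raise StructuralError(f"{attr} must be positive")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, 0.0, 0.0, self.cell_size)

    @property
    def fine_grid(self) -> GridSpec:
        return GridSpec(
            self.n_rows * self.fine_factor,
            self.n_cols * self.fine_factor,
            0.0,
            0.0,
            self.cell_size / self.fine_factor,
        )


def gaussian_field(
    grid: GridSpec,
    smoothing_radius: float,
    seed: int | np.random.Generator,
    mask: np.ndarray | None = None,
) -> RasterLayer:
    """Smooth standardized Gaussian random field on a grid.

    White noise is convolved with a Gaussian kernel (sigma =
    ``smoothing_radius`` cells; radius 0 returns the raw noise), then
    standardized to zero mean and unit variance over the valid mask.
    """
    if smoothing_radius < 0:
        raise StructuralError("smoothing radius must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    smooth = gaussian_filter(noise, smoothing_radius) if smoothing_radius > 0 else noise
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    vals = np.where(mask, smooth, np.nan)
    m, s = np.nanmean(vals), np.nanstd(vals)
    return RasterLayer(grid, "field", (vals - m) / s)


def _north_south_gradient(grid: GridSpec) -> np.ndarray:
    """Unit-variance linear trend increasing southwards (row 0 = north)."""
    rows = np.arange(grid.n_rows, dtype=float)
    g = np.repeat(rows[:, None], grid.n_cols, axis=1)
    return (g - g.mean()) / g.std()


def _country_mask(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Ellipse-based country outline with a noisy coastline."""
    grid = cfg.grid
    r = (np.arange(grid.n_rows) - (grid.n_rows - 1) / 2) / (grid.n_rows / 2)
    c = (np.arange(grid.n_cols) - (grid.n_cols - 1) / 2) / (grid.n_cols / 2)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    radius = np.sqrt(rr**2 + cc**2)
    wobble = gaussian_filter(rng.standard_normal(grid.shape), 8.0)
    wobble = wobble / (np.abs(wobble).max() + 1e-12)
    return radius <= 0.95 + 0.12 * wobble


def _provinces(cfg: SyntheticConfig, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Partition the mask into provinces (nearest-seed regions), then
    carve a small southern disk as the extreme province (highest id)."""
    valid = np.argwhere(mask)
    seeds = valid[rng.choice(len(valid), size=cfg.n_provinces - 1, replace=False)]
    seed_img = np.zeros(mask.shape, dtype=int)
    seed_img[seeds[:, 0], seeds[:, 1]] = np.arange(1, cfg.n_provinces)
    # nearest seed by Euclidean distance (a Voronoi-style growth)
    _, (ir, ic) = distance_transform_edt(seed_img == 0, return_indices=True)
    prov = seed_img[ir, ic]
    prov[~mask] = 0

    # small extreme province in the southern third
    south = valid[valid[:, 0] >= int(cfg.n_rows * 0.7)]
    center = south[rng.integers(len(south))]
    target_cells = max(1, int(cfg.extreme_area_fraction * len(valid)))
    radius = np.sqrt(target_cells / np.pi)
    rr, cc = np.meshgrid(np.arange(cfg.n_rows), np.arange(cfg.n_cols), indexing="ij")
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    prov[disk & mask] = cfg.n_provinces
    return prov


@dataclass
class CountryBundle:
    """In-memory synthetic inputs plus the planted ground truth."""

    config: SyntheticConfig
    mask: np.ndarray
    provinces: np.ndarray  # 0 outside the country, 1..n_provinces inside
    stations: dict[str, StationSet]
    rasters: dict[str, RasterLayer]  # indicator -> native-resolution layer
    groups: dict[str, str]
    truth: pd.DataFrame  # per-layer generation record
    province_table: pd.DataFrame

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    @property
    def gradient(self) -> RasterLayer:
        """The planted north–south trend on the analysis grid (truth)."""
        vals = np.where(self.mask, _north_south_gradient(self.grid), np.nan)
        return RasterLayer(self.grid, "planted_gradient", vals)

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write every input as text files readable by :mod:`ecovuln.io_gis`.

        Returns indicator -> relative path, plus province/mask/truth
        entries.
        """
        from . import io_gis

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}
        for name, st in self.stations.items():
            rel = f"stations_{name}.csv"
            io_gis.write_stations(st, outdir / rel)
            paths[name] = rel
        for name, lyr in self.rasters.items():
            rel = f"{name}.asc"
            io_gis.write_raster(lyr, outdir / rel)
            paths[name] = rel
        prov_layer = RasterLayer(
            self.grid, "provinces", np.where(self.mask, self.provinces, np.nan)
        )
        io_gis.write_raster(prov_layer, outdir / "provinces.asc")
        paths["provinces"] = "provinces.asc"
        mask_layer = RasterLayer(self.grid, "mask", np.where(self.mask, 1.0, np.nan))
        io_gis.write_raster(mask_layer, outdir / "mask.asc")
        paths["mask"] = "mask.asc"
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.province_table.to_csv(outdir / "provinces.csv", index=False)
        paths["truth"] = "truth.csv"
        return paths

    def write_config(self, outdir: str | Path, **overrides) -> Path:
        """Write the bundle plus a matching YAML run config; returns its path."""
        import yaml

        outdir = Path(outdir)
        paths = self.write(outdir)
        g = self.grid
        cfg = {
            "grid": {
                "n_rows": g.n_rows,
                "n_cols": g.n_cols,
                "x_origin": g.x_origin,
                "y_origin": g.y_origin,
                "cell_size": g.cell_size,
            },
            "idw": {"power": 2.0, "neighbors": 12},
            "retention_threshold": 0.80,
            "seed": self.config.seed,
            "mask": paths["mask"],
            "provinces": paths["provinces"],
            "indicators": [
                {
                    "name": name,
                    "source": "stations" if name in self.stations else "raster",
                    "path": paths[name],
                    "group": self.groups[name],
                    "polarity": "direct",
                }
                for name in list(self.stations) + list(self.rasters)
            ],
        }
        cfg.update(overrides)
        path = outdir / "config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)
        return path


def _blend(field: np.ndarray, gradient: np.ndarray, g: float) -> np.ndarray:
    """Variance-preserving mix: fraction g of variance from the trend."""
    return np.sqrt(g) * gradient + np.sqrt(1.0 - g) * field


def make_country(cfg: SyntheticConfig = SyntheticConfig()) -> CountryBundle:
    """Generate the full synthetic input bundle for one seed."""
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid
    mask = _country_mask(cfg, rng)
    provinces = _provinces(cfg, mask, rng)
    gradient = _north_south_gradient(grid)
    g = cfg.gradient_strength
    truth_rows = []

    # climate stations: noiseless samples of smooth + trend fields
    stations: dict[str, StationSet] = {}
    scale = {"temperature": (28.0, 3.0), "rainfall": (1000.0, 200.0),
             "humidity": (60.0, 12.0), "sunlight": (6.5, 1.2)}
    valid = np.argwhere(mask)
    for name in CLIMATE:
        fld = gaussian_field(grid, cfg.smoothing_radius, rng, mask).values
        mixed = _blend(fld, gradient, g)
        loc, sd = scale[name]
        surface = loc + sd * mixed
        idx = rng.choice(len(valid), size=min(cfg.n_stations, len(valid)), replace=False)
        pts = valid[idx]
        xs, ys = [], []
        for r, c in pts:
            x, y = grid.cell_center(int(r), int(c))
            xs.append(x)
            ys.append(y)
        stations[name] = StationSet(name, np.array(xs), np.array(ys), surface[pts[:, 0], pts[:, 1]])
        truth_rows.append((name, "climate", g, cfg.smoothing_radius))

    # province-level socio-economic statistics -> province-constant layers
    prov_ids = np.arange(1, cfg.n_provinces + 1)
    prov_rows = []
    centroid_row = np.array(
        [np.argwhere(provinces == pid)[:, 0].mean() if (provinces == pid).any() else 0.0
         for pid in prov_ids]
    )
    south_score = g * (centroid_row - centroid_row.mean()) / (centroid_row.std() + 1e-12)
    base = {
        "population": 3e5 * np.exp(0.6 * south_score + 0.3 * rng.standard_normal(cfg.n_provinces)),
        "density": 60.0 * np.exp(0.7 * south_score + 0.3 * rng.standard_normal(cfg.n_provinces)),
        "gdp": 1e9 * np.exp(0.45 * south_score + 0.4 * rng.standard_normal(cfg.n_provinces)),
        "houses": 5e4 * np.exp(0.6 * south_score + 0.3 * rng.standard_normal(cfg.n_provinces)),
    }
    base["density"][-1] *= cfg.extreme_density_multiplier  # the Littoral-like province
    rasters: dict[str, RasterLayer] = {}
    for name in SOCIO:
        vals = np.full(grid.shape, np.nan)
        for pid, v in zip(prov_ids, base[name]):
            vals[provinces == pid] = v
        rasters[name] = RasterLayer(grid, name, vals)
        truth_rows.append((name, "socioeconomic", 0.0, 0.0))
    for i, pid in enumerate(prov_ids):
        prov_rows.append((int(pid), int((provinces == pid).sum()),
                          float(base["density"][i]), float(base["population"][i])))

    # thematic layers at finer native resolution (bilinear-resampling input)
    fine = cfg.fine_grid
    f = cfg.fine_factor
    fine_mask = np.repeat(np.repeat(mask, f, axis=0), f, axis=1)
    fine_gradient = _north_south_gradient(fine)
    dens_coarse = np.log(np.where(mask, rasters["density"].values, np.nan))
    dens_fine = np.repeat(np.repeat(dens_coarse, f, axis=0), f, axis=1)
    dens_std = (dens_fine - np.nanmean(dens_fine)) / (np.nanstd(dens_fine) + 1e-12)
    for name in THEMATIC:
        fld = gaussian_field(fine, cfg.smoothing_radius * f, rng, fine_mask).values
        if name == "ndvi":
            mixed = -0.7 * dens_std + 0.5 * fld - 0.3 * np.sqrt(g) * fine_gradient
            vals = 0.55 + 0.18 * mixed / (np.nanstd(mixed) + 1e-12)
        elif name == "elevation":
            mixed = _blend(fld, -fine_gradient, 0.5 * g)  # higher ground north
            vals = 250.0 + 120.0 * mixed
        elif name == "slope":
            gy, gx = np.gradient(np.nan_to_num(fld))
            vals = np.where(fine_mask, np.hypot(gx, gy), np.nan)
            vals = vals / (np.nanstd(vals) + 1e-12) * 3.0 + 2.0
        else:  # soil organic carbon
            vals = 15.0 + 5.0 * _blend(fld, fine_gradient, 0.3 * g)
        rasters[name] = RasterLayer(fine, name, np.where(fine_mask, vals, np.nan))
        truth_rows.append((name, "thematic", g, cfg.smoothing_radius * f))

    # patchy hazard-frequency layers with a southern bias
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols), indexing="ij")
    for name in HAZARD:
        freq = np.zeros(grid.shape)
        # bias blob centers south in proportion to the planted gradient
        weights = np.exp(0.8 * g * gradient[mask])
        weights /= weights.sum()
        centers = valid[rng.choice(len(valid), size=cfg.hazard_blobs, p=weights)]
        for r0, c0 in centers:
            d2 = (rr - r0) ** 2 + (cc - c0) ** 2
            freq += np.exp(-d2 / (2.0 * cfg.hazard_radius**2))
        freq += 0.05 * rng.standard_normal(grid.shape)
        rasters[name] = RasterLayer(grid, name, np.where(mask, np.clip(freq, 0, None), np.nan))
        truth_rows.append((name, "hazard", g, cfg.hazard_radius))

    truth = pd.DataFrame(
        truth_rows, columns=["indicator", "group_kind", "gradient_strength", "smoothing"]
    )
    province_table = pd.DataFrame(
        prov_rows, columns=["province_id", "cells", "density", "population"]
    )
    return CountryBundle(
        cfg, mask, provinces, stations, rasters, dict(DEFAULT_GROUPS), truth, province_table
    )
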