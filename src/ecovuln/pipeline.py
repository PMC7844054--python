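"""One-call orchestration of the hybrid vulnerability analysis.

Stages, in order: station interpolation (IDW) -> bilinear resampling to
the analysis grid -> polarity-aware min-max standardization -> fishnet
extraction -> composite EVI (PCA) and additive EVI (E/S/A) ->
classification and area accounting -> Moran's I and Gi* hot spots ->
Pearson / regression comparison of the two systems -> best-subsets
weight enhancement and observed-vs-enhanced comparison.  Failures are
raised immediately with the failing stage named; everything already
written stays on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_gis
from .additive_index import additive_evi, component_index, equal_weights
from .composite_pca import (
    PCAResult,
    WeightVector,
    composite_evi,
    pca_fit,
    retain_components,
    variance_weights,
)
from .core_model import (
    AreaReport,
    RasterLayer,
    area_by_class,
    classify_surface,
    compare_reports,
)
from .enhancement import best_subsets, enhanced_evi, reweight
from .errors import EcovulnError
from .interpolation import idw_surface
from .preprocess import ObservationMatrix, build_matrix, minmax_normalize, resample_bilinear
from .spatial_stats import (
    MoranResult,
    build_weights,
    getis_ord_gstar,
    linear_fit,
    morans_i,
    pearson_matrix,
)

log = logging.getLogger("ecovuln")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a full run produces, in memory."""

    config: io_gis.RunConfig
    matrix: ObservationMatrix
    pca: PCAResult
    q: int
    cumulative_pct: float
    composite_weights: WeightVector
    evi_pca: RasterLayer
    evi_pca_raw: RasterLayer
    components: dict[str, RasterLayer]
    evi_ad: RasterLayer
    areas_pca: AreaReport
    areas_ad: AreaReport
    moran_pca: MoranResult
    moran_ad: MoranResult
    pearson: pd.DataFrame
    regression: "pd.Series"
    enhanced: dict[str, dict] = field(default_factory=dict)
    system_comparison: pd.DataFrame | None = None


class StageError(EcovulnError):
    """Wraps a failure with the pipeline stage that raised it."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage
        self.cause = err


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as err:
                raise StageError(name, err) from err

        return wrapper

    return deco


@_stage("preprocess")
def _load_standardized(cfg: io_gis.RunConfig, mask: np.ndarray | None):
    layers = {}
    for ind in cfg.indicators:
        if ind.source == "stations":
            st = io_gis.read_stations(ind.path, name=ind.name)
            lyr = idw_surface(st, cfg.grid, cfg.idw, mask=mask)
        else:
            lyr = io_gis.read_raster(ind.path, name=ind.name)
            if lyr.grid != cfg.grid:
                lyr = resample_bilinear(lyr, cfg.grid)
            if mask is not None:
                lyr = lyr.with_values(np.where(mask, lyr.values, np.nan))
        std = minmax_normalize(lyr, ind.polarity)
        log.info("  %-12s polarity=%s source=%s", ind.name, ind.polarity, ind.source)
        layers[ind.name] = std
    return layers


def run_pipeline(cfg: io_gis.RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full hybrid analysis for a validated configuration.

    When ``outdir`` is given, writes all rasters (.asc), report CSVs and
    a JSON run log there.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    mask = None
    if cfg.mask_path:
        mask = io_gis.read_raster(cfg.mask_path).valid_mask

    layers = _load_standardized(cfg, mask)

    @_stage("matrix")
    def _matrix():
        return build_matrix(list(layers.values()), order=cfg.indicator_names)

    matrix = _matrix()

    @_stage("composite")
    def _composite():
        pca = pca_fit(matrix)
        q, cum = retain_components(pca, cfg.retention_threshold)
        w = variance_weights(pca.eigenvalues[:q])
        raw, evi = composite_evi(pca, w, matrix)
        return pca, q, cum, w, raw, evi

    pca, q, cum, w_pca, evi_pca_raw, evi_pca = _composite()
    log.info("retained %d components, cumulative %.3f%%", q, cum)

    @_stage("additive")
    def _additive():
        comps = {}
        for comp in ("exposure", "sensitivity", "adaptation"):
            comps[comp] = component_index(layers, cfg.group_members(comp), comp)
        evi = additive_evi(
            comps["exposure"], comps["sensitivity"], comps["adaptation"], equal_weights()
        )
        return comps, evi

    components, evi_ad = _additive()

    @_stage("classify")
    def _areas():
        return (
            area_by_class(classify_surface(evi_pca, cfg.scheme)),
            area_by_class(classify_surface(evi_ad, cfg.scheme)),
        )

    areas_pca, areas_ad = _areas()

    @_stage("autocorrelation")
    def _moran():
        weights = build_weights(evi_pca.valid_mask, "queen", True)
        return (
            morans_i(evi_pca, weights),
            morans_i(evi_ad, weights),
            getis_ord_gstar(evi_pca, weights),
            getis_ord_gstar(evi_ad, weights),
        )

    moran_pca, moran_ad, hot_pca, hot_ad = _moran()
    log.info("Moran's I: composite %.6f, additive %.6f", moran_pca.I, moran_ad.I)

    @_stage("comparison")
    def _compare():
        m = evi_pca.valid_mask & evi_ad.valid_mask
        table = pd.DataFrame(
            {
                "EVI_ad": evi_ad.values[m],
                "adaptation": components["adaptation"].values[m],
                "sensitivity": components["sensitivity"].values[m],
                "exposure": components["exposure"].values[m],
                "EVI_pca": evi_pca.values[m],
                **{
                    f"PC{i + 1}": matrix.to_raster(pca.scores[:, i], f"PC{i+1}").values[m]
                    for i in range(q)
                },
            }
        )
        corr = pearson_matrix(table)
        fit = linear_fit(
            table["EVI_ad"].to_numpy(),
            table[["adaptation", "sensitivity", "exposure"]],
        )
        reg = pd.Series(
            {"R": fit.r, "R2": fit.r2, "R2_adj": fit.r2_adj, **fit.coefficients.to_dict()}
        )
        return table, corr, reg

    comp_table, pearson, regression = _compare()

    @_stage("enhancement")
    def _enhance():
        from .composite_pca import orientation_sign

        result = {}
        # composite branch: observed EVI regressed on its retained scores;
        # scores are sign-aligned with the EVI orientation so the
        # self-calibration coefficients come out nonnegative
        y = evi_pca.values[evi_pca.valid_mask]
        sign = orientation_sign(pca.scores[:, :q] @ w_pca.weights, matrix)
        preds = pd.DataFrame({f"PC{i + 1}": sign * pca.scores[:, i] for i in range(q)})
        bs = best_subsets(y, preds)
        w_enh = reweight(bs.fit.coefficients, component_names=list(preds.columns),
                         selected=list(bs.subset))
        surf, comp = enhanced_evi(
            "pca", w_enh, matrix=matrix, scores=pca.scores,
            observed=evi_pca, scheme=cfg.scheme,
        )
        result["pca"] = {"weights": w_enh, "subset": bs.subset, "surface": surf,
                         "comparison": comp, "fit": bs.fit}
        # additive branch
        y2 = evi_ad.values[evi_ad.valid_mask]
        preds2 = comp_table[["exposure", "sensitivity", "adaptation"]]
        bs2 = best_subsets(y2, preds2)
        w2 = reweight(bs2.fit.coefficients,
                      component_names=["exposure", "sensitivity", "adaptation"],
                      selected=list(bs2.subset))
        surf2, comp2 = enhanced_evi(
            "additive", w2,
            components=[components["exposure"], components["sensitivity"],
                        components["adaptation"]],
            observed=evi_ad, scheme=cfg.scheme,
        )
        result["additive"] = {"weights": w2, "subset": bs2.subset, "surface": surf2,
                              "comparison": comp2, "fit": bs2.fit}
        return result

    enhanced = _enhance()

    system_comparison = compare_reports(areas_ad, areas_pca)

    result = PipelineResult(
        cfg, matrix, pca, q, cum, w_pca, evi_pca, evi_pca_raw, components, evi_ad,
        areas_pca, areas_ad, moran_pca, moran_ad, pearson, regression, enhanced,
        system_comparison,
    )

    if out is not None:
        _write_outputs(result, hot_pca, hot_ad, out)
    return result


@_stage("write")
def _write_outputs(res: PipelineResult, hot_pca, hot_ad, out: Path) -> None:
    io_gis.write_raster(res.evi_pca, out / "evi_pca.asc")
    io_gis.write_raster(res.evi_pca_raw, out / "evi_pca_raw.asc")
    io_gis.write_raster(res.evi_ad, out / "evi_ad.asc")
    for name, lyr in res.components.items():
        io_gis.write_raster(lyr, out / f"{name}.asc")
    io_gis.write_raster(hot_pca.grid_z, out / "gistar_pca.asc")
    io_gis.write_raster(hot_ad.grid_z, out / "gistar_ad.asc")
    for sysname, d in res.enhanced.items():
        io_gis.write_raster(d["surface"], out / f"evi_{sysname}_enhanced.asc")
        d["comparison"].to_csv(out / f"areas_{sysname}_obs_vs_enh.csv", index=False)
    res.pca.report().to_csv(out / "pca_report.csv", index=False)
    res.pca.loadings_frame().to_csv(out / "pca_loadings.csv")
    res.areas_pca.to_frame().to_csv(out / "areas_pca.csv", index=False)
    res.areas_ad.to_frame().to_csv(out / "areas_ad.csv", index=False)
    res.system_comparison.to_csv(out / "areas_ad_vs_pca.csv", index=False)
    res.pearson.to_csv(out / "pearson.csv")
    res.regression.to_csv(out / "regression.csv", header=["value"])
    runlog = {
        "seed": res.config.seed,
        "idw": {"power": res.config.idw.power, "neighbors": res.config.idw.neighbors},
        "retention_threshold": res.config.retention_threshold,
        "retained_components": res.q,
        "cumulative_pct": res.cumulative_pct,
        "composite_weights": res.composite_weights.weights.tolist(),
        "enhanced_weights": {
            k: d["weights"].weights.tolist() for k, d in res.enhanced.items()
        },
        "moran": {"composite": res.moran_pca.I, "additive": res.moran_ad.I},
        "indicators": [
            {"name": i.name, "group": i.group, "polarity": i.polarity,
             "source": i.source}
            for i in res.config.indicators
        ],
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(runlog, fh, indent=2)
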