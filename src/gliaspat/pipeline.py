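"""End-to-end pipeline: segmentation → point statistics → phenotype
clustering → Ripley territory analysis → Dixon segregation, over a set of
retinas organised in treatment groups.

The run is driven by a JSON-serialisable :class:`RunConfig`. Every retina
provides either an image (TIFF, segmented here) or a pre-extracted point
table plus boundary polygon. All randomness flows from config seeds, so a
rerun with the same config reproduces every numeric output byte for byte.
Outputs and their provenance are listed in a machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dixon as dixon_mod
from . import io as gio
from . import phenotyping, pointstats, ripley
from .patterns import PointPattern
from .segmentation import SegmentationParams, segment_image

log = logging.getLogger("gliaspat")


@dataclass
class RetinaSource:
    """One retina's inputs: an image to segment, or a point table +
    boundary; the ONH centre is always supplied manually."""

    retina_id: str
    group: str
    image_path: str | None = None
    point_table_path: str | None = None
    boundary_path: str | None = None
    onh_x_um: float = 0.0
    onh_y_um: float = 0.0

    def __post_init__(self) -> None:
        if self.image_path is None and self.point_table_path is None:
            raise ValueError(
                f"retina {self.retina_id!r}: need an image or a point table"
            )
        if self.point_table_path is not None and self.boundary_path is None:
            raise ValueError(
                f"retina {self.retina_id!r}: point-table input needs a boundary"
            )


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (JSON round-trippable)."""

    retinas: list[RetinaSource]
    output_dir: str = "gliaspat_out"
    pixel_size_um: float = 1.24
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    r_max_um: float = 150.0
    r_step_um: float = 1.0
    edge_correction: str = "translation"
    artefact_floor_um: float = ripley.DEFAULT_ARTEFACT_FLOOR_UM
    cluster_seed: int = 0
    cluster_starts: int = 10
    eccentricity_bin_um: float = 50.0
    nnd_map_range_um: tuple[float, float] = (15.0, 70.0)
    write_maps: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        doc["retinas"] = [RetinaSource(**r) for r in doc["retinas"]]
        seg = doc.get("segmentation")
        if isinstance(seg, dict):
            if "low_intensity_range" in seg:
                seg["low_intensity_range"] = tuple(seg["low_intensity_range"])
            doc["segmentation"] = SegmentationParams(**seg)
        if "nnd_map_range_um" in doc:
            doc["nnd_map_range_um"] = tuple(doc["nnd_map_range_um"])
        return cls(**doc)


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage and retina where it arose."""

    def __init__(self, stage: str, retina_id: str | None, cause: Exception):
        self.stage = stage
        self.retina_id = retina_id
        where = f" (retina {retina_id})" if retina_id else ""
        super().__init__(f"stage {stage!r}{where}: {cause}")


def _load_retina(src: RetinaSource, config: RunConfig):
    """One retina → (PointPattern, area_mm2, particle frame)."""
    if src.point_table_path is not None:
        frame = gio.read_point_table(src.point_table_path)
        window = gio.read_boundary_csv(src.boundary_path)
        pattern = gio.pattern_from_table(frame, window, src.retina_id)
        return pattern, window.area / 1e6, frame
    image = gio.read_tiff(src.image_path, config.pixel_size_um)
    particles = segment_image(image, config.segmentation)
    from .segmentation import retina_area_and_boundary

    area_mm2, window = retina_area_and_boundary(
        image, config.segmentation.low_intensity_range,
        config.segmentation.tissue_is_complement,
    )
    frame = gio.particles_to_frame(particles, src.retina_id, src.group)
    pattern = PointPattern(
        frame[["x_um", "y_um"]].to_numpy(float), window,
        retina_id=src.retina_id, group=src.group,
    )
    return pattern, area_mm2, frame


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage over every retina; returns the manifest dict.

    Files are written under ``config.output_dir``; any stage failure raises
    :class:`StageError` after preserving the outputs produced so far.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "stages": {}, "retinas": {}}
    radii = np.arange(0.0, config.r_max_um + config.r_step_um / 2,
                      config.r_step_um)

    def _register(key: str, path: Path):
        manifest["outputs"].setdefault(key, []).append(str(path))

    # ---- stage: load / segment -------------------------------------------
    t0 = time.perf_counter()
    patterns: dict[str, PointPattern] = {}
    areas: dict[str, float] = {}
    frames: list[pd.DataFrame] = []
    for src in config.retinas:
        try:
            pattern, area_mm2, frame = _load_retina(src, config)
        except Exception as exc:  # noqa: BLE001 - tag and halt
            raise StageError("load", src.retina_id, exc) from exc
        patterns[src.retina_id] = pattern
        areas[src.retina_id] = area_mm2
        frames.append(frame)
        manifest["retinas"][src.retina_id] = {
            "group": src.group, "n_cells": pattern.n, "area_mm2": area_mm2,
        }
        path = gio.write_point_table(
            frame, out / f"{src.retina_id}_points.csv")
        _register("point_table", path)
        path = gio.write_boundary_csv(
            pattern.window, out / f"{src.retina_id}_boundary.csv")
        _register("boundary", path)
    manifest["stages"]["load"] = time.perf_counter() - t0
    log.info("load: %d retinas in %.2fs", len(patterns),
             manifest["stages"]["load"])

    # ---- stage: point statistics -----------------------------------------
    t0 = time.perf_counter()
    stat_rows = []
    try:
        for src in config.retinas:
            pattern = patterns[src.retina_id]
            nnd = pointstats.nearest_neighbour_distances(pattern)
            density = pointstats.global_density(pattern, areas[src.retina_id])
            profile = pointstats.eccentricity_profile(
                pattern, (src.onh_x_um, src.onh_y_um),
                config.eccentricity_bin_um,
            )
            ppath = out / f"{src.retina_id}_eccentricity.csv"
            profile.to_frame().to_csv(ppath, index=False)
            _register("eccentricity_profile", ppath)
            stat_rows.append(
                {
                    "retina_id": src.retina_id, "group": src.group,
                    "n_cells": pattern.n, "area_mm2": areas[src.retina_id],
                    "density_per_mm2": density,
                    "nnd_mean_um": nnd.mean_um, "nnd_sd_um": nnd.sd_um,
                    "regularity_index": nnd.ri,
                }
            )
            if config.write_maps:
                import matplotlib

                matplotlib.use("Agg", force=False)
                import matplotlib.pyplot as plt

                ax = pointstats.nnd_colour_map(
                    pattern, config.nnd_map_range_um)
                mpath = out / f"{src.retina_id}_nnd_map.png"
                ax.figure.savefig(mpath, dpi=150)
                plt.close(ax.figure)
                _register("nnd_map", mpath)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("pointstats", None, exc) from exc
    spath = out / "retina_stats.csv"
    pd.DataFrame(stat_rows).to_csv(spath, index=False)
    _register("retina_stats", spath)
    manifest["stages"]["pointstats"] = time.perf_counter() - t0

    # ---- stage: pooled clustering ----------------------------------------
    t0 = time.perf_counter()
    try:
        pooled = pd.concat(frames, ignore_index=True)
        model = phenotyping.kmeans_two(
            pooled, seed=config.cluster_seed, n_starts=config.cluster_starts)
        pooled = pooled.assign(activity_label=model.labels)
        for src in config.retinas:
            sel = pooled["retina_id"] == src.retina_id
            patterns[src.retina_id].marks = (
                pooled.loc[sel, "activity_label"].to_numpy(object))
        cpath = gio.write_point_table(pooled, out / "points_labelled.csv")
        _register("labelled_point_table", cpath)
        summary = phenotyping.cluster_densities(
            pooled["activity_label"].to_numpy(object),
            pooled["retina_id"].to_numpy(object), areas)
        sumpath = out / "cluster_summary.csv"
        summary.to_csv(sumpath, index=False)
        _register("cluster_summary", sumpath)
        if config.write_maps:
            import matplotlib.pyplot as plt

            for src in config.retinas:
                ax = phenotyping.activity_colour_map(patterns[src.retina_id])
                mpath = out / f"{src.retina_id}_activity_map.png"
                ax.figure.savefig(mpath, dpi=150)
                plt.close(ax.figure)
                _register("activity_map", mpath)
    except Exception as exc:  # noqa: BLE001
        raise StageError("phenotyping", None, exc) from exc
    manifest["stages"]["phenotyping"] = time.perf_counter() - t0

    # ---- stage: Ripley territory analysis --------------------------------
    t0 = time.perf_counter()
    domain_rows = []
    try:
        for src in config.retinas:
            pattern = patterns[src.retina_id]
            components = {"all": ripley.ripley_k(
                pattern, radii, config.edge_correction)}
            try:
                marked = ripley.marked_ripley(
                    pattern, radii, config.edge_correction)
                components.update(
                    low=marked.k_ii, high=marked.k_jj, cross=marked.k_ij)
            except ValueError as exc:
                log.warning("retina %s: marked Ripley skipped (%s)",
                            src.retina_id, exc)
            table = {"r_um": radii}
            for name, est in components.items():
                table[f"K_{name}"] = est.k
                table[f"L_{name}"] = est.l
                table[f"H_{name}"] = est.h
                try:
                    dr = ripley.domain_radius(
                        est, config.artefact_floor_um)
                    domain_rows.append(
                        {"retina_id": src.retina_id, "group": src.group,
                         "component": name, "domain_radius_um": dr.radius_um,
                         "h_at_minimum": dr.h_at_minimum})
                except ValueError:
                    domain_rows.append(
                        {"retina_id": src.retina_id, "group": src.group,
                         "component": name, "domain_radius_um": np.nan,
                         "h_at_minimum": np.nan})
            rpath = out / f"{src.retina_id}_ripley.csv"
            pd.DataFrame(table).to_csv(rpath, index=False)
            _register("ripley_table", rpath)
    except Exception as exc:  # noqa: BLE001
        raise StageError("ripley", None, exc) from exc
    dpath = out / "domain_radii.csv"
    pd.DataFrame(domain_rows).to_csv(dpath, index=False)
    _register("domain_radii", dpath)
    manifest["stages"]["ripley"] = time.perf_counter() - t0

    # ---- stage: Dixon segregation ----------------------------------------
    t0 = time.perf_counter()
    dixon_rows, excluded = [], []
    per_group: dict[str, list] = {}
    try:
        for src in config.retinas:
            pattern = patterns[src.retina_id]
            try:
                table = dixon_mod.build_nn_table(pattern)
                result = dixon_mod.dixon_test(table)
            except ValueError as exc:
                excluded.append({"retina_id": src.retina_id,
                                 "reason": str(exc)})
                log.warning("retina %s excluded from Dixon analysis: %s",
                            src.retina_id, exc)
                continue
            per_group.setdefault(src.group, []).append(result)
            dixon_rows.append(
                {"retina_id": src.retina_id, "group": src.group,
                 "N_i": table.n_i, "N_j": table.n_j,
                 "N_ii": table.n_ii, "N_ij": table.n_ij,
                 "N_ji": table.n_ji, "N_jj": table.n_jj,
                 "z_ii": result.z_ii, "z_jj": result.z_jj,
                 "C": result.c, "df": result.df_c, "p": result.p_c})
        group_rows = []
        for group, results in per_group.items():
            agg = dixon_mod.aggregate(results)
            group_rows.append(
                {"group": group, "n_retinas": agg.n_retinas,
                 "N_i": agg.n_i_total, "N_j": agg.n_j_total,
                 "C": agg.c_sum, "df_C": agg.df_c, "p_C": agg.p_c,
                 "p_C_display": dixon_mod.format_p(agg.p_c),
                 "sum_z_ii_sq": agg.z_ii_sq_sum, "df_z": agg.df_z,
                 "p_z_ii": agg.p_z_ii,
                 "p_z_ii_display": dixon_mod.format_p(agg.p_z_ii),
                 "sum_z_jj_sq": agg.z_jj_sq_sum,
                 "p_z_jj": agg.p_z_jj,
                 "p_z_jj_display": dixon_mod.format_p(agg.p_z_jj)})
    except Exception as exc:  # noqa: BLE001
        raise StageError("dixon", None, exc) from exc
    dxpath = out / "dixon_per_retina.csv"
    pd.DataFrame(dixon_rows).to_csv(dxpath, index=False)
    _register("dixon_per_retina", dxpath)
    gpath = out / "dixon_per_group.csv"
    pd.DataFrame(group_rows).to_csv(gpath, index=False)
    _register("dixon_per_group", gpath)
    manifest["stages"]["dixon"] = time.perf_counter() - t0
    manifest["dixon_exclusions"] = excluded

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest
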