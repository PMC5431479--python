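"""File contracts, configuration round trips, CLI and the end-to-end
pipeline runner."""

import json

import numpy as np
import pandas as pd
import pytest

from gliaspat import io as gio
from gliaspat.patterns import rectangle_window
from gliaspat.pipeline import RetinaSource, RunConfig, run_pipeline
from gliaspat.segmentation import RasterImage
from gliaspat.synthgen import MarkModel, SynthPatternParams, simulate_pattern


def _study_fixture(tmp_path, groups=("naive", "onc", "co_eye"),
                   n_retinas=3, intensity=150, side=1200.0):
    """Point-table + boundary files for a small synthetic study."""
    sources = []
    for g_idx, group in enumerate(groups):
        for r in range(n_retinas):
            rid = f"{group}_{r}"
            pat = simulate_pattern(SynthPatternParams(
                window=rectangle_window(side, side), intensity=intensity,
                seed=1000 + 37 * g_idx + r))
            rng = np.random.default_rng(5000 + g_idx * 10 + r)
            frame = pd.DataFrame({
                "retina_id": rid, "group": group,
                "x_um": pat.points[:, 0], "y_um": pat.points[:, 1],
                "area_um2": rng.normal(60, 15, pat.n).clip(20, 150),
                "roundness": rng.normal(0.17, 0.04, pat.n).clip(0.02, 1.0),
            })
            ppath = tmp_path / f"{rid}.csv"
            bpath = tmp_path / f"{rid}_boundary.csv"
            gio.write_point_table(frame, ppath)
            gio.write_boundary_csv(pat.window, bpath)
            sources.append(RetinaSource(
                retina_id=rid, group=group,
                point_table_path=str(ppath), boundary_path=str(bpath),
                onh_x_um=side / 2, onh_y_um=side / 2))
    return sources


class TestPointTableIO:
    def test_round_trip_equality(self, tmp_path):
        frame = pd.DataFrame({
            "retina_id": ["r1", "r1"], "group": ["naive", "naive"],
            "x_um": [1.5, 2.5], "y_um": [3.25, 4.0],
            "area_um2": [50.0, 60.0], "roundness": [0.8, 0.6]})
        path = gio.write_point_table(frame, tmp_path / "t.csv")
        back = gio.read_point_table(path)
        pd.testing.assert_frame_equal(frame, back)

    def test_missing_column_rejected(self, tmp_path):
        frame = pd.DataFrame({"x_um": [1.0]})
        with pytest.raises(ValueError, match="missing columns"):
            gio.write_point_table(frame, tmp_path / "t.csv")

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "retina_id,group,x_um,y_um,area_um2,roundness\n"
            "r1,naive,1.0,2.0,50.0,0.8\n"
            "r1,naive,oops,2.0,50.0,0.8\n")
        with pytest.raises(ValueError, match="line 3"):
            gio.read_point_table(path)


class TestBoundaryIO:
    def test_round_trip(self, tmp_path):
        poly = rectangle_window(100, 50)
        path = gio.write_boundary_csv(poly, tmp_path / "b.csv")
        back = gio.read_boundary_csv(path)
        assert back.equals(poly)

    def test_too_few_vertices_rejected(self, tmp_path):
        path = tmp_path / "b.csv"
        path.write_text("x_um,y_um\n0,0\n1,1\n")
        with pytest.raises(ValueError, match="3 vertices"):
            gio.read_boundary_csv(path)


class TestTiffIO:
    def test_round_trip_with_pixel_size(self, tmp_path, rng):
        img = RasterImage(rng.integers(0, 256, (32, 48)).astype(np.uint8),
                          pixel_size_um=1.24)
        path = gio.write_tiff(img, tmp_path / "i.tif")
        back = gio.read_tiff(path)
        np.testing.assert_array_equal(back.intensities, img.intensities)
        assert back.pixel_size_um == pytest.approx(1.24, rel=1e-4)

    def test_missing_metadata_falls_back_with_warning(self, tmp_path, rng):
        import tifffile

        path = tmp_path / "bare.tif"
        tifffile.imwrite(path, rng.integers(0, 256, (16, 16)).astype(np.uint8))
        with pytest.warns(UserWarning, match="1.24"):
            back = gio.read_tiff(path)
        assert back.pixel_size_um == 1.24


class TestRunConfig:
    def test_json_round_trip_lossless(self, tmp_path):
        cfg = RunConfig(
            retinas=[RetinaSource(retina_id="r1", group="onc",
                                  point_table_path="p.csv",
                                  boundary_path="b.csv", onh_x_um=10.0)],
            output_dir=str(tmp_path / "out"), cluster_seed=3)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        back = RunConfig.from_json(path)
        assert back == cfg

    def test_source_without_input_rejected(self):
        with pytest.raises(ValueError, match="image or a point table"):
            RetinaSource(retina_id="r1", group="naive")


class TestRunPipeline:
    def test_manifest_lists_all_outputs(self, tmp_path):
        sources = _study_fixture(tmp_path)
        cfg = RunConfig(retinas=sources, output_dir=str(tmp_path / "out"),
                        write_maps=False, r_max_um=100, r_step_um=2)
        manifest = run_pipeline(cfg)
        outputs = manifest["outputs"]
        for key in ("point_table", "boundary", "eccentricity_profile",
                    "retina_stats", "labelled_point_table",
                    "cluster_summary", "ripley_table", "domain_radii",
                    "dixon_per_retina", "dixon_per_group"):
            assert key in outputs, key
        assert len(outputs["ripley_table"]) == 9
        assert (tmp_path / "out" / "manifest.json").exists()
        stats = pd.read_csv(tmp_path / "out" / "retina_stats.csv")
        assert len(stats) == 9 and stats["density_per_mm2"].gt(0).all()
        groups = pd.read_csv(tmp_path / "out" / "dixon_per_group.csv")
        assert set(groups["group"]) == {"naive", "onc", "co_eye"}
        assert (groups["df_C"] == 2 * groups["n_retinas"]).all()

    def test_rerun_byte_identical(self, tmp_path):
        sources = _study_fixture(tmp_path, groups=("naive",), n_retinas=2)
        out1, out2 = tmp_path / "o1", tmp_path / "o2"
        for out in (out1, out2):
            cfg = RunConfig(retinas=sources, output_dir=str(out),
                            write_maps=False, r_max_um=80, r_step_um=2)
            run_pipeline(cfg)
        for name in ("points_labelled.csv", "retina_stats.csv",
                     "cluster_summary.csv", "domain_radii.csv",
                     "dixon_per_retina.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_labelled_cell_count_preserved(self, tmp_path):
        sources = _study_fixture(tmp_path, groups=("naive",), n_retinas=2)
        cfg = RunConfig(retinas=sources, output_dir=str(tmp_path / "out"),
                        write_maps=False, r_max_um=80, r_step_um=2)
        manifest = run_pipeline(cfg)
        labelled = pd.read_csv(tmp_path / "out" / "points_labelled.csv")
        total = sum(v["n_cells"] for v in manifest["retinas"].values())
        assert len(labelled) == total
        assert labelled["activity_label"].isin(["low", "high"]).all()


class TestCli:
    def test_simulate_then_stats_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from gliaspat.cli import main

        runner = CliRunner()
        pts = tmp_path / "pts.csv"
        bnd = tmp_path / "bnd.csv"
        res = runner.invoke(main, [
            "simulate", "--process", "poisson", "--intensity", "150",
            "--width", "1000", "--height", "1000", "--seed", "3",
            "--out", str(pts), "--boundary-out", str(bnd)])
        assert res.exit_code == 0, res.output
        out = tmp_path / "stats.csv"
        res = runner.invoke(main, [
            "stats", str(pts), str(bnd), "--onh", "500", "500",
            "--out", str(out)])
        assert res.exit_code == 0, res.output
        stats = pd.read_csv(out)
        assert stats["n_cells"].iloc[0] > 100
        assert stats["regularity_index"].iloc[0] > 1.0

    def test_cluster_command_labels_table(self, tmp_path):
        from click.testing import CliRunner

        from gliaspat.cli import main
        from .fixtures import gaussian_mixture_features

        feats, _ = gaussian_mixture_features(200, seed=3)
        frame = feats.assign(retina_id="r1", group="naive",
                             x_um=np.arange(len(feats), dtype=float),
                             y_um=0.0)
        pts = tmp_path / "pts.csv"
        gio.write_point_table(frame, pts)
        out = tmp_path / "labelled.csv"
        runner = CliRunner()
        res = runner.invoke(main, ["cluster", str(pts), "--out", str(out)])
        assert res.exit_code == 0, res.output
        labelled = pd.read_csv(out)
        assert set(labelled["activity_label"]) == {"low", "high"}
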