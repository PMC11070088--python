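"""Infiltration quantification: shell profiles, totals, decay fits, markers."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from assembloid_quant import (
    BoundaryROI,
    ImageStack,
    Projection2D,
    bin_shells,
    fit_decay_length,
    generate_assembloid_scene,
    generate_group_dataset,
    GroupSpec,
    h3k27m_distances,
    infiltration_metric,
    interior_distance_field,
    load_manifest,
    marker_ratio,
    max_project,
    normalize_to_control,
    pooled_decay_length,
    quantify_manifest_markers,
    shell_profile,
    total_infiltration,
    write_group_dataset,
)
from assembloid_quant.infiltration import EmptyRegionError, decay_curve
from conftest import small_scene_params


def _projection(channels: dict[str, np.ndarray], pixel_size_um=1.0):
    names = list(channels)
    data = np.stack([channels[n] for n in names]).astype(float)
    return Projection2D(data=data, channel_names=names,
                        pixel_size_um=pixel_size_um)


@pytest.fixture
def square_field(square_roi):
    return interior_distance_field(square_roi, (24, 24), 1.0)


class TestShellProfile:
    def test_means_match_loop_oracle(self, rng, square_roi, square_field):
        binning = bin_shells(square_field, 4)
        proj = _projection({
            "DAPI": rng.uniform(1, 10, (24, 24)),
            "eGFP": rng.uniform(0, 5, (24, 24)),
        })
        prof = shell_profile(proj, binning)
        labels = binning.shell_label
        for s in range(4):
            sel = labels == s
            if sel.sum() == 0:
                continue
            for ch in ("DAPI", "eGFP"):
                assert prof.table.loc[s, f"mean_{ch}"] == pytest.approx(
                    proj.channel(ch)[sel].mean())

    def test_metric_is_ratio_of_means(self, rng, square_field):
        binning = bin_shells(square_field, 3)
        proj = _projection({
            "DAPI": rng.uniform(1, 10, (24, 24)),
            "eGFP": rng.uniform(0, 5, (24, 24)),
        })
        prof = shell_profile(proj, binning)
        metric = infiltration_metric(prof)
        t = prof.table
        expect = t["mean_eGFP"] / t["mean_DAPI"]
        assert np.allclose(metric.to_numpy(), expect.to_numpy())

    def test_zero_nuclear_shell_is_nan_not_inf(self, square_field):
        binning = bin_shells(square_field, 2)
        dapi = np.ones((24, 24))
        dapi[binning.shell_label == 1] = 0.0
        proj = _projection({"DAPI": dapi, "eGFP": np.ones((24, 24))})
        metric = infiltration_metric(shell_profile(proj, binning))
        assert np.isnan(metric.loc[1])
        assert np.isfinite(metric.loc[0])

    def test_all_zero_nuclear_raises(self, square_field):
        binning = bin_shells(square_field, 2)
        proj = _projection({"DAPI": np.zeros((24, 24)),
                            "eGFP": np.ones((24, 24))})
        with pytest.raises(EmptyRegionError):
            infiltration_metric(shell_profile(proj, binning))

    def test_shape_mismatch_rejected(self, rng, square_field):
        binning = bin_shells(square_field, 2)
        proj = _projection({"DAPI": rng.uniform(1, 2, (10, 10)),
                            "eGFP": rng.uniform(0, 1, (10, 10))})
        with pytest.raises(ValueError, match="shape"):
            shell_profile(proj, binning)


class TestTotalInfiltration:
    def test_threshold_zero_equals_interior_ratio(self, rng, square_field):
        proj = _projection({"DAPI": rng.uniform(1, 10, (24, 24)),
                            "eGFP": rng.uniform(0, 5, (24, 24))})
        got = total_infiltration(proj, square_field, threshold=0.0)
        mask = square_field.interior_mask
        expect = (proj.channel("eGFP")[mask].mean()
                  / proj.channel("DAPI")[mask].mean())
        assert got == pytest.approx(expect, rel=1e-12)

    def test_percent_mode_matches_um_mode(self, rng, square_field):
        proj = _projection({"DAPI": rng.uniform(1, 10, (24, 24)),
                            "eGFP": rng.uniform(0, 5, (24, 24))})
        half_um = 0.5 * square_field.max_depth_um
        a = total_infiltration(proj, square_field, half_um, mode="past_um")
        b = total_infiltration(proj, square_field, 0.5, mode="past_percent")
        assert a == pytest.approx(b, rel=1e-12)

    def test_threshold_bounds_enforced(self, rng, square_field):
        proj = _projection({"DAPI": np.ones((24, 24)),
                            "eGFP": np.ones((24, 24))})
        with pytest.raises(ValueError):
            total_infiltration(proj, square_field,
                               square_field.max_depth_um + 1)
        with pytest.raises(ValueError):
            total_infiltration(proj, square_field, 1.5, mode="past_percent")
        with pytest.raises(ValueError, match="mode"):
            total_infiltration(proj, square_field, 0.0, mode="nope")

    def test_joint_rescale_invariance(self, rng, square_field):
        """Multiplying every channel by one constant leaves the ratio
        metric unchanged; scaling only the tumor channel scales it."""
        channels = {"DAPI": rng.uniform(1, 10, (24, 24)),
                    "eGFP": rng.uniform(0, 5, (24, 24))}
        base = total_infiltration(_projection(channels), square_field, 2.0)
        joint = total_infiltration(
            _projection({k: 7.3 * v for k, v in channels.items()}),
            square_field, 2.0)
        assert joint == pytest.approx(base, rel=1e-12)
        scaled = total_infiltration(
            _projection({"DAPI": channels["DAPI"],
                         "eGFP": 2.0 * channels["eGFP"]}),
            square_field, 2.0)
        assert scaled == pytest.approx(2.0 * base, rel=1e-12)


class TestDecayLength:
    def _scene_field(self, seed, **overrides):
        stack, roi, truth = generate_assembloid_scene(
            small_scene_params(seed, **overrides))
        proj = max_project(stack)
        fld = interior_distance_field(roi, proj.shape, proj.pixel_size_um)
        return proj, fld, truth

    def test_decay_curve_columns_and_monotone_counts(self):
        proj, fld, _ = self._scene_field(0)
        curve = decay_curve(proj, fld)
        assert {"threshold_um", "sum_tumor", "sum_nuclear", "count",
                "max_depth_um"} <= set(curve.columns)
        assert (np.diff(curve["count"].to_numpy()) <= 0).all()

    def test_single_default_scene_within_25pct(self):
        proj, fld, truth = self._scene_field(0, image_shape=(1, 420, 420),
                                             organoid_polygon=None,
                                             n_cells=400)
        lam = fit_decay_length(proj, fld)
        assert lam == pytest.approx(truth.true_decay_length_um, rel=0.25)

    def test_pooled_beats_typical_single_scene(self):
        scenes, truths = [], []
        for s in range(6):
            proj, fld, truth = self._scene_field(
                s, image_shape=(1, 420, 420), organoid_polygon=None,
                n_cells=400)
            scenes.append((proj, fld))
            truths.append(truth.true_decay_length_um)
        lam = pooled_decay_length(scenes)
        assert lam == pytest.approx(50.0, rel=0.15)


class TestMarkerRatio:
    def test_whole_image_is_sum_ratio(self, rng):
        proj = _projection({"DAPI": rng.uniform(1, 10, (24, 24)),
                            "CC3": rng.uniform(0, 5, (24, 24))})
        got = marker_ratio(proj, "CC3")
        assert got == pytest.approx(
            proj.channel("CC3").sum() / proj.channel("DAPI").sum())

    def test_interface_band_subset_of_interior(self, rng, square_field):
        channels = {"DAPI": rng.uniform(1, 10, (24, 24)),
                    "CC3": rng.uniform(0, 5, (24, 24))}
        proj = _projection(channels)
        interior = marker_ratio(proj, "CC3", region="interior",
                                fld=square_field)
        band = marker_ratio(proj, "CC3", region=("interface_band", 2.0),
                            fld=square_field)
        mask = square_field.interior_mask & (square_field.depth_um <= 2.0)
        expect = channels["CC3"][mask].sum() / channels["DAPI"][mask].sum()
        assert band == pytest.approx(expect)
        assert interior != band  # band is a strict subregion here

    def test_median_background_recovers_offset_free_ratio(self, rng):
        """With a constant offset on mostly-empty channels, raw ratios are
        biased toward 1 and median subtraction removes the bias."""
        signal = np.zeros((60, 60))
        signal[28:32, 28:32] = 100.0
        dapi = np.zeros((60, 60))
        dapi[10:50, 10:50] = 50.0
        offset = 20.0
        proj = _projection({"DAPI": dapi + offset, "CC3": signal + offset})
        truth = signal.sum() / dapi.sum()
        raw = marker_ratio(proj, "CC3")
        corrected = marker_ratio(proj, "CC3", background="median")
        assert abs(corrected - truth) < abs(raw - truth)
        assert corrected == pytest.approx(truth, rel=1e-6)

    def test_zero_dapi_raises(self):
        proj = _projection({"DAPI": np.zeros((8, 8)),
                            "CC3": np.ones((8, 8))})
        with pytest.raises(EmptyRegionError):
            marker_ratio(proj, "CC3")


class TestNormalizeToControl:
    def test_untreated_means_exactly_one(self, rng):
        rows = []
        for g in ("NT", "KD"):
            for treat, untreated in (("untreated", True), ("RT", False)):
                for rep in range(3):
                    rows.append({"group": g, "treatment": treat,
                                 "is_untreated": untreated,
                                 "ratio": rng.uniform(0.5, 2.0)})
        result = normalize_to_control(pd.DataFrame(rows))
        df = result.per_image
        for g in ("NT", "KD"):
            sel = (df["group"] == g) & df["is_untreated"]
            assert df.loc[sel, "relative"].mean() == pytest.approx(1.0)

    def test_normalization_never_crosses_groups(self):
        df = pd.DataFrame([
            {"group": "A", "is_untreated": True, "ratio": 2.0},
            {"group": "A", "is_untreated": False, "ratio": 4.0},
            {"group": "B", "is_untreated": True, "ratio": 10.0},
            {"group": "B", "is_untreated": False, "ratio": 5.0},
        ])
        rel = normalize_to_control(df).per_image["relative"]
        assert list(rel) == [1.0, 2.0, 1.0, 0.5]

    def test_missing_untreated_arm_names_group(self):
        df = pd.DataFrame([
            {"group": "A", "is_untreated": True, "ratio": 2.0},
            {"group": "B", "is_untreated": False, "ratio": 5.0},
        ])
        with pytest.raises(ValueError, match="'B'"):
            normalize_to_control(df)


class TestH3K27MDistances:
    def test_recovers_planted_cells(self):
        params = small_scene_params(
            5, image_shape=(1, 260, 260),
            organoid_polygon="ellipse(130, 130, 105, 105, 48, 0.03)",
            n_cells=50, min_cell_separation_um=14.0,
            marker_effect={"H3K27M": 1.0}, noise=(0.5, 1.0, 2.0))
        stack, roi, truth = generate_assembloid_scene(params)
        proj = max_project(stack)
        result = h3k27m_distances(proj, roi)
        assert len(result.distances_um) >= 0.9 * len(truth.cell_positions)
        tree = cKDTree(truth.cell_positions)
        d, _ = tree.query(result.centroids)
        assert np.sqrt((d**2).mean()) < 1.0  # sub-pixel localization

    def test_flat_image_returns_empty(self):
        proj = _projection({"H3K27M": np.ones((20, 20)),
                            "DAPI": np.ones((20, 20))})
        roi = BoundaryROI(np.array([[2, 2], [18, 2], [18, 18], [2, 18]],
                                   float))
        result = h3k27m_distances(proj, roi)
        assert len(result.distances_um) == 0

    def test_exterior_cells_counted_not_measured(self, square_roi):
        img = np.zeros((24, 24))
        img[10, 10] = 100.0   # inside (5..15 square)
        img[2, 2] = 100.0     # outside
        proj = _projection({"H3K27M": img, "DAPI": np.ones((24, 24))})
        result = h3k27m_distances(proj, square_roi, threshold_method=50.0,
                                  min_area_px=1)
        assert len(result.distances_um) == 1
        assert result.n_exterior == 1


class TestManifestDriver:
    def test_end_to_end_marker_quantification(self, tmp_path):
        specs = {
            "NT": GroupSpec(
                params=small_scene_params(0, marker_effect={"CC3": 1.0}),
                n_images=2, is_control=True),
            "KD": GroupSpec(
                params=small_scene_params(0, marker_effect={"CC3": 1.0}),
                n_images=2, marker_effects={"CC3": 2.5}),
        }
        records = generate_group_dataset(specs, base_seed=7)
        manifest = load_manifest(write_group_dataset(records, tmp_path))
        result = quantify_manifest_markers(manifest, "CC3",
                                           background="median")
        df = result.per_image
        assert len(df) == 4
        for g in ("NT", "KD"):
            sel = (df["group"] == g) & df["is_untreated"]
            assert df.loc[sel, "relative"].mean() == pytest.approx(1.0)
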