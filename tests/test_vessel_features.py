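import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ioradiomics.image_core import ImageVolume, zscore_standardize
from ioradiomics.simulate import (PhantomSpec, generate_phantom,
                                  generate_vessel_branch)
from ioradiomics.vessel_features import (OutlierFeatureFilter, branch_geometry,
                                         extract_centerlines,
                                         extract_peritumoral,
                                         morphological_cleanup, otsu_threshold,
                                         peritumoral_cube, vessel_features,
                                         vessel_manifest_names, vesselness,
                                         VesselTree)
from conftest import straight_tube


class TestVesselness:
    def test_uniform_volume_zero_response(self):
        out = vesselness(ImageVolume(np.full((20, 20, 20), 3.0)), scales_mm=(1.0, 2.0))
        assert np.allclose(out.values, 0.0)

    def test_tube_scale_selection(self):
        tube = straight_tube((40, 40, 40), radius=3.0)
        vol = ImageVolume(tube.astype(np.float64))
        resp, scales = vesselness(vol, scales_mm=(1, 2, 3, 4, 5), return_scales=True)
        axis_scales = scales[20, 20, 8:32]
        assert np.all(np.abs(axis_scales - 3.0) <= 1.0)

    def test_axis_outranks_off_axis(self):
        tube = straight_tube((40, 40, 40), radius=3.0)
        resp = vesselness(ImageVolume(tube.astype(np.float64)),
                          scales_mm=(1, 2, 3, 4)).values
        for z in range(8, 32):
            on_axis = resp[20, 20, z]
            off = resp[20 + 8, 20, z]  # > 2 radii off-axis
            assert on_axis > off

    def test_response_in_unit_interval(self, phantom):
        resp = vesselness(zscore_standardize(phantom["volume"]), scales_mm=(1.0, 2.0))
        assert resp.values.min() >= 0.0 and resp.values.max() <= 1.0


class TestOtsu:
    def test_two_deltas(self):
        vals = np.array([0.1] * 50 + [0.9] * 50)
        thr = otsu_threshold(vals)
        assert 0.1 < thr < 0.9

    def test_matches_exhaustive_search(self, rng):
        vals = np.concatenate([rng.normal(0, 0.5, 400), rng.normal(10, 0.5, 300)])
        thr = otsu_threshold(vals, n_bins=256)
        counts, edges = np.histogram(vals, bins=256)
        centers = 0.5 * (edges[:-1] + edges[1:])
        p = counts / counts.sum()
        best, best_var = None, -1
        for k in range(1, 256):
            w0, w1 = p[:k].sum(), p[k:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (p[:k] * centers[:k]).sum() / w0
            m1 = (p[k:] * centers[k:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best, best_var = centers[k - 1], var
        assert abs(thr - best) <= (edges[1] - edges[0]) * 1.5

    def test_permutation_invariance(self, rng):
        vals = rng.uniform(size=300)
        assert otsu_threshold(vals) == otsu_threshold(rng.permutation(vals))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.ones(10))


class TestCleanupAndCube:
    def test_speckles_removed(self, rng):
        mask = np.zeros((20, 20, 20), bool)
        pts = rng.integers(0, 20, size=(15, 3))
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        out = morphological_cleanup(mask, min_component_voxels=10, opening_radius_mm=0)
        assert not out.any()

    def test_tube_kept_appendage_removed(self):
        mask = straight_tube((30, 30, 30), radius=2.5)
        mask[0, 0, :2] = True  # 2-voxel appendage
        out = morphological_cleanup(mask, min_component_voxels=10, opening_radius_mm=0)
        assert not out[0, 0, 0]
        assert out[14, 14, 15]

    def test_empty_in_empty_out(self):
        out = morphological_cleanup(np.zeros((5, 5, 5), bool))
        assert not out.any()

    def test_cube_bounds_interior(self):
        mask = np.zeros((100, 100, 100), bool)
        mask[40:61, 40:61, 40:61] = True
        bounds = peritumoral_cube(mask, extension_mm=25.0)
        assert bounds == ((15, 86), (15, 86), (15, 86))

    def test_cube_clipped_at_edge(self):
        mask = np.zeros((40, 40, 40), bool)
        mask[0:5, 0:5, 0:5] = True
        bounds = peritumoral_cube(mask, extension_mm=25.0)
        assert bounds[0][0] == 0

    def test_zero_extension_is_bbox(self):
        mask = np.zeros((30, 30, 30), bool)
        mask[10:20, 12:18, 5:25] = True
        assert peritumoral_cube(mask, extension_mm=0.0) == ((10, 20), (12, 18), (5, 25))

    def test_empty_tumor_rejected(self):
        with pytest.raises(ValueError):
            peritumoral_cube(np.zeros((5, 5, 5), bool))


class TestCenterlines:
    def test_straight_tube_single_branch_on_axis(self):
        tube = straight_tube((40, 40, 40), radius=3.0)
        tree = extract_centerlines(tube)
        assert tree.n_branches == 1
        pts = tree.branches[0]
        # axis is x=y=19.5; skeleton within 1 voxel
        assert np.all(np.abs(pts[:, 0] - 20.0) <= 1.0)
        assert np.all(np.abs(pts[:, 1] - 20.0) <= 1.0)

    def test_y_junction_three_branches(self):
        mask = np.zeros((50, 50, 50), bool)
        x, y, z = np.meshgrid(*[np.arange(50)] * 3, indexing="ij")
        # trunk along z then two arms diverging in x
        mask |= ((x - 25) ** 2 + (y - 25) ** 2 <= 9) & (z < 25)
        for s in (+1, -1):
            t = np.arange(25, 45)
            for ti in t:
                cx = 25 + s * (ti - 25)
                if 0 <= cx < 50:
                    mask |= (((x - cx) ** 2 + (y - 25) ** 2 <= 9) & (z == ti))
        tree = extract_centerlines(mask)
        assert tree.n_branches >= 3
        assert len(tree.junctions) >= 1

    def test_radius_estimates(self):
        tube = straight_tube((40, 40, 40), radius=3.0)
        tree = extract_centerlines(tube)
        mid = tree.radii[0][2:-2]
        assert np.all(np.abs(mid - 3.0) <= 0.7)

    def test_empty_mask_empty_tree(self):
        tree = extract_centerlines(np.zeros((10, 10, 10), bool))
        assert tree.n_branches == 0


class TestBranchGeometry:
    def test_collinear_zero(self):
        pts = np.stack([np.linspace(0, 20, 41)] * 3, axis=1)
        g = branch_geometry(pts)
        assert np.abs(g["curvature"]).max() < 1e-6
        assert np.abs(g["torsion"]).max() < 1e-6
        assert g["straightness"] == pytest.approx(1.0)

    def test_helix_closed_form(self):
        pts = generate_vessel_branch((0, 0, 0), (0, 0, 1), 60.0, 5.0, 2.0, seed=1)
        g = branch_geometry(pts, smoothing_mm=0.5)
        assert g["curvature"].mean() == pytest.approx(5 / 29, rel=0.05)
        assert np.abs(g["torsion"]).mean() == pytest.approx(2 / 29, rel=0.05)

    def test_planar_arc(self):
        th = np.linspace(0, np.pi, 80)
        pts = np.stack([10 * np.cos(th), 10 * np.sin(th), np.zeros_like(th)], axis=1)
        g = branch_geometry(pts, smoothing_mm=0.5)
        assert g["curvature"].mean() == pytest.approx(0.1, rel=0.05)
        assert np.abs(g["torsion"]).max() <= 0.005

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            branch_geometry(np.zeros((2, 3)))


class TestVesselFeatureBlock:
    def test_exactly_91_names(self):
        names = vessel_manifest_names()
        assert len(names) == 91
        assert len([n for n in names if n.startswith("morph_")]) == 61
        assert len([n for n in names if n.startswith("org_")]) == 30

    def test_empty_tree_zeros_with_flag(self):
        f = vessel_features(VesselTree(), cube_volume_mm3=1000.0)
        assert f["empty_tree"] == 1.0
        assert all(v == 0.0 for k, v in f.items() if k != "empty_tree")
        assert len(f) == 92

    def test_single_straight_branch(self):
        pts = np.stack([np.full(30, 5.0), np.full(30, 5.0), np.linspace(0, 29, 30)], 1)
        tree = VesselTree(branches=[pts], radii=[np.full(30, 2.0)])
        f = vessel_features(tree, cube_volume_mm3=8000.0)
        assert f["org_branch_count"] == 1.0
        assert f["org_junction_count"] == 0.0
        assert f["morph_mean_curvature_mean"] < 0.02
        assert f["empty_tree"] == 0.0

    def test_full_extraction_91(self, std_phantom, phantom):
        f = extract_peritumoral(std_phantom, phantom["tumor"],
                                lung_mask=phantom["lung"])
        assert len(f) == 92  # 91 + emptiness flag
        assert f["empty_tree"] == 0.0
        assert all(np.isfinite(v) for v in f.values())

    def test_high_vs_low_tortuosity_ordering(self):
        base = dict(grid_shape=(64, 64, 64), tumor_radius_mm=8.0, seed=7)
        specs = [PhantomSpec(tortuosity=t, **base) for t in (0.0, 0.3)]
        vals = []
        for spec in specs:
            vol, tumor, lung, vessel, gt = generate_phantom(spec)
            f = extract_peritumoral(zscore_standardize(vol), tumor,
                                    vessel_mask=vessel)
            vals.append(f)
        assert vals[1]["morph_mean_torsion_mean"] > vals[0]["morph_mean_torsion_mean"]
        assert vals[1]["morph_torsion_skewness_mean"] != vals[0]["morph_torsion_skewness_mean"]

    def test_translation_invariance(self):
        spec = PhantomSpec(grid_shape=(96, 96, 96), tumor_radius_mm=7.0, seed=3,
                           tumor_center_mm=(44.0, 44.0, 44.0))
        vol, tumor, lung, vessel, gt = generate_phantom(spec)
        f0 = extract_peritumoral(zscore_standardize(vol), tumor, vessel_mask=vessel)
        shift = (4, 4, 4)
        vol2 = ImageVolume(np.roll(vol.values, shift, (0, 1, 2)), vol.spacing_mm)
        f1 = extract_peritumoral(zscore_standardize(vol2),
                                 np.roll(tumor, shift, (0, 1, 2)),
                                 vessel_mask=np.roll(vessel, shift, (0, 1, 2)))
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], abs=1e-6), k

    def test_torsion_monotone_in_tortuosity(self):
        levels = (0.0, 0.15, 0.3)
        means = []
        for t in levels:
            vals = []
            for s in range(10):
                spec = PhantomSpec(grid_shape=(64, 64, 64), tumor_radius_mm=8.0,
                                   tortuosity=t, seed=200 + s)
                vol, tumor, lung, vessel, gt = generate_phantom(spec)
                f = extract_peritumoral(zscore_standardize(vol), tumor,
                                        vessel_mask=vessel)
                vals.append(f["morph_mean_torsion_mean"])
            means.append(np.mean(vals))
        rho = stats.spearmanr(levels, means).statistic
        assert rho == pytest.approx(1.0)
        assert means[0] < means[1] < means[2]


class TestOutlierFilter:
    def test_standard_normal_kept(self, rng):
        X = pd.DataFrame({"f": rng.standard_normal(1000)})
        filt = OutlierFeatureFilter().fit(X)
        assert "f" in filt.kept_features_

    def test_shifted_block_removed(self, rng):
        n = 200
        ref = rng.standard_normal(n)
        vals = ref.copy()
        vals[:50] = 10.0  # 25% of all rows, 10 reference SDs away
        X = pd.DataFrame({"bad": vals, "good": rng.standard_normal(n)})
        filt = OutlierFeatureFilter().fit(X, reference_index=X.index[50:])
        assert "bad" in filt.removed_features_
        assert "good" in filt.kept_features_
        assert filt.removal_report_["bad"]["fraction"] > 0.20

    def test_exactly_twenty_percent_kept(self):
        n = 100
        vals = np.zeros(n)
        vals[:20] = 100.0  # exactly 20%, strict "exceeding" keeps it
        ref = np.concatenate([np.zeros(40), np.ones(40)])  # sd > 0
        X = pd.DataFrame({"f": np.concatenate([vals[:20], ref])})
        filt = OutlierFeatureFilter().fit(X, reference_index=X.index[20:])
        assert filt.removal_report_.get("f", {}).get("fraction", 0.2) <= 0.2001
        assert "f" in filt.kept_features_

    def test_zero_sd_removed_and_reported(self):
        X = pd.DataFrame({"const": np.ones(50), "ok": np.arange(50.0)})
        filt = OutlierFeatureFilter().fit(X)
        assert "const" in filt.removed_features_
        assert filt.removal_report_["const"]["reason"] == "zero reference SD"

    def test_transform_drops_removed_columns(self, rng):
        X = pd.DataFrame({"const": np.ones(30), "ok": rng.standard_normal(30)})
        out = OutlierFeatureFilter().fit_transform(X)
        assert list(out.columns) == ["ok"]
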