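import numpy as np
import pytest

from ioradiomics.image_core import ImageVolume, zscore_standardize
from ioradiomics.simulate import PhantomSpec, generate_phantom
from ioradiomics.tumor_features import (DIRECTIONS_3D, extract_intratumoral,
                                        feature_manifest, geometry_features,
                                        glcm_features, glcm_matrix,
                                        glrlm_features, glrlm_matrix,
                                        histogram_features, lbp_codes,
                                        lbp_features, quantize)


class TestQuantize:
    def test_identity_labelling(self):
        vals = np.arange(64, dtype=float)
        assert np.array_equal(quantize(vals, 64), np.arange(1, 65))

    def test_constant_single_bin(self):
        assert np.array_equal(quantize(np.full(10, 3.0), 64), np.ones(10, int))

    def test_counts_match_histogram_oracle(self, rng):
        vals = rng.uniform(-5, 5, 500)
        q = quantize(vals, 16)
        lo, hi = vals.min(), vals.max()
        edges = lo + (hi - lo) * np.arange(17) / 16
        expected, _ = np.histogram(vals, bins=edges)
        # np.histogram closes the last bin on the right, same as the clip
        got = np.bincount(q, minlength=17)[1:]
        assert np.array_equal(got, expected)


class TestHistogram:
    def test_hand_computed_small_roi(self):
        vol = ImageVolume(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1) * np.ones((4, 2, 2)))
        mask = np.zeros((4, 2, 2), bool)
        mask[:, 0, 0] = True
        f = histogram_features(vol, mask)
        assert f["mean"] == pytest.approx(2.5)
        assert f["variance"] == pytest.approx(1.25)  # population convention
        assert f["median"] == pytest.approx(2.5)
        assert f["range"] == pytest.approx(3.0)

    def test_constant_roi_degenerate_conventions(self):
        vol = ImageVolume(np.full((4, 4, 4), 7.0))
        mask = np.ones((4, 4, 4), bool)
        f = histogram_features(vol, mask)
        assert f["variance"] == 0.0
        assert f["entropy"] == 0.0
        assert f["skewness"] == 0.0

    def test_symmetric_values_zero_skew(self, rng):
        half = rng.standard_normal(200)
        vals = np.concatenate([half, -half])
        vol = ImageVolume(vals.reshape(20, 20, 1) * np.ones((20, 20, 2)))
        mask = np.zeros((20, 20, 2), bool)
        mask[:, :, 0] = True
        assert abs(histogram_features(vol, mask)["skewness"]) < 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            histogram_features(ImageVolume(np.zeros((3, 3, 3))), np.zeros((3, 3, 3), bool))


class TestGeometry:
    def test_cube_analytic(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[5:15, 5:15, 5:15] = True
        f = geometry_features(mask, (1.0, 1.0, 1.0))
        assert f["volume_mm3"] == pytest.approx(1000.0)
        assert f["extent_x_mm"] == pytest.approx(10.0)
        assert f["max_diameter_3d_mm"] == pytest.approx(10 * np.sqrt(3), rel=1e-6)

    def test_ball_sphericity_near_one(self):
        c = np.arange(40)
        x, y, z = np.meshgrid(c, c, c, indexing="ij")
        mask = (x - 19.5) ** 2 + (y - 19.5) ** 2 + (z - 19.5) ** 2 <= 10**2
        f = geometry_features(mask, (1.0, 1.0, 1.0))
        assert f["sphericity"] == pytest.approx(1.0, abs=0.05)
        assert f["elongation"] == pytest.approx(1.0, abs=0.05)

    def test_single_voxel(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        f = geometry_features(mask, (1.0, 2.0, 3.0))
        assert f["volume_mm3"] == pytest.approx(6.0)
        assert f["max_diameter_3d_mm"] == pytest.approx(np.sqrt(1 + 4 + 9))


def brute_force_glcm(q, mask, n_bins, offsets):
    """Exhaustive pair enumeration over all voxels and offsets (both signs)."""
    mat = np.zeros((n_bins, n_bins))
    shape = q.shape
    for off in offsets:
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    if not mask[x, y, z]:
                        continue
                    nx, ny, nz = x + off[0], y + off[1], z + off[2]
                    if (0 <= nx < shape[0] and 0 <= ny < shape[1]
                            and 0 <= nz < shape[2] and mask[nx, ny, nz]):
                        a, b = q[x, y, z] - 1, q[nx, ny, nz] - 1
                        mat[a, b] += 1
                        mat[b, a] += 1
    return mat / mat.sum()


class TestGLCM:
    def test_constant_roi(self):
        q = np.ones((4, 4, 4), int)
        f = glcm_features(q, np.ones((4, 4, 4), bool), n_bins=4)
        assert f["contrast"] == 0.0
        assert f["energy"] == pytest.approx(1.0)

    def test_matrix_matches_brute_force(self, rng):
        q = rng.integers(1, 5, size=(4, 4, 4))
        mask = rng.uniform(size=(4, 4, 4)) > 0.3
        got = glcm_matrix(q, mask, n_bins=4)
        expected = brute_force_glcm(q, mask, 4, DIRECTIONS_3D)
        assert np.allclose(got, expected, atol=1e-12)

    def test_normalization(self, rng):
        q = rng.integers(1, 9, size=(5, 5, 5))
        mat = glcm_matrix(q, np.ones((5, 5, 5), bool), n_bins=8)
        assert mat.sum() == pytest.approx(1.0, abs=1e-12)


def brute_force_glrlm(q, mask, n_bins, direction):
    """Direct run scanning along one direction."""
    qm = np.where(mask, q, 0)
    shape = qm.shape
    max_len = max(shape)
    mat = np.zeros((n_bins, max_len))
    seen = set()
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if qm[x, y, z] == 0 or (x, y, z) in seen:
                    continue
                px, py, pz = x - direction[0], y - direction[1], z - direction[2]
                if (0 <= px < shape[0] and 0 <= py < shape[1] and 0 <= pz < shape[2]
                        and qm[px, py, pz] == qm[x, y, z]):
                    continue  # not a run start
                g = qm[x, y, z]
                length = 0
                cx, cy, cz = x, y, z
                while (0 <= cx < shape[0] and 0 <= cy < shape[1]
                       and 0 <= cz < shape[2] and qm[cx, cy, cz] == g):
                    seen.add((cx, cy, cz))
                    length += 1
                    cx, cy, cz = cx + direction[0], cy + direction[1], cz + direction[2]
                mat[g - 1, length - 1] += 1
    return mat


class TestGLRLM:
    def test_single_run_line(self):
        q = np.ones((6, 1, 1), int)
        mask = np.ones((6, 1, 1), bool)
        f = glrlm_features(q, mask, n_bins=2, directions=((1, 0, 0),))
        assert f["lre"] == pytest.approx(36.0)  # one run of length 6
        assert f["rp"] == pytest.approx(1 / 6)

    def test_alternating_line_all_short_runs(self):
        q = np.array([1, 2, 1, 2, 1, 2]).reshape(6, 1, 1)
        f = glrlm_features(q, np.ones((6, 1, 1), bool), n_bins=2,
                           directions=((1, 0, 0),))
        assert f["sre"] == pytest.approx(1.0)

    def test_matrix_matches_brute_force(self, rng):
        q = rng.integers(1, 4, size=(5, 5, 5))
        mask = rng.uniform(size=(5, 5, 5)) > 0.25
        for d in ((1, 0, 0), (1, 1, 0), (1, -1, 1)):
            got = glrlm_matrix(q, mask, n_bins=3, directions=(d,))
            expected = brute_force_glrlm(q, mask, 3, d)
            assert np.allclose(got, expected), f"direction {d}"


class TestLBP:
    def test_constant_volume_single_bin(self):
        vol = ImageVolume(np.full((5, 5, 5), 2.0))
        f = lbp_features(vol, np.ones((5, 5, 5), bool))
        assert f["bin_00"] == pytest.approx(1.0)
        assert f["entropy"] == 0.0

    def test_codes_match_per_voxel_enumeration(self, rng):
        vals = rng.standard_normal((6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        got = np.sort(lbp_codes(vals, mask))
        expected = []
        for x in range(1, 5):
            for y in range(1, 5):
                for z in range(1, 5):
                    cnt = 0
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                if (dx, dy, dz) == (0, 0, 0):
                                    continue
                                cnt += vals[x + dx, y + dy, z + dz] > vals[x, y, z]
                    expected.append(min(15, cnt * 16 // 27))
        assert np.array_equal(got, np.sort(expected))

    def test_histogram_sums_to_one(self, rng):
        vol = ImageVolume(rng.standard_normal((8, 8, 8)))
        f = lbp_features(vol, np.ones((8, 8, 8), bool))
        assert sum(f[f"bin_{i:02d}"] for i in range(16)) == pytest.approx(1.0, abs=1e-12)

    def test_no_interior_rejected(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="interior"):
            lbp_features(ImageVolume(np.zeros((4, 4, 4))), mask)


class TestManifestAndExtraction:
    def test_manifest_count_and_subtotals(self):
        entries = feature_manifest()
        assert len(entries) == 593
        fam = {}
        for e in entries:
            fam[e.family] = fam.get(e.family, 0) + 1
        assert fam == {"histogram": 9 * 14, "geometry": 17, "glcm": 9 * 22,
                       "glrlm": 9 * 11, "lbp": 9 * 17}
        names = [e.name for e in entries]
        assert len(set(names)) == 593
        assert all(e.image_set == "n/a" for e in entries if e.family == "geometry")

    def test_full_extraction_593_finite(self, std_phantom, phantom):
        feats = extract_intratumoral(std_phantom, phantom["tumor"])
        assert len(feats) == 593
        assert all(np.isfinite(v) for v in feats.values())

    def test_determinism(self, phantom):
        spec = phantom["spec"]
        v1, t1, *_ = generate_phantom(spec)
        v2, t2, *_ = generate_phantom(spec)
        f1 = extract_intratumoral(zscore_standardize(v1), t1)
        f2 = extract_intratumoral(zscore_standardize(v2), t2)
        assert f1 == f2

    def test_heterogeneity_changes_texture_not_geometry(self):
        base = dict(grid_shape=(48, 48, 48), tumor_radius_mm=7.0, n_branches=0,
                    noise_sd=0.0, seed=5)
        va, ta, *_ = generate_phantom(PhantomSpec(heterogeneity=0.1, **base))
        vb, tb, *_ = generate_phantom(PhantomSpec(heterogeneity=0.5, **base))
        assert np.array_equal(ta, tb)
        fa = extract_intratumoral(zscore_standardize(va), ta)
        fb = extract_intratumoral(zscore_standardize(vb), tb)
        geo = [k for k in fa if k.startswith("geometry_")]
        assert all(fa[k] == pytest.approx(fb[k]) for k in geo)
        assert fa["original_histogram_sd"] != pytest.approx(fb["original_histogram_sd"])

    def test_translation_invariance_even_shift(self, rng):
        vals = rng.standard_normal((32, 32, 32))
        mask = np.zeros((32, 32, 32), bool)
        mask[8:16, 8:16, 8:16] = True
        f0 = extract_intratumoral(ImageVolume(vals), mask)
        vals2 = np.roll(vals, (2, 4, 2), axis=(0, 1, 2))
        mask2 = np.roll(mask, (2, 4, 2), axis=(0, 1, 2))
        f1 = extract_intratumoral(ImageVolume(vals2), mask2)
        for k in f0:
            assert f0[k] == pytest.approx(f1[k], abs=1e-6), k
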