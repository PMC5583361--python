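"""Handcrafted features: catalog contract, geometry, intensity, texture."""

import dataclasses
import warnings

import numpy as np
import pytest
from scipy import stats

from _oracles import count_runs_bruteforce, count_zones_bruteforce
from radsurv.handcrafted import (
    GEOMETRY_FEATURES,
    OFFSETS_13,
    NGTDM_COARSENESS_CAP,
    compute_geometry_features,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    compute_intensity_features,
    compute_ngtdm,
    default_catalog,
    extract_handcrafted,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from radsurv.preprocess import SubregionMask


def _ball_mask(radius_vox, spacing=(1.0, 1.0, 1.0), label=3):
    n = 2 * radius_vox + 3
    c = (n - 1) / 2
    idx = np.indices((n, n, n))
    ball = sum((idx[a] - c) ** 2 * spacing[a] ** 2 for a in range(3)) <= (radius_vox * min(spacing)) ** 2
    labels = np.zeros((n, n, n), dtype=np.uint8)
    labels[ball] = label
    # carve minimal nested structure so all labels exist
    labels[int(c), int(c), int(c)] = 1
    labels[int(c) + 1, int(c), int(c)] = 2
    return SubregionMask(labels, spacing)


class TestCatalog:
    def test_composition_counts(self):
        cat = default_catalog()
        frame = cat.to_frame()
        assert len(cat) == 1403
        assert (frame["family"] == "geometry").sum() == 23
        assert (frame["family"] == "intensity").sum() == 340
        assert frame["family"].isin(["GLCM", "GLRLM", "GLSZM", "NGTDM"]).sum() == 1040
        assert frame["name"].is_unique

    def test_bad_composition_rejected(self):
        from radsurv.handcrafted import CatalogEntry, FeatureCatalog

        entries = [CatalogEntry(f"g{i}", None, None, "geometry") for i in range(22)]
        with pytest.raises(ValueError, match="composition"):
            FeatureCatalog(entries)


class TestGeometry:
    def test_single_voxel_volume(self):
        labels = np.zeros((3, 3, 3), dtype=np.uint8)
        labels[1, 1, 1] = 1
        g = compute_geometry_features(SubregionMask(labels, (1.0, 1.0, 1.0)))
        assert g["volume"] == pytest.approx(1.0)
        assert g["necrosis_fraction"] == pytest.approx(1.0)

    def test_ball_sphericity_approaches_one(self):
        g = compute_geometry_features(_ball_mask(20))
        assert g["sphericity"] > 0.9
        assert g["elongation"] == pytest.approx(1.0, abs=0.05)

    def test_spacing_scaling_law(self):
        m1 = _ball_mask(8, spacing=(1.0, 1.0, 1.0))
        m2 = SubregionMask(m1.labels, (2.0, 2.0, 2.0))
        g1 = compute_geometry_features(m1)
        g2 = compute_geometry_features(m2)
        assert g2["volume"] == pytest.approx(8 * g1["volume"])
        assert g2["max_diameter_3d"] == pytest.approx(2 * g1["max_diameter_3d"])

    def test_empty_region_named_error(self):
        labels = np.zeros((3, 3, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="ST"):
            compute_geometry_features(SubregionMask(labels, (1.0, 1.0, 1.0)))

    def test_returns_all_23(self):
        g = compute_geometry_features(_ball_mask(5))
        assert set(g) == set(GEOMETRY_FEATURES)


class TestIntensity:
    def test_constant_region(self):
        vol = np.full((3, 3, 3), 4.2)
        f = compute_intensity_features(vol, np.ones_like(vol, bool))
        assert f["mean"] == pytest.approx(4.2)
        assert f["variance"] == pytest.approx(0.0, abs=1e-24)
        assert f["entropy"] == 0 and f["uniformity"] == 1

    def test_small_example(self):
        vol = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        f = compute_intensity_features(vol, np.ones_like(vol, bool))
        assert f["mean"] == pytest.approx(2.5)
        assert f["range"] == pytest.approx(3.0)

    def test_symmetric_skewness_zero(self):
        vol = np.array([-3.0, 0.0, 3.0]).reshape(3, 1, 1)
        f = compute_intensity_features(vol, np.ones_like(vol, bool))
        assert f["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence(self, rng):
        vals = rng.normal(10, 3, size=(4, 4, 4))
        region = rng.uniform(size=vals.shape) > 0.3
        f = compute_intensity_features(vals, region)
        v = vals[region]
        assert f["mean"] == pytest.approx(v.mean())
        assert f["variance"] == pytest.approx(v.var())
        assert f["skewness"] == pytest.approx(stats.skew(v))
        assert f["energy"] == pytest.approx((v**2).sum())
        assert f["rms"] == pytest.approx(np.sqrt((v**2).mean()))
        assert f["p90"] == pytest.approx(np.percentile(v, 90))
        assert f["iqr"] == pytest.approx(np.percentile(v, 75) - np.percentile(v, 25))


class TestGLCM:
    def test_hand_enumerated_2x2(self):
        levels = np.array([[1, 1], [2, 2]])
        tm = compute_glcm(levels, 2, offsets=[(0, 1, 0)])
        p = tm.matrix / tm.matrix.sum()
        assert np.allclose(p, [[0.5, 0.0], [0.0, 0.5]])
        f = glcm_features(tm)
        assert f["energy"] == pytest.approx(0.5)
        assert f["contrast"] == pytest.approx(0.0)

    def test_constant_region(self):
        levels = np.ones((3, 3, 3), dtype=int)
        f = glcm_features(compute_glcm(levels, 4))
        assert f["max_probability"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)

    def test_normalization_sums_to_one(self, rng):
        levels = rng.integers(1, 6, size=(5, 5, 5))
        tm = compute_glcm(levels, 5)
        assert (tm.matrix / tm.matrix.sum()).sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(tm.matrix, tm.matrix.T)  # symmetrized

    def test_single_voxel_warns_and_zeroes(self):
        levels = np.zeros((3, 3, 3), dtype=int)
        levels[1, 1, 1] = 2
        with pytest.warns(UserWarning, match="no co-occurrence"):
            tm = compute_glcm(levels, 4)
        assert all(v == 0 for v in glcm_features(tm).values())

    def test_pair_counts_match_bruteforce(self, rng):
        levels = rng.integers(0, 4, size=(4, 4, 4))
        tm = compute_glcm(levels, 3)
        expected = 0
        for off in OFFSETS_13:
            for idx in np.ndindex(levels.shape):
                nb = tuple(np.add(idx, off))
                if all(0 <= p < s for p, s in zip(nb, levels.shape)):
                    if levels[idx] > 0 and levels[nb] > 0:
                        expected += 2  # symmetric counting
        assert tm.matrix.sum() == expected


class TestGLRLM:
    def test_single_run(self):
        levels = np.array([1, 1, 1]).reshape(1, 1, 3)
        tm = compute_glrlm(levels, 2, offsets=[(0, 0, 1)])
        f = glrlm_features(tm)
        assert tm.matrix[0, 2] == 1 and tm.matrix.sum() == 1
        assert f["sre"] == pytest.approx(1 / 9)
        assert f["lre"] == pytest.approx(9.0)
        assert f["rp"] == pytest.approx(1 / 3)

    def test_all_distinct_levels_rp_one(self):
        levels = (np.arange(27) + 1).reshape(3, 3, 3)
        f = glrlm_features(compute_glrlm(levels, 27))
        assert f["rp"] == pytest.approx(1.0)

    def test_constant_line_run_percentage(self):
        n = 7
        levels = np.ones((1, 1, n), dtype=int)
        f = glrlm_features(compute_glrlm(levels, 2, offsets=[(0, 0, 1)]))
        assert f["rp"] == pytest.approx(1 / n)

    def test_runs_match_bruteforce(self, rng):
        levels = rng.integers(0, 4, size=(5, 5, 5))
        if not (levels > 0).any():
            levels[0, 0, 0] = 1
        tm = compute_glrlm(levels, 3)
        expected = np.zeros_like(tm.matrix)
        for off in OFFSETS_13:
            for g, r in count_runs_bruteforce(levels, off):
                expected[g - 1, r - 1] += 1
        assert np.array_equal(tm.matrix, expected)


class TestGLSZM:
    def test_single_zone(self):
        levels = np.ones((2, 2, 2), dtype=int)
        tm = compute_glszm(levels, 2)
        f = glszm_features(tm)
        assert tm.matrix[0, 7] == 1 and tm.matrix.sum() == 1
        assert f["zp"] == pytest.approx(1 / 8)

    def test_all_distinct_sae_one(self):
        levels = (np.arange(8) + 1).reshape(2, 2, 2)
        f = glszm_features(compute_glszm(levels, 8))
        assert f["sae"] == pytest.approx(1.0)
        assert f["zp"] == pytest.approx(1.0)

    def test_two_blobs_histogram(self):
        levels = np.zeros((1, 1, 9), dtype=int)
        levels[0, 0, :3] = 2
        levels[0, 0, 4:9] = 2
        tm = compute_glszm(levels, 2)
        assert tm.matrix[1, 2] == 1 and tm.matrix[1, 4] == 1 and tm.matrix.sum() == 2

    def test_zones_match_bruteforce(self, rng):
        levels = rng.integers(0, 4, size=(5, 5, 5))
        if not (levels > 0).any():
            levels[0, 0, 0] = 1
        tm = compute_glszm(levels, 3)
        expected = np.zeros_like(tm.matrix)
        for g, s in count_zones_bruteforce(levels):
            expected[g - 1, s - 1] += 1
        assert np.array_equal(tm.matrix, expected)


class TestNGTDM:
    def test_constant_region_coarseness_cap(self):
        levels = np.full((3, 3, 3), 2, dtype=int)
        f = ngtdm_features(compute_ngtdm(levels, 4))
        assert f["coarseness"] == NGTDM_COARSENESS_CAP

    def test_alternating_line_hand_computed(self):
        # 1D line 1,2,1,2,1: interior voxel i has neighbors i-1, i+1 (equal
        # levels), ends have one neighbor; |level - mean| per voxel:
        # ends: |1-2|=1, |2-1|=1 at index 3? enumerate directly below
        levels = np.array([1, 2, 1, 2, 1]).reshape(1, 1, 5)
        tm = compute_ngtdm(levels, 2)
        s = tm.extra
        # voxel 0 (lvl1): nb mean 2 -> 1 ; voxel 2 (lvl1): nbs 2,2 -> 1
        # voxel 4 (lvl1): nb 2 -> 1 => s_1 = 3
        # voxel 1 (lvl2): nbs 1,1 -> 1 ; voxel 3 same -> s_2 = 2
        assert s[0] == pytest.approx(3.0)
        assert s[1] == pytest.approx(2.0)

    def test_contrast_shift_invariant(self, rng):
        levels = rng.integers(1, 5, size=(4, 4, 4))
        f1 = ngtdm_features(compute_ngtdm(levels, 6))
        f2 = ngtdm_features(compute_ngtdm(levels + 1, 6))
        assert f1["contrast"] == pytest.approx(f2["contrast"])


class TestExtract:
    def test_vector_length_and_determinism(self, one_patient):
        v1 = extract_handcrafted(one_patient)
        v2 = extract_handcrafted(one_patient)
        assert len(v1) == 1403
        assert v1.equals(v2)
        assert v1.notna().all()

    def test_spacing_doubling(self, one_patient):
        doubled = dataclasses.replace(
            one_patient,
            mask=SubregionMask(one_patient.mask.labels, tuple(2 * s for s in one_patient.spacing)),
        )
        v1 = extract_handcrafted(one_patient)
        v2 = extract_handcrafted(doubled)
        assert v2["GEOM_volume"] == pytest.approx(8 * v1["GEOM_volume"])
        # identical voxel grids quantize identically: texture is unchanged
        tex = [n for n in v1.index if "_GLCM_" in n or "_GLRLM_" in n]
        assert np.allclose(v1[tex], v2[tex])

    def test_empty_subregion_yields_nan(self, one_patient):
        labels = one_patient.mask.labels.copy()
        labels[labels == 1] = 2  # erase necrosis
        broken = dataclasses.replace(one_patient, mask=SubregionMask(labels, one_patient.spacing))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v = extract_handcrafted(broken)
        assert np.isnan(v["T1C_SN_INT_mean"])
        assert np.isfinite(v["T1C_ST_INT_mean"])
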