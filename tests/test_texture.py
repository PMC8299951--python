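"""Texture extractor: worked examples, brute-force oracles, invariants."""

import numpy as np
import pytest

from habitat_tex import texture
from habitat_tex.texture import (
    ANGLES,
    CoocMatrix,
    RunLengthMatrix,
    extract_all,
    feature_names,
    glcm,
    glcm_block,
    glcm_stats,
    grlm,
    grlm_block,
    grlm_stats,
    histogram_features,
)

STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(img, mask, angle, distance, levels):
    """Independent pair enumerator: explicit python loops over positions."""
    dr, dc = (distance * s for s in STEPS[angle])
    P = np.zeros((levels, levels))
    R, C = img.shape
    for r in range(R):
        for c in range(C):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < R and 0 <= c2 < C and mask[r, c] and mask[r2, c2]:
                P[img[r, c], img[r2, c2]] += 1
                P[img[r2, c2], img[r, c]] += 1
    return P / P.sum() if P.sum() else None


def brute_runs(img, mask, angle):
    """Independent run enumerator: walk every line pixel by pixel."""
    R, C = img.shape
    dr, dc = STEPS[angle]
    starts = [(r, c) for r in range(R) for c in range(C)
              if not (0 <= r - dr < R and 0 <= c - dc < C)]
    runs = []
    for r0, c0 in starts:
        r, c, cur, length = r0, c0, None, 0
        while 0 <= r < R and 0 <= c < C:
            v = img[r, c] if mask[r, c] else None
            if v is not None and v == cur:
                length += 1
            else:
                if cur is not None:
                    runs.append((cur, length))
                cur, length = v, (1 if v is not None else 0)
            r, c = r + dr, c + dc
        if cur is not None:
            runs.append((cur, length))
    return sorted(runs)


def runs_from_matrix(rlm):
    out = []
    for g, l in zip(*np.nonzero(rlm.R)):
        out.extend([(g, l + 1)] * rlm.R[g, l])
    return sorted(out)


class TestSchema:
    def test_counts_by_family(self):
        names = feature_names()
        assert len(names) == 467
        assert len(set(names)) == 467
        assert sum(n.startswith("hist_") for n in names) == 4
        assert sum(n.startswith("glcm_") for n in names) == 380
        assert sum(n.startswith("grlm_") for n in names) == 44
        for w in ("haar", "db2", "sym4"):
            assert sum(n.startswith(f"dwt_{w}_") for n in names) == 13


class TestHistogram:
    def test_constant_region(self):
        h = histogram_features(np.full(10, 7.0))
        assert h == {"mean": 7.0, "variance": 0.0, "skewness": 0.0, "kurtosis": 0.0}

    def test_moments_oracle(self):
        h = histogram_features(np.array([2.0, 4.0, 6.0]))
        assert h["mean"] == pytest.approx(4.0)
        assert h["variance"] == pytest.approx(8 / 3)
        assert h["skewness"] == pytest.approx(0.0)

    def test_two_extremes(self):
        assert histogram_features(np.array([0.0, 255.0]))["mean"] == 127.5


class TestGLCM:
    def test_worked_example_horizontal(self):
        img = np.array([[0, 0], [1, 1]], dtype=np.uint8) * 255
        mask = np.ones((2, 2), dtype=bool)
        cm = glcm(img, mask, 0, 1, levels=2)
        assert cm.P[0, 0] == pytest.approx(0.5)
        assert cm.P[1, 1] == pytest.approx(0.5)
        assert glcm_stats(cm)["contrast"] == pytest.approx(0.0)

    def test_worked_example_vertical(self):
        img = np.array([[0, 0], [1, 1]], dtype=np.uint8) * 255
        mask = np.ones((2, 2), dtype=bool)
        cm = glcm(img, mask, 90, 1, levels=2)
        assert cm.P[0, 1] == pytest.approx(0.5)
        assert cm.P[1, 0] == pytest.approx(0.5)
        s = glcm_stats(cm)
        assert s["contrast"] == pytest.approx(1.0)
        assert s["dissimilarity"] == pytest.approx(1.0)
        assert s["homogeneity"] == pytest.approx(0.5)

    def test_normalized_and_symmetric(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, (9, 9)).astype(np.uint8)
            mask = rng.random((9, 9)) > 0.3
            for a in ANGLES:
                cm = glcm(img, mask, a, 2, levels=8)
                if cm is None:
                    continue
                assert cm.P.sum() == pytest.approx(1.0, abs=1e-12)
                assert np.allclose(cm.P, cm.P.T)

    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(15):
            img = rng.integers(0, 4, (6, 6))
            mask = rng.random((6, 6)) > 0.25
            for a in ANGLES:
                for d in (1, 2):
                    cm = glcm((img * 64).astype(np.uint8), mask, a, d, levels=4)
                    ref = brute_glcm(img, mask, a, d, 4)
                    if ref is None:
                        assert cm is None
                    else:
                        assert np.abs(cm.P - ref).max() < 1e-12

    def test_delta_distribution_stats(self):
        P = np.zeros((4, 4))
        P[2, 2] = 1.0
        s = glcm_stats(CoocMatrix(P=P, levels=4, angle=0, distance=1))
        assert s["energy"] == 1.0
        assert s["entropy"] == 0.0
        assert s["max_probability"] == 1.0
        assert s["contrast"] == 0.0

    def test_uniform_distribution_stats(self):
        L = 8
        P = np.full((L, L), 1.0 / L**2)
        s = glcm_stats(CoocMatrix(P=P, levels=L, angle=0, distance=1))
        assert s["energy"] == pytest.approx(1 / L**2)
        assert s["entropy"] == pytest.approx(2 * np.log(L))

    def test_energy_homogeneity_bounds(self, rng):
        img = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        mask = np.ones((12, 12), dtype=bool)
        for d in (1, 3):
            s = glcm_stats(glcm(img, mask, 45, d))
            assert 0 < s["energy"] <= 1
            assert 0 < s["homogeneity"] <= 1

    def test_block_count_and_angle_average(self, rng):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        mask = np.ones((16, 16), dtype=bool)
        block = glcm_block(img, mask, levels=16)
        assert len(block) == 380
        # the angle-averaged matrix is the mean of the directional matrices,
        # so a linear statistic averages exactly
        for d in (1, 2):
            vals = [block[f"glcm_contrast_a{a}_d{d}"] for a in ANGLES]
            mats = [glcm(img, mask, a, d, levels=16).P for a in ANGLES]
            s = glcm_stats(CoocMatrix(np.mean(mats, 0), 16, None, d))
            assert block[f"glcm_contrast_amean_d{d}"] == pytest.approx(s["contrast"])
            assert s["contrast"] == pytest.approx(np.mean(vals))


class TestGRLM:
    def test_row_example(self):
        img = np.array([[0, 0, 1]], dtype=np.uint8)
        rlm = grlm(img, np.ones((1, 3), bool), 0)
        assert runs_from_matrix(rlm) == [(0, 2), (1, 1)]

    def test_constant_square(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        rlm = grlm(img, np.ones((4, 4), bool), 0, levels=2)
        assert runs_from_matrix(rlm) == [(0, 4)] * 4

    def test_pixel_conservation_horizontal(self, rng):
        img = rng.integers(0, 256, (7, 9)).astype(np.uint8)
        rlm = grlm(img, np.ones((7, 9), bool), 0)
        total = sum(l for _, l in runs_from_matrix(rlm))
        assert total == 63

    def test_matches_brute_force(self, rng):
        for _ in range(15):
            img = rng.integers(0, 3, (6, 6))
            mask = rng.random((6, 6)) > 0.25
            if not mask.any():
                continue
            for a in ANGLES:
                rlm = grlm(img.astype(np.uint8), mask, a)
                ref = [(g, l) for g, l in brute_runs(img, mask, a)]
                assert runs_from_matrix(rlm) == ref

    def test_stats_worked_example(self):
        R = np.zeros((2, 2), dtype=np.int64)
        R[0, 1] = 1  # gray 0, length 2
        R[1, 0] = 1  # gray 1, length 1
        s = grlm_stats(RunLengthMatrix(R=R, levels=2, angle=0, n_pixels=3))
        assert s["sre"] == pytest.approx(0.625)
        assert s["rln"] == pytest.approx(1.0)
        assert s["rp"] == pytest.approx(2 / 3)

    def test_unit_runs_degenerate(self):
        R = np.zeros((3, 1), dtype=np.int64)
        R[:, 0] = [2, 3, 1]
        s = grlm_stats(RunLengthMatrix(R=R, levels=3, angle=0, n_pixels=6))
        assert s["sre"] == 1.0
        assert s["lre"] == 1.0

    def test_block_count(self, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        assert len(grlm_block(img, np.ones((10, 10), bool))) == 44


class TestDWT:
    def test_constant_patch_details_vanish(self):
        patch = np.full((32, 32), 40.0)
        mask = np.ones((32, 32), dtype=bool)
        out = texture.dwt_block(patch, mask, "haar")
        for s in (1, 2, 3, 4):
            for o in ("H", "V", "D"):
                assert out[f"dwt_haar_{s}{o}H"] == pytest.approx(0.0, abs=1e-9)
        # 2D orthonormal scaling gain is 2 per level -> 2^4 at scale 4
        assert out["dwt_haar_4LL"] == pytest.approx(40.0 * 16)

    def test_block_size(self, rng):
        patch = rng.uniform(0, 255, (24, 24))
        mask = np.ones((24, 24), dtype=bool)
        total = {}
        for w in texture.WAVELETS:
            total.update(texture.dwt_block(patch, mask, w))
        assert len(total) == 39

    @pytest.mark.parametrize("wavelet", texture.WAVELETS)
    def test_parseval_on_dyadic_patch(self, wavelet, rng):
        x = rng.standard_normal((32, 32))
        coeffs = texture.dwt_decompose(x, wavelet, levels=4, mode="periodization")
        energy = sum(float((np.asarray(c) ** 2).sum())
                     for part in coeffs
                     for c in (part if isinstance(part, tuple) else (part,)))
        assert energy == pytest.approx(float((x**2).sum()), abs=1e-8)

    def test_small_region_padded_not_missing(self):
        patch = np.arange(25, dtype=float).reshape(5, 5)
        mask = np.ones((5, 5), dtype=bool)
        out = texture.dwt_block(patch, mask, "haar")
        assert np.isfinite(list(out.values())).all()


class TestExtractAll:
    def test_full_vector_on_lesion(self, small_feature_table):
        table, _ = small_feature_table
        names = feature_names()
        whole = table[table.region == "whole"]
        assert list(whole.columns[5:]) == names
        assert np.isfinite(whole[names].to_numpy(float)).all()

    def test_empty_zone_all_missing(self):
        fv = extract_all(np.zeros((8, 8), dtype=np.uint8),
                         np.zeros((8, 8), dtype=bool), region="late")
        assert fv.is_missing
        assert len(fv.values) == 467

    def test_purity_and_translation_invariance(self, rng):
        img = rng.integers(0, 256, (20, 20)).astype(np.uint8)
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:12, 4:13] = rng.random((9, 9)) > 0.3
        fv1 = extract_all(img, mask)
        fv2 = extract_all(img, mask)
        assert (fv1.values == fv2.values).all()
        big = np.zeros((40, 40), dtype=np.uint8)
        bigmask = np.zeros((40, 40), dtype=bool)
        big[15:35, 10:30] = img
        bigmask[15:35, 10:30] = mask
        fv3 = extract_all(big, bigmask)
        np.testing.assert_allclose(fv1.values, fv3.values, rtol=1e-12)
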