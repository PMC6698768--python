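"""Texture families against brute-force oracles and closed forms."""

from __future__ import annotations

import numpy as np
import pytest

from phantex.texture import (
    AGGREGATIONS,
    DIRECTIONS_2D,
    DIRECTIONS_3D,
    FEATURE_FAMILIES,
    FEATURE_NAMES,
    embed_frame,
    extract_panel,
    feature_family,
    fft_features,
    glcm,
    glcm_stats,
    gldm,
    gldm_stats,
    glrlm,
    glrlm_stats,
    histogram_features,
    second_order_block,
    spectrum_sample,
)

from conftest import quantized_from_levels, volume_roi
from oracles import (
    brute_glcm,
    brute_gldm,
    brute_glrlm,
    naive_glcm_stats,
    naive_gldm_stats,
    naive_glrlm_stats,
)


def random_level_grid(rng, shape, n_bins):
    """Random bin-level grid with a sprinkling of out-of-mask zeros."""
    grid = rng.integers(1, n_bins + 1, size=shape)
    grid[rng.random(shape) < 0.15] = 0
    return grid


class TestGLCM:
    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(30):
            ndim = rng.integers(2, 4)
            shape = tuple(rng.integers(2, 7, size=ndim))
            n_bins = int(rng.integers(2, 7))
            grid = random_level_grid(rng, shape, n_bins)
            dirs = DIRECTIONS_2D.values() if ndim == 2 else DIRECTIONS_3D
            for off in dirs:
                expected = brute_glcm(grid, off, n_bins)
                if expected.sum() == 0:
                    with pytest.raises(ValueError, match="direction"):
                        glcm(grid, off, n_bins)
                    continue
                np.testing.assert_allclose(
                    glcm(grid, off, n_bins).probabilities, expected, atol=1e-12
                )

    def test_constant_image_single_entry(self):
        m = glcm(np.ones((4, 4), dtype=int), (0, 1), 5)
        expected = np.zeros((5, 5))
        expected[0, 0] = 1.0
        np.testing.assert_array_equal(m.probabilities, expected)

    def test_checkerboard_off_diagonal_mass(self):
        board = np.indices((6, 6)).sum(axis=0) % 2 + 1
        m = glcm(board, (0, 1), 2)
        assert m.probabilities[0, 0] == 0.0 and m.probabilities[1, 1] == 0.0
        stats, _ = glcm_stats(m)
        assert stats["contrast"] == pytest.approx(1.0)  # (level difference)^2
        assert stats["correlation"] == pytest.approx(-1.0)

    def test_stats_match_naive_oracle(self, rng):
        for _ in range(20):
            grid = rng.integers(1, 7, size=(6, 6))
            m = glcm(grid, (0, 1), 6)
            ours, _ = glcm_stats(m)
            theirs = naive_glcm_stats(m.probabilities)
            for k, v in theirs.items():
                assert ours[k] == pytest.approx(v, abs=1e-10), k

    def test_constant_image_degenerate_stats(self):
        stats, flags = glcm_stats(glcm(np.ones((4, 4), dtype=int), (0, 1), 5))
        assert stats["energy"] == 1.0
        assert stats["entropy"] == 0.0
        assert stats["contrast"] == 0.0
        assert stats["max_probability"] == 1.0
        assert "correlation" in flags


class TestGLDM:
    def test_matches_brute_force(self, rng):
        for _ in range(20):
            grid = random_level_grid(rng, (6, 6), 5)
            for off in DIRECTIONS_2D.values():
                expected = brute_gldm(grid, off, 5)
                if expected.sum() == 0:
                    continue
                np.testing.assert_allclose(
                    gldm(grid, off, 5).probabilities, expected, atol=1e-12
                )
                ours = gldm_stats(gldm(grid, off, 5))
                theirs = naive_gldm_stats(expected)
                for k, v in theirs.items():
                    assert ours[k] == pytest.approx(v, abs=1e-10), k

    def test_constant_image_all_mass_at_zero(self):
        stats = gldm_stats(gldm(np.full((3, 5), 2), (0, 1), 4))
        assert stats == {"contrast": 0.0, "asm": 1.0, "entropy": 0.0,
                         "mean": 0.0, "idm": 1.0}

    def test_horizontal_ramp_all_differences_one(self):
        ramp = np.tile(np.arange(1, 6), (4, 1))
        stats = gldm_stats(gldm(ramp, (0, 1), 5))
        assert stats["mean"] == pytest.approx(1.0)
        assert stats["contrast"] == pytest.approx(1.0)
        assert stats["idm"] == pytest.approx(0.5)


class TestGLRLM:
    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(20):
            ndim = rng.integers(2, 4)
            shape = tuple(rng.integers(2, 7, size=ndim))
            grid = random_level_grid(rng, shape, 4)
            dirs = DIRECTIONS_2D.values() if ndim == 2 else DIRECTIONS_3D
            for off in dirs:
                ours = glrlm(grid, off, 4)
                expected = brute_glrlm(grid, off, 4)
                np.testing.assert_array_equal(ours.counts, expected)
                assert ours.n_voxels_scanned == (grid > 0).sum()

    def test_toy_image_run_matrix(self):
        img = np.array([[1, 1, 2], [2, 2, 2], [3, 1, 1]])
        m = glrlm(img, (0, 1), 3)
        expected = np.zeros((3, 3))
        expected[0, 1] = 2  # two runs of level 1, length 2
        expected[1, 0] = 1  # level 2, length 1
        expected[1, 2] = 1  # level 2, length 3
        expected[2, 0] = 1  # level 3, length 1
        np.testing.assert_array_equal(m.counts, expected)

    def test_single_run_closed_forms(self):
        length = 7
        m = glrlm(np.ones((1, length), dtype=int), (0, 1), 3)
        stats = glrlm_stats(m)
        assert stats["rp"] == pytest.approx(1.0 / length)
        assert stats["sre"] == pytest.approx(1.0 / length**2)
        assert stats["lre"] == pytest.approx(length**2)

    def test_stats_match_naive_oracle(self, rng):
        grid = rng.integers(0, 5, size=(7, 7))
        m = glrlm(grid, (-1, 1), 4)
        ours = glrlm_stats(m)
        theirs = naive_glrlm_stats(m.counts, m.n_voxels_scanned)
        for k, v in theirs.items():
            assert ours[k] == pytest.approx(v, abs=1e-10), k


class TestHistogram:
    def test_returns_13_features(self, rng):
        roi = volume_roi(rng.normal(50, 10, size=(6, 6, 6)))
        values, _ = histogram_features(roi)
        assert len(values) == 13

    def test_constant_roi_degenerate(self):
        roi = volume_roi(np.full((5, 5, 5), 30.0))
        values, flags = histogram_features(roi)
        assert values["hist_variance"] == 0.0
        assert values["hist_entropy"] == 0.0
        assert values["hist_range"] == 0.0
        assert {"hist_skewness", "hist_kurtosis"} <= flags

    def test_uniform_bins_entropy_log2_20(self):
        # 20 voxels per level over 20 equal-width bins
        levels = np.repeat(np.arange(20), 20).astype(float)
        vals = (levels * 10 + 5).reshape((4, 10, 10))  # bin centres 5,15,...
        roi = volume_roi(vals)
        values, _ = histogram_features(roi)
        assert values["hist_entropy"] == pytest.approx(np.log2(20), abs=1e-9)
        assert values["hist_energy"] == pytest.approx(1.0 / 20, abs=1e-9)


class TestSecondOrderBlock:
    def test_block_sizes_make_160_total(self, rng):
        roi = volume_roi(rng.normal(0, 10, size=(6, 6, 6)))
        v2, _ = second_order_block(roi, "2D")
        v3, _ = second_order_block(roi, "3D")
        assert len(v2) == 80 and len(v3) == 80

    def test_constant_roi_energy_one_entropy_zero(self):
        roi = volume_roi(np.full((5, 5, 5), 10.0))
        for mode in ("2D", "3D"):
            values, _ = second_order_block(roi, mode)
            for name, v in values.items():
                if name.endswith(("_energy", "_asm")) and "range" not in name:
                    assert v == pytest.approx(1.0), name
                if name.endswith(("_entropy", "_contrast")) and "range" not in name:
                    assert v == pytest.approx(0.0), name

    def test_range_aggregation_small_on_isotropic_texture(self, rng):
        """On a phase-randomized (direction-isotropic) texture, the range
        across directions is small relative to the mean."""
        n = 24
        spectrum = rng.normal(size=(n, n, n)) + 1j * rng.normal(size=(n, n, n))
        radial = np.sqrt(
            sum(g**2 for g in np.meshgrid(*[np.fft.fftfreq(n)] * 3, indexing="ij"))
        )
        field = np.fft.ifftn(spectrum * np.exp(-((radial / 0.2) ** 2))).real
        roi = volume_roi(field / field.std() * 10, n_bins=8)
        values, _ = second_order_block(roi, "3D")
        ratio = values["glcm_3d_range_entropy"] / values["glcm_3d_mean_entropy"]
        assert 0 <= ratio < 0.2

    def test_thin_roi_skips_unusable_directions(self):
        roi = quantized_from_levels(np.array([[[1, 2, 1, 2]]]))  # 1 x 1 x 4
        values, flags = second_order_block(roi, "3D")
        assert "glcm_3d_directions_skipped" in flags
        assert len(values) == 80


class TestFFT:
    def test_returns_18_features(self, rng):
        roi = volume_roi(rng.normal(size=(1, 8, 8)))
        values, _ = fft_features(spectrum_sample(roi.plane_slice))
        assert len(values) == 18

    def test_constant_plane_degenerate_magnitude(self):
        values, flags = fft_features(spectrum_sample(np.ones((8, 8))))
        assert values["fft_mag_entropy"] == 0.0
        assert "fft_mag_entropy" in flags

    def test_sinusoid_radial_centroid(self):
        """A single in-band sinusoid concentrates the magnitude spectrum at
        its radial frequency (within one 1/512 frequency bin)."""
        f_cyc = 40  # cycles across the 512 frame: radial frequency 40/512
        x = np.arange(512) / 512
        img = 5.0 + np.sin(2 * np.pi * f_cyc * x)[None, :].repeat(512, axis=0)
        s = spectrum_sample(img)
        values, _ = fft_features(s)
        assert values["fft_mag_radial_centroid"] == pytest.approx(
            f_cyc / 512, abs=1.0 / 512
        )
        two_tone = np.log2(2)
        assert values["fft_mag_entropy"] <= two_tone + 1e-6

    def test_full_spectrum_parseval(self, rng):
        plane = rng.integers(0, 5, size=(20, 17)).astype(float)
        frame = embed_frame(plane, 512)
        spec = np.fft.fft2(frame)
        lhs = (np.abs(spec) ** 2).sum() / 512**2
        rhs = (frame**2).sum()
        assert lhs == pytest.approx(rhs, rel=1e-6)


class TestPanel:
    def test_235_features_in_canonical_blocks(self, rng):
        roi = volume_roi(rng.normal(40, 15, size=(7, 7, 7)))
        panel = extract_panel(roi)
        assert len(panel) == 235
        assert panel.names == FEATURE_NAMES
        from collections import Counter

        by_family = Counter(FEATURE_FAMILIES)
        assert by_family == {
            "histogram": 13, "glcm_2d": 60, "gldm_2d": 20, "glcm_3d": 60,
            "gldm_3d": 20, "glrlm_2d": 33, "glrlm_3d": 11, "fft": 18,
        }
        # FFT block occupies trailing indices 218..235 (1-based)
        assert all(n.startswith("fft_") for n in FEATURE_NAMES[217:])
        assert not FEATURE_NAMES[216].startswith("fft_")

    def test_deterministic_and_translation_invariant(self, rng):
        from phantex import VolumeImage, extract_roi, make_sphere_roi

        core = rng.normal(40, 15, size=(6, 6, 6))
        a = np.pad(core, ((1, 2), (0, 3), (2, 1)), constant_values=-600.0)
        b = np.pad(core, ((2, 1), (3, 0), (0, 3)), constant_values=-600.0)

        def panel_of(vals):
            # identical content at a different grid position; the -600 HU
            # padding is excluded as air, leaving the translated core
            vol = VolumeImage(vals, spacing=(1.0, 1.0, 1.0))
            mask = make_sphere_roi(vol, (4.0, 4.0, 4.0), 20.0)
            return extract_panel(extract_roi(vol, mask, min_voxels=8))

        pa = panel_of(a)
        np.testing.assert_array_equal(pa.values, panel_of(a).values)
        np.testing.assert_array_equal(pa.values, panel_of(b).values)

    def test_entropy_invariant_under_level_permutation(self, rng):
        grid = rng.integers(1, 6, size=(5, 5, 5))
        perm = np.concatenate(([0], rng.permutation(np.arange(1, 6))))
        roi_a = quantized_from_levels(grid, n_bins=5)
        roi_b = quantized_from_levels(perm[grid], n_bins=5)
        for roi_pair_stat in ["entropy"]:
            for off in DIRECTIONS_3D[:4]:
                sa, _ = glcm_stats(glcm(roi_a.grid, off, 5))
                sb, _ = glcm_stats(glcm(roi_b.grid, off, 5))
                assert sa["entropy"] == pytest.approx(sb["entropy"], abs=1e-10)

    def test_manifest_file_matches_code(self):
        from importlib import resources

        text = resources.files("phantex").joinpath("data/feature_names.txt").read_text()
        rows = [l.split("\t") for l in text.strip().splitlines() if not l.startswith("#")]
        assert len(rows) == 235
        assert tuple(r[1] for r in rows) == FEATURE_NAMES
        assert tuple(r[2] for r in rows) == FEATURE_FAMILIES
        assert [int(r[0]) for r in rows] == list(range(1, 236))

    def test_family_lookup_rejects_unknown(self):
        with pytest.raises(ValueError):
            feature_family("unknown_feature")
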