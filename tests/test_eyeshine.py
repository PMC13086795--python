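import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.spatial import cKDTree

from retinatune.errors import ConfigurationError, DataError
from retinatune.eyeshine import (
    DEFAULT_WAVELENGTHS,
    EyeshineStack,
    classify_ommatidia,
    detect_ommatidia,
    fraction_profile,
    map_to_rgb,
    subtract_background,
)
from retinatune.synth import GeneratorConfig, simulate_eyeshine_stack


def constant_stack(value=1.0, shape=(40, 40), bg=0.0):
    frames = {wl: np.full(shape, value) for wl in DEFAULT_WAVELENGTHS}
    bgs = {wl: np.full(shape, bg) for wl in DEFAULT_WAVELENGTHS}
    return EyeshineStack(0.0, frames, bgs)


class TestSubtractBackground:
    def test_self_subtraction(self):
        stack = constant_stack(0.5, bg=0.5)
        cleaned = subtract_background(stack)
        for wl in DEFAULT_WAVELENGTHS:
            assert np.all(cleaned.frames[wl] <= 1.0 / 255)

    def test_spots_survive_gradient_removed(self):
        yy, xx = np.mgrid[0:60, 0:60]
        gradient = 0.3 * xx / 60.0
        spot = np.exp(-(((yy - 30) ** 2 + (xx - 30) ** 2) / (2 * 2.5**2)))
        frames = {wl: spot + gradient for wl in DEFAULT_WAVELENGTHS}
        bgs = {wl: gradient.copy() for wl in DEFAULT_WAVELENGTHS}
        cleaned = subtract_background(EyeshineStack(0.0, frames, bgs))
        c = cleaned.frames[675]
        assert c[30, 30] == pytest.approx(1.0, abs=0.02)
        corner = c[5, 50]  # gradient-only region
        assert corner < 0.02 * c[30, 30]

    def test_negative_clipped(self):
        stack = constant_stack(0.1, bg=0.5)
        cleaned = subtract_background(stack)
        assert np.all(cleaned.frames[675] >= 0.0)

    def test_shape_mismatch(self):
        frames = {wl: np.zeros((10, 10)) for wl in DEFAULT_WAVELENGTHS}
        bgs = {wl: np.zeros((10, 10)) for wl in DEFAULT_WAVELENGTHS}
        with pytest.raises(DataError):
            EyeshineStack(0.0, frames | {675: np.zeros((5, 5))}, bgs)


class TestMapToRgb:
    def test_channel_separation(self):
        frames = {wl: np.zeros((8, 8)) for wl in DEFAULT_WAVELENGTHS}
        frames[675] = np.ones((8, 8))
        frames[653] = np.ones((8, 8))
        stack = EyeshineStack(0.0, frames, {wl: np.zeros((8, 8)) for wl in frames})
        rgb = map_to_rgb(stack)
        assert np.all(rgb[..., 0] == 1.0)
        assert np.all(rgb[..., 1] == 0.0)

    def test_constant_frames(self):
        rgb = map_to_rgb(constant_stack(0.7))
        assert np.all(rgb[..., 0] == pytest.approx(0.7))
        assert np.all(rgb[..., 1] == pytest.approx(0.7))

    def test_even_median(self):
        # G channel = median of 4 frames: median(1,3,5,7) = 4
        frames = {675: np.zeros((4, 4)), 653: np.zeros((4, 4))}
        for wl, v in zip((635, 622, 610, 594), (1.0, 3.0, 5.0, 7.0)):
            frames[wl] = np.full((4, 4), v)
        frames[575] = np.full((4, 4), 99.0)  # recorded but unused
        stack = EyeshineStack(0.0, frames, {wl: np.zeros((4, 4)) for wl in frames})
        rgb = map_to_rgb(stack)
        assert np.all(rgb[..., 1] == 4.0)

    def test_missing_wavelength_error(self):
        frames = {wl: np.zeros((4, 4)) for wl in (675, 653, 635)}
        stack = EyeshineStack(0.0, frames, {wl: np.zeros((4, 4)) for wl in frames})
        with pytest.raises(ConfigurationError, match="622"):
            map_to_rgb(stack)

    def test_white_rendering(self):
        rgb = map_to_rgb(constant_stack(0.5), white=True)
        assert np.all(rgb[..., 2] == rgb[..., 1])


def hex_spot_image(rows=10, cols=10, spacing=12.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    margin = 2 * spacing
    pts = []
    for r in range(rows):
        for c in range(cols):
            pts.append(
                ((c + 0.5 * (r % 2)) * spacing + margin,
                 r * spacing * np.sqrt(3) / 2 + margin)
            )
    pts = np.array(pts)
    h = int(pts[:, 1].max() + margin)
    w = int(pts[:, 0].max() + margin)
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w))
    for x, y in pts:
        img += np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2 * (spacing / 5) ** 2)))
    img += noise * rng.standard_normal((h, w))
    return img, pts[:, ::-1]  # truth as (row, col)


class TestDetectOmmatidia:
    def test_noiseless_lattice(self):
        img, truth = hex_spot_image(rows=14, cols=15)  # ~200 spots
        centers = detect_ommatidia(img, 12.0)
        assert len(centers) == len(truth)
        d, _ = cKDTree(truth).query(centers)
        assert np.max(d) <= 1.0

    def test_blank_image_warns_empty(self):
        with pytest.warns(UserWarning, match="noise floor"):
            centers = detect_ommatidia(np.zeros((50, 50)), 12.0)
        assert centers.shape == (0, 2)

    def test_noisy_recall_precision(self):
        img, truth = hex_spot_image(rows=14, cols=15, noise=0.05, seed=4)
        centers = detect_ommatidia(img, 12.0)
        d, idx = cKDTree(truth).query(centers)
        matched = d <= 2.0
        precision = matched.mean()
        recall = len(set(idx[matched])) / len(truth)
        assert recall >= 0.98
        assert precision >= 0.98

    def test_spacing_too_small(self):
        with pytest.raises(DataError):
            detect_ommatidia(np.zeros((10, 10)), 2.0)


def spot_rgb(r_value, g_value, shape=(40, 40), center=(20, 20), sigma=2.5):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    blob = np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / (2 * sigma**2)))
    return np.stack([r_value * blob, g_value * blob, np.zeros(shape)], axis=-1)


class TestClassifyOmmatidia:
    def test_pure_red(self):
        rgb = spot_rgb(1.0, 0.0)
        (det,) = classify_ommatidia(np.array([[20.0, 20.0]]), rgb, 12.0)
        assert det.redness == pytest.approx(1.0)
        assert det.label == "red"

    def test_midpoint_non_red(self):
        rgb = spot_rgb(0.5, 0.5)
        (det,) = classify_ommatidia(np.array([[20.0, 20.0]]), rgb, 12.0)
        assert det.redness == pytest.approx(0.5)
        assert det.label == "non-red"

    def test_dark_precedence(self):
        # bright reference spot sets the percentile scale; the faint spot
        # falls below theta_dark of it regardless of redness
        rgb = spot_rgb(1.0, 0.0) + spot_rgb(0.001, 0.0, center=(10, 30))
        dets = classify_ommatidia(
            np.array([[20.0, 20.0], [10.0, 30.0]]), rgb, 12.0
        )
        assert dets[0].label == "red"
        assert dets[1].label == "dark"

    def test_redness_scale_invariant_dark_not(self):
        rgb = spot_rgb(0.8, 0.2)
        centers = np.array([[20.0, 20.0]])
        (a,) = classify_ommatidia(centers, rgb, 12.0)
        (b,) = classify_ommatidia(centers, rgb * 10.0, 12.0)
        assert a.redness == pytest.approx(b.redness)
        assert a.label == b.label == "red"
        # dark threshold is relative to the image's own percentile: a spot
        # that is bright in isolation is dark next to a 100x brighter one
        crowded = rgb + spot_rgb(100.0, 0.0, center=(10, 30))
        (c, _) = classify_ommatidia(
            np.array([[20.0, 20.0], [10.0, 30.0]]), crowded, 12.0
        )
        assert c.label == "dark"

    def test_center_outside_image_skipped(self):
        rgb = spot_rgb(1.0, 0.0)
        with pytest.warns(UserWarning, match="outside"):
            dets = classify_ommatidia(np.array([[20.0, 20.0], [99.0, 2.0]]), rgb, 12.0)
        assert len(dets) == 1

    def test_bad_thresholds(self):
        with pytest.raises(ConfigurationError):
            classify_ommatidia(np.zeros((1, 2)), np.zeros((5, 5, 3)), 12.0, theta_dark=0.0)


class TestFractionProfile:
    def test_simple_arithmetic(self):
        det = pd.DataFrame(
            {"eye_id": "e1", "elevation": 0.0,
             "label": ["red"] * 60 + ["non-red"] * 40}
        )
        prof = fraction_profile(det)
        assert prof.f_red.item() == pytest.approx(0.6)
        assert prof.f_nonred.item() == pytest.approx(0.4)
        assert prof.f_dark.item() == 0.0

    def test_mean_sd_across_eyes(self):
        det = pd.DataFrame(
            {"eye_id": ["e1"] * 10 + ["e2"] * 10, "elevation": 30.0,
             "label": ["red"] * 5 + ["non-red"] * 5 + ["red"] * 7 + ["non-red"] * 3}
        )
        prof = fraction_profile(det)
        assert prof.f_red.item() == pytest.approx(0.6)
        assert prof.f_red_sd.item() == pytest.approx(0.1414, abs=1e-3)

    def test_all_dark(self):
        det = pd.DataFrame({"eye_id": "e1", "elevation": 0.0, "label": ["dark"] * 8})
        prof = fraction_profile(det)
        assert prof.f_dark.item() == 1.0
        assert prof.f_red.item() == 0.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        det = pd.DataFrame(
            {"eye_id": rng.choice(["e1", "e2"], 200),
             "elevation": rng.choice([-60.0, 0.0, 60.0], 200),
             "label": rng.choice(["red", "non-red", "dark"], 200)}
        )
        prof = fraction_profile(det)
        s = prof.f_red + prof.f_nonred + prof.f_dark
        np.testing.assert_allclose(s, 1.0, atol=1e-9)

    def test_missing_columns(self):
        with pytest.raises(DataError):
            fraction_profile(pd.DataFrame({"label": ["red"]}))


class TestEndToEnd:
    def test_fraction_recovery(self):
        cfg = replace(GeneratorConfig(seed=11), lattice_rows=14, lattice_cols=14,
                      pixel_noise=0.01)
        rows = []
        for elev in (-90.0, 0.0, 90.0):
            stack, truth = simulate_eyeshine_stack(cfg, elev)
            rgb = map_to_rgb(subtract_background(stack))
            centers = detect_ommatidia(rgb, cfg.lattice_spacing)
            dets = classify_ommatidia(centers, rgb, cfg.lattice_spacing)
            f_red = np.mean([d.label == "red" for d in dets])
            # detected spots are the lit ones, whose red probability is the
            # configured p_red
            assert f_red == pytest.approx(cfg.red_gradient(elev), abs=0.05)
            rows.append(f_red)
        assert rows[0] > rows[1] > rows[2]  # ventral-high red fraction

    def test_monotone_profiles_across_seeds(self):
        # 10-seed version of the monotonicity property: recovered red
        # fraction decreases dorsally whenever the generator's does
        from scipy.stats import spearmanr

        elevs = np.arange(-90.0, 90.1, 45.0)
        neg = 0
        for seed in range(10):
            cfg = replace(GeneratorConfig(seed=seed), lattice_rows=10,
                          lattice_cols=10, pixel_noise=0.02)
            fr = []
            for elev in elevs:
                stack, _ = simulate_eyeshine_stack(cfg, float(elev))
                rgb = map_to_rgb(subtract_background(stack))
                centers = detect_ommatidia(rgb, cfg.lattice_spacing)
                dets = classify_ommatidia(centers, rgb, cfg.lattice_spacing)
                fr.append(np.mean([d.label == "red" for d in dets]))
            if spearmanr(elevs, fr).statistic < 0:
                neg += 1
        assert neg >= 9
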