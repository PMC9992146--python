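"""Synthetic scenes: chemistry, geometry, rendering, segmentation, augmentation."""

import math

import numpy as np
import pytest

from cestmrf.dictionary import ParameterGrid, dot_product_match, generate_dictionary
from cestmrf.phantom import (LARG_DEFAULTS, augment_pairs,
                             fs_from_concentration, inject_b0_artifact,
                             larg_exchange_rate, make_brain_scene,
                             make_larg_scene, random_vial_layout,
                             render_raw_stack, segment_vials)
from cestmrf.physics import simulate_schedule, PoolParameters, TissueParameters
from cestmrf.schedule import generate_pseudorandom_schedule


class TestChemistry:
    def test_anchor_point(self):
        assert larg_exchange_rate(6.0, k_base=500.0, k_0=0.0) == \
            pytest.approx(500.0)

    def test_tenfold_per_ph_unit(self):
        k0 = 25.0
        lo = larg_exchange_rate(4.5, k_base=800.0, k_0=k0)
        hi = larg_exchange_rate(5.5, k_base=800.0, k_0=k0)
        assert (hi - k0) == pytest.approx(10 * (lo - k0), rel=1e-12)

    def test_monotone_in_ph(self):
        ph = np.linspace(4, 6, 21)
        k = larg_exchange_rate(ph)
        assert np.all(np.diff(k) > 0)

    def test_ph_bounds(self):
        with pytest.raises(ValueError):
            larg_exchange_rate(-0.5)
        with pytest.raises(ValueError):
            larg_exchange_rate(15.0)

    def test_fs_from_concentration(self):
        assert fs_from_concentration(50.0, 3) == pytest.approx(150 / 111000)
        assert fs_from_concentration(0.0) == 0.0
        assert fs_from_concentration(100.0) == \
            pytest.approx(4 * fs_from_concentration(25.0))
        with pytest.raises(ValueError):
            fs_from_concentration(-1.0)


class TestLargScene:
    def test_vial_geometry(self):
        layout = [(20.0, 20.0, 7.0), (20.0, 44.0, 6.0), (44.0, 32.0, 8.0)]
        scene = make_larg_scene(layout, [25, 50, 100], [4.0, 5.0, 6.0])
        assert set(np.unique(scene.region_labels)) == {0, 1, 2, 3}
        for i, (_, _, r) in enumerate(layout, start=1):
            area = (scene.region_labels == i).sum()
            # discretized disk area within a one-voxel-wide ring of pi r^2
            assert abs(area - math.pi * r ** 2) <= 2 * math.pi * r + math.pi

    def test_aux_maps_piecewise_constant(self):
        layout = [(20.0, 20.0, 6.0), (44.0, 44.0, 6.0)]
        scene = make_larg_scene(layout, [25, 100], [4.4, 5.6])
        for i, (conc, ph) in enumerate(zip([25, 100], [4.4, 5.6]), start=1):
            m = scene.region_labels == i
            assert np.all(scene.aux_maps["concentration"][m] == conc)
            assert np.all(scene.aux_maps["pH"][m] == ph)
        # saline background: water only
        bg = scene.region_labels == 0
        assert np.all(scene.truth_maps["volume_fraction"][bg] == 0)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_larg_scene([(20, 20, 8), (25, 25, 8)], [25, 50], [4, 5])

    def test_empty_layout(self):
        scene = make_larg_scene([], [], [])
        assert np.all(scene.region_labels == 0)

    def test_random_layout_non_overlapping(self):
        layout = random_vial_layout(6, (64, 64), seed=4)
        for i, (y1, x1, r1) in enumerate(layout):
            for y2, x2, r2 in layout[i + 1:]:
                assert np.hypot(y1 - y2, x1 - x2) > r1 + r2


class TestBrainScene:
    def test_wm_statistics(self):
        """WM-mask mean f_ss close to the configured 18.7% on ~1e4 voxels."""
        scene = make_brain_scene(shape=(128, 128), seed=0)
        assert scene.region_labels.size >= 10_000
        wm = scene.region_labels == 1
        mean_fss = scene.truth_maps["volume_fraction"][wm].mean()
        assert abs(mean_fss - 0.187) < 0.005
        gm = scene.region_labels == 2
        assert abs(scene.truth_maps["volume_fraction"][gm].mean() - 0.124) \
            < 0.005
        assert abs(scene.truth_maps["exchange_rate"][wm].mean() - 33.9) < 1.5
        assert abs(scene.truth_maps["exchange_rate"][gm].mean() - 49.1) < 1.5

    def test_seeded_determinism(self):
        a = make_brain_scene(seed=3)
        b = make_brain_scene(seed=3)
        np.testing.assert_array_equal(a.region_labels, b.region_labels)
        for k in a.truth_maps:
            np.testing.assert_array_equal(a.truth_maps[k], b.truth_maps[k])

    def test_physical_bounds(self):
        scene = make_brain_scene(shape=(96, 96), tumor=True, seed=1)
        fg = scene.foreground
        fss = scene.truth_maps["volume_fraction"][fg]
        assert np.all((fss > 0) & (fss < 1))
        assert scene.lineshape is not None
        assert 3 in np.unique(scene.region_labels)


class TestB0Artifact:
    def test_zero_amplitude_is_identity(self):
        scene = make_larg_scene([(32, 32, 8)], [50], [5.0])
        out = inject_b0_artifact(scene, n_blobs=3, max_shift_ppm=0.0, seed=0)
        np.testing.assert_array_equal(out.truth_maps["b0_shift"],
                                      scene.truth_maps["b0_shift"])

    def test_single_blob_peak_amplitude(self):
        scene = make_larg_scene([(32, 32, 8)], [50], [5.0])
        out = inject_b0_artifact(scene, n_blobs=1, max_shift_ppm=0.4, seed=2)
        peak = np.max(np.abs(out.truth_maps["b0_shift"]))
        assert peak == pytest.approx(0.4, rel=0.01)
        for k in ("volume_fraction", "exchange_rate", "t1_water"):
            np.testing.assert_array_equal(out.truth_maps[k],
                                          scene.truth_maps[k])

    def test_matching_error_concentrates_in_blob(self, larg_tissue):
        """Dictionary matching degrades inside the B0 blob, not outside."""
        sched = generate_pseudorandom_schedule(12, "cest_3ppm", seed=5)
        scene = make_larg_scene([(20, 20, 9), (44, 44, 9)], [100, 100],
                                [5.5, 5.5], t1_jitter=0.0)
        pert = inject_b0_artifact(scene, n_blobs=1, max_shift_ppm=0.5, seed=8)
        grid = ParameterGrid(axes={
            "volume_fraction": list(np.linspace(1e-4, 3.5e-3, 15)),
            "exchange_rate": list(np.linspace(20, 1400, 15))})
        d = generate_dictionary(grid, sched, larg_tissue)
        stack = render_raw_stack(pert, sched, noise_sigma=0.0)
        est, _ = dot_product_match(np.moveaxis(stack.images, 0, -1), d)
        vials = scene.region_labels > 0
        blob = pert.meta["b0_blob_mask"]
        err = np.abs(est["exchange_rate"]
                     - scene.truth_maps["exchange_rate"])
        in_blob, out_blob = vials & blob, vials & ~blob
        if in_blob.sum() >= 10 and out_blob.sum() >= 10:
            assert err[in_blob].mean() > err[out_blob].mean()


class TestRendering:
    def test_noiseless_matches_direct_simulation(self, schedule6):
        scene = make_larg_scene([(32, 32, 8)], [50], [5.0], t1_jitter=0.0)
        stack = render_raw_stack(scene, schedule6, noise_sigma=0.0)
        assert len(stack) == 6
        vial = scene.region_labels == 1
        yx = np.argwhere(vial)[0]
        tissue = TissueParameters(
            water=PoolParameters(t1=LARG_DEFAULTS["t1_water"],
                                 t2=LARG_DEFAULTS["t2_water"]),
            solute=PoolParameters(
                t1=LARG_DEFAULTS["t1_solute"], t2=LARG_DEFAULTS["t2_solute"],
                chemical_shift=3.0,
                exchange_rate=float(scene.truth_maps["exchange_rate"][vial][0]),
                volume_fraction=float(
                    scene.truth_maps["volume_fraction"][vial][0])))
        direct = simulate_schedule(tissue, schedule6)
        np.testing.assert_allclose(stack.images[:, yx[0], yx[1]], direct,
                                   rtol=1e-10)

    def test_rician_background_bias(self, schedule6):
        """Zero-signal voxels acquire the Rician mean sigma*sqrt(pi/2)."""
        scene = make_larg_scene([], [], [], shape=(32, 32))
        scene.truth_maps["t1_water"][:] = 0.0  # empty FOV: pure noise
        sigma = 0.05
        stack = render_raw_stack(scene, schedule6, noise_sigma=sigma,
                                 noise_model="rician", seed=9)
        mean = stack.images.mean()
        expected = sigma * math.sqrt(math.pi / 2)
        assert mean == pytest.approx(expected, rel=0.02)

    def test_seeded_determinism(self, schedule6):
        scene = make_larg_scene([(32, 32, 8)], [50], [5.0])
        a = render_raw_stack(scene, schedule6, noise_sigma=0.01, seed=3)
        b = render_raw_stack(scene, schedule6, noise_sigma=0.01, seed=3)
        np.testing.assert_array_equal(a.images, b.images)

    def test_noiseless_matching_recovers_grid(self, larg_tissue, schedule6):
        """On-grid vial parameters are recovered exactly for every voxel."""
        grid = ParameterGrid(axes={
            "volume_fraction": list(np.linspace(1e-4, 3.5e-3, 15)),
            "exchange_rate": list(np.linspace(20, 1400, 15))})
        d = generate_dictionary(grid, schedule6, larg_tissue)
        scene = make_larg_scene([(20, 20, 7), (44, 44, 7)], [50, 100],
                                [4.8, 5.6], t1_jitter=0.0)
        # pin the vial physics to exact grid nodes (and the water pool to the
        # dictionary's base tissue, which a matched dictionary assumes known)
        for i, (jf, jk) in enumerate(((4, 6), (10, 11)), start=1):
            m = scene.region_labels == i
            scene.truth_maps["volume_fraction"][m] = \
                grid.axes["volume_fraction"][jf]
            scene.truth_maps["exchange_rate"][m] = \
                grid.axes["exchange_rate"][jk]
            scene.truth_maps["t1_water"][m] = larg_tissue.water.t1
            scene.truth_maps["t2_water"][m] = larg_tissue.water.t2
        stack = render_raw_stack(scene, schedule6, noise_sigma=0.0)
        est, _ = dot_product_match(np.moveaxis(stack.images, 0, -1), d)
        for i, (jf, jk) in enumerate(((4, 6), (10, 11)), start=1):
            m = scene.region_labels == i
            assert np.all(est["volume_fraction"][m]
                          == grid.axes["volume_fraction"][jf])
            assert np.all(est["exchange_rate"][m]
                          == grid.axes["exchange_rate"][jk])


class TestSegmentation:
    def test_recovers_vials(self):
        layout = [(16.0, 16.0, 7.0), (16.0, 48.0, 6.0), (48.0, 16.0, 8.0),
                  (48.0, 48.0, 7.0), (32.0, 32.0, 6.0)]
        scene = make_larg_scene(layout, [50] * 5, [5.0] * 5)
        img = scene.truth_maps["volume_fraction"]
        labels, circles = segment_vials(img, radius_range=(4, 10))
        assert len(circles) == 5
        for cy, cx, r in circles:
            d = [np.hypot(cy - y, cx - x) for y, x, _ in layout]
            j = int(np.argmin(d))
            assert d[j] <= 2.0
            assert abs(r - layout[j][2]) <= 0.1 * layout[j][2] + 1e-9

    def test_blank_image_warns_empty(self):
        with pytest.warns(UserWarning, match="no circles"):
            labels, circles = segment_vials(np.zeros((64, 64)))
        assert circles == []
        assert np.all(labels == 0)


class TestAugmentation:
    def test_sevenfold_count(self):
        rng = np.random.default_rng(0)
        pairs = [(rng.normal(size=(3, 16, 16)), rng.normal(size=(2, 16, 16)))
                 for _ in range(4)]
        out = augment_pairs(pairs, seed=1)
        assert len(out) == 7 * 4

    def test_flip_involution(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 8, 8))
        out = augment_pairs([(x, x.copy())], seed=0)
        hflip = out[1][0]
        np.testing.assert_array_equal(hflip[..., :, ::-1], x)

    def test_paired_transforms_share_offsets(self):
        """A marker voxel moves identically in input and target."""
        x = np.zeros((1, 16, 16))
        y = np.zeros((1, 16, 16))
        x[0, 8, 8] = 1.0
        y[0, 8, 8] = 2.0
        for xi, yi in augment_pairs([(x, y)], seed=5):
            px = np.argwhere(xi[0] == 1.0)
            py = np.argwhere(yi[0] == 2.0)
            np.testing.assert_array_equal(px, py)
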