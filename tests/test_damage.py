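"""Damage quantification: detection, fate classification, relative densities."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial import cKDTree

from celltribo.damage import (
    DamageError,
    NucleiSet,
    RegionLayout,
    classify_fates,
    compute_damage,
    detect_nuclei,
    estimate_track_width,
)
from celltribo.synthetic import ImageScenario, generate_image_pair


def labelled_from_truth(truth):
    """Fate-labelled NucleiSet straight from generator ground truth."""
    retained = truth[truth.fate != "removed"]
    xy = retained[["x_um", "y_um"]].to_numpy()
    dead = (retained.fate == "dead").to_numpy()
    return NucleiSet(xy=xy, blue=np.ones(len(retained), bool), red=dead,
                     fate=np.where(dead, "dead", "healthy"))


def match_stats(detected_xy, truth_xy, radius=5.0):
    """Greedy nearest-neighbour matching: (precision, recall)."""
    if len(detected_xy) == 0 or len(truth_xy) == 0:
        return 0.0, 0.0
    d_det, _ = cKDTree(truth_xy).query(detected_xy)
    d_tru, _ = cKDTree(detected_xy).query(truth_xy)
    return float(np.mean(d_det <= radius)), float(np.mean(d_tru <= radius))


class TestDetectNuclei:
    def test_blank_image_with_noise_yields_nothing(self):
        rng = np.random.default_rng(0)
        img = rng.normal(300, 40, (250, 250)).clip(0, 65535).astype(np.uint16)
        assert len(detect_nuclei(img, pixel_size=2.0)) == 0

    def test_constant_image_yields_nothing(self):
        img = np.full((100, 100), 500, dtype=np.uint16)
        assert len(detect_nuclei(img, pixel_size=2.0)) == 0

    def test_recall_precision_on_well_separated_field(self):
        # 500 nuclei on a jittered grid (>= 20 um apart), rendered like the
        # generator does, plus background and shot-like noise
        rng = np.random.default_rng(4)
        pixel_size = 1.5
        gx, gy = np.meshgrid(40.0 * np.arange(25) + 20, 40.0 * np.arange(20) + 20)
        truth_xy = np.column_stack([gx.ravel(), gy.ravel()])
        truth_xy += rng.uniform(-10, 10, truth_xy.shape)
        ny, nx = int(820 / pixel_size), int(1020 / pixel_size)
        yy, xx = np.mgrid[0:ny, 0:nx] * pixel_size
        img = np.full((ny, nx), 300.0)
        amps = 12000 * rng.lognormal(0, 0.2, len(truth_xy))
        for (cx, cy), amp in zip(truth_xy, amps):
            img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 4.0**2))
        img += rng.normal(0, 40, img.shape)
        det = detect_nuclei(img.clip(0, 65535).astype(np.uint16), pixel_size)
        assert len(truth_xy) == 500
        precision, recall = match_stats(det.xy, truth_xy)
        assert precision >= 0.98
        assert recall >= 0.98

    def test_touching_blobs_merge_below_resolution(self):
        # two nuclei 2 um apart with 4 um blobs: one detected object
        img = np.full((200, 200), 300.0)
        yy, xx = np.mgrid[0:200, 0:200]
        for cx in (99.0, 101.0):  # 2 um apart at 1 um/px
            img += 10000 * np.exp(-((xx - cx) ** 2 + (yy - 100) ** 2) / (2 * 4.0**2))
        det = detect_nuclei(img.astype(np.uint16), pixel_size=1.0)
        assert len(det) == 1

    def test_missing_pixel_size_is_an_error(self):
        with pytest.raises(DamageError):
            detect_nuclei(np.zeros((10, 10)), pixel_size=0.0)

    def test_intensity_rescaling_invariance(self):
        s = ImageScenario(density_ref=250.0, track_width=80.0, p_remove=0.5,
                          p_dead=0.5, image_size=(300, 400), seed=8)
        blue, red, _ = generate_image_pair(s)
        det1 = detect_nuclei(blue, s.pixel_size)
        det2 = detect_nuclei((blue.astype(float) * 0.37), s.pixel_size)
        assert len(det1) == len(det2)
        assert np.allclose(np.sort(det1.xy, axis=0), np.sort(det2.xy, axis=0),
                           atol=0.5)


class TestClassifyFates:
    def test_empty_red_means_all_healthy(self):
        blue = NucleiSet(np.array([[10.0, 10.0], [50.0, 50.0]]),
                         np.ones(2, bool), np.zeros(2, bool))
        red = NucleiSet(np.empty((0, 2)), np.empty(0, bool), np.empty(0, bool))
        out = classify_fates(blue, red)
        assert (out.fate == "healthy").all()

    def test_identical_sets_all_dead(self):
        xy = np.array([[10.0, 10.0], [50.0, 50.0], [90.0, 30.0]])
        blue = NucleiSet(xy, np.ones(3, bool), np.zeros(3, bool))
        red = NucleiSet(xy.copy(), np.zeros(3, bool), np.ones(3, bool))
        out = classify_fates(blue, red)
        assert (out.fate == "dead").all()
        assert len(out) == 3  # each nucleus counted once

    def test_unmatched_red_counted_once_as_dead(self):
        blue = NucleiSet(np.array([[10.0, 10.0]]), np.ones(1, bool), np.zeros(1, bool))
        red = NucleiSet(np.array([[200.0, 200.0]]), np.zeros(1, bool), np.ones(1, bool))
        out = classify_fates(blue, red)
        assert len(out) == 2
        assert sorted(out.fate) == ["dead", "healthy"]

    def test_dead_fraction_within_binomial_bound(self):
        s = ImageScenario(density_ref=400.0, track_width=400.0, p_remove=0.0,
                          p_dead=0.5, image_size=(400, 500), seed=12)
        blue, red, truth = generate_image_pair(s)
        det_b = detect_nuclei(blue, s.pixel_size)
        det_r = detect_nuclei(red, s.pixel_size)
        out = classify_fates(det_b, det_r)
        in_track = np.abs(out.xy[:, 1] - s.center_y) <= s.track_width / 2
        frac = np.mean(out.fate[in_track] == "dead")
        n = in_track.sum()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n) + 0.02


class TestComputeDamage:
    def layout_for(self, s, **kw):
        return RegionLayout.default(s.image_size, s.pixel_size, s.center_y,
                                    s.track_width, **kw)

    def test_uniform_field_no_damage(self):
        s = ImageScenario(density_ref=600.0, track_width=150.0, p_remove=0.0,
                          p_dead=0.0, image_size=(600, 700), seed=3)
        _, _, truth = generate_image_pair(s)
        res = compute_damage(labelled_from_truth(truth), self.layout_for(s))
        n = res.n_healthy_band
        sigma = 1 / np.sqrt(n) + 1 / np.sqrt(res.n_blue_ref)
        assert abs(res.rel_removed) < 3 * sigma
        assert res.rel_blue == pytest.approx(1.0, abs=3 * sigma)

    def test_partition_identity_exact(self):
        s = ImageScenario(density_ref=500.0, track_width=200.0, p_remove=0.5,
                          p_dead=0.3, image_size=(700, 600), seed=6)
        _, _, truth = generate_image_pair(s)
        res = compute_damage(labelled_from_truth(truth), self.layout_for(s))
        assert res.rel_blue + res.rel_red + res.rel_removed == pytest.approx(1.0, abs=1e-12)

    def test_negative_removed_reported_unclipped(self):
        # band denser than the references -> removed fraction below zero
        xy_band = np.column_stack([np.linspace(5, 95, 40), np.full(40, 50.0)])
        xy_ref = np.column_stack([np.tile(np.linspace(5, 95, 10), 2),
                                  np.r_[np.full(10, 15.0), np.full(10, 85.0)]])
        xy = np.vstack([xy_band, xy_ref])
        n = len(xy)
        nuclei = NucleiSet(xy, np.ones(n, bool), np.zeros(n, bool),
                           fate=np.full(n, "healthy"))
        layout = RegionLayout(
            track_center_y=50.0, track_width=20.0, x_range=(0.0, 100.0),
            ref_regions=((0.0, 100.0, 10.0, 20.0), (0.0, 100.0, 80.0, 90.0)),
            image_size_um=(100.0, 100.0),
        )
        res = compute_damage(nuclei, layout)
        assert res.rel_removed < 0.0

    def test_zero_reference_density_is_an_error(self):
        nuclei = NucleiSet(np.array([[50.0, 50.0]]), np.ones(1, bool),
                           np.zeros(1, bool), fate=np.array(["healthy"]))
        layout = RegionLayout(
            track_center_y=50.0, track_width=20.0, x_range=(0.0, 100.0),
            ref_regions=((0.0, 100.0, 0.0, 10.0),),
            image_size_um=(100.0, 100.0),
        )
        with pytest.raises(DamageError):
            compute_damage(nuclei, layout)

    def test_harsh_regime_recovery_through_full_pipeline(self):
        # mirrors the hard-substrate 80 mN regime: 10% healthy, 10% dead, 80% removed
        from celltribo.damage import analyse_image_pair

        s = ImageScenario(density_ref=400.0, track_width=250.0, p_remove=0.8,
                          p_dead=0.5, seed=21)
        blue, red, truth = generate_image_pair(s)
        res, _ = analyse_image_pair(blue, red, s.pixel_size, self.layout_for(s))
        n_band = truth.in_track.sum()
        sigma = 3 / np.sqrt(n_band) + 0.02
        assert res.rel_blue == pytest.approx(0.10, abs=sigma)
        assert res.rel_red == pytest.approx(0.10, abs=sigma)
        assert res.rel_removed == pytest.approx(0.80, abs=sigma)

    def test_mild_regime_recovery(self):
        from celltribo.damage import analyse_image_pair

        # soft-substrate low-load regime: ~10% killed, essentially none removed
        s = ImageScenario(density_ref=400.0, track_width=250.0, p_remove=0.0,
                          p_dead=0.1, seed=22)
        blue, red, truth = generate_image_pair(s)
        res, _ = analyse_image_pair(blue, red, s.pixel_size, self.layout_for(s))
        n_band = truth.in_track.sum()
        sigma = 3 / np.sqrt(n_band) + 0.02
        assert res.rel_removed == pytest.approx(0.0, abs=sigma)
        assert res.rel_red == pytest.approx(0.10, abs=sigma)


class TestTrackWidth:
    def width_from_truth(self, s, bin_um=10.0, **kw):
        _, _, truth = generate_image_pair(s)
        labelled = labelled_from_truth(truth)
        h_um, w_um = s.field_um
        # reference density from the undamaged outer half of the field
        outer = np.abs(labelled.xy[:, 1] - s.center_y) > 1.5 * s.track_width
        area = (np.mean(outer) * h_um) * w_um * 1e-6
        rho = max(outer.sum(), 1) / max(area, 1e-9)
        return estimate_track_width(labelled, rho, (0, h_um), (0, w_um),
                                    bin_um=bin_um, **kw)

    def test_known_width_within_one_bin(self):
        s = ImageScenario(density_ref=3000.0, track_width=78.0, p_remove=0.9,
                          p_dead=0.5, image_size=(400, 1000), seed=30)
        est = self.width_from_truth(s)
        assert est.width_um == pytest.approx(78.0, abs=10.0)

    def test_doubled_width_doubles_estimate(self):
        s1 = ImageScenario(density_ref=3000.0, track_width=80.0, p_remove=0.9,
                           p_dead=0.5, image_size=(400, 1000), seed=31)
        s2 = dataclasses.replace(s1, track_width=160.0)
        w1 = self.width_from_truth(s1).width_um
        w2 = self.width_from_truth(s2).width_um
        assert w2 == pytest.approx(2 * w1, rel=0.2)

    def test_no_damage_reports_zero_with_warning(self):
        s = ImageScenario(density_ref=2000.0, track_width=78.0, p_remove=0.0,
                          p_dead=0.0, image_size=(400, 600), seed=32)
        with pytest.warns(UserWarning):
            est = self.width_from_truth(s)
        assert est.width_um == 0.0


class TestRegionLayout:
    def test_overlapping_reference_rejected(self):
        with pytest.raises(DamageError):
            RegionLayout(
                track_center_y=50.0, track_width=40.0, x_range=(0.0, 100.0),
                ref_regions=((0.0, 100.0, 40.0, 60.0),),
                image_size_um=(100.0, 100.0),
            )

    def test_default_layout_flanks_track(self):
        layout = RegionLayout.default((875, 1000), 2.0, 875.0, 100.0)
        assert len(layout.ref_regions) == 2
        assert layout.area_ref_mm2 > 0 and layout.area_slide_mm2 > 0
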