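import math

import numpy as np
import pytest

from spheromon.config import ConfigurationError
from spheromon.features import extract_features
from spheromon.phantom import (
    AggregationParams,
    PhantomSpec,
    generate_frame,
    generate_timelapse,
    timelapse_spec,
    validation_benchmark,
    well_grid,
)


class TestSpecValidation:
    def test_geometry_invariant(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(well_inner_radius=90.0, well_outer_radius=83.0).validate()
        with pytest.raises(ConfigurationError):
            PhantomSpec(well_outer_radius=120.0, well_pitch=225.0).validate()

    def test_intensity_ranges(self):
        with pytest.raises(ConfigurationError):
            PhantomSpec(rim_darkness=1.5).validate()
        with pytest.raises(ConfigurationError):
            PhantomSpec(noise_sigma=-0.1).validate()

    def test_frame_index_range(self):
        spec = PhantomSpec(image_shape=(300, 300), layout_margin=95.0, n_frames=2)
        with pytest.raises(ConfigurationError):
            generate_frame(spec, 2)


class TestDeterminism:
    def test_bit_identical_frames_and_truth(self, single_well_spec):
        f1, t1 = generate_frame(single_well_spec, 0)
        f2, t2 = generate_frame(single_well_spec, 0)
        assert (f1.pixels == f2.pixels).all()
        assert (t1.wells[0].mask.pixels == t2.wells[0].mask.pixels).all()
        assert t1.wells[0].features.area_px == t2.wells[0].features.area_px

    def test_different_seed_differs(self, single_well_spec):
        import dataclasses

        other = dataclasses.replace(single_well_spec, seed=99)
        f1, _ = generate_frame(single_well_spec, 0)
        f2, _ = generate_frame(other, 0)
        assert not (f1.pixels == f2.pixels).all()


class TestSingleBlobLimit:
    def test_noise_free_single_disk_truth(self, single_well_spec):
        frame, truth = generate_frame(single_well_spec, 0)
        w = truth.wells[0]
        # truth is exactly the lattice disk of the steady-state area
        r = math.sqrt(5000.0 / math.pi)
        r0, c0 = w.mask.offset
        h, ww = w.mask.pixels.shape
        yy, xx = np.mgrid[r0 : r0 + h, c0 : c0 + ww]
        disk = (xx - w.center[0]) ** 2 + (yy - w.center[1]) ** 2 <= r * r
        assert (w.mask.pixels == disk).all()
        # the only dark in-well object is that disk: everything well inside
        # the well but outside the (slightly padded) disk is background-bright
        dist = np.hypot(xx - w.center[0], yy - w.center[1])
        annulus = (dist > r + 5) & (dist < 70)
        assert frame.pixels[r0 : r0 + h, c0 : c0 + ww][annulus].min() > 0.7

    def test_infinite_rate_all_frames_steady(self, single_well_spec):
        import dataclasses

        spec = dataclasses.replace(single_well_spec, n_frames=3)
        frames, truths = generate_timelapse(spec)
        for t in truths[1:]:
            assert (t.wells[0].mask.pixels == truths[0].wells[0].mask.pixels).all()


class TestTruthContracts:
    def test_containment_in_inner_disk(self):
        spec = PhantomSpec(image_shape=(480, 700), layout_margin=110.0, seed=21)
        _, truth = generate_frame(spec, 0)
        for w in truth.visible_occupied():
            r0, c0 = w.mask.offset
            rows, cols = np.nonzero(w.mask.pixels)
            d = np.hypot(cols + c0 - w.center[0], rows + r0 - w.center[1])
            assert d.max() <= w.inner_radius

    def test_self_consistency_features(self):
        spec = PhantomSpec(image_shape=(480, 700), layout_margin=110.0, seed=22)
        _, truth = generate_frame(spec, 0)
        for w in truth.visible_occupied():
            rec = extract_features(w.mask, spec.pixel_size_um)
            assert rec.area_px == w.features.area_px
            assert rec.perimeter_px == w.features.perimeter_px
            assert rec.circularity == w.features.circularity
            assert rec.centroid == w.features.centroid


class TestKinetics:
    def test_area_decays_circularity_rises_monotonically(self):
        spec = PhantomSpec(
            image_shape=(300, 300),
            layout_margin=95.0,
            n_frames=20,
            frame_interval_min=50.0,
            seed=11,
        )
        _, truths = generate_timelapse(spec)
        areas = [t.wells[0].features.area_px for t in truths]
        circs = [t.wells[0].features.circularity for t in truths]
        perims = [t.wells[0].features.perimeter_px for t in truths]
        for i in range(len(areas) - 1):
            # tolerance: one rendering-quantization step (1-px boundary band)
            assert areas[i + 1] <= areas[i] + perims[i]
            assert circs[i + 1] >= circs[i] - 0.05
        assert areas[-1] < areas[0]
        assert circs[-1] > circs[0]

    def test_drift_zero_keeps_centers_constant(self):
        spec = PhantomSpec(
            image_shape=(300, 300), layout_margin=95.0, n_frames=3, drift_per_frame=0.0
        )
        _, truths = generate_timelapse(spec)
        assert truths[0].wells[0].center == truths[2].wells[0].center

    def test_drift_bounded_per_frame(self):
        spec = PhantomSpec(
            image_shape=(300, 300), layout_margin=95.0, n_frames=5, drift_per_frame=2.0
        )
        _, truths = generate_timelapse(spec)
        centers = [t.wells[0].center for t in truths]
        for a, b in zip(centers, centers[1:]):
            assert math.hypot(b[0] - a[0], b[1] - a[1]) <= 2.0 + 1e-9


class TestPresets:
    def test_default_timelapse_preset(self):
        spec = timelapse_spec(0)
        assert spec.n_frames == 193
        assert spec.frame_interval_min == 5.0
        # 193 frames at 5-minute spacing span 16 hours
        assert (spec.n_frames - 1) * spec.frame_interval_min == 960.0
        assert spec.image_shape == (1532, 2048)
        spec.validate()
        assert len(well_grid(spec)) >= 50  # ~60 wells in the field of view


@pytest.fixture(scope="module")
def benchmark():
    return validation_benchmark(7)


class TestValidationBenchmark:
    def test_four_sets_with_55_to_65_wells(self, benchmark):
        assert [s.name for s in benchmark] == ["set1", "set2", "set3", "set4"]
        for s in benchmark:
            assert 55 <= s.n_wells <= 65

    def test_truth_masks_nonempty_and_inside_disk(self, benchmark):
        for s in benchmark:
            for truth in s.truths:
                for w in truth.visible_occupied():
                    assert w.mask.pixels.any()
                    r0, c0 = w.mask.offset
                    rows, cols = np.nonzero(w.mask.pixels)
                    d = np.hypot(cols + c0 - w.center[0], rows + r0 - w.center[1])
                    assert d.max() <= w.inner_radius

    def test_final_sets_more_circular_than_initial(self, benchmark):
        def mean_circ(s):
            vals = [
                w.features.circularity
                for t in s.truths
                for w in t.visible_occupied()
            ]
            return float(np.mean(vals))

        assert mean_circ(benchmark[1]) > mean_circ(benchmark[0])  # small
        assert mean_circ(benchmark[3]) > mean_circ(benchmark[2])  # large

    def test_steady_state_area_ranges(self, benchmark):
        for s, (lo, hi) in zip(benchmark, [(0, 1e9), (3000, 8000), (0, 1e9), (5000, 12000)]):
            if s.stage != "final":
                continue
            areas = [
                w.features.area_px for t in s.truths for w in t.visible_occupied()
            ]
            # near steady state the truth area is close to the sampled range
            assert np.mean(areas) > lo * 0.9
            assert np.mean(areas) < hi * 1.1
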