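"""Detection core: reference stats, threshold, components, aggregation."""

import numpy as np
import pytest

from aortamac.calcium import (
    AortaMask,
    AxialSlice,
    LumenReference,
    SliceMetrics,
    aggregate_level,
    calcification_threshold,
    compute_lumen_reference,
    detect_calcification,
    slice_metrics,
    summarize_participant,
)
from aortamac.errors import DegenerateReferenceError, InputError
from aortamac.phantom import CalcArc, PhantomSpec, generate_phantom_slice
from conftest import detect_on_phantom


def make_slice(hu, spacing=(1.0, 1.0)):
    return AxialSlice(hu=np.asarray(hu, dtype=float), pixel_spacing=spacing, slice_thickness=5.0)


def full_mask(shape, lumen=None):
    aorta = np.ones(shape, dtype=bool)
    lz = np.zeros(shape, dtype=bool)
    if lumen is not None:
        lz[lumen] = True
    return AortaMask(lumen_zone=lz, aorta=aorta)


class TestLumenReference:
    def test_constant_zone(self):
        hu = np.full((4, 4), 150.0)
        mask = full_mask((4, 4), lumen=(slice(0, 2), slice(0, 2)))
        ref = compute_lumen_reference(make_slice(hu), mask)
        assert (ref.mean_hu, ref.sd_hu, ref.n_pixels) == (150.0, 0.0, 4)

    def test_two_pixel_hand_value(self):
        hu = np.zeros((2, 2))
        hu[0, 0], hu[0, 1] = 140.0, 160.0
        mask = full_mask((2, 2), lumen=(0, slice(None)))
        ref = compute_lumen_reference(make_slice(hu), mask)
        assert ref.mean_hu == pytest.approx(150.0)
        assert ref.sd_hu == pytest.approx(14.1421356, abs=1e-6)  # n-1 denominator

    def test_phantom_reference_recovers_lumen_statistics(self):
        slc, mask, _ = generate_phantom_slice(
            PhantomSpec(lumen_mean_hu=200.0, lumen_noise_sd=10.0, seed=8)
        )
        assert mask.lumen_zone.sum() >= 500
        ref = compute_lumen_reference(slc, mask)
        assert ref.mean_hu == pytest.approx(200.0, abs=2.0)
        assert ref.sd_hu == pytest.approx(10.0, abs=2.0)

    def test_degenerate_zone_raises(self):
        mask = full_mask((3, 3), lumen=(0, 0))
        with pytest.raises(DegenerateReferenceError):
            compute_lumen_reference(make_slice(np.zeros((3, 3))), mask)


@pytest.mark.parametrize(
    "mean,sd,expected", [(150.0, 10.0, 200.0), (150.0, 0.0, 150.0), (40.0, 8.0, 80.0)]
)
def test_threshold_is_mean_plus_five_sd(mean, sd, expected):
    assert calcification_threshold(LumenReference(mean, sd, 100)) == expected


class TestDetection:
    def test_nothing_above_threshold(self):
        slc = make_slice(np.zeros((8, 8)))
        calc = detect_calcification(slc, full_mask((8, 8)), threshold=10.0)
        assert not calc.mask.any() and calc.regions == ()

    def test_matches_naive_pixel_loop(self, rng):
        """Thresholding equals a brute-force double loop, pixel for pixel."""
        for _ in range(10):
            hu = rng.normal(100, 80, (32, 32))
            aorta = rng.random((32, 32)) < 0.6
            lumen = aorta & (rng.random((32, 32)) < 0.3)
            mask = AortaMask(lumen_zone=lumen, aorta=aorta)
            thr = float(rng.uniform(50, 200))
            calc = detect_calcification(make_slice(hu), mask, thr)
            naive = np.zeros((32, 32), dtype=bool)
            for i in range(32):
                for j in range(32):
                    if aorta[i, j] and not lumen[i, j] and hu[i, j] > thr:
                        naive[i, j] = True
            assert np.array_equal(calc.mask, naive)

    def test_phantom_ground_truth_recovery(self, arc90_phantom):
        _, slc, mask, truth = arc90_phantom
        calc = detect_on_phantom(slc, mask)
        px = slc.pixel_area
        assert abs(calc.total_area - truth.calc_area) <= px
        assert np.array_equal(calc.mask, truth.calc_mask)

    def test_region_count_disjoint_vs_merged(self):
        two = PhantomSpec(
            calc_arcs=(CalcArc(0, 40, 3.0, 600.0), CalcArc(180, 40, 3.0, 600.0)), seed=4
        )
        slc, mask, _ = generate_phantom_slice(two)
        assert len(detect_on_phantom(slc, mask).regions) == 2
        merged = PhantomSpec(
            calc_arcs=(CalcArc(0, 40, 3.0, 600.0), CalcArc(40, 40, 3.0, 600.0)), seed=4
        )
        slc, mask, _ = generate_phantom_slice(merged)
        assert len(detect_on_phantom(slc, mask).regions) == 1

    def test_min_region_px_filters_small_components(self):
        hu = np.zeros((8, 8))
        hu[1, 1] = 500.0  # single candidate pixel
        hu[5:7, 5:7] = 500.0  # 4-pixel block
        calc = detect_calcification(make_slice(hu), full_mask((8, 8)), 100.0, min_region_px=2)
        assert len(calc.regions) == 1 and calc.regions[0].n_pixels == 4

    def test_area_conservation_and_strict_inequality(self, rng):
        hu = rng.normal(100, 60, (24, 24))
        hu[3, 3] = 150.0  # exactly at threshold: a tie must be excluded
        calc = detect_calcification(make_slice(hu), full_mask((24, 24)), 150.0)
        assert not calc.mask[3, 3]
        assert calc.total_area == pytest.approx(calc.mask.sum() * 1.0)

    def test_monotone_in_threshold(self, arc90_phantom):
        _, slc, mask, _ = arc90_phantom
        areas = [
            detect_calcification(slc, mask, thr).total_area
            for thr in np.linspace(100, 700, 13)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_shape_mismatch_raises(self):
        with pytest.raises(InputError):
            detect_calcification(make_slice(np.zeros((4, 4))), full_mask((5, 5)), 0.0)


class TestAggregation:
    def test_slice_metrics_arithmetic(self):
        hu = np.zeros((10, 10))
        hu[:5, :5] = 500.0
        slc = make_slice(hu)
        mask = full_mask((10, 10))
        calc = detect_calcification(slc, mask, 100.0)
        m = slice_metrics(slc, mask, calc)
        assert m.calc_area == pytest.approx(25.0)
        assert m.mean_attenuation == pytest.approx(hu.mean())
        assert m.n_regions == 1

    def test_level_mean_and_volume(self):
        mets = [SliceMetrics(a, 100.0, 1 if a else 0) for a in (0.0, 10.0, 20.0)]
        lm = aggregate_level(mets, "L3", slice_thickness=3.0)
        assert lm.calc_area == pytest.approx(10.0)
        assert lm.calc_volume == pytest.approx(90.0)
        assert lm.n_slices == 3

    def test_empty_level_is_missing_marker(self):
        assert aggregate_level([], "L2", 3.0) is None

    def test_participant_means_over_available_levels(self):
        l3 = aggregate_level([SliceMetrics(6.0, 150.0, 1)], "L3", 3.0)
        l4 = aggregate_level([SliceMetrics(10.0, 170.0, 1)], "L4", 3.0)
        p = summarize_participant({"L3": l3, "L4": l4})
        assert p.l1l4_calc_area == pytest.approx(8.0)
        assert p.l1l4_mean_attenuation == pytest.approx(160.0)
        assert not p.zero_calcification

        single = summarize_participant({"L3": l3})
        assert single.l1l4_calc_area == pytest.approx(6.0)

    def test_zero_calcification_flag_and_exclusion_marker(self):
        zero = aggregate_level([SliceMetrics(0.0, 150.0, 0)], "L1", 3.0)
        p = summarize_participant({"L1": zero})
        assert p.zero_calcification
        assert summarize_participant({}) is None
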