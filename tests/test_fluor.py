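"""Fluorescence quantification: dot counting, fiber morphometry, ratios."""

import math

import numpy as np
import pytest

from ecmorph import synthgen as sg
from ecmorph.fluor import (
    DotParams,
    channel_ratio,
    count_pla_dots,
    fiber_diameter,
    fiber_length,
    mean_dots_per_image,
)

PARAMS = DotParams(rolling_ball_radius=15.0)


class TestDotCounting:
    def test_blank_image_counts_zero(self):
        assert count_pla_dots(np.full((64, 64), 100, dtype=np.uint16), PARAMS).count == 0

    def test_saturated_image_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            count_pla_dots(np.full((64, 64), 65535, dtype=np.uint16), PARAMS)

    def test_exact_count_across_seeds(self, spot_image_factory):
        for seed in range(10):
            image, truth = spot_image_factory(seed=seed)
            result = count_pla_dots(image, PARAMS)
            assert result.count == truth.data["n_spots"]

    def test_maxima_near_true_centers(self, spot_image_factory):
        image, truth = spot_image_factory(seed=1)
        result = count_pla_dots(image, PARAMS)
        centers = np.array(truth.data["centers"])
        for m in result.maxima:
            assert np.min(np.hypot(*(centers - m).T)) < 3.0

    @pytest.mark.parametrize("sep_sigma,expected", [(4.0, 2), (1.0, 1)])
    def test_two_spot_resolution_limit(self, sep_sigma, expected):
        sigma = 2.0
        sep = sep_sigma * sigma
        cfg = sg.SynthConfig(
            seed=0, image_shape=(64, 64),
            spot=sg.SpotSpec(
                n_spots=2, sigma_px=sigma, amplitude=1000.0, background=10.0,
                poisson=False,
                centers=[(32.0, 32.0 - sep / 2), (32.0, 32.0 + sep / 2)],
            ),
        )
        image, _ = sg.make_spot_image(cfg)
        assert count_pla_dots(image, PARAMS).count == expected

    def test_count_non_increasing_in_prominence(self, spot_image_factory):
        image, _ = spot_image_factory(seed=3)
        counts = [
            count_pla_dots(
                image, DotParams(rolling_ball_radius=15.0, prominence_fraction=p)
            ).count
            for p in (0.05, 0.1, 0.3, 0.6, 0.9)
        ]
        assert np.all(np.diff(counts) <= 0)

    def test_invariant_under_background_offset(self, spot_image_factory):
        image, truth = spot_image_factory(seed=4)
        offset = int(0.2 * truth.data["amplitude"])
        shifted = (image.astype(np.int64) + offset).astype(np.uint16)
        assert count_pla_dots(shifted, PARAMS).count == count_pla_dots(image, PARAMS).count


class TestMeanDots:
    def test_simple_mean(self):
        rows = [
            {"count": 4, "coverslip": "cs1", "group": "WT"},
            {"count": 6, "coverslip": "cs1", "group": "WT"},
        ]
        out = mean_dots_per_image(rows)
        assert out.loc[0, "mean_count"] == 5.0

    def test_single_image_is_own_mean(self):
        out = mean_dots_per_image([{"count": 7, "coverslip": "c", "group": "KO"}])
        assert out.loc[0, "mean_count"] == 7.0

    def test_planted_group_difference_recovered(self, spot_image_factory):
        rows = []
        for i, (group, n) in enumerate([("WT", 10), ("KO", 25)] * 4):
            image, _ = spot_image_factory(seed=100 + i, n_spots=n)
            rows.append(
                {"count": count_pla_dots(image, PARAMS).count,
                 "coverslip": f"cs{i}", "group": group}
            )
        out = mean_dots_per_image(rows).groupby("group")["mean_count"].mean()
        assert out["KO"] - out["WT"] == pytest.approx(15.0, abs=2.0)

    def test_empty_input_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            mean_dots_per_image(pd.DataFrame(columns=["count", "coverslip", "group"]))


class TestFiberDiameter:
    @pytest.fixture
    def gaussian_fiber_image(self):
        cfg = sg.SynthConfig(
            seed=0, image_shape=(64, 64), pixel_size_um=0.1,
            fluor_fibers=[sg.FluorFiberSpec((0.5, 3.2), (5.9, 3.2), 1000.0, 0.3)],
        )
        return sg.make_fiber_image(cfg)[0]

    def test_base_to_base_width_closed_form(self, gaussian_fiber_image):
        m = fiber_diameter(gaussian_fiber_image, ((32, 2), (32, 62)), 0.1, band_fraction=0.10)
        expected = 2 * 0.3 * math.sqrt(2 * math.log(10))  # width at 10% amplitude
        assert m.diameter_um == pytest.approx(expected, abs=0.025)

    def test_flat_profile_raises_no_fiber(self):
        with pytest.raises(ValueError, match="no fiber"):
            fiber_diameter(np.full((64, 64), 10.0), ((32, 2), (32, 62)), 0.1)

    @pytest.mark.parametrize("angle_deg", [-15.0, -7.0, 7.0, 15.0])
    def test_probe_direction_tolerance(self, gaussian_fiber_image, angle_deg):
        straight = fiber_diameter(
            gaussian_fiber_image, ((32, 2), (32, 62)), 0.1, band_fraction=0.10
        ).diameter_um
        a = math.radians(angle_deg)
        p0 = (32 - 30 * math.sin(a), 32 - 30 * math.cos(a))
        p1 = (32 + 30 * math.sin(a), 32 + 30 * math.cos(a))
        tilted = fiber_diameter(gaussian_fiber_image, (p0, p1), 0.1, band_fraction=0.10).diameter_um
        assert tilted == pytest.approx(straight, rel=0.05)

    def test_amplitude_insensitivity_with_fractional_band(self, gaussian_fiber_image):
        d1 = fiber_diameter(gaussian_fiber_image, ((32, 2), (32, 62)), 0.1, band_fraction=0.10)
        d2 = fiber_diameter(gaussian_fiber_image * 2.0, ((32, 2), (32, 62)), 0.1, band_fraction=0.10)
        assert d2.diameter_um == pytest.approx(d1.diameter_um, rel=0.05)


class TestFiberLength:
    def test_straight_fiber_length(self):
        cfg = sg.SynthConfig(
            seed=0, image_shape=(256, 256), pixel_size_um=0.1,
            fluor_fibers=[sg.FluorFiberSpec((12.8, 2.8), (12.8, 22.8), 1000.0, 0.3)],
        )
        image, truth = sg.make_fiber_image(cfg)
        lengths = fiber_length(image, 0.1)
        assert len(lengths) == 1
        assert lengths[0] == pytest.approx(truth.data["total_length_um"], abs=0.25)

    def test_blank_image_gives_empty_list(self):
        assert fiber_length(np.zeros((64, 64)), 0.1) == []

    def test_crossing_fibers_total_length(self):
        cfg = sg.SynthConfig(
            seed=0, image_shape=(256, 256), pixel_size_um=0.1,
            fluor_fibers=[
                sg.FluorFiberSpec((5.0, 5.0), (20.0, 20.0), 1000.0, 0.3),
                sg.FluorFiberSpec((20.0, 5.0), (5.0, 20.0), 1000.0, 0.3),
            ],
        )
        image, truth = sg.make_fiber_image(cfg)
        total = sum(fiber_length(image, 0.1))
        assert total == pytest.approx(truth.data["total_length_um"], rel=0.10)


class TestChannelRatio:
    @pytest.fixture
    def stacks(self):
        rng = np.random.default_rng(0)
        yy, xx = np.mgrid[-32:32, -32:32]
        nucleus = (np.hypot(yy, xx) < 10) * 500.0
        dapi1 = rng.poisson(50, (64, 64)) + nucleus
        dapi2 = rng.poisson(50, (64, 64)) + nucleus
        signal = rng.poisson(200, (64, 64)).astype(float)
        return signal, dapi1, dapi2

    def test_identical_stacks_ratio_one(self, stacks):
        signal, dapi1, _ = stacks
        assert channel_ratio(signal, dapi1, signal, dapi1) == pytest.approx(1.0)

    def test_linearity(self, stacks):
        signal, dapi1, dapi2 = stacks
        base = channel_ratio(signal, dapi1, signal, dapi2)
        assert channel_ratio(signal * 2.0, dapi1, signal, dapi2) == pytest.approx(2 * base)

    def test_planted_ratio_with_unequal_cell_amounts(self, stacks):
        signal, dapi1, dapi2 = stacks
        # denominator field has 2x the cell material and proportionate stain
        ratio = channel_ratio(signal * 1.5, dapi1, signal * 2.0, dapi2 * 2.0)
        expected = 1.5 / 1.0  # per-cell-amount signal ratio
        assert ratio == pytest.approx(expected, rel=0.10)

    def test_nucleus_count_normalization(self, stacks):
        signal, dapi1, dapi2 = stacks
        r = channel_ratio(signal, dapi1, signal, dapi2, normalization="nuclei")
        assert r == pytest.approx(1.0, rel=0.01)

    def test_zero_denominator_raises(self, stacks):
        signal, dapi1, dapi2 = stacks
        with pytest.raises(ZeroDivisionError):
            channel_ratio(signal, dapi1, np.full((64, 64), 5.0), dapi2)
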