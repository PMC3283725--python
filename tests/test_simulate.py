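"""Simulator contracts: placement, rendering physics, determinism."""

import numpy as np
import pandas as pd
import pytest

import seqihc as s

from conftest import clean_params, place_cells


class TestGroundTruth:
    def test_zero_expected_count_gives_empty_table(self):
        params = clean_params(class_table=[s.CellClass("c", {"A": 1.0}, 0)])
        gt = s.generate_ground_truth(params)
        assert len(gt.cells) == 0

    def test_same_seed_reproduces_cell_table(self):
        params = clean_params(
            field_width_um=400, field_height_um=400,
            class_table=[s.CellClass("c", {"A": 0.8}, 40)], seed=11)
        a = s.generate_ground_truth(params)
        b = s.generate_ground_truth(params)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_realized_counts_are_poisson_around_expectation(self):
        # Monte-Carlo oracle: over many seeds the mean realized count of a
        # Poisson(50) class must sit within 3 standard errors of 50
        counts = []
        for seed in range(200):
            params = clean_params(
                field_width_um=1000, field_height_um=1000,
                class_table=[s.CellClass("c", {"A": 1.0}, 50)], seed=seed)
            counts.append(len(s.generate_ground_truth(params).cells))
        se = np.sqrt(50 / 200)
        assert abs(np.mean(counts) - 50) < 3 * se

    def test_minimum_spacing_respected(self):
        params = clean_params(
            field_width_um=300, field_height_um=300,
            class_table=[s.CellClass("c", {"A": 1.0}, 60)], seed=2)
        xy = s.generate_ground_truth(params).cells[["x_um", "y_um"]].to_numpy()
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= params.cell_radius_um

    def test_expression_vectors_match_class_table(self):
        params = clean_params(
            markers=["A", "B"], field_width_um=400, field_height_um=400,
            class_table=[s.CellClass("both", {"A": 0.7, "B": 0.2}, 20),
                         s.CellClass("a_only", {"A": 0.5}, 20)], seed=3)
        gt = s.generate_ground_truth(params)
        for cls in params.class_table:
            sub = gt.cells[gt.cells.class_label == cls.label]
            assert (sub["expr_A"] == cls.expression.get("A", 0.0)).all()
            assert (sub["expr_B"] == cls.expression.get("B", 0.0)).all()

    def test_overfull_field_raises_naming_class(self):
        params = clean_params(
            field_width_um=20, field_height_um=20,
            class_table=[s.CellClass("crowded", {"A": 1.0}, 500)], seed=4)
        with pytest.raises(RuntimeError, match="crowded"):
            s.generate_ground_truth(params)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            clean_params(class_table=[s.CellClass("c", {"A": 1.5}, 10)])
        with pytest.raises(ValueError):
            clean_params(carryover_fraction=1.5)
        with pytest.raises(ValueError):
            clean_params(pixel_size_um=0.0)
        with pytest.raises(ValueError):
            clean_params(class_table=[s.CellClass("c", {"Z": 0.5}, 10)])


class TestRendering:
    def test_empty_tissue_is_blank_white(self):
        gt = s.generate_ground_truth(clean_params())
        im = s.render_round(gt, "A")
        assert np.array_equal(im.pixels, np.ones_like(im.pixels))

    def test_zero_expression_matches_empty_tissue(self):
        gt0 = s.generate_ground_truth(clean_params())
        empty = s.render_round(gt0, "A")
        gt1 = place_cells(s.generate_ground_truth(clean_params()),
                          [{"x_um": 25.0, "y_um": 25.0, "A": 0.0}])
        with_cell = s.render_round(gt1, "A")
        assert np.array_equal(empty.pixels, with_cell.pixels)

    def test_closed_form_transmittance_at_kernel_peak(self):
        # Beer-Lambert: a unit-expression soma at a pixel center transmits
        # exp(-od_c) per channel at that pixel (no blur/noise, amplitude 1)
        od = (0.3, 0.7, 0.65)
        gt = place_cells(
            s.generate_ground_truth(clean_params(chromogen_od=od)),
            [{"x_um": 25.25, "y_um": 25.25, "A": 1.0}])
        im = s.render_round(gt, "A")
        center = im.pixels[50, 50]  # pixel whose center is (25.25, 25.25) um
        assert np.allclose(center, np.exp(-np.array(od)), atol=1e-9)

    def test_carryover_scales_previous_round_absorbance(self):
        params = clean_params(markers=["A", "B"], carryover_fraction=0.05)
        gt = place_cells(s.generate_ground_truth(params),
                         [{"x_um": 25.25, "y_um": 25.25, "A": 1.0, "B": 0.0}])
        a1 = s.round_absorbance(gt, "A")
        a2 = s.round_absorbance(gt, "B", prev_absorbance=a1)
        assert np.allclose(a2, 0.05 * a1, atol=1e-12)
        assert a1[50, 50] > 0.9

    def test_series_has_one_aligned_image_per_marker(self):
        params = clean_params(
            markers=["A", "B", "C", "D", "E"], field_width_um=100,
            field_height_um=100,
            class_table=[s.CellClass("c", {m: 1.0 for m in "ABCDE"}, 5)],
            seed=6)
        images = s.render_series(s.generate_ground_truth(params))
        assert [im.marker for im in images] == ["A", "B", "C", "D", "E"]
        assert len({im.shape for im in images}) == 1
        # identity misalignment: the darkest pixel sits at the same place
        # in every round
        mins = {tuple(np.unravel_index(np.argmin(im.pixels.sum(axis=2)),
                                       im.shape)) for im in images}
        assert len(mins) == 1

    def test_rendered_channels_stay_in_unit_range(self):
        params = s.SimulationParams(
            markers=["A"],
            class_table=[s.CellClass("c", {"A": 1.0}, 30)],
            field_width_um=200, field_height_um=200,
            stain_amplitude=50.0, noise_sd=0.2, seed=7)
        im = s.render_round(s.generate_ground_truth(params), "A")
        assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0
        assert im.blank_reference.min() >= 0.0 and im.blank_reference.max() <= 1.0

    def test_noise_free_rendering_is_deterministic(self):
        params = s.SimulationParams(
            markers=["A"], class_table=[s.CellClass("c", {"A": 1.0}, 20)],
            field_width_um=200, field_height_um=200, noise_sd=0.0, seed=8)
        gt = s.generate_ground_truth(params)
        assert np.array_equal(s.render_round(gt, "A").pixels,
                              s.render_round(gt, "A").pixels)

    def test_seeded_series_reproducible_with_noise(self):
        params = s.SimulationParams(
            markers=["A", "B"],
            class_table=[s.CellClass("c", {"A": 1.0, "B": 0.5}, 20)],
            field_width_um=200, field_height_um=200, seed=9)
        s1 = s.render_series(s.generate_ground_truth(params))
        s2 = s.render_series(s.generate_ground_truth(params))
        for a, b in zip(s1, s2):
            assert np.array_equal(a.pixels, b.pixels)
            assert np.array_equal(a.blank_reference, b.blank_reference)

    @pytest.mark.parametrize("expr_pair", [(0.2, 0.4), (0.5, 1.0)])
    def test_more_expression_never_brightens_center(self, expr_pair):
        lo, hi = expr_pair
        pixels = []
        for e in (lo, hi):
            gt = place_cells(s.generate_ground_truth(clean_params()),
                             [{"x_um": 25.25, "y_um": 25.25, "A": e}])
            pixels.append(s.render_round(gt, "A").pixels[50, 50])
        assert (pixels[1] <= pixels[0] + 1e-12).all()

    def test_unknown_marker_rejected(self):
        gt = s.generate_ground_truth(clean_params())
        with pytest.raises(ValueError, match="unknown marker"):
            s.render_round(gt, "nope")


class TestPostStrip:
    def test_complete_strip_shows_only_tissue_tint(self):
        params = clean_params(
            markers=["A", "B"], background_od=0.1, carryover_fraction=0.0,
            class_table=[s.CellClass("c", {"A": 1.0, "B": 0.0}, 0)])
        gt = s.generate_ground_truth(params)
        im = s.render_post_strip(gt, "A")
        expected = np.exp(-0.1 * np.array(params.chromogen_od))
        assert np.allclose(im.pixels, expected[None, None, :], atol=1e-9)
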