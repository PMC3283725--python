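"""Detection, merging, quantification, and the co-localization report."""

import numpy as np
import pytest

import seqihc as s

from conftest import clean_params, place_cells


def _det(x_px, y_px, marker="M"):
    return s.CellDetection(x_px=x_px, y_px=y_px, area_px=400,
                           mean_signal=0.5, marker=marker)


def _detect_and_match(params, marker="M", radius_um=5.0):
    gt = s.generate_ground_truth(params)
    sig = s.extract_signal(s.white_balance(s.render_round(gt, marker)))
    dets = s.detect_cells(sig)
    px = params.pixel_size_um
    det_um = np.array([[(d.x_px + 0.5) * px, (d.y_px + 0.5) * px]
                       for d in dets]) if dets else np.empty((0, 2))
    matched, nd, nt = s.match_centroids(
        det_um, gt.cells[["x_um", "y_um"]].to_numpy(), radius_um)
    return matched, nd, nt


class TestDetect:
    def test_empty_tissue_yields_no_detections(self):
        params = clean_params(field_width_um=200, field_height_um=200)
        sig = s.extract_signal(s.white_balance(
            s.render_round(s.generate_ground_truth(params), "A")))
        assert s.detect_cells(sig) == []

    def test_all_zero_map_yields_empty_list(self):
        sig = s.SignalMap(values=np.zeros((64, 64)), marker="M")
        assert s.detect_cells(sig) == []

    def test_planted_cells_recovered_with_high_recall_and_precision(self):
        params = s.SimulationParams(
            markers=["M"], class_table=[s.CellClass("c", {"M": 1.0}, 120)],
            field_width_um=700, field_height_um=700, min_spacing_um=10.0,
            seed=17)
        matched, nd, nt = _detect_and_match(params)
        assert matched / nt >= 0.95
        assert matched / nd >= 0.95

    def test_puncta_only_field_yields_zero_detections(self):
        params = s.SimulationParams(markers=["M"], class_table=[],
                                    field_width_um=700, field_height_um=700,
                                    seed=18)
        sig = s.extract_signal(s.white_balance(
            s.render_round(s.generate_ground_truth(params), "M")))
        assert s.detect_cells(sig) == []


class TestMerge:
    def test_coincident_detections_across_markers_merge(self):
        # grid spacing far beyond the merge radius
        pts = np.array([[60.0 + 40 * i, 60.0 + 40 * j]
                        for i in range(5) for j in range(2)])
        per_marker = {
            "A": [_det(x, y, "A") for x, y in pts],
            "B": [_det(x + 0.6, y - 0.4, "B") for x, y in pts],
        }
        merged = s.merge_detections(per_marker, merge_radius_um=5.0,
                                    pixel_size_um=0.5)
        assert len(merged) == 10

    def test_distant_detections_stay_separate(self):
        per_marker = {
            "A": [_det(20 * i, 20, "A") for i in range(1, 4)],
            "B": [_det(20 * i, 200, "B") for i in range(1, 5)],
        }
        merged = s.merge_detections(per_marker, merge_radius_um=5.0,
                                    pixel_size_um=0.5)
        assert len(merged) == 7

    def test_output_sorted_by_y_then_x_regardless_of_marker_order(self):
        per_marker = {"A": [_det(40, 40)], "B": [_det(10, 10)]}
        reversed_order = {"B": [_det(10, 10)], "A": [_det(40, 40)]}
        a = s.merge_detections(per_marker, 5.0, 0.5)
        b = s.merge_detections(reversed_order, 5.0, 0.5)
        assert np.array_equal(a, b)
        assert (np.diff(a[:, 1]) >= 0).all()


class TestQuantify:
    def _two_marker_maps(self, rows, **overrides):
        params = clean_params(markers=["G", "P"], field_width_um=200,
                              field_height_um=200, noise_sd=0.005,
                              background_od=0.1, stain_amplitude=4.0,
                              **overrides)
        gt = place_cells(s.generate_ground_truth(params), rows)
        return {im.marker: s.extract_signal(s.white_balance(im))
                for im in s.render_series(gt)}

    def test_background_centroid_classified_none(self):
        maps = self._two_marker_maps(
            [{"x_um": 50.0, "y_um": 50.0, "G": 1.0}])
        records, _ = s.build_cell_records(np.array([[150.0, 150.0]]), maps,
                                          markers=["G", "P"])
        assert records[0].class_label == "none"
        assert not any(records[0].positive.values())

    def test_single_marker_cell_classified_only(self):
        maps = self._two_marker_maps(
            [{"x_um": 50.0, "y_um": 50.0, "G": 1.0},
             {"x_um": 150.0, "y_um": 150.0, "G": 1.0, "P": 1.0}])
        records, _ = s.build_cell_records(
            np.array([[50.0, 50.0], [150.0, 150.0]]), maps,
            markers=["G", "P"])
        assert records[0].class_label == "G-only"
        assert records[1].class_label == "G+P"
        assert records[1].relative_expression["G"] > 0

    def test_disc_outside_raster_is_an_error(self):
        maps = self._two_marker_maps([{"x_um": 50.0, "y_um": 50.0, "G": 1.0}])
        with pytest.raises(ValueError, match="outside"):
            s.quantify_cell(0, (500.0, 500.0), maps, {"G": 0.1, "P": 0.1},
                            5.0, ["G", "P"])

    def test_relative_expression_recovers_two_to_one_ratio(self):
        # analytic expectation from the linear (deconvolution) signal model
        params = clean_params(markers=["G"], field_width_um=200,
                              field_height_um=200, blur_sigma_um=0.5)
        gt = place_cells(s.generate_ground_truth(params),
                         [{"x_um": 60.0, "y_um": 60.0, "G": 1.0},
                          {"x_um": 140.0, "y_um": 140.0, "G": 0.5}])
        # full-range rescale: "no saturation" means nothing may clip
        sig = s.extract_signal(s.white_balance(s.render_round(gt, "G")),
                               mode="deconvolution", rescale_percentile=100.0)
        records, _ = s.build_cell_records(
            np.array([[60.0, 60.0], [140.0, 140.0]]), {"G": sig},
            markers=["G"])
        ratio = (records[0].relative_expression["G"]
                 / records[1].relative_expression["G"])
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_doubling_expression_leaves_classifications_unchanged(self):
        labels = []
        for scale in (1.0, 2.0):
            maps = self._two_marker_maps(
                [{"x_um": 50.0, "y_um": 50.0, "G": 0.4 * scale},
                 {"x_um": 150.0, "y_um": 150.0, "G": 0.4 * scale,
                  "P": 0.35 * scale}])
            records, _ = s.build_cell_records(
                np.array([[50.0, 50.0], [150.0, 150.0]]), maps,
                markers=["G", "P"])
            labels.append([r.class_label for r in records])
        assert labels[0] == labels[1] == ["G-only", "G+P"]


class TestSummarize:
    def _record(self, i, positive, markers=("G", "P")):
        flags = {m: m in positive for m in markers}
        return s.CellRecord(record_id=i, x_um=0.0, y_um=0.0,
                            mean_signal={m: 0.5 for m in markers},
                            positive=flags,
                            class_label=s.cells.class_label(flags, markers))

    def test_all_double_positive_gives_unit_conditional_fraction(self):
        records = [self._record(i, ("G", "P")) for i in range(5)]
        rep = s.summarize(records, ["G", "P"])
        assert rep.conditional_fractions["P->G"] == 1.0
        assert rep.class_counts == {"G+P": 5}

    def test_empty_records_give_zero_counts_and_null_fractions(self):
        rep = s.summarize([], ["G", "P"])
        assert rep.n_cells == 0
        assert rep.class_counts == {}
        assert rep.conditional_fractions["G->P"] is None

    def test_counts_sum_to_total(self):
        records = ([self._record(i, ("G",)) for i in range(6)]
                   + [self._record(i + 6, ("G", "P")) for i in range(4)])
        rep = s.summarize(records, ["G", "P"])
        assert sum(rep.class_counts.values()) == rep.n_cells == 10
        assert rep.conditional_fractions["G->P"] == pytest.approx(0.4)

    def test_planted_class_fractions_recovered_at_true_centroids(self):
        # 60/40 mixture quantified at ground-truth positions: recovered
        # fractions must sit within binomial tolerance of the plant
        params = s.SimulationParams(
            markers=["G", "P"],
            class_table=[s.CellClass("G-only", {"G": 1.0, "P": 0.0}, 120),
                         s.CellClass("G+P", {"G": 1.0, "P": 1.0}, 80)],
            field_width_um=700, field_height_um=700, min_spacing_um=10.0,
            seed=23)
        gt = s.generate_ground_truth(params)
        maps = {im.marker: s.extract_signal(s.white_balance(im))
                for im in s.render_series(gt)}
        records, _ = s.build_cell_records(
            gt.cells[["x_um", "y_um"]].to_numpy(), maps, markers=["G", "P"])
        rep = s.summarize(records, ["G", "P"])
        true_frac = (gt.cells.class_label == "G+P").mean()
        est_frac = rep.class_counts.get("G+P", 0) / rep.n_cells
        assert abs(est_frac - true_frac) <= 0.04
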