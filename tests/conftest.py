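"""Shared scenes for the test suite.

Everything is generated by the simulator at test time; session-scoped
fixtures hold the larger rendered series so expensive scenes are built
once.
"""

from __future__ import annotations

import numpy as np
import pytest

import seqihc as s


def clean_params(**overrides) -> s.SimulationParams:
    """A noise-free, clutter-free, unit-amplitude scene for algebraic checks.

    These are the conditions under which the Beer–Lambert rendering has a
    closed form: no puncta, no tissue tint, no blur, no noise, flat white
    illumination, expression mapping one-to-one to optical density.
    """
    defaults = dict(markers=["A"], class_table=[], field_width_um=50.0,
                    field_height_um=50.0, puncta_density_per_mm2=0.0,
                    stain_amplitude=1.0, background_od=0.0, blur_sigma_um=0.0,
                    noise_sd=0.0, illumination=(1.0, 1.0, 1.0), seed=0)
    defaults.update(overrides)
    return s.SimulationParams(**defaults)


def place_cells(gt: s.GroundTruth, rows: list[dict]) -> s.GroundTruth:
    """Overwrite the planted cell table with hand-chosen cells."""
    import pandas as pd

    markers = list(gt.params.markers)
    full = []
    for i, r in enumerate(rows):
        row = {"cell_id": i, "x_um": r["x_um"], "y_um": r["y_um"],
               "radius_um": r.get("radius_um", 5.0),
               "class_label": r.get("class_label", "cell")}
        for m in markers:
            row[f"expr_{m}"] = float(r.get(m, 0.0))
        full.append(row)
    cols = (["cell_id", "x_um", "y_um", "radius_um", "class_label"]
            + [f"expr_{m}" for m in markers])
    gt.cells = pd.DataFrame(full, columns=cols)
    return gt


@pytest.fixture(scope="session")
def colocalization_scene():
    """Two-marker cortex analog: GAD67 in all cells, PV in a subset.

    Cells are planted at one soma diameter so every planted cell is
    spatially resolvable, which is the regime the co-localization claims
    are about.
    """
    params = s.SimulationParams(
        markers=["GAD67", "PV"],
        class_table=[
            s.CellClass("GAD67-only", {"GAD67": 1.0, "PV": 0.0}, 60),
            s.CellClass("GAD67+PV", {"GAD67": 1.0, "PV": 1.0}, 60),
        ],
        field_width_um=600.0, field_height_um=600.0, min_spacing_um=10.0,
        misalignment_per_round=[(0.0, 0.0, 0.0), (3.5, -2.25, 0.3)],
        seed=1021)
    gt = s.generate_ground_truth(params)
    images = s.render_series(gt)
    return params, gt, images


@pytest.fixture(scope="session")
def coloc_signals(colocalization_scene):
    _, _, images = colocalization_scene
    balanced = [s.white_balance(im) for im in images]
    signals = [s.extract_signal(im) for im in balanced]
    return balanced, signals
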