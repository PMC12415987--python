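"""Geometry measurement, the vehicle reference, and the giant/MNC classifier."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage import measure as skmeasure

from nucleoquant import (
    VehicleReference,
    aggregate_cells,
    build_vehicle_reference,
    classify_cells,
    confluence,
    measure_nuclei,
)
from nucleoquant.simulate import ellipse_mask


def _nucleus_df(areas, perimeters=None, censored=None):
    n = len(areas)
    if perimeters is None:
        perimeters = [40.0 + 0.5 * i for i in range(n)]
    return pd.DataFrame({
        "nucleus_id": range(1, n + 1),
        "cell_id": range(1, n + 1),
        "centroid_y": 0.0, "centroid_x": 0.0,
        "area_px2": np.asarray(areas, float),
        "area_um2": np.asarray(areas, float),
        "perimeter_px": np.asarray(perimeters, float),
        "perimeter_um": np.asarray(perimeters, float),
        "mean_dapi": 100.0,
        "border_censored": censored if censored is not None else [False] * n,
    })


def test_square_area_and_perimeter_cross_check():
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[5:15, 5:15] = 1
    df = measure_nuclei(labels, pixel_size_um=1.0)
    assert df.loc[0, "area_um2"] == 100.0
    # Crofton perimeter vs an independent marching-squares contour length
    contour = skmeasure.find_contours(labels.astype(float), 0.5)[0]
    contour_len = np.sum(np.hypot(*np.diff(contour, axis=0).T))
    assert df.loc[0, "perimeter_um"] == pytest.approx(contour_len, rel=0.10)


def test_ellipse_area_close_to_analytic():
    shape = (40, 60)
    labels = np.zeros(shape, dtype=np.int32)
    sl, m = ellipse_mask(shape, (20, 30), 10, 5, 0.0)
    labels[sl][m] = 1
    df = measure_nuclei(labels, pixel_size_um=1.0)
    assert df.loc[0, "area_um2"] == pytest.approx(math.pi * 10 * 5, rel=0.05)


def test_vehicle_reference_hand_arithmetic():
    ref = build_vehicle_reference(_nucleus_df([90.0, 100.0, 110.0]))
    assert ref.mean_area == pytest.approx(100.0)
    assert ref.sd_area == pytest.approx(10.0)
    assert ref.area_threshold == pytest.approx(130.0)
    assert ref.n_nuclei == 3


def test_vehicle_reference_degenerate_warns():
    with pytest.warns(UserWarning, match="SD is zero"):
        ref = build_vehicle_reference(_nucleus_df([100.0, 100.0],
                                                  perimeters=[40.0, 40.0]))
    assert ref.area_threshold == ref.mean_area


def test_vehicle_reference_requires_two_nuclei():
    with pytest.raises(ValueError, match="insufficient vehicle reference"):
        build_vehicle_reference(_nucleus_df([100.0]))
    # censored nuclei do not count toward the minimum
    with pytest.raises(ValueError):
        build_vehicle_reference(_nucleus_df([90.0, 100.0, 110.0],
                                            censored=[False, True, True]))


def test_aggregate_sums_exactly():
    records = _nucleus_df([40.0, 60.0, 75.0], perimeters=[20.0, 30.0, 35.0])
    cells = aggregate_cells({1: [1, 2], 2: [3]}, records)
    assert cells.loc[0, "total_area_um2"] == 100.0
    assert cells.loc[0, "total_perimeter_um"] == 50.0
    assert bool(cells.loc[0, "is_mnc"]) and not bool(cells.loc[1, "is_mnc"])
    assert cells.loc[1, "total_area_um2"] == 75.0


def test_aggregate_missing_record_errors():
    with pytest.raises(KeyError):
        aggregate_cells({1: [1, 99]}, _nucleus_df([40.0]))


def _ref(mean_area=100.0, sd_area=10.0, mean_perim=40.0, sd_perim=2.0):
    return VehicleReference(n_nuclei=100, mean_area=mean_area, sd_area=sd_area,
                            mean_perimeter=mean_perim, sd_perimeter=sd_perim)


def test_classifier_threshold_arithmetic():
    ref = _ref()  # area threshold 130, perimeter threshold 46
    cells = pd.DataFrame({
        "cell_id": [1, 2, 3],
        "n_nuclei": [1, 1, 2],
        "nucleus_ids": ["1", "2", "3;4"],
        "total_area_px2": [131.0, 100.0, 140.0],
        "total_area_um2": [131.0, 100.0, 140.0],
        "total_perimeter_px": [40.0, 40.0, 44.0],
        "total_perimeter_um": [40.0, 40.0, 44.0],
        "is_mnc": [False, False, True],
        "flagged": False,
    })
    out, summary = classify_cells(cells, ref, group="exposed")
    assert list(out["is_giant"]) == [True, False, True]
    assert list(out["is_mnc"]) == [False, False, True]
    assert summary.n_cells == 3 and summary.n_giant == 2 and summary.n_mnc == 1
    assert summary.n_giant_and_mnc == 1
    assert summary.pct_giant == pytest.approx(200.0 / 3)


def test_classifier_or_rule_perimeter_alone_suffices():
    ref = _ref()
    cells = pd.DataFrame({
        "cell_id": [1], "n_nuclei": [1], "nucleus_ids": ["1"],
        "total_area_px2": [100.0], "total_area_um2": [100.0],
        "total_perimeter_px": [47.0], "total_perimeter_um": [47.0],
        "is_mnc": [False], "flagged": False,
    })
    out, _ = classify_cells(cells, ref)
    assert bool(out.loc[0, "is_giant"])


def test_classifier_strict_inequality_at_threshold():
    ref = VehicleReference(n_nuclei=10, mean_area=100.0, sd_area=0.0,
                           mean_perimeter=40.0, sd_perimeter=0.0)
    cells = pd.DataFrame({
        "cell_id": [1], "n_nuclei": [1], "nucleus_ids": ["1"],
        "total_area_px2": [100.0], "total_area_um2": [100.0],
        "total_perimeter_px": [40.0], "total_perimeter_um": [40.0],
        "is_mnc": [False], "flagged": False,
    })
    out, _ = classify_cells(cells, ref)
    assert not bool(out.loc[0, "is_giant"])


def test_classifier_alternative_rule_and_empty_input():
    ref = _ref()
    out, summary = classify_cells(pd.DataFrame(), ref, group="x")
    assert summary.n_cells == 0 and out.empty
    cells = pd.DataFrame({
        "cell_id": [1], "n_nuclei": [1], "nucleus_ids": ["1"],
        "total_area_px2": [31.0], "total_area_um2": [31.0],
        "total_perimeter_px": [5.0], "total_perimeter_um": [5.0],
        "is_mnc": [False], "flagged": False,
    })
    out, _ = classify_cells(cells, ref, rule="3sd_abs")  # 3*SD = 30
    assert bool(out.loc[0, "is_giant"])
    with pytest.raises(ValueError):
        classify_cells(cells, ref, rule="bogus")


def test_mnc_unavailable_reported_as_none():
    ref = _ref()
    cells = pd.DataFrame({
        "cell_id": [1], "n_nuclei": [1], "nucleus_ids": ["1"],
        "total_area_px2": [100.0], "total_area_um2": [100.0],
        "total_perimeter_px": [40.0], "total_perimeter_um": [40.0],
        "is_mnc": [False], "flagged": False,
    })
    _, summary = classify_cells(cells, ref, mnc_available=False)
    assert summary.n_mnc is None and summary.pct_mnc is None


def test_confluence_arithmetic():
    mask = np.zeros((100, 100), dtype=bool)
    mask[:25, :] = True
    res = confluence(mask, pixel_size_um=2.0)
    assert res["fraction"] == 0.25
    assert res["occupied_um2"] == 2500 * 4.0
    assert confluence(np.zeros((10, 10)))["fraction"] == 0.0


def test_confluence_doubles_with_doubling_series():
    fracs = []
    for k in (1, 2, 4):
        mask = np.zeros((100, 100), dtype=bool)
        mask[: 10 * k, :] = True
        fracs.append(confluence(mask)["fraction"])
    assert fracs[1] == pytest.approx(2 * fracs[0])
    assert fracs[2] == pytest.approx(2 * fracs[1])
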