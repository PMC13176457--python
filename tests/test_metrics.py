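"""Landscape-metric correctness against hand calculations and oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escarp.metrics import (
    adjacency_counts,
    composition_metrics,
    configuration_metrics,
    label_patches,
    max_like_adjacencies,
    unit_metrics,
    zonal_metrics,
)
from escarp.raster import LandUseRaster


def ras(values, cell=100.0):
    return LandUseRaster(values=np.asarray(values, dtype=np.int16),
                         cell_size_m=cell)


def checkerboard(n=4):
    v = np.indices((n, n)).sum(axis=0) % 2 + 1
    return ras(v)


# ---------------------------------------------------------------------------
# patch labeling


def test_single_square_patch_area_and_perimeter():
    _, patches = label_patches(ras(np.ones((4, 4))), connectivity=8)
    assert len(patches) == 1
    assert patches.area_m2.iloc[0] == pytest.approx(160_000.0)
    assert patches.perimeter_m.iloc[0] == pytest.approx(1_600.0)


@pytest.mark.parametrize("connectivity,expected", [(4, 16), (8, 2)])
def test_checkerboard_patch_topology(connectivity, expected):
    _, patches = label_patches(checkerboard(4), connectivity=connectivity)
    assert len(patches) == expected


def _flood_fill_count(values, connectivity):
    """Independent recursive flood-fill patch counter."""
    nr, nc = values.shape
    seen = np.zeros_like(values, dtype=bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    count = 0
    for i in range(nr):
        for j in range(nc):
            if seen[i, j]:
                continue
            count += 1
            stack = [(i, j)]
            seen[i, j] = True
            while stack:
                r, c = stack.pop()
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < nr and 0 <= cc < nc and not seen[rr, cc]
                            and values[rr, cc] == values[r, c]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return count


@pytest.mark.parametrize("connectivity", [4, 8])
def test_patch_count_matches_flood_fill_oracle(connectivity):
    rng = np.random.default_rng(3)
    values = rng.integers(1, 3, size=(8, 8)).astype(np.int16)
    _, patches = label_patches(ras(values), connectivity=connectivity)
    assert len(patches) == _flood_fill_count(values, connectivity)


def test_all_nodata_unit_yields_empty_table_and_undefined_metrics():
    r = LandUseRaster(values=np.zeros((4, 4), dtype=np.int16),
                      cell_size_m=100.0)
    _, patches = label_patches(r)
    assert patches.empty
    assert all(np.isnan(v) for v in unit_metrics(r).values())


# ---------------------------------------------------------------------------
# composition


def test_single_class_composition():
    m = unit_metrics(ras(np.ones((10, 10))))  # 1 km2 unit
    assert m["SHDI"] == pytest.approx(0.0)
    assert m["PLAND_1"] == pytest.approx(100.0)
    assert m["PRD"] == pytest.approx(1.0)  # 1 class per 100 ha


def test_shdi_closed_forms():
    m = unit_metrics(checkerboard(4))
    assert m["SHDI"] == pytest.approx(math.log(2))
    # proportions (0.5, 0.3, 0.2): -sum p ln p = 1.02965 (by hand)
    v = np.array([1] * 50 + [2] * 30 + [3] * 20).reshape(10, 10)
    m = unit_metrics(ras(v))
    assert m["SHDI"] == pytest.approx(1.02965, abs=1e-4)


# ---------------------------------------------------------------------------
# configuration


def test_uniform_unit_configuration():
    m = unit_metrics(ras(np.ones((10, 10))))
    assert m["PD"] == pytest.approx(1.0)
    assert m["LPI"] == pytest.approx(100.0)
    assert m["ED"] == pytest.approx(0.0)
    assert m["AI"] == pytest.approx(100.0)


def test_checkerboard_fully_disaggregated():
    assert unit_metrics(checkerboard(4))["AI"] == pytest.approx(0.0)


def test_half_split_edge_density_and_lpi():
    # 10x10 unit, classes 1|2 in vertical halves, cell 100 m:
    # one internal boundary of 10 edges = 1000 m over 100 ha -> ED 10
    v = np.ones((10, 10), dtype=np.int16)
    v[:, 5:] = 2
    m = unit_metrics(ras(v))
    assert m["ED"] == pytest.approx(10.0)
    assert m["LPI"] == pytest.approx(50.0)
    adj = adjacency_counts(ras(v))
    assert adj.interclass_edge_m == pytest.approx(1_000.0)


@given(st.integers(min_value=1, max_value=400))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_max_like_adjacency_closed_form_equivalence(n):
    # three-case quasi-square formula == 2n - ceil(2 sqrt(n))
    assert max_like_adjacencies(n) == 2 * n - math.ceil(2 * math.sqrt(n))


def test_relabeling_classes_leaves_configuration_invariant():
    rng = np.random.default_rng(12)
    v = rng.integers(1, 4, size=(12, 12)).astype(np.int16)
    perm = {1: 3, 2: 1, 3: 2}
    w = np.vectorize(perm.get)(v).astype(np.int16)
    a, b = unit_metrics(ras(v)), unit_metrics(ras(w))
    for key in ("SHDI", "PD", "ED", "AI", "PRD", "LPI"):
        assert a[key] == pytest.approx(b[key], abs=1e-12)
    for orig, new in perm.items():
        assert a[f"PLAND_{orig}"] == pytest.approx(b[f"PLAND_{new}"])


def test_pland_sums_to_100_on_random_rasters():
    rng = np.random.default_rng(8)
    for _ in range(10):
        v = rng.integers(1, 7, size=(9, 9)).astype(np.int16)
        m = unit_metrics(ras(v))
        total = sum(m[f"PLAND_{c}"] for c in range(1, 7))
        assert total == pytest.approx(100.0, abs=1e-9)


def test_pafrac_undefined_below_ten_patches():
    m = unit_metrics(ras(np.ones((10, 10))))
    assert np.isnan(m["PAFRAC"])


def test_pafrac_in_unit_interval_when_defined():
    rng = np.random.default_rng(5)
    v = rng.integers(1, 4, size=(30, 30)).astype(np.int16)
    m = unit_metrics(ras(v))
    assert not np.isnan(m["PAFRAC"])
    assert 1.0 <= m["PAFRAC"] <= 2.0


# ---------------------------------------------------------------------------
# zonal aggregation


def test_zonal_units_are_independent_landscapes():
    v = np.zeros((8, 8), dtype=np.int16)
    v[:4, :4], v[:4, 4:], v[4:, :4], v[4:, 4:] = 1, 2, 3, 4
    table = zonal_metrics(ras(v), cells_per_unit=4)
    assert len(table) == 4
    assert (table["SHDI"] == 0).all()
    assert (table["AI"] == 100).all()


def test_zonal_rejects_indivisible_extent():
    with pytest.raises(ValueError, match="width"):
        zonal_metrics(ras(np.ones((8, 9))), cells_per_unit=4)
    with pytest.raises(ValueError, match="height"):
        zonal_metrics(ras(np.ones((9, 8))), cells_per_unit=4)


def test_zonal_matches_manual_crop_oracle():
    rng = np.random.default_rng(7)
    v = rng.integers(1, 5, size=(24, 24)).astype(np.int16)
    table = zonal_metrics(ras(v), cells_per_unit=8)
    for _, row in table.iterrows():
        r, c = int(row["row"]), int(row["col"])
        sub = ras(v[r * 8:(r + 1) * 8, c * 8:(c + 1) * 8])
        expected = unit_metrics(sub)
        for key, val in expected.items():
            if np.isnan(val):
                assert np.isnan(row[key])
            else:
                assert row[key] == pytest.approx(val, abs=1e-12)


def test_area_weighted_pland_conservation():
    rng = np.random.default_rng(9)
    v = rng.integers(1, 7, size=(20, 20)).astype(np.int16)
    whole = zonal_metrics(ras(v), cells_per_unit=20)
    parts = zonal_metrics(ras(v), cells_per_unit=10)
    for c in range(1, 7):
        assert whole[f"PLAND_{c}"].iloc[0] == pytest.approx(
            parts[f"PLAND_{c}"].mean(), abs=1e-9
        )
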