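"""Supply/demand assembly and the ESDR/CESDR normalization."""

import numpy as np
import pandas as pd
import pytest

from escarp.services import (
    SERVICES,
    compute_esdr,
    cs_fp_demand,
    downscale_fp_supply,
    sc_demand_rusle,
    wy_demand_quota,
)


def service_frame(**overrides):
    """Minimal two-unit service table; supply=demand=1 unless overridden."""
    data = {"unit_id": [0, 1]}
    for s in SERVICES:
        data[f"supply_{s}"] = overrides.get(f"supply_{s}", [1.0, 1.0])
        data[f"demand_{s}"] = overrides.get(f"demand_{s}", [1.0, 1.0])
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# FP downscaling


def test_fp_downscale_proportional_split():
    out = downscale_fp_supply({0: 100.0}, np.array([0.2, 0.8]),
                              np.array([0, 0]))
    assert out == pytest.approx([20.0, 80.0])


def test_fp_downscale_uniform_ndvi_splits_evenly():
    out = downscale_fp_supply({0: 90.0}, np.full(9, 0.5), np.zeros(9))
    assert out == pytest.approx(np.full(9, 10.0))


def test_fp_downscale_conserves_county_totals():
    rng = np.random.default_rng(5)
    county = rng.integers(0, 3, 60)
    ndvi = rng.uniform(0.01, 1.0, 60)
    yields = {0: 123.4, 1: 0.0, 2: 77.7}
    out = downscale_fp_supply(yields, ndvi, county)
    for c, y in yields.items():
        assert out[county == c].sum() == pytest.approx(y, abs=1e-9)


def test_fp_downscale_zero_ndvi_with_yield_is_error():
    with pytest.raises(ValueError, match="cannot allocate"):
        downscale_fp_supply({0: 10.0}, np.zeros(3), np.zeros(3))


# ---------------------------------------------------------------------------
# demand formulas


def test_rusle_difference_demand():
    assert sc_demand_rusle(100, 1, 1, 0.2, 1) == pytest.approx(80.0)
    assert sc_demand_rusle(100, 1, 1, 1.0, 1.0) == pytest.approx(0.0)


def test_rusle_vectorized_matches_elementwise_oracle():
    rng = np.random.default_rng(9)
    R, K, LS = rng.uniform(0, 5000, 30), rng.uniform(0, 1, 30), \
        rng.uniform(0, 20, 30)
    C, P = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
    out = sc_demand_rusle(R, K, LS, C, P)
    for i in range(30):
        assert out[i] == pytest.approx(R[i] * K[i] * LS[i]
                                       * (1 - C[i] * P[i]))
    with pytest.raises(ValueError, match="nonnegative"):
        sc_demand_rusle(-1, 1, 1, 0.5, 0.5)


def test_population_driven_demand():
    assert cs_fp_demand(1000.0, 100.0, 2.0) == pytest.approx(200_000.0)
    assert cs_fp_demand(0.0, 100.0, 2.0) == pytest.approx(0.0)
    rng = np.random.default_rng(13)
    pop, area = rng.uniform(0, 500, 20), rng.uniform(50, 150, 20)
    out = cs_fp_demand(pop, area, 1.7)
    for i in range(20):
        assert out[i] == pytest.approx(pop[i] * area[i] * 1.7)


def test_wy_quota_demand_cropland_unit():
    areas = pd.DataFrame({c: [0.0] for c in range(1, 7)})
    areas[3] = 10_000.0  # all cropland, ha
    out = wy_demand_quota(areas, {"agricultural": 4500.0})
    assert out == pytest.approx([4.5e7])


def test_wy_quota_only_ecological_without_built_or_cropland():
    areas = pd.DataFrame({c: [0.0] for c in range(1, 7)})
    areas[1] = 500.0  # forest only
    quotas = {"agricultural": 4500.0, "domestic": 600.0, "ecological": 150.0}
    assert wy_demand_quota(areas, quotas) == pytest.approx([75_000.0])


def test_wy_quota_unmapped_sector_is_error():
    areas = pd.DataFrame({c: [1.0] for c in range(1, 7)})
    with pytest.raises(ValueError, match="unmapped"):
        wy_demand_quota(areas, {"mystery": 10.0})


def test_wy_quota_matches_per_sector_loop_oracle():
    rng = np.random.default_rng(21)
    areas = pd.DataFrame(
        {c: rng.uniform(0, 3000, 25) for c in range(1, 7)})
    quotas = {"domestic": 600.0, "agricultural": 4500.0,
              "industrial": 400.0, "public": 200.0, "ecological": 150.0}
    out = wy_demand_quota(areas, quotas)
    from escarp.services import DEFAULT_SECTOR_CLASSES
    for i in range(25):
        expected = sum(
            q * sum(areas.loc[i, c] for c in DEFAULT_SECTOR_CLASSES[s])
            for s, q in quotas.items()
        )
        assert out[i] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# ESDR / CESDR


def test_esdr_formula_printed_example():
    # S=8, D=2 with basin maxima (10, 6): (8-2)/((10+6)/2) = 0.75
    table = service_frame(supply_WY=[8.0, 10.0], demand_WY=[2.0, 6.0])
    esdr, meta = compute_esdr(table)
    assert esdr.ESDR_WY.iloc[0] == pytest.approx(0.75)
    assert meta["norm_constant"]["WY"] == pytest.approx(8.0)


def test_balance_gives_zero_everywhere():
    esdr, _ = compute_esdr(service_frame())
    assert np.allclose(esdr[[f"ESDR_{s}" for s in SERVICES]], 0.0)
    assert np.allclose(esdr.CESDR, 0.0)


def test_cesdr_is_arithmetic_mean():
    table = service_frame(
        supply_WY=[1.2, 1.0], supply_CS=[0.9, 1.0],
        supply_SC=[1.3, 1.0], supply_FP=[1.0, 1.0],
    )
    esdr, _ = compute_esdr(table)
    # per-service norms are (max S + max D)/2 over both units
    vals = [esdr[f"ESDR_{s}"].iloc[0] for s in SERVICES]
    assert esdr.CESDR.iloc[0] == pytest.approx(np.mean(vals))
    manual = [(1.2 - 1) / 1.1, (0.9 - 1) / 1.0, (1.3 - 1) / 1.15, 0.0]
    assert vals == pytest.approx(manual)


def test_esdr_scale_invariance_and_sign_fidelity():
    rng = np.random.default_rng(17)
    table = service_frame(
        supply_WY=rng.uniform(0, 10, 2).tolist(),
        demand_WY=rng.uniform(0, 10, 2).tolist(),
    )
    base, _ = compute_esdr(table)
    scaled = table.copy()
    scaled["supply_WY"] *= 7.3
    scaled["demand_WY"] *= 7.3
    out, _ = compute_esdr(scaled)
    assert np.allclose(out.ESDR_WY, base.ESDR_WY)
    sign = np.sign(table.supply_WY - table.demand_WY)
    assert np.all(np.sign(base.ESDR_WY) == sign)


def test_esdr_bounded_by_two(hinge_run):
    esdr = hinge_run["esdr"]
    cols = [f"ESDR_{s}" for s in SERVICES]
    assert (esdr[cols].abs() <= 2.0).all().all()


def test_all_zero_service_is_error():
    table = service_frame(supply_WY=[0.0, 0.0], demand_WY=[0.0, 0.0])
    with pytest.raises(ValueError, match="undefined"):
        compute_esdr(table)


def test_planted_esdr_round_trip_exact(noiseless_run):
    """With zero noise the full supply/demand construction reproduces the
    planted piecewise boundary through compute_esdr to 1e-9."""
    planted = noiseless_run["surfaces"]["planted"]
    esdr = noiseless_run["esdr"].set_index("unit_id")
    recovered = esdr.loc[planted.unit_id, "ESDR_CS"].to_numpy()
    assert np.abs(recovered - planted.boundary.to_numpy()).max() < 1e-9
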