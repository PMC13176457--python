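"""Per-unit ecosystem-service supply, demand, ESDR and CESDR.

Four services are tracked: water yield (WY), carbon sequestration (CS),
soil conservation (SC) and food production (FP).  Supply surfaces for
WY/CS/SC are pipeline inputs (typically biophysical model output); FP
supply is downscaled from county statistical yields with NDVI weights.
Demand is assembled from population density and per-capita rates (CS,
FP), the potential-minus-actual erosion difference of the RUSLE
framework (SC), and sectoral water quotas allocated by land-use area
(WY).

The supply-demand ratio of service s in unit u is

    ESDR_s(u) = (S_s(u) - D_s(u)) / ((max_u S_s + max_u D_s) / 2)

with the normalization maxima taken over the full analyzed unit set
(the basin), so ESDR < 0 marks a deficit, 0 balance, > 0 a surplus.
CESDR is the arithmetic mean of the four service ESDRs in a unit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

SERVICES = ("WY", "CS", "SC", "FP")

#: water-use sectors and a default sector -> land-use class mapping
#: (1 forest, 2 grassland, 3 cropland, 4 water, 5 built, 6 bare)
DEFAULT_SECTOR_CLASSES = {
    "domestic": [5],
    "agricultural": [3],
    "industrial": [5],
    "public": [5],
    "ecological": [1, 2, 4],
}


def downscale_fp_supply(county_yield: pd.Series | dict,
                        ndvi: np.ndarray,
                        county_of_unit: np.ndarray) -> np.ndarray:
    """Downscale county grain yields (t) to units with NDVI weights.

    ``supply_FP(u) = yield(county(u)) * ndvi(u) / sum_{v in county} ndvi(v)``;
    county totals are conserved exactly.
    """
    county_yield = pd.Series(county_yield, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    county_of_unit = np.asarray(county_of_unit)
    if (ndvi < 0).any():
        raise ValueError("NDVI must be nonnegative")
    supply = np.zeros(len(ndvi))
    for county, y in county_yield.items():
        mask = county_of_unit == county
        if not mask.any():
            continue
        total = ndvi[mask].sum()
        if total == 0:
            if y > 0:
                raise ValueError(
                    f"county {county!r} has positive yield but zero total "
                    "NDVI: cannot allocate"
                )
            continue
        supply[mask] = y * ndvi[mask] / total
    return supply


def sc_demand_rusle(R: np.ndarray, K: np.ndarray, LS: np.ndarray,
                    C: np.ndarray, P: np.ndarray) -> np.ndarray:
    """SC demand as potential minus actual erosion (RUSLE difference).

    potential = R*K*LS (bare ground, C = P = 1); actual = R*K*LS*C*P;
    demand = R*K*LS*(1 - C*P) >= 0.
    """
    R, K, LS, C, P = (np.asarray(a, dtype=float) for a in (R, K, LS, C, P))
    for name, a in (("R", R), ("K", K), ("LS", LS)):
        if (a < 0).any():
            raise ValueError(f"RUSLE factor {name} must be nonnegative")
    for name, a in (("C", C), ("P", P)):
        if ((a < 0) | (a > 1)).any():
            raise ValueError(f"RUSLE factor {name} must lie in [0, 1]")
    return R * K * LS * (1.0 - C * P)


def cs_fp_demand(pop_density: np.ndarray, area_km2: np.ndarray | float,
                 per_capita_rate: float) -> np.ndarray:
    """Population-driven demand: density (persons/km2) x area x rate."""
    pop_density = np.asarray(pop_density, dtype=float)
    if (pop_density < 0).any() or per_capita_rate < 0:
        raise ValueError("population density and rate must be nonnegative")
    return pop_density * np.asarray(area_km2, dtype=float) * per_capita_rate


def wy_demand_quota(class_area_ha: pd.DataFrame,
                    quotas_m3_per_ha: dict[str, float],
                    sector_classes: dict[str, list[int]] | None = None
                    ) -> np.ndarray:
    """WY demand from sectoral quotas allocated over land-use areas.

    ``class_area_ha`` has one column per class code (int); each sector's
    quota (m3/ha) applies to the summed area of its mapped classes.
    """
    sector_classes = sector_classes or DEFAULT_SECTOR_CLASSES
    missing = set(quotas_m3_per_ha) - set(sector_classes)
    if missing:
        raise ValueError(f"unmapped sector(s) in quota table: {sorted(missing)}")
    demand = np.zeros(len(class_area_ha))
    for sector, quota in quotas_m3_per_ha.items():
        if quota < 0:
            raise ValueError(f"negative quota for sector {sector!r}")
        cols = [c for c in sector_classes[sector] if c in class_area_ha.columns]
        if cols:
            demand += quota * class_area_ha[cols].sum(axis=1).to_numpy()
    return demand


def compute_esdr(service_table: pd.DataFrame
                 ) -> tuple[pd.DataFrame, dict]:
    """ESDR per service and CESDR per unit, plus normalization metadata.

    Expects columns ``supply_<s>`` and ``demand_<s>`` for each service.
    Normalization maxima are taken over the full unit set after masking
    non-finite rows; an all-zero service is an error (ESDR undefined).
    """
    out = pd.DataFrame({"unit_id": service_table["unit_id"]})
    norms = {}
    for s in SERVICES:
        S = service_table[f"supply_{s}"].to_numpy(dtype=float)
        D = service_table[f"demand_{s}"].to_numpy(dtype=float)
        if (S < 0).any() or (D < 0).any():
            raise ValueError(f"negative supply/demand for service {s}")
        finite = np.isfinite(S) & np.isfinite(D)
        norm = (S[finite].max() + D[finite].max()) / 2.0
        if norm == 0:
            raise ValueError(
                f"service {s} has zero supply and demand everywhere; "
                "ESDR undefined"
            )
        norms[s] = norm
        out[f"ESDR_{s}"] = (S - D) / norm
    out["CESDR"] = out[[f"ESDR_{s}" for s in SERVICES]].mean(axis=1)
    meta = {
        "normalization": "(max supply + max demand) / 2, basin-wide",
        "norm_constant": {s: float(v) for s, v in norms.items()},
    }
    return out, meta


def write_esdr(esdr: pd.DataFrame, meta: dict, path: str | Path) -> None:
    path = Path(path)
    esdr.to_csv(path, index=False, float_format="%.12g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2) + "\n"
    )
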