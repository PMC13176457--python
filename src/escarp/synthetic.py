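"""Synthetic gridded basins with known cluster and threshold structure.

A scenario plants (i) landscape-composition regimes — each analysis unit
gets a categorical mosaic drawn from its regime's class proportions with
a tunable spatial-aggregation level — and (ii) piecewise-linear upper
boundaries relating a configuration metric to the supply-demand ratio
(ESDR) of a service.  Both are exact ground truth for the downstream
clustering and threshold-detection stages.

Mosaic construction: per unit, a smooth latent field (Gaussian-filtered
white noise, smoothing length increasing in the aggregation parameter)
is thresholded at the quantiles of the regime's class proportions, so
per-unit composition matches the regime to within rounding while the
aggregation parameter monotonically controls patch coherence.

Boundary construction: for a planted threshold the target ESDR of unit
u is ``b(x_u) - |eps|`` with ``b(x) = intercept + slope_pre * min(x, x0)
+ slope_post * max(x - x0, 0)`` and half-normal noise below the line, so
the planted curve is the envelope (constraint line) of the scatter by
construction.  Supply is back-solved from the target ESDR against
demand surfaces built from the package's own demand formulas, so
:func:`escarp.services.compute_esdr` recovers the plant exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import ndtri as _norm_ppf

from . import services as svc
from .raster import LandUseRaster, write_raster

SERVICES = svc.SERVICES
CONFIG_METRICS = ("PD", "LPI", "ED", "PAFRAC", "AI")


class ConfigurationError(ValueError):
    """Raised for impossible scenario configurations."""


@dataclass
class CompositionRegime:
    """A landscape-composition background (e.g. forest-dominated)."""

    name: str
    class_probs: tuple[float, ...]          # 6 proportions summing to 1
    aggregation_range: tuple[float, float]  # subset of [0, 1]

    def __post_init__(self) -> None:
        p = np.asarray(self.class_probs, dtype=float)
        if p.shape != (6,):
            raise ConfigurationError(
                f"regime {self.name!r}: class_probs must have 6 entries"
            )
        if (p < 0).any():
            raise ConfigurationError(
                f"regime {self.name!r}: negative class proportion"
            )
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"regime {self.name!r}: class_probs sum to {p.sum():.12g}, "
                "expected 1"
            )
        lo, hi = self.aggregation_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                f"regime {self.name!r}: aggregation_range must lie in [0, 1]"
            )


@dataclass
class PlantedThreshold:
    """Ground-truth piecewise upper boundary for one (regime, service)."""

    regime: str
    service: str                 # WY | CS | SC | FP
    metric: str                  # PD | LPI | ED | PAFRAC | AI
    x0: float                    # breakpoint on the metric scale
    slope_pre: float
    slope_post: float
    intercept: float

    def __post_init__(self) -> None:
        if self.service not in SERVICES:
            raise ConfigurationError(f"unknown service {self.service!r}")
        if self.metric not in CONFIG_METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")

    def boundary(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.intercept
                + self.slope_pre * np.minimum(x, self.x0)
                + self.slope_post * np.maximum(x - self.x0, 0.0))


@dataclass
class ScenarioConfig:
    seed: int
    n_units_x: int
    n_units_y: int
    cells_per_unit: int
    cell_size_m: float
    regimes: list[CompositionRegime]
    breakpoint_specs: list[PlantedThreshold] = field(default_factory=list)
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n_units_x * self.n_units_y < 50:
            raise ConfigurationError("need at least 50 analysis units")
        if self.cells_per_unit < 8:
            raise ConfigurationError("cells_per_unit must be >= 8")
        if self.cell_size_m <= 0:
            raise ConfigurationError("cell_size_m must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not self.regimes:
            raise ConfigurationError("at least one regime is required")
        names = {r.name for r in self.regimes}
        for bp in self.breakpoint_specs:
            if bp.regime not in names:
                raise ConfigurationError(
                    f"planted threshold references unknown regime "
                    f"{bp.regime!r}"
                )

    @property
    def n_units(self) -> int:
        return self.n_units_x * self.n_units_y

    @property
    def unit_area_km2(self) -> float:
        return (self.cells_per_unit * self.cell_size_m / 1000.0) ** 2

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        d = json.loads(text)
        d["regimes"] = [
            CompositionRegime(
                name=r["name"],
                class_probs=tuple(r["class_probs"]),
                aggregation_range=tuple(r["aggregation_range"]),
            )
            for r in d["regimes"]
        ]
        d["breakpoint_specs"] = [
            PlantedThreshold(**bp) for bp in d.get("breakpoint_specs", [])
        ]
        return cls(**d)


def _regime_assignment(config: ScenarioConfig) -> np.ndarray:
    """Regime index per unit: contiguous row-major blocks, near-equal."""
    n, k = config.n_units, len(config.regimes)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return np.repeat(np.arange(k), sizes)


def _unit_mosaic(rng: np.random.Generator, probs: np.ndarray,
                 aggregation: float, cells: int) -> np.ndarray:
    """Quantile-thresholded smoothed noise mosaic for one unit.

    The smoothing length grows log-spaced in the aggregation parameter
    (correlation lengths act multiplicatively), which keeps realized
    aggregation metrics spread smoothly along the [0, 1] control axis
    instead of clumping at the extremes.
    """
    latent = rng.standard_normal((cells, cells))
    sigma_min, sigma_max = 0.15, cells / 2.5
    sigma = sigma_min * (sigma_max / sigma_min) ** aggregation
    latent = gaussian_filter(latent, sigma=sigma, mode="reflect")
    z = (latent - latent.mean()) / max(latent.std(), 1e-12)
    # threshold at normal quantiles of the class proportions: realized
    # per-unit composition fluctuates around the regime's class_probs
    # (more for smoother fields, which have fewer independent blobs) and
    # converges to them as the cell count grows
    cuts = _norm_ppf(np.cumsum(probs)[:-1])
    return (np.searchsorted(cuts, z.ravel(), side="left")
            .astype(np.int16) + 1).reshape(cells, cells)


def generate_landuse(config: ScenarioConfig
                     ) -> tuple[LandUseRaster, pd.DataFrame]:
    """Generate the categorical raster and the unit-regime assignment.

    Deterministic given the config (seed included); units are visited
    row-major with a single RNG stream.
    """
    rng = np.random.default_rng(config.seed)
    assignment = _regime_assignment(config)
    cpu = config.cells_per_unit
    values = np.zeros(
        (config.n_units_y * cpu, config.n_units_x * cpu), dtype=np.int16
    )
    rows = []
    for u in range(config.n_units):
        r, c = divmod(u, config.n_units_x)
        regime = config.regimes[assignment[u]]
        lo, hi = regime.aggregation_range
        agg = float(rng.uniform(lo, hi))
        values[r * cpu:(r + 1) * cpu, c * cpu:(c + 1) * cpu] = _unit_mosaic(
            rng, np.asarray(regime.class_probs, dtype=float), agg, cpu
        )
        rows.append({"unit_id": u, "row": r, "col": c,
                     "regime": regime.name, "aggregation": agg})
    raster = LandUseRaster(values=values, cell_size_m=config.cell_size_m)
    return raster, pd.DataFrame(rows)


def _solve_norm_constant(demand: np.ndarray, esdr: np.ndarray) -> float:
    """Fixed point of N = (max(D + e*N) + max D) / 2.

    The map is a contraction for |e| <= 1 (slope <= max|e| / 2), so plain
    iteration converges geometrically from N = max D.
    """
    max_d = demand.max()
    N = max_d if max_d > 0 else 1.0
    for _ in range(200):
        new = ((demand + esdr * N).max() + max_d) / 2.0
        if abs(new - N) <= 1e-14 * max(1.0, abs(N)):
            N = new
            break
        N = new
    return float(N)


def generate_service_surfaces(
    config: ScenarioConfig,
    metrics: pd.DataFrame,
    assignment: pd.DataFrame,
    per_capita_c: float = 1.5,       # t C / person / yr
    per_capita_food: float = 0.4,    # t grain / person / yr
    quotas_m3_per_ha: dict | None = None,
) -> dict:
    """Build demand surfaces, plant ESDR boundaries, back-solve supply.

    Returns a dict with keys ``service_table`` (unit_id, supply_*,
    demand_*), ``aux`` (NDVI, county zone, population density, RUSLE
    factors), ``planted`` (per planted unit: metric value, boundary
    value, target ESDR) and ``meta`` (normalization constants used).
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_units
    area_km2 = config.unit_area_km2
    area_ha = area_km2 * 100.0
    quotas = quotas_m3_per_ha or {
        "domestic": 600.0, "agricultural": 4500.0, "industrial": 400.0,
        "public": 200.0, "ecological": 150.0,
    }

    # ---- demand from the package's own demand formulas -------------------
    urban_frac = metrics["PLAND_5"].to_numpy(dtype=float) / 100.0
    pop_density = (20.0 + 800.0 * urban_frac) * np.exp(
        0.3 * rng.standard_normal(n)
    )
    demand = {
        "CS": svc.cs_fp_demand(pop_density, area_km2, per_capita_c),
        "FP": svc.cs_fp_demand(pop_density, area_km2, per_capita_food),
    }
    class_area_ha = pd.DataFrame(
        {c: metrics[f"PLAND_{c}"].to_numpy(dtype=float) / 100.0 * area_ha
         for c in range(1, 7)}
    )
    demand["WY"] = svc.wy_demand_quota(class_area_ha, quotas)
    rusle = {
        "R": rng.uniform(1000.0, 6000.0, n),
        "K": rng.uniform(0.2, 0.5, n),
        "LS": rng.uniform(0.5, 15.0, n),
        "C": rng.uniform(0.05, 0.6, n),
        "P": np.ones(n),
    }
    demand["SC"] = svc.sc_demand_rusle(**rusle) * area_ha  # t soil / unit

    # ---- target ESDR: baseline + planted boundaries ----------------------
    baseline = {"WY": 0.05, "CS": 0.10, "SC": 0.05, "FP": 0.02}
    esdr = {
        s: baseline[s] - np.abs(rng.normal(0.0, config.noise_sd, n))
        for s in SERVICES
    }
    regime_of = assignment.set_index("unit_id")["regime"]
    planted_rows = []
    for bp in config.breakpoint_specs:
        mask = (regime_of.loc[metrics["unit_id"]] == bp.regime).to_numpy()
        if not mask.any():
            raise ConfigurationError(
                f"no units assigned to regime {bp.regime!r}"
            )
        x = metrics.loc[mask, bp.metric].to_numpy(dtype=float)
        if not (x.min() <= bp.x0 <= x.max()):
            raise ConfigurationError(
                f"planted breakpoint x0={bp.x0} outside realized "
                f"{bp.metric} range [{x.min():.3g}, {x.max():.3g}] "
                f"of regime {bp.regime!r}"
            )
        b = bp.boundary(x)
        if (np.abs(b) > 1.0).any():
            raise ConfigurationError(
                f"planted boundary for {bp.regime}/{bp.service} leaves "
                "[-1, 1]; adjust intercept or slopes"
            )
        eps = np.abs(rng.normal(0.0, config.noise_sd, mask.sum()))
        esdr[bp.service][mask] = b - eps
        planted_rows.append(pd.DataFrame({
            "unit_id": metrics.loc[mask, "unit_id"].to_numpy(),
            "regime": bp.regime, "service": bp.service, "metric": bp.metric,
            "x": x, "boundary": b, "esdr_target": b - eps,
        }))

    # ---- back-solve supply so compute_esdr recovers the plant ------------
    table = pd.DataFrame({"unit_id": metrics["unit_id"].to_numpy()})
    norms = {}
    for s in SERVICES:
        N = _solve_norm_constant(demand[s], esdr[s])
        supply = demand[s] + esdr[s] * N
        if supply.min() < 0:
            raise ConfigurationError(
                f"back-solved {s} supply negative (min {supply.min():.3g}); "
                "planted ESDR too negative for the demand surface"
            )
        table[f"supply_{s}"] = supply
        table[f"demand_{s}"] = demand[s]
        norms[s] = N

    # ---- county zones + NDVI consistent with FP downscaling --------------
    row = assignment.set_index("unit_id").loc[table["unit_id"], "row"]
    col = assignment.set_index("unit_id").loc[table["unit_id"], "col"]
    county = (
        (row.to_numpy() // max(1, config.n_units_y // 2)).clip(max=1) * 2
        + (col.to_numpy() // max(1, config.n_units_x // 2)).clip(max=1)
    )
    s_fp = table["supply_FP"].to_numpy()
    ndvi = np.zeros(n)
    for cty in np.unique(county):
        m = county == cty
        peak = s_fp[m].max()
        ndvi[m] = s_fp[m] / peak if peak > 0 else 0.3
    county_yield = pd.Series(s_fp).groupby(county).sum()

    aux = pd.DataFrame({
        "unit_id": table["unit_id"], "county": county, "ndvi": ndvi,
        "pop_density": pop_density, "area_km2": area_km2, **rusle,
    })
    planted = (pd.concat(planted_rows, ignore_index=True)
               if planted_rows else pd.DataFrame(
                   columns=["unit_id", "regime", "service", "metric",
                            "x", "boundary", "esdr_target"]))
    meta = {
        "norm_constant": norms,
        "county_yield": {int(k): float(v) for k, v in county_yield.items()},
        "per_capita_c": per_capita_c, "per_capita_food": per_capita_food,
        "quotas_m3_per_ha": quotas,
    }
    return {"service_table": table, "aux": aux, "planted": planted,
            "meta": meta}


# ---------------------------------------------------------------------------
# Canned scenarios


def default_regimes() -> list[CompositionRegime]:
    """Five composition regimes emulating a heterogeneous basin."""
    return [
        CompositionRegime("forest", (0.70, 0.15, 0.05, 0.02, 0.03, 0.05),
                          (0.3, 0.9)),
        CompositionRegime("desert", (0.02, 0.10, 0.03, 0.01, 0.04, 0.80),
                          (0.4, 0.9)),
        CompositionRegime("urban", (0.05, 0.10, 0.15, 0.02, 0.63, 0.05),
                          (0.2, 0.8)),
        CompositionRegime("cropland", (0.05, 0.15, 0.68, 0.03, 0.06, 0.03),
                          (0.3, 0.9)),
        CompositionRegime("mixed", (0.25, 0.25, 0.20, 0.05, 0.10, 0.15),
                          (0.1, 0.7)),
    ]


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """A 20 x 20-unit basin (10 km units of 1 km cells), five regimes."""
    return ScenarioConfig(
        seed=seed, n_units_x=20, n_units_y=20, cells_per_unit=10,
        cell_size_m=1000.0, regimes=default_regimes(),
        breakpoint_specs=[
            PlantedThreshold("forest", "CS", "AI", x0=65.0,
                             slope_pre=0.008, slope_post=-0.008,
                             intercept=0.2),
        ],
        noise_sd=0.01,
    )


def hinge_scenario(seed: int, n_units_x: int = 20, n_units_y: int = 20,
                   x0: float = 60.0, slope_pre: float = 0.02,
                   slope_post: float = -0.02, intercept: float = -0.4,
                   noise_sd: float = 0.01, metric: str = "AI",
                   service: str = "CS", cells_per_unit: int = 10,
                   ) -> ScenarioConfig:
    """Single-regime scenario with one planted hinge on a wide AI gradient."""
    regime = CompositionRegime(
        "gradient", (0.35, 0.25, 0.20, 0.10, 0.06, 0.04), (0.35, 1.0)
    )
    return ScenarioConfig(
        seed=seed, n_units_x=n_units_x, n_units_y=n_units_y,
        cells_per_unit=cells_per_unit, cell_size_m=1000.0,
        regimes=[regime],
        breakpoint_specs=[PlantedThreshold(
            "gradient", service, metric, x0=x0, slope_pre=slope_pre,
            slope_post=slope_post, intercept=intercept,
        )],
        noise_sd=noise_sd,
    )


def write_scenario_outputs(config: ScenarioConfig, out_dir: str | Path,
                           raster: LandUseRaster, assignment: pd.DataFrame,
                           metrics: pd.DataFrame, surfaces: dict) -> None:
    """Write rasters (TIFF + sidecar), tables (CSV) and the config (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_raster(raster, out / "landuse.tif")
    shape = (config.n_units_y, config.n_units_x)
    aux = surfaces["aux"].sort_values("unit_id")
    write_raster(aux["ndvi"].to_numpy().reshape(shape), out / "ndvi.tif",
                 cell_size_m=config.cells_per_unit * config.cell_size_m)
    write_raster(aux["pop_density"].to_numpy().reshape(shape),
                 out / "population.tif",
                 cell_size_m=config.cells_per_unit * config.cell_size_m)
    assignment.to_csv(out / "assignment.csv", index=False,
                      float_format="%.12g")
    metrics.to_csv(out / "unit_metrics.csv", index=False,
                   float_format="%.12g")
    surfaces["service_table"].to_csv(out / "services.csv", index=False,
                                     float_format="%.12g")
    aux.to_csv(out / "aux.csv", index=False, float_format="%.12g")
    surfaces["planted"].to_csv(out / "planted.csv", index=False,
                               float_format="%.12g")
    (out / "scenario.json").write_text(config.to_json() + "\n")
    (out / "surfaces_meta.json").write_text(
        json.dumps(surfaces["meta"], indent=2) + "\n"
    )
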