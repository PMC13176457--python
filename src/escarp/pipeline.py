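"""Configured, logged, resumable pipeline runs.

Stage order: ``synth -> metrics -> cluster -> esdr -> thresholds``.  A
run is driven by a schema-validated :class:`RunConfig` (unknown keys
rejected); every stage writes CSV/JSON outputs plus an entry in the run
manifest (parameter snapshot, input/output SHA-256 hashes, timestamps),
and an unchanged stage is skipped on re-run.  The global seed
deterministically derives per-stage seeds, so stages can be re-run
independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .clustering import cluster_morans_i, fit_cluster_model, k_selection, zscore
from .metrics import COMPOSITION_FEATURES, write_unit_metrics, zonal_metrics
from .raster import read_landuse
from .services import compute_esdr, downscale_fp_supply, write_esdr
from .synthetic import (
    CompositionRegime,
    PlantedThreshold,
    ScenarioConfig,
    default_regimes,
    generate_landuse,
    generate_service_surfaces,
    write_scenario_outputs,
)
from .thresholds import analyze_pair, screen_pairs

log = logging.getLogger("escarp")

STAGES = ("synth", "metrics", "cluster", "esdr", "thresholds")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class RegimeBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    class_probs: list[float]
    aggregation_range: tuple[float, float]


class BreakpointBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    regime: str
    service: str
    metric: str
    x0: float
    slope_pre: float
    slope_post: float
    intercept: float


class ScenarioBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_units_x: int = 20
    n_units_y: int = 20
    cells_per_unit: int = 10
    cell_size_m: float = 1000.0
    regimes: list[RegimeBlock] | None = None
    breakpoint_specs: list[BreakpointBlock] = Field(default_factory=list)
    noise_sd: float = 0.01

    def to_scenario(self, seed: int) -> ScenarioConfig:
        regimes = (
            [CompositionRegime(r.name, tuple(r.class_probs),
                               r.aggregation_range) for r in self.regimes]
            if self.regimes is not None else default_regimes()
        )
        return ScenarioConfig(
            seed=seed, n_units_x=self.n_units_x, n_units_y=self.n_units_y,
            cells_per_unit=self.cells_per_unit, cell_size_m=self.cell_size_m,
            regimes=regimes,
            breakpoint_specs=[PlantedThreshold(**bp.model_dump())
                              for bp in self.breakpoint_specs],
            noise_sd=self.noise_sd,
        )


class ClusteringBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int | Literal["auto"] = "auto"
    k_candidates: list[int] = Field(default_factory=lambda: [2, 3, 4, 5, 6])
    n_init: int = 25
    n_repeats: int = 10
    morans_permutations: int = 999


class ThresholdBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    tau: float = 0.90
    rho_min: float = 0.20
    n_min: int = 30
    min_bin_n: int = 10
    bootstrap_b: int = 1000


class MetricsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    connectivity: int = 8


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "run"
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    scenario: ScenarioBlock = Field(default_factory=ScenarioBlock)
    metrics: MetricsBlock = Field(default_factory=MetricsBlock)
    clustering: ClusteringBlock = Field(default_factory=ClusteringBlock)
    thresholds: ThresholdBlock = Field(default_factory=ThresholdBlock)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: global seed mixed with a stable stage-name hash."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class RunManifest:
    """Per-stage parameter snapshots and file hashes, JSON-backed."""

    def __init__(self, path: Path):
        self.path = path
        self.data = (json.loads(path.read_text()) if path.exists()
                     else {"version": __version__, "stages": {}})

    def stage_unchanged(self, stage: str, params_hash: str,
                        out_dir: Path) -> bool:
        entry = self.data["stages"].get(stage)
        if entry is None or entry["params_hash"] != params_hash:
            return False
        for name, digest in entry["outputs"].items():
            f = out_dir / name
            if not f.exists() or _sha256(f) != digest:
                return False
        return True

    def record(self, stage: str, params_hash: str, outputs: list[Path],
               out_dir: Path) -> None:
        self.data["stages"][stage] = {
            "params_hash": params_hash,
            "outputs": {str(p.relative_to(out_dir)): _sha256(p)
                        for p in outputs},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "version": __version__,
        }
        self.path.write_text(json.dumps(self.data, indent=2) + "\n")


def _params_hash(config: RunConfig, stage: str) -> str:
    # a stage depends on its own block, the scenario and the global seed
    block = (getattr(config, stage).model_dump()
             if stage in ("metrics", "clustering", "thresholds") else None)
    relevant = {
        "seed": config.seed,
        "scenario": config.scenario.model_dump(),
        "block": block,
    }
    return hashlib.sha256(
        json.dumps(relevant, sort_keys=True).encode()
    ).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run the enabled stages in dependency order; halt on first failure."""
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out / "manifest.json")
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        phash = _params_hash(config, stage)
        if manifest.stage_unchanged(stage, phash, out) and stage in (
                "synth", "metrics", "cluster", "esdr", "thresholds"):
            log.info("stage %s unchanged; skipped", stage)
            _load_stage_outputs(stage, out, state, config)
            continue
        log.info("running stage %s", stage)
        try:
            outputs = _run_stage(stage, config, out, state)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        manifest.record(stage, phash, outputs, out)
    return manifest


def _load_stage_outputs(stage: str, out: Path, state: dict,
                        config: RunConfig) -> None:
    """Rehydrate in-memory state for a skipped (cached) stage."""
    if stage == "synth":
        state["raster"] = read_landuse(out / "landuse.tif")
        state["assignment"] = pd.read_csv(out / "assignment.csv")
        state["scenario"] = ScenarioConfig.from_json(
            (out / "scenario.json").read_text()
        )
    elif stage == "metrics":
        state["metrics"] = pd.read_csv(out / "unit_metrics.csv")
    elif stage == "cluster":
        state["labels"] = pd.read_csv(out / "labels.csv")["cluster"].to_numpy()
    elif stage == "esdr":
        state["esdr"] = pd.read_csv(out / "esdr.csv")
        state["services"] = pd.read_csv(out / "services.csv")


def _run_stage(stage: str, config: RunConfig, out: Path,
               state: dict) -> list[Path]:
    if stage == "synth":
        scenario = config.scenario.to_scenario(stage_seed(config.seed,
                                                          "synth"))
        raster, assignment = generate_landuse(scenario)
        state.update(scenario=scenario, raster=raster, assignment=assignment)
        from .raster import write_raster
        write_raster(raster, out / "landuse.tif")
        assignment.to_csv(out / "assignment.csv", index=False,
                          float_format="%.12g")
        (out / "scenario.json").write_text(scenario.to_json() + "\n")
        return [out / "landuse.tif", out / "landuse.tif.json",
                out / "assignment.csv", out / "scenario.json"]

    if stage == "metrics":
        if "raster" not in state:
            raise StageError("metrics", "missing land-use raster; "
                             "run stage 'synth' first")
        table = zonal_metrics(state["raster"],
                              state["scenario"].cells_per_unit,
                              connectivity=config.metrics.connectivity)
        state["metrics"] = table
        write_unit_metrics(table, out / "unit_metrics.csv",
                           connectivity=config.metrics.connectivity)
        return [out / "unit_metrics.csv", out / "unit_metrics.csv.json"]

    if stage == "cluster":
        if "metrics" not in state:
            raise StageError("cluster", "missing unit metrics; "
                             "run stage 'metrics' first")
        seed = stage_seed(config.seed, "cluster")
        table = state["metrics"]
        Z, _ = zscore(table, COMPOSITION_FEATURES)
        outputs = []
        if config.clustering.k == "auto":
            report = k_selection(Z, config.clustering.k_candidates,
                                 n_repeats=config.clustering.n_repeats,
                                 n_init=config.clustering.n_init, seed=seed)
            k = report.chosen_k
            report.table.to_csv(out / "k_selection.csv", index=False,
                                float_format="%.12g")
            outputs.append(out / "k_selection.csv")
        else:
            k = int(config.clustering.k)
        model = fit_cluster_model(table, k, COMPOSITION_FEATURES,
                                  n_init=config.clustering.n_init, seed=seed)
        state["labels"] = model.labels
        pd.DataFrame({"unit_id": table["unit_id"],
                      "cluster": model.labels}).to_csv(
            out / "labels.csv", index=False)
        n_rows = int(table["row"].max()) + 1
        n_cols = int(table["col"].max()) + 1
        morans = cluster_morans_i(
            model.labels, n_rows, n_cols,
            n_permutations=config.clustering.morans_permutations, seed=seed)
        (out / "cluster_diagnostics.json").write_text(json.dumps({
            "k": k, "inertia": model.inertia,
            "morans_i": morans.to_dict(orient="records"),
        }, indent=2, default=float) + "\n")
        return outputs + [out / "labels.csv",
                          out / "cluster_diagnostics.json"]

    if stage == "esdr":
        for key, prev in (("metrics", "metrics"), ("assignment", "synth")):
            if key not in state:
                raise StageError("esdr", f"missing {key}; run stage "
                                 f"'{prev}' first")
        surfaces = generate_service_surfaces(
            state["scenario"], state["metrics"], state["assignment"])
        table = surfaces["service_table"].copy()
        # recompute FP supply through the NDVI downscaling path
        aux = surfaces["aux"]
        table["supply_FP"] = downscale_fp_supply(
            surfaces["meta"]["county_yield"], aux["ndvi"].to_numpy(),
            aux["county"].to_numpy())
        esdr, meta = compute_esdr(table)
        state["services"] = table
        state["esdr"] = esdr
        write_scenario_outputs(state["scenario"], out, state["raster"],
                               state["assignment"], state["metrics"],
                               surfaces)
        write_esdr(esdr, meta, out / "esdr.csv")
        return [out / "services.csv", out / "aux.csv", out / "planted.csv",
                out / "esdr.csv", out / "esdr.csv.json",
                out / "surfaces_meta.json", out / "ndvi.tif",
                out / "population.tif"]

    if stage == "thresholds":
        for key, prev in (("metrics", "metrics"), ("labels", "cluster"),
                          ("esdr", "esdr")):
            if key not in state:
                raise StageError("thresholds", f"missing {key}; run stage "
                                 f"'{prev}' first")
        tp = config.thresholds
        seed = stage_seed(config.seed, "thresholds")
        screen = screen_pairs(
            state["esdr"], state["metrics"], state["labels"],
            alpha=tp.alpha, rho_min=tp.rho_min, n_min=tp.n_min, seed=seed)
        screen.to_csv(out / "screen.csv", index=False, float_format="%.12g")
        merged = state["metrics"].merge(state["esdr"], on="unit_id")
        merged["_cluster"] = state["labels"]
        rows, diags = [], {}
        for _, sr in screen[screen["passed"]].iterrows():
            sub = merged[merged["_cluster"] == sr["cluster"]][
                [sr["metric"], sr["response"]]].dropna()
            pair = {"cluster": int(sr["cluster"]), "metric": sr["metric"],
                    "response": sr["response"]}
            pair_key = f"c{pair['cluster']}:{pair['metric']}:{pair['response']}"
            try:
                result, diag = analyze_pair(
                    sub[sr["metric"]].to_numpy(),
                    sub[sr["response"]].to_numpy(),
                    pair=pair, tau=tp.tau, min_bin_n=tp.min_bin_n,
                    B=tp.bootstrap_b,
                    seed=stage_seed(seed, pair_key))
            except ValueError as exc:
                diags[pair_key] = {"error": str(exc)}
                continue
            diags[pair_key] = diag
            if result is not None:
                rows.append({
                    **pair, "family": result.family,
                    "threshold": result.threshold_2dp,
                    "threshold_exact": result.threshold,
                    "pre_mean": result.pre_mean,
                    "post_mean": result.post_mean,
                    "direction": result.direction,
                    "ci_low": result.bootstrap["ci_low"],
                    "ci_high": result.bootstrap["ci_high"],
                    "success_rate": result.bootstrap["success_rate"],
                    "flags": ";".join(result.flags),
                })
        cols = ["cluster", "metric", "response", "family", "threshold",
                "threshold_exact", "pre_mean", "post_mean", "direction",
                "ci_low", "ci_high", "success_rate", "flags"]
        pd.DataFrame(rows, columns=cols).to_csv(
            out / "thresholds.csv", index=False, float_format="%.12g")
        (out / "threshold_diagnostics.json").write_text(
            json.dumps(diags, indent=2, default=float) + "\n")
        return [out / "screen.csv", out / "thresholds.csv",
                out / "threshold_diagnostics.json"]

    raise StageError(stage, "unknown stage")


def report(run_dir: str | Path) -> str:
    """Assemble a plain-text summary of a (possibly partial) run."""
    run_dir = Path(run_dir)
    lines = [f"# escarp run report: {run_dir}", ""]

    metrics_f = run_dir / "unit_metrics.csv"
    labels_f = run_dir / "labels.csv"
    if metrics_f.exists() and labels_f.exists():
        metrics = pd.read_csv(metrics_f)
        labels = pd.read_csv(labels_f)
        merged = metrics.merge(labels, on="unit_id")
        prof = merged.groupby("cluster")[COMPOSITION_FEATURES].mean().round(3)
        lines += ["## Cluster composition profile (feature means)",
                  prof.to_string(), ""]
    else:
        lines += ["## Cluster composition profile", "(stage not run)", ""]

    esdr_f = run_dir / "esdr.csv"
    if esdr_f.exists() and labels_f.exists():
        esdr = pd.read_csv(esdr_f).merge(pd.read_csv(labels_f), on="unit_id")
        cols = [c for c in esdr.columns if c.startswith("ESDR_")] + ["CESDR"]
        summ = esdr.groupby("cluster")[cols].mean().round(4)
        lines += ["## ESDR by cluster (means)", summ.to_string(), ""]
    else:
        lines += ["## ESDR by cluster", "(stage not run)", ""]

    screen_f = run_dir / "screen.csv"
    thr_f = run_dir / "thresholds.csv"
    if screen_f.exists() and thr_f.exists():
        screen = pd.read_csv(screen_f)
        thr = pd.read_csv(thr_f)
        lines += [
            "## Screening attrition",
            f"pairs tested: {len(screen)}",
            f"passed screen (FDR, |rho|, n): {int(screen['passed'].sum())}",
            f"valid thresholds: {len(thr)}",
            "",
            "## Threshold table",
            thr.to_string(index=False) if len(thr) else
            "0 valid thresholds detected",
            "",
        ]
    else:
        lines += ["## Thresholds", "(stage not run)", ""]
    return "\n".join(lines) + "\n"
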