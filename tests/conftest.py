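"""Shared fixtures: generated scenarios reused across test modules."""

import numpy as np
import pytest

from escarp import synthetic as syn
from escarp.metrics import zonal_metrics
from escarp.services import compute_esdr


@pytest.fixture(scope="session")
def hinge_run():
    """Full single-regime hinge scenario (seed 7): the planted-breakpoint
    study condition used by several test modules."""
    cfg = syn.hinge_scenario(seed=7)
    raster, assignment = syn.generate_landuse(cfg)
    metrics = zonal_metrics(raster, cfg.cells_per_unit)
    surfaces = syn.generate_service_surfaces(cfg, metrics, assignment)
    esdr, esdr_meta = compute_esdr(surfaces["service_table"])
    return {
        "config": cfg, "raster": raster, "assignment": assignment,
        "metrics": metrics, "surfaces": surfaces, "esdr": esdr,
        "esdr_meta": esdr_meta,
    }


@pytest.fixture(scope="session")
def noiseless_run():
    """Hinge scenario with noise_sd=0: ESDR lies exactly on the plant."""
    cfg = syn.hinge_scenario(seed=5, noise_sd=0.0)
    raster, assignment = syn.generate_landuse(cfg)
    metrics = zonal_metrics(raster, cfg.cells_per_unit)
    surfaces = syn.generate_service_surfaces(cfg, metrics, assignment)
    esdr, _ = compute_esdr(surfaces["service_table"])
    return {"config": cfg, "metrics": metrics, "surfaces": surfaces,
            "esdr": esdr, "assignment": assignment}


def hinge_xy(rng, n=400, lo=40.0, hi=90.0, x0=60.0, s_pre=0.02,
             s_post=-0.02, intercept=-0.4, noise=0.01):
    """Raw scatter under a planted hinge boundary with one-sided noise."""
    x = rng.uniform(lo, hi, n)
    b = intercept + s_pre * np.minimum(x, x0) + s_post * np.maximum(x - x0, 0)
    return x, b - np.abs(rng.normal(0.0, noise, n))
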