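"""Model selection rules, threshold summaries and bootstrap uncertainty."""

import numpy as np
import pytest

from escarp.thresholds import (
    analyze_pair,
    bootstrap_threshold,
    extract_boundary,
    select_model,
    summarize_threshold,
    triple_fit,
)
from escarp.thresholds.fits import CandidateFit

from conftest import hinge_xy


def fake_fit(family, bic, threshold=5.0, valid=True, n_params=None):
    return CandidateFit(
        family=family, params={}, loglik=0.0,
        n_params=n_params or {"quadratic": 3, "segmented": 4,
                              "gam": 5.0}[family],
        bic=bic, threshold=threshold if valid else None,
        in_range=valid, significant=valid,
    )


# ---------------------------------------------------------------------------
# selection


def test_single_valid_candidate_selected():
    fits = [fake_fit("quadratic", 10.0, valid=False),
            fake_fit("segmented", 12.0)]
    selected, reasons = select_model(fits)
    assert selected.family == "segmented"
    assert reasons["quadratic"] != "valid"


def test_parsimony_resolves_delta_bic_tie():
    # segmented wins on BIC by 1.5 <= 2 -> quadratic (less complex) chosen
    fits = [fake_fit("quadratic", 11.5), fake_fit("segmented", 10.0)]
    selected, _ = select_model(fits)
    assert selected.family == "quadratic"
    # beyond the tie window the BIC winner stands
    fits = [fake_fit("quadratic", 13.0), fake_fit("segmented", 10.0)]
    selected, _ = select_model(fits)
    assert selected.family == "segmented"


def test_no_valid_candidate_is_legal_outcome():
    fits = [fake_fit("quadratic", 10.0, valid=False),
            fake_fit("gam", 11.0, valid=False)]
    selected, reasons = select_model(fits)
    assert selected is None
    assert set(reasons) == {"quadratic", "gam"}


def test_selection_is_pure():
    fits = [fake_fit("quadratic", 10.2), fake_fit("segmented", 9.5),
            fake_fit("gam", 9.4)]
    first, _ = select_model(fits)
    second, _ = select_model(fits)
    assert first is second or first.family == second.family


def test_hinge_data_select_segmented_most_of_the_time():
    """Strong-break, low-noise hinge series: segmented chosen >= 80%."""
    from test_fits import series_from
    wins = 0
    for rep in range(100):
        rng = np.random.default_rng(31 + rep)
        x = np.sort(rng.uniform(0, 100, 20))
        y = np.minimum(x, 100.0 - x) + rng.normal(0, 1.0, 20)
        selected, _ = select_model(triple_fit(series_from(x, y)))
        wins += selected is not None and selected.family == "segmented"
    assert wins >= 80


def test_parabola_data_select_quadratic_most_of_the_time():
    from test_fits import series_from
    wins = 0
    for rep in range(100):
        rng = np.random.default_rng(101 + rep)
        x = np.sort(rng.uniform(0, 10, 20))
        y = -0.3 * (x - 5) ** 2 + 2 + rng.normal(0, 0.1, 20)
        selected, _ = select_model(triple_fit(series_from(x, y)))
        wins += selected is not None and selected.family == "quadratic"
    assert wins >= 80


# ---------------------------------------------------------------------------
# summaries


def test_step_boundary_summary():
    from test_fits import series_from
    x = np.arange(10.0)
    y = np.where(x < 5, 1.0, 2.0)
    fit = fake_fit("segmented", 0.0, threshold=5.0)
    res = summarize_threshold(series_from(x, y), fit)
    assert res.pre_mean == pytest.approx(1.0)
    assert res.post_mean == pytest.approx(2.0)
    assert res.direction == "increase"
    assert res.threshold_2dp == 5.0


def test_symmetric_tent_is_a_flagged_tie():
    from test_fits import series_from
    x = np.arange(10.0)
    y = -np.abs(x - 4.5)
    res = summarize_threshold(series_from(x, y),
                              fake_fit("segmented", 0.0, threshold=5.0))
    assert res.delta == pytest.approx(0.0)
    assert res.direction == "tie" and "tie" in res.flags


def test_edge_supported_threshold_flagged():
    from test_fits import series_from
    x = np.arange(10.0)
    res = summarize_threshold(series_from(x, x),
                              fake_fit("segmented", 0.0, threshold=0.5))
    assert "edge-supported" in res.flags


def test_planted_scenario_direction_decrease(hinge_run):
    """Planted tent (x0=60, slopes +/-0.02) on the AI in [40, 90] window:
    boundary falls after the breakpoint, so pre_mean > post_mean."""
    p = hinge_run["surfaces"]["planted"]
    sub = p[(p.x >= 40) & (p.x <= 90)]
    res, _ = analyze_pair(sub.x.to_numpy(), sub.esdr_target.to_numpy(),
                          run_bootstrap=False)
    assert res is not None
    assert res.direction == "decrease"
    assert res.pre_mean > res.post_mean


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_stable_on_strong_hinge():
    """Strong hinge at the generator's noise floor: nearly every
    replicate re-detects a segmented threshold, tight CI."""
    rng = np.random.default_rng(41)
    x, y = hinge_xy(rng, n=400, noise=0.01, lo=25, hi=90)
    boot = bootstrap_threshold(x, y, "segmented", B=200, seed=8)
    assert boot["success_rate"] >= 0.95
    assert boot["ci_high"] - boot["ci_low"] < 0.1 * np.ptp(x)
    assert boot["flags"] == []


def test_bootstrap_unstable_on_pure_noise():
    rng = np.random.default_rng(43)
    x = rng.uniform(0, 100, 300)
    y = rng.normal(0, 1, 300)
    boot = bootstrap_threshold(x, y, "segmented", B=100, seed=9)
    assert boot["success_rate"] < 0.5
    assert "unstable" in boot["flags"]


def test_bootstrap_deterministic_under_seed():
    rng = np.random.default_rng(47)
    x, y = hinge_xy(rng, n=200, noise=0.02)
    a = bootstrap_threshold(x, y, "segmented", B=100, seed=5)
    b = bootstrap_threshold(x, y, "segmented", B=100, seed=5)
    assert a == b


def test_false_threshold_rate_controlled_on_linear_pairs():
    """200 no-break linear pairs at the study-condition scales (400
    units, slope 0.02, half-normal noise 0.01): at most 10% yield a
    valid selected threshold."""
    hits = 0
    for rep in range(200):
        rng = np.random.default_rng(1000 + rep)
        x = rng.uniform(25, 90, 400)
        y = 0.02 * x - np.abs(rng.normal(0, 0.01, 400))
        try:
            res, _ = analyze_pair(x, y, run_bootstrap=False)
        except ValueError:
            res = None
        hits += res is not None
    assert hits / 200 <= 0.10


def test_raw_point_fitting_flag_recovers_mean_hinge():
    """Sensitivity mode: fitting raw points (no envelope extraction)
    recovers a hinge planted in the mean response."""
    rng = np.random.default_rng(53)
    x = rng.uniform(25, 90, 400)
    y = (np.minimum(x, 120 - x) / 100) + rng.normal(0, 0.02, 400)
    res, _ = analyze_pair(x, y, run_bootstrap=False, fit_boundary=False)
    assert res is not None and res.family == "segmented"
    assert abs(res.threshold - 60.0) < 2.0
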