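import math

import numpy as np
import pandas as pd
import pytest

from replitrack import get_scenario
from replitrack.pipeline import RunConfig, run_pipeline
from replitrack.speed import (LocusStats, compare_split_lengths, delta_t,
                              doubling_time, estimate_alpha,
                              locus_split_frame, speed_between_loci)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def test_delta_t_zero_for_equal_lengths():
    assert delta_t(2.0, 2.0, 0.01) == 0.0


def test_delta_t_closed_form():
    alpha = math.log(2) / 90
    assert delta_t(2.0, 2.2, alpha) == pytest.approx(90 * math.log(1.1) / math.log(2),
                                                     rel=1e-12)


def test_delta_t_round_trip_identity():
    alpha = 0.0077
    for t in (1.0, 13.7, 50.0, 111.0):
        assert delta_t(2.0, 2.0 * math.exp(alpha * t), alpha) == pytest.approx(t, rel=1e-12)


def test_delta_t_additivity():
    alpha = 0.006
    L1, L2, L3 = 2.0, 2.6, 3.3
    assert delta_t(L1, L2, alpha) + delta_t(L2, L3, alpha) == \
        pytest.approx(delta_t(L1, L3, alpha), rel=1e-12)


def test_delta_t_negative_warns():
    with pytest.warns(UserWarning, match="negative"):
        assert delta_t(2.2, 2.0, 0.01) < 0


def test_delta_t_invalid_inputs():
    with pytest.raises(ValueError):
        delta_t(2.0, 2.2, 0.0)
    with pytest.raises(ValueError):
        delta_t(-1.0, 2.0, 0.01)


def test_doubling_time_examples():
    assert doubling_time(0.1, 0.2, 60) == pytest.approx(60.0)
    assert doubling_time(0.1, 0.4, 120) == pytest.approx(60.0)
    assert doubling_time(0.1, 0.3, 200) == pytest.approx(200 * math.log(2) / math.log(3))
    with pytest.raises(ValueError):
        doubling_time(0.2, 0.1, 60)


def test_speed_between_loci_closed_form():
    """L3 -> L6 with mean lengths 2.4/2.9 µm at alpha = ln2/120."""
    alpha = math.log(2) / 120
    a = LocusStats("L3", -0.99, 2.4, 100, 100)
    b = LocusStats("L6", -1.67, 2.9, 100, 100)
    est = speed_between_loci(a, b, alpha)
    expected_dt = 120 * math.log(2.9 / 2.4) / math.log(2)
    assert est.delta_t == pytest.approx(expected_dt, rel=1e-12)
    assert est.speed == pytest.approx(0.68e6 / expected_dt, rel=1e-12)
    assert est.speed == pytest.approx(2.08e4, rel=0.01)


def test_speed_undefined_for_equal_lengths():
    a = LocusStats("L3", -0.99, 2.4, 100, 100)
    b = LocusStats("L6", -1.67, 2.4, 100, 100)
    with pytest.warns(UserWarning):
        est = speed_between_loci(a, b, 0.006)
    assert math.isnan(est.speed)


def test_speed_requires_same_arm_and_ordering():
    a = LocusStats("L3", -0.99, 2.4, 100, 100)
    r = LocusStats("R6", +1.69, 2.9, 100, 100)
    with pytest.raises(ValueError):
        speed_between_loci(a, r, 0.006)
    with pytest.raises(ValueError):
        speed_between_loci(LocusStats("L6", -1.67, 2.9, 100, 100), a, 0.006)


def test_speed_invariant_to_length_rescaling():
    alpha = 0.006
    a = LocusStats("L3", -0.99, 2.4, 100, 100)
    b = LocusStats("L6", -1.67, 2.9, 100, 100)
    a2 = LocusStats("L3", -0.99, 2.4 * 1.7, 100, 100)
    b2 = LocusStats("L6", -1.67, 2.9 * 1.7, 100, 100)
    assert speed_between_loci(a, b, alpha).speed == \
        pytest.approx(speed_between_loci(a2, b2, alpha).speed, rel=1e-12)


# ---------------------------------------------------------------------------
# growth-rate estimation
# ---------------------------------------------------------------------------

def test_alpha_recovered_exactly_from_exponential():
    t = np.arange(0, 60, 2.0)
    L = 2.0 * np.exp(0.0077 * t)
    assert estimate_alpha(t, L) == pytest.approx(0.0077, rel=1e-10)


def test_alpha_zero_for_constant_length():
    t = np.arange(0, 20, 2.0)
    assert estimate_alpha(t, np.full_like(t, 3.0)) == pytest.approx(0.0)


def test_alpha_input_validation():
    with pytest.raises(ValueError):
        estimate_alpha([0, 2], [1, 2])
    with pytest.raises(ValueError):
        estimate_alpha([0, 2, 4], [1.0, -1.0, 2.0])


# ---------------------------------------------------------------------------
# locus split detection
# ---------------------------------------------------------------------------

def _locus_foci(split_frame, n_frames=30, sep_px=4.0, blips=()):
    rows = []
    for f in range(n_frames):
        split = f >= split_frame or f in blips
        if split:
            rows.append(dict(cell_id="c", frame=f, x_px=20 - sep_px / 2,
                             y_px=13.5, accepted=True))
            rows.append(dict(cell_id="c", frame=f, x_px=20 + sep_px / 2,
                             y_px=13.5, accepted=True))
        else:
            rows.append(dict(cell_id="c", frame=f, x_px=20.0, y_px=13.5,
                             accepted=True))
    return pd.DataFrame(rows)


def test_persistent_separation_detected():
    assert locus_split_frame(_locus_foci(20), pixel_size=103.0) == 20


def test_never_separating_track_undetected():
    assert locus_split_frame(_locus_foci(999), pixel_size=103.0) is None


def test_transient_one_frame_separation_ignored():
    assert locus_split_frame(_locus_foci(999, blips=(12,)), pixel_size=103.0) is None


def test_subthreshold_separation_ignored():
    # 2 px ~ 206 nm < 300 nm threshold
    assert locus_split_frame(_locus_foci(10, sep_px=2.0), pixel_size=103.0) is None


def test_ttest_distinguishes_strains():
    rng = np.random.default_rng(0)
    a = rng.normal(2.4, 0.2, 80)
    b = rng.normal(2.9, 0.2, 80)
    t, p = compare_split_lengths(a, b)
    assert p < 1e-6 and t < 0


# ---------------------------------------------------------------------------
# end-to-end speed recovery
# ---------------------------------------------------------------------------

def test_constant_speed_arm_recovered_within_ten_percent():
    """An arm simulated at constant 3.0e4 bp/min yields inter-locus speed
    estimates within 10% from the full imaging + detection chain."""
    true_speed = 3.0e4
    arm = ((2.02, true_speed),)
    stats = []
    for strain in ("L3", "L4", "L6"):
        cfg = RunConfig(scenario=f"locus:{strain}", n_cells=100, rng_seed=23,
                        scenario_overrides=dict(left_arm_speed=arm))
        s = run_pipeline(cfg)
        stats.append(LocusStats(strain, get_scenario(f"locus:{strain}").locus_position_mb,
                                s["length_at_split_mean"],
                                s["length_at_split_n"], s["n_cells"]))
    alpha = get_scenario("locus:L3").growth_rate_alpha
    for a, b in zip(stats, stats[1:]):
        est = speed_between_loci(a, b, alpha)
        assert est.speed == pytest.approx(true_speed, rel=0.10)
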