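import numpy as np
import pandas as pd
import pytest

from replitrack import get_scenario
from replitrack.events import (any_two_foci_flag, classify_frame, colocalize,
                               detect_early_splitting, detect_late_splitting,
                               frame_patterns, link_tracks, segregation_time,
                               similar_foci_duration, step_sizes,
                               two_bright_early_flag, two_foci_frequency)
from replitrack.simulate import _build_geometry
from replitrack.timeline import ReplicationWindow

WIN = ReplicationWindow(10, 59)   # 50-frame window


def _patterns(spec_by_frame):
    """Build a patterns frame from {frame: (n_foci, ratio)}."""
    rows = []
    for f in range(WIN.init_frame, WIN.end_frame + 1):
        n, ratio = spec_by_frame.get(f, (1, np.nan))
        if n == 0:
            cls = "none"
        elif n == 1:
            cls = "single"
        else:
            cls = "similar" if ratio <= 1.5 else "dissimilar"
        tau = (f - (WIN.init_frame - 1)) / (WIN.end_frame + 1 - (WIN.init_frame - 1))
        rows.append(dict(cell_id="c", frame=f, tau=tau, n_foci=n,
                         ratio=ratio, similarity_class=cls))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frame classification
# ---------------------------------------------------------------------------

def test_ratio_boundary_is_inclusive_similar():
    p = classify_frame([300.0, 200.0], "c", 20, WIN)
    assert p.ratio == pytest.approx(1.5)
    assert p.similarity_class == "similar"


def test_clearly_unequal_foci_are_dissimilar():
    p = classify_frame([300.0, 100.0], "c", 20, WIN)
    assert p.ratio == pytest.approx(3.0)
    assert p.similarity_class == "dissimilar"


def test_single_focus_has_undefined_ratio():
    p = classify_frame([300.0], "c", 20, WIN)
    assert p.similarity_class == "single"
    assert np.isnan(p.ratio)


def test_classification_partition_is_exhaustive():
    """Every frame is exactly one of none/single/similar/dissimilar."""
    foci = pd.DataFrame(dict(
        cell_id="c",
        frame=[10, 11, 11, 12, 12, 14],
        accepted=[True] * 6,
        integrated_intensity=[100, 100, 90, 100, 40, 80.0],
    ))
    pats = frame_patterns(foci, WIN)
    assert set(pats["similarity_class"]) <= {"none", "single", "similar", "dissimilar"}
    assert pats.loc[pats["frame"] == 10, "similarity_class"].iloc[0] == "single"
    assert pats.loc[pats["frame"] == 11, "similarity_class"].iloc[0] == "similar"
    assert pats.loc[pats["frame"] == 12, "similarity_class"].iloc[0] == "dissimilar"
    assert pats.loc[pats["frame"] == 13, "similarity_class"].iloc[0] == "none"
    assert len(pats) == WIN.n_frames


def test_threshold_monotonicity_of_similar_count():
    rng = np.random.default_rng(0)
    ratios = rng.uniform(1.0, 3.0, 100)
    counts = []
    for thr in (1.2, 1.5, 2.0, 2.5):
        counts.append(sum(r <= thr for r in ratios))
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# early / late splitting on constructed patterns
# ---------------------------------------------------------------------------

def test_early_event_fires_on_dissimilar_frame_in_first_half():
    pats = _patterns({15: (2, 2.5), 16: (2, 2.5)})
    e = detect_early_splitting(pats, WIN, frame_interval=2.0)
    assert e is not None and e.kind == "early"
    assert e.onset_frame == 15
    assert e.onset_tau <= 0.5


def test_single_focus_cell_has_no_events():
    pats = _patterns({})
    assert detect_early_splitting(pats, WIN, 2.0) is None
    assert detect_late_splitting(pats, WIN, 2.0) is None


def test_dissimilar_after_midpoint_does_not_fire_early():
    pats = _patterns({50: (2, 2.5), 51: (2, 2.5)})
    assert detect_early_splitting(pats, WIN, 2.0) is None


def test_late_event_measures_run_length():
    pats = _patterns({f: (2, 1.1) for f in range(48, 54)})
    e = detect_late_splitting(pats, WIN, frame_interval=2.0)
    assert e is not None and e.kind == "late"
    assert e.onset_frame == 48
    assert e.onset_tau > 0.5
    assert e.duration == pytest.approx(12.0)
    assert e.rel_duration == pytest.approx(6 / 50)
    assert e.merged


def test_similar_run_in_early_window_is_not_late_splitting():
    pats = _patterns({f: (2, 1.1) for f in range(14, 19)})
    assert detect_late_splitting(pats, WIN, 2.0) is None


def test_unmerged_run_flagged():
    pats = _patterns({f: (2, 1.1) for f in range(55, 60)})
    e = detect_late_splitting(pats, WIN, 2.0)
    assert e is not None and not e.merged


def test_first_onset_recorded_for_multiple_runs():
    pats = _patterns({**{f: (2, 1.1) for f in range(45, 47)},
                      **{f: (2, 1.1) for f in range(50, 56)}})
    e = detect_late_splitting(pats, WIN, 2.0)
    assert e.onset_frame == 50          # longest run
    tau45 = (45 - 9) / 51
    assert e.first_onset_tau == pytest.approx(tau45)


def test_similar_duration_fraction():
    pats = _patterns({f: (2, 1.2) for f in range(40, 45)})
    assert similar_foci_duration(pats, WIN) == pytest.approx(5 / 50)
    assert similar_foci_duration(_patterns({}), WIN) == 0.0


def test_population_flags():
    assert two_bright_early_flag(_patterns({15: (2, 1.2)}))
    assert not two_bright_early_flag(_patterns({50: (2, 1.2)}))
    assert any_two_foci_flag(_patterns({50: (2, 1.2)}))
    assert not any_two_foci_flag(_patterns({}))


# ---------------------------------------------------------------------------
# segregation timing
# ---------------------------------------------------------------------------

def _cell_with_parb(arrival_frame, window, n_frames=30, length=3.0):
    params = get_scenario("WT", photon_scale=0.0)
    lengths = length * np.exp(0.006 * 2.0 * np.arange(n_frames))
    cell = _build_geometry("c", lengths, False, np.full(n_frames, np.nan), params)
    rows = []
    for f in range(n_frames):
        ax = 0.95 * lengths[f] if f >= arrival_frame else 0.3 * lengths[f]
        rows.append(dict(cell_id="c", frame=f, accepted=True, axial_um=ax,
                         x_px=0.0, y_px=0.0))
    return cell, pd.DataFrame(rows)


def test_segregation_time_arithmetic():
    """Arrival 6 frames after initiation at 2-min frames gives 12 min."""
    win = ReplicationWindow(3, 28)
    cell, parb = _cell_with_parb(arrival_frame=9, window=win)
    rec = segregation_time(win, parb, cell, "with_dim")
    assert rec is not None
    assert rec.T_seg == pytest.approx(12.0)
    assert rec.dim_class == "with_dim"


def test_segregation_unresolved_when_parb_never_arrives():
    win = ReplicationWindow(3, 28)
    cell, parb = _cell_with_parb(arrival_frame=999, window=win)
    assert segregation_time(win, parb, cell, "with_dim") is None


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def test_identical_foci_lists_fully_matched():
    a = pd.DataFrame(dict(x_px=[10.0, 20.0], y_px=[10.0, 10.0]))
    pairs = colocalize(a, a.copy(), pixel_size=103.0)
    assert sorted(pairs) == [(0, 0), (1, 1)]


def test_empty_channel_b_yields_no_pairs():
    a = pd.DataFrame(dict(x_px=[10.0], y_px=[10.0]))
    b = pd.DataFrame(columns=["x_px", "y_px"])
    assert colocalize(a, b, pixel_size=103.0) == []


def test_distant_foci_not_matched():
    a = pd.DataFrame(dict(x_px=[10.0], y_px=[10.0]))
    b = pd.DataFrame(dict(x_px=[30.0], y_px=[10.0]))   # ~2 µm away
    assert colocalize(a, b, pixel_size=103.0, d_max_nm=250.0) == []


# ---------------------------------------------------------------------------
# tracking and steps
# ---------------------------------------------------------------------------

def _track_df(positions_px, cell_id="c"):
    rows = []
    for f, pts in enumerate(positions_px):
        for (x, y) in pts:
            rows.append(dict(cell_id=cell_id, frame=f, x_px=x, y_px=y,
                             accepted=True, axial_um=x * 0.103))
    return pd.DataFrame(rows)


def test_static_focus_has_zero_steps():
    df = _track_df([[(10.0, 10.0)]] * 5)
    tracked = link_tracks(df, pixel_size=103.0)
    assert tracked["track_id"].nunique() == 1
    params = get_scenario("WT", photon_scale=0.0)
    lengths = np.full(5, 3.0) + np.arange(5) * 1e-3
    cell = _build_geometry("c", lengths, False, np.full(5, np.nan), params)
    steps = step_sizes(tracked, cell)
    assert len(steps) == 4
    assert np.allclose(steps["step_nm"], 0.0)
    assert (steps["location_class"] == "away").all()


def test_distant_parallel_tracks_never_cross_linked():
    df = _track_df([[(10.0, 10.0), (30.0, 10.0)]] * 6)   # 2 µm apart
    tracked = link_tracks(df, pixel_size=103.0, max_link_nm=500.0)
    assert tracked["track_id"].nunique() == 2
    for _, g in tracked.groupby("track_id"):
        assert g["x_px"].nunique() == 1


def test_broken_link_splits_track():
    # focus jumps 2 µm between frames 2 and 3: two track halves
    pos = [[(10.0, 10.0)]] * 3 + [[(30.0, 10.0)]] * 3
    tracked = link_tracks(_track_df(pos), pixel_size=103.0, max_link_nm=500.0)
    assert tracked["track_id"].nunique() == 2


def test_division_site_classification():
    params = get_scenario("WT", photon_scale=0.0)
    lengths = np.full(4, 3.0) + np.arange(4) * 1e-3
    constr = np.full(4, 1.65)     # division site at 1.65 µm
    cell = _build_geometry("c", lengths, False, constr, params)
    at_site_px = 1.65 * 1000 / 103.0
    df = _track_df([[(at_site_px, 13.5)]] * 4)
    df["axial_um"] = 1.65
    steps = step_sizes(link_tracks(df, 103.0), cell)
    assert (steps["location_class"] == "at_division_site").all()


# ---------------------------------------------------------------------------
# frequency curves
# ---------------------------------------------------------------------------

def test_two_foci_frequency_zero_for_single_focus_population():
    pats = pd.concat([_patterns({}).assign(cell_id=f"c{i}") for i in range(4)])
    freq = two_foci_frequency(pats)
    assert np.allclose(freq["frac_two"], 0.0)
    assert len(freq) == 10


def test_two_foci_frequency_stratifies_classes():
    # dissimilar episode around tau ~0.15 (frames 16-18), similar around ~0.85
    pats = pd.concat([
        _patterns({f: (2, 2.5) for f in (16, 17, 18)}).assign(cell_id="a"),
        _patterns({f: (2, 1.1) for f in (51, 52, 53)}).assign(cell_id="b"),
    ])
    freq = two_foci_frequency(pats)
    early_bin = freq.iloc[1]      # center tau 0.15
    assert early_bin["frac_dissimilar"] > 0
    assert early_bin["frac_similar"] == 0
    assert freq["frac_similar"].sum() > 0
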