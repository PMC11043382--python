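import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from replitrack.detect import (FocusFit, detect_cell_foci, filter_foci,
                               fit_spots, integrated_intensity,
                               project_to_axis, select_top_foci)
from replitrack.render import add_gaussian_spot
from replitrack import get_scenario, simulate_cell


def _spot_image(x, y, amp, sigma, offset=50.0, shape=(28, 60)):
    img = np.full(shape, float(offset))
    add_gaussian_spot(img, x, y, amp, sigma)
    return img


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_noiseless_single_spot_recovered_within_one_percent():
    img = _spot_image(30.4, 13.7, 200.0, 1.3, offset=50.0)
    fits = fit_spots(img)
    assert len(fits) == 1
    f = fits[0]
    assert f.amplitude == pytest.approx(200.0, rel=0.01)
    assert f.sigma_x == pytest.approx(1.3, rel=0.01)
    assert f.sigma_y == pytest.approx(1.3, rel=0.01)
    assert f.offset == pytest.approx(50.0, rel=0.01)
    assert f.center_x == pytest.approx(30.4, abs=0.1)
    assert f.center_y == pytest.approx(13.7, abs=0.1)


def test_flat_image_yields_empty_list():
    assert fit_spots(np.full((28, 60), 50.0)) == []


def test_nonfinite_image_rejected():
    img = np.full((28, 60), 50.0)
    img[3, 3] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit_spots(img)


def test_two_spots_eight_px_apart_recovered():
    img = np.full((28, 60), 50.0)
    add_gaussian_spot(img, 26.0, 13.5, 180.0, 1.3)
    add_gaussian_spot(img, 34.0, 13.5, 140.0, 1.3)
    fits = sorted(fit_spots(img), key=lambda f: f.center_x)
    assert len(fits) == 2
    assert fits[0].center_x == pytest.approx(26.0, abs=0.2)
    assert fits[1].center_x == pytest.approx(34.0, abs=0.2)


def test_noiseless_oracle_over_random_spots():
    """Fit parameters equal generator emitters within 1% / 0.1 px."""
    rng = np.random.default_rng(0)
    for _ in range(30):
        x = rng.uniform(15, 45)
        y = rng.uniform(10, 18)
        amp = rng.uniform(50, 400)
        sig = rng.uniform(1.05, 2.5)
        fits = fit_spots(_spot_image(x, y, amp, sig))
        assert len(fits) == 1
        f = fits[0]
        assert f.amplitude == pytest.approx(amp, rel=0.01)
        assert f.sigma_x == pytest.approx(sig, rel=0.01)
        assert f.center_x == pytest.approx(x, abs=0.1)
        assert f.center_y == pytest.approx(y, abs=0.1)


def test_localization_bias_statistically_zero():
    """|mean localization error| < 3 SEM on noisy spots (n=1000)."""
    rng = np.random.default_rng(1)
    errs = []
    for _ in range(1000):
        x = rng.uniform(28, 32)
        img = rng.poisson(_spot_image(x, 13.5, 250.0, 1.3, offset=100.0)).astype(float)
        fits = [f for f in filter_foci(fit_spots(img)) if f.accepted]
        if len(fits) == 1:
            errs.append(fits[0].center_x - x)
    errs = np.asarray(errs)
    assert len(errs) > 950
    assert abs(errs.mean()) < 3 * errs.std() / np.sqrt(len(errs))


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _fit(amp, sx, sy, off):
    return FocusFit(center_x=10, center_y=10, amplitude=amp,
                    sigma_x=sx, sigma_y=sy, offset=off)


@pytest.mark.parametrize("amp,off,sx,sy,accepted,reason", [
    # SNR boundary: 0.25 is inclusive
    (10.0, 50.0, 1.5, 1.5, False, "snr"),     # SNR 0.2
    (12.5, 50.0, 1.5, 1.5, True, ""),          # SNR 0.25
    (15.0, 50.0, 1.5, 1.5, True, ""),          # SNR 0.3
    # width boundary: [1, 3] inclusive
    (100.0, 100.0, 0.9, 1.5, False, "width"),
    (100.0, 100.0, 1.0, 1.5, True, ""),
    (100.0, 100.0, 3.0, 1.5, True, ""),
    (100.0, 100.0, 3.1, 1.5, False, "width"),
    (100.0, 100.0, 3.5, 1.5, False, "width"),
    # width failure reported before SNR failure
    (10.0, 100.0, 3.5, 1.5, False, "width"),
])
def test_filter_boundary_cases(amp, off, sx, sy, accepted, reason):
    out = filter_foci([_fit(amp, sx, sy, off)])
    assert out[0].accepted is accepted
    assert out[0].reject_reason == reason


def test_zero_offset_counts_as_infinite_snr():
    out = filter_foci([_fit(5.0, 1.5, 1.5, 0.0)])
    assert out[0].accepted


def test_integrated_intensity_examples():
    assert integrated_intensity(_fit(100.0, 1.5, 2.0, 10)) == pytest.approx(300.0)
    assert integrated_intensity(_fit(0.0, 1.5, 2.0, 10)) == 0.0
    assert integrated_intensity(_fit(87.5, 1.1, 1.3, 10)) == pytest.approx(125.125)
    out = filter_foci([_fit(100.0, 2.0, 1.2, 100.0)])
    assert out[0].accepted and out[0].integrated_intensity == pytest.approx(240.0)


@st.composite
def focus_lists(draw):
    n = draw(st.integers(0, 6))
    fits = []
    for _ in range(n):
        fits.append(_fit(draw(st.floats(0, 300)),
                         draw(st.floats(0.5, 4.0)),
                         draw(st.floats(0.5, 4.0)),
                         draw(st.floats(0, 200))))
    return fits


@settings(max_examples=50, deadline=None, derandomize=True)
@given(focus_lists())
def test_filter_idempotent(fits):
    once = filter_foci(fits)
    twice = filter_foci(once)
    assert [(f.accepted, f.reject_reason) for f in once] == \
        [(f.accepted, f.reject_reason) for f in twice]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(focus_lists(), st.floats(0.0, 2.0), st.floats(0.0, 2.0))
def test_raising_snr_threshold_never_accepts_more(fits, thr1, thr2):
    lo, hi = sorted((thr1, thr2))
    n_lo = sum(f.accepted for f in filter_foci(fits, snr_min=lo))
    n_hi = sum(f.accepted for f in filter_foci(fits, snr_min=hi))
    assert n_hi <= n_lo


def test_width_rule_either_is_more_permissive():
    fits = [_fit(100, 3.5, 1.5, 100)]
    assert not filter_foci(fits, width_rule="both")[0].accepted
    assert filter_foci(fits, width_rule="either")[0].accepted


def test_select_top_foci_keeps_two_brightest():
    fits = filter_foci([_fit(300, 1.5, 1.5, 100), _fit(200, 1.5, 1.5, 100),
                        _fit(100, 1.5, 1.5, 100)])
    out = select_top_foci(fits, n_max=2)
    flags = [f.accepted for f in out]
    assert flags == [True, True, False]
    assert out[2].reject_reason == "rank"


# ---------------------------------------------------------------------------
# axial projection
# ---------------------------------------------------------------------------

def test_projection_alignment_conventions():
    cell, _ = simulate_cell(get_scenario("WT", photon_scale=0.0), 5)
    L = cell.lengths_um[0]
    old = cell.old_pole_px[0]
    # a focus at the old pole projects to ~0; at the midpoint to L/2
    f_old = FocusFit(center_x=old[0], center_y=old[1], amplitude=1,
                     sigma_x=1.3, sigma_y=1.3, offset=1)
    assert project_to_axis(f_old, cell, 0) == pytest.approx(0.0, abs=0.05)
    mx, my = cell.axial_to_px(0, L / 2, 0.0)
    f_mid = FocusFit(center_x=mx, center_y=my, amplitude=1,
                     sigma_x=1.3, sigma_y=1.3, offset=1)
    assert project_to_axis(f_mid, cell, 0) == pytest.approx(L / 2, abs=0.05)


def test_focus_outside_boundary_rejected():
    cell, _ = simulate_cell(get_scenario("WT", photon_scale=0.0), 5)
    f = FocusFit(center_x=1.0, center_y=1.0, amplitude=1,
                 sigma_x=1.3, sigma_y=1.3, offset=1)
    with pytest.raises(ValueError, match="outside"):
        project_to_axis(f, cell, 0)


def test_axial_positions_match_ground_truth():
    """Mean axial localization error below 0.5 px on noisy synthetic data."""
    params = get_scenario("WT")
    errs = []
    for seed in range(6):
        cell, truth = simulate_cell(params, 100 + seed)
        foci = detect_cell_foci(cell, "dnaN")
        acc = foci[foci["accepted"]]
        em = truth.emitters
        bright = em[(em["channel"] == "dnaN") & (em["label"] == "replisome")]
        for _, e in bright.iterrows():
            g = acc[acc["frame"] == e["frame"]]
            if len(g) == 0:
                continue
            errs.append(np.min(np.abs(g["axial_um"].to_numpy() - e["axial_um"])))
    err_px = np.mean(errs) * 1000.0 / params.pixel_size
    assert err_px < 0.5
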