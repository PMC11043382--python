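"""Mechanistic single-cell simulator.

One simulated cell is a straight rod growing exponentially in length, carrying
diffraction-limited fluorescent emitters whose trajectories follow the
replisome model the package analyses:

* a bright replisome focus assembles near the old (stalked) pole at
  replication initiation and drifts towards the future division site;
* in the fast-segregation class, residual sliding-clamp signal travels with
  the segregating DNA to the new-pole side, first as a streak, then as a
  compact dim focus that decays exponentially;
* the two active replisomes may transiently decouple into two similar
  brightness foci, either early (loss of inter-arm alignment) or late
  (asynchronous arrival at the terminus), merging again before disassembly;
* a ParB focus duplicates at initiation and one copy migrates old pole ->
  new pole over the segregation time.

Everything the detection/classification pipeline is later asked to recover is
recorded in a :class:`GroundTruth` table, which is the oracle for every
recovery test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .render import render_frames
from .scenarios import ScenarioParams

__all__ = [
    "CellSeries",
    "GroundTruth",
    "simulate_cell",
    "simulate_population",
    "iter_population",
    "ground_truth_table",
]

CELL_RADIUS_UM = 0.38   # half-width of the rod
PAD_PX = 9              # image padding on each side of the cell
IMG_HEIGHT = 28

# relative axial positions (fractions of cell length)
BRIGHT_START_FRAC = 0.13
DIM_END_FRAC = 0.85
PARB_OLD_FRAC = 0.08
PARB_NEW_FRAC = 0.92
LOCUS_FRAC = 0.45

PARB_AMP_FACTOR = 0.8   # ParB focus brightness relative to bright_amplitude
MIN_EMITTER_AMP = 5.0   # truth emitters dimmer than this are not rendered
N_STREAK_SUB = 4        # sub-emitters forming the travelling dim streak


@dataclass
class CellSeries:
    """Per-frame geometry and rendered image crops of one cell.

    Axial positions run from the old pole (0) to the new pole (cell length);
    pixel coordinates are 0-based with sub-pixel precision.
    """

    cell_id: str
    frame_interval: float                 # min
    pixel_size: float                     # nm
    lengths_um: np.ndarray                # (T,)
    old_pole_px: np.ndarray               # (T, 2) x, y
    new_pole_px: np.ndarray               # (T, 2)
    boundaries: list                      # per frame: (N, 2) polygon, px
    constriction_um: np.ndarray           # (T,) axial position, NaN when absent
    img_shape: tuple = (0, 0)             # (H, W) of the rendered crops
    images: dict = field(default_factory=dict)   # channel -> (T, H, W) float

    @property
    def n_frames(self) -> int:
        return len(self.lengths_um)

    def axial_to_px(self, frame: int, axial_um: float, trans_um: float = 0.0) -> tuple[float, float]:
        """Map an (axial, transverse) position in µm to image (x, y) in px."""
        old = self.old_pole_px[frame]
        new = self.new_pole_px[frame]
        vec = new - old
        norm = np.hypot(*vec)
        u = vec / norm
        px_per_um = 1000.0 / self.pixel_size
        p = old + u * (axial_um * px_per_um)
        # transverse: rotate u by +90 degrees
        n = np.array([-u[1], u[0]])
        p = p + n * (trans_um * px_per_um)
        return float(p[0]), float(p[1])


@dataclass
class GroundTruth:
    """Per-cell event labels plus the per-frame emitter list."""

    cell_id: str
    t_init: int
    t_end: int
    seg_class: str = "none"                  # fast | slow | none
    T_seg: float = float("nan")              # min
    dim_signal_present: bool = False
    late_split_flag: bool = False
    late_split_onset_tau: float = float("nan")
    late_split_duration: float = float("nan")   # min
    early_bright_split_flag: bool = False
    two_foci_any_flag: bool = False
    ssb_coloc_flag: bool = False
    alpha: float = float("nan")              # 1/min
    division_site_um: float = float("nan")   # axial constriction position at last frame
    locus_duplication_length: float = float("nan")  # µm (locus scenarios)
    locus_split_frame: int = -1              # -1: not applicable / undetectable
    emitters: pd.DataFrame | None = None     # frame, channel, axial_um, trans_um, amplitude

    def as_row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "emitters"}
        return d


def ground_truth_table(truths) -> pd.DataFrame:
    """Stack per-cell :class:`GroundTruth` records into one DataFrame."""
    return pd.DataFrame([t.as_row() for t in truths])


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _capsule_polygon(x0: float, x1: float, yc: float, r: float, n_arc: int = 7) -> np.ndarray:
    """Rod-shaped (capsule) outline from pole x0 to pole x1, half-width r."""
    lo, hi = (x0, x1) if x0 <= x1 else (x1, x0)
    th_right = np.linspace(-np.pi / 2, np.pi / 2, n_arc)
    th_left = np.linspace(np.pi / 2, 3 * np.pi / 2, n_arc)
    right = np.stack([hi + r * np.cos(th_right), yc + r * np.sin(th_right)], axis=1)
    left = np.stack([lo + r * np.cos(th_left), yc + r * np.sin(th_left)], axis=1)
    return np.vstack([right, left])


def _build_geometry(cell_id: str, lengths_um: np.ndarray, flipped: bool,
                    constriction_um: np.ndarray, params: ScenarioParams) -> CellSeries:
    px_per_um = 1000.0 / params.pixel_size
    max_len_px = float(np.max(lengths_um)) * px_per_um
    width = int(math.ceil(max_len_px)) + 2 * PAD_PX
    yc = (IMG_HEIGHT - 1) / 2.0
    r_px = CELL_RADIUS_UM * px_per_um

    T = len(lengths_um)
    old_pole = np.empty((T, 2))
    new_pole = np.empty((T, 2))
    boundaries = []
    for f in range(T):
        L_px = lengths_um[f] * px_per_um
        if not flipped:
            x_old, x_new = float(PAD_PX), float(PAD_PX) + L_px
        else:
            x_old, x_new = width - 1.0 - PAD_PX, width - 1.0 - PAD_PX - L_px
        old_pole[f] = (x_old, yc)
        new_pole[f] = (x_new, yc)
        boundaries.append(_capsule_polygon(x_old, x_new, yc, r_px))

    return CellSeries(
        cell_id=cell_id,
        frame_interval=params.frame_interval,
        pixel_size=params.pixel_size,
        lengths_um=lengths_um,
        old_pole_px=old_pole,
        new_pole_px=new_pole,
        boundaries=boundaries,
        constriction_um=constriction_um,
        img_shape=(IMG_HEIGHT, width),
        images={},
    )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Normal draw resampled until > lo (guards against nonphysical values)."""
    if sd == 0.0:
        return max(mean, lo)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lo:
            return x
    return lo  # pragma: no cover


# ---------------------------------------------------------------------------
# emitter trajectory construction
# ---------------------------------------------------------------------------

def _emit(rows: list, frame: int, channel: str, axial: float, trans: float,
          amp: float, label: str) -> None:
    if amp >= MIN_EMITTER_AMP:
        rows.append(
            dict(frame=frame, channel=channel, axial_um=axial, trans_um=trans,
                 amplitude=amp, label=label)
        )


def _simulate_standard(params: ScenarioParams, rng: np.random.Generator,
                       cell_id: str, render: bool = True) -> tuple[CellSeries, GroundTruth]:
    dt = params.frame_interval
    L0 = _trunc_normal(rng, params.birth_length_mean, params.birth_length_sd, 1.2)
    D = _trunc_normal(rng, params.rep_duration_mean, params.rep_duration_sd, 20 * dt)
    W = max(10, int(round(D / dt)))            # frames in the replication window
    margin = params.margin_frames
    T = margin + W + margin
    t_init, t_end = margin, margin + W - 1

    times = np.arange(T) * dt
    lengths = L0 * np.exp(params.growth_rate_alpha * times)
    flipped = bool(rng.random() < 0.5)

    def tau(f: int) -> float:
        return (f - (t_init - 1)) / ((t_end + 1) - (t_init - 1))

    truth = GroundTruth(cell_id=cell_id, t_init=t_init, t_end=t_end,
                        alpha=params.growth_rate_alpha)

    # --- bright replisome trajectory (fraction of cell length) ------------
    start_frac = BRIGHT_START_FRAC
    if params.p_mispositioned_init > 0 and rng.random() < params.p_mispositioned_init:
        start_frac = float(rng.uniform(0.3, 0.6))
    u_grid = np.linspace(0.0, 1.0, W)
    bright_frac = start_frac + (params.division_site_frac - start_frac) * u_grid
    bright_frac = bright_frac + rng.normal(0.0, 0.01, W)
    bright_trans = rng.normal(0.0, 0.04, W)    # µm

    # --- two-foci episodes -------------------------------------------------
    split_mask = np.zeros(W, dtype=bool)       # late splitting
    tb_mask = np.zeros(W, dtype=bool)          # early two-bright episode
    any_mask = np.zeros(W, dtype=bool)         # brief episode at arbitrary time

    if rng.random() < params.p_late_split:
        n_split = max(2, int(round(params.late_split_rel_duration * W)))
        tau_lo, tau_hi = params.late_onset_tau_range
        lo = int(math.ceil(tau_lo * (W + 1)))
        # merge at least 2 frames before the end, onset no later than tau_hi
        hi = min(W - n_split - 2, int(math.floor(tau_hi * (W + 1))) - n_split)
        if hi >= lo:
            s = int(rng.integers(lo, hi + 1))
            split_mask[s:s + n_split] = True
            truth.late_split_flag = True
            truth.late_split_onset_tau = tau(t_init + s)
            truth.late_split_duration = n_split * dt

    if rng.random() < params.p_two_bright_early:
        n_tb = max(2, int(round(params.two_bright_rel_duration * W)))
        lo = max(1, int(round(0.08 * W)))
        hi = int(math.floor(0.5 * (W + 1))) - n_tb   # whole episode at tau <= 0.5
        if hi >= lo:
            s = int(rng.integers(lo, hi + 1))
            tb_mask[s:s + n_tb] = True
            truth.early_bright_split_flag = True

    if params.p_two_foci_any > 0 and rng.random() < params.p_two_foci_any:
        n_any = 3
        s = int(rng.integers(1, max(2, W - n_any - 1)))
        any_mask[s:s + n_any] = True
        truth.two_foci_any_flag = True

    # --- segregation class / dim residual signal --------------------------
    has_seg = "parB" in params.channels or params.p_fast_seg > 0
    if has_seg:
        fast = rng.random() < params.p_fast_seg
        truth.seg_class = "fast" if fast else "slow"
        if fast:
            truth.T_seg = _trunc_normal(rng, params.seg_time_fast_mean,
                                        params.seg_time_fast_sd, 2 * dt)
        else:
            truth.T_seg = _trunc_normal(rng, params.seg_time_slow_mean,
                                        params.seg_time_slow_sd, 2 * dt)
        truth.dim_signal_present = fast

    if "ssb" in params.channels:
        truth.ssb_coloc_flag = bool(rng.random() < params.p_ssb_coloc)

    truth.division_site_um = params.division_site_frac * float(lengths[-1])

    # --- build the emitter table -------------------------------------------
    rows: list[dict] = []
    A = params.bright_amplitude

    def episode_sep(mask: np.ndarray, i: int, max_sep: float) -> float:
        """Trapezoidal separation profile (µm) over a contiguous episode."""
        idx = np.flatnonzero(mask)
        j = np.searchsorted(idx, i)
        n = len(idx)
        if n == 1:
            return 0.45
        frac_through = j / (n - 1)
        return 0.45 + (max_sep - 0.45) * (1.0 - abs(2.0 * frac_through - 1.0))

    for i in range(W):
        f = t_init + i
        L = lengths[f]
        pos = float(np.clip(bright_frac[i], 0.03, 0.97)) * L
        tr = float(bright_trans[i])
        if split_mask[i] or tb_mask[i] or any_mask[i]:
            if split_mask[i]:
                sep = episode_sep(split_mask, i, 0.85)
            elif tb_mask[i]:
                sep = episode_sep(tb_mask, i, 1.00)
            else:
                sep = 0.55
            lo_pos = max(0.05 * L, pos - sep / 2)
            hi_pos = min(0.95 * L, pos + sep / 2)
            _emit(rows, f, "dnaN", lo_pos, tr, A / 2, "replisome_a")
            _emit(rows, f, "dnaN", hi_pos, tr, A / 2, "replisome_b")
            pair = (lo_pos, hi_pos)
        else:
            _emit(rows, f, "dnaN", pos, tr, A, "replisome")
            pair = None

        # SSB channel mirrors the active replisomes
        if "ssb" in params.channels:
            if pair is None:
                _emit(rows, f, "ssb", pos, tr, A, "ssb")
            elif truth.ssb_coloc_flag:
                _emit(rows, f, "ssb", pair[0], tr, A / 2, "ssb_a")
                _emit(rows, f, "ssb", pair[1], tr, A / 2, "ssb_b")
            else:
                _emit(rows, f, "ssb", pair[0], tr, A, "ssb")

    # dim residual-clamp signal (fast-segregation cells only)
    if truth.dim_signal_present:
        n_seg = max(1, int(round(truth.T_seg / dt)))
        dim_A0 = params.dim_intensity_frac * A
        for i in range(1, W):
            f = t_init + i
            t_since = i * dt
            amp = dim_A0 * math.exp(-(t_since - dt) / params.dim_decay_tau)
            if amp < MIN_EMITTER_AMP:
                break
            L = lengths[f]
            bright_pos = float(np.clip(bright_frac[i], 0.03, 0.97)) * L
            progress = min(1.0, i / n_seg)
            front_frac = BRIGHT_START_FRAC + (DIM_END_FRAC - BRIGHT_START_FRAC) * progress
            front_pos = front_frac * L
            if progress < 1.0 and params.streak_mode:
                # travelling: streak of sub-emitters trailing from the bright focus
                for k in range(1, N_STREAK_SUB + 1):
                    frac_k = k / N_STREAK_SUB
                    p_k = bright_pos + (front_pos - bright_pos) * frac_k
                    _emit(rows, f, "dnaN", p_k, 0.0, amp / N_STREAK_SUB, f"streak{k}")
            else:
                _emit(rows, f, "dnaN", front_pos, float(rng.normal(0, 0.03)), amp, "dim")

    # ParB channel: one focus stays at the old pole, the sister migrates
    if "parB" in params.channels:
        n_seg = max(1, int(round(truth.T_seg / dt)))
        for f in range(T):
            L = lengths[f]
            _emit(rows, f, "parB", PARB_OLD_FRAC * L, 0.0, PARB_AMP_FACTOR * A, "parB_old")
            if f >= t_init:
                prog = min(1.0, (f - t_init) / n_seg)
                frac = PARB_OLD_FRAC + (PARB_NEW_FRAC - PARB_OLD_FRAC) * prog
                _emit(rows, f, "parB", frac * L, 0.0, PARB_AMP_FACTOR * A, "parB_mig")

    emitters = pd.DataFrame(rows, columns=["frame", "channel", "axial_um",
                                           "trans_um", "amplitude", "label"])
    truth.emitters = emitters

    constr = np.full(T, np.nan)
    for f in range(T):
        if tau(f) >= 0.7:
            constr[f] = params.division_site_frac * lengths[f]
    cell = _build_geometry(cell_id, lengths, flipped, constr, params)
    if render:
        cell.images = render_frames(emitters, cell, params, rng)
    return cell, truth


def _simulate_fast_frame(params: ScenarioParams, rng: np.random.Generator,
                         cell_id: str, render: bool = True) -> tuple[CellSeries, GroundTruth]:
    """A late-splitting episode imaged at high frame rate (step-size assay).

    The series is a short crop of a pre-divisional cell: one focus confined at
    the constriction site, the sister still approaching, both performing 2D
    random walks whose mean per-interval displacement is the preset
    confined/free step.
    """
    dt = params.frame_interval
    T = params.n_frames_fast
    L0 = _trunc_normal(rng, 3.8, 0.2, 3.0)
    times = np.arange(T) * dt
    lengths = L0 * np.exp(params.growth_rate_alpha * times)
    flipped = bool(rng.random() < 0.5)

    site = params.division_site_frac * L0
    away_center = site - 1.2

    # isotropic 2D Gaussian steps: mean |step| = sd * sqrt(pi/2)
    sd_conf = params.confined_step_mean / math.sqrt(math.pi / 2) / 1000.0  # µm
    sd_free = params.free_step_mean / math.sqrt(math.pi / 2) / 1000.0

    conf = np.empty((T, 2))
    free = np.empty((T, 2))
    conf[0] = (site, 0.0)
    free[0] = (away_center, 0.0)
    conf[1:] = conf[0] + np.cumsum(rng.normal(0.0, sd_conf, (T - 1, 2)), axis=0)
    free[1:] = free[0] + np.cumsum(rng.normal(0.0, sd_free, (T - 1, 2)), axis=0)

    rows: list[dict] = []
    A = params.bright_amplitude / 2
    for f in range(T):
        _emit(rows, f, "dnaN", float(conf[f, 0]), float(conf[f, 1]), A, "site")
        _emit(rows, f, "dnaN", float(free[f, 0]), float(free[f, 1]), A, "away")
    emitters = pd.DataFrame(rows, columns=["frame", "channel", "axial_um",
                                           "trans_um", "amplitude", "label"])

    truth = GroundTruth(cell_id=cell_id, t_init=0, t_end=T - 1,
                        alpha=params.growth_rate_alpha,
                        late_split_flag=True,
                        division_site_um=site)
    truth.emitters = emitters

    constr = np.full(T, site)
    cell = _build_geometry(cell_id, lengths, flipped, constr, params)
    if render:
        cell.images = render_frames(emitters, cell, params, rng)
    return cell, truth


def replication_time_to(position_mb: float, arm_speed) -> float:
    """Minutes for a fork to reach |position_mb| on a piecewise-constant
    speed profile ``((until_mb, bp_per_min), ...)``."""
    pos = abs(position_mb)
    t = 0.0
    prev = 0.0
    for until, speed in arm_speed:
        seg = min(pos, until) - prev
        if seg <= 0:
            break
        t += seg * 1e6 / speed
        prev = min(pos, until)
        if prev >= pos:
            break
    if prev < pos:  # beyond the last segment: extend it
        t += (pos - prev) * 1e6 / arm_speed[-1][1]
    return t


def _simulate_locus(params: ScenarioParams, rng: np.random.Generator,
                    cell_id: str, render: bool = True) -> tuple[CellSeries, GroundTruth]:
    """FROS / orthogonal-ParB locus strain: one labelled genomic locus whose
    focus duplicates when the fork passes it; cell length at duplication is
    the age proxy used by the replication-speed estimator."""
    dt = params.frame_interval
    pos_mb = params.locus_position_mb
    assert pos_mb is not None
    arm = params.left_arm_speed if pos_mb < 0 else params.right_arm_speed
    t_split = replication_time_to(pos_mb, arm) + rng.normal(0.0, params.locus_split_sd)
    t_split = max(t_split, 2 * dt)

    margin = params.margin_frames
    f_split = margin + int(round(t_split / dt))
    T = f_split + 8
    L0 = _trunc_normal(rng, params.birth_length_mean, params.birth_length_sd, 1.2)
    times = np.arange(T) * dt
    lengths = L0 * np.exp(params.growth_rate_alpha * times)
    flipped = bool(rng.random() < 0.5)

    detected = rng.random() < params.locus_detect_p

    rows: list[dict] = []
    A = params.bright_amplitude
    for f in range(T):
        L = lengths[f]
        base = LOCUS_FRAC * L
        if detected and f >= f_split:
            k = f - f_split
            sep = min(0.33 + 0.17 * k, 0.8)   # µm, ramps up then saturates
            _emit(rows, f, "locus", max(0.05 * L, base - sep / 2), 0.0, A / 2, "locus_a")
            _emit(rows, f, "locus", min(0.95 * L, base + sep / 2), 0.0, A / 2, "locus_b")
        else:
            _emit(rows, f, "locus", base, 0.0, A, "locus")
    emitters = pd.DataFrame(rows, columns=["frame", "channel", "axial_um",
                                           "trans_um", "amplitude", "label"])

    truth = GroundTruth(cell_id=cell_id, t_init=margin, t_end=T - 1,
                        alpha=params.growth_rate_alpha)
    truth.emitters = emitters
    truth.locus_duplication_length = float(lengths[f_split])
    truth.locus_split_frame = f_split if detected else -1

    constr = np.full(T, np.nan)
    cell = _build_geometry(cell_id, lengths, flipped, constr, params)
    if render:
        cell.images = render_frames(emitters, cell, params, rng)
    return cell, truth


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_cell(params: ScenarioParams, rng_seed: int,
                  cell_id: str | None = None,
                  render: bool = True) -> tuple[CellSeries, GroundTruth]:
    """Simulate one cell: emitter trajectories, ground truth and rendered images.

    Deterministic for a given ``(params, rng_seed)``.  With ``render=False``
    the image stacks are skipped (truth-level studies run much faster).
    """
    params.validate()
    rng = np.random.default_rng(rng_seed)
    if cell_id is None:
        cell_id = f"{params.name.replace(':', '_')}_{rng_seed}"
    if params.fast_frame:
        return _simulate_fast_frame(params, rng, cell_id, render)
    if params.locus_position_mb is not None:
        return _simulate_locus(params, rng, cell_id, render)
    return _simulate_standard(params, rng, cell_id, render)


def iter_population(params: ScenarioParams, n_cells: int, rng_seed: int,
                    render: bool = True):
    """Yield ``(CellSeries, GroundTruth)`` pairs, one per cell.

    Per-cell streams are spawned from ``rng_seed`` so the population is
    reproducible bit-for-bit and independent of iteration order.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    children = np.random.SeedSequence(rng_seed).spawn(n_cells)
    for i, child in enumerate(children):
        seed = int(child.generate_state(1)[0] % (2**31))
        yield simulate_cell(params, seed,
                            cell_id=f"{params.name.replace(':', '_')}_{i:04d}",
                            render=render)


def simulate_population(params: ScenarioParams, n_cells: int, rng_seed: int,
                        render: bool = True) -> list[tuple[CellSeries, GroundTruth]]:
    """Materialized version of :func:`iter_population` (small populations)."""
    return list(iter_population(params, n_cells, rng_seed, render))
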