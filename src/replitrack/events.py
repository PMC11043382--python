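"""Classification of per-frame focus patterns and per-cell splitting events.

Frames are partitioned by the number of accepted replisome foci and, when
two are present, by the ratio of their integrated intensities: with the
ratio threshold 1.5, a bright/dim pair (ratio > 1.5, "dissimilar")
corresponds to residual clamp signal left behind by fast DNA segregation,
whereas two similar foci (ratio <= 1.5) correspond to genuinely decoupled
sister replisomes.

Per-cell detectors build on those frame patterns:

* early splitting — a dim secondary signal in the first half of replication
  (a dissimilar frame, or a sub-threshold streak towards the new pole);
* late splitting — a run of similar two-foci frames after mid-replication
  that merges back before the replisome disassembles;
* segregation time — replication initiation to the ParB focus completing
  its migration to the new pole;
* colocalization, nearest-neighbour track linking and step sizes for the
  fast-frame mobility measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeline import ReplicationWindow, normalize_time

__all__ = [
    "FramePattern", "SplitEvent", "SegregationRecord",
    "classify_frame", "frame_patterns",
    "detect_early_splitting", "detect_late_splitting",
    "similar_foci_duration", "segregation_time",
    "colocalize", "conditional_coloc_fraction",
    "link_tracks", "step_sizes",
    "two_foci_frequency", "two_bright_early_flag", "any_two_foci_flag",
]

RATIO_THRESHOLD = 1.5
TAU_BOUNDARY = 0.5          # early/late boundary in normalized time
K_STREAK = 1.5              # streak detector: band intensity vs background
D_MIN_PX = 5                # streak detector: min axial distance from bright focus
ARRIVAL_FRAC = 0.1          # ParB arrival: within this fraction of length of new pole
D_MAX_COLOC_NM = 250.0
MAX_LINK_NM = 500.0
W_DIV_NM = 400.0            # at-division-site classification half-width


@dataclass
class FramePattern:
    cell_id: str
    frame: int
    tau: float
    n_foci: int
    ratio: float                # >= 1 when defined, NaN otherwise
    similarity_class: str       # none | single | similar | dissimilar


@dataclass
class SplitEvent:
    cell_id: str
    kind: str                   # early | late
    onset_frame: int
    onset_tau: float
    duration: float             # min
    rel_duration: float         # fraction of the replication window
    first_onset_tau: float = float("nan")   # onset of the first qualifying run
    merged: bool = True         # late events: run ended before disassembly


@dataclass
class SegregationRecord:
    cell_id: str
    T_seg: float                # min
    dim_class: str              # with_dim | without_dim


# ---------------------------------------------------------------------------
# frame patterns
# ---------------------------------------------------------------------------

def classify_frame(intensities, cell_id: str, frame: int,
                   window: ReplicationWindow,
                   ratio_threshold: float = RATIO_THRESHOLD) -> FramePattern:
    """Classify one frame from the integrated intensities of its accepted foci."""
    tau = normalize_time(frame, window)
    vals = [float(v) for v in intensities]
    n = len(vals)
    if n == 0:
        return FramePattern(cell_id, frame, tau, 0, float("nan"), "none")
    if n == 1:
        return FramePattern(cell_id, frame, tau, 1, float("nan"), "single")
    if n > 2:
        raise ValueError(f"at most 2 accepted foci expected per frame, got {n}")
    ratio = max(vals) / min(vals)
    cls = "similar" if ratio <= ratio_threshold else "dissimilar"
    return FramePattern(cell_id, frame, tau, 2, ratio, cls)


def frame_patterns(foci: pd.DataFrame, window: ReplicationWindow,
                   ratio_threshold: float = RATIO_THRESHOLD) -> pd.DataFrame:
    """Per-frame patterns for one cell over its replication window."""
    acc = foci[foci["accepted"]]
    cell_id = str(foci["cell_id"].iloc[0]) if len(foci) else ""
    by_frame = {f: g["integrated_intensity"].tolist() for f, g in acc.groupby("frame")}
    rows = []
    for f in range(window.init_frame, window.end_frame + 1):
        p = classify_frame(by_frame.get(f, []), cell_id, f, window, ratio_threshold)
        rows.append(p.__dict__)
    return pd.DataFrame(rows, columns=["cell_id", "frame", "tau", "n_foci",
                                       "ratio", "similarity_class"])


# ---------------------------------------------------------------------------
# early splitting
# ---------------------------------------------------------------------------

def _streak_frames(cell, foci: pd.DataFrame, window: ReplicationWindow,
                   channel: str, k_streak: float, d_min_px: int) -> np.ndarray:
    """Frames with sub-threshold streak signal towards the new pole.

    A frame qualifies when the intensity in a narrow band along the axis,
    at least ``d_min_px`` on the new-pole side of the brightest focus,
    reaches ``k_streak`` times the background.
    """
    from scipy import ndimage

    acc = foci[foci["accepted"]]
    stack = cell.images[channel]
    px_per_um = 1000.0 / cell.pixel_size
    hits = []
    for f in range(window.init_frame, window.end_frame + 1):
        g = acc[acc["frame"] == f]
        if len(g) != 1:
            continue
        bright_ax_px = float(g["axial_um"].iloc[0]) * px_per_um
        img = stack[f].astype(float)
        bg = float(np.median(img))
        if bg <= 0:
            continue
        sm = ndimage.uniform_filter(img, size=3, mode="nearest")
        yc = int(round(cell.old_pole_px[f][1]))
        band = sm[max(0, yc - 2): yc + 3, :]   # 5-px band around the axis
        prof = band.max(axis=0)
        # orient the profile old pole -> new pole
        old_x = cell.old_pole_px[f][0]
        new_x = cell.new_pole_px[f][0]
        L_px = abs(new_x - old_x)
        direction = 1 if new_x >= old_x else -1
        idx0 = int(round(old_x))
        bins = np.arange(int(L_px) + 1)
        cols = idx0 + direction * bins
        valid = (cols >= 0) & (cols < prof.shape[0])
        axial_prof = prof[cols[valid]]
        axial_bins = bins[valid]
        distal = axial_bins >= bright_ax_px + d_min_px
        if np.any(axial_prof[distal] >= k_streak * bg):
            hits.append(f)
    return np.asarray(hits, dtype=int)


def detect_early_splitting(patterns: pd.DataFrame, window: ReplicationWindow,
                           frame_interval: float, cell=None,
                           foci: pd.DataFrame | None = None,
                           channel: str = "dnaN",
                           tau_boundary: float = TAU_BOUNDARY,
                           k_streak: float = K_STREAK,
                           d_min_px: int = D_MIN_PX) -> SplitEvent | None:
    """Detect an early-splitting (dim secondary signal) episode.

    Fires when, at normalized time in (0, ``tau_boundary``], either a
    dissimilar two-foci frame occurs, or — when ``cell`` and ``foci`` are
    supplied — a streak towards the new pole is present for at least two
    consecutive frames.  Onset is the first qualifying frame.
    """
    early = patterns[(patterns["tau"] > 0) & (patterns["tau"] <= tau_boundary)]
    dissim = early[early["similarity_class"] == "dissimilar"]
    qual_frames = set(dissim["frame"].tolist())

    if cell is not None and foci is not None:
        sf = _streak_frames(cell, foci, window, channel, k_streak, d_min_px)
        tau_sf = normalize_time(sf, window) if len(sf) else np.array([])
        sf = sf[(tau_sf > 0) & (tau_sf <= tau_boundary)]
        # streak route requires >= 2 consecutive frames
        for i in range(len(sf) - 1):
            if sf[i + 1] == sf[i] + 1:
                qual_frames.update((int(sf[i]), int(sf[i + 1])))

    if not qual_frames:
        return None
    onset = min(qual_frames)
    cell_id = str(patterns["cell_id"].iloc[0]) if len(patterns) else ""
    duration = len(qual_frames) * frame_interval
    return SplitEvent(
        cell_id=cell_id, kind="early", onset_frame=int(onset),
        onset_tau=float(normalize_time(onset, window)),
        duration=float(duration),
        rel_duration=float(len(qual_frames) / window.n_frames),
    )


# ---------------------------------------------------------------------------
# late splitting
# ---------------------------------------------------------------------------

def _similar_runs(patterns: pd.DataFrame) -> list[np.ndarray]:
    sim_frames = np.sort(patterns.loc[patterns["similarity_class"] == "similar",
                                      "frame"].to_numpy())
    if len(sim_frames) == 0:
        return []
    breaks = np.nonzero(np.diff(sim_frames) > 1)[0]
    return np.split(sim_frames, breaks + 1)


def detect_late_splitting(patterns: pd.DataFrame, window: ReplicationWindow,
                          frame_interval: float,
                          tau_boundary: float = TAU_BOUNDARY) -> SplitEvent | None:
    """Detect a late-splitting episode: two similar foci that merge again.

    The event is the longest run of >= 2 consecutive similar two-foci frames
    whose onset is after ``tau_boundary``; runs still open at the window end
    are kept but flagged unmerged (``merged=False``).  ``first_onset_tau``
    records the onset of the first qualifying run (the first-occurrence
    statistic).
    """
    runs = [
        r for r in _similar_runs(patterns)
        if len(r) >= 2 and normalize_time(int(r[0]), window) > tau_boundary
    ]
    if not runs:
        return None
    best = max(runs, key=len)
    first = runs[0]
    cell_id = str(patterns["cell_id"].iloc[0]) if len(patterns) else ""
    return SplitEvent(
        cell_id=cell_id, kind="late", onset_frame=int(best[0]),
        onset_tau=float(normalize_time(int(best[0]), window)),
        duration=float(len(best) * frame_interval),
        rel_duration=float(len(best) / window.n_frames),
        first_onset_tau=float(normalize_time(int(first[0]), window)),
        merged=bool(best[-1] < window.end_frame),
    )


def similar_foci_duration(patterns: pd.DataFrame, window: ReplicationWindow) -> float:
    """Fraction of the replication window spent with two similar foci."""
    n_sim = int((patterns["similarity_class"] == "similar").sum())
    return n_sim / window.n_frames


# ---------------------------------------------------------------------------
# segregation timing
# ---------------------------------------------------------------------------

def segregation_time(window: ReplicationWindow, parb_foci: pd.DataFrame, cell,
                     dim_class: str, arrival_frac: float = ARRIVAL_FRAC,
                     sustain: int = 2) -> SegregationRecord | None:
    """ParB segregation time for one cell.

    The clock starts at replication initiation (window start) and stops at
    the first frame where a ParB focus lies within ``arrival_frac`` of the
    cell length of the new pole and stays there for ``sustain`` consecutive
    frames.  Returns ``None`` (unresolved) when the ParB focus never
    arrives.
    """
    acc = parb_foci[parb_foci["accepted"]]
    arrived = np.zeros(cell.n_frames, dtype=bool)
    for f, g in acc.groupby("frame"):
        L = cell.lengths_um[f]
        if np.any(g["axial_um"].to_numpy() >= (1.0 - arrival_frac) * L):
            arrived[f] = True
    for f in range(window.init_frame, cell.n_frames - sustain + 1):
        if arrived[f:f + sustain].all():
            T = (f - window.init_frame) * cell.frame_interval
            return SegregationRecord(cell.cell_id, float(T), dim_class)
    return None


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def colocalize(foci_a: pd.DataFrame, foci_b: pd.DataFrame, pixel_size: float,
               d_max_nm: float = D_MAX_COLOC_NM) -> list[tuple[int, int]]:
    """Greedy nearest-neighbour matching of two single-frame foci lists.

    Returns index pairs (row position in ``foci_a``, row position in
    ``foci_b``) with center distance <= ``d_max_nm``; each focus is used at
    most once, closest pairs first.
    """
    if len(foci_a) == 0 or len(foci_b) == 0:
        return []
    pa = foci_a[["x_px", "y_px"]].to_numpy() * pixel_size
    pb = foci_b[["x_px", "y_px"]].to_numpy() * pixel_size
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    pairs = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if d[i, j] > d_max_nm:
            break
        if i not in used_a and j not in used_b:
            pairs.append((int(i), int(j)))
            used_a.add(int(i))
            used_b.add(int(j))
    return pairs


def conditional_coloc_fraction(foci_a: pd.DataFrame, foci_b: pd.DataFrame,
                               patterns_a: pd.DataFrame, pixel_size: float,
                               d_max_nm: float = D_MAX_COLOC_NM) -> tuple[float, int]:
    """Per-cell conditional colocalization of channel B with two bright A foci.

    Over cells that have at least one frame with two similar-intensity
    (bright) A foci, a cell counts as colocalized when any such frame also
    shows two B foci, each matched to a distinct A focus within
    ``d_max_nm``.  Returns ``(fraction, n_qualifying_cells)``; the fraction
    is NaN when no cell qualifies.
    """
    acc_a = foci_a[foci_a["accepted"]]
    acc_b = foci_b[foci_b["accepted"]]
    frac_hits = 0
    n_cells = 0
    for cell_id, pat in patterns_a.groupby("cell_id"):
        qual = pat[(pat["n_foci"] == 2) & (pat["similarity_class"] == "similar")]
        if len(qual) == 0:
            continue
        n_cells += 1
        hit = False
        ga = acc_a[acc_a["cell_id"] == cell_id]
        gb = acc_b[acc_b["cell_id"] == cell_id]
        for f in qual["frame"]:
            fa = ga[ga["frame"] == f]
            fb = gb[gb["frame"] == f]
            if len(fa) == 2 and len(fb) >= 2:
                if len(colocalize(fa, fb, pixel_size, d_max_nm)) == 2:
                    hit = True
                    break
        frac_hits += int(hit)
    if n_cells == 0:
        return float("nan"), 0
    return frac_hits / n_cells, n_cells


# ---------------------------------------------------------------------------
# tracking and step sizes
# ---------------------------------------------------------------------------

def link_tracks(foci: pd.DataFrame, pixel_size: float,
                max_link_nm: float = MAX_LINK_NM) -> pd.DataFrame:
    """Link accepted foci across frames into tracks (greedy nearest
    neighbour under ``max_link_nm``).  A focus with no match starts a new
    track, so a broken link splits a track into two.

    Returns a copy of the accepted rows with a ``track_id`` column.
    """
    acc = foci[foci["accepted"]].copy().sort_values("frame").reset_index(drop=True)
    track_ids = np.full(len(acc), -1, dtype=int)
    next_id = 0
    prev_idx: list[int] = []
    prev_frame = None
    for frame, g in acc.groupby("frame"):
        cur_idx = list(g.index)
        if prev_frame is not None and frame == prev_frame + 1 and prev_idx:
            pa = acc.loc[prev_idx, ["x_px", "y_px"]].to_numpy() * pixel_size
            pb = acc.loc[cur_idx, ["x_px", "y_px"]].to_numpy() * pixel_size
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            used_a: set[int] = set()
            used_b: set[int] = set()
            for i, j in order:
                if d[i, j] > max_link_nm:
                    break
                if i not in used_a and j not in used_b:
                    track_ids[cur_idx[j]] = track_ids[prev_idx[i]]
                    used_a.add(int(i))
                    used_b.add(int(j))
        for j in cur_idx:
            if track_ids[j] < 0:
                track_ids[j] = next_id
                next_id += 1
        prev_idx = cur_idx
        prev_frame = frame
    acc["track_id"] = track_ids
    return acc


def step_sizes(tracked: pd.DataFrame, cell, w_div_nm: float = W_DIV_NM) -> pd.DataFrame:
    """Per-interval displacements (nm) with division-site classification.

    Each consecutive-frame pair within a track contributes one step; the
    step is classified ``at_division_site`` when the starting focus lies
    within ``w_div_nm`` (axially) of the constriction position recorded for
    that frame, else ``away``.
    """
    rows = []
    for tid, g in tracked.groupby("track_id"):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        xy = g[["x_px", "y_px"]].to_numpy() * cell.pixel_size
        ax = g["axial_um"].to_numpy()
        for k in range(len(g) - 1):
            if frames[k + 1] != frames[k] + 1:
                continue
            step = float(np.linalg.norm(xy[k + 1] - xy[k]))
            constr = cell.constriction_um[frames[k]]
            if np.isfinite(constr) and abs(ax[k] - constr) * 1000.0 <= w_div_nm:
                loc = "at_division_site"
            else:
                loc = "away"
            rows.append(dict(cell_id=cell.cell_id, track_id=int(tid),
                             frame=int(frames[k]), step_nm=step,
                             location_class=loc))
    return pd.DataFrame(rows, columns=["cell_id", "track_id", "frame",
                                       "step_nm", "location_class"])


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

def two_foci_frequency(patterns: pd.DataFrame, bin_width: float = 0.1) -> pd.DataFrame:
    """Fraction of cells showing two foci per normalized-time bin.

    For each bin center, each cell contributes its frame with tau nearest
    the center; the fraction of those frames with two foci is reported,
    stratified by similarity class.
    """
    if patterns["cell_id"].nunique() < 1:
        raise ValueError("at least one cell required")
    centers = np.arange(bin_width / 2, 1.0, bin_width)
    rows = []
    per_cell = list(patterns.groupby("cell_id"))
    for c in centers:
        n_two = n_sim = n_dis = 0
        for _, pat in per_cell:
            idx = (pat["tau"] - c).abs().idxmin()
            row = pat.loc[idx]
            if row["n_foci"] == 2:
                n_two += 1
                if row["similarity_class"] == "similar":
                    n_sim += 1
                else:
                    n_dis += 1
        n = len(per_cell)
        rows.append(dict(tau_bin=float(c), frac_two=n_two / n,
                         frac_similar=n_sim / n, frac_dissimilar=n_dis / n))
    return pd.DataFrame(rows)


def two_bright_early_flag(patterns: pd.DataFrame,
                          tau_boundary: float = TAU_BOUNDARY) -> bool:
    """True when the cell shows two similar foci in the first half of replication."""
    early = patterns[patterns["tau"] <= tau_boundary]
    return bool((early["similarity_class"] == "similar").any())


def any_two_foci_flag(patterns: pd.DataFrame) -> bool:
    """True when the cell shows two accepted foci at any replication time."""
    return bool((patterns["n_foci"] == 2).any())
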