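"""Replication windows, normalized replication time, kymographs, demographs.

The replication window of a cell spans the first to the last frame with an
accepted replisome focus.  Normalized replication time tau maps the frame
before the focus appears to 0 and the frame after it disassembles to 1, so
cells with different replication durations can be pooled on a common axis.

Kymographs stack each frame's axial intensity profile (old pole first) and
are rescaled per cell to the full 8-bit range (0–255).  Demographs stack one
axial profile per cell, sampled at the frame whose tau is nearest a target,
and order the rows by cell length at replication initiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReplicationWindow",
    "detect_replication_window",
    "normalize_time",
    "axial_profile",
    "build_kymograph",
    "build_demograph",
]


@dataclass(frozen=True)
class ReplicationWindow:
    """Frames bounding active replication for one cell."""

    init_frame: int
    end_frame: int
    gap_frames: int = 1

    def __post_init__(self):
        if self.init_frame > self.end_frame:
            raise ValueError("init_frame must be <= end_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.init_frame + 1


def detect_replication_window(foci: pd.DataFrame, gap_frames: int = 1) -> ReplicationWindow | None:
    """Find the replication window from one cell's foci table.

    Frames with at least one accepted focus are grouped into runs; gaps of at
    most ``gap_frames`` (transient fit failures) are bridged.  If a longer
    gap splits the series, the longest run is kept with a warning.  Returns
    ``None`` when the cell has no accepted focus (excluded downstream).
    """
    frames = np.sort(foci.loc[foci["accepted"], "frame"].unique())
    if len(frames) == 0:
        return None
    # split where consecutive focus frames differ by more than gap_frames + 1
    breaks = np.nonzero(np.diff(frames) > gap_frames + 1)[0]
    runs = np.split(frames, breaks + 1)
    if len(runs) > 1:
        warnings.warn(
            f"focus frames split into {len(runs)} runs by a gap longer than "
            f"{gap_frames}; keeping the longest window", stacklevel=2)
    best = max(runs, key=lambda r: r[-1] - r[0])
    return ReplicationWindow(int(best[0]), int(best[-1]), gap_frames)


def normalize_time(frame, window: ReplicationWindow) -> float | np.ndarray:
    """Normalized replication time: 0 at ``init_frame - 1``, 1 at ``end_frame + 1``.

    Values outside the window are clipped to [0, 1].  Accepts scalars or
    arrays of frames.
    """
    start = window.init_frame - 1
    span = (window.end_frame + 1) - start
    tau = (np.asarray(frame, dtype=float) - start) / span
    tau = np.clip(tau, 0.0, 1.0)
    return float(tau) if np.isscalar(frame) else tau


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def axial_profile(cell, frame: int, channel: str, subtract_background: bool = True) -> np.ndarray:
    """Width-integrated intensity along the cell axis, old pole first.

    One bin per pixel of cell length; intensity is summed across the cell
    width (the rows covered by the cell body).  Background (the image
    median) is subtracted first, clipping at zero.
    """
    img = cell.images[channel][frame].astype(float)
    if subtract_background:
        img = np.clip(img - np.median(img), 0.0, None)
    H, W = img.shape
    old = cell.old_pole_px[frame]
    new = cell.new_pole_px[frame]
    L_px = int(round(abs(new[0] - old[0])))
    yc = old[1]
    half_w = max(2, int(round(0.45 * 1000.0 / cell.pixel_size)))  # cell half-width, px
    y0, y1 = max(0, int(yc - half_w)), min(H, int(yc + half_w) + 1)
    direction = 1 if new[0] >= old[0] else -1
    prof = np.zeros(L_px + 1)
    for b in range(L_px + 1):
        x = int(round(old[0])) + direction * b
        if 0 <= x < W:
            prof[b] = img[y0:y1, x].sum()
    return prof


def build_kymograph(cell, channel: str) -> np.ndarray:
    """Per-cell kymograph: frames x axial bins, 8-bit normalized.

    Rows are frames; columns are 1-px axial bins with the old pole at bin 0
    (shorter, earlier frames are zero-padded on the right).  The whole matrix
    is min–max rescaled to integers 0–255; a constant matrix maps to 0.
    """
    if channel not in cell.images:
        raise KeyError(f"channel {channel!r} missing for cell {cell.cell_id}")
    profiles = [axial_profile(cell, f, channel) for f in range(cell.n_frames)]
    width = max(len(p) for p in profiles)
    mat = np.zeros((cell.n_frames, width))
    for i, p in enumerate(profiles):
        mat[i, :len(p)] = p
    lo, hi = mat.min(), mat.max()
    if hi > lo:
        mat = (mat - lo) / (hi - lo) * 255.0
    else:
        mat = np.zeros_like(mat)
    return np.round(mat).astype(np.uint8)


def build_demograph(cells, windows, channel: str, target_tau: float,
                    n_bins: int = 40) -> pd.DataFrame:
    """Population demograph at one normalized time point.

    For each cell, the axial profile at the frame whose tau is nearest
    ``target_tau`` is resampled onto a common ``n_bins`` grid (old pole
    left) and min–max rescaled to 0–255; rows are ordered by cell length at
    replication initiation (stable sort, so ties keep input order).

    Parameters
    ----------
    cells, windows
        Equal-length sequences of ``CellSeries`` and their
        ``ReplicationWindow`` (cells without a window must be excluded by
        the caller).

    Returns
    -------
    DataFrame with columns ``cell_id``, ``length_at_init`` and ``bin_0`` ..
    ``bin_{n_bins-1}``.
    """
    if len(cells) == 0:
        raise ValueError("empty population")
    if len(cells) != len(windows):
        raise ValueError("cells and windows must have equal length")
    rows = []
    for cell, win in zip(cells, windows):
        frames = np.arange(cell.n_frames)
        tau = normalize_time(frames, win)
        f = int(frames[np.argmin(np.abs(tau - target_tau))])
        prof = axial_profile(cell, f, channel)
        grid = np.linspace(0, len(prof) - 1, n_bins)
        resampled = np.interp(grid, np.arange(len(prof)), prof)
        lo, hi = resampled.min(), resampled.max()
        if hi > lo:
            resampled = (resampled - lo) / (hi - lo) * 255.0
        else:
            resampled = np.zeros_like(resampled)
        rows.append((cell.cell_id, float(cell.lengths_um[win.init_frame]), resampled))
    rows.sort(key=lambda r: r[1])  # Timsort: stable under ties
    out = pd.DataFrame(
        [dict(cell_id=cid, length_at_init=length,
              **{f"bin_{i}": v for i, v in enumerate(prof)})
         for cid, length, prof in rows]
    )
    return out
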