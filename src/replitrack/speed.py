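"""Replication-speed estimation from locus-duplication timing.

Cell length is used as a proxy for cell age under exponential length growth
L(t) = L(0) * exp(alpha * t).  If L' and L'' are the mean cell lengths at
duplication of two loci on the same chromosome arm, the time between the
two duplications is

    delta_t = ln(L'' / L') / alpha,

and the replication speed over that span is the genomic distance divided by
delta_t (bp/min).  Growth statistics from microplate curves use the standard
doubling time T_db = delta_T * ln2 / ln(OD2/OD1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LocusStats", "SpeedEstimate",
    "locus_split_frame", "estimate_alpha", "delta_t",
    "speed_between_loci", "doubling_time", "length_at_split",
    "compare_split_lengths",
]

D_SPLIT_NM = 300.0      # min separation for a duplication call
SPLIT_PERSIST = 2       # frames the separation must persist


@dataclass
class LocusStats:
    """Per-strain summary of locus-duplication observations."""

    strain: str
    genomic_position_mb: float          # signed: left arm negative
    mean_length_um: float               # mean cell length at duplication
    n_detected: int
    n_total: int

    @property
    def arm(self) -> str:
        return "left" if self.genomic_position_mb < 0 else "right"

    @property
    def detection_fraction(self) -> float:
        return self.n_detected / self.n_total if self.n_total else float("nan")


@dataclass
class SpeedEstimate:
    arm: str
    from_locus: str
    to_locus: str
    L_prime: float          # µm
    L_doubleprime: float    # µm
    alpha: float            # 1/min
    delta_t: float          # min
    speed: float            # bp/min (NaN when delta_t <= 0)


def locus_split_frame(foci: pd.DataFrame, pixel_size: float,
                      d_split_nm: float = D_SPLIT_NM,
                      persist: int = SPLIT_PERSIST) -> int | None:
    """First frame at which a labelled locus is visibly duplicated.

    The call requires two accepted foci separated by at least ``d_split_nm``
    in ``persist`` consecutive frames; a transient one-frame separation does
    not count.  Returns ``None`` when splitting is undetectable.
    """
    acc = foci[foci["accepted"]]
    sep_ok = {}
    for f, g in acc.groupby("frame"):
        if len(g) == 2:
            xy = g[["x_px", "y_px"]].to_numpy() * pixel_size
            sep_ok[int(f)] = float(np.linalg.norm(xy[0] - xy[1])) >= d_split_nm
    frames = sorted(sep_ok)
    for f in frames:
        if all(sep_ok.get(f + k, False) for k in range(persist)):
            return f
    return None


def length_at_split(foci: pd.DataFrame, cell, pixel_size: float | None = None,
                    d_split_nm: float = D_SPLIT_NM,
                    persist: int = SPLIT_PERSIST) -> float | None:
    """Cell length (µm) at the detected locus-duplication frame, or None."""
    ps = pixel_size if pixel_size is not None else cell.pixel_size
    f = locus_split_frame(foci, ps, d_split_nm, persist)
    if f is None:
        return None
    return float(cell.lengths_um[f])


def estimate_alpha(times_min, lengths_um) -> float:
    """Exponential growth rate (1/min): least-squares slope of ln(length) vs time."""
    t = np.asarray(times_min, dtype=float)
    L = np.asarray(lengths_um, dtype=float)
    if len(t) < 3:
        raise ValueError("at least 3 frames are required to estimate alpha")
    if np.any(L <= 0):
        raise ValueError("lengths must be positive")
    slope, _ = np.polyfit(t, np.log(L), 1)
    return float(slope)


def delta_t(L_prime: float, L_doubleprime: float, alpha: float) -> float:
    """Time (min) between two mean lengths under exponential growth.

    Negative when ``L_doubleprime < L_prime`` (returned with a warning).
    """
    if L_prime <= 0 or L_doubleprime <= 0:
        raise ValueError("lengths must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    dt = math.log(L_doubleprime / L_prime) / alpha
    if dt < 0:
        warnings.warn(f"negative delta_t ({dt:.2f} min): second locus "
                      "duplicated at a shorter mean length", stacklevel=2)
    return dt


def speed_between_loci(a: LocusStats, b: LocusStats, alpha: float) -> SpeedEstimate:
    """Replication speed (bp/min) between two loci on the same arm.

    ``b`` must be the more ter-proximal locus.  A non-positive delta_t gives
    an undefined (NaN) speed with a warning.
    """
    if a.arm != b.arm:
        raise ValueError("loci must lie on the same chromosome arm")
    if abs(b.genomic_position_mb) <= abs(a.genomic_position_mb):
        raise ValueError("second locus must be farther from ori than the first")
    dt = delta_t(a.mean_length_um, b.mean_length_um, alpha)
    dist_bp = (abs(b.genomic_position_mb) - abs(a.genomic_position_mb)) * 1e6
    if dt <= 0:
        warnings.warn("delta_t <= 0: replication speed undefined for "
                      f"{a.strain} -> {b.strain}", stacklevel=2)
        speed = float("nan")
    else:
        speed = dist_bp / dt
    return SpeedEstimate(arm=a.arm, from_locus=a.strain, to_locus=b.strain,
                         L_prime=a.mean_length_um, L_doubleprime=b.mean_length_um,
                         alpha=alpha, delta_t=dt, speed=speed)


def doubling_time(OD1: float, OD2: float, delta_T_min: float) -> float:
    """Population doubling time from two optical densities ``delta_T_min`` apart."""
    if not (OD2 > OD1 > 0):
        raise ValueError("require OD2 > OD1 > 0")
    if delta_T_min <= 0:
        raise ValueError("delta_T_min must be positive")
    return delta_T_min * math.log(2) / math.log(OD2 / OD1)


def compare_split_lengths(lengths_a, lengths_b) -> tuple[float, float]:
    """Two-tailed Welch t-test on lengths-at-duplication of two strains.

    Returns ``(t_statistic, p_value)``.
    """
    res = stats.ttest_ind(np.asarray(lengths_a, float),
                          np.asarray(lengths_b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)
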