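"""Scenario parameter sets for the synthetic-microscopy generator.

Each scenario describes one strain/imaging condition of a *Caulobacter
crescentus* replisome time-lapse experiment: exponential single-cell growth,
the timing statistics of replication and ParB-mediated origin segregation,
the prevalence of the two replisome-focus splitting phenotypes (an early dim
secondary signal left behind by fast DNA segregation, and a late transient
separation of the two active replisomes), and the optics used to render the
cells to images.

Probabilities and timing statistics in the presets are the population values
the analysis pipeline is expected to recover; see ``docs/methods.md`` for
their provenance and for every constant the presets add on top of them.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

__all__ = ["ScenarioParams", "get_scenario", "list_scenarios", "LOCUS_POSITIONS_MB"]

#: Genomic positions (Mb from ori; left arm negative, right arm positive) of
#: the fluorescently labelled loci used in the replication-speed experiments.
LOCUS_POSITIONS_MB = {
    "L2": -0.37, "R2": +0.43,
    "L3": -0.99, "R3": +0.98,
    "L4": -1.38, "R4": +1.38,
    "L5": -1.52, "R5": +1.52,
    "L6": -1.67, "R6": +1.69,
}

#: Position of the replication terminus on the right arm (Mb).
TER_POSITION_MB = 2.02


@dataclass
class ScenarioParams:
    """Full parameterization of one simulated condition.

    Times are minutes, lengths are µm unless a field name says otherwise
    (steps in nm, PSF width and pixel-scale quantities in px, pixel size
    in nm).  All probabilities are per cell.
    """

    name: str = "WT"

    # --- growth ---
    growth_rate_alpha: float = 0.006        # 1/min, exponential length growth
    birth_length_mean: float = 2.1          # µm
    birth_length_sd: float = 0.15

    # --- replication window ---
    rep_duration_mean: float = 111.0        # min (back-derived: 11.9 min / 0.107)
    rep_duration_sd: float = 10.0

    # --- segregation / dim residual-clamp signal ---
    p_fast_seg: float = 0.847               # fraction of cells in the fast class
    seg_time_fast_mean: float = 12.6
    seg_time_fast_sd: float = 4.4
    seg_time_slow_mean: float = 29.8
    seg_time_slow_sd: float = 8.1
    dim_intensity_frac: float = 0.4         # initial dim/bright amplitude ratio
    dim_decay_tau: float = 25.0             # min, residual signal decay constant

    # --- splitting phenotypes ---
    p_late_split: float = 0.38
    late_split_rel_duration: float = 0.107  # fraction of the replication window
    late_onset_tau_range: tuple[float, float] = (0.56, 0.90)  # onset sampling window
    p_two_bright_early: float = 0.069       # early decoupling into two bright foci
    two_bright_rel_duration: float = 0.13   # fraction of the replication window
    p_two_foci_any: float = 0.0             # brief two-foci episode at random time
    p_mispositioned_init: float = 0.0       # off-pole initiation (off by default)

    # --- focus mobility (fast-frame step-size experiments) ---
    confined_step_mean: float = 25.0        # nm per interval, at the division site
    free_step_mean: float = 45.0            # nm per interval, away from it
    division_site_frac: float = 0.55        # constriction position / cell length

    # --- imaging ---
    frame_interval: float = 2.0             # min
    pixel_size: float = 103.0               # nm
    psf_sigma: float = 1.3                  # px
    bright_amplitude: float = 300.0         # counts above background
    background_level: float = 100.0         # counts
    photon_scale: float = 1.0               # photons per count; 0 = noise-free
    channels: tuple[str, ...] = ("dnaN",)
    margin_frames: int = 3                  # frames rendered before/after the window
    streak_mode: bool = True                # render the travelling dim signal as a streak

    # --- dual-channel (SSB) condition ---
    p_ssb_coloc: float = 0.881              # P(two SSB foci | two bright DnaN foci)

    # --- fast-frame condition ---
    fast_frame: bool = False
    n_frames_fast: int = 40

    # --- genomic-locus (FROS / orthogonal ParB) condition ---
    locus_position_mb: float | None = None  # signed; None when not a locus scenario
    locus_detect_p: float = 0.9             # P(duplication resolvable as two foci)
    locus_split_sd: float = 3.0             # min, cell-to-cell spread of duplication time
    # piecewise-constant replication speed per arm: list of (until |Mb|, bp/min)
    left_arm_speed: tuple[tuple[float, float], ...] = ((2.02, 18200.0),)
    right_arm_speed: tuple[tuple[float, float], ...] = ((0.98, 22000.0), (2.02, 15500.0))

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        probs = {
            "p_fast_seg": self.p_fast_seg,
            "p_late_split": self.p_late_split,
            "p_two_bright_early": self.p_two_bright_early,
            "p_two_foci_any": self.p_two_foci_any,
            "p_mispositioned_init": self.p_mispositioned_init,
            "p_ssb_coloc": self.p_ssb_coloc,
            "locus_detect_p": self.locus_detect_p,
            "dim_intensity_frac": self.dim_intensity_frac,
        }
        for key, value in probs.items():
            if not (math.isfinite(value) and 0.0 <= value <= 1.0):
                raise ValueError(f"{key} must be a finite probability in [0, 1], got {value!r}")
        positive = {
            "growth_rate_alpha": self.growth_rate_alpha,
            "birth_length_mean": self.birth_length_mean,
            "rep_duration_mean": self.rep_duration_mean,
            "seg_time_fast_mean": self.seg_time_fast_mean,
            "seg_time_slow_mean": self.seg_time_slow_mean,
            "dim_decay_tau": self.dim_decay_tau,
            "frame_interval": self.frame_interval,
            "pixel_size": self.pixel_size,
            "psf_sigma": self.psf_sigma,
            "confined_step_mean": self.confined_step_mean,
            "free_step_mean": self.free_step_mean,
        }
        for key, value in positive.items():
            if not (math.isfinite(value) and value > 0.0):
                raise ValueError(f"{key} must be finite and > 0, got {value!r}")
        nonneg = {
            "birth_length_sd": self.birth_length_sd,
            "rep_duration_sd": self.rep_duration_sd,
            "seg_time_fast_sd": self.seg_time_fast_sd,
            "seg_time_slow_sd": self.seg_time_slow_sd,
            "bright_amplitude": self.bright_amplitude,
            "background_level": self.background_level,
            "photon_scale": self.photon_scale,
        }
        for key, value in nonneg.items():
            if not (math.isfinite(value) and value >= 0.0):
                raise ValueError(f"{key} must be finite and >= 0, got {value!r}")
        if not (0.0 < self.late_split_rel_duration < 1.0):
            raise ValueError("late_split_rel_duration must lie in (0, 1)")
        lo, hi = self.late_onset_tau_range
        if not (0.5 <= lo < hi <= 1.0):
            raise ValueError("late_onset_tau_range must satisfy 0.5 <= lo < hi <= 1.0")
        if self.locus_position_mb is not None:
            if abs(self.locus_position_mb) > TER_POSITION_MB:
                raise ValueError(
                    f"|locus_position_mb| must not exceed the ter position "
                    f"({TER_POSITION_MB} Mb), got {self.locus_position_mb}"
                )

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channels"] = list(self.channels)
        d["late_onset_tau_range"] = list(self.late_onset_tau_range)
        d["left_arm_speed"] = [list(seg) for seg in self.left_arm_speed]
        d["right_arm_speed"] = [list(seg) for seg in self.right_arm_speed]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioParams":
        d = dict(d)
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        if "late_onset_tau_range" in d:
            d["late_onset_tau_range"] = tuple(d["late_onset_tau_range"])
        for key in ("left_arm_speed", "right_arm_speed"):
            if key in d:
                d[key] = tuple(tuple(seg) for seg in d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _wt(**overrides) -> ScenarioParams:
    return ScenarioParams(**overrides)


_PRESETS = {
    # Wild type, dual-colour DnaN + ParB imaging every 2 min.
    "WT": dict(name="WT", channels=("dnaN", "parB")),
    # Segregation-deficient ParA mutant: no fast segregation, no dim signals,
    # a single replisome focus in all but ~0.8% of cells.
    "parAK20R": dict(
        name="parAK20R",
        channels=("dnaN",),
        p_fast_seg=0.0,
        p_late_split=0.0,
        p_two_bright_early=0.0,
        p_two_foci_any=0.008,
    ),
    # SMC knockout: reduced inter-arm alignment, frequent early decoupling
    # into two bright foci.
    "dsmc": dict(
        name="dsmc",
        channels=("dnaN",),
        p_two_bright_early=0.418,
        two_bright_rel_duration=0.094,
    ),
    # Partial chromosome inversion with an ectopic parS: decoupling in most
    # cells, and the split foci stay apart longer.
    "flip1_5": dict(
        name="flip1_5",
        channels=("dnaN",),
        p_two_bright_early=0.685,
        two_bright_rel_duration=0.233,
    ),
    # Extra rsaA copy moved ori-proximal on the right arm: late splitting in
    # most cells, with onset ~13.6% of replication time earlier than WT.
    "rsaA_plus": dict(
        name="rsaA_plus",
        channels=("dnaN",),
        p_late_split=0.75,
        late_onset_tau_range=(0.51, 0.68),
    ),
    # Dual-labelled DnaN + SSB strain for the colocalization measurement.
    "dual_channel": dict(
        name="dual_channel",
        channels=("dnaN", "ssb"),
    ),
    # 10-s frame interval acquisition of late-splitting pre-divisional cells
    # for the step-size measurement. Brighter excitation: short acquisitions
    # tolerate more light, and step sizes need nm-scale localization.
    "fast_frame": dict(
        name="fast_frame",
        channels=("dnaN",),
        fast_frame=True,
        frame_interval=10.0 / 60.0,
        bright_amplitude=800.0,
        photon_scale=2.0,
    ),
}


def list_scenarios() -> list[str]:
    """Names accepted by :func:`get_scenario` (locus strains via ``locus:<name>``)."""
    return sorted(_PRESETS) + [f"locus:{k}" for k in sorted(LOCUS_POSITIONS_MB)]


def get_scenario(name: str, **overrides) -> ScenarioParams:
    """Return the preset for ``name``, optionally overriding fields.

    ``name`` is one of the strain presets (``WT``, ``parAK20R``, ``dsmc``,
    ``flip1_5``, ``rsaA_plus``, ``dual_channel``, ``fast_frame``) or a locus
    strain ``locus:<L2..L6|R2..R6>``.
    """
    if name.startswith("locus:"):
        strain = name.split(":", 1)[1]
        if strain not in LOCUS_POSITIONS_MB:
            raise KeyError(f"unknown locus strain {strain!r}; choose from {sorted(LOCUS_POSITIONS_MB)}")
        base = dict(
            name=name,
            channels=("locus",),
            locus_position_mb=LOCUS_POSITIONS_MB[strain],
            p_late_split=0.0,
            p_two_bright_early=0.0,
        )
    elif name in _PRESETS:
        base = dict(_PRESETS[name])
    else:
        raise KeyError(f"unknown scenario {name!r}; choose from {list_scenarios()}")
    base.update(overrides)
    return ScenarioParams(**base)
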