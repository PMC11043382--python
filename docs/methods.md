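# Methods

## The generative model

One simulated cell is a straight rod of half-width 0.38 µm growing
exponentially, L(t) = L₀·e^(αt), with α = 0.006 /min (doubling time
≈ 115 min, a typical minimal-medium rate for *C. crescentus*) and birth
length L₀ ~ N(2.1, 0.15²) µm. A series covers one replication cycle plus a
3-frame margin on either side; division itself is not simulated because all
statistics the pipeline computes are per replication cycle. Replication
lasts D ~ N(111, 10²) min. The 111-min mean is back-derived from the pair
"late splitting lasts 11.9 min = 10.7% of replication"; it is a derived
default, not an independently known quantity.

Within the replication window the cell carries point emitters whose
trajectories are parameterized as fractions of the current cell length:

* **Bright replisome focus** (amplitude 300 counts): assembles at 0.13 L
  (the *ori* region near the old pole) and drifts linearly to the division
  site at 0.55 L (the stalked daughter is the longer one), with small
  positional jitter (σ = 0.01 L axially, 40 nm transversely).
* **Segregation class and dim signal.** A cell is in the fast-segregation
  class with probability `p_fast_seg`; its ParB segregation time is drawn
  from N(12.6, 4.4²) min (slow class: N(29.8, 8.1²)), truncated at two
  frame intervals. The generator's operational rule is
  *dim signal present ⇔ fast class*: this is the association the data
  establish, and it keeps the ground truth unambiguous. The dim emitter
  starts at 0.4× the bright amplitude and decays with τ = 25 min. The
  published per-clamp dissociation times (0.78–2.75 min in *E. coli*) apply
  to single clamps; the collective focus, continuously fed while forks run,
  persists for tens of minutes in kymographs, which 25 min reproduces.
  While travelling (linearly over T_seg to 0.85 L) the signal is rendered
  as a chain of four sub-emitters between the bright focus and the front —
  the streak appearance — and as a single compact focus after arrival.
* **Two-bright episodes.** Late splitting (probability `p_late_split`)
  replaces the bright focus by two emitters of half amplitude whose
  separation follows a trapezoid 0.45 → 0.85 → 0.45 µm over
  round(0.107·W) frames (W = window frames), with onset uniform over a
  configurable window (`late_onset_tau_range`, default τ ∈ [0.56, 0.90])
  and always merged ≥ 2 frames before the window end. The rsaA_plus preset
  narrows that window to [0.51, 0.68], which reproduces the reported
  ~13.6-point earlier mean onset; with the τ > 0.5 late-split definition, a
  mean shift of that size forces the onset distribution tight above
  mid-replication. Early two-bright episodes (probability
  `p_two_bright_early`, separation up to 1.0 µm) are placed entirely at
  τ ≤ 0.5. The 0.45 µm minimum separation is a resolvability choice: pairs
  below ~4 px cannot be fit as two clean Gaussians at this PSF, so the
  generator only produces "two foci" configurations a detector could in
  principle count. Episode relative durations are 0.13 (WT), 0.094
  (dsmc) and 0.233 (flip1_5), back-derived so the similar-foci time
  fraction reproduces the reported ~5% / ~8% / ~20% of replication.
* **ParB channel**: one focus fixed at 0.08 L, a sister migrating
  0.08 L → 0.92 L linearly over T_seg from initiation (amplitude 0.8× the
  bright focus).
* **SSB channel** (dual_channel preset): follows the bright replisome; when
  the DnaN channel shows a two-bright pair the SSB channel splits with the
  cell's colocalization flag (probability 0.881), otherwise it stays single
  — the SSB channel never mirrors the dim signal.
* **Locus strains**: a single labelled genomic position |p| Mb from *ori*;
  the duplication time is the fork travel time on a piecewise-constant
  speed profile (left arm 18.2 kb/min flat; right arm 22.0 kb/min to
  +0.98 Mb then 15.5 kb/min — a *ter*-proximal delay; both profiles total
  ≈ 111 min to *ter* at 2.02 Mb) plus N(0, 3²) min of cell-to-cell noise.
  With probability 0.9 the duplication is resolvable (separation ramping to
  0.8 µm); otherwise the focus never splits, mimicking the strains where
  splitting was undetectable.
* **Fast-frame preset** (10-s intervals, 40 frames): a cropped
  late-splitting episode with one focus random-walking at the constriction
  site and one 1.2 µm away; isotropic 2D Gaussian displacements with
  component σ = mean/√(π/2), so the mean Euclidean step equals the preset
  25 nm (confined) / 45 nm (free). The 45 nm free-step default is chosen to
  make the two distributions cleanly separable; only the 25 nm confined
  value is an externally reported number.

Rendering: each emitter is an isotropic Gaussian of σ = 1.3 px evaluated at
pixel centers on a uniform background of 100 counts (103 nm pixels); shot
noise is Poisson at `photon_scale` photons/count (1 by default, 0 =
noise-free). The fast-frame preset uses amplitude 800 and photon_scale 2:
brief acquisitions tolerate more excitation, and nm-scale step sizes
require the ~1–2 nm localization precision that budget provides, keeping
noise inflation of the 25 nm mean below 1%.

Seeding: a population spawns per-cell `SeedSequence` children, so results
are bit-for-bit reproducible and independent of iteration order.

## Detection and classification

Candidate seeds are local maxima exceeding the image median by 5 robust
(MAD-based) noise SDs — the conventional single-particle threshold; at 4 SD,
rare noise peaks survived the downstream filters (~1 per 500 cells) and
contaminated the sub-1% two-foci statistic of the segregation-deficient
scenario. Seeds within 14 px of each other are fit **jointly** as a sum of
elliptical Gaussians with a shared constant offset over the union of their
7×7 windows; single-spot fits of close pairs are biased (σ inflated by the
neighbour's flank), and joint fitting removes that bias exactly on noiseless
pairs. Non-converged or degenerate components are dropped; overlapping fits
(< 2 px) are merged keeping the brighter.

Acceptance filters: both σx and σy in [1, 3] px — the "or" in the width rule
is read as "both", which rejects streak-like elongated fits, consistent with
streaks being handled by a separate detector — and amplitude/offset ≥ 0.25
(a zero offset with positive amplitude passes). The rejection reason records
the first failed rule (width before SNR). At most the two brightest accepted
foci per frame and channel are kept (ties break towards the old pole);
accepted foci are projected onto the pole-to-pole axis and reported in µm
from the old pole.

Replication windows span the first to last accepted-focus frame, bridging
gaps ≤ 1 frame (transient fit failures should not split a cycle); a longer
gap keeps the longest run with a warning. Normalized time is
τ = (f − (init−1)) / ((end+1) − (init−1)), clipped to [0, 1].

Frame patterns use integrated intensity (amplitude·σx·σy) with ratio
threshold 1.5, boundary inclusive on the similar side. The early/late
boundary is τ = 0.5 (early events are described at 10–50% replication, late
at ~80–90%; 0.5 separates them cleanly and is config-exposed). The early
detector fires on any dissimilar frame at τ ∈ (0, 0.5], or on a streak —
band intensity ≥ 1.5× background at ≥ 5 px on the new-pole side of the
bright focus for ≥ 2 consecutive frames. The late detector takes the
longest run of ≥ 2 consecutive similar frames with onset τ > 0.5; runs
still open at the window end are flagged unmerged. Segregation time runs
from window start to the first of ≥ 2 consecutive frames with a ParB focus
within 0.1 L of the new pole ("full migration" is not quantified
externally; 0.1 L sustained 2 frames is the operational reading, and the
generator's 0.92 L endpoint makes the induced bias < 1 frame).
Colocalization is greedy nearest-neighbour matching under 250 nm; tracking
links accepted foci frame-to-frame under 500 nm (a broken link starts a new
track); steps are classified at-division-site within 400 nm (axially) of
the constriction.

Demographs sample each cell at the frame nearest the target τ (matching the
per-frame nature of montages), resample the width-integrated axial profile
onto a 40-bin grid, and sort rows stably by length at initiation.
Kymographs are per-cell min–max rescaled to 0–255 (8-bit) as the published
displays are; raw synthetic stacks are written as 16-bit TIFF.

## Numerical choices

Levenberg–Marquardt with analytic Jacobians, xtol = ftol = 1e-7 (recovery
on noiseless renders is exact to ≪ 0.1%); fit failures drop the candidate.
Bootstrap CIs: 1000 resamples, percentile method, seeded. Sub-threshold
emitters (< 5 counts) are not rendered. Degenerate kymograph normalization
(constant input) maps to zero.

## What the generator does and does not emulate

It reproduces the event structure (dim signals tied to fast segregation,
merging late-splitting runs, two-bright episodes), realistic SNR (~3 for
the bright focus), Poisson shot noise, pole-orientation randomization, and
frame-rate effects. It does **not** model curved (crescentoid) cell
geometry, photobleaching, background structure or autofluorescence
gradients, chromosome polymer physics, drift, segmentation error (outlines
are exact by construction), or division. Passing recovery tests therefore
demonstrates that the analysis chain is unbiased under these idealized but
noise-realistic conditions — not that it is robust to segmentation or focus
drift artefacts in real microscopy.

## Problem sizes

Unit tests run populations of 25–500 cells; the recovery suite uses 500
cells per scenario (400 for the dual-channel condition, 30 for fast-frame,
which already yields > 1000 steps). `scripts/acceptance.py` uses 1000
wild-type cells, 500 per alignment mutant, 2500 segregation-deficient cells
(the 0.8% two-foci rate needs the larger n for a stable estimate), 500
dual-channel cells and 35 fast-frame cells; the full run takes ~10 min on
one CPU. Stochastic recoveries are judged against 3σ binomial bands at the
simulated n, and timing quantities within one frame interval.

## Known limitations

* The early-splitting detector relies mainly on the dim signal's compact
  phase; the streak-phase detector contributes little at default SNR
  because streak sub-emitters fall below the band threshold. The reported
  dim-signal fractions are nevertheless recovered without bias because the
  compact phase lasts many frames.
* Two-foci separations below ~0.45 µm are neither generated nor reliably
  resolvable; real data presumably contain such sub-resolution splits, so
  absolute splitting fractions on real images would depend on the optics.
* The axial-profile machinery assumes the synthetic horizontal-rod
  geometry; `project_to_axis` is general (pole-to-pole projection), but
  `axial_profile` integrates image columns and would need a medial-axis
  walk for curved cells.
* Stalked-pole identity comes from simulator metadata; inferring it from
  daughter-cell asymmetry in real lineages is out of scope.
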