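# replitrack

Single-cell time-lapse analysis of bacterial replisome focus dynamics in
*Caulobacter crescentus*, bundled with a mechanistic synthetic-microscopy
generator so that every stage of the analysis can be exercised — and its
biases measured — without any real imaging data.

## The scientific problem

In *C. crescentus* the two sister replisomes assemble at the origin near the
old (stalked) cell pole and usually appear as a **single bright focus** of
the fluorescently tagged β-clamp (DnaN). Two deviations from that pattern
carry biological meaning:

* **Early splitting** — a dim secondary DnaN focus or streak extends towards
  the new pole soon after initiation. It is *not* a replisome: it is
  residual clamp left on newly replicated DNA that segregates to the new
  pole faster than the clamp can unload. Cells with a dim signal segregate
  their ParB/*parS* origin region in ~12.6 min versus ~29.8 min for cells
  without one.
* **Late splitting** — near the end of replication the two active replisomes
  transiently separate into two foci of *similar* intensity, then merge at
  the division site before disassembling. Its prevalence rises sharply when
  chromosome inter-arm alignment is disrupted (Δ*smc*, *flip1-5*).

The package implements the quantitative toolbox used for such data:

| stage | module | what it does |
|---|---|---|
| synthetic data | `replitrack.scenarios`, `replitrack.simulate`, `replitrack.render` | growing rod-shaped cells with replisome/ParB/SSB/locus emitters, rendered as Gaussian spots + Poisson noise, with full ground truth |
| spot detection | `replitrack.detect` | elliptical 2D Gaussian fits at intensity maxima; filters: both σ ∈ [1, 3] px and amplitude/offset ≥ 0.25; integrated intensity = amplitude·σx·σy; axial projection from the old pole |
| timeline | `replitrack.timeline` | replication windows, normalized time τ (0 = frame before the focus appears, 1 = frame after it disassembles), 8-bit kymographs, demographs ordered by length at initiation |
| events | `replitrack.events` | frame patterns at intensity-ratio threshold 1.5 (≤ 1.5 similar, > 1.5 dissimilar), early/late splitting detectors, ParB segregation times, colocalization, nearest-neighbour tracking and step sizes |
| replication speed | `replitrack.speed` | locus-duplication frames, cell length as an age proxy, Δt = ln(L″/L′)/α, inter-locus speeds in bp/min, doubling times |
| orchestration | `replitrack.pipeline`, `replitrack.cli`, `replitrack.fileio` | end-to-end seeded runs, CSV/TIFF/YAML/JSON formats, thin `replitrack` command-line tool |

Scenario presets (`WT`, `parAK20R`, `dsmc`, `flip1_5`, `rsaA_plus`,
`dual_channel`, `fast_frame`, `locus:L2..R6`) encode the published
population statistics, so recovering them through the full
simulate → render → detect → classify chain is a direct check that the
analysis is unbiased. See `docs/methods.md` for the model and every
parameter.

## Worked example

`examples/04_classify_events.py` runs 60 dual-colour (DnaN + ParB) wild-type
cells end to end:

```text
analyzed 60 cells
early-splitting fraction: 0.750
late-splitting fraction:  0.333
late-splitting duration:  12.0 min (95% CI 11.5-12.5)
similar-foci time:        0.053 of the replication window

ParB segregation time by dim-signal class:
  with dim signal:    13.6 +/- 4.4 min (n=45)
  without dim signal: 27.1 +/- 6.4 min (n=15)
```

Three quarters of the cells show the dim residual-clamp signal and a third
show a late-splitting episode lasting ~12 min (at n = 60 these scatter
around the preset values 0.847 and 0.38; at n = 500 they converge within
3σ binomial bands). The segregation-time split — fast segregation in cells
*with* a dim signal, slow in cells without — reproduces the mechanistic link
between segregation speed and residual clamp signal. The other example
scripts cover simulation/ground truth, focus detection, kymographs and
demographs, step-size tracking, and replication-speed estimation.

The same pipeline is available from the shell:

```sh
replitrack simulate --scenario WT --n 20 --seed 1 --outdir out/
replitrack detect --in out/ --channel dnaN
replitrack run --scenario dsmc --n 200 --seed 1 --outdir out_dsmc/
```

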