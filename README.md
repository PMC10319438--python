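# ddrdyn

Quantitative analysis of live-cell imaging of DNA damage response (DDR)
factors: single-particle tracking of HaloTag-labeled nuclear proteins,
two/three-state diffusion-model fitting of jump-length distributions,
residence-time survival analysis bounded by photobleaching, recruitment
kinetics at laser-microirradiation sites, and absolute protein abundance
from in-gel fluorescence. A synthetic-data module generates movies,
trajectories, recruitment series, and gel datasets with known ground truth,
so every stage of the pipeline is testable end to end.

Intended users: cell biologists and biophysicists running fast (≈100–200
fps) HILO single-molecule experiments on chromatin-interacting proteins,
and anyone who wants a transparent, scriptable re-implementation of the
standard analysis chain for such data.

## The models

**Diffusion states.** Each molecule is either chromatin-**bound**
(D_bound ∈ [0.0001, 0.5] µm²/s) or **free** (D_free ∈ [0.5, 25] µm²/s).
For a Brownian state, displacement magnitudes r over n frames follow

    p(r | n) = (r / 2a) · exp(−r² / 4a),   a = D·n·Δt + σ²,

with σ the static localization error. Histograms of jump lengths for lags
n = 1..7 (0.01 µm bins) are fit by bounded least squares with a mixture of
these densities to estimate D_free, D_bound, and the bound fraction
F_bound. Because free molecules diffuse out of the axial detection slice
(depth dZ = 0.7 µm), each state's weight at lag n is multiplied by a
defocus survival factor — the probability that a 1D Brownian particle
started uniformly in the slice is still inside at each sampled frame —
before per-lag renormalization. Without that correction F_bound is biased
upward. A three-state variant adds an intermediate coefficient D_free2 for
molecules moving inside phase-separated repair compartments, and
`split_by_mask` partitions trajectories by overlap with a repair-foci mask.

**Residence times.** Movies are block-averaged over 10 consecutive frames
(138 → 13.8 fps), which blurs out mobile molecules; low-mobility molecules
are then tracked with D_max = 0.5 µm²/s and no gap closing. Track-duration
survival curves S(τ) = 1 − CDF(τ) are fit with

    S(τ) = (1 − f)·2^(−(τ−τ₀)/t_fast) + f·2^(−(τ−τ₀)/t_slow),

and the photobleaching half-life — estimated from integrated nuclear
intensity decay of a chromatin-locked species — bounds what the slow
component can mean: durations, not true residence, once binding outlives
the dye.

**Recruitment kinetics.** Drift-corrected movies yield per-cell ROI
intensity curves, baseline-subtracted and normalized to each cell's
brightest frame; the cell average (renormalized to its brightest frame) is
fit with the one-phase association Y = 1 − exp(−K·t), t₁/₂ = ln2/K.

**Absolute abundance.** Lane fluorescence is calibrated against purified
labeled-tag standards (fmol) and cell-number standards; molecules per cell
= fmol × 10⁻¹⁵ × N_A / cells, corrected by a TEV cleavage factor (the free
tag runs brighter than the fusion) and a western factor (tagged vs untagged
expression), with uncertainties combined in quadrature.

## Worked example

The `demo` subcommand simulates data for all four pipelines and analyzes
it:

```bash
ddrdyn demo --seed 2 --out demo_out
```

prints (abridged):

```
diffusion.D_free=1.9473989417396376
diffusion.D_bound=0.009757409513268986
diffusion.F_bound=0.5227345522915936
residence.t_half_slow_s=3.669760442530978
residence.r_squared=0.9920671236495272
recruitment.t_half_s=22.592655478942284
abundance.mean_molecules_per_cell=50000.0
```

The simulation truth was D_free = 2.0 µm²/s, D_bound = 0.01 µm²/s,
F_bound = 0.5; the demo recovers 1.95 / 0.0098 / 0.52 from ~150,000 jumps.
The residence movie was generated with a 3.62 s bleach half-life and
effectively permanent binding, so the slow survival component (3.67 s)
reads back the bleaching limit, as it should. The recruitment series were
generated with t₁/₂ = 22.1 s (recovered 22.6 s), and the synthetic gel was
built from 50,000 molecules per cell (recovered exactly — the calibration
is a linear round trip).

Equivalent library calls live in `ddrdyn.simkit` (generation),
`ddrdyn.tracking`, `ddrdyn.diffusion`, `ddrdyn.residence`,
`ddrdyn.recruitment`, `ddrdyn.abundance` (analysis), and
`ddrdyn.workbench` (I/O, configs, pipeline drivers). `ddrdyn.studies`
holds the end-to-end validation studies.

## Scope

Inputs are multi-page TIFF movies (with plain-text calibration sidecars),
delimited-text trajectory tables, binary masks, and delimited lane tables.
Band densitometry, flow-cytometry gating, 3D localization, and
multi-emitter fitting are out of scope.
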