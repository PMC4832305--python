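# mttrack

Nanometre-precision tracking of dynamic microtubule ends in fluorescence
microscopy movies, plus a model-convolution simulator to characterize how
well the tracking can possibly work.

Microtubules are 25 nm-wide polymers of 8 nm tubulin subunits arranged in
13 protofilaments. In vitro TIRF movies of dynamically growing
microtubules have low signal-to-noise ratios (free labelled tubulin in
solution raises the background), yet many analyses — growth-fluctuation
statistics, end-binding-protein profiles, catastrophe alignment — need
the end position of each microtubule in every frame to tens of
nanometres. `mttrack` is for microscopists and quantitative biologists
who want to (a) track ends in such movies and (b) know, for their imaging
parameters, what offset and precision to expect.

## What it does

**Simulate** — a stochastic 13-protofilament lattice grows diffusively
(mean speed v_g, tip diffusion D_p), maintains a linear protofilament
taper of extent TL, wiggles as a thermally driven cantilever (tip SD
σ_LD), and is rendered by model convolution: each labelled subunit
becomes a 2D Gaussian (σ_PSF = 135 nm) point-sampled on the pixel grid,
plus background, Poisson noise, EMCCD gain and offset. Ground truth (the
mean protofilament tip position) is recorded per frame. Movies can be
calibrated to a requested first-frame SNR, measured with the standard
two-box definition SNR = (I_MT − I_BK)/√(σ_MT² + σ_BK²).

**Track** — per frame: Wiener + Wallis filtering (segmentation only),
backbone refinement perpendicular to the previous axis, an axial
intensity profile extended beyond the end, a predictive two-state
(polymerizing/depolymerizing) dynamic model that proposes the new end,
and a sub-pixel least-squares fit of the wall-end model

    I(u, v) = b + A · exp(−v²/2σ²) · Φ(−u/σ_end)

to the **raw** image, the end being the half-maximum of the axial edge
(σ_end = σ for a blunt wall; a free-σ_end variant measures tip taper via
σ_end = √(σ_PSF² + σ_PF²)).

**Evaluate** — localization errors against ground truth are projected
into axial/lateral components; the mean is the offset, the SD the
precision, with bootstrap standard errors; sweep utilities reproduce
precision-vs-SNR characterizations, and the single-emitter theory
σ² = (s² + a²/12)/N_eff + 8πs⁴b²/(a²N_eff²) (EMCCD excess noise as
N_eff = N/1.4²) and the image-averaging relation
√(σ_track² + σ_PSF²)/√n are provided for comparison.

## Worked example

```
$ python -c "from mttrack import RunConfig; \
    RunConfig(n_frames=60, snr_target=2.5, seed=7).to_yaml('example.yaml')"
$ mttrack simulate --config example.yaml --out movie.tif --sidecar meta.json
wrote 60 frames to movie.tif (seed 7, intensity scale 0.003325)
$ mttrack track --movie movie.tif --init movie.backbone.csv \
    --config example.yaml --out tracks.csv
tracked 60 frames (100.0% reliable) -> tracks.csv
$ mttrack evaluate --tracks tracks.csv --truth movie.truth.csv
axial_offset_nm: 30.588
lateral_offset_nm: -4.122
axial_precision_nm: 27.604
lateral_precision_nm: 15.363
rmse_nm: 41.048
n_frames: 60
se_axial_offset_nm: 3.640
...
```

Reading the numbers: at SNR 2.5 every frame was tracked; the frame-to-
frame scatter of the end position around truth is 27.6 nm along the
microtubule axis and 15.4 nm perpendicular to it (the lateral fit is
better constrained, as expected). The +31 nm axial offset of this
particular movie is typical of a *single* microtubule at labelling ratio
0.2: the frozen pattern of labelled subunits near the tip biases the
apparent edge by tens of nm per movie (the bootstrap SE of 3.6 nm only
reflects frame noise). Averaged over many independently labelled
microtubules the offset is a few nm — which is why per-condition
characterizations pool several movies.

The Python API mirrors the CLI: `simulate_movie`, `track_movie`,
`project_errors`, `sweep_runner`; see the docstrings and
`docs/methods.md` for the model details and defaults.

## Performance characterization

`scripts/acceptance.py` re-runs the full characterization from scratch:
static microtubules at SNR > 3; a mixed sweep of labelling ratio,
exposure, pixel size and intensity with offsets/precisions summarized
against the measured first-frame SNR; noiseless growth-velocity and
taper sweeps; tracking efficiency down to SNR 1.2; and the averaging
image-count calculation. Run it as

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(about 10–15 minutes on one CPU; every random draw derives from
`--seed`).
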