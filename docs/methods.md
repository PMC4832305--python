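# Methods

`mttrack` bundles two things: a model-convolution simulator that turns a
stochastic microtubule lattice into realistic TIRF-like movies with known
ground truth, and a tracking pipeline that localizes the microtubule end
in each frame with sub-pixel precision. The evaluation layer compares the
two and reports the *offset* (mean localization error) and *precision*
(SD of the error), projected into axial (along-backbone) and lateral
components.

## Lattice simulation

A microtubule is 13 protofilaments of 8 nm tubulin dimers on a 3-start
B-lattice (radius 12.5 nm, helical rise 3·8/13 nm per protofilament).
Per frame interval Δt the net number of exchanged subunits is drawn from

    N ~ Normal( v_g·Δt·n_pf/d ,  2·D_p·Δt·(n_pf/d)² )

rounded half-to-even, so the ground-truth tip performs diffusion with
coefficient `D_p` (nm²/s) about a mean trajectory of speed `v_g` (nm/s).
Subunits fill the shortest protofilaments so that the sorted tip
positions maintain a stationary linear ramp of axial extent `TL` (the
taper). New subunits are labelled with probability `labelling_ratio`,
once, at incorporation; flags are never resampled (no photophysics).

The ground-truth end is the mean of the 13 protofilament tip positions,
where a tip is the **distal edge** of the terminal subunit — half a
subunit beyond the rendered emitter position. With the emitter-position
convention the apparent intensity edge of a blunt end sits a constant
+4 nm (half the 8 nm spacing) beyond the "truth", which would put a
4 nm offset on every noiseless measurement; the distal-edge convention
makes blunt noiseless offsets ≈ 0 and leaves a ~3 nm residual only at
the largest tapers, which is the physically meaningful behaviour.

Thermal wiggling is a first-order uniformly loaded cantilever clamped at
the seed: each frame an independent tip deflection d ~ Normal(0, σ_LD²)
displaces every subunit perpendicular to the axis by d·w(s/L) with
w(u) = u²(6−4u+u²)/3; axial positions are unchanged. The deflection is
applied identically to the emitters, the ground-truth tip coordinates
and the true centreline, so truth and image always agree.

## Rendering and noise

Each labelled subunit contributes a unit-peak isotropic 2D Gaussian of
width σ_PSF (default 135 nm) **point-sampled at pixel centres** (no area
integration), scaled by the expected peak photons per fluorophore, plus
a uniform background from labelled tubulin in solution. Subunits
exchanged during the exposure enter with linearly distributed residence
weights: the j-th of K subunits added within the exposure window gets
(K−j+1)/(K+1), removals mirror this. Poisson photon noise, a scalar
EMCCD gain and a constant camera offset produce 16-bit frames; EMCCD
excess noise is not simulated per pixel (it appears only in the
precision theory as the conventional factor 1.4). Noiseless renders stay
float-valued so quantization never enters the noise-free benchmarks.

Photon budget. The paper-style parameters state no absolute photon
numbers, so the package works with a per-fluorophore detection rate
(photons/s) and a background of `background_factor` fluorophore
equivalents per (120 nm)² pixel at labelling ratio 1. The default 8.7
is the estimate for ~10 µM labelled free tubulin in a ~100 nm
evanescent field; background therefore scales with labelling ratio,
exposure and pixel area. An SNR target can be requested per movie: both
signal and background scale together by s, the box SNR is
s·D/√(s²V+sM) in terms of the first frame's expected image (D contrast,
V spatial variance, M shot variance), and s is solved in closed form.
The SNR saturates at D/√V — the spatial structure of the microtubule
inside its measurement box bounds the measurable SNR near ~4.5–5 for
the default geometry, matching the experimentally reported range.

SNR definition: two 1.0 × 0.4 µm boxes, one on the backbone trailing
the end by one PSF FWHM, one shifted 1 µm perpendicular;
SNR = (I_MT − I_BK)/√(σ_MT² + σ_BK²). The boxes follow the local true
(or tracked) backbone so a thermally bent microtubule stays centred.
With ~24 pixels per box the single-frame measured SNR scatters by
roughly ±0.5 around the calibrated value and is slightly biased high;
this is intrinsic to the box definition, not to the calibration.

## Tracking

Per frame: the raw image is Wiener-denoised (local MMSE, window 3) and
Wallis-normalized (window 15, gain limit 5) *for segmentation only*;
the backbone from the previous frame is refined by perpendicular
intensity maxima (±3 px) with a Savitzky–Golay-smoothed displacement
field, the seed-side endpoint pinned (the seed is surface-immobilized).
A 1D profile is sampled along the backbone and extrapolated beyond the
end; an approximately Gaussian proposal weight of width
√(2·D_p·Δt + (2σ_PSF)²), centred on the expected end (previous anchor
advanced by the state-signed v_g·Δt), multiplies the
background-subtracted profile. The weighted maximum within ±3 widths is
the detection; from it the proposal marches tip-ward to the
half-plateau crossing, which recovers the apparent end even when the
expectation lags. A two-state dynamic model (polymerizing /
depolymerizing) flips only after `k_switch` = 3 consecutive misses
(weighted maximum below 2 background SDs) and not within
`k_refractory` = 5 frames of the previous flip.

The sub-pixel fit always consumes the **raw** frame. The wall-end model
is a Gaussian lateral profile times an integrated-Gaussian axial edge,

    I(u,v) = b + A · exp(−v²/2σ²) · Φ(−u/σ_end),

with the end at the half maximum (u = 0) and σ_end ≡ σ in the wall
variant; the free-σ_end variant fits the axial edge width separately
and recovers σ_end = √(σ_PSF² + σ_PF²) on tapered ends at high SNR.
The fit is a Levenberg–Marquardt least-squares with analytic Jacobian
over a rotated box window extending 6σ_PSF beyond and 12σ_PSF behind
the proposed end and ±4σ_PSF laterally. The long backward extent
stabilizes the fitted PSF width at low SNR; shortening it trades a
few nm of bend-induced offset against a larger noiseless taper offset.
Standard errors come from the local quadratic approximation. A fit is
*reliable* when it converged, r² > 0.2, the fitted width lies in
[0.5, 3]·σ_PSF, and the end stayed within max(3·width, 3σ_PSF) of the
proposal; a frame counts as *tracked* when a converged,
proposal-consistent end was produced at all (reliability additionally
gates all error statistics). The expected-end anchor absorbs each
accepted measurement with a variance-weighted (Kalman-like) gain using
the fit's standard error, so single noisy fits cannot walk the track
away at SNR ≈ 1.2.

## Evaluation

Errors are (fit − truth) rotated into the movie's axis; offsets are
means, precisions sample SDs (ddof = 1), RMSE over axial errors, with
seeded percentile-bootstrap SEs (1000 resamples of frames). Because the
labelling pattern near the tip is frozen within a movie, frames are not
independent: between-movie offset SDs are ~15 nm at labelling ratio 0.2
and ~35 nm at 0.075 even when the per-frame precision is good. Sweep
summaries therefore pool several independently seeded movies per
condition, and frame-level bootstraps understate offset uncertainty.

Single-emitter theory: σ² = (s² + a²/12)/N_eff + 8π s⁴ b²/(a² N_eff²)
with N_eff = N/1.4² (excess noise as an effective-photon reduction),
s the PSF sigma, a the pixel size, b the rms background. Averaging
end-aligned images of a second channel has precision
√(σ_track² + σ_PSF²)/√n; with σ_track = 40 nm and σ_PSF = 135 nm,
reaching one 8 nm subunit takes n ≈ 310 ≈ 300 images.

## What the simulator does and does not establish

The generator reproduces diffusive growth, taper, thermal bending,
finite exposure, labelling stochasticity, PSF blur, pixelation, Poisson
noise, and gain/offset. It does **not** model photobleaching/blinking,
TIRF axial intensity decay, defocus/3D lattice projection beyond a
plane, catastrophe/rescue kinetics, crossing microtubules, or camera
excess-noise statistics. A green benchmark therefore says the tracker
handles the stated image-formation physics at the stated SNR — not that
every real-data pathology is covered.

Known behaviour worth noting:

* With all stochastic terms off (D_p = σ_LD = TL = 0, instantaneous
  exposure) the noiseless tracking error is essentially deterministic,
  so noiseless precisions evaluate to ~0.01 nm rather than the few nm a
  simulator with residual per-frame randomness would report.
* The box SNR is not a pure information measure: at fixed photon flux,
  larger pixels collect more photons per pixel and read a higher box
  SNR at unchanged tracking precision. The pixel-size series therefore
  lies somewhat off the single precision-vs-SNR curve formed by the
  labelling/exposure/intensity series.
* Offsets at low labelling ratio are dominated by the frozen label
  pattern near the tip (tens of nm per movie); they average out over
  movies, not over frames.

## Defaults

| parameter | default | origin |
| --- | --- | --- |
| protofilaments / subunit | 13 / 8 nm | lattice structure |
| lattice radius | 12.5 nm | 25 nm outer diameter |
| σ_PSF | 135 nm | far-red TIRF measurement |
| pixel size | 120 nm | EMCCD at 100× |
| labelling ratio | 0.2 | baseline imaging condition |
| exposure = frame interval | 200 ms | baseline imaging condition |
| v_g, D_p | 11 nm/s, 271 nm²/s | baseline growth episode |
| σ_LD, TL | 150 nm, 96 nm | baseline growth episode |
| photon rate | 2000 /fluor/s (before SNR calibration) | free scale |
| background_factor | 8.7 eq/(120 nm px)² at LR 1 | 10 µM free tubulin estimate |
| gain, offset | 20 counts/photon, 100 counts | arbitrary detector scale |
| free microtubule length | ~4 µm (5 µm minus 1 µm seed) | keeps box-SNR saturation ≈ experimental range |
| k_switch, k_refractory | 3, 5 frames | dynamic-model hysteresis |
| r2_min | 0.2 | reliability flag |
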