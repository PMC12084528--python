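# Methods

`dropcode` simulates and decodes time-domain-encoded fluorescence videos of
dye-loaded beads flowing through a parallel-channel droplet imager, the
readout geometry used by optofluidic multiplexed digital ELISA (dELISA)
platforms. This note records the model, the defaults and the design choices
in enough detail to reproduce or re-derive every number the package
computes.

## Imaging model

Beads travel single-file through `n = 76` horizontal microfluidic channels
(110 µm pitch, 23 mm imaged length) and are photographed by a 16-bit
monochrome camera (960 × 720 px, so ~24 µm/px along the flow axis). The
camera alternates between two exposure roles (HDR mode):

- **Bead frames** (`T1 = 41.5 ms`): the blue and green excitation lasers are
  switched by two distinct 63-bit maximal-length sequences (MLS) spanning
  the exposure. A bead moving at velocity `v` leaves a streak of length
  `v·T1` whose intensity profile is the superposition
  `B1·d·MLS1(v,x) + B2·MLS2(v,x)`, where `B1`, `B2` are the blue/green dye
  intensities and `d = 0.5` is the PWM duty factor that dims the blue laser
  to balance the two dyes' use of the dynamic range. The PWM carrier runs
  far above the pixel integration scale, so it is modelled as a pure
  amplitude factor.
- **Substrate frames** (`T2 = 10 ms`): the red laser is on continuously; an
  HRP-positive droplet leaves a solid streak of length `v·T2`, a negative
  droplet leaves nothing. Because the frames abut in time, the substrate
  streak ends exactly where the next bead streak begins, and its length is
  `T2/T1 ≈ 1/4` of the bead streak.

The design (nominal) speed makes the bead streak one third of the channel,
`v* = (23 mm / 3)/41.5 ms ≈ 185 µm/ms`, so every bead is imaged at least
twice; at that speed the substrate streak is ~1.85 mm, while 1%-positive
80-µm droplets are on average `diameter/fraction = 8 mm` apart, so positive
streaks rarely overlap.

All signal amplitudes are expressed in *normalized units*: a pixel under a
streak of amplitude `B` records `background·(1 + B)` expected counts. The
background itself is the product of a level (17,000 counts in bead frames,
5,000 in substrate frames, echoing a strongly scattering device) and a
smooth illumination profile, so dividing by a background frame recovers
amplitudes independent of position — which is exactly why the decoder
normalizes before anything else.

## Synthetic data generator

`simulate.sample_beads` draws beads round-robin from five populations
(A–E) whose mean `(B1, B2)` pairs span the 2-D intensity map — A dimmest in
blue, E dimmest in green, C brightest in both — with per-dye normal
intensity CVs of 20%, within the 17–28% range such dual-encoded bead sets
exhibit. The default layout
(A (0.20, 0.80), B (0.55, 1.60), C (1.60, 1.60), D (1.60, 0.55),
E (0.80, 0.20)) keeps neighbouring groups ≥ ~4 combined standard deviations
apart, i.e. resolvable but not trivially so. Velocities are normal with
mean `v*` and 5% CV; 1% of droplets are HRP-positive.

Placement: each bead is assigned a channel and a bead-frame cycle such that
its streak is fully visible in exactly two consecutive bead frames, and at
most one bead enters a given channel per two cycles. This emulates a dilute
bead suspension (most droplets carry no bead and are invisible to
fluorescence imaging); it also means each trace usually holds one bead,
with entering/leaving beads contributing truncated partial streaks exactly
as on a real instrument.

Noise: Poisson shot noise on expected counts, Gaussian read noise
(σ = 50 counts), then rounding and 16-bit clipping. In addition, every
appearance of a bead multiplies each dye's amplitude by an independent
factor of CV `frame_jitter_cv = 5%`. This emulates the frame-to-frame
measurement variability of a real instrument (defocus, depth position in
the channel, illumination flicker) that repeat averaging exists to
suppress; without it, decode errors are almost entirely systematic per bead
and averaging two frames would — unrealistically — gain nothing. The value
is deliberately conservative; real instruments show appreciably more.

What the generator does *not* emulate: optical point-spread blur, lens
distortion (the correction hook applies a supplied map but the default is
identity), droplet boundary refraction, bead aggregates/doublets, debris
and non-streak artefacts, and acceleration within a frame. Passing tests
therefore demonstrate the correctness of the decoding chain under the
stated imaging model, not robustness to every real-world artefact class.

## Decoding chain

1. **Preprocess** (`preprocess`): optional undistortion map + rotation
   (supplied, never fitted), division by a Gaussian-smoothed (σ = 5 px)
   per-role background frame (floored at 1 count, floor events logged),
   segmentation into 76 strips of 7 rows, and a line average over the strip
   width giving `S(x)` per channel. Whole-frame division was chosen over
   peak-local normalization: it is linear, and makes background-only pixels
   sit at 1 everywhere.
2. **Velocity search** (`demod.scan_velocity`): the median-subtracted trace
   is correlated (raw inner products, un-normalized) against the
   superimposed template `d·MLS1(v,x)+MLS2(v,x)` at 500 linearly spaced
   velocities spanning 0.5–1.5× `v*`; the global maximum of `Ψ(x,v)` gives
   `(v_c, x_c)`. Ties break to the lowest velocity, then smallest lag.
   Masks are sampled by nearest-pixel bit-boundary assignment (error ≤1 px
   per bit edge); sub-pixel interpolation and sub-grid velocity refinement
   are deliberately omitted.
3. **Detection threshold**: a peak counts as a bead when it exceeds
   `k·σ·sqrt(Σ mask²)` with `k = 6` and `σ` the 1.4826·MAD robust noise of
   the trace — the matched-filter noise level. (A median+MAD rule applied
   to the correlation vector itself fails here: a streak spanning a third
   of the channel contaminates about half of all lags.) A tiny absolute
   floor (1e-6) keeps exactly-zero noiseless traces quiet.
4. **Multiple beads** (`locate_all_peaks`): local maxima above threshold
   with suppression within one mask length; each peak's velocity is then
   refined as the `Ψ` argmax within ±1 bit extent of its lag, since beads
   sharing a channel can flow at slightly different speeds.
5. **Quantification** (`quantify_bead`): raw peaks `p1, p2` are inner
   products of the baseline-subtracted trace window with the
   unit-amplitude single-code templates at `(v_c, x_c)`. The 2×2 crosstalk
   matrix maps true intensities to raw peaks; with on-bit counts `n1, n2`,
   overlap `o` (32, 32, 16 for the recorded pair), bit extent `E` and duty
   factors `d1, d2` it is `[[n1·d1, o·d2], [o·d1, n2·d2]]·E`. The decoder
   uses the exact Gram-matrix form built from the pixel-sampled templates
   (identical for integer `E`, exact for fractional `E`); its inverse turns
   `(p1, p2)` into `(b1, b2)`. Negative solutions are clamped to zero and
   flagged. Beads whose mask support would overhang the trace are rejected
   (truncated codes cannot be quantified).
6. **Tracking** (`track`): the next-frame position is predicted as
   `x + v·(T1 + T2 + dead_time)` (one substrate frame sits between bead
   frames; `T1 + dead_time` in bead-only mode) and detections are linked
   greedily per channel within 2 bit extents (~10 px). Repeats are averaged
   per dye on the *corrected* intensities; a bead is kept only if seen ≥2
   times with both per-dye repeat CVs (sample SD / mean) ≤ 20%. Chains
   longer than a bead can physically persist in the field of view are split
   at the largest prediction residual.
7. **Substrate calls** (`calls`): for each included bead the expected
   substrate window is `[x_c − v·T2, x_c]` in the preceding and
   `[x_c + v·T1, x_c + v·(T1+T2)]` in the succeeding substrate frame. The
   signal is the baseline-subtracted normalized sum over the window
   (baseline-subtraction makes bead-free windows sum to ~0 regardless of
   their velocity-dependent length). The threshold is mean + 4 SD of
   window sums from channels with no detected bead in the adjacent bead
   frames (≥30 windows required); a droplet is positive if *either*
   window's signal exceeds it — the union rule is the permissive reading of
   checking both neighbours, chosen so a window clipped at one frame edge
   cannot mask a positive.
8. **Gating** (`calls.GateSet`): reproducible stand-in for manually drawn
   gates — per-group covariance ellipses at Mahalanobis radius 3 fit on a
   training cohort, discretised to 64-gons; hand-drawn polygon files load
   from JSON. A bead inside exactly one gate gets that label; inside none,
   unclassified; inside several, ambiguous (excluded and logged). Accuracy
   is correct/gated over uniquely gated beads, tabulated against ground
   truth.

## Mask and code conventions

The two codes are fixed fixtures: MLS1 from the primitive polynomial
x⁶+x+1, MLS2 from x⁶+x⁵+1, both seeded with register state 000001, chosen
once for reproducibility — any primitive pair with audited cross-correlation
serves. Their ±1 circular cross-correlation peaks at 15 (vs the lag-0
autocorrelation of 63), and each has 32 on-bits with pairwise overlap 16.
Masks are 0/amplitude encoded (lasers are off or on; the physical signal is
non-negative), so correlations are plain inner products and the peak
magnitude carries the streak amplitude.

`B1`/`B2` are reported in normalized-intensity units (multiples of local
background); raw peaks `p1`/`p2` are in normalized-intensity × mask-weight
units (they scale with the bit extent, i.e. with velocity, which is exactly
what the crosstalk inversion divides out).

## Numerical choices and degenerate inputs

- Correlation uses FFT batching (one trace FFT against 500 precomputed
  template spectra); equality with the naive sliding inner product to 1e-9
  relative is property-tested.
- An all-zero LFSR seed and non-primitive tap sets are rejected (the latter
  detected by the register returning to its seed before the full period).
- Background pixels below 1 count are floored before division and counted
  in the log.
- A velocity grid whose fastest mask exceeds the trace is rejected at bank
  construction; zero/negative velocities are rejected at mask rendering.
- Zero-variance repeat sets give CV 0 (included); zero-mean repeats give
  infinite CV (excluded).
- Determinism: every stochastic step flows from one integer seed through
  `numpy.random.default_rng`; identical configurations are bit-identical,
  which is asserted in the suite.

## Problem sizes

The reference experiment (`experiments.classification_accuracy`, also run
by `scripts/acceptance.py`) simulates 200 beads per group × 5 groups per
arm (two independent arms: gate-fitting and evaluation), about 57 frames of
960×720 16-bit video per arm, and decodes ~2,000 bead appearances — a
desk-scale stand-in for the millions of droplets an instrument run
processes. Typical results: ~90% of simulated beads survive decoding,
linking and QC; classification accuracy of gated beads is ≈99.5–99.9%
at the default separations and 20% CVs.

## Known limitations

- Velocity is constant per bead; no acceleration model, and linking is
  greedy rather than globally optimal — adequate at one visible bead per
  channel, not for dense traffic.
- Nearest-pixel mask sampling leaves a per-bead systematic amplitude error
  of a few percent; it is common to both dyes and largely removed by the
  crosstalk inversion's Gram form, but a sub-pixel renderer would reduce it
  further.
- The 4σ substrate threshold presumes approximately Gaussian background
  window sums; heavy-tailed real backgrounds would need a robust variant.
- Two simultaneous codes only; extending to >2 dyes needs a code family
  with controlled pairwise overlaps (Gold/Kasami sets), deliberately out of
  scope.
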