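# dropcode

Simulation and decoding of **time-domain MLS-encoded droplet fluorescence
videos** for multiplexed digital bead assays.

High-throughput droplet digital ELISA readers image dye-encoded beads
flowing through many parallel microfluidic channels at once. Instead of
separating fluorophores with optics, the excitation lasers are switched in
time: during a long "bead" exposure (T₁ = 41.5 ms) the blue and green
lasers follow two distinct 63-bit maximal-length sequences (MLS), so each
moving bead leaves a streak whose intensity profile superimposes both
codes, `S(x) = B₁·d·MLS₁(v,x) + B₂·MLS₂(v,x)`; in the alternating short
"substrate" exposure (T₂ = 10 ms) a continuous red laser probes whether the
droplet's enzymatic substrate has turned over — the digital HRP signal.
`dropcode` is the software half of such an instrument: it renders
ground-truthed synthetic 16-bit HDR frame stacks, and decodes frame stacks
back into per-bead velocity `v_c`, location `x_c`, dye intensities
`(B₁, B₂)`, population identity and digital droplet positivity.

The decoder is a matched filter. Each channel's line-averaged trace
`S_{m,n}(x)` is correlated with the superimposed template at 500 candidate
velocities, `Ψ_{m,n}(x, v) = S_{m,n}(x) ⊗ (MLS₁(v,x) + MLS₂(v,x))`; the
global correlation peak fixes `(v_c, x_c)`, the two single-code correlation
peaks `(p₁, p₂)` at that point are unmixed through a 2×2 crosstalk matrix
(the codes share 16 of their 32 on-bits) into `(B₁, B₂)`, repeat
detections in consecutive frames are linked via `x + v·(T₁+T₂)` prediction
and averaged, and beads with repeat CV > 20% are discarded. Populations
are called by covariance-ellipse gates in the `(B₁, B₂)` plane; droplet
positivity is a 4σ-above-background threshold on the substrate-window sum.

Who it is for: groups building or evaluating time-domain-encoded
optofluidic readouts who need a reference decoder, a ground-truthed
simulator to stress it, and reproducible end-to-end accuracy numbers.

## Worked example

```python
from dropcode import RunConfig, simulate_run, decode_stack, match_tracks_to_truth

cfg = RunConfig(n_beads=150, seed=42)
stack, backgrounds, truth = simulate_run(
    cfg.population, cfg.n_beads, cfg.seed, cfg.geometry, cfg.schedule)
print(f"{len(stack)} frames, {len(truth)} beads, "
      f"{int(truth.hrp_positive.sum())} HRP-positive droplets")

result = decode_stack(stack, backgrounds, cfg)
table = result.track_table
print(f"{len(result.detections)} detections -> {len(table)} tracks, "
      f"{int(table.included.sum())} pass QC")

matched = match_tracks_to_truth(table, truth)
usable = matched[matched.included & (matched.bead_id >= 0)]
err = (usable.b1_mean - usable.true_b1) / usable.true_b1
print(f"median |B1 error| {err.abs().median():.1%}; "
      f"positive droplets called: {int(result.call_table.positive.sum())}")
```

prints

```
8 frames, 150 beads, 0 HRP-positive droplets
401 detections -> 246 tracks, 143 pass QC
median |B1 error| 2.8%; positive droplets called: 0
```

Reading it: 150 beads across 76 channels need 4 bead/substrate frame pairs;
each bead is fully imaged twice, and beads entering or leaving the field of
view contribute extra truncated detections that remain singletons, which is
why 401 detections collapse to 246 tracks of which 143 two-detection tracks
survive the repeat-and-CV quality control. Decoded blue intensities land
within ~3% of ground truth (median), and with 1% HRP incidence this
particular 150-droplet draw contains no positives — correctly called zero.

The same chain is available from the shell:

```sh
dropcode simulate --n-beads 150 --seed 42 run/
dropcode decode run/
dropcode report run/
```

which writes `stack.tif` (+ frame-role sidecar CSV, background TIFFs,
config snapshot) and then `detections.csv`, `tracks.csv`, `calls.csv` and a
confusion-matrix report.

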