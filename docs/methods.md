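# Methods notes

## Problem setting

Walking is a cyclic activity anchored by two events per leg and cycle:
heel strike (HS) opens the stance phase, toe off (TO) opens the swing
phase. With a 50 Hz thigh-mounted IMU and an insole pressure sensor as
reference, gait-event detection becomes supervised sequence labeling: map
a short window of multichannel sensor history to the stance/swing state
of the next sample, then read events off the predicted state trace. All
timing quality is expressed as the mean absolute difference, in
milliseconds, between detected and reference events of the same kind.

## The synthetic data generator

No recordings ship with this package, so `gaitkit.simulate` generates
them. What it emulates, and why each feature is there:

- **Gait-locked periodicity.** Six channels (Ax, Ay, Gy, Gz, Yaw, Roll)
  are 3-harmonic Fourier series of the stride phase, phase-locked to heel
  strike, with fixed per-channel amplitude/phase tables and a mild
  (±15%) per-subject amplitude rescaling. Real thigh waveforms are not
  published in a reusable form; harmonics-plus-transients supply the
  learnable structure a sequence model needs without claiming
  biomechanical exactness.
- **Event transients.** A Gaussian impact bump on Ay (and weakly Ax) at
  every heel strike, σ = 40 ms, and a swing-initiation bump on Gz (and
  weakly Gy) at every toe off, σ = 50 ms. These give both event kinds a
  local signature, which is what makes sub-sample timing learnable even
  though the stance fraction varies across subjects.
- **Quiet channels.** Az, Gx and Pitch carry only noise (SD 0.1) and
  drift; their variance stays below 10% of the quietest informative
  channel, so the channel-exclusion rule of the preprocessing stage is a
  property of the data, not an arbitrary convention.
- **Noise and drift.** Additive white noise per channel
  (SD 0.05 default) plus a random-walk drift (SD 0.002/sample) emulating
  sensor bias wander.
- **Speed conditions.** low/normal/high multiply cadence and stride
  length by 0.8/1.0/1.25; low and high also multiply noise by 1.5,
  encoding the observation that phone sensors are harder to use away
  from comfortable speed. This makes "normal is easiest" a testable
  property of the benchmark rather than an assumption.
- **Dual tasks.** VFT (counting words while walking) multiplies cadence
  by 0.842, adds 0.042 to the stance fraction, and adds 2% cycle-to-cycle
  stride-time jitter; PTW (carrying a tray) uses 0.914 / +0.027 / 1.2%.
  The magnitudes reproduce published healthy-elderly and clinical
  single- vs dual-task contrasts in direction and rough size.
- **Cohort structure.** Subjects cycle through six decade age bands
  (20–29 … 70–79); cadence is drawn uniformly from 95–115 steps/min and
  stance fraction from 0.58–0.62. True stride length follows
  0.30 + 1.05·f meters at stride frequency f Hz (±0.03 m noise), which
  places typical simulated walkers near 1.2 m strides at 1.18 s stride
  time.
- **Exact ground truth.** Event times are real-valued; the binary
  stance trace assigns sample k (covering time [k/fs, (k+1)/fs)) the
  state active at k/fs. Cohort recordings include a 0.3 s swing lead-in
  before the first heel strike — recording starts before walking does —
  so every true event, including the first HS, appears as a transition
  in the binary trace.

What the simulator does **not** model: biomechanically exact thigh
kinematics, sensor-axis cross-talk, turning, uneven ground, freezing
episodes, or realistic inter-channel noise correlation. Passing the
benchmark therefore shows that the pipeline is correct and that the
models can exploit gait-locked structure at realistic noise levels; it
does not certify accuracy on real smartphone data.

## Preprocessing

Kalman first, low-pass second, per channel. The Kalman filter is the
scalar random-walk model (state = latent channel value, predict variance
+= q, gain K = P/(P+r)), initialized at the first observation with prior
variance r. Variances are fractions of each channel's sample variance so
behaviour is unit-independent: q = 0.1·var, r = 0.001·var. With these the
steady-state gain is ≈0.99: the causal stage is nearly transparent in the
gait band (adds <1 ms of lag, which matters because the end metric is
event timing) and only shaves broadband noise; the real band-limiting is
done by the zero-phase 4th-order Butterworth at 10 Hz (gait energy at
50 Hz sampling lives below ~10 Hz, and forward–backward filtering keeps
events where they are). A lower-gain Kalman would act as a sub-1 Hz
one-pole filter, attenuate the gait fundamental and lag events by >100 ms
— measurably worse on every downstream metric — and would also violate
the pipeline's re-filtering stability requirement (second application
changes RMS by <1%).

After filtering, Az/Gx/Pitch are dropped and the remaining six channels
are z-scored with statistics fit on the training subjects only.

## Windowing and splits

The t-th pair is window [t, t+ω−1] → label t+ω (ω = 40 samples = 0.8 s),
giving n−ω pairs per trial; windows never cross trial boundaries. The
60/20/20 split assigns whole subjects to partitions (default), stratified
within age band, largest-remainder allocation, ties by subject order; a
`by_pair` mode exists because splitting at the pair level is a defensible
alternative reading, but it leaks subject-specific waveform style across
partitions and is not the default. For cohorts too small for stratified
allocation to populate every partition, the split falls back to one
global allocation.

## Models

All three architectures end in a sigmoid scalar, so training with L1
loss against the binary label is well-posed and the output trace is
directly comparable to the reference trace.

- `tcn_gru`: residual stack of dilated causal convolutions (kernel 3,
  dilations 1/2/4) → unidirectional GRU → sigmoid head on the last
  hidden state.
- `bitcn_bigru`: TCNs are causal, so bidirectionality is constructed:
  a second stack runs on the time-reversed window and features are
  concatenated; a BiGRU follows; mean pooling over time feeds the head.
- `bitcn_bigru_crossattn`: multi-head scaled dot-product cross-attention
  (4 heads) with queries from the BiGRU sequence and keys/values from
  the BiTCN features (the reverse wiring is a config switch), then mean
  pooling and the head.

Defaults: 64 TCN channels, 64 GRU units, dropout 0.2, Adam lr 1e-3,
batch 64, 50 epochs, validation after every epoch, best weights by
validation MAE with ties to the earlier epoch. Layer widths, learning
rate and batch size are conventional small-sequence settings; none were
tuned per-dataset, and all live in `ModelConfig`.

The networks run on an in-repo reverse-mode autodiff core (`_autodiff.py`)
in float32; the GRU is a single fused graph node with a hand-written
backpropagation-through-time rule for speed. Correctness rests on
finite-difference gradient checks (float64, tolerance 1e-7) that cover
every layer type through all three architectures. Training is
deterministic given the config seed: weight init, dropout and batch order
all draw from seeded generators.

## Events and timing

Probability → events: threshold at 0.5 (the natural decision point of an
L1-trained sigmoid), then debounce — any run shorter than 100 ms (no real
stance or swing phase is that short at walking speeds) is flipped into
its neighbours, leftmost run first, until all runs are long enough.
HS = 0→1 transition, TO = 1→0, each stamped at the first sample of the
new phase (the insole's first-contact semantics; no sub-sample
interpolation). Matching is greedy nearest-neighbour per event kind
within 250 ms (≈ half a swing, so matches cannot jump cycles); unmatched
and spurious events are counted separately and never pollute the MAE.
Reference events inside the first ω samples of a trial have no prediction
window and are excluded from matching.

## Gait parameters

Cycles are consecutive same-foot HS→TO→HS triples; malformed stretches
are skipped and counted, never silently imputed. Per-cycle identities
(stance + swing = stride; phases sum to 100; cadence·stride-time = 120)
hold by construction and are enforced in tests. Stride length is not
observable from a thigh IMU, so it is estimated by a linear model on
stride frequency 1/stride-time — regressing on frequency rather than on
walking speed avoids the circularity speed = length/time — calibrated by
OLS on simulator ground truth (shipping default: intercept 0.30 m, slope
1.05 m·s) and clipped to [0.2, 2.5] m. Trial values are unweighted means
over complete cycles.

## Statistics

Condition comparisons are two-sided paired t tests on per-subject trial
means, eight parameters per contrast, uncorrected — matching the
conventional presentation of dual-task gait tables — with an optional
Holm flag. Degenerate difference vectors resolve by convention (all-zero:
t = 0, p = 1; constant nonzero: p = 0). Bland–Altman summaries use
detected − reference differences with limits bias ± 1.96·SD (sample SD).
The t tests assume approximately normal within-subject differences; with
n ≈ 25 subjects this is a caveat, not a verified property.

## Benchmark sizing

The standard benchmark (`pipeline.benchmark_config`) uses 20 subjects ×
3 speed conditions, ω = 40, and 10 epochs of the cross-attention model at
reduced width (32 TCN channels / 32 GRU units, batch 128) so one
simulate→train→evaluate pass takes ~3 minutes on a single CPU; the
end-to-end check takes the median over three training seeds. At this
scale the held-out event MAE is ~10 ms for both event kinds, far inside
the 60 ms (3-sample) bound the test asserts, so the reduced width costs
nothing measurable against the full-width default.

## Known limitations

- Synthetic waveforms are a stand-in; see the generator section.
- One-leg convention: all events come from the instrumented side;
  cadence doubles strides to steps, and left/right asymmetry is out of
  scope.
- The MAE loss on a binary target drives predictions toward hard 0/1,
  which is intended here, but probability calibration between the
  extremes is meaningless and the 0.5 threshold is the only supported
  operating point.
- Float32 training is deterministic on a fixed platform; across BLAS
  implementations histories may differ in the last ulps.
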