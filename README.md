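# gaitkit

Gait-event detection from smartphone-style thigh IMU signals with deep
sequence models, plus the downstream gait analysis that clinicians care
about: millisecond event timing, spatiotemporal gait parameters, and
single- vs dual-task comparison statistics.

## The problem

A phone strapped to the thigh records nine channels at 50 Hz — triaxial
acceleration (Ax, Ay, Az), triaxial angular velocity (Gx, Gy, Gz) and
rotation angles (Yaw, Pitch, Roll). From these, we want the two instants
that anchor all gait analysis: **heel strike** (HS, foot touches ground;
stance begins) and **toe off** (TO, foot leaves ground; swing begins).
An insole pressure sensor provides the binary reference trace
(1 = stance, 0 = swing).

The pipeline:

1. **preprocess** — per-channel scalar random-walk Kalman filter, then a
   zero-phase 4th-order Butterworth low-pass (10 Hz), then exclusion of
   the three low-variation channels (Az, Gx, Pitch), then z-scoring with
   train-set statistics.
2. **windows** — sliding-window pairs: window X = samples *t … t+ω−1*
   over the 6 retained channels (ω = 40) predicts the stance label
   Y at sample *t+ω*; pairs split 60/20/20 into train/validation/test,
   stratified by age group, whole subjects per partition.
3. **models** — three architectures map an ω×C window to a stance
   probability: `tcn_gru`, `bitcn_bigru`, and `bitcn_bigru_crossattn`
   (queries from the BiGRU sequence, keys/values from the BiTCN features).
   Adam, L1 loss against the binary label, 50 epochs by default, best
   checkpoint by validation MAE. The networks run on a small in-repo
   numpy autodiff core whose gradients are finite-difference-checked.
4. **events** — threshold the probability trace at 0.5, debounce phases
   shorter than 100 ms, read HS/TO off the binary transitions, greedily
   match to reference events within 250 ms, and report per-kind MAE in ms.
5. **params** — per cycle (HS→TO→HS): stride time, stance/swing time,
   stance/swing phase (%), cadence = 120/stride-time, stride length from a
   calibrated linear model on stride frequency, walking speed =
   length/time.
6. **stats** — paired two-sided t tests between walking conditions
   (single-task STW vs cognitive VFT / physical PTW dual tasks) and
   Bland–Altman bias ± 1.96 SD agreement limits.

Because no public dataset of this kind exists, the **simulate** module is
a first-class citizen: it generates 50 Hz recordings with gait-locked
harmonics on six channels, a heel-strike impact bump on Ay, a
swing-initiation bump on Gz, near-flat Az/Gx/Pitch, sensor noise and
drift, three speed conditions, dual-task effects, and *exact* real-valued
ground-truth event times.

## Worked example

```python
import numpy as np
from gaitkit import pipeline
from gaitkit.types import EventKind

cfg = pipeline.benchmark_config(seed=1)   # 20 subjects x 3 speeds, 10 epochs
result = pipeline.run_event_benchmark(cfg)
pooled = result.pooled_report()
print(f"val MAE {result.model.best_val_mae:.4f}")
print(f"HS MAE {pooled.mae_ms(EventKind.HEEL_STRIKE):.1f} ms, "
      f"TO MAE {pooled.mae_ms(EventKind.TOE_OFF):.1f} ms")
```

prints (about 3 minutes on one CPU):

```
val MAE 0.0189
HS MAE 10.8 ms, TO MAE 12.4 ms
```

i.e. the trained cross-attention model predicts the stance probability of
the next sample with a mean absolute error of 0.019 on held-out subjects,
and the events recovered from its output trace land within about half a
sample (at 50 Hz one sample = 20 ms) of the simulator's ground truth.

The same pipeline is scriptable from the shell:

```bash
gaitkit --seed 1 simulate --out-dir cohort/ --n-subjects 20
gaitkit --seed 1 train --data-dir cohort/ --out-model model.npz --arch bitcn_bigru_crossattn
gaitkit --seed 1 evaluate --model model.npz --data-dir cohort/ --out report.json
gaitkit --seed 1 params --data-dir cohort/ --out params.csv
gaitkit --seed 1 compare --params-csv params.csv --task-a STW --task-b VFT --out ttests.csv
```

## Layout

```
src/gaitkit/
  simulate.py        synthetic cohorts with exact ground truth
  preprocess.py      Kalman + Butterworth + channel selection + z-score
  windows.py         sliding-window pairs, subject-level splits
  models/            autodiff core, TCN/GRU/attention layers, training
  events.py          trace -> events -> timing MAE
  params.py          gait cycles -> spatiotemporal parameters
  stats.py           paired t tests, Bland-Altman
  pipeline.py        end-to-end benchmark glue
  io.py, config.py, cli.py
docs/methods.md      model, simulator and design notes
scripts/acceptance.py
tests/
```
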