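# fmgrip

Grip-strength estimation from force myography (FMG) — inferring hand grip
force from the mechanical deformation of the forearm rather than from EMG.
The target application is rehabilitation engineering: restoring grip
control for wrist-amputation patients using only lower-arm muscle signals.

The pipeline models a wearable sleeve with two sensing modalities:

* **12 photoresistor channels** — sponge-coupled light sensors whose
  voltage rises with local muscle-surface compression (a saturating
  nonlinear characteristic), read through a 10-bit 0–5 V ADC
  (LSB = 4.88 mV);
* **3 Hall channels** — magnetic-field sensors reading a wrist-mounted
  magnet, which encode wrist rotation.

Two models sit on top:

1. **Wrist-angle classifier.** Each 200 ms Hall window is stitched into a
   single 1-D vector `[h1 | h2 | h3]`, min-max normalized to [0, 1], and
   classified into one of three wrist angles (−90°, 0°, +90°) by a
   time-series 1-D CNN (two conv + max-pool stages, softmax head),
   implemented directly in numpy with exact backpropagation and fully
   seeded training.
2. **Voigt grip-force model.** The forearm is abstracted as a Voigt
   viscoelastic element (spring + damper in parallel, a linearization of
   the Hill muscle model):

   ```
   F = a · X + b · Ẋ + c
   ```

   with deformation `X ∈ R¹²` (filtered sensor voltages), elastic
   coefficients `a`, viscosities `b` and offset `c` — 25 parameters per
   wrist angle, estimated by ordinary least squares
   (minimizing Q = Σᵢ (Fᵢ − F(Xᵢ))²) on ramp-grip calibration trials of
   n = 1000 samples.

At run time the classifier gates the model: per 200 ms window the wrist
angle is recognized from the Hall channels and that angle's parameter set
is applied to the moving-average-filtered (window 6) photoresistor
channels. Accuracy is scored by the RMSE between measured and estimated
force and by the Pearson correlation between force and mean deformation.

No public recordings of the hardware exist, so the package ships a
synthetic sensor-physics generator (`fmgrip.synth`) that emulates the
response curves, ADC quantization, noise and corruption scenarios, making
every stage testable end to end.

## Worked example

```python
import fmgrip as fg

result = fg.run_experiment(seed=42)   # full desk-scale experiment
print(result.headline())
```

prints (about five seconds on one CPU):

```
{'angle_accuracy_pct': 100.0,
 'rmse_mean_N': 1.2246208925206343,
 'rmse_per_angle_N': {'-90': 1.6511815359867161,
                      '0': 1.0049703504963734,
                      '90': 1.0177107910788137},
 'force_deformation_r': 0.9927216298364007}
```

Reading the numbers: the CNN recognizes all held-out wrist-angle windows
(100 % of a 200-window test split of 999 windows); the gated Voigt model
estimates grip force on held-out ramp trials to an average RMSE of 1.22 N
over the 0–35 N range, with the −90° posture hardest (1.65 N — that
posture is simulated with inflated noise, matching the observation that
forceful supination is awkward); and force tracks the mean deformation
with r = 0.993.

The same experiment is available from the shell, with per-trial CSV
traces and PNG plots:

```sh
fmgrip reproduce --seed 42 --out-dir out/
```

Individual stages (`simulate`, `preprocess`, `train-angle`, `fit-grip`,
`estimate`, `evaluate`) are exposed as subcommands; see `fmgrip --help`.

## Layout

| module | contents |
| --- | --- |
| `fmgrip.synth` | sensor-physics generator: response curves, ADC, Hall field, grip trials, corruption, CSV dialect |
| `fmgrip.preprocess` | moving-average filter, min-max normalization, 200 ms window stitching, stratified 4:1 split |
| `fmgrip.angle_cnn` | `AngleCNNClassifier` (numpy 1-D CNN, sklearn estimator API) |
| `fmgrip.voigt` | `VoigtModel` least-squares estimator, derivative estimation, classifier-gated `estimate_grip` |
| `fmgrip.evaluate` | RMSE, Pearson r, confusion matrix, experiment summary |
| `fmgrip.experiment` / `fmgrip.cli` | end-to-end reproducible experiment and the `fmgrip` CLI |

See `docs/methods.md` for the modeling assumptions, generator design and
numerical choices.
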