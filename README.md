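# ecgfusion

Five-class arrhythmia detection from single-lead ECG, built for signal-processing
and ML researchers who want every stage of a dual-channel classification
pipeline — from raw WFDB records to a confusion matrix — as tested, composable
library code that also runs end-to-end on synthetic data with no downloads.

## What it implements

**Denoising.** The signal is decomposed by ICEEMDAN (improved complete ensemble
empirical mode decomposition with adaptive noise): the k-th residual is the
ensemble average of envelope local means of the previous residual perturbed by
the k-th EMD mode of white noise,

    r_k = AVG_i[ M(r_{k-1} + a_{k-1} E_k(d_i)) ],    IIMF_k = r_{k-1} - r_k,

so `sum(IIMF) + r_K = x` holds exactly. Components whose FFT-peak frequency
falls below 1.5 Hz are discarded as baseline wander; the rest are shrunk with a
sym8 / 5-level DWT whose detail coefficients pass through an improved threshold
function

    f(x) = sign(x) (|x| - 2T / (exp((|x|-T)/T) + 1)),   |x| >= T;   0 otherwise,

continuous at T, soft-threshold-like near T and hard-threshold-like far above it.

**Slicing and labeling.** Denoised records are cut into overlapping 5 s windows
(1,800 points at 360 Hz). Each window takes one AAMI label (N/S/V/F/Q) by four
rules: all-normal → N; one abnormal type → that type; several → the most
frequent; tie → the abnormal type occurring first. No R-peak detector is needed.

**Balancing.** SMOTE fills each minority class to the majority count with convex
combinations `x + u (x_nn - x)` of same-class nearest neighbours; originals are
kept bit-identical and synthetic rows are flagged.

**Imaging.** Each segment (PAA-compressed to 100 points) becomes a Gramian
angular difference field (`sin(phi_i - phi_j)`, antisymmetric, zero diagonal),
a Markov transition field (quantile-binned first-order chain), and a recurrence
plot (`H(eps - ||x_i - x_j||)`, eps = 30 in ADC units), stacked into one
100 × 100 × 3 RGB image.

**Classifier.** A dual-channel network: a 1-D ResNet (stage widths 32-64-128-256)
whose residual blocks embed an improved convolutional block attention module
(ICBAM — channel and spatial attention, each residually re-adding the backbone
features), and a three-convolution 2-D CNN over the RGB image. The 256- and
144-wide feature vectors are concatenated (400), passed through dropout, a
400→200 ReLU layer and a 200→5 softmax. Training uses Adam, cross-entropy,
learning rate 0.0007, batch 256. Evaluation reports the 5 × 5 confusion matrix
with per-class PPV/Sen/Spec/F1/Acc and overall accuracy (trace/total). The
network runs on a self-contained numpy autodiff engine (`ecgfusion.nnet`),
gradient-checked against finite differences.

## Worked example

```python
import numpy as np
from ecgfusion.synth import SynthConfig, NoiseSpec, generate_clean_record, add_noise
from ecgfusion.denoise import ICEEMDANConfig, denoise_record, denoise_metrics

rec = generate_clean_record(SynthConfig(360.0, 4.0, {"N": 1.0}, beat_rate_bpm=96.0, seed=7))
noisy = add_noise(rec, NoiseSpec(baseline_amp=0.3, baseline_freq_hz=0.5,
                                 gaussian_snr_db=10.0, powerline_amp=0.05, seed=2))
den = denoise_record(noisy.lead(0), ICEEMDANConfig(ensemble_size=50, seed=1), fs=360.0)
m = denoise_metrics(rec.lead(0), den, noisy.lead(0))
print(f"input SNR  {m.input_snr_db:6.2f} dB")
print(f"output SNR {m.snr_db:6.2f} dB")
print(f"RMSE       {m.rmse:6.4f}")
print(f"NCC        {m.ncc:6.4f}")
```

prints

```
input SNR   -1.85 dB
output SNR  10.47 dB
RMSE       0.0545
NCC        0.9544
```

i.e. a record corrupted with 0.5 Hz baseline wander, 10 dB Gaussian noise and
powerline interference (net −1.9 dB) is restored to +10.5 dB with waveform
correlation 0.95 against the known clean signal.

The full pipeline runs from one config:

```bash
ecgfusion run-all --seed 5 --out runs/demo          # or --config cfg.yaml
```

which synthesizes annotated records, denoises, slices, balances, encodes and
trains, then writes `report.json` (confusion matrix, per-class metrics, overall
accuracy) into the run directory. Stages are cached by config hash, so a rerun
with the same config is a no-op.

## Layout

| module | contents |
| --- | --- |
| `ecgfusion.synth` | annotated synthetic ECG + noise generator |
| `ecgfusion.io_wfdb` | WFDB format-212 reader/writer, AAMI symbol mapping |
| `ecgfusion.denoise` | EMD, ICEEMDAN, improved threshold, metrics |
| `ecgfusion.segmentation` | slicing, slice labeling, train/val/test splits |
| `ecgfusion.balance` | SMOTE oversampling |
| `ecgfusion.imaging` | PAA, GADF, MTF, RP, RGB stacking, PNG export |
| `ecgfusion.nnet` | numpy autodiff, layers, Adam |
| `ecgfusion.model` | ICBAM attention, 1-D ResNet branch, 2-D CNN branch, fusion |
| `ecgfusion.train_eval` | training loop, confusion-matrix metric suite |
| `ecgfusion.pipeline` / `ecgfusion.cli` | cached end-to-end orchestration, CLI |

See `docs/methods.md` for modelling assumptions, parameter choices and known
limitations.
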