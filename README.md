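# wingbeat

Signal analysis for optoelectronic insect sensors: detect fruit-fly passage
events in a sensor recording, measure the wing-beat frequency of each event,
characterize a species statistically, and discriminate between two pest
species of major agricultural importance — *Anastrepha fraterculus*
(South American fruit fly, wing-beat fundamental near 114 Hz) and
*Ceratitis capitata* (Mediterranean fruit fly, near 161 Hz).

The intended user is anyone building or evaluating an "intelligent trap":
an infrared light curtain whose phototransistor output is amplitude-modulated
by the partial occlusion of the beam by a flying insect's wings. The
digitized output is an audio-rate signal in which each passage appears as a
short harmonic burst. Because such recordings are hard to come by, the
package includes a ground-truth-labeled simulator of the whole measurement
chain, so every stage can be exercised and validated without hardware.

## Method

**Event detection.** The RMS value of a sliding window (30 ms window, 10 ms
overlap) is compared to a threshold:

    RMS = sqrt( (1/n) * sum_i x_i^2 )

Maximal runs of supra-threshold windows become passage events, stored with
50 ms of context on each side. Events enter the *standard group* used for
characterization only if their core duration is at least 100 ms and the
passage was direct (no mid-event collapse of signal strength).

**Feature extraction.** Each event is windowed with a 4-term
Blackman–Harris window and analyzed twice:

* *autocorrelation method* — r_xx(l) = Σ x(i+l)·x(i) is scanned over lags
  in a physiological band (70–500 Hz); the best lag gives the fundamental
  period T0 and F0 = 1/T0;
* *FFT method* — the windowed event is zero-padded to one second (1 Hz
  bins); the largest in-band spectral peak is the fundamental F0 and the
  next four local maxima above it are the components F1–F4 with magnitudes
  M0–M4.

The classification features are F0 (autocorrelation), F0 (FFT) and F1 − F0.

**Characterization.** Per feature: gate out octave errors (values that are
double or half the physiological range), remove boxplot-fence outliers
(Q1 − 1.5·IQR, Q3 + 1.5·IQR), check normality (Shapiro–Wilk, p > 0.05),
then model the feature as Normal(μ, σ) with a Student-t confidence interval
IC(μ) = X̄ ± T·Sx for the population mean.

**Classification.** For two species with per-feature models N(μ_A, σ_A) and
N(μ_C, σ_C), the decision boundary x\* is the abscissa between the means
where the two densities are equal; the normal tail areas beyond x\* are the
per-species misclassification probabilities

    Pr(x1 ≤ x ≤ x2) = ∫ (1/√(2πσ²)) exp(−(x−μ)²/2σ²) dx .

Events are labeled by majority vote of the three frequency features
(magnitude ratios overlap too heavily between these species to vote).

## Worked example

Simulate two minutes of *C. capitata* activity, detect passages, extract
features, and characterize the species:

```python
import numpy as np
from wingbeat import (SynthConfig, ccapitata_params, generate_track,
                      run_detection, extract_features, build_profile)

cfg = SynthConfig(seed=42, event_rate_per_min=30)
track, truth = generate_track(cfg, [(ccapitata_params(), 1.0)], length_s=120.0)
events = [e for e in run_detection(track) if e.standard_group]
feats = {"f0_aut": [], "f0_fft": [], "f1_minus_f0": []}
for ev in events:
    _, vec = extract_features(ev)
    for k in feats:
        feats[k].append(getattr(vec, k))
profile = build_profile({k: np.array(v) for k, v in feats.items()}, "C. capitata")
print(f"{len(truth.events)} simulated events, {len(events)} in the standard group")
for name, m in profile.models.items():
    print(f"{name:12s}: {m.mu:6.2f} +/- {m.ci_half_width:.2f} Hz "
          f"(SD {m.sigma:5.2f}, n={m.n}, Shapiro-Wilk p={m.shapiro_p:.2f})")
```

which prints

```
60 simulated events, 60 in the standard group
f0_aut      : 160.82 +/- 2.61 Hz (SD 10.10, n=60, Shapiro-Wilk p=0.31)
f0_fft      : 160.87 +/- 2.60 Hz (SD 10.05, n=60, Shapiro-Wilk p=0.28)
f1_minus_f0 : 160.65 +/- 2.66 Hz (SD 10.29, n=60, Shapiro-Wilk p=0.37)
```

All three wing-beat estimates recover the generating population mean
(160.81 Hz) within the confidence interval, every simulated event is
detected and passes the standard-group criteria, and each feature sample is
consistent with a normal distribution — which is what licenses the
Gaussian-overlap classification step.

The same pipeline is available from the shell:

```sh
wingbeat --config cfg.yaml simulate --seed 42 --out track.wav
wingbeat --config cfg.yaml detect track.wav --out events.csv
wingbeat --config cfg.yaml extract track.wav --out features.csv
wingbeat characterize features.csv --species "C. capitata" --out profile.json
wingbeat classify features.csv --model model.json --out labels.csv
```

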