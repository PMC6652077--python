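# covertbci

Single-trial EEG decoding of covert "yes"/"no" answers, with the
time–frequency statistics to explain *where* the discriminative signal
lives.

## The problem

When a person covertly answers a binary question, the intention to answer
"no" (a violation of an autobiographical fact) leaves a spectral signature
in the EEG: stronger theta-band (4–8 Hz) power over right frontal channels
early after the critical word, and stronger alpha-band (8–13 Hz) power over
right centroparietal channels later in the epoch. This package implements a
complete pipeline that decodes the answer from single trials and
characterizes those effects statistically — the core machinery of a
question-and-answer brain–computer interface for users who cannot respond
overtly.

Because the original recordings were never released, the package ships a
first-class synthetic-cohort generator that plants exactly those class
effects (band-limited induced oscillations over localized channel groups on
a 1/f background), so the entire pipeline is testable end to end and its
calibration can be audited.

## The method

**Decoding.** The 0–1200 ms × 4–50 Hz plane is tiled into 200 ms × 2 Hz
subwindows. Per subwindow, trials are band-pass filtered (linear-phase FIR,
order 512), cropped, and spatially filtered by common spatial patterns
(CSP): with class covariances Σ₁, Σ₂, the projection W solves
Σ₁w = λ(Σ₁+Σ₂)w and simultaneously diagonalizes both, WᵀΣ₁W = Λ₁,
WᵀΣ₂W = Λ₂, Λ₁+Λ₂ = I. The first and last m = 2 projections give
log-normalized variance features

    f_p = log( var(Z_p) / Σᵢ var(Zᵢ) ),   p = 1…4,

classified by an RBF-kernel SVM under balanced 10-fold cross-validation
(CSP and SVM fitted on training folds only). Subwindows whose group-mean
accuracy exceeds mean + 2·SD of the accuracy map are fused by concatenating
their features (4 per window) into one combined decoder. The chance level
for 10 test trials per class is the exact binomial 95% limit, 75%.

**Statistics.** Induced power is computed per trial with a complex Morlet
CWT whose cycle count rises linearly from 4 (at 1 Hz) to 13.5 (at 100 Hz),
averaged over trials, and normalized as relative change against the
−300…0 ms baseline. Paired t tests over all 241 × 26 × 29 = 181,714
time–frequency–electrode bins screen the top 10% of electrodes per band;
the band's electrode-averaged maps are then thresholded (p < 0.05),
clustered by contiguity, scored by t_mass (the summed t values), and tested
against a permutation null of maximum t_mass from subject-level condition
swaps.

## Worked example

```python
import numpy as np
from covertbci import (SimulationConfig, generate_subject,
                       decode_subwindow, chance_threshold)

subject = generate_subject(SimulationConfig(seed=1), 0)   # 200 trials, 29 ch
res = decode_subwindow(subject, window=(1000, 1200, 10, 12), seed=0)
print(f"accuracy {res.mean_accuracy:.3f} +- {res.sd_accuracy:.3f}")
print(f"chance threshold {chance_threshold(10, 0.05):.2f}")
```

prints

```
accuracy 0.815 +- 0.085
chance threshold 0.75
```

the cross-validated accuracy in the late alpha subwindow (10–12 Hz,
1000–1200 ms) for one simulated subject, and the exact binomial chance
threshold — any subwindow above 0.75 decodes better than guessing at the
5% level. The full pipeline (accuracy map over all 138 subwindows,
subwindow selection, combined decoding, ERSP maps, cluster statistics) runs
from one config:

```bash
covertbci run --seed 1 --out results/run
```

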