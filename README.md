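# entrainkit

Estimators and simulators for **behavioral and neural entrainment to
rhythmic auditory and electrical stimulation**, built around a gap-detection
psychophysics paradigm: listeners press a button when they hear brief silent
gaps embedded in noise, while the noise is frequency-modulated (FM) at a
fixed rate and/or transcranial alternating current stimulation (tACS) is
applied. Because detection probability waxes and wanes with the phase of the
entraining rhythm, the strength of entrainment can be read out behaviorally.

The package is organized as an analysis project: every computation lives in
the importable library under `src/entrainkit/`, and the numbered scripts
under `analysis/` run the experiment-level analyses end to end on synthetic
data generated to match the three study designs.

## What it computes

**Phase-binned cosine fits.** Gaps are binned by the phase of the entraining
signal at gap onset (FM phase, tACS phase, or an imaginary oscillator that
resets at stimulus onset). Hit rates per bin are fitted with

&nbsp;&nbsp;&nbsp;&nbsp;r(φ) = offset + *entAmp* · cos(φ − *prefPhase*)

by closed-form least squares in the sin/cos basis. *entAmp* quantifies
behavioral entrainment; *prefPhase* is the optimal phase. Significance comes
from permutation surrogates (accuracy values shuffled across trials with
phase labels fixed, 1000 by default) via z-scores and 95th-percentile tests.

**tACS lag analysis (Experiment 1).** With FM sound and tACS both at 2 Hz,
gaps are cross-binned 9 FM phases × 6 FM–tACS lags; a second-level cosine
fit of *entAmp-FM* over lag finds each participant's optimal tACS lag. Lag
profiles are realigned to that optimum, the realigned peak and trough bins
are excluded (bias control), and the two bins adjacent to the optimum
(tACS+) and to its opposite (tACS−) are averaged and contrasted against
sham, z-scored against lag-shuffled surrogates that rerun the full pipeline.

**Frequency tuning and the oscillator model (Experiment 2).** tACS at
0.8/2/3.2/4.4 Hz without any sound rhythm; normalized effects
(*entAmp-tACS* − baseline)/baseline against imaginary-oscillator sham
baselines. A Stuart–Landau oscillator

&nbsp;&nbsp;&nbsp;&nbsp;dx/dt = λx − ωy − γ(x²+y²)x + k·s(t),&nbsp;
dy/dt = λy + ωx − γ(x²+y²)y

(λ=0.2, γ=1.0, limit-cycle amplitude √(λ/γ) ≈ 0.45) is driven by a sinusoid
at each tACS frequency over a grid of intrinsic frequencies ω (0.1–8 Hz) and
drive strengths k (0–100 % of baseline amplitude). Each participant's
resonance frequency is the ω whose model response profile correlates best
with their empirical 4-frequency effect profile; estimates are clustered by
average-linkage hierarchical clustering.

**EEG frequency tagging (Experiment 3).** Hann-windowed amplitude spectra of
trial-averaged epochs, intertrial phase coherence (resultant vector length
of per-trial spectral phases), fronto-central channel-cluster averaging,
cross-condition normalization (value at frequency f in the matching
condition divided by the mean at f in all other conditions), preferred-rate
extraction and linear trends over FM rate.

**Trial-wise models.** Mixed-effects logistic regressions of single-gap
accuracy on circularly linearized phases (sin + cos pairs), modulation depth
and interactions, with a participant random intercept (maximum likelihood
via Gauss–Hermite quadrature), ranked by AIC, with surrogate-AUC
significance.

A seeded synthetic-data generator (`entrainkit.simulate`) reproduces all
three designs — gap placement at phase-bin centers with ≥1.5 s spacing,
~136 gaps per 32-stimulus block, hit probabilities that are clipped additive
cosines of the relevant phase — so every estimator can be validated against
known ground truth.

## Worked example

```python
import numpy as np
import entrainkit as ek

b = ek.PhaseBinning(9)
rates = 0.5 + 0.2 * np.cos(b.bin_centers - np.pi / 2)
fit = ek.fit_cosine(b.bin_centers, rates)
print(fit.offset, fit.amplitude, fit.phase)
# 0.5 0.1999999999999999 1.5707963267948968
```

The fit recovers the generating offset 0.5, entrainment amplitude 0.2 and
preferred phase π/2 exactly (equally spaced bins make the sin/cos basis
orthogonal). At the experiment level:

```sh
python analysis/01_simulate_experiments.py   # synthetic datasets
python analysis/03_exp2_tacs_frequency.py    # tACS frequency effects
python analysis/04_oscillator_resonance.py   # model-based resonance fits
```

prints, among other things,

```
estimated resonance frequencies for 24 participants
  cluster 1: n = 18, mean resonance 1.2 Hz
  cluster 2: n = 6, mean resonance 4.4 Hz
```

i.e., the model-based resonance estimates split the simulated sample into a
lower- and a higher-frequency cluster within the delta range, and

```
normalized vector length ~ FM rate: slope 1.003, R2 0.919, F 524.3, p 8.7e-27
```

from `analysis/05_exp3_frequency_tagging.py`: on synthetic EEG whose
phase-locked component grows with FM rate, normalized intertrial coherence
increases linearly with rate.

## Layout

```
src/entrainkit/     library: circstats, cosinefit, simulate, lagalign,
                    tacs_frequency, oscillator, freqtag, glm, io
analysis/           numbered experiment-level drivers (write to results/)
tests/              pytest suite, including end-to-end acceptance checks
scripts/            acceptance.py
docs/methods.md     model, estimator and simulation details
```
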