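# Methods

This note documents the models, estimators and numerical choices behind
entrainkit, and what the synthetic-data generators do and do not emulate.

## Phase conventions and binning

All phases are radians wrapped to the half-open interval [−π, π);
`wrap_phase(π) = −π`. Phase bins are equally spaced with bin j centered at
wrap(2πj/n) and edges at center ± π/n, so bin 0 is centered on phase zero
and every phase maps to exactly one bin. The placement of the first bin
edge is a convention; all estimators are invariant to a global rotation of
the binning up to the corresponding shift of the fitted preferred phase.

## Cosine fits

Hit rates over bin centers are fitted with r(φ) = c + A·cos(φ − φ₀) via the
linear basis [1, cos φ, sin φ] and ordinary least squares; A = √(β₁²+β₂²),
φ₀ = atan2(β₂, β₁). This has the same optimum as a nonlinear fit of the
cosine model, and on equally spaced bins the basis is orthogonal, so
noiseless cosine data are recovered to machine precision. A is non-negative
by construction (the amplitude is a magnitude; its direction lives in φ₀).
Perfectly flat data yield A = 0 with a `degenerate` flag and φ₀ reported
as 0. Fits require at least 3 distinct centers.

Because A ≥ 0, amplitude estimates are positively biased under the null;
every inference about amplitudes therefore runs against permutation nulls
rather than against zero.

## Permutation surrogates

The generic null (`surrogate_null`) shuffles single-gap accuracy values
across trials within participant × session × condition, keeping all phase
labels fixed, and recomputes the statistic per shuffle; 1000 permutations by
default, seeded. Participants are declared significant when the observed
amplitude exceeds the 95th percentile of their own surrogate distribution
(one-sided). z-scores use the surrogate mean and SD; a zero-spread null
raises rather than dividing. A vectorized path (`amplitude_null`) computes
all permutations of the cosine-fit amplitude in one matrix product and is
used inside the calibration suites; a test verifies it samples the same
distribution as the generic path.

Under exchangeability this test is exact; the measured type-I rate at the
Experiment-1 per-participant scale (680 gaps, 9 bins, 1000 permutations) is
0.03–0.05 over 500 null simulations.

## Experiment-1 lag pipeline

Active-tACS gaps are cross-binned 9 FM bins × 6 lag bins (54 cells, all
required non-empty; participants failing this are excluded with a recorded
reason). First-level fits give entAmp-FM per lag; a second-level cosine fit
over the 6 lag centers gives the optimal lag (its fitted phase — the lag
maximizing the predicted amplitude). The profile is rotated so the bin
nearest the optimum (ties to the lower index) sits at lag 0; the realigned
zero bin and its opposite are excluded, tACS+ is the mean of the bins at
±60° and tACS− the mean at ±120°. Contrasts (tACS+ − sham, tACS− − sham,
tACS+ − tACS−) are z-scored against surrogates that shuffle the per-trial
lag labels and rerun the entire pipeline, including the second-level fit
and realignment.

Realigning to a fitted optimum selects noise maxima; excluding the aligned
peak and trough removes the first-order selection bias, and the full
pipeline applied to lag-shuffled null data gives mean z(tACS+ − tACS−)
within ±0.1 of zero over 400 simulated participants. A consequence worth
knowing: when the observed realignment is dominated by true signal, the
surrogates (which realign to pure noise) can carry *more* residual
selection bias than the observed data, so the z-scores are conservative for
moderate true modulation.

## Experiment-2 pipeline

entAmp-tACS and prefPhase-tACS come from 6-bin cosine fits over the tACS
phase at gap onset, per frequency. The sham baseline per frequency f is the
fitted amplitude over bins of an imaginary oscillator phase wrap(2πf·t)
that resets at stimulus onset. The normalized effect
(entAmp-tACS − baseline)/baseline exceeds 1 exactly when entrainment is at
least twice baseline (the responder criterion). Baselines below 10⁻³ flag
the ratio as unstable rather than silently dividing. Group-level uniformity
of preferred phases uses the Rayleigh test (R, z = nR², and the standard
exp-series p approximation; cross-checked against an independent circular
statistics implementation).

## Stuart–Landau oscillator

dx/dt = λx − ωy − γ(x²+y²)x + k·√(λ/γ)·s(t), dy/dt = λy + ωx − γ(x²+y²)y,
with λ=0.2, γ=1.0, (x₀,y₀)=(0,−1); ω is given in Hz in the API and
multiplied by 2π internally. The drive s(t) = sin(2πf·(t−10 s)) switches on
at 10 s with zero phase offset; k scales the drive relative to the
limit-cycle amplitude √(λ/γ) ≈ 0.447. Integration uses adaptive Runge–Kutta
(rtol 10⁻⁶, atol 10⁻⁹), split at drive onset so the solver never steps
across the discontinuity; an independent fixed-step RK4 oracle agrees to
<10⁻³ in state and a tolerance-halving test to <10⁻⁴ in amplitude.

**Entrainment change** is (Ā_driven − Ā_undriven)/Ā_undriven × 100, where Ā
is the mean envelope √(x²+y²) over the 15–30 s window (5 s after onset, an
integer number of cycles of every tested drive frequency) and the undriven
reference is the k=0 trajectory from the same initial state. Comparing
driven against undriven over identical windows cancels the
initial-condition transient exactly (k=0 gives exactly 0). The envelope was
chosen over the Fourier amplitude at the drive-frequency bin after direct
comparison: the spectral version is dominated by leakage of the intrinsic
oscillation for small frequency mismatches and produces non-smooth,
sign-flipping response surfaces, whereas the envelope yields a smooth
Arnold-tongue ridge (+38 % at matched frequency for k=0.5, near zero or
negative off-resonance — a near-miss drive outside the locking range can
genuinely suppress the oscillation, mirroring the interpretation of
negative empirical tACS effects).

**Resonance estimation.** The (ω, k) sweep covers 0.1–8 Hz × 0–1 × the four
drive frequencies (3520 cells, integrated in vectorized batches, memoized).
A participant's 4-point normalized-effect profile is Pearson-correlated
with every (ω, k) model profile (k=0 excluded: zero variance); the ω of the
global maximum is the resonance estimate, ties breaking toward lower ω then
lower k. On noiseless model-generated profiles every grid point with a
unique maximum is recovered exactly. With Gaussian noise at 10 % of the
profile range, recovery within ±0.5 Hz holds for ≈87 % of draws whose true
resonance lies inside the tested 0.8–4.4 Hz band; resonances far above the
highest drive frequency respond to none of the drives and are structurally
unidentifiable from a 4-frequency design, so recovery simulations sample
the in-band population (where the empirical clusters live). Resonance
estimates are clustered by average-linkage hierarchical clustering on 1-D
Euclidean distances, labels relabeled in order of cluster mean.

## EEG frequency tagging

Evoked spectra: trials are averaged in the time domain, Hann-windowed, and
Fourier-transformed; amplitude = modulus × 2/N ÷ 0.5 (one-sided scaling and
Hann coherent-gain compensation), so a phase-locked unit sinusoid on a bin
reads 1. Intertrial coherence: the same windowed transform per trial, unit
phasors per frequency, R = |mean phasor| ∈ [0, 1]. Epochs default to 10 s at
500 Hz, putting all four rates (0.8, 2, 3.2, 4.4 Hz) exactly on the 0.1-Hz
grid; off-grid frequencies use the nearest bin with a logged warning.
Cluster averages use the nine fronto-central channels (F3, Fz, F4, FC1,
FCz, FC2, C3, Cz, C4) by default. Cross-condition normalization divides the
value at frequency f in the matching condition by the mean value at f in
the other conditions, cancelling frequency-specific noise floors; it is
invariant to global gain. Preferred rate is the argmax of normalized vector
length, ties to the lower rate with a flag. Linear trends are OLS with
intercept (slope, R², F vs constant model, p).

## Trial-wise mixed logistic models

Candidates predict accuracy from sin/cos pairs of FM and tACS phase, a
centered depth code, and phase × depth interactions, with a participant
random intercept. The marginal likelihood integrates the intercept by
20-node Gauss–Hermite quadrature and is maximized by L-BFGS with analytic
gradients; with the variance at the boundary it reduces to ordinary
logistic regression. Estimates agree with R's lme4::glmer (nAGQ=20) to
~10⁻⁴ on a reference fit. AIC counts fixed effects + 1 variance parameter;
candidates are fitted on the common trial set (rows with all phases
defined) so AICs are comparable, and ties break toward fewer parameters.
AUC is computed in-sample from conditional predictions (posterior-mean
random intercepts included); surrogate significance refits the winner on
accuracy values shuffled within participant. Conditional in-sample AUC
carries a small optimism that decays with trials per participant (≈0.52 at
1.2k trials, ≈0.504 at 37k); null calibration checks run at ≥6.8k trials.

AIC selection among nested candidates retains a structural overfit
probability (≈0.157 per single spurious parameter), which caps the
probability of the most parsimonious true model winning all pairwise
comparisons at roughly 0.77 under this five-candidate family — a property
of AIC, not of the implementation.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the three designs' structure: gap onsets at the
centers of 9 (or 15) equally spaced phase bins, 3–5 gaps per 20-s stimulus
with ≥1.5 s spacing and 1-s edge margins, ~136 gaps per 32-stimulus block,
eight equiprobable stimulus start phases, per-stimulus FM–tACS lags
(uniform, since they arise from random start phases), sessions/blocks per
design, and response events scored with the 100–1500 ms hit window
(first-press-wins; other presses are false alarms).

Hit probability is an additive clipped cosine of the relevant phase
(clip at 0.02/0.98), so the cosine-fit estimand equals the generating
parameters exactly in expectation. Experiment 1: per-depth FM amplitudes
(defaults 0.08 and 0.12), amplitude gain 1 + 0.4·cos(lag − lag_opt) with
participant-specific uniform lag_opt; preferred FM phases scatter around a
common center (SD 0.4 rad) — listeners broadly agree on when in the cycle
detection is easiest, which is what gives the trial-wise group model a
fixed effect to find — while optimal tACS lags are idiosyncratic.
Experiment 2: Gaussian-in-log-frequency tACS tuning (width 0.35) around a
latent resonance drawn log-uniformly in 0.8–4.4 Hz, plus a weak (0.03)
endogenous sham rhythm resetting at stimulus onset. Experiment 3:
amplitude 0.04 + 0.015/Hz × rate over 15 bins. EEG epochs: a phase-locked
cosine at the FM rate (amplitude 0.02 + 0.02/Hz × rate by default) in
unit-RMS 1/f noise, 30 trials × 9 channels × 10 s at 500 Hz, with a
coherence parameter jittering the phase across trials.

Not emulated: audio waveforms, adaptive staircases (thresholds are absorbed
into the 0.5 base rate), realistic EEG topography/forward models, reaction
time structure beyond uniform 0.2–1.0 s hits, non-stationarities (fatigue,
learning), and any dependence between participants. Passing tests therefore
demonstrate estimator correctness and calibration under the assumed effect
structure, not robustness to real-data artifacts.

## Analysis sizes

Simulation-based checks balance Monte-Carlo error against runtime: 500 null
participants for surrogate calibration; 400 participants with 200
permutations each for the realignment-bias check (SE of the mean z ≈ 0.05);
200 noisy draws for resonance recovery (sweep memoized, dt 0.02 s there and
0.01 s by default elsewhere); 100 generator runs at 10 participants × 16
stimuli/block for model recovery (the AIC overfit probability that governs
recovery is independent of sample size); surrogate counts inside heavy
pipelines use 200 permutations where the production default is 1000.
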