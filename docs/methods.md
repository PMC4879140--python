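# Methods

`nirscombo` implements an end-to-end pipeline for finding the optimal 2- and
3-feature combination for LDA classification of mental-arithmetic vs. rest
fNIRS signals, together with a synthetic-study generator that stands in for
recordings that were never publicly deposited. This note documents the models,
the defaults and their rationale, the numerical choices, and what the
synthetic results do and do not show.

## The classification procedure

**Modified Beer–Lambert law.** Two-wavelength optical-density changes
ΔA(t, λ₁), ΔA(t, λ₂) convert to chromophore concentration changes by inverting
the 2×2 extinction system

    [ΔcHbO; ΔcHbR] = (1 / (l·d)) · α⁻¹ · [ΔA(λ1); ΔA(λ2)]

with α in μM⁻¹·mm⁻¹ (rows wavelength, columns HbO/HbR), l the emitter–detector
distance (default 28 mm) and d the differential path-length factor. The
shipped α defaults are the Gratzer/Cope compiled hemoglobin spectra at
760/830 nm; d defaults to 6.0, a common adult-forehead convention. Neither
choice affects any numeric test: correctness is established by the exact
round-trip property `mbll_invert ∘ concentrations_to_od = identity`, which
holds for *any* invertible extinction spec (verified to 1e-9 μM). A single
scalar d is used for both wavelengths.

**Filtering.** Physiological noise is removed with zero-phase band-reject
filters at 1–1.2 Hz (cardiac), 0.3–0.4 Hz (respiration) and optionally below
0.1 Hz (Mayer waves / drift). The default realization is an FFT-domain mask
with raised-cosine band edges (width 0.02 Hz): exactly zero-phase, no ringing
parameters, trivially linear. A zero-phase Butterworth band-stop
(`filtfilt`) is available behind the same contract. A reject band lying
entirely above the Nyquist frequency — the cardiac band at the 1.81 Hz
acquisition rate, whose Nyquist is 0.905 Hz — is skipped with a logged
warning rather than an error: the contract is honest about what is
mathematically possible at that rate, and the band applies normally to
higher-rate data.

Two spectral options are deliberately **off** in the default end-to-end
pipeline although both are implemented: the reject-below-0.1 Hz highpass and
the 0.1–0.3 Hz analysis band-pass. With 44-s task blocks the evoked response
has its fundamental at 1/88 Hz ≈ 0.011 Hz, far below 0.1 Hz; either filter
removes nearly all block-locked signal and with it the epoch-mean feature the
method is built around. Slow drift is removed instead by per-channel
polynomial detrending (default order 1), and stochastic baseline wander is
treated as part of the noise the classifier must cope with. Users with
event-related or faster paradigms can enable both options via `FilterSpec`.

**Features.** Each contiguous task or rest block, per channel and
chromophore, is one epoch and one classification sample. Six features are
computed per epoch with population (1/N) moments, exactly as conventionally
printed: mean, variance Σ(X−μ)²/N, skewness E[((X−μ)/σ)³], non-excess
kurtosis E[((X−μ)/σ)⁴], signed maximum (peak), and the least-squares slope
against time in seconds. The signed maximum applies to both chromophores, so
an HbR "peak" is its least-negative value; an absolute-peak option exists but
is off. Zero-variance epochs raise an error by default (a drop-with-warning
batch mode exists). Features are min-max rescaled to [0, 1] per subject ×
chromophore over all epochs — reproducing the protocol of scaling before
cross-validation — while a fold-safe mode refits the scaling on each training
fold for leakage-free estimates.

The default pipeline drops the initial 44-s baseline rest block, leaving one
rest epoch per task epoch (80 task + 80 rest samples per subject per
chromophore with 16 channels × 5 trials). Balanced classes make chance level
exactly 50%; with the baseline block included (available via
`drop_initial_rest=False`) the majority-class rate is 54.5% and every null
accuracy shifts accordingly.

**Classification.** LDA is implemented from scratch as the textbook
pooled-covariance Bayes rule: w = Σ⁻¹(μ₁−μ₀), b = −½(μ₁+μ₀)ᵀw + log(π₁/π₀),
with priors from training-fold frequencies and the unbiased (n−2) pooled
covariance denominator (matching the scikit-learn convention, which serves as
an independent cross-check in the tests, never as the implementation). A
ridge of 1e-8 × trace(Σ)/d on the diagonal guards against degenerate
features; exact-oracle tests disable it. Exact boundary ties go to the larger
prior, then class 0. Accuracy is estimated by stratified 10-fold
cross-validation repeated over 10 runs, each run re-shuffling with a seed
derived from the master seed (repeating identical folds would make the runs
vacuous); the reported accuracy is the grand mean over runs × folds, which
equals the mean of run means when folds are equal-sized. Stratification is a
deliberate choice — with balanced epochs, unstratified folds only add noise —
and can be toggled.

**Combination search and inference.** All C(6,2)=15 pairs and C(6,3)=20
triples per chromophore (70 combinations in total) are scored per subject;
combinations are ordered canonically (mean < slope < variance < peak <
skewness < kurtosis, lexicographic), which also breaks ranking ties. The best
combination is compared to the others with an exact one-sided paired
sign-flip permutation test on per-subject accuracies: all 2ⁿ sign assignments
of the paired differences are enumerated (128 for n=7) and p is the
proportion whose mean is ≥ the observed difference; the identity assignment
counts, so p ≥ 1/2ⁿ and p=1 for identical samples. No multiple-testing
correction is applied by default, matching the raw-p protocol being
reproduced; a Holm flag exists for honest reporting. The published
per-subject accuracy tables ship as a sha256-checksummed fixture; the
`reproduce` verb recomputes the cross-subject means (93.08% HbO, 89.92% HbR
for mean+peak, printed as 93.0/89.9 after rounding) and rankings from the
cells, and *flags* — rather than resolves — the published claim that every
subject exceeds 89% with mean+peak (three HbR cells print below that floor).

## The synthetic-study generator

The generator emulates the study conditions: 7 subjects, 16 prefrontal
channels, 1.81 Hz sampling, two wavelengths (760/830 nm, 2.8 cm separation),
and a block paradigm of 44 s baseline rest followed by five 44-s
task / 44-s rest cycles. The stated total of 440 s is inconsistent with that
block arithmetic (44 + 5×88 = 484 s); the generator emits the full block
structure and reports the true duration. Each block is quantized to
round(44 × 1.81) = 80 output samples.

Simulation runs at 16 Hz internally and is point-decimated (linear
interpolation, no anti-alias filter) to 1.81 Hz, deliberately reproducing the
aliasing a real acquisition at that rate shows for cardiac components above
its Nyquist frequency.

**Task response.** The neural drive is phasic-plus-sustained: full drive for
the first 8 s of each block, 35% of it for the remainder — the attenuation
commonly seen across a long cognitive block. The drive is convolved with a
canonical double-gamma HRF (peak 6 s, mild undershoot at 16 s, ratio 1/6),
normalized so a sustained step peaks at exactly `hbo_amp` (default 1.3 μM).
HbR is a −1/3-scaled copy delayed by 1 s. Each trial × channel receives a
multiplicative amplitude jitter (relative SD 0.25, floored at 0).

**Noise.** Sinusoidal cardiac (1.1 Hz), respiratory (0.35 Hz) and Mayer-wave
(0.08 Hz) oscillations with per-channel random phase, per-channel frequency
jitter (±8%, keeping every realization inside its nominal reject band), and
slow stochastic amplitude modulation (depth 0.5, bandwidth 0.05 Hz); white
sensor noise (SD 0.15 μM); per-channel linear drift (≤0.002 μM/s); and
stochastic baseline wander — Gaussian noise low-passed below 0.04 Hz with SD
0.45 μM — representing slow spontaneous hemodynamics. HbR receives the same
sources at half amplitude. Two of these choices matter and are worth
defending: perfectly coherent constant-amplitude sinusoids are nearly
invisible to epoch statistics (they shift every epoch's variance and peak by
the same amount), so without amplitude modulation band-reject filtering shows
no measurable benefit; and without baseline wander and trial jitter a boxcar
response makes every feature separate the classes at 100%, erasing the
structure in which mean and peak are the informative pair.

**Calibration.** The published subjects' signal amplitudes are unknown; the
defaults above were chosen once so that the default pipeline lands in the
published 85–95% accuracy band for the informative combinations and near
chance for skewness/kurtosis pairs. Under these defaults (20 master seeds,
two-feature HbO search): mean+peak ≈ 86–88%, ranks in the top 3 of 15 in
~90–95% of seeds; skewness+kurtosis ≈ 55–60%; a zero-amplitude study yields
45–54% for every combination, consistent with binomial noise around chance.

**Seeding.** One master seed; per-subject generators derive as
`default_rng([seed, subject_index])`, so subjects are independent but the
whole study is bitwise reproducible. CV runs derive per-run seeds from the
master seed by a fixed affine map.

**What passing tests show — and do not.** The synthetic studies demonstrate
that the pipeline recovers a mean/peak-borne effect, that filtering helps
when band-limited noise is actually present, and that nothing in the scaling
or fold handling leaks labels. They do not establish anything about real
prefrontal recordings: the generator has no scalp/skull optics, no motion
artifacts, no inter-subject anatomical variability, and its noise model is
three narrowband oscillations plus Gaussian processes. Published-table
arithmetic (the `reproduce` path) is kept strictly separate from synthetic
results for exactly this reason.

## Problem sizes used in the checks

Fixture arithmetic is exact and instantaneous. The synthetic acceptance
checks use the full default study (7 subjects × 16 channels × 5 trials):
effect recovery over 20 master seeds with 10-fold CV repeated twice per
combination; the permutation calibration uses 2000 simulated paired null
replicates of 7 subjects. The one-seed demonstration run in the acceptance
script uses the full 10×10-fold protocol.

## Known limitations

- The cardiac reject band cannot act at the native 1.81 Hz rate (logged
  skip); cardiac power is present only as aliased energy.
- Per-subject min-max scaling before CV reproduces the original protocol but
  is mildly optimistic; the fold-safe mode is the honest estimator and is the
  one to use for new data.
- The exact sign-flip test is limited to n ≤ 20 subjects (2ⁿ enumeration).
- SNIRF I/O is not implemented; CSV/TSV long format is the interchange
  format.
- Whether the original analysis band-passed to 0.1–0.3 Hz or only
  notch-filtered is not stated unambiguously in the source; both behaviours
  are available here, and the default (no band-pass) is a documented choice,
  not a claim about the original pipeline.
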