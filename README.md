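# nirscombo

Optimal feature-combination search for a two-class fNIRS brain–computer
interface: which pair or triple of time-domain signal features best separates
mental arithmetic from rest with linear discriminant analysis?

The package is aimed at fNIRS/BCI researchers who want a tested, reproducible
implementation of the full procedure:

1. **MBLL conversion** — two-wavelength optical-density changes ΔA(t, λ) to
   hemoglobin concentration changes via the modified Beer–Lambert law,
   `[ΔcHbO; ΔcHbR] = (1/(l·d)) α⁻¹ [ΔA(λ₁); ΔA(λ₂)]`, in μM.
2. **Noise removal** — zero-phase band-reject filtering of cardiac
   (1–1.2 Hz), respiratory (0.3–0.4 Hz) and low-frequency components, plus
   polynomial detrending.
3. **Feature extraction** — per task/rest epoch, per channel and chromophore:
   mean, variance, skewness, kurtosis (population moments), signed peak, and
   least-squares slope (μM/s); min-max rescaled to [0, 1].
4. **Exhaustive combination search** — all C(6,2)=15 pairs and C(6,3)=20
   triples per chromophore (70 combinations), each scored per subject by
   from-scratch LDA under stratified 10-fold cross-validation repeated 10
   times.
5. **Inference** — an exact paired sign-flip permutation test (2ⁿ sign
   assignments of per-subject accuracy differences) comparing the best
   combination against the rest.

Because the original recordings were never deposited, the package ships (a)
the published per-subject accuracy tables as a checksummed fixture, from
which all cross-subject means and rankings are *recomputed*, and (b) a
synthetic-study generator (`nirscombo.synthetic`) that emulates the study
conditions — 7 subjects, 16 prefrontal channels at 1.81 Hz, 44-s block
paradigm, physiological noise placed in the notch-reject bands — so every
pipeline stage is testable end to end. See `docs/methods.md` for the models
and the reasoning behind every default.

## Worked example

Recompute the published results from the packaged tables:

```sh
$ nirscombo reproduce
{
 "hbo_mean_peak_avg": 93.076,
 "hbr_mean_peak_avg": 89.923,
 "hbo_matches_93.0_within_0.1pp": true,
 "hbr_matches_89.9_within_0.1pp": true,
 "top_2feature_HbO": "mean+peak",
 "top4_3feature_HbO": ["mean+peak+skewness", "mean+peak+kurtosis",
                       "mean+variance+peak", "mean+slope+peak"],
 "max_p_mean_peak_vs_others_HbO": 0.0078125,
 ...
}
FLAG: HbO mean+peak cross-subject mean is 93.08; published 93.0 (rounding gap)
FLAG: HbR mean+peak subject S6 prints 86.07, below the claimed >89% floor
```

Reading this: averaging the mean+peak rows over the seven subjects gives
93.08% (HbO) and 89.92% (HbR) — the published 93.0/89.9 up to printed
rounding; mean+peak is the top-ranked pair for both chromophores; and the
exact sign-flip test against every other pair gives p = 1/128 ≈ 0.008 < 0.05
(with seven subjects, all paired differences share one sign). Discrepancies
in the source tables are flagged, not silently resolved.

Run the synthetic pipeline end to end (simulate → convert → filter →
features → score → permutation test):

```sh
$ nirscombo run --seed 1 --out runs/demo
{
 "seed": 1,
 "n_combos": 70,
 "best_combo": "mean+peak",
 "best_chromophore": "HbO",
 "best_mean_accuracy": 88.09,
 "runner_up_combo": "mean+variance+peak",
 "permutation_p_best_vs_runner_up": 0.34375,
 ...
}
```

or from Python:

```python
import nirscombo as nc
from nirscombo.classify import CVSpec

recordings = nc.generate_study(n=nc.NoiseSpec(seed=1))   # 7 synthetic subjects
features = nc.compute_study_features(recordings)          # MBLL + filter + epochs
combos = nc.enumerate_combos(sizes=(2,), chromophores=("HbO",))
results = nc.rank_combos(nc.score_all(features, combos, CVSpec(seed=1)))
for r in results[:3]:
    print(f"{r.combo.label:20s} {r.mean_accuracy:5.1f}%")
```

```
mean+peak             88.1%
mean+variance         87.6%
mean+skewness         87.0%
```

On synthetic studies the mean+peak pair sits at ~86–88% accuracy and in the
top 3 of the 15 pairs for ~90% of random seeds, while skewness/kurtosis
pairs hover near chance — the same qualitative structure as the published
tables. The CLI verbs `simulate`, `preprocess`, `features` and `score` expose
the individual stages; `--config` takes a YAML file mapping onto the
`ParadigmSpec` / `ActivationSpec` / `NoiseSpec` / `ExtinctionSpec` /
`FilterSpec` / `CVSpec` dataclasses.

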