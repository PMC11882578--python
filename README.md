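# neurocmc

Analysis toolkit for audiovisual cross-modal congruency experiments that
combine an implicit association test (IAT) with EEG: behavioral
statistics, single-trial multivariate EEG decoding, and a neurally
informed hierarchical drift-diffusion model (DDM) — plus a synthetic-data
generator with known ground truth, so the whole chain is verifiable by
parameter recovery without access to raw recordings.

**Who it is for.** Researchers studying how cross-modal correspondences
(e.g. pitch–size, pitch–elevation) shape perceptual decisions, and anyone
who wants a tested, seedable reference implementation of the
sliding-window LDA + max-statistic threshold + neurally informed
hierarchical DDM analysis stack.

## The analysis

1. **Behavior.** Per participant, RT outliers are removed (rt < 250 ms,
   or rt > median + 3·1.4826·MAD); congruent-vs-incongruent contrasts of
   median RT and mean accuracy use paired sign-flip permutation tests
   with Cliff's delta (RT) and paired Cohen's *d* (accuracy).
2. **Decoding.** Same-condition trials are averaged into pseudo-trials
   (groups of four); a shrinkage-regularized linear discriminant is fit
   in sliding 60 ms windows stepped by 5 ms, giving spatial filters *w*
   and projections y(t) = wᵀx(t); performance is the ROC AUC from 20-fold
   Monte-Carlo stratified cross-validation; group significance is the
   99th percentile of the distribution of the maximum group-mean AUC
   over time under label randomization (family-wise error 0.01 over
   windows). Forward models a = Xᵀy/(yᵀy) give scalp topographies,
   clustered over time with k-means (k by silhouette); per participant,
   peak discriminant amplitudes y_early_max / y_late_max are extracted
   in the Early/Late component windows.
3. **Modeling.** Those amplitudes (congruency-normalized) and the
   stimulus modality S enter the DDM parameters linearly, per
   congruency condition:

       δ = α₀ + α₁·y_early_max + α₂·y_late_max + α₃·S
       θ = β₀ + β₁·y_early_max + β₂·y_late_max
       τ = γ₀ + γ₁·y_early_max + γ₂·y_late_max

   with the starting point fixed at z = 0.5 and accuracy coding (upper
   boundary = correct). Participant-level coefficients are hierarchical
   normal draws around inferred group means; sampling is adaptive
   Metropolis-within-Gibbs over an exact series-expansion Wiener
   first-passage likelihood; convergence is checked with Gelman-Rubin
   R-hat, models compared by DIC, and directional hypotheses tested with
   posterior log-odds: logit(P(coefficient in predicted direction))
   against logit(0.95) = ln 19 ≈ 2.944.

See `docs/methods.md` for assumptions, priors, numerics and limitations.

## Worked example

```python
import numpy as np
from neurocmc import (synthesize_dataset, reject_outliers, congruency_stats,
                      epoch_preprocess, build_pseudo_trials, decode_participant,
                      extract_peak_amplitudes, SlidingWindowConfig, EpochSet)

trials, epochs, truth = synthesize_dataset(n_participants=8, rng_seed=1)
kept, report = reject_outliers(trials)
print(f"retained {len(kept)}/{len(trials)} trials "
      f"({100 * report['fraction_rejected_pooled']:.1f}% rejected)")
print(congruency_stats(kept, rng_seed=0)[["measure", "p_value",
                                          "effect_size", "effect_type"]])

pre = epoch_preprocess(epochs)                      # 30 Hz low-pass + baseline
cfg = SlidingWindowConfig()                         # 60 ms windows, 5 ms steps
m = (trials.participant_id == 0).to_numpy()
pset = build_pseudo_trials(EpochSet(pre.data[m], pre.sampling_rate, pre.times),
                           trials[m], rng_seed=0)
res = decode_participant(pset, cfg, rng_seed=0)
peaks = extract_peak_amplitudes(res, early_window=(0.125, 0.300),
                                late_window=(0.400, 0.600))
print(f"peak AUC {res.auc.max():.2f} at "
      f"{res.onsets[res.auc.argmax()]*1000:.0f} ms (window onset)")
print(f"early peak: {peaks['early_peak_latency'][0]*1000:.0f} ms, "
      f"AUC {peaks['early_peak_auc'][0]:.2f}; "
      f"late peak: {peaks['late_peak_latency'][0]*1000:.0f} ms, "
      f"AUC {peaks['late_peak_auc'][0]:.2f}")
```

Output:

```
retained 2362/2560 trials (7.7% rejected)
      measure  p_value  effect_size  effect_type
    median_rt 0.007812    -1.000000 cliffs_delta
mean_accuracy 0.007812     1.360528     cohens_d
peak AUC 0.81 at 470 ms (window onset)
early peak: 185 ms, AUC 0.76; late peak: 470 ms, AUC 0.81
```

Reading this: the generator plants slower, less accurate incongruent
trials, so congruent median RTs are lower for all 8 simulated
participants (Cliff's delta −1.0; p = 2/2⁸ is the smallest two-sided
p an 8-participant exhaustive sign-flip test can produce) and accuracy
is higher (d = 1.36). Participant 0's congruency decoder peaks inside
both planted component windows (Early ~185 ms, Late ~470 ms), where the
projections feed the hierarchical model as neural regressors.

The same chain runs as a configured, cached pipeline from the shell:

```sh
neurocmc run --out runs/demo --seed 1          # generate → … → report
neurocmc decode --out runs/demo --randomizations 1000
```

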