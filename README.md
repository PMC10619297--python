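# thermovar

Variability analysis of longitudinal wearable distal-temperature time
series: does including cycling females in a study inflate variance compared
with males?

Ring-style wearables record distal (finger) skin temperature every 1–5
minutes together with an activity metric (MET) and nightly sleep summaries
(sleep start/end, nightly temperature maximum, temperature trend deviation).
Distal temperature is higher and less noisy during sleep, and in many
females the nightly level additionally oscillates with a roughly monthly
(26–32-day) ovulatory rhythm.  `thermovar` implements the full analysis
chain for such data:

1. **Preprocessing** — local-time indexing and de-duplication, dropping
   samples with MET < 0.5 (non-wear/charging artifacts), a per-participant
   0.05/0.95 quantile band on temperature, one summary row per night
   (longest sleep), half-open `[sleep_start, sleep_end)` sleep/wake
   annotation, and a 70 % daily-completeness filter.
2. **Cyclicity classification** — each participant's nightly signal is
   summarised by its autocorrelation profile r(k), k = 0…90 days; profiles
   are compared by exact dynamic-time-warping distance, grouped by
   agglomerative clustering (average linkage, k = 3), and labelled cyclic
   when the cluster mean profile shows a wave-like ACF peak in the
   20–32-day window (prominence and height ≥ θ = 0.15, with the antiphase
   trough at half the lag), with per-individual overrides.
3. **Rhythm power** — continuous Morlet wavelet transform of nightly
   temperature maxima (Δt = 1 day, 64 log-spaced scales spanning periods
   2–64 d); rhythm strength is mean |W(s,t)|² over the 26–32-day band
   outside the cone of influence.
4. **Variability statistics** per participant and time state
   (24 h / wake / sleep), on hourly-rolled series:
   - CV = s / x̄ (sample sd over mean),
   - PV = 2 Σ_{i<j} (1 − min(z_i,z_j)/max(z_i,z_j)) / (n(n−1)),
   - D = (1/(n−1)) Σ |ln(p_{i+1}/p_i)|,
   - cumulative error: running sum of SE_i = ((t_i − m_p)/s_p) − 1 against
     a static population reference (m_p, s_p), optionally after alignment
     by menstrual-cycle phase.
5. **Group comparisons** — Mann–Whitney–Wilcoxon two-sided tests with
   Bonferroni correction (families of 9 state×pair and 15 age-bin
   comparisons), Kruskal–Wallis on final cumulative errors at the 0.01/4 =
   0.0025 threshold, and Cohen's d with pooled sd.

Because real ring data cannot be redistributed, the package ships a
first-class synthetic-cohort generator (`thermovar.synth`) that plants a
circadian waveform, a sleep offset, per-category mean offsets calibrated to
published effect sizes, optional 26–32-day infradian oscillations,
state-dependent noise, charging artifacts, naps, duplicates and
missingness — so every stage is testable end to end against known ground
truth.

## Worked example

```python
from thermovar.synth import SimConfig, generate_nightly_cohort
from thermovar.cyclicity import classify_cohort
from thermovar.spectral import cohort_band_power, group_band_summary

cfg = SimConfig(n_per_group={"cyclic_female": 30, "acyclic_female": 30,
                             "male": 30}, n_days=180, seed=0)
roster, nightly = generate_nightly_cohort(cfg)
labels, _ = classify_cohort(nightly)
truth = roster.set_index("pid")["truth_cyclic"]
pred = labels.set_index("pid")["label"].eq("cyclic")
print("accuracy:", (pred == truth.loc[pred.index]).mean())
print(group_band_summary(cohort_band_power(nightly),
                         roster.set_index("pid")["category"]))
```

prints

```
accuracy: 1.0
         category   n  mean_power  se_power
0  acyclic_female  30    0.008874  0.000954
1   cyclic_female  30    1.379171  0.021028
2            male  30    0.010177  0.001075
```

i.e. every participant's planted cyclicity is recovered, and the mean
26–32-day wavelet power of the cyclic group exceeds both acyclic groups by
two orders of magnitude, while acyclic females and males are
indistinguishable.

The `analysis/` directory holds the same study as six numbered scripts
(simulate → preprocess → classify → band power → variability metrics →
group comparisons); run them in order from the repository root.  Each
prints what it found and writes its tables under `results/study/`.  On the
default scaled cohort (24/24/30 participants, 120 days) the classifier
agrees with the generator truth for 98–100 % of participants, the
Kruskal–Wallis test on final cumulative errors stays far from significance
(the groups accumulate error at the same rate), and only below-50 vs
above-50 female age bins separate after Bonferroni correction.

`thermovar.pipeline.run_pipeline(RunConfig(...), outdir)` runs the whole
chain in one call and writes a manifest (config hash, seed, per-stage row
counts) plus all numeric tables as CSV.

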