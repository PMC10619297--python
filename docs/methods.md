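# Methods

## The synthetic cohort model

The generator (`thermovar.synth`) emulates minute-level distal temperature
T(t) for a participant of category g ∈ {cyclic female, acyclic female,
male}:

    T(t) = B + μ_g + β_i + A_c · c(t) + S · 1[sleep(t)] + w_g · 1[wake(t)]
           + A_m · sin(2π (d(t) − φ_i) / P_i) · 1[cyclic]
           + η_{night(t)} + ε(t)

| symbol | meaning | default | unit |
|---|---|---|---|
| B | wake-time distal baseline | 34.0 | °C |
| μ_g | category mean offset | from effect-size calibration (below) | °C |
| β_i | personal offset, N(0, σ_b), σ_b = `between_sd` | σ_b = 0.25 | °C |
| A_c | circadian amplitude; c(t) = −cos(2π(h−3)/24), nadir 03:00 | 0.5 | °C |
| S | sleep offset (distal temperature is higher asleep) | 1.0 | °C |
| w_g | extra wake-time category offset | from calibration | °C |
| A_m, P_i, φ_i | infradian amplitude / period (U(26, 32) d) / phase | 0.3 | °C, d |
| η | nightly noise, one N(0, 0.1) draw per night | 0.1 | °C |
| ε | per-sample noise, sd 0.35 awake / 0.15 asleep | | °C |

Nights are ~23:00 ± 30 min onset with 7–9 h duration; the infradian term
moves whole nights (it shifts the nightly maximum), not minute noise.
Device realism: short naps that appear as extra summary rows (the
longest-sleep selection must discard them), charging artifacts (MET = 0,
temperature +1 °C, 30–60 min), duplicated rows, uniform sample dropout plus
occasional whole-day gaps.  Nightly summaries report sleep bounds, the
nightly temperature maximum, and the trend deviation (night mean minus the
participant's overall night-mean level).

A reduced nightly-resolution path emits one summary row per night directly
(night mean = expectation of the minute model over the sleep window, using
the sleep-window circadian mean −(3/π)sin(π/3) ≈ −0.827·A_c; nightly
maximum = night mean + 2 sleep-noise sd).  It is used for analyses that
consume only nightly summaries (cyclicity, band power, nightly cumulative
error) and for large replicate studies.

All draws flow from one seed; per-participant substreams are derived by
CRC-32 hashing of the participant id, so any participant regenerates
bit-identically in isolation.

**Effect-size calibration.**  Per-participant sleep means differ between
categories by μ_g (β_i and noise average out), so a target between-group
Cohen's d maps to μ_g = d·σ_b.  Defaults plant the published narrative
values (sleep: cyclic vs male 1.40, acyclic vs male 0.41; wake: −0.41 and
−0.33) via `offsets_for_effect_sizes`; the wake-only offset is
w_g = d_wake·σ_b − μ_g.  Personal offsets are centred within each category
after drawing, so the configured contrast is planted exactly rather than up
to the sampling error of the nuisance draws — with iid offsets a 600-person
cohort can realise a "configured" d = 1.40 as anything in ≈ 1.22–1.58.
Females aged ≥ 50 get an additional −0.30 °C by default (the menopausal
drop that drives the age-bin contrasts); calibration checks disable it.

**What the generator does not emulate:** hormonal physiology (no luteal
asymmetry — cycles are sinusoidal), anovulatory or irregular cycles,
birth-control or pregnancy effects, seasonal drift, fevers, or any coupling
between age and cyclicity.  Passing tests therefore demonstrate that the
pipeline recovers planted structure of realistic magnitude, not that it
handles every physiological contingency of real cohorts.

## Preprocessing

Filter order is de-duplication (first occurrence kept) → MET filter
(strictly below 0.5 dropped, 0.5 retained) → quantile filter, so charging
spikes cannot distort the quantile band.  The band uses
linear-interpolation quantiles at 0.05/0.95; a lower cut at the *median*
would discard half of each participant's data, so the lower bound is 0.05
by design (configurable).  The band is estimated **once** per participant:
re-running the pipeline with the stored band is a no-op.  (Re-estimating on
already-filtered data would remove a further ~10 % each pass — a
band-re-estimation fixed point does not exist, so idempotence is defined
with estimate-once semantics.)  Every dropped sample carries exactly one
reason (duplicate / met_artifact / quantile) in an audit table.

Sleep windows are half-open [start, end) so adjacent windows partition
time; a night's summary covers its own calendar date and the following
morning for wake labelling; dates with no summary are `unknown`.
Completeness is the mean over spanned days of observed/expected samples
(expected 1440/`sample_minutes`); participants below 70 % are dropped.

Note an interaction worth knowing: the asymmetric 0.05/0.95 band trims the
warm (sleep) tail more for groups with wider sleep distributions, so
pipeline-measured group contrasts are mildly attenuated relative to the
planted offsets (≈ 0.1–0.2 d units at default noise).  Generator
calibration is therefore verified on truth-state means; the pipeline's own
effect-size table reflects what the full procedure would report.

## Cyclicity classification

ACF profiles use the biased estimator (statsmodels `acf`, FFT) over lags
0–90 d (≈ 3 cycles in 6 months; capped to the cohort span when shorter,
never below twice the longest candidate period).  Missing nights are
linearly interpolated; > 20 % gaps or a > 14-night run disqualifies.

DTW is the exact full-window dynamic programme with absolute-difference
local cost (numba-compiled; profile length ~91 makes exact DP cheap and
deterministic, unlike the approximate variant often used on longer
signals).  Clustering is scipy agglomerative linkage on the precomputed
distance matrix, cut at k = 3; average linkage is the default as the
standard choice for non-Euclidean distances (single/complete/weighted
available; "ward" runs on a deterministic classical-MDS embedding, since
Ward requires Euclidean coordinates).

A profile "has an infradian peak" when a local ACF maximum in the
20–32-day window has prominence ≥ θ and height ≥ θ (θ = 0.15) **and** the
ACF dips below zero near half the peak lag.  The trough requirement encodes
the wave shape of a genuine oscillation; prominence alone lets ~2 σ noise
peaks (sd ≈ n^(−1/2) ≈ 0.075 at 180 nights) through, which mislabels
occasional members of all-acyclic cohorts.  Clusters are labelled from
their mean profile; members of a cyclic cluster lacking an individual peak
are relabelled acyclic with `override_applied=True` (automating the manual
reassignment step).  Males are reported as one category downstream
regardless of the classifier, matching the study design.

The default source signal is the nightly temperature trend deviation;
nightly maximum is available via `signal="temp_max"` (the two are described
inconsistently in the source material; both work on synthetic cohorts).

## Wavelet band power

Morlet CWT on mean-centred (not variance-normalised — amplitude differences
between groups must stay visible) nightly maxima, 64 log-spaced scales
covering periods 2–64 d, period = scale / f_c at Δt = 1 day.  Band power
averages |W|² over 26 ≤ period ≤ 32 d, excluding times within one period
length of either edge (cone-of-influence margin; edge artifacts otherwise
inflate short series).  Absolute power depends on the normalisation
convention, so only orderings and ratios between groups are asserted.

## Variability metrics

State series are trailing 60-minute rolling means computed within
contiguous state bouts (a bout breaks at a state change or a time gap
> 1.5× the sampling interval), requiring ≥ 50 % of the nominal window
count — smoothing never leaks wake values into sleep bouts.  Variance and
sd are sample (n−1) throughout.  PV and D require strictly positive
values, so they are computed on absolute °C, never on deviation signals
(which raise `UndefinedMetricError`).  PV is evaluated in O(n log n) via
the sorted prefix-sum identity Σ_{i<j} min/max = Σ_j (Σ_{i<j} z_(i)) / z_(j);
tests verify exact agreement with the O(n²) pairwise definition.

Cumulative error defaults to the signed form SE_i = ((t_i − m_p)/s_p) − 1;
an absolute-deviation variant |t_i − m_p|/s_p − 1 is available via
`form="absolute"` (the verbal description "more than 1 sd from the mean"
suggests it, the printed formula does not; the printed formula is the
default).  The population reference is the mean of per-participant means
and the mean of per-participant sds within the individual's own category.

Cycle-phase alignment estimates cycle day 0 (the nadir preceding the
luteal-like rise) by circular cross-correlation with a one-period template:
a first pass against a sinusoid yields per-participant phases, the
period-normalised fold of all cyclic participants gives the group template,
and a second pass refines the shift (0.25-day grid).  This construction is
ours; no published method exists for it.

## Statistics

Mann–Whitney U uses the exact null distribution when min(n_a, n_b) ≤ 8
without ties, otherwise the tie-corrected normal approximation; the
reported U is min(U_a, U_b) (printed U values in the literature are
orientation-ambiguous).  Bonferroni multiplies p by the stated family size
(9 = 3 category pairs × 3 time states; 15 = all pairs of six age bins),
capped at 1.  Kruskal–Wallis on final cumulative errors uses the 0.01/4 =
0.0025 corrected threshold.  Cohen's d uses the pooled (n−1)-weighted sd;
the implementation is cross-checked against pingouin in the tests.

## Problem sizes and determinism

Test and acceptance runs use nightly-resolution cohorts of 90 participants
× 180 nights for classification/band power, a 600-participant × 30-day
minute-level cohort for effect-size calibration, 200-replicate null studies
at 24 × 14 days (minute) and 60 × 60 nights (nightly), and a 78-participant
× 120-day cohort in the analysis scripts — sizes chosen so the full suite
runs in a few minutes on one CPU while keeping every statistical check
well-powered.  Every run is bit-reproducible given the seed; pipeline runs
write a manifest with the config hash and per-stage row counts.

## Known limitations

- Cluster membership counts of any real cohort are not reproducible (they
  depend on private data); only recovery of planted structure is asserted.
- The quantile-band attenuation described above means pipeline effect
  sizes are conservative relative to planted ones.
- Phase alignment assumes a stable period per participant; drifting or
  irregular cycles will misalign.
- `sample_minutes` supports 1 and 5; other cadences would need resampling.
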