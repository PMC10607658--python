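# Methods

This note documents the models, estimators and design choices behind
`vrphobia`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
demonstrate.

## Study design and data model

The pipeline targets a repeated-measures design: each participant
performs two exercises — *Puzzle* (placing 10 objects at prescribed
positions) and *Shooting* (10 shots at moving targets) — under three
environments (*norm*, *arachnophobia*, *acrophobia*), six scenes in all.
Per scene there are two observations: a behavioral action log and a
multichannel EEG record (21 electrodes of the 10–20 system, monopolar CZ
reference, 500 Hz, device pass band 0.5–70 Hz). The default synthetic
cohort has 28 participants → 168 records, 84 per exercise.

Analysis uses 18 channels (FP1, FP2, F3, F4, C3, C4, P3, P4, O1, O2, F7,
F8, T3, T4, T5, T6, PZ, OZ): CZ carries no information under a
CZ-referenced montage, and FPZ/FZ lie on the midline away from the
regions of interest. Sidedness follows the standard convention — odd
labels left, even labels right, Z midline.

## Behavioral metrics

- Positioning accuracy (Puzzle): `A = (Σ_{i≤B} |x_i − x_i*| / N) · 100`,
  with |·| the Euclidean distance in normalized scene units, B the
  number of placements and N all user actions. The formula is a scaled
  mean deviation, so *lower is better*; the returned metrics carry an
  explicit `accuracy_lower_is_better` flag rather than silently
  inverting the scale.
- Reaction accuracy (Shooting): `A = (K/N)·100`, K = successful shots.
- Duration `T = T_f − T₀` and speed `S = N/T`, so `S·T = N` identically.

Positions are 3-D; the norm is Euclidean. Units are normalized scene
units, so absolute positioning-accuracy values are only comparable
within one scene geometry.

## EEG features

**Amplitude statistics** per channel: maximum, mean, and sample standard
deviation (n−1 denominator) of the raw samples in µV; aggregates are
arithmetic means over the retained channels. The maximum is of the raw
(signed) samples, so for a zero-mean signal the mean amplitude is near
zero while the maximum is the positive peak.

**Hurst exponent.** Classical rescaled-range analysis: for window sizes
n = 16, 32, …, N/4 (powers of two) the series is cut into non-overlapping
blocks; each block yields R (range of mean-adjusted cumulative deviates)
over S (block standard deviation); block-averaged R/S is regressed on n
in log–log coordinates. The raw slope is biased upward for short series
(≈0.54 instead of 0.5 at N = 8192 for white noise), so the
Anis–Lloyd–Peters finite-sample expectation E[R/S](n) is divided out and
the estimate is `H = 1/2 + slope(log(R/S / E[R/S]))`. This calibrates
memoryless (iid / Brownian-increment) series to 0.5, pushes smooth
trending series toward 1, and recovers fractional Gaussian noise with
H = 0.8 to within about 0.05–0.1. Estimates are reported clipped to
[0, 1.05]; inputs shorter than 256 samples or constant are rejected.

**Band power.** Welch PSD with 2 s Hann windows, 50 % overlap and
per-window linear detrending (0.5 Hz resolution at 500 Hz; DC-offset
invariant). Band edges are the standard clinical choices — theta 4–8,
alpha 8–13, beta 13–30 Hz. Power is reported as the *mean spectral
density over the band's bins* (µV²/Hz), not the band integral; only
ratios and comparisons are used downstream, so the convention cancels.
The total integrated PSD reproduces the signal variance to within 5 %
(Parseval check in the test suite).

**Interhemispheric asymmetry.**
`IHA(h) = (PSD_r(h) − PSD_l(h)) / (PSD_r(h) + PSD_l(h)) · 100` for the
eight homologous pairs FP2–FP1, F4–F3, C4–C3, P4–P3, O2–O1, F8–F7,
T4–T3, T6–T5. Bounded in [−100, 100], antisymmetric under swapping the
pair; positive values mean more right-hemisphere power.

## Coherence

Magnitude-squared coherence `C_xy(f) = |P_xy|² / (P_xx P_yy)` from
multi-window Welch cross/auto-spectra with the same window parameters as
band power (internal consistency). At least four windows are required —
a single-window estimate is identically 1. The per-record *coherence
matrix* stores, in the strict upper triangle, each pair's mean coherence
over the analysis range (default 4–30 Hz, the theta-through-beta range
the pipeline analyzes elsewhere; configurable).

An entry is kept only if it is statistically reliable: it must exceed
the (1 − α) quantile (default α = 0.05, `method="higher"` for a
conservative empirical quantile) of a null distribution built from
circular phase-randomized surrogates. The null is generated from a
*per-channel surrogate pool*: `surrogate_count` (default 100)
phase-randomized copies of each channel are spectrally decomposed once,
and the null statistic for pair (x, y) is the band-mean coherence of the
real x against each surrogate of y. This is the same null hypothesis —
independent signals with the observed amplitude spectra — at
O(channels·surrogates) rather than O(pairs·surrogates) transforms, which
is what makes 18-channel matrices with 153 pairs tractable. The measured
false-positive rate on independent channels is ≈0.05–0.06 at α = 0.05.
Fewer than ⌈1/α⌉−1 surrogates cannot resolve the quantile and raise.

Group summaries are entrywise NaN-aware means over the records where an
entry is defined, plus per-record deviations from the mean; heatmap
renderings carry the min/max of the defined entries in the title.

## Statistical cascade

Each metric is screened with Shapiro–Wilk (3 ≤ n ≤ 5000); the outcome is
recorded in the report metadata, and the pipeline proceeds
nonparametrically regardless — these metrics routinely fail normality.
Comparisons use Kruskal–Wallis (tie-corrected) across groups; *only*
when the omnibus p < 0.05 are pairwise two-sided Mann–Whitney U tests
(with continuity correction) computed — the reports cannot contain a
pairwise p without omnibus significance, by construction. Identical-value
inputs are reported as H = 0, p = 1 rather than as an error. No
multiple-comparison correction is applied; every report carries a note to
that effect. Human-readable tables print p to three decimals; the JSON
rendering keeps full precision.

Two calibration caveats, verified by simulation and reflected in the
test suite:

- Across-scene comparisons are *repeated measures* (the same
  participants appear in every scene group). With participant-level
  heterogeneity the independent-groups Kruskal–Wallis is therefore
  conservative (measured type-I rate ≈0.003 at nominal 0.05). The
  type-I calibration test runs on exchangeable cohorts (participant
  random effects off), where the measured rate is ≈0.04.
- The chi-square Kruskal–Wallis p-value deviates from the exact
  permutation distribution by up to ≈0.06 for groups of n ≤ 7; the
  permutation-oracle test asserts agreement to 0.07.

## Subgroup discovery

Participant vectors are (A, T, S) for the three scenes of one exercise,
in ascending scene order (9 values), optionally extended by the
participant's mean IHA in alpha, beta and theta (12). Features are
z-scored before clustering — duration (tens of seconds) and speed (~0.1/s)
differ by orders of magnitude, so raw-scale clustering would be dominated
by T. Zero-variance features are dropped with a warning.

Three algorithms (k-means with 10 restarts and a fixed seed, Birch's
CF-tree method, spectral clustering on an RBF affinity) × k ∈ {2, 3} are
run; each candidate partition is scored by the between-cluster
Kruskal–Wallis p on the record-level A, T, S samples. Candidates with
all three p < 0.05 are *feasible*; among feasible candidates the
smallest k wins (more participants per subgroup), ties broken by lowest
mean p, then by fixed algorithm order. No feasible candidate is a
reported outcome ("no statistically separable subgroups"), not an
exception. The selection is a pure function of its inputs and the seed.

One property of this procedure is worth stating plainly: the clusters
are selected on the very metrics they are afterwards tested on, so under
a null with genuinely identical participants the feasibility rate is not
the nominal α — simulation puts spurious feasibility near 35–40 %.
Discovered subgroups should therefore be treated as hypotheses to be
confirmed on independent data (e.g. the EEG characteristics, which the
selection never sees), which is exactly how the downstream subgroup
reports use them.

Per-subgroup reports re-run the cascade between subgroups within each
scene (subgroups smaller than two records are skipped with a note), add
a star to a subgroup×metric cell when that subgroup's *across-scene*
Kruskal–Wallis difference is significant, and tabulate IHA per
pair × band × scene with Mann–Whitney marks and an up/down flag giving
the second subgroup's direction relative to the first.

## Synthetic cohort generator

The generator defines the study conditions the pipeline is validated
under. Each channel is

    x(t) = Σ_band a_band · g_side · m(t) · sin(2π f_band t + φ)
           + c · w_ch · s(t) + pink(t)

with carriers at 6 Hz (theta), 10 Hz (alpha) and 20 Hz (beta); base
amplitudes ≈20/30/15 µV (lognormal participant jitter); per-band
left/right hemisphere gains; a slow (<≈0.5 Hz) nonnegative
amplitude-modulation envelope m(t) of depth 0.3; a shared 4–30 Hz
band-limited source s(t) mixed into every channel with per-channel
weights w_ch ∈ [0.5, 1] and participant coupling c (≈8 µV, ≈14 µV for
abnormal participants — coherence matrices of the abnormal subgroup are
uniformly more connected); and unit-amplitude-shaped 1/f pink noise of
8 µV. Amplitudes are microvolts; values are plausible for scalp EEG but
deliberately not calibrated to any particular device.

The planted *abnormal* subgroup (default 4 of 28, the first participant
ids) differs in two ways:

- **Phobic-scene EEG effects** (abnormal × phobic records only): all
  band powers ×3.0; right-hemisphere alpha power ×0.6 (depression,
  pulling alpha IHA negative); right-hemisphere beta power ×1.4.
- **Performance**: trait-level deficits in all scenes (pace ×2.0,
  placement noise ×2.2, hit probability −0.15) — the susceptible
  subgroup differs throughout the session, not only under stimulus —
  plus phobic-scene decrements (placement noise ×2.5, hit probability
  ×0.55).

Effect sizes are generative conventions chosen once to make the planted
structure comfortably but not trivially recoverable; they are knobs on
`CohortConfig`, not measured quantities. Action logs use gamma
inter-action gaps (mean pace 8 s Puzzle / 2 s Shooting), uniform
unit-cube targets with Gaussian placement noise (σ = 0.04), and
Bernoulli hits (p ≈ 0.78).

Randomness is structured as a spawned seed tree (participant → profile /
per-scene EEG / per-scene actions), so identical seeds give bit-identical
cohorts and the behavioral fast path (`include_eeg=False`) leaves action
logs unchanged. Recruitment attrition is not simulated: the generator
emits usable records, and noisy-record exclusion is modeled separately by
the amplitude-threshold rejection in the I/O layer (1 s windows, default
200 µV peak threshold, whole-record rejection below a 50 % clean
fraction — the criterion the pipeline applies is deliberately simple and
auditable, since real noisy-area removal is usually manual).

**What passing tests do and do not show.** The generator reproduces the
*band-power / asymmetry / coherence / performance structure* of a phobic
response, with known ground truth; it is not biophysical EEG (no
dipole/forward model, no 1/f slope variation, no movement or ocular
artifacts beyond an optional spike injector, stationary narrowband
carriers rather than broadband rhythms). Recovery of planted effects
demonstrates that the estimators and the discovery procedure work as
specified; it does not certify sensitivity on real recordings, where
effect sizes, artifacts and inter-subject variability are unknown.

## Pipeline and reproducibility

`run_pipeline` executes ingest (synthetic or EDF/CSV files) →
channel selection + noise rejection → features → scene comparisons →
coherence matrices and group means → subgroup discovery → subgroup/IHA
reports, writing CSV/Markdown/JSON artifacts plus PNG heatmaps and a
manifest (seed, parameters, config hash, rejected records). Machine-
readable outputs are byte-identical across reruns with the same seed and
parameters. The feature stage is cached on disk keyed by the config
hash, since surrogate coherence dominates runtime. Configs come from
YAML/JSON with unknown-key and range validation; normalization is
idempotent.

Problem sizes in the shipped tests and examples are scaled down (short
records of 0.5–6 s, 2–12 participants for EEG-bearing paths, 20–200
Monte-Carlo replicates) — the estimators are length-invariant by
construction, and the scaled runs keep the full suite within a few
minutes while exercising every code path at the default study shape
(28 × 6) wherever EEG synthesis is not required.

## Known limitations

- Scene-comparison tests ignore the repeated-measures structure (as does
  the procedure they implement); with heterogeneous participants they
  are conservative, not anticonservative.
- Cluster selection is circular with respect to A/T/S significance (see
  above); subgroup EEG contrasts are the independent confirmation.
- The EDF writer targets the plain (uncompressed, 16-bit) profile with
  one-second records and zero-pads non-integer-second signals.
- No multiple-testing correction anywhere, mirroring the analysis design
  the pipeline implements; treat individual p-values accordingly.
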