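# Methods

`nirslat` implements an end-to-end analysis of hemispheric asymmetry in
fNIRS functional networks: preprocessing of dual-wavelength recordings to
residual HbO, Pearson connectivity matrices per condition, repeated Louvain
module detection, and two module-level laterality statistics compared
across tinnitus groups. A synthetic-data generator with known ground truth
drives all testing.

## Laterality statistics

For a detected module containing `Nr` channels whose source-detector
midpoint lies in the right hemisphere, `Nl` in the left, and `Nt` channels
in total:

    ML  = |Nr - Nl| / Nt        in [0, 1]
    MML = (Nr - Nl) / Nt        in [-1, 1]

ML is 0 for a hemispherically balanced module and 1 for a single-hemisphere
module; MML adds polarity (positive = right-dominant). Channels whose
midpoint |x| < 5 mm are "midline": they count in `Nt` but in neither `Nr`
nor `Nl` (the definition of `Nt` is the module size; a central channel
belongs to no hemisphere, and a hard sign cut at x = 0 would assign it
arbitrarily). Per run, module values are averaged unweighted — the
size-weighted mean is available via `weighted=True` and changes nothing
when all modules lie in one hemisphere — and per subject the run means are
averaged over repeated Louvain runs. Singleton modules score ML = 1 by
definition; they are included and their frequency is logged so their
influence is auditable.

Consequences used as test invariants: |MML| = ML per module whenever no
midline channel is present; mirroring the montage in x leaves ML unchanged
and flips the sign of MML; refining a single-hemisphere module leaves every
fragment at ML = 1.

## Preprocessing chain

Order: SCI flagging -> optical density -> TDDR -> modified Beer-Lambert ->
short-channel regression -> 0.03-0.4 Hz band-pass -> GLM residualization.
Flagged channels are dropped (not interpolated); HbO only is carried into
connectivity. Every stage preserves the time axis.

* **SCI.** Per channel, both wavelength series are zero-phase band-passed
  to the cardiac band (0.5-1.8 Hz, 4th-order Butterworth) and correlated;
  channels with r < 0.4 are flagged. A recording must span at least ten
  cardiac cycles. Subjects with >= 8 flags trigger a warning; exclusion is
  left to the caller.
* **Optical density.** `OD(t) = -log(I(t)/mean(I))`, invariant to channel
  gain; non-positive intensities are an error naming channel and sample.
* **TDDR.** The temporal derivative of the sub-0.5 Hz component is
  robustly re-estimated (iterated Tukey biweight location, MAD scale,
  tune 4.685) and reintegrated; the >= 0.5 Hz component passes through.
  The applied weights depart deliberately from the published continuous
  reweighting: every inlier keeps weight 1 and outliers are rejected
  outright by hysteresis thresholding — a contiguous stretch of
  derivatives above 4.685 robust SD is zeroed iff it contains a sample
  beyond twice that cutoff (~9.4 robust SD). Rationale: with continuous
  shrinkage, every weighted derivative sample reintegrates into a small
  permanent baseline shift, and on clean band-limited haemodynamics these
  accumulate into an in-band random walk of 10-40% RMS; measured motion
  spikes and baseline shifts sit 13-90 robust SD out in the derivative
  while the steepest clean excursions stay below ~5, so the hysteresis
  rule removes artifact events with their full flanks and is transparent
  otherwise (< 2% RMS change on a clean 0.05 Hz sinusoid, >= 90% step
  removal at 10 sigma). `inlier_preserving=False` restores the published
  continuous weighting (cross-checked against an independent reference
  implementation in the tests).
* **Beer-Lambert.** Per channel, the 2x2 system
  `dOD_l = eps(l, HbX) * dC * d_cm * DPF_l` is solved per time point.
  Extinction coefficients (cm^-1 M^-1) at 760/850 nm are from the standard
  compiled haemoglobin tables; DPF defaults to 6.0 at both wavelengths
  (configurable — the value rescales concentrations linearly and cancels
  out of every correlation-based quantity downstream). Concentrations are
  reported in micromolar with distances in cm.
* **Short-channel regression.** Each long channel is residualized on an
  intercept plus the nearest (3-D midpoint distance) unflagged short
  channel of the same chromophore; `mode="mean"` uses the mean of all
  unflagged shorts instead. The residual is exactly orthogonal to the
  regressor. If every short is flagged the data pass through with a
  warning.
* **Band-pass.** 8th-order Butterworth high-pass at 0.03 Hz and low-pass
  at 0.4 Hz, each applied forward-backward (zero phase). Even-extension
  padding over three high-pass time constants is used: odd extension
  mirrors large edge values into spurious sub-band content that a 0.03 Hz
  zero-phase high-pass smears over the first and last minute of a run.
* **GLM residualization.** Evoked runs are residualized on an intercept
  plus one canonical-HRF-convolved boxcar per condition (double gamma,
  peak 6 s, undershoot 16 s, ratio 1/6, 32 s duration). The task columns
  are passed through the same band-pass as the data, so the design spans
  the evoked component exactly as the data carry it. Resting runs are
  demeaned. No drift regressors are included beyond the band-pass.

## Connectivity

Pearson correlation of residual HbO across retained long channels:
full-run for rest; for evoked conditions, the window 0-22 s after each
onset (`floor(22 fs)` samples) is extracted per trial, demeaned per channel
— without this, slow baseline offsets between trials inflate every
correlation; it is switchable — and concatenated in onset order. Trials
whose window crosses the run end are dropped with a warning; fewer than two
usable trials is an error. Three matrices per subject: rest, auditory,
visual. Diagonals are zeroed.

## Module detection

Greedy two-phase Louvain maximization of Newman-Girvan modularity
`Q = sum_c [W_c/W - (S_c/2W)^2]` on the positive part of the matrix
(negative correlations zeroed — the most common convention for correlation
networks and the one that keeps Q's range interpretable; a signed variant
with asymmetric positive/negative contributions is available via
`negative="signed"`). Nodes are visited in seeded-random order; equal-gain
moves break to the lowest community index with a 1e-10 gain threshold;
resolution is fixed at 1. Because the node order is random, detection is
repeated (default 50 runs, seeds derived from one master seed) and the
laterality measures are averaged over runs; partitions are never merged
across runs. An exhaustive-search oracle over all set partitions (<= 10
nodes) verifies optimality in tests; 50-restart Louvain attains the global
optimum on 98-100 of 100 random 5-8-node graphs.

On the default 20-long-channel montage, modularity's resolution limit
makes Louvain merge adjacent planted 5-channel modules in some runs, so
detected module counts range 2-5 rather than exactly matching the planted
four. ML is insensitive to this (merges within a hemisphere keep ML = 1);
the signed MML is noisier because merging the lateralized modules shifts
the module-count balance, which is why the left-vs-right contrast is the
statistically marginal one — in both the synthetic study and, notably, the
phenomenon it emulates.

## Group statistics

Omnibus policy: Shapiro-Wilk per group and median-centred Levene, both at
alpha = 0.05, select one-way ANOVA + Tukey (normal, homoscedastic), Welch
ANOVA + Games-Howell (normal, heteroscedastic), or Kruskal-Wallis + Dunn
with Holm correction (non-normal). All tests are two-sided at alpha =
0.05. A device confound is assessed by two-way ANOVA (type-II sums of
squares; interaction dropped with a note when group x device cells are
empty; single-device cohorts reduce to the one-way policy). Within the
tinnitus groups, laterality is regressed on a group indicator, THI,
loudness, annoyance, duration, device and hearing asymmetry
(left-minus-right threshold); covariates constant in the subset are
dropped. VIF is computed as the diagonal of the inverse correlation matrix
of the regressors (exactly 1 for uncorrelated covariates, >= 1 always);
values above 10 are flagged and perfect collinearity is an error naming
the factors. Type-I error of the whole policy measures 0.04-0.06 at
alpha = 0.05 over 1000 null simulations.

A note on an identity sometimes assumed: with exactly equal group
variances and sizes, Welch's F does not equal the classical F; it equals
`F / (1 + 2(k-2)/(k^2-1) * Lambda)` with
`Lambda = k (1-1/k)^2 / (n-1)` (about a 2% gap at k = 3, n = 15). The test
suite asserts this exact relation.

## Synthetic studies

The generator emulates the study design: a 16-source/16-detector montage
(20 long channels at exactly 30 mm, 10 per hemisphere, mirror-symmetric
over frontal/temporal/occipital regions; 8 short channels at 11 mm, at
least one per region), 6-minute resting runs, and evoked runs of 10
15-second auditory and 10 visual blocks in random order with at most two
alike consecutively and 20/25 s intervals. Default cohort composition is
18 controls, 18 unilateral (11 left- / 7 right-sided) and 26 bilateral.
Sampling rate defaults to 7.8 Hz, typical of the device class.

Signal model, per channel: latent HbO is built by a shared-factor
construction over band-limited (0.04-0.35 Hz) unit-variance noise, giving
expected pairwise correlation rho_in = 0.7 within and rho_out = 0.15
between latent modules (verified empirically to 0.02 at 10x duration).
Evoked runs add a canonical-HRF-convolved block response, peak-normalized
so the region amplitude (default 0.8 uM temporal/auditory and
occipital/visual, 0.2 uM frontal/auditory) is the peak concentration
change. HbR = -0.3 HbO + noise (carried only so Beer-Lambert and SNIRF
stages are exercised; it is never analysed). Haemoglobin maps to OD by the
forward Beer-Lambert relation and to intensity as `gain * exp(-OD)`;
cardiac (1.1-1.3 Hz), a shared ~0.1 Hz systemic wave (stronger on short
channels), motion spikes and baseline shifts (onsets recorded), and white
measurement noise are added in OD. "Bad" channels model a decoupled
optode: independent per-wavelength noise with no cardiac or common-mode
content — the property the scalp-coupling index detects. All randomness
derives from the single config seed; identical configs are bit-identical.

Group structure encodes the laterality regimes: controls and bilateral
subjects get interhemispheric modules (one frontal, one occipital, two
temporal spanning both sides; per-module |Nr-Nl|/Nt = 0), unilateral
subjects get the tinnitus-side hemisphere split into three
single-hemisphere modules with the opposite hemisphere as one module
(ground truth ML = 1, MML = +/-0.5; a montage with equal channels per
hemisphere cannot make *every* module majority-one-side, by pigeonhole).
The default group difference is in module topology, not response
amplitude; an evoked-amplitude reduction for tinnitus groups exists as an
option but is off by default, since laterality is the effect under test.

What the generator does not emulate: physiological spectra beyond single
sinusoid-plus-noise components, photon-transport effects, inter-subject
montage registration error, eye-state or run-order effects, and any true
neural difference other than module layout. Passing tests therefore show
the pipeline recovers the stated structure under these idealized
conditions, not that the effect exists in real recordings.

## Oracle choices and problem sizes

The forward model composed with OD conversion and Beer-Lambert inversion
is the identity on injected haemoglobin up to a per-channel constant (the
baseline the OD definition removes), to 1e-9. With all noise sources off,
the full chain recovers injected latent HbO with per-channel r > 0.99;
evoked runs are compared after applying the same task-regressor
residualization to the truth, since removing the latent's chance
projection on the design (~1% of variance) is the GLM stage's intended
effect, not error. The headline contrast is demonstrated on a 15/15/15
cohort (8 left- and 7 right-sided in the unilateral group) with 50 Louvain
runs per matrix — about one minute end to end — and the calibration study
uses 1000 null simulations at n = 15 per group; these sizes keep the whole
suite and the acceptance script to a few minutes while leaving the group
contrasts far from threshold (ML omnibus p ~ 1e-7).
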