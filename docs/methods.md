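# Methods

This note documents the generative model behind the synthetic cortex, the
statistical procedures each analysis module implements, the defaults and
why they were chosen, and what the recovery tests do and do not establish
about real recordings.

## Time base and recording conventions

All times are continuous seconds quantized to a 30-kHz acquisition clock;
every interval is half-open `[start, end)`, and a spike on a bin edge
belongs to the later bin. Spikes are threshold-crossing events per channel
(`unit_id` 0 = unsorted); no waveform-level simulation (filtering,
thresholding, sorting) is attempted because every analysis consumes events,
not waveforms. Stimulation pulses are charge-balanced asymmetric biphasic
pulses — 200 µs cathodal at the nominal amplitude, 100 µs interphase,
400 µs anodal at half amplitude — so net charge per pulse is identically
zero. Each pulse triggers 1.6 ms of hardware blanking (sample-and-hold);
analyses additionally discard the first 2 ms after each pulse to clear
residual artifact. The generator removes events only in the 1.6-ms
hardware window, leaving the 2-ms analysis discard to the analyses
themselves, which mirrors the actual recording chain; because every
analysis re-applies the 2-ms discard, the two conventions give identical
results downstream.

## Synthetic cortex

Each M1 channel is an inhomogeneous Poisson process with log-normal
baseline rate (median 10 Hz, σ = 0.3 log-units — typical threshold-crossing
rates on chronic arrays). Three signal classes modify it:

1. **Direct (pulse-locked) input.** A coupled (S1, M1) pair fires one
   evoked spike per pulse with probability `p_direct` (0.1–0.5 at the 60-µA
   reference, scaled linearly with amplitude and clipped to [0, 1]), at
   latency `Normal(µ_lat, σ_lat)` with µ ∈ [2.5, 5.5] ms and σ ∈
   [0.1, 0.8] ms, truncated below the 2-ms analysis blank and above the
   inter-pulse interval. Direct input is task-invariant by construction:
   the same `p_direct` applies in every behavioral condition.
2. **Indirect input.** An additive firing-rate shift (signed Hz, default
   exponential magnitude with mean 8 Hz, 80% excitatory) during the train,
   rectified at 0 Hz — negative shifts thin the background; they saturate
   once the rate floor is reached, as real suppression must. The shift
   scales with pulse amplitude through a thresholded, supralinear
   recruitment curve `r(A) = ((A − 20)⁺ / 40)²` (zero at ≤ 20 µA, 1 at the
   60-µA reference): trans-synaptic recruitment curves are sigmoidal, and
   this is the lower limb of one. Task dependence enters as a
   multiplicative per-channel, per-task gain on the indirect shift
   (log-normal with configurable spread; sign flips can be injected to
   model responses that invert across tasks).
3. **Movement-related activity.** Per-channel digit-preference profiles
   (Gaussian bumps over digits 1–5, mean-subtracted) scale the rate during
   attempted flexion; a 3-D linear velocity tuning (default 8 Hz per unit
   velocity) drives reach/transport activity; planar cosine tuning falls
   out of the same vectors for center-out reaches.

**Somatotopy.** Preferred movement digits follow a lateral-to-medial
gradient across the 10-column M1 grid; S1 projected-field (PF) digits
follow the same gradient across two 32-electrode stimulable arrays. A bias
factor β ≥ 1 multiplies both `p_direct` and |indirect gain| wherever the S1
channel's dominant PF digit equals the M1 channel's preferred digit. An
optional `coupling_smoothness` Gaussian-smooths both coupling fields across
each S1 array so neighboring electrodes evoke similar M1 patterns (default
0: couplings independent, which is the right null for the calibration
suites).

**Protocols.** Passive stimulation: each S1 channel at least 15 times at
60 µA, 100 Hz, 1-s trains, shuffled order, inter-train gaps uniform in
[3, 4] s. Digit flexion: 125 cued flexions, movement onset = cue + 200 ms
fixed reaction lag (real analyses use recorded movement start; the fixed
lag is the generator's stand-in). Squeeze and grasp-and-transport: 208
trials each, ICMS on a two-electrode pair (thumb + index PF) at one of
{20, 32, 44, 56} µA, balanced and randomized; 8 cube-corner targets for
transport. Center-out: 8 planar targets × 10 reps. All randomness flows
from one seeded generator recorded in the session metadata.

## Modulation detection

Per motor channel, the null distribution is built from 1000 draws; each
draw samples `n_pairs_per_draw` pairs of consecutive 1-s intervals from the
intertrial periods (with replacement) and records the mean rate difference.
`n_pairs_per_draw` defaults to the per-stim-channel train count so the
null's sampling variance matches the statistic's. Blanking is simulated in
the baseline: candidate interval starts sit on the blanking-period lattice
(10 ms at 100 Hz), which lets the simulated blank be applied to the spike
train once, exactly. Rates divide blanked counts by the full interval
duration in both numerator and baseline, so the ~20% duty cycle cancels in
the comparison (a measured +30-Hz injected shift reads as +24 Hz; all
calibrations and recoveries are performed on the same scale).

The pair statistic is the train-vs-preceding-1-s rate change averaged over
trains, z-scored by the null; significance requires the change to fall
beyond all 1000 draws (empirical p < 1/1001, two-sided, operationalizing
p < 0.001 with a p-value floor of 1/(n+1)). A degenerate null (SD = 0)
flags the result unusable instead of producing infinities. On uncoupled
synthetic cortex the z-scores come out ≈ N(0, 1) and the positive rate
matches the nominal level (the calibration suite checks both).

## Pulse locking

The PTA covers one inter-pulse interval in 0.5-ms bins (final partial bin
dropped); per-bin probability is the fraction of pulses with ≥ 1 spike in
the bin. Bins whose start precedes 2 ms are masked — excluded from every
statistic, not zero-filled, so the median is over valid bins only. The
phase-locking index is mean(peak bin and its valid neighbors) − median
(valid bins); ties break to the earliest bin, and a peak at the mask
boundary simply has fewer neighbors. The index is exactly zero for any
constant PTA and insensitive to uniform rate shifts, which is what makes it
a *direct*-input detector.

Significance: 5000 surrogates, each sampling 20% of the intervals without
replacement, keeping each interval's (valid-region) spike count and
redistributing spikes uniformly over the non-blanked portion of the
interval; significant iff the observed index exceeds the 99th percentile of
surrogates, via the exact empirical p-value (1 + #{null ≥ obs})/(n + 1).
Two interpretation choices are worth flagging. First, redistribution is
uniform over the *non-blanked* region: observed spikes cannot occupy
blanked bins, so redistributing over the full interval would dilute
surrogate probabilities and inflate false positives. Second, surrogates are
built on 20% subsamples while the observed index uses all pulses; under the
null the subsample inflates surrogate variance, making the threshold
conservative — measured specificity on uncoupled pairs is at or above the
nominal 99%, never below.

Latency and jitter: 5000 resamples of 20% of intervals; each resample's
latency is the center of its maximum-probability valid bin; the estimate is
the mean, the jitter the variance (SD also reported). Injected latencies of
3–5 ms are recovered within half a bin at `p_direct` ≥ 0.2 and ≥ 1500
pulses. Running the identical estimator at 25/50/100 Hz exposes aliasing: a
response slower than the inter-pulse interval wraps at 100 Hz but not at
50 Hz, and the cross-frequency latency spread flags it.

## Somatotopic mapping

Motor maps: per-channel peri-movement histograms (20-ms bins, 2 s centered
on movement start) per digit; the contiguous 10-bin (200-ms) window
maximizing the max-minus-min digit spread is selected per channel (window
length is unstated in the source protocol and exposed as config; 200 ms
covers a phasic response without diluting it), and modulation is
(rate_d − mean)/mean. The max-spread selection slightly inflates the top
digit's rate — an inherent property of the estimator, visible in the exact
arithmetic tests' tolerances. Projection maps: per M1 channel, the mean
modulation z over stim channels whose dominant PF is digit d, divided by
the grand mean over M1 channels for that digit; this within-digit
normalization makes the map invariant to digit-wide rescaling of
stimulation efficacy (verified as a property test). Multi-digit PFs
contribute through their dominant digit only.

Smoothing convolves grid maps with a 2-D Gaussian (σ = one electrode
pitch), renormalized over wired, unmasked electrodes so edges and unwired
cells neither leak nor dilute; constant maps are fixed points. The
matched-vs-unmatched test pools, across channels, projection-map activation
at each channel's preferred movement digit against all other digits
(two-sided Wilcoxon rank-sum, with the median direction reported). The
preference-profile analysis orders activations by motor-preference rank
(Kruskal–Wallis across ranks) and correlates per-channel motor and
projection profiles against a null that shuffles electrode and digit
assignments *and then smooths*, so smoothing artifacts cannot masquerade as
somatotopic structure. A calibration caveat: the matched-vs-unmatched
rank-sum on *smoothed* maps treats spatially correlated channels as
independent samples and rejects well above nominal under the null
(measured ~33% at the 0.05 level over 12 null cortices); the unsmoothed
variant is calibrated (~5–8%). Positive findings on smoothed maps should
therefore be confirmed unsmoothed — a β = 2 somatotopic bias is detected
decisively either way — and the package's null-calibration checks use the
unsmoothed test. Gradient maps are per-channel Spearman correlations
of the digit profile against digit index. Activation-pattern correlations
compare within- vs between-array stim-electrode pairs (rank-sum) and
regress within-array correlation on grid distance.

## Task dependence

Rates are extracted in three windows with identical ICMS but different
movement context — 1 s post-contact in squeeze, 1 s post-contact (grasp),
first 1 s of transport — with phase-specific baselines (half-second before
contact for squeeze/grasp; first half-second of the reach for transport).
The "multi-way ANOVA" is implemented per channel as a two-factor
(phase × amplitude) fixed-effects ANOVA with interaction, type-II sums of
squares; the design is balanced by construction so type-II and type-III
agree up to noise. The td-index F_interaction/F_amplitude is reported only
for amplitude-significant channels (it is meaningless otherwise). Because
direct input is task-invariant in the generator, direct-only channels sit
near zero td-index while task-gated indirect channels spread wide — the
pipeline's key dissociation, checked as a rank-sum contrast at
96-channel scale.

Amplitude classifiers: shrinkage LDA (`lsqr` solver, Ledoit–Wolf 'auto'
shrinkage — the small-sample default, which also absorbs singular
within-class covariance) on baseline-subtracted half-second rates;
within-condition accuracy by leave-one-out, cross-condition by
train-on-all/test-on-all; chance 1/4. Target classifiers: Gaussian naive
Bayes on 1 s of rates starting 400 ms before movement onset, channels
filtered at a 5-Hz session-mean activity floor, leave-one-out, chance 1/8;
the center-out variant smooths 20-ms binned rates with a 100-ms Gaussian,
averages over the reach, and classifies the top-10 principal components
with LDA.

## Closed-loop decoding

The decoder is an indirect OLE: per-channel encoding `rate = b0 + B·v` fit
by ridge regression on 20-ms bins (penalty on velocity coefficients only),
decoded through `v̂ = (BᵀB + λI)⁻¹ Bᵀ (r − b0)`. λ defaults to 1e-3 times
the mean diagonal of the velocity normal matrix; λ = 0 is exact OLS and
raises on rank deficiency. Training uses ideal cursor-following
trajectories with contact-phase blanking but no stimulation — the
calibration regime for ICMS-feedback use — collapsing the two-stage
(observation, then assisted) calibration into one supervised fit, since the
staging is an operator convenience, not an algorithmic requirement.

The task simulator runs 20-ms steps: intended velocity is a proportional
pull toward the goal (gain 1.5 s⁻¹, capped at 0.3 units/s), the population
fires Poisson counts from its tuning plus ICMS contamination, contact-phase
counts are thinned at the 16% blanking duty cycle (in *all* conditions,
including no-stim), and the decoded velocity (exponentially smoothed,
α = 0.1) moves the hand. Targets are 8 cube corners at 0.4 units; a phase
exceeding 10 s fails the trial; transport path length accumulates
regardless. These scales were fixed so an uncontaminated decoder completes
trials comfortably within the timeout. Contamination is the generator's
indirect shift for the feedback pair, amplitude-scaled by the recruitment
curve; the feedback pair is the thumb/index-PF pair whose contamination
most strongly drives the decoder at 52 µA, emulating the experimental
selection of electrodes with robust, percept-evoking effects. Because
contact persists through transport, the *linear* policy (52 µA) injects a
constant decoded-velocity bias for the whole transport, while the
*biomimetic* policy's 72-µA transients play out during the automatic grasp
hold and its 32-µA sustained phase sits low on the recruitment curve —
which is why biomimetic feedback tracks the no-stim condition. Outcome
statistics: per-condition failure proportions with pairwise Pearson
chi-squared (uncorrected — the Yates correction is unnecessarily
conservative at 60 trials and is not the standard test here), and path
lengths with two-sample KS and Wilcoxon rank-sum.

A charge note: over a contact of duration T, linear cathodal charge is
52·100·T µA·pulses against 72·40 + 32·(100T − 40) for biomimetic; the
policies break even at T = 0.8 s, biomimetic delivering *more* charge for
shorter contacts (transients dominate) and increasingly less beyond it
(4800 vs 5200 at 1 s).

## Problem sizes and determinism

Calibration suites run at study scale (96 M1 channels; 60–64 stim
channels; 15 trains per channel; 500–5000 resamples); recovery tests use
the smallest cortex that pins down the parameter in question (single pairs
for exact-value oracles, 48–96 channels for distributional claims). The
acceptance script derives every generator from `--seed` and runs in a few
minutes on one CPU. The pipeline is deterministic given the seed; each CLI
stage spawns its generator as `default_rng([seed, stage_id])` and records
its parameter block in the output metadata.

## What the synthetic tests do not show

The generator's background is Poisson — no refractoriness, bursting,
oscillations, or slow nonstationarity — so the bootstrap null is, if
anything, narrower than on real baselines; real-data type-I control
depends on the intertrial periods capturing genuine baseline variability.
Indirect effects are instantaneous, non-adapting additive shifts (onset lag
and adaptation are exposed as parameters defaulting to 0, as their
statistical form is not characterized in the source protocol); evoked
latencies are unimodal Gaussians with no antidromic/orthodromic structure.
Electrode crosstalk, artifact residue beyond the blank window, and unit
drift are absent, so the pulse-locking specificity measured here is an
upper bound. The closed-loop simulator uses its own arm-scale units and a
disembodied proportional controller: failure rates and path lengths
reproduce the *direction and ordering* of the feedback-policy effects, not
participant-specific magnitudes.
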