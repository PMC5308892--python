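# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the numerical edge cases.

## Trial paradigm and conventions

All analyses are aligned to CS onset. The default geometry is a 100 ms CS, a
500 ms trace interval, a 100 ms US (paired trials only), so US onset sits at
+600 ms. Every analysis window is half-open in milliseconds relative to CS
onset — `[a, b)` — and a spike or sample at exactly `b` belongs to the next
bin. The trace interval `[100, 600)` is the default window for single-trial
rates; decoding uses the first 200 ms after CS offset, `[100, 300)`.
Condition labels are `{ACS,VCS} x {ALONE,US}`; the relational axis contrasts
`*_ALONE` vs `*_US`, the physical axis `ACS_*` vs `VCS_*`. The
context-manipulation variant of the paradigm needs no new machinery: box
identity is carried as a label token and collapsed with `BOX_BINARY`.

## Synthetic-data generator

The generator exists to exercise the statistics, not to model biophysics.

**Schedule.** Per session, `epochs_per_session` epochs of
`n_cs_alone + n_paired` trials; one CS modality per epoch, order
pseudorandomized per session from the seed; ITIs uniform over 20–40 s by
default. Defaults reproduce the paradigm's published structure (20 + 80
trials, two epochs).

**EMG.** Baseline is zero-mean Gaussian noise (SD 1, arbitrary units). A CR
is a 150 Hz burst with a smooth envelope filling the 200 ms before
(expected) US onset, amplitude 8x the noise SD; per-(session, condition) CR
probability follows a logistic learning curve over sessions (floor 5%,
ceiling 90%, midpoint and slope configurable) for paired conditions and
stays at the floor for CS-alone conditions. Hyperactive (grooming-like)
bursts occupy most of the 300 ms pre-CS window on a configurable fraction of
trials (default 5%), with log-normal amplitude variability. Paired trials
carry a saturated 100 ms US stimulation artifact; event windows use the same
half-open sample indexing as the trace slicing so the artifact never leaks a
sample into the CR window (the Hilbert transform is global, so even a single
saturated sample inside the scored segment would bias the envelope).

**Spike trains.** Inhomogeneous Poisson: baseline rate everywhere (so ITI
contrasts have a substrate), scaled during the CS + trace window by
`1 + (gain - 1) * stage_magnitude` and a mean-one multiplicative log-normal
per-trial noise whose sigma is `trial_noise_sd * stage_consistency`. The
log-normal choice lets consistency be degraded without moving the mean rate,
which is what separates the magnitude and consistency components of
selectivity. Gains apply uniformly over the CS + trace window (a single
boxcar); diverse PSTH shapes are deliberately out of scope. Class
definitions: relational units share gains across modalities within pairing;
physical units share gains across pairing within modality; conjunctive units
elevate exactly one condition; non-selective units respond equally
everywhere; unresponsive units ignore the task. Mixture sampling
(`EnsembleSpec.from_mixture`) draws per-unit gain signs and log-normal
magnitudes — without that heterogeneity the condition-mean population
vectors are flat across units and carry no similarity structure, so
homogeneous ensembles are useless for the ensemble-level tests. Default
class proportions follow the published prevalence of the classes (10.5%
relational, 13.7% physical, 17.6% conjunctive, ~65% responsive in total).

**What the generator does not emulate.** No spike-sorting noise, bursting,
refractoriness, correlated variability between simultaneously recorded
units, PSTH dynamics within the trace interval, cross-day identity of units,
or multi-rat variance structure. Tests passing on this generator show the
statistics are implemented and calibrated correctly, not that the biological
effect sizes are realistic.

## Behavior scoring

The instantaneous EMG amplitude is `|hilbert(x)|` computed over
`[CS - 1.1 s, US)` per trial, so analytic-signal edge effects fall outside
the scored windows. Pre-Value = mean over `[-300, 0)` ms; CR-Value = mean
over the 200 ms ending at US onset; a pre-CS-phase control value is taken
over `[-1000, -800)` ms ("around 0.9 s before CS onset" is fixed to that
window; only the center is prescribed). The session Threshold is the mean
Pre-Value across all trials plus two SDs, computed in a single pass —
hyperactive determination does not feed back into the threshold, because the
mean+2SD rule is only meaningful when pre-CS bursts are rare (at ~5%
prevalence the threshold sits between the noise and burst distributions; in
a hypothetical all-hyperactive session no trial-relative threshold could
flag every trial). CR% per condition is `100 x CRs / valid trials` with
hyperactive trials excluded from the denominator, and zero valid trials is
an explicit error, never a silent zero.

Stage segmentation: BEFORE is the maximal prefix of days below 30% CR; the
first two consecutive days at or above 60% belong to LEARNING and the
post-learning weeks start the following day (a literal reading of "days
following two consecutive days"), in 7-day blocks POST_1W/2W/3W; later days
are tagged BEYOND and excluded. Staging uses paired-condition CR% only,
since CS-alone CR% stays flat. If the asymptote criterion is never met, all
non-BEFORE days are LEARNING and a warning is raised.

## Rate tensors

Raw rates are counts per bin / bin width (Hz) on the 50 ms grid over
`[-400, 600)`. MAX normalization divides each unit by the maximum of its
condition-mean matrices across the four conditions (so the scale is set by
the condition-averaged response, not by single-trial extremes; single-trial
maxima are used only inside the decoder, where the procedure prescribes
them). Z-scoring uses the mean/SD of the unit's binned rates over the 1 s
pre-CS baseline pooled across trials. Degenerate units (zero max, zero
baseline SD) are emitted as all-zero with a warning record rather than
dropped, keeping tensor shapes stable. The 1500-spike QC criterion is strict
(`> 1500`), following the stated "more than 1500" wording.

## Ensemble similarity

Similarity between two conditions in a bin is the Pearson r across units of
the normalized condition-mean rates. The relational-vs-physical contrast
Δr = r(ACS_US, VCS_US) − r(ACS_US, ACS_ALONE) is tested per 50 ms bin over
`[0, 500)` by reassigning trials between the two conditions of each pair
independently (per-condition counts preserved; normalization constants are
held fixed, as a per-unit constant rescaling) and recomputing Δr 1000 times.
The p-value is two-sided with the (b+1)/(n+1) convention — it can never be
exactly zero — and a bin is significant at α = 0.05/10. A stated per-tail
mass of 0.0025% is unreachable with 1000 permutations and is read as 0.25%
per tail (0.05/10 split across two tails). Fewer than 100 permutations are
refused as too coarse for the adjusted α.

Template correlation: the template is the mean trace-interval population
vector over the 10th–80th paired trials of a reference condition; each of
the 200 trials' PVs is correlated against it, template members included by
default (a leave-one-out mode exists but is off). The 95% band uses the
Fisher z transform with n = number of units; a bootstrap band was
considered and rejected as needlessly expensive for a per-trial display.

## Decoding

One run: draw 20 trials per condition without replacement; divide each
unit's rate by its maximum over those 80 trials (an all-silent unit
contributes zeros); split 10/10 per condition; select (cost, gamma) for the
RBF kernel by 5-fold stratified CV on the training half over the standard
log2 grid (cost 2^-5..2^15, gamma 2^-15..2^3, step 2), ties broken toward
the smallest cost then gamma for reproducibility; refit and score the
held-out 40 trials. Runs repeat 20 times with fresh samplings. A reduced
3x3 subgrid (cost 2^{-1,3,7}, gamma 2^{-7,-3,1}) is provided for
calibration studies where the full grid's cost is not warranted.

Chance is calibrated per classifier: 50 repetitions of the identical
procedure after assigning every trial a random label, each contributing its
40 held-out readouts (2000 pooled readouts). The cutoff defaults to the 95th
percentile of the 50 per-repetition accuracies; a pooled alternative
(binomial quantile at the pooled readout success rate) is also exposed,
since the wording "distribution with 2000 datasets" admits both readings.
Relative accuracy = raw − cutoff.

Stage comparisons sample 20 sets of 150 units from the stage pool
(degrading with a recorded note if the pool is smaller), re-pair trials at
random within condition per unit (pseudo-population — correlated activity is
deliberately ignored), and report per-set relative accuracy. Binary
collapses relabel after sampling, which stays stratified by the original
four conditions to preserve modality balance. Parameter sweeps (bin size,
window position, ensemble size) reuse the same machinery.

## Single-neuron selectivity

Differentiation index: (Fr1−Fr2)/(Fr1+Fr2) on trace-interval means, Fr1 =
CS-alone (relational) or auditory-CS (physical) group; magnitude analyses
use |index|; both rates zero is undefined and excluded. Mutual information:
plug-in estimate between condition and the trial rate discretized into 10
equal-width bins over the unit's pooled observed range (last bin
right-closed), log base 2 — the base cancels in the normalized MI and the
p-value, so nothing downstream depends on it. Bin edges depend only on the
pooled rates and are therefore fixed across permutations. Trial-count
imbalance (20 alone vs 80 paired) is left as is: permutations preserve
group sizes, so the null absorbs the imbalance.

Permutation significance: 1000 label shuffles, p = (#{null ≥ obs}+1)/1001,
significant in the 5% upper tail; normalized statistic = (obs − null mean)
/ null SD (undefined, with a valid p, when the null is degenerate).
Responsiveness is a permutation test of |mean rate difference| between the
CS+trace window and equal-duration ITI windows placed 10 s before each CS
(configurable; far from any stimulus under the default ITIs), α = 0.05 per
condition — the comparison is prescribed, the statistic is this package's
choice. Categories: relational / physical / conjunctive by which contrasts
are significant (both ⇒ conjunctive); a one-vs-rest conjunctive variant is
available behind an argument since the class's operational definition
admits either reading; only responsive units are categorized.

## Calibration and problem sizes

The acceptance checks run at desk scale, chosen as the smallest sizes at
which the binomial confidence bands are informative: 1000 neurons x 1000
shuffles for MI calibration; 100 null datasets x 150 units with the reduced
grid for the decoding type-I error; 200 null tensors for the Δr test; stage
probes are exact and instant. Stage-contrast demonstrations (decoding
crossing, magnitude/consistency dissociation) use 60-unit ensembles, 3
neuron-sets and the reduced grid; directions of effect, not effect sizes,
are asserted. The test suite asserts only properties these runs themselves
compute.

## Known limitations

Permutation p-values are conservative under heavy ties (discrete spike
counts at small trial numbers), so calibration sits slightly below the
nominal level. The plug-in MI estimator is positively biased at finite
trial counts; the normalized MI and permutation p inherit and correct for
this under the null, but raw MI values should not be compared across very
different trial counts. The single-pass threshold rule cannot flag
hyperactive trials when they dominate a session. The pipeline treats units
as independent samples; nothing here addresses noise correlations or
cross-day unit identity.
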