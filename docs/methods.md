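# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Conventions

Positions are 0-based cm in `[0, 200)`; the track is discretized into 40
half-open 5 cm bins whose centers `(i + 0.5)·5` are used whenever a bin
maps back to cm.  Frames with speed below 1 cm/s are immobile and excluded
from rate maps and decoder training.  Condition labels are `R` (rewarded),
`UR` (unrewarded), `RR` (re-rewarded), `N` (novel rewarded), `DARK`.
Reward delivery is a single-frame pulse; the 1.5 s consumption /
teleportation pause appears as zero-velocity frames after it, not as a
separate channel.  Storage is float32 (HDF5 + TSV); computation float64.

## Behavioral segmentation

A lap starts where position wraps (teleportation) or the condition
changes; condition changes mid-track flag both fragments partial, and
partial laps are excluded from lap-wise statistics.  Lap duration is the
traversal time excluding the pause.

**Lick-stop lap.**  The anticipation zone starts at the mean position of
the first lick on licking R laps and runs through the pause.  The stop lap
is the lap *following* the first run of `k = 2` consecutive UR laps with
zero anticipatory licks; later isolated licks never relabel
(first-occurrence rule).  UR laps before it are `RE_HIGH`, from it onward
`RE_LOW`.

**Engagement.**  The approach ratio is mean binned velocity over
100–150 cm divided by 175–200 cm.  A `RE_LOW` lap is `ENGAGED` when its
ratio is at least `mean_R − 1.5·sd_R`.  The threshold is one-sided
(engaged = not unusually flat): the criterion describes a lower bound, and
the analogous pupil criterion is unambiguous about the direction, so the
same reading is used for both (`engagement_sd_mult` config).  The pupil
variant correlates each lap's 40-bin pupil-area curve with the mean R-lap
template after blink removal (blink area < mean − 2 sd, linearly
interpolated) and immobility filtering; the default threshold is
`mean_R − 1.5·sd_R` of R-lap correlations, with the plain `≥ mean_R`
variant available by config.

**Matched-velocity laps.**  A UR lap is matched when its duration falls
within `[min, max]` of R durations (range inclusion).  A histogram variant
(1 s bins, matched iff the lap falls in a nonempty R bin) is config-
selectable, since the original histogram bin width is not recorded.

Rolling averages are trailing (causal) means over 3 laps; a "running"
average is read as causal, and a centered variant would shift the apparent
transition lap.

## Position decoding

Gaussian naive Bayes over cells with the 40 position bins as classes,
uniform class prior (occupancy on a forced-run track is near uniform), and
a per-cell per-bin variance floor of 1e-6.  Prediction is the posterior
argmax with ties toward the lower bin.  The track is treated as a circle:
residuals wrap to at most 100 cm.  R² uses circular residuals against a
linear total sum of squares about the arithmetic mean of true positions;
`circular_r2=False` restores raw residuals (both are implemented because
the choice is not derivable from the description; circular is the
default).  Cross-condition protocol: train on the first 60% of R laps,
test on the rest of R and all UR/RR laps.  Within-condition protocol:
down-sample every condition to the smallest condition's lap count, then
slide a 20% test window one lap at a time, averaging each lap's R² over
the folds containing it.

**Inflection.**  The UR lap-wise R² series (rolling-averaged, window 3) is
fit with the reverse Boltzmann sigmoid
`f(x) = A₂ + (A₁−A₂)/(1+exp((x−x₀)/dx))`, initialized at
`A₁ = max`, `A₂ = min`, `x₀ =` lap of steepest drop, `dx = 1`, with
bounded least squares.  The inflection lap is the first sign change of the
discrete second derivative on a 0.01-lap grid, rounded to the nearest
lap; fits with indistinguishable plateaus are flagged degenerate with no
inflection.

## Place fields

**Transients.**  The cited transient-extraction procedure is not spelled
out in the source literature, so the package defines one: noise σ is the
RMS of below-median residuals; a significant transient is a maximal run
above `median + 2σ` lasting ≥ 0.33 s with peak ΔF/F ≥ 0.10.  All three
thresholds are config.  For somatic traces arriving as raw fluorescence, a
rolling 8th-percentile baseline over 500 frames defines
ΔF/F = (F−F0)/F0 (`baseline_percentile`, `baseline_window`).

**Rate maps.**  Laps × 40 mean ΔF/F over running frames, computed on the
transient-masked trace, so out-of-field bins reflect real transients
rather than measurement noise (binning the raw trace leaves positive
noise in most bins and fuses candidates into track-wide runs).  The
per-cell baseline (25th percentile of bin means) is subtracted and
negatives clipped.

**Candidates.**  Maximal runs of bins above a noise floor of 5% of the
curve peak (`candidate_rel_floor`; 0 restores strict positivity), each
containing its run's local peak; runs touching bin 39 are clipped at the
track end.  Separate bumps give separate candidates — multiple fields in
one cell are treated independently.

**Criteria**, evaluated in order, first failure recorded: (1) width
> 10 cm unless clipped; (2) in-field mean ΔF/F > 0.10 above baseline,
read as baseline-subtracted per-cell units; (3) in-field mean > 4× the
out-of-field mean; (4) in-field transients on > 30% of laps; (5) the
rising phase lies on the track — a field confined to the final bin fails,
and in-field transient onsets must predominantly occur during running,
not during the post-reward pause; (6) bootstrap p < 0.05.  The bootstrap
rotates every lap's 40-bin row by an independent uniform circular offset
(1000 shuffles), the statistic is the in/out mean ratio of the candidate
interval, and p uses the add-one estimator `(1+#{shuffle ≥ obs})/(1+n)` —
the originally cited shuffle construction is not published in-text, so
per-lap independent rotation is this package's definition.

**Parameters.**  Per-lap COM `Σ Fᵢxᵢ/Σ Fᵢ` over field bins with bin
centers, averaged over laps with nonzero in-field activity.  Reliability:
out-of-field bins zeroed, L×L lap-pair Pearson matrix over laps with
in-field variance, mean of the off-diagonal (the diagonal is identically
1 and would only inflate the score) times the fraction of laps with an
in-field transient — 1.0 for a cell firing identically every lap, 0.5 for
one firing at the same place on half the laps.  Out/in ratio is mean
ΔF/F outside over inside (criterion 2's per-cell baseline is used, not a
per-field one).  Width is the bin-run length × 5 cm, with clipped fields
ending at the track end.  Intensity is the peak of the mean curve.
Spatial correlation between conditions uses the unrestricted mean curves
(out-of-field activity retained), with a half-split within-condition
control.

**Fate.**  An R field is *stable* in a later condition when the same cell
has a field there overlapping its bin interval by ≥ 1 bin, *remapped*
when the cell has only non-overlapping fields, *disappeared* when it has
none; later-condition fields with no overlapping earlier field are *new*.
The overlap rule is parameter-free (no stability threshold is published).
Note its interaction with field width: a field shifted by less than its
own width still overlaps, so small remaps are counted as stable — the
generator's minimum remap shift (25 cm) is smaller than typical widths
(~45 cm), and recovered remap fractions run below the configured fraction
accordingly.  Percentages are printed to one decimal,
round-half-away-from-zero.

**Over-representation.**  Maximum-likelihood Gaussian on all field COMs,
KS comparison against uniform, and the density delta: % of fields in
150–200 cm minus the mean % per 50 cm bin over 50–150 cm (uniform
expectation 25% per bin).

**Reward cells.**  A cell qualifies when significant transients occur in
the final 40 cm of the track and within ±2 s of reward delivery on > 30%
of laps in *both* a familiar and a novel rewarded environment (cells
matched by row index); peri-reward lap × time-bin profiles and their time
COM accompany the set.

## Population dynamics

Each analyzed lap's population vector holds, per 5 cm bin, the mean ΔF/F
of every R-defined place cell.  The lap-pair correlation averages, over
the 40 positions, the Pearson correlation of the two laps' cell vectors
at that position (zero-variance positions skipped and counted).  K-means
runs on the flattened lap vectors — the literal reading of "lap-wise
population vectors" — with Euclidean distance on raw ΔF/F (entries share
units; z-scoring available by config).  The elbow choice of k anchors the
WCSS curve at k = 1 and takes the maximum second difference over k =
2..8, falling back to a configured k when clustering reduces WCSS by less
than 20% (no real structure).  The Rewarded-cluster probability runs
k-means 1000 times with fresh random initialization; per run the Rewarded
cluster is the modal cluster of R laps (ties to the larger cluster), and
each lap's probability is the fraction of runs assigning it there.

## Dopaminergic axons

ROIs with pairwise Pearson r ≥ 0.7 merge by connected components (mean of
members).  Axon ΔF/F uses a centered rolling 8th-percentile baseline over
2000 frames, edge-truncated.  Each lap's pre-reward span is divided into
34 equal time bins and the 2 s after reward into 6 (per-lap equal
fractions, so laps of different duration align bin-wise); rows are
min-subtracted per lap and the session is divided by its maximum bin.
Unrewarded laps lack a reward frame and align to the teleportation frame,
where reward previously occurred — preserving comparability of the
34-bin pre span.  On R laps the maximum is located within 15 pre-reward
bins of lap end and the minimum within 25 bins of lap start; other
conditions search only within the ranges where the R maxima/minima fell.
The slope is an ordinary least-squares line over the bins between the
located minimum and maximum inclusive (units: normalized ΔF/F per bin);
slope, max and slope×max are each divided by their R-lap means, making
the R means exactly 1 (laps whose minimum bin reaches their maximum bin
are flagged and excluded from means).  A motion-initiation-aligned view
(epochs of ≥ 1 s above 1 cm/s; −2 s..+8 s windows; per-epoch
max-normalized velocity) supports identifying velocity-coupled axons.

## Estimation statistics

Condition comparisons report the observed mean difference with a
percentile bootstrap CI (5000 resamples; pairwise resampling when
paired).  The headline statistic is the mean — figure-style reporting in
this literature labels Δ as a bootstrapped *mean* difference even where
prose says median — with the median variant behind a flag.  Boxplots use
linear-interpolation (type-7) quantiles, 1.5·IQR whiskers, and explicit
outlier listing so tests can run with and without outliers.

## Synthetic sessions

The generator emulates the study conditions: 34/28/27 laps in R/UR/RR;
lap durations lognormal with median 7.3 s (disengaged laps 1.6× slower);
engaged laps flat to 150 cm then linearly decelerating so the approach
ratio is 1.3 ± 0.04, disengaged laps flat (ratio ≈ 1.0); licking at 8 Hz
inside the zone from 180 cm; licking ceases on a UR lap drawn from
N(5, 1) — the `lick_stop_lap` recorded in ground truth is the boundary
the k = 2 rule implies (first silent lap + 2), which is what the detector
estimates; 30% of RE_low laps disengaged.  An optional random-relick flag
adds isolated licks on laps at or after the boundary (15%/lap) to test
stop-detection robustness.

Place cells (45% of cells) have Gaussian tuning (σ = 10 cm), lap-wise
Bernoulli reliability (default 0.8), and amplitudes lognormal around
0.6 ΔF/F — chosen so planted fields clear the fixed detection floor
(criterion 2's 0.10 ΔF/F) and realized field intensities land near 0.35;
field centers mix uniform with a reward-end Gaussian (114, 55) cm at
weight 0.5.  Activity is the Gaussian rate on hit laps convolved with a
unit-area difference-of-exponentials kernel (rise 50 ms, decay 500 ms,
standing in for unpublished GCaMP6f kinetics), plus Poisson stray
transients (0.02 Hz) and white noise (sd 0.05).  Ground-truth field COMs
are computed from the noise-free calcium signal over the contiguous bins
above 5% of its peak — the realized calcium field's core, which is what
the detector can recover; the kernel shifts this several cm forward of
the latent tuning center, as it does in real recordings.  Fates follow
the configured fractions (0.367 stable / 0.412 disappear / 0.221 remap
into RE_low, with an RR transition matrix consistent with the reference
ledger); remapped centers move > 25 cm; new fields form in silent cells
at 0.49 (RE_low) and 0.23 (RR) per R field.  The map switch occurs at the
lick-stop lap, not at reward removal: UR laps before the boundary express
the R map.

The axon signal is `a · f^2` of the elapsed fraction of the pre-reward
span, resetting within 2 s post reward, with `a` per reward-expectation
state.  Configured levels (R 1.0, RE_high 0.57, RE_low 0.24, RR 1.0) are
on the slope×max readout scale: both slope and max scale linearly with
fluorescence, so slope×max scales quadratically and the signal is scaled
by √a, making the configured level the recovered quantity.

The optional pupil channel is a bump over the final 25 cm (flattened on
disengaged laps) plus noise, with sparse blink dips.

**What the generator does not emulate** — and hence what passing recovery
tests do not establish about real data: drifting baselines and neuropil
contamination, spike-to-calcium nonlinearity, theta-timescale structure,
behavioral variability beyond the velocity-profile family (no stops
mid-track, no backward motion), multi-field cells, and session-to-session
registration error.  Recovery results bound estimator behavior under the
stated noise model only.

## Problem sizes and reproducibility

Default verification sizes: 100 behavior-only sessions for lick-stop
recovery; one 200-cell session for decoder cross-validation, detector
calibration and cluster probability (1000 k-means runs); 50 seeds at 48
cells for the inflection sweep; 120-cell single-condition sessions (~54
planted fields) per reliability level; 600 sampled field centers for the
density fits; 20 axon sessions for ramp recovery; 500 replications × 5000
resamples for bootstrap coverage, with 50 samples per group — the
percentile bootstrap is known to undercover nominal levels at very small
group sizes, so coverage is evaluated where the interval is
well-calibrated.  `scripts/acceptance.py` re-derives all of these from a
single seed; every random stream in the pipeline descends from named
substreams of one master seed, so stages are independently reproducible
and bit-identical under rerun.

## Known limitations

The fate ledger's overlap rule undercounts remaps smaller than a field
width (above).  Criterion 5's operationalization (onsets during running,
field not confined to the final bin) is this package's reading of an
exclusion described only in prose.  The elbow heuristic is sensitive to
its minimum-reduction threshold on weakly clustered data; fixing k = 3 by
config matches the reference analyses.  Reward-cell identification
assumes cells are already matched across environments.
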