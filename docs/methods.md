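# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite does not itself compute.

## Data model

An ERP dataset is a complete subject × condition grid of time × channel
matrices (µV) sharing one sampling step `dt` (ms), one epoch origin `t0`
(stimulus onset = 0 ms) and one montage.  Missing cells are not
supported: every test's permutation scheme assumes a complete grid.
Analysis windows are inclusive ms intervals mapped to the nearest sample.
All statistics operate on average-referenced maps; functions re-reference
on entry if the dataset is not flagged as average-referenced already.

File formats are plain text: whitespace-delimited time × channel ASCII
matrices (optionally transposed on import), and an `xyz` electrode file.
The `xyz` reader accepts both a count-header dialect and headerless
`x y z [label]` lines, auto-detected from the first line's token count;
unlabeled channels are named `Ch1…`.  Dataset archives written by the
package use 17 significant digits so a round trip is bit-exact.

## Permutation machinery

All tests share one engine.  Per randomization run, one shuffle is drawn:
an independent uniform permutation of each subject's condition labels,
plus (when a between-subject factor exists) a uniform permutation of the
group labels across subjects.  Every effect of the design is evaluated on
the same run's shuffle, so null statistics are comparable run-by-run
across effects and reusable by the overall statistics.  All randomness is
drawn from one seeded generator up front, which makes results independent
of internal chunking; in particular, a single-sample window test with the
same seed reproduces the corresponding per-time-point p exactly.

p-values use the add-one convention p = (1 + b)/(n + 1), where b counts
null statistics ≥ the observed one (ties count as exceeding, which is
conservative).  This guarantees p > 0 — required by Fisher's method — and
corresponds to including the identity permutation in the reference set.
A `legacy_p` switch reverts to the literal fraction b/n.

Default runs: 5000 (publication standard); 1000 is adequate for decisions
at the 5% level and is the CLI default.

## Effects and statistics

For a main effect, level means are marginal means over subjects and the
conditions at each level.  For interactions, cell-combination means are
double-centered (both marginal main-effect patterns subtracted) before
entering the statistic, so the interaction test is not contaminated by
main effects; a `raw` mode (cells minus grand mean only) is available via
the config.  The per-effect overall mean is defined as the mean of the
level means, so level deviations always sum to zero.  A single within
factor declared rank- or interval-scaled is tested as a linear contrast:
level deviations are replaced by the single contrast map with centered,
unit-norm level values as weights.

The GFP test applies the identical machinery to the per-map GFP values,
i.e. the dGFP formula with the channel dimension collapsed to the scalar
GFP (n = 1).  Maps are never normalized for the GFP test, since the GFP
is exactly what normalization divides out.  TANOVA normalization, when
requested, divides each subject × condition map by its own GFP at each
time point *before* averaging (per-individual-map normalization); maps
with GFP ≤ 1e-12 µV become zero maps and are counted in a warning rather
than raising, so permutation loops stay total.

## Overall statistics

Each TANOVA run is converted into a p-series by ranking it against the
*other* runs with the same add-one convention used for the observed
series against all runs; under the null the observed series is then
exchangeable with the run series, which is what calibrates the overall
test.  Supported summaries: count of sub-threshold points, longest
sub-threshold duration (ms), and Fisher's −2 Σ ln p.  The duration test
also reports the critical duration — the shortest duration whose null
exceedance probability is ≤ θ, i.e. the "green line" above which an
observed run of significant points survives correction.

Note that θ plays two coupled roles (it defines sub-threshold points and
the significance level).  Larger θ lengthens chance sub-threshold runs in
the null, so the critical duration *grows* with θ; and a θ below the rank
resolution 1/n_runs makes the duration test degenerate because no null
run can ever be sub-threshold.  Use n_runs ≥ 20/θ.

## Screening

Subjects are screened as whole data vectors (all conditions, time points
and channels concatenated).  Pearson correlations between subjects are
mapped to chord distances d = √(2(1 − r)) — metric, standard for
correlation MDS — and embedded in the plane by classical (Torgerson)
MDS, with coordinates centered so the origin is the mean of the sample.
The advisory auto-flagging uses the classic single-outlier test on the
maximum Mahalanobis distance: under bivariate normality the scaled
squared distance follows a Beta(p/2, (n−p−1)/2) law; its tail probability
is Bonferroni-corrected by n and the test iterates (flag, remove, repeat)
while significant and ≥ 5 points remain.  Flags are advisory output
only — exclusion is the analyst's decision.

Filters are 2nd-order Butterworth (order configurable) applied
forward-backward for zero phase; the notch is an IIR notch (Q = 30).
The pre-filter dataset can be retained for exact undo, and the applied
settings are recorded.

## t-maps

Selections name conditions (averaged), optional subject subsets and an
optional baseline selection subtracted first; maps are averaged over the
analysis window per subject.  Paired vs unpaired is auto-detected from
whether the selections share subjects.  Zero-variance channels yield a
0/±inf sentinel with a warning so output stays rectangular.  The
companion TANOVA p of the paired contrast is computed by sign-flipping
each subject's difference map (equivalent to within-subject swapping and
exactly antisymmetric, so the p is invariant under operand order); the
unpaired contrast shuffles group labels over a canonically ordered
concatenation for the same invariance.

## Microstates

Spatial correlation between maps is the Pearson correlation across
channels; assignment is to the template with the highest (polarity
"sensitive") or highest absolute ("ignore") correlation, ties to the
lowest index.  For ERPs the default is polarity-sensitive: an inverted
field is a different component.  Explained variance is GFP²-weighted,
EV = Σ (GFP_t · r_t)² / Σ GFP_t².

Modified k-means: best of `n_init` random restarts; cluster centers are
the normalized sums of member maps (sensitive) or the first singular
vector of the member matrix (ignore); empty clusters are re-seeded on the
worst-fit map; convergence when EV improves by < 1e-7.  AAHC starts with
one cluster per map and repeatedly disbands the cluster contributing
least explained variance, reassigning its members to the best-fitting
survivors — deterministic by construction.  Clustering operates on
group × condition grand-mean maps, not on single subjects.

Cross-validation of k: subjects are split (default 50/50, 10 splits) into
learning and test sets; models fitted on learning-set grand means are
projected onto test-set grand means by best-fit re-assignment.  Within a
split, each k-means fit includes a warm start from the previous k's
templates plus the worst-fit map, which guarantees the learning-EV curve
is non-decreasing in k.  The preferred k is where the test-EV curve
plateaus.

Label smoothing suppresses microstate segments shorter than a minimum
duration (default 3 samples): the shortest offending segment is merged
into its temporal neighbours at the split point that maximizes summed
correlation with the neighbour templates, iterating until no short
segment remains.  The contiguous split guarantees the segment count
decreases every iteration (pointwise reassignment could oscillate).

Quantifiers per class and design cell, pooled over all of the class's
segments inside the analysis window: onset/offset = times of first/last
assigned sample; duration = sample count × dt; AUC = Σ GFP · dt; center
of gravity = Σ t·GFP / Σ GFP (the most robust timing measure, since it
uses all samples); mean GFP.  If a class recurs at distant latencies and
should be treated as two states, restrict the analysis window.

Quantifier statistics: observed statistic = variance of each quantifier
across the effect's cell grand means; the null shuffles condition labels
within subjects (and group labels), recomputes grand means, labels,
smooths and quantifies.  Absent classes: duration, AUC and mean GFP count
as 0; timing quantifiers are computed over the cells where the class is
present, and when fewer than two cells have it the run's timing variance
is 0 (a minimal null value) — absence is thus informative for the global
quantifiers without inventing latencies for the timing ones.  Classes
absent from every observed cell are reported untestable.

## Synthetic data

The generator emulates the data model the statistics assume: per subject
and condition, a sum of orthogonal zero-mean unit-GFP source maps with
raised-cosine amplitude envelopes (default: sequential activation of
every template across the epoch, peak 10 µV), plus independent Gaussian
channel noise, average-referenced.  Defaults mirror a typical
multichannel ERP study: 16 subjects, 74 channels, 250 samples at 250 Hz.
Default noise is 2 µV (20% of the signal peak) and subject gain
variability 10% — values a scalp ERP practitioner would call realistic
for trial-averaged data.  Optional spatially correlated noise adds a
random unit-GFP map with a random time course per cell.

Condition effects dissociate the two ways fields can differ: a
*quantitative* effect multiplies the condition's complete maps (signal
and noise — all active sources scale, leaving normalized topography
exactly unchanged); a *qualitative* effect rotates a template within the
plane spanned by two orthogonal templates (topography changes at constant
GFP); latency effects shift activation windows.  Ground truth (templates,
per-condition effective maps, subject gains and jitter) is returned for
every generated dataset.

What a green test on synthetic data does *not* establish: real ERP noise
is spatially and temporally correlated and non-stationary, real
topographies are not orthogonal, and real effect sizes are smaller.  The
calibration results (Type-I error of all tests at nominal rate) transfer
because permutation tests are distribution-free given exchangeability;
the power and recovery results are best-case.

## Degenerate inputs and numerical conventions

GFP requires ≥ 2 channels; dGFP requires ≥ 2 levels; zero maps get label
0 with a warning during microstate assignment and zero weight in EV; the
TCT of all-zero data returns p = 1 everywhere.  Exhaustive-oracle tests
of the TCT must treat global channel permutations — which tie the
grand-mean GFP exactly — with a tolerance, since floating-point summation
order splits such ties either way.
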