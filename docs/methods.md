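# Methods

This note documents the statistical model behind `specsim`, the
conventions and defaults chosen where several were defensible, what the
synthetic-data generator does and does not emulate, and the numerical
details that matter for reproducing results.

## Similarity model

Input is per-subject single-trial spectral power P(trial, electrode,
frequency, time) from a design with C object categories, 2 exemplars per
category, and 2 presentations per exemplar. Similarity between two
trials at one electrode is the Pearson correlation (Spearman optional)
of their frequency vectors at every combination of time points,

    r(t1, t2) = corr_f( x1(·, t1), x2(·, t2) ),

computed on log₁₀ power after background removal (below), then
variance-stabilized with the Fisher z transform z′ = atanh(r). Three
pair sets operationalize the representational levels:

- within-item: (exemplar 1, presentation 1) vs (exemplar 1,
  presentation 2) of each category — one pair per category;
- within-category: (exemplar 1, presentation 1) vs (exemplar 2,
  presentation 1) — one pair per category;
- between-category: (exemplar 1, presentation 1) of every ordered pair
  of distinct categories — n(n−1) pairs.

Between-category pairs are deliberately *ordered*: correlating X with Y
and Y with X produces transposed matrices, and averaging over all
ordered pairs makes the mean matrix exactly symmetric (to float
round-off; verified at 1e−12). A common alternative counts each
unordered pair once and yields (n−1)²-style bookkeeping; we consider the
ordered convention the self-consistent one and use it throughout, since
only with it does the documented mirror symmetry of the mean matrix hold
identically.

Categories missing a required trial (e.g. one presentation rejected
during artifact screening) are skipped for the affected level and
reported in the pair list and the dataset validation report; they are
never imputed. This is a package policy for incomplete designs, chosen
because it requires no assumption about the missing trial.

## Background (1/f) removal

EEG power falls approximately as a power law of frequency. Left in the
data, this shared spectral shape correlates any two frequency vectors
strongly and positively, swamping pattern information. Power is
therefore log₁₀-transformed and a per-electrode background spectrum is
subtracted from every frequency vector. Two estimators are implemented:

- `mean_spectrum` (default): the mean log-power over all trials and all
  time points of the epoch, per electrode and frequency;
- `loglog_fit`: an OLS line of that mean log-power on log₁₀ frequency,
  evaluated at the grid frequencies — the background model of the
  better-oscillation-detection (BOSC) family, which removes only the
  power-law trend.

The default is `mean_spectrum`; whether the intended background is the
time-mean spectrum or the log–log fit is ambiguous in the method
literature, so both are available behind a config key and every output
records which was used. The background is estimated per subject and
electrode over the full epoch including the pre-stimulus baseline
(maximizing samples; no window choice to defend), and log base 10 is
fixed and recorded because the base is not correlation-neutral for the
fitted variant.

One measurable consequence of `mean_spectrum`: the estimate contains a
share (≈ T_signal/T) of the mean evoked signal, so subtracting it leaves
a small component common to all trials. This induces a baseline
correlation of roughly var(δ)/(var(δ)+σ²) where δ is the estimation
error — about z′ ≈ 0.005 under the default synthetic conditions, an
order of magnitude below planted effects. The test suite checks that
baseline similarity equals this analytical leakage rather than assuming
it is exactly zero.

## Degenerate values

- Zero-variance frequency vectors (possible with constant test inputs,
  not with real noise) would make r undefined; they yield r = 0 and a
  warning counter in the tensor's provenance, keeping all tensors
  finite.
- |r| = 1 (identical patterns) would map to infinite z′; r is clipped to
  1 − 1e−12 (z′ ≈ 14.4) before atanh, and clip events are counted.
  Values above 1 + 1e−9 raise.
- Paired/one-sample t at samples with zero mean and zero spread is
  defined as 0.

## Cluster-based permutation inference

First level: at every (electrode, t1, t2) sample, a paired t over the
C_used categories of d_c = z′_within-item − z′_within-category, df =
C_used − 1, with categories intersected between the two tensors and at
least three required. The t-map stack of a group feeds the second level.

Second level: the observed statistic map is the one-sample t of the
subject t-maps against zero (df = n_subjects − 1). Samples exceeding the
two-sided critical value at sample alpha 0.05 (derived from that df, not
a fixed t) are grouped into connected components:

- within an electrode, samples connect if they differ by one step in t1
  or one step in t2 — no diagonal moves in the (t1, t2) plane;
- across electrodes, the same (t1, t2) sample connects electrodes that
  are neighbors in the adjacency graph (Euclidean distance threshold on
  sensor positions, or an explicit neighbor list).

The cluster statistic is the summed t (mass). The reference distribution
is Monte Carlo: whole subject maps are randomly sign-flipped, the map
and clusters recomputed, and the maximum positive / minimum negative
mass recorded per draw. The observed labeling counts as one of the
n_perm draws, so p = k/n_perm with k ≥ 1 and floor 1/n_perm (0.002 at
the default 500 draws). Significance is declared at p < 0.025 per tail.
Sign-flipping is the natural exchangeability argument for a one-sample
test; a `zero_group` mode (independent-samples t against an all-zero
group with permuted group labels) is provided for comparability with
toolboxes that phrase the test that way. Single-channel cluster masses
are cross-checked in the tests against an established M/EEG
implementation, and Monte-Carlo p-values against exhaustive sign-flip
enumeration at n = 8.

Third level: the union of significant clusters of both signs defines a
mask per group. Per subject, mean z′ inside the mask is computed for the
within-item and within-category stacks; their difference Δ is the item
specificity score. Masks are group-specific (groups may use different
EEG systems and channel counts); only the scalar Δ crosses groups,
avoiding interpretation of absolute between-group level differences.
Groups are compared with a pooled-variance two-sided t-test. If no
cluster is significant there is no mask; the step raises an explicit
no-mask error and downstream steps skip with a message.

All permutation draws flow from a single documented seed; every result
records seed, n_perm, and thresholds.

## Brain–behavior association

Pearson correlation of Δ with a scalar memory score, per group and
pooled over groups, with two-sided p from t = r√((n−2)/(1−r²)). Groups
with fewer than three matched subjects are skipped with a message. The
pooled analysis uses raw scores; a group-mean-centered variant is
available behind a flag and warns that it changes the estimand (pooled r
on raw scores can reflect between-group differences in both variables).

## Synthetic-data generator

The generator emulates the statistical structure the pipeline assumes,
in log-power space:

    log₁₀ P = B(f) + w_cat·g_cat(c) + w_item·g_item(c, e) + σ·ε

with B(f) = intercept + slope·log₁₀ f (default 2.0, −2.0: a 1/f²
broadband falloff), g fields i.i.d. standard normal over (signal
electrode, frequency) — g_cat shared by all trials of a category,
g_item by both presentations of an exemplar — and ε i.i.d. per tensor
cell. The signal is constant over a rectangular time window (default
0.3–1.2 s after onset, covering the bulk of a 1.5 s stimulus
presentation after the early transient) and absent elsewhere. Planting
in log space makes background removal exactly linear, so the planted
population correlations at signal samples have closed form:

    ρ_item = (w_cat² + w_item²) / (w_cat² + w_item² + σ²)
    ρ_cat  =  w_cat²             / (w_cat² + w_item² + σ²),   ρ_between = 0.

Defaults mirror the reference study design: 40 categories × 2 × 2 (160
trials), 31 frequency bins (2–20 Hz step 2 plus 25–125 Hz step 5), 326
time points from −0.6 to 2 s at 8 ms (the 8 ms step follows from the
2.6 s span divided into 325 intervals), 60 electrodes, 10 subjects per
group, w_cat = w_item = σ = 1 (hence ρ_item = 2/3, ρ_cat = 1/3).
Electrodes are laid out on a unit-spacing ring so that a distance
threshold of 1.1 gives each channel exactly two neighbors. Memory
scores with a target correlation to specificity are generated as
r·z(Δ) + √(1−r²)·noise.

What the generator does **not** emulate: oscillatory burst dynamics,
volume conduction and realistic topographies, autocorrelated noise in
time or frequency, trial-count imbalance from artifact rejection, or
temporal-distance confounds between repetitions. Passing recovery and
error-control tests therefore demonstrates correctness of the
computations under the assumed signal model, not robustness to every
property of real EEG.

## Simulation scales and runtime choices

Simulation studies use reduced grids that keep the design intact:
`SynthConfig.reduced()` keeps all 40 categories and 31 frequencies but
samples time at 40 ms (66 points) with 8 electrodes. Parameter recovery
runs 4 subjects at that scale (160 category units); error control uses
200 null and 50 planted-effect replicates at a further reduced scale
(10 categories, 3 electrodes, 15 frequencies, 11 time points, 80
permutation draws, 8–10 subjects); the acceptance script analyzes a
10 + 10 cohort at the reduced grid with the full 500 draws. These sizes
were chosen so the whole suite runs on a laptop-class machine in
minutes; all tolerances are 4·SE bands or exact conventions, not tuned
margins.

Memory: similarity tensors are float64; a full-scale within-item tensor
is ≈ 1 GB per subject and the ordered between-category tensor at C = 40
is ~40× larger, so full-scale between-category analyses should be run
per subject and averaged immediately (the CLI does this subject by
subject).

## Data formats

Datasets persist to an HDF5 container (`/power`, `/freqs`, `/times`,
`/channels/{labels,pos}`, `/trials/{category,exemplar,presentation,
orig_index}` plus root attributes), chosen for language neutrality and
partial reads; the stored dtype is exactly the in-memory dtype so round
trips are bit-identical. FieldTrip-style TFR structs (fields
`powspctrm`, `label`, `freq`, `time`, `trialinfo`) are importable from
both MAT dialects (v7 via scipy, v7.3/HDF5 via h5py). The mapping from
`trialinfo` columns to category/exemplar/presentation is supplied by the
caller in the config — trial bookkeeping is experiment-specific and
hard-coding a column order would silently misread other datasets. The
two time axes of a similarity matrix are represented honestly as two
time dimensions in the data model; no "fake frequency axis" is used
internally, that convention exists only at FieldTrip import/export.

## Known limitations

- Exact reproduction of published cluster *counts* from the reference
  sample dataset depends on the electrode-neighborhood template and the
  (t1, t2) connectivity order used there, which are not fully
  documented; our conventions are stated above and such counts should be
  treated as sensitive to them.
- The number of units differs between levels (C for within-item vs
  n(n−1) for between-category), so between-level comparisons of
  *variance* are not like-for-like.
- Spearman correlation is implemented for the core pattern correlation
  but the t-based inference still assumes approximately normal z′.
- The permutation test requires at least ~6 subjects for the sign-flip
  null to have enough support (2ⁿ assignments) to reject at
  alpha = 0.025.
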