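# Methods

## The analysis model

The pipeline decides, per subject and per temporal window, whether
multivoxel activity distinguishes trials the subject answered "true" from
trials answered "false".

The per-voxel encoding model is ordinary least squares of the z-scored
signal on a single condition regressor coded +1 (true) / −1 (false) with an
intercept. With a two-level regressor the fitted values are the class
means, so the slope is half the class-mean difference and
R² = 1 − SS_within / SS_total on the training trials. Coding the conditions
{0, 1} instead would change neither R² nor any match decision (the
intercept absorbs the shift); ±1 is used so the weight's sign reads
directly as "more active for true".

Cross-validation leaves out exactly one true and one false trial per fold
and iterates over all true × false pairs (n_T × n_F folds; 576 at the
default 24 + 24). Fold enumeration is deterministic (ascending trial
indices). Voxel selection ranks in-mask voxels by training R² (ties broken
by ascending linear voxel index), keeps the top 2,000, and removes
connected clusters of 20 voxels or fewer (face/6-connectivity by default;
18 and 26 are available). The held-out pair is scored by the
cosine-similarity assignment; an exact tie counts as incorrect, and a fold
whose post-filter selection is empty also counts as incorrect (both
conservative).

The subject's *decoding map* at a window is the selection from a model
fitted on all trials at that window — the unique voxel set consistent with
the group-level reliability test's premise that an idealized cohort would
contribute the same voxels at every probability threshold. An alternative
(the union or intersection of per-fold selections) would make map size
depend on fold count; it is not used.

### Why the chance level is not 50%

Two properties push the pair-match accuracy away from 0.5 under the null:
empty post-filter selections score incorrect (frequent at windows where the
top-R² voxels are spatially scattered), and per-run z-scoring couples each
trial weakly to every other trial in its run. Both affect the observed
accuracy and the permutation replicates identically, which is exactly why
significance is assessed against the empirical null rather than against
0.5. The null shuffles the behavioral vector once per replicate and reuses
it across all folds of that replicate (shuffle-then-CV), preserving the
dependence structure among folds; fold enumeration and the held-out test
patterns keep the true labels. 100 replicates per window are pooled over
the 7 windows into one 700-value null, giving a common threshold across the
time window; p = (1 + #{null ≥ observed}) / (1 + 700) (add-one, so p is
never 0; the smallest attainable value is 1/701 ≈ 0.0014). No correction
is applied across windows or subjects.

## Group level

The posterior probability map is the per-voxel fraction of subjects whose
best-window decoding map contains the voxel. Thresholding keeps voxels with
probability strictly above 0.33 — with 14 subjects, at least 5 — and
clusters of at least 20 voxels (note the asymmetry with selection: the
single-subject filter keeps clusters strictly larger than 20, the group
filter keeps clusters of exactly 20 as well). The cluster table reports
size, center of mass and peak-probability voxel in grid coordinates,
sorted by size.

The sparseness test draws one window uniformly per subject, rebuilds the
probability map, and counts suprathreshold voxels at every threshold k/n
(strict >, so threshold k/n counts voxels shared by more than k subjects).
The observed best-window combination is compared one-sided (low counts =
high overlap) with an add-one p per threshold, so p ≥ 1/(n_iter + 1) and
the test degenerates to p = 1 when all maps are identical. The seven
fixed-window combinations are evaluated against the same null. The
observed combination is defined by best *accuracy* per subject (not by
searching for the sparsest combination, which would bias the test in its
own favor). The null band is pointwise per threshold, not simultaneous.

Sparseness has a geometric precondition worth stating: with ~2,000-voxel
maps in a gray mask about twice that size, map density (~0.5) sits above
the 3D site-percolation threshold (~0.31), so even noise-driven selections
survive the cluster filter as one large component and the probability mass
argument applies — aligning subjects at their best windows concentrates
mass at probability 1 and thins it at intermediate thresholds, which is
what the test detects. With much sparser maps the direction of the effect
at a given threshold can invert; the synthetic cohorts used in testing keep
the density of the full-scale design.

## Valence comparison

Best-window times are compared with an exact Mann-Whitney U test
(mid-ranks for ties; two-tailed p doubles the smaller tail over all
C(n1+n2, n1) label assignments, capped at 1). Exact enumeration is used
because the groups are small (8 and 6); it is verified against a
brute-force oracle and, on tie-free data, against an independent
implementation. Spatial specificity is
R = mean within-group Dice / mean between-group Dice over the best-window
maps (28 + 15 within pairs, 48 between pairs at 8/6). The 95% CI is the
2.5th/97.5th percentile of R under 10,000 size-preserving label
permutations; "group-specific maps" is declared only when the observed R
falls outside the CI. R is undefined (an error) when the between-group
mean Dice is 0.

## The synthetic-data generator

The generator emulates the study design: 14 subjects (8 "wedding", 6
"funeral"), 48 trials each (24 true / 24 false) over 3 runs, TR 2 s, trial
onsets ≥ 18 s apart so the 0–16 s extraction windows never overlap within a
run. Signal is generated directly as trial-locked normalized response — no
hemodynamic convolution — because the decoder's contract only involves the
residualized, z-scored signal; response shape within the window is carried
by the latency structure instead.

Per subject, a true/false amplitude difference of `effect_size` noise-SD
units (±effect_size/2) is added to the informative voxels at the three TRs
whose 3-point moving average centers on the subject's informative latency
(drawn uniformly from {2, 4, …, 14} s unless fixed). Informative voxels are
planted as a few contiguous blobs (≥ 21 voxels each where the total allows)
so the cluster filter has structure to act on; the blobs and the
quasi-spherical gray-matter mask are drawn at the cohort level (from the
cohort seed alone) so that subjects share informative anatomy — the
premise of the group probability map and of the sparseness test.

Noise has two components, both AR(1) in time with lag-1 autocorrelation
0.3 (a typical residual autocorrelation after prewhitening):

- per-voxel noise, unit stationary variance, independent across voxels;
- a regional fluctuation (SD 0.8) added identically to all in-mask voxels.

The shared component models the fact that trial-level BOLD variability is
spatially correlated. It is load-bearing: with purely independent voxel
noise, averaging over hundreds of informative voxels removes essentially
all trial-level variability, every window touching the response decodes at
100%, and the planted latency becomes unrecoverable (ties broken by
earliest window) — the generator would contradict its own contract. With
SD 0.8 the planted-latency window is the accuracy argmax in 20/20 seeded
subjects at effect size 2 while flanking windows remain clearly weaker.

Defaults (14 subjects, 48 trials, 20³ grid, mask fraction 0.5 → ~4,000
gray voxels, 2,000 informative, effect size 2.0) mirror the study's scale
and give map density ~0.5, the regime described above.

What the generator does **not** emulate: hemodynamic response shape and
undershoot, motion and physiological artifacts, spatial autocorrelation of
the *noise* (only the signal and the global component are spatially
structured), inter-subject anatomical variability, and trial exclusions
(all 48 trials always survive). Passing tests therefore demonstrate the
correctness and calibration of the procedure under its own assumptions,
not the effect sizes to be expected from scanner data.

## Numerical and design choices

- All randomness flows from explicit seeds; the pipeline derives named
  substreams (bootstrap, null, group permutation, R permutation) so adding
  consumers to one stream never perturbs the others. Reruns are
  byte-identical.
- Zero-variance voxels are flagged, zeroed during normalization, and get
  weight 0 / R² 0 in the model; zero-norm vectors in the cosine match are
  treated as similarity 0 (logged).
- Onsets not aligned to the TR grid are rounded to the nearest TR with a
  warning; the design has TR-aligned onsets.
- Normalization precedes trial extraction and is computed per run, so
  run-level offsets cannot leak into the decoder.
- The moving average uses one point on each side of the reference sample:
  it is the only width for which nine samples spanning 0–16 s produce
  exactly seven windows centered 2–14 s.
- Bootstrap SE resamples the fold outcomes with replacement; fold outcomes
  are dependent (each trial appears in many folds), so the SE describes
  resampling variability of the fold mean, matching the procedure it
  accompanies.

## Problem sizes in tests and the acceptance script

Tests and the acceptance script scale simulations down while preserving
every structural property: grids of 8–14 voxels per side, 60–600
informative voxels, 12–48 trials, selection sizes at ~half the mask (the
density regime of the full design), 100 permutations per window for nulls,
1,000 iterations for the sparseness test and 500–2,000 for R. The
acceptance cohort uses 14 subjects with 24 trials each on a 12³ grid. Full
structural counts (576 folds, 700-value nulls, 2,000-voxel selection, 7
windows) are exercised at their true sizes where the count itself is the
quantity of interest.
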