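# amdecode

Multivoxel decoding of **true vs. false autobiographical memories** from fMRI.

During scanning, subjects read sentences describing details of a highly
emotional personal event (a wedding for one group, the funeral of a loved one
for the other) and answered whether each detail really belonged to their
memory. Because the moment of successful retrieval differs across people,
standard group-level analysis washes the effect out: this package implements
the single-subject-first analysis — an encoding-model decoder applied at
seven post-onset temporal windows, permutation-based significance per
subject, then group aggregation by posterior probability maps — together
with a seeded synthetic-cohort generator so the entire pipeline is testable
without scanner data.

## The method

**Preprocessing.** Each voxel's (residualized) signal is z-scored per run.
For every trial the nine TR samples 0–16 s post-onset are extracted and a
3-point central moving average yields seven overlapping windows centered
t = 2, 4, …, 14 s after sentence onset.

**Single-subject decoding.** At each window, a per-voxel linear encoding
model regresses signal on the condition x ∈ {+1 (true), −1 (false)}:

    y_v = β0_v + β1_v · x + ε_v

Within a leave-two-stimuli-out cross-validation (one true and one false
trial left out; all true × false pairs, so 24 + 24 trials give 576 folds
trained on 46 stimuli), the 2,000 voxels with the highest training R² are
kept after removing connected clusters of ≤ 20 voxels. The two held-out
patterns are assigned to the two predicted patterns by cosine similarity;
the fold is correct iff

    cos(ŷ_T, y_T) + cos(ŷ_F, y_F) > cos(ŷ_T, y_F) + cos(ŷ_F, y_T).

Accuracy is the fraction of correct folds; its SE comes from a
1,000-iteration bootstrap over folds.

**Significance.** The chance level of this statistic is not 50%, so each
accuracy is tested against an empirical null: the whole procedure re-run
with the behavioral vector shuffled during training, 100 times per window,
pooled into 700 values; one-sided add-one rank test, p < 0.05.

**Group level.** Each subject contributes their decoding map at their
best-accuracy window; the posterior probability map holds the per-voxel
fraction of subjects whose map includes it, thresholded at p > 0.33
(≥ 5 of 14 subjects, minimum cluster 20). A sparseness permutation test
(random window per subject, 10,000 iterations) checks that this combination
is more spatially concentrated than chance, while the seven fixed-window
group maps are not.

**Valence comparison.** Best-window times are compared between groups with
an exact Mann-Whitney U test; spatial specificity is the ratio
R = mean within-group Sørensen-Dice / mean between-group Dice, with a 95%
CI from 10,000 size-preserving label permutations.

## Worked example

Decode one synthetic subject with a 2-SD effect planted at 8 s latency
(reduced 14³ grid, 600 informative of ~1,370 gray-mask voxels):

```python
import amdecode as am

spec = am.CohortSpec(
    n_subjects=1, group_sizes=(1,), n_trials=48, n_runs=3,
    grid_shape=(14, 14, 14), mask_fraction=0.5,
    n_informative_voxels=600, informative_latency=8.0,
    effect_size=2.0, seed=7,
)
ds = am.generate_subject(spec, 0)
tensor = am.build_tensor(ds.timeseries, ds.mask, ds.trials, ds.tr,
                         ds.run_length_trs)
result = am.decode_subject(tensor, n_top=600, min_cluster=21, seed=0)
null = am.build_null(tensor, n_per_window=25, seed=1, n_top=600,
                     min_cluster=21)
for w, t in enumerate(result.window_times):
    p = am.rank_test(result.accuracy_by_window[w], null)
    print(f"{t:4.0f} s  {result.accuracy_by_window[w]:6.3f} "
          f"± {result.se_by_window[w]:.3f}  p={p:.4f}")
print("best window:", result.best_window, "s")
```

prints

```
   2 s   0.627 ± 0.021  p=0.3125
   4 s   0.825 ± 0.015  p=0.1250
   6 s   0.976 ± 0.006  p=0.0284
   8 s   0.991 ± 0.004  p=0.0114
  10 s   0.986 ± 0.005  p=0.0170
  12 s   0.880 ± 0.014  p=0.0852
  14 s   0.564 ± 0.020  p=0.4318
best window: 8.0 s
```

Accuracy peaks at the planted 8 s latency, falls off at flanking windows as
the moving average dilutes the response, and the rank test flags windows
6–10 s against the pooled null (25 replicates/window here; use 100 for the
full null). The best-window decoding map recovers the planted blobs exactly
(Jaccard 1.00 against the ground-truth mask).

The same steps are available from the shell:

```bash
amdecode simulate --config cohort.json --out data/ --seed 1
amdecode decode --bold data/sub-01_bold.nii.gz --mask data/sub-01_mask.nii.gz \
    --events data/sub-01_events.tsv --out out/ --seed 1
amdecode run-all --out results/ --seed 1      # full cohort, end to end
```

scikit-learn users can drive the per-window model directly:
`EncodingModelDecoder` is a standard estimator and `LeaveTrueFalsePairOut`
a CV splitter, so
`cross_val_score(est, X, y, cv=LeaveTrueFalsePairOut())`
reproduces the 576-fold accuracy fold by fold.

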