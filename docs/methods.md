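# Methods

`sentencode` implements a voxel-wise encoding-model analysis of
sentence-level semantic structure during sentence production, as a fully
testable pipeline driven by a synthetic beta-map generator with planted
ground truth. This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic data can and cannot show.

## Stimulus design

The stimulus space crosses 16 Dutch nouns (8 denoting athletes, 8
musicians) with 16 transitive verbs (8 contact verbs taking agent/patient
roles, 8 experiencer-subject perception verbs taking experiencer/stimulus
roles). Excluding identical agent and patient, the pool contains
16 x 15 x 16 = 3,840 noun-verb-noun sentences.

`select_balanced_set` draws 288 sentences under exact constraints: each
verb used 18 times; each noun 18 times as agent and 18 as patient; every
(noun, verb) combination present at least once in each role; each of the
8 category patterns (agent category x verb category x patient category)
represented by exactly 36 sentences; repeated unordered noun pairs kept
minimal. The construction is per-verb: agent and patient multisets contain
every noun once plus category-balanced extras, and are paired within
category blocks by Hungarian assignment whose costs forbid agent = patient
and already-used triples and penalize noun-pair repeats. This is
deterministic-by-construction for every seed; feasibility requires
`n_target` divisible by 32 with at least 16 sentences per verb (288
qualifies). Half of each category-pattern cell is assigned active voice;
the passive half splits equally between the two word orders Dutch allows,
which requires cell sizes divisible by 4.

36 of the 288 sentences become question trials (drawn stratified over
category patterns so the joint balance identities hold — how question
trials relate to the balancing scheme is otherwise an open choice), and
72 free-form fillers are added. Scheduling distributes trials over 6 runs
of 60 (42 production + 6 question + 12 filler), splitting per-verb counts
exactly (3 per run) and balancing per-noun-per-role counts across runs to
a maximum spread of 2 by greedy assignment with swap repair; "2" is our
reading of "similar distribution", and is verified by tests rather than
assumed.

## Encoding models

Each sentence maps to a binary predictor vector; thematic roles are deep
roles derived from (agent, patient, verb category) only, so active and
passive realizations of the same event featurize identically:

| model | predictors | meaning |
|---|---|---|
| `bag_of_nouns_cat` | 2 | noun category present |
| `broad_roles` | 8 | category x broad role (agent/patient/experiencer/stimulus) |
| `narrow_roles` | 64 | category x verb-specific role |
| `bag_of_verbs` | 16 | verb identity |
| `bag_of_nouns_specific` | 16 | noun identity |
| `noun_specific_broad_roles` | 64 | noun identity x broad role |
| `full_relational` | 512 | noun identity x verb-specific role |

`noun_specific_broad_roles` uses 16 nouns x 4 broad roles, the natural
parallel to `broad_roles`. `full_relational` is featurized and counted but
flagged (a warning, not an error) when fitted with fewer sentences than
predictors, since a 288-sentence design cannot constrain 512 predictors;
the minimum-norm solver still returns a well-defined fit.

## Per-voxel cross-validated generalization

For each participant, model weights are fit per voxel by ordinary least
squares with an intercept on five of six runs and evaluated on the
held-out run, rotating over runs (leave-one-run-out). Rank-deficient
designs (expected: a single run's 42 sentences cannot span 64 predictors)
are solved by minimum-norm least squares via a Moore-Penrose
pseudoinverse with singular-value cutoff 1e-10 relative — binary designs
have O(1) genuine singular values, so the cutoff only removes the
numerical null space. No ridge penalty is used: the procedure is plain
multiple regression.

The fold statistic forms D[i,j] = (pred_i − obs_j)^2 over the held-out
run's sentences, z-scores all n^2 entries jointly (population SD), and
contrasts the matched diagonal against the mismatched off-diagonal. Two
equivalent routes exist; the implementation uses power sums (the z-scored
contrast reduces to (mean_diag − mean_off)/SD(D)), which never
materializes D and is validated against a brute-force oracle to 1e-12.
Choices worth noting:

* z-scoring is joint over all n^2 entries with the population SD;
  row- or column-wise alternatives would change magnitudes but not the
  sign logic.
* a degenerate matrix (all entries equal) scores 0, flagged on request;
  exactly-constant predictions also score 0, which the symmetry of the
  diagonal/off-diagonal weighting forces analytically.
* fold scores are averaged over runs and multiplied by −1 so informative
  voxels are positive.
* runs with fewer than 2 usable sentences are dropped with a warning;
  fewer than 2 surviving runs is an error.
* duplicate feature rows in a held-out run are retained; tied predictions
  merely dilute the diagonal contrast.

Maps are computed on unsmoothed betas and smoothed afterwards with a
Gaussian kernel at 8 mm FWHM (sigma = FWHM / (voxel size x 2*sqrt(2 ln 2)),
about 1.359 voxels at 2.5 mm). Smoothing is mask-renormalized
(smooth(map x mask)/smooth(mask)); on an unmasked grid a centered delta
keeps unit mass to 1e-6 relative.

## Group inference

Null maps come from re-running the full pipeline after shuffling each
run's sentence -> descriptor mapping (within run, so fold sizes and the
null/observed pipelines stay exchangeable), 100 permutations per
participant by default. A bootstrap ensemble (default 10,000 draws, one
permutation map per participant with replacement, averaged) yields the
group-null distribution per voxel. Observed group means are tested
one-sided with add-one correction p = (r+1)/(B+1); suprathreshold voxels
(default P < 0.005) are clustered (18-connectivity by default, 6/26
configurable). Each cluster's p-value is the proportion of bootstrap maps
whose largest suprathreshold cluster (same height rule, leave-self-out
rank) is at least as large — the standard completion of a bootstrapped
cluster-forming threshold; a global pooled height threshold is available
behind `height_mode="global"`. Benjamini-Hochberg FDR at q < 0.05 is
applied across clusters via statsmodels, and cross-checked in tests
against an independently coded BH transform.

The add-one rule makes the voxelwise test exactly calibrated on the
achievable p-grid: with B = 2,000, P < 0.005 passes exactly the top 10
ranks, i.e. a true rate of 10/2001. The calibration estimate in tests and
the acceptance script averages the leave-self-out suprathreshold rate
over the whole bootstrap ensemble, because a single smoothed null map has
few spatial degrees of freedom and its one-shot rate is dominated by
kernel-scale correlation.

## ROI analysis

Voxels inside each ROI are selected for each participant from a
one-sample t-map (score vs 0) over the N−1 *other* participants — the
only statistic computable from the stated inputs — at t > 2.4, falling
back to t > 1.68 if nothing survives, and excluding the row if even that
fails. Selection never reads the held-out participant's own map
(verified by a perturbation test). Performance is each participant's own
smoothed-map mean over their selected voxels (smoothed by default,
configurable). Model comparison fits a linear mixed model
(`mean_score ~ model * roi * modality`, participant random effects;
fitting delegated to statsmodels MixedLM, ML estimation) with
likelihood-ratio chi-squares obtained by dropping each term together with
the higher-order terms containing it; singular random-effects structures
fall back to a random intercept with a note. Pairwise model contrasts
within ROI x modality cells are paired t-tests with N−1 degrees of
freedom, uncorrected by default. The random-effects formula is exposed as
configuration rather than guessed.

## Synthetic data generator

The generator emulates the pipeline's inputs: per-sentence 3D beta images
for ~38 participants x 6 runs x 42 production trials on an isotropic grid
(default 20^3 voxels at 2.5 mm, full-box mask). Spherical blobs (default
radius 3 voxels) carry per-voxel weight vectors over one model's
predictors; activity is

    beta = signal_amplitude * (w . x) + N(0, noise_sd)

independently per trial and voxel. Weights are drawn N(0,1) and rescaled
per voxel so the signal has unit SD over the design, making
`signal_amplitude / noise_sd` the exact per-trial SNR. Imperfect recall
is emulated by substitution (default rate 0.23: the produced sentence is
a different lexicon-conforming sentence with the same voice) and
attrition (default 0.07 of trials dropped as erroneous; acceptable
productions average ~0.93 of trials).

What the generator does **not** emulate: BOLD dynamics and HRF
convolution, temporal autocorrelation (inputs are beta maps, not time
series), motion and physiological noise, spatial noise correlation,
between-voxel signal correlation beyond blob membership, anatomical
geometry, and between-participant anatomical variability. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the design's sampling scheme — not that real-brain effect sizes or
cluster anatomy are reproduced, which desk-scale synthetic data cannot
show.

## Problem sizes used in tests and the acceptance script

Stochastic checks run at reduced scale, chosen once: null calibration
with 10 participants, a 20^3 grid, 50 permutations/participant and 2,000
bootstraps; planted-signal recovery with 8 participants, a 16^3 grid, 30
permutations, 600 bootstraps, 20 seeds (10 in the acceptance script) at
SNR 2 with substitution 0.23 and attrition 0.07; ROI specificity with 12
participants on a 20^3 grid, two independent replicate datasets, null
parcels placed beyond the smoothing kernel's support of the planted blob.
The replication rule for ROI specificity (significant in both replicates)
keeps the per-null-ROI false-replication rate at 0.25% where a single
dataset would flip a 5% coin per parcel.

## Known limitations

* The balanced-selection construction requires the 8+8 / 8+8 lexicon
  shape and `n_target` divisible by 32; other shapes raise a named
  infeasibility error rather than attempting approximate balance.
* Cluster inference loops over bootstrap maps for connected-component
  labeling; at 10,000 bootstraps on large grids this is the slowest step.
* The mixed-model LRTs use ML refits of nested fixed-effect structures;
  degrees of freedom are parameter-count differences, which is standard
  but approximate for small participant counts.
* Bit-level determinism is guaranteed for a fixed package version and
  BLAS; across numerical libraries only statistical equivalence holds.
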