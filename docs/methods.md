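# Methods

This note documents the models, defaults, and numerical choices behind
`codebrain`, and what the synthetic validation does and does not establish.

## The analysis pipeline

### Designs

The code-comprehension session has six runs of twenty trials (8 *for*, 8
*if*, 4 *fake*), each trial a 24 s function phase, 0.5 s fixation, 6 s input
phase, 0.5 s fixation, 6 s question phase, and a 5 s inter-trial interval
(42 s per trial, back-to-back). Per participant: 48 for functions (24 per
variant), 48 if (24 per variant), 24 fake (12 fake-for, 12 fake-if); half of
the real and half of the fake trials are keyed "true". The stimulus
inventory holds 96 base real functions in two variants (192 stimuli, 96 per
counterbalance group) and 48 fake functions (24 per group); a participant
never sees both variants of a base function. Trial order within a run is a
seeded uniform permutation — the original study balanced orders across
participants with a dedicated permutation scheme whose details are not
published, so per-seed randomization stands in for it.

The MSIT schedule has two runs of eight interleaved blocks (4 interference,
4 control; the starting kind alternates with seed parity), flanked by 15 s
fixations. Interference trials are the 12 digit triplets with a unique
target digit in {1,2,3} placed at a position different from its identity and
two identical non-zero distractors; control trials are '100', '020', '003'.
Each interference block presents each interference triplet exactly twice
(24 trials); each control block presents each control triplet exactly six
times (18 trials). The published description is internally inconsistent
here — 42 s blocks at 1.75 s/trial imply 24 trials for both kinds, which the
six-repetition rule for three control triplets cannot fill — so the package
follows the explicit multiset rules and treats the block/trial durations as
timing metadata. No two identical triplets appear in succession, and the 8
blocks of one kind all use distinct orders (rejection sampling over seeded
permutations).

### GLM

The canonical HRF is the standard double-gamma: a gamma density peaking at
6 s minus 1/6 of a gamma density peaking at 16 s, peak-normalized to 1
(its shape matches the SPM canonical HRF; a correlation check against an
independent implementation is part of the test suite). Each modeled
condition (or each function, for pattern estimation) contributes a 24 s
function-phase boxcar convolved with the HRF, plus its first temporal
derivative; derivative betas are nuisance and never enter contrasts.
Nuisance covariates can be appended as extra design columns; no signal
processing (filtering, prewhitening, motion correction) is performed here —
those belong to upstream preprocessing.

Run-wise fits are ordinary least squares; contrast t = c'β̂/se with
se² = σ̂² c'(X'X)⁻¹c and two-sided p on n − rank(X) degrees of freedom.
Rank-deficient designs are an error that names the collinear columns. Runs
are pooled per subject with inverse-variance (fixed-effects) weights:
β_fe = Σ(βᵢ/vᵢ)/Σ(1/vᵢ), var = 1/Σ(1/vᵢ), z = β_fe/√var. Binarization is
Benjamini–Hochberg at q = 0.05 over all vertices of one contrast map, both
hemispheres jointly (the original correction was whole-brain).

### ROIs

Subject ROIs are the top k = 500 vertices of the code contrast inside fixed
group search spaces (IPS, pMTG, PFC, Occ; left hemisphere). "Active" is
interpreted as largest statistic with no significance gate — the published
description states no threshold precondition, so none is imposed; ties
break by ascending vertex index, and a space smaller than k is an error
rather than a silent truncation. Search spaces are configuration (vertex
lists): the parcellation-based construction of the originals is out of
scope, and on the synthetic sheet the default spaces are four equal
contiguous blocks of left-hemisphere indices.

### MVPA

The 96 real-function patterns are standardized once per condition: one
scalar mean and sd over the full 48 × |ROI| block of each condition. This
follows the published procedure literally, including the train/test leakage
it implies (normalization precedes splitting); a `normalize_within_split`
flag provides the leakage-free variant for sensitivity analysis. The
classifier is the libsvm linear SVM (`sklearn.svm.SVC(kernel="linear")`,
hinge loss, C = 5.0, tol = 1e-4, unpenalized intercept), deterministic
given the seed; an iteration cap (2×10⁴) only bites on inseparable
label-shuffled data where the fit has long since stabilized. Accuracy is
the mean over 100 independent stratified 90/10 splits (drawn independently,
so test sets may overlap across splits). The per-subject null is 1000 label
shuffles, each scored by the same 100-split procedure.

Group inference Fisher-z transforms accuracies as z = arctanh(a), applied
directly to the proportion and to chance (arctanh(0.5) ≈ 0.549); the
alternative arctanh(2a − 1) convention is deliberately not the default, as
the source leaves the transform unspecified. The observed statistic is the
one-sample t of z(accuracy) − z(0.5) across subjects; each of 10⁶ bootstrap
iterations draws one z-transformed null accuracy per subject (uniformly,
with replacement, independently per subject) and recomputes the t; the
empirical p is the one-sided proportion of bootstrap t values ≥ the
observed t. Accuracies across ROIs are compared with a one-way ANOVA using
the (k − 1, N − k) degrees-of-freedom convention, giving F(3, 56) for
15 subjects × 4 ROIs.

### Overlap

Binary maps are compared by cosine similarity |A∩B|/√(|A||B|), which
normalizes away each map's activation extent. The empirical lower bound
permutes the **localizer** map's vertex assignment uniformly within the
analyzed hemisphere (active count preserved; 100 draws); under this null
the expected cosine is √(|A||B|)/N by the hypergeometric expectation of
|A∩B|. The group p bootstraps one null cosine per subject per iteration
(10⁶ iterations) and reports the proportion of null group means ≥ the
observed group mean. The ceiling is the self-similarity of the code
contrast across the 10 unordered 3/3 partitions of six runs, each half
pooled with fixed effects and FDR-binarized; values are averaged within
subject first, then across subjects (a `pooled` flag averages everything in
one pass — the published sentence is ambiguous between the two). Headline
statistics use the left hemisphere; the right is available by flag. Task
differences use a one-way repeated-measures ANOVA (subject as blocking
factor, df = (k−1, (k−1)(n−1)) = (3, 42) at n = 15, k = 4) with BH-corrected
post-hoc paired t-tests.

### Lateralization

LI = (n_L − n_R)/(n_L + n_R) over suprathreshold vertex counts at the same
FDR q = 0.05 as the overlap maps; the source never prints its formula, so
the count-based definition was chosen for consistency with the binarized
maps, with a magnitude-weighted variant (summed |statistic|) by flag. Group
inference is a two-sided one-sample t against 0 (df = n − 1); the
code–language association is the OLS R² with its F-test p.

## The synthetic generator

`surface_synth` emulates the measured structure of the study — 15 subjects,
six runs, 96 real + 24 fake patterns per subject, five contrasts on a
2 × 2000-vertex sheet — with three planted effects:

- **Pattern separation.** Inside the code-active set, for and if mean
  patterns differ by `pattern_effect_d` noise-sd units per vertex (random
  sign per vertex). The default d = 0.25 was calibrated so that the default
  geometry yields single-subject decoding accuracies around 0.65–0.70, the
  range the study reports; d = 0 gives chance decoding, and the noiseless
  limit gives accuracy 1.
- **Overlap.** Each contrast's active set is built from disjoint pairwise
  shared pools sized s_ij = round(target_ij·√(|A_i||A_j|)), so realized
  binary-map cosines hit the targets within rounding (≤ 0.02). Infeasible
  targets (a contrast's shared pools exceeding its size, or the pool
  exhausted) raise by default; per-subject generation uses a proportional
  shrink instead, which only bites in the minor hemisphere of strongly
  lateralized subjects. Default targets mirror the study's ordering
  (code–logic 0.40 > code–math 0.25 > code–MSIT 0.15 > code–language 0.10).
- **Laterality.** Per-subject code and language LIs are drawn from a
  bivariate normal (mean 0.45, sd 0.3, correlation 0.8, clipped to ±0.95);
  the sd matches the between-subject spread implied by the reported group
  t-statistic (t(14) ≈ 5.5 at mean 0.451 implies sd ≈ 0.32). Each
  contrast's active count is split across hemispheres as
  n_L/(n_L + n_R) = (1 + LI)/2, so the ground-truth count-based LI equals
  the planted LI exactly. (Planting by amplitude scaling was considered and
  rejected: once both hemispheres' vertices are reliably detected, a
  count-based LI no longer depends on amplitude, so the planted mean could
  not be recovered.)

Run-level contrast estimates are emitted directly as beta = amplitude ×
indicator + N(0, σ²) with known variance, the amplitude set so a truly
active vertex reaches fixed-effects z = `contrast_snr` (default 5) after
pooling six runs. Full time series can be rendered from a trial schedule
(per-function design matrix × true betas + iid Gaussian noise) for
end-to-end GLM tests. Fake trials activate an independent vertex set (a
memory-task proxy) so real-vs-fake contrasts are nontrivial.

What the generator does **not** emulate: cortical geometry and spatial
autocorrelation (noise is iid per vertex), hemodynamic nonlinearity,
physiological noise, inter-subject anatomical variability, and any
relationship between the pattern effect and the univariate contrast beyond
co-location. Passing tests therefore validate the statistical machinery —
estimators, resampling schemes, error control, parameter recovery — not the
realism of any effect size on real cortical data. Known bias worth noting:
the estimated LI is attenuated by ≈ 0.02 relative to the planted value
because BH false positives land symmetrically in both hemispheres.

## Problem sizes and numerical choices

Full-scale resampling defaults (100 splits, 1000 shuffles, 10⁶ bootstrap
iterations) are the configuration defaults. Test runs use documented
reduced presets: the demo pipeline (3 subjects, 400 vertices/hemisphere,
6 splits × 12 shuffles), and the type-I calibration suite (100 null groups
of 8 subjects, 32-pattern 12-vertex matrices, 30 shuffles × 4 splits,
4000 bootstrap iterations). These sizes are the package's validation
choices; the calibrated property — the exchangeability of the bootstrap-t
null — does not depend on resampling depth beyond Monte-Carlo resolution.
Bootstrap loops are chunked (10⁵ iterations per block) to bound memory at
full scale.

Tie-breaks and degenerate inputs are deterministic and explicit throughout:
top-k ties break by vertex index; a zero contrast vector returns t = 0,
p = 1; all-zero binary maps make cosine and LI undefined (errors, not
NaNs); identical task columns return F = 0 directly rather than a 0/0; and
every random draw descends from one global seed through named
`SeedSequence` streams, so any stage can be re-run from saved intermediates
and reproduce the end-to-end result.

## Known limitations

- Whole-brain group random-effects maps and cluster-level FWER correction
  are out of scope (they need surface adjacency); the package starts from
  per-subject maps.
- The split-half ceiling requires both half-maps to be non-empty; on pure
  noise (no stable activation) it is undefined and raises rather than
  returning a number.
- The MSIT control-block length follows the trial-count rules, not the
  stated block duration (see the design section).
- Search-space construction from a parcellation, and real-data I/O beyond
  plain arrays + JSON/TSV (e.g. GIFTI), are intentionally thin: maps are
  plain arrays with hemisphere labels and JSON sidecars.
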