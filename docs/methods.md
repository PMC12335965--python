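# Methods

This note records the scientific and numerical choices behind `gfcpm`: what
the synthetic cohorts emulate, how the connectivity and prediction stages
are defined, and where the design was genuinely open.

## Synthetic cohorts

The generator produces, per subject, two task runs (318 s each: nine 30-s
copying blocks — three per condition, five 6-s trials each — and four 12-s
fixation blocks) and one 480-s resting run at TR = 1 s, matching the study
design the pipeline targets. `duration_scale` tiles the task design and
lengthens the rest run by an integer factor when longer series are needed.

**Latent connectomes.** The group-mean correlation matrix is a network block
structure: within-network correlation 0.3, between-network 0.05 (12 labels,
11 named networks plus "Unc"). Subject matrices add independent Gaussian
perturbations on Fisher-z edges (SD 0.1) and are repaired to valid
correlation matrices by eigenvalue clipping at 1e-6 followed by rescaling to
unit diagonal. The repair is not innocuous at realistic dimensions: for
hundreds of nodes it shrinks the subject-specific deviations by roughly half
and mixes them slightly across edges. The *repaired* matrix is the subject's
latent connectome — it is what the time series are drawn from — so all
ground truth refers to it.

**Planted behavior link.** A latent factor g per subject drives the
deviations of `n_signal_edges` planted edges (half with positive sign, half
negative); behavior is g plus Gaussian noise (SD 0.3). Because the repair
attenuates planted loadings, the factor loading is calibrated by two
fixed-point iterations (with common random numbers) so that the mean
sign-aligned correlation between behavior and the repaired latent edge
values equals the requested `effect_size`. Copy times for the two character
lists are exact affine transforms of the behavior factor on the inverse-time
scale (cohort means/SDs 35.10 ± 6.33 s and 40.09 ± 7.75 s), so the
handwriting composite z(1/t_HFC) + z(1/t_LFC) carries the planted effect
without additional measurement noise; the reading score correlates 0.5 with
the factor by default (mean 1766.77, SD 369.92). Age, sex and motion
covariates are independent of behavior by default.

**Realism added on top of the latent draw** — so the cleaning stages have
real work to do: slow sinusoidal drift (0.002–0.006 Hz, amplitude 0.6 signal
SD, below the high-pass cutoff), HRF-convolved evoked responses on 30
task-responsive nodes (amplitude 0.5), motion series as Gaussian random
walks (step SD 0.03 mm translations, 6e-4 rad rotations, giving average FD
near 0.15 mm), and a motion-coupled artifact (amplitude 0.3) projected onto
all nodes.

**What the generator does not emulate:** spatial autocorrelation and
voxel-level noise (generation starts at ROI level), physiological rhythms,
scanner spike artifacts, non-Gaussian BOLD distributions, and
heteroscedastic motion across subjects. Passing tests demonstrate that the
*procedure* is correct and calibrated under these conditions, not that real
fMRI data would yield comparable accuracies.

## Connectivity

* **FD** uses the 50-mm-sphere convention: FD(t) = Σ|Δd| + 50·Σ|Δθ| with
  rotations in radians; frame 0 contributes 0 and the average includes all
  frames.
* **Task regressors**: boxcar per non-fixation condition convolved with the
  canonical double-gamma HRF (peak 6 s, undershoot 16 s; nilearn's
  `spm_hrf`), plus first temporal differences.
* **Nuisance regression** is plain OLS per node on [intercept | confounds];
  collinear columns are dropped left-to-right with a logged warning, so the
  fit is deterministic and auditable. CompCor-style components (top PCs of
  variance-normalized noise-source signals, default 5) are supported but off
  for synthetic cohorts, which have no designated noise sources.
* **Filtering** is a zero-phase FFT-domain mask with hard cutoffs — exactly
  order-free and deterministic; a Butterworth filter would satisfy the same
  contract. Task runs: high-pass 0.008 Hz (band-pass variant available);
  rest: band-pass 0.008–0.09 Hz.
* **Condition extraction** takes frames whose acquisition time falls inside
  a condition block, with a configurable hemodynamic onset shift
  (default 0 s, exposed because block-windowing conventions differ between
  toolboxes); windows are clipped at the run end.
* **GFC**: Pearson r on the concatenated frames, |r| clamped at 1 − 1e-7
  before atanh (finite z on degenerate inputs; clamped pairs are counted in
  provenance). Edge vectors are row-major over node pairs i < j, 0-based —
  the single canonical ordering used everywhere, stated in file headers.
* Zero-variance inputs: a dead node is an error naming the node; a constant
  behavior column z-scores to 0 with a warning.

## CPM engine

* Sample-SD (n−1) convention for every z-score.
* Selection p-values use the t distribution with df = n − 2 − k (k
  covariates); internally the threshold is applied as a critical |r|, which
  is algebraically identical and lets selection run vectorized over all
  edges. Degenerate edges (zero residual variance) are excluded, never
  selected.
* Folds that select no edge for a model predict with the intercept-only fit
  (the training mean) and are counted, rather than aborting — this keeps
  null simulations runnable, where empty folds are the norm.
* The combined model is OLS on both summary features with intercept.
* Covariates enter selection only; they are not re-residualized out of the
  summary features at prediction time.
* Permutations shuffle behavior only, covariates stay with their subjects;
  p = (1 + k)/(1 + N), which is valid (never 0) and has floor 1/1001 at
  N = 1000. Per-fold covariate-residualized, unit-normalized edge matrices
  are cached across permutations — they do not depend on behavior — making
  the 1000-permutation default tractable; a brute-force equivalence test
  pins the cached path to the naive implementation at 1e-10.
* Under a true null the LOOCV accuracy is *not* tightly concentrated near 0:
  Monte-Carlo shows a wide (SD ≈ 0.3), negatively biased distribution, a
  known artifact of within-fold selection. Inference therefore always goes
  through the permutation test, which is calibrated (rejection rate ≈ α).

## Fingerprint

* Stable edges: selection frequency ≥ threshold (default 0.90); subsets are
  monotone in the threshold by construction.
* Network weight = sum of node degrees in the network; Σ weights =
  2 × |edges| (handshake identity, asserted in tests).
* The network-pair strength matrix aggregates the **group-mean** Fisher z
  per edge before summing over the edges joining each network pair —
  mean-then-sum keeps the scale independent of cohort size; the choice is
  recorded in output metadata.
* Threshold sensitivity compares vectorized upper triangles (including the
  diagonal, i.e., intra-network cells) by Spearman correlation at
  85/95/100% vs the 90% reference; matrices with < 3 nonzero cells are
  flagged not-computable instead of returning a meaningless rank
  correlation.
* "Unc" (uncertain) is a first-class network label so the handshake identity
  stays exact.

## Pipeline and I/O

Cohorts live as delimited text (one matrix per run per subject, header = node
ids; motion series alongside; `behavior.csv`, `covariates.csv`,
`parcellation.tsv`, `design.json`, `ground_truth.json`). Subject screening
excludes runs with peak motion over 3 mm translation or 3° rotation and
records average-FD outcomes against 0.25 mm (strict) and 0.5 mm (lenient)
thresholds without excluding on them. Every pipeline output is checksummed
into a manifest; config + seed determine all outputs bit for bit. Exit
codes: 0 ok, 1 stage failure, 2 configuration error.

## Problem sizes used by the acceptance script and tests

* Oracle equivalence: cohorts of 12 subjects × 50 edges, tolerance 1e-10.
* Null calibration: 200 seeds × 200 permutations, 30 subjects, 500 edges,
  threshold 0.001; selection calibration: 100 seeds, 50 subjects, 2000
  edges at threshold 0.01 (binomial check).
* Planted-edge recovery: 20 seeds, 50 subjects, 120-node scheme, 20 planted
  edges at effect size 0.6, `duration_scale = 12`. The long-run regime is
  deliberate: recovery is a property of the *selection procedure*, so the
  series are made long enough (≈ 2,500 effective frames after filtering)
  that finite-series sampling noise in the GFC (Fisher-z SD ≈ 0.015–0.02)
  is small against the between-subject deviation SD that carries the planted
  signal. At the literal 318-s/480-s run lengths the band-pass filtering
  leaves few effective degrees of freedom in the rest run and the measured
  per-edge correlation attenuates from 0.6 toward ≈ 0.54, pushing expected
  recovery below the design target; a 120-node scheme keeps the run within
  minutes at unchanged statistical structure.

## Known limitations

* The generator's independent edge perturbations are incompatible with
  exact positive definiteness at high dimension; the eigenvalue-clipping
  repair is the honest resolution but makes the *requested* deviation SD an
  upper bound on the realized one (hence the loading calibration).
* Only LOOCV is implemented (no k-fold or nested variants), only univariate
  partial-correlation selection, and only unregularized linear models.
* No voxel-level preprocessing and no NIfTI ingestion: the artifact starts
  at ROI time series.
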