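# Methods

## Model and assumptions

`genratio` builds a logistic classifier over pairwise log-ratios of gene
expression.  The working assumptions are:

- Expression values are non-negative and on a **linear MAS5-like scale**
  (values around a baseline of ~150 for modestly expressed genes).  The
  package never renormalizes input; normalization differences are exactly
  what the ratio representation is designed to absorb.
- Sensitivity labels are **binary** at modeling time.  Three-class screen
  calls (sensitive / intermediate / insensitive) are produced by the screen
  module; intermediate and conflicting lines are expected to be removed
  before model fitting, not inside it.
- The biological signal of interest lives in **relative** expression of
  gene pairs (regulator vs effector, receptor vs inhibitor), so a
  classifier on within-sample ratios can transfer across platforms whose
  main difference is per-sample (and mild per-gene) scaling.

### Pipeline stages and defaults

| stage | default | rationale |
|---|---|---|
| gene filter: 75th percentile | ≥ 250 (linear units) | removes unexpressed genes whose ratios are pseudocount noise |
| gene filter: IQR | ≥ 500 (linear units) | removes flat genes with no per-sample information |
| pseudocount c | 32 expression units | damps low-expression ratio noise; well below the ~150 baseline so expressed genes are barely shrunk; c = 0 gives exact scale invariance and is supported |
| log base | natural | affects only coefficient scale |
| t statistic | Welch (unequal variance) | robust to per-class variance differences; pooled-variance option provided |
| permutations | 100 joint label permutations | permuting labels (not genes) preserves the inter-gene correlation structure under the null |
| p-values | per-feature exceedance count, +1 smoothed | guarantees p ≥ 1/(B+1), a valid test; pooled counting available for resolution below 1/101 |
| q-values | plug-in permutation FDR | expected null exceedances / observed exceedances at each observed \|t\|, clipped to [0,1], forced monotone in \|t\| |
| FDR cutoff | q < 0.1 | |
| AP similarity | Pearson correlation of ratio vectors | clusters are "the same signal measured through different pairs" |
| AP preference | median off-diagonal similarity | the standard default; cluster count grows monotonically with it |
| AP damping / iters / window | 0.9 / 1000 / 50 | heavy damping plus a long unchanged-exemplar window; non-convergence falls back to all-singletons (no merging) and is flagged |
| logistic regularization | L2, C = 1 | exemplar ratios can linearly separate small training sets; light L2 keeps coefficients finite; the separation case is thereby handled without a special path |
| decision threshold | probability > 0.5 | |
| CV | stratified 5-fold, all stages refit per fold | the 23%-sensitive class imbalance makes stratification necessary for stable folds; per-fold refitting removes selection leakage |

Determinism: one integer seed drives label permutations and fold
assignment; affinity propagation is deterministic by construction (ties in
the exemplar election are broken toward the lowest feature index via an
index-ordered tilt of ~1e−10 of the similarity scale on the preference
diagonal, which also prevents message oscillation on exactly symmetric
inputs).  Refitting with the same seed reproduces coefficients bit-for-bit,
and a saved model records the training probabilities computed through the
same code path that `predict` uses.

### Screen processing

Dose-response curves are fit with a variable-slope sigmoid whose lower
plateau is fixed at 0% inhibition: inh(d) = Amax / (1 + (EC50/d)^h).
Least squares over multi-start initializations (EC50 from the interpolated
half-maximum crossing and dose quantiles; Hill from {0.5, 1, 2, 4}); the
flat no-response model is always evaluated as a candidate.  IC50 is where
the fitted curve crosses 50% inhibition, clamped to — and pinned at — the
maximum tested dose when Amax < 50.  Calls: Amax ≥ 70 sensitive, ≤ 50
insensitive, otherwise intermediate (boundaries inclusive, taking the
threshold definitions literally).  Consensus is a strict majority of
non-missing per-screen calls; any tie (including one-vote-each patterns) is
a conflict, and intermediate votes count as their own class.  Replicate
curves are averaged per dose before fitting (configurable upstream).
Xenograft response: %T/C = 100·ΔT/ΔC when the treated arm grew (ΔT ≥ 0,
Δ = final − initial), %REG = 100·ΔT/T_initial when it shrank; responder
means %T/C < 10 (stasis) or any regression.

### Probe collapse and filters

"Best probe per gene" is the probe with maximal mean expression across
samples (ties to the lexicographically smaller probe id), configurable to
maximal IQR.  Quantiles use linear interpolation between order statistics.
Filters run on training samples only inside CV folds.

## The synthetic generator

`generate_expression` emulates a screened cell-line panel:

- gene log-expression ~ Normal(log 150 + 1.3, 1.0) per gene location plus
  per-sample Normal(0, 0.5) noise.  The location spread is calibrated so the
  expression/IQR filters remove roughly half the genes — the regime the
  filters are designed for;
- labels Bernoulli(prevalence), default 23%;
- each of the `n_true_ratios` planted pairs is **anti-correlated**: a latent
  factor (sd 0.6 × noise sd) enters the numerator positively and the
  denominator negatively — the reciprocal-regulation motif (a buffering
  inhibitor rising as its target falls).  Sensitive samples additionally
  shift the numerator up and the denominator down by effect_size·noise_sd/2
  each.  The planted log-ratio therefore concentrates both the latent
  variance and the class effect, which is what makes it the exemplar of the
  cluster of ratios sharing its genes.  Signal genes draw their locations
  from a clearly-expressed band (log offset 2.0 ± 0.3 above baseline): a
  gene near the noise floor cannot carry a measurable ratio signal, and the
  filters would correctly remove it;
- a per-sample scale factor, log-uniform over `per_sample_scale_range`
  (default 0.5–2; widened to emulate heavy batch/platform confounding),
  multiplies all genes of a sample.  It cancels in every ratio and
  contaminates every single-gene feature — the designed contrast behind the
  ratio-vs-gene ablation ordering.

`generate_platform_replica` applies fresh per-sample factors plus
log-normal per-gene factors (probe-efficiency differences).
`generate_screens` draws per-screen Amax inside the class bands (75–95
sensitive, 10–45 insensitive), flips the band with a configurable
concordance-noise probability, and emits noiseless sigmoids on an 11-point
2.5-fold dilution grid from 20 nM down to ~2 pM, so zero-noise screens
round-trip the labels exactly.

What the generator does **not** emulate: realistic gene–gene correlation
networks beyond the planted pairs, lineage structure, count-based RNA-seq
noise, heterogeneous per-gene variances, or missing values.  Passing tests
therefore demonstrate the pipeline's statistical behavior under its own
stated mechanism, not performance on any real cohort.

## Validation scenarios (as run by tests and `scripts/acceptance.py`)

- **Oracle equivalence** — Welch t vs `scipy.stats.ttest_ind`; one-sided
  Fisher p vs direct hypergeometric tail sums over every 2×2 table with
  total ≤ 30; BH vs the step-up definition on 1000 random p-vectors; AUC vs
  exhaustive concordant-pair counting at n ≤ 12.  Agreement is at the
  1e−10 level.
- **Null calibration** — 20 label-independent datasets, 2016 ratios from 64
  genes, 100 permutations: mean KS distance of p-values from uniform
  (per-seed KS carries lattice noise from the 1/101 grid), mean count of
  q < 0.1 selections, and full-pipeline CV AUC near 0.5.
- **Planted recovery** — 10 datasets at n = 400, 5 planted ratios, effect
  size 2: fraction of planted pairs found as exemplars (or ≥ 0.9-correlated
  with one) and pooled out-of-fold AUC.
- **Gene elimination** — a single independent planted pair (latent factor
  off) makes each planted gene's removal decisive; "pure noise" genes are
  genes in none of the fitted model's ratios, because in a ratio model any
  hypothesis gene can genuinely earn weight as a reference denominator.
  With five redundant planted ratios, single-gene removals cost ~0.01 AUC —
  inside fold noise — so the decisive-gene scenario is the informative one.
- **Scale invariance** — at c = 0, predictions under arbitrary per-sample
  rescaling agree to ~1e−15 (exact up to floating-point rounding of the
  logs); at c = 32 and expression ≥ 20c, max probability drift < 0.05 for
  scale factors in [0.5, 2].
- **Ablation ordering** — with per-sample scale factors spanning 0.02–50×,
  single-gene variants collapse to chance while ratio variants stay > 0.9
  AUC; with a single-gene signal and no confounding, all four pipeline
  variants agree within 0.05 AUC.  The fixed 2-gene rule is reported
  alongside but is not expected inside that band when only one gene carries
  signal.
- **Screen processing** — noiseless sigmoid parameter recovery over 100
  random draws (errors at numerical precision), threshold/consensus/%T/C
  worked examples, zero-noise label round trip.

Problem sizes were chosen so the whole suite runs in well under an hour on
one CPU while every statistical check retains a comfortable margin.

## Known limitations

- Permutation p-values at B = 100 have resolution 1/101 per feature; use
  pooled counting or more permutations for finer claims.
- The plug-in FDR can be anticonservative when many features are true
  positives (the null-exceedance numerator includes signal permutations).
- Affinity propagation on very large significant sets (≫ 10⁴ features) is
  O(n²) memory; restrict the hypothesis set accordingly.
- The 2-gene rule's ROC score (min of median-centered expressions) is a
  reconstruction: the original rule is binary and defines no ranking.
- `fit_dose_response` assumes inhibition reaches a plateau inside or near
  the tested range; curves still rising at the top dose get an extrapolated
  EC50 flag.
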