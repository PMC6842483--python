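# Methods

## Problem and model

Somatic copy-number variation (CNV) is a pervasive form of genetic
alteration in tumors, and for many genes the simplest mechanism linking
it to phenotype is dosage: more copies, more transcript. This package
implements a pan-cancer style concordance analysis that quantifies that
dosage relationship gene by gene from paired copy-number and expression
matrices, classifies per-sample variation tendencies, identifies genes
whose amplification couples to upregulation (AUGs) or whose deletion
couples to downregulation (DDGs), and asks whether carrying such a
concordant event stratifies overall survival.

The analysis chain is:

1. **Copy-number harmonization.** Input is either a discrete five-level
   call matrix (−2 homozygous deletion, −1 hemizygous deletion, 0
   neutral, +1 gain, +2 high-level amplification) or absolute total copy
   number with per-sample average genome ploidy. In the second dialect a
   gene is *amplified* when (ploidy ≤ 2.7 and CN ≥ 5) or (ploidy > 2.7
   and CN ≥ 9), and *deleted* when (ploidy ≤ 2.7 and CN = 0) or
   (ploidy > 2.7 and CN < ploidy − 2.7); everything else is neutral. The
   inequalities are applied exactly as written (strict `<` for
   high-ploidy deletion, `≥` for amplification, `≤ 2.7` for the
   near-diploid branch) with no rounding of ploidy − 2.7. Only the
   extreme levels ±2 count as variant *events*; gains and hemizygous
   losses remain regression abscissae for the correlation statistics.
2. **Diploid-referenced Z-scores.** For gene *g*, the reference set is
   the samples with call 0 for *g*; `z = (x − u) / o` with `u`, `o` the
   mean and sample (n−1) standard deviation of expression over that
   set — the convention used by cBioPortal-style mRNA Z-scores, chosen
   because reference sets can be small. A sample is an upregulation
   event iff z > 2 and a downregulation event iff z < −2, both strict
   ("more than" / "less than"). Genes with fewer than `min_diploid`
   (default 3) diploid samples or zero reference variance are excluded
   with a logged reason rather than imputed; a 1–2 sample reference
   makes `o` meaningless.
3. **Tendency classification.** Each (gene, sample) pair with a variant
   event and a co-occurring expression event gets one of four labels:
   A&U (amplified and upregulated), A&D, D&U, D&D. Cohort-level
   fractions divide by the *total variant-event count* of valid genes,
   whether or not an expression event co-occurs, so the denominator is a
   CNV-event total, not a DEG total.
4. **Association statistics.** Spearman's ρ between a gene's calls and
   Z-scores is computed as the Pearson correlation of midrank-transformed
   vectors (average ranks for ties). Per-gene and cohort-level linearity
   is summarized by ordinary least squares of the *median* Z-score per
   observed call level against the level — one unweighted point per
   level, so levels with few samples count equally, matching how
   median-Z-versus-copy-number plots are drawn. Group comparisons use
   Welch's unequal-variance t with Welch–Satterthwaite degrees of
   freedom.
5. **AUG/DDG identification.** A gene qualifies as AUG when its A&U
   share of concordant events exceeds 50% (denominator n_AU + n_DD
   only, per the ratio's definition) *and* its ρ and n_AU strictly
   exceed thresholds; DDG symmetrically on D&D. Thresholds are the
   medians of a reference oncogene list (for AUG) and tumor-suppressor
   list (for DDG) — the median of an even-length list is the mean of the
   central pair, which is how half-integer count thresholds arise. A
   fixed mode instead applies ρ > 0.4 / n_AU > 146.5 and ρ > 0.41 /
   n_DD > 18.5, the calibration obtained on a ~9,000-tumor pan-cancer
   cohort; these counts only make sense at a comparable cohort size.
   The ρ criterion for DDGs is read symmetrically (TSG-median of the
   same signed ρ): a true DDG pairs deletion with downregulation, a
   *positive* dosage relationship, so a signed threshold points the same
   way for both classes.
6. **Survival.** For a chosen gene and tendency, samples split into
   carriers (labeled with that tendency) and non-carriers; overall
   survival is compared with the Kaplan–Meier product-limit estimator
   and the two-group log-rank test, both implemented directly from their
   defining formulas (at each event time, O − E and the hypergeometric
   variance) so the package embodies the computation; `lifelines` serves
   only as an independent cross-check in the test suite. Events precede
   censorings at tied times (the standard convention). Raw p-values are
   reported alongside Benjamini–Hochberg adjusted ones across the tested
   genes.

## Synthetic cohorts

Real pan-cancer cohorts are large downloads with restricted access, so
the package ships a generator that plants exactly the statistical
structure the analysis assumes:

* Discrete calls are i.i.d. per (gene, sample) with P(+2) = `amp_rate`
  (default 0.02), P(−2) = `del_rate` (0.005), P(+1) = 0.05, P(−1) =
  0.03. Amplification is four times as frequent as deletion, emulating
  the selection asymmetry observed in tumors. No segmental correlation
  is simulated: every downstream procedure is gene-wise, so chromosomal
  linkage would add nothing the tests could detect.
* A `dosage_fraction` (default 0.85) of genes is dosage-sensitive:
  expression = baseline + slope·call + Gaussian noise, floored at zero
  (RSEM-like values are non-negative). Slopes are |N(1.0, 0.2)| in
  expression units per copy-number level against noise σ = 0.5, giving
  amplified-event Z-scores around 4 — strong but not deterministic
  coupling. The remaining genes draw expression independently of the
  call. With probability `discord_rate` (default 0.01) a variant
  event's slope contribution is sign-flipped; the mechanism generating
  discordance in real tumors is unknown, so this is a free parameter,
  not an estimate.
* Gene tiers: besides background genes, the generator plants strongly
  concordant AUGs (amplification rate 0.15) and DDGs (deletion rate
  0.08), plus *calibration-reference* tiers — oncogene and
  tumor-suppressor stand-ins with intermediate event rates (0.08 /
  0.03) and slopes attenuated by 0.75. Because calibrated thresholds
  are reference-list *medians* compared strictly, about half of the
  calibration genes always sit below their own threshold; planting the
  reference tier between background and planted tiers makes the
  calibrated thresholds discriminative, and recovery metrics
  (sensitivity, false-discovery proportion) are evaluated over
  non-calibration genes only — one does not score on the calibration
  set.
* Absolute copy number and ploidy are generated by *inverting* the
  ploidy-conditional calling rules (e.g. a +2 call in a near-diploid
  sample draws CN uniformly from 5–8), so a single cohort exercises both
  calling dialects and the calls round-trip exactly.
* Survival times are exponential (baseline hazard 1/24 per month,
  independent exponential censoring at 1/36) with the hazard multiplied
  by `survival_hazard_ratio` (default 3) for samples carrying the first
  planted AUG's concordant amplification — the simplest model with a
  known log-rank alternative.

The default study conditions are 2,000 genes × 500 samples with 50
planted AUGs and 30 planted DDGs. These sizes keep the full analysis
under a few seconds while leaving every statistic well inside its
asymptotic regime; the acceptance script uses the same sizes.

What the generator deliberately does **not** emulate: segment-level CNV
and genomic positions (chromosome labels are uniform over the 22
autosomes, so chromosome summaries are near-uniform by construction),
cancer-type heterogeneity, expression compositionality/library-size
effects, and any realistic discordance mechanism. Passing tests
therefore demonstrate correctness of the computations and
recoverability of planted structure, not biological claims about real
cohorts; the published pan-cancer magnitudes (e.g. concordant events
near 20% of variant events, 94% of genes with positive ρ) arise from
far noisier data than the default simulation.

## Numerical choices and degenerate inputs

* Spearman ρ is undefined (NaN with a reason) below 3 complete pairs or
  when a rank vector is constant; NaN pairs are removed pairwise first.
* Median-Z fits require ≥ 3 observed call levels; the fit p-value is the
  two-sided t-test on the slope with n_levels − 2 degrees of freedom.
* Welch's t with two zero-variance groups returns t = 0, p = 1 at equal
  means and ±∞, p = 0 otherwise (flagged by undefined df).
* Z-score boundary: z exactly 2 is *not* an event (strict inequality).
* Missing calls are "not evaluable", never imputed as neutral — imputing
  0 would inflate diploid reference sets.
* AUG/DDG comparisons are all strict, so at-threshold genes never
  qualify, and a gene can never satisfy both ratio criteria
  (au_ratio + dd_ratio = 1).
* Ranking of top concordant genes breaks count ties by ρ, then by gene
  symbol, making orderings deterministic.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configuration yields
  byte-identical files.

## Known limitations

* The shipped oncogene/TSG reference lists are generic stand-ins for
  threshold calibration on real data; studies should substitute their
  own curated lists.
* The fixed thresholds (146.5 / 18.5 counts) are cohort-size-specific
  and meaningless on small cohorts; calibrated mode is the default.
* Cell-line and tumor cohorts are z-scored identically (against diploid
  samples of the same cohort); no cross-cohort normalization is
  attempted.
* The log-rank implementation is the unweighted two-group test; no Cox
  adjustment for covariates is provided.
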