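# Methods

## The TH index

For each tumor the somatic variant allele frequencies (VAFs, percentages in
[0, 100]) observed in a targeted gene panel are assigned to N equal-width
bins and the Shannon diversity index

    H' = - Σ_{i=1}^{N} p_i ln p_i

is evaluated over the bin probabilities p_i (0·ln 0 := 0).  The default bin
width is 10 percentage points (N = 10), so 0 ≤ H' ≤ ln 10 ≈ 2.303 nats.  The
index is reported unnormalized, in nats.

Binning convention: bin i covers [(i−1)·w, i·w) for i < N and the last bin
is closed at 100, so every admissible VAF maps to exactly one bin.  The
convention matters only for values exactly on an edge; it guarantees a
partition and is applied identically everywhere (full panels, down-sampled
panels, simulated data).

A cohort is dichotomized at a cutoff, by default 1.30 — the reference
colorectal cohort's average TH — or at the mean of the cohort at hand
(`cohort_cutoff`).  "High TH" strictly exceeds the cutoff; a value exactly
at the cutoff is low, so the high group strictly exceeds the average.  A
sample with zero usable mutations gets an *undefined* TH (NaN, group
`undefined`) rather than 0 and is excluded from cohort summaries: H' = 0 is
a meaningful statement (a clonal VAF distribution), absence of data is not.

### Variant pre-filters

Before binning, variants flagged as germline or as upstream false positives
are removed, as are variants whose population allele frequency exceeds a
threshold (default 0.01, applied only when the annotation is present) or
whose depth falls below `min_depth` (default 0).  The depth and
population-AF defaults are configuration, not claims about any particular
pipeline; the upstream false-positive filter is modeled only as a boolean
verdict.  Indels are accepted when a table provides counts, but the
simulator emits SNVs only; the statistic is agnostic.

## Purity estimation

A specimen of purity P mixes tumor cells with diploid normal cells.  At a
germline-heterozygous SNP where the tumor carries X total and Y alternative
copies, the expected alternative allele frequency is

    AAF = (P·Y + (1−P)) / (P·X + 2(1−P)),

and inverting gives the closed form P = (1 − 2·AAF) / (AAF·(X−2) − Y + 1).
The copy-neutral heterozygous state (X, Y) = (2, 1) yields AAF = 1/2 for
every P and is uninformative; so is the balanced gain (4, 2).  For every
other catalogue state AAF is strictly monotone in P, making the inversion
unique on [0, 1].

The pipeline reconstructs the estimation procedure in four steps:

1. **Copy-neutral detection.** SNPs with BAF within 0.15 of 0.5 are
   pre-screened as heterozygous candidates; the most prominent peak of
   their read-coverage histogram is the modal (copy-neutral) coverage, and
   regions whose median screened coverage lies within 10% of the peak are
   called neutral.  No passing SNP means the sample is unusable for purity
   (reported as such, never as a number).
2. **Copy-state calls.** Each region's "adjusted coverage" is its median
   SNP coverage divided by the neutral coverage; ratios ≥ 1.25 are gains
   and ≤ 0.75 losses.  The ratio statistic is the simplest one consistent
   with coverage-based copy-state inference; the thresholds are
   configurable.
3. **Allele-state assignment.** Non-neutral clusters are matched against a
   small catalogue of states {(1,1), (1,0), (3,1), (3,2), (4,1), (4,2),
   (4,3)}.  A candidate is viable if inverting the cluster's mean AAF gives
   a purity inside [0, 1] (a tolerance of 0.1 absorbs sampling noise;
   larger excursions mark the state inconsistent); among viable candidates
   the one whose implied purity best reproduces the observed coverage ratio
   (P·X + 2(1−P))/2 wins.  States with proportional excesses (X−2, Y−1) —
   (4,3) at purity P versus (3,2) at purity 2P, and likewise (4,1)/(3,1) —
   predict *identical* AAF and coverage and are inherently
   indistinguishable from a single cluster; near-ties are resolved by
   parsimony (fewest copies).
4. **Aggregation.** The sample purity is the **maximum** over per-cluster
   estimates.  The maximum is upward-biased under noise; a mean-based
   aggregate is available behind `aggregate="mean"` but the maximum is the
   default behavior being reproduced.

Steps 1–3 are this package's reconstruction of a procedure whose full
details live in a pipeline we do not reimplement; they are deliberately
simple and every threshold is exposed.

**Detectability limits.**  With the default ±25% coverage thresholds a
single-copy change is visible only for P ≳ 0.5 ((2−P)/2 ≤ 0.75 requires
P ≥ 0.5, likewise (P+2)/2 ≥ 1.25); lower-purity specimens surface as
"unusable" rather than as bad numbers, consistent with the observation that
only about half of clinical specimens are ideal for purity estimation.  The
recovery benchmark therefore draws P uniformly from [0.55, 0.95] and gives
each specimen one arm-level loss (1,1) and one single-copy gain (3,2) —
the two commonest informative events — beside six neutral regions, with
20 SNPs per cluster at mean depth 500.  Under those conditions the
closed-form inversion plus maximum rule lands within 0.05 of the truth in
well over 90% of specimens; the residual misses are the upper tail the
maximum rule inherits from the most noise-sensitive cluster (for X = 3
states dP/dAAF = (P+2)², so a 0.004 standard error on the mean AAF is a
~0.03 standard error on P).

## The cohort simulator

The generator exists so that every downstream analysis can be exercised,
calibrated and power-checked without any patient data.  Its model is the
minimal one under which the TH index is meaningful:

- **Clonal architecture.** `n` clones, founding clone at cancer-cell
  fraction f = 1, each subclone's fraction drawn uniformly on (0.05, 0.95)
  and sorted so children nest strictly inside parents.  Per-clone mutation
  weights are small uniform integers; a tumor's mutation budget is
  apportioned over clones by largest remainder.
- **Reads.** Mutations are diploid heterozygous SNVs: expected VAF is
  100·P·f/2.  Per-site depth is Poisson around the sample's mean depth with
  a floor of 30 reads (no zero-depth records); alternative counts are
  Binomial.  Copy number does not perturb somatic VAFs; germline SNPs for
  the purity module are simulated separately with explicit (X, Y) states
  and coverage scaled by relative DNA content.
- **Cohort defaults** mirror the reference colorectal cohort: 304
  patients; stage mix 3.3 / 9.9 / 41.1 / 45.7% (expected counts 10 / 30 /
  125 / 139); purity uniform on [0.2, 1.0]; mean depth uniform on
  [100, 1000]×; mutation count Poisson with mean 25 (floor 3), a realistic
  burden for a ~400-gene panel in colorectal cancer; 1–6 clones per tumor
  with a stage-increasing mean (1 + Binomial(5, p_stage), p = 0.15 / 0.30
  / 0.45 / 0.60 by stage).
- **Outcomes.** Survival is exponential with proportional hazards:
  log-hazard = β_TH·1[high TH] + Σ β_k·flag_k, with hazard ratio 2 for
  high TH and 1.5 per adverse clinical flag (lymphatic/vascular/perineural
  invasion, tumor budding; gene alterations APC/KRAS/TP53 at 1.2), baseline
  median 24 months, and independent exponential censoring tuned to a 30%
  censoring fraction.  Flag prevalences follow the reference cohort's
  known-value margins (LI 0.58, VI 0.46, PNI 0.41, TB 0.72) and typical
  colorectal alteration rates (APC 0.70, KRAS 0.45, TP53 0.60).
  Crucially, the TH group entering the hazard is the one the pipeline
  itself computes from the generated reads (cohort-mean cutoff), so the
  simulated prognostic signal attaches to the *measured* statistic.

All randomness flows through a single `numpy` Generator; one seed and one
configuration reproduce every table byte for byte.

What the simulator does **not** emulate: copy-number–VAF interaction,
sequencing artifacts (FFPE damage, strand bias), mutational signatures,
shared driver landscapes, non-proportional or non-exponential hazards, and
correlated clinical covariates.  Tests passing on simulated cohorts
therefore establish that the machinery is correct and calibrated under the
stated model, not that the clinical effect sizes generalize.

## Evaluations

- **Down-sampling curve.** TH is recomputed on uniform random gene subsets
  of size k (20 replicates per k by default; the number of subsets per k is
  a knob, since no canonical value exists) and Spearman-correlated against
  the full-panel TH.  Samples whose reduced profile is empty are dropped
  pairwise for that draw rather than assigned TH 0, avoiding artificial
  zero-inflation; draws with fewer than 3 evaluable samples or a constant
  TH vector are reported as missing, never fabricated.
- **Clonality association.** One-sided Wilcoxon rank-sum (higher-clonality
  TH > lower-clonality TH), split at the cohort median subclone count by
  default.  All-tied inputs carry no evidence and return p = 1 by
  convention.  Exact p-values are used where SciPy supports them (no ties,
  small n), matching a brute-force permutation oracle.
- **Stage trend.** M² = (n−1)·r² with equally spaced stage scores 1..4
  (the standard linear-by-linear default) and a χ²(1) reference; computed
  directly from the contingency table, cross-checked against patient-level
  expansion.
- **Survival.** Kaplan-Meier, log-rank and Cox proportional hazards come
  from `lifelines` (Efron tie handling).  The feature × TH stratification
  compares only the two extreme strata (feature−/low TH vs feature+/high
  TH); a constant feature collapses the four strata to two and the
  comparison reduces to the plain TH contrast (warned).  Patients missing
  the feature being analysed are excluded listwise for that analysis only.
- **C-index.** For each covariate set, each of 500 iterations draws an 80%
  subsample without replacement (redrawn if event-free), fits the Cox model
  and records Harrell's C on that subsample; covariates enter jointly.
  Non-convergent fits are skipped with a log; more than 10% skips is a hard
  failure.  Whether to subsample with or without replacement and whether
  covariates enter jointly are open choices; without replacement and
  jointly are the defaults, both exposed.

## Numerical conventions and problem sizes

- Shannon terms with p_i = 0 contribute exactly 0; the index of an empty
  distribution raises rather than returning 0.
- Purity inversion treats |denominator| < 1e−12 as uninformative; inverted
  values are clamped to [0, 1] only within the 0.1 consistency tolerance.
- The calibration and power checks use the sizes at which their Monte-Carlo
  error is small relative to the asserted bands: 400 replicates of n = 120
  cohorts for the null log-rank rate, 100 replicates of full-size (n = 304)
  cohorts for power, 200 specimens for purity recovery, and cohorts of
  200–300 tumors for the down-sampling and clonality checks.
- Welch's t-test between C-index distributions can underflow to p = 0 at
  500 iterations when the separation is many standard errors; the value is
  reported as computed.

## Known limitations

- The purity state catalogue is small by design; subclonal copy number,
  allele-specific segmentation and states beyond four copies are out of
  scope, and aliased state pairs are resolved by parsimony, not evidence.
- The TH index is a *binned* entropy: tumors whose VAF structure differs
  only within a bin are indistinguishable, and the index is sensitive to
  purity (documented positive correlation) — it measures the VAF
  distribution, not clonality directly.
- Cutoff dichotomization at the cohort mean makes the TH group a
  cohort-relative label; groups are not transferable across cohorts with
  different VAF distributions.
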