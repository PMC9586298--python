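# Methods

## The analysis problem

A three-member model soil community — *Bacillus cereus* (B), *Flavobacterium
johnsoniae* (F) and *Pseudomonas koreensis* (K) — is cultured in every
subset combination (B, F, K, BF, BK, FK, BFK) plus sterile-media blanks,
five replicates each, in two parallel series: one with wild-type
*P. koreensis* and one with a koreenceine-null (Δkec) knockout in which the
koreenceine biosynthetic gene cluster (BGC) is deleted.  Two data types are
analysed:

* **metatranscriptomes** — per-species gene count matrices, from which
  BGC-level expression and condition-vs-monoculture fold changes are
  derived; and
* **metametabolomes** — untargeted LC-MS molecular-feature tables (peak
  area per feature per sample), from which per-feature factorial models,
  presence/absence tallies and sample-level ordinations are derived.

`cocomet` implements both arms as a reusable library + CLI, together with a
synthetic-study generator that emulates the design and plants known ground
truth, so every statistical component can be validated by parameter
recovery rather than by eyeballing.

## Transcriptome arm

**CPM.** Counts per million are plain library-size scaling:
`cpm[g,s] = counts[g,s] / colsum(s) * 1e6`.  No between-sample
normalisation factors (TMM etc.) are applied; the pipeline names only CPM
and keeps the method switchable in the run configuration (`cpm_method`).

**Low-expression filter.** Per reference genome, each gene's maximum CPM
across all samples is computed; genes strictly below the empirical 2.5th
percentile (linear interpolation between order statistics, the numpy
default) of their genome's maxima are removed.  "Maximum across
replicates" is read as the maximum over *all* samples of the experiment;
the per-condition alternative would retain strictly more genes and is not
implemented.

**Ψ fold change.** Effect sizes are the digamma-based posterior-mean log2
fold change

    psi(kA, kB; LA, LB) = [ψ0(kA + a) − ψ0(kB + a)] / ln 2 − log2(LA / LB)

with prior pseudo-count `a = 0.5` (Jeffreys-type, configurable).  It is
finite for all non-negative counts (including double zeros), antisymmetric
under swapping the two conditions at equal library size, strictly
increasing in `kA`, and converges to the naive log2 ratio for large counts.
Ψ is applied to replicate-summed **raw counts**, with library sizes — the
genome's total counts in the same samples — entering the estimator; this is
the natural domain of a count-based posterior.  Library sizes are per
*genome*, mirroring upstream per-species read splitting, so coculture
dilution of a genome's read share cancels out of the contrast.
Median-centering of the per-contrast LFC distribution is available
(`center`) but off by default.

**BGC aggregation.** Region-level expression is the exact sum of
member-gene CPMs; genes lost to the low-expression filter contribute zero
and are counted in a per-region report.  Wild-type-vs-knockout percent
changes use the "X% higher" convention, `(mut − wt)/wt × 100`, on
replicate-mean region totals of matched conditions.

## Metabolome arm

For each molecular feature *m*, log peak area is regressed on ±1-coded
community-membership indicators with all interactions:

    log(y_im) = β0m + Σ_j βjm·x_ij + Σ_jk βjkm·x_ijk + βBFKm·x_iBFK + ε_im

* **Containment coding** (default): an interaction entry is +1 iff *all*
  species of the term are present — the subset-indicator reading of the
  model.  **Product coding** (classical effect coding) is provided as an
  alternative; the two differ exactly on samples where some but not all of
  a term's species are present.
* **Rank structure.** Over the seven culture conditions either coding has
  rank 7 with null vector ∝ (1, −1, −1, −1, 1, 1, 1, −1) over (β0, B, F, K,
  BF, BK, FK, BFK).  The all-absent design point — the sterile media
  blank — restores rank 8.  Default fits therefore include the blanks as
  that eighth point, which is what makes the three-way term identifiable; a
  strict mode excludes them and reports the trailing term (BFK, by the
  entry-order pivoting convention intercept → mains → pairs → triple) as
  aliased.
* **Fitting.** Ordinary least squares on `ln(area + offset)` (offset 1 by
  default, so zero areas stay finite; irrelevant to t statistics for areas
  well above it).  The whole feature ensemble is fit in one vectorised
  solve; SEs come from the inverse normal-equations diagonal with
  `s² = RSS/(n − rank)`; `t = β/SE`; exact interpolation (RSS = 0) flags t
  as infinite rather than erroring.  Per-term ensembles are summarised by
  median and interquartile range.
* **Tail selection.** For a term, the upper/lower tails are features with
  t at or beyond the (100 − p)th / pth empirical quantiles (linear
  interpolation, p = 2.5 by default).  Ties at a threshold are included, so
  a degenerate all-equal ensemble selects everything — deterministic and
  superset-safe.
* **Two models.** One fit per genotype series (wild-type series, Δkec
  series), sharing the media blanks as the baseline point; variance is
  estimated per feature per series, not pooled.

## Presence/absence accounting

The detection threshold is anchored on analytes *known* to be absent:
koreenceine congeners A/B/C in knockout cultures, whose recorded areas are
pure noise.  The baseline is their **maximum** observed area over those
samples (simplest rule; mean + k·sd alternatives were deliberately not
layered on).  A feature is present in a condition when its replicate areas
beat the threshold under a rule — `median` (default; robust to one dropped
injection), `any`, or `all`.  Features present in media blanks are
classified media-derived and removed before tallying.  Tallies report, per
series, features seen only in multi-member cultures and only in the full
three-member community, and across series the shared / unique-to-each
partition of the non-media union (the three counts partition the union
exactly).  Presence is antitone in the threshold by construction.

## Ordination and clustering

PCA runs on per-feature unit-normalised (z-scored) areas via SVD;
zero-variance features are dropped and reported; variance explained sums to
100% and full reconstruction reproduces the normalised matrix.  Replicate
clustering uses Spearman correlation distance (1 − ρ) with average linkage
(a conventional pairing for correlation distances; configurable), making
the tree invariant to strictly monotone per-sample transforms.

## The synthetic-study generator

The generator produces the default layout (2 series × 7 conditions × 5
replicates + 5 shared blanks) with planted truth:

* **Features are log-normal**: log area follows the containment-coded model
  exactly, so the factorial fit is correctly specified under the null and
  recovers every planted coefficient exactly in the zero-noise limit
  (verified by test).  "Absence" is encoded at `detection_floor/10`
  (default floor 1e5 area units) rather than zero so logs stay finite,
  mirroring LC-MS noise floors.
* **Every non-media feature has a producer** — a species (main effect ~
  N(2.0, 0.4) clipped ≥ 1.2 on the natural-log scale), a pair (effect 3.0),
  or the full triple (effect 3.0) — whose containment effect places the
  absent side exactly at the noise level.  30% of species-produced features
  carry an additional positive modulation (half-normal, sd 0.3) on a pair
  containing their producer, giving the pairwise t ensembles realistic
  mass without perturbing blanks or the three-way truth.
* **Class sizes** default to 1,000 features with 10% media-derived, 75
  pairwise-only + 18 three-way-only (so 93 coculture-only features), and
  20 koreenceine-dependent features forced to the noise level in every
  knockout sample.
* **The flagship "community metabolite"** is one of the 18 three-way
  features with effect 6.0 instead of 3.0.  Rationale: at 5 replicates the
  three-way contrast is identified only by the 5 blanks, giving a
  coefficient SE of σ·0.632 ≈ 0.32 at σ = 0.5; an effect 6.0 separates the
  flagship's expected t from the bulk's maximum by more than four SEs, so
  "the largest planted effect carries the ensemble's maximum t" is a
  property of the design, not of a lucky draw.
* **Counts are negative-binomial** with one shared dispersion (0.05;
  Poisson in the dispersion → 0 limit), lognormal baseline gene means
  (median 200, sd 1 log unit), per-sample library sizes jittered ±30%
  around 1e6, and genes of absent genomes at zero.  Each genome carries 4
  BGC regions of 8 consecutive genes; planted region fold changes cycle
  (−2, +1, +3, 0) log2, each in its own coculture condition.  The
  koreenceine region is zeroed in knockout samples, and two *B. cereus*
  siderophore regions (bacillibactin, petrobactin) are boosted +3.5/+4.5
  log2 in knockout cocultures, emulating knockout-dependent up-regulation
  at a realistic order of magnitude.
* **Determinism**: one integer seed; child seeds for truth, counts and
  features are drawn from it in a fixed order; identical (config, seed)
  yields byte-identical tables.

### What the generator does **not** emulate

Retention-time drift, adducts/isotopes, missing injections, gene-length
effects, batch structure, between-feature correlation, and real feature
abundance distributions (log-normality is this module's assumption, not a
claim about the data).  Passing recovery tests therefore demonstrate that
the statistical machinery is correct under its stated model, not that the
model captures every property of real LC-MS or RNA-seq data.

## Numerical choices and degenerate inputs

Rank and null spaces via SVD with the standard eps-scaled tolerance;
rank-deficient fits retain a greedy maximal independent column subset in
term order and alias the rest; saturated fits (zero residual df) and
non-finite responses are errors; zero-total count columns, constant sample
profiles (undefined Spearman ρ) and empty analyte/sample sets are errors
naming the offender.  Result tables are written with six significant
digits, so file round-trips are exact to that precision.

## Known limitations

* CPM-ratio percent changes are compressed by library composition: a
  region boosted 2^4.5 in the knockout inflates that genome's library, so
  the measured percent change is smaller than the planted multiplier.
  This is a genuine property of CPM-based comparisons, shared with the
  original analysis style, and the tests assert direction and ordering
  rather than the raw multiplier.
* The same mechanism consumes part of the Ψ-recovery error budget for
  large positive fold changes: with 500 lognormal-mean genes per genome a
  planted +3 log2 region can hold ~5% of its genome's expression, biasing
  that condition's LFCs by up to ≈ −0.4 log2.  At paper-scale genomes
  (~5,000 genes) the bias shrinks roughly tenfold.
* The strict (blank-free) factorial mode cannot estimate the three-way
  term at all; any three-way statistic requires the all-absent design
  point or an external constraint.
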