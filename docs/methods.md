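# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `wheatpheno`, in the spirit of a
statistical-software methods appendix.

## Phenology model

Each plot's percent-heading trajectory is modeled as a logistic with fixed
asymptote, `y = 100 / (1 + exp(-(phi2 + phi3·day)))`. The asymptote is fixed
because percent heading saturates at 100 by definition; freeing it would let
short series trade asymptote against slope. Before fitting, six anchor
points are added — 0% at 10, 20 and 30 days before the first observation and
100% at 10, 20 and 30 days after the last — encoding the agronomic fact that
plots are unheaded well before scoring starts and fully headed well after it
ends. On a noise-free logistic series the anchors lie on the asymptotes and
move the 50% intersect by less than 0.1 day (tested).

Fitting is nonlinear least squares over (phi2, phi3) by Levenberg–Marquardt.
Initialization regresses logit(percent/100), with percents clipped into
[1, 99] for the logit only, on day to get phi3, and sets
phi2 = −phi3·(day nearest 50%). If LM stalls from that start, two fallback
starts at phi3 = 0.3 and 0.7 per day (the span of realistic wheat heading
slopes) are tried. A solution is accepted as converged when the solver
reports success, or when it exhausts its evaluation budget at a point that is
already first-order optimal (gradient below 1e-4) or effectively
interpolating (SSE below 1e-6); very steep plots that jump 0→100 between
scoring visits land in this regime. Non-converged fits are returned flagged
rather than raised so whole-trial tables stay aligned.

Heading date is the grid day in the fitted range (0.1-day steps, first
minimizer wins ties) whose prediction is closest to 50%; it agrees with the
closed form −phi2/phi3 to within half a step whenever the intersect is in
range. The rate of heading is phi3. Observations of exactly 0 or 100 are
kept as data; a series that never rises (all 0) or never falls below 100 is
rejected as unidentified. Day-of-year is 1-based.

Agreement between two measurement routes (e.g. visual vs classifier heading
dates) reports MAE, RMSE, the fractions within 1 and 2 days, and the slope of
an ordinary regression with intercept of method B on method A as a bias
check.

## Mixed model and heritability

The plot model is `y_ijk = mu + g_i + y_j + r_k(j) + e` with entry, year and
rep-within-year random. Single-year data drop the year and rep terms,
matching the single-year heritability denominator `σ²G + σ²e/r`; multi-year
data add a genotype-by-year component and use
`σ²G + σ²GY/y + σ²e/(y·r)`. Both H² forms are evaluated exactly from the
fitted components.

The residual is iid or separable AR1 (rows) ⊗ AR1 (columns), built as a
dense correlation over the occupied plot coordinates within each year (years
independent); missing grid cells are simply absent rows, no imputation.
REML maximizes the restricted log-likelihood directly over log-variances and
atanh-correlations: Nelder–Mead from a moment-based start (the spatial model
warm-starts from the iid solution with ρ = 0) with three jittered restarts,
then a BFGS polish with numerical gradients. On balanced single-year data
with an iid residual the estimates match the classical one-way ANOVA
expected-mean-squares solutions to ~1e-8 (tested), and the returned optimum
beats 20 random perturbations of the components (audited in tests).
Variances are parameterized on the log scale, so estimates are positive by
construction; a component driven to the boundary shows up as a vanishingly
small variance rather than a negative one.

Entry values: BLUEs are generalized least squares with entry fixed and the
non-genetic covariance as weight (arithmetic entry means under balance);
BLUPs are `mu + σ²G Z' V⁻¹ (y − mu)` and shrink toward the grand mean by
`σ²G/(σ²G + σ²e/r)` under balance (tested against that closed form).

## Genome scan, epistasis, segregation, prediction

A biparental RIL population has no population structure and no kinship beyond
the cross, so the association model is a per-marker simple regression of the
line value on genotype dose with a two-sided t-test, Bonferroni-corrected at
α = 0.05 over the tested markers. Heterozygous calls (≤6% after filtering)
are set missing by default because the tested effect is an allele
substitution between homozygote classes; midpoint coding is available. The
scan is vectorized over markers with per-marker missingness handled by
masked sufficient statistics; it matches statsmodels OLS per marker to 1e-8
(tested). Markers are pre-filtered at MAF < 0.1, missingness > 30% or
heterozygosity > 6%, the standard thresholds for GBS-derived RIL maps.

Epistasis is tested for every pair of scan-significant markers by comparing
the full model (intercept, two mains in symmetric ±1 coding, product
interaction) against the additive model with a 1-df F-test, Bonferroni over
the tested pairs. LOD is reported as `(n/2)·log10(RSS_add/RSS_full)`, the
standard regression-LOD mapping. Pairs with perfectly collinear markers are
skipped with a flag.

The segregation test is a 1-df Pearson χ² of the early/late line counts
against (0.75, 0.25) — the proportions obtained by enumerating the four
equal-frequency two-locus homozygote classes under dominant epistasis, where
one double-homozygote class is late and the other three are early.

Genomic prediction uses G-BLUP: a VanRaden genomic relationship matrix from
centered, frequency-scaled doses (missing calls mean-imputed for the
relationship only), the variance ratio λ = σ²e/σ²g estimated by a spectral
1-D REML on the training lines each replicate, and prediction of masked lines
by the mixed-model solution. Cross-validation masks 10% of lines, 100
replicates by default, and reports the mean predictive r, its 2.5–97.5%
interval, and "heritable variance modeled" defined as mean(r)²/H², with H²
supplied by the caller or taken from the genomic REML fit — one reasonable
reading of that ratio; it is flagged undefined when H² ≤ 0. A Bayesian
per-marker-variance sampler is deliberately out of scope; the method argument
accepts only `"gblup"` and says so.

## Label machinery

Labels for imaging days that fall between scoring days are the weighted
average of the flanking scores with weights proportional to the distance
from the other score — i.e. linear interpolation in time, which recovers the
endpoints exactly and is monotone between them. Patch grids are pure
geometry records (rows × cols offsets, top-left anchored); no pixels are
read, and the classifier is an injected function, so the consensus machinery
is testable with stubs.

The soft-label target puts 0.7 on the annotated class, 0.1 one class away
and 0.05 two classes away, reflecting measured rescoring discrepancies of
~10% at one class and ~5% at two. At the boundary classes the out-of-range
mass is folded back onto the annotated class rather than renormalized
proportionally: this keeps the sum exactly 1 while leaving the annotated
class strictly dominant (0.85 at 0% and 100%). The training error is the
mean absolute per-class probability mismatch, which is a metric up to the
1/11 scale factor (property-tested).

Image-level consensus is the argmax of the summed patch distributions;
plot-level consensus is a majority vote over image-level hard labels. Both
break ties toward the lower class deterministically. Whether plot-level
percent-heading consensus should vote classes or average them is not settled
by practice; both are exposed (`classify_prediction_table(mode=...)`) with
vote as the default.

## Synthetic-data generator

The generator is first-class, tested code; it defines the conditions under
which everything downstream is validated.

* **Map and population.** Evenly spaced markers on equal-length chromosomes
  (defaults 5 × 40 markers × 150 cM; a 21 × 400 map reproduces the scale of a
  real wheat GBS map). RILs descend by single-seed descent from a uniform F1
  with crossovers per chromosome Poisson(length/100), uniform positions, no
  interference (Haldane model — no map function was prescribed, this is the
  standard choice). Five selfing generations leave 0.5⁵ ≈ 3.1% residual
  heterozygosity, consistent with an F5 population passing a 6% het filter.
  Segregation distortion is gametic viability selection at one marker applied
  at every meiosis; its expectation follows a three-state Markov chain per
  locus, which the tests use as the oracle.
* **Trait architectures.** The default heading-date architecture has three
  loci (−2.5, −1.6, −1.2 days in ±1 coding) with −1.2-day interactions
  between the major locus and each of the other two, so the third locus acts
  only in the presence of the major locus's late allele — the conditional-
  effect signature seen at photoperiod loci — plus a 0.25 days² polygenic
  tail on an intercept of day 128. The rate trait is purely polygenic
  (variance 0.01 around 0.55/day), mirroring the empirical finding that rate
  of heading shows heritable variance but no mappable large-effect loci. The
  polygenic term is rescaled to hit its target sample variance exactly, which
  makes downstream heritability conditions reproducible. Effect sizes were
  fixed by a power analysis at n = 300 lines (smallest marginal effect ≈ 6
  residual SDs of the line mean) before any acceptance run.
* **Trial.** Entries × reps are laid on a rows × cols grid, reps in
  contiguous row bands with entries randomized within rep (augmented-design
  style blocking). Plot heading date = genetic value + year + rep-within-year
  + genotype-by-year + a spatial residual drawn with separable AR1
  correlation (Cholesky of the two AR1 factors applied to an iid grid).
  phi3 is the line's rate value plus optional plot noise (default 0.08/day in
  the pipeline — chosen to put rate heritability in the 0.4–0.6 range
  reported for this kind of trait); phi2 = −phi3 × heading date, so the
  latent curve crosses 50% exactly at the plot's heading date.
* **Scores and images.** Visual scores round the true curve to the nearest
  10%, then with probability 0.10 shift one class and probability 0.05 two
  classes (random direction, clipped at 0 and 100 — clipping, not
  reflection, keeps the support valid). No monotonization is applied,
  matching raw field scoring. Image-level prediction tables draw a perceived
  class with configurable leakage to adjacent classes and emit a peaked
  probability vector per image.

What the generator does **not** emulate: weather-driven scoring gaps,
observer drift over a season, spatial trends beyond stationary AR1,
check-plot augmentation structure, genotyping error or real LD decay
patterns, and multi-environment G×E beyond a year main effect and G×Y
variance. Passing tests therefore demonstrate correctness of the estimators
under the stated generating model, not robustness to every field artifact.

## Problem sizes and determinism

Validation uses populations of 300 lines × 200 markers (50 replicates for
architecture recovery), 12 simulated trials of 150 entries × 2 reps for
variance-component recovery, 200 plots for heading-date recovery, 800
permutations for family-wise-error calibration and 4,000 draws for χ²
calibration — sizes chosen so the full statistical battery runs in a few
minutes while keeping Monte-Carlo error well inside the asserted bands.
Every stochastic operation takes a single integer seed expanded into fixed
per-operation substreams (`core.rng_for`), and repeated runs are
bit-identical; the pipeline writes a manifest with the seed and a hash of the
full parameter set.

## Known limitations

* The REML surface is explored derivative-free; with many variance
  components and small data, restarts can land on a boundary (a variance
  pinned near zero). The log-likelihood and a convergence flag are reported
  so such fits are visible.
* The AR1⊗AR1 residual is dense; trials beyond a few thousand plots would
  need a sparse or Kronecker-factorized implementation.
* The single-marker scan assumes line means as input; it does not propagate
  uncertainty from the phenology fit or the BLUP stage.
* `heading_date` requires a rising curve (phi3 > 0) inside the searched day
  range; plots scored entirely before or after heading cannot be dated.
* The imputation operation is defined between flanking scores only; imaging
  days outside a plot's scored range are skipped, not extrapolated.
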