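# Methods

## Scope and data model

The pipeline starts at a quantified miRNA × sample integer count matrix
with per-sample metadata (group ∈ {PC, BTC, HC}, age in years, gender
M/F, BMI in kg/m²). Upstream read processing (quality trimming,
alignment, quantification) is out of scope, as are survival statistics
and stage-stratified analyses. Counts must be non-negative integers
with no missing cells; age/BMI may be missing only when the covariate
model is run without them.

## Expression filter

A miRNA is "expressed" when its count strictly exceeds 10 reads in at
least two samples. The strict inequality is deliberate (a count of
exactly 10 does not qualify). The filter precedes normalization, is
idempotent, and is invariant to sample order.

## TMM normalization

Between-sample scaling factors follow the trimmed-mean-of-M-values
scheme. The reference sample is the one whose 75th-percentile count
fraction is closest to the mean of those fractions. For sample $i$
against reference $r$, over miRNAs nonzero in both:

- $M_g = \log_2\!\big((y_{gi}/N_i) / (y_{gr}/N_r)\big)$,
  $A_g = \tfrac12 \log_2\!\big((y_{gi}/N_i)(y_{gr}/N_r)\big)$;
- two-sided trimming removes the outer 30% of the $M$ distribution and
  the outer 5% of the $A$ distribution (rank-based, keeping ranks in
  $[\lfloor k\,t\rfloor{+}1,\; k - \lfloor k\,t\rfloor]$);
- the factor is $2^{\sum w_g M_g / \sum w_g}$ with inverse asymptotic
  binomial variances $w_g^{-1} = (N_i-y_{gi})/(N_i y_{gi}) +
  (N_r-y_{gr})/(N_r y_{gr})$;
- factors are rescaled to geometric mean 1.

Depth invariance ("doubling one sample's counts leaves its factor
unchanged") holds only asymptotically because the precision weights
depend on absolute counts; the property test asserts it at 2% relative
tolerance, while compositional invariance (columns that are exact
scalar multiples) is exact.

All downstream modules operate on
$\log_2(y_{gi} \cdot 10^6/(N_i f_i) + 1)$ (log2-CPM, pseudocount 1, TMM
-effective library sizes). Euclidean distances on raw counts would be
dominated by a few high-abundance miRNAs; the log-CPM scale is the
standard variance-stabilizing choice and is applied uniformly to PCA,
clustering and KNN. Per-feature z-scoring is deliberately not applied
by default for KNN (distances act on the expression scale itself);
features are already on a common log scale.

## Negative-binomial differential expression

Counts are modelled as $y_{gi} \sim \mathrm{NB}(\mu_{gi}, \phi_g)$ with
$\mathrm{Var} = \mu + \phi\mu^2$ and
$\log \mu_{gi} = x_i^\top \beta_g + \log(N_i f_i)$. The full design is
intercept + group indicators (HC reference) + age + gender + BMI;
gender is coded 0/1 (F/M) and continuous covariates are centered and
scaled to unit variance for conditioning. Disease stage is deliberately
not a covariate: the cancer groups are modelled as wholes, since
per-stage subgroups are too small to support stable estimates. A
rank-deficient design (e.g. a covariate perfectly confounded with a
group) is an error naming the collinear columns.

Fitting is IRLS with working weights $\mu/(1+\phi\mu)$, relative
deviance tolerance $10^{-8}$, at most 50 iterations, batched across
miRNAs sharing the design. Non-converged fits are flagged and excluded
from the FDR with a warning rather than raising.

Dispersion is estimated in two stages:

1. **Common**: maximize the Cox–Reid adjusted profile likelihood
   $\sum_g [\ell_g(\hat\beta_g(\phi), \phi) - \tfrac12 \log\det
   X^\top W_g X]$ on an 18-point log grid over
   $[10^{-4}, 4]$, refined by a parabola through the three points
   around the peak (in log-dispersion). The grid floor doubles as the
   degenerate-input answer: an all-constant matrix returns the floor
   $10^{-6}$ with a warning.
2. **Per-miRNA**: a residual moment estimate
   $\hat\phi_g = \max\{0, (\sum_i[(y-\hat\mu)^2 \frac{n}{n-p} -
   \hat\mu]) / \sum_i \hat\mu^2\}$ about the common fit, then shrunk as
   $0.7\,\hat\phi_{\text{common}} + 0.3\,\hat\phi_g$ (weight
   configurable). This transparent common-plus-shrinkage scheme stands
   in for full empirical-Bayes tagwise machinery; its adequacy is
   asserted statistically — type-I error within 5% ± 2% under the null
   and high power/precision on planted effects — not by coefficient
   -level equality with any external implementation.

The group effect is tested per miRNA by LR = (reduced − full deviance)
against $\chi^2$ with (groups − 1) = 2 df; p-values are adjusted by the
Benjamini–Hochberg step-up (own implementation, checked against the
direct $\min_{j\ge i} p_{(j)} m/j$ formula). Pairwise log2 fold changes
are reported both from the GLM group coefficients (in the DE table) and
as descriptive group-mean log2-CPM differences with >2-fold flags (the
screening view; codes BP = BTC vs PC, PN = PC vs HC, BN = BTC vs HC).

## Cluster evaluation

PCA treats samples as observations and miRNAs as centered, unscaled
variables (all features share the log2-CPM scale, so variance scaling
is unnecessary); scores come from the SVD of the centered matrix with
a deterministic sign convention (largest-magnitude loading positive).

Correlation distances are $d(i,j) = 1 - r(i,j)$ with Pearson or
Spearman $r$ computed across miRNAs; a zero-variance sample is an
error. Agglomerative hierarchical clustering uses average linkage by
default (complete/single selectable — the linkage is genuinely an open
choice) and is cut at every $k \in \{2, \dots, 10\}$. The silhouette
width $s(i) = (b_i - a_i)/\max(a_i, b_i)$ uses the convention
$s(i) = 0$ for singleton clusters; the chosen $k$ maximizes the average
width, ties resolved toward the smallest $k$.

## KNN classification and marker ranking

`knn_predict` is fully deterministic: distance ties at the $k$-th
position are broken by stable training order, vote ties by the
smallest summed distance to the query among tied labels, then
lexicographic label order (with $K = 11$ a three-class vote can tie
5–5–1, so this matters). LOOCV processes samples in canonical
sample-ID order, making reports invariant to input column order.
Accuracy is the contingency trace over $n$; sensitivity(c) is the
diagonal over the true-class column sum; specificity(c) the correctly
rejected negatives over all negatives. In the two-group task "cancer"
(PC ∪ BTC) is the positive class.

Marker ranking scores each candidate alone by LOOCV, sorts descending
by the chosen criterion (accuracy, or sensitivity of the positive
class; macro-averaged sensitivity for multi-class tasks without a
positive class; ties: higher accuracy, then higher sensitivity, then
ID), and re-scores growing prefixes by LOOCV. By default ranking is
done once on the full dataset and the cumulative curves are therefore
optimistically biased as generalization estimates; `nested=True`
(CLI `--nested`) re-ranks candidates inside each leave-one-out fold
for an honest estimate.

$K$ is selected by bootstrap: per replicate, samples are resampled with
replacement, out-of-bag samples are predicted for every odd
$k \in [1, 21]$, and per $k$ the mean out-of-bag accuracy, its
bootstrap standard error and the mean winning-vote share are recorded.
The chosen $k$ is the smallest whose mean accuracy is within one
standard error of the maximum — an explicit, documented rule for a
selection step that is otherwise underdetermined. Replicates whose
in-bag set misses a class are discarded (error if more than half are).

## Validation t tests

The independent-cohort comparison is an unpaired two-sample test —
group sizes differ (34 cancer vs 19 control), so a paired test is
impossible — with the Welch unequal-variance variant by default and
Student's pooled variant selectable. Missing values are dropped per
miRNA; a group with fewer than 2 usable values flags the miRNA as
untested. No multiplicity correction is applied: the stage re-tests a
handful of pre-selected candidates. Ct-to-expression preprocessing is
out of scope; the module consumes an already-normalized table.

## Enrichment

Targets are the sorted union of genes mapped to the query miRNAs by a
user-supplied two-column table (no database content is bundled). Each
gene set is tested by the hypergeometric upper tail on the 2×2 table of
(list ∩ set, list \ set, set \ list, rest); the EASE option subtracts
one from the overlap before taking the tail (a non-positive reduced
overlap gives p = 1). Fold enrichment is
$(k/n)/(K/N)$; Bonferroni multiplies by the number of sets tested,
capped at 1. The background defaults to the union of the supplied
collection and is overridable; the gene list is intersected with the
background before testing (genes outside the universe cannot inform an
urn model).

## Synthetic cohorts

`simulate_cohort` emulates the cohort structure the analysis assumes:

- **Sizes**: 24 PC / 10 BTC / 21 HC; 677 miRNAs, 42 planted
  dysregulated at $|\log_2 FC| = 1$ with random sign.
- **Baselines**: log-normal CPM, median 100, $\sigma_{\log} = 1.3$ —
  heavy-tailed, chosen so roughly 95% of miRNAs pass the >10-reads
  filter at the simulated depths; planted effects are restricted to
  miRNAs with baseline ≥ 25 CPM so the filter cannot silently remove
  ground truth.
- **Counts**: NB with dispersion 0.2 (biological CV ≈ 0.45, a
  documented assumption for serum miRNA-seq, config-exposed); library
  sizes uniform in [5×10⁵, 2×10⁶].
- **Shared cancer signal**: by default 80% of planted miRNAs carry the
  same effect in PC and BTC (emulating the near-indistinguishable
  profiles of the two cancers); the rest are dysregulated in exactly
  one cancer. Setting the fraction to 1 reproduces the structural
  finding that three-group classification collapses BTC into PC while
  two-group classification stays strong.
- **Covariate confounding is on by default**: HC ages center on 43.9 y
  vs 62.8 y for both cancer groups (SDs 11.8/11.1/7.8), male fractions
  11/24, 7/10, 15/21 and group-specific BMI distributions; 10% of
  miRNAs respond to age (0.3 log2 units per SD), 5% to gender (0.4)
  and 5% to BMI (0.2). This makes the covariate-adjusted test
  meaningfully different from an unadjusted one; `confound=False`
  draws all ages from the control distribution.
- **Outliers**: `n_outliers` healthy controls (N01, N02, …) can be
  given cancer-like expression, emulating controls with benign biliary
  disease.
- Deterministic under the seed; the ground-truth record (planted IDs,
  effects, baselines, library sizes, covariate coefficients) suffices
  to regenerate the dataset.

`simulate_qpcr` draws Gaussian expression (34 cancer / 19 control by
default) with specified group shifts in SD units.

What the generator does *not* emulate: batch/hemolysis effects,
miRNA-miRNA correlation beyond shared covariate responses, zero
inflation, and adapter/sequence biases. Passing tests therefore
demonstrate correctness and calibration of the statistical machinery
under the stated model, not performance guarantees on real sera.

## Numerical choices and limitations

- IRLS linear predictor is clipped to offset ± 30 and means floored at
  $10^{-10}$; a tiny ridge ($10^{-10}$) stabilizes the weighted
  normal equations.
- Problem sizes in the test-suite simulations (e.g. 677 × 55 for
  calibration, 2000 miRNAs for the null-uniformity check, 500–1000
  replicates for type-I/power checks) were chosen as the smallest
  scales at which the asserted statistical properties are stable.
- The grid floor/ceiling bound the common dispersion to
  $[10^{-4}, 4]$; datasets with true dispersion outside this range are
  not expected in this application.
- Exact numerical replication of any external empirical-Bayes tagwise
  dispersion machinery is a non-goal; the acceptance standard is
  statistical (calibration, power, structure), as the original patient
  data are not available for value-level comparison.
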