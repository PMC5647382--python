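# Methods

## The problem

A handful of CpG loci, chosen well, can carry nearly all of the
subgroup-discriminating information of a genome-scale methylation profile.
The catch is robustness: a signature assayed by multiplex PCR and primer
extension on degraded DNA loses loci unpredictably, so the panel must be
*multiply redundant* — classification has to survive the loss of several
member loci — and the classifier must know when to refuse a call.
`msmimic` implements that design loop and the classification machinery
around it, exercised end to end on synthetic cohorts.

## Synthetic cohorts

`simulate_cohort` draws a samples × loci β matrix from Beta distributions:
background loci are exchangeable across subgroups (Beta(2, 2), a broad
unimodal distribution centred at 0.5), while each subgroup carries a
disjoint set of informative loci, half hypermethylated in-group
(Beta(8, 2), mean 0.8; Beta(2, 8) elsewhere) and half hypomethylated
(mirrored). The Beta family matches the bimodal, [0, 1]-bounded character
of array β-values, and the high/low shape pairs give one-vs-rest effect
sizes of Δβ ≈ 0.6, comfortably above the 0.3 margin the recovery tests
assert. Informative sets are disjoint by default so that "top 50 per
subgroup" pools to exactly 4 × 50 = 200 loci; an overlap option exists for
deduplication testing.

Defaults: 4 subgroups × 55 samples (220 total, the size of a realistic
genome-scale training cohort), 5,000 loci, 150 informative per subgroup.

Degraded source material is modelled purely as additive Gaussian noise on β
(clipped to [0, 1]) plus per-locus dropout: frozen tissue (σ = 0.02,
dropout 0.2%), FFPE sections (0.05, 3%) and cytospin nuclear preparations
(0.07, 5%), mixed 38/36/26% as in a validation cohort spanning all three
materials. No fragment-length or amplicon model is attempted — PCR
chemistry is out of scope — so the generator reproduces the *statistical*
signature of degradation (noise + missingness), not its mechanism.
Consequences for interpretation: tests passing here show the pipeline
tolerates independent, material-homogeneous noise and random dropout; they
say nothing about correlated locus failures (e.g. a whole multiplex
dropping out) or batch effects, which real assays can show.

Assay records emulate primer-extension read-out: each locus yields a
methylated/unmethylated intensity pair with m/(m+u) = β + truncated
Gaussian noise; a missing β becomes a failed call (zero intensities); the
bisulfite-conversion control is near 0 normally and near 0.5 when a
conversion failure is injected. Mixture series place every locus at the
input methylated fraction plus noise, supporting the linearity check used
to accept or reject amplicons. Survival is exponential per subgroup with
administrative censoring at 60 months — the simplest model supporting a
5-year progression-free survival framing. Default monthly hazards put
Grp4 at ~82% 5-year PFS (λ = 0.0033) and the other subgroups at ~95%
(λ = 0.00086).

All generation flows from one `numpy` Generator seeded by the config, so a
fixed seed reproduces cohorts bit for bit.

## Subgroup discovery

NMF minimises ‖X − WH‖_F by Lee–Seung multiplicative updates (the variant
is a package choice; 200 iterations, relative tolerance 1e-4 outside
consensus runs). Consensus clustering runs 50 factorizations per rank k
over random 80% sample subsets, accumulating co-assignment frequencies
normalised by co-occurrence counts; consensus runs use a lighter budget
(100 iterations, tolerance 1e-3, float32) because assignment argmaxes
stabilise long before the objective converges. Before clustering, loci
are restricted to the 2,000 most variably methylated (missing entries
filled with locus medians) — with 5,000-locus cohorts this keeps every
planted informative locus while cutting the factorization cost.

Rank selection: for each k, the consensus matrix is hierarchically
clustered (average linkage on 1 − consensus) and scored by the cophenetic
correlation and the mean silhouette width of the resulting partition. On
strongly structured data the cophenetic coefficient saturates — measured
values sit within ~0.001 of 1.0 across several ranks, with the ordering
among them dominated by Monte-Carlo noise — so ranks whose cophenetic is
within 0.01 of the maximum are treated as tied and the silhouette decides
among them (then the smaller k, for determinism). Clustering operates on
β directly; a logit transform is available upstream but not default, since
the factorization requires non-negativity.

## Signature design

**Moderated t.** For each subgroup, a one-vs-rest contrast per locus:
pooled two-sample variance s² with d = n₁+n₂−2 degrees of freedom, shrunk
toward a scaled-inverse-χ² prior, s̃² = (d₀s₀² + d·s²)/(d₀+d), with
t̃ = Δβ/(s̃√(1/n₁+1/n₂)) referred to t with d+d₀ df and
Benjamini–Hochberg adjustment. The prior (d₀, s₀²) is fitted by matching
the mean and variance of the observed s² to the marginal s₀²·F(d, d₀)
distribution; when the observed spread of variances is no larger than
sampling noise alone (r·d ≤ 2 where r = Var(s²)/E[s²]²) the prior df is
infinite and all variances shrink to s₀² = E[s²]. Setting the prior df to
0 recovers the ordinary two-sample t exactly — the shrinkage-off limit the
tests use as an oracle.

**Candidates.** Top 50 loci per subgroup by |t̃| (ties broken by locus id),
pooled with deduplication: 200 candidates under the default disjoint
planting. A pluggable design filter emulates the in-silico assay-design
triage — rejected loci are recorded with reasons and replaced by the
next-ranked locus of the same contrast. The default filter passes all,
since real primer design is out of scope.

**Fusion ranking.** Two stages mirror a hierarchical subgrouping model —
stage 1: WNT vs SHH vs Grp3∪Grp4 (three-class); stage 2: Grp3 vs Grp4
(two-class). Within each stage, four base learners are trained per
stratified 10-fold CV split: a linear SVM (importance = mean |weight|
across classes), a single-hidden-layer perceptron (16 units, LBFGS;
permutation importance on the held-out fold), a CART tree (Gini impurity
importance), and a naive-Bayes model over β discretized into three bins
(unmethylated < 0.25 / hemimethylated / methylated > 0.75; importance =
mean pairwise L1 distance between Laplace-smoothed class-conditional bin
distributions — a tractable stand-in for the Bayesian-network family).
Importances are averaged over folds, converted per learner to ranks, and
fused as the arithmetic mean of ranks (the simplest order-statistic
aggregation); ties break by mean absolute importance, then locus id.

**Redundancy optimization.** A candidate signature is scored by mean
stratified 10-fold CV accuracy of a linear SVM over random masks, each
deleting uniform(0..6) member loci (20 masks per score by default).
Starting from the top 17 fused-rank loci, each round finds the member
whose removal degrades the masked score least and trials swapping it for
the next-ranked candidate, keeping the swap only if the masked score
improves; the search stops when a swap fails or the candidate list is
exhausted (at most 8 rounds). `n_iter=0` disables the search and returns
the top-ranked loci unchanged. The target size (17) and mask depth (6)
are configuration parameters matching the shipped assay design.
Multiplexes 1–3 are assigned round-robin.

## Classification

Both models are `SVC(kernel="linear", probability=True)` — one-vs-one
decisions with pairwise-coupled probability calibration. The genome-scale
model uses the 10,000 most-variable loci and imputes by training medians
(a 10,000-dimensional Gaussian would be neither estimable from 220
samples nor needed, since array data has minimal missingness). The
signature model stores the mean and ridge-regularized covariance
(λ = 1e-3) of logit₂-transformed training β (clipped to [0.01, 0.99]; the
Gaussian fits transformed values far better than bounded β).

EM imputation holds the training parameters fixed and iterates
Gauss–Seidel sweeps on the precision-matrix linear system for the missing
block; for a symmetric positive-definite precision this converges to the
joint Gaussian conditional mean (the Schur-complement closed form the
tests verify against at 1e-6). Observed entries are never altered;
imputed values back-transform into (0, 1). Imputation is pooled across
classes by default — at classification time the class is unknown, so a
class-conditional impute would presuppose the answer — but class-
conditional statistics are stored and available behind a flag for
workflows where the label is fixed upstream.

The QC cascade orders failure modes by precedence: bisulfite-conversion
failure (control apparent β above 0.1 — the cut-off is configurable since
no canonical value exists) dominates; then more than 6 of 17 missing loci
(LOCUS_QC_FAIL); then EM imputation and SVM probabilities; calls with
maximum probability below 0.69 are non-classifiable (NC). Both
thresholds ship as defaults (6 and 0.69) and both have documented
re-calibration procedures: the missing-locus threshold is the largest
mask size whose bootstrap agreement with complete-data calls stays ≥ 0.99
(the agreement curve is monotonized by a running minimum first; the
bootstrap budget is the total number of masked classifications, spread
over mask sizes), and the probability threshold is the smallest 0.01-grid
value whose retained calls are error-free on validation predictions.
Classification is deterministic given model and input.

Model files are versioned JSON — parameters, means, covariance and the
fitted SVM coefficients — rather than binary pickles, for auditability;
the payload records the scikit-learn version it was written with.

## Survival

Kaplan–Meier curves come from lifelines' product-limit estimator per
group; 5-year PFS is read at 60 months from the right-continuous step
function. The k-group log-rank test is computed in-package with explicit
per-group observed/expected event bookkeeping (hypergeometric covariance,
χ² reference with k−1 df); lifelines' implementation serves as an
independent cross-check in the tests, and the asymptotic reference is the
default (a permutation option was considered and dropped — the cohort
sizes in play make the χ² approximation accurate, as the null-calibration
test confirms). Both the 4-group comparison and any merged one-vs-rest
comparison are supported by relabeling.

## Problem sizes and numerical choices

Test and acceptance runs use the generator defaults (220 × 5,000) for
end-to-end claims and a smaller planted cohort (80 × 600) for unit tests.
Fusion and redundancy scoring use 20–30 masks per score; the
masking-robustness checks use 250–500 masks. Monte-Carlo assertions carry
explicit allowances (e.g. ±0.01 on 250-mask agreement curves). Ties are
everywhere broken deterministically by (statistic, locus id); all
stochastic steps consume seeds derived from a single Generator.

## Known limitations

- The noise model is independent per locus and sample; correlated
  failures (multiplex-level dropout, batch effects, bisulfite-conversion
  gradients) are not emulated.
- The design filter for primer/multiplex feasibility is a pass-all stub
  with a pluggable interface; real signatures would be shaped by assay
  chemistry the package does not model.
- The signature model's Gaussian imputation assumes logit-β normality;
  heavily multimodal loci are handled only through the covariance
  structure.
- Whether the 17-locus target is pre-set or emergent is a modelling
  choice here: the package treats it as a configured target size, with
  the redundancy search selecting *which* 17 loci.
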