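# Methods

## Model and procedure

The phenotype vector **y** (length *n*) is modeled jointly on all
markers through the high-dimensional linear model
**y** = **Xβ** + **ε** with *p* ≫ *n* and sparse **β** (binary traits:
the logistic analogue).  Correlated markers are exchangeable members of
any "best subset", so the unit of inference is a *cluster* of
correlated markers, organized in a genome-wide hierarchy, and the
procedure asks for the smallest clusters that remain significantly
associated.

**Clustering.**  Dissimilarity between markers is d = 1 − |r| with r
the Pearson correlation of dosage columns.  The absolute value is
deliberate: anti-correlated markers explain the phenotype equally well
up to sign and must co-cluster.  Clustering is always genome-wide,
never per chromosome — population structure correlates unlinked
markers, and a cluster that combines two distant regions is a correct
statement that those regions cannot be statistically separated.  For
p ≤ `max_partition_size` (default 2,000) the tree is exact average
linkage on the full dissimilarity matrix.  Above that, a seeded
k-medoids pass partitions the markers (recursive bisection enforces the
size bound), each partition is agglomerated exactly, and partition
roots are joined by agglomerating partition medoids, with parent
heights clamped to be ≥ child heights.  The two-stage tree keeps the
contract that matters (every node is a candidate cluster; correlated
markers co-cluster) and is deterministic given the matrix and seed.

**Screening.**  Each sample split assigns a random half of the
individuals (split fraction 0.5) to screening.  Screening is a LASSO
with the penalty chosen at *minimum* tenfold cross-validated error —
deliberately liberal, since the testing stage controls the error.
Implementation: coordinate descent over a 100-value penalty grid with
`alpha_min/alpha_max = 0.01` in the n < p regime (the glmnet
`lambda.min.ratio` convention) and convergence tolerance 1e-3; markers
are standardized internally; the intercept and any fixed covariates are
unpenalized (covariates are projected out of the marker columns, and
out of a gaussian response, before the penalized fit).  Binary traits
use an L1-penalized logistic path over 25 penalty values scored by
log-loss.

**Testing.**  On the complementary half, clusters are tested from the
root down.  For cluster C with selected members C ∩ S ≠ ∅, the test
contrasts the model on all of S against the model on S \ C: a partial
F-test (gaussian) or likelihood-ratio χ² between nested logistic models
(binomial).  Collinear columns are dropped by pivoted QR and the
degrees of freedom adjusted; a cluster whose members add no rank gets
p = 1.  The raw p-value is adjusted by the selection-proportion factor
|S| / |C ∩ S| (capped at 1) and monotonized against the parent's
adjusted p.  Children are visited only while the current cluster's
adjusted p ≤ α.  If the LASSO selects more than n_test / 2 markers, S
is truncated to the largest-|coefficient| markers (logged), preserving
residual degrees of freedom.

**Aggregation.**  B independent splits (default 50) give per-node
p-value lists (1 for splits that did not test the node).  They are
combined with the quantile rule Q(γ) = min(1, γ-quantile of {p_b/γ}),
aggregated p = min(1, (1 − log γ_min) · inf_{γ ∈ [γ_min, 1]} Q(γ)) with
γ_min = 0.05; the infimum is attained on the grid of order statistics
and is evaluated there.  A final top-down monotonization pass makes the
minimal-significant-cluster rule well defined.  Per-split seeds derive
from the master seed via counter-indexed seed sequences, so results are
independent of execution order and thread count.

**QTC calling.**  QTCs are the minimal significant clusters (aggregated
p ≤ α, no significant descendant) **whose height does not exceed
`max_height` = 0.5**, i.e. whose members are correlated at roughly
|r| ≥ 0.5 on average.  The height bound is part of what a QTC *is*: a
set of markers that cannot be distinguished for their individual
contribution.  Without it, a phenotype that tracks population structure
makes the near-root cluster — thousands of weakly correlated markers,
height ≈ 0.95 — formally significant, because structure is genuinely
predictive genome-wide; such a diffuse polygenic signal remains visible
in the cluster p-value table but is not a locus and is not called.
Perfectly correlated markers (|r| = 1 up to 1e-12) are collapsed before
clustering — the first marker in genome order represents the class,
anti-correlated members carry a sign flag — and are reinstated into
their representative's QTC, contributing to localization.

## Synthetic data

**Island model** (structured populations).  Ancestral frequencies are
Uniform(0.05, 0.5); subpopulation frequencies are Beta-distributed with
mean p₀ and variance FST·p₀(1−p₀); individuals are assigned to
subpopulations in equal blocks; inbred material is coded {0, 2} from a
single allele draw so the dosage scale matches outbred {0, 1, 2}.
Marker positions are uniform over 5 chromosomes of 30 Mb and sorted.
What this emulates: structure-induced correlation between unlinked
markers, the one feature the error-control claim depends on.  What it
does not: physical LD along a chromosome, realistic allele-frequency
spectra, gene density (causal-locus placement is uniform).  Passing
tests therefore speak to robustness against *structure*, not against
tight local LD in real panels.

**RIL populations.**  Two parental haplotypes plus a genetic map;
crossovers per chromosome are Poisson(map_expansion × length in
Morgans) with positions uniform on the map, no interference;
map_expansion defaults to 2 to approximate the extra effective
recombination of selfing to homozygosity.  Lines are fully homozygous.

**Phenotypes.**  n_causal markers are drawn uniformly without
replacement; effects come from Gamma(shape 0.5, scale 1) — heavy-tailed,
a few large loci — or a standard normal, and attach to a randomly
chosen allele (a random sign on the dosage scale).  Environmental noise
is Gaussian with variance var(g)·(1 − h²)/h², calibrated on the
*realized* genetic variance, so the expected realized heritability
var(g)/var(y) equals the target (h² = 1 means y = g exactly).  Binary
traits threshold the realized liability at its (1 − prevalence)
empirical quantile, giving an exact case count.

## Default parameters

| parameter | default | why |
|---|---|---|
| α (FWER) | 0.05 | conventional family-wise level |
| n_splits B | 50 | simulation-scale default; 500 for fine selection-frequency maps |
| γ_min | 0.05 | standard lower bound of the aggregation quantile |
| split fraction | 0.5 | equal information for screening and testing |
| CV folds | 10 | tenfold CV for the screening penalty |
| dedup tolerance | 1e-12 | "perfect" correlation up to float error |
| max_partition_size | 2,000 | largest exact O(p²) linkage block |
| QTC max_height | 0.5 | minimum average within-cluster \|r\| for a callable locus |
| RIL map_expansion | 2.0 | selfed single-seed descent |

## Study scales

The bundled studies (`hitgwas.studies`, also used by
`scripts/acceptance.py`) run at desk scale, chosen so a full
reproduction completes on a single CPU in well under half an hour:
error control uses 50 structured-null replicates of 400 × 3,000 at 10
splits; heritability calibration uses 100 phenotype replicates on one
500 × 5,000 genotype matrix; localization precision uses 20 replicates
of 500 × 2,000 with 5 causal loci at h² = 0.9 and 10 splits.  The
statistical contracts being checked (FWER bound, calibration targets,
precision ≥ 95%) do not depend on these sizes beyond the quoted
binomial/SEM tolerances.

## Numerical choices and degenerate inputs

Missing dosages are mean-imputed per marker (an all-missing marker is
an error).  Zero-variance markers are dropped before clustering and
logged.  Rank decisions use pivoted QR with the tolerance
`|R₀₀|·max(n,p)·eps`.  Ties in medoid selection break toward genome
order.  A constant phenotype, a single-class binary phenotype, a
saturated testing design, and FST = 1 are errors with explicit
messages; an empty LASSO selection yields a split with no tested nodes
(all p = 1), and an empty QTC list is a valid result.

## Known limitations

Non-genetic confounders that co-occur with structure must be modeled
explicitly as covariates — nothing else corrects for them here.  The
method is conservative by construction (FWER, not FDR).  Effect sizes
are not estimated with confidence intervals; dominance and epistasis
are out of scope; the simulators produce no local LD, so localization
inside an LD block cannot be studied with them.
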