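# Methods

## Problem and model

Synthetic lethality (SL) is the phenomenon where simultaneous loss of two
genes kills a cell although either single loss is tolerated. In a tumor
cohort, SL partners of frequently mutated genes are candidate drug targets.
`cttkit` identifies *core therapeutic targets* (CTTs): genes that occupy hub
positions in a predicted SL network, so that a drug against one CTT exploits
many distinct SL dependencies across a heterogeneous patient population.

The workflow has four statistical stages.

### 1. Mechanism screens over known SL pairs

Both screens condition on a per-sample **gene inactivation call**: gene *g*
is inactive in sample *s* iff it carries a non-silent somatic mutation, or
its copy number is below `cnv_loss_cutoff` (default −0.3 on the log2
copy-ratio scale) *and* its expression falls below the per-gene
`expression_quantile` (default 0.1). The mutation-OR-(loss-AND-low-expression)
rule operationalizes "loss of function" in a way that is testable on every
layer the bundle carries; both thresholds are recorded in the
`InactivationProfile` for provenance.

* **Compensation screen.** For a pair (A, B) and each orientation, the
  expression of the partner in the conditioning gene's inactive samples is
  compared with its active samples by a Wilcoxon rank-sum test, one-sided
  "greater": if B compensates for the loss of A it should be
  *over*-expressed where A is inactive. An orientation is evaluated only
  when both groups have at least `min_group = 5` samples (a rank-sum test
  below that is noise); a pair passes when any evaluated orientation has
  p < 0.01 (strict). The p-value is exact (full enumeration of the rank
  null) for pooled sizes up to 16 without ties, otherwise the normal
  approximation with tie and continuity corrections.
* **Co-expression screen.** Pearson correlation of the two expression
  profiles, with the two-sided t-test p-value on n−2 degrees of freedom; a
  pair passes iff p < 0.05 **and** r > 0.5, both strict.

Raw per-pair thresholds are applied, matching the screening design this
package implements; Benjamini–Hochberg correction is available
(`bh_correct=True`) but off by default. Sidedness and orientation handling
are the package's own choices — the compensation narrative implies
one-sided over-expression, and testing both orientations avoids an
arbitrary choice of which gene is "the mutated one". Testing two
orientations per pair roughly doubles the pair-level null pass rate; in
practice the continuity-corrected approximation is conservative enough that
the measured null rate stays near the nominal 0.01 (about 0.014–0.018 at
1000 null pairs in our calibration runs).

### 2. Pair features and per-mechanism classifiers

Each gene gets a per-layer summary profile (expression mean and sample sd,
mutation frequency, CNV mean and sd, methylation mean, auxiliary-layer
means, pathway-membership count). Because an SL pair is unordered, the
pair encoding must be permutation-invariant: profiles are combined
elementwise as min / max / |difference|, plus symmetric pair-interaction
features (expression r, co-mutation frequency, CNV and methylation
correlations, pathway Jaccard). Summaries rather than raw per-sample
vectors keep the dimension independent of cohort size. Correlation
matrices are explicitly symmetrized, so `pair_vector(A,B) == pair_vector(B,A)`
holds exactly, not approximately.

Per mechanism, positives are the known SL pairs passing that mechanism's
screen and negatives are sampled uniformly without replacement from the
gene-pair universe at 1:20, excluding known positives (exact count,
reproducible from the seed). A random forest (500 trees, fixed seed) is
trained per mechanism; its reported score is the positive-class
probability. Accuracy is the AUC of pooled out-of-fold scores from a
stratified tenfold cross-validation, computed by the rank (Mann–Whitney)
formulation with midranks for ties. Candidate pairs (by default all pairs
among the genes of the known-SL input — the full genome-wide pair universe
is intractable and adds nothing testable) are scored by both models; a
pair is predicted at score > 0.5 (strict), and the final **consensus**
prediction is the intersection of the two mechanisms' predicted sets.

### 3. Co-expression modules and CTT selection

Weighted co-expression analysis is implemented from scratch: unsigned
adjacency a_ij = |cor_ij|^β; soft power β chosen as the smallest candidate
whose scale-free topology fit reaches 0.85 (signed R² of the log-log
degree-distribution regression, standard equal-width connectivity binning
with empty bins retained through a 1e-9 frequency pseudo-count); the
topological overlap matrix

    TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_{u≠i,j} a_iu a_uj

as similarity; average-linkage hierarchical clustering of 1 − TOM with a
**static** height cut (default 0.99) and minimum module size 30. The
static cut replaces the dynamic hybrid tree cut deliberately: it is fully
specified by two numbers and therefore exactly testable. Surviving
modules are renumbered by decreasing size (ties by smallest member gene
id); module eigengenes are the first principal component of the
standardized module submatrix, sign-anchored to correlate non-negatively
with the mean member profile.

Two caveats discovered while validating the power selection: the
scale-free criterion responds to *hub heterogeneity*. Data driven by a
single factor with equal loadings, or homogeneous planted correlation
blocks, have concentrated degree distributions and never reach the fit
target; heterogeneous loadings do. For planted-block recovery runs we
therefore fix the conventional unsigned-network power β = 6
(`ModuleConfig(powers=[6])`) rather than let the fallback select an
extreme power that pushes every TOM dissimilarity above the static cut.

CTTs are the per-module hubs of the consensus SL network: within each
module, the ceil(1% × module members present in the graph) highest-degree
genes, minimum one per module, ties broken by degree then lexicographic
gene id. Degree is computed in the full predicted network (SL partners
straddle module boundaries); an induced-subgraph mode exists. The
coverage statistic counts predicted pairs touching at least one CTT.

### 4. Annotation and mutation landscape

Regulator tables (miRNA, lncRNA, super-enhancer) are joined to CTT
targets; drug tables reach CTTs directly (drug→gene) or through a two-hop
join (drug→regulator→gene). Enrichment is an in-package hypergeometric
upper-tail test over user GMT sets with BH FDR — an explicit replacement
for web-service enrichment tools, documented as a methodological
substitution rather than a reproduction. Mutation summaries restrict a
MAF to a gene set and tabulate variant classifications, variant types,
the six pyrimidine-referenced SNV classes, per-sample burden (raw
qualifying-variant counts, not per-megabase), top mutated genes by
distinct mutated samples, and an oncoplot-style matrix with a `Multi_Hit`
category; Silent variants are excluded by default.

## Synthetic cohorts

The generator (`synthetic_data`) emulates a tumor multi-omics cohort on a
continuous, post-normalization expression scale (unit-variance Gaussian; no
count model, since every downstream stage consumes normalized values):

* co-expression modules as shared latent factors with loading
  √`within_module_r` (default 0.7, realized mean within-module correlation
  within ±0.1 at ≥100 samples);
* planted compensation pairs: A forcibly mutated in a
  `comp_inactive_fraction` (default 0.15) sample subset; B shifted upward
  by `comp_shift` (default 2) within-gene sd exactly there. Compensation
  pairs also carry baseline within-pair co-expression
  (`comp_coexpr_r`, default 0.7): biologically, SL partners act in coupled
  pathways, so the compensation and co-expression signatures co-occur on
  the same pairs — without this the intersection of the two mechanism
  models would be empty by construction and the consensus step untestable;
* planted co-expression pairs at target correlation `coexpr_r`
  (default 0.7); the comp and coexpr pair *sets* are disjoint;
* Bernoulli mutations (default rate 0.05 per gene/sample, a 5%
  hypermutator sample subpopulation at 10× rate), standard-normal CNV with
  focal losses of mean −1 at rate 0.05, Beta(2, 2) methylation.

Default sizes (500 genes × 200 samples, 100 + 100 planted pairs) keep a
full screen-train-predict-consensus cycle around 40 s on one CPU while
leaving all group sizes large enough for the rank-sum and CV machinery.

**What passing tests do and do not show.** The planted signals are clean,
Gaussian and independent across pairs; real cohorts have batch effects,
copy-number-driven expression dosage, non-Gaussian tails and correlated
mutational processes. Recovery of planted structure validates the
implementation, not the biological accuracy of the screens. In
particular, the default cohort plants module structure and SL pairs on
*disjoint* gene sets, so the end-to-end pipeline finds no ≥30-gene module
among consensus SL genes; hub selection is exercised by dedicated
constructions, and the acceptance script reports global top-1% hubs of
the consensus network treated as a single module.

## Numerical and degenerate-input choices

* Missing values: gene-mean imputation for real-valued layers (error when
  a gene has no observed value); missing mutation entries are 0.
* Constant genes: correlations set to 0 with a log entry (features,
  adjacency); zero-variance inputs to the Pearson test raise; a fully
  constant rank-sum comparison returns p = 1 with no signal.
* All pass rules use strict inequalities (p < α, r > 0.5, score > 0.5).
* Pair tables are always canonical: lexicographically sorted within pair,
  deduplicated, self-pairs dropped, row-order invariant.
* Seeds: every stochastic component (negative sampling, forest, CV folds,
  generator) takes an explicit integer seed; identical seed and data give
  bit-identical outputs.

## Known limitations

* No dynamic tree cut and no module merging by eigengene similarity.
* No essentiality-screen (shRNA/CRISPR) arm of the inactivation logic —
  no such modality among the supported inputs.
* Candidate pair universe defaults to genes seen in the known-SL input;
  genuinely genome-wide prediction would need blocked scoring.
* The enrichment test ignores GO graph structure and pathway topology.
* TMB is a raw count; cohorts with different capture sizes are not
  comparable without external normalization.
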