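# Methods

This note records the models, conventions and design choices behind
`myelotrace`, in the order the pipeline runs.

## Synthetic data model

The generator emulates a three-tissue (blood, cortex, hippocampus) mouse TBI
single-cell study with a 2 × 2 condition × timepoint design (TBI/Sham at
24 h/7 d) and a small number of mice per group (3 per condition × timepoint;
blood, cortex and hippocampus are generated independently, mirroring
per-tissue analysis without integration).

**Counts.** Gene counts are negative binomial with a common dispersion,
sampled through the gamma–Poisson mixture: `mean = μ_g · s_c`,
`var = μ + φμ²` with dispersion `φ = 0.3` (a typical droplet-data value) and
log-normal per-cell library-size factors `s_c` (σ = 0.25). The baseline mean
is 0.5 counts/gene over a 1,000-gene universe, giving realistic totals
(~500 counts, ~350 detected genes per cell). Ten mitochondrial genes carry
the mouse `mt-` prefix and a 4× elevated baseline, producing mitochondrial
fractions of a few percent.

**Structure.** Per-subgroup cell numbers default to the atlas-level subgroup
totals the study reports, split evenly over the four condition × timepoint
groups and scaled down uniformly by 0.25 so the default simulation stays
desk-sized (~20,000 cells); the scale is a package choice, exposed as a
parameter. Marker genes are elevated multiplicatively (2^lfc) in their
subgroup; condition effects multiply TBI cells of the stated tissue,
subgroup and timepoint. The default configuration plants the study's
reported regulation — Ccl2/Ccl7/Tnf up 1.5 log₂ at 24 h in CNS
microglia/activated microglia, Grn up 1.2 log₂ at 7 d, Ccr2/Tnfrsf1b up at
24 h and Flna at 7 d in blood monocytes — and doubles the aMG count in the
TBI-24h CNS groups as the composition signal.

**Trajectory data.** Branches form a rooted tree laid out in a 2-D latent
space (children fan out at ±70° from the parent's endpoint); cells are
uniform along their branch with isotropic Gaussian positional noise
(σ = 0.6 against branch length 10). Branch gene programs multiply the NB
mean of their member genes on that branch. The bundled three-branch
specification (monocyte root forking into MG and aMG branches) plants six
gene programs — per branch, one program up only there and one up on the
other two branches — which yields six distinct standardized state profiles,
the ground truth for branch-gene clustering.

**Determinism.** All randomness flows from one integer seed through
`numpy.random.SeedSequence` stream-splitting into PCG64 generators, one
named stream per public generator; output is bit-identical across runs and
platforms, and consuming one generator never perturbs another.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: doublets, ambient RNA, batch and chemistry
effects, gene–gene correlation beyond the planted programs, mean-dependent
dispersion, zero inflation beyond NB, and realistic trajectory geometry
(real differentiation manifolds are not noisy piecewise-linear trees).
Recovery results here demonstrate correctness of the implementations under
the stated model, not robustness to everything real tissue does.

## QC and normalization

Cell filtering keeps cells with `min_genes ≤ detected ≤ max_genes` and
`mito_fraction ≤ max_mito` (defaults 200 / 6,000 / 0.10). The exclusion rule
is stated with strict inequalities, so equality is retained; this boundary
semantics is pinned by tests. Filtering is idempotent, and all-zero cells
get a defined mito fraction of 0 (they fail the detected-genes filter
regardless).

Normalization is `ln(1 + count/total · 10⁴)` (natural log), which preserves
sparsity and is invariant to per-cell depth rescaling.

Variable genes use the vst recipe: a lowess trend (span 0.3) of
log₁₀ variance on log₁₀ mean of raw counts, each gene standardized by its
trend-predicted sd, values clipped at √N, genes ranked by the variance of
the clipped values. Fixtures with fewer than 50 usable genes (or too few
distinct means) fall back to a low-degree polynomial trend, since lowess is
unstable there.

PCA z-scores the selected genes (|z| clipped at 10) and uses exact SVD at
desk scale, switching to a seeded randomized solver above 2×10⁶ matrix
entries. Component signs follow the convention that the largest-magnitude
gene loading is positive, making embeddings reproducible. The number of PCs
(default 30) is a configuration choice; no value is prescribed by the
analysis itself.

## Composition

Percentages are pooled over mice within each tissue × grouping stratum
(matching atlas-level reporting; a per-mouse mode can be had by adding
`mouse` to the grouping columns) and printed half-up to two decimals — the
rounding needed to reproduce printed values such as 13,416/22,800 = 58.84%
exactly. Restricted fractions renormalize within a subgroup family (e.g.
aMG/(MG+aMG)). Condition contrasts are descriptive percentage-point
differences; no inferential machinery is attached, deliberately.

## Trajectory

Full reversed-graph-embedding trajectory inference (DDRTree-style) is out of
scope; the surrogate preserves the observable contract — a small number of
states, a monocyte root, a cell ordering, branch-dependent genes — with a
transparent construction:

1. k-means (fixed seed, default k = 25) summarizes the 2-D embedding;
2. the Euclidean minimum spanning tree over centroids is the backbone;
3. leaf segments shorter than 15% of the tree diameter are pruned
   iteratively (shortest first, MST re-derived each round) — raw MSTs on
   noisy embeddings always carry short spurious side-branches, and pruning
   is what reduces the tree to its genuine branch structure;
4. the root is the degree-1 node whose cells are richest in the designated
   root subgroup (ties to the lower centroid id);
5. states are maximal unbranched segments walking from the root (every
   child of a branch point starts a new state), so a linear tree has one
   state and a single fork has three;
6. pseudotime is the tree-geodesic distance from the root to the orthogonal
   projection of the cell onto the best incident edge of its centroid,
   clamped to the edge — non-negative, zero at the root end.

Branch-dependent genes: one-way ANOVA of normalized expression across
states, vectorized from sums of squares; genes constant everywhere get
F = 0, p = 1. BH correction, significance at adjusted p < 0.05. Significant
genes are clustered on row-standardized state-mean profiles with Ward
linkage cut at k = 6; subgroup ids follow dendrogram leaf order, making the
partition deterministic and invariant to gene order. When trajectories are
fitted jointly across tissues, the gene universe is intersected first.

## Enrichment

ORA is the upper-tail hypergeometric probability `P(X ≥ overlap)` with sets
intersected against the universe and BH correction across sets. The default
universe is all genes in the atlas (configurable); tests pin equivalence to
exhaustive enumeration for universes ≤ 25.

The pathway-activity score is in the ssGSEA/GSVA family rather than the full
kernel-CDF estimator of the original GSVA publication (the analysis names
the tool but no parameters; the tested contract is group-wise activity
differences). Per cell, genes are ranked by decreasing expression (ties
broken by stable gene order); walking down the ranking the running sum
steps up by `rank^τ / Σ_members rank^τ` at member genes (τ = 1) and down by
`1/(n_genes − n_members)` otherwise; the score is max + min deviation,
bounded in [−1, 1]. Being rank-based it is invariant to monotone per-cell
transforms, so log₂ input is a convention, not a requirement. Note the
τ = 1 weighting carries a deterministic positive offset under random
membership; null calibration is therefore judged against a permutation
baseline (or with τ = 0, which is a plain KS statistic centered at zero).
Group comparisons use Student's t at raw p < 0.05 — uncorrected across
pathways, mirroring how such comparisons are conventionally reported — with
an optional BH flag and a Welch flag.

## Ligand–receptor screen

The screen is the literal five-predicate conjunction over ordered gene pairs
from the branch-gene subgroup map: ligand subgroup ∈ {1,2,3,6}, ligand
secreted, receptor subgroup ∈ {4,5}, receptor plasma-membrane, interaction
edge present. Direction is fixed microglia→monocyte/macrophage; self-pairs
are excluded; a gene may carry only one location label (validated at input).
Candidates matching ≥ 4 predicates are kept as an audit trail. The
{1,2,3,6}/{4,5} numbering refers to the six branch-gene expression subgroups;
since a fresh clustering numbers its subgroups arbitrarily,
`eligibility_from_profiles` re-derives the split from the data — subgroups
whose mean state profile peaks at the root (monocyte) state are
receptor-eligible, the rest ligand-eligible — which the pipeline uses to
couple the screen to its own trajectory stage.

Expression annotation runs two-sided Student's t-tests of TBI vs sham on
log-normalized per-cell expression per (gene, tissue, subgroup, timepoint),
with stars at p < 0.05/0.01/0.001 (strict). Per-cell tests pseudoreplicate
relative to the mouse; a pseudobulk alternative can be built by averaging
per mouse before testing, and the per-cell default mirrors common practice.

## qPCR

Technical replicates are averaged per biological replicate;
ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the control-group mean ΔCt;
per-replicate fold change is 2^−ΔΔCt, reported as mean ± SD across treated
biological replicates (SD on the fold-change scale, matching how such
tables are presented; a log₂-scale SD is available by flag). P-values come
from Student's t on ΔCt — the scale on which Ct noise is approximately
additive — not on fold changes, and are BH-corrected across target genes.
Amplification-efficiency correction is out of scope. Exact identities
(shift invariance in Ct, 2^−ΔΔCt inversion, label-swap reciprocity in the
noise-free case) are test-pinned.

## Statistics conventions

All tests are two-sided (sidedness is otherwise unstated; two-sided is the
conservative default). Zero-variance edge cases: equal means → p = 1;
unequal means → p = 0 with a warning. BH is step-up with clipping and
monotone enforcement, order-preserving. Star thresholds are strict.

## Pipeline and problem sizes

The `run` orchestrator executes stages in dependency order from one YAML
config, rejects unknown keys, and writes a SHA-256 manifest of every
artifact; identical config + seed gives identical manifests. Default
problem sizes — the 0.25-scaled atlas (~20,000 cells × 1,000 genes), 600
trajectory cells, 50-seed qPCR recovery, 500-gene null calibration — were
chosen once as the smallest sizes at which the planted effects are
comfortably detectable at the study's effect magnitudes; they are package
defaults, not tuned quantities.

## Known limitations

The trajectory surrogate has no notion of embedding uncertainty, assumes the
2-D embedding already separates branches, and its pruning threshold (15% of
diameter) is a geometry heuristic — very short genuine branches would be
pruned. The GSVA-like score is not numerically comparable to GSVA's
kernel-CDF scores (only group contrasts are). The LR screen is annotation
driven: it cannot propose pairs absent from the PPI table, and its subgroup
eligibility inherits whatever instability the upstream gene clustering has.
The ΔΔCt model assumes perfect amplification efficiency.
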