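# myelotrace

Multi-tissue single-cell analysis of myeloid responses to traumatic brain
injury (TBI), packaged as a tested, reusable pipeline.

After a controlled cortical impact, CNS-resident microglia (MG) shift into an
activated state (aMG), macrophages accumulate in cortex and hippocampus, and
circulating Ly6c⁺/Treml4⁺ monocytes expand — a coordinated response that
unfolds between 24 h and 7 days and is orchestrated in part by secreted
microglial ligands signalling to receptors on peripheral myeloid cells
(Ccl2/Ccl7→Ccr2, Tnf→Tnfrsf1b, Grn→Flna). `myelotrace` implements the full
analysis chain for this kind of study — for computational biologists who want
each stage as a testable library function rather than a notebook — and pairs
it with a ground-truth synthetic-data generator so every stage can be
exercised offline, without downloading any accession.

## What it computes

* **QC & normalization** (`qc_normalize`) — cells are excluded when they have
  fewer than 200 or more than 6,000 detected genes or over 10% mitochondrial
  counts (strict inequalities: boundary cells survive). Expression is
  depth-normalized as `ln(1 + c_gc / C_c · 10⁴)`; highly variable genes are
  ranked by vst-style standardized variance (log₁₀ mean–variance trend,
  clipped standardized counts); PCA with a deterministic sign convention
  provides the embedding.
* **Composition dynamics** (`composition`) — subgroup percentages per
  tissue × condition × timepoint (half-up, two decimals), restricted family
  fractions such as aMG/(MG+aMG), and descriptive TBI−Sham contrasts in
  percentage points.
* **Branching pseudotime** (`trajectory`) — k-means centroids summarize a 2-D
  embedding, a Euclidean minimum spanning tree (with short-leaf pruning)
  gives the trajectory backbone, the leaf richest in monocytes is the root,
  states are maximal unbranched segments, and pseudotime is geodesic distance
  along the tree. Branch-dependent genes (one-way ANOVA across states,
  Benjamini–Hochberg) are grouped into k = 6 expression subgroups by Ward
  clustering of standardized state profiles.
* **Enrichment scoring** (`enrichment_scoring`) — upper-tail hypergeometric
  over-representation `P(X ≥ k)` with BH correction (significance at adjusted
  p < 0.05), and a rank-based per-cell pathway activity score (ssGSEA-family
  weighted running sum, score = max + min deviation ∈ [−1, 1]) compared
  between groups by Student's t-test.
* **Ligand–receptor screen** (`lr_screen`) — an ordered gene pair (A, B) is
  retained iff (1) A lies in branch-gene subgroup 1, 2, 3 or 6, (2) A is
  annotated *secreted*, (3) B lies in subgroup 4 or 5, (4) B is annotated
  *plasma membrane*, and (5) an A–B protein–protein interaction exists.
  Surviving pairs are annotated with per-stratum TBI-vs-sham t-tests and
  significance stars (\*p<0.05, \*\*p<0.01, \*\*\*p<0.001).
* **qPCR validation** (`qpcr`) — relative expression by the 2^−ΔΔCt method
  against a reference gene (Gapdh by default), mean ± SD across biological
  replicates, t-tests on ΔCt with BH correction across target genes.
* **Synthetic data** (`synthetic_data`) — negative-binomial count atlases
  with the study's tissue/subgroup inventory, planted marker genes, planted
  condition × timepoint effects, trajectory-structured data with branch gene
  programs, annotated PPI/location fixtures, GMT collections and qPCR plates
  — all with recorded ground truth and bit-reproducible under a fixed seed.

## Worked example

Screen the study-like annotated fixture (four true ligand–receptor edges
hidden among 50 decoys, each decoy failing exactly one criterion), then
analyse a simulated qPCR plate:

```python
from myelotrace import synthetic_data as sd, lr_screen as lrs, qpcr as qp

subgroups, locations, ppi, truth = sd.generate_lr_fixture(n_decoys=50)
retained, audit = lrs.screen_lr_pairs(subgroups, locations, ppi)
print(f"{len(ppi)} candidate interactions -> {len(retained)} retained pairs")
for p in retained:
    print(f"  {p.ligand} -> {p.receptor}")

plate, _ = sd.generate_qpcr(
    sd.SimConfig(seed=1, n_genes=50),
    genes=["Ccl2", "Tnf", "Grn"], fold_changes=[4.5, 5.1, 3.7],
    n_bio=3, n_tech=3, ct_sd=0.2,
)
res = qp.ddct_analysis(plate, reference_gene="Gapdh", control_group="control")
print(res[["fold_change", "sd", "pvalue", "p_adj"]])
```

prints

```
54 candidate interactions -> 4 retained pairs
  Ccl2 -> Ccr2
  Ccl7 -> Ccr2
  Grn -> Flna
  Tnf -> Tnfrsf1b

      fold_change    sd   pvalue    p_adj
gene
Ccl2         5.22 0.504 1.92e-05 1.92e-05
Grn          4.02 0.221 2.19e-06 6.57e-06
Tnf          5.34  0.42 9.28e-06 1.39e-05
```

The screen recovers exactly the four planted signalling axes — monocyte
recruitment (Ccl2/Ccl7→Ccr2), M1 polarization (Tnf→Tnfrsf1b) and delayed
macrophage differentiation (Grn→Flna) — and the ΔΔCt analysis recovers the
injected fold changes (4.5, 5.1, 3.7) within the noise of three biological
replicates at 0.2-cycle Ct noise.

## Command line

Each stage is a subcommand; `run` orchestrates the whole chain from one YAML
config with a hash manifest for reproducibility:

```bash
myelotrace simulate --seed 1 --out data/
myelotrace qc --input data/atlas_cortex --out qc_cortex/
myelotrace run --config config.yaml --seed 1
```

A config needs only `seed` and `out`; re-running with the same seed produces
byte-identical artifact hashes.

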