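# pathmix

Pathway-level mixed-model analysis of GWAS summary statistics.

Single-SNP genome-wide association studies of complex quantitative traits
(the motivating application is stature in dairy cattle) usually explain only
a small share of the phenotypic variation: the signal is spread over many
loci with small effects. `pathmix` moves the unit of analysis from the
single SNP to the functional gene set (KEGG-style pathway). It takes per-SNP
additive effect estimates from an existing GWAS, collapses them to one value
per gene, and fits a mixed linear model whose random effects are the
pathways themselves, with a between-pathway covariance given by the Jaccard
similarity of their gene memberships. The result is a predicted effect and a
one-sided p-value for every pathway — no genotypes or raw phenotypes needed.

## Model

Let **y** (one entry per gene) hold the absolute value of the additive
effect of the gene's strongest SNP. Then

```
y = 1μ + Zt + e,     t ~ N(0, V σ_t²),     e ~ N(0, I σ_e²)
```

where **Z** is the binary gene×pathway incidence matrix and **V** is the
pathway similarity matrix with entries

```
V[i,j] = J(i,j) = M / N
```

(M = genes shared by pathways i and j, N = total distinct genes in the two
pathways — the Jaccard coefficient; V has unit diagonal and is a positive
semidefinite kernel). Variance components are treated as known, as a fixed
split of the sample variance of y: σ_t² = 0.3 σ_y², σ_e² = 0.7 σ_y² (the
ratio is a parameter). μ̂ and the BLUPs t̂ solve Henderson's mixed model
equations

```
[ 1'R⁻¹1   1'R⁻¹Z        ] [μ̂]   [1'R⁻¹y]
[ Z'R⁻¹1   Z'R⁻¹Z + G⁻¹  ] [t̂] = [Z'R⁻¹y]
```

with R = I σ_e² and G = V σ_t². Each pathway is tested one-sided
(H₀: tᵢ ≤ 0 vs H₁: tᵢ > 0) against the prior density N(0, σ_t²):
pᵢ = 1 − Φ(t̂ᵢ/σ_t). See `docs/methods.md` for assumptions and numerical
details.

## Worked example

Simulate a small dataset with known truth (10 pathways of 12 genes, half of
them forced null) and analyse it:

```
pathmix simulate --config sim.yaml --out demo/     # or use the library API
pathmix run \
    --summary-stats demo/summary_stats.tsv \
    --gene-sets demo/gene_sets.gmt \
    --gene-models demo/gene_models.bed \
    --out demo/run
```

which logs the stage counts (333 SNPs read and assigned, 111 genes
collapsed, 10 pathways retained), prints

```
10 pathways retained, 0 significant at alpha=0.05
```

and writes `demo/run.pathways.tsv`:

```
pathway_id  n_genes_observed  t_hat      pvalue     significant
pw0008      12                0.217198   0.0850833  0
pw0000      12                0.151178   0.169856   0
pw0003      12                0.0506127  0.374623   0
...
pw0007      12                -0.381768  0.992045   0
```

`t_hat` is the predicted pathway effect on the scale of y (here, absolute
SNP effects), shrunken toward zero by the mixed model; `pvalue` is the
one-sided upper-tail probability under N(0, σ_t²), so negative predictions
can never be significant. A companion `demo/run.genes.tsv` lists each gene's
selected SNP and response value, and `demo/run.meta.json` records the
configuration and stage counts for reproducibility. Real data enter the
same way: a delimited summary-statistic table (column names configurable),
a GMT file of gene sets, and either gene models (GFF3/BED, positional
assignment with optional `--flank-bp`) or a precomputed SNP→gene TSV.

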