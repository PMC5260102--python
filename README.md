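# glints

Disease-specific prioritization of coding **and flanking noncoding**
single-nucleotide variants from exome sequencing candidates.

Exome pipelines leave hundreds of rare, predicted-deleterious SNVs per case
after frequency and consequence filtering, and they routinely discard the
variants captured in promoters, near-boundary introns and splice sites.
`glints` ranks such candidates for a *specific query disease* by requiring
evidence at two levels at once:

* **variant level** — up to 14 functional deleteriousness scores (8
  whole-genome scores usable in all regions, 6 protein scores for coding
  variants), consumed as precomputed columns and calibrated to empirical
  p-values against a background score database;
* **gene level** — 9 association scores between the host gene and the query
  disease, obtained by regressing p = 3 phenotype similarities (UMLS, MeSH,
  HPO vocabularies) on the genotype similarity
  x_de = Σ_{g∈D} Σ_{h∈E} φ_gh for each gene functional-similarity measure
  φ, testing H₀: λ′β = 0 against λ′β > 0 with
  T = λ′β̂ / √(λ′(x_c′x_c)⁻¹Σ̂_ε λ) ~ t_{n−2}.

The per-source p-values are combined with Fisher's statistic
U = Σ −2 log pᵢ under a dependence-corrected null: U is approximated by a
scaled chi-squared η·χ²_v with ηv = 2K and 2η²v = Var(U) = Σᵢⱼ cov(Vᵢ, Vⱼ),
where each covariance follows from the shrunk Pearson correlation of the
normal-transformed p-values through the quartic polynomial
a₁ρ̃ + a₂ρ̃² + a₃ρ̃³ + a₄ρ̃⁴ (a₁ = 3.263119, a₂ = 0.709866, a₃ = 0.026589,
a₄ = −0.709866/n). Missing sources simply reduce K. Combined p-values are
converted to q-values controlling the positive false discovery rate.
See `docs/methods.md` for the full model, numerical choices and limitations.

## Worked example

Everything the pipeline needs can be simulated — a toy genome with
multi-exon gene models, a correlated score database, a disease space with a
planted gene–disease signal, and a candidate VCF with one spiked causal
variant:

```bash
glints simulate --preset small --seed 11 --out demo --n-neutral 150
glints run --vcf demo/candidates_exon.vcf --disease D000 \
    --space demo --out demo/ranked.tsv --discard-out demo/discarded.tsv
```

which prints

```
ranked 151 variants (0 discarded, 0 non-SNV alleles skipped)
 rank    variant_key region gene_id  p_combined  q_value
    1 chr1:36878:G:A   Exon    G014    0.011948 0.999685
    2 chr1:36085:A:C   Exon    G014    0.055988 0.999685
    3 chr1:59449:T:C   Exon    G023    0.057680 0.999685
    4 chr1:31514:G:T   Exon    G014    0.074216 0.999685
    5 chr1:36892:G:T   Exon    G014    0.076224 0.999685
```

The spiked causal variant (`chr1:36892:G:T`, recorded in
`demo/candidates_exon.truth.json`) is ranked 5 of 151: its strong
functional scores and its host gene's association evidence lift it — and,
visibly, other exonic variants on the same gene G014 share the gene-level
boost. With essentially one causal variant among 150 neutral candidates the
q-values are rightly near 1; ranking, not thresholding, is the use case at
this sample size. Scoring the ranking against the truth:

```bash
echo chr1:36892:G:T > demo/causal.txt
glints evaluate --truth demo/causal.txt --ranking demo/ranked.tsv \
    --k 10 --out demo/metrics.json
# {"mrr": 0.0333, "auc": 0.9733, "top_10": 1, ...}
```

The rank ratio 5/150 = 0.033 is this run's mean rank ratio (MRR); the rank
-ROC AUC is 0.973. The same objects are available as a library:

```python
from glints import make_world, simulate_candidates, run_prioritization
from glints.pipeline import resources_from_world
from glints.synthetic_data import Region

world = make_world(seed=11)
resources = resources_from_world(world)
candidates = simulate_candidates(world, Region.PROMOTER, n_neutral=500, seed=0)
result = run_prioritization(candidates.variants,
                            world.truth["query_disease"], resources)
print(result.ranked.head())
```

Other subcommands: `glints annotate` (region classification only),
`glints calibrate` (scores → empirical p-values), `glints associate`
(gene–disease association p-values), `glints combine` (p-value matrix →
combined p and q-values).

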