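# Methods

`glints` prioritizes candidate single-nucleotide variants for a query
disease by integrating two kinds of evidence — per-variant functional
deleteriousness scores and gene–disease association strength — after
converting both to calibrated empirical p-values and combining them with a
dependence-corrected Fisher statistic. This note documents the model, the
numerical choices, the synthetic data the package validates itself on, and
the limits of what those validations show.

## 1. Region classification

Variants are classified against transcript models (BED12 or minimal GFF3)
using 0-based half-open internal coordinates (VCF positions are converted on
read):

| class | definition |
|---|---|
| Exon | nonsynonymous substitution inside the CDS (standard genetic code) |
| Splice site | intronic offsets 1–2 from an exon/intron boundary (canonical dinucleotides) |
| Intron | intronic offsets 3–10 from a boundary |
| Promoter | 500 bp strand-aware upstream of the TSS, plus 5′ and 3′ UTRs |

Anything else — intergenic, deep intronic, synonymous coding — is discarded
with a recorded reason. When a variant hits several transcripts or classes,
the most severe class wins (Exon > Splice site > Intron > Promoter); gene
models do not dictate a precedence, so this mirrors common annotator
behaviour. Splice offsets are counted from the intron side at both donor and
acceptor ends, and for very short introns the nearest boundary decides.
Stop-gain/stop-loss changes count as amino-acid-changing by default
(`count_stop_changes=False` restricts to missense). The promoter window
length is configurable; 500 bp is the default.

If a CDS length is not a multiple of three, the variant is judged on its
local codon only and a warning is issued; a trailing incomplete codon is
treated as not amino-acid-changing. A VCF REF that contradicts the reference
genome is a hard error rather than a silent skip.

## 2. Score orientation and empirical calibration

Fourteen score sources are configured by default: eight whole-genome scores
(CADD, DANN, FATHMM-MKL, Eigen, GERP, phastCons, SiPhy, PhyloP) applicable
to all four regions and six protein scores (MutationAssessor, SIFT, LRT,
MSRV, PolyPhen2, SinBaD) applicable to coding variants only. Scores where
smaller means more deleterious are oriented as `1 − x` when declared on a
[0, 1] scale (SIFT, LRT) and negated otherwise, so that larger always means
more deleterious.

Each oriented score is converted to an empirical p-value against a null
panel built from a background score database with known causal variants
excluded:

    p = (r + 1) / (n + 1),   r = #{null ≥ score}, ties inclusive.

The +1 smoothing (instead of the raw proportion r/n) keeps p strictly
positive — required by the −2·log p transform downstream — and converges to
the raw proportion for large panels; counting ties as "more extreme" is
conservative. Null panels are whole-database by default; per-region panels
are a matter of passing region-restricted background tables. Gene-level
analytical p-values are calibrated the same way against analytical
p-values of neutral (never disease-associated) genes, with "more extreme"
meaning smaller.

## 3. Gene–disease association regression

Under guilt-by-association, phenotype similarity between diseases should be
explained by the functional similarity of their gene sets. For candidate
gene g and query disease d, the genotype similarity to every other disease
e with a non-empty gene set is x_e = Σ_{h∈genes(e)} φ(g, h) for a gene
functional-similarity measure φ; d is treated as associated with g only.
The p = 3 phenotype similarities (UMLS, MeSH, HPO vocabularies in the
intended application; any symmetric unit-diagonal matrices here) are
regressed jointly on x:

    Y = X Θ + E,   X = (1, x),   rows of E iid N(0, Σ_ε),

with closed-form MLE β̂ = (x_c′x_c)⁻¹x_c′Y_c, α̂ = ȳ − x̄β̂,
Σ̂_ε = (n−2)⁻¹Ê′Ê. Association is tested one-sided via

    T = λ′β̂ / sqrt(λ′ (x_c′x_c)⁻¹ Σ̂_ε λ) ~ t_{n−2},   p = P(t_{n−2} ≥ T),

with λ = (1, 1, 1)′ by default (configurable). Under H₀: λ′β = 0 the
centring term vanishes, so the statistic is computed without it. The design
has a single regressor; the normal equation is a scalar division, so no
matrix inversion is performed.

Choices where the design was open: diseases with empty gene sets are
dropped from the rows (an `include_empty` flag keeps them as x = 0 rows);
fewer than 3 usable rows, a constant x, an absent gene, or an exactly-zero
residual variance all downgrade that measure's p-value to *missing* rather
than aborting the variant — missingness simply reduces K in the
combination. The nine measures are computed independently; a leave-out flag
removes the query disease's known genes (and the candidate itself) from
every other disease's gene set before computing x, which is how all
spike-in evaluations run.

## 4. Dependence-corrected combination and q-values

For the K present sources of a variant, Fisher's statistic is
U = Σ −2 log p_i. The sources are correlated (scores share training signals;
gene measures share the same gene), so the null of U is approximated by a
scaled chi-squared η·χ²_v matched on two moments:

    η v = 2K,      2 η² v = Var(U) = Σ_ij cov(V_i, V_j)
    ⇒  η = Var(U) / (4K),   v = 2K / η.

Pairwise covariances come from the Pearson correlation ρ̂ of the
normal-transformed p-values z = Φ⁻¹(1 − p) over a background panel (by
default the candidate set itself, pairwise-complete; pairs with fewer than
3 complete rows are treated as independent), the finite-sample shrinkage
ρ̃ = ρ̂(1 + (1 − ρ̂²)/(2n − 1)), and the quartic polynomial

    cov(V_i, V_j) = 3.263119 ρ̃ + 0.709866 ρ̃² + 0.026589 ρ̃³ − (0.709866/n) ρ̃⁴,

where n is the per-pair complete-observation count. Numerical choices:

* diagonal entries are fixed at exactly Var(χ²₂) = 4 rather than the
  polynomial's value at ρ̃ = 1 (≈ 3.999574 − 0.709866/n); this makes the
  reduction to classical Fisher **exact** when all correlations vanish
  (η = 1, v = 2K);
* negative ρ̃ passes through the polynomial (it is odd-dominated and near
  antisymmetric); η is floored at 10⁻⁶ if a pathological covariance sum
  turns non-positive;
* the null is re-fitted per distinct missingness pattern and cached, so a
  variant missing sources is combined over its own K_effective;
* closed-form sanity limits: independence → (η, v) = (1, 2K); perfect
  dependence → (K, 2); K = 1 → (1, 2).

Combined p-values are converted to q-values controlling the positive false
discovery rate. π̂₀ uses Storey's smoother — π₀(λ) over λ ∈ {0.05, …, 0.95},
a cubic-polynomial smooth evaluated at λ = 0.95 (the closed-form equivalent
of the customary df = 3 spline), clipped to [1/m, 1]; with fewer than 20
p-values π₀ defaults to 1. `pi0_mode="fixed"` (π₀ = 1) reproduces
Benjamini–Hochberg adjusted p-values exactly.

Ranking sorts by combined p ascending, breaking ties by larger U then by
variant key — deterministic and documented. A variant overlapping two genes
is scored against both and keeps the smaller combined p; both rows remain
in the audit table.

## 5. Synthetic worlds

The generator emulates, at desk scale, the structure of a spike-in
benchmark built on a population-scale variant panel. Defaults (the study
conditions used by all experiments here):

| parameter | default | rationale |
|---|---|---|
| genes / transcripts | 80, four 120-bp exons, 300-bp introns, 30-bp UTRs | every region class has a usable position pool per gene |
| score copula correlation | two-factor block structure (`SCORE_FACTOR_LOADINGS`): a conservation cluster (GERP, phastCons, PhyloP, FATHMM-MKL tightly correlated), an ensemble/protein cluster (CADD, DANN, Eigen, the protein predictors), SiPhy nearly independent | the block pattern real deleteriousness predictors exhibit; an equicorrelated alternative (`score_corr=<float>`) is available but concentrates too much variance on one common factor, which makes whole causal score vectors sink together and produces an unrealistically heavy rank tail |
| causal score shift | +1.5 SD per applicable source | per-source standalone rank-ROC AUC ≈ 0.86, the ballpark of a good individual predictor |
| score missingness | 5% whole-genome, 15% protein | coverage differences between score families |
| diseases / measures | 40 diseases, 9 gene measures, 3 phenotype measures | small but non-degenerate regression designs (n ≈ 39) |
| gene similarity | φ₀ = exp(−d²/2) over a 3-d latent embedding; measures are φ₀ + N(0, 0.05) noise | correlated but distinct measures |
| phenotype model | y = 0.30 + 0.08·x + ε, ε correlated (ρ = 0.3), SD 0.10, truncated to [0, 1] | causal-gene t statistic ≈ 1: genuine but moderate gene evidence, so gene sources inform the combination without single-handedly dominating it |
| causal genes | 5, attached to the query disease in the truth record only | the released disease→gene map mimics a disease with unknown genetics |

Marginals are standardized (no attempt to mimic per-score raw scales beyond
the [0, 1] orientation of SIFT/LRT), phenotype-similarity truncation bias is
accepted (recovery experiments use interior-range parameters), and neutral
control variants may land on causal genes, as real controls do.

What passing on this world does **not** show: behaviour under realistic
score marginals and region-dependent score coverage, linkage between
variants, miscalibrated or adversarial similarity matrices, or
database-scale candidate counts. The spike-in study (50 runs, 500 controls
each, one fixed world per study, 50 distinct spiked causal variants)
mirrors the qualitative benchmark finding — integration outperforms every
individual source — not any headline number from external datasets.

## 6. Evaluation metrics

Rank ratio = causal rank / #neutral; MRR is its mean over spiked causal
variants; the rank ROC sweeps a ratio threshold over all observed
breakpoints (trapezoidal AUC); TOP counts causal variants ranked within
k = 10. Causal ranks use conservative competition ranking: ties with
neutral variants, and a missing causal value in single-source rankings,
count against the causal variant. The top-list enrichment test is the
hypergeometric upper tail P(X ≥ x), identical to the one-sided Fisher exact
test on the 2×2 table.

## 7. Verification experiments and problem sizes

`scripts/acceptance.py` recomputes, from scratch at run time: the exact
Fisher reduction (16 × 1000 input grid), type-I calibration under an
equicorrelated copula (20,000 draws, K = 10, ρ = 0.6), the closed-form
null limits, regression agreement with textbook per-response least squares
(500 datasets, 10⁻¹⁰ tolerance), null uniformity of the association test
(2,000 β = 0 datasets), planted-parameter recovery (500 replicates,
per-coefficient 3-SE coverage — joint coverage of all six coefficients is
~97–98% even for a correct estimator, so coverage is pooled per
coefficient), empirical-p self-consistency (5,000 scores against a 50,000
-value panel; a same-size panel would feed the panel's own empirical-CDF
error into every query p-value and invalidate the KS test's independence
assumption), q-value/BH agreement (m = 10,000), the enrichment-test
enumeration oracle (all N ≤ 12), and the spike-in study (50 runs × 500
controls). These sizes keep a full verification run under a few minutes on
one CPU while leaving each stochastic check comfortably powered.

## 8. Known limitations

* Only SNVs: no indels or structural variants, no deep-intronic or
  intergenic assignment.
* The scaled-χ² null is a two-moment approximation; it is not exact for
  strongly dependent sources and no permutation-based alternative is
  provided.
* Gene-level p-values shared by a gene's variants are treated as ordinary
  sources; no within-gene correlation adjustment beyond the estimated
  source correlations.
* Score and similarity inputs are consumed as given — the package neither
  recomputes functional predictions nor constructs vocabulary-based
  phenotype similarities.
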