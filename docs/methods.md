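# Methods

This note documents the statistical models behind each stage, the
parameters that matter, the numerical choices, what the synthetic-data
generator emulates, and the known limitations.

## Indirect meta-analysis (`sumstats`)

Two case–control GWAS sharing a marker give estimates (β₁, se₁) and
(β₂, se₂). Treating them as independent, the Wald difference statistic

    z = (β₁ − β₂) / √(se₁² + se₂²),  χ² = z²  (1 df)

tests β₁ = β₂. This is the unique 1-df chi-square consistent with two
independent estimates; since the original reports do not print a formula
for their indirect comparison, this standard form is adopted as a
documented assumption. Correlation between the two comparisons (shared
controls make the estimates positively correlated, so the default is
conservative in the variance) is ignored by default; `cov` is exposed as
an optional covariance term (default 0) for sensitivity analysis.

Allele harmonization resolves ref/alt swaps by negating β₂; strand flips
are deliberately **not** auto-resolved — silent strand guessing is a known
source of sign errors, and ambiguous alleles raise instead.

## Suggestive loci (`loci`)

- `p_thresh` = 1 × 10⁻⁴, strict `<`. A marker at exactly 10⁻⁴ is excluded.
- MHC mask = chr6:26,000,000–34,000,000, both bounds inclusive, "chr"
  prefixes normalized. The megabase range is stated without a base-level
  convention in the sources, so inclusive bounds are the documented choice;
  the mask is configurable.
- `max_gap` = 500,000 bp, strict `<`, measured between adjacent sorted
  member positions. The greedy sweep equals the transitive closure of the
  pairwise "< max_gap" relation on a line (verified against a
  connected-components oracle).
- Single-marker loci are permitted. Duplicate (chrom, pos) markers collapse
  to the smaller p, ties to the lexicographically smaller id, for
  determinism.
- Published locus tables of this kind are sometimes exactly 1 Mb wide,
  suggesting lead-marker ±500 kb windows rather than marker-span hulls;
  `lead_windows` offers that view alongside the hull report without
  preferring either.

## Enhancer overlap (`overlap`)

Markers are points at their 1-based variant position (indels: leftmost
base). BED intervals are 0-based half-open: position p overlaps [s, e) iff
s ≤ p−1 < e, so [10, 20) covers 1-based 11..20. Intervals are merged on
load (abutting intervals merge — half-open adjacency carries no gap), and
lookup is a binary search over the merged set, verified against a naive
O(n·m) scan. Overlap is invariant to interval fragmentation by
construction. Chromosomes absent from a track yield "no overlap" rather
than an error, since tracks routinely cover only part of the genome.

## Cell-type enrichment (`enrich`)

The baseline reference is the set of markers overlapping an active
enhancer of **any** cell type; restricting to it removes the gross
"enhancer-dense regions attract both kinds of markers" confounding. For
cell type k among baseline markers:

|                | overlap k | no overlap k |
|----------------|-----------|--------------|
| suggestive     | a         | b            |
| non-suggestive | c         | d            |

- Fisher's exact test, two-sided by default ("greater" by flag); the
  two-sided rule sums table probabilities ≤ observed with relative
  tolerance 1e-7.
- Headline odds ratio is the sample cross-product ad/bc (∞, 0 or NaN in
  the zero corners); the conditional MLE is also computed for reference.
- Bonferroni multiplies by the number of cell types with ≥ 1 overlapping
  baseline marker — untestable tracks contribute no test.
- The tested cell type is included in its own baseline ("any" mode); a
  strict "any other cell type" mode is available by flag. When a single
  cell type constitutes the entire baseline the table margin degenerates
  (b = d = 0); the sweep reports p = 1 there rather than failing, while
  the public `fisher_exact` keeps the strict zero-margin error.
- `n_loci` counts loci contributing ≥ 1 marker to cell a.

Binned fold change: bins [0,1), [1,2), … on −log₁₀(p), last bin
open-ended. Per bin and cell type, the proportion is computed among the
bin's **any-overlap** markers (consistent with the Fisher baseline; an
all-markers denominator is a flag) and divided by the [0,1) reference-bin
proportion, so the reference bin's fold change is 1 wherever defined.
Bins with no any-overlap markers are emitted with `defined = False`.

## LD-cluster sensitivity analysis (`ldclust`)

Marker-level enrichment can double-count markers in tight LD. r² is the
squared Pearson correlation of 0/1/2 dosage vectors, pairwise-complete
over missing calls; markers with > 20 % missingness are rejected and
monomorphic markers raise. Clustering uses Ward's criterion in its
squared-distance (ward.D2) form via the Lance–Williams update

    d(ij,k) = √(((nᵢ+nₖ)d²ᵢₖ + (nⱼ+nₖ)d²ⱼₖ − nₖd²ᵢⱼ)/(nᵢ+nⱼ+nₖ))

on d = 1 − r², cut at height 1 − r²_threshold (default r² = 0.9). The cut
interprets the threshold as a dendrogram height; a constrained alternative
(complete linkage, guaranteeing every within-cluster pair satisfies
r² ≥ threshold) is available by flag. One representative per cluster
(smallest association p, ties by position) is compared against
`n_perm` draws of equally many markers taken uniformly without replacement
from the non-suggestive pool:

    p = (1 + #{perm stat ≥ observed}) / (1 + n_perm)

Add-one smoothing bounds p in [1/(n_perm+1), 1] and is reproducible given
the seed. Density-matched sampling and whole-cluster union overlap are
exposed as options but default off, since the motivating description
specifies neither.

A note on null uniformity: the permutation statistic is an integer count,
so its empirical p-value is uniform only up to the statistic's largest
atom. Calibration checks use representative sets of ~150 markers (pool
5,000, overlap rate 0.3), keeping the largest Binomial atom ≈ 0.07 —
small sets (say 50) would fail a KS check purely through discreteness.

## Gene prioritization and drugs (`genes`)

Per locus, only the members overlapping enriched-cell-type enhancers are
used (a flag relaxes to all members). The candidate is the gene with the
smallest eQTL p among those markers' records (ties: smaller marker-to-gene
distance, then gene symbol); eQTL records are trusted as given — no cis
window by default, because external whole-blood eQTL tables come
pre-filtered — with an optional 1 Mb cis filter. Without any eQTL the
fallback is the gene nearest the lead overlapping marker (gap to the
1-based inclusive span; 0 inside a gene, rendered "intragenic"). eQTL
evidence takes precedence over proximity wherever both exist; no stated
rule dictates otherwise, so the choice is documented here. If no gene
lies within 1 Mb (configurable) and no eQTL exists, the locus reports
`gene = none`.

Drug annotation filters a 3-column (drug, gene, indication) table by
indication, deduplicating names case-insensitively. Parsing vendor dumps
of the named pharmacogenomics databases is out of scope; the schema-level
TSV is the interface.

## Moderated-t differential expression (`degx`)

Two-group design only (the motivating comparison is 3 vs 3 arrays).
Per probeset: logFC = mean₂ − mean₁; pooled residual variance s²_g on
d_g = n − 2 df. The hierarchical model places a scaled inverse-chi-square
prior on σ²_g with prior df d₀ and scale s₀², giving posterior variance

    s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)

and t̃ = logFC/(s̃_g√(1/n₁+1/n₂)) with d₀ + d_g df. Hyperparameters are
estimated by moment matching on z_g = log s²_g: under the model
Var(z) = ψ′(d_g/2) + ψ′(d₀/2) and E[z] = log s₀² + log(d₀/2) − ψ(d₀/2)
+ ψ(d_g/2) − log(d_g/2), so ψ′(d₀/2) is set to the unbiased sample
variance of z minus ψ′(d_g/2) and inverted by monotone bisection on
(10⁻⁶, 10⁶) to tolerance 10⁻¹⁰. A non-positive target means no excess
dispersion: d₀ = +∞ and s̃² = s₀². Probesets with zero sample variance
are excluded from the fit (their log variance is −∞) but still shrunk
and flagged. Setting the prior df to 0 recovers the classical pooled t
exactly, and the fit agrees with the reference R implementation (limma)
to ~10⁻⁶ on shared inputs.

Probesets collapse to one row per gene (smallest p; ties: larger |t̃|,
then probeset id). DEG calls use Benjamini–Hochberg step-up adjustment
with a strict `fdr < 0.05` default. Input is assumed normalized log2
intensities (fold changes are reported as 2^logFC on the ratio scale);
no array preprocessing is performed.

## Synthetic data (`synth`)

The generator encodes the target study's conditions as defaults:

| parameter | default | meaning |
|---|---|---|
| n_markers | 20,000 | null markers across 22 chromosomes |
| n_planted_loci / mean markers per locus | 49 / 165⁄49 | ≈165 suggestive markers in 49 loci |
| planted_z | 8 | indirect noncentrality of planted markers (essentially all cross p < 10⁻⁴) |
| se / beta_sd | 0.05 / 0.1 | per-comparison standard error; spread of shared true effects |
| n_celltypes / planted | 20 / 2 | tracks; planted cell-type analogues |
| planted_or / base_overlap_rate | 3.0 / 0.3 | overlap odds ratio for suggestive markers of planted cell types |
| n_samples / block_r2 | 200 / 0.95 | LD panel size; within-block pairwise r² target |
| d0 / s0_sq / pi_de / n_per_group | 4 / 0.05 / 0.1 / 3 | expression variance hierarchy and design |

Null markers share a true effect between comparisons (central indirect
χ²); planted markers differ by δ = z√2·se. Planted loci occupy reserved
coordinate bands (> 205 Mb) disjoint from null positions so planted spans
are recoverable exactly; chance-suggestive null markers form their own
loci without touching them. Enhancer overlap is drawn per
(marker, cell type) as a Bernoulli — exactly the model the enrichment
stage tests, keeping ground truth exact — and then materialized as
200–2,000 bp BED intervals clipped so each interval covers precisely its
own marker point. The LD panel copies a latent haplotype per block with
per-gamete flip probability ε = (1 − r²^¼)/2, calibrating expected
pairwise within-block r²; blocks are independent. Each planted locus's
causal gene receives the smallest eQTL p at its locus by construction;
expression variances follow s₀²·d₀/χ²_{d₀} with group means ± logFC/2.

What the generator does **not** emulate: realistic allele-frequency
spectra and human LD maps, genome-wide peak landscapes (enhancer-dense
regions, peak length distributions), correlated eQTL effects, array-level
artifacts, or population structure. Passing tests therefore demonstrate
the correctness and calibration of the machinery under the assumed
statistical structure, not robustness to those real-data features.

## Scales used in verification

The verification suite and `scripts/acceptance.py` use problem sizes
chosen to make Monte-Carlo error small relative to the tolerances while
keeping a single-CPU run around a minute: exhaustive 2×2 enumeration to
N ≤ 30; 1,000 random instances for the locus and overlap oracles; 200
instances (≤ 6 leaves) for the clustering oracle; 500 null and 200
planted replicates at 200 suggestive + 5,000 non-suggestive markers × 20
cell types for enrichment; 10,000 probesets for hyperparameter recovery
and 100 replicates of 2,000 genes for realized FDR; 200 replicates × 499
permutations for the permutation null; and the full default scenario,
twice, for end-to-end determinism.

## Known limitations

- The indirect comparison ignores shared-control correlation unless `cov`
  is supplied; with substantial control overlap the default χ² is
  miscalibrated (conservative direction depends on the sign of the
  covariance).
- Enrichment treats markers as exchangeable within the baseline; LD is
  addressed only by the cluster-level sensitivity analysis, not by the
  primary test.
- The moderated-t fit covers two-group designs without trend/robust
  variants; general design matrices are out of scope.
- Strand-ambiguous (A/T, C/G) variants are not specially handled beyond
  the no-strand-guessing rule.
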