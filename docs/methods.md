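# Methods

## Scope and model

`hkgscout` operationalizes a simple definition of a housekeeping gene
(HKG): a gene whose normalized expression is nearly constant across all
samples of a study, regardless of which condition group a sample belongs
to. Stability is measured by the coefficient of variation
CV_i = σ_i / μ_i of gene *i*'s normalized counts over samples, with σ the
sample standard deviation (n−1 denominator — "standard deviation"
unqualified is read as the sample SD, matching standard statistical
software) and μ the arithmetic mean. Genes whose CV falls below a chosen
percentile of the CV distribution are the HKG set for that normalization.

Because the CV ranking depends on how counts are normalized, the pipeline
runs nine normalizations side by side and reports both the per-method HKG
sets and their intersection. The premise is that a gene stable under
*every* reasonable normalization is a safer reference than one stable
under only one.

## The nine normalizations

Six are scaling-factor methods (each sample's counts divided by one
positive factor s_j):

* **total counts (TC)** — s_j ∝ the sample's column sum over the
  zero-filtered gene set;
* **library size** — s_j ∝ externally supplied aligned-read totals N_j
  when given, else column sums. (Aligned-read totals can legitimately
  exceed in-matrix totals — reads aligning outside the quantified
  transcript set — which is why the two methods are kept distinct.)
* **upper quartile (UQ)** — s_j ∝ the sample's 75th percentile of counts;
* **median** — the same with the 50th percentile;
* **TMM** — weighted trimmed mean of M-values: with reference sample r
  (the sample whose P75-to-total fraction is closest to the mean
  fraction), over genes positive in both samples,
  M_g = log2((K_gj/N_j)/(K_gr/N_r)) and A_g = ½·log2((K_gj/N_j)(K_gr/N_r));
  the top and bottom 30% of M and 5% of A are trimmed (rank-based, average
  ranks over ties, the published defaults of the algorithm) and
  f_j = 2^(Σ w_g M_g / Σ w_g) with inverse-asymptotic-variance weights
  w_g = ((N_j−K_gj)/(N_j·K_gj) + (N_r−K_gr)/(N_r·K_gr))^(−1).
  s_j = f_j·N_j, rescaled to geometric mean 1. If trimming leaves no gene,
  f_j = 1.
* **median-of-ratios (DESeq-style)** — s_j = median over genes positive in
  all samples of K_ij / geomean_i(K_i·).

UQ/median/TC/library-size factors are divided by their arithmetic mean
over samples; TMM factors by their geometric mean; median-of-ratios
factors are left as computed. These centring conventions are cosmetic:
the CV (and hence every selection) is provably invariant to a single
global rescale of any factor set, and the unit tests assert this.

The remaining three reshape values rather than scale samples:

* **quantile** — every column is forced onto the reference distribution of
  per-rank means of the sorted columns; ties within a column receive the
  mean of the reference values over the tied ranks (the behaviour of
  limma's `normalizeQuantiles`). Exact multiset equality across columns
  therefore holds only when a column has no tied counts.
* **RPKM** — depth first, length second: K_ij / (N_j/10⁶) / (L_i/1000),
  with L_i the gene length in bases.
* **TPM** — length first, depth second: rates K_ij/(L_i/1000) rescaled so
  every column sums to 10⁶.

All percentiles (UQ, median, TMM's reference choice, CV quartile
summaries) use linear interpolation between order statistics (numpy's
default, the "type 7" rule) over *all* counts of the zero-filtered
matrix, zeros included. Zero handling in the percentile is the one point
the underlying definitions leave open; including zeros after the
all-zero-gene filter is deterministic and matches mainstream
implementations.

## Selection rule

The HKG count is `floor(percentile/100 × N)` where N is the number of
genes with defined CV — a rank-based rule, so the count is deterministic:
47,613 genes at the 2nd percentile give exactly 952. Ties in CV are broken
lexicographically by gene ID. Genes with zero normalized mean are excluded
from the CV table (σ/μ undefined) rather than assigned CV = ∞; after the
upstream all-zero filter this is rare, and the exclusion count is kept.
Raising the percentile always yields a superset (tested).

## Expression ratios

For a selection, each gene's mean normalized value is expressed as a
fraction of the maximum normalized value attained within that selection
(any gene, any sample), and binned into the fixed intervals
0–0.01, 0.01–0.05, 0.05–0.20, 0.20–0.40, 0.40–0.60, 0.60–0.80, 0.80–1.0
(right-closed; the first bin includes 0). A `denominator="global_max"`
variant divides by the matrix-wide maximum instead — the two readings of
"the maximum" that circulate; the set-wide maximum is the default because
it is the self-contained one.

## Bias and variance of a normalization

Per gene, with r_ij = log2(K_ij / K̄_i) and K̄_i the gene's mean:

    bias_i     = sqrt( (1/n) Σ_j r_ij² )
    variance_i = (1/(n−1)) Σ_j (r_ij − r̄_i)²

The inner centring term of the variance is the per-gene mean of the
log2-ratios — the standard sample-variance form, and the only reading that
yields a variance. Both quantities are invariant to rescaling a gene by a
constant. Genes containing any zero value are skipped and counted (the log
is undefined); a pseudocount escape hatch exists but is off by default,
because silently shifting all values would bias the metric for exactly the
low-expression genes it is most sensitive to. Method-level scores are
arithmetic means over the retained genes of the evaluated set — here, each
method's own HKG selection, so the comparison asks "how quiet are the
genes this method itself calls quiet".

## Overlap validation

Overlaps between HKG selections and external gene lists are plain set
intersections after symbol normalization (strip whitespace, uppercase; no
alias or cross-database ID mapping — that is annotation work out of scope
here). Percentages can be computed on the external list's size
(`basis="list_size"`, the convention for both DE-signature depletion
checks and published-HKG-compendium comparisons) or on the selection's own
size (`basis="hkg_size"`); the basis is recorded in the output.

## The synthetic-data generator

`simulate_dataset` draws K_ij ~ NB(mean = μ_i · 2^{fc_{i,g(j)}} · ℓ_j,
dispersion = φ_i), NB variance mean + φ·mean². Defaults describe the
emulated study design and are not meant to be tuned per run:

| parameter | default | meaning |
|---|---|---|
| n_genes | 10,000 | transcripts (a scaled-down expressed transcriptome) |
| groups × replicates | 6 × 5 | condition groups (one stable + five disease) |
| fraction_hkg | 0.04 | planted HKG: fc ≡ 0 **and** φ = 0.005 |
| fraction_de | 0.06 | DE genes, each perturbed in exactly one disease group |
| base_dispersion | 0.2 | biological dispersion of non-HKG genes |
| \|log2 FC\| | ~ Normal(2, 0.5), random sign | DE effect sizes |
| library factors ℓ_j | ~ logNormal(0, 0.3) | sequencing-depth heterogeneity |
| baseline means μ_i | ~ logNormal(log 50, 1.5) | long-tailed expression levels |
| gene lengths | ~ logNormal(log 1500, 0.6) bp, ≥ 100 | for RPKM/TPM |

Planted HKG get both constancy properties the HKG concept implies — no
condition effect *and* low biological dispersion. Aligned-read totals are
simulated as column sums inflated by a Uniform(1.05, 1.15) factor, so the
library-size method sees genuinely external (and slightly noisier) depth
estimates. All draws come from one seeded generator in a fixed order;
identical config + seed reproduce byte-identical files.

What the generator does **not** emulate: gene–gene correlation, batch
effects, FFPE-style degradation, length-dependent coverage bias, isoform
structure, or composition effects strong enough to defeat total-count
normalization. Consequently, passing recovery tests show the pipeline's
machinery is sound under its own model assumptions — planted HKG are
recovered with precision 1.0 and zero DE contamination at the default
design — but say nothing about how large the real-data gap between
normalization methods is. The qualitative ordering (RPKM/TC score worse
than quantile/TMM/median-of-ratios on bias and variance) does reproduce in
simulation, driven by the noise of raw-total depth estimates under a
heavy-tailed mean distribution, yet the margins are far smaller than on
real tissue data, where composition and coverage artefacts widen them.

## Verification strategy and problem sizes

Every normalization is checked against an independent oracle: a
hand-coded median-of-ratios enumeration and pydeseq2's `deseq2_norm` for
the size factors, a naive sort-trim-weight loop and edgeR's
`calcNormFactors` (via Rscript) for TMM, hand-derived two-column examples
for UQ/quantile/RPKM/TPM, and a brute-force transcript of the
bias/variance formulas (agreement to 10⁻¹²). Property tests (hypothesis,
derandomized) cover scale recovery of all six factor methods on
proportional columns, filter idempotence, selection monotonicity and CV
scale invariance. End-to-end checks run the default simulated design
(10,000 genes × 30 samples; ten seeds for the method-ordering check) —
sizes chosen to make the statistical assertions stable while keeping the
full suite fast.

## Known limitations

* Symbol matching is string-based; lists using aliases or Ensembl IDs must
  be harmonized upstream.
* The 2nd-percentile rule fixes the HKG count, not an absolute stability
  level; on noisy data the "most stable 2%" may still be unusably noisy.
* CV is computed pooled across all samples, not per condition group; a
  gene quietly bimodal between groups but with small pooled CV would pass.
* Quantile normalization equalizes distributions by construction, which
  deflates its bias/variance scores; the metric comparison should be read
  together with the recovery results, not alone.
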