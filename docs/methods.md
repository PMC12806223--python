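# Methods

## The ceRNA model and the pipeline's reading of it

The sponge hypothesis treats a miRNA as a shared repressive resource: a
lncRNA carrying the miRNA's binding sites competes with the miRNA's mRNA
targets, so raising the lncRNA de-represses the mRNA. In a case/control
comparison the expected signature of a real axis (lncRNA, miRNA, mRNA) is

* lncRNA and mRNA differentially expressed in the **same** direction,
* the miRNA differentially expressed in the **opposite** direction,
* optionally, negative miRNA–ceRNA expression correlation across samples.

The pipeline implements this as a sequence of monotone filters over a
reference interaction network: DE overlap → direction discordance →
(optional) correlation → miRNA pruning → triple enumeration → scoring →
GWAS annotation. Every filter only removes edges, so stage counts in
`report.json` decrease monotonically, which is asserted in the tests.

The mandatory filter is the DE-direction rule. Requiring in addition
negative sample-level correlation is scientifically attractive but
statistically fragile in the small cohorts this tool targets (six samples
per group): rank correlations at n = 12 have a standard error of roughly
0.3, so the stage is **off by default** and exposed as
`use_correlation_filter` (miRNA–ceRNA anticorrelation: rho < 0,
|rho| ≥ `min_abs_rho` = 0.3, p < `corr_p` = 0.05, Spearman by default) and
`require_pos_corr` (the complementary positive lncRNA–mRNA check, applied
per triple at enumeration). Both directions of the criterion are exposed
separately precisely because published descriptions of this filter are
often ambiguous about which pairs must correlate with which sign.

miRNA pruning removes miRNAs that interact with only one ceRNA class
(such a miRNA cannot anchor a lncRNA–miRNA–mRNA triple). Removal can
orphan ceRNA nodes and thereby expose further violations, so the rule is
iterated to a fixed point rather than applied once; the fixed point is
the only self-consistent definition and is verified against a
loop-until-stable reference implementation.

## Reference-network assembly

Interaction tables are treated as exchangeable two-column TSV exports
(configurable column names), one per source database. Identifiers are
harmonized before merging: gene symbols upper-cased and stripped; miRNA
names lower-cased with the species prefix (`hsa-`/`mmu-`/`rno-`) removed
and the arm suffix (`-5p`/`-3p`) preserved; an optional alias map applies
after normalization. Edges are merged by set union; an edge's
`support_count` is the number of distinct source labels attesting it,
and a `min_support` threshold (default 1, i.e. keep everything) is
exposed rather than guessed. An identifier appearing in two RNA classes
(e.g. as lncRNA in one table and mRNA in another) is an error listing the
offending ids, not a silent choice.

## Differential expression

The DE stage is a deliberately small, fully documented NB Wald test — not
a reimplementation of DESeq2 (no dispersion shrinkage, no Cook's
filtering, no independent filtering). Users who want DESeq2 semantics
import its result table verbatim via `import_de_table`, which feeds the
identical downstream gate.

* **Size factors**: median-of-ratios. For each sample, the median over
  genes positive in all samples of count / geometric-mean-across-samples.
  If no gene qualifies, the error message points to
  `allow_pseudocount=True` (adds 0.5 for factor estimation only).
* **Fold change**: `log2fc = log2((mean_case + c) / (mean_control + c))`
  on normalized counts with pseudocount c = 0.5, so genes absent in one
  group get large but finite fold changes. Genes with zero counts
  everywhere are dropped with a warning.
* **Dispersion**: per-gene method of moments, `alpha = (var − mu)/mu²`
  within each group, combined by the elementwise **maximum** across the
  two groups and floored at 1e-8. The maximum (rather than an average) is
  a conservative choice: with five degrees of freedom per group the
  moment estimate is noisy, and averaging lets genes with one
  underestimated group through with inflated Wald statistics. With this
  combination the empirical type-I error at p < 0.05 on null NB data
  (6 vs 6, dispersion 0.1) sits near 0.05, which the acceptance test
  checks against the band [0.03, 0.08].
* **Wald test**: `stat = log2fc / SE`, with SE from the delta method
  under `Var(K) = mu + alpha·mu²` propagated through the normalized group
  means, two-sided p from the standard normal, and BH-adjusted p-values
  reported alongside.
* **Gate**: a gene is DE iff |log2fc| > 2 **and** p < 0.05, both strict,
  on the raw p-value by default (`use_padj` switches to BH). The strict
  boundary and the raw-p default match the printed form of these
  thresholds in the literature this tool follows; both are overridable.

Two exact symmetries are tested: swapping case/control labels negates
every log2fc bit-for-bit, and rescaling one sample's counts by a constant
changes only the relative size factors (log fold changes are unchanged;
with a non-zero pseudocount the invariance is exact only in the limit of
large counts, so the test uses pseudocount 0 on noiseless input).

### Accuracy versus sampling noise in the tests

At the emulated cohort size (6 vs 6) and bulk-typical dispersion 0.1, the
sampling standard deviation of a per-gene log2fc estimate is ≈ 0.26, so
tolerances like ±0.3 or ±0.5 per gene are statements about *sampling
noise*, not estimator accuracy. The tests therefore separate regimes:

* calibration (type-I error) runs at the emulated conditions
  (2,000 genes, dispersion 0.1, base mean 500);
* accuracy checks (fold-change recovery within ±0.3–0.5 per gene,
  size-factor recovery within 1%) run at high counts and low dispersion
  (base mean 2,000–5,000, dispersion 0.01–0.02), where residual error is
  dominated by bias rather than noise;
* at generator defaults the end-to-end tests assert what the defaults
  support: every planted member clears the |log2FC| > 2 gate and the
  planted axes are recovered.

## GWAS annotation

Coordinates are 0-based half-open internally (BED convention); GFF3
(1-based inclusive) is converted on load, multiple intervals per gene
collapse to their union, and GWAS positions (1-based) are converted at
the single comparison point: SNP at `pos` hits a span iff
`start − flank ≤ pos − 1 < end + flank`. Risk SNPs are those with
OR > 1 and p < 0.05, strict, as printed conventions state them; the
`flank` default is 0 bp (strict transcriptional region) because promoter
or UTR extension conventions vary — the knob is explicit. Odds ratios are
taken as printed; allele harmonization, LD clumping and liftover are out
of scope. Mapping uses an interval tree and is tested for exact equality
against an all-pairs oracle, including the off-by-one boundaries.

## Axis scoring

Published axis selection in this area is narrative (direction
consistency, correlation, GWAS support, expression level), not a formula.
The ranking implemented here is an explicit, package-defined heuristic:

```
score = w1 · mean(min(|log2fc|, cap) over the three members)
      + w2 · (lnc_support + m_support)
      + w3 · (n_risk_snps_lnc + n_risk_snps_m)
      + w4 · mean(|rho| over computed edge correlations)
```

with defaults w = (1, 1, 1, 1) and cap = 10 (the cap keeps
near-zero-control genes with huge fold changes from dominating). The
score is monotone in every evidence term; ties break lexicographically on
(lncRNA, miRNA, mRNA) for reproducible output. Weights are configuration,
not science — the default treats each evidence channel as roughly
comparable in magnitude on the synthetic data and makes no claim beyond
that.

## Synthetic-data generator

`SimConfig` defaults describe the emulated study: 30 lncRNAs, 12 miRNAs,
40 mRNAs; 5 planted axes and 5 direction-concordant decoys; background
bipartite edges at density 0.05 spread over three pseudo-source databases
(~30% of background edges duplicated into a second source, giving a known
support ≥ 2 subset); 6 case and 6 control samples; NB counts with base
mean 500 and dispersion 0.1; planted |log2FC| = 4 (comfortably past the
gate of 2, estimable at this sample size); per-sample scale factors
log-uniform in [0.5, 2]; one pseudo-chromosome with non-overlapping
2 kb gene spans; 1–4 planted risk SNPs (OR in (1.05, 1.3), p < 0.05)
inside every planted lncRNA/mRNA span, and noise SNPs that fail the risk
filter scattered everywhere else. All draws flow through one
`numpy.random.default_rng(seed)` generator passed explicitly, so a config
is reproducible to the byte.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: correlated gene–gene expression beyond
the planted effects, LD structure among SNPs, multi-chromosome genomes,
overlapping transcripts, miRNA target-site sequence realism, batch
effects, or library-composition artifacts. Planted-recovery results show
the pipeline's filters are implemented correctly, not that the sponge
signature is detectable in any particular real cohort.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 2,000-gene expression
matrices, networks of tens of nodes, 10–20 seed replicates for
stochastic claims, and 10,000 SNPs × 200 spans for the interval oracle —
sizes at which every oracle comparison is exact and the whole suite runs
in seconds on one CPU while still exercising each code path at realistic
density. Degenerate inputs are defined, not accidental: empty DE overlap
warns and yields an empty network; constant expression vectors drop the
edge with a warning (rho undefined); all-zero genes are dropped before
testing; a group with all-zero totals is an error. Dispersion estimates
floor at 1e-8; SE² floors at 1e-300 to avoid division by zero on
degenerate constructed inputs.

## Known limitations

* The NB test is intentionally simpler than DESeq2; at n = 6 + 6 its
  power and its fold-change noise differ from shrinkage-based estimators.
  The import path exists for exactly this reason.
* Support counts treat databases as independent attestations; they are
  not (several databases aggregate each other).
* The axis score is a transparent heuristic, not a calibrated
  probability; downstream experimental triage should treat it as an
  ordering, not a significance level.
* One gene → one union span; isoform-specific sponge activity is
  invisible at this resolution.
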