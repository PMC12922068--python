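# Methods

## Scope and data model

`retromethyl` implements the integration layer of a retroelement
epigenomics analysis: it consumes per-tool differential-expression (DE)
tables for HERV-K (HML-2) loci and for genes, a differential-methylation
table for CpG probes with an array manifest, gene annotation (GTF) and
locus coordinates (BED or TSV), and paired tumor/normal qPCR Ct tables.
Upstream quantification (read alignment, locus-level counting, DESeq2
model fitting, methylation normalization, subtype classification) is out
of scope; the package treats their outputs as given.

Internal coordinates are 1-based inclusive (the GTF convention); BED
input is converted at the boundary (`start+1`, `end`) and converted back
on write, so round-trips are lossless. Every reader counts rejected
records and preserves input order. Missing p-values are treated as
not-significant in all downstream filters and are never imputed.

## Cross-tool concordance

DE calls are categorized as up (padj < α and log₂FC ≥ t), down
(padj < α and log₂FC ≤ −t), else not significant; the defaults α = 0.05,
t = 1 match the consensus selection rule so the same thresholds govern
both stages. Boundary conventions: the fold-change comparison is
inclusive (≥), the significance comparison strict (<).

Agreement between two tools is measured on the intersection of feature
ids quantified by both (features seen by only one tool are excluded
rather than counted as not-significant, which would inflate agreement):
Pearson's *r* and *R²* on the log₂ fold changes, and the unweighted
Cohen's kappa on the 3×3 confusion matrix,

    kappa = (P0 - Pe) / (1 - Pe),

with P₀ the diagonal mass and Pₑ = Σ_c row_c · col_c. Two identical
constant raters give Pₑ = 1; kappa is then reported as 1 with a
degeneracy flag instead of 0/0.

Two consensus policies are provided, because both appear in practice:

- `all_significant_two_lfc` — padj < α in **all** tools and |log₂FC| ≥ t
  in at least two;
- `anchor_plus_one` — the feature passes both thresholds in a designated
  anchor tool and in at least one other tool.

Direction is the shared sign of log₂FC among the tools counted by the
rule; a sign conflict excludes the feature (conflicts are logged, never
majority-voted).

## Locus–gene association

A locus is *intragenic* to a gene when their intervals share at least one
base, on any strand; the relative strand is recorded as an attribute
because antisense-embedded loci are biologically meaningful. A gene is
*nearby* when it does not overlap and the number of bases strictly
between the two inclusive intervals is at most the window (default
50,000 bp). Distance is therefore `start₂ − end₁ − 1` for ordered
disjoint intervals; directly abutting intervals get distance 0 but are
classified nearby, not intragenic (the only case where a nearby distance
is below 1). Host and nearby link sets are disjoint by construction.
Interval queries use an interval tree per chromosome; correctness is
property-tested against an all-pairs scan. Mixed chromosome naming
("chr1" vs "1") between the two inputs is detected and rejected with a
remediation hint rather than silently returning no links.

## CpG pairing, filtering and coupling

CpGs pair with genes when the probe position falls within the gene body
extended by ±3,000 bp (chosen to capture promoter regions, which lie
within a few kb of the TSS), and with HML-2 loci within ±10,000 bp.
Distance is to the nearest interval boundary (0 inside). The design
variables per pair:

- X1 — differential methylation log₂FC of the CpG;
- X2 — 1 if CpG probe strand equals the partner strand. Array probes are
  not meaningfully stranded for this purpose; X2 uses the manifest's
  strand column when present and defaults the probe to "+" otherwise.
  This is the largest interpretive assumption in the package and is why
  X2 is carried as an explicit, inspectable column in all outputs;
- X3 (gene pairs only) — 1 if the manifest places the CpG in the
  partner's TSS200 promoter zone. The manifest flag is authoritative;
  geometry only gates pairing.

Filtering keeps a pair iff |X1| > 0.1 with methylation significance
< 0.05 **and** the partner's |log₂FC| > 1 with expression significance
< 0.05 — all four comparisons strict. By default both significance
columns are BH-adjusted p-values; `use_adjusted_meth_p` /
`use_adjusted_expr_p` switch either side to raw p-values, since both
conventions appear in published filter descriptions. For locus pairs a
consensus locus set can additionally be required. Filtering is
idempotent and reports kept/dropped counts per reason.

Note the deliberate asymmetry with the DE-call stage: the filter uses
strict `> 1` while consensus categorization uses inclusive `≥ 1`; each
stage keeps its own written convention.

Coupling on the filtered pairs:

- **Spearman correlation** between X1 and Y (partner expression log₂FC),
  midranks for ties, chosen over Pearson because pair sets are small and
  the relationship need not be linear. The two-sided p-value uses the
  t approximation for n > 10 and exact enumeration of all n! pairings for
  n ≤ 10. Counts are reported as (pairs, unique CpGs, unique partners);
  one CpG may contribute one pair per partner.
- **Interaction regressions** by ordinary least squares
  (statsmodels), unweighted, with plain (non-robust) standard errors:

      locus: Y = β₀ + β₁X1 + β₂X2 + β₃X1·X2 + ε,    n ≥ 5
      gene:  Y = β₀ + β₁X1 + β₂X2 + β₃X3 + β₄X1·X2 + β₅X1·X3 + ε,  n ≥ 7

  ε is assumed independent Normal with zero mean. Before fitting, every
  non-intercept design column is checked for zero variance and the full
  matrix for rank deficiency; failures return `applicable = False` with a
  reason instead of coefficients. This reproduces the situation where all
  filtered pairs lie on the same strand, or no CpG is promoter-located —
  then the strand or promoter effect is simply not estimable from the
  data. The gene model also reports whether the promoter interaction
  flips the methylation slope (sign of β₁ vs β₁ + β₅). Regression
  p-values are two-sided.

### Promoter β aggregation

For gene-level methylation matrices, β-values (methylated / total signal,
in [0,1]) of TSS200 CpGs are aggregated per gene by arithmetic mean;
genes without promoter probes are absent from the result, and β-values
outside [0,1] raise an error naming the probe.

## qPCR quantification

ΔCt = Ct(target) − Ct(reference gene), ΔΔCt = ΔCt(tumor) − ΔCt(normal)
per patient, fold change = 2^−ΔΔCt; per-patient log₂FC = −ΔΔCt.
Technical replicates are averaged per (patient, tissue, target, gene)
before the ΔCt step. Cohort summaries report mean ± sample SD (n − 1
denominator) of ΔΔCt, and both the mean of per-patient fold changes and
2^−(mean ΔΔCt): the former is always ≥ the latter (Jensen's inequality
for the convex map 2^−x), and published cohort means may refer to
either, so both are emitted. Primer-efficiency correction (Pfaffl) is
out of scope.

## Synthetic-data generator

The generator produces every input class with machine-readable ground
truth, emulating the structure of a tumor/normal retroelement cohort at
desk scale. What it models:

- **Layout** — genes on a regular grid along one synthetic chromosome
  (default 200 genes, 100 Mb); loci placed strictly inside a partner gene,
  1–40,000 bp from one, or > 50 kb from every gene, per configurable
  fractions (defaults 0.60 / 0.25 / 0.15, reflecting the predominantly
  intragenic distribution of HML-2 copies). Strand concordance with the
  partner follows `same_strand_frac` in expectation.
- **Methylation** — each partner receives one *driver* CpG whose
  differential methylation X1 is drawn from a mixture (65% clear shifts
  beyond the ±0.1 filter threshold, the rest near-zero), plus passenger
  CpGs whose X1 tracks the driver with SD 0.3, emulating probes tiling a
  coherent methylation region. Gene CpGs land in the TSS200 zone with
  probability 0.3. Methylation p-values come from a z-model with scale
  0.04 and are BH-adjusted.
- **Coupling** — the partner's true expression log₂FC is generated from
  the interaction forward model using the driver CpG: locus coefficients
  default to β₁ = −1.5 (inverse coupling at retroelement loci, i.e.
  hypomethylation with overexpression), gene coefficients to β₁ = +1.6
  with β₅ = −3.0 (promoter CpGs reverse the methylation–expression
  relationship); residual SD 0.4.
- **DE tables** — each pseudo-tool observes the true log₂FC plus
  independent Normal(0, `tool_noise_sd` = 0.25) noise; p-values from a
  z-test of the observation against the noise scale, BH-adjusted per
  tool. The expected inter-tool Pearson correlation is
  Var(true)/(Var(true) + σ²) and is recorded in the truth metadata; the
  defaults land in the strong-agreement regime (r ≈ 0.9) reported for
  multi-tool retroelement quantification.
- **qPCR** — per patient, normal-tissue ΔCt around 5 cycles and tumor
  ΔCt offset by ΔΔCt ~ Normal(mean, SD) per target; the default targets
  are env (−0.92 ± 1.16) and gag (−0.52 ± 1.30) over 40 patients, the
  regime of a small clinical validation cohort.

All randomness flows from one integer seed through per-stage
`SeedSequence` children; identical configuration gives byte-identical
output files (fixed float formatting, no timestamps).

What the generator does **not** model — and hence what passing tests do
not demonstrate about real data: linkage between neighbouring loci,
realistic chromosome structure (gene clusters, CpG islands, repeats),
count-level noise (everything is Gaussian on the log scale, matching the
OLS assumptions rather than challenging them), cell-type composition,
batch effects, and the correlation structure of adjusted p-values within
a region. The pair-selection filter truncates small |Y|, so coefficient
estimates from pipeline (post-filter) pairs are biased away from zero
relative to the generator's coefficients; parameter-recovery tests
therefore use unfiltered forward-model pairs.

## Numerical and design choices

- OLS is solved by statsmodels; tests verify equality with the
  normal-equations solution to 1e-10 and exact recovery on noise-free
  data to 1e-8.
- Spearman's exact small-n p-value enumerates pairings in vectorized
  chunks (8! rows at a time), so n = 10 stays tractable.
- Kappa is computed from the confusion matrix directly; the permutation
  null (mean kappa ≈ 0) and an independent library implementation are
  both used as cross-checks in the test suite.
- Venn regions are all 2^k − 1 exclusive intersections; they partition
  the union by construction.
- Pipeline outputs are pure functions of (inputs, config); the run
  metadata sidecar records the package version, seed and a SHA-256 of
  the canonical config, but no timestamps, so reruns are byte-identical.
- The pipeline pairs CpGs with genes that host a consensus locus
  (the analysis targets retroelement-containing genes); pairing against
  an arbitrary gene set is available through the library/`couple` CLI.
- Subtype labels are free-form strings supplied with the inputs; the
  package does not classify samples.

## Known limitations

- X2 (strand dichotomy) inherits the manifest-strand assumption above;
  for unstranded probes it reduces to "partner is on the + strand".
- The `n ≥ 5` / `n ≥ 7` regression minima are hard floors, not power
  guarantees; estimates from a handful of pairs are reported with their
  standard errors and should be read accordingly.
- The exact Spearman p-value treats ties via midranks within the
  permutation distribution, which is standard but not the only
  convention.
- Sensitivity analysis of the regression models (e.g. omitted-variable
  robustness) is not implemented.
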