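# Methods

This note documents the statistical procedure the package implements,
the defaults and numerical choices, what the synthetic cohorts emulate,
and the known limitations.

## Model

The method is a rule-based evidence counter, not a fitted probabilistic
model.  For one cancer type, each gene is tested independently in up to
five data types; each data type contributes a binary *activating* and a
binary *inactivating* flag.  The oncogene score (OG) and tumor
suppressor score (TS) are the counts of activating resp. inactivating
flags; `overall = OG − TS` and `aberration = OG + TS` hold by
construction and are re-asserted after every aggregation.  The implicit
assumptions are: (i) tumor and tissue-matched normal samples are
exchangeable under the null within each gene; (ii) data types are
treated as equally informative, one vote each; (iii) a dosage-style
aberration (copy number, methylation) only matters if it propagates to
expression, hence the mandatory correlation gates.

### Cohort preprocessing

Sample bookkeeping records patient, sample class (primary tumor,
recurrent/metastatic, normal) and cancer type.  Recurrent and
metastatic samples are always removed — the analysis only ever compares
primary tumors to normals — and a patient with two or more primary
samples is removed entirely, normals included, because the pairing
would be ambiguous.  The operation is idempotent and downstream scorers
refuse non-deduplicated maps (a flag on the type enforces this).

### Per-data-type tests

* **Expression**: paired Wilcoxon signed-rank per gene over complete
  tumor–normal pairs (≥ 3 required, otherwise the gene is marked
  unavailable rather than erroring), BH across all tested genes, flag at
  q < 0.05 in the direction of the mean paired difference.
* **Copy number**: the same paired test on gene-level log-ratios.  SEG
  input is collapsed to genes by overlap-length-weighted means of
  segment values (coordinates 1-based inclusive externally, converted
  to 0-based half-open internally).  Two further gates: the absolute
  mean paired difference must strictly exceed 0.1 (protects against
  trivially small effects turning significant in large cohorts), and
  the Spearman correlation between copy number and expression across
  *all* tumor samples carrying both measurements must be significantly
  positive (BH at 0.05 across the genes that passed the first stage —
  conditional testing, mirroring the sequential phrasing of the rule).
  A gene without expression data can never receive a CN flag: the
  correlation requirement is mandatory, not optional.
* **Methylation**: probe-wise unpaired rank-sum tests (tumor vs normal
  beta values, ≥ 3 per group), BH across probes, eligibility at
  q < 0.05 and |mean Δβ| strictly > 0.1.  For eligible probes, Spearman
  probe-beta vs expression of each annotated gene across tumors, BH
  across those probe–gene links, significance at q < 0.05.  Gene-body
  probes and all other probe contexts behave oppositely (body
  hypermethylation with positive expression correlation is
  oncogene-like; promoter-style hypermethylation with negative
  correlation is suppressor-like), and one gene can collect both flags
  through different probes.  Illumina region labels are collapsed to
  the binary body/other vocabulary at read time; a probe annotated to
  several genes is evaluated once per (probe, gene, region) link.
* **Mutations**: the 20/20 rule.  Oncogene-class = missense + in-frame
  indels; suppressor-class = frameshift indels, nonsense, splice site;
  everything else (e.g. silent) stays in the total-count denominator
  only.  Distinct identity is the genomic change
  (chrom, pos, ref, alt, class) — protein-level annotation is not
  consumed.  OGMR = 1 − distinct-OG/total, TSMR = distinct-TS/total;
  thresholds OGMR > 0.2 & TSMR < 0.05 (activating), TSMR > 0.2 or
  (OGMR > 0.2 & TSMR > 0.05) (inactivating), all strict, plus at least
  five mutations of the corresponding class (class records, not
  distinct sites).  Strictness makes the two flags provably exclusive.
  Note OGMR = 1 when a gene has no oncogene-class mutations at all —
  a direct consequence of the formula; the five-mutation gate prevents
  the resulting spurious calls.
* **shRNA**: only genes with a single consolidated "gene solution" are
  used.  Quartiles are computed per gene across all screened cell
  lines (linear-interpolation quantiles); a cancer type's flag needs at
  least 25 % (inclusive) of its lines strictly beyond the respective
  global quartile.  "At least" vs "beyond" resolves every boundary case
  deterministically: exactly 25 % of lines strictly below Q1 triggers,
  a line exactly at the quartile never counts.

### Aggregation

Unavailable data types contribute nothing and decrement the per-gene
availability mask, so OG and TS can never exceed the number of data
types actually measured.  Rankings sort by one of the four scores with
alphabetical tie-breaking for run-to-run determinism.  Dual-role genes
are those with OG ≥ 2 in one cancer type and TS ≥ 2 in a *different*
one.  Pathway scores average `overall` over the member genes present in
the scored universe; unmeasured members are excluded (and counted),
not imputed as zero — measured-but-unaberrated genes already contribute
their 0.  Affected-sample fractions use tumor−matched-normal
differences (paired) or tumor minus the normal mean (unpaired); a
sample is affected when its difference lies strictly more than one
sample standard deviation (n−1 denominator) from the difference mean.

## Rank statistics

The test layer is self-contained so that every decision threshold is
reproducible to machine precision:

* Signed-rank: zero differences are dropped before ranking (the
  classical convention); mid-ranks for ties.  The null distribution is
  computed **exactly by convolution over doubled mid-ranks** for up to
  25 non-zero pairs — doubling makes tied mid-ranks integral, so ties
  cost nothing.  Beyond 25, a tie-corrected normal approximation with
  continuity correction is used, matching the defaults of the usual R
  implementation.  The two paths agree within 0.02 at the crossover
  (property-tested on 1 000 random instances).
* Rank-sum: exact by fixed-subset-size convolution for pooled n ≤ 12,
  the same tie-corrected, continuity-corrected normal approximation
  above.
* Two-sided p-values are twice the smaller tail, capped at 1.
* BH adjustment implements the step-up formula directly
  (q(i) = min over j ≥ i of p(j)·m/j on the sorted values, capped at
  1); missing p-values pass through without counting towards m.
* Spearman: Pearson correlation of mid-ranks; exact permutation p for
  n ≤ 8, t-approximation above.  A constant vector makes the
  correlation undefined; the result is flagged degenerate and treated
  downstream as "no significant correlation".
* Quantiles: linear interpolation on the sorted vector (position
  1 + q·(n−1)), i.e. the common type-7 rule.

Numerical tie-breaking: the strict 0.1 effect gates compare the mean
difference after rounding at 1e-12, so an effect that equals the gate
up to floating-point noise does not pass.  This is far below the
resolution of any real measurement and makes the boundary behaviour
exact and testable.

## Synthetic cohorts

`simulate.generate_cohort` emulates the statistical structure each
scorer assumes, not the genome.  Defaults: 1 000 genes, 50 tumor/normal
pairs, 20 planted oncogenes and 20 tumor suppressors with large effects
in four data types (expression, copy number, methylation, mutations);
an shRNA screen over 100 cell lines (20 of the target type) is
generated when requested.  Planted effect sizes — a 2-noise-SD
expression shift, a 0.4 log-ratio copy-number shift against 0.05 noise,
a 0.25 beta shift on the gene-body probe, eight recurrent missense or
six distinct truncating mutations, a 3-SD viability displacement — put
drivers far from every threshold while the nulls (exchangeable Gaussian
noise; logit-style clipped noise for betas; sparse Poisson background
mutations at distinct sites) calibrate the false-positive side.  A
shared per-sample dosage latent couples copy number and methylation to
expression in planted genes, which is what the correlation gates
require.  One `numpy` generator seeded by a single integer drives
everything; identical seeds give byte-identical output bundles.

What the simulator does **not** emulate: genomic coordinates and
arm-level copy-number linkage between neighbouring genes, batch
effects, subclonality, count-based expression noise, probe
cross-reactivity.  Passing the recovery tests therefore demonstrates
that the decision rules are implemented correctly and have the intended
operating point — not that the method's error rates transfer to real
cohorts with correlated genes and batch structure.

`simulate.boundary_fixture` provides the deterministic threshold
probes: sweep grids for the mutation-rate cut-offs (OGMR/TSMR on
0.05/0.025 grids), the five-mutation minimum, the copy-number and
methylation shift gates ({0.05, 0.10, 0.15} with a symmetric,
exactly-zero-mean jitter so the mean shift is the nominal value), the
screen's displaced-line sweeps (exact integer partitions of 1..100 so
the global quartiles are always 25.75 and 75.25), the 1-SD
affected-sample rule and the one-data-type unit-score cohort.

## Problem sizes and determinism

The shipped tests run the full pipeline on cohorts of 150–1 000 genes
and 20–50 pairs, the planted-recovery check on the default
1 000 × 50 spec, and the null calibration across 20 seeds; the whole
suite completes in about a minute on a single core.  All scoring is
deterministic given the inputs; the only randomness anywhere is the
simulator's seed.

## Limitations

* Equal weighting of data types is a modelling choice, not an inference;
  a data type with systematically noisier inputs dilutes the scores.
* The correlation gates use all tumor samples with both measurements,
  which assumes expression and the gated data type were profiled on
  largely overlapping samples.
* Mutation recurrence is summarised purely through distinct-site
  counts; no positional clustering statistic is computed.
* Matrices are assumed pre-normalised and batch-corrected; the package
  performs no cross-platform harmonisation.
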