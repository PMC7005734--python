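# Methods

This note documents the models, conventions and design choices behind
`oncopanel`, in the spirit of a statistical-software methods appendix.
Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Variant representation and left-normalization

A variant is identified by its left-normalized `(chrom, pos, ref, alt)`
with 1-based positions and VCF-style anchor bases for indels.
Normalization follows the standard parsimony/left-shift algorithm:
shared trailing bases are trimmed, the allele pair is extended leftward
from the reference context whenever an allele empties, and shared
leading bases are trimmed last. The procedure is idempotent and maps
every spelling of one edit (in particular, any placement of an indel
inside a repeat run) to a single canonical form; this is verified
exhaustively in the tests by grouping candidate spellings by the edited
haplotype they produce. Two boundary conventions matter:

- an indel whose leftmost equivalent position is the first base of the
  available context window keeps its anchor there (the right-anchored
  edge form, as VCF prescribes at position 1 of a contig);
- a `ref` allele that disagrees with the reference context is an error,
  not a silent pass-through.

## The caller

The caller operates on per-site allele counts (pileups), not reads.
Each non-reference allele with at least one read becomes a candidate
call and receives exactly one filter status, checked in the order
LOW_DEPTH → LOW_MAF → LOW_ALT_READS → PASS. Defaults:

| parameter | default | rationale |
|---|---|---|
| `maf_threshold` | 0.05 | the assay's published cut-off for SNVs and indels |
| `min_depth` | 20 | below ~20× a 5% variant is expected at ≤1 read; sites are uncallable |
| `min_alt_reads` | 4 | an absolute floor that dominates the MAF rule at the low end of the titration grid (4 reads at 50× is 8%) and suppresses error-driven false positives |

Only the 5% MAF rule is inherited from the validated assay; the depth
and alt-read floors are this package's own defaults, both exposed in
`CallerConfig`. Multi-allelic sites emit one call per allele; there is
no joint genotyping, strand-bias testing or quality recalibration.

A consequence of a hard MAF cut-off worth stating explicitly: for a
variant whose true allele fraction sits *below* the threshold, raising
depth makes detection *less* likely (the observed MAF concentrates
around its sub-threshold expectation), and a variant *at* the threshold
is detected with probability ≈ 1/2 at any depth. Monotone
depth–sensitivity claims therefore apply to the strata at or above the
cut-off, and the test suite checks them there.

## Synthetic data

### Reference standards and pileups

Truth sets emulate engineered multiplex standards: variants with exact
expected allele fractions in (0, 1]. Mixing two standards k:1−k
produces the exact weighted average of each variant's fractions (0 when
absent), mirroring how laboratories dilute standards to extend the MAF
range.

Pileup simulation, per panel site:

- depth ~ NegativeBinomial(mean = target median, shape = 20). Amplicon
  coverage is overdispersed relative to Poisson; shape 20 gives a
  coefficient of variation ≈ 0.23, a typical mid-range value. The
  distribution's median tracks its mean closely at these depths.
- mutant reads ~ Binomial(depth, expected MAF) for each truth variant at
  the site;
- substitution noise: each remaining non-reference base receives
  Binomial(remaining reads, error_rate/3); default error_rate 0.1%,
  roughly a post-filter FFPE amplicon error floor;
- insertion noise at one-tenth the substitution rate (indel errors are
  rarer after primer/adapter trimming); the model is deliberately the
  simplest one able to generate false positives.

Allele counts always sum to depth. Per-site random streams derive from
`(seed, site index)`, and per-(depth, replicate) titration streams from
`(seed, depth, replicate)`, so any single cell of a study is
reproducible in isolation.

What this generator does *not* model: read-level artifacts (strand
bias, position-in-read effects), PCR duplicates, FFPE deamination
spectra (C>T concentration), alignment error around long indels, or
tumor purity. Passing validation on this generator therefore
demonstrates that the statistical machinery — thresholding, titration,
scoring — behaves correctly, not that any specific wet-lab assay meets
its specification.

### The validation study

`make_validation_study` packages the standard desk-scale conditions: 40
SNVs with expected MAFs drawn from {10, 12.5, 15, 20, 25, 35}% placed on
a 48-site panel (8 wild-type sites exercise specificity), sequenced to
1200× median with the 0.1% error floor. 1200× keeps the overdispersed
achieved median safely above the 1000× top of the titration grid, which
matches practice (real validation libraries land at 1025–1469×; one
cannot titrate to a depth one did not sequence).

### Cohorts

Per patient, each characteristic level is drawn from a configurable
distribution (defaults reproduce a retrospective NSCLC FFPE archive,
including its heavy missingness: e.g. smoking status known for only
~23% of patients), with NA handled as a separate outcome. Each gene's
mutation indicator follows a logistic model: baseline odds × the product
of odds multipliers matching the patient's non-missing covariate levels.
Because multipliers move most patients off the intercept, baseline
intercepts are calibrated by bisection so each gene's *marginal*
per-patient rate equals its target (EGFR 42%, TP53 30%, KRAS 5.5%, ...).
A mutated gene carries 1 + Poisson(0.2) variants — reproducing the
observed multi-hit pattern in which ~210 EGFR variants arise from ~175
carriers — with protein positions drawn from per-gene hotspot weights
(EGFR L858/E746/T790, TP53 R273/G266/R213/R175/R280, KRAS G12, ...),
consequence classes from per-gene mixes (TP53 ~74% missense; PTEN
in-frame-insertion-dominated), and cohort allele fractions uniform on
[5%, 60%].

The generator programs only marginal gene rates and gene × covariate
effects; gene–gene dependence is not modeled directly, but induced
correlations arise through shared covariates (e.g. EGFR and TP53 load on
subtype and gender with opposite signs, which is sufficient for their
mutual exclusivity to surface in the pairwise tests at n = 422).

## Titration accounting

Cells are keyed by (target depth, MAF stratum) with half-open strata
[0, 5%), [5%, 10%), [10%, 100%]. Sensitivity pools (variant ×
replicate) trials rather than averaging per-site rates — matching the
"detected trials / sampling trials" definition — and a per-site average
is recoverable from the per-cell counts. True positives are binned by
the truth variant's *expected* MAF; false positives carry no expected
value and are binned by *observed* MAF, so each called variant is
counted exactly once. PPV cells with TP + FP = 0 are reported as
undefined (`None`), never 0 or 1. Downsampling thins every allele count
binomially with retention = target/current median: at pileup
granularity this is the exact marginal of subsampling read records, is
expectation-preserving for allele fractions, and is seedable.

## Exact tests

`fisher_2x2` delegates to `scipy.stats.fisher_exact` (two-sided), whose
minimum-likelihood rule matches R's `fisher.test`; the test suite
verifies it against exhaustive integer-arithmetic enumeration on every
2×2 table with total ≤ 40. A table with a zero margin carries no
information about association and returns p = 1 with a warning.

`fisher_rx2` (Freeman–Halton) is implemented by direct enumeration:
all r×2 tables with the observed margins are generated, their
multivariate hypergeometric probabilities computed in log space, and
those not exceeding the observed table's probability × (1 + 1e-7) are
summed. SciPy's r×c `fisher_exact` is permutation-based and resolves
only ~4 decimal digits, which is insufficient to reproduce published
small p-values; the enumeration agrees with R's exact implementation to
5+ significant digits on reference tables. An enumeration-size bound
(default 5×10⁶ tables) guards against infeasible inputs.

Pairwise comparisons for r > 2 use 2×2 Fisher tests on row pairs with a
Bonferroni multiplier of C(r, 2), capped at 1. Significance stars use
≤ comparisons at 0.05/0.01/0.001. For histologic subtype, association
tests contrast the two major groups (adenocarcinoma vs squamous);
rare mixed/large-cell categories are excluded as untestably small.
Samples missing a characteristic are excluded listwise for that
characteristic only.

Mutual-exclusivity testing reports unadjusted p-values by default (the
convention of pairwise co-occurrence displays, e.g. maftools), with
optional Bonferroni or Benjamini–Hochberg switches. Odds ratios use
exact conventions for zero cells — 0 or ∞, NaN when both numerator and
denominator vanish — with no continuity correction; direction labels
(mutually exclusive for OR < 1, co-occurring for OR > 1) are assigned
only at p ≤ α.

## Reproducibility metric

The headline statistic is detection-based: detected (expected variant,
replicate) events divided by |expected| × replicates, so 24 detections
of 5 variants over 5 replicates gives 96%. The inter-/intra-run split
is this package's own definition (the detection formula does not induce
one): mean pairwise agreement — the fraction of expected variants on
which two replicates agree (both detect or both miss) — over replicate
pairs from different runs and from the same run respectively.

## Numerical and scale choices

- Exact-test enumerations use log-gamma arithmetic (r×2) or exact
  integers (test oracles); no Monte-Carlo approximation is enabled by
  default.
- Protein positions parse as the first integer in an HGVS-like `p.`
  string; range events (`p.E746_A751del`) attribute to the start
  residue; unparseable strings are excluded from hotspot tallies, whose
  fraction denominator is the positioned-variant count unless an
  explicit denominator is supplied (published percentages sometimes use
  a different base).
- Consequence-class ties in the modal-class summary break
  lexicographically, deterministically.
- Test and acceptance problem sizes — a 48-site panel, 40 truth SNVs,
  130 titration replicates, cohorts of 300–20 000 — were chosen so the
  statistical assertions have comfortable power (binomial SEs of 1–4
  percentage points per cell) while the whole suite stays interactive;
  the statistics are invariant to panel scale because every metric is a
  ratio over trials or calls.
- Statistical acceptance bands were fixed from first principles before
  measurement: ±3 standard errors for parameter-recovery checks, and
  for the type-I calibration of the discrete exact tests an upper bound
  of α + 3 Monte-Carlo SEs with a loose 1% floor (exact tests are
  conservative, so a symmetric band around α would be wrong).

## Known limitations

- The pileup generator's independence assumptions (site-independent
  depths, binomial mutant reads) understate the correlated failure
  modes of real FFPE libraries; sensitivity/PPV estimates here are
  upper bounds on what a wet-lab validation would show.
- The Freeman–Halton enumeration is exponential in the number of rows;
  it is intended for the r ≤ 4, n ≤ a-few-hundred tables of clinical
  association reports.
- The cohort generator draws genes independently given covariates;
  explicit gene–gene interaction effects are out of scope.
- No BAM/FASTQ ingestion: the pileup TSV is the ingestion boundary by
  design, keeping the package free of alignment dependencies.
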