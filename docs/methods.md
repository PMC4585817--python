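# Methods

## Differential expression and cross-study intersection

Each expression study is a probeset × sample matrix of normalized log2
intensities with case/control labels, gender, brain compartment and an
optional disease-severity score per sample.  The default per-probeset
statistic is the Welch t-test (unequal variances, Welch–Satterthwaite df);
an optional variance-moderated mode shrinks per-probeset pooled variances
toward a common prior whose scale and degrees of freedom are estimated by
method of moments on the log-variances (the trigamma equation is inverted
by Newton iteration).  The moderated mode matters at very small group sizes,
where single-probeset variance estimates are unstable; with the default
10+10 groups the two modes agree closely.  Probesets with zero variance in
both groups get p = 1 by convention.  P-values are BH-adjusted over all
tested probesets and called significant below FDR 0.05.

Per-study QC follows two rules applied per brain compartment: a compartment
is discarded if array control probesets (the `AFFX-` prefix on Affymetrix
chips) make up strictly more than 0.25 % of its significant results or
appear among its ten smallest raw p-values; among surviving compartments the
one with the most significant probesets is analyzed (ties broken by
lexicographically smallest label, for determinism).  Where detection calls
exist (A=0, M=1, P=2), a significant probeset is kept only if the mean call
in the group with the *higher* mean expression is at least marginal (mean ≥
1, inclusive) — a downregulated transcript must at least be reliably
detected in controls.

Severity-based contrasts (e.g. neurofibrillary-tangle burden) are built as
extreme groups: the n highest-scoring samples versus the n lowest, ties at
either boundary broken by sample id ascending, intermediate samples
excluded.

Probesets map many-to-one to gene symbols; a gene enters a direction's set
when *any* of its probesets is significant in that direction (genes hit in
both directions are kept in both sets and logged).  The per-study down-sets
are intersected across discovery studies; the intersection is then confirmed
as its overlap with the held-out study's down-set.  Gender balance of each
cohort is checked with a two-sided Fisher exact test on the (case/control) ×
(M/F) table; a zero margin returns p = 1 by convention.

## Compendium scan

For a gene with k probesets in a dataset of N probesets, each sample is
scored with a one-sided two-sample rank-sum test of the gene's k values
against the remaining N − k values of the same sample.  A one-sample
signed-rank variant (gene values against the sample median) is available
behind a flag for audits, but is uninformative at small k: its one-sided p
cannot fall below 2⁻ᵏ, so k ≤ 4 probesets can never clear α = 0.05.  The
rank-sum p is computed from the exact null distribution whenever the pooled
values are tie-free and enumeration is cheap (k ≤ 2 at any N ≤ 1000, or any
k at N ≤ 50); otherwise the tie-corrected normal approximation with
continuity correction is used.  The approximation truncates the extreme
tail — for k = 3 its smallest attainable p is ≈ 1.4×10⁻³ regardless of N —
which is conservative and documented as a deviation risk; the BH step-up
still flags a block of m strongly enriched samples whenever
1.4×10⁻³ ≤ α·m/N.

BH is applied *within* each dataset (enrichment counts are per-dataset
quantities), and samples below adjusted 0.05 form the enriched set.
Attribute enrichment among the m enriched samples uses the inclusive upper
tail P(X ≥ k) of the hypergeometric (N, K, m).  The calculation is skipped
when m < 15: with so few flags the attribute split carries little evidence.
The threshold is the fixed count 15 (configurable), not a fraction of the
dataset.

## Stratified gene-windowed association

Subjects carry case/control status, gender and APOE4 carrier status (an
input label, not inferred from genotypes).  The nine canonical strata are
{M, F, any} × {carrier, non-carrier, any}.  For each candidate gene the SNPs
with start − D ≤ pos ≤ end + D (1-based inclusive; BED input converted from
0-based half-open on read) are tested with the allelic 1-df Pearson
chi-square on the 2×2 table of alt/ref allele counts in cases versus
controls, without continuity correction; missing genotypes drop the subject
from that SNP's counts only; monomorphic SNPs get p = 1 and an undefined
odds ratio.  The odds ratio adds a 0.5 pseudocount to every cell when any
cell is zero.  A Fisher-exact mode exists; the chi-square p agrees with it
within 0.01 in the decision-relevant tail (p < 0.05 with all cells ≥ 20),
while mid-range p-values can differ by several percent due to the exact
test's discreteness.

Raw p-values are compared to the targeted threshold (5×10⁻⁴ with D = 200 kb;
1×10⁻² with D = 1 Mb) with no multiple-testing correction — the restriction
to candidate windows is the false-positive control; a BH-within-window mode
exists for sensitivity analysis.  A gene–stratum pair is flagged when at
least `min_studies` (default 2) cohorts hold a below-threshold SNP in the
window; strata left untested in a cohort (empty stratum, no windowed SNPs)
count as not significant there.

Genotype propensity for class i ∈ {0,1,2} alt-allele copies is
log₂[(CASEᵢ/CASE)/(CONTROLᵢ/CONTROL)].  Classes absent from both groups are
reported missing rather than ±∞; when any class count is zero the 0.5
pseudocount is added to all six class counts and the totals recomputed, so
the statistic stays antisymmetric under case/control swap.  A linear-ratio
output is available behind a flag.

## Compound search

Treatment profiles are taken as already vehicle-normalized vectors; the test
is the same rank statistic as the compendium scan (single shared
implementation), one-sided for elevation.  BH is applied jointly across all
loaded profiles regardless of build — the search pools builds into one
screen.  Significant profiles are collapsed by compound name to the best
(minimum) raw p, its adjusted p, and the supporting-profile count; the
collapse is idempotent and order-invariant.

## Tissue display

Per-gene tissue profiles are scaled as (x − median)/MAD with no consistency
constant (display scaling, not variance estimation); constant rows map to
zeros, and an alternative mean-absolute-deviation divisor sits behind a
flag.  Genes are clustered on 1 − Pearson r with average linkage (the
linkage method is a documented choice; nothing downstream depends on it),
on the scaled values, after dropping zero-variance rows; rows are
label-sorted before linkage so the dendrogram is deterministic under input
permutation.  Brain specificity is the mean scaled value over brain tissues
minus the mean over the rest.

## Synthetic data

The generator produces every input from one seed through independent
per-stream generators, so identical configurations are byte-identical on
disk.  Defaults are the package's study conditions:

* **Expression** — five studies, two compartments each, 10 cases + 10
  controls per compartment, 2000 probesets (≈ 2 per gene, ~1 % `AFFX-`
  controls), per-probeset baselines U(4, 12) log2 units, Gaussian residual
  noise of 0.5 log2 units, and a 24-gene signature shifted down by 2 log2
  units in cases in every compartment.  Planted genes draw baselines from
  U(8, 12) so detection calls in controls are present.  Detection calls are
  thresholded from intensity (< 5 absent, < 6.5 marginal, else present) —
  the filter's semantics without probe-level modeling.  Severity scores are
  drawn higher in cases so extreme-group contrasts are exercisable.
* **Compendium** — one dataset of 173 samples (91 male, mirroring a
  well-balanced healthy-brain collection), 1000 probesets, N(8, 1) values;
  the biased gene's three probesets gain +3 sd in a random 42 % of male
  samples.  Partial penetrance is what produces a male-dominated but
  incomplete enriched set, the regime the attribute test is designed for.
* **Genotypes** — three cohorts on one 50-Mb chromosome, candidate genes
  laid out every 2 Mb, 120 SNPs per cohort with MAF ~ U(0.05, 0.5) under
  Hardy–Weinberg and no LD (the replication criterion only needs "a
  significant SNP in the window").  The planted SNP (MAF 0.3, a common
  tag-SNP frequency) sits mid-gene and multiplies disease odds by 3 per alt
  allele only in APOE4+ females.  Cohorts are collected retrospectively, as
  case/control cohorts are in practice: a source population with logistic
  disease risk at prevalence 0.1 (intercept tuned by bisection) is sampled
  for exactly 300 cases and 300 controls.  Retrospective sampling keeps the
  allelic odds ratio at its planted value (prospective sampling at high case
  fractions attenuates it) and enriches the risk subset among cases.  The
  APOE4 carrier frequency of 0.45 matches typical AD case/control cohort
  composition; gender is balanced.
* **Compounds** — 60 profiles of 1000 standard-Gaussian log-ratios; each of
  two planted compounds appears once per cell line (two lines) with the
  target gene's three probesets shifted up 4 sd; remaining profiles carry
  arbitrary compound labels across two builds.
* **Tissue** — 24 signature genes + 12 housekeeping genes over 6 brain and
  18 non-brain tissues, signature genes +3 units in brain.

What the generator does **not** emulate: linkage disequilibrium, population
structure and relatedness, batch and platform effects, probe-level intensity
models, correlated genes, dosage/vehicle structure in treatment profiles.
Passing tests therefore demonstrate that the pipeline's statistics and
decision rules behave as designed under the assumed sampling models — not
that the pipeline is robust to the artifacts of real cohorts.

## Calibration and test problem sizes

The suite checks, alongside unit-level oracles: null calibration (no
planted effects) of each screening arm — the DE arm's gene-level
false-discovery proportion averaged over 100 seeds stays at the nominal
0.05 (the assertion allows two binomial standard errors around the level,
since under the global null the seed-average estimates a probability whose
expectation equals α); the null genotype trio replicates in ≤ 5 % of 100
seeds; the null compendium flags ≤ 5 % of samples on average — and planted
recovery: ≥ 90 % of signature genes with zero false genes, target-stratum
replication in ≥ 80 % of 50 seeds with no male-stratum flags, and planted
compounds outranking all null compounds in ≥ 90 % of 50 seeds.  Simulation
sizes in these checks (single-study 1000-probeset collections for the DE
null; 60-SNP panels for the genotype null) are scaled-down versions of the
default conditions chosen to keep the suite quick; effect sizes, thresholds
and cohort sizes are the defaults above.

## Known limitations

* The rank-sum normal approximation's truncated extreme tail (above) makes
  single-profile p-values at large N coarser than exact enumeration would
  give; rankings and block-rejections are unaffected.
* The allelic test assumes Hardy–Weinberg within groups (alleles counted
  independently); cohorts with strong inbreeding or genotyping artifacts
  would need a genotype-level test.
* The moderated-variance mode assumes exchangeable variances across
  probesets within a study; strongly heteroscedastic platforms violate the
  prior.
* Replication counts windows, not specific variants: two cohorts can be
  "replicated" by different SNPs in the same window.  This matches the
  criterion's definition, but is weaker than variant-level replication.
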