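# Methods

`noarvas` implements the desk analysis of a whole-exome rare-variant
association study (RVAS) of non-obstructive azoospermia (NOA), combined with
parent–proband trio linkage. This note describes the statistical model, the
numerical choices, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Variant-level screens

**Loss-of-function (LOF) classification.** A variant is a putative LOF if
its annotated consequence is frameshift, nonsense (premature stop), loss of
the initiation codon, or loss of the stop codon; splice acceptor/donor
variants qualify only when the intronic offset parsed from the coding HGVS
string has magnitude ≤ 2 bp (the canonical splice dinucleotide). A splice
variant whose HGVS cannot be parsed raises an error rather than silently
classifying as non-LOF: a silent false negative would bias the burden test
toward the null. In-frame indels, missense, synonymous and stop-retained
changes are never LOF.

**Rare-frequency filter.** A variant passes if its reference-catalog allele
frequency is below the threshold (default 1%) *or* it is absent from the
catalogs. Uncatalogued status is stored as a missing value, not zero — it is
a distinct pass condition, and conflating it with 0 would silently change
the meaning of a threshold of 0.

**Exact Hardy–Weinberg screen.** Sites whose genotype counts deviate from
Hardy–Weinberg equilibrium (HWE) at p < α (default 0.05) are removed as
likely genotyping artifacts. The p-value is the exact conditional test: the
full enumeration, given the allele counts, of all heterozygote counts of the
same parity, summing the probabilities of configurations no more probable
than the observed one. No mid-p adjustment is applied, and the test is
symmetric under allele relabeling. The screen is computed on all sequenced
samples jointly — an artifact screen should see every genotype the caller
produced — and skips sex-chromosome sites, where the all-male cohort is
hemizygous and the heterozygote class does not exist.

Discreteness matters here: at the rare allele frequencies this pipeline
retains (≤ 10 minor-allele copies in ~500 samples) the conditional
distribution has only a handful of support points and the exact test is
strongly conservative — its rejection rate at α = 0.05 is far below 5%. The
suite therefore verifies the α-calibration at a common minor-allele
frequency (MAF 0.2, where the null is nearly continuous and the rejection
rate approaches α from below) and verifies conservatism separately on
rare-variant data. On a realistic synthetic cohort the screen removes few or
no sites; it earns its keep on real callsets where alignment artifacts
produce gross heterozygote excess.

## Gene-burden association

For each gene with at least one retained rare LOF, samples are collapsed to
carrier status (any nonzero dosage at any retained variant; a sample hit
twice counts once), giving a carrier 2×2 table, and the variant-level dosage
matrix `G` (n × m) enters a variance-component score statistic

    Q = Σ_j w_j² (g_jᵀ r)²,    r = y − μ̂,

with `y` the case indicator, `μ̂` the null case fraction, and per-variant
weights `w_j`. Weights default to the Beta(1, 25) density at the in-cohort
MAF (the customary rare-variant kernel, upweighting the rarest variants);
flat weights are available.

**Null distribution.** The reference null is the permutation distribution of
Q over case-label reassignments — the conditional distribution given the
genotype matrix and the case count, which is also the score test's exact
small-sample null. Because the variants are rare, Q depends on the labels
only through how many carriers of each *distinct genotype pattern* fall in
the case group, and those counts follow a multivariate hypergeometric law
over a small set of carrier classes. The default method therefore
**enumerates the permutation null exactly** (including the tie atom at the
observed value) whenever the number of carrier-class assignments is below a
cap (4 × 10⁵; a gene with ~18 distinct carriers or fewer per class
combination). This is exact conditional inference, deterministic, and for
typical rare-LOF genes costs well under a millisecond.

For dense genes the p-value falls back to a mixture-of-χ²₁ approximation
with mixing weights the eigenvalues of `σ̂² · W Gcᵀ Gc W` (`Gc`
column-centered, `σ̂² = Σr²/(n−1)`), affinely rescaled so the mixture's mean
and variance equal the *exact* permutation moments of Q. The exact moments
are computed by Möbius inversion over the set-partition lattice of the
quadratic form's index slots, with free contractions evaluated in the
low-rank factor `G·diag(w)`; the implementation is verified against complete
subset enumeration in the tests. Tail probabilities come from Imhof's
numerically integrated inversion formula. The classical large-sample
approximations are retained as explicit options (`method="liu"` for
Liu-type moment matching, `method="imhof"` for the unadjusted inversion);
measured against permutation sampling they can be off by 0.01–0.05 in
absolute terms for lattice-like rare-variant statistics at these sample
sizes, which is why neither is the default.

Known property of the exact default: like every exact conditional test on
discrete data it is conservative, so the empirical type-I error at α = 0.05
on null cohorts sits near the bottom of the nominal range (measured ≈ 0.032
over 10⁴ null gene tests) rather than at 0.05.

**Companion statistics.** Each gene also reports a two-sided Fisher exact
p-value on the carrier 2×2 table (a simple burden alternative), and the
carrier odds ratio with a Wald 95% CI, `exp(ln OR ± 1.96·SE)`,
`SE = √(1/a + 1/b + 1/c + 1/d)`. When any cell is zero the OR is reported as
**not estimable** — no continuity correction is applied, because for rare
LOFs the zero cell (usually zero control carriers) is the scientifically
meaningful outcome, and any corrected number would be an artifact of the
correction constant. Gene p-values are adjusted by Benjamini–Hochberg
step-up FDR across the reported genes. Genes with no normalized testis
expression (NE) record are excluded from association reporting. Q–Q data
pair the sorted observed −log₁₀ p-values with expected quantiles
−log₁₀(i/(n+1)).

## Trio linkage

Inheritance of each proband variant is classified from allele presence in
the parents: mother only → maternal, father only → paternal, both →
biparental, neither → de novo; a missing parental genotype → unresolved. A
Mendelian-impossible configuration (homozygous-alt proband with a hom-ref
parent) is flagged unresolved with a warning, never silently classified. On
the male X a hemizygous allele cannot come from the father: mother-negative
means de novo.

The linkage filter retains a call iff it is LOF, maternal or de novo (NOA is
gender-limited — the proband's father was fertile, so paternal transmission
cannot explain the phenotype), and the *exact variant* (chrom, pos, ref,
alt) is absent from all sequenced controls. Control absence is evaluated at
the variant level, not the gene level, because the rule concerns the allele
itself. Retained calls are joined to their gene's burden statistics,
expression, and a network-linkage flag; missing statistics stay missing
rather than being coerced to zero. Sanger validation outcomes are consumed
as input flags; calls with failed or absent validation are disqualified from
candidacy downstream, reflecting the high artifact rate of short-read de
novo calls.

## Interaction-network linkage and enrichment

The protein-interaction graph is an input edge list (gene A, gene B,
confidence), never a live database query; edges below a confidence threshold
(default 0.4, the conventional "medium confidence") and self-loops are
dropped at load time. A candidate gene is **linked** when, inside the
subgraph induced by the seed genes (previously reported NOA genes) plus the
candidate set, it lies in a connected component containing at least one seed
and has at least one edge. Component membership (rather than requiring a
direct seed edge) is a declared choice: a candidate attached through another
candidate that reaches the seeds is biologically "in the network". The rule
is monotone — adding edges can only create links. Pathway enrichment is a
hypergeometric over-representation test with BH adjustment across pathways.

## Prioritization

Association hits are tiered: **red** = p < 10⁻⁴ with an estimable OR > 1;
**blue** = 10⁻⁴ ≤ p < 0.05, NE > 16 (the expression level of the known NOA
genes, used as a reference), and OR > 6 or not estimable; **yellow** = p <
0.05 and a previously reported NOA gene — yellow takes precedence, so a
known gene with red/blue numerics is still reported yellow and the tiers
stay disjoint.

Known-gene screening honours each gene's inheritance model: autosomal
dominant — one heterozygous LOF is reportable; X-linked — a hemizygous LOF
in a male is reportable; autosomal recessive — a single heterozygous LOF
leaves causality *uncertain* (second allele undetermined); biallelic hits
are reportable.

Trio **top candidates** require, per retained validated call: association
p < 0.05, OR not estimable (no control carries the gene's rare LOFs), and
network linkage. **Expansive candidates** relax to p < 0.05, OR > 1 or not
estimable, NE ≥ 1, validated, excluding genes already in the top set.

A proband is *solved* by a top candidate; a screened patient is solved by a
LOF in a known gene that the association scan itself recovered (the yellow
genes) — for those genes the case-control evidence stands in for the
second-allele requirement of recessive models. Heritability fractions are
100 × solved/cohort, rounded half-up to two decimals. The enrollment
waterfall is sequential subtraction with a negative-remainder guard.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes, not
sequence-level realism. Defaults are the emulated study conditions: 133
cases, 343 fertile male controls, 11 trios. Each of `n_genes` (default 200)
genes carries 1 + Poisson(2) rare LOF variants plus occasional non-LOF
variants (including near-splice variants beyond ±2 bp, which the classifier
must reject); every variant is uncatalogued with probability 0.3 or has a
catalog frequency drawn below 1%. Carrier status is drawn per gene and
sample: planted risk genes (default 5) use case/control carrier rates
0.05/0.002; all other genes use a background rate of 0.015 in both groups —
about seven carriers per gene in 476 samples, chosen as typical of genes
that actually enter a rare-LOF burden test. Carriers are heterozygous
(dominant-model dosage), matching the zygosity column of the emulated
study's tables; one X-linked gene is included with hemizygous 0/2 coding.
Planted genes always have NE > 16 and attach to the seed network with
probability 0.9, so the full prioritization chain can recover them.
Normalized expression for background genes is log-normal with ~5% of genes
missing. Trio probands receive ≥ 1 maternal, Poisson(2) paternal and ≥ 1 de
novo LOF; 30% of inherited sites reuse a control-carried cohort variant (to
exercise the control-absence rule), 30% of novel maternal/de-novo sites land
in planted risk genes (so trio and case-control evidence can corroborate),
and de novo calls fail validation with probability 0.7, the high artifact
rate the emulated study reports. All draws flow from one integer seed;
identical configurations produce byte-identical files.

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: linkage disequilibrium and population
structure, relatedness, batch effects between case and control platforms,
genotyping error outside the HWE-violation channel, X-inactivation, CNVs,
and realistic gene length/constraint variation. Calibration and recovery
results on synthetic cohorts validate the machinery, not the study's
biological conclusions.

## Problem sizes used in the checks

The shipped worked-example tables (53 trio calls, 7 known-gene findings) are
complete transcriptions, run in full. Synthetic checks use: type-I
calibration 200 genes × 50 seeds (~10⁴ gene tests); permutation-oracle
comparison ≥ 10 gene instances at cohort scale (n = 476) and at n = 30 with
10⁵ permutations each; parameter recovery 200 genes with 5 planted at
case-carrier rate 0.08 vs 0 in controls ("strong enrichment"); HWE-oracle
grid 120 random tables with totals ≤ 200 verified against exact rational
arithmetic.

## Limitations

- No covariate adjustment, kinship correction, or SKAT-O style optimal
  kernel mixing; the null is exchangeability of case labels.
- The exact conditional test is conservative on very sparse genes (one or
  two carriers); such genes cannot reach significance at any configuration,
  which is a property of the data, not the method.
- The dense-gene fallback approximation is accurate to roughly the size of
  its residual third-moment mismatch (~0.005 absolute in the CDF mid-range
  at n ≈ 500); exact enumeration covers the regime the pipeline is built
  for.
- Multi-allelic sites and phasing are out of scope; inputs are assumed
  biallelic with one ALT per row.
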