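# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Pedigree model and kinship

A pedigree is a directed acyclic graph of individuals; parents are either
both recorded or both absent (a founder — original colonists and married-in
spouses alike).  Validation enforces referential integrity, acyclicity, and
sex-by-parental-role consistency; a parent of unknown sex is assigned by
role with a logged warning rather than an error, since PED files in the
wild frequently omit spouse sexes.  Individuals drawn repeatedly in
published pedigree figures (one person shown through several lines of
descent) are a rendering artifact; the data model stores each individual
once.

Kinship is computed by the classical recursion in ancestors-first order
(topological sort by parent relation, ties broken by input order):
founders get φ_ii = 1/2 and φ_ij = 0 among themselves; an individual with
parents (f, m) gets φ_ii = (1 + φ_fm)/2 and φ_ij = (φ_fj + φ_mj)/2 for any
j that is not its descendant — the processing order guarantees j is not.
The inbreeding coefficient h = 2φ_ii − 1 equals the kinship of the parents.
The resulting matrix is symmetric positive semi-definite; the genotype
correlation structure used by the association test is K = 2Φ (diagonal
1 + h_i, off-diagonal 2φ_ij), the covariance structure of allele
half-counts under Mendelian transmission.

The kinship implementation is checked against an independent Monte-Carlo
oracle: founder alleles are given 2F distinct labels and gene-dropped, and
φ̂_ij is the mean over replicates of the fraction of the four allele
pairings between i and j that share a label.  A 3-standard-error band
around the truth misses by chance roughly 0.3% of the time, so across many
pedigree-pairs the check is on the *rate* of 3-SE exceedances (at most the
chance rate plus three binomial standard errors), not on every single pair.

## Binomial read-evidence model and the filter cascade

At a heterozygous site each read is assumed to carry the variant allele
with probability ½, so the probability of observing at least k variant
reads at depth n is an exact binomial upper tail.  Depth 10 gives
P(≥2) = 0.9893 — the familiar "ten reads for 99% detection" rule; the exact
smallest depth reaching 0.99 is 11.

The cascade applies, in order: quality (≥4 unique-start variant reads AND
variant allele fraction ≥ 15%, both inclusive; zero depth is a removal
reason, not a division error), consequence (keep missense, nonsense,
frameshift, canonical splice — the two intronic bases at each exon
boundary; consequence is taken from the input annotation, never recomputed
from a gene model), novelty (allele-aware identity (chrom, pos, ref, alt)
against the union of user-supplied catalogues — a known site with a
different alternate allele still counts as novel, the conservative choice
for downstream association), and sharing (variant present in ≥3 of the
sequenced samples).  The first three stages are per-record predicates and
therefore commute; sharing is applied last.  Reports count records at every
stage so that kept + removed = input holds throughout.  Indels are carried
with the frameshift class; their position is the first changed base,
1-based.  Region annotation (for prior linkage regions) uses 1-based
inclusive intervals; BED input is converted on read.  Whether the 15% rule
should treat indels differently is unspecified in this field's pipelines;
they are treated identically here.

## Quasi-likelihood association test

The test is a quasi-likelihood score statistic for case-control association
among related individuals, defined in this package by the closed form:

* genotypes y as allele half-counts (0, ½, 1), missing individuals dropped
  from y, A and K for that variant only;
* phenotype transform T: affected 1, unaffected −k/(1−k) with sex-specific
  prevalence k (mean of the two prevalences when sex is unknown), unknown
  phenotype 0 — so unaffected controls and unknown-phenotype controls
  contribute differently;
* enrichment A = T_N + Φ_NN⁻¹ Φ_NM T_M folds phenotyped-but-ungenotyped
  relatives M into the genotyped set N;
* allele frequency by the best linear unbiased estimator
  p̂ = (1ᵀK⁻¹y)/(1ᵀK⁻¹1);
* W = [Aᵀ(y − p̂1)]² / {(p̂(1−p̂)/2)·[AᵀKA − (Aᵀ1)²/(1ᵀK⁻¹1)]}, referred to
  χ²(1).  The subtracted term is exactly the variance reduction from
  estimating p̂, so Var(Aᵀ(y − p̂1)) is correct under the null.

Fidelity is asserted through properties rather than numerical identity
with any external implementation: with K = I, no ungenotyped relatives and
all phenotypes known, the statistic equals the hand-evaluated classical
1-df allelic quasi-score (W = 4.8 on the four-individual example); on null
cohorts of related individuals the rejection rate at α = 0.05 stays inside
the exact binomial 99% interval over 2,000 replicates, and remains there
when the supplied prevalence (0.10) is far from the generating one (0.25)
— the robustness the method is known for.

Monomorphic variants and zero-variance contrasts are flagged untestable
with p = 1 by convention.  X-linked markers are excluded from the default
scan with a warning (the autosomal variance structure is wrong for them);
an override applies the autosomal statistic and labels the result
approximate.  Linear solves use a Cholesky factorization guarded by a
condition-number check (>1e12 is an error, never a silent pseudo-inverse).
A Bonferroni threshold 0.05/m is reported with each scan; the statistics
themselves are not adjusted.

## Gene dropping

Founder genotypes come either from designated heterozygous carriers
(fixed mode — carriers get exactly one copy, matching the
"both founder brothers carry one copy" scenario) or from independent
Bernoulli(q) draws per founder allele (random mode — Hardy-Weinberg in the
founder pool; the sampling scheme is this package's choice).  Children
inherit one uniformly chosen allele per parent, processed in topological
order, vectorized across replicates of a seeded generator
(`numpy.random.Generator` with `SeedSequence` substreams for sweeps, so
per-seed reproducibility survives parallel structure).  The default target
set is the latest generation (individuals who are nobody's parent);
explicit id lists are accepted since real "current population" membership
is a study-specific notion.

`enumerate_exact` is the oracle: all 2^(2·non-founders) transmission
patterns (and, in random mode, all 3^founders genotype configurations with
Hardy-Weinberg weights) are enumerated, capped at 16 meioses.  The pmf sums
to 1 to 1e−12 and the Monte Carlo agrees with it by χ² goodness of fit.
Frequency sweeps optionally condition on designated founders being
heterozygous — "carrier" conditioning is interpreted as heterozygous to
match fixed-carrier mode; conditional means then exceed the unconditional
martingale value q among the carriers' descendants.

## Burden comparisons

Two-sided Fisher's exact p-values use the small-probability method (the sum
of probabilities of all tables with the observed margins whose point
probability is at most the observed one, with a ~1e−7 relative slack for
floating-point ties), the convention of the common online calculators and
of `scipy.stats.fisher_exact`, which provides the computation here.  Two
conventions circulate for two-sided Fisher tests; this one is fixed and
documented because the alternatives (doubling, mid-p) give different
values.  Carrier counts enter as allele counts assuming heterozygosity
(each carrier contributes 1 of 2 chromosomes).  Control chromosome totals
are supplied per panel and summed.  Categories: private (exactly one case
carrier and absent from the panels), rare (control frequency < 1% by
default), common; private implies rare.  Verification selection follows the
pooled-sequencing rule: nonsynonymous calls always, synonymous calls when
the pooled frequency estimate is below 5%.

## Synthetic-data generator

The generator emulates the statistical structure of a small island founder
cohort, not any real family:

* **Demography** — founding couples (8), five generations, Poisson
  offspring (mean 2.0), a union formed by every non-final-generation member
  either within the pedigree (probability 0.14, the published consanguinity
  rate; full sibs excluded) or with a new married-in founder.  These
  choices put the mean pedigree size near the published 288 (85 founders,
  203 non-founders); per-run sizes vary with branching-process noise, so
  size calibration is a statement about the mean across seeds, not about
  each seed.
* **Risk variant** — two designated carrier founders (generation-0 males
  in input order, emulating variant-introducing founder brothers), gene-dropped.
* **Phenotypes** — a two-penetrance Bernoulli model: carriers affected with
  probability 0.76, non-carriers with a sex-specific baseline calibrated so
  that a population with the study's risk-allele frequency (0.125, carrier
  fraction 0.234 under Hardy-Weinberg) has prevalence 0.25 (male) / 0.27
  (female).  This is the minimal model consistent with the penetrance,
  phenocopy and prevalence arithmetic; no liability threshold is modelled.
  Two consequences are worth stating plainly: (i) in a full simulated
  pedigree the variant is much rarer than 12.5% (two carrier founders among
  ~85), so whole-pedigree prevalence sits below the configured values —
  the prevalences describe the carrier-enriched study regime; (ii) the
  observed phenocopy rate in an ascertained, affection-enriched cohort
  (0.61 in the source study) exceeds what the calibrated baselines imply
  for an unascertained population (~0.33); the generator does not model
  ascertainment, and tests accordingly check penetrance recovery, not
  phenocopy recovery.
* **Exomes** — per-sample variant tables with negative-binomial depth
  (mean 56, shape 2, which puts ≥90% of sites at depth ≥10), binomial
  variant reads, and unique start sites bounded by variant reads.  A known
  number of novel, deleterious, well-supported variants is planted into at
  least 3 of 5 samples; background variants draw consequence, known status,
  carriers and evidence from the configured mixes, and any that would
  survive the cascade by chance is thinned below the sharing threshold.
  Truth labels are therefore exact by construction — the point of the
  fixture is a cascade with a known answer, not a realistic site-frequency
  spectrum.  No reads, haplotypes, linkage disequilibrium or population
  structure beyond the pedigree are simulated, so passing tests say nothing
  about annotation accuracy or calling error in real data.

Bundles (PED, per-sample VCF, known-site VCF, BED regions, panel counts,
truth JSON) are byte-identical under a fixed seed and carry a manifest with
the seed and full configuration.

## Numerical and interface choices

* Evaluation order everywhere is ancestors-first topological with input
  order as tie-break; statistics are invariant to individual ordering.
* Genotype values are validated to {0, ½, 1, missing}; the BLUE of a valid
  vector cannot leave [0, 1].
* PED dialect: six mandatory whitespace-delimited columns, extra columns
  ignored, `0` for missing, `-9` accepted for phenotype.
* Degenerate inputs are conventions, not errors, where the analysis has a
  natural continuation: empty contingency tables and monomorphic variants
  give p = 1 with a flag; empty subgroups are returned undefined-flagged.
* Problem sizes in the statistical tests (2,000 null replicates on 50
  families; 200 pedigrees × 200,000 drops for the kinship oracle; 100,000
  replicates for gene-drop goodness of fit; 200 cohorts for penetrance
  recovery) were chosen to make the Monte-Carlo error small relative to the
  tolerances tested.

## Known limitations

* The association statistic is this package's normative closed form for
  the quasi-likelihood score construction; other implementations may
  differ in degenerate-case conventions and X-chromosome handling.
* No linkage analysis, LOD scores, haplotype/LD computation, identity
  coefficients beyond pairwise kinship, covariate adjustment, or
  gene-collapsing tests beyond count aggregation.
* Novelty is defined only relative to user-supplied catalogues; public
  database membership is not bundled.
* The burden module's private/rare aggregation reports its own exact
  p-values; published one-off values computed with unstated conventions
  cannot always be reconciled from printed counts alone.
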