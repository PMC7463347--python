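# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `musselmix`.

## Genotype model and QC

Genotypes are biallelic alt-allele dosages (0/1/2) with per-genotype read
depth (DP) and quality (GQ); phase is discarded because no analysis here
uses it. The QC chain applies, in order: genotype masking (GQ ≤ 5 or
DP ≤ 5 set missing — thresholds are strict "greater than"), a site
call-rate filter (≥ 60% typed is kept — inclusive), removal of loci whose
mean depth exceeds twice the mean depth of the *raw* dataset (putative
paralogs; the raw mean is computed before any masking), removal of
individuals with > 50% missing data, a strict MAF > 0.01 floor, and
sliding-window LD pruning (window 50 SNPs, step 5, both configurable;
within a window the member of any pair with r² > 0.5 that has the lower
call rate is removed, ties dropping the later locus). Masking at the
genotype level rather than dropping whole sites follows standard VCF
practice; the window/step defaults are the ubiquitous pruning convention,
as no principled value exists for de novo RAD loci without positions. The
chain runs once in the stated order by default; a `fixed_point` option
re-runs the site filters after individual removal, since MAF can newly
fail once samples drop.

## Reference panel, classes, diagnostic loci

Per-species allele frequencies come only from the pure reference sites.
A locus is polymorphic in species *s* iff 0 < p̂ < 1 with at least
`min_typed` (default 10) typed pure genotypes — the guard keeps tiny
denominators from generating spurious fixation or polymorphism calls;
reference panels of 16–18 individuals comfortably exceed it. A locus is
MT-diagnostic iff all three panels are exactly fixed, ME and MG share one
allele and MT carries the other. Exact fixation is a deliberately
conservative definition: high-but-incomplete differentiation does not
qualify.

A caveat quantified during design: when true allele-frequency spectra are
U-shaped (see calibration below), a truly polymorphic private locus has a
non-trivial probability of being *sampled* fixed in a 16–18 individual
panel, so diagnostic calls from finite panels include apparent fixed
differences beyond the truly fixed set, and sample-based class counts
deviate from the truth accordingly. Exact planted-truth recovery is
therefore asserted against the panel built from the generator's true
frequencies (`RefPanel.from_frequencies`); genotype-built panels are
checked statistically (frequency error within binomial standard error;
every truly fixed difference present among the calls).

## Supervised ancestry estimation

Genotypes are modelled as Binomial(2, f) with f the Q-weighted mixture of
panel frequencies. Panel frequencies are clamped into [ε, 1−ε], ε = 1e−3,
so an introgressed allele absent from a finite pure panel cannot produce
an infinite penalty. The EM update attributes each allele copy to a
source species by its posterior responsibility and sets q to the mean
responsibility; the log-likelihood is concave in Q (f is linear in Q and
the binomial log-density is concave in f), so the estimator is globally
convergent. Defaults: relative log-likelihood tolerance 1e−6, max 1,000
iterations, uniform start plus four seeded Dirichlet(1,1,1) multi-starts
(a safeguard against flat directions, e.g. when two species' frequencies
coincide on the typed loci). Individuals typed at fewer than 50 usable
loci are flagged and not profiled.

The grid oracle used in tests evaluates the exact log-likelihood on a
coarse 0.005-resolution simplex grid and then on the full 0.001-resolution
grid within one coarse cell of the coarse argmax; by concavity this equals
the full fine-grid argmax at a fraction of the cost.

"Ancestry dosage" is 2·Q, placing numbers on the 0–2 expected-allele-copy
scale; the population-level introgression score is 1 − (mean dosage of the
site's main species)/2, and the mean of individual scores is reported
alongside since the two differ when main ancestry varies within a site.
Exact argmax ties are broken in the fixed order ME < MG < MT and flagged.

## Heterozygosity

Population Ho averages per-locus heterozygote frequencies over loci (not
per-individual proportions) — the two differ under missingness, and the
locus-wise average matches the "averaged over all loci" convention. sMLH
uses the dataset-wide (all sites pooled) per-locus heterozygote frequency
as its baseline, the standard definition; a per-population baseline is
available via the `locus_subset` mechanism but is not the default. Class-
partitioned sMLH recomputes baselines within each SNP class (ME-only,
MG-only, ME∧MG).

## Statistical models

The population model is an OLS fit of Ho on main ancestry, introgression
and their interaction with sequential (type-I) F tests in that term
order. Main-ancestry classes with fewer than two units (the single pure
MT site at population level) are excluded from slope estimation and
reported without a test. Per-background slopes are within-class OLS fits,
matching how per-species regression lines are usually drawn.

The individual model adds a random site intercept:
y = Xβ + u_site + ε. It is fitted by maximum likelihood — not REML,
because likelihood-ratio tests on fixed effects are invalid under REML —
via closed-form GLS profiling over λ = σ²_site/σ²_resid (Woodbury
identity per group), leaving a one-dimensional bounded optimisation over
log λ with the λ = 0 boundary checked explicitly. The implementation is
authored here because the parametric bootstrap refits the model thousands
of times and needs sub-millisecond fits; it is cross-checked in the test
suite against an independent ML mixed-model implementation and against
exhaustive grid maximisation of the exact likelihood.

Bootstrap LRTs simulate responses from the *fitted null* (site intercepts
first, then residuals), refit both models, and use the +1 convention so
p ∈ [1/(B+1), 1]; B = 1000 by default. Replicates whose refit fails are
dropped and counted; more than 5% failures aborts. BH-FDR uses the
step-up construction. Environment tests are the six Pearson correlations
of per-site mean dosage (three species × SST, salinity) with BH
adjustment across the tests actually performed; constant covariates are
flagged and excluded from the family size.

## Ordination

PCA mean-imputes missing dosages per locus, column-centres without
variance scaling, and fixes component signs by making the largest-
magnitude loading positive. The tree uses Euclidean distances with Ward's
minimum-variance criterion in the squared-distance ("ward.D2") variant,
heights on the distance scale; mean imputation is also used for the
distances (a drop-incomplete alternative is available). Node support is
the fraction of locus-bootstrap replicate trees containing the same leaf
set, with loci resampled with replacement — loci are the exchangeable
unit here since individuals carry the population structure being tested.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes:

* **Classes.** Locus classes (private to one species / shared by two /
  shared by three / monomorphic, plus planted MT-diagnostic fixed
  differences) get exact deterministic counts from the configured
  fractions (defaults 52.3% / 24.3% / 9.0%, 60 diagnostic of 2,000 loci)
  and are placed in seeded random order.
* **Frequencies.** Polymorphic frequencies follow symmetric Beta(a, a)
  spectra. Shared loci carry *one* common ancestral frequency across
  their member species, and species monomorphic at a private locus are
  fixed at the owner's *major* allele — both encode shared ancestral
  variation. These choices matter: with independent frequencies at
  shared loci, or with non-owners fixed at a random or always-reference
  allele, admixture would mechanically *increase* expected heterozygosity
  on every background (2f(1−f) is concave in f), erasing the asymmetry
  between backgrounds that the analysis is designed to detect.
* **Calibration.** Shapes are set so the expected all-locus Ho of a pure
  population hits the targets Ho(ME)=0.09 < Ho(MG)=0.11 < Ho(MT)=0.13:
  with a fixed shared-locus heterozygosity (default E[2p(1−p)] = 0.25),
  the private-locus het solves
  h_priv = (Ho_target − f_shared·h_shared)/f_private and a = h/(1−2h)
  (the symmetric-Beta moment E[2p(1−p)] = a/(2a+1)). Post-QC Ho values
  are proportionally higher than the targets because monomorphic and
  rare loci are filtered; the ordering is what the calibration pins down.
* **Individuals.** Per site, Q is fixed at a simplex vertex (pure
  reference sites) or drawn from Dirichlet(30 × mean). At each locus,
  *both* allele copies descend from a single ancestry source drawn from
  Cat(Q) — a diploid local-ancestry mosaic, reflecting that in long-
  admixed, backcrossing populations homologous segments usually share
  ancestry. Setting `ancestry_correlation = 0` recovers the classic
  allele-copy-independent mixture. Under the diploid model the expected
  heterozygosity of an admixed genome is the Q-weighted average of the
  parental heterozygosities, which yields the background-dependent
  introgression slopes (positive on the less diverse ME background,
  negative on the more diverse MG background); under the copy-independent
  model both slopes are mechanically positive. The supervised estimator
  remains consistent either way, since the per-locus expected genotype is
  2f in both models.
* **Degradation.** MCAR missingness (default 5%), negative-binomial
  depth (mean 20, size 8) and a deterministic GQ = min(99, 4·DP) map
  exercise every QC rule; an optional "plant" mode injects known
  violations of each rule (low-call-rate loci, over-deep loci, sub-MAF
  loci, high-missingness individuals, adjacent duplicated loci for the
  LD filter) and returns the manifest.
* **Environment.** Site SST = 14 + 6·(q̄_MG − q̄_ME) + N(0, 0.8);
  salinity = 33 − 20·q̄_MT + N(0, 1) — warm-water MG, cold-water ME,
  brackish-water MT.
* **Default scenario.** Three pure sites (17/16/18 individuals) plus a
  12-site cline of 14–18 individuals each (252 total), 2,000 loci: MG-
  dominated southern sites with increasing ME fractions, ME-dominated
  northern sites with varying MG and small MT fractions peaking near the
  Baltic-like sites.

What the generator does **not** emulate: linkage beyond the explicitly
planted duplicates (the analysis operates post-pruning), inbreeding
within ancestry sources (Hardy–Weinberg holds given the source),
genotype-calling error beyond the DP/GQ degradation model, ancestry-
informative missingness, and tract-length structure along a genome
(sources are drawn independently per locus). Passing tests therefore
demonstrate correctness of the estimators and the qualitative
introgression–heterozygosity structure under these assumptions, not
robustness to batch effects or reference bias in real RAD data.

## Problem sizes and numerical choices

The test suite uses the default 252 × 2,000 scenario for end-to-end
checks (40 seeded replicates for the sign-structure test, with a single
EM start, valid by concavity), 100-individual panels for ancestry
recovery, 100 simulations of n = 500 for mixed-model recovery, and 500
outer replicates with B = 200 for bootstrap calibration; the acceptance
script runs one full default study with B = 1000. Tolerances: EM 1e−6
relative log-likelihood (1e−11 where EM is compared against the 0.001
grid); LMM profile optimisation xatol 1e−7 on log λ; LR statistics
clamped at 0 beyond −1e−8; simplex sums enforced to 1e−8. Degenerate
inputs are errors, not silent results: empty sites, all-removed samples,
subsets with no heterozygotes, constant covariates (flagged), single-
level factors.

## Limitations

* Ancestry is global and supervised: K is fixed at 3 and the pure panels
  are trusted; per-locus ancestry tracts are out of scope.
* The diagnostic-locus definition requires exact panel fixation and so
  inherits panel sampling noise (quantified above).
* The population-level MT class contains a single site in the default
  design, so MT slopes are reported without a test.
* Bootstrap p-values are granular at 1/(B+1); B = 1000 gives a floor of
  ~0.001.
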