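# Methods

`nipthap` implements haplotype-based noninvasive prenatal testing (NIPT)
for an autosomal-recessive locus from targeted sequencing of maternal
plasma cell-free DNA, with 21-hydroxylase deficiency (CYP21A2) as the
worked case. This note describes the model, its assumptions, the tunable
parameters, and what the synthetic-data experiments do and do not show.

## Problem setting

Maternal plasma contains a mixture of maternal cell-free DNA (fraction
1 − f) and fetal cell-free DNA (fraction f, typically 1–15%). Direct
fetal genotyping at a single pathogenic site is unreliable at these
fractions, so the method infers which *haplotype* each parent transmitted
by aggregating small allele-count imbalances over hundreds of SNPs
flanking the gene (relative haplotype dosage, RHDO). Parental haplotypes
are anchored to the pathogenic allele through an existing child (the
proband).

## Trio phasing (`phasing`)

At each biallelic SNP the pair of transmitted alleles is solved from the
father/mother/child genotypes under Mendel's law of segregation. Hap 0 of
each parent is *defined* as the haplotype transmitted to the proband when
the proband carries that parent's pathogenic allele (an explicit
`ProbandCarries` annotation; the complementary labelling covers an
unaffected proband). Sites where both parents and the child are
heterozygous are underdetermined and marked `unphasable`;
Mendelian-inconsistent sites are excluded with a logged warning rather
than aborting, since real panels contain genotyping errors and the HMM is
robust to site loss. Proband recombination inside the 2 Mbp window is not
modelled: Hap 0/Hap 1 are defined by the proband's transmitted
chromosome, which is exactly what the trio genotypes identify.

Informative SNPs are those whose distinguishing allele occurs on exactly
one of the four parental haplotypes: father heterozygous × mother
homozygous (paternal-informative) or the reverse (maternal-informative).

## Fetal fraction (`fraction`)

At SNPs where the parents are homozygous for different alleles the fetus
is an obligate heterozygote and the paternal-specific allele comes only
from fetal DNA:

    f = (1/n) Σ_i 2 p_i / (p_i + q_i)

with p_i the paternal-specific and q_i the maternal allele count; n is
the number of sites entering the sum. The estimator is applied verbatim
by default. An optional correction inverts the known assay error rate
(background substitutions add ~2ε/3 to the raw estimate, about 0.3
percentage points at ε = 0.005); the replicate experiments enable it
because the error rate there is a known instrument parameter.

## Plasma site filters (`filters`)

Four independent predicates reproduce the plasma SNP-pipeline thresholds:
depth ≥ 40 reads; minor-allele ratio > 1% supported by a Beta(1,1)
posterior at 0.99 credibility; Fisher exact strand-bias test at
P < 1e-4; Kolmogorov–Smirnov in-read position-bias test at P < 1e-6.
Because each predicate is pure, the pipeline outcome is order-independent.
The allele-ratio rule is a variant-*discovery* criterion: when counting
alleles at panel sites whose genotypes are already known from parental
gDNA, a near-zero alternate ratio is an expected biological signal (the
fetus did not inherit the allele), so `full-run` disables that one
predicate for panel-joined counts. Mapping-quality, base-quality and
duplicate filters act upstream of the site counts this package consumes.

## The two-state HMM (`hmm`)

Hidden states Q = {Hap 0, Hap 1} are the haplotype a given parent
transmitted, with initial distribution π = (1/2, 1/2). Each parent's
chain is decoded independently on its own informative sites.

**Emissions.** At site j with k reads of the distinguishing allele out of
n, the likelihood under state i is Binomial(k; n, prob_i). The expected
proportions come from mixture arithmetic:

* paternal-informative: the allele is fetal-specific — f/2 if the fetus
  carries the haplotype bearing it, else 0 (error floor only);
* maternal-informative: 1/2 if the informative maternal allele is
  transmitted, (1 − f)/2 if not — an imbalance of f/2 around 50%.

True proportions are passed through a uniform-substitution error model
(per-base error ε, default 0.005; a specific wrong allele is produced at
rate ε/3, reads matching neither allele are dropped), applied identically
in the simulator, so emissions and generator share one observation model.
Posteriors are normalised by the *sum* of the two likelihoods (with equal
priors), the only normalisation that yields a probability; all
probability arithmetic is in natural-log space via `binom.logpmf`, never
linear-space products.

**Transitions.** The per-interval recombination probability comes from
the genetic distance d (Morgans) via the Haldane map function
P = (1 − e^(−2d))/2, floored at 1e-6 and capped at 0.5. A 3-column
genetic map (chrom, pos, cM) is interpolated linearly; without a map a
constant 1 cM/Mb is assumed.

**Decoding.** Textbook max-product Viterbi in log space; ties break
toward staying in the current state (no recombination), and a terminal
tie resolves to Hap 0. Two per-site tracks are reported: the Viterbi
score gap δ_j(Hap 0) − δ_j(Hap 1) — the log-odds of the best path ending
in each state, including recombination penalties — and the cumulative
emission-only evidence Σ log b(·|Hap 0)/b(·|Hap 1). The score gap
saturates near the switch cost ln((1−P)/P) once the path is certain, so
the emission-evidence track is the right quantity for "is there any
usable signal" comparisons.

**Locus call.** The transmitted haplotype is the Viterbi state over the
informative sites inside the gene interval plus the nearest flank on each
side; disagreement (a recombination at the locus) yields a no-call rather
than a silent majority vote. Below a fetal-fraction floor (default 1%)
the maternal call is refused — the f/2 imbalance around 50% is too small
to trust — while the chain is still decoded for diagnostics.

## Fetal sex (`sexing`)

Male fetuses contribute chrY fragments, giving the Y-specific capture
target high mean depth and near-complete 4× coverage; female pregnancies
show only non-specific mapping noise. Observed classes are separated by a
wide margin (male ≥ 97% 4× coverage in validation data, female ≤ 25%),
so the defaults cut inside the gap — male requires cov4x ≥ 0.50 and mean
depth ≥ 20, female requires cov4x ≤ 0.30 — and the buffer in between
reports `indeterminate` rather than forcing a class.

## Simulator (`simulator`)

The generator emulates the validation study's design: 1,607 SNPs placed
uniformly over a 2 Mbp window with the gene interval (3.4 kb) at the
centre; plasma depth Poisson around the target mean (the study gives no
depth distribution; a fixed-depth mode exists for unit tests); allele
counts binomial at the maternal/fetal mixture proportion with the
uniform-substitution error model; fetal gametes drawn with Poisson
crossovers on the genetic map (forced crossover positions supported for
deterministic tests); strand counts and in-read positions unbiased unless
bias injection is requested. Downsampling thins each count binomially,
which preserves allele-ratio expectations and never exceeds the original
counts.

Because the real capture panel is ascertained for heterozygosity, a
Hardy–Weinberg draw cannot reproduce the reported informative-site counts
(it caps at ~25% per class, versus 393–866 paternal and 534–1,330
maternal informative sites in the validation families). The simulator
therefore draws each site's class directly — 44% paternal-informative,
46% maternal-informative, 4% opposite-homozygote (fetal-fraction sites),
6% other — giving ≈707/≈739 informative sites per parent and ≈64
fraction sites, inside the reported ranges. These weights are study
conditions, not fitting knobs.

Not modelled: fragment-size differences between fetal and maternal
cfDNA, capture-efficiency/GC bias, read-level artifacts (the simulator
emits site-level counts, not reads), proband recombination, and twin
pregnancies. Passing simulation tests therefore demonstrates decoder
correctness under the stated mixture model, not robustness to every
artifact of real plasma libraries.

## Replication experiments and their statistical envelope

`experiments.run_replicate` chains simulate → phase → estimate f →
decode → score-against-truth at the gene locus; `accuracy_grid` maps the
fetal-fraction × depth surface (20 replicates per cell in the shipped
tests and acceptance script — a grid cell costs ~40 ms, so the full
surface runs in seconds on one CPU). The replicate pipeline decodes
unfiltered counts: a 30× dataset cannot pass a 40-read floor, and the
panel genotypes are known a priori.

One envelope is worth stating explicitly. At f = 2% and 30× mean depth,
~740 maternal-informative sites carry ≈22,000 reads; distinguishing
allele fraction 0.50 from 0.49 with that many reads gives a per-replicate
accuracy of ~93–95% — an information-theoretic bound that no decoder can
beat under this observation model. Demanding perfection across 20
replicates in such a cell therefore fails with substantial probability
even for a correct implementation, and single-sample validation data can
print 100% there by chance. The paternal chain, whose signal is
fetal-specific (f/2 against an error floor rather than against 50%),
remains essentially perfect down to f = 1% at ≥100×. The tests assert
the nominal targets as stated and the accompanying analysis records
where the statistical envelope, not the implementation, is binding.

## Numerical and degenerate-input choices

Zero-depth sites are skipped with a warning; empty chains, empty panels
and out-of-order positions raise. Emission likelihoods that both
underflow to zero yield a (1/2, 1/2) posterior. Fetal-fraction estimates
above 1 are clipped with a warning. Recombination probabilities are
floored (1e-6) so log-transitions stay finite at zero genetic distance.
All randomness flows through `numpy.random.Generator` seeded explicitly;
every CLI command requires or accepts a seed and produces byte-identical
outputs for identical inputs.
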