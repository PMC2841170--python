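# Methods

## Data model and site filtering

The universal input is a `PopAlignment`: aligned haploid gene copies (one
sequence per sampled chromosome) with a sample→population map, an optional
exon annotation (0-based, half-open column intervals plus a frame offset)
and an optional single outgroup sequence, which never counts toward the
sample size n.

All polymorphism statistics use a listwise complete-case convention: any
column carrying a gap, `N` or IUPAC ambiguity code in *any* ingroup
sequence is dropped from every statistic, and the number of analysed sites
is reported alongside each estimate.  Haplotype identity is likewise
decided on the complete-case columns, so haplotype counts are consistent
with S.  Directly sequenced (unphased) loci arrive with IUPAC heterozygote
codes; those columns are removed by the same rule, and when more than 10%
of columns are lost the haplotype table is flagged unavailable and
haplotype-based tests report "n/a" rather than a silently different
statistic.

## Diversity and neutrality statistics

Per-site π is k/L with k the mean pairwise difference count; θ_W is
S/(a₁L).  Multi-allelic sites contribute (alleles − 1) to the total
mutation count η but one unit to S; Tajima's D uses S, Fu & Li's D and D*
use η.  All normalizing constants (Tajima's a₁…e₂, Fu & Li's u, v) are
derived fresh from n at each call.  Singletons for R2 and D* are alleles
observed exactly once, regardless of outgroup; external mutations for
Fu & Li's D are derived singletons from the outgroup-polarized spectrum,
with η for that statistic counted on the polarizable sites so numerator
terms stay consistent.  The folded spectrum uses minor-allele counts at
biallelic sites; the unfolded spectrum requires the outgroup to carry one
of the two ingroup alleles and drops sites where it is gapped, ambiguous
or carries a third state.

Fu's Fs evaluates S′ = P(K ≥ K_obs | θ = k) under the Ewens sampling
formula with exact big-integer Stirling numbers of the first kind (the
normalizing rising factorial is accumulated in log space, stable to
n = 100), then Fs = ln(S′/(1 − S′)).

Simulation p-values condition on the observed S: genealogies from the
constant-size coalescent receive exactly S mutations placed on branches
proportionally to branch length, and the two-tailed p is
2·min(P(X ≤ obs), P(X ≥ obs)) capped at 1 (one-tailed variants are
available).  The default is 10,000 replicates.

Two distributional facts worth stating because they differ from common
shorthand: the null mean of Tajima's D is not exactly zero (the
square-root normalization and conditioning on S ≥ 1 leave a small negative
bias, about −0.08 at n = 10, θ = 5), and Fay & Wu's H has *exactly* zero
expectation under constant size but drifts weakly *positive* under pure
growth — H < 0 is a hitchhiking signature, not an expansion one.  The test
suite encodes both facts.

## Synonymous/nonsynonymous counting

Both the within-species π_syn/π_nonsyn partition and pairwise dN/dS use
Nei–Gojobori (1986) bookkeeping: per-codon synonymous-site fractions
(mutations to stop codons excluded from the denominator), site counts
averaged over sequences, and difference counts averaged over all minimal
substitution pathways between codon pairs, with pathways through stops
excluded; a codon pair whose every pathway hits a stop is skipped with a
warning.  Codons containing any excluded column are dropped whole.
Distances are Jukes–Cantor corrected, d = −(3/4)·ln(1 − 4p/3), undefined
at p ≥ 3/4.  This is a counting estimator: maximum-likelihood codon-model
estimates of the same quantities differ modestly (usually slightly higher
dS), so panel summaries (means, 95% intervals of dS, dN, ω) should be
compared within a method, not across methods.

## McDonald–Kreitman and HKA

A fixed difference is a site monomorphic within the ingroup and different
from the outgroup; a site polymorphic within the ingroup counts as
polymorphic only, whatever the outgroup carries.  Each variable position
is classed synonymous/nonsynonymous by exchanging the variant base inside
the majority codon context.  An optional low-frequency filter removes
polymorphisms whose minor allele occurs c times or fewer.  P-values are
the two-tailed Fisher exact test and the log-likelihood-ratio G-test of
the 2×2 table; if any marginal is zero the table is returned with the
p-value flagged undefined.

The HKA test uses the one-species-plus-divergence expectations with equal
species sizes: E[Sᵢ] = θᵢa₁(nᵢ), Var[Sᵢ] = E[Sᵢ] + θᵢ²a₂(nᵢ),
E[Dᵢ] = θᵢ(T + 1), Var[Dᵢ] = E[Dᵢ] + θᵢ², with divergence counts rescaled
to the polymorphism length when the two differ.  The per-locus θᵢ and
shared T are fitted by direct minimization of the X² statistic
(Nelder–Mead from the moment-equation solution, with a multi-start
fallback); X² is referred to χ² with (loci − 1) degrees of freedom.  The
moment equations alone do not minimize X² — on a three-locus example they
sit about one X² unit above the minimum — so minimization is the contract,
and the saturated single-locus case returns X² = 0 exactly.

The exon G-test compares observed polymorphism counts per exon with
expectations proportional to exon lengths, G = 2ΣOᵢ ln(Oᵢ/Eᵢ) on
df = categories − 1 (zero-observation categories contribute nothing); both
printed (G, P) pairs of the motivating analysis are consistent with df = 1
under the upper-tail χ² (5.99 → 0.014, 0.43 → 0.512).

## AMOVA, Fst and exact tests

Distances are pairwise nucleotide difference counts; these serve directly
as squared Euclidean distances in the Excoffier sum-of-squares
decomposition with unequal-sample-size coefficients n′, n″, n‴.  Negative
variance components and negative Fst are reported as computed — truncation
would silently break the percentages-sum-to-100 identity the output
guarantees to 1e−9.  Permutation schemes: Φ_ST permutes haplotypes over
the whole sample, Φ_SC within groups, Φ_CT permutes whole populations
among groups (defaults 10,100 permutations); pairwise Fst is Φ_ST of the
two-population sub-analysis with a one-tailed permutation p.  Populations
with n < 2 are excluded.  The migrant-number conversion is the haploid
one, M = (1/Fst − 1)/2, reported as `inf` when Fst ≤ 0 — sequence data are
haploid gene copies here, and the conversion is applied per locus.

The exact test of differentiation runs the Raymond–Rousset Markov chain
over haplotype×population tables with fixed margins (two-row/two-column
switch proposals, Metropolis acceptance by the hypergeometric probability
ratio), defaults 400,000 steps after 100,000 dememorization steps; p is
the visited fraction of states no more probable than the observed table,
with a batch-means standard error.  A permutation-floor caveat: with tiny
samples the attainable minimum p of permutation tests is set by the number
of distinct relabellings (e.g. 2/C(8,4) for a 4|4 split), not by
1/(n_perm + 1).

## Coalescent simulator

Time is measured in units of 4N₀ generations (the ms convention):
the pair-coalescence rate is 2/λ(t) with λ the relative population size,
giving E[TMRCA] = 0.5 for n = 2 and (1 − 1/n) in general, and mutation
counts are Poisson(θ₀ × total branch length), giving E[S] = θ₀a₁ and
E[π] = θ₀.  The expansion model has three parameters: θ₀ (per locus),
t_b in generations before present (converted through the stated N₀), and
the coalescent-scaled growth rate g; backward in time the size shrinks as
e^(−gt) until t_b/(4N₀) and is constant at N₀e^(−g·t_b/4N₀) earlier.  A
ten-fold expansion therefore satisfies g·t_b/(4N₀) = ln 10, which the
converter reproduces exactly.  Waiting times under growth come from the
analytic inverse transform of the time-varying hazard — no discretization.
Loci are non-recombining: the downstream summaries (θ_W, π, R2) were
chosen for robustness to recombination, and simulating it is out of scope.

Mutations are binary infinite-sites; a nucleotide wrapper (random
ancestral base per column, mutations at distinct random columns with a
random derived base) feeds the alignment layer for synthetic FASTA.  The
island extension gives each deme modern size N₀ (so under strong
migration D demes behave as one population of size D·N₀), symmetric
migration at rate M/2 per lineage split uniformly over the other demes,
by competing-risks sampling of the growth-scaled coalescence hazard
against the constant migration hazard; M = 0 with several demes requires
an ancient merge time.  All randomness flows from one explicit seed
through numpy Generators, with per-replicate streams derived
deterministically.

## ABC

The reference table is built from independent uniform prior draws
(θ₀ per site, t_b in generations, g), each simulated at the study's
per-locus sample sizes and lengths and reduced to length-weighted
(θ_W, π, R2) across loci; replicates in which every locus is monomorphic
have no R2 and are flagged invalid.  Multi-locus observed summaries use
the same length-weighted mean — pooling by concatenation was the main
alternative, but weighting keeps per-locus sample-size differences
explicit and matches how the table is built.  Rejection standardizes each
summary by its whole-table standard deviation (simplest defensible
choice; MAD is a one-line change) and accepts the ceil(tolerance×n_sims)
closest draws in Euclidean distance.  The regression step is the Beaumont
local-linear adjustment: Epanechnikov weights on distance, weighted least
squares of log(x + 1e−8)-transformed parameters on the summaries, residual
translation to the observed summaries, back-transform, then clamping to
the prior support; a singular design falls back to the unadjusted
rejection posterior with a note.  The log transform keeps demographic
draws positive; `transform="none"` exists for parameters with signed
support (the calibration toy uses it).  Posterior summaries are the
weighted mean and weighted 2.5/97.5 percentiles — the "lower/upper" values
are credible bounds, not the accepted-sample range.

The two-step scheme runs a liberal pass (tolerance 0.01) over broad
priors, derives run-2 priors as [0, 3 × run-1 posterior mean] per
parameter (the mean plus two means above it, floored at zero), and reruns
at tolerance 0.001.  Year-based prior bounds convert to generations
explicitly (default 2 generations/year, configurable in
`SamplingDesign`).

Calibration is part of the package (`popgenkit.calibration`): a
linear-Gaussian toy with analytic posterior N(s_obs, 1), and a coverage
experiment that builds one 100,000-draw reference table and, for 50
repetitions, simulates fresh pseudo-observed data at a known truth
(θ₀ = 0.01/site, t_b = 942 generations, g = 2.85 at N₀ = 10,000 — an
inferred expansion history with N₀ scaled down ten-fold to keep
genealogies cheap; design: two loci of n = 20 chromosomes, 500 and 400
sites) and scores whether the truth falls in the 95% adjusted interval.

## Synthetic data generator

The default `StudyDesign` emulates a four-population, two-continent survey
(DE, FR, IT, US; 10 diploid individuals each) of seven loci spanning
211–943 bp: one intron-bearing candidate segment (943 columns, 594
coding), a second candidate segment, four exonic references and one
mitochondrial-like locus; two are marked direct-sequenced and emitted as
IUPAC-collapsed unphased calls, the rest as two phased clones per
individual.  Demography is the island model with M = 20 (weak structure,
high gene flow) and a recent expansion (g = 2.85, t_b = 942 generations at
N₀ = 10,000); per-site θ values (0.005–0.018) bracket the diversity
spread typical of such panels.  The generator is strictly neutral — every
dataset is a draw from the demographic null, so selection signals in
downstream tests are false-positive checks by construction.  What it does
not emulate: recombination within loci, sequencing/cloning error, base
composition and codon-usage bias, and mutation-rate heterogeneity along
the sequence; passing tests therefore validate the statistical machinery,
not robustness to those real-data features.

## Numerical and degenerate-input conventions

Statistics undefined at S = 0 (D, D*, R2) or k = 0 (Fs) return NaN with an
explanatory note and no p-value; a single haplotype gives Fs = +inf.
ω is undefined when dS = 0; the Jukes–Cantor correction is flagged at
p ≥ 3/4.  AMOVA with zero total variance reports NaN percentages.  Holm
rejection proceeds in ascending p order and stops at the first failure.
Floating-point output in pipeline tables is fixed at 5 decimals.

## Known limitations

Fu & Li's D with outgroup ignores within-outgroup polymorphism (a single
outgroup sequence is assumed); the HKA variances take equal species sizes
(f = 1); the MK classification uses the majority codon context rather
than enumerating full codon genealogies; the exact-test chain reports a
batch-means standard error rather than an exact Monte-Carlo bound; and the
expansion coalescent assumes one panmictic (or island-symmetric)
population — no bottlenecks, admixture or recombination.
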