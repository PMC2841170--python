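# popgenkit

Multilocus molecular population genetics for candidate-gene studies in
non-model organisms: given per-locus alignments of sampled gene copies with
population labels (e.g. a detoxification gene and a panel of reference loci
sequenced in butterflies from several populations), the package computes
within-sample diversity and neutrality statistics, tests population
structure, contrasts polymorphism with interspecific divergence, and infers
a population-expansion history by Approximate Bayesian Computation — all
runnable end-to-end on synthetic study-shaped data it generates itself.

It is written for population geneticists who would otherwise chain DnaSP,
Arlequin, ms and ABCreg by hand and want the same analyses as one tested,
scriptable library.

## What it computes

**Diversity and neutrality** (per locus, on the complete-case columns):
segregating sites *S*, mean pairwise differences *k*, nucleotide diversity
π = k/L, Watterson's θ_W = S/(a₁L) with a₁ = Σ_{i<n} 1/i, synonymous and
nonsynonymous diversity by Nei–Gojobori site counting, haplotype counts;
Tajima's *D*, Fu & Li's *D* and *D**, Fay & Wu's *H*, Ramos-Onsins &
Rozas' *R2*, and Fu's *Fs* (exact Ewens/Stirling arithmetic).  Empirical
p-values come from a constant-size coalescent conditioned on the observed
*S* (10,000 replicates by default).

**Structure**: hierarchical AMOVA on pairwise difference counts (Excoffier
sums of squares, unequal sample sizes, negative components preserved),
pairwise Fst = Φ_ST with permutation p-values, haploid migrant numbers
M = (1/Fst − 1)/2, Raymond–Rousset Markov-chain exact tests of haplotype
differentiation, and Holm's sequential-Bonferroni adjustment.

**Divergence**: Nei–Gojobori (1986) pairwise dN/dS with Jukes–Cantor
correction and distribution summaries across gene panels, the
McDonald–Kreitman 2×2 test (Fisher exact and G), the standard multilocus
HKA test (per-locus θᵢ and shared divergence time *T* fitted by minimizing
the HKA X² statistic), and a goodness-of-fit G-test of polymorphism counts
against exon lengths.

**Demography**: an infinite-sites Hudson coalescent (ms time convention,
units of 4N₀ generations) with a three-parameter expansion model — modern
θ₀, onset of expansion t_b (generations), coalescent-scaled growth rate
*g* — extended to a symmetric island model for the data generator; and
two-step rejection + local-linear-regression ABC conditioned on
(θ_W, π, R2), where run-2 priors are [0, 3 × run-1 posterior mean] with a
tighter tolerance.

## Worked example

```python
from popgenkit import watterson_theta
from popgenkit.diversity import tajimas_d_value
from popgenkit.diversity import NeutralityResult, coalescent_pvalue

# a 12-chromosome sample over 260 coding sites with 5 segregating sites
print(round(watterson_theta(5, 12, 260), 5))       # 0.00637
d = tajimas_d_value(12, 5, 0.00321 * 260)          # pi = 0.00321 per site
print(round(d, 2))                                 # -1.83
res = coalescent_pvalue(NeutralityResult("tajima_d", d), n=12, S=5,
                        n_sims=10_000, seed=1, tail="lower")
print(res.p_value < 0.05)                          # True
```

The first two numbers are the per-site Watterson estimate and Tajima's D of
that sample: D is strongly negative because π sits well below θ_W, an
excess of rare variants.  The coalescent p-value says fewer than 5% of
constant-size neutral genealogies with the same S produce a D that low.

A complete synthetic study (4 populations × 10 diploid individuals, 7 loci
of 211–943 bp, recent expansion, weak structure) runs from the shell:

```sh
popgenkit --seed 1 synth bundle/
popgenkit --seed 1 all bundle/ --out report/ --n-perm 1000 --n-sims 2000
```

which writes `diversity.tsv`, `neutrality.tsv`, `amova.tsv`, `fst.tsv`,
`exact.tsv`, `migration.tsv` and a JSON run manifest under `report/`.

## Layout

| module | contents |
|---|---|
| `popgenkit.alignment` | FASTA/popmap/annotation I/O, `PopAlignment`, haplotype collapsing |
| `popgenkit.diversity` | diversity summaries, SFS, neutrality statistics, coalescent p-values |
| `popgenkit.divergence` | NG86 dN/dS, MK test, HKA, G-test |
| `popgenkit.structure` | AMOVA, pairwise Fst, exact tests, Holm adjustment |
| `popgenkit.coalescent` | expansion-model coalescent, fixed-S simulator, island model |
| `popgenkit.abc` | reference tables, rejection, regression adjustment, two-step scheme |
| `popgenkit.calibration` | linear-Gaussian toy, recovery/coverage experiment |
| `popgenkit.synth` | study-shaped synthetic data bundles |
| `popgenkit.pipeline` / `popgenkit.cli` | batch TSV reports and the `popgenkit` command |

See `docs/methods.md` for the models, conventions and limitations.
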