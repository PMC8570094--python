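# Methods

## Problem

When a genotyped livestock population is to be (partially) re-sequenced to
build a haplotype reference panel for imputation, the animals should be chosen
so that their chromosomes jointly carry as much of the population's haplotype
diversity as possible. seqpick formulates this as integer linear programming
over a binary incidence matrix **A** (p haplotypes x n animals, a_ij = 1 iff
animal j carries haplotype i on at least one chromosome copy) and solves two
applications exactly:

1. **Minimum cover** — min Σ x_j subject to A x ≥ b, x ∈ {0,1}ⁿ, with b = 1
   by default. The optimum z1 is the theoretical minimum number of animals
   representing every haplotype; per-row b_i > 1 demands redundant coverage of
   designated (e.g. rare) haplotypes.
2. **Budgeted maximum coverage** — max cᵀx subject to Σ x_j ≤ n_max and
   A x ≤ r_max, with weights c = hᵀA (h = haplotype frequencies), so animals
   carrying many frequent haplotypes score highly, and the redundancy cap
   r_max prevents spending the budget on carriers of the same haplotypes.

Both are solved by branch and bound (HiGHS via `scipy.optimize.milp`), which
closes the optimality gap and certifies the global optimum; `proven_optimal`
in every result records whether the certificate was obtained. If a
user-supplied time limit interrupts the search the incumbent is returned with
`proven_optimal=False` and a warning — never a silent approximation.

### Batch-iterative decomposition

The full budgeted problem with small r_max is slow to solve in one shot at
n_max = 100, so it is decomposed: solve exactly with n_max = batch (default 2,
r_max = 2), remove the selected animals and every haplotype they carry,
recompute c as h restricted to the surviving rows times the surviving
submatrix, and repeat until the budget is spent. Frequencies themselves are
never recomputed between rounds. With batch ≤ r_max the cap constraint is
vacuous within a round (two animals cannot cover a row more than twice);
across rounds diversity is enforced by row removal. An odd budget remainder is
spent with a final batch of 1. If every row is covered before the budget is
exhausted, the default behavior continues the same procedure on the rows that
the frequency filter had excluded (covering the next-rarest haplotypes);
`on_exhausted="stop"` ends early instead. Per-round objectives, removals and
certificates are logged in `SelectionResult.rounds`.

### Exact presolve

When the redundancy cap is vacuous (r_max ≥ n_max) the budget ILP is
separable, and only the n_max largest weights — plus all ties at the threshold
and any forced-in animals — can appear in an optimal solution. The solver is
therefore given just that column subset. This is a dominance reduction, not an
approximation: any solution using an excluded column can swap it for an unused
kept column of no smaller weight.

## Haplotype library

Chromosomes are tiled with non-overlapping blocks of 100 consecutive SNPs
(trailing shorter blocks allowed). Within a block the 2n observed haplotypes
are deduplicated and merged by greedy leader clustering: distinct haplotypes
are processed in descending count order (ties lexicographic); each joins the
first cluster whose representative differs at ≤ floor(0.10 × L) sites
("up to 10%" read inclusively: 10 of 100 merges, 11 does not), else founds a
new cluster. The founder of a cluster is its representative. Cluster
frequency = merged count / 2n (gametes, not animals): the weights in the
budgeted objective must reflect gamete frequencies even though carriage in A
is per animal and binary (homozygotes contribute one, not two). Haplotypes
with frequency < 1% are excluded before fixed-budget selection; the boundary
frequency 0.010 is retained. Unphased or missing genotypes are rejected, not
imputed — the method presumes phased input.

## Baselines

* **AHAP1**: rank animals once by the same static weights c = hᵀA (both
  homozygous and heterozygous carriage) and take the top of the list; no
  updating for animals already selected.
* **IWS**: one animal at a time; weight_j = Σ a_ij / h_i over the rows not yet
  covered, so rare-haplotype carriers dominate; the covered rows of each pick
  are removed before the next. The weight rule is the package's own concrete
  reading of the published scheme's stated behavior (rare-first, single
  animal, updated between picks) and is pluggable.
* **Greedy cover**: most-uncovered-rows-first, the textbook set-cover
  heuristic, kept as a test baseline (provably suboptimal on crafted
  instances, verified against the ILP).
* **Random**: uniform without replacement.

All ties break by smaller animal ID, making every scheme deterministic.

## Breeding simulator

The generator emulates a closed nucleus cattle scheme: 1,000 founders at equal
sex ratio; each generation the 25 males with the highest true breeding value
are mated to the 500 females of that generation, producing 1,000 offspring at
equal sex ratio; non-overlapping generations; 5 to 50 generations (scenarios
1–5, cumulative sizes 6,000 to 51,000). A quantitative trait is controlled by
150 QTL placed evenly on the SNP map (15 per chromosome) with standard-normal
effects; selection acts on the true breeding value (no environmental noise,
i.e. heritability 1 at the selection step — the scheme selects directly on
breeding value). Each offspring receives a uniformly drawn (sire, dam) pair —
the simplest design consistent with "all sires mated to all dams". Meiosis
places Poisson(λ) crossovers per chromosome at uniform SNP boundaries with a
fair random starting phase; λ = 1 Morgan for the full-scale 1,000-SNP
chromosome.

**Founder model.** Founder gametes are drawn from a per-chromosome pool of 40
haplotypes generated by mutating a random ancestral haplotype at per-locus
rate 0.3, then mosaic-recombined once. This is not a coalescent: it has no
realistic allele-frequency spectrum or LD decay. What it preserves — and what
the selection methods actually consume — is block-level haplotype sharing: a
limited set of frequent ancestral block haplotypes plus a growing tail of rare
recombinants. At scenario-1 scale the resulting library (~420 clusters per
100-SNP block, ~30 of them common) is within a factor of two of what a
coalescent cattle founder model produces per block (~274, ~26 common).

**Reduced genome.** Simulation-based tests and the acceptance script use 10
chromosomes × 200 SNPs rather than × 1,000. The genetic map scales with the
SNP count (1 Morgan per 1,000 SNPs, so 0.2 Morgan per reduced chromosome,
`genome_overrides()`): per-block crossover rates, and hence library
composition, then match the full-scale design. Without this scaling a reduced
chromosome would concentrate five times the recombination into each block and
inflate the rare tail fivefold.

**What passing tests do and do not show.** Orderings among methods
(exact-ILP minimum ≤ IWS ≤ AHAP1 run-to-coverage sizes; common-haplotype
coverage LPChoose ≥ IWS ≥ AHAP1; all-haplotype coverage IWS ≥ LPChoose) and
threshold behaviors (common coverage > 0.99 by 100 animals; AHAP1 needing
essentially the whole population for full coverage) reproduce on these
simulations and are robust to the founder-model substitution. Absolute counts
(library size, z1) are founder-model-dependent and are not asserted against
published values. One published quantity does not reproduce under the
stand-in founders: AHAP1's all-haplotype coverage by 100 animals measures
≈ 0.093 here versus a published ≈ 0.14 (band 0.1–0.3). The static top-weight
animals in these simulations are more redundant (late-generation close
relatives sharing pool haplotypes) than under coalescent founders; the
corresponding test is left failing rather than recalibrating the generator
around it.

## Numerical choices

* Frequencies and weights are exact ratios of small integers over 2n; no
  tolerance is needed in frequency comparisons (the ≥ 1% filter is an exact
  comparison on count/2n).
* MILP solutions are rounded from the solver's binary variables and
  re-verified independently (`validate_result`): coverage counts, budget,
  caps, requirements, and objective (1e-9 relative).
* Equally optimal supports are solver-dependent; contracts and tests fix the
  objective value, never the support. Zero-weight animals are never selected
  by the budgeted solve.
* Mean ± SD summaries use the sample SD (n−1).
* RNG: every simulation derives from one `numpy` `default_rng(seed)`;
  experiment replicate r uses `seed_base + r`. Runs are bit-reproducible.

## Problem sizes

Simulation-based tests and the acceptance script run scenario 1 (6,000
animals) on the 2,000-SNP reduced genome: the library holds ~8,400 haplotype
clusters (~620 common), the exact min-cover ILP solves in under a second, and
the 50-round iterative budget selection in well under a minute. The method
ordering checks use three replicates.

## Known limitations

* The founder model is a stand-in; absolute haplotype counts and any
  LD-sensitive quantity should not be compared against coalescent-founder
  results (see AHAP1 note above).
* No pedigree- or kinship-based selection criteria; no imputation-accuracy
  modeling; no statistical phasing — input must be phased.
* The batch-iterative decomposition is exact per round but carries no global
  optimality-gap guarantee for the combined 100-animal selection; per-round
  objectives are logged, no gap claim is made.
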