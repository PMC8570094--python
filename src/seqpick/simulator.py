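"""Forward-in-time breeding-population simulator.

Generates phased SNP populations with the structure of a closed nucleus
cattle breeding scheme: a founder generation of fixed size and equal sex
ratio, followed by discrete generations in which the males with the
highest true breeding value are used as sires on the full dam cohort.
A quantitative trait is controlled by additive QTL placed on the SNP map
with standard-normal effects.

Founder haplotypes are drawn from a finite per-chromosome haplotype pool
derived by mutating a random ancestral haplotype, then mosaic-recombined
once.  This is a deliberately simple founder model: it reproduces the
block-level haplotype-sharing structure (a limited number of frequent
ancestral block haplotypes plus a tail of rare recombinants) that the
downstream selection methods consume, without running a coalescent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SimConfig",
    "PhasedPopulation",
    "simulate_founders",
    "breeding_value",
    "meiosis",
    "advance_generation",
    "simulate_scenario",
    "simulate_population",
    "genome_overrides",
    "concat_populations",
    "SCENARIO_GENERATIONS",
]

#: generations simulated in each of the five standard scenarios
SCENARIO_GENERATIONS = {1: 5, 2: 10, 3: 15, 4: 30, 5: 50}

MALE, FEMALE = 0, 1


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the breeding-scheme simulation.

    Defaults correspond to the standard design: 1,000 animals per
    generation at equal sex ratio, 25 sires selected on true breeding
    value and mated to 500 dams, a 150-QTL trait, and a genome of 10
    chromosomes x 1,000 SNPs.
    """

    n_founders: int = 1000
    sex_ratio: float = 0.5
    n_generations: int = 5
    n_sires: int = 25
    n_dams: int = 500
    offspring_per_gen: int = 1000
    n_chromosomes: int = 10
    snps_per_chromosome: int = 1000
    n_qtl: int = 150
    #: expected crossovers per chromosome per meiosis (Morgans)
    recombination_rate: float = 1.0
    #: founder-pool haplotypes per chromosome
    founder_pool_size: int = 40
    #: per-locus flip probability from the ancestral haplotype
    founder_flip_rate: float = 0.3
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    def validate(self) -> None:
        positive = {
            "n_founders": self.n_founders,
            "n_generations": self.n_generations,
            "n_sires": self.n_sires,
            "n_dams": self.n_dams,
            "offspring_per_gen": self.offspring_per_gen,
            "n_chromosomes": self.n_chromosomes,
            "snps_per_chromosome": self.snps_per_chromosome,
            "n_qtl": self.n_qtl,
            "founder_pool_size": self.founder_pool_size,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ValueError(f"sex_ratio must be in (0,1), got {self.sex_ratio}")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed the number of SNPs")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be non-negative")
        n_males = round(self.offspring_per_gen * (1.0 - self.sex_ratio))
        n_females = self.offspring_per_gen - n_males
        if self.n_sires > n_males:
            raise ValueError("n_sires exceeds the male count per generation")
        if self.n_dams > n_females:
            raise ValueError("n_dams exceeds the female count per generation")


@dataclass
class PhasedPopulation:
    """A set of animals with two phased allele vectors each.

    ``haplotypes`` has shape (n_animals, 2, n_snps) over {0, 1};
    ``snp_chrom`` maps each SNP column to its chromosome (0-based);
    ``sire``/``dam`` hold parent animal IDs or -1 for founders.
    """

    animal_ids: np.ndarray
    haplotypes: np.ndarray
    snp_chrom: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    breeding_values: np.ndarray | None = None
    qtl_positions: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.animal_ids)
        if self.haplotypes.shape[0] != n or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_animals, 2, n_snps)")
        if self.haplotypes.shape[2] != len(self.snp_chrom):
            raise ValueError("haplotype length must match the SNP map")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    def subset(self, index: np.ndarray) -> "PhasedPopulation":
        bv = None if self.breeding_values is None else self.breeding_values[index]
        return PhasedPopulation(
            animal_ids=self.animal_ids[index],
            haplotypes=self.haplotypes[index],
            snp_chrom=self.snp_chrom,
            sex=self.sex[index],
            generation=self.generation[index],
            sire=self.sire[index],
            dam=self.dam[index],
            breeding_values=bv,
            qtl_positions=self.qtl_positions,
            qtl_effects=self.qtl_effects,
        )


def _snp_chrom_map(config: SimConfig) -> np.ndarray:
    return np.repeat(np.arange(config.n_chromosomes), config.snps_per_chromosome)


def _qtl_layout(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """QTL positions spread equally over chromosomes, evenly spaced within."""
    per_chrom = config.n_qtl // config.n_chromosomes
    remainder = config.n_qtl % config.n_chromosomes
    positions = []
    for c in range(config.n_chromosomes):
        k = per_chrom + (1 if c < remainder else 0)
        if k == 0:
            continue
        local = np.linspace(0, config.snps_per_chromosome - 1, num=k).round().astype(int)
        positions.append(c * config.snps_per_chromosome + np.unique(local))
    pos = np.concatenate(positions)
    effects = rng.standard_normal(len(pos))
    return pos, effects


def breeding_value(
    haplotype_pair: np.ndarray,
    qtl_positions: np.ndarray,
    qtl_effects: np.ndarray,
) -> float:
    """True additive breeding value: sum over QTL of dosage x effect.

    ``haplotype_pair`` is the (2, m) allele array of one animal; dosage at
    a QTL is the 0/1/2 count of the effect allele over both chromosomes.
    """
    if qtl_positions.max(initial=-1) >= haplotype_pair.shape[1]:
        raise IndexError("QTL position outside the SNP map")
    dosage = haplotype_pair[0, qtl_positions].astype(np.int64) + haplotype_pair[
        1, qtl_positions
    ].astype(np.int64)
    return float(dosage @ qtl_effects)


def _breeding_values(pop_haps: np.ndarray, qtl_pos: np.ndarray, effects: np.ndarray) -> np.ndarray:
    dosage = pop_haps[:, 0, :][:, qtl_pos].astype(np.int64) + pop_haps[:, 1, :][:, qtl_pos].astype(
        np.int64
    )
    return dosage @ effects


def meiosis(parent: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Produce one gamete from a (2, m) parental haplotype pair.

    Per chromosome: a Poisson(recombination_rate) number of crossovers at
    uniform positions, starting from a fair random parental phase.
    Crossovers never carry over a chromosome boundary.
    """
    if parent.shape[0] != 2:
        raise ValueError("parent must hold exactly 2 haplotypes")
    m = parent.shape[1]
    if m != config.n_snps:
        raise ValueError("parent haplotype length does not match the config")
    gamete = np.empty(m, dtype=parent.dtype)
    L = config.snps_per_chromosome
    for c in range(config.n_chromosomes):
        lo = c * L
        phase = _chromosome_phase(L, config.recombination_rate, rng)
        seg = parent[:, lo : lo + L]
        gamete[lo : lo + L] = np.where(phase == 0, seg[0], seg[1])
    return gamete


def _chromosome_phase(L: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """0/1 vector saying which parental haplotype each locus comes from."""
    start = int(rng.integers(2))
    k = int(rng.poisson(rate))
    if k == 0:
        return np.full(L, start, dtype=np.int8)
    cuts = np.sort(rng.integers(1, L, size=k))
    phase = np.full(L, start, dtype=np.int8)
    flip = np.zeros(L + 1, dtype=np.int8)
    np.add.at(flip, cuts, 1)
    phase = (start + np.cumsum(flip[:L])) % 2
    return phase.astype(np.int8)


def _sex_vector(n: int, sex_ratio: float) -> np.ndarray:
    n_males = round(n * (1.0 - sex_ratio))
    sex = np.full(n, FEMALE, dtype=np.int8)
    sex[:n_males] = MALE
    return sex


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None) -> PhasedPopulation:
    """Generate the founder generation from the per-chromosome haplotype pool.

    Each founder gamete is, chromosome by chromosome, a single-meiosis
    mosaic of two haplotypes drawn from the pool.  Half the founders are
    male, half female (per ``sex_ratio``).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m = config.n_founders, config.n_snps
    L = config.snps_per_chromosome
    P = config.founder_pool_size

    haps = np.empty((n, 2, m), dtype=np.uint8)
    for c in range(config.n_chromosomes):
        ancestral = rng.integers(0, 2, size=L, dtype=np.uint8)
        flips = rng.random((P, L)) < config.founder_flip_rate
        pool = np.bitwise_xor(ancestral[None, :], flips.astype(np.uint8))
        lo = c * L
        # each gamete: mosaic of two pool haplotypes, recombined once
        picks = rng.integers(0, P, size=(n, 2, 2))
        for j in range(n):
            for g in range(2):
                a, b = picks[j, g]
                phase = _chromosome_phase(L, config.recombination_rate, rng)
                haps[j, g, lo : lo + L] = np.where(phase == 0, pool[a], pool[b])

    qtl_pos, qtl_eff = _qtl_layout(config, rng)
    pop = PhasedPopulation(
        animal_ids=np.arange(n),
        haplotypes=haps,
        snp_chrom=_snp_chrom_map(config),
        sex=_sex_vector(n, config.sex_ratio),
        generation=np.zeros(n, dtype=np.int64),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
        qtl_positions=qtl_pos,
        qtl_effects=qtl_eff,
    )
    pop.breeding_values = _breeding_values(haps, qtl_pos, qtl_eff)
    return pop


def _select_sires(pop: PhasedPopulation, current_gen: int, n_sires: int) -> np.ndarray:
    """Indices of the top-n males of the current generation by breeding value.

    Ties are broken by smaller animal ID.
    """
    mask = (pop.generation == current_gen) & (pop.sex == MALE)
    idx = np.flatnonzero(mask)
    if len(idx) < n_sires:
        raise ValueError(f"need {n_sires} males in generation {current_gen}, found {len(idx)}")
    bv = pop.breeding_values[idx]
    order = np.lexsort((pop.animal_ids[idx], -bv))
    return idx[order[:n_sires]]


def advance_generation(
    pop: PhasedPopulation, config: SimConfig, rng: np.random.Generator
) -> PhasedPopulation:
    """Produce the next generation from the cumulative population.

    Sires are the ``n_sires`` males of the newest generation with the
    highest breeding values; dams are ``n_dams`` females of that
    generation.  Each offspring receives a uniformly drawn (sire, dam)
    pair and one recombinant gamete from each parent.  Returns the
    offspring as a new population (IDs continue from the parents').
    """
    current_gen = int(pop.generation.max())
    sire_idx = _select_sires(pop, current_gen, config.n_sires)
    dam_mask = (pop.generation == current_gen) & (pop.sex == FEMALE)
    dam_candidates = np.flatnonzero(dam_mask)
    if len(dam_candidates) < config.n_dams:
        raise ValueError(
            f"need {config.n_dams} females in generation {current_gen}, "
            f"found {len(dam_candidates)}"
        )
    dam_idx = dam_candidates[np.argsort(pop.animal_ids[dam_candidates])][: config.n_dams]

    n_off = config.offspring_per_gen
    chosen_sires = sire_idx[rng.integers(0, len(sire_idx), size=n_off)]
    chosen_dams = dam_idx[rng.integers(0, len(dam_idx), size=n_off)]

    haps = np.empty((n_off, 2, pop.n_snps), dtype=np.uint8)
    for j in range(n_off):
        haps[j, 0] = meiosis(pop.haplotypes[chosen_sires[j]], config, rng)
        haps[j, 1] = meiosis(pop.haplotypes[chosen_dams[j]], config, rng)

    next_id = int(pop.animal_ids.max()) + 1
    offspring = PhasedPopulation(
        animal_ids=np.arange(next_id, next_id + n_off),
        haplotypes=haps,
        snp_chrom=pop.snp_chrom,
        sex=_sex_vector(n_off, config.sex_ratio),
        generation=np.full(n_off, current_gen + 1, dtype=np.int64),
        sire=pop.animal_ids[chosen_sires],
        dam=pop.animal_ids[chosen_dams],
        qtl_positions=pop.qtl_positions,
        qtl_effects=pop.qtl_effects,
    )
    offspring.breeding_values = _breeding_values(haps, pop.qtl_positions, pop.qtl_effects)
    return offspring


def concat_populations(pops: list[PhasedPopulation]) -> PhasedPopulation:
    first = pops[0]
    return PhasedPopulation(
        animal_ids=np.concatenate([p.animal_ids for p in pops]),
        haplotypes=np.concatenate([p.haplotypes for p in pops]),
        snp_chrom=first.snp_chrom,
        sex=np.concatenate([p.sex for p in pops]),
        generation=np.concatenate([p.generation for p in pops]),
        sire=np.concatenate([p.sire for p in pops]),
        dam=np.concatenate([p.dam for p in pops]),
        breeding_values=np.concatenate([p.breeding_values for p in pops]),
        qtl_positions=first.qtl_positions,
        qtl_effects=first.qtl_effects,
    )


def simulate_population(config: SimConfig) -> PhasedPopulation:
    """Run the full scheme: founders plus ``n_generations`` of selection.

    Returns the cumulative population (founders and every later
    generation), so the total size is
    ``n_founders + n_generations * offspring_per_gen``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = [simulate_founders(config, rng)]
    for _ in range(config.n_generations):
        cumulative = concat_populations(pops) if len(pops) > 1 else pops[0]
        pops.append(advance_generation(cumulative, config, rng))
    return concat_populations(pops)


def genome_overrides(snps_per_chromosome: int) -> dict:
    """Config overrides for a reduced genome at constant map density.

    The full-scale design places 1,000 SNPs on a 1-Morgan chromosome;
    shrinking a chromosome to fewer SNPs scales its genetic length
    proportionally (1 Morgan per 1,000 SNPs), so the expected crossover
    count per haplotype block is unchanged and the block-level library
    composition is comparable across genome sizes.
    """
    return {
        "snps_per_chromosome": snps_per_chromosome,
        "recombination_rate": snps_per_chromosome / 1000.0,
    }


def simulate_scenario(scenario: int, seed: int, **overrides) -> PhasedPopulation:
    """Simulate one of the five standard scenarios (5/10/15/30/50 generations).

    Keyword overrides are applied to the default :class:`SimConfig`
    (e.g. ``snps_per_chromosome=200`` for a reduced genome).
    """
    if scenario not in SCENARIO_GENERATIONS:
        raise ValueError(f"scenario must be 1..5, got {scenario}")
    config = SimConfig(seed=seed, n_generations=SCENARIO_GENERATIONS[scenario])
    if overrides:
        config = replace(config, **overrides)
    return simulate_population(config)
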