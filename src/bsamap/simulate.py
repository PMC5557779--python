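"""Synthetic F2 bulk-sequencing experiments.

The generator mirrors the design the analysis assumes: two fully homozygous
inbred parents carrying opposite alleles at every SNP, an F2 population
derived from selfed F1s, a single fully penetrant dominant trait locus, and
equal-size phenotype bulks pool-sequenced at configurable mean depth.

Gametes are produced by a crossover process without interference: crossover
counts are Poisson with mean (genetic length)/100 and crossover positions
are uniform on the genetic map, which is linear in physical position.

All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import BASES, BaseDepths, ConfigurationError, DataError, SnpSite


@dataclass
class SimulationConfig:
    n_chromosomes: int = 3
    chrom_length_bp: int = 500_000_000
    n_snps_per_chrom: int = 200
    genetic_length_cm: float = 150.0
    causal_chrom: str = "1H"
    causal_pos_bp: int | None = None  # None -> middle SNP of causal_chrom
    n_f2: int = 723
    bulk_size: int = 50
    mean_depth_dom: float = 45.0
    mean_depth_rec: float = 41.0
    mean_depth_parents: tuple[float, float] = (16.0, 27.0)
    sequencing_error_rate: float = 0.001
    position_jitter_bp: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.n_snps_per_chrom < 1:
            raise ConfigurationError("need >= 1 chromosome and >= 1 SNP per chromosome")
        if not 0.0 <= self.sequencing_error_rate <= 1.0:
            raise ConfigurationError("sequencing_error_rate must be in [0, 1]")
        if min(self.mean_depth_dom, self.mean_depth_rec, *self.mean_depth_parents) <= 0:
            raise ConfigurationError("mean depths must be > 0")
        if self.genetic_length_cm < 0:
            raise ConfigurationError("genetic_length_cm must be >= 0")
        if self.n_f2 < 2 or self.bulk_size < 1:
            raise ConfigurationError("n_f2 must be >= 2 and bulk_size >= 1")

    @property
    def chrom_names(self) -> list[str]:
        return [f"{i + 1}H" for i in range(self.n_chromosomes)]


@dataclass
class F2Population:
    """Genotypes of every F2 plant at every SNP and at the trait locus.

    ``genotypes[chrom]`` has shape (n_f2, n_loci, 2) with 1 = dominant-parent
    (M) allele, 0 = recessive-parent (P) allele; the two slices along the
    last axis are the maternal and paternal gametes.
    """

    config: SimulationConfig
    snp_positions: dict[str, np.ndarray]
    genotypes: dict[str, np.ndarray]
    causal_chrom: str
    causal_index: int  # locus index of the trait locus on causal_chrom
    phenotypes: np.ndarray  # bool, True = dominant (black) phenotype

    @property
    def causal_pos_bp(self) -> int:
        return int(self.snp_positions[self.causal_chrom][self.causal_index])


def _snp_positions(config: SimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    n, length = config.n_snps_per_chrom, config.chrom_length_bp
    base = np.round(np.linspace(length / (n + 1), length * n / (n + 1), n)).astype(np.int64)
    positions = {}
    for chrom in config.chrom_names:
        pos = base.copy()
        if config.position_jitter_bp:
            pos = pos + rng.integers(
                -config.position_jitter_bp, config.position_jitter_bp + 1, size=n
            )
            pos = np.maximum.accumulate(np.clip(pos, 1, length))  # keep sorted
        positions[chrom] = pos
    return positions


def _gametes(
    map_cm: np.ndarray, n_gametes: int, total_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_gametes, n_loci) array of 0/1 parental origins along one chromosome."""
    n_loci = len(map_cm)
    out = np.empty((n_gametes, n_loci), dtype=np.int8)
    n_cross = rng.poisson(total_cm / 100.0, size=n_gametes)
    starts = rng.integers(0, 2, size=n_gametes)
    for g in range(n_gametes):
        if n_cross[g] == 0:
            out[g] = starts[g]
            continue
        xlocs = np.sort(rng.uniform(0.0, total_cm, size=n_cross[g]))
        switches = np.searchsorted(xlocs, map_cm, side="right")
        out[g] = (starts[g] + switches) % 2
    return out


def simulate_f2(config: SimulationConfig, rng: np.random.Generator | int | None = None) -> F2Population:
    """Simulate the F2 population's genotypes and phenotypes."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if config.causal_chrom not in config.chrom_names:
        raise ConfigurationError(
            f"causal_chrom {config.causal_chrom!r} not among {config.chrom_names}"
        )
    positions = _snp_positions(config, rng)

    # trait locus: snap to nearest SNP (default: middle SNP of the chromosome)
    cpos = positions[config.causal_chrom]
    if config.causal_pos_bp is None:
        causal_index = len(cpos) // 2
    else:
        causal_index = int(np.argmin(np.abs(cpos.astype(float) - config.causal_pos_bp)))

    genotypes: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names:
        map_cm = positions[chrom] / config.chrom_length_bp * config.genetic_length_cm
        gam = _gametes(map_cm, 2 * config.n_f2, config.genetic_length_cm, rng)
        genotypes[chrom] = np.stack(
            (gam[: config.n_f2], gam[config.n_f2 :]), axis=2
        )

    causal_geno = genotypes[config.causal_chrom][:, causal_index, :].sum(axis=1)
    phenotypes = causal_geno >= 1  # dominant trait: any M allele shows it
    return F2Population(
        config=config,
        snp_positions=positions,
        genotypes=genotypes,
        causal_chrom=config.causal_chrom,
        causal_index=causal_index,
        phenotypes=phenotypes,
    )


def make_bulks(
    population: F2Population,
    bulk_size: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample plants without replacement within each phenotype class.

    Returns (dominant-bulk indices, recessive-bulk indices).
    """
    config = population.config
    bulk_size = config.bulk_size if bulk_size is None else bulk_size
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    dom_pool = np.flatnonzero(population.phenotypes)
    rec_pool = np.flatnonzero(~population.phenotypes)
    for name, pool in (("dominant", dom_pool), ("recessive", rec_pool)):
        if len(pool) < bulk_size:
            raise DataError(
                f"{name} class has {len(pool)} plants < bulk_size {bulk_size}"
            )
    dom = np.sort(rng.choice(dom_pool, size=bulk_size, replace=False))
    rec = np.sort(rng.choice(rec_pool, size=bulk_size, replace=False))
    return dom, rec


def _read_probabilities(freq_m: float, m_idx: int, p_idx: int, error: float) -> np.ndarray:
    """Per-base read probabilities for a pool with M-allele frequency freq_m."""
    probs = np.full(4, 0.0)
    e_m = np.full(4, error / 3.0)
    e_m[m_idx] = 1.0 - error
    e_p = np.full(4, error / 3.0)
    e_p[p_idx] = 1.0 - error
    probs = freq_m * e_m + (1.0 - freq_m) * e_p
    return probs


def simulate_depths(
    population: F2Population,
    bulks: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator | int | None = None,
) -> list[SnpSite]:
    """Sequence both bulks and both parents over every SNP site.

    Per site and bulk: total depth ~ Poisson(mean depth); base counts
    multinomial with success probabilities set by the bulk's allele
    frequency (2 * bulk_size chromosomes) and the sequencing error rate,
    which redistributes reads uniformly over the other three bases.
    """
    config = population.config
    rng = np.random.default_rng(config.seed + 2 if rng is None else rng)
    dom_idx, rec_idx = bulks
    sites: list[SnpSite] = []
    for chrom in config.chrom_names:
        pos = population.snp_positions[chrom]
        geno = population.genotypes[chrom]
        freq_dom = geno[dom_idx].reshape(len(dom_idx), len(pos), 2).mean(axis=(0, 2))
        freq_rec = geno[rec_idx].reshape(len(rec_idx), len(pos), 2).mean(axis=(0, 2))
        # random distinct M/P bases per site
        base_pair = np.array(
            [rng.choice(4, size=2, replace=False) for _ in range(len(pos))]
        )
        dom_totals = rng.poisson(config.mean_depth_dom, size=len(pos))
        rec_totals = rng.poisson(config.mean_depth_rec, size=len(pos))
        p1_totals = rng.poisson(config.mean_depth_parents[0], size=len(pos))
        p2_totals = rng.poisson(config.mean_depth_parents[1], size=len(pos))
        for i in range(len(pos)):
            m_idx, p_idx = int(base_pair[i, 0]), int(base_pair[i, 1])
            err = config.sequencing_error_rate
            dom_counts = rng.multinomial(
                dom_totals[i], _read_probabilities(float(freq_dom[i]), m_idx, p_idx, err)
            )
            rec_counts = rng.multinomial(
                rec_totals[i], _read_probabilities(float(freq_rec[i]), m_idx, p_idx, err)
            )
            m_base, p_base = BASES[m_idx], BASES[p_idx]
            sites.append(
                SnpSite(
                    chrom=chrom,
                    pos=int(pos[i]),
                    ref=m_base,
                    alts=(p_base,),
                    parent1_allele=m_base,
                    parent2_allele=p_base,
                    bulk_dom=BaseDepths(*(int(x) for x in dom_counts)),
                    bulk_rec=BaseDepths(*(int(x) for x in rec_counts)),
                    parent1_depth=int(p1_totals[i]),
                    parent2_depth=int(p2_totals[i]),
                )
            )
    return sites


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    population: F2Population
    bulk_dom: np.ndarray
    bulk_rec: np.ndarray
    sites: list[SnpSite]

    @property
    def truth(self) -> dict:
        return {
            "causal_chrom": self.population.causal_chrom,
            "causal_pos_bp": self.population.causal_pos_bp,
            "seed": self.config.seed,
        }


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """End-to-end convenience: population -> bulks -> depth table."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    population = simulate_f2(config, rng)
    bulk_dom, bulk_rec = make_bulks(population, rng=rng)
    sites = simulate_depths(population, (bulk_dom, bulk_rec), rng=rng)
    return SimulatedDataset(
        config=config,
        population=population,
        bulk_dom=bulk_dom,
        bulk_rec=bulk_rec,
        sites=sites,
    )
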