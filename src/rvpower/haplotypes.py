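"""Synthetic genotype engine: haplotype pool and gene-replicate sampling.

A single large pool of binary haplotypes over a fixed region (default 200 kb)
is simulated once from a neutral coalescent with recombination and strong
recent population growth, calibrated so that 3 kb "genes" sampled from the
pool and paired into n = 1,000 diploid individuals carry on average roughly
33 non-monomorphic SNVs with a site-frequency spectrum dominated by
singletons and doubletons, as seen in deep-resequencing data of European
ancestry.  Gene replicates are then drawn by (i) choosing a uniformly random
3 kb window, (ii) drawing 2n haplotypes from the pool without replacement and
summing them pairwise into 0/1/2 genotypes, (iii) re-orienting each site to
count the sample minor allele and discarding monomorphic sites.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import msprime
import numpy as np

__all__ = [
    "HaplotypePool",
    "GeneReplicate",
    "DemographicParams",
    "EmptyGeneError",
    "simulate_haplotype_pool",
    "sample_gene_region",
    "pair_haplotypes",
    "sample_gene_replicate",
    "load_haplotype_pool",
    "save_haplotype_pool",
    "write_gene_vcf",
    "DEFAULT_GENE_LENGTH",
]

DEFAULT_GENE_LENGTH = 3_000.0
_POOL_MAGIC = "#haplotype-pool"


class EmptyGeneError(RuntimeError):
    """Raised when a sampled gene window has no polymorphic site."""


@dataclass(frozen=True)
class DemographicParams:
    """Single-population coalescent calibration of the haplotype pool.

    The defaults describe a population that grew exponentially from an
    ancestral effective size to a much larger present-day size — the
    growth is what pushes the site-frequency spectrum towards singletons.
    Rates are per base pair per generation.
    """

    effective_size: float = 300_000.0     # present-day N_e
    ancestral_size: float = 15_000.0      # N_e before the growth phase
    growth_duration: float = 350.0        # generations of exponential growth
    mutation_rate: float = 2.15e-8
    recombination_rate: float = 1.0e-8

    def __post_init__(self):
        for name in ("effective_size", "ancestral_size", "growth_duration",
                     "recombination_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be non-negative")

    @property
    def growth_rate(self) -> float:
        return np.log(self.effective_size / self.ancestral_size) \
            / self.growth_duration


@dataclass(frozen=True)
class HaplotypePool:
    """Binary haplotype matrix with physical site positions.

    ``haplotypes[h, s]`` is 1 where haplotype ``h`` carries the derived
    (pool-minor) allele at segregating site ``s``; ``positions`` are strictly
    increasing base-pair coordinates in ``[0, region_length)``.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    region_length: float
    provenance: str = "simulated"

    def __post_init__(self):
        hap = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        pos = np.asarray(self.positions, dtype=float)
        if hap.ndim != 2:
            raise ValueError("haplotypes must be a 2-d matrix")
        if pos.shape != (hap.shape[1],):
            raise ValueError("positions must match the number of sites")
        if not np.isin(hap, (0, 1)).all():
            raise ValueError("haplotypes must be binary")
        if pos.size and (np.any(np.diff(pos) <= 0) or pos[0] < 0
                         or pos[-1] >= self.region_length):
            raise ValueError("positions must be strictly increasing within "
                             "[0, region_length)")
        counts = hap.sum(axis=0)
        if np.any(counts == 0) or np.any(counts == hap.shape[0]):
            raise ValueError("every site must be segregating in the pool")
        object.__setattr__(self, "haplotypes", hap)
        object.__setattr__(self, "positions", pos)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


@dataclass(frozen=True)
class GeneReplicate:
    """Diploid genotypes (minor-allele counts) for one sampled gene."""

    genotypes: np.ndarray      # (n, k) int8 values in {0, 1, 2}
    mafs: np.ndarray           # (k,) minor-allele frequency, mac / (2n)
    macs: np.ndarray           # (k,) minor-allele count
    site_positions: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.genotypes)
        n2 = 2 * g.shape[0]
        if g.shape[1] == 0:
            raise ValueError("gene replicate must keep at least one site")
        if np.any(self.macs <= 0) or np.any(self.macs >= n2):
            raise ValueError("monomorphic site in gene replicate")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


def _rng_from(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_haplotype_pool(n_haplotypes: int = 10_000,
                            region_length: float = 200_000.0,
                            params: DemographicParams | None = None,
                            seed: int = 1) -> HaplotypePool:
    """Simulate the haplotype pool from the calibrated coalescent model.

    Deterministic given ``seed``.  With ``mutation_rate == 0`` the pool has
    zero segregating sites (and is returned with an empty site list).
    """
    if n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    params = params or DemographicParams()
    ss = np.random.SeedSequence(seed)
    anc_seed, mut_seed = (int(s) for s in
                          ss.generate_state(2, dtype=np.uint32) % (2**31 - 1) + 1)
    demography = msprime.Demography()
    demography.add_population(name="pop",
                              initial_size=params.effective_size,
                              growth_rate=params.growth_rate)
    demography.add_population_parameters_change(
        time=params.growth_duration, population="pop",
        initial_size=params.ancestral_size, growth_rate=0.0)
    ts = msprime.sim_ancestry(
        samples=n_haplotypes, ploidy=1, demography=demography,
        sequence_length=region_length,
        recombination_rate=params.recombination_rate,
        discrete_genome=False, random_seed=anc_seed)
    ts = msprime.sim_mutations(ts, rate=params.mutation_rate,
                               discrete_genome=False, random_seed=mut_seed)
    hap = ts.genotype_matrix().T.astype(np.uint8)
    pos = ts.sites_position.astype(float)
    # infinite-sites continuous coordinates are already strictly increasing
    return HaplotypePool(haplotypes=hap, positions=pos,
                         region_length=float(region_length),
                         provenance="simulated")


def sample_gene_region(pool: HaplotypePool, gene_length: float = DEFAULT_GENE_LENGTH,
                       seed=None, start: float | None = None) -> np.ndarray:
    """Site indices of a uniformly placed half-open window [s, s + L).

    ``start`` pins the window instead of drawing it (must leave the window
    inside the region).
    """
    if gene_length > pool.region_length:
        raise ValueError("gene_length exceeds the pool region")
    if start is None:
        rng = _rng_from(seed)
        start = rng.uniform(0.0, pool.region_length - gene_length)
    elif not 0.0 <= start <= pool.region_length - gene_length:
        raise ValueError("window start leaves the region")
    lo = np.searchsorted(pool.positions, start, side="left")
    hi = np.searchsorted(pool.positions, start + gene_length, side="left")
    return np.arange(lo, hi)


def pair_haplotypes(pool: HaplotypePool, window: np.ndarray,
                    n_individuals: int, seed=None) -> GeneReplicate:
    """Pair randomly drawn haplotypes into diploid genotypes for one gene.

    Draws ``2 * n_individuals`` haplotypes without replacement, sums them
    pairwise, re-orients each site so the counted allele is the sample minor
    allele, and drops sites monomorphic in the sample.

    Raises
    ------
    EmptyGeneError
        if no polymorphic site remains (caller resamples the window).
    """
    n2 = 2 * n_individuals
    if n2 > pool.n_haplotypes:
        raise ValueError("not enough haplotypes to pair without replacement")
    rng = _rng_from(seed)
    chosen = rng.choice(pool.n_haplotypes, size=n2, replace=False)
    window = np.asarray(window, dtype=np.intp)
    if window.size == 0:
        raise EmptyGeneError("window contains no pool sites")
    sub = pool.haplotypes[chosen][:, window]
    geno = (sub[0::2, :] + sub[1::2, :]).astype(np.int8)
    counts = sub.sum(axis=0, dtype=np.int64)
    flip = counts * 2 > n2
    if np.any(flip):
        geno[:, flip] = 2 - geno[:, flip]
        counts[flip] = n2 - counts[flip]
    keep = counts > 0
    if not np.any(keep):
        raise EmptyGeneError("all sites monomorphic after pairing")
    macs = counts[keep]
    return GeneReplicate(genotypes=np.ascontiguousarray(geno[:, keep]),
                         mafs=macs / n2, macs=macs,
                         site_positions=pool.positions[window[keep]])


def sample_gene_replicate(pool: HaplotypePool, n_individuals: int,
                          gene_length: float = DEFAULT_GENE_LENGTH,
                          seed=None, max_attempts: int = 100,
                          ) -> tuple[GeneReplicate, int]:
    """Sample a window and pair haplotypes, resampling empty genes.

    Returns the replicate and the number of resampling attempts that were
    needed (0 when the first window was polymorphic).
    """
    rng = _rng_from(seed)
    for attempt in range(max_attempts):
        window = sample_gene_region(pool, gene_length, rng)
        try:
            return pair_haplotypes(pool, window, n_individuals, rng), attempt
        except EmptyGeneError:
            continue
    raise EmptyGeneError(f"no polymorphic gene in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# pool persistence and VCF export


def save_haplotype_pool(pool: HaplotypePool, path) -> None:
    """Write a pool as plain text (gzip if the suffix is ``.gz``).

    Format: a header line ``#haplotype-pool H S region_length``, one line of
    space-separated positions, then H lines of S adjacent 0/1 characters.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(f"{_POOL_MAGIC} {pool.n_haplotypes} {pool.n_sites} "
                 f"{pool.region_length!r}\n")
        fh.write(" ".join(repr(float(p)) for p in pool.positions) + "\n")
        for row in pool.haplotypes:
            fh.write(row.tobytes().translate(_BYTES_TO_ASCII).decode() + "\n")


_BYTES_TO_ASCII = bytes.maketrans(bytes([0, 1]), b"01")


def load_haplotype_pool(path) -> HaplotypePool:
    """Read a pool written by :func:`save_haplotype_pool` (or compatible)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().split()
        if len(header) != 4 or header[0] != _POOL_MAGIC:
            raise ValueError("not a haplotype-pool file")
        n_hap, n_sites = int(header[1]), int(header[2])
        region_length = float(header[3])
        positions = np.array(fh.readline().split(), dtype=float) \
            if n_sites else np.empty(0)
        if positions.size != n_sites:
            raise ValueError("positions row does not match the header")
        hap = np.empty((n_hap, n_sites), dtype=np.uint8)
        for i in range(n_hap):
            line = fh.readline().strip()
            if len(line) != n_sites:
                raise ValueError(f"haplotype row {i} has wrong length")
            row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            if np.any(row > 1):
                raise ValueError(f"non-binary entry in haplotype row {i}")
            hap[i] = row
    return HaplotypePool(haplotypes=hap, positions=positions,
                         region_length=region_length, provenance="loaded")


def write_gene_vcf(gene: GeneReplicate, path, chrom: str = "1",
                   sample_prefix: str = "S") -> None:
    """Export a gene replicate as a minimal diploid VCF (GT only)."""
    n = gene.n_individuals
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j in range(gene.n_sites):
            pos = int(np.floor(gene.site_positions[j])) + 1  # 1-based
            row = gt_strings[gene.genotypes[:, j]]
            fh.write(f"{chrom}\t{pos}\tsnv{j}\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(row) + "\n")
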