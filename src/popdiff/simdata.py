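"""Synthetic SNP-panel generator with known ground truth.

Emulates a diverse panel of inbred diploid lines: K subpopulations of
accessions genotyped at tens of thousands of biallelic SNPs on ~10
chromosomes, with low residual heterozygosity (~0.05), moderate missingness,
linkage disequilibrium extending a few tens of kilobases, optional planted
highly differentiated genomic regions, and an optional quantitative trait
driven by planted QTNs.

Model
-----
* Subpopulation allele frequencies follow the Balding–Nichols model: for a
  SNP with ancestral frequency :math:`p` and drift parameter
  :math:`\\theta \\in (0,1)`, each subpopulation draws its frequency from
  ``Beta(p(1-θ)/θ, (1-p)(1-θ)/θ)`` — mean :math:`p`, variance
  :math:`\\theta p(1-p)`.  Larger θ yields stronger differentiation.
* LD arises from haplotype blocks: SNPs within a block of ``ld_block_bp``
  consecutive base pairs share one ancestral frequency draw, and within each
  block the two haplotypes of an individual are sampled comonotonically (one
  latent uniform per haplotype per block), so alleles of SNPs sharing a
  block are strongly correlated while blocks are mutually independent.
* Inbreeding: with probability F, an individual's two haplotypes within a
  block are identical (block autozygosity), collapsing every genotype in the
  block to a homozygote and giving an expected heterozygosity of
  :math:`2p(1-p)(1-F)` per locus while preserving the block LD structure.
* Phenotype: sum of QTN dosage effects plus Gaussian noise scaled so the
  genetic variance fraction equals the requested heritability.

All randomness descends from a single integer seed through
``numpy.random.SeedSequence`` spawning, so each stage is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, make_snp_map

__all__ = [
    "PlantedRegion",
    "Qtn",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_subpop_frequencies",
    "simulate_snp_map",
    "plant_differentiated_regions",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_panel",
    "delta_for_target_dest",
]


@dataclass(frozen=True)
class PlantedRegion:
    """A genomic interval whose SNPs are pushed apart between two subpopulations.

    Coordinates are 1-based inclusive base pairs.  ``target_dest`` is the
    population-level Jost's D the frequency shift should produce between the
    two named subpopulations.
    """

    chrom: str
    start_bp: int
    end_bp: int
    subpop_pair: tuple
    target_dest: float = 0.5


@dataclass(frozen=True)
class Qtn:
    """A causal SNP (by index into the simulated SNP set) with additive effect."""

    snp_index: int
    effect: float


@dataclass
class SimulationConfig:
    """Study-condition knobs for one simulated panel.

    Defaults mirror a diverse inbred maize chip panel: 10 chromosomes, 10,000
    SNPs, three subpopulations of 100 lines, drift producing pairwise Jost's D
    in the 0.05–0.31 range, genotype-level inbreeding F = 0.9 (heterozygosity
    ≈ 0.05 at intermediate frequencies), 5% missing calls, and 30-kb LD
    blocks.  Chromosomes are compressed to 1.2 Mb so that 2×LD windows hold
    enough SNPs for stable window means at desk scale.
    """

    n_subpops: int = 3
    sizes: tuple = (100, 100, 100)
    n_snps: int = 10_000
    n_chromosomes: int = 10
    chrom_length_bp: int = 1_200_000
    differentiation: float = 0.15
    inbreeding_coefficient: float = 0.9
    missing_rate: float = 0.05
    maf_floor: float = 0.05
    ld_block_bp: int = 30_000
    planted_regions: list = field(default_factory=list)
    qtns: list = field(default_factory=list)
    heritability: float = 0.5
    n_admixed: int = 0
    admix_pair: tuple | None = None
    admix_proportion: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_subpops < 1 or len(self.sizes) != self.n_subpops:
            raise ValueError("sizes must list one count per subpopulation")
        if any(s < 2 for s in self.sizes):
            raise ValueError("each subpopulation needs at least 2 accessions")
        if not (0.0 < self.differentiation < 1.0):
            raise ValueError("differentiation must lie in (0, 1)")
        if not (0.0 <= self.inbreeding_coefficient <= 1.0):
            raise ValueError("inbreeding_coefficient must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 < self.heritability <= 1.0):
            raise ValueError("heritability must lie in (0, 1]")
        if self.n_snps < 1 or self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ValueError("panel dimensions must be positive")
        if not (0.0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must lie in [0, 0.5)")
        for r in self.planted_regions:
            if not (1 <= r.start_bp <= r.end_bp <= self.chrom_length_bp):
                raise ValueError(f"planted region {r} outside chromosome bounds")
            if not (0.0 < r.target_dest <= 1.0):
                raise ValueError("target_dest must lie in (0, 1]")
        for q in self.qtns:
            if not (0 <= q.snp_index < self.n_snps):
                raise ValueError("QTN index outside SNP range")

    @property
    def subpop_labels(self):
        return [f"P{k + 1}" for k in range(self.n_subpops)]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated panel, for recovery testing."""

    ancestral_freqs: np.ndarray
    subpop_freqs: pd.DataFrame  # subpop label x snp_id
    true_assignment: pd.Series  # accession -> subpop label
    planted_region_coords: list
    qtn_effects: list


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_subpop_frequencies(ancestral_freqs, differentiation, n_subpops, seed,
                                labels=None, snp_ids=None) -> pd.DataFrame:
    """Draw per-subpopulation allele frequencies under Balding–Nichols drift.

    Each entry is ``Beta(p(1-θ)/θ, (1-p)(1-θ)/θ)`` with ``p`` the ancestral
    frequency and ``θ`` the drift parameter; mean ``p``, variance ``θp(1-p)``.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if not (0.0 < differentiation < 1.0):
        raise ValueError("differentiation must lie in (0, 1)")
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    rng = _as_rng(seed)
    scale = (1.0 - differentiation) / differentiation
    a = p * scale
    b = (1.0 - p) * scale
    draws = rng.beta(a, b, size=(n_subpops, p.size))
    labels = labels or [f"P{k + 1}" for k in range(n_subpops)]
    cols = snp_ids if snp_ids is not None else np.arange(p.size)
    return pd.DataFrame(draws, index=labels, columns=cols)


def simulate_snp_map(config: SimulationConfig, rng) -> pd.DataFrame:
    """Uniformly place SNPs along equal-length chromosomes (sorted, unique positions)."""
    rng = _as_rng(rng)
    per_chrom = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    per_chrom[: config.n_snps % config.n_chromosomes] += 1
    snp_ids, chroms, positions = [], [], []
    for c in range(config.n_chromosomes):
        m = int(per_chrom[c])
        pos = np.sort(rng.choice(config.chrom_length_bp, size=m, replace=False)) + 1
        chrom = f"chr{c + 1}"
        for i, pbp in enumerate(pos):
            snp_ids.append(f"{chrom}_s{i + 1}")
            chroms.append(chrom)
            positions.append(int(pbp))
    return make_snp_map(snp_ids, chroms, positions, ["A"] * len(snp_ids), ["G"] * len(snp_ids))


def ld_block_ids(snp_map: pd.DataFrame, chrom_length_bp: int, ld_block_bp: int) -> np.ndarray:
    """Consecutive 0-based LD-block index per SNP (blocks tile each chromosome)."""
    chrom_codes = pd.factorize(snp_map["chrom"])[0]
    blocks_per_chrom = chrom_length_bp // ld_block_bp + 1
    raw = chrom_codes * blocks_per_chrom + (snp_map["pos"].values - 1) // ld_block_bp
    _, inverse = np.unique(raw, return_inverse=True)
    return inverse


def delta_for_target_dest(target_d: float) -> float:
    """Half-spacing δ around 0.5 such that p = 0.5±δ in two subpops gives
    population-level Jost's D equal to ``target_d`` (δ = sqrt(D/(8-4D)))."""
    if not (0.0 < target_d <= 1.0):
        raise ValueError("target D must lie in (0, 1]")
    return math.sqrt(target_d / (8.0 - 4.0 * target_d))


def plant_differentiated_regions(subpop_freqs: pd.DataFrame, snp_map: pd.DataFrame,
                                 planted_regions) -> pd.DataFrame:
    """Shift allele frequencies inside each planted region between its subpop pair.

    SNPs inside a region get frequencies 0.5+δ and 0.5−δ in the two named
    subpopulations, with δ solving the population-level Jost's D target;
    other subpopulations and SNPs outside regions are untouched.  A region
    containing no SNP raises ``ValueError``.
    """
    out = subpop_freqs.copy()
    smap = snp_map.set_index("snp_id")
    for region in planted_regions:
        in_region = (
            (smap["chrom"] == region.chrom)
            & (smap["pos"] >= region.start_bp)
            & (smap["pos"] <= region.end_bp)
        )
        ids = smap.index[in_region]
        if len(ids) == 0:
            raise ValueError(f"planted region {region} contains no SNP")
        a, b = region.subpop_pair
        delta = delta_for_target_dest(region.target_dest)
        out.loc[a, ids] = 0.5 + delta
        out.loc[b, ids] = 0.5 - delta
    return out


def _sample_block_haplotypes(rng, freqs_per_snp, n_ind, block_of_snp, n_blocks,
                             inbreeding=0.0):
    """Sample (n_ind, n_snps) dosages with block-comonotone haplotypes.

    ``inbreeding`` is the per-(individual, block) autozygosity probability:
    the second haplotype's latent uniform is copied from the first, making
    every genotype in the block homozygous.
    """
    u = rng.random((n_ind, n_blocks, 2))
    if inbreeding > 0:
        az = rng.random((n_ind, n_blocks)) < inbreeding
        u[:, :, 1] = np.where(az, u[:, :, 0], u[:, :, 1])
    hap = u[:, block_of_snp, :] < freqs_per_snp[None, :, None]
    return hap.sum(axis=2).astype(np.int8)


def simulate_genotypes(subpop_freqs: pd.DataFrame, config: SimulationConfig,
                       snp_map: pd.DataFrame | None = None, seed=None):
    """Sample a diploid genotype panel from subpopulation frequencies.

    Returns ``(GenotypeMatrix, snp_map, SimulationTruth)``.  Haplotypes share
    latent draws within ``ld_block_bp`` blocks (inducing LD), genotypes are
    collapsed to homozygotes with probability ``inbreeding_coefficient``, and
    entries are masked missing at ``missing_rate``.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed).spawn(4)
    rng_map, rng_geno, rng_miss, rng_adx = (np.random.default_rng(s) for s in ss)

    if snp_map is None:
        snp_map = simulate_snp_map(config, rng_map)
    freqs = subpop_freqs.reindex(columns=snp_map["snp_id"])
    if freqs.isna().any().any():
        raise ValueError("subpop_freqs missing entries for SNPs in the map")

    block_of_snp = ld_block_ids(snp_map, config.chrom_length_bp, config.ld_block_bp)
    n_blocks = int(block_of_snp.max()) + 1

    labels = list(subpop_freqs.index)
    rows, accession_ids, assignment = [], [], []
    for k, label in enumerate(labels):
        n_k = config.sizes[k]
        rows.append(
            _sample_block_haplotypes(
                rng_geno, freqs.loc[label].values, n_k, block_of_snp, n_blocks,
                inbreeding=config.inbreeding_coefficient,
            )
        )
        accession_ids.extend(f"{label}_{i + 1:03d}" for i in range(n_k))
        assignment.extend([label] * n_k)

    if config.n_admixed > 0:
        pair = config.admix_pair or (labels[0], labels[1])
        pa = freqs.loc[pair[0]].values
        pb = freqs.loc[pair[1]].values
        n_a = config.n_admixed
        src = rng_adx.random((n_a, n_blocks, 2)) < config.admix_proportion
        u = rng_adx.random((n_a, n_blocks, 2))
        if config.inbreeding_coefficient > 0:
            az = rng_adx.random((n_a, n_blocks)) < config.inbreeding_coefficient
            u[:, :, 1] = np.where(az, u[:, :, 0], u[:, :, 1])
            src[:, :, 1] = np.where(az, src[:, :, 0], src[:, :, 1])
        p_eff = np.where(src[:, block_of_snp, :], pa[None, :, None], pb[None, :, None])
        hap = u[:, block_of_snp, :] < p_eff
        rows.append(hap.sum(axis=2).astype(np.int8))
        accession_ids.extend(f"ADX_{i + 1:03d}" for i in range(n_a))
        assignment.extend(["ADX"] * n_a)

    dosage = np.vstack(rows)
    mask = rng_miss.random(dosage.shape) < config.missing_rate

    gm = GenotypeMatrix(accession_ids, list(snp_map["snp_id"]), dosage, mask)
    truth = SimulationTruth(
        ancestral_freqs=np.full(gm.n_snps, np.nan),
        subpop_freqs=freqs,
        true_assignment=pd.Series(assignment, index=accession_ids, name="subpop"),
        planted_region_coords=list(config.planted_regions),
        qtn_effects=list(config.qtns),
    )
    return gm, snp_map, truth


def simulate_phenotype(genotypes: GenotypeMatrix, qtns, heritability, seed) -> pd.Series:
    """Additive QTN phenotype with noise scaled to the requested heritability.

    ``y_i = Σ_q dosage_iq · effect_q + ε_i`` with ``Var(ε)`` chosen so the
    genetic variance fraction equals ``heritability`` (missing dosages are
    mean-imputed).  ``heritability = 1`` gives the noiseless limit.
    """
    if not (0.0 < heritability <= 1.0):
        raise ValueError("heritability must lie in (0, 1]")
    rng = _as_rng(seed)
    d = genotypes.dosage_float()
    g = np.zeros(genotypes.n_accessions)
    for q in qtns:
        col = d[:, q.snp_index]
        col = np.where(np.isnan(col), np.nanmean(col), col)
        g += q.effect * col
    var_g = float(np.var(g))
    if var_g == 0.0:
        if qtns and heritability > 0:
            raise ValueError("zero genetic variance: QTNs are monomorphic or absent")
        noise_sd = 1.0
    elif heritability == 1.0:
        noise_sd = 0.0
    else:
        noise_sd = math.sqrt(var_g * (1.0 - heritability) / heritability)
    y = g + rng.normal(0.0, noise_sd, size=g.size) if noise_sd > 0 else g.copy()
    return pd.Series(y, index=genotypes.accession_ids, name="trait")


def simulate_panel(config: SimulationConfig):
    """Full pipeline input from one config: panel, map, truth, phenotype.

    Returns ``(GenotypeMatrix, snp_map, SimulationTruth, phenotype)`` where
    the phenotype is ``None`` when no QTNs are configured.
    """
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_anc, rng_freq, rng_map, rng_phen = (np.random.default_rng(s) for s in ss)

    snp_map = simulate_snp_map(config, rng_map)
    # one ancestral frequency per LD block: SNPs on a shared haplotype block
    # descend from the same ancestral segment
    blocks = ld_block_ids(snp_map, config.chrom_length_bp, config.ld_block_bp)
    lo = max(config.maf_floor, 1e-3)
    anc_block = rng_anc.uniform(lo, 1.0 - lo, size=int(blocks.max()) + 1)
    ancestral = anc_block[blocks]
    freqs = simulate_subpop_frequencies(
        ancestral,
        config.differentiation,
        config.n_subpops,
        rng_freq,
        labels=config.subpop_labels,
        snp_ids=list(snp_map["snp_id"]),
    )
    if config.planted_regions:
        freqs = plant_differentiated_regions(freqs, snp_map, config.planted_regions)
    gm, snp_map, truth = simulate_genotypes(freqs, config, snp_map=snp_map, seed=config.seed)
    truth.ancestral_freqs = ancestral
    phenotype = None
    if config.qtns:
        phenotype = simulate_phenotype(gm, config.qtns, config.heritability, rng_phen)
    return gm, snp_map, truth, phenotype
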