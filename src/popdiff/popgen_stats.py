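"""Per-locus and per-pair population-genetic statistics.

Gene diversity (GD), polymorphism information content (PIC), per-accession
heterozygosity, identity-by-state (IBS) distance, background-centered IBS
kinship, and LD r² with a decay profile.

Conventions
-----------
* GD at locus *l*: :math:`1 - \\sum_u p_{lu}^2` — the probability two alleles
  drawn at random from the sample differ.
* PIC at locus *l*: :math:`1 - \\sum_u p_{lu}^2 - \\sum_{u<v} 2 p_{lu}^2 p_{lv}^2`.
* Per-locus IBS between two diploid genotypes is the probability a random
  allele from each matches: identical homozygotes 1, opposite homozygotes 0,
  any pair involving a heterozygote 0.5 (het–het included).
* Kinship: :math:`F_{ij} = (Q_{ij} - Q_m)/(1 - Q_m)` with :math:`Q_{ij}` the
  mean pairwise IBS and :math:`Q_m` the mean over off-diagonal pairs.
  Negative values are clamped to 0 for reporting; raw values are retained for
  the mixed model.
* LD r² is the squared Pearson correlation between dosage vectors over
  jointly non-missing accessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "locus_allele_frequencies",
    "gene_diversity",
    "pic",
    "heterozygosity",
    "diversity_summary",
    "ibs_matrix",
    "ibs_distance_matrix",
    "KinshipMatrix",
    "kinship_matrix",
    "ld_r2",
    "pairwise_r2",
    "LdDecayProfile",
    "ld_decay",
]


def locus_allele_frequencies(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Biallelic allele-frequency table: columns ``p_ref``, ``p_alt``, ``n_called``."""
    p = genotypes.allele_frequency()
    return pd.DataFrame(
        {"p_ref": 1.0 - p, "p_alt": p, "n_called": genotypes.n_called()},
        index=genotypes.snp_ids,
    )


def _freq_array(freqs):
    f = np.asarray(freqs, dtype=float)
    if f.ndim == 1:
        f = f[None, :]
    return f


def gene_diversity(freqs):
    """GD = 1 − Σ p²  for one locus (1-D allele-frequency vector) or many (2-D)."""
    f = _freq_array(freqs)
    out = 1.0 - np.sum(f**2, axis=1)
    return float(out[0]) if np.asarray(freqs).ndim == 1 else out


def pic(freqs):
    """PIC = 1 − Σ p² − Σ_{u<v} 2 p_u² p_v²  (≤ GD at every locus).

    The double sum is evaluated as ``(Σp²)² − Σp⁴``.
    """
    f = _freq_array(freqs)
    s2 = np.sum(f**2, axis=1)
    s4 = np.sum(f**4, axis=1)
    out = 1.0 - s2 - (s2**2 - s4)
    return float(out[0]) if np.asarray(freqs).ndim == 1 else out


def heterozygosity(genotypes: GenotypeMatrix) -> pd.Series:
    """Fraction of non-missing loci called heterozygous, per accession.

    Accessions with all loci missing get NaN (reported, excluded from group
    means by callers).
    """
    called = (~genotypes.missing_mask).sum(axis=1).astype(float)
    het = ((genotypes.dosage == 1) & ~genotypes.missing_mask).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(called > 0, het / called, np.nan)
    return pd.Series(frac, index=genotypes.accession_ids, name="heterozygosity")


def diversity_summary(genotypes: GenotypeMatrix, assignment: pd.Series | None = None) -> pd.DataFrame:
    """Diversity table: mean GD, PIC and heterozygosity, overall and per group.

    GD and PIC are computed per locus from each group's allele frequencies and
    averaged across polymorphic-and-monomorphic loci alike (loci with no call
    in a group are excluded for that group).
    """
    groups = {"Total": np.arange(genotypes.n_accessions)}
    if assignment is not None:
        assignment = assignment.reindex(genotypes.accession_ids)
        for label in assignment.dropna().unique():
            groups[str(label)] = np.flatnonzero((assignment == label).values)
    rows = []
    for label, idx in groups.items():
        sub = genotypes.take_accessions(idx)
        p = sub.allele_frequency()
        ok = ~np.isnan(p)
        f = np.column_stack([1.0 - p[ok], p[ok]])
        het = heterozygosity(sub)
        rows.append(
            {
                "group": label,
                "n_accessions": len(idx),
                "gene_diversity": float(np.mean(gene_diversity(f))),
                "pic": float(np.mean(pic(f))),
                "heterozygosity": float(het.mean(skipna=True)),
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# IBS / kinship
# ---------------------------------------------------------------------------

def ibs_matrix(genotypes: GenotypeMatrix, skip_heterozygotes: bool = False) -> pd.DataFrame:
    """Pairwise IBS averaged over jointly non-missing loci.

    Per-locus IBS uses the random-allele-draw rule, which in dosage terms is
    ``x_i x_j + (1-x_i)(1-x_j)`` with ``x = dosage/2``.  Pairs with zero
    jointly called loci get NaN (flagged with a warning).

    ``skip_heterozygotes`` restricts each pair's average to loci where both
    genotypes are homozygous (the convention of some toolkits); the default
    random-draw rule scores heterozygote-involving loci 0.5 instead.
    """
    excluded = genotypes.missing_mask
    if skip_heterozygotes:
        excluded = excluded | (genotypes.dosage == 1)
    m = (~excluded).astype(np.float64)
    x = np.where(excluded, 0.0, genotypes.dosage / 2.0)
    xc = np.where(excluded, 0.0, 1.0 - genotypes.dosage / 2.0)
    s = x @ x.T + xc @ xc.T
    n = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n > 0, s / n, np.nan)
    if np.isnan(q).any():
        warnings.warn("some accession pairs share no called loci; IBS undefined there")
    return pd.DataFrame(q, index=genotypes.accession_ids, columns=genotypes.accession_ids)


def ibs_distance_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Genetic distance D = 1 − IBS similarity (symmetric, in [0, 1])."""
    return 1.0 - ibs_matrix(genotypes)


@dataclass
class KinshipMatrix:
    """Background-centered IBS kinship.

    ``values`` clamps negatives to 0 (reporting convention); ``raw`` keeps the
    untruncated transform for the mixed model.
    """

    accession_ids: list
    raw: np.ndarray
    q_m: float

    @property
    def values(self) -> np.ndarray:
        return np.maximum(self.raw, 0.0)

    def to_frame(self, clamped: bool = True) -> pd.DataFrame:
        v = self.values if clamped else self.raw
        return pd.DataFrame(v, index=self.accession_ids, columns=self.accession_ids)


def kinship_matrix(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """F_ij = (Q_ij − Q_m)/(1 − Q_m), Q_m the mean off-diagonal pairwise IBS."""
    if genotypes.n_accessions < 2:
        raise ValueError("kinship needs at least two accessions")
    q = ibs_matrix(genotypes).values
    off = ~np.eye(q.shape[0], dtype=bool)
    q_m = float(np.nanmean(q[off]))
    if q_m >= 1.0:
        raise ValueError("degenerate panel: all accessions identical (Q_m = 1)")
    f = (q - q_m) / (1.0 - q_m)
    return KinshipMatrix(list(genotypes.accession_ids), f, q_m)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(snp_a, snp_b) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly non-missing
    accessions (NaN inputs are missing).  Returns NaN when either SNP has zero
    variance on the joint set or fewer than two joint calls."""
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def pairwise_r2(genotypes: GenotypeMatrix, cols=None) -> np.ndarray:
    """All-pairs r² with exact pairwise-complete handling of missing calls.

    Implemented with masked matrix products: for each pair, the Pearson
    correlation over jointly called accessions.  Zero-variance pairs are NaN.
    """
    if cols is not None:
        genotypes = genotypes.take_snps(cols)
    m = (~genotypes.missing_mask).astype(np.float64)
    z = np.where(genotypes.missing_mask, 0.0, genotypes.dosage.astype(np.float64))
    z2 = z * z
    n = m.T @ m
    sx = z.T @ m          # sum of x over jointly-called, per (x_snp, y_snp)
    sy = sx.T
    sxy = z.T @ z
    sxx = z2.T @ m
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(varx <= 0) | (vary <= 0) | (n < 2)] = np.nan
    return r2


@dataclass
class LdDecayProfile:
    """Binned mean r² vs physical distance and the distance where it crosses
    ``threshold`` (linear interpolation, anchored at (0 bp, r² = 1))."""

    label: str
    bins: pd.DataFrame  # bin_start, bin_end, mean_r2, n_pairs
    decay_distance: float
    threshold: float


def _decay_distance(bins: pd.DataFrame, threshold: float) -> float:
    pts = [(0.0, 1.0)]
    for _, row in bins.iterrows():
        if row["n_pairs"] > 0:
            pts.append(((row["bin_start"] + row["bin_end"]) / 2.0, row["mean_r2"]))
    for (d0, r0), (d1, r1) in zip(pts[:-1], pts[1:]):
        if r0 >= threshold > r1:
            return d0 + (r0 - threshold) / (r0 - r1) * (d1 - d0)
    if pts and pts[0][1] < threshold:
        return 0.0
    return float("nan")  # never decays below threshold within max_dist


def ld_decay(genotypes: GenotypeMatrix, snp_map: pd.DataFrame, max_dist: int = 200_000,
             bin_width: int = 5_000, threshold: float = 0.1):
    """LD decay profiles per chromosome and genome-wide.

    All intra-chromosomal SNP pairs within ``max_dist`` are binned by physical
    distance; the decay distance is where binned mean r² first falls below
    ``threshold``.  Returns ``(per_chromosome: dict, genome: LdDecayProfile)``.
    """
    smap = snp_map.set_index("snp_id").loc[genotypes.snp_ids]
    snp_pos = {s: i for i, s in enumerate(genotypes.snp_ids)}
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = len(edges) - 1
    per_chrom = {}
    tot_sum = np.zeros(n_bins)
    tot_n = np.zeros(n_bins)
    for chrom, grp in smap.groupby("chrom", sort=False):
        if len(grp) < 2:
            warnings.warn(f"chromosome {chrom} has < 2 SNPs; skipped in LD decay")
            continue
        idx = [snp_pos[s] for s in grp.index]
        order = np.argsort(grp["pos"].values, kind="stable")
        idx = np.asarray(idx)[order]
        pos = grp["pos"].values[order]
        r2 = pairwise_r2(genotypes, cols=idx)
        dist = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(len(pos), k=1)
        d, v = dist[iu], r2[iu]
        ok = (d <= max_dist) & ~np.isnan(v)
        d, v = d[ok], v[ok]
        which = np.clip(((d - 1) // bin_width).astype(int), 0, n_bins - 1)
        ssum = np.bincount(which, weights=v, minlength=n_bins)
        cnt = np.bincount(which, minlength=n_bins)
        tot_sum += ssum
        tot_n += cnt
        bins = _bin_frame(edges, ssum, cnt)
        per_chrom[chrom] = LdDecayProfile(chrom, bins, _decay_distance(bins, threshold), threshold)
    genome_bins = _bin_frame(edges, tot_sum, tot_n)
    genome = LdDecayProfile("genome", genome_bins, _decay_distance(genome_bins, threshold), threshold)
    return per_chrom, genome


def _bin_frame(edges, ssum, cnt) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, ssum / np.maximum(cnt, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "mean_r2": mean,
            "n_pairs": cnt.astype(int),
        }
    )
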