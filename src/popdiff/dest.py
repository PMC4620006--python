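"""Jost's D_EST differentiation statistics and the windowed genome scan.

For a set of *n* subpopulations, per-locus Jost's D is estimated as

.. math::

    D = \\frac{H_T - H_S}{1 - H_S} \\cdot \\frac{n}{n-1}

with :math:`H_S` the mean within-subpopulation gene diversity (small-sample
corrected by the factor :math:`\\tilde n/(\\tilde n - 1)`, :math:`\\tilde n`
the harmonic mean of subpopulation sample sizes) and :math:`H_T` the gene
diversity of the equal-weight pooled allele frequencies.  The
:math:`n/(n-1)` factor multiplies by default so that a fixed allelic
difference between two subpopulations yields D = 1 (complete
differentiation); a variant that divides instead is available via
``literal_division=True``.

The genome scan tiles each chromosome with non-overlapping windows whose
size is twice the panel's LD decay distance, averages per-SNP D within each
window, and calls highly differentiated regions at three cutoffs: the
genome-wide mean per-SNP D, twice that mean, or the absolute value 0.2.
Adjacent qualifying windows merge into a single region.  Regions can be
intersected with QTL intervals (full containment as the primary criterion,
any-overlap reported alongside) and compared across subpopulation pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "DestComponents",
    "dest_per_locus",
    "pairwise_dest_matrix",
    "window_scan",
    "call_regions",
    "read_qtl_bed",
    "overlap_qtl",
    "common_regions",
    "gst_per_locus",
]

REGION_COLUMNS = ["chrom", "start", "end", "mean_dest", "n_snps", "cutoff_class"]


@dataclass
class DestComponents:
    """Per-locus ingredients of the D estimate (arrays over SNPs)."""

    h_s_est: np.ndarray
    h_t_est: np.ndarray
    n_subpops: int
    n_harmonic: np.ndarray


def _subpop_freq_counts(genotypes: GenotypeMatrix, assignment: pd.Series, labels):
    """Per-subpop alt-allele frequency and called-individual count per locus."""
    assignment = assignment.reindex(genotypes.accession_ids)
    freqs, counts = [], []
    for label in labels:
        idx = np.flatnonzero((assignment == label).values)
        if idx.size == 0:
            raise ValueError(f"subpopulation {label!r} has no accessions")
        sub = genotypes.take_accessions(idx)
        called = (~sub.missing_mask).sum(axis=0).astype(float)
        alt = np.where(sub.missing_mask, 0, sub.dosage).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(called > 0, alt / (2.0 * called), np.nan)
        freqs.append(p)
        counts.append(called)
    return np.vstack(freqs), np.vstack(counts)


def dest_per_locus(genotypes: GenotypeMatrix, assignment: pd.Series,
                   subpops=None, literal_division: bool = False):
    """Per-SNP Jost's D for a subpopulation pair (or any subset / all subpops).

    Returns ``(d, components)`` where ``d`` is an array over SNPs, NaN at
    masked loci (any included subpopulation with < 2 called accessions, or a
    degenerate H_S = 1).
    """
    labels = list(subpops) if subpops is not None else sorted(assignment.dropna().unique())
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two subpopulations")
    p, counts = _subpop_freq_counts(genotypes, assignment, labels)

    valid = (counts >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_harm = n / np.sum(1.0 / np.maximum(counts, 1e-12), axis=0)
        h_within = 2.0 * p * (1.0 - p)                       # per subpop x locus
        h_s_raw = h_within.mean(axis=0)
        h_s = n_harm / (n_harm - 1.0) * h_s_raw
        p_bar = p.mean(axis=0)                               # equal subpop weight
        h_t = 2.0 * p_bar * (1.0 - p_bar)
        core = (h_t - h_s) / (1.0 - h_s)
        factor = n / (n - 1.0)
        d = core / factor if literal_division else core * factor
    bad = ~valid | np.isnan(d) | np.isclose(h_s, 1.0)
    d = np.where(bad, np.nan, d)
    comps = DestComponents(
        h_s_est=np.where(valid, h_s, np.nan),
        h_t_est=np.where(valid, h_t, np.nan),
        n_subpops=n,
        n_harmonic=np.where(valid, n_harm, np.nan),
    )
    return d, comps


def gst_per_locus(genotypes: GenotypeMatrix, assignment: pd.Series, subpops=None):
    """Plain G_ST = (H_T − H_S)/H_T per locus (internal cross-check statistic)."""
    d, comps = dest_per_locus(genotypes, assignment, subpops=subpops)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (comps.h_t_est - comps.h_s_est) / comps.h_t_est
    return np.where(np.isnan(d) | (comps.h_t_est <= 0), np.nan, g)


def pairwise_dest_matrix(genotypes: GenotypeMatrix, assignment: pd.Series,
                         literal_division: bool = False) -> pd.DataFrame:
    """K x K matrix of genome-average pairwise D (diagonal exactly 0.000)."""
    labels = sorted(assignment.dropna().unique())
    if len(labels) < 2:
        raise ValueError("need at least two subpopulations")
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        d, _ = dest_per_locus(genotypes, assignment, subpops=[a, b],
                              literal_division=literal_division)
        if np.all(np.isnan(d)):
            warnings.warn(f"pair ({a}, {b}) shares no usable loci; entry masked")
            val = np.nan
        else:
            val = float(np.nanmean(d))
        out.loc[a, b] = out.loc[b, a] = val
    return out


# ---------------------------------------------------------------------------
# Window scan and region calling
# ---------------------------------------------------------------------------

def window_scan(per_snp_dest: np.ndarray, snp_map: pd.DataFrame,
                window_size_bp: int) -> pd.DataFrame:
    """Mean per-SNP D in non-overlapping windows tiled from position 1.

    Returns a table with 1-based inclusive window coordinates; windows with
    no unmasked SNP are omitted.
    """
    if window_size_bp <= 0:
        raise ValueError("window_size_bp must be positive")
    d = np.asarray(per_snp_dest, dtype=float)
    smap = snp_map.reset_index(drop=True)
    if len(d) != len(smap):
        raise ValueError("per-SNP D length differs from SNP map length")
    ok = ~np.isnan(d)
    df = pd.DataFrame(
        {
            "chrom": smap["chrom"][ok].values,
            "widx": (smap["pos"][ok].values - 1) // window_size_bp,
            "d": d[ok],
        }
    )
    grouped = df.groupby(["chrom", "widx"], sort=False).agg(
        mean_dest=("d", "mean"), n_snps=("d", "size")
    ).reset_index()
    grouped["start"] = grouped["widx"] * window_size_bp + 1
    grouped["end"] = (grouped["widx"] + 1) * window_size_bp
    grouped = grouped.sort_values(["chrom", "widx"], kind="stable").reset_index(drop=True)
    return grouped[["chrom", "start", "end", "mean_dest", "n_snps", "widx"]]


_CUTOFF_MODES = ("mean", "twice_mean", "absolute_0.2")


def call_regions(window_table: pd.DataFrame, per_snp_dest: np.ndarray | None = None,
                 cutoff_mode: str = "twice_mean") -> pd.DataFrame:
    """Call highly differentiated regions from a window scan.

    ``cutoff_mode``: ``"mean"`` — genome-wide mean per-SNP D; ``"twice_mean"``
    — twice it; ``"absolute_0.2"`` — the fixed value 0.2.  The per-SNP mean is
    taken from ``per_snp_dest`` (required for the mean-based modes).  Windows
    strictly above the cutoff become regions; adjacent qualifying windows
    (consecutive tiles on one chromosome) merge, with SNP-count-weighted mean
    D.  Returns a region table (possibly empty).
    """
    if cutoff_mode not in _CUTOFF_MODES:
        raise ValueError(f"cutoff_mode must be one of {_CUTOFF_MODES}")
    if window_table.empty:
        raise ValueError("window table is empty")
    if cutoff_mode == "absolute_0.2":
        cutoff = 0.2
    else:
        if per_snp_dest is None:
            raise ValueError("mean-based cutoffs need per_snp_dest")
        base = float(np.nanmean(np.asarray(per_snp_dest, dtype=float)))
        cutoff = base if cutoff_mode == "mean" else 2.0 * base

    qual = window_table[window_table["mean_dest"] > cutoff]
    regions = []
    for chrom, grp in qual.groupby("chrom", sort=False):
        grp = grp.sort_values("widx")
        run = []
        prev = None
        for _, row in grp.iterrows():
            if prev is not None and row["widx"] != prev + 1:
                regions.append(_merge_run(run, chrom, cutoff_mode))
                run = []
            run.append(row)
            prev = row["widx"]
        if run:
            regions.append(_merge_run(run, chrom, cutoff_mode))
    out = pd.DataFrame(regions, columns=REGION_COLUMNS)
    out.attrs["cutoff"] = cutoff
    return out


def _merge_run(run, chrom, cutoff_mode):
    n = sum(int(r["n_snps"]) for r in run)
    mean_d = sum(r["mean_dest"] * r["n_snps"] for r in run) / n
    return {
        "chrom": chrom,
        "start": int(run[0]["start"]),
        "end": int(run[-1]["end"]),
        "mean_dest": float(mean_d),
        "n_snps": n,
        "cutoff_class": {"mean": "above-mean", "twice_mean": "above-2xmean",
                         "absolute_0.2": "above-0.2"}[cutoff_mode],
    }


# ---------------------------------------------------------------------------
# QTL overlap and cross-pair comparison
# ---------------------------------------------------------------------------

def read_qtl_bed(path) -> pd.DataFrame:
    """Read QTL intervals from BED (0-based half-open; columns chrom, start,
    end[, trait_class[, source]]).  Returned table uses 1-based inclusive
    coordinates to match region tables."""
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path} line {line_no}: need >= 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path} line {line_no}: start >= end")
            rows.append(
                {
                    "chrom": chrom,
                    "start": start + 1,
                    "end": end,
                    "trait_class": parts[3] if len(parts) > 3 else "unspecified",
                    "source": parts[4] if len(parts) > 4 else "",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "trait_class", "source"])


def overlap_qtl(regions: pd.DataFrame, qtl_intervals: pd.DataFrame):
    """Intersect called regions with QTL intervals (both 1-based inclusive).

    A region is *contained* iff it lies fully within at least one QTL
    interval (the primary criterion); any-overlap hits are reported
    separately.  Returns ``(per_region_table, summary_dict)``.
    """
    region_chroms = set(regions["chrom"]) if len(regions) else set()
    qtl_chroms = set(qtl_intervals["chrom"]) if len(qtl_intervals) else set()
    unmatched = region_chroms - qtl_chroms
    if unmatched:
        warnings.warn(f"region chromosomes absent from QTL table: {sorted(unmatched)}")
    rows = []
    for _, reg in regions.iterrows():
        q = qtl_intervals[qtl_intervals["chrom"] == reg["chrom"]]
        contained_in = q[(q["start"] <= reg["start"]) & (reg["end"] <= q["end"])]
        overlapping = q[(q["start"] <= reg["end"]) & (reg["start"] <= q["end"])]
        rows.append(
            {
                "chrom": reg["chrom"],
                "start": reg["start"],
                "end": reg["end"],
                "contained": len(contained_in) > 0,
                "any_overlap": len(overlapping) > 0,
                "n_qtl_containing": len(contained_in),
                "n_qtl_overlapping": len(overlapping),
                "trait_classes": ";".join(sorted(set(overlapping["trait_class"]))),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "contained", "any_overlap",
                 "n_qtl_containing", "n_qtl_overlapping", "trait_classes"],
    )
    summary = {
        "n_regions": len(regions),
        "n_contained": int(table["contained"].sum()) if len(table) else 0,
        "n_any_overlap": int(table["any_overlap"].sum()) if len(table) else 0,
    }
    return table, summary


def common_regions(region_tables: dict, min_pairs: int = 2) -> pd.DataFrame:
    """Genomic intervals shared (any-overlap) by >= ``min_pairs`` pair scans.

    ``region_tables`` maps a subpopulation-pair label to its region table.
    A sweep over interval breakpoints reports maximal intervals covered by at
    least ``min_pairs`` distinct pairs, with the pairs sharing them.
    """
    if len(region_tables) < 2:
        raise ValueError("need region lists for at least two pairs")
    events = {}
    for pair, table in region_tables.items():
        for _, reg in table.iterrows():
            events.setdefault(reg["chrom"], []).append((int(reg["start"]), int(reg["end"]), pair))
    rows = []
    for chrom, intervals in sorted(events.items()):
        points = sorted({p for s, e, _ in intervals for p in (s, e + 1)})
        for lo, hi in zip(points[:-1], points[1:]):
            covering = sorted({pair for s, e, pair in intervals if s <= lo and hi - 1 <= e})
            if len(covering) >= min_pairs:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": lo,
                        "end": hi - 1,
                        "n_pairs": len(covering),
                        "pairs": ";".join(str(p) for p in covering),
                    }
                )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_pairs", "pairs"])
    # merge adjacent segments with the identical pair set
    merged = []
    for _, row in out.iterrows():
        if merged and merged[-1]["chrom"] == row["chrom"] \
                and merged[-1]["end"] + 1 == row["start"] \
                and merged[-1]["pairs"] == row["pairs"]:
            merged[-1]["end"] = row["end"]
        else:
            merged.append(dict(row))
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "n_pairs", "pairs"])
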