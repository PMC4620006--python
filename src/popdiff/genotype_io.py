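"""Reading, merging, filtering and writing SNP genotype panels.

A panel is a pair of objects: a :class:`GenotypeMatrix` (accessions x SNPs
allele-dosage matrix with a missing-data mask) and a SNP map (a pandas
DataFrame with one row per SNP giving chromosome, 1-based physical position
and the reference-strand allele pair).  Two on-disk formats are supported:

* VCF v4.x (biallelic SNPs, GT field; read through cyvcf2), and
* a HapMap-style tabular format: a header row of accession ids after the
  four map columns, then one row per SNP with ``snp_id  chrom  pos  alleles``
  followed by per-accession nucleotide calls (``AA``/``AG``/single-letter
  IUPAC codes; ``NN``, ``N``, ``--`` or ``./.`` mean missing).

Merging follows panel-integration practice for chip data: SNPs are matched
on (name, chromosome, position); a panel reporting the complementary-strand
allele pair is re-expressed on the first panel's strand; A/T and C/G SNPs
cannot be strand-resolved by complementing and are dropped by default.
Filtering applies the three screening criteria: MAF strictly above a floor,
missing fraction strictly below a ceiling, and an unambiguous map position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "FilterReport",
    "MergeReport",
    "make_snp_map",
    "validate_snp_map",
    "read_genotypes",
    "write_genotypes",
    "merge_panels",
    "filter_snps",
]

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "allele1", "allele2"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# IUPAC ambiguity codes for the six heterozygous base pairs
_IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}

_MISSING_CALLS = {"NN", "N", "--", "-", "./.", ".", "??"}


@dataclass
class GenotypeMatrix:
    """Accessions x SNPs dosage matrix counting copies of the alternate allele.

    ``dosage`` holds 0/1/2 (heterozygotes are always 1; phase is discarded);
    entries flagged in ``missing_mask`` are undefined and excluded from every
    statistic computed downstream.
    """

    accession_ids: list
    snp_ids: list
    dosage: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self):
        self.accession_ids = list(self.accession_ids)
        self.snp_ids = list(self.snp_ids)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = self.dosage.shape
        if len(self.accession_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id lists inconsistent with dosage matrix shape")
        if self.missing_mask.shape != self.dosage.shape:
            raise ValueError("missing_mask shape differs from dosage shape")
        if len(set(self.accession_ids)) != n:
            raise ValueError("duplicate accession ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        called = self.dosage[~self.missing_mask]
        if called.size and (called.min() < 0 or called.max() > 2):
            raise ValueError("dosage outside {0,1,2} at non-missing entries")

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def dosage_float(self) -> np.ndarray:
        """Dosage as float64 with NaN at missing entries."""
        d = self.dosage.astype(np.float64)
        d[self.missing_mask] = np.nan
        return d

    def n_called(self) -> np.ndarray:
        """Number of non-missing calls per SNP."""
        return (~self.missing_mask).sum(axis=0)

    def allele_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over non-missing calls (NaN if none)."""
        called = (~self.missing_mask).sum(axis=0).astype(float)
        alt = np.where(self.missing_mask, 0, self.dosage).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, alt / (2.0 * called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.accession_ids,
            [self.snp_ids[i] for i in index],
            self.dosage[:, index],
            self.missing_mask[:, index],
        )

    def take_accessions(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.accession_ids[i] for i in index],
            self.snp_ids,
            self.dosage[index, :],
            self.missing_mask[index, :],
        )


@dataclass
class FilterReport:
    """Outcome counts of the three SNP screening criteria (failures may overlap)."""

    n_input: int
    n_failed_maf: int
    n_failed_missing: int
    n_failed_position: int
    n_passed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


@dataclass
class MergeReport:
    """Book-keeping of a multi-panel merge (SNP intersection, strand handling)."""

    n_snps_per_panel: list
    n_shared: int
    n_merged: int
    n_dropped_irreconcilable: int
    n_dropped_strand_ambiguous: int
    dropped_irreconcilable: list = field(default_factory=list)
    dropped_strand_ambiguous: list = field(default_factory=list)
    note: str = "SNP set is the intersection across panels; accessions are concatenated"


def make_snp_map(snp_ids, chroms, positions, allele1, allele2) -> pd.DataFrame:
    """Assemble a SNP map DataFrame (columns snp_id, chrom, pos, allele1, allele2)."""
    df = pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": [str(c) for c in chroms],
            "pos": np.asarray(positions, dtype=np.int64),
            "allele1": list(allele1),
            "allele2": list(allele2),
        }
    )
    validate_snp_map(df)
    return df


def validate_snp_map(snp_map: pd.DataFrame) -> None:
    missing_cols = [c for c in SNP_MAP_COLUMNS if c not in snp_map.columns]
    if missing_cols:
        raise ValueError(f"SNP map lacks columns {missing_cols}")
    if (snp_map["pos"] <= 0).any():
        raise ValueError("SNP positions must be positive (1-based)")
    if snp_map["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_id in map")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith((".vcf", ".vcf.gz")):
        return "vcf"
    return "tabular"


def read_genotypes(path, fmt: str | None = None):
    """Read a genotype panel; returns ``(GenotypeMatrix, snp_map)``.

    ``fmt`` is ``"vcf"`` or ``"tabular"``; inferred from the extension when
    omitted.  Heterozygotes are coded 1; unresolvable calls are masked.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tabular":
        return _read_tabular(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, positions, a1, a2 = [], [], [], [], []
    dosage_rows, mask_rows = [], []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            raise ValueError(
                f"record {i + 1} ({v.CHROM}:{v.POS}): multi-allelic sites unsupported"
            )
        for g in v.genotypes:
            if len(g) - 1 != 2:  # last element is the phased flag
                raise ValueError(
                    f"record {i + 1} ({v.CHROM}:{v.POS}): ploidy != 2 rejected"
                )
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage_rows.append(np.choose(gt, [0, 1, 0, 2]).astype(np.int8))
        mask_rows.append(gt == 2)
        snp_ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        positions.append(v.POS)
        a1.append(v.REF)
        a2.append(v.ALT[0])
    if not snp_ids:
        raise ValueError(f"{path}: no SNP records")
    dosage = np.vstack(dosage_rows).T
    mask = np.vstack(mask_rows).T
    gm = GenotypeMatrix(samples, snp_ids, dosage, mask)
    return gm, make_snp_map(snp_ids, chroms, positions, a1, a2)


def _parse_call(call: str, alleles: tuple, line_no: int):
    """Return (dosage, missing) for one nucleotide call against (ref, alt)."""
    call = call.strip().upper()
    if call in _MISSING_CALLS:
        return 0, True
    if len(call) == 1:
        if call in _IUPAC_HET:
            pair = _IUPAC_HET[call]
            if set(pair) != set(alleles):
                return 0, True  # ambiguity code inconsistent with the allele pair
            return 1, False
        call = call + call  # single homozygous base
    if len(call) != 2:
        raise ValueError(f"line {line_no}: malformed genotype call {call!r}")
    ref, alt = alleles
    n_alt = sum(1 for b in call if b == alt)
    n_ref = sum(1 for b in call if b == ref)
    if n_alt + n_ref != 2:
        return 0, True  # allele not in the declared pair: unresolvable, masked
    return n_alt, False


def _read_tabular(path):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 5 or header[:4] != ["snp_id", "chrom", "pos", "alleles"]:
            raise ValueError(
                f"{path} line 1: expected header 'snp_id chrom pos alleles <accessions...>'"
            )
        accessions = header[4:]
        snp_ids, chroms, positions, a1, a2 = [], [], [], [], []
        dosage_rows, mask_rows = [], []
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4 + len(accessions):
                raise ValueError(f"{path} line {line_no}: wrong number of fields")
            sid, chrom, pos, alleles = parts[:4]
            try:
                ref, alt = alleles.split("/")
                pos = int(pos)
            except ValueError as exc:
                raise ValueError(f"{path} line {line_no}: malformed map fields") from exc
            drow, mrow = [], []
            for call in parts[4:]:
                d, miss = _parse_call(call, (ref, alt), line_no)
                drow.append(d)
                mrow.append(miss)
            snp_ids.append(sid)
            chroms.append(chrom)
            positions.append(pos)
            a1.append(ref)
            a2.append(alt)
            dosage_rows.append(drow)
            mask_rows.append(mrow)
    if not snp_ids:
        raise ValueError(f"{path}: no SNP records")
    dosage = np.asarray(dosage_rows, dtype=np.int8).T
    mask = np.asarray(mask_rows, dtype=bool).T
    gm = GenotypeMatrix(accessions, snp_ids, dosage, mask)
    return gm, make_snp_map(snp_ids, chroms, positions, a1, a2)


def write_genotypes(genotypes: GenotypeMatrix, snp_map: pd.DataFrame, path, fmt=None):
    """Write a panel to VCF (GT-only, v4.2) or the tabular format."""
    validate_snp_map(snp_map)
    fmt = fmt or _infer_format(path)
    smap = snp_map.set_index("snp_id").loc[genotypes.snp_ids]
    if fmt == "vcf":
        _write_vcf(genotypes, smap, path)
    elif fmt == "tabular":
        _write_tabular(genotypes, smap, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_vcf(gm, smap, path):
    order = np.argsort(
        pd.factorize(smap["chrom"])[0] * (smap["pos"].max() + 1) + smap["pos"].values,
        kind="stable",
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=popdiff\n")
        for chrom in pd.unique(smap["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotype_id for genotype_id in gm.accession_ids)
            + "\n"
        )
        for j in order:
            row = smap.iloc[j]
            calls = [
                "./." if gm.missing_mask[i, j] else _GT_STRINGS[int(gm.dosage[i, j])]
                for i in range(gm.n_accessions)
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{smap.index[j]}\t{row['allele1']}\t"
                f"{row['allele2']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def _write_tabular(gm, smap, path):
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\talleles\t" + "\t".join(gm.accession_ids) + "\n")
        for j, sid in enumerate(gm.snp_ids):
            row = smap.iloc[j]
            ref, alt = row["allele1"], row["allele2"]
            geno = {0: ref + ref, 1: ref + alt, 2: alt + alt}
            calls = [
                "NN" if gm.missing_mask[i, j] else geno[int(gm.dosage[i, j])]
                for i in range(gm.n_accessions)
            ]
            fh.write(f"{sid}\t{row['chrom']}\t{row['pos']}\t{ref}/{alt}\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _is_strand_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def reconcile_alleles(ref_pair: tuple, other_pair: tuple):
    """How to re-express dosages coded on ``other_pair`` onto ``ref_pair``.

    Returns ``"same"`` (keep), ``"flip"`` (dosage -> 2 - dosage) or ``None``
    (irreconcilable).  Complementary-strand pairs (A/G vs T/C etc.) are
    treated as the same physical SNP reported on the opposite strand.
    """
    a1, a2 = ref_pair
    comp = (_COMPLEMENT.get(a1), _COMPLEMENT.get(a2))
    if other_pair == (a1, a2) or other_pair == comp:
        return "same"
    if other_pair == (a2, a1) or other_pair == (comp[1], comp[0]):
        return "flip"
    return None


def merge_panels(panels, keep_strand_ambiguous: bool = False):
    """Merge >= 2 panels into one; returns ``(GenotypeMatrix, snp_map, MergeReport)``.

    SNPs are matched on (name, chromosome, position) and the merged SNP set is
    the intersection across panels.  Dosages of non-reference panels are
    re-expressed on the first panel's strand/orientation; A/T and C/G SNPs are
    strand-unresolvable and dropped unless ``keep_strand_ambiguous`` (which
    trusts names and never complements them).
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to merge")
    all_accessions = [a for gm, _ in panels for a in gm.accession_ids]
    if len(set(all_accessions)) != len(all_accessions):
        raise ValueError("duplicate accession ids across panels")

    keys = []
    for gm, smap in panels:
        validate_snp_map(smap)
        smap_idx = smap.set_index("snp_id")
        keys.append(
            {
                sid: (sid, smap_idx.at[sid, "chrom"], int(smap_idx.at[sid, "pos"]))
                for sid in gm.snp_ids
            }
        )
    shared = set(keys[0].values())
    for k in keys[1:]:
        shared &= set(k.values())
    # deterministic order: reference panel order
    ref_gm, ref_map = panels[0]
    ref_map_idx = ref_map.set_index("snp_id")
    shared_ids = [sid for sid in ref_gm.snp_ids if keys[0][sid] in shared]

    report = MergeReport(
        n_snps_per_panel=[gm.n_snps for gm, _ in panels],
        n_shared=len(shared_ids),
        n_merged=0,
        n_dropped_irreconcilable=0,
        n_dropped_strand_ambiguous=0,
    )

    kept_ids = []
    actions = []  # per kept SNP: list of "same"/"flip" per non-reference panel
    other_maps = [smap.set_index("snp_id") for _, smap in panels[1:]]
    for sid in shared_ids:
        ref_pair = (str(ref_map_idx.at[sid, "allele1"]), str(ref_map_idx.at[sid, "allele2"]))
        if _is_strand_ambiguous(*ref_pair) and not keep_strand_ambiguous:
            report.n_dropped_strand_ambiguous += 1
            report.dropped_strand_ambiguous.append(sid)
            continue
        acts, ok = [], True
        for om in other_maps:
            pair = (str(om.at[sid, "allele1"]), str(om.at[sid, "allele2"]))
            if keep_strand_ambiguous and _is_strand_ambiguous(*ref_pair):
                act = "same" if pair == ref_pair else (
                    "flip" if pair == ref_pair[::-1] else None
                )
            else:
                act = reconcile_alleles(ref_pair, pair)
            if act is None:
                ok = False
                break
            acts.append(act)
        if not ok:
            report.n_dropped_irreconcilable += 1
            report.dropped_irreconcilable.append(sid)
            continue
        kept_ids.append(sid)
        actions.append(acts)
    report.n_merged = len(kept_ids)

    ref_pos = {sid: j for j, sid in enumerate(ref_gm.snp_ids)}
    cols = [ref_pos[sid] for sid in kept_ids]
    dosage_blocks = [ref_gm.dosage[:, cols]]
    mask_blocks = [ref_gm.missing_mask[:, cols]]
    for p_idx, (gm, _) in enumerate(panels[1:]):
        pos = {sid: j for j, sid in enumerate(gm.snp_ids)}
        cols_p = [pos[sid] for sid in kept_ids]
        d = gm.dosage[:, cols_p].copy()
        m = gm.missing_mask[:, cols_p]
        flip = np.array([acts[p_idx] == "flip" for acts in actions], dtype=bool)
        d[:, flip] = 2 - d[:, flip]
        dosage_blocks.append(d)
        mask_blocks.append(m)

    merged = GenotypeMatrix(
        all_accessions,
        kept_ids,
        np.vstack(dosage_blocks),
        np.vstack(mask_blocks),
    )
    merged_map = ref_map.set_index("snp_id").loc[kept_ids].reset_index()
    return merged, merged_map, report


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_snps(
    genotypes: GenotypeMatrix,
    snp_map: pd.DataFrame,
    maf_min: float = 0.05,
    missing_max: float = 0.2,
):
    """Apply the three SNP screening criteria; returns filtered panel + report.

    A SNP is kept iff MAF > ``maf_min`` strictly, missing fraction <
    ``missing_max`` strictly, and it has an unambiguous map position (ties at
    either threshold fail).  MAF is computed over non-missing calls; an
    all-missing SNP fails the missing criterion.
    """
    if not (0 <= maf_min < 1) or not (0 < missing_max <= 1):
        raise ValueError("thresholds out of range")
    validate_snp_map(snp_map)
    smap = snp_map.set_index("snp_id")
    maf = genotypes.maf()
    miss = genotypes.missing_fraction()

    in_map = np.array([sid in smap.index for sid in genotypes.snp_ids])
    dup_positions = set()
    pos_counts = snp_map.groupby(["chrom", "pos"]).size()
    ambiguous = set(pos_counts[pos_counts > 1].index)
    for sid in genotypes.snp_ids:
        if sid in smap.index:
            key = (smap.at[sid, "chrom"], smap.at[sid, "pos"])
            if key in ambiguous:
                dup_positions.add(sid)
    pos_ok = in_map & np.array([sid not in dup_positions for sid in genotypes.snp_ids])

    fail_missing = ~(miss < missing_max)
    fail_maf = ~(maf > maf_min)
    fail_maf[np.isnan(maf)] = True
    keep = pos_ok & ~fail_missing & ~fail_maf

    report = FilterReport(
        n_input=genotypes.n_snps,
        n_failed_maf=int(fail_maf.sum()),
        n_failed_missing=int(fail_missing.sum()),
        n_failed_position=int((~pos_ok).sum()),
        n_passed=int(keep.sum()),
    )
    idx = np.flatnonzero(keep)
    filtered = genotypes.take_snps(idx)
    kept_ids = [genotypes.snp_ids[i] for i in idx]
    filtered_map = snp_map.set_index("snp_id").loc[kept_ids].reset_index()
    return filtered, filtered_map, report
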