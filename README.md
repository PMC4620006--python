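# popdiff

Population-differentiation analysis for diverse SNP panels of inbred lines
(built around the kind of maize diversity panel genotyped on SNP chips:
hundreds to thousands of accessions, tens of thousands of biallelic markers
on ten chromosomes).

The package covers the full analysis chain:

* **Panel integration and QC** — read VCF or HapMap-style tabular genotypes,
  merge panels by SNP name + physical position with complementary-strand
  allele reconciliation (A/T and C/G SNPs are strand-unresolvable and dropped
  by default), and screen SNPs by MAF > 0.05, missing rate < 0.2 and an
  unambiguous map position.
* **Diversity and relatedness** — gene diversity GD = 1 − Σp², PIC
  = 1 − Σp² − Σ<sub>u&lt;v</sub>2p²<sub>u</sub>p²<sub>v</sub>, per-accession
  heterozygosity, identity-by-state distance D = 1 − IBS, and centered-IBS
  kinship F<sub>ij</sub> = (Q<sub>ij</sub> − Q<sub>m</sub>)/(1 − Q<sub>m</sub>).
* **Structure inference** — Patterson-normalized PCA, Saitou–Nei
  neighbor-joining trees on the IBS distance matrix, cluster extraction by
  cutting the K−1 longest branches, and a marker-subsampling sufficiency
  curve (mean |r| of the first five PCs between a genome-spread SNP subset
  and the full panel).
* **Differentiation scans** — per-locus Jost's
  D<sub>EST</sub> = [(H<sub>T</sub> − H<sub>S</sub>)/(1 − H<sub>S</sub>)] · n/(n−1)
  for subpopulation pairs, genome-average pairwise matrices, windowed scans
  with window size = 2 × the panel's LD decay distance (where binned mean r²
  drops below 0.1), region calling at the mean / twice-mean / absolute-0.2
  cutoffs, QTL-interval overlap and cross-pair shared regions.
* **Association** — EMMA-style mixed-model GWAS (y = Wα + xβ + u + ε with
  u ~ N(0, σ²<sub>g</sub>K); REML on the null model, variance components then
  fixed across SNPs), Bonferroni threshold −log10(α/markers), QTN calling
  and colocalization with differentiated regions.
* **Synthetic panels with known truth** — a Balding–Nichols generator with
  haplotype-block LD, block autozygosity for inbred lines, plantable
  differentiated regions and QTN-driven phenotypes, so every stage is
  testable against ground truth.

## Worked example

```python
import numpy as np
from popdiff import *
from popdiff.simdata import SimulationConfig, PlantedRegion, simulate_panel

cfg = SimulationConfig(
    n_subpops=2, sizes=(200, 200), n_snps=5000, n_chromosomes=10,
    chrom_length_bp=1_200_000, differentiation=0.08, seed=42,
    planted_regions=[PlantedRegion("chr2", 500_001, 620_000, ("P1", "P2"), 0.5)],
)
genotypes, snp_map, truth, _ = simulate_panel(cfg)

print(diversity_summary(genotypes, truth.true_assignment).round(3))

_, genome_ld = ld_decay(genotypes, snp_map, max_dist=100_000)
print(f"LD decay distance: {genome_ld.decay_distance/1000:.1f} kb")

d, _ = dest_per_locus(genotypes, truth.true_assignment)
print(f"genome-average D_EST: {np.nanmean(d):.3f}")

windows = window_scan(d, snp_map, int(round(2 * genome_ld.decay_distance)))
regions = call_regions(windows, per_snp_dest=d, cutoff_mode="twice_mean")
print(regions[["chrom", "start", "end", "mean_dest", "n_snps"]].to_string(index=False))
```

Output:

```
       n_accessions  gene_diversity    pic  heterozygosity
group
Total           400           0.354  0.282           0.034
P1              200           0.338  0.270           0.034
P2              200           0.336  0.269           0.033
LD decay distance: 24.2 kb
genome-average D_EST: 0.048
chrom   start     end  mean_dest  n_snps
 chr2  483341  628342   0.430088      64
 chr3  193337  241670   0.109189      28
 chr3 1111683 1160016   0.104307      21
 chr8  773345  821678   0.114366      14
 chr8  870013  918346   0.110452      13
```

Reading it: the two simulated subpopulations are mildly differentiated
(genome-average D ≈ 0.05) with the low heterozygosity (~0.03) typical of
inbred panels; the scan window is set to twice the measured ~24 kb LD
distance; and the planted chr2 region stands out sharply (window mean
D ≈ 0.43 across 64 SNPs, spanning the planted interval) above a handful of
weaker background calls near the twice-mean cutoff.

A command-line layer mirrors the library
(`popdiff simulate | merge | filter | diversity | kinship | ld | pca | tree |
clusters | ascertainment | dest | scan | regions | overlap | gwas`); run
`popdiff --help` for the subcommand list.

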