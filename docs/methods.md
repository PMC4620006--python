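# Methods

## Statistics

All statistics operate on an accessions × SNPs dosage matrix (0/1/2 copies
of the alternate allele, heterozygotes always 1, phase discarded) with a
missing-data mask; every estimate is computed over non-missing calls only.

**Gene diversity and PIC.** At locus *l* with allele frequencies p_lu,
GD_l = 1 − Σ_u p_lu², and
PIC_l = 1 − Σ_u p_lu² − Σ_{u<v} 2 p_lu² p_lv² (evaluated as
1 − s₂ − (s₂² − s₄) with s_k the k-th power sum). PIC ≤ GD ≤ 1 − 1/k holds
for every frequency vector. Group summaries average loci (GD, PIC) or
accessions (heterozygosity: the fraction of non-missing loci called
heterozygous).

**IBS distance and kinship.** Per-locus IBS between two diploid genotypes is
the probability that one allele drawn at random from each matches — in
dosage terms x_i x_j + (1−x_i)(1−x_j) with x = dosage/2, giving 1 for
identical homozygotes, 0 for opposite homozygotes and 0.5 for any pair
involving a heterozygote (including het–het, which the random-draw
definition forces). Pairwise IBS Q_ij averages the jointly called loci;
distance is 1 − Q_ij. Kinship is the background-centered transform
F_ij = (Q_ij − Q_m)/(1 − Q_m), with Q_m the mean over off-diagonal pairs
only (the diagonal would inflate the background). Negative values are
clamped to 0 in reports; the raw matrix feeds the mixed model. A variant
that skips heterozygous calls entirely (averaging only hom–hom loci, as
some toolkits do) is exposed as `skip_heterozygotes=True`; the random-draw
rule is the default because it follows directly from the IBS definition.

**LD.** r² is the squared Pearson correlation of dosage vectors over
jointly non-missing accessions (exact pairwise-complete sums via masked
matrix products). The decay profile bins all intra-chromosomal pairs within
`max_dist` (default 200 kb, 5-kb bins) and the decay distance is where the
binned mean r² first crosses the threshold (default 0.1), by linear
interpolation anchored at (0 bp, r² = 1) — the anchor makes the degenerate
threshold 1.0 give distance 0 and position-shuffled data give a distance at
or before the first bin midpoint.

**Jost's D.** For n subpopulations at one locus,
D = [(H_T − H_S)/(1 − H_S)] · n/(n−1), where H_S is the mean
within-subpopulation gene diversity with the small-sample correction
ñ/(ñ−1) (ñ the harmonic mean of subpopulation sample sizes) and H_T is the
gene diversity of the equal-weight pooled frequencies. The n/(n−1) factor
*multiplies*: a fixed allelic difference between two subpopulations then
yields D = 1, the defining property of complete differentiation. A variant
that divides by n/(n−1) instead (yielding 0.25 in that case) is available
via `literal_division=True` for comparability with sources that print the
expression that way. Loci where any included subpopulation has fewer than
two called accessions are masked. The simpler H_S correction (without an
observed-heterozygosity term) is used throughout; the difference from the
fuller Nei–Chesser form is O(1/ñ) and immaterial at the panel sizes the
package targets.

## Genome scan

Windows tile each chromosome from position 1, non-overlapping, with window
size set to **twice the LD decay distance** of the panel (so one window spans
roughly one correlation length on each side). Window statistic: mean
per-SNP D of unmasked SNPs inside; empty windows are omitted. Regions are
windows strictly above a cutoff — the genome-wide mean of per-SNP D, twice
that mean, or the absolute value 0.2 — with adjacent qualifying windows
merged (SNP-count-weighted mean). The cutoff base is the per-SNP mean
rather than the per-window mean (the two differ when SNP density varies);
tiling rather than sliding keeps region counts disjoint and interpretable.
QTL overlap uses full containment as the primary criterion ("within the
interval"), with any-overlap counts reported alongside; cross-pair common
regions are maximal intervals covered by ≥ m pair scans, found by a
breakpoint sweep.

## Mixed-model association

Single-random-effect MLM y = Wα + xβ + u + ε, u ~ N(0, σ²_g K),
ε ~ N(0, σ²_e I). K is the raw (unclamped) kinship matrix repaired to PSD by
eigenvalue clipping. The variance ratio λ = σ²_g/σ²_e is estimated by REML
on the null model (no SNP) in the eigenbasis of K, with a bounded scalar
search over log λ ∈ [−6, 6]·ln10; it is then fixed and every SNP is tested
by GLS on the rotated data (the P3D scheme, the default of the common GWAS
toolkits and the only desk-scale option). With K = I the procedure is
algebraically identical to OLS — the test suite holds it to within 1e-8 of
an independent OLS fit. Structure covariates default to the first three
Patterson PCs; externally produced membership tables are accepted as a
covariate TSV. Significance is the Bonferroni cutoff −log10(α/markers) with
a strict inequality, so a p-value exactly at the cutoff is not called.

## Synthetic panels

The generator emulates a diverse inbred SNP-chip panel; its defaults are the
study conditions, not tuning knobs:

| parameter | default | rationale |
| --- | --- | --- |
| chromosomes | 10 | maize karyotype |
| SNPs | 10,000 | desk-scale stand-in for a ~43k chip |
| chromosome length | 1.2 Mb | compressed genome so a 60-kb window holds ~50 SNPs (see below) |
| drift θ | 0.15 | pairwise genome-average D ≈ 0.1, the middle of the observed 0.05–0.31 range |
| inbreeding F | 0.9 | heterozygosity ≈ 2pq(1−F) ≈ 0.03–0.05, the inbred-panel scale |
| missing rate | 0.05 | below the 0.2 QC ceiling |
| MAF floor | 0.05 | ancestral frequencies drawn U(0.05, 0.95) |
| LD block | 30 kb | the panel-level average LD distance being emulated |

Model: ancestral frequencies are drawn per **LD block** (SNPs on one block
descend from one ancestral segment); each subpopulation then draws per-SNP
frequencies from the Balding–Nichols Beta(p(1−θ)/θ, (1−p)(1−θ)/θ)
distribution. Haplotypes are sampled comonotonically within a block (one
latent uniform per haplotype per block), and with probability F per
individual per block the second haplotype copies the first (block
autozygosity). This yields E[het] = 2pq(1−F), the F = 1 ⇒ het = 0 limit,
and within-block dosage correlation that decays linearly with the
probability of sharing a block — the measured genome-wide decay distance is
~22–24 kb for 30-kb blocks at the default drift, inside the 20–50 kb band
being emulated. Genotype-level independent homozygote collapse was
considered and rejected: it randomizes heterozygous dosages independently
per SNP and destroys the block LD (within-block mean r² ≈ 0.06 at F = 0.9).

Planted regions set frequencies 0.5 ± δ in the two named subpopulations,
with δ = sqrt(D/(8 − 4D)) solving the population-level Jost's D target
exactly (δ = 0.5, i.e. fixation, at D = 1). Phenotypes are Σ dosage·effect
over the configured QTNs plus Gaussian noise scaled so the genetic variance
fraction equals the heritability. All randomness descends from one seed via
`numpy.random.SeedSequence` spawning. Optional two-way admixture (per-block
source-population switching) is available; no default scenario uses it
because nothing calibrates the admixture proportion.

What the generator does **not** reproduce: coalescent-grade LD (the decay is
piecewise-linear, not exponential; no recombination-rate variation),
mutation/ascertainment spectra of real chips, relatedness structure within
subpopulations beyond exchangeability, and genotype-error processes. Tests
passing on these panels therefore demonstrate correctness of the estimators
and the recovery machinery under the stated model, not robustness to every
property of real chip data.

## Scenario sizes and numerical choices

Test and acceptance scenarios use subpopulations of 30–500 accessions and
2,000–10,000 SNPs — the subpopulation scale of a panel with hundreds of
accessions per major group — with chromosomes compressed to 1.2 Mb so that
scan windows average ~50 SNPs and window means are stable. Region-scan
recovery runs 2 × 500 accessions at background drift 0.08 (background
D ≈ 0.05) with three 120-kb regions planted at D ≈ 0.5; GWAS calibration
uses 300 accessions × 10,000 SNPs with a structure-plus-polygenic null
phenotype, and power uses 500 accessions × 5,000 SNPs with one QTN at 10%
explained variance (a hit is a Bonferroni-significant SNP in the QTN's LD
block).

Numerical details: PCA mean-imputes missing dosages per SNP before
Patterson scaling and drops monomorphic columns; components are truncated
at numerical rank. NJ breaks Q-criterion ties by the lowest (row, column)
index and permits (and flags) negative branch lengths. Cluster extraction
cuts branches longest-first, internal before external, skipping cuts that
would not separate leaves from leaves, so exactly K leaf-bearing components
result and K = leaf-count yields singletons. Subsampling windows are
total-genome-length/m tiles; replicate subsamples jitter the window offset
rather than sampling freely, preserving the even genome spread. Ascertainment
correlations match subset to full-panel components greedily by largest
absolute correlation, absorbing sign flips and reordering. The filter reads
"exceeds 0.05" and "less than 0.2" strictly, so boundary values fail.
Positions are 1-based in all files and reports; BED input is converted from
0-based half-open on read.

## Known limitations

* Only biallelic diploid SNPs; no imputation, liftover or multi-allelic
  support. Merging intersects SNP sets across panels (partial chip overlap
  is recorded, not unioned with missingness).
* D_EST is the only reported differentiation statistic (a plain G_ST exists
  as an internal cross-check); no significance model for scan regions beyond
  the descriptive cutoffs.
* The MLM is single-trait, single-variance-component, additive; no
  multi-locus or Bayesian association.
* Model-based admixture clustering is out of scope; externally produced
  membership tables can be supplied as covariates or assignments.
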