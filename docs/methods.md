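# Methods

## The inference problem

Given (i) biallelic SNP genotypes for N individuals from several
differentiated populations, (ii) a catalog-locus × individual read-count
matrix from the same reduced-representation libraries, and (iii)
phenotypic sex for a subset of individuals, decide whether the species
has genetic sex determination, whether the heterogametic sex is male
(XX/XY) or female (ZW/ZZ), and assign a genetic sex to every individual.
The two marker classes exploited are independent: gametologous SNPs
(shared by both sex chromosomes, divergent between them) show
sex-patterned heterozygosity in the genotype matrix; hemizygous loci
(Y- or W-only) show sex-patterned presence/absence in the read counts.
The SNP universe and the presence-locus universe are deliberately kept
distinct — genotyped SNPs pass call-rate filtering, while
presence/absence uses the full catalog.

## Sex-linked SNP detection

**Imputation and centring.** Genotypes are alternate-allele counts
{0,1,2} with an out-of-band missing sentinel. Missing calls are replaced
by the per-SNP mean observed genotype (equal to twice the alternate
allele frequency, i.e. mean-allele-frequency imputation on the genotype
scale) and columns are centred. No variance scaling is applied:
equal-variance scaling would up-weight rare alleles and is not part of
the procedure being reproduced.

**PCA.** Full-SVD PCA (deterministic up to per-axis sign; verified in
the tests against a brute-force eigendecomposition of the covariance
matrix at 1e-8). Mean imputation shrinks missing entries toward the
column mean, which slightly attenuates, never inflates, between-group
separation.

**Axis choice.** Among the first `n_axes_scanned` axes (default 10), the
sex axis is the one maximising the standardized separation
|mean_m − mean_f| / pooled within-sex SD over phenotyped individuals,
ties to the lower index; below `min_separation` (default 2.0 — roughly
3× the null scale of the statistic at 25 individuals per sex scanned
over 10 axes) the dataset is declared to have no sex axis. With k
populations of comparable divergence there are up to k−1 structure axes,
so `n_axes_scanned` should be at least k + a few; the analysis drivers
use 15 for the 12-population cohort. The axis sign is normalised so
males have positive mean coordinate.

**Candidate SNPs and classification.** The contribution of SNP j to an
axis is 100·l_j²/Σl² (sums to 100). Since an S-SNP axis spreads 100%
over S loci, candidacy uses a scale-free enrichment rule: contribution
above `contribution_enrichment` × the uniform share 100/S %, default 3.
The cut is deliberately permissive — the decisive filter is the
genotype-pattern classification. For each candidate, over phenotyped
non-missing calls: fraction of males heterozygous, fraction of females
homozygous for the majority female allele, and the sex-swapped pair.
"Diagnostic" requires 100% fixed homozygous in one sex and 100%
heterozygous in the other; "sex-linked" requires both fractions beyond
`het_fraction_linked` (default 0.70, the boundary of the reported
majority-heterozygous class) in a consistent orientation; anything else
is rejected. Fixation is evaluated on observed calls only, so a SNP with
missing female calls can still be "fixed in all females" — matching the
operational counting on genotyped individuals. The majority-allele
convention makes classification invariant to ref/alt relabelling.

**System inference.** XY if the heterozygous-enriched sex among
diagnostic + sex-linked SNPs is male, ZW if female, undetermined when
neither orientation holds a strict majority or no axis was found.

## Sex-specific locus detection

Presence is count ≥ 1 ("one read or more"); absence is zero reads, which
confounds biological absence with technical missingness. A locus is
male-specific iff present in every phenotyped male and absent in every
phenotyped female (female-specific symmetric); unsexed individuals are
ignored. Instead of distinguishing the confound per locus, the closed
form L·[(1−m)^{n_m}·m^{n_f} + (1−m)^{n_f}·m^{n_m}] reports how many
neutral, everywhere-present loci would pass by chance at missingness m.
Detection is monotone: adding a sexed individual can only shrink the
sets. Expected recall of a true hemizygous locus is
((1−d_ss)(1−m))^{n_m} under per-individual dropout d_ss — with tens of
sexed males, even a few percent dropout hides a large fraction of true
loci (the all-individuals filter is maximally specific, not sensitive).
Each single-end restriction-site flank yields at most two catalog loci,
so k detected loci imply at least ⌈k/2⌉ sex-specific cut sites.

**Exclusion of axis-discordant individuals.** Phenotyped individuals
whose sex-axis call contradicts their recorded phenotype are excluded
(treated as unsexed) from presence/absence detection only: a single
genetically-male individual recorded as female otherwise erases every
true Y locus from the male-specific set. They remain in all other stages
and are reported, never relabelled — they are biologically interesting
(sex reversal, XY females).

## Per-individual assignment and cross-validation

Axis calls use the midpoint of the sexed-male and sexed-female centroids
with an unassigned dead zone of total width 10% of the centroid distance.
Hemizygous-locus calls use the fraction of detected loci carried:
heterogametic sex at ≥0.50, homogametic at ≤0.05 (echoing the observed
bimodality: males carry most loci minus dropout; females carry almost
none), unassigned between. The consensus is the shared call when both
methods agree; a call made by only one method stands; contradictory
calls leave the individual unassigned and flagged. Discordance with
phenotype is only reported for consensus-called, phenotyped individuals.
Cohort and per-population sex ratios use an exact two-sided binomial
test of 0.5 (chosen for determinism; the choice is echoed in the run
summary). The Wilcoxon–Mann–Whitney operation uses exact enumeration up
to n=20 without ties and the tie-corrected normal approximation
otherwise; in the pipeline it compares the hemizygous-locus fraction
between phenotyped sexes. The exact binomial p-value is discrete and
conservative; for calibration diagnostics a randomized (U-smoothed)
variant is provided that is exactly Uniform(0,1) under the null — it is
never used for reporting.

## The synthetic cohort generator

The generator emulates the statistical structure of a multi-population
RAD-seq study of a gonochoric species with a young sex-chromosome pair:

- **Structure:** per-SNP ancestral frequencies ~ Beta(1,1) (clipped away
  from 0/1); per-population frequencies Balding–Nichols Beta with mean p
  and variance F·p(1−p); genotypes Hardy–Weinberg within populations.
  Default 12 populations × 30 individuals, F = 0.08 ("strong structure").
- **Gametologs (default 500 of 27 500 SNPs):** homogametic individuals
  homozygous for the X/Z allele; heterogametic individuals heterozygous
  with probability (1−r)(1−d), r = leakage (recombination/recurrent
  mutation, default 0.05), d = Y/W-allele dropout (restriction-site
  polymorphism, default 0.05). The X-side allele is fixed in the
  homogametic sex by default.
- **Presence loci:** 2 000 neutral loci present in everyone plus 450
  hemizygous loci present only in heterogametic individuals, zeroed per
  individual-locus with dropout `sexspecific_dropout_rate` (defaults to
  d; kept separate because restriction-site polymorphism at a SNP and
  loss of a whole hemizygous locus are distinct mechanisms). Counts are
  negative-binomial with mean 37 and dispersion k = 2 (RAD coverage is
  overdispersed), clamped to ≥1 so that "present" always means at least
  one read; the clamp biases the realized mean by <0.3% at default
  coverage.
- **Observation noise:** technical missingness m (default 0.05) zeroes
  presence cells and blanks genotype calls; phenotypes are copied from
  genetic sex, flipped with probability ρ (default 0.05 ≈ the plausible
  rate of histological mis-sexing), and hidden for all but
  `sexed_fraction` (default 0.15) of individuals.
- **Symmetry:** every random draw conditions on heterogametic status
  only, never on the male/female label, so an XY and a ZW run from the
  same seed are numerically identical with labels swapped — downstream
  outputs must swap exactly, which is tested. Under `system="none"` the
  configured gametolog and hemizygous counts are generated as ordinary
  neutral loci.

What the generator does **not** emulate: linkage disequilibrium among
autosomal SNPs, hierarchical/unequal population divergence, block-wise
(haplotype) dropout, coverage differences between sexes, and
locus-specific missingness. Passing tests therefore demonstrate the
correctness and calibration of the inference chain under the assumed
generating process, not robustness to every artefact of real libraries.

## Numerical and degenerate-case choices

- Zero pooled within-sex SD with separated means → separation ∞ (axis
  selected); identical centroids → all individuals unassigned with a
  warning.
- All-missing SNPs are rejected by imputation with a pointer to the
  filters; MAF filtering removes them with a warning.
- Requested PCA axes beyond min(N−1, S) are truncated with a warning.
- Filters are idempotent, drop only SNP columns, preserve order, and are
  applied in the fixed order call-rate → MAF → het-excess. The
  heterozygote-excess paralog screen defaults to off and warns below
  0.6: true gametologs are ~50% heterozygous cohort-wide and would be
  destroyed.
- Identical values in both rank-sum groups → p = 1.0.
- Seeds derived from a user seed stay below 2³¹.

## Known limitations

- **Spectral degeneracy at small scale.** The sex axis is resolvable
  only when its eigenvalue (≈ n_gametologs × 0.2 in genotype-variance
  units for a balanced cohort) is separated from the population-structure
  eigenvalues and the Marchenko–Pastur noise bulk. In small simulations
  (e.g. ~5 000 SNPs, 4 weakly differentiated populations, N ≈ 120 with
  200 gametologs) the sex eigenvalue falls inside the structure band,
  the sex direction mixes across axes, and the standardized separation
  hovers around the `min_separation` default — the PCA route then
  returns "undetermined" in a fraction of replicates even though the
  hemizygous-locus route still sexes individuals perfectly. At the
  study-mirroring scale (27 500 SNPs, 12 populations, N = 360) the sex
  axis separates cleanly below the structure axes.
- The all-individuals presence filter trades sensitivity for
  specificity; reported locus counts are lower bounds under dropout.
- Population structure is exchangeable (single F); real hierarchical
  structure concentrates variance in fewer, stronger axes, which makes
  axis separation easier, not harder.
- No linkage information is used; each SNP is treated independently.
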