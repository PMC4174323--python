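# Methods

`peachpop` implements the population-genomic machinery used to dissect
artificial selection in domesticated peach (*Prunus persica*): windowed
diversity statistics on a multi-subgroup diploid cohort, Tajima's-D-based
candidate-region detection against analytic neutral ranges, set-logic
separation of edible- from ornamental-selection signals, ROD/Fst
corroboration, functional SNP classification, LD decay, heterozygosity
profiling, and a synthetic cohort generator that reproduces the cohort's
statistical structure so every stage can be tested without resequencing
data.

## Data model

Genotypes are held as a dosage matrix over biallelic SNPs: 0 (homozygous
reference), 1 (heterozygous), 2 (homozygous alternate), −1 (missing).
Positions are 1-based VCF coordinates externally and 0-based half-open
intervals internally and in all BED output. Samples carry a subgroup label
and a role (wild / ornamental / edible); "cultivated" is the union of the
latter two.

The raw-read filters of a resequencing pipeline (depth, mapping rate) act
upstream of this package's inputs; they are abstracted to two genotype-level
proxies, a minimum called fraction per site (default 0.5) and a minimum
minor-allele frequency (default 0 for scans), both config-exposed.

## Diversity statistics

For one subgroup and window of physical length `L` with `S` segregating
sites among called genotypes:

* π (nucleotide diversity) per site: Σ over usable sites of
  `2·p̂(1−p̂)·n/(n−1)` divided by the effective length, where `p̂` is the
  derived-allele frequency among the `n` called haplotypes at that site.
  This frequency form equals the average over all haplotype pairs under
  dosage expansion (verified in tests against explicit pair enumeration).
  Variant sites with fewer than two called diploids are skipped and the
  effective length reduced accordingly.
* Watterson's θw per site: `S/(a1·L)` with `a1 = Σ_{i<n} 1/i`.
* Tajima's D: `(π_total − S/a1)/√(e1·S + e2·S(S−1))` with the full 1989
  constant set computed at `n = 2 ×` subgroup size. Windows with fewer than
  `S_min = 3` segregating sites give an undefined D (the variance estimate
  is degenerate at tiny S); `S_min` is config-exposed.

Hudson-style Fst is `(π_B − π_W)/π_B`, where π_B is the mean pairwise
difference between haplotypes from different groups and π_W the mean of the
two unbiased within-group values; it is undefined when π_B = 0. ROD
(reduction of diversity) is `1 − π_cul/π_wild` per window, undefined when
the wild window is monomorphic. Both are corroborating statistics, not
detection statistics.

LD is the composite (unphased) r²: the squared Pearson correlation of
dosage vectors over samples called at both sites, with a per-pair MAF
floor (default 0.1, the conventional association-panel setting). The decay
curve bins pairs by distance (default 1 kb bins up to 1 Mb) and reports the
linearly interpolated distance at which mean r² first falls to half its
maximum. On dense cohorts sites are thinned evenly to a per-contig cap
(default 1500) before pairing; thinning is deterministic.

PCA follows the plain 0/1/2 covariance convention: sites are mean-centred
(missing imputed to the site mean), no variance standardisation, sample
coordinates are covariance eigenvectors scaled by the square root of their
eigenvalues, with signs fixed by the largest-magnitude loading.

## Neutral mutation range and the selection scan

Under neutrality D is confined to `[d_min, d_max]` where
`d_min = (2/n − 1/a1)/√e2` and `d_max = (π_max − 1/a1)/√e2` with
`π_max = n/(2(n−1))` for even `n` and `(n+1)/(2n)` for odd `n` (the
maximal per-site pairwise heterozygosity is attained at derived count
`n/2`, respectively `(n±1)/2`). The null density is approximated by a beta
distribution rescaled to that support with mean 0 and variance 1; the
equal-tail 2.5%/97.5% quantiles (computed numerically from the beta CDF,
no lookup table) give the 95% neutral range. The parity-dependent `d_max`
matters: with the even-`n` formula applied to odd `n`, the published
ranges for n = 7 and n = 9 are missed by up to 0.05, while the
parity-correct form reproduces all four published ranges (n = 6..9) to
±0.002.

By default the limits are computed at the subgroup's accession count, not
its haplotype count (`ci_sample_size: accessions|haplotypes`). The
accession convention reproduces the published per-subgroup ranges; both
conventions are available because the mapping from diploid samples to
Tajima's `n` is a modelling choice, and the haplotype convention is the
statistically matched one when D is computed from 2n haplotypes (the
coverage property test uses it for exactly that reason).

A window's **intensity** is its percent distance from the midpoint `m` of
the neutral range, normalised asymmetrically so that each limit sits at
100%: `100·(D−m)/(upper−m)` above the midpoint, `100·(m−D)/(m−lower)`
below. Windows with intensity strictly above 100% (equivalently, D
strictly outside the open range) are candidates in that subgroup. The scan
tiles the genome with disjoint 10 kb windows by default; window and step
are config-exposed.

Candidates are combined on the shared window grid:
`edible_selected = (C ∩ D ∩ E ∩ F) \ A` and
`ornamental_selected = A \ (C ∪ D ∪ E ∪ F)`, with subgroup B ignored by
default (`ignore_subgroups`) as an intermediate subgroup whose candidate
sets overlap all others heavily. Labeled windows are merged into maximal
contiguous regions, annotated with mean ROD and Fst (cultivated vs wild)
and with every gene whose span overlaps the region by at least 1 bp.

## Functional classification

Each SNP receives exactly one genomic context with priority
CDS > 5′ UTR > 3′ UTR > intronic > intergenic. Overlapping genes are each
represented by their longest transcript (ties broken by smallest
transcript ID); the annotation format is silent on how multi-transcript
genes should be counted, so this rule is a documented package choice.
Coding effects substitute the alternate allele into the strand-corrected
codon and translate with the standard genetic code; a reference-allele
mismatch against the FASTA is a hard error. The implementation is checked
for exact agreement against an oracle that rebuilds the mutant genome,
re-splices the transcript and compares full protein sequences.

## QC arithmetic

Mean genotyping accuracy is the mixture `ρ·acc_het + (1−ρ)·acc_hom` with
ρ the heterozygous-call fraction (validation defaults 63.6% / 99.4%).
Pooled variant-calling sensitivity is Σcalled/Σtruth over validation sets.
Group shares are percent-of-total; groups overlap, so shares need not sum
to 100. Reported ratios and percents are rounded to two decimals.

## Synthetic cohort generator

The generator emulates the study design: one wild subgroup (10 accessions,
θ = 2.6×10⁻³ per site, the genome-wide wild diversity scale) and six
cultivated subgroups at the published sample sizes (ornamental A: 8;
edible B–F: 6, 8, 7, 9, 9) with θ = 1.3×10⁻³, on two 200 kb contigs with
10 kb windows and ~20 multi-exon genes per contig on both strands.

Sites are simulated independently per subgroup-window: the number of
segregating sites is Poisson with mean `θ·a1·L`, each site's derived count
is drawn from the mode's frequency spectrum (neutral: `P(i) ∝ 1/i`;
low-frequency excess: `∝ 1/i³`; intermediate excess: Gaussian weights
tightly centred on `n/2`), assigned to a uniform random haplotype subset,
and collapsed to diploid genotypes. Inbreeding acts per accession per site:
with probability F the two alleles are forced identical by descent.
Expected heterozygosity therefore scales by (1−F). The defaults
F = 0.50 (wild) and F = 0.65 (cultivated) place per-accession heterozygous
call ratios at ≈4% and ≈1.5% on the default design — the regime reported
for wild vs cultivated peach, where selfing and graft propagation have
collapsed heterozygosity.

Sweep windows thin S by a configurable `diversity_reduction` factor and
switch the spectrum of affected subgroups. A consequence of realistic
selfing worth stating plainly: at F ≥ ~0.7 the genotype-level D cannot
reach the lower neutral-range limit at all — singleton heterozygotes
collapse into 0/2 dosages, lifting D's floor to about −1.0 against a limit
near −1.7 — so in inbred subgroups only the upper (intermediate-frequency)
exit of the neutral range has detection power. The canonical detectable
sweep used in recovery tests is therefore `intermediate_excess` with
`diversity_reduction = 0.35`: it exits the neutral range upward with
per-subgroup power ≈0.99 while still reducing windowed π (ratio ≈0.6), so
D exceedance and ROD corroboration are exercised together. Outbred
subgroups detect classic low-frequency sweeps with power ≥ 0.9, and the
low-frequency power property is tested in that regime.

Sites are unlinked unless `ld_block_bp` is set, in which case consecutive
sites within a block share one haplotype partition (perfect within-block
association), giving an LD decay with half-decay distance on the order of
half the block length — used to validate the decay estimator, not to model
recombination. With `missing_rate > 0`, calls are masked independently.
Sites left with no called non-reference allele after inbreeding collapse
are dropped (they are not SNP records); with F = 0 no sites are dropped,
so configured sweep-thinning factors are exact in expectation.

Determinism: one `numpy` generator seeded from the spec drives everything,
and identical spec + seed yields byte-identical FASTA/GFF3/VCF/TSV/BED
output.

## What the synthetic cohort does not model — limitations

* No linkage except the artificial block-copy mode; no recombination
  gradient, so LD half-decay distances are a function of the configured
  block length, not of population history.
* No shared polymorphism between subgroups (each subgroup's sites are
  private), so cross-group statistics on the default cohort overstate
  differentiation relative to real sister populations; panmictic Fst
  properties are tested by splitting one simulated population instead.
* Site positions are uniform; no mutation-rate or gene-density covariance.
* Genes are structurally valid (in-frame, spliced, stranded) but their
  sequences are random: codon usage and selective constraint are absent,
  so synthetic Nonsyn/Syn ratios reflect the genetic code alone (≈3), not
  purifying selection.
* Passing tests demonstrate the estimators and the scan logic are correct
  under the generator's assumptions; they do not certify performance on
  real resequencing data. All real-cohort quantities — the cohort's SNP
  totals and θw tables, the specific selected-gene inventories, LD
  half-decay distances of the real groups, and per-accession heterozygosity
  values — depend on the original 84-accession resequencing cohort
  (SRA accession SRA073649, raw reads, deliberately not consumed here) and
  are out of scope for the synthetic pipeline; only their arithmetic
  identities and the method's behaviour under simulation are verified.

## Problem sizes used in tests and the acceptance script

Simulation-backed checks use one- or two-contig cohorts of 40–200 kb with
the full subgroup design (56 accessions), 500-window Monte Carlo for
calibration properties, 50 seeds for sweep recovery, and 10 000 windows
for neutral-range coverage; these sizes give standard errors comfortably
inside the asserted bounds while keeping the default test run in minutes.
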