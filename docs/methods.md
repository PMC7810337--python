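# Methods

`breedtrace` implements the standard genomic toolkit for characterizing a
small livestock breed from SNP-array genotypes: runs of homozygosity (ROH)
and genomic inbreeding, maximum-likelihood admixture, and breed
traceability by discriminant analysis of principal components (DAPC).  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic panels used in testing do and do not establish.

## Genotype representation and quality control

Genotypes are diploid dosages g_ij ∈ {0, 1, 2} of the counted allele, with
a single missing sentinel.  The counted allele is the PLINK `.bim` A1
allele; when reading text `.ped`/`.map` files (which carry no A1/A2
assignment) the minor allele is counted, ties broken by first appearance in
file order.  Merging two panels takes the union of samples over the
intersection of SNP ids, requires chromosome/position agreement, flips
dosage (d → 2−d) when the counted alleles are swapped, and refuses any
other allele mismatch rather than guessing strand for ambiguous A/T and C/G
pairs.

QC applies three filters in a fixed, configurable order: keep autosomes
(labels 1–29 by default, the goat karyotype), keep SNPs with call rate
strictly above 95%, keep samples with missingness strictly below 10%.  The
boundaries are strict because that is how the thresholds are conventionally
quoted; the order is configurable because SNP call rates change if
high-missingness samples are removed first.

## Runs of homozygosity

Detection uses the consecutive method: one left-to-right scan per sample
and chromosome, extending the current run while its allowances hold and
closing it at the first violation.  Parameters (defaults in parentheses)
are the minimum SNP count per run (15), minimum span (1 Mbp), heterozygous
calls allowed inside a run (1, absorbing genotyping error), missing calls
allowed (1), and the maximum inter-SNP gap (1 Mbp; disable with `None`).
Run bounds are the bp positions of the first and last SNP, and length is
the open difference end − start, the convention under which the 1 Mbp
filter is applied.

When a run closes because the next SNP would exceed the heterozygote (or
missing) allowance, the scan restarts after the *first* heterozygous (or
missing) call inside the closed run, so a long run sharing its tail with
the closed window is still found; the end of a chromosome closes a run the
same way.  A consequence worth knowing: reported runs of one sample may
overlap when both the head and tail windows pass the filters.  Every
coverage-derived statistic — per-SNP ROH frequency, islands, F_ROH —
therefore uses the per-sample coverage union, which keeps frequencies and
inbreeding coefficients in [0, 1] regardless of overlap.  Raising the
minimum SNP count or span never increases the number of reported runs
(candidate windows do not depend on those filters); raising the heterozygote
allowance can merge adjacent runs into fewer, longer ones, but never
shrinks the reported coverage.

Lengths are classed into (0,2], (2,4], (4,8], (8,16], (16,∞) Mbp — a
partition, with edges right-closed.  ROH islands are maximal stretches of
consecutive SNPs whose within-breed ROH frequency reaches the threshold
(default 45%), reported with start/end SNP ids, SNP count and bp bounds.
F_ROH is ROH coverage over the total mapped autosome length; the
denominator defaults to the SNP-covered span (last minus first SNP) of each
post-QC autosome, with assembly chromosome lengths accepted as an option.
A breeds × chromosomes matrix of mean ROH counts can be decomposed by
column-centered SVD to place breeds by their ROH profiles.

## Admixture

The model: individual i draws each allele from ancestry k with probability
q_ik (rows of Q on the simplex) and that ancestry contributes the counted
allele with frequency f_kj, so g_ij ~ Binomial(2, π_ij), π = QF, and

    ℓ(Q, F) = Σ_ij [ g_ij log π_ij + (2 − g_ij) log(1 − π_ij) ]

over observed entries.  Fitting uses plain EM — both blocks updated from
one set of responsibilities per iteration — which never decreases ℓ;
quasi-Newton acceleration was deliberately left out in favour of the
provable ascent property, with seeded random restarts (default 3) guarding
against local optima.  Frequencies are clamped to [1e-6, 1−1e-6];
iteration stops when the relative gain drops below 1e-6 (default) or at
2000 iterations, reporting `converged=False` rather than raising.

The number of ancestries K is chosen by entry-masked cross-validation:
observed genotype entries are partitioned into 10 folds, each fold in turn
is hidden and the model refit, and the fold error is the mean squared
difference between hidden dosages and their expected value 2·π̂.  The K
with the lowest mean error wins; ties go to the smallest K.  CV refits use
a looser stopping rule (tol 1e-4, 100–500 iterations) since prediction
error stabilizes long before the likelihood tail.

## DAPC traceability

DAPC is PCA followed by linear discriminant analysis on the retained
scores.  PCA centers on training means (which also serve as imputation
values for missing calls); when loci outnumber samples the rotation comes
from the Gram-matrix eigendecomposition, an exact and much cheaper
equivalent of the thin SVD.  LDA uses the pooled within-class covariance
regularized by ridge·(trace/d)·I (ridge 1e-6; the scale falls back to an
absolute unit when classes are perfectly separated and the trace is zero),
Gaussian posteriors with priors proportional to training class sizes, and
alphabetical tie-breaking.  New samples are always centered with the
*training* means and projected with the training rotation; a sample with no
observed genotype carries no information and receives the prior vector.

The retained-PC count is selected by stratified k-fold CV (default 10
folds × 30 repetitions, candidates every 10 PCs up to 259 or the data
limit), keeping the count with the highest mean assignment success,
smallest on ties.  Classes smaller than the fold count degrade to
leave-one-out with a warning.

Three validation scenarios: (1) supervised — select, fit and report on the
full panel; (2) semi-supervised — repeatedly hold out a few target-breed
samples (default 5 × 10 repetitions), reselect and refit on the remainder,
classify the holdout; (3) unsupervised — the target breed is excluded from
training entirely and its samples (80% drawn per repetition) must be
attributed to the remaining breeds, across training fractions 20–90%.  PC
selection is rerun inside every repetition, so the reported assignment
variability includes selection variability.

## Synthetic panels

The generator draws an ancestral frequency p_j ~ Uniform(0.05, 0.95) per
SNP and breed frequencies f_kj ~ Beta with mean p_j and variance
c·p_j(1−p_j) — the Balding–Nichols model, whose drift parameter c
approximates the breed's F_ST against the ancestral pool (Hudson's
estimator between two breeds simulated at c recovers ≈ c).  Genotypes are
unphased binomial draws at π = QF, so mixed-ancestry individuals follow
directly from a true-Q design.  The default desk-scale panel is 10 breeds
× 25 diploids × 29 chromosomes of 100 Mbp with ~172 SNPs each (~5,000
markers), drift 0.1, and 0.2% missing calls — a miniature of a typical
50k-array multi-breed study.

Autozygosity is planted after genotype draw: non-overlapping intervals
(2–8 Mbp by default) are placed until a target fraction of the genome is
covered, the final interval trimmed toward the exact target, and every SNP
inside is forced homozygous by drawing one allele at π_ij and doubling it.
Ground truth (Q, breed frequencies, planted intervals, realized fractions)
travels with the dataset.

What these panels do not emulate: linkage disequilibrium, recombination
maps, selection, or pedigree structure.  Two consequences for interpreting
green tests.  First, background runs of homozygosity in real 50k data are
genuine signal (LD plus inbreeding) — here they are noise, so
planted-fraction recovery is checked on high-heterozygosity panels
(ancestral frequencies 0.3–0.7, drift 0.02) at 0.033 Mbp marker spacing,
where chance runs are negligible and the detector's boundary overshoot
(runs extend past a planted interval until the heterozygote allowance is
spent, roughly one marker spacing per flank) stays within the 0.02
tolerance.  Second, assignment accuracies on drifted panels bound what the
method does under its own model, not what any particular real breed panel
will give.

## Problem sizes used in tests and the acceptance script

Chosen so the whole suite runs in minutes on one core, and stated here as
the package's own defaults for verification runs: ROH oracle equivalence on
1,000 random 300-SNP chromosomes across 20 parameter settings; F_ROH
recovery at planted fractions 0, 0.05 and 0.20 on 50-sample panels (4
chromosomes × 3,000 SNPs); admixture recovery on K=3 panels with n=120,
m=1,000, c=0.2 (5 seeds), with K chosen from {2..5} by 10-fold CV in 10
seeded runs; DAPC on a 10-breed, 25-per-breed, 5,000-SNP panel at c=0.1
(supervised CV with 3 repetitions over a 10–60 PC grid; 10 semi-supervised
repetitions); leave-breed-out attribution of a 50/50 admixed target among
9 pools over 10 seeds × 3 repetitions with a compact {8, 12} PC grid.
Library defaults remain the full-scale settings described above.

## Known limitations

- No VCF input, liftover, LD pruning, sliding-window ROH, supervised
  admixture, or gene annotation of islands — all out of scope by design.
- The EM optimizer is first-order; on very large panels the cited
  quasi-Newton accelerators converge in far fewer iterations.
- Island calls inherit the per-SNP frequency grid: bounds are SNP
  positions, not interpolated midpoints.
- Text-dialect round-trips preserve genotype content but may re-orient
  per-SNP dosage (the counted allele is re-derived as the minor allele);
  the binary dialect round-trips byte-exactly.
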