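# Methods

This note documents the models, parameter choices and numerical decisions
behind `dnvsex`, and what the synthetic cohorts do and do not establish
about real data.

## Trio de novo posterior with partial origin

Each member's PL vector is converted to normalized likelihoods
`L(g) = 10^(-PL_g/10) / Σ`. Genotype priors are Hardy–Weinberg at the
site's population alt frequency `q`, floored at `af_floor` (default 1e-4)
so that sites absent from the reference panel still receive a proper
prior. The five scenario masses (maternal de novo, paternal de novo,
maternal transmission, paternal transmission, child miscall) are products
of priors, likelihoods, Mendelian transmission factors (1/2 for a het
parent, 1 for a hom-alt parent) and — for the de novo scenarios — a
mutation prior `mu_total` (default 3e-8 per site, the order of the human
per-base per-generation rate) split by `maternal_fraction` (default 0.5).
"The parent is not homozygous [reference] and the allele was inherited" is
read as the parent carrying the alternate allele (het or hom-alt); the
child-miscall scenario defaults to the hom-ref error state, with hom-alt
optionally included.

Properties pinned by tests: the decomposition equals a brute-force
enumeration over all 27 trio genotype configurations to 1e-12 relative
error; `p_dn` is non-increasing in `q` (rarer alleles make the de novo
explanation relatively stronger); `a/(a+b)` equals the maternal prior
share when the parental evidence is symmetric; `p_dn` is invariant to
rescaling all masses.

The printed child gate "AB_child < 0.3" would discard exactly the
well-balanced heterozygotes the caller is meant to keep; the default gate
therefore requires AB_child ≥ 0.3, and a `literal_child_ab` switch honors
the text as printed. The GQ gate applies to the child call. The
recurrence clause removes sites called de novo in ≥ 5 children (recurrent
artifacts); a switch inverts the reading. Paternal-age adjustment of
per-child counts is the OLS residual plus the grand mean — mean-preserving
and orthogonal to age; exact binomial tests use the raw integer counts,
with adjusted rates reported alongside, because an exact test on
continuous adjusted counts is not defined.

## Variant QC

Multiallelic sites are split one record per alt allele; other alt alleles
are localized to reference, AD collapses the remaining depth onto the
reference column, and PL keeps the `{ref, alt}` genotypes re-anchored at
zero. Hom-ref calls whose likelihood arrays were dropped upstream are
reconstructed as `AD = [DP, 0]` and `PL = [0, GQ, 3·DP]`; empty PL slots
are padded with the sample's maximum PL before selection.

The rare- and common-variant cascades use the published cutoff blocks per
genotype class, every inequality inclusive as printed, with two printed
ambiguities resolved as follows: the self-contradictory het allele-balance
constraints ("0.275 ≥ AB ≥ 0.725") are read as inclusive windows
(0.275–0.725 for SNVs, 0.214–0.786 for indels), and "gDP" is the
genotype-level FORMAT DP as opposed to the site's mean depth. The rare
call-rate rule removes sites with call rate below 10%; the common cascade
additionally requires founder allele frequency strictly above 0.05. The AN
floors (4312/3504 called alleles) are cohort-size specific and should be
rescaled for smaller cohorts. Sites failing call-rate or HWE floors are
dropped whole; genotype calls failing a class block are set to missing,
and all rejections are tallied per rule.

Hardy–Weinberg equilibrium uses the exact conditional test (full
enumeration of heterozygote counts given the minor-allele count), computed
in log space because the rare cascade's floor sits at P < 1e-12, far
beyond chi-square accuracy. HWE and internal AF are computed on founders
only, since trio offspring are not independent draws.

Coordinates: VCF positions are 1-based inclusive, BED intervals 0-based
half-open, and region overlap is evaluated on the REF footprint. The
allele-length rule removes alleles of length ≥ 50.

## Polygenic scores

Alleles longer than 13 bp are canonicalized to their first 13 bases plus
the decimal remainder of the length, matching the weight-table dialect.
Matching is positional after normalization; allele-swapped SNPs are
retained as flips (scored on the other allele), strand-ambiguous A/T and
C/G SNPs are excluded, and indel pairs that are reverses of each other at
a locus are excluded because a flip cannot be distinguished from a
different variant. The AF harmonization text conflates a chi-square test
with a 1-SD outlier rule; both are implemented as separable screens
applied conjunctively — a per-SNP chi-square on allele counts (off by
default, enabled by an alpha) and the 1-SD rule on target-minus-reference
AF differences. Note the 1-SD rule removes roughly a quarter of SNPs when
differences are Gaussian; that is a property of the published rule, not of
this implementation. Missing dosages are mean-imputed per SNP.
Standardization is `(x - mean_ref)/sd_ref` against a declared reference
(population or within-family). Group contrasts default to Welch t tests;
the logistic odds ratio is per SD of score with Wald intervals, and
non-convergence or separation is flagged rather than reported.

## Liability-threshold model

Liability is the sum of a Gaussian polygenic component, a rare
large-effect de novo carrier component (centered Bernoulli with carrier
probability 0.02 scaled to its variance share) and a Gaussian residual;
default variance shares are 0.5 / 0.05 / 0.45 and the total is constrained
to 1. Default thresholds (male 1.7, female 2.3 SD) put the upper-tail
prevalence near 4.5% and 1.1%, i.e. roughly the 4:1 affected sex ratio of
an unascertained population. Because the de novo component is a mixture,
the affected tail is exactly Gaussian only when its variance share is
zero; the tests use that configuration when asserting Gaussian-tail
prevalence. Severity strata among the affected are pooled liability
tertiles by default, mirroring the normative / mild-moderate / severe
instrument bands; with a positive threshold gap the most severe stratum
can contain no affected females in the mildest band at all, in which case
the stratum ratio is reported as infinite.

Sex-ratio intervals are Clopper–Pearson on the male proportion mapped to
the ratio scale by `p/(1-p)` — monotone, exact and reproducible. The
stratum odds ratio from a sex-by-stratum table equals the quotient of the
two strata's male:female ratios algebraically; display rounding (ratios to
1 decimal, ORs to 2) happens only at the report layer.

## Synthetic cohorts

The generator's defaults mirror the study design: 673 families, proband
male:female odds 5.6, sibling availability 213/673, paternal ages uniform
on 240–600 months, Poisson de novo counts with slope 0.13 per month and
intercept 13.4 (so the mean per-child count is ~68 at the mean age, the
published aggregate count divided by cases), polygenic shifts of +0.32 SD
(cases) and +0.16 SD (parents, also used for siblings as the familial
background), 30x mean depth, and a 0.5% per-read miscall rate. Inherited
sites are unlinked, drawn from founders in Hardy–Weinberg proportions and
transmitted Mendelianly over a compact pseudo-genome; artifact sites
(truth hom-ref everywhere, child reads contaminated at 15% alt fraction,
0.2 expected per child) exercise caller specificity and are recorded in
the truth ledger alongside the planted de novo events.

The read model draws depth Poisson at the target coverage and alt reads
binomially at the true allele fraction mixed with the miscall rate; PL is
the phred-scaled binomial likelihood over the three dosage hypotheses
(capped at 255), GQ is the gap between the two smallest PLs, and GT the
maximum-likelihood dosage — the same likelihood the caller inverts, which
keeps the noiseless limit exact: with a zero miscall rate every emitted
genotype equals the ledger truth and planted de novos score `p_dn > 0.99`
while inherited hets score `< 0.01`.

Phenotypes follow the liability link: probands' residuals are drawn
truncated above their sex's threshold (ascertainment), all other roles
truncated below; instrument scores (SRS-T, ADOS CSS, ADI-R domains) are
deterministic affine maps of the liability excess over the sex threshold,
truncated to declared instrument ranges, and the cognitive/adaptive scores
(FSIQ, VABS) derive from a second, partially correlated liability
dimension. No generative phenotype model is published; this link is the
package's own minimal choice that yields the qualitative family patterns
(more severe male siblings, higher tolerated polygenic burden in females).

What the synthetic cohorts do **not** emulate: linkage disequilibrium,
chromosome-scale coordinates, X-chromosome inheritance, mosaicism,
instrument psychometrics, and diagnostic ascertainment biases beyond the
threshold conditioning. Passing tests therefore establish the correctness
of the statistics and the caller's behavior under its own read model, not
calibration against real sequencing error processes.

## Problem sizes and determinism

Tests and examples run on scaled-down cohorts (tens of families, hundreds
of sites) chosen so the full suite completes in a few minutes; parameter-
recovery checks use the study-scale designs (900 trios, 696 vs 2500
samples, 20 replicates; liability simulations at 10^6 individuals). All
randomness flows from explicit seeds; identical configuration and seed
reproduce cohorts byte-identically.
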