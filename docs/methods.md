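# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `urometh`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Haplotype extraction

A methylation haplotype is the per-fragment methylation frequency
mf = (methylated CpGs) / (covered CpGs), rounded to one decimal. Rounding is
half-away-from-zero (0.75 → 0.8, 0.65 → 0.7); a fixed, documented rule
avoids platform-dependent banker's rounding. mf is computed over covered
CpGs only; reads covering fewer than half of the amplicon's CpGs are dropped
(configurable `min_cpg_fraction`), and reads covering none are excluded with
their own reason code.

Read QC applies, in order: conversion rate (converted / covered non-CpG
cytosines) < 99% → discard; ≥ 2 unconverted non-CpG cytosines → discard
(applied independently of the rate rule, since both are stated rules even
though they overlap); strand-conversion inconsistency → discard; MAPQ < 30 →
discard (30 passes). A read covering no non-CpG cytosine passes the rate
rule vacuously — an undefined ratio cannot fail. Strand inconsistency is an
operational heuristic: a fragment showing both C→T and G→A conversion
evidence above 5% is treated as both-strand converted. Overlapping mates
sharing a query name are collapsed to one fragment before haplotyping
(first non-missing CpG call wins; conversion counts summed; minimum MAPQ);
duplicate marking is assumed done upstream.

Amplicons with zero passing reads are reported missing, never zero-filled,
so downstream means and tests skip them instead of being biased toward 0.

## Entropy typing

Ent_i = −Σ_j p_ij log p_ij over observed haplotype bins, natural log (the
base only rescales and does not affect t-tests or calls). Entropy needs a
minimum number of fragments to be stable; the default minimum is 20 passing
reads per (sample, amplicon), configurable. Per amplicon, a two-sample
t-test (Welch by default, pooled optional) compares entropies between the
two tumour groups; BH adjustment runs across amplicons; adjusted p < .05 →
T2 (driver), adjusted p ≥ .05 → T1 (passenger) — the boundary value is T1.

## Signature features

Each (amplicon, bin) haplotype is tested in three pairwise contrasts
(HG vs LG, HG vs urine, LG vs urine) with BH adjustment within each
contrast family. A class requires the candidate group to be higher in
*both* of its contrasts, each individually significant (adjusted p ≤ .001)
with mean frequency ≥ 10% in the higher group; the location statistic for
the 10% rule is the group mean. This conjunction makes the three classes
mutually exclusive. An empty class yields a 0 feature with a warning so the
GLM design stays well-defined.

Reference profiles are per-class mean haplotype-frequency vectors on the
training samples. NNLS (Lawson–Hanson active set, via `scipy.optimize.nnls`)
decomposes a sample into LG/HG/Urine components; weights are reported raw
and never renormalized — they are similarities, not proportions. Missing
entries are dropped pairwise from sample and references.

## Score models

UCAS and BLCAS are Gaussian-family GLMs with identity link on a 0/1 class
indicator — exactly OLS on the binary response, implemented as such (no
logistic substitution). Rank-deficient designs raise an error naming the
collinear predictors. Default decision cutoffs are 0.42 (UCAS) and 0.52
(BLCAS); a score exactly at the cutoff is called positive/basal-like.
The cutoffs are treated as configurable constants. Models serialize to a
plain-text key-value file for audit.

## DMR discovery

All coordinates are 0-based half-open (BED native). Loci missing in more
than half of either group are skipped. t-tests are Welch by default with a
pooled-variance option.

* DML: locus t-test p < .01 **and** |Δβ| > .1 (both strict).
* Initial DMRs: DML within 100 bp merge; singletons become width-1 intervals.
* Seed DMRs: the region-mean beta is re-tested; p < .01 (strict) survives.
* CBS: the per-locus Δβ track is segmented recursively. At each step the
  arc (i, j] maximizing the pooled two-sample t-statistic between inside and
  outside loci is found (arcs keep ≥ 2 loci on each side); the split is
  accepted if its within-segment permutation p-value (default 1000
  permutations, early exit once significance is impossible) is below
  α = .01. Segments shorter than 4 loci are never split. An explicit seed is
  required. Output segments always partition the input loci.
* Segment clustering: k-means (default k = 3 — hypo/neutral/hyper; the
  cluster count is an open choice) on segment mean Δβ. A cluster is selected
  iff one of its segments fully contains a seed DMR (segment ⊇ seed; the
  containment direction is ambiguous in prose descriptions of this
  procedure and is flagged for review), and all segments of selected
  clusters become candidates.
* Accessibility filter: candidates must overlap a peak by ≥ 1 bp.
* Core selection: per-candidate sample mean betas are Z-normalized; samples
  are Ward-clustered (default cut k = 2, reported for inspection); each
  candidate's hyper-methylation state (sample mean beta above the
  per-candidate median — the dichotomization is an open choice) is tested
  against the pathology label by Fisher's exact test, BH-adjusted, retained
  at p < .05. The Fisher test is the operationally defined retention rule;
  the unsupervised grouping is exposed alongside it.

## Evaluation statistics

`fisher_exact` follows the R `fisher.test` convention: two-sided p by
probability-mass summation over the hypergeometric support at OR = 1 (the
dominant convention; doubling is an alternative not used here), conditional
MLE odds ratio, and an exact CI from inverting the conditional noncentral
hypergeometric test. Zero-cell tables give OR 0 or ∞ with one-sided
intervals. scipy provides the solver; the test suite cross-checks p-values
against an independent full-enumeration oracle and verifies that the CI
endpoints carry α/2 tail mass.

AUC is the Mann–Whitney statistic over n1·n0 with ties counting ½.
BH adjustment is the standard step-up procedure with monotonicity
enforcement.

The limit of detection of a scored dilution series follows the 2× rule:
each fraction is compared with the next lower dilution (ending at the
blank) by a two-sided Student's t-test; the smallest fraction with p < α
(default .05) is doubled. If no fraction separates, the result is flagged
not-reached. Comparisons with fewer than two replicates are skipped with a
warning; if both groups are exactly constant the p-value is taken as 0 when
the means differ and 1 when they agree (the vanishing-noise limit).

## Synthetic-data generator

The generator emulates the three reference tissue classes — LG tumour, HG
tumour, normal urine — at the level of per-amplicon haplotype
distributions on the 11 bins, with these committed defaults:

* Urine background per amplicon: a dominant "home" bin at 0.9 prevalence
  (home ∈ {0.0, 0.1} per amplicon) with 0.1 on the adjacent bin — normal
  urothelium is epigenetically stable but not perfectly homogeneous.
* T1 (passenger) amplicons: both tumour classes share a dominant tumour
  haplotype ({1.0: 0.85, 0.9: 0.15}); tumour-vs-urine signal without grade
  information.
* T2 (driver) amplicons: LG carries a low-diversity tumour haplotype
  ({0.5: 0.7, home: 0.3}); HG spreads 0.9 of its mass uniformly over
  2 + round(entropy_contrast) tumour-specific bins (plus 0.1 on home).
  Tumour-specific haplotypes have exactly zero prevalence in urine,
  reflecting the driver-DMR concept that these epialleles arise de novo in
  cancer cells.
* Class profiles interpolate between the urine background and the class
  target with weight s = entropy_contrast / 2 (clipped to [0, 1]):
  `entropy_contrast = 2` is full contrast and the default study condition;
  0 collapses all classes onto urine (no signal, classifiers at chance).
* Reads: 10 CpGs per amplicon (the smallest count for which every bin is
  expressible as an integer methylated-CpG ratio; the methylated count is
  sampled uniformly among counts whose ratio rounds to the drawn bin),
  10 isolated non-CpG cytosines (escaping conversion at rate 0.003 each, so
  ≈ 3% of reads fail the conversion-rate rule), and 2% of reads at MAPQ 20
  (rest 60) — the QC filters are genuinely exercised.
* Cohort donors: Dirichlet dispersion around the class profile
  (concentration 300) on the profile's support — zero bins stay exactly
  zero. Within-class dispersion across donors is not quantified anywhere
  we could anchor it; 300 gives coefficient-of-variation a few percent on
  dominant bins, a moderate, realistic choice made once.
* Dilution series: exact convex mixtures fraction·tumour + (1−fraction)·urine,
  sampled as multinomial counts at the configured coverage. Replicates of a
  fraction are technical replicates of the same mixture, as in a serial
  dilution of pooled material. The default fraction list is
  100/20/10/5/2.5/1/0.5/0.1%, plus blanks.
* Count-level vs read-level paths: the dilution and cohort generators draw
  haplotype counts directly from the profile (multinomial), which is
  distributionally identical to simulating reads and extracting them when
  conversion failures touch only non-CpG cytosines, as modelled. The
  read-level path (SAM + reference FASTA, one contig per amplicon) is used
  to exercise parsing and QC end to end.

WGBS-like beta matrices place CpGs at 30–150 bp spacings with per-locus base
levels uniform on [0.2, 0.6] and Gaussian per-sample noise (sd 0.08,
clipped to [0, 1]); planted DMRs shift the case-group mean by the requested
effect. An accessibility-peak BED covers a configurable subset of planted
DMRs plus an optional decoy peak.

What the generator does **not** emulate: PCR duplicates and UMIs,
sequencing error beyond bisulfite conversion failure, indels, CpG-site
conversion failure (which would leak a small amount of apparent methylation
into unmethylated backgrounds), batch effects, and fragment-length
variation. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean assay model, not robustness to every
artefact of real libraries.

## Problem sizes and the detection limit

Module tests run at 400 reads/amplicon with 16+16+12 cohorts; the
dilution-series experiment in the acceptance script uses the full study
condition (2000 reads/amplicon, 5 replicates per fraction, 20 amplicons).
DMR discovery tests use 200 CpG loci, 10 vs 10 samples, effect 0.3 and 1000
CBS permutations.

The 2×-rule detection limit of the UCAS score on this generator is
coverage-limited. At 2000 reads/amplicon the blank-score standard deviation
(≈ 2.6 × 10⁻³, driven by multinomial noise on the urine-background
features) exceeds the score shift of a 0.1% mix-in (≈ 1 × 10⁻³, since the
score is affine in the mix-in fraction), so the smallest fraction that
separates from the next lower dilution is 0.5% and the reported LoD is
2 × 0.5% = 1%. Raising per-amplicon coverage to ~10⁵ — the regime of a
multi-million-read amplicon library over ~20 amplicons — shrinks the
multinomial noise ~7-fold and the same pipeline separates 0.1% from blank,
giving LoD 0.2%, i.e. below half a percent. Sub-half-percent detection at
2000 reads/amplicon would require an essentially noise-free urine
background (a point-mass profile on every amplicon), which we consider
unrealistically clean; the generator's committed background stands.

## Reproducibility

Every stochastic component takes an explicit seed (numpy `default_rng` with
`SeedSequence` namespacing); reruns with the same configuration are
bit-identical, which the pipeline manifest verifies by output hashing.
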