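# urometh

Urine ctDNA methylation-haplotype analysis for bladder cancer: from aligned
bisulfite amplicon reads to methylation haplotypes, epiallele-entropy
driver/passenger DMR typing, trait-associated haplotype classes, NNLS
tissue-of-origin decomposition and the UCAS/BLCAS cancer scores — plus a
synthetic-data generator so the whole pipeline is testable with known ground
truth and no external data.

## Who this is for

Bladder cancer (BLCA) sheds tumour DNA into urine. Methylation changes at
tumour-specific differentially methylated regions (DMRs) are abundant and
biologically stable markers of that DNA, so targeted bisulfite amplicon
sequencing of urine cfDNA can detect and classify tumours non-invasively.
This package implements the statistical core of such an assay for people
building or evaluating methylation liquid-biopsy pipelines.

## The model

**Methylation haplotypes.** Each sequenced fragment on an amplicon carries a
joint CpG methylation pattern, summarized as the read methylation frequency
mf = C_CpG / N_CpG rounded to one decimal, giving 11 haplotype bins
0.0, 0.1, …, 1.0. Per sample and amplicon, haplotype *j* has relative
prevalence p_j = N_j / Σ_i N_i. Reads with conversion rate < 99%, ≥ 2
unconverted non-CpG cytosines, inconsistent strand conversion or MAPQ < 30
are removed first.

**Epiallele entropy and DMR typing.** The haplotype entropy index of an
amplicon in a sample is Ent = −Σ_j p_j log p_j (nats). Passenger (T1) DMRs
inherit a low-diversity haplotype spectrum from the tumour's ancestral cell
type; driver (T2) DMRs acquire methylation de novo and show elevated entropy
in high-grade disease. A per-amplicon t-test on entropies between tumour
groups with Benjamini–Hochberg adjustment types each amplicon: adjusted
p < .05 → T2, otherwise T1.

**Signature features.** Haplotypes significantly higher (BH-adjusted
p ≤ .001, mean frequency ≥ 10% in the higher group) in one tissue class than
in *both* others form the HG_high / LG_high / Urine_high classes; a sample's
class feature is its mean prevalence over that class. Non-negative least
squares decomposes each sample's haplotype-frequency vector into
LG/HG/Urine reference components (similarities).

**Scores.** Two Gaussian-family GLMs (identity link, i.e. OLS on a 0/1
response):

    UCAS  ~ Urine_high + HG_high + LG_high + Urine_similarity   (cutoff 0.42)
    BLCAS ~ HG_high + LG_high                                   (cutoff 0.52)

UCAS separates cancer tissue from normal urine; BLCAS separates high-grade
(basal-like) from low-grade (luminal-like) tumours. High risk = UCAS
positive or BLCAS basal-like.

**DMR discovery** (from WGBS-like beta matrices) chains DML calling
(t-test p < .01 and |Δβ| > .1), 100-bp merging, seed-region re-testing,
circular binary segmentation of the Δβ track (permutation-tested max-t
arcs), k-means segment clustering with seed containment, accessibility-peak
filtering and Fisher-test core-DMR selection against pathology labels.

## Worked example

Train on a synthetic labelled cohort (16 HG + 16 LG tumour tissues, 12
normal urines at 2000 reads/amplicon), then score held-out donors:

```python
from urometh import (SimulationConfig, simulate_cohort, HaplotypeSignature,
                     fit_ucas, fit_blcas, roc_auc)
from urometh.models import score_samples

cfg = SimulationConfig(seed=11, coverage=2000)
train = simulate_cohort(cfg, n_hg=16, n_lg=16, n_urine=12)
test = simulate_cohort(cfg, n_hg=8, n_lg=8, n_urine=8, donor_seed=99)

sig = HaplotypeSignature().fit(train.haplotype_table, train.truth["class"])
X = sig.transform(train.haplotype_table)
y = (train.truth["class"] != "URINE").astype(int).reindex(X.index)
ucas = fit_ucas(X, y)
tissue = X[y == 1]
blcas = fit_blcas(tissue, (train.truth.loc[tissue.index, "class"] == "HG").astype(int))

scores = score_samples(ucas, blcas, sig.transform(test.haplotype_table))
print(scores.groupby(test.truth["class"])[["ucas_score", "blcas_score"]].mean().round(3))
```

prints

```
       ucas_score  blcas_score
class
HG          1.000        1.001
LG          0.999        0.002
URINE       0.005        0.257
```

Held-out UCAS AUC is 1.000 on this cohort: tumour tissue scores sit at the
cancer pole (≈ 1, above the 0.42 cutoff), urine at ≈ 0, and BLCAS separates
HG (basal, ≈ 1) from LG (luminal, ≈ 0) at the 0.52 cutoff. The evaluation
module reproduces clinical 2×2 comparisons exactly, e.g. UCAS vs FISH
sensitivity in low-grade tumours (16/26 vs 33/118):

```python
from urometh import fisher_exact
r = fisher_exact([[16, 10], [33, 85]])
# OR = 4.08 [1.56, 11.17], p = 0.002349  (conditional MLE, exact CI)
```

A command-line interface mirrors the stages
(`urometh simulate | extract | discover | type-dmr | signature | features |
train | score | eval | run-all`).

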