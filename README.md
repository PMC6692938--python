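# cptmethsig

DNA-methylation signature discovery and validation for choroid plexus
tumors (CPTs), as a tested, reusable pipeline.

Choroid plexus carcinomas (CPC, WHO grade III) need aggressive treatment,
while papillomas (CPP, grade I) and atypical papillomas (aCPP, grade II)
mostly do not — but histology separates them imperfectly. The pipeline
starts from an Illumina 450K-style beta-value matrix (β = mC/(mC+C) per CpG
probe, β ∈ [0,1]) and derives a carcinoma-specific methylation signature,
validates it without selection leakage, and links it to regulatory genomic
context, gene expression, and patient outcome. A first-class synthetic
cohort generator plants known differential CpGs, TP53-subgroup structure,
group-dependent hazards, and expression-linked genes, so every stage is
testable end to end without array downloads.

## Stages

1. **Probe filtering** — drop sex-chromosome, SNP-proximal (variant within
   5 bp at MAF ≥ 1%), internal-control, cross-reactive, and unannotated
   probes, with a per-rule exclusion report.
2. **Differential methylation** — per-CpG two-sided Mann–Whitney *U*
   (carcinoma vs papilloma, aCPP pooled with CPP), Benjamini–Hochberg FDR,
   and Δβ = β̄_carcinoma − β̄_papilloma. Two signature tiers:
   *tier 1*: q < 0.05 and |Δβ| ≥ 0.30; *tier 2* (biomarker grade):
   q < 0.001 and |Δβ| ≥ 0.40.
3. **Genomic-context enrichment** — two-sided Fisher exact tests of the
   signature against the retained-probe background over enhancer, DHS,
   cDMR, rDMR, and CpG island/shore/shelf/open-sea categories.
4. **Methylation–expression concordance** — signature genes whose promoter
   (TSS1500/TSS200/5'UTR/1st exon) methylation is inverse to expression, or
   whose gene-body methylation is positively concordant, requiring
   expression q < 0.05.
5. **Classification** — leave-one-out cross-validation in which the tier-2
   signature is re-derived from the 33 retained samples of every fold
   (never touching the held-out sample), optional correlation-based
   feature selection (CFS merit
   `k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)` with forward best-first search), and
   ridge-logistic or Gaussian naive Bayes models; sensitivity, specificity
   and AUROC over pooled held-out scores.
6. **Clustering / PCA** — two-way hierarchical clustering (1 − Pearson or
   Euclidean distance, average/complete/Ward linkage), k-group cuts,
   sign-stabilized PCA, and projection of the signature onto external
   cohorts.
7. **Survival** — Kaplan–Meier estimates, k-sample log-rank and
   Gehan–Wilcoxon χ² tests (weights 1 and n-at-risk respectively), and
   death/recurrence frequency tables by methylation subgroup or diagnosis.
8. **Factor analysis** — maximum-likelihood factor extraction with varimax
   rotation over signature betas jointly with 0/1-coded clinical
   covariates.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (5000 probes; 34 samples: 14 CPC with 5 TP53-hom / 7 het / 2 wt,
5 aCPP, 15 CPP; 60 probes planted at Δβ = 0.40 and 140 at 0.30):

```sh
python analysis/01_simulate_cohort.py        # writes results/cohort/
python analysis/02_filter_probes.py
python analysis/03_differential_methylation.py
...
python analysis/09_factor_analysis.py
```

Output of the central stages (seed 11):

```
tier1: 199 probes (111 hyper/88 hypo); recall of >= 0.3 planted probes 99.5%, false discoveries 0
tier2: 60 probes (36 hyper/24 hypo); recall of >= 0.4 planted probes 100.0%, false discoveries 0
enriched categories (q<0.05, OR>1): enhancer, dhs, cdmr, rdmr, open_sea
promoter-inverse genes: 10; body-positive genes: 7; union: 17
logistic_full_signature: sensitivity 100.0%, specificity 100.0%, AUROC 100.0%
k=3 clusters: {1: 20, 2: 5, 3: 9}
methylation_cluster logrank: chi2 = 20.4 (df=2), p = 3.8e-05
replication: coverage 100.0% of signature probes, k=2 carcinoma/papilloma ARI 1.00
```

Reading: the tiered extraction finds essentially all planted differential
CpGs with no false discoveries; the signature is enriched exactly in the
planted regulatory categories (and not in shores/shelves); the planted
promoter/body expression links are recovered; leave-one-out classification
is perfect under this much signal; the k=3 cut separates papillomas (n=20)
from TP53-homozygous carcinomas (n=5) and the remaining carcinomas (n=9),
and the methylation grouping stratifies survival while a new cohort drawn
from the same probe architecture reproduces the carcinoma split.

The same pipeline runs from TSV inputs (beta matrix, probe annotation,
sample metadata, optional expression) through the `cptmethsig` CLI:

```sh
cptmethsig run --config config.yaml --out rundir
cptmethsig simulate|filter|diffmeth|enrich|methexpr|crossval|cluster|survival|factors --help
```

## Layout

- `src/cptmethsig/` — library: `io`, `simulate`, `filtering`, `diffmeth`,
  `enrichment`, `meth_expr`, `classify`, `cluster`, `survival`, `factors`,
  `pipeline`, `cli`, `plots`
- `analysis/` — numbered narrative drivers writing under `results/`
- `tests/` — pytest suite (unit, property, and acceptance tests)
- `docs/methods.md` — modeling and design notes
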