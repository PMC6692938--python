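# Methods notes

## The statistical procedure

Per CpG probe the carcinoma/papilloma contrast is a two-sided Mann–Whitney
*U* test on beta values. The exact null distribution of *U* is used when
the combined non-missing sample count is ≤ 25 and the probe has no tied
values; otherwise the tie-corrected normal approximation with continuity
correction. *U* is reported for the carcinoma group. P-values are adjusted
by Benjamini–Hochberg step-up with monotonicity enforcement, so q ≥ p
always holds. Effect size is Δβ = β̄_carcinoma − β̄_papilloma ("hyper" means
hypermethylated in carcinomas); aCPP samples are pooled with CPP as
"papilloma" throughout, matching the predictive-modeling labeling. Tier
thresholds are strict on q and non-strict on |Δβ| ("at least"): tier 1 is
q < 0.05 ∧ |Δβ| ≥ 0.30, tier 2 is q < 0.001 ∧ |Δβ| ≥ 0.40, which makes
tier 2 ⊆ tier 1 by construction. Missing betas use pairwise deletion per
probe; a probe with an empty group is skipped and logged.

Enrichment uses two-sided Fisher exact tests on 2×2 tables of signature
vs non-signature membership per category, with the sample odds ratio
(a·d)/(b·c) (Haldane 0.5 correction when a cell is zero) and BH adjustment
across the eight categories. The background defaults to the retained
(post-filter) probes, which removes filtering-induced composition bias;
the full-manifest background is available by passing the unfiltered
annotation. The island-relation categories merge N_/S_ shores and shelves,
so {island, shore, shelf, open sea} partition the probes.

Methylation–expression "correlation" is operationalized as sign
concordance of group-level differences with dual significance: the
deliverable of this stage is gene counts, not per-sample correlation
coefficients.
Differential expression (log2FC, q) is consumed as input, not recomputed;
a gene is promoter-inverse when ≥ 1 promoter probe (TSS1500, TSS200,
5'UTR, 1st exon; promoter takes precedence over body when transcripts
disagree) has Δβ opposite in sign to the gene's log2FC with expression
q < 0.05, and body-positive analogously with equal signs. Multi-gene
probes contribute to every annotated gene.

Classification is deliberately leakage-free: inside each leave-one-out
fold the tier-2 signature is re-derived from the retained samples only,
CFS (if enabled) runs on that fold signature, and the model never sees the
held-out sample. CFS merit is k·r̄_cf / sqrt(k + k(k−1)·r̄_ff) with
absolute Pearson correlations (point-biserial against the binary class);
Weka's CfsSubsetEval instead uses symmetrical uncertainty after
discretization — a declared deviation; selected subsets can differ.
Search is forward best-first with a 5-non-improving-expansion stop
(Weka's BestFirst default), ties broken toward the lexicographically smallest
subset. Note an algebraic subtlety of the merit: duplicating a feature
whose class relevance exceeds the subset mean *can* raise the merit (it
raises r̄_cf faster than the redundancy term grows); what is exactly true
is that a subset of k copies of one feature has the merit of one copy, so
the search never benefits from retaining duplicates. The logistic model
uses ridge λ = 1e−8 — near-unpenalized, but enough to keep coefficients
finite under complete separation, which is the expected regime for a
strong signature; odds ratios are per unit of β. Gaussian naive Bayes uses
empirical class priors. AUROC is computed over pooled held-out scores.
A fold with an empty signature predicts the class prior and is logged.

The k-sample survival tests accumulate, at each distinct event time, the
per-group observed minus hypergeometric-expected events and the
multivariate hypergeometric covariance, weighted by 1 (log-rank) or by the
total number at risk (Gehan–Breslow, emphasizing early differences); χ²
uses a generalized inverse of the covariance of the first k−1 groups with
k−1 degrees of freedom. Censoring times tied with an event time remain at
risk at that time. The weighted (O−E) sign convention is "positive =
excess deaths"; with no censoring and distinct times the Gehan numerator
equals the pairwise losses-minus-wins count of the Mann–Whitney form.
Kaplan–Meier estimation is delegated to lifelines.

Factor analysis standardizes the attributes (signature betas plus 0/1
covariates: TP53 mutant, death, recurrence, adult) and uses
maximum-likelihood extraction with varimax rotation (n = 12 factors by
default), with a deterministic LAPACK SVD. Two properties worth knowing:
varimax deliberately redistributes a general factor across columns, so
"one dominant factor" statements refer to the unrotated extraction; and
with finite samples single pure-noise attributes can reach communalities
well above the textbook near-zero (≈ 0.3–0.6 at n = 200–1000 in our
measurements), while the *average* communality of noise attributes stays
low — tests bound the mean, not the maximum.

## The synthetic cohort generator

The generator emulates the study conditions, not array physics. Defaults:

- **Cohort** — 34 samples: 14 carcinomas (5 TP53-homozygous, 7
  heterozygous, 2 wild-type), 5 aCPP, 15 CPP. These counts model the canonical
  CPT discovery-cohort composition: a papilloma majority with carcinomas
  enriched for TP53 mutation, at the sample sizes typical of this rare
  tumor.
- **Betas** — per probe a baseline mean from a three-component mixture
  (weights 0.4/0.2/0.4 at means 0.10/0.50/0.85 with 0.03 jitter): the
  standard bimodal 450K shape with an intermediate shoulder. Sample betas
  are Beta-distributed with that mean and precision κ = 50
  (variance m(1−m)/(κ+1), i.e. per-sample noise ≈ 0.07 sd at m = 0.5),
  clipped to (0,1) strictly. Beta noise was chosen over logit-normal
  because its support matches β ∈ [0,1] by construction.
- **Planted signal** — configurable blocks of differential probes
  (default 60 at Δβ = 0.40 and 140 at 0.30, ≈ 1% of probes), 59%
  hypermethylated in carcinomas (the tier-1 direction split). Shifts are
  applied on the mean scale; baselines are clipped so that the *full*
  planted architecture (main shift plus subgroup shift) fits inside
  [0.02, 0.98] — planted effects are never attenuated by boundary
  clipping.
- **TP53 subgroup** — homozygous-mutant carcinomas carry an extra shift of
  0.12 (≈ one third of the biomarker-tier effect) in the planted
  direction on a configurable fraction of planted probes (default all),
  making the hom subgroup globally more aberrant across the signature —
  the TP53-homozygous tumors are the epigenetically most deviant group. Because this shift amplifies the
  same CpG pattern, correlation distance — which is scale-free — cannot
  see it; the signature-level trichotomy is therefore assessed with the
  Euclidean metric, the conventional choice for signature-heatmap
  clustering.
- **Annotation** — flag rates: 3% sex-chromosome, 2% SNP-proximal, 0.5%
  control, 2% cross-reactive, assigned only among non-planted probes (the
  planted signature must survive filtering, as the real signature survived
  the real filters). Regulatory enrichment is planted: enhancer 40% vs
  10% background, DHS 45%/12%, cDMR and rDMR 20%/5%; island relations
  skew planted probes toward open sea while keeping shore/shelf fractions
  at background level, so the planted signature is enriched in
  enhancer/DHS/DMR/open-sea context but not at shores or shelves, the
  pattern the enrichment stage is designed to detect.
- **Outcome** — exponential survival with hazards 0.060 / 0.020 / 0.002
  events/month for hom-carcinoma / other-carcinoma / papilloma (median
  ≈ 12, 35, 350 months — a severe, an intermediate, and a benign course)
  under independent uniform censoring over a 120-month follow-up window;
  recurrence uses doubled hazards.
- **Expression** — 10 promoter-linked and 7 body-linked genes among the
  planted probes; linked genes get log2FC = ∓3·Δβ (promoter inverse, body
  positive) with per-sample Gaussian noise (sd 0.3) and q = 1e−4;
  unlinked genes are null with q ∈ [0.2, 1].
- **Randomness** — two seeded streams: an *architecture* stream (planted
  probe identities, annotation, gene links, baselines) and a *sampling*
  stream (patients: betas, outcomes, expression noise). A replication
  cohort shares the architecture seed and changes the sampling seed: same
  biology, new patients. Identical seeds give byte-identical output.

What the generator does **not** emulate: type I/II probe chemistry, batch
effects, cell-composition mixtures, detection p-values, spatially
correlated probes (DMRs), or non-exponential hazards. Passing tests
therefore demonstrate correctness of the statistical machinery and its
leakage control under the assumed generative model, not robustness to
array artifacts.

## Numerical and design choices

- Probe-filter rules apply in a fixed precedence (sex chromosome →
  SNP-proximal → control → cross-reactive → unannotated); a probe is
  counted under its first matching rule so the report partitions the
  input. SNP proximity and cross-reactivity are consumed as precomputed
  flags rather than recomputed from variant catalogs, whose versions
  drift.
- Mann–Whitney on a complete matrix is a vectorized scipy call (one exact
  call for tie-free probes, one asymptotic call for tied probes at small
  n); matrices with missing cells fall back to a per-probe loop with
  pairwise deletion.
- Hierarchical clustering cuts trees with a maxclust criterion;
  determinism follows from scipy's fixed merge order. Ward linkage is
  restricted to the Euclidean metric. Only the sample tree drives group
  assignments; the probe tree is computed on request for two-way
  heatmaps.
- PCA fixes each component's sign so its largest-magnitude loading is
  positive, making projections reproducible.
- The pipeline's single seed feeds the simulation; downstream stages are
  deterministic, so a rerun with the same config and seed is
  byte-identical (asserted in tests).
- Problem sizes in tests and the acceptance script (2000-probe benchmark
  cohort, 1000-probe null replicates, 300–600-probe property-test
  cohorts) are chosen as the smallest sizes at which the examined
  quantities are stable; the statistics are scale-free in the probe
  dimension.

## Known limitations

- Reproducing any particular cohort's headline counts (retained-probe
  totals, signature sizes, survival χ² values) depends on the deposited
  cohort data and the exact manifest/exclusion-list versions; this
  artifact reproduces the *procedure* and validates it on planted
  synthetic truth. The pipeline ingests real beta/annotation/metadata TSVs
  of the documented schema unchanged.
- Multilayer perceptron, SVM, and random-forest model variants are out of
  scope; logistic regression and Gaussian naive
  Bayes exercise the validation procedure.
- Region-level (DMR) calling, covariate-adjusted models, Cox regression,
  and competing risks are out of scope.
- CFS uses Pearson-based correlations, not Weka's discretized symmetrical
  uncertainty; selected subsets can differ.
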