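"""Synthetic choroid plexus tumor cohort generator.

Emulates the statistical structure the downstream stages assume: a 450K-style
beta matrix with group-structured planted differential CpGs, manifest-like
probe annotation, outcome metadata with group-dependent hazards, and
expression values sign-linked to planted promoter/body methylation.

Per probe a baseline methylation level is drawn from a three-component
mixture (hypomethylated / intermediate / hypermethylated, the classic
bimodal-with-shoulder 450K shape). Sample betas are Beta-distributed with
that mean and precision ``kappa`` (variance m(1-m)/(kappa+1)), which keeps
support inside (0, 1). Differential probes shift the carcinoma-group mean by
the planted delta-beta, hypermethylated in carcinomas for the configured
majority fraction; a subset of planted probes carries an extra shift in
TP53-homozygous carcinomas, mirroring the TP53-driven methylation subgroup.
Survival is exponential with a per-group hazard under independent uniform
censoring over the follow-up window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (BetaMatrix, ExpressionMatrix, ISLAND_RELATIONS)

# methylation subgroup labels used for hazards and clustering truth
GROUP_CPC_HOM = "cpc_hom"
GROUP_CPC_OTHER = "cpc_het_wt"
GROUP_PAPILLOMA = "papilloma"


@dataclass(frozen=True)
class PlantedTier:
    """A block of differential probes with a common target delta-beta."""
    n_probes: int
    delta_beta: float


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the discovery cohort: 34 samples — 14 carcinomas (5
    TP53-homozygous, 7 heterozygous, 2 wild-type), 5 atypical papillomas and
    15 papillomas — with ~1% differential probes, 59% of them
    hypermethylated in carcinomas.
    """

    n_probes: int = 20_000
    n_cpc_hom: int = 5
    n_cpc_het: int = 7
    n_cpc_wt: int = 2
    n_acpp: int = 5
    n_cpp: int = 15
    planted: tuple[PlantedTier, ...] = (PlantedTier(60, 0.40), PlantedTier(140, 0.30))
    hyper_fraction: float = 0.59          # planted probes hypermethylated in CPC
    mixture_weights: tuple[float, float, float] = (0.40, 0.20, 0.40)
    mixture_means: tuple[float, float, float] = (0.10, 0.50, 0.85)
    kappa: float = 50.0                   # beta-noise precision
    tp53_extra_delta: float = 0.12        # extra shift in hom samples
    tp53_extra_fraction: float = 1.0      # fraction of planted probes carrying it
    # per-group death hazards, events/month
    hazard_cpc_hom: float = 0.060
    hazard_cpc_other: float = 0.020
    hazard_papilloma: float = 0.002
    recurrence_hazard_scale: float = 2.0  # recurrence hazard = scale * death hazard
    follow_up_months: float = 120.0
    # annotation composition
    frac_sex_chrom: float = 0.03
    frac_snp_proximal: float = 0.02
    frac_control: float = 0.005
    frac_cross_reactive: float = 0.02
    enhancer_rate: tuple[float, float] = (0.10, 0.40)   # (background, planted)
    dhs_rate: tuple[float, float] = (0.12, 0.45)
    cdmr_rate: tuple[float, float] = (0.05, 0.20)
    rdmr_rate: tuple[float, float] = (0.05, 0.20)
    island_background: tuple[float, ...] = (0.31, 0.12, 0.11, 0.05, 0.05, 0.36)
    island_planted: tuple[float, ...] = (0.15, 0.11, 0.11, 0.05, 0.05, 0.53)
    # expression link
    n_promoter_linked: int = 10
    n_body_linked: int = 7
    expression_link_strength: float = 3.0  # |log2FC| per unit planted delta-beta
    expression_noise_sd: float = 0.30
    cohort_label: str = "discovery"
    seed: int = 0
    # architecture (planted probes, annotation, gene links) is drawn from its
    # own stream so a replication cohort can share the underlying biology
    # while sampling new patients; defaults to the cohort seed
    architecture_seed: int | None = None

    def validate(self) -> None:
        probs = [self.hyper_fraction, self.tp53_extra_fraction,
                 self.frac_sex_chrom, self.frac_snp_proximal,
                 self.frac_control, self.frac_cross_reactive,
                 *self.mixture_weights, *self.mixture_means,
                 *self.island_background, *self.island_planted]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0,1]")
        sizes = (self.n_cpc_hom, self.n_cpc_het, self.n_cpc_wt,
                 self.n_acpp, self.n_cpp)
        if any(s < 0 for s in sizes):
            raise ValueError("group sizes must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if min(self.hazard_cpc_hom, self.hazard_cpc_other,
               self.hazard_papilloma) <= 0:
            raise ValueError("hazards must be > 0")
        n_planted = sum(t.n_probes for t in self.planted)
        if n_planted > self.n_probes:
            raise ValueError(
                f"{n_planted} differential probes exceed {self.n_probes} probes"
            )
        n_linked = self.n_promoter_linked + self.n_body_linked
        if n_linked > n_planted and n_linked > 0 and n_planted > 0:
            raise ValueError("more expression-linked genes than planted probes")
        if n_planted == 0 and n_linked > 0:
            raise ValueError("expression links require planted probes")


@dataclass
class SimulatedCohort:
    beta: BetaMatrix
    annotation: pd.DataFrame
    metadata: pd.DataFrame
    expression: ExpressionMatrix
    truth: pd.DataFrame  # per-probe planted status and effect


def _sample_labels(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for diag, tp53, group, n in (
        ("CPC", "hom", GROUP_CPC_HOM, config.n_cpc_hom),
        ("CPC", "het", GROUP_CPC_OTHER, config.n_cpc_het),
        ("CPC", "wt", GROUP_CPC_OTHER, config.n_cpc_wt),
        ("aCPP", "wt", GROUP_PAPILLOMA, config.n_acpp),
        ("CPP", "wt", GROUP_PAPILLOMA, config.n_cpp),
    ):
        for _ in range(n):
            rows.append((diag, tp53, group))
    df = pd.DataFrame(rows, columns=["diagnosis", "tp53", "sim_group"])
    df.index = [f"S{i+1:03d}" for i in range(len(df))]
    df.index.name = "sample_id"
    return df


def simulate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> SimulatedCohort:
    """Draw one full synthetic cohort; identical seed implies identical output."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    arch_seed = config.architecture_seed
    if arch_seed is None:
        arch_seed = config.seed
    arch = np.random.default_rng([arch_seed, 1])   # probe architecture
    rng = np.random.default_rng([config.seed, 2])  # patient sampling

    samples = _sample_labels(config)
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("empty cohort")
    n_probes = config.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])

    # planted layout: planted probes occupy a random subset, then flags are
    # assigned only among non-planted probes so every planted probe survives
    # filtering
    n_planted = sum(t.n_probes for t in config.planted)
    planted_idx = arch.choice(n_probes, size=n_planted, replace=False)
    planted_delta = np.zeros(n_probes)
    offset = 0
    for tier in config.planted:
        planted_delta[planted_idx[offset:offset + tier.n_probes]] = tier.delta_beta
        offset += tier.n_probes
    is_planted = planted_delta > 0
    sign = np.ones(n_probes)
    hyper = arch.random(n_probes) < config.hyper_fraction
    sign[~hyper] = -1.0

    # baseline means from the three-component mixture
    comp = arch.choice(3, size=n_probes, p=np.asarray(config.mixture_weights) /
                       sum(config.mixture_weights))
    base = np.asarray(config.mixture_means)[comp]
    base = base + arch.normal(0, 0.03, size=n_probes)
    base = np.clip(base, 0.02, 0.98)
    # TP53-homozygous subgroup shift on a subset of planted probes, in the
    # same direction as the planted effect
    extra_mask = np.zeros(n_probes, dtype=bool)
    n_extra = int(round(config.tp53_extra_fraction * n_planted))
    extra_idx = planted_idx[arch.permutation(n_planted)[:n_extra]]
    extra_mask[extra_idx] = True
    shift = np.where(is_planted, sign * planted_delta, 0.0)
    extra = np.where(extra_mask, sign * config.tp53_extra_delta, 0.0)
    # keep the full planted architecture (main + subgroup shift) inside the
    # valid mean range so planted effects are never attenuated by clipping
    total = shift + extra
    base = np.clip(base, np.maximum(0.02, 0.02 - np.minimum(total, 0)),
                   np.minimum(0.98, 0.98 - np.maximum(total, 0)))

    is_cpc = (samples["diagnosis"] == "CPC").to_numpy()
    is_hom = (samples["sim_group"] == GROUP_CPC_HOM).to_numpy()

    mean = np.tile(base[:, None], (1, n_samples))
    mean[:, is_cpc] += shift[:, None]
    if is_hom.any():
        mean[:, is_hom] += extra[:, None]
    mean = np.clip(mean, 0.02, 0.98)

    a = mean * config.kappa
    b = (1.0 - mean) * config.kappa
    betas = rng.beta(a, b)
    betas = np.clip(betas, 1e-6, 1 - 1e-6)  # strictly inside (0,1)
    beta = BetaMatrix(pd.DataFrame(betas, index=probe_ids,
                                   columns=samples.index))

    annotation = _simulate_annotation(config, arch, probe_ids, is_planted)
    metadata = _simulate_metadata(config, rng, samples)
    expression, truth = _simulate_expression(
        config, arch, rng, annotation, samples, probe_ids, is_planted,
        planted_delta * sign)
    truth["tp53_extra"] = extra_mask
    return SimulatedCohort(beta, annotation, metadata, expression, truth)


def _simulate_annotation(config, rng, probe_ids, is_planted) -> pd.DataFrame:
    n = len(probe_ids)
    chrom = rng.choice([str(c) for c in range(1, 23)], size=n)
    flags = {k: np.zeros(n, dtype=bool)
             for k in ("snp_proximal", "is_control", "cross_reactive")}
    clean = ~is_planted
    clean_idx = np.flatnonzero(clean)
    rng.shuffle(clean_idx)
    n_sex = int(round(config.frac_sex_chrom * n))
    n_snp = int(round(config.frac_snp_proximal * n))
    n_ctl = int(round(config.frac_control * n))
    n_xr = int(round(config.frac_cross_reactive * n))
    take = clean_idx[: n_sex + n_snp + n_ctl + n_xr]
    sex_idx = take[:n_sex]
    chrom[sex_idx] = rng.choice(["X", "Y"], size=len(sex_idx), p=[0.85, 0.15])
    flags["snp_proximal"][take[n_sex:n_sex + n_snp]] = True
    flags["is_control"][take[n_sex + n_snp:n_sex + n_snp + n_ctl]] = True
    flags["cross_reactive"][take[n_sex + n_snp + n_ctl:]] = True

    def rate_col(pair):
        bg, pl = pair
        p = np.where(is_planted, pl, bg)
        return rng.random(n) < p

    island = np.empty(n, dtype=object)
    bg_idx = np.flatnonzero(~is_planted)
    pl_idx = np.flatnonzero(is_planted)
    island[bg_idx] = rng.choice(ISLAND_RELATIONS, size=len(bg_idx),
                                p=np.asarray(config.island_background) /
                                sum(config.island_background))
    if len(pl_idx):
        island[pl_idx] = rng.choice(ISLAND_RELATIONS, size=len(pl_idx),
                                    p=np.asarray(config.island_planted) /
                                    sum(config.island_planted))
    return pd.DataFrame({
        "probe_id": probe_ids,
        "chr": chrom,
        "pos": rng.integers(10_000, 200_000_000, size=n),
        "gene": "",      # filled by the expression step
        "gene_region": "",
        "island_relation": island,
        "enhancer": rate_col(config.enhancer_rate),
        "dhs": rate_col(config.dhs_rate),
        "cdmr": rate_col(config.cdmr_rate),
        "rdmr": rate_col(config.rdmr_rate),
        "snp_proximal": flags["snp_proximal"],
        "cross_reactive": flags["cross_reactive"],
        "is_control": flags["is_control"],
    }, index=pd.Index(probe_ids, name="probe_id"))


def _simulate_metadata(config, rng, samples) -> pd.DataFrame:
    hazards = {GROUP_CPC_HOM: config.hazard_cpc_hom,
               GROUP_CPC_OTHER: config.hazard_cpc_other,
               GROUP_PAPILLOMA: config.hazard_papilloma}
    n = len(samples)
    h = samples["sim_group"].map(hazards).to_numpy(dtype=float)
    death_t = rng.exponential(1.0 / h)
    censor_t = rng.uniform(0, config.follow_up_months, size=n)
    os_time = np.minimum(death_t, censor_t)
    death = death_t <= censor_t
    rec_t = rng.exponential(1.0 / (h * config.recurrence_hazard_scale))
    recurrence = rec_t <= censor_t
    return pd.DataFrame({
        "sample_id": samples.index,
        "diagnosis": samples["diagnosis"].to_numpy(),
        "tp53": samples["tp53"].to_numpy(),
        "age_class": rng.choice(["pediatric", "adult"], size=n, p=[0.8, 0.2]),
        "os_time": np.round(os_time, 2),
        "death_event": pd.array(death, dtype="boolean"),
        "recurrence_event": pd.array(recurrence, dtype="boolean"),
        "cohort": config.cohort_label,
        "sim_group": samples["sim_group"].to_numpy(),
    }, index=samples.index)


def _simulate_expression(config, arch, rng, annotation, samples, probe_ids,
                         is_planted, signed_delta):
    """Assign genes to probes and generate sign-linked expression.

    Promoter-linked genes respond inversely to the planted methylation shift
    (hypermethylated promoter -> downregulated); body-linked genes respond
    positively. Unlinked genes are null.
    """
    n = len(probe_ids)
    planted_order = np.flatnonzero(is_planted)
    arch.shuffle(planted_order)
    n_prom, n_body = config.n_promoter_linked, config.n_body_linked
    prom_probes = planted_order[:n_prom]
    body_probes = planted_order[n_prom:n_prom + n_body]

    gene_names = np.array([f"GENE{i:05d}" for i in range(max(n // 4, n_prom + n_body))])
    gene = np.empty(n, dtype=object)
    region = np.empty(n, dtype=object)
    gene[:] = ""
    region[:] = ""
    # background gene assignment: ~75% of probes map to one gene
    assigned = arch.random(n) < 0.75
    gene[assigned] = arch.choice(gene_names[n_prom + n_body:], size=assigned.sum())
    region[assigned] = arch.choice(
        ["TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"],
        size=assigned.sum(), p=[0.12, 0.10, 0.10, 0.08, 0.45, 0.15])
    prom_regions = ("TSS1500", "TSS200", "5UTR", "1stExon")
    link_rows = []
    for j, p_idx in enumerate(prom_probes):
        gene[p_idx] = gene_names[j]
        region[p_idx] = prom_regions[j % len(prom_regions)]
        link_rows.append((probe_ids[p_idx], gene_names[j], "promoter"))
    for j, p_idx in enumerate(body_probes):
        gene[p_idx] = gene_names[n_prom + j]
        region[p_idx] = "Body"
        link_rows.append((probe_ids[p_idx], gene_names[n_prom + j], "body"))
    annotation["gene"] = gene
    annotation["gene_region"] = region

    all_genes = np.unique(gene[gene != ""])
    is_cpc = (samples["diagnosis"] == "CPC").to_numpy()
    base_expr = arch.normal(6.0, 1.0, size=len(all_genes))
    values = (base_expr[:, None] +
              rng.normal(0, config.expression_noise_sd,
                         size=(len(all_genes), len(samples))))
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    log2fc = pd.Series(0.0, index=all_genes)
    qvals = pd.Series(arch.uniform(0.2, 1.0, size=len(all_genes)),
                      index=all_genes)
    for probe, g, kind in link_rows:
        p_idx = np.flatnonzero(probe_ids == probe)[0]
        fc = config.expression_link_strength * signed_delta[p_idx]
        fc = -fc if kind == "promoter" else fc
        values[gene_pos[g], is_cpc] += fc
        log2fc[g] = fc
        qvals[g] = 1e-4
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(all_genes, name="gene_symbol"),
                     columns=samples.index),
        pd.DataFrame({"log2fc": log2fc, "q": qvals}))

    link_df = pd.DataFrame(link_rows, columns=["probe_id", "gene", "link"]) \
        .set_index("probe_id")
    truth = pd.DataFrame({
        "probe_id": probe_ids,
        "planted": is_planted,
        "planted_delta": np.where(is_planted, signed_delta, 0.0),
        "linked_gene": link_df["gene"].reindex(probe_ids).fillna("").to_numpy(),
        "link_region": link_df["link"].reindex(probe_ids).fillna("").to_numpy(),
    }, index=pd.Index(probe_ids, name="probe_id"))
    return expr, truth
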