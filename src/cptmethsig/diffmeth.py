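"""Per-CpG differential methylation between carcinoma and papilloma groups.

Each retained CpG is tested with a two-sided Mann-Whitney U test; p-values
are adjusted with Benjamini-Hochberg, and probes are assigned to two
signature tiers by effect size:

* tier 1 ("subsequent investigations"): q < 0.05 and |delta-beta| >= 0.30
* tier 2 ("biomarker discovery"):       q < 0.001 and |delta-beta| >= 0.40

Delta-beta is carcinoma mean minus papilloma mean, so "hyper" means
hypermethylated in carcinomas. The exact U null distribution is used when
the combined per-probe sample count is <= 25 and the probe has no ties;
otherwise the tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix

logger = logging.getLogger("cptmethsig")

CARCINOMA = "carcinoma"
PAPILLOMA = "papilloma"

TIER1_Q, TIER1_DELTA = 0.05, 0.30
TIER2_Q, TIER2_DELTA = 0.001, 0.40

EXACT_MAX_N = 25


@dataclass
class Signature:
    """Ordered tiered CpG records plus the thresholds that produced them."""
    table: pd.DataFrame  # columns probe_id, gene, delta_beta, q, tier
    tier: str
    q_threshold: float
    delta_threshold: float

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)

    @property
    def direction_counts(self) -> dict[str, int]:
        d = self.table["delta_beta"]
        return {"hyper": int((d > 0).sum()), "hypo": int((d < 0).sum())}


def labels_from_diagnosis(diagnosis: pd.Series) -> pd.Series:
    """CPC -> carcinoma; CPP and aCPP -> papilloma."""
    return diagnosis.map(lambda d: CARCINOMA if d == "CPC" else PAPILLOMA)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _exact_ok(x: np.ndarray, y: np.ndarray) -> bool:
    combined = np.concatenate([x, y])
    return (len(combined) <= EXACT_MAX_N and
            len(np.unique(combined)) == len(combined))


def mann_whitney_per_probe(matrix: BetaMatrix, labels: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per probe; U reported for the carcinoma group.

    ``labels`` maps sample id to 'carcinoma'/'papilloma'. Probes lacking a
    non-missing value in either group are skipped and logged. Returns a
    DataFrame with columns u, p_raw, mean_beta_carcinoma,
    mean_beta_papilloma, delta_beta, direction, n_carcinoma, n_papilloma.
    """
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("every sample needs a carcinoma/papilloma label")
    bad = ~labels.isin([CARCINOMA, PAPILLOMA])
    if bad.any():
        raise ValueError(f"unknown label {labels[bad].iloc[0]!r}")
    carc = labels.index[labels == CARCINOMA]
    pap = labels.index[labels == PAPILLOMA]
    if len(carc) == 0 or len(pap) == 0:
        raise ValueError("both groups must be non-empty")

    X = matrix.values[carc].to_numpy(dtype=float)
    Y = matrix.values[pap].to_numpy(dtype=float)
    probes = np.asarray(matrix.probe_ids)
    n_probes = len(probes)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_c = np.nanmean(X, axis=1)
        mean_p = np.nanmean(Y, axis=1)

    u = np.full(n_probes, np.nan)
    p = np.full(n_probes, np.nan)
    complete = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    n_total = X.shape[1] + Y.shape[1]

    if complete.all():
        if n_total > EXACT_MAX_N:
            # common large-cohort case: one vectorized asymptotic pass
            res = stats.mannwhitneyu(X, Y, axis=1, alternative="two-sided",
                                     method="asymptotic")
            u = np.asarray(res.statistic, float)
            p = np.asarray(res.pvalue, float)
        else:
            # small cohort: exact path for tie-free probes, tie-corrected
            # asymptotic for the rest, each as one vectorized call
            pooled = np.sort(np.hstack([X, Y]), axis=1)
            has_ties = (np.diff(pooled, axis=1) == 0).any(axis=1)
            for mask, method in ((~has_ties, "exact"), (has_ties, "asymptotic")):
                if mask.any():
                    res = stats.mannwhitneyu(X[mask], Y[mask], axis=1,
                                             alternative="two-sided",
                                             method=method)
                    u[mask] = np.asarray(res.statistic, float)
                    p[mask] = np.asarray(res.pvalue, float)
    else:
        for i in range(n_probes):
            x = X[i][~np.isnan(X[i])]
            y = Y[i][~np.isnan(Y[i])]
            if len(x) == 0 or len(y) == 0:
                logger.info("diffmeth: probe %s skipped (empty group)", probes[i])
                continue
            method = "exact" if _exact_ok(x, y) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            u[i], p[i] = res.statistic, min(float(res.pvalue), 1.0)
    p = np.minimum(p, 1.0)

    delta = mean_c - mean_p
    out = pd.DataFrame({
        "probe_id": probes,
        "u": u,
        "p_raw": p,
        "mean_beta_carcinoma": mean_c,
        "mean_beta_papilloma": mean_p,
        "delta_beta": delta,
        "direction": np.where(delta > 0, "hyper", "hypo"),
        "n_carcinoma": np.sum(~np.isnan(X), axis=1),
        "n_papilloma": np.sum(~np.isnan(Y), axis=1),
    }, index=pd.Index(probes, name="probe_id"))
    return out[out["p_raw"].notna()]


def differential_methylation(matrix: BetaMatrix, labels: pd.Series) -> pd.DataFrame:
    """Full per-probe table: U, raw p, BH q, group means, delta-beta, tier."""
    res = mann_whitney_per_probe(matrix, labels)
    res = res.copy()
    res["q"] = bh_fdr(res["p_raw"].to_numpy())
    tier1 = (res["q"] < TIER1_Q) & (res["delta_beta"].abs() >= TIER1_DELTA)
    tier2 = (res["q"] < TIER2_Q) & (res["delta_beta"].abs() >= TIER2_DELTA)
    res["tier"] = np.where(tier2 & tier1, "tier2",
                           np.where(tier1, "tier1", "none"))
    return res


def extract_signature(results: pd.DataFrame, tier: str = "tier2",
                      annotation: pd.DataFrame | None = None,
                      q_threshold: float | None = None,
                      delta_threshold: float | None = None) -> Signature:
    """Select the tiered probe set from a differential-methylation table.

    ``tier`` picks the default thresholds (tier1: q<0.05, |db|>=0.30;
    tier2: q<0.001, |db|>=0.40); explicit thresholds override them.
    """
    if tier not in ("tier1", "tier2"):
        raise ValueError("tier must be 'tier1' or 'tier2'")
    q_thr = q_threshold if q_threshold is not None else (
        TIER1_Q if tier == "tier1" else TIER2_Q)
    d_thr = delta_threshold if delta_threshold is not None else (
        TIER1_DELTA if tier == "tier1" else TIER2_DELTA)
    sel = results[(results["q"] < q_thr) &
                  (results["delta_beta"].abs() >= d_thr)]
    sel = sel.reset_index(drop=True).sort_values(["q", "probe_id"],
                                                 kind="mergesort")
    gene = ""
    if annotation is not None:
        gene = annotation["gene"].reindex(sel["probe_id"]).fillna("").to_numpy()
    table = pd.DataFrame({
        "probe_id": sel["probe_id"].to_numpy(),
        "gene": gene,
        "delta_beta": sel["delta_beta"].to_numpy(),
        "q": sel["q"].to_numpy(),
        "tier": tier,
    })
    if len(table) == 0:
        logger.warning("extract_signature: empty %s signature", tier)
    return Signature(table, tier, q_thr, d_thr)


def volcano_table(results: pd.DataFrame) -> pd.DataFrame:
    """(delta_beta, -log10 raw p, tier flag) projection for volcano plots."""
    with np.errstate(divide="ignore"):
        y = -np.log10(results["p_raw"].to_numpy(dtype=float))
    out = pd.DataFrame({
        "delta_beta": results["delta_beta"].to_numpy(),
        "neg_log10_p": y,
        "tier": results["tier"].to_numpy() if "tier" in results else "none",
    })
    return out.dropna()


def r_squared(x, y) -> float:
    """Squared Pearson correlation of two paired vectors; NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in paired vectors")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: r^2 undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def platform_concordance(a: BetaMatrix, b: BetaMatrix) -> pd.Series:
    """Per-probe r^2 between two platforms measured on the same samples."""
    common_p = [p for p in a.probe_ids if p in set(b.probe_ids)]
    common_s = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if len(common_s) < 3:
        raise ValueError("need >= 3 shared samples")
    out = {}
    for probe in common_p:
        out[probe] = r_squared(a.values.loc[probe, common_s],
                               b.values.loc[probe, common_s])
    return pd.Series(out, name="r_squared")
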