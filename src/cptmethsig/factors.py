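"""Joint factor analysis of signature CpG betas with phenotype/genotype
attributes.

Attributes (signature beta values plus 0/1-coded covariates such as TP53
mutation, death, recurrence, pediatric/adult age class) are standardized
and decomposed by maximum-likelihood factor analysis with varimax rotation.
The question the analysis answers is whether the methylation signature
forms its own block of factors, independent of the clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

DEFAULT_N_FACTORS = 12


@dataclass
class FactorResult:
    loadings: pd.DataFrame       # attributes x factors
    communalities: pd.Series     # per attribute, in [0,1] up to tolerance
    n_factors: int
    rotation: str = "varimax"


def encode_covariates(metadata: pd.DataFrame) -> pd.DataFrame:
    """0/1 covariate coding used alongside the beta attributes."""
    out = pd.DataFrame(index=metadata.index)
    out["tp53_mutant"] = metadata["tp53"].isin(["het", "hom"]).astype(float)
    out["death_event"] = metadata["death_event"].astype("boolean") \
        .fillna(False).astype(float)
    out["recurrence_event"] = metadata["recurrence_event"].astype("boolean") \
        .fillna(False).astype(float)
    out["adult"] = (metadata["age_class"] == "adult").astype(float)
    return out


def factor_analyze(table: pd.DataFrame, n_factors: int = DEFAULT_N_FACTORS,
                   drop_attributes: list[str] | None = None,
                   rotation: str | None = "varimax") -> FactorResult:
    """ML factor extraction with varimax rotation on standardized attributes.

    ``table`` is samples x attributes; ``drop_attributes`` re-runs the
    analysis with attributes removed (e.g. the recurrence-removed variant).
    """
    if drop_attributes:
        table = table.drop(columns=list(drop_attributes))
    if n_factors >= table.shape[1]:
        raise ValueError("n_factors must be < number of attributes")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = table.columns[int(np.argmax(sd == 0))]
        raise ValueError(
            f"attribute {bad!r} is constant; prune it before factor analysis")
    Z = (X - X.mean(axis=0)) / sd
    fa = FactorAnalysis(n_components=n_factors, rotation=rotation,
                        svd_method="lapack", max_iter=5000)
    fa.fit(Z)
    load = pd.DataFrame(fa.components_.T, index=table.columns,
                        columns=[f"F{j+1}" for j in range(n_factors)])
    comm = (load ** 2).sum(axis=1)
    return FactorResult(load, comm, n_factors, rotation or "none")


def loading_heatmap_table(result: FactorResult,
                          cpg_prefix: str = "cg") -> pd.DataFrame:
    """|loading| by attribute x factor, CpG attributes first."""
    mag = result.loadings.abs()
    is_cpg = mag.index.str.startswith(cpg_prefix)
    return pd.concat([mag[is_cpg], mag[~is_cpg]])
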