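#!/usr/bin/env python
"""Joint factor analysis of the signature CpG betas with 0/1-coded clinical
covariates (TP53 mutation, death, recurrence, age class), with and without
the recurrence attribute, asking whether the methylation signature forms a
factor block independent of the clinical attributes."""

import argparse
from pathlib import Path

import pandas as pd

from cptmethsig import io
from cptmethsig.factors import (encode_covariates, factor_analyze,
                                loading_heatmap_table)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--n-factors", type=int, default=12)
    args = ap.parse_args()

    beta = io.read_beta_matrix(args.results / "filtering" / "beta_filtered.tsv")
    meta = io.read_metadata(args.results / "cohort" / "metadata.tsv")
    tier2 = pd.read_csv(args.results / "diffmeth" / "signature_tier2.tsv",
                        sep="\t", dtype={"probe_id": str})
    attrs = pd.concat([beta.values.loc[tier2["probe_id"]].T,
                       encode_covariates(meta)], axis=1)
    attrs = attrs.loc[:, attrs.std(ddof=0) > 0]

    out = args.results / "factors"
    out.mkdir(parents=True, exist_ok=True)
    for tag, drop in (("full", None), ("no_recurrence", ["recurrence_event"])):
        res = factor_analyze(attrs, n_factors=min(args.n_factors,
                                                  attrs.shape[1] - 2),
                             drop_attributes=drop)
        loading_heatmap_table(res).to_csv(out / f"loadings_{tag}.tsv",
                                          sep="\t", index_label="attribute",
                                          float_format="%.6g")
        cov_cols = [c for c in ("tp53_mutant", "death_event",
                                "recurrence_event", "adult")
                    if c in res.loadings.index]
        beta_mass = (res.loadings.drop(index=cov_cols) ** 2).sum(axis=0)
        top = beta_mass.sort_values(ascending=False).index[:3]
        max_cov = res.loadings.loc[cov_cols, top].abs().max().max()
        print(f"{tag}: top beta-dominated factors {list(top)}; max covariate "
              f"|loading| there {max_cov:.2f}")


if __name__ == "__main__":
    main()
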