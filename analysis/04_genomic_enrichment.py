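#!/usr/bin/env python
"""Fisher-exact enrichment of the tier-1 signature in regulatory categories
(enhancer, DHS, cDMR, rDMR, island relation) against the retained-probe
background."""

import argparse
from pathlib import Path

import pandas as pd

from cptmethsig import io
from cptmethsig.diffmeth import Signature
from cptmethsig.enrichment import enrich

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    sig_table = pd.read_csv(args.results / "diffmeth" / "signature_tier1.tsv",
                            sep="\t", dtype={"probe_id": str})
    sig = Signature(sig_table, "tier1", 0.05, 0.30)
    ann = io.read_annotation(args.results / "cohort" / "annotation.tsv")
    retained = io.read_beta_matrix(
        args.results / "filtering" / "beta_filtered.tsv").probe_ids
    background = ann.loc[ann.index.isin(retained)]

    res = enrich(sig, background)
    out = args.results / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    res.to_csv(out / "enrichment.tsv", sep="\t", index=False,
               float_format="%.6g")
    print(res.to_string(index=False,
                        float_format=lambda v: f"{v:.3g}"))
    hits = res[(res["q"] < 0.05) & (res["odds_ratio"] > 1)]["category"]
    print("enriched categories (q<0.05, OR>1):", ", ".join(hits))


if __name__ == "__main__":
    main()
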