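#!/usr/bin/env python
"""Promoter/body methylation-expression concordance of the tier-1 signature
genes: counts genes whose promoter methylation is inverse to expression and
whose body methylation is positively concordant."""

import argparse
import json
from pathlib import Path

import pandas as pd

from cptmethsig import io
from cptmethsig.diffmeth import Signature
from cptmethsig.meth_expr import correlate_meth_expr

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    sig_table = pd.read_csv(args.results / "diffmeth" / "signature_tier1.tsv",
                            sep="\t", dtype={"probe_id": str})
    sig = Signature(sig_table, "tier1", 0.05, 0.30)
    ann = io.read_annotation(args.results / "cohort" / "annotation.tsv")
    expr = io.read_expression(args.results / "cohort" / "expression.tsv",
                              args.results / "cohort" / "expression_stats.tsv")
    records, summary = correlate_meth_expr(sig, ann, expr)

    out = args.results / "meth_expr"
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "concordance.tsv", sep="\t", index=False,
                   float_format="%.6g")
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"promoter-inverse genes: {summary['promoter_inverse_genes']}; "
          f"body-positive genes: {summary['body_positive_genes']}; "
          f"union: {summary['union_genes']}")


if __name__ == "__main__":
    main()
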