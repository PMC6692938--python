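#!/usr/bin/env python
"""Leakage-free leave-one-out validation of the carcinoma classifier: the
stringent signature is re-derived inside every fold, optionally reduced by
correlation-based feature selection; a fixed minimal 3-CpG panel is
evaluated the same way."""

import argparse
import json
from pathlib import Path

import pandas as pd

from cptmethsig import io
from cptmethsig.classify import loo_cross_validate
from cptmethsig.diffmeth import labels_from_diagnosis

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    beta = io.read_beta_matrix(args.results / "filtering" / "beta_filtered.tsv")
    meta = io.read_metadata(args.results / "cohort" / "metadata.tsv")
    labels = labels_from_diagnosis(meta["diagnosis"])
    tier2 = pd.read_csv(args.results / "diffmeth" / "signature_tier2.tsv",
                        sep="\t", dtype={"probe_id": str})
    panel = list(tier2["probe_id"].head(3))  # most significant 3 CpGs

    out = args.results / "crossval"
    out.mkdir(parents=True, exist_ok=True)
    runs = {
        "logistic_full_signature": ("logistic", "signature"),
        "logistic_cfs": ("logistic", "cfs"),
        "naive_bayes_full_signature": ("nb", "signature"),
        "logistic_minimal3": ("logistic", panel),
        "naive_bayes_minimal3": ("nb", panel),
    }
    summaries = {}
    for name, (model, features) in runs.items():
        report = loo_cross_validate(beta, labels, model=model,
                                    features=features)
        report.folds.to_csv(out / f"folds_{name}.tsv", sep="\t", index=False,
                            float_format="%.6g")
        summaries[name] = report.summary()
        s = summaries[name]
        print(f"{name}: sensitivity {s['sensitivity']:.1%}, "
              f"specificity {s['specificity']:.1%}, AUROC {s['auroc']:.1%}")
    (out / "cv_summaries.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
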