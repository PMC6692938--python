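#!/usr/bin/env python
"""Kaplan-Meier estimates and k-sample log-rank / Gehan-Wilcoxon tests of
overall survival by methylation cluster, plus death/recurrence frequency
tables by cluster and by histological diagnosis."""

import argparse
import json
from pathlib import Path

import pandas as pd

from cptmethsig import io
from cptmethsig.survival import (event_frequency_table, k_sample_test,
                                 km_estimate)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    meta = io.read_metadata(args.results / "cohort" / "metadata.tsv")
    clusters = pd.read_csv(args.results / "cluster" / "clusters.tsv",
                           sep="\t", dtype={"sample_id": str}) \
        .set_index("sample_id")["cluster"]

    out = args.results / "survival"
    out.mkdir(parents=True, exist_ok=True)
    sub = meta[meta["os_time"].notna()]
    tests = {}
    for grouping, name in ((clusters, "methylation_cluster"),
                           (meta["diagnosis"], "diagnosis")):
        for test in ("logrank", "gehan"):
            r = k_sample_test(sub["os_time"], sub["death_event"].astype(bool),
                              grouping.reindex(sub.index), test=test)
            tests[f"{name}_{test}"] = {"chi_square": round(r.chi_square, 2),
                                       "df": r.df,
                                       "p_value": float(f"{r.p_value:.3g}")}
            print(f"{name} {test}: chi2 = {r.chi_square:.1f} "
                  f"(df={r.df}), p = {r.p_value:.2g}")
    (out / "tests.json").write_text(json.dumps(tests, indent=2) + "\n")

    for g in sorted(clusters.unique()):
        ids = clusters[clusters == g].index.intersection(sub.index)
        est = km_estimate(sub.loc[ids, "os_time"],
                          sub.loc[ids, "death_event"].astype(bool))
        est.table.to_csv(out / f"km_cluster{g}.tsv", sep="\t", index=False,
                         float_format="%.6g")

    freq = event_frequency_table(meta, clusters)
    freq.to_csv(out / "event_frequencies_by_cluster.tsv", sep="\t",
                index=False)
    print(freq.to_string(index=False))
    event_frequency_table(meta, meta["diagnosis"]).to_csv(
        out / "event_frequencies_by_diagnosis.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
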