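#!/usr/bin/env python
"""Unsupervised structure: two-way hierarchical clustering and PCA on the
signature CpGs, and projection of the discovery signature onto the
replication cohort with a joint k=3 cut."""

import argparse
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from cptmethsig import io, plots
from cptmethsig.cluster import (hierarchical_cluster, pca_project,
                                project_external)
from cptmethsig.diffmeth import Signature

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    beta = io.read_beta_matrix(args.results / "filtering" / "beta_filtered.tsv")
    meta = io.read_metadata(args.results / "cohort" / "metadata.tsv")
    tier2 = pd.read_csv(args.results / "diffmeth" / "signature_tier2.tsv",
                        sep="\t", dtype={"probe_id": str})
    sig = Signature(tier2, "tier2", 0.001, 0.40)
    sig_matrix = beta.restrict_probes(sig.probe_ids)

    out = args.results / "cluster"
    out.mkdir(parents=True, exist_ok=True)
    assign = hierarchical_cluster(sig_matrix, metric="euclidean",
                                  linkage="average", k=3, cluster_probes=True)
    assign.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t",
                                    index_label="sample_id")
    scores, evr = pca_project(sig_matrix)
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id",
                  float_format="%.6g")
    plots.heatmap(sig_matrix, out / "signature_heatmap.png", assign.labels)
    plots.pca_scatter(scores, out / "pca.png", meta["diagnosis"])
    print(f"k=3 clusters: {assign.labels.value_counts().sort_index().to_dict()}")
    print(f"PCA explained variance: {[round(float(v), 3) for v in evr]}")

    # project the discovery signature onto the replication cohort
    rep_beta = io.read_beta_matrix(args.results / "replication" / "beta.tsv")
    rep_meta = io.read_metadata(args.results / "replication" / "metadata.tsv")
    restricted, coverage = project_external(rep_beta, sig)
    rep_assign = hierarchical_cluster(restricted, metric="euclidean",
                                      linkage="average", k=2)
    rep_assign.labels.to_frame().to_csv(out / "replication_clusters.tsv",
                                        sep="\t", index_label="sample_id")
    truth = (rep_meta["diagnosis"] == "CPC").astype(int)
    ari = adjusted_rand_score(truth, rep_assign.labels)
    print(f"replication: coverage {coverage:.1%} of signature probes, "
          f"k=2 carcinoma/papilloma ARI {ari:.2f}")


if __name__ == "__main__":
    main()
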