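#!/usr/bin/env python
"""Simulate the discovery cohort (34 samples: 14 carcinomas split 5 TP53-hom
/ 7 het / 2 wt, 5 atypical papillomas, 15 papillomas) and a replication
cohort drawn from the same probe architecture with new patients.

Writes beta matrix, probe annotation, sample metadata, expression (+ stats)
and the planted-probe truth table under results/cohort/ and
results/replication/.
"""

import argparse
import dataclasses
from pathlib import Path

from cptmethsig import io
from cptmethsig.simulate import SimulationConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def write_cohort(cohort, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io.write_beta_matrix(cohort.beta, out / "beta.tsv")
    io.write_annotation(cohort.annotation, out / "annotation.tsv")
    io.write_metadata(cohort.metadata, out / "metadata.tsv")
    io.write_expression(cohort.expression, out / "expression.tsv",
                        out / "expression_stats.tsv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--n-probes", type=int, default=5000,
                    help="down-scaled array size (the method is scale-free)")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    cfg = SimulationConfig(n_probes=args.n_probes, seed=args.seed)
    discovery = simulate_cohort(cfg)
    write_cohort(discovery, args.out / "cohort")
    n_planted = int(discovery.truth["planted"].sum())
    print(f"discovery: {cfg.n_probes} probes x {discovery.beta.shape[1]} "
          f"samples, {n_planted} planted differential CpGs")

    rep_cfg = dataclasses.replace(cfg, seed=args.seed + 1,
                                  architecture_seed=args.seed,
                                  n_cpc_hom=6, n_cpc_het=10, n_cpc_wt=5,
                                  n_acpp=22, n_cpp=18,
                                  cohort_label="replication")
    replication = simulate_cohort(rep_cfg)
    write_cohort(replication, args.out / "replication")
    print(f"replication: {replication.beta.shape[1]} samples, same probe "
          f"architecture, new patients")


if __name__ == "__main__":
    main()
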