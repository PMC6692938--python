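#!/usr/bin/env python
"""Apply the probe exclusion rules (sex chromosomes, SNP-proximal, control,
cross-reactive, unannotated) to the simulated discovery cohort and report
how many probes each rule removed."""

import argparse
from pathlib import Path

from cptmethsig import io
from cptmethsig.filtering import filter_probes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    beta = io.read_beta_matrix(args.results / "cohort" / "beta.tsv")
    ann = io.read_annotation(args.results / "cohort" / "annotation.tsv")
    filtered, report = filter_probes(beta, ann)

    out = args.results / "filtering"
    out.mkdir(parents=True, exist_ok=True)
    io.write_beta_matrix(filtered, out / "beta_filtered.tsv")
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    for rule, n in report.removed.items():
        print(f"removed {n:5d} probes: {rule}")
    print(f"retained {report.retained} of {report.input_probes} probes")


if __name__ == "__main__":
    main()
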