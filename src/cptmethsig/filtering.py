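"""Probe exclusion rules applied before any statistics.

Mirrors standard 450K practice: drop sex-chromosome probes, probes within
5 bp of common variants (MAF >= 1%), internal control probes, cross-reactive
probes, and probes without an annotation record. SNP proximity and
cross-reactivity are consumed as precomputed flags in the annotation; each
probe is counted under the first matching rule so the report is a partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import BetaMatrix

logger = logging.getLogger("cptmethsig")

RULE_ORDER = ("sex_chromosome", "snp_proximal", "control", "cross_reactive",
              "unannotated")


@dataclass
class FilterReport:
    removed: dict[str, int]
    retained: int
    input_probes: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": self.removed.get(r, 0)} for r in RULE_ORDER]
        rows.append({"rule": "retained", "removed": self.retained})
        return pd.DataFrame(rows)


def filter_probes(matrix: BetaMatrix,
                  annotation: pd.DataFrame) -> tuple[BetaMatrix, FilterReport]:
    """Return the matrix restricted to retained probes plus per-rule counts."""
    probes = pd.Index(matrix.probe_ids)
    ann = annotation.reindex(probes)
    known = ann["probe_id"].notna()

    rules = {
        "sex_chromosome": known & ann["chr"].isin(["X", "Y"]),
        "snp_proximal": known & ann["snp_proximal"].eq(True),
        "control": known & ann["is_control"].eq(True),
        "cross_reactive": known & ann["cross_reactive"].eq(True),
        "unannotated": ~known,
    }
    removed = {}
    already = pd.Series(False, index=probes)
    for rule in RULE_ORDER:
        hit = rules[rule] & ~already
        removed[rule] = int(hit.sum())
        already |= hit
    keep = probes[~already]
    report = FilterReport(removed=removed, retained=len(keep),
                          input_probes=len(probes))
    for rule in RULE_ORDER:
        logger.info("filter: removed %d probes by rule %s", removed[rule], rule)
    logger.info("filter: retained %d of %d probes", report.retained, len(probes))
    if len(keep) == 0:
        logger.warning("filter: retained set is empty")
    return matrix.restrict_probes(keep), report
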