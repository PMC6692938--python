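"""Promoter/body methylation-expression concordance for signature genes.

The promoter is the region 1500 bp upstream of the TSS, the 5'UTR and the
first exon (Illumina region groups TSS1500, TSS200, 5UTR, 1stExon); Body
probes are gene-body. A gene is "promoter-inverse" when at least one of its
promoter probes in the signature has a delta-beta of opposite sign to the
gene's expression log2 fold change and the gene is differentially expressed
(q < 0.05); "body-positive" is the same-sign analogue for body probes.
Differential expression is consumed as input (log2FC + q per gene), not
recomputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffmeth import Signature
from .io import ExpressionMatrix, split_gene_regions

logger = logging.getLogger("cptmethsig")

PROMOTER_GROUPS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})
EXPRESSION_Q = 0.05


def _region_class(groups: list[str]) -> str:
    # promoter takes precedence when a probe maps to both promoter and body
    # annotations of different transcripts
    if any(g in PROMOTER_GROUPS for g in groups):
        return "promoter"
    if "Body" in groups:
        return "body"
    return "other"


def correlate_meth_expr(signature: Signature, annotation: pd.DataFrame,
                        expression: ExpressionMatrix,
                        expression_q: float = EXPRESSION_Q,
                        ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per (probe, gene) concordance records plus gene-level summary counts.

    Returns a record table (gene, probe, region_class, delta_beta, log2fc,
    expression_q, pattern) and a summary dict with the number of
    promoter-inverse genes, body-positive genes, and their union.
    """
    if expression.gene_stats is None:
        raise ValueError("expression matrix lacks per-gene log2fc/q statistics")
    stats = expression.gene_stats
    records = []
    for _, sig_row in signature.table.iterrows():
        probe = sig_row["probe_id"]
        if probe not in annotation.index:
            logger.info("meth_expr: probe %s lacks annotation, skipped", probe)
            continue
        ann = annotation.loc[probe]
        pairs = split_gene_regions(ann)
        # group region assignments per gene (multi-gene probes contribute
        # to every annotated gene)
        per_gene: dict[str, list[str]] = {}
        for gene, region in pairs:
            per_gene.setdefault(gene, []).append(region)
        for gene, groups in per_gene.items():
            if gene not in stats.index:
                logger.info("meth_expr: gene %s absent from expression, skipped",
                            gene)
                continue
            log2fc = float(stats.loc[gene, "log2fc"])
            q = float(stats.loc[gene, "q"])
            region_class = _region_class(groups)
            db = float(sig_row["delta_beta"])
            pattern = "none"
            if q < expression_q and log2fc != 0 and db != 0:
                concord = np.sign(db) * np.sign(log2fc)
                if region_class == "promoter" and concord == -1:
                    pattern = "inverse"
                elif region_class == "body" and concord == 1:
                    pattern = "positive"
                elif concord == -1:
                    pattern = "inverse"
                elif concord == 1:
                    pattern = "positive"
            records.append({
                "gene": gene, "probe_id": probe, "region_class": region_class,
                "delta_beta": db, "log2fc": log2fc, "expression_q": q,
                "pattern": pattern,
            })
    table = pd.DataFrame(records, columns=["gene", "probe_id", "region_class",
                                           "delta_beta", "log2fc",
                                           "expression_q", "pattern"])
    prom = set(table.loc[(table["region_class"] == "promoter") &
                         (table["pattern"] == "inverse"), "gene"])
    body = set(table.loc[(table["region_class"] == "body") &
                         (table["pattern"] == "positive"), "gene"])
    summary = {
        "promoter_inverse_genes": len(prom),
        "body_positive_genes": len(body),
        "union_genes": len(prom | body),
    }
    return table, summary
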