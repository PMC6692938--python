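"""Genomic-context enrichment of signature CpGs against the array background.

For each regulatory category (enhancer, DHS, cancer- and
reprogramming-specific DMRs, and the CpG-island relation classes) a 2x2
table of signature vs non-signature membership is tested with a two-sided
Fisher exact test; odds ratios use the sample (a*d)/(b*c) form with a 0.5
Haldane correction when any cell is zero, and p-values are BH-adjusted
across the category list. Shores and shelves merge their N_/S_ variants,
so {island, shore, shelf, open_sea} partition the probes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import Signature, bh_fdr

CATEGORIES = ("enhancer", "dhs", "cdmr", "rdmr", "island", "shore", "shelf",
              "open_sea")

_ISLAND_MAP = {"Island": "island", "N_Shore": "shore", "S_Shore": "shore",
               "N_Shelf": "shelf", "S_Shelf": "shelf", "OpenSea": "open_sea"}


def category_membership(annotation: pd.DataFrame) -> pd.DataFrame:
    """Boolean per-probe membership for each enrichment category."""
    rel = annotation["island_relation"].map(_ISLAND_MAP)
    out = pd.DataFrame(index=annotation.index)
    for cat in ("enhancer", "dhs", "cdmr", "rdmr"):
        out[cat] = annotation[cat].astype(bool)
    for cat in ("island", "shore", "shelf", "open_sea"):
        out[cat] = rel == cat
    return out


def enrich(signature: Signature, background: pd.DataFrame) -> pd.DataFrame:
    """Per-category 2x2 counts, odds ratio, Fisher p and BH q.

    ``background`` is the annotation of all retained probes; the signature
    must be a subset of it. The non-signature row of each table is
    background minus signature, so rows are disjoint.
    """
    sig_probes = pd.Index(signature.probe_ids)
    if not sig_probes.isin(background.index).all():
        missing = sig_probes[~sig_probes.isin(background.index)][0]
        raise ValueError(f"signature probe {missing!r} not in background")
    member = category_membership(background)
    in_sig = member.index.isin(sig_probes)
    rows = []
    for cat in CATEGORIES:
        m = member[cat].to_numpy()
        a = int(np.sum(m & in_sig))
        b = int(np.sum(~m & in_sig))
        c = int(np.sum(m & ~in_sig))
        d = int(np.sum(~m & ~in_sig))
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append({"category": cat, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": orr, "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
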