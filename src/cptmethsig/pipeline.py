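"""End-to-end orchestration: simulate or load a cohort, then run filtering,
differential methylation, enrichment, methylation-expression concordance,
cross-validated classification, clustering, survival, and factor analysis,
writing every stage's table plus a machine-readable run manifest.

Reruns with the same configuration and seed reproduce identical outputs: a
single seed governs the simulation, and every downstream stage is
deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import loo_cross_validate
from .cluster import hierarchical_cluster, pca_project
from .diffmeth import (differential_methylation, extract_signature,
                       labels_from_diagnosis)
from .enrichment import enrich
from .factors import encode_covariates, factor_analyze
from .filtering import filter_probes
from .io import (read_annotation, read_beta_matrix, read_expression,
                 read_metadata)
from .meth_expr import correlate_meth_expr
from .simulate import PlantedTier, SimulationConfig, simulate_cohort
from .survival import event_frequency_table, k_sample_test

logger = logging.getLogger("cptmethsig")


class PipelineConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "inputs" not in cfg and "simulate" not in cfg:
        raise PipelineConfigError(
            "config needs either an 'inputs' block (beta/annotation/metadata"
            " paths) or a 'simulate' block")
    return cfg


def _simulation_config(block: dict, seed: int | None) -> SimulationConfig:
    block = dict(block or {})
    if "planted" in block:
        block["planted"] = tuple(PlantedTier(int(t["n_probes"]),
                                             float(t["delta_beta"]))
                                 for t in block["planted"])
    if seed is not None:
        block["seed"] = seed
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(block) - known
    if unknown:
        raise PipelineConfigError(f"unknown simulate options {sorted(unknown)}")
    return SimulationConfig(**block)


def _load_inputs(cfg: dict, seed: int | None):
    if "simulate" in cfg:
        sim_cfg = _simulation_config(cfg.get("simulate"), seed)
        cohort = simulate_cohort(sim_cfg)
        return (cohort.beta, cohort.annotation, cohort.metadata,
                cohort.expression, cohort.truth)
    inputs = cfg["inputs"]
    for key in ("beta", "annotation", "metadata"):
        if key not in inputs:
            raise PipelineConfigError(f"inputs block missing {key!r} path")
    beta = read_beta_matrix(inputs["beta"])
    annotation = read_annotation(inputs["annotation"])
    metadata = read_metadata(inputs["metadata"])
    expression = None
    if "expression" in inputs:
        expression = read_expression(inputs["expression"],
                                     inputs.get("expression_stats"))
    return beta, annotation, metadata, expression, None


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict | str | Path, out_dir, seed: int | None = None
                 ) -> dict:
    """Run every stage in dependency order; returns the manifest dict."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = config.get("options", {})
    seed = seed if seed is not None else int(config.get("seed", 0))

    beta, annotation, metadata, expression, truth = _load_inputs(config, seed)
    manifest: dict = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
        "n_probes_input": beta.shape[0],
        "n_samples": beta.shape[1],
        "stages": {},
    }

    def stage(name):
        logger.info("pipeline: stage %s", name)
        return manifest["stages"].setdefault(name, {})

    # filtering ------------------------------------------------------------
    st = stage("filter")
    filtered, report = filter_probes(beta, annotation)
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    st.update(removed=report.removed, retained=report.retained)

    # differential methylation ----------------------------------------------
    st = stage("diffmeth")
    labels = labels_from_diagnosis(metadata["diagnosis"])
    dm = differential_methylation(filtered, labels)
    dm.to_csv(out / "diffmeth.tsv", sep="\t", index=False, float_format="%.6g")
    tier1 = extract_signature(dm, "tier1", annotation)
    tier2 = extract_signature(dm, "tier2", annotation)
    tier1.table.to_csv(out / "signature_tier1.tsv", sep="\t", index=False,
                       float_format="%.6g")
    tier2.table.to_csv(out / "signature_tier2.tsv", sep="\t", index=False,
                       float_format="%.6g")
    st.update(n_tested=len(dm), tier1=len(tier1), tier2=len(tier2),
              tier1_directions=tier1.direction_counts)

    # enrichment ------------------------------------------------------------
    st = stage("enrichment")
    background = annotation.loc[annotation.index.isin(filtered.probe_ids)]
    if len(tier1):
        enr = enrich(tier1, background)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        st.update(categories=len(enr),
                  significant=int(((enr["q"] < 0.05) & (enr["odds_ratio"] > 1)).sum()))
    else:
        st.update(skipped="empty tier1 signature")

    # methylation-expression -------------------------------------------------
    st = stage("meth_expr")
    if expression is not None and expression.gene_stats is not None and len(tier1):
        records, summary = correlate_meth_expr(tier1, annotation, expression)
        records.to_csv(out / "meth_expr.tsv", sep="\t", index=False,
                       float_format="%.6g")
        st.update(**summary)
    else:
        st.update(skipped="no expression statistics supplied")

    # cross-validated classification -----------------------------------------
    st = stage("crossval")
    cv = loo_cross_validate(filtered, labels,
                            model=opts.get("model", "logistic"),
                            features=opts.get("features", "signature"))
    cv.folds.to_csv(out / "cv_folds.tsv", sep="\t", index=False,
                    float_format="%.6g")
    _write_json(cv.summary(), out / "cv_report.json")
    st.update(**{k: v for k, v in cv.summary().items()})

    # clustering -------------------------------------------------------------
    st = stage("cluster")
    sig_for_cluster = tier1 if len(tier1) else tier2
    if len(sig_for_cluster) >= 2:
        sig_matrix = filtered.restrict_probes(sig_for_cluster.probe_ids)
        k = int(opts.get("k", 3))
        assign = hierarchical_cluster(sig_matrix,
                                      metric=opts.get("metric", "pearson"),
                                      linkage=opts.get("linkage", "average"),
                                      k=min(k, sig_matrix.shape[1]))
        assign.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t",
                                        index_label="sample_id")
        scores, evr = pca_project(sig_matrix)
        scores.to_csv(out / "pca_scores.tsv", sep="\t",
                      index_label="sample_id", float_format="%.6g")
        st.update(k=int(assign.k),
                  cluster_sizes=assign.labels.value_counts().sort_index()
                  .to_dict(),
                  pca_explained=[round(float(v), 6) for v in evr])
        grouping = assign.labels
    else:
        st.update(skipped="signature too small to cluster")
        grouping = None

    # survival ---------------------------------------------------------------
    st = stage("survival")
    has_os = metadata["os_time"].notna()
    if grouping is not None and has_os.sum() >= 4:
        sub = metadata[has_os]
        res = {}
        for test in ("logrank", "gehan"):
            r = k_sample_test(sub["os_time"], sub["death_event"].astype(bool),
                              grouping.reindex(sub.index), test=test)
            res[test] = {"chi_square": r.chi_square, "df": r.df,
                         "p_value": r.p_value}
        _write_json(res, out / "survival_tests.json")
        freq = event_frequency_table(metadata, grouping)
        freq.to_csv(out / "event_frequencies.tsv", sep="\t", index=False)
        st.update(**res)
    else:
        st.update(skipped="no usable grouping or outcomes")

    # factor analysis ---------------------------------------------------------
    st = stage("factors")
    sig_probes = tier2.probe_ids if len(tier2) else sig_for_cluster.probe_ids
    n_factors = int(opts.get("n_factors", 12))
    if len(sig_probes) > n_factors:
        attrs = pd.concat(
            [filtered.values.loc[sig_probes].T, encode_covariates(metadata)],
            axis=1)
        attrs = attrs.loc[:, attrs.std(axis=0, ddof=0) > 0]
        try:
            fr = factor_analyze(attrs, n_factors=min(n_factors,
                                                     attrs.shape[1] - 1))
            fr.loadings.to_csv(out / "factor_loadings.tsv", sep="\t",
                               index_label="attribute", float_format="%.6g")
            st.update(n_factors=fr.n_factors,
                      n_attributes=int(attrs.shape[1]))
        except ValueError as exc:
            st.update(skipped=str(exc))
    else:
        st.update(skipped="signature smaller than the factor count")

    _write_json(manifest, out / "manifest.json")
    return manifest
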