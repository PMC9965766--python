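"""End-to-end orchestration of the analysis pipeline.

Stage order mirrors the study flow: QC (outlier removal) -> normalization
(INT) -> univariate testing -> classification -> per-group network
inference -> differential connectivity -> topology comparison -> pathway
enrichment.  Every stage writes its outputs under the configured output
directory and is recorded in a JSON manifest with parameters, seeds and
wall-clock time; a rerun with the same config and seed reproduces all
result files bit-for-bit.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, diffcon, enrichment, pclrc, preprocessing, topology, univariate
from .classification import ResamplingScheme, permutation_test, rf_classify
from .config import PipelineConfig
from .data_io import GroupPair
from .synthetic_data import crc_cohort_design, simulate

log = logging.getLogger("metabonet")

__all__ = ["run_all", "load_design_yaml"]


def load_design_yaml(path):
    """Read a SyntheticDesign from YAML."""
    import yaml

    from .synthetic_data import CorrelationBlock, SyntheticDesign

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    blocks = {
        g: [CorrelationBlock(tuple(b["indices"]), float(b["rho"])) for b in bl]
        for g, bl in (raw.get("blocks_per_group") or {}).items()
    }
    shifts = {
        g: (tuple(s["indices"]), float(s["delta"]))
        for g, s in (raw.get("shifted_metabolites") or {}).items()
    }
    return SyntheticDesign(
        n_per_group=dict(raw["n_per_group"]),
        n_metabolites=int(raw["n_metabolites"]),
        blocks_per_group=blocks,
        shifted_metabolites=shifts,
        noise_sd=float(raw.get("noise_sd", 1.0)),
        seed=int(raw.get("seed", 0)),
    )


def _stage_seed(master: int, name: str) -> int:
    """Deterministic per-stage integer seed below 2**31 (stable across runs)."""
    import zlib

    h = np.random.SeedSequence([master, zlib.crc32(name.encode())])
    return int(h.generate_state(1)[0] % (2**31 - 1))


def _pairs(config: PipelineConfig, groups: list[str]) -> list[GroupPair]:
    if config.pairs:
        return [GroupPair(a, b) for a, b in config.pairs]
    return [GroupPair(a, b) for a, b in itertools.combinations(sorted(groups), 2)]


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; return (and write) the output manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(config.__dict__)), "stages": {}}

    def record(stage: str, t0: float, outputs: dict, **params) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "params": params,
            "wall_seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("stage=%s params=%s outputs=%s", stage, params, list(outputs))

    # -- ingest ------------------------------------------------------
    t0 = time.perf_counter()
    if config.input_path:
        data = data_io.read_abundance_table(
            config.input_path, config.input_format,
            group_aliases=config.group_aliases or data_io.DEFAULT_GROUP_ALIASES,
        )
        src = config.input_path
    else:
        design = (
            load_design_yaml(config.design_path)
            if config.design_path
            else crc_cohort_design(seed=_stage_seed(config.seed, "simulate"))
        )
        data = simulate(design)
        src = config.design_path or "crc_cohort_design"
    raw_path = out / "raw.csv"
    data_io.write_abundance_table(data, raw_path)
    record("ingest", t0, {"raw": raw_path}, source=src, n_samples=data.n_samples,
           n_metabolites=data.n_metabolites)

    # -- qc ----------------------------------------------------------
    t0 = time.perf_counter()
    data = data.impute_missing()
    clean, report = preprocessing.remove_outliers(data, config.outlier_confidence)
    qc_path = out / "clean.csv"
    rep_path = out / "outliers.tsv"
    data_io.write_abundance_table(clean, qc_path)
    pd.DataFrame(
        {"removed_sample_id": report.removed_sample_ids}
    ).to_csv(rep_path, sep="\t", index=False)
    record("qc", t0, {"clean": qc_path, "outliers": rep_path},
           confidence=config.outlier_confidence,
           n_removed=len(report.removed_sample_ids),
           per_group_removed=report.per_group_removed_counts)

    # -- normalization ------------------------------------------------
    t0 = time.perf_counter()
    normed = preprocessing.blom_transform_matrix(clean, config.blom_offset)
    int_path = out / "int.csv"
    normed.values.to_csv(int_path)
    record("normalize", t0, {"int": int_path}, blom_offset=config.blom_offset)

    pairs = _pairs(config, clean.group_labels)

    # -- univariate ---------------------------------------------------
    t0 = time.perf_counter()
    if config.univariate_input == "sqrt_raw":
        uni_data = preprocessing.sqrt_transform(clean)
    elif config.univariate_input == "int":
        uni_data = normed
    else:  # sqrt_int: signed square root of the INT z-scores (defined for negatives)
        v = normed.values
        uni_data = normed.with_values(np.sign(v) * np.sqrt(np.abs(v)), scale="sqrt_int")
    uni_rows = []
    for pair in pairs:
        uni_rows += univariate.t_test_all(uni_data, pair, alpha=config.fdr_alpha)
    uni_path = out / "univariate.tsv"
    data_io.write_results_table(
        [
            {
                "metabolite": r.metabolite, "comparison": str(r.pair),
                "t_statistic": r.t_statistic, "p_value": r.p_value,
                "q_value": r.q_value, "significant": r.significant,
                "mean_a": r.mean_a, "mean_b": r.mean_b,
            }
            for r in uni_rows
        ],
        uni_path,
    )
    record("univariate", t0, {"univariate": uni_path},
           input=config.univariate_input,
           n_significant={str(p): sum(r.significant and r.pair == p for r in uni_rows)
                          for p in pairs})

    # -- classification ----------------------------------------------
    t0 = time.perf_counter()
    rf_rows = []
    for pair in pairs:
        scheme = ResamplingScheme(
            k=config.rf_k, train_fraction=config.rf_train_fraction,
            seed=_stage_seed(config.seed, f"rf:{pair}"), n_trees=config.rf_trees,
        )
        res = rf_classify(normed, pair, scheme)
        perm = permutation_test(
            normed, pair, scheme, n_perm=config.rf_n_perm,
            perm_k=config.rf_perm_k, perm_trees=config.rf_perm_trees,
        )
        for m in ("accuracy", "sensitivity", "specificity", "auroc"):
            s = res.metric(m)
            rf_rows.append({
                "comparison": str(pair), "metric": m, "mean": s.mean,
                "ci_lo": s.ci95[0], "ci_hi": s.ci95[1],
                "p_value": perm.p_values[m],
            })
    rf_path = out / "classification.tsv"
    data_io.write_results_table(pd.DataFrame(rf_rows), rf_path)
    record("classify", t0, {"classification": rf_path}, k=config.rf_k,
           train_fraction=config.rf_train_fraction, n_perm=config.rf_n_perm)

    # -- networks -----------------------------------------------------
    t0 = time.perf_counter()
    pclrc_settings = {
        "n_iterations": config.pclrc_iterations,
        "subsample_fraction": config.pclrc_subsample_fraction,
        "retention_quantile": config.pclrc_retention_quantile,
    }
    net_outputs = {}
    results = {}
    networks = {}
    for g in clean.group_labels:
        res = pclrc.pclrc_infer(
            normed.group_values(g), seed=_stage_seed(config.seed, f"pclrc:{g}"),
            **pclrc_settings,
        )
        res.metabolite_names = clean.metabolite_names
        results[g] = res
        net = pclrc.build_network(res, config.p_min, config.r_min)
        networks[g] = net
        path = out / f"network_{g}.graphml"
        data_io.write_network(net, path, "graphml")
        net_outputs[g] = path
    record("network", t0, net_outputs, **pclrc_settings,
           p_min=config.p_min, r_min=config.r_min,
           edges={g: n.n_edges for g, n in networks.items()})

    # -- differential connectivity -----------------------------------
    t0 = time.perf_counter()
    dc_outputs = {}
    dc_sig: dict[str, list[str]] = {}
    for pair in pairs:
        rows = diffcon.differential_connectivity(
            normed, pair, pclrc_settings,
            n_perm=config.diffcon_n_perm,
            seed=_stage_seed(config.seed, f"diffcon:{pair}"),
            perm_iterations=config.diffcon_perm_iterations,
            statistic=config.diffcon_statistic,
            alpha=config.fdr_alpha,
        )
        path = out / f"diffcon_{pair}.tsv"
        data_io.write_results_table(rows, path)
        dc_outputs[str(pair)] = path
        dc_sig[str(pair)] = [r.metabolite for r in rows if r.significant]
    record("diffcon", t0, dc_outputs, n_perm=config.diffcon_n_perm,
           perm_iterations=config.diffcon_perm_iterations,
           statistic=config.diffcon_statistic,
           n_significant={k: len(v) for k, v in dc_sig.items()})

    # -- topology -----------------------------------------------------
    t0 = time.perf_counter()
    tables = {g: topology.node_topology(networks[g]) for g in networks}
    topo_path = out / "topology.tsv"
    stacked = pd.concat(
        [t.assign(network=g) for g, t in tables.items()], names=["node"]
    )
    stacked.to_csv(topo_path, sep="\t")
    pca = topology.topology_pca(tables)
    pca_path = out / "topology_pca.tsv"
    pca.scores.to_csv(pca_path, sep="\t", index=False)
    record("topology", t0, {"topology": topo_path, "pca": pca_path},
           centroid_distances={f"{a}|{b}": d for (a, b), d in pca.centroid_distances.items()})

    # -- enrichment ---------------------------------------------------
    t0 = time.perf_counter()
    lib = (
        enrichment.load_pathway_library(config.pathway_library)
        if config.pathway_library
        else enrichment.toy_pathway_library()
    )
    enr_outputs = {}
    import warnings as _warnings

    for pair in pairs:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # synthetic names may not match any library
            res = enrichment.hypergeometric_enrich(
                set(dc_sig[str(pair)]), lib, impact_min=config.impact_min
            )
        path = out / f"enrichment_{pair}.tsv"
        data_io.write_results_table(
            [
                {
                    "pathway_id": r.pathway_id, "pathway_name": r.pathway_name,
                    "k_matched": r.k_matched, "pathway_size": r.pathway_size,
                    "p_value": r.p_value, "q_value": r.q_value, "impact": r.impact,
                }
                for r in res
            ] or pd.DataFrame(columns=["pathway_id", "pathway_name", "k_matched",
                                       "pathway_size", "p_value", "q_value", "impact"]),
            path,
        )
        enr_outputs[str(pair)] = path
    record("enrich", t0, enr_outputs, impact_min=config.impact_min,
           library=config.pathway_library or "toy")

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
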