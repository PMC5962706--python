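"""End-to-end orchestration: normalize, detect, aggregate, cluster, outcome.

``run_pipeline`` executes the full analysis from a validated
:class:`~pathosig.config.PipelineConfig`: it loads (or simulates) the
experiment, normalizes microbial signals, detects signatures per cancer
type against the controls, builds signature tables and the cross-type
Venn partition, clusters each cancer type (and all cases pooled) on the
reported-signature profiles with CH-index model selection, contrasts the
selected clusters, runs both one-sided outcome tests per type and writes
every table plus a JSON run manifest.  Outputs contain no timestamps, so
a fixed seed reproduces the output directory byte for byte (the log file
aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy

import pathosig
from pathosig import cluster as clu
from pathosig import detect, io, outcome, signatures, simulate
from pathosig.config import PipelineConfig, effective_config_dict
from pathosig.normalize import normalize_experiment

logger = logging.getLogger(__name__)


def _load_experiment(config: PipelineConfig):
    if config.simulation is not None:
        exp = simulate.simulate_experiment(config.simulation)
        return exp.arrays, exp.annotations, exp.metadata, exp
    paths = config.inputs
    arrays = io.read_signal_table(paths.signals, signal_floor=config.normalization.signal_floor)
    annotations = io.read_probe_annotations(paths.annotations)
    metadata = io.read_sample_metadata(paths.metadata)
    extra = arrays.sample_ids.difference(metadata.index)
    if len(extra):
        raise ValueError(f"sample {extra[0]!r} has signals but no metadata row")
    return arrays, annotations, metadata, None


def _cluster_block(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig,
    outdir: Path,
    tag: str,
    manifest: dict[str, Any],
) -> None:
    """Cluster one samples x organisms matrix and write all cluster outputs."""
    n = matrix.shape[0]
    k_max = min(config.clustering.k_max, n - 1)
    if n < 3 or matrix.shape[1] == 0 or k_max < config.clustering.k_min:
        manifest["clustering"][tag] = {"skipped": True, "n_samples": n, "n_organisms": matrix.shape[1]}
        return
    result = clu.cluster_samples(matrix, range(config.clustering.k_min, k_max + 1))
    io.write_matrix(matrix, outdir / f"signature_matrix_{tag}.tsv")
    io.write_table(clu.linkage_table(result.linkage), outdir / f"linkage_{tag}.tsv")
    labels_df = pd.DataFrame({"sample_id": result.sample_ids})
    for k, lab in sorted(result.labels.items()):
        labels_df[f"k{k}"] = lab
    io.write_table(labels_df, outdir / f"cluster_labels_{tag}.tsv")
    io.write_table(
        pd.DataFrame(
            {"k": list(result.ch_curve), "ch_index": list(result.ch_curve.values())}
        ),
        outdir / f"ch_curve_{tag}.tsv",
    )
    io.write_text(
        clu.linkage_to_newick(result.linkage, result.sample_ids),
        outdir / f"dendrogram_{tag}.nwk",
    )
    io.write_text("\n".join(result.leaf_order()) + "\n", outdir / f"leaf_order_{tag}.txt")

    labels = pd.Series(result.selected_labels, index=pd.Index(result.sample_ids, name="sample_id"))
    contrasts = []
    for a in range(result.selected_k):
        for b in range(a + 1, result.selected_k):
            ids_a = labels.index[labels == a].tolist()
            ids_b = labels.index[labels == b].tolist()
            if len(ids_a) < 2 or len(ids_b) < 2:
                continue
            contrast = clu.cluster_contrast(
                matrix, ids_a, ids_b, alternative=config.clustering.contrast_alternative
            )
            contrast.insert(0, "cluster_b", b)
            contrast.insert(0, "cluster_a", a)
            contrasts.append(contrast)
    if contrasts:
        io.write_table(pd.concat(contrasts, ignore_index=True), outdir / f"cluster_contrasts_{tag}.tsv")

    proportions = outcome.cluster_outcome_proportions(labels, metadata.loc[labels.index, "outcome"])
    io.write_table(proportions, outdir / f"cluster_outcomes_{tag}.tsv")
    manifest["clustering"][tag] = {
        "n_samples": n,
        "n_organisms": matrix.shape[1],
        "selected_k": result.selected_k,
        "ch_curve": {str(k): v for k, v in result.ch_curve.items()},
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full analysis; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("pathosig").addHandler(handler)
    try:
        return _run(config, outdir)
    finally:
        logging.getLogger("pathosig").removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict[str, Any]:
    effective = effective_config_dict(config)
    io.write_text(json.dumps(effective, indent=2, sort_keys=True) + "\n", outdir / "effective_config.json")
    config_hash = hashlib.sha256(
        json.dumps(effective, sort_keys=True).encode("utf-8")
    ).hexdigest()[:16]

    arrays, annotations, metadata, experiment = _load_experiment(config)
    logger.info("loaded %d probes x %d samples", arrays.n_probes, arrays.n_samples)
    if experiment is not None:
        simulate.write_fixture(experiment, outdir / "simulated_input")

    norm = normalize_experiment(arrays, annotations, mode=config.normalization.mode)
    io.write_matrix(norm.signal, outdir / "normalized_matrix.tsv")
    io.write_table(
        norm.scale_factors.rename_axis("sample_id").reset_index(), outdir / "scale_factors.tsv"
    )

    control_ids = detect.group_sample_ids(metadata, config.control_group)
    types = detect.case_groups(metadata, config.control_group)
    manifest: dict[str, Any] = {
        "package_version": pathosig.__version__,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__, "pandas": pd.__version__},
        "config_sha256": config_hash,
        "seed": config.seed,
        "n_probes": int(arrays.n_probes),
        "n_microbial_probes": int((annotations["is_human"] == 0).sum()),
        "n_samples": int(arrays.n_samples),
        "cancer_types": types,
        "detection": {},
        "clustering": {},
        "outcome": {},
    }

    per_type_calls: dict[str, pd.DataFrame] = {}
    per_type_sets: dict[str, set[str]] = {}
    for cancer_type in types:
        case_ids = detect.group_sample_ids(metadata, cancer_type)
        stats_df, calls, _ = detect.detect_signatures(
            norm.signal,
            annotations,
            case_ids,
            control_ids,
            thresholds=config.detection.thresholds,
            prevalence_rule=config.detection.prevalence_rule,
            equal_var=config.detection.equal_var,
        )
        io.write_table(
            stats_df.rename_axis("probe_id").reset_index(), outdir / f"probe_stats_{cancer_type}.tsv"
        )
        table = signatures.signature_table(calls, cancer_type)
        io.write_table(table, outdir / f"signatures_{cancer_type}.tsv")
        per_type_calls[cancer_type] = calls
        per_type_sets[cancer_type] = set(calls["organism"])
        manifest["detection"][cancer_type] = {
            "n_case_samples": len(case_ids),
            "n_probes_tested": int(stats_df.shape[0]),
            "n_significant_probes": int(calls["n_significant_probes"].sum()) if len(calls) else 0,
            "n_reported_signatures": int(len(calls)),
        }
        logger.info("%s: %d signature(s) reported", cancer_type, len(calls))

    partition = signatures.partition_signatures(per_type_sets)
    io.write_text(json.dumps(partition, indent=2) + "\n", outdir / "venn_partition.json")
    io.write_table(signatures.partition_table(partition), outdir / "venn_partition.tsv")
    manifest["venn_cells"] = {k: len(v) for k, v in partition.items()}

    # clustering: per cancer type on its own reported signatures, and all
    # case samples pooled on the union of reported signatures
    for cancer_type in types:
        case_ids = detect.group_sample_ids(metadata, cancer_type)
        calls = per_type_calls[cancer_type]
        matrix = signatures.signature_sample_matrix(norm.signal, calls).loc[case_ids]
        _cluster_block(matrix, metadata, config, outdir, cancer_type, manifest)

    union_calls = pd.concat(per_type_calls.values(), ignore_index=True)
    if len(union_calls):
        union_calls = (
            union_calls.sort_values("n_significant_probes", ascending=False)
            .drop_duplicates("organism")
            .sort_values("organism", ignore_index=True)
        )
    all_cases = [s for t in types for s in detect.group_sample_ids(metadata, t)]
    pooled = signatures.signature_sample_matrix(norm.signal, union_calls).loc[all_cases]
    _cluster_block(pooled, metadata, config, outdir, "all_cases", manifest)

    for cancer_type in types:
        case_ids = detect.group_sample_ids(metadata, cancer_type)
        calls = per_type_calls[cancer_type]
        outcomes = metadata.loc[case_ids, "outcome"]
        n_alive = int((outcomes == "alive").sum())
        n_deceased = int((outcomes == "deceased").sum())
        if len(calls) == 0 or n_alive < 2 or n_deceased < 2:
            manifest["outcome"][cancer_type] = {
                "skipped": True,
                "n_alive": n_alive,
                "n_deceased": n_deceased,
                "n_signatures": int(len(calls)),
            }
            continue
        matrix = signatures.signature_sample_matrix(norm.signal, calls).loc[case_ids]
        table = outcome.outcome_tables(matrix, outcomes)
        table.insert(0, "cancer_type", cancer_type)
        io.write_table(table, outdir / f"outcome_{cancer_type}.tsv")
        io.write_table(
            outcome.boxplot_export(matrix, outcomes), outdir / f"outcome_boxplot_{cancer_type}.tsv"
        )
        manifest["outcome"][cancer_type] = {
            "n_alive": n_alive,
            "n_deceased": n_deceased,
            "n_signatures": int(len(calls)),
            "n_significant_deceased_greater": int(
                ((table["direction"] == "deceased_greater") & (table["flag"] == "significant")).sum()
            ),
        }

    io.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", outdir / "manifest.json")
    return manifest
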