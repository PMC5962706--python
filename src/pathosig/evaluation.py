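"""Calibration and power studies of the detection pipeline on synthetic data.

These helpers run repeated simulated experiments under fixed study
conditions and summarize operating characteristics: the null
false-positive rate of the joint signature filter, planted-signature
sensitivity and decoy specificity, Calinski-Harabasz cluster-count
recovery, and the power/size of the one-sided outcome test.  They are the
computational backbone of the acceptance checks and of the analysis
scripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pathosig import detect, simulate
from pathosig.cluster import select_cluster_count
from pathosig.detect import FilterThresholds
from pathosig.normalize import normalize_experiment
from pathosig.outcome import outcome_association
from pathosig.simulate import CONTROL_GROUP, PlantedSignature, SimulationConfig


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds below 2**31 from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def reported_organisms(
    config: SimulationConfig, thresholds: FilterThresholds | None = None
) -> dict[str, set[str]]:
    """Simulate one experiment and run detection for every cancer type.

    Returns the mapping cancer type -> set of reported organisms.
    """
    exp = simulate.simulate_experiment(config)
    norm = normalize_experiment(exp.arrays, exp.annotations)
    control_ids = detect.group_sample_ids(exp.metadata, CONTROL_GROUP)
    out: dict[str, set[str]] = {}
    for cancer_type in detect.case_groups(exp.metadata, CONTROL_GROUP):
        case_ids = detect.group_sample_ids(exp.metadata, cancer_type)
        _, calls, _ = detect.detect_signatures(
            norm.signal, exp.annotations, case_ids, control_ids, thresholds=thresholds
        )
        out[cancer_type] = set(calls["organism"])
    return out


def null_config(seed: int = 0, n_microbial_probes: int = 500) -> SimulationConfig:
    """The emulated study design with no planted signatures.

    Default group sizes (50/34/24/40 cases + 20 controls), the requested
    number of microbial probes spread over 5-probe decoy organisms, and
    log2 noise SD 0.5.
    """
    return SimulationConfig(
        signatures=(),
        n_decoy_organisms=n_microbial_probes // 5,
        probes_per_signature=5,
        noise_sd_log2=0.5,
        seed=seed,
    )


def null_signature_rate(n_seeds: int = 100, seed: int = 0) -> pd.DataFrame:
    """Reported-signature counts across replicate null experiments.

    One row per replicate with the total number of organisms reported in
    any cancer type (expected: 0 under default thresholds).
    """
    rows = []
    for s in _derive_seeds(seed, n_seeds):
        reported = reported_organisms(null_config(seed=int(s)))
        total = set().union(*reported.values())
        rows.append({"seed": int(s), "n_reported": len(total)})
    return pd.DataFrame(rows)


def planted_config(
    seed: int = 0,
    n_planted: int = 10,
    n_decoys: int = 40,
    effect_log2: float = 2.0,
    case_prevalence_frac: float = 0.6,
) -> SimulationConfig:
    """Planted-recovery design: planted organisms in all case groups + decoys."""
    classes = simulate.ORGANISM_CLASSES
    target_groups = tuple(
        g for g in simulate.DEFAULT_GROUP_SIZES if g != CONTROL_GROUP
    )
    planted = [
        PlantedSignature(
            organism=f"planted_{classes[i % len(classes)]}_{i + 1:02d}",
            organism_class=classes[i % len(classes)],
            target_groups=target_groups,
            effect_log2=effect_log2,
            case_prevalence_frac=case_prevalence_frac,
            control_prevalence_frac=0.0,
        )
        for i in range(n_planted)
    ]
    return SimulationConfig(
        signatures=planted, n_decoy_organisms=n_decoys, probes_per_signature=5, seed=seed
    )


def planted_recovery(n_seeds: int = 50, seed: int = 0) -> pd.DataFrame:
    """Sensitivity/specificity of the joint filter on planted experiments.

    One row per replicate: number of planted organisms recovered (in any
    cancer type) and number of decoys falsely reported.
    """
    rows = []
    for s in _derive_seeds(seed, n_seeds):
        config = planted_config(seed=int(s))
        truth = {sig.organism for sig in config.signatures}
        reported = set().union(*reported_organisms(config).values())
        rows.append(
            {
                "seed": int(s),
                "n_planted": len(truth),
                "n_recovered": len(reported & truth),
                "n_decoys_reported": len(reported - truth),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BlobDesign:
    """Well-separated Gaussian blob layout for cluster-count recovery."""

    n_clusters: int
    points_per_cluster: int = 20
    n_features: int = 3
    within_sd: float = 1.0
    center_spacing: float = 15.0  # 15 within-cluster SDs between adjacent centers


def sample_blobs(design: BlobDesign, rng: np.random.Generator) -> np.ndarray:
    centers = np.zeros((design.n_clusters, design.n_features))
    centers[:, 0] = np.arange(design.n_clusters) * design.center_spacing
    points = [
        rng.normal(center, design.within_sd, size=(design.points_per_cluster, design.n_features))
        for center in centers
    ]
    return np.vstack(points)


def cluster_count_recovery(
    planted_ks: tuple[int, ...] = (2, 3, 4), n_seeds: int = 100, seed: int = 0
) -> pd.DataFrame:
    """CH-index cluster-count recovery on planted blob designs.

    One row per (planted k, replicate) with the selected k.
    """
    rows = []
    seeds = _derive_seeds(seed, n_seeds * len(planted_ks)).reshape(len(planted_ks), n_seeds)
    for ki, k in enumerate(planted_ks):
        design = BlobDesign(n_clusters=k)
        for s in seeds[ki]:
            rng = np.random.default_rng(int(s))
            selected, _, _ = select_cluster_count(sample_blobs(design, rng))
            rows.append({"planted_k": k, "seed": int(s), "selected_k": selected})
    return pd.DataFrame(rows)


def outcome_power_and_size(
    n_seeds: int = 100,
    seed: int = 0,
    delta_log2: float = 1.5,
    n_per_group: int = 20,
    sd: float = 1.0,
    n_null_organisms: int = 20,
) -> pd.DataFrame:
    """Power and size of the one-sided outcome test on synthetic signals.

    Each replicate builds a samples x organisms signature matrix with one
    organism elevated by ``delta_log2`` in the deceased group plus
    ``n_null_organisms`` null organisms, runs the deceased > alive test,
    then permutes the outcome labels and re-runs it to measure the
    false-positive rate with no effect.
    """
    rows = []
    for s in _derive_seeds(seed, n_seeds):
        rng = np.random.default_rng(int(s))
        n = 2 * n_per_group
        sample_ids = [f"S{i:03d}" for i in range(n)]
        outcomes = pd.Series(
            ["deceased"] * n_per_group + ["alive"] * n_per_group,
            index=sample_ids,
        )
        signals = rng.normal(0.0, sd, size=(n, 1 + n_null_organisms))
        signals[:n_per_group, 0] += delta_log2
        matrix = pd.DataFrame(
            signals,
            index=sample_ids,
            columns=["planted"] + [f"null_{i:02d}" for i in range(n_null_organisms)],
        )
        table = outcome_association(matrix, outcomes, direction="deceased_greater")
        planted_p = float(table.set_index("organism").loc["planted", "p"])

        permuted = pd.Series(rng.permutation(outcomes.to_numpy()), index=outcomes.index)
        null_table = outcome_association(matrix, permuted, direction="deceased_greater")
        null_cols = null_table[null_table["organism"] != "planted"]
        rows.append(
            {
                "seed": int(s),
                "planted_p": planted_p,
                "planted_detected": planted_p < 0.05,
                "n_null_tests": len(null_cols),
                "n_null_positive": int((null_cols["p"] < 0.05).sum()),
            }
        )
    return pd.DataFrame(rows)


def binomial_bounds(p: float, n: int, z: float = 2.5758293035489004) -> tuple[float, float]:
    """Normal-approximation binomial bounds (z defaults to the 99% quantile)."""
    half = z * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
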