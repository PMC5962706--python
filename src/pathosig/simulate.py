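"""Synthetic two-channel pan-pathogen array experiments with planted truth.

The generator emulates a PathoChip-style case/control study: human
reference probes are bright in both channels, microbial probes sit at a
low cross-hybridization background in both channels, and each planted
organism signature elevates the green (sample) channel of its probes in a
fixed fraction of its target-group samples.  Signals are log-normal:
additive Gaussian noise on the log2 scale, independent across probes,
samples and channels.  Carrier assignment is deterministic given the seed
(exactly ``round(frac * group size)`` carriers chosen by seeded
permutation), so prevalence filters are exactly testable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pathosig import io
from pathosig.io import ORGANISM_CLASSES, ArraySet

#: study design emulated by default: four breast-cancer case groups + controls
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "BRER": 50,
    "BRHR": 34,
    "BRTP": 24,
    "BRTN": 40,
    "control": 20,
}
CONTROL_GROUP = "control"


@dataclass(frozen=True)
class PlantedSignature:
    """A ground-truth organism signature elevated in the green channel.

    Parameters
    ----------
    organism
        Signature name (genus or viral-family level).
    organism_class
        One of ``virus``, ``bacterium``, ``fungus``, ``parasite``.
    target_groups
        Case groups whose samples can carry the signature.
    effect_log2
        Green-channel elevation in carriers, log2 units (> 0).
    case_prevalence_frac
        Fraction of each target group carrying the elevation, in (0, 1].
    control_prevalence_frac
        Fraction of control samples carrying it, in [0, 1].
    """

    organism: str
    organism_class: str
    target_groups: tuple[str, ...]
    effect_log2: float = 2.0
    case_prevalence_frac: float = 0.6
    control_prevalence_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.organism_class not in ORGANISM_CLASSES:
            raise ValueError(
                f"organism_class {self.organism_class!r} not in {ORGANISM_CLASSES}"
            )
        if not self.target_groups:
            raise ValueError(f"signature {self.organism!r}: target_groups is empty")
        if not self.effect_log2 > 0:
            raise ValueError(f"signature {self.organism!r}: effect_log2 must be > 0")
        if not 0 < self.case_prevalence_frac <= 1:
            raise ValueError(f"signature {self.organism!r}: case_prevalence_frac must be in (0, 1]")
        if not 0 <= self.control_prevalence_frac <= 1:
            raise ValueError(f"signature {self.organism!r}: control_prevalence_frac must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Study design and noise model for a synthetic experiment.

    Defaults reproduce the emulated study layout: case groups of
    50/34/24/40 samples plus 20 controls, 100 human reference probes,
    5 probes per organism, 20 decoy organisms with no planted effect,
    microbial background at 6 log2 units, human probes at 14 log2 units,
    and per-channel log2 noise SD 0.35 (the two channels combine under
    normalization to an SD of about 0.5 on the normalized log2 scale).
    """

    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_human_probes: int = 100
    signatures: Sequence[PlantedSignature] = ()
    probes_per_signature: int = 5
    n_decoy_organisms: int = 20
    baseline_log2: float = 6.0
    noise_sd_log2: float = 0.35
    human_log2: float = 14.0
    outcome_deceased_frac: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if CONTROL_GROUP not in self.group_sizes:
            raise ValueError(f"group_sizes must include the {CONTROL_GROUP!r} group")
        for group, n in self.group_sizes.items():
            minimum = 2 if group == CONTROL_GROUP else 1
            if n < minimum:
                raise ValueError(f"group {group!r} needs >= {minimum} samples, got {n}")
        if self.n_human_probes < 1:
            raise ValueError("n_human_probes must be >= 1")
        if self.probes_per_signature < 1:
            raise ValueError("probes_per_signature must be >= 1")
        if self.n_decoy_organisms < 0:
            raise ValueError("n_decoy_organisms must be >= 0")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if not 0 <= self.outcome_deceased_frac <= 1:
            raise ValueError("outcome_deceased_frac must be in [0, 1]")
        for sig in self.signatures:
            missing = [g for g in sig.target_groups if g not in self.group_sizes]
            if missing:
                raise ValueError(
                    f"signature {sig.organism!r} targets unknown group(s): {', '.join(missing)}"
                )


@dataclass
class SyntheticExperiment:
    """A simulated experiment plus its ground truth."""

    arrays: ArraySet
    annotations: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame  # long: organism, sample_id, carrier
    config: SimulationConfig


def decoy_signatures(config: SimulationConfig) -> list[str]:
    """Names of the decoy organisms (classes cycled through all four)."""
    return [
        f"decoy_{ORGANISM_CLASSES[i % len(ORGANISM_CLASSES)]}_{i + 1:02d}"
        for i in range(config.n_decoy_organisms)
    ]


def build_probe_library(config: SimulationConfig) -> pd.DataFrame:
    """Build the probe annotation table for a configuration.

    Human probes come first, then ``probes_per_signature`` probes for each
    planted signature, then the decoy organisms.  Probe ids are unique by
    construction; duplicated organism names are rejected.
    """
    config.validate()
    rows: list[tuple[str, str, str, int]] = []
    for i in range(config.n_human_probes):
        rows.append((f"HUM_{i + 1:04d}", "human", "human", 1))

    organisms: list[tuple[str, str]] = [(s.organism, s.organism_class) for s in config.signatures]
    decoys = decoy_signatures(config)
    organisms += [
        (name, ORGANISM_CLASSES[i % len(ORGANISM_CLASSES)]) for i, name in enumerate(decoys)
    ]
    seen: set[str] = set()
    for name, _ in organisms:
        if name in seen:
            raise ValueError(f"duplicate organism name {name!r} in probe library")
        seen.add(name)
    for name, cls in organisms:
        for j in range(config.probes_per_signature):
            rows.append((f"{name}_P{j + 1:02d}", name, cls, 0))
    df = pd.DataFrame(rows, columns=io.ANNOTATION_COLUMNS)
    return df.set_index("probe_id")


def _sample_ids(config: SimulationConfig) -> tuple[pd.Index, pd.Series]:
    ids: list[str] = []
    groups: list[str] = []
    for group, n in config.group_sizes.items():
        for i in range(n):
            ids.append(f"{group}_{i + 1:03d}")
            groups.append(group)
    index = pd.Index(ids, name="sample_id")
    return index, pd.Series(groups, index=index, name="group")


def _choose_carriers(rng: np.random.Generator, members: np.ndarray, frac: float) -> np.ndarray:
    """Exactly round(frac * n) carriers by seeded permutation."""
    k = int(round(frac * len(members)))
    return rng.permutation(members)[:k]


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Simulate raw two-channel signals with planted signatures.

    Raw signal = ``2 ** (log2-mean + Normal(0, noise_sd_log2))`` per probe,
    sample and channel.  Human probes are centered at ``human_log2`` in both
    channels; microbial probes at ``baseline_log2``; carrier samples get
    ``effect_log2`` added to the green-channel log2 mean of the signature's
    probes.  The red channel carries the human-reference hybridization and
    therefore no planted microbial effect.
    """
    config.validate()
    annotations = build_probe_library(config)
    samples, groups = _sample_ids(config)
    rng = np.random.default_rng(config.seed)

    n_probes, n_samples = len(annotations), len(samples)
    is_human = (annotations["is_human"] == 1).to_numpy()
    mu = np.where(is_human, config.human_log2, config.baseline_log2)
    mu_green = np.tile(mu[:, None], (1, n_samples)).astype(float)
    mu_red = mu_green.copy()

    group_positions = {g: np.flatnonzero((groups == g).to_numpy()) for g in config.group_sizes}
    carrier = np.zeros((len(config.signatures), n_samples), dtype=bool)
    for si, sig in enumerate(config.signatures):
        probe_rows = np.flatnonzero((annotations["organism"] == sig.organism).to_numpy())
        cols: list[np.ndarray] = [
            _choose_carriers(rng, group_positions[g], sig.case_prevalence_frac)
            for g in sig.target_groups
        ]
        if sig.control_prevalence_frac > 0:
            cols.append(
                _choose_carriers(rng, group_positions[CONTROL_GROUP], sig.control_prevalence_frac)
            )
        carrier_cols = np.concatenate(cols) if cols else np.empty(0, dtype=int)
        carrier[si, carrier_cols] = True
        mu_green[np.ix_(probe_rows, carrier_cols)] += sig.effect_log2

    shape = (n_probes, n_samples)
    green = 2.0 ** (mu_green + rng.normal(0.0, config.noise_sd_log2, shape))
    red = 2.0 ** (mu_red + rng.normal(0.0, config.noise_sd_log2, shape))
    arrays = ArraySet(
        green=pd.DataFrame(green, index=annotations.index, columns=samples),
        red=pd.DataFrame(red, index=annotations.index, columns=samples),
    )

    # outcomes: deceased/alive assigned by seeded permutation within each case
    # group, independent of signals; controls have unknown outcome
    outcome = pd.Series(io.OUTCOME_UNKNOWN, index=samples, name="outcome")
    for group, pos in group_positions.items():
        if group == CONTROL_GROUP:
            continue
        deceased = _choose_carriers(rng, pos, config.outcome_deceased_frac)
        alive = np.setdiff1d(pos, deceased)
        outcome.iloc[deceased] = "deceased"
        outcome.iloc[alive] = "alive"
    metadata = pd.DataFrame({"group": groups, "outcome": outcome})

    truth = pd.DataFrame(
        {
            "organism": np.repeat([s.organism for s in config.signatures], n_samples),
            "sample_id": np.tile(samples.to_numpy(), len(config.signatures)),
            "carrier": carrier.astype(int).ravel(),
        }
    )
    return SyntheticExperiment(
        arrays=arrays, annotations=annotations, metadata=metadata, truth=truth, config=config
    )


def write_fixture(experiment: SyntheticExperiment, directory: str | Path) -> dict[str, Path]:
    """Write the four fixture tables; round-trips losslessly through io."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = experiment.arrays
    long = pd.DataFrame(
        {
            "probe_id": np.repeat(arrays.probe_ids.to_numpy(), arrays.n_samples),
            "sample_id": np.tile(arrays.sample_ids.to_numpy(), arrays.n_probes),
            "green_signal": arrays.green.to_numpy().ravel(),
            "red_signal": arrays.red.to_numpy().ravel(),
        }
    )
    paths = {
        "signals": io.write_table(long, directory / "signals.tsv", float_format="%.17g"),
        "annotations": io.write_table(
            experiment.annotations.reset_index(), directory / "annotations.tsv"
        ),
        "metadata": io.write_table(
            experiment.metadata.reset_index().replace({"outcome": {io.OUTCOME_UNKNOWN: "NA"}}),
            directory / "metadata.tsv",
        ),
        "truth": io.write_table(experiment.truth, directory / "truth.tsv"),
    }
    return paths


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed (convenience for replicates)."""
    return replace(config, seed=seed)
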