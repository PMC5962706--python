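"""Pipeline configuration: schema, defaults and strict validation.

The config is a YAML (or JSON) mapping with exactly one of an ``inputs``
block (paths to the three tables) or a ``simulation`` block (a synthetic
experiment specification).  Unknown keys anywhere are rejected, and all
schema violations are reported at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from pathosig.detect import ALTERNATIVES, PREVALENCE_RULES, FilterThresholds
from pathosig.normalize import NORMALIZATION_MODES
from pathosig.simulate import PlantedSignature, SimulationConfig


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


@dataclass
class InputPaths:
    signals: Path
    annotations: Path
    metadata: Path


@dataclass
class NormalizationConfig:
    mode: str = "literal"
    signal_floor: float = 1.0


@dataclass
class DetectionConfig:
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    prevalence_rule: str = "union"
    equal_var: bool = False


@dataclass
class ClusteringConfig:
    k_min: int = 2
    k_max: int = 10
    contrast_alternative: str = "two-sided"


@dataclass
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    control_group: str = "control"
    inputs: InputPaths | None = None
    simulation: SimulationConfig | None = None
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    output_dir: Path | None = None


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str, problems: list[str]) -> None:
    for key in block:
        if key not in allowed:
            problems.append(f"unknown key {key!r} in {where}")


def _parse_signature(raw: Mapping[str, Any], i: int, problems: list[str]) -> PlantedSignature | None:
    allowed = {
        "organism",
        "organism_class",
        "target_groups",
        "effect_log2",
        "case_prevalence_frac",
        "control_prevalence_frac",
    }
    _check_keys(raw, allowed, f"simulation.signatures[{i}]", problems)
    try:
        return PlantedSignature(
            organism=raw["organism"],
            organism_class=raw["organism_class"],
            target_groups=tuple(raw.get("target_groups", ())),
            effect_log2=float(raw.get("effect_log2", 2.0)),
            case_prevalence_frac=float(raw.get("case_prevalence_frac", 0.6)),
            control_prevalence_frac=float(raw.get("control_prevalence_frac", 0.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        problems.append(f"simulation.signatures[{i}]: {exc}")
        return None


def _parse_simulation(raw: Mapping[str, Any], seed: int, problems: list[str]) -> SimulationConfig | None:
    allowed = {
        "group_sizes",
        "n_human_probes",
        "signatures",
        "probes_per_signature",
        "n_decoy_organisms",
        "baseline_log2",
        "noise_sd_log2",
        "human_log2",
        "outcome_deceased_frac",
        "seed",
    }
    _check_keys(raw, allowed, "simulation", problems)
    signatures = [
        sig
        for i, entry in enumerate(raw.get("signatures", []))
        if (sig := _parse_signature(entry, i, problems)) is not None
    ]
    kwargs: dict[str, Any] = {
        k: raw[k]
        for k in allowed - {"signatures", "seed"}
        if k in raw
    }
    try:
        config = SimulationConfig(signatures=signatures, seed=int(raw.get("seed", seed)), **kwargs)
        config.validate()
        return config
    except (TypeError, ValueError) as exc:
        problems.append(f"simulation: {exc}")
        return None


def parse_config(raw: Mapping[str, Any]) -> PipelineConfig:
    """Validate a raw config mapping; raises ConfigError listing all problems."""
    problems: list[str] = []
    allowed = {
        "seed",
        "log_level",
        "control_group",
        "inputs",
        "simulation",
        "normalization",
        "detection",
        "clustering",
        "output_dir",
    }
    _check_keys(raw, allowed, "the top level", problems)

    has_inputs = "inputs" in raw
    has_sim = "simulation" in raw
    if has_inputs == has_sim:
        problems.append("exactly one of 'inputs' or 'simulation' must be present")

    cfg = PipelineConfig(seed=int(raw.get("seed", 0)), log_level=str(raw.get("log_level", "INFO")))
    cfg.control_group = str(raw.get("control_group", "control"))
    if raw.get("output_dir") is not None:
        cfg.output_dir = Path(raw["output_dir"])

    if has_inputs and not has_sim:
        block = raw["inputs"] or {}
        _check_keys(block, {"signals", "annotations", "metadata"}, "inputs", problems)
        missing = [k for k in ("signals", "annotations", "metadata") if k not in block]
        if missing:
            problems.append(f"inputs block is missing: {', '.join(missing)}")
        else:
            cfg.inputs = InputPaths(
                signals=Path(block["signals"]),
                annotations=Path(block["annotations"]),
                metadata=Path(block["metadata"]),
            )
    if has_sim and not has_inputs:
        cfg.simulation = _parse_simulation(raw["simulation"] or {}, cfg.seed, problems)

    norm = raw.get("normalization", {}) or {}
    _check_keys(norm, {"mode", "signal_floor"}, "normalization", problems)
    cfg.normalization = NormalizationConfig(
        mode=norm.get("mode", "literal"), signal_floor=float(norm.get("signal_floor", 1.0))
    )
    if cfg.normalization.mode not in NORMALIZATION_MODES:
        problems.append(
            f"normalization.mode must be one of {NORMALIZATION_MODES}, "
            f"got {cfg.normalization.mode!r}"
        )

    det = raw.get("detection", {}) or {}
    threshold_keys = set(FilterThresholds.__dataclass_fields__)
    _check_keys(det, threshold_keys | {"prevalence_rule", "equal_var"}, "detection", problems)
    try:
        thresholds = FilterThresholds(**{k: det[k] for k in threshold_keys if k in det})
    except ValueError as exc:
        problems.append(f"detection: {exc}")
        thresholds = FilterThresholds()
    cfg.detection = DetectionConfig(
        thresholds=thresholds,
        prevalence_rule=det.get("prevalence_rule", "union"),
        equal_var=bool(det.get("equal_var", False)),
    )
    if cfg.detection.prevalence_rule not in PREVALENCE_RULES:
        problems.append(f"detection.prevalence_rule must be one of {PREVALENCE_RULES}")

    clu = raw.get("clustering", {}) or {}
    _check_keys(clu, {"k_min", "k_max", "contrast_alternative"}, "clustering", problems)
    cfg.clustering = ClusteringConfig(
        k_min=int(clu.get("k_min", 2)),
        k_max=int(clu.get("k_max", 10)),
        contrast_alternative=clu.get("contrast_alternative", "two-sided"),
    )
    if cfg.clustering.k_min < 2 or cfg.clustering.k_max < cfg.clustering.k_min:
        problems.append("clustering: need 2 <= k_min <= k_max")
    if cfg.clustering.contrast_alternative not in ALTERNATIVES:
        problems.append(f"clustering.contrast_alternative must be one of {ALTERNATIVES}")

    if problems:
        raise ConfigError(problems)
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline configuration file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, Mapping):
        raise ConfigError([f"{path}: top level must be a mapping"])
    return parse_config(raw)


def effective_config_dict(cfg: PipelineConfig) -> dict[str, Any]:
    """Serializable echo of the effective configuration (defaults filled)."""
    out: dict[str, Any] = {
        "seed": cfg.seed,
        "log_level": cfg.log_level,
        "control_group": cfg.control_group,
        "normalization": {"mode": cfg.normalization.mode, "signal_floor": cfg.normalization.signal_floor},
        "detection": {
            **{k: getattr(cfg.detection.thresholds, k) for k in FilterThresholds.__dataclass_fields__},
            "prevalence_rule": cfg.detection.prevalence_rule,
            "equal_var": cfg.detection.equal_var,
        },
        "clustering": {
            "k_min": cfg.clustering.k_min,
            "k_max": cfg.clustering.k_max,
            "contrast_alternative": cfg.clustering.contrast_alternative,
        },
    }
    if cfg.inputs is not None:
        out["inputs"] = {
            "signals": str(cfg.inputs.signals),
            "annotations": str(cfg.inputs.annotations),
            "metadata": str(cfg.inputs.metadata),
        }
    if cfg.simulation is not None:
        sim = cfg.simulation
        out["simulation"] = {
            "group_sizes": dict(sim.group_sizes),
            "n_human_probes": sim.n_human_probes,
            "probes_per_signature": sim.probes_per_signature,
            "n_decoy_organisms": sim.n_decoy_organisms,
            "baseline_log2": sim.baseline_log2,
            "noise_sd_log2": sim.noise_sd_log2,
            "human_log2": sim.human_log2,
            "outcome_deceased_frac": sim.outcome_deceased_frac,
            "seed": sim.seed,
            "signatures": [
                {
                    "organism": s.organism,
                    "organism_class": s.organism_class,
                    "target_groups": list(s.target_groups),
                    "effect_log2": s.effect_log2,
                    "case_prevalence_frac": s.case_prevalence_frac,
                    "control_prevalence_frac": s.control_prevalence_frac,
                }
                for s in sim.signatures
            ],
        }
    if cfg.output_dir is not None:
        out["output_dir"] = str(cfg.output_dir)
    return out
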