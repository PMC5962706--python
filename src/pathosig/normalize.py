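"""Human-probe scale-factor normalization of microbial probe signals.

Each hybridization carries its own Cy3/Cy5 pair, so a scale factor is
computed per sample/array from the human reference probes:

    sf = sum(green over human probes) / sum(red over human probes)

Microbial probes are then normalized on the log2 scale.  Two readings of
the normalization are supported:

``literal`` (default)
    N = log2(g) - sf * log2(r)    (sf multiplies the log signal)
``ratio``
    N = log2(g) - log2(sf * r) = log2(g / (sf * r))

When sf = 1 both modes coincide at log2(g) - log2(r).  Human probes are
excluded from the normalized matrix and from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pathosig.io import ArraySet

NORMALIZATION_MODES = ("literal", "ratio")


@dataclass
class NormalizedMatrix:
    """Normalized microbial probe signals (log2 units) plus scale factors."""

    signal: pd.DataFrame       # non-human probes x samples
    scale_factors: pd.Series   # per sample, dimensionless, > 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.signal.to_numpy()).all():
            raise ValueError("normalized matrix contains non-finite values")
        if not (self.scale_factors > 0).all():
            raise ValueError("scale factors must be positive")


def compute_scale_factor(green_human: np.ndarray, red_human: np.ndarray) -> float:
    """Scale factor for one array: sum of green over sum of red human signals."""
    green_human = np.asarray(green_human, dtype=float)
    red_human = np.asarray(red_human, dtype=float)
    if green_human.size == 0:
        raise ValueError("no human probes: scale factor undefined")
    if green_human.shape != red_human.shape:
        raise ValueError("green and red human-probe vectors differ in length")
    total_red = red_human.sum()
    if total_red <= 0:
        raise ValueError("sum of red human signals must be positive")
    return float(green_human.sum() / total_red)


def compute_scale_factors(arrays: ArraySet, annotations: pd.DataFrame) -> pd.Series:
    """Per-sample scale factors from the human probes of each array."""
    human = annotations.index[annotations["is_human"] == 1]
    human = human.intersection(arrays.probe_ids)
    if len(human) == 0:
        raise ValueError("no human probes found: cannot compute scale factors")
    sf = arrays.green.loc[human].sum(axis=0) / arrays.red.loc[human].sum(axis=0)
    sf.name = "scale_factor"
    return sf


def normalize_array(
    green: np.ndarray, red: np.ndarray, sf: float, mode: str = "literal"
) -> np.ndarray:
    """Normalize one array's microbial signals given its scale factor."""
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}, got {mode!r}")
    if not sf > 0:
        raise ValueError("scale factor must be positive")
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if mode == "literal":
        return np.log2(green) - sf * np.log2(red)
    return np.log2(green) - np.log2(sf * red)


def normalize_experiment(
    arrays: ArraySet, annotations: pd.DataFrame, mode: str = "literal"
) -> NormalizedMatrix:
    """Compute per-sample scale factors and normalize all microbial probes."""
    sf = compute_scale_factors(arrays, annotations)
    microbial = annotations.index[annotations["is_human"] == 0].intersection(arrays.probe_ids)
    g = arrays.green.loc[microbial].to_numpy()
    r = arrays.red.loc[microbial].to_numpy()
    if mode == "literal":
        n = np.log2(g) - sf.to_numpy()[None, :] * np.log2(r)
    elif mode == "ratio":
        n = np.log2(g) - np.log2(sf.to_numpy()[None, :] * r)
    else:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}, got {mode!r}")
    bad = ~np.isfinite(n)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite normalized signal for probe {microbial[i]!r}, sample "
            f"{arrays.sample_ids[j]!r}"
        )
    signal = pd.DataFrame(n, index=microbial, columns=arrays.sample_ids)
    return NormalizedMatrix(signal=signal, scale_factors=sf)
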