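"""Tabular I/O and in-memory containers for two-channel array experiments.

All external formats are UTF-8 tab-delimited text with a header row:

signal table
    long format, one row per (probe, sample):
    ``probe_id  sample_id  green_signal  red_signal``
annotation table
    ``probe_id  organism  organism_class  is_human`` with
    organism_class in {virus, bacterium, fungus, parasite, human} and
    is_human in {0, 1}
metadata table
    ``sample_id  group  outcome`` with outcome in {alive, deceased, NA}

Readers validate rather than coerce: malformed rows raise ``ValueError``
with the offending row number (counting the header as line 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ORGANISM_CLASSES = ("virus", "bacterium", "fungus", "parasite")
ALLOWED_CLASSES = ORGANISM_CLASSES + ("human",)
OUTCOME_UNKNOWN = "unknown"
ALLOWED_OUTCOMES = ("alive", "deceased", OUTCOME_UNKNOWN)

SIGNAL_COLUMNS = ["probe_id", "sample_id", "green_signal", "red_signal"]
ANNOTATION_COLUMNS = ["probe_id", "organism", "organism_class", "is_human"]
METADATA_COLUMNS = ["sample_id", "group", "outcome"]
TRUTH_COLUMNS = ["organism", "sample_id", "carrier"]

#: default floor (fluorescence units) applied to non-positive raw signals
DEFAULT_SIGNAL_FLOOR = 1.0


@dataclass
class ArraySet:
    """Raw two-channel signals: probes x samples, one matrix per channel.

    ``green`` holds the sample-material channel (Cy3) and ``red`` the
    common human-reference channel (Cy5).  Both matrices share identical
    probe and sample index sets and are strictly positive (non-positive
    scanner exports are floored on read).
    """

    green: pd.DataFrame
    red: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.green.index.equals(self.red.index):
            raise ValueError("green and red channels have different probe sets")
        if not self.green.columns.equals(self.red.columns):
            raise ValueError("green and red channels have different sample sets")
        for name, mat in (("green", self.green), ("red", self.red)):
            if not np.all(mat.to_numpy() > 0):
                raise ValueError(f"{name} channel contains non-positive signals; floor them on read")

    @property
    def probe_ids(self) -> pd.Index:
        return self.green.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.green.columns

    @property
    def n_probes(self) -> int:
        return self.green.shape[0]

    @property
    def n_samples(self) -> int:
        return self.green.shape[1]


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match required columns {columns}"
        )
    return df


def _floor_signals(values: np.ndarray, signal_floor: float, channel: str, path: Path) -> np.ndarray:
    bad = values <= 0.0
    if bad.any():
        logger.warning(
            "%s: floored %d non-positive %s signal(s) at %g", path, int(bad.sum()), channel, signal_floor
        )
        values = np.where(bad, signal_floor, values)
    return values


def read_signal_table(path: str | Path, signal_floor: float = DEFAULT_SIGNAL_FLOOR) -> ArraySet:
    """Read a long-format signal table and pivot to probe x sample matrices.

    Every (probe, sample) cell must be present exactly once; duplicates and
    missing cells are errors, not silently filled.  Non-positive signals are
    floored at ``signal_floor`` with a logged warning.
    """
    path = Path(path)
    df = _read_table(path, SIGNAL_COLUMNS)
    dup = df.duplicated(subset=["probe_id", "sample_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"{path}: duplicate (probe_id, sample_id) row at line {i + 2}: "
            f"({df.iloc[i]['probe_id']}, {df.iloc[i]['sample_id']})"
        )
    try:
        g = df["green_signal"].astype(float)
        r = df["red_signal"].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric signal value ({exc})") from exc
    df = df.assign(green_signal=g, red_signal=r)

    probes = pd.Index(pd.unique(df["probe_id"]), name="probe_id")
    samples = pd.Index(pd.unique(df["sample_id"]), name="sample_id")
    green = df.pivot(index="probe_id", columns="sample_id", values="green_signal")
    red = df.pivot(index="probe_id", columns="sample_id", values="red_signal")
    green = green.reindex(index=probes, columns=samples)
    red = red.reindex(index=probes, columns=samples)
    if green.isna().to_numpy().any():
        stacked = green.isna().stack()
        probe, sample = stacked.index[np.flatnonzero(stacked.to_numpy())[0]]
        raise ValueError(f"{path}: missing signal cell for probe {probe!r}, sample {sample!r}")

    green[:] = _floor_signals(green.to_numpy(), signal_floor, "green", path)
    red[:] = _floor_signals(red.to_numpy(), signal_floor, "red", path)
    return ArraySet(green=green, red=red)


def read_probe_annotations(path: str | Path) -> pd.DataFrame:
    """Read the probe annotation table.

    Returns a DataFrame indexed by ``probe_id`` with columns ``organism``
    (whitespace-trimmed, case preserved), ``organism_class`` and the
    integer flag ``is_human``.
    """
    path = Path(path)
    df = _read_table(path, ANNOTATION_COLUMNS)
    dup = df.duplicated(subset=["probe_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{path}: duplicated probe_id {df.iloc[i]['probe_id']!r} at line {i + 2}")
    df = df.assign(organism=df["organism"].str.strip())
    bad_class = ~df["organism_class"].isin(ALLOWED_CLASSES)
    if bad_class.any():
        i = int(np.flatnonzero(bad_class.to_numpy())[0])
        raise ValueError(
            f"{path}: unknown organism_class {df.iloc[i]['organism_class']!r} at line {i + 2}; "
            f"allowed values: {', '.join(ALLOWED_CLASSES)}"
        )
    if not df["is_human"].isin(["0", "1"]).all():
        raise ValueError(f"{path}: is_human must be 0 or 1")
    df = df.assign(is_human=df["is_human"].astype(int))
    mismatch = (df["is_human"] == 1) != (df["organism_class"] == "human")
    if mismatch.any():
        i = int(np.flatnonzero(mismatch.to_numpy())[0])
        raise ValueError(
            f"{path}: line {i + 2}: is_human flag must match organism_class == 'human' "
            f"(probe {df.iloc[i]['probe_id']!r})"
        )
    empty = (df["is_human"] == 0) & (df["organism"] == "")
    if empty.any():
        i = int(np.flatnonzero(empty.to_numpy())[0])
        raise ValueError(f"{path}: line {i + 2}: non-human probe {df.iloc[i]['probe_id']!r} has empty organism")
    return df.set_index("probe_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; outcome 'NA' (or empty) maps to 'unknown'."""
    path = Path(path)
    df = _read_table(path, METADATA_COLUMNS)
    dup = df.duplicated(subset=["sample_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{path}: duplicated sample_id {df.iloc[i]['sample_id']!r} at line {i + 2}")
    empty = df["group"] == ""
    if empty.any():
        i = int(np.flatnonzero(empty.to_numpy())[0])
        raise ValueError(f"{path}: line {i + 2}: empty group label")
    outcome = df["outcome"].replace({"NA": OUTCOME_UNKNOWN, "": OUTCOME_UNKNOWN})
    bad = ~outcome.isin(ALLOWED_OUTCOMES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: unknown outcome {df.iloc[i]['outcome']!r} at line {i + 2}; "
            "allowed: alive, deceased, NA"
        )
    return df.assign(outcome=outcome).set_index("sample_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide numeric matrix written by :func:`write_matrix`."""
    return pd.read_csv(path, sep="\t", index_col=0)


#: numeric rendering used by all writers: >= 6 significant digits
FLOAT_FORMAT = "%.8g"


def write_matrix(df: pd.DataFrame, path: str | Path, float_format: str = FLOAT_FORMAT) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", float_format=float_format)
    return path


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = FLOAT_FORMAT) -> Path:
    """Write a tab-delimited table without the index."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
    return path


def write_tables(results: Mapping[str, pd.DataFrame], directory: str | Path) -> dict[str, Path]:
    """Write a mapping of result-name -> DataFrame as ``<name>.tsv`` files.

    Values round-trip through :func:`pandas.read_csv` to at least six
    significant digits.  Returns the mapping of names to written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return {name: write_table(df, directory / f"{name}.tsv") for name, df in results.items()}


def write_text(text: str, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(text, encoding="utf-8")
    return path
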