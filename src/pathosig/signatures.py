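"""Organism-level aggregation, percent-signal shares and Venn partition.

Reported signatures are summarized by averaging the normalized signals of
their significant probes.  Percent-of-total hybridization-signal shares
are computed within one (cancer type, organism class) cell, and the
per-type signature sets are partitioned into the unique/shared cells of a
Venn diagram across cancer types.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)


def _split_probes(calls: pd.DataFrame) -> dict[str, list[str]]:
    return {
        row["organism"]: row["significant_probe_ids"].split(",")
        for _, row in calls.iterrows()
    }


def aggregate_signature_signal(
    normalized: pd.DataFrame,
    signature_calls: pd.DataFrame,
    group_ids: Sequence[str],
) -> pd.Series:
    """Mean signal per organism over its significant probes and a sample group.

    organism mean = mean over significant probes of the per-probe mean over
    the group's samples (log2 units).
    """
    group_ids = list(group_ids)
    if not group_ids:
        raise ValueError("cannot aggregate over an empty sample group")
    means = {
        organism: float(normalized.loc[probes, group_ids].mean(axis=1).mean())
        for organism, probes in _split_probes(signature_calls).items()
    }
    return pd.Series(means, name="mean_signal", dtype=float)


def signature_sample_matrix(
    normalized: pd.DataFrame, signature_calls: pd.DataFrame
) -> pd.DataFrame:
    """Samples x organisms matrix of per-sample mean significant-probe signal.

    This is the clustering input: each reported organism contributes one
    column holding, per sample, the mean normalized signal over the
    organism's significant probes.
    """
    cols = {
        organism: normalized.loc[probes].mean(axis=0)
        for organism, probes in _split_probes(signature_calls).items()
    }
    out = pd.DataFrame(cols, index=normalized.columns)
    out.index.name = "sample_id"
    return out


def percent_signal_share(means: pd.Series) -> pd.Series:
    """Percent of the total signal held by each organism within one cell.

    Negative normalized means are handled by shifting all means in the
    cell up by the cell minimum (shares presume non-negative totals); the
    shift is logged.  A zero total yields an empty result with a warning.
    """
    if means.empty:
        raise ValueError("at least one organism is required")
    shifted = means.astype(float)
    min_val = float(shifted.min())
    if min_val < 0:
        logger.info("shifting %d signature mean(s) by %g before share computation", len(means), -min_val)
        shifted = shifted - min_val
    total = float(shifted.sum())
    if total == 0:
        logger.warning("total signal is zero; percent shares undefined")
        return pd.Series(dtype=float, name="percent_share")
    share = 100.0 * shifted / total
    share.name = "percent_share"
    return share


def signature_table(
    signature_calls: pd.DataFrame, cancer_type: str
) -> pd.DataFrame:
    """Per-organism summary for one cancer type with percent shares by class.

    Adds a ``percent_share`` column: each organism's share of the total
    mean case signal within its (cancer type, organism class) cell.
    """
    table = signature_calls.copy()
    table.insert(0, "cancer_type", cancer_type)
    table["percent_share"] = float("nan")
    for _, idx in table.groupby("organism_class").groups.items():
        cell = table.loc[idx].set_index("organism")["mean_case_signal"]
        shares = percent_signal_share(cell)
        if not shares.empty:
            table.loc[idx, "percent_share"] = shares.loc[table.loc[idx, "organism"]].to_numpy()
    return table


def partition_signatures(per_type_sets: Mapping[str, set[str]]) -> dict[str, list[str]]:
    """Venn partition of organisms across cancer types.

    Each organism is assigned to the exact subset of types reporting it.
    Keys are '+'-joined type labels (in the input's label order); cells are
    ordered by subset size then key, organisms sorted within each cell.
    Empty cells are omitted.
    """
    labels = list(per_type_sets)
    if len(set(labels)) != len(labels):
        raise ValueError("cancer type labels must be distinct")
    membership: dict[str, tuple[str, ...]] = {}
    for organism in sorted(set().union(*per_type_sets.values()) if per_type_sets else set()):
        subset = tuple(lbl for lbl in labels if organism in per_type_sets[lbl])
        membership[organism] = subset
    cells: dict[tuple[str, ...], list[str]] = {}
    for organism, subset in membership.items():
        cells.setdefault(subset, []).append(organism)
    ordered = sorted(cells.items(), key=lambda kv: (len(kv[0]), "+".join(kv[0])))
    return {"+".join(subset): sorted(orgs) for subset, orgs in ordered}


def partition_table(partition: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Venn partition as a long table (subset, n_organisms, organism)."""
    rows = [
        {"subset": subset, "n_organisms": len(orgs), "organism": organism}
        for subset, orgs in partition.items()
        for organism in orgs
    ]
    return pd.DataFrame(rows, columns=["subset", "n_organisms", "organism"])
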