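"""Association of signature signals and cluster memberships with outcome.

Within one cancer type, samples with known clinical outcome are split
into alive and deceased groups.  Each reported organism's aggregated
signature signal is compared between the groups with a one-sided Welch
t-test, run in both directions (deceased > alive and alive > deceased).
Nominal p-values are reported (a BH-adjusted column is added for
completeness); organisms at nominal p < 0.05 are flagged significant and
the rest are kept as trends.  Cluster/sub-cluster outcome composition is
summarized as the deceased proportion among known outcomes.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from pathosig.detect import adjust_bh, welch_t_test
from pathosig.io import OUTCOME_UNKNOWN

DIRECTIONS = ("deceased_greater", "alive_greater")
NOMINAL_ALPHA = 0.05


def _outcome_groups(outcomes: pd.Series) -> tuple[list[str], list[str]]:
    known = outcomes[outcomes != OUTCOME_UNKNOWN]
    deceased = known.index[known == "deceased"].tolist()
    alive = known.index[known == "alive"].tolist()
    return deceased, alive


def outcome_association(
    signature_matrix: pd.DataFrame,
    outcomes: pd.Series,
    direction: str = "deceased_greater",
) -> pd.DataFrame:
    """One-sided outcome test per organism on a samples x organisms matrix.

    ``logfc`` is always mean(deceased) - mean(alive) in log2 units,
    regardless of direction.  Samples with unknown outcome are excluded
    listwise.  Requires at least 2 samples per outcome group.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    outcomes = outcomes.loc[signature_matrix.index]
    deceased_ids, alive_ids = _outcome_groups(outcomes)
    if len(deceased_ids) < 2 or len(alive_ids) < 2:
        raise ValueError(
            f"need >= 2 samples per outcome group, got {len(deceased_ids)} deceased / "
            f"{len(alive_ids)} alive"
        )
    d = signature_matrix.loc[deceased_ids].to_numpy().T  # organisms x samples
    a = signature_matrix.loc[alive_ids].to_numpy().T
    alternative = "greater" if direction == "deceased_greater" else "less"
    t, p = welch_t_test(d, a, alternative=alternative)
    out = pd.DataFrame(
        {
            "organism": signature_matrix.columns,
            "direction": direction,
            "t": t,
            "p": p,
            "adj_p": adjust_bh(p),
            "logfc": d.mean(axis=1) - a.mean(axis=1),
        }
    )
    out["flag"] = np.where(out["p"] < NOMINAL_ALPHA, "significant", "trend")
    return out


def outcome_tables(signature_matrix: pd.DataFrame, outcomes: pd.Series) -> pd.DataFrame:
    """Both one-sided outcome tests, concatenated."""
    return pd.concat(
        [outcome_association(signature_matrix, outcomes, d) for d in DIRECTIONS],
        ignore_index=True,
    )


def cluster_outcome_proportions(labels: pd.Series, outcomes: pd.Series) -> pd.DataFrame:
    """Alive/deceased/unknown counts and deceased % of known, per cluster.

    The deceased percentage is NaN when a cluster has no known outcomes.
    """
    missing = labels.index.difference(outcomes.index)
    if len(missing):
        raise ValueError(f"sample {missing[0]!r} has no outcome record")
    rows = []
    for cluster, ids in labels.groupby(labels).groups.items():
        sub = outcomes.loc[ids]
        n_alive = int((sub == "alive").sum())
        n_deceased = int((sub == "deceased").sum())
        n_unknown = int((sub == OUTCOME_UNKNOWN).sum())
        known = n_alive + n_deceased
        rows.append(
            {
                "cluster": cluster,
                "n_samples": len(ids),
                "n_alive": n_alive,
                "n_deceased": n_deceased,
                "n_unknown": n_unknown,
                "deceased_pct": 100.0 * n_deceased / known if known else float("nan"),
            }
        )
    return pd.DataFrame(rows).sort_values("cluster", ignore_index=True)


def boxplot_export(signature_matrix: pd.DataFrame, outcomes: pd.Series) -> pd.DataFrame:
    """Long-format (organism, sample, signal, outcome) export for box plots."""
    long = signature_matrix.stack().reset_index()
    long.columns = ["sample_id", "organism", "signal"]
    long["outcome"] = outcomes.loc[long["sample_id"]].to_numpy()
    long = long[long["outcome"] != OUTCOME_UNKNOWN]
    return long[["organism", "sample_id", "signal", "outcome"]].reset_index(drop=True)
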