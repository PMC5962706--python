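"""Probe-level differential detection and signature-level filtering.

The detection stage compares one case group against the controls on
normalized log2 signals:

1. per-probe one-sided t-test (Welch by default) for case > control;
2. Benjamini-Hochberg step-up adjustment across all microbial probes of
   the comparison;
3. per-sample presence calls: a probe is "detected" in a sample when its
   normalized signal exceeds the control mean by ``presence_delta`` log2
   units (default 1, mirroring the log2FC >= 1 significance cut-off);
4. organism prevalence: percent of group samples in which at least one of
   the organism's probes is detected (union rule; a max-over-probes rule
   is available);
5. joint filter: a probe is significant iff log2FC >= min_log2fc and
   adjusted p <= max_adj_p; an organism is reported iff it has at least
   one significant probe, case prevalence >= min_case_prev_pct and
   control prevalence <= max_control_prev_pct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ALTERNATIVES = ("greater", "less", "two-sided")
PREVALENCE_RULES = ("union", "max")


@dataclass
class FilterThresholds:
    """Joint significance cut-offs for reporting an organism signature.

    Defaults: log2 fold change >= 1, BH-adjusted p <= 0.01, case
    prevalence >= 40%, control prevalence <= 25%, per-sample presence at
    1 log2 unit above the control mean.
    """

    min_log2fc: float = 1.0
    max_adj_p: float = 0.01
    min_case_prev_pct: float = 40.0
    max_control_prev_pct: float = 25.0
    presence_delta: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.max_adj_p <= 1:
            raise ValueError("max_adj_p must be in [0, 1]")
        if not 0 <= self.min_case_prev_pct <= 100:
            raise ValueError("min_case_prev_pct must be in [0, 100]")
        if not 0 <= self.max_control_prev_pct <= 100:
            raise ValueError("max_control_prev_pct must be in [0, 100]")


def welch_t_test(
    a: np.ndarray,
    b: np.ndarray,
    alternative: str = "greater",
    equal_var: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-test of ``a`` vs ``b`` (last axis = samples).

    Welch (unequal variance) by default; ``equal_var=True`` selects the
    pooled-variance test.  Degenerate rows where both groups have zero
    variance get t = 0, p = 0.5 when the means are equal, otherwise an
    infinite t in the direction of the difference (with a logged warning).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}, got {alternative!r}")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[-1] < 2 or b.shape[-1] < 2:
        raise ValueError("each group needs at least 2 samples")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) rows trip scipy's precision warning;
        # they are overwritten by the explicit conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=-1, equal_var=equal_var, alternative=alternative)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    degenerate = (a.var(axis=-1) == 0) & (b.var(axis=-1) == 0)
    if degenerate.any():
        diff = a.mean(axis=-1) - b.mean(axis=-1)
        equal = degenerate & (diff == 0)
        t[equal], p[equal] = 0.0, 0.5
        unequal = degenerate & (diff != 0)
        if unequal.any():
            logger.warning(
                "%d probe(s) constant within both groups with unequal means", int(unequal.sum())
            )
            t[unequal] = np.where(diff[unequal] > 0, np.inf, -np.inf)
            if alternative == "greater":
                p[unequal] = np.where(diff[unequal] > 0, 0.0, 1.0)
            elif alternative == "less":
                p[unequal] = np.where(diff[unequal] < 0, 0.0, 1.0)
            else:
                p[unequal] = 0.0
    return t, p


def probe_differential_test(
    normalized: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    alternative: str = "greater",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-probe case-vs-control t-test on a normalized probes x samples matrix.

    Returns a DataFrame indexed by probe with columns ``t``, ``p`` and
    ``log2fc`` (mean case - mean control, log2 units).
    """
    case = normalized[list(case_ids)].to_numpy()
    control = normalized[list(control_ids)].to_numpy()
    t, p = welch_t_test(case, control, alternative=alternative, equal_var=equal_var)
    return pd.DataFrame(
        {"t": t, "p": p, "log2fc": case.mean(axis=1) - control.mean(axis=1)},
        index=normalized.index,
    )


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order.

    Sort p ascending, set q_i = p_i * m / i, enforce monotonicity from the
    largest rank downward, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out


def call_probe_presence(
    normalized: pd.DataFrame,
    control_ids: Sequence[str],
    presence_delta: float = 1.0,
) -> pd.DataFrame:
    """Boolean probe x sample detection matrix.

    A probe is detected in a sample iff its normalized signal exceeds the
    mean control signal of that probe by at least ``presence_delta`` log2
    units.  Control samples are called against the same baseline.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("at least one control sample is required for presence calls")
    baseline = normalized[control_ids].mean(axis=1)
    return normalized.sub(baseline, axis=0) >= presence_delta


def signature_prevalence(
    presence: pd.DataFrame,
    organisms: pd.Series,
    group_ids: Sequence[str],
    rule: str = "union",
) -> pd.Series:
    """Per-organism prevalence (%) within a sample group.

    ``union`` (default): percent of group samples in which at least one of
    the organism's probes is detected.  ``max``: the maximum over the
    organism's probes of the per-probe detected-sample count, as percent.
    """
    if rule not in PREVALENCE_RULES:
        raise ValueError(f"rule must be one of {PREVALENCE_RULES}, got {rule!r}")
    group_ids = list(group_ids)
    if not group_ids:
        raise ValueError("prevalence over an empty group is undefined")
    missing = presence.index.difference(organisms.index)
    if len(missing):
        raise ValueError(f"probe {missing[0]!r} missing from the organism map")
    sub = presence[group_ids]
    by_org = organisms.loc[sub.index]
    if rule == "union":
        detected = sub.groupby(by_org).any()  # organism x sample
        prev = detected.mean(axis=1) * 100.0
    else:
        per_probe = sub.sum(axis=1)
        prev = per_probe.groupby(by_org).max() / len(group_ids) * 100.0
    prev.name = "prevalence_pct"
    return prev.astype(float)


def filter_significant(
    probe_stats: pd.DataFrame,
    case_prevalence: pd.Series,
    control_prevalence: pd.Series,
    annotations: pd.DataFrame,
    normalized: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    thresholds: FilterThresholds | None = None,
) -> pd.DataFrame:
    """Apply the joint probe- and organism-level significance filter.

    Returns one row per reported organism: class, surviving probe ids,
    case/control prevalence (%) and mean normalized signal per group over
    the significant probes.
    """
    thresholds = thresholds or FilterThresholds()
    sig = probe_stats[
        (probe_stats["log2fc"] >= thresholds.min_log2fc)
        & (probe_stats["adj_p"] <= thresholds.max_adj_p)
    ]
    rows = []
    for organism, probes in sig.groupby(annotations.loc[sig.index, "organism"], sort=True):
        case_prev = float(case_prevalence.get(organism, 0.0))
        control_prev = float(control_prevalence.get(organism, 0.0))
        if case_prev < thresholds.min_case_prev_pct:
            continue
        if control_prev > thresholds.max_control_prev_pct:
            continue
        probe_ids = list(probes.index)
        sub = normalized.loc[probe_ids]
        rows.append(
            {
                "organism": organism,
                "organism_class": annotations.loc[probe_ids[0], "organism_class"],
                "n_significant_probes": len(probe_ids),
                "significant_probe_ids": ",".join(probe_ids),
                "case_prevalence_pct": case_prev,
                "control_prevalence_pct": control_prev,
                "mean_case_signal": float(sub[list(case_ids)].mean(axis=1).mean()),
                "mean_control_signal": float(sub[list(control_ids)].mean(axis=1).mean()),
            }
        )
    columns = [
        "organism",
        "organism_class",
        "n_significant_probes",
        "significant_probe_ids",
        "case_prevalence_pct",
        "control_prevalence_pct",
        "mean_case_signal",
        "mean_control_signal",
    ]
    return pd.DataFrame(rows, columns=columns)


def detect_signatures(
    normalized: pd.DataFrame,
    annotations: pd.DataFrame,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    thresholds: FilterThresholds | None = None,
    prevalence_rule: str = "union",
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full detection for one case group vs the controls.

    Returns ``(probe_stats, signature_calls, presence)`` where probe_stats
    carries t, one-sided p, BH-adjusted p, log2fc and per-probe detection
    counts, signature_calls is the filtered organism table and presence is
    the boolean probe x sample detection matrix.
    """
    thresholds = thresholds or FilterThresholds()
    organisms = annotations.loc[normalized.index, "organism"]
    stats_df = probe_differential_test(
        normalized, case_ids, control_ids, alternative="greater", equal_var=equal_var
    )
    stats_df["adj_p"] = adjust_bh(stats_df["p"].to_numpy())
    presence = call_probe_presence(normalized, control_ids, thresholds.presence_delta)
    stats_df["case_detected_count"] = presence[list(case_ids)].sum(axis=1)
    stats_df["control_detected_count"] = presence[list(control_ids)].sum(axis=1)
    stats_df.insert(0, "organism", organisms)

    case_prev = signature_prevalence(presence, organisms, case_ids, rule=prevalence_rule)
    control_prev = signature_prevalence(presence, organisms, control_ids, rule=prevalence_rule)
    calls = filter_significant(
        stats_df,
        case_prev,
        control_prev,
        annotations,
        normalized,
        case_ids,
        control_ids,
        thresholds,
    )
    return stats_df, calls, presence


def group_sample_ids(metadata: pd.DataFrame, group: str) -> list[str]:
    """Sample ids belonging to one metadata group."""
    ids = metadata.index[metadata["group"] == group].tolist()
    if not ids:
        raise ValueError(f"no samples in group {group!r}")
    return ids


def case_groups(metadata: pd.DataFrame, control_group: str = "control") -> list[str]:
    """Case group labels in metadata order (everything but the controls)."""
    seen: dict[str, None] = {}
    for g in metadata["group"]:
        if g != control_group:
            seen.setdefault(g, None)
    return list(seen)


def mean_group_signal(
    normalized: pd.DataFrame, probe_ids: Sequence[str], sample_ids: Sequence[str]
) -> float:
    """Mean over probes of the per-probe mean over samples."""
    return float(normalized.loc[list(probe_ids), list(sample_ids)].mean(axis=1).mean())


def thresholds_from_mapping(block: Mapping[str, float] | None) -> FilterThresholds:
    """Build FilterThresholds from a config mapping, rejecting unknown keys."""
    block = dict(block or {})
    known = {f for f in FilterThresholds.__dataclass_fields__}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown threshold key(s): {', '.join(sorted(unknown))}")
    return FilterThresholds(**block)
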