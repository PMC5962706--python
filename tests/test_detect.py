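"""Probe tests, BH adjustment, presence calls, prevalence and joint filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bh_oracle, max_prevalence_oracle, union_prevalence_oracle, welch_oracle
from pathosig.detect import (
    FilterThresholds,
    adjust_bh,
    call_probe_presence,
    detect_signatures,
    probe_differential_test,
    signature_prevalence,
    welch_t_test,
)
from pathosig.normalize import normalize_experiment


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([[1, 2, 3]], [[1, 2, 3]])
        assert t[0] == 0.0
        assert p[0] == 0.5

    def test_hand_checked_example(self):
        # se = sqrt(2/3), t = 4 / sqrt(2/3) ~= 4.899, Welch df = 4
        t, p = welch_t_test([[5, 6, 7]], [[1, 2, 3]])
        assert t[0] == pytest.approx(4.898979485566356, abs=1e-9)
        assert p[0] == pytest.approx(0.004025, rel=1e-3)

    def test_direction(self):
        t, p = welch_t_test([[1, 2, 3]], [[5, 6, 7]])
        assert t[0] < 0
        assert p[0] > 0.5

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            welch_t_test([[1.0]], [[1, 2, 3]])

    def test_constant_unequal_groups_warn(self, caplog):
        with caplog.at_level("WARNING", logger="pathosig.detect"):
            t, p = welch_t_test([[2, 2, 2]], [[1, 1, 1]])
        assert t[0] == np.inf
        assert p[0] == 0.0
        assert caplog.records

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    @pytest.mark.parametrize("equal_var", [False, True])
    def test_matches_formula_oracle(self, rng, alternative, equal_var):
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 12))
            t, p = welch_t_test([a], [b], alternative=alternative, equal_var=equal_var)
            t_ref, p_ref = welch_oracle(a, b, alternative=alternative, equal_var=equal_var)
            assert t[0] == pytest.approx(t_ref, abs=1e-10)
            assert p[0] == pytest.approx(p_ref, abs=1e-10)


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.05], [0.05]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_hand_step_up(self, p, expected):
        np.testing.assert_allclose(adjust_bh(p), expected, atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_bh([-0.1])

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=200)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= p)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=120))
    @settings(max_examples=300, derandomize=True)
    def test_matches_brute_force(self, p):
        np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 400))
            np.testing.assert_allclose(
                adjust_bh(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
            )


class TestPresence:
    def test_presence_against_control_mean(self):
        n = pd.DataFrame(
            {"c1": [0.0, 0.0], "c2": [0.2, -0.2], "s1": [1.5, 0.1], "s2": [1.05, 0.0]},
            index=["P1", "P2"],
        )
        detected = call_probe_presence(n, ["c1", "c2"], presence_delta=1.0)
        assert bool(detected.loc["P1", "s1"]) is True      # 1.5 - 0.1 >= 1
        assert bool(detected.loc["P1", "s2"]) is False     # 1.05 - 0.1 < 1
        assert bool(detected.loc["P2", "s1"]) is False

    def test_exact_baseline_not_detected(self):
        n = pd.DataFrame({"c1": [1.0], "s1": [1.0]}, index=["P1"])
        assert not call_probe_presence(n, ["c1"], presence_delta=1.0).loc["P1", "s1"]

    def test_zero_delta_boundary(self):
        n = pd.DataFrame({"c1": [1.0], "s1": [1.0]}, index=["P1"])
        assert bool(call_probe_presence(n, ["c1"], presence_delta=0.0).loc["P1", "s1"]) is True


class TestPrevalence:
    def test_union_and_max_rules(self, presence_example):
        presence, organisms = presence_example
        group = ["s1", "s2", "s3", "s4"]
        assert signature_prevalence(presence, organisms, group, "union")["orgA"] == 75.0
        assert signature_prevalence(presence, organisms, group, "max")["orgA"] == 50.0

    def test_single_probe_both_rules_agree(self):
        presence = pd.DataFrame(
            [[True, True] + [False] * 38], index=["P1"], columns=[f"s{i}" for i in range(40)]
        )
        organisms = pd.Series({"P1": "org"})
        group = list(presence.columns)
        for rule in ("union", "max"):
            assert signature_prevalence(presence, organisms, group, rule)["org"] == 5.0

    def test_no_detections(self, presence_example):
        presence, organisms = presence_example
        assert signature_prevalence(presence & False, organisms, ["s1", "s2"])["orgA"] == 0.0

    def test_empty_group_rejected(self, presence_example):
        presence, organisms = presence_example
        with pytest.raises(ValueError, match="empty"):
            signature_prevalence(presence, organisms, [])

    def test_matches_set_oracles_on_random_matrices(self, rng):
        for _ in range(50):
            n_probes, n_samples = rng.integers(1, 12), rng.integers(1, 15)
            samples = [f"s{i}" for i in range(n_samples)]
            presence = pd.DataFrame(
                rng.random((n_probes, n_samples)) < 0.3,
                index=[f"P{i}" for i in range(n_probes)],
                columns=samples,
            )
            organisms = pd.Series(
                [f"org{rng.integers(3)}" for _ in range(n_probes)], index=presence.index
            )
            union = signature_prevalence(presence, organisms, samples, "union")
            best = signature_prevalence(presence, organisms, samples, "max")
            for org in organisms.unique():
                detected = {
                    p: set(presence.columns[presence.loc[p]])
                    for p in organisms.index[organisms == org]
                }
                assert union[org] == pytest.approx(union_prevalence_oracle(detected, samples))
                assert best[org] == pytest.approx(max_prevalence_oracle(detected, samples))


class TestJointFilter:
    @pytest.mark.parametrize(
        "log2fc, adj_p, case_prev, control_prev, reported",
        [
            (1.2, 0.005, 45.0, 20.0, True),    # passes every filter
            (0.9, 0.001, 45.0, 20.0, False),   # fails fold change
            (1.2, 0.02, 45.0, 20.0, False),    # fails adjusted p
            (1.2, 0.005, 35.0, 20.0, False),   # fails case prevalence
            (1.2, 0.005, 45.0, 30.0, False),   # fails control prevalence
        ],
        ids=["reported", "low_fc", "high_p", "low_case_prev", "high_control_prev"],
    )
    def test_joint_filter_boundaries(self, log2fc, adj_p, case_prev, control_prev, reported):
        from pathosig.detect import filter_significant

        probe_stats = pd.DataFrame(
            {"organism": ["orgA"], "t": [3.0], "p": [adj_p], "adj_p": [adj_p], "log2fc": [log2fc]},
            index=pd.Index(["P1"], name="probe_id"),
        )
        annotations = pd.DataFrame(
            {"organism": ["orgA"], "organism_class": ["virus"], "is_human": [0]},
            index=pd.Index(["P1"], name="probe_id"),
        )
        normalized = pd.DataFrame({"c1": [0.0], "c2": [0.0], "s1": [2.0]}, index=["P1"])
        calls = filter_significant(
            probe_stats,
            pd.Series({"orgA": case_prev}),
            pd.Series({"orgA": control_prev}),
            annotations,
            normalized,
            case_ids=["s1"],
            control_ids=["c1", "c2"],
        )
        assert ("orgA" in set(calls["organism"])) is reported

    def test_planted_organisms_reported(self, small_experiment):
        exp = small_experiment
        norm = normalize_experiment(exp.arrays, exp.annotations)
        control = exp.metadata.index[exp.metadata["group"] == "control"].tolist()
        brer = exp.metadata.index[exp.metadata["group"] == "BRER"].tolist()
        _, calls, _ = detect_signatures(norm.signal, exp.annotations, brer, control)
        assert {"Alphatestvirus", "Testomonas"} <= set(calls["organism"])
        assert (calls["case_prevalence_pct"] >= 40).all()
        assert (calls["control_prevalence_pct"] <= 25).all()

    def test_filter_monotone_in_thresholds(self, small_experiment):
        """Loosening adj-p or fold-change thresholds never shrinks the call set."""
        exp = small_experiment
        norm = normalize_experiment(exp.arrays, exp.annotations)
        control = exp.metadata.index[exp.metadata["group"] == "control"].tolist()
        brer = exp.metadata.index[exp.metadata["group"] == "BRER"].tolist()
        strict = detect_signatures(norm.signal, exp.annotations, brer, control)[1]
        loose = detect_signatures(
            norm.signal,
            exp.annotations,
            brer,
            control,
            thresholds=FilterThresholds(min_log2fc=0.5, max_adj_p=0.05),
        )[1]
        assert set(strict["organism"]) <= set(loose["organism"])

    def test_noiseless_null_reports_nothing(self, noiseless_null_experiment):
        exp = noiseless_null_experiment
        norm = normalize_experiment(exp.arrays, exp.annotations)
        control = exp.metadata.index[exp.metadata["group"] == "control"].tolist()
        case = exp.metadata.index[exp.metadata["group"] == "BRER"].tolist()
        _, calls, _ = detect_signatures(norm.signal, exp.annotations, case, control)
        assert calls.empty

    def test_probe_stats_fields(self, small_experiment):
        exp = small_experiment
        norm = normalize_experiment(exp.arrays, exp.annotations)
        control = exp.metadata.index[exp.metadata["group"] == "control"].tolist()
        case = exp.metadata.index[exp.metadata["group"] == "BRER"].tolist()
        stats_df = probe_differential_test(norm.signal, case, control)
        assert ((stats_df["p"] >= 0) & (stats_df["p"] <= 1)).all()
        adj = adjust_bh(stats_df["p"].to_numpy())
        assert (adj >= stats_df["p"].to_numpy() - 1e-15).all()
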