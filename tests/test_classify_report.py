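"""Trajectory classification, swap-fraction estimation, reporting."""

import numpy as np
import pytest

from crysmech import (GateResult, PullConfig, UnfoldingEvent, analyze_trace,
                      classify_trajectory, estimate_swap_fraction,
                      fingerprint_gate, generate_dataset, run_swap_inference,
                      simulate_pull, summarize_distributions)
from crysmech.classify_report import TrajectoryCall, merge_intermediates
from crysmech.errors import ConfigError, EstimationError, InputError


def _event(force, dlc, label, idx=0):
    return UnfoldingEvent(idx, force, 40.0, 40.0 + dlc, dlc, label)


def _regular_events():
    # Fig-style regular pattern: two Ctd-like then two Ntd-like ~30 nm steps
    vals = [(96.0, 29.9, "Ctd"), (97.0, 29.9, "Ctd"),
            (136.0, 29.3, "Ntd"), (135.0, 29.3, "Ntd"),
            (250.0, 28.4, "I27"), (252.0, 28.4, "I27")]
    return [_event(f, d, c, i) for i, (f, d, c) in enumerate(vals)]


class TestClassifyTrajectory:
    def test_textbook_regular_pattern(self, dimer):
        call = classify_trajectory(_regular_events(), dimer)
        assert call.verdict == "regular"

    def test_four_step_swapped_pattern(self, dimer):
        vals = [(82.0, 29.9, "Ctd"), (118.0, 35.7, "Ntd"),
                (35.0, 30.5, "swap-weak"), (95.0, 29.9, "Ctd"),
                (250.0, 28.4, "I27"), (252.0, 28.4, "I27")]
        call = classify_trajectory([_event(f, d, c, i)
                                    for i, (f, d, c) in enumerate(vals)], dimer)
        assert call.verdict == "anomalous_swap"
        assert [s[0] for s in call.steps] == ["dL1", "dL2", "dL3", "dL4"]

    def test_unresolved_weak_peak_combined_step(self, dimer):
        """12/57-style trajectories: the weak peak is invisible and a ~67 nm
        combined increment follows the Ntd-force peak."""
        vals = [(82.0, 29.9, "Ctd"), (118.0, 66.2, "Ntd"),
                (95.0, 29.9, "Ctd"),
                (250.0, 28.4, "I27"), (252.0, 28.4, "I27")]
        call = classify_trajectory([_event(f, d, c, i)
                                    for i, (f, d, c) in enumerate(vals)], dimer)
        assert call.verdict == "anomalous_swap"
        assert "dL2+dL3" in [s[0] for s in call.steps]

    def test_gate_failure_is_rejected(self, dimer):
        call = classify_trajectory(_regular_events(), dimer,
                                   gate=GateResult(False, 1, "incomplete"))
        assert call.verdict == "rejected"
        assert call.matched_ledger is None

    def test_too_few_events_unclassified(self, dimer):
        call = classify_trajectory(_regular_events()[:2], dimer)
        assert call.verdict == "unclassified"

    def test_off_ledger_lengths_unclassified(self, dimer):
        vals = [(96.0, 45.0, "Ctd"), (97.0, 12.0, "Ctd"),
                (136.0, 50.0, "Ntd"), (135.0, 21.0, "Ntd")]
        call = classify_trajectory([_event(f, d, c, i)
                                    for i, (f, d, c) in enumerate(vals)], dimer)
        assert call.verdict == "unclassified"

    def test_intermediates_folded_into_parent(self, dimer):
        vals = [(96.0, 21.9, "Ctd"), (50.0, 8.0, "intermediate"),
                (97.0, 29.9, "Ctd"), (136.0, 29.3, "Ntd"),
                (135.0, 29.3, "Ntd")]
        events = [_event(f, d, c, i) for i, (f, d, c) in enumerate(vals)]
        merged = merge_intermediates(events)
        assert len(merged) == 4
        assert merged[0].delta_Lc == pytest.approx(29.9)
        assert classify_trajectory(events, dimer).verdict == "regular"

    def test_simulated_verdict_agreement(self, dimer, dimer_batch):
        """>= 95 % of gate-passing simulated traces get the truth verdict."""
        agree = total = 0
        for trace in dimer_batch:
            events = analyze_trace(trace)
            gate = fingerprint_gate(events, dimer)
            if not gate.accepted:
                continue
            call = classify_trajectory(events, dimer, gate=gate)
            want = ("anomalous_swap" if trace.metadata["pathway"] == "swapped"
                    else "regular")
            total += 1
            agree += call.verdict == want
        assert total >= 50
        assert agree / total >= 0.95


class TestSwapFraction:
    @staticmethod
    def _calls(n_anom, n_reg):
        return ([TrajectoryCall(f"a{i}", "anomalous_swap")
                 for i in range(n_anom)]
                + [TrajectoryCall(f"r{i}", "regular") for i in range(n_reg)])

    def test_paper_counts(self):
        frac, (lo, hi) = estimate_swap_fraction(self._calls(57, 323))
        assert frac == pytest.approx(0.15)
        assert lo < 0.15 < hi

    def test_zero_anomalous(self):
        frac, (lo, hi) = estimate_swap_fraction(self._calls(0, 50))
        assert frac == 0.0
        assert hi > 0.0

    def test_no_classified_calls(self):
        with pytest.raises(EstimationError):
            estimate_swap_fraction([TrajectoryCall("x", "rejected")])

    def test_wilson_interval_covers_binomial_truth(self, rng):
        """Across replicate batches of Bernoulli(p) verdicts the 95 % CI
        covers p nearly always."""
        for p in (0.0, 0.15, 0.5):
            covered = 0
            for _ in range(20):
                k = rng.binomial(60, p)
                _, (lo, hi) = estimate_swap_fraction(self._calls(k, 60 - k))
                covered += lo - 1e-12 <= p <= hi + 1e-12
            assert covered >= 18


class TestSummaries:
    def test_sampling_check(self, rng):
        forces = rng.normal(136.0, 18.0, size=106)
        events = [_event(f, 29.3, "Ntd", i) for i, f in enumerate(forces)]
        (s_force,) = [s for s in summarize_distributions(events)
                      if s.quantity == "rupture_force"]
        assert s_force.n == 106
        assert abs(s_force.mean - 136.0) < 3 * 18.0 / np.sqrt(106)
        assert s_force.counts.sum() == 106

    def test_identical_values_zero_sd(self):
        events = [_event(100.0, 29.9, "Ctd", i) for i in range(5)]
        for s in summarize_distributions(events):
            assert s.sd == 0.0

    def test_two_classes_two_quantity_pairs(self):
        events = ([_event(96.0, 29.9, "Ctd", i) for i in range(3)]
                  + [_event(136.0, 29.3, "Ntd", i) for i in range(3)])
        out = summarize_distributions(events)
        assert {(s.class_label, s.quantity) for s in out} == {
            ("Ctd", "rupture_force"), ("Ctd", "delta_Lc"),
            ("Ntd", "rupture_force"), ("Ntd", "delta_Lc")}

    def test_singleton_class_skipped_with_warning(self):
        events = [_event(96.0, 29.9, "Ctd", 0)]
        with pytest.warns(UserWarning):
            assert summarize_distributions(events) == []


class TestSwapInference:
    def test_paper_worked_arithmetic(self):
        call = TrajectoryCall("t", "anomalous_swap",
                              steps=(("dL1", 32.3), ("dL2", 35.9),
                                     ("dL3", 31.0), ("dL4", 29.7)),
                              construct="dimer")
        report = run_swap_inference([call], 29.3)
        row = report.per_construct["dimer"]
        assert row["combined_L23_nm"] == pytest.approx(66.9)
        assert row["loop_extension_nm"] == pytest.approx(6.6)
        assert row["loop_residues"] == 16

    def test_missing_reference_is_config_error(self):
        with pytest.raises(ConfigError):
            run_swap_inference([], None)

    def test_no_anomalous_calls_is_input_error(self):
        with pytest.raises(InputError):
            run_swap_inference([TrajectoryCall("t", "regular")], 29.3)

    def test_linker_variant_comparison(self, dimer):
        from crysmech import preset
        long = preset("dimer_long_linker")
        calls = [TrajectoryCall("a", "anomalous_swap",
                                steps=(("dL1", 29.9), ("dL2", 35.7),
                                       ("dL3", 30.5), ("dL4", 29.9)),
                                construct="dimer"),
                 TrajectoryCall("b", "anomalous_swap",
                                steps=(("dL1", 29.9), ("dL2", 35.7),
                                       ("dL3", 36.1), ("dL4", 29.9)),
                                construct="dimer_long_linker")]
        report = run_swap_inference(calls, 29.3,
                                    topologies={"dimer": dimer,
                                                "dimer_long_linker": long})
        assert report.linker_comparison["measured_diff_nm"] == pytest.approx(5.6)
        assert report.linker_comparison["predicted_diff_nm"] == pytest.approx(5.6)
        assert report.linker_comparison["delta_residues"] == 14

    def test_end_to_end_loop_recovery(self, dimer):
        """Simulated swapped trajectories return the injected 16-residue
        swapping loop within one residue."""
        traces = generate_dataset([{"construct": dimer, "n": 50, "seed": 77,
                                    "config": {"swap_probability": 1.0,
                                               "seed": 77}}])
        calls = []
        for trace in traces:
            events = analyze_trace(trace)
            calls.append(classify_trajectory(
                events, dimer, gate=fingerprint_gate(events, dimer),
                trace_id=trace.trace_id))
        report = run_swap_inference(calls, 29.3)
        assert abs(report.per_construct["dimer"]["loop_residues"] - 16) <= 1
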