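"""Fluidic run parsing, simulated execution, triggers, flow monitoring."""

import collections

import numpy as np
import pandas as pd
import pytest

from fishflow import fluidics as fl

MINIMAL = """
n_rounds: 3
buffers:
  wash: {kind: syringe, address: 1}
  hyb:  {kind: plate, address: "{round_well}"}
steps:
  - {id: hyb,  action: flush, buffer: hyb, volume_ml: 1.0, rate_ml_per_min: 0.5}
  - {id: wash, action: flush, buffer: wash, volume_ml: 1.5, rate_ml_per_min: 1.0}
  - {id: image, action: image}
"""


def _rig_for(spec, seed=0, **kw):
    wells = {
        b.resolve_well(r)
        for b in spec.buffers.values()
        if b.kind == "plate"
        for r in range(1, spec.n_rounds + 1)
    }
    defaults = dict(plate={w: 2.0 for w in wells}, syringes={1: 100.0, 2: 100.0}, seed=seed)
    defaults.update(kw)
    return fl.SimulatedRig(**defaults)


class TestParseRunSpec:
    def test_minimal_spec_parses(self):
        spec = fl.parse_run_spec(MINIMAL)
        assert spec.n_rounds == 3
        assert len(spec.steps) == 3
        assert all(s.rounds == "all" for s in spec.steps)

    def test_undeclared_buffer_names_step(self):
        bad = MINIMAL.replace("buffer: wash", "buffer: missing")
        with pytest.raises(fl.RunSpecError, match="wash"):
            fl.parse_run_spec(bad)

    def test_round_condition_resolves_to_single_round(self):
        text = MINIMAL + '  - {id: dapi, action: flush, buffer: wash, volume_ml: 0.5, rate_ml_per_min: 0.5, rounds: [1]}\n'
        spec = fl.parse_run_spec(text)
        dapi = [s for s in spec.steps if s.id == "dapi"][0]
        assert dapi.applies_to(1) and not dapi.applies_to(2)

    def test_round_out_of_range_rejected(self):
        text = MINIMAL + '  - {id: x, action: flush, buffer: wash, volume_ml: 0.5, rate_ml_per_min: 0.5, rounds: [9]}\n'
        with pytest.raises(fl.RunSpecError, match="x"):
            fl.parse_run_spec(text)

    def test_flush_needs_exactly_one_of_volume_or_duration(self):
        text = MINIMAL.replace(
            "volume_ml: 1.5, rate_ml_per_min: 1.0",
            "volume_ml: 1.5, duration_s: 60, rate_ml_per_min: 1.0",
        )
        with pytest.raises(fl.RunSpecError, match="wash"):
            fl.parse_run_spec(text)

    def test_round_well_template_walks_plate(self):
        spec = fl.parse_run_spec(MINIMAL.replace("n_rounds: 3", "n_rounds: 20"))
        hyb = spec.buffers["hyb"]
        assert hyb.resolve_well(1) == "A1"
        assert hyb.resolve_well(12) == "A12"
        assert hyb.resolve_well(13) == "B1"


class TestExecuteStep:
    def test_flush_arithmetic(self):
        spec = fl.parse_run_spec(MINIMAL)
        rig = _rig_for(spec)
        step = [s for s in spec.steps if s.id == "wash"][0]
        fl.execute_step(rig, step, 1, spec)
        assert rig.clock == 90.0  # 1.5 mL at 1 mL/min
        assert rig.syringes[1] == 100.0 - 1.5
        stop = rig.log.of_kind("pump_stop")[0]
        assert stop["interval_s"] == 90.0

    def test_plate_aspiration_deducts_well(self):
        spec = fl.parse_run_spec(MINIMAL)
        rig = _rig_for(spec)
        step = spec.steps[0]
        fl.execute_step(rig, step, 2, spec)
        assert rig.plate["A2"] == pytest.approx(1.0)
        assert rig.log.of_kind("aspirate")[0]["well"] == "A2"

    def test_overdraw_halts_with_error_event(self):
        spec = fl.parse_run_spec(
            'n_rounds: 2\nbuffers: {h: {kind: plate, address: A1}}\n'
            'steps:\n  - {id: h, action: flush, buffer: h, volume_ml: 1.2, rate_ml_per_min: 1.0}\n'
        )
        rig = fl.SimulatedRig(plate={"A1": 2.0}, seed=0)
        log = fl.run_experiment(rig, spec, fl.TTLTriggerMock())
        errors = log.of_kind("error")
        assert len(errors) == 1 and errors[0]["reason"] == "well_overdraw"
        assert errors[0]["round"] == 2  # second 1.2 mL draw exceeds the 0.8 left
        assert log.of_kind("run_abort")

    def test_incubate_advances_clock_only(self):
        spec = fl.parse_run_spec(
            'n_rounds: 1\nbuffers: {}\nsteps:\n  - {id: inc, action: incubate, incubate_s: 600}\n'
        )
        rig = _rig_for(spec)
        fl.execute_step(rig, spec.steps[0], 1, spec)
        assert rig.clock == 600.0
        assert not rig.flow_samples


class TestRunExperiment:
    def test_twenty_rounds_alternating_trigger_pairs(self):
        spec = fl.parse_run_spec(MINIMAL.replace("n_rounds: 3", "n_rounds: 20"))
        rig = _rig_for(spec)
        log = fl.run_experiment(rig, spec, fl.TTLTriggerMock(responder=fl.MockAcquirer(60.0)))
        log.validate()
        assert len(log.of_kind("trigger_armed")) == 20
        assert len(log.of_kind("acquisition_done")) == 20
        kinds = [e["kind"] for e in log.events if e["kind"] in ("trigger_armed", "acquisition_done")]
        assert kinds == ["trigger_armed", "acquisition_done"] * 20

    def test_round_conditioned_step_runs_exactly_twice(self):
        text = MINIMAL.replace("n_rounds: 3", "n_rounds: 8") + (
            '  - {id: saber, action: flush, buffer: wash, volume_ml: 0.5, '
            'rate_ml_per_min: 0.5, rounds: [3, 6]}\n'
        )
        spec = fl.parse_run_spec(text)
        rig = _rig_for(spec)
        log = fl.run_experiment(rig, spec, fl.TTLTriggerMock(responder=fl.MockAcquirer(10.0)))
        saber = [e for e in log.of_kind("pump_start") if e["step"] == "saber"]
        assert [e["round"] for e in saber] == [3, 6]

    def test_same_seed_byte_identical_logs(self):
        spec = fl.parse_run_spec(MINIMAL)
        logs = []
        for _ in range(2):
            rig = _rig_for(spec, seed=5)
            logs.append(
                fl.run_experiment(rig, spec, fl.TTLTriggerMock(responder=fl.MockAcquirer(30.0))).to_jsonl()
            )
        assert logs[0] == logs[1]

    def test_volume_conservation_exact(self):
        spec = fl.parse_run_spec(MINIMAL.replace("n_rounds: 3", "n_rounds: 20"))
        rig = _rig_for(spec)
        log = fl.run_experiment(rig, spec, fl.TTLTriggerMock(responder=fl.MockAcquirer(60.0)))
        per_step = collections.defaultdict(float)
        rates = {}
        for e in log.events:
            if e["kind"] == "pump_start":
                rates[(e["step"], e["round"])] = e["rate_ml_per_min"]
            elif e["kind"] == "pump_stop":
                per_step[e["step"]] += rates[(e["step"], e["round"])] * e["interval_s"] / 60.0
        assert abs(per_step["wash"] - rig.dispensed["wash"]) < 1e-9
        assert abs(per_step["hyb"] - rig.dispensed["hyb"]) < 1e-9
        assert rig.dispensed["wash"] == pytest.approx(20 * 1.5, abs=1e-9)

    def test_clock_equals_sum_of_durations(self):
        spec = fl.parse_run_spec(MINIMAL)
        rig = _rig_for(spec)
        delay = 42.0
        fl.run_experiment(rig, spec, fl.TTLTriggerMock(responder=fl.MockAcquirer(delay)))
        per_round = 1.0 / 0.5 * 60 + 1.5 / 1.0 * 60 + delay
        assert rig.clock == pytest.approx(3 * per_round)

    def test_trigger_timeout_aborts_cleanly(self):
        spec = fl.parse_run_spec(MINIMAL)
        rig = _rig_for(spec)
        log = fl.run_experiment(rig, spec, fl.TTLTriggerMock(responder=None))
        log.validate()
        errors = log.of_kind("error")
        assert errors and errors[0]["reason"] == "trigger_timeout"
        assert log.of_kind("run_abort")
        assert not log.of_kind("acquisition_done")

    def test_fuzzed_specs_preserve_log_invariants(self, rng):
        """Random specs: monotone time, armed/done pairing, conditional counts."""
        for trial in range(30):
            n_rounds = int(rng.integers(1, 7))
            n_steps = int(rng.integers(1, 5))
            lines = [f"n_rounds: {n_rounds}", "buffers:", "  w: {kind: syringe, address: 1}", "steps:"]
            expected_counts = {}
            for i in range(n_steps):
                action = rng.choice(["flush", "incubate", "image"])
                rounds = "all"
                if rng.random() < 0.5:
                    sel = sorted(
                        rng.choice(np.arange(1, n_rounds + 1), size=rng.integers(1, n_rounds + 1), replace=False).tolist()
                    )
                    rounds = "[" + ", ".join(map(str, sel)) + "]"
                    expected_counts[f"s{i}"] = len(sel)
                else:
                    expected_counts[f"s{i}"] = n_rounds
                if action == "flush":
                    lines.append(
                        f'  - {{id: s{i}, action: flush, buffer: w, volume_ml: 0.2, rate_ml_per_min: 1.0, rounds: {rounds}}}'
                    )
                elif action == "incubate":
                    lines.append(f'  - {{id: s{i}, action: incubate, incubate_s: 10, rounds: {rounds}}}')
                else:
                    lines.append(f'  - {{id: s{i}, action: image, rounds: {rounds}}}')
            spec = fl.parse_run_spec("\n".join(lines))
            rig = fl.SimulatedRig(syringes={1: 1000.0}, seed=trial)
            log = fl.run_experiment(rig, spec, fl.TTLTriggerMock(responder=fl.MockAcquirer(5.0)))
            log.validate()
            observed = collections.Counter(
                e["step"] for e in log.events if e["kind"] in ("pump_start", "incubate", "trigger_armed")
            )
            for sid, n in expected_counts.items():
                assert observed.get(sid, 0) == n


class TestTriggers:
    def test_file_trigger_content_mode_handshake(self, tmp_path):
        trig = fl.FileTrigger(tmp_path, mode="content", responder=fl.MockAcquirer(5.0))
        trig.arm(1, 100.0)
        assert (tmp_path / "sync.txt").read_text() == "1"
        done = trig.wait(100.0)
        assert done == 105.0
        assert (tmp_path / "sync.txt").read_text() == "0"

    def test_file_trigger_existence_mode(self, tmp_path):
        trig = fl.FileTrigger(tmp_path, mode="existence", responder=fl.MockAcquirer(2.0))
        trig.arm(1, 0.0)
        assert (tmp_path / "sync.txt").exists()
        assert trig.wait(0.0) == 2.0
        assert not (tmp_path / "sync.txt").exists()

    def test_file_trigger_no_responder_times_out(self, tmp_path):
        trig = fl.FileTrigger(tmp_path, mode="content", responder=None, timeout_s=10.0)
        trig.arm(1, 0.0)
        assert trig.wait(0.0) is None

    def test_ttl_pulses_alternate_over_rounds(self):
        spec = fl.parse_run_spec(MINIMAL.replace("n_rounds: 3", "n_rounds: 2"))
        rig = _rig_for(spec)
        trig = fl.TTLTriggerMock(responder=fl.MockAcquirer(3.0))
        fl.run_experiment(rig, spec, trig)
        assert len(trig.out_pulses) == 2 and len(trig.in_pulses) == 2
        interleaved = sorted(
            [(t, "out") for t in trig.out_pulses] + [(t, "in") for t in trig.in_pulses]
        )
        assert [k for _, k in interleaved] == ["out", "in", "out", "in"]
        assert trig.in_pulses[0] == trig.out_pulses[0] + 3.0


class TestFlowAnomalies:
    def _trace(self, rate=1.0, n=60, noise=0.0, seed=0, drops=()):
        rng = np.random.default_rng(seed)
        t = np.arange(1, n + 1, dtype=float)
        measured = rate * (1 + rng.normal(0, noise, n))
        for t0, t1, mult in drops:
            measured[(t >= t0) & (t < t1)] *= mult
        return pd.DataFrame(
            {"t": t, "measured_ml_per_min": measured, "expected_ml_per_min": rate}
        )

    def test_clean_traces_no_false_alarms(self):
        for seed in range(100):
            trace = self._trace(noise=0.02, seed=seed)
            assert fl.detect_flow_anomaly(trace, 0.2, 5.0, 1.0) == []

    def test_ten_second_drop_detected_within_one_sample(self):
        trace = self._trace(drops=[(20.0, 30.0, 0.1)])
        intervals = fl.detect_flow_anomaly(trace, 0.2, 5.0, 1.0)
        assert len(intervals) == 1
        t0, t1 = intervals[0]
        assert abs(t0 - 20.0) <= 1.0 and abs((t1 - t0 + 1.0) - 10.0) <= 1.0

    def test_short_drop_below_min_duration_ignored(self):
        trace = self._trace(drops=[(20.0, 23.0, 0.1)])
        assert fl.detect_flow_anomaly(trace, 0.2, 5.0, 1.0) == []

    def test_pump_off_samples_excluded(self):
        trace = self._trace()
        trace.loc[:10, "expected_ml_per_min"] = 0.0
        trace.loc[:10, "measured_ml_per_min"] = 0.0
        assert fl.detect_flow_anomaly(trace, 0.2, 5.0, 1.0) == []

    def test_scheduled_anomaly_reaches_event_log(self):
        spec = fl.parse_run_spec(
            'n_rounds: 1\nbuffers: {w: {kind: syringe, address: 1}}\n'
            'steps:\n  - {id: f, action: flush, buffer: w, volume_ml: 1.0, rate_ml_per_min: 1.0}\n'
        )
        rig = fl.SimulatedRig(
            syringes={1: 10.0}, seed=3, anomalies=[fl.FlowAnomaly(20.0, 30.0, 0.1)]
        )
        fl.run_experiment(rig, spec, fl.TTLTriggerMock())
        assert len(rig.log.of_kind("anomaly")) == 1
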