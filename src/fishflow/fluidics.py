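"""Declarative fluidic runs on a fully simulated rig.

A run specification -- a YAML document listing buffers (syringe ports or
96-well plate wells, well names optionally templated on the round
number), ordered steps (flush / incubate / image / pause) and the rounds
each step applies to -- is executed round by round on a simulated rig:
a rotary valve, a peristaltic pump with a flow sensor, a plate robot
aspirating from 2.0 mL deep wells, and syringe reservoirs. Time is
simulated (the clock advances by step durations; nothing sleeps), every
action is logged with its simulated timestamp, and acquisition is
synchronized through pluggable triggers: a shared sync file (content or
existence handshake) or a TTL pulse pair, each with a mock acquirer for
closed-loop tests.

The flow sensor samples the pump rate at a fixed period with
multiplicative noise; scheduled anomalies (bubbles, clogs) multiply the
measured flow over an interval, and a threshold/duration detector flags
them in the log while the run continues.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunSpecError",
    "RunHalted",
    "BufferSource",
    "Step",
    "RunSpec",
    "parse_run_spec",
    "FlowAnomaly",
    "SimulatedRig",
    "EventLog",
    "execute_step",
    "run_experiment",
    "detect_flow_anomaly",
    "FileTrigger",
    "TTLTriggerMock",
    "MockAcquirer",
]

WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")
PLATE_CAPACITY_ML = 2.0


class RunSpecError(ValueError):
    """Malformed run specification; the message names the offending entry."""


class RunHalted(RuntimeError):
    """Unrecoverable fluidic error (e.g. well over-aspiration)."""


@dataclass(frozen=True)
class BufferSource:
    name: str
    kind: str  # "syringe" | "plate"
    address: int | str  # syringe port or well (template) like "A1" / "A{round}"

    def resolve_well(self, round_idx: int) -> str:
        """Resolve a (possibly round-templated) well name for one round.

        ``{round}`` substitutes the round number directly (e.g. ``A{round}``
        -> A1..A12); ``{round_well}`` walks the 96-well plate row-major
        (round 1 -> A1, round 13 -> B1, ...), for runs longer than one row.
        """
        if self.kind != "plate":
            raise RunSpecError(f"buffer '{self.name}' is not a plate buffer")
        row = "ABCDEFGH"[(round_idx - 1) // 12 % 8]
        well = str(self.address).format(
            round=round_idx, round_well=f"{row}{(round_idx - 1) % 12 + 1}"
        )
        if not WELL_RE.match(well):
            raise RunSpecError(
                f"buffer '{self.name}': '{well}' is not a valid 96-well address"
            )
        return well


@dataclass(frozen=True)
class Step:
    id: str
    action: str  # "flush" | "incubate" | "image" | "pause"
    buffer: str | None = None
    volume_ml: float | None = None
    duration_s: float | None = None
    rate_ml_per_min: float | None = None
    incubate_s: float = 0.0
    rounds: str | tuple[int, ...] = "all"

    def applies_to(self, round_idx: int) -> bool:
        return self.rounds == "all" or round_idx in self.rounds

    def flush_duration_s(self) -> float:
        if self.duration_s is not None:
            return float(self.duration_s)
        return float(self.volume_ml) / float(self.rate_ml_per_min) * 60.0

    def flush_volume_ml(self) -> float:
        if self.volume_ml is not None:
            return float(self.volume_ml)
        return float(self.rate_ml_per_min) * float(self.duration_s) / 60.0


@dataclass(frozen=True)
class RunSpec:
    n_rounds: int
    buffers: dict[str, BufferSource]
    steps: tuple[Step, ...]


def parse_run_spec(text: str) -> RunSpec:
    """Parse and validate a YAML run specification.

    Validation covers: positive round count; buffer kinds and addresses;
    per-step schema (a flush needs a buffer, a rate, and a volume or a
    duration); step round lists within 1..n_rounds; and resolvability of
    every templated well name for every round its step runs in. Errors
    name the step or buffer at fault.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise RunSpecError(f"invalid YAML: {e}") from e
    if not isinstance(doc, dict):
        raise RunSpecError("run spec must be a mapping")
    n_rounds = doc.get("n_rounds")
    if not isinstance(n_rounds, int) or n_rounds < 1:
        raise RunSpecError("n_rounds must be a positive integer")
    buffers: dict[str, BufferSource] = {}
    for name, b in (doc.get("buffers") or {}).items():
        if not isinstance(b, dict) or "kind" not in b or "address" not in b:
            raise RunSpecError(f"buffer '{name}': needs 'kind' and 'address'")
        kind = b["kind"]
        if kind not in ("syringe", "plate"):
            raise RunSpecError(f"buffer '{name}': unknown kind '{kind}'")
        if kind == "syringe" and not isinstance(b["address"], int):
            raise RunSpecError(f"buffer '{name}': syringe address must be a port number")
        buffers[name] = BufferSource(name, kind, b["address"])
    steps: list[Step] = []
    for i, s in enumerate(doc.get("steps") or []):
        sid = s.get("id", f"step{i + 1}")
        action = s.get("action")
        if action not in ("flush", "incubate", "image", "pause"):
            raise RunSpecError(f"step '{sid}': unknown action '{action}'")
        rounds = s.get("rounds", "all")
        if rounds != "all":
            if not isinstance(rounds, list) or not all(isinstance(r, int) for r in rounds):
                raise RunSpecError(f"step '{sid}': rounds must be 'all' or a list of ints")
            bad = [r for r in rounds if not 1 <= r <= n_rounds]
            if bad:
                raise RunSpecError(f"step '{sid}': rounds out of range: {bad}")
            rounds = tuple(rounds)
        step = Step(
            id=str(sid),
            action=action,
            buffer=s.get("buffer"),
            volume_ml=s.get("volume_ml"),
            duration_s=s.get("duration_s"),
            rate_ml_per_min=s.get("rate_ml_per_min"),
            incubate_s=float(s.get("incubate_s", 0.0)),
            rounds=rounds,
        )
        if action == "flush":
            if step.buffer is None:
                raise RunSpecError(f"step '{sid}': flush needs a buffer")
            if step.buffer not in buffers:
                raise RunSpecError(f"step '{sid}': undeclared buffer '{step.buffer}'")
            if step.rate_ml_per_min is None or step.rate_ml_per_min <= 0:
                raise RunSpecError(f"step '{sid}': flush needs a positive rate_ml_per_min")
            if (step.volume_ml is None) == (step.duration_s is None):
                raise RunSpecError(
                    f"step '{sid}': flush needs exactly one of volume_ml / duration_s"
                )
            src = buffers[step.buffer]
            if src.kind == "plate":
                for r in range(1, n_rounds + 1):
                    if step.applies_to(r):
                        src.resolve_well(r)  # raises on bad template
        if action == "incubate" and step.incubate_s <= 0:
            raise RunSpecError(f"step '{sid}': incubate needs incubate_s > 0")
        if action == "pause" and (step.duration_s is None or step.duration_s <= 0):
            raise RunSpecError(f"step '{sid}': pause needs duration_s > 0")
        steps.append(step)
    return RunSpec(n_rounds=n_rounds, buffers=buffers, steps=tuple(steps))


# ---------------------------------------------------------------------------
# event log


class EventLog:
    """Ordered, timestamped record of a simulated run."""

    def __init__(self) -> None:
        self.events: list[dict] = []

    def add(self, t: float, kind: str, **payload) -> dict:
        if self.events and t < self.events[-1]["t"] - 1e-9:
            raise ValueError("event log time must be nondecreasing")
        ev = {"t": round(float(t), 6), "kind": kind, **payload}
        self.events.append(ev)
        return ev

    def of_kind(self, kind: str) -> list[dict]:
        return [e for e in self.events if e["kind"] == kind]

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(e, sort_keys=True) for e in self.events) + "\n"

    def validate(self) -> None:
        """Check monotone time and armed/done trigger pairing."""
        ts = [e["t"] for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise AssertionError("event times not nondecreasing")
        pending = 0
        for e in self.events:
            if e["kind"] == "trigger_armed":
                if pending:
                    raise AssertionError("trigger armed while one is pending")
                pending = 1
            elif e["kind"] == "acquisition_done":
                if not pending:
                    raise AssertionError("acquisition_done without armed trigger")
                pending = 0
            elif e["kind"] == "error" and e.get("reason") == "trigger_timeout":
                pending = 0
        if pending:
            raise AssertionError("armed trigger never completed")

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# simulated rig


@dataclass(frozen=True)
class FlowAnomaly:
    """Scheduled flow disturbance: measured flow x multiplier in [t0, t1)."""

    t0: float
    t1: float
    multiplier: float


class SimulatedRig:
    """Valve + peristaltic pump + flow sensor + plate robot, in simulated time.

    ``plate`` maps well name -> current volume (mL, capacity 2.0);
    ``syringes`` maps port -> remaining volume. The flow sensor samples
    every ``flow_sample_period_s`` of pumping with multiplicative
    Gaussian noise of fractional sd ``flow_noise_frac``; scheduled
    ``anomalies`` multiply the measured flow while active.
    """

    def __init__(
        self,
        plate: dict[str, float] | None = None,
        syringes: dict[int, float] | None = None,
        n_valve_ports: int = 8,
        flow_noise_frac: float = 0.02,
        flow_sample_period_s: float = 1.0,
        anomalies: Sequence[FlowAnomaly] = (),
        anomaly_tolerance_frac: float = 0.2,
        anomaly_min_duration_s: float = 5.0,
        plate_capacity_ml: float = PLATE_CAPACITY_ML,
        seed: int = 0,
    ) -> None:
        self.plate = dict(plate or {})
        for well, v in self.plate.items():
            if not 0.0 <= v <= plate_capacity_ml + 1e-12:
                raise ValueError(f"well {well}: volume {v} outside [0, {plate_capacity_ml}] mL")
        self.syringes = dict(syringes or {})
        self.n_valve_ports = n_valve_ports
        self.flow_noise_frac = flow_noise_frac
        self.flow_sample_period_s = flow_sample_period_s
        self.anomalies = list(anomalies)
        self.anomaly_tolerance_frac = anomaly_tolerance_frac
        self.anomaly_min_duration_s = anomaly_min_duration_s
        self.plate_capacity_ml = plate_capacity_ml
        self.rng = np.random.default_rng(seed)
        self.clock = 0.0
        self.valve_port: int | str | None = None
        self.pump_running = False
        self.log = EventLog()
        self.flow_samples: list[tuple[float, float, float]] = []  # (t, measured, expected)
        self.dispensed: dict[str, float] = {}

    def flow_trace(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.flow_samples, columns=["t", "measured_ml_per_min", "expected_ml_per_min"]
        )

    def _anomaly_multiplier(self, t: float) -> float:
        m = 1.0
        for a in self.anomalies:
            if a.t0 <= t < a.t1:
                m *= a.multiplier
        return m


def execute_step(rig: SimulatedRig, step: Step, round_idx: int, spec: RunSpec) -> None:
    """Execute one fluidic step, advancing the simulated clock.

    A flush selects the valve port, aspirates from the source (erroring
    and halting if a plate well lacks the requested volume), runs the
    pump for volume/rate, records flow-sensor samples, and emits anomaly
    events for detected disturbances; incubate/pause only advance the
    clock. ``image`` steps are handled by :func:`run_experiment`.
    """
    if step.action == "incubate":
        rig.log.add(rig.clock, "incubate", step=step.id, round=round_idx, duration_s=step.incubate_s)
        rig.clock += step.incubate_s
        return
    if step.action == "pause":
        rig.log.add(rig.clock, "pause", step=step.id, round=round_idx, duration_s=step.duration_s)
        rig.clock += float(step.duration_s)
        return
    if step.action != "flush":
        raise ValueError(f"execute_step cannot run action '{step.action}'")

    src = spec.buffers[step.buffer]
    volume = step.flush_volume_ml()
    duration = step.flush_duration_s()
    rate = float(step.rate_ml_per_min)

    port = src.address if src.kind == "syringe" else "plate"
    rig.valve_port = port
    rig.log.add(rig.clock, "valve_select", step=step.id, round=round_idx, port=str(port), buffer=src.name)

    if src.kind == "plate":
        well = src.resolve_well(round_idx)
        available = rig.plate.get(well, 0.0)
        if volume > available + 1e-12:
            rig.log.add(
                rig.clock,
                "error",
                reason="well_overdraw",
                step=step.id,
                round=round_idx,
                well=well,
                requested_ml=volume,
                available_ml=round(available, 9),
            )
            raise RunHalted(f"step '{step.id}': well {well} holds {available} mL, requested {volume} mL")
        rig.plate[well] = available - volume
        rig.log.add(rig.clock, "aspirate", step=step.id, round=round_idx, well=well, volume_ml=volume)
    else:
        available = rig.syringes.get(src.address, np.inf)
        if volume > available + 1e-12:
            rig.log.add(
                rig.clock, "error", reason="syringe_empty", step=step.id, round=round_idx,
                port=src.address, requested_ml=volume,
            )
            raise RunHalted(f"step '{step.id}': syringe {src.address} exhausted")
        if src.address in rig.syringes:
            rig.syringes[src.address] = available - volume

    t0 = rig.clock
    rig.pump_running = True
    rig.log.add(t0, "pump_start", step=step.id, round=round_idx, rate_ml_per_min=rate)
    period = rig.flow_sample_period_s
    n_samples = int(np.floor(duration / period))
    new_samples = []
    for k in range(1, n_samples + 1):
        t = t0 + k * period
        noise = 1.0 + rig.rng.normal(0.0, rig.flow_noise_frac)
        measured = rate * noise * rig._anomaly_multiplier(t)
        new_samples.append((t, measured, rate))
    rig.flow_samples.extend(new_samples)
    rig.clock = t0 + duration
    rig.pump_running = False
    rig.log.add(rig.clock, "pump_stop", step=step.id, round=round_idx, interval_s=duration)
    rig.dispensed[src.name] = rig.dispensed.get(src.name, 0.0) + rate * duration / 60.0

    if new_samples:
        trace = pd.DataFrame(new_samples, columns=["t", "measured_ml_per_min", "expected_ml_per_min"])
        for a0, a1 in detect_flow_anomaly(
            trace, rig.anomaly_tolerance_frac, rig.anomaly_min_duration_s, period
        ):
            rig.log.add(rig.clock, "anomaly", step=step.id, round=round_idx, t0=a0, t1=a1)


def run_experiment(rig: SimulatedRig, spec: RunSpec, trigger) -> EventLog:
    """Run every round of the spec, arming the trigger at each image step.

    At an image step the trigger is armed and the run blocks (in
    simulated time) until the acquirer reports completion; a timeout
    logs an error and aborts cleanly with the log intact, as does any
    fluidic halt. The returned log always satisfies the EventLog
    invariants.
    """
    rig.log.add(rig.clock, "run_start", n_rounds=spec.n_rounds)
    try:
        for r in range(1, spec.n_rounds + 1):
            rig.log.add(rig.clock, "round_start", round=r)
            for step in spec.steps:
                if not step.applies_to(r):
                    continue
                if step.action == "image":
                    rig.log.add(rig.clock, "trigger_armed", step=step.id, round=r)
                    trigger.arm(r, rig.clock)
                    done_t = trigger.wait(rig.clock)
                    if done_t is None:
                        rig.log.add(rig.clock, "error", reason="trigger_timeout", step=step.id, round=r)
                        rig.log.add(rig.clock, "run_abort", round=r)
                        return rig.log
                    rig.clock = max(rig.clock, done_t)
                    rig.log.add(rig.clock, "acquisition_done", step=step.id, round=r)
                else:
                    execute_step(rig, step, r, spec)
    except RunHalted:
        rig.log.add(rig.clock, "run_abort")
        return rig.log
    rig.log.add(rig.clock, "run_end")
    return rig.log


def detect_flow_anomaly(
    trace: pd.DataFrame,
    tolerance_frac: float,
    min_duration_s: float,
    sample_period_s: float,
) -> list[tuple[float, float]]:
    """Find sustained deviations of measured flow from the expected rate.

    A sample deviates when |measured - expected| / expected exceeds
    ``tolerance_frac`` (samples with expected rate 0 are excluded).
    Deviating samples are grouped into maximal runs, merging runs whose
    gap is below the sample period; a run is reported when it spans at
    least ``min_duration_s`` (n_samples * period). Returns (t_start,
    t_end) intervals.
    """
    if not 0.0 < tolerance_frac < 1.0:
        raise ValueError("tolerance_frac must be in (0, 1)")
    valid = trace[trace["expected_ml_per_min"] > 0]
    if valid.empty:
        return []
    dev = (
        (valid["measured_ml_per_min"] - valid["expected_ml_per_min"]).abs()
        / valid["expected_ml_per_min"]
    ) > tolerance_frac
    ts = valid["t"].to_numpy(float)[dev.to_numpy(bool)]
    if ts.size == 0:
        return []
    runs: list[list[float]] = []
    for t in np.sort(ts):
        if runs and t - runs[-1][-1] <= sample_period_s * (1 + 1e-9):
            runs[-1].append(t)
        else:
            runs.append([t])
    return [
        (r[0], r[-1])
        for r in runs
        if len(r) * sample_period_s >= min_duration_s - 1e-9
    ]


# ---------------------------------------------------------------------------
# acquisition triggers


class MockAcquirer:
    """Stand-in microscope: completes each acquisition after a fixed delay.

    ``delay_s=None`` models a dead microscope (never responds).
    """

    def __init__(self, delay_s: float | None = 5.0) -> None:
        self.delay_s = delay_s
        self.acquisitions: list[int] = []


class FileTrigger:
    """Acquisition handshake through a shared synchronization file.

    ``content`` mode: arming writes "1"; the acquirer writes "0" when
    done. ``existence`` mode: arming creates the file; the acquirer
    deletes it. Completion is polled in simulated time; a mock acquirer
    (if attached) answers after its configured delay.
    """

    def __init__(
        self,
        directory: str | Path,
        mode: str = "content",
        responder: MockAcquirer | None = None,
        timeout_s: float = 600.0,
        filename: str = "sync.txt",
    ) -> None:
        if mode not in ("content", "existence"):
            raise ValueError("mode must be 'content' or 'existence'")
        self.path = Path(directory) / filename
        self.mode = mode
        self.responder = responder
        self.timeout_s = timeout_s
        self._armed_at: float | None = None

    def arm(self, round_idx: int, t: float) -> None:
        if self.mode == "content":
            self.path.write_text("1")
        else:
            self.path.touch()
        self._armed_at = t
        if self.responder is not None:
            self.responder.acquisitions.append(round_idx)

    def _respond(self) -> None:
        if self.mode == "content":
            self.path.write_text("0")
        else:
            self.path.unlink(missing_ok=True)

    def _completed(self) -> bool:
        if self.mode == "content":
            return self.path.exists() and self.path.read_text().strip() == "0"
        return not self.path.exists()

    def wait(self, t: float) -> float | None:
        assert self._armed_at is not None, "wait() before arm()"
        if self.responder is not None and self.responder.delay_s is not None:
            if self.responder.delay_s <= self.timeout_s:
                done_t = self._armed_at + self.responder.delay_s
                self._respond()
                if self._completed():
                    return done_t
            return None
        # no responder: accept an externally completed handshake, else time out
        return t if self._completed() else None


class TTLTriggerMock:
    """In-process model of the TTL trigger pair.

    Arming raises the outgoing line (one out-pulse starts an
    acquisition); completion is an incoming pulse from the microscope.
    The attached mock acquirer answers after its delay; without one the
    in-pulse never arrives and the round times out.
    """

    def __init__(self, responder: MockAcquirer | None = None, timeout_s: float = 600.0) -> None:
        self.responder = responder
        self.timeout_s = timeout_s
        self.out_pulses: list[float] = []
        self.in_pulses: list[float] = []
        self._armed_at: float | None = None

    def arm(self, round_idx: int, t: float) -> None:
        self.out_pulses.append(t)
        self._armed_at = t
        if self.responder is not None:
            self.responder.acquisitions.append(round_idx)

    def wait(self, t: float) -> float | None:
        assert self._armed_at is not None, "wait() before arm()"
        if self.responder is None or self.responder.delay_s is None:
            return None
        if self.responder.delay_s > self.timeout_s:
            return None
        done_t = self._armed_at + self.responder.delay_s
        self.in_pulses.append(done_t)
        return done_t
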