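"""Protocol compilation, G-code emission and execution logging.

A :class:`Protocol` says *what* to illuminate (wells, irradiance, time or
dose, working height); :func:`compile_protocol` resolves every step through
the dosimetry calibrations and orders the visits, producing an
:class:`ExecutionPlan` of motion and laser events.  :func:`emit_gcode`
renders the plan as the G-code dialect of GRBL-class engraver firmware
(G21/G90 preamble, G0 moves, M3/M5 laser gating with a timed G4 dwell
between them), and :func:`execute` streams it line by line over any channel
with a ``send(line) -> response`` contract — the shipped simulator or a
user-supplied serial wrapper — using ok/error send-response flow control.

Exposure timing lives in the emitted program (G4 dwell), not in host-side
sleeps, so a plan's timing is checkable by replaying its G-code through the
simulator.  Dose accounting is commanded-value: the hardware modeled here is
open-loop, with no photodiode feedback.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .dosimetry import (
    DosimetryContext,
    IrisSetting,
    OpticalState,
    StepTarget,
    iris_for_well,
    resolve_step_settings,
)
from .plate import (
    PlateCalibration,
    PlateFormat,
    WellAddress,
    check_bounds,
    expand_selection,
    format_well,
    get_format,
    well_center_xy,
)

__all__ = [
    "IlluminationStep",
    "Protocol",
    "PlannedStep",
    "ExecutionPlan",
    "ExecutionLogRecord",
    "ExecutionTimeout",
    "compile_protocol",
    "emit_gcode",
    "execute",
    "dose_report",
    "load_protocol",
    "protocol_from_dict",
    "write_log",
]

ORDERING_POLICIES = ("as-given", "serpentine", "nearest-neighbor")


@dataclass(frozen=True)
class IlluminationStep:
    well: WellAddress
    target: StepTarget
    z_mm: float | None = None  # falls back to the protocol working height
    replicate_tag: str = ""


@dataclass(frozen=True)
class Protocol:
    """A validated illumination protocol bound to one plate."""

    fmt: PlateFormat
    cal: PlateCalibration
    steps: tuple[IlluminationStep, ...]
    dark_controls: frozenset[WellAddress] = frozenset()
    ordering: str = "serpentine"
    temperature_C: float | None = None  # recorded metadata; not driven here
    z_height_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.ordering not in ORDERING_POLICIES:
            raise ValueError(
                f"unknown ordering policy {self.ordering!r}; "
                f"choose from {ORDERING_POLICIES}"
            )
        if not self.steps:
            raise ValueError("protocol has no steps")
        for s in self.steps:
            check_bounds(s.well, self.fmt)
            if s.well in self.dark_controls:
                raise ValueError(
                    f"step targets dark-control well {format_well(s.well)}"
                )
        for w in self.dark_controls:
            check_bounds(w, self.fmt)


@dataclass(frozen=True)
class PlannedStep:
    """One compiled step: target coordinates, resolved optics, iris."""

    step: IlluminationStep
    x: float
    y: float
    optical: OpticalState
    iris: IrisSetting

    @property
    def well_label(self) -> str:
        return format_well(self.step.well)


@dataclass(frozen=True)
class ExecutionPlan:
    steps: tuple[PlannedStep, ...]
    protocol: Protocol

    def total_exposure_s(self) -> float:
        return sum(p.optical.time_s for p in self.steps)

    def travel_mm(self, start: tuple[float, float] = (0.0, 0.0)) -> float:
        x, y = start
        total = 0.0
        for p in self.steps:
            total += math.hypot(p.x - x, p.y - y)
            x, y = p.x, p.y
        return total


@dataclass
class ExecutionLogRecord:
    timestamp: str
    well: str
    irradiance_mW_cm2: float
    time_s: float
    dose_J_cm2: float
    responses: list[str]
    status: str  # completed | aborted | error | timeout

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "well": self.well,
            "commanded": {
                "irradiance_mW_cm2": self.irradiance_mW_cm2,
                "time_s": self.time_s,
                "dose_J_cm2": self.dose_J_cm2,
            },
            # commanded-value accounting: delivered == commanded iff completed
            "delivered_dose_J_cm2": (
                self.dose_J_cm2 if self.status == "completed" else 0.0
            ),
            "responses": self.responses,
            "status": self.status,
        }


class ExecutionTimeout(RuntimeError):
    """Device stopped answering; the partial log is preserved on .records."""

    def __init__(self, message: str, records: list[ExecutionLogRecord]):
        super().__init__(message)
        self.records = records


# -- ordering policies ------------------------------------------------------


def _order_serpentine(steps: Sequence[IlluminationStep]) -> list[IlluminationStep]:
    # Row-major boustrophedon: even rows left->right, odd rows right->left.
    return sorted(
        steps,
        key=lambda s: (s.well.row, s.well.col if s.well.row % 2 == 0 else -s.well.col),
    )


def _order_nearest_neighbor(
    steps: Sequence[IlluminationStep],
    fmt: PlateFormat,
    cal: PlateCalibration,
    start: tuple[float, float] = (0.0, 0.0),
) -> list[IlluminationStep]:
    """Greedy nearest-neighbor visit order, never worse than the given order.

    Greedy construction alone can occasionally lose to the input order, so
    the shorter of the two is returned.
    """
    coords = [well_center_xy(s.well, fmt, cal) for s in steps]

    def travel(order: Sequence[int]) -> float:
        x, y = start
        tot = 0.0
        for i in order:
            tot += math.hypot(coords[i][0] - x, coords[i][1] - y)
            x, y = coords[i]
        return tot

    remaining = list(range(len(steps)))
    order: list[int] = []
    x, y = start
    while remaining:
        nxt = min(
            remaining,
            key=lambda i: (math.hypot(coords[i][0] - x, coords[i][1] - y), i),
        )
        remaining.remove(nxt)
        order.append(nxt)
        x, y = coords[nxt]
    given = list(range(len(steps)))
    if travel(order) > travel(given):
        order = given
    return [steps[i] for i in order]


# -- compilation ------------------------------------------------------------


def compile_protocol(protocol: Protocol, ctx: DosimetryContext) -> ExecutionPlan:
    """Resolve, order and lay out a protocol as an executable plan."""
    if protocol.ordering == "serpentine":
        ordered = _order_serpentine(protocol.steps)
    elif protocol.ordering == "nearest-neighbor":
        ordered = _order_nearest_neighbor(
            protocol.steps, protocol.fmt, protocol.cal
        )
    else:
        ordered = list(protocol.steps)

    planned: list[PlannedStep] = []
    for step in ordered:
        z = step.z_mm if step.z_mm is not None else protocol.z_height_mm
        optical = resolve_step_settings(
            step.target, ctx.beam, z, ctx.power_cal, ctx.attenuator_cal
        )
        x, y = well_center_xy(step.well, protocol.fmt, protocol.cal)
        iris = iris_for_well(protocol.fmt, optical.beam_diameter_mm)
        planned.append(PlannedStep(step, x, y, optical, iris))
    return ExecutionPlan(tuple(planned), protocol)


# -- G-code -----------------------------------------------------------------


def _step_lines(p: PlannedStep) -> list[str]:
    # S carries the commanded output power in mW.
    return [
        f"G0 X{p.x:.3f} Y{p.y:.3f}",
        f"M3 S{p.optical.power_mW:.3f}",
        f"G4 P{p.optical.time_s:.3f}",
        "M5",
    ]


def emit_gcode(plan: ExecutionPlan) -> str:
    """Render the plan as G-code text, byte-for-byte deterministic."""
    if not plan.steps:
        raise ValueError("cannot emit G-code for an empty plan")
    lines = ["G21", "G90"]
    for p in plan.steps:
        lines.extend(_step_lines(p))
    return "\n".join(lines) + "\n"


# -- execution --------------------------------------------------------------


def _now_iso() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def execute(
    plan: ExecutionPlan,
    device,
    timeout_s: float = 2.0,
) -> list[ExecutionLogRecord]:
    """Stream the plan to a device, one line at a time, waiting for "ok".

    ``device`` is any object with ``send(line) -> response`` semantics (the
    GRBL simulator or a serial-port wrapper).  An "error:N" response aborts
    the remaining events and marks the affected and following records.  A
    missing/empty response, or one slower than ``timeout_s``, raises
    :class:`ExecutionTimeout` carrying the partial log.
    """
    if not plan.steps:
        raise ValueError("cannot execute an empty plan")
    records: list[ExecutionLogRecord] = []

    def _send(line: str) -> str:
        t0 = time.monotonic()
        resp = device.send(line)
        if resp is None or resp == "" or (time.monotonic() - t0) > timeout_s:
            raise ExecutionTimeout(
                f"device did not answer {line!r} within {timeout_s} s", records
            )
        return resp

    for line in ("G21", "G90"):
        resp = _send(line)
        if resp.startswith("error"):
            raise RuntimeError(f"device rejected preamble {line!r}: {resp}")

    aborted = False
    for p in plan.steps:
        rec = ExecutionLogRecord(
            timestamp=_now_iso(),
            well=p.well_label,
            irradiance_mW_cm2=p.optical.irradiance_mW_cm2,
            time_s=p.optical.time_s,
            dose_J_cm2=p.optical.dose_J_cm2,
            responses=[],
            status="aborted",
        )
        records.append(rec)
        if aborted:
            continue
        ok = True
        for line in _step_lines(p):
            resp = _send(line)
            rec.responses.append(resp)
            if resp.startswith("error"):
                rec.status = "error"
                ok = False
                aborted = True
                break
        if ok:
            rec.status = "completed"
    return records


def dose_report(plan: ExecutionPlan) -> pd.DataFrame:
    """Tidy per-step table of resolved settings and optical quantities."""
    rows = []
    for p in plan.steps:
        rows.append(
            {
                "well": p.well_label,
                "x_mm": round(p.x, 3),
                "y_mm": round(p.y, 3),
                "irradiance_mW_cm2": p.optical.irradiance_mW_cm2,
                "time_s": p.optical.time_s,
                "dose_J_cm2": p.optical.dose_J_cm2,
                "power_mW": p.optical.power_mW,
                "beam_diameter_mm": p.optical.beam_diameter_mm,
                "drive_current_A": p.optical.drive_current_A,
                "attenuator_setting": p.optical.attenuator_setting,
                "iris_aperture_mm": p.iris.aperture_mm,
                "spill_warning": p.iris.spill_warning,
                "replicate_tag": p.step.replicate_tag,
            }
        )
    return pd.DataFrame(rows)


def write_log(records: Iterable[ExecutionLogRecord], path: str | Path) -> None:
    """JSON-lines execution log with ISO timestamps."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")


# -- protocol files ---------------------------------------------------------


def protocol_from_dict(doc: dict) -> Protocol:
    """Build a protocol from the documented YAML-style mapping.

    Schema (version 1)::

        version: 1
        plate:
          format: "96"
          a1_machine_x: 14.38
          a1_machine_y: 11.24
          col_axis_sign: 1       # optional, default +1
          row_axis_sign: 1       # optional, default +1
        temperature_C: 37.0      # optional metadata
        z_height_mm: 10.0
        ordering: serpentine     # as-given | serpentine | nearest-neighbor
        dark_controls: "A12:H12" # optional selection string
        steps:
          - wells: "A1:A3"       # selection string
            irradiance_mW_cm2: 450.0
            time_s: 10.0         # or dose_J_cm2: 4.5
            tag: "rep1"          # optional
    """
    if doc.get("version") != 1:
        raise ValueError("protocol file must declare 'version: 1'")
    plate = doc["plate"]
    fmt = get_format(plate["format"])
    cal = PlateCalibration(
        a1_machine_x=float(plate["a1_machine_x"]),
        a1_machine_y=float(plate["a1_machine_y"]),
        col_axis_sign=int(plate.get("col_axis_sign", 1)),
        row_axis_sign=int(plate.get("row_axis_sign", 1)),
    )
    dark = frozenset(
        expand_selection(doc["dark_controls"], fmt) if doc.get("dark_controls") else []
    )
    steps: list[IlluminationStep] = []
    for item in doc.get("steps", []):
        target = StepTarget(
            irradiance_mW_cm2=_opt_float(item, "irradiance_mW_cm2"),
            time_s=_opt_float(item, "time_s"),
            dose_J_cm2=_opt_float(item, "dose_J_cm2"),
            power_mW=_opt_float(item, "power_mW"),
        )
        for well in expand_selection(str(item["wells"]), fmt):
            steps.append(
                IlluminationStep(
                    well=well,
                    target=target,
                    z_mm=_opt_float(item, "z_mm"),
                    replicate_tag=str(item.get("tag", "")),
                )
            )
    return Protocol(
        fmt=fmt,
        cal=cal,
        steps=tuple(steps),
        dark_controls=dark,
        ordering=str(doc.get("ordering", "serpentine")),
        temperature_C=_opt_float(doc, "temperature_C"),
        z_height_mm=float(doc.get("z_height_mm", 10.0)),
    )


def _opt_float(d: dict, key: str) -> float | None:
    v = d.get(key)
    return None if v is None else float(v)


def load_protocol(path: str | Path) -> Protocol:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"protocol file {path} is not a mapping")
    return protocol_from_dict(doc)
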