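"""A virtual GRBL-v1.1-subset device used as the hardware stand-in.

The simulator speaks the same line-in / line-out channel contract as a
serial port: one command line per ``send()`` call, one in-band response
("ok", "error:N", or a status report for "?").  Only the command subset the
protocol engine emits is implemented — G21, G90, G0/G1 moves, G4 dwells and
M3/M5 laser gating — this is a test double, not a firmware clone.  Motion is
instantaneous in simulated time; an optional response latency exists so
host-side timeout handling can be exercised.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field

__all__ = ["GrblSimulator", "DeviceState"]

_WORD_RE = re.compile(r"^([XYPSF])(-?\d+(?:\.\d+)?)$")


@dataclass
class DeviceState:
    x: float = 0.0
    y: float = 0.0
    laser_on: bool = False
    laser_s: float = 0.0
    elapsed_dwell_s: float = 0.0
    metric: bool = True
    absolute: bool = True


class GrblSimulator:
    """Line-based virtual device implementing the engraver command subset.

    Parameters
    ----------
    response_latency_s:
        Wall-clock delay before each response, for timeout tests.  Default 0.
    """

    def __init__(self, response_latency_s: float = 0.0) -> None:
        self.state = DeviceState()
        self.response_latency_s = response_latency_s
        self._command_index = 0  # "?" status queries do not consume this
        self._faults: dict[int, str] = {}
        self.history: list[tuple[str, str]] = []

    # -- fault injection ----------------------------------------------------

    def inject_fault(self, index: int, response: str) -> None:
        """Force the response of the future command with ordinal ``index``."""
        if index < self._command_index:
            raise ValueError(
                f"command index {index} already consumed "
                f"(next is {self._command_index})"
            )
        self._faults[index] = response

    # -- channel contract ---------------------------------------------------

    def send(self, line: str) -> str:
        """Process one command line and return the in-band response."""
        if self.response_latency_s:
            time.sleep(self.response_latency_s)
        line = line.strip()
        if line == "?":
            resp = self._status_report()
            self.history.append((line, resp))
            return resp
        idx = self._command_index
        self._command_index += 1
        if idx in self._faults:
            resp = self._faults.pop(idx)
            if resp == "ok":  # scripted ok: state still mutates
                self._process(line)
            self.history.append((line, resp))
            return resp
        resp = self._process(line)
        self.history.append((line, resp))
        return resp

    def reset(self) -> None:
        self.state = DeviceState()

    # -- internals ----------------------------------------------------------

    def _status_report(self) -> str:
        return f"<Idle|MPos:{self.state.x:.3f},{self.state.y:.3f},0.000|FS:0,0>"

    def _process(self, line: str) -> str:
        if not line:
            return "error:1"  # empty/expected command letter
        fields = line.split()
        head = fields[0].upper()
        try:
            if head == "G21":
                self.state.metric = True
            elif head == "G90":
                self.state.absolute = True
            elif head in ("G0", "G1", "G00", "G01"):
                return self._move(fields[1:])
            elif head == "G4" or head == "G04":
                return self._dwell(fields[1:])
            elif head == "M3" or head == "M03":
                return self._laser_on(fields[1:])
            elif head == "M5" or head == "M05":
                self.state.laser_on = False
                self.state.laser_s = 0.0
            else:
                return "error:20"  # unsupported command
        except _Malformed:
            return "error:2"  # bad number format
        return "ok"

    def _words(self, fields: list[str]) -> dict[str, float]:
        out: dict[str, float] = {}
        for f in fields:
            m = _WORD_RE.match(f.upper())
            if not m:
                raise _Malformed(f)
            out[m.group(1)] = float(m.group(2))
        return out

    def _move(self, fields: list[str]) -> str:
        words = self._words(fields)
        if "X" not in words and "Y" not in words:
            return "error:2"
        # feed (F) accepted and ignored: motion is instantaneous in sim time
        if "X" in words:
            self.state.x = words["X"] if self.state.absolute else self.state.x + words["X"]
        if "Y" in words:
            self.state.y = words["Y"] if self.state.absolute else self.state.y + words["Y"]
        return "ok"

    def _dwell(self, fields: list[str]) -> str:
        words = self._words(fields)
        if "P" not in words or words["P"] < 0:
            return "error:2"
        self.state.elapsed_dwell_s += words["P"]
        return "ok"

    def _laser_on(self, fields: list[str]) -> str:
        words = self._words(fields)
        if "S" not in words or words["S"] < 0:
            return "error:2"
        self.state.laser_on = True
        self.state.laser_s = words["S"]
        return "ok"


class _Malformed(Exception):
    pass
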