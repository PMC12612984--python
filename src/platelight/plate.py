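"""Microplate geometry: standard formats and well-to-machine-coordinate mapping.

Plates follow the ANSI/SLAS footprint (127.76 x 85.48 mm).  A plate format
fixes the well grid (rows x columns, pitch); a :class:`PlateCalibration`
anchors well A1 to a machine coordinate and fixes the direction of increasing
column / row along the machine X / Y axes.  Rotation of the plate relative to
the machine axes is deliberately not modeled: a leveled stage bed with a
square plate nest needs translation and axis sign only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "PlateFormat",
    "WellAddress",
    "PlateCalibration",
    "PLATE_FORMATS",
    "get_format",
    "parse_well",
    "format_well",
    "well_center_xy",
    "expand_selection",
]

SLAS_FOOTPRINT_X = 127.76
SLAS_FOOTPRINT_Y = 85.48


@dataclass(frozen=True)
class PlateFormat:
    """Geometry of one microplate format.

    ``a1_offset_x`` / ``a1_offset_y`` are the distances from the plate's
    reference corner (A1 corner) to the center of well A1.  All lengths in mm.
    """

    name: str
    n_rows: int
    n_cols: int
    well_pitch: float
    well_diameter: float
    a1_offset_x: float
    a1_offset_y: float
    footprint_x: float = SLAS_FOOTPRINT_X
    footprint_y: float = SLAS_FOOTPRINT_Y

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("plate must have at least one row and one column")
        if self.well_pitch <= 0:
            raise ValueError("well_pitch must be positive")
        if self.well_diameter <= 0:
            raise ValueError("well_diameter must be positive")
        # Consistency of the constants table: offsets + grid span ~ footprint.
        span_x = 2 * self.a1_offset_x + (self.n_cols - 1) * self.well_pitch
        span_y = 2 * self.a1_offset_y + (self.n_rows - 1) * self.well_pitch
        if abs(span_x - self.footprint_x) > 2.0 or abs(span_y - self.footprint_y) > 2.0:
            raise ValueError(
                f"format {self.name!r}: offsets/pitch inconsistent with footprint "
                f"(span {span_x:.2f} x {span_y:.2f} vs "
                f"{self.footprint_x} x {self.footprint_y})"
            )

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def wells(self) -> Iterator["WellAddress"]:
        """All addresses in row-major order (A1, A2, ..., B1, ...)."""
        for r in range(self.n_rows):
            for c in range(1, self.n_cols + 1):
                yield WellAddress(r, c)


@dataclass(frozen=True, order=True)
class WellAddress:
    """Zero-based row (A=0) and 1-based column."""

    row: int
    col: int

    def __str__(self) -> str:
        return format_well(self)


@dataclass(frozen=True)
class PlateCalibration:
    """Machine coordinates (mm) of the A1 well center and axis directions.

    The stage may home to any plate corner; both axis signs are free so that
    increasing column / row can run along either machine direction.
    """

    a1_machine_x: float
    a1_machine_y: float
    col_axis_sign: int = 1
    row_axis_sign: int = 1

    def __post_init__(self) -> None:
        if self.col_axis_sign not in (-1, 1) or self.row_axis_sign not in (-1, 1):
            raise ValueError("axis signs must be +1 or -1")


# One record per supported format.  96/384 pitches and A1 offsets are the
# ANSI/SLAS standard values; 24- and 12-well pitches are vendor-typical
# (Corning-style) with offsets centering the grid on the SLAS footprint.
PLATE_FORMATS: dict[str, PlateFormat] = {
    "12": PlateFormat("12", 3, 4, 26.01, 22.1, 24.865, 16.73),
    "24": PlateFormat("24", 4, 6, 19.30, 15.6, 15.63, 13.79),
    "96": PlateFormat("96", 8, 12, 9.00, 6.96, 14.38, 11.24),
    "384": PlateFormat("384", 16, 24, 4.50, 3.70, 12.13, 8.99),
}


def get_format(name: str) -> PlateFormat:
    try:
        return PLATE_FORMATS[str(name)]
    except KeyError:
        raise KeyError(
            f"unknown plate format {name!r}; known: {sorted(PLATE_FORMATS)}"
        ) from None


_WELL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def parse_well(text: str, fmt: PlateFormat | None = None) -> WellAddress:
    """Parse a well label like ``"B7"`` (case-insensitive) into an address.

    When ``fmt`` is given the address is bounds-checked against it.
    """
    m = _WELL_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed well address {text!r}")
    letters, digits = m.group(1).upper(), m.group(2)
    row = 0
    for ch in letters:  # bijective base-26: A..Z, AA..AZ, ...
        row = row * 26 + (ord(ch) - ord("A") + 1)
    row -= 1
    col = int(digits)
    if col < 1:
        raise ValueError(f"column must be >= 1 in {text!r}")
    addr = WellAddress(row, col)
    if fmt is not None:
        check_bounds(addr, fmt)
    return addr


def format_well(addr: WellAddress) -> str:
    """Inverse of :func:`parse_well`; always uppercase."""
    if addr.row < 0 or addr.col < 1:
        raise ValueError(f"invalid address {addr!r}")
    row = addr.row + 1
    letters = ""
    while row > 0:
        row, rem = divmod(row - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return f"{letters}{addr.col}"


def check_bounds(addr: WellAddress, fmt: PlateFormat) -> None:
    if not (0 <= addr.row < fmt.n_rows and 1 <= addr.col <= fmt.n_cols):
        raise ValueError(
            f"well {format_well(addr)} outside {fmt.name}-well plate "
            f"({fmt.n_rows} rows x {fmt.n_cols} cols)"
        )


def well_center_xy(
    addr: WellAddress, fmt: PlateFormat, cal: PlateCalibration
) -> tuple[float, float]:
    """Machine X-Y (mm) of a well center, computed in full precision.

    Columns advance along machine X, rows along machine Y, each with the
    calibration's axis sign.  Callers that print coordinates round to 0.1 mm,
    the device's positional accuracy.
    """
    check_bounds(addr, fmt)
    x = cal.a1_machine_x + cal.col_axis_sign * (addr.col - 1) * fmt.well_pitch
    y = cal.a1_machine_y + cal.row_axis_sign * addr.row * fmt.well_pitch
    return x, y


def expand_selection(spec: str, fmt: PlateFormat) -> list[WellAddress]:
    """Expand a selection string into an ordered, de-duplicated address list.

    The grammar is a comma list of single wells (``"B7"``) and rectangular
    ranges (``"A1:C4"``).  Ranges expand row-major; the first occurrence of a
    duplicate wins.
    """
    out: list[WellAddress] = []
    seen: set[WellAddress] = set()
    if not spec or not spec.strip():
        raise ValueError("empty selection")
    for token in spec.split(","):
        token = token.strip()
        if not token:
            raise ValueError(f"empty element in selection {spec!r}")
        if ":" in token:
            lo_s, _, hi_s = token.partition(":")
            lo = parse_well(lo_s, fmt)
            hi = parse_well(hi_s, fmt)
            r0, r1 = sorted((lo.row, hi.row))
            c0, c1 = sorted((lo.col, hi.col))
            cells = [
                WellAddress(r, c)
                for r in range(r0, r1 + 1)
                for c in range(c0, c1 + 1)
            ]
        else:
            cells = [parse_well(token, fmt)]
        for a in cells:
            if a not in seen:
                seen.add(a)
                out.append(a)
    return out
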