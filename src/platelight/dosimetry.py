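"""Optical dosimetry: device settings <-> optical quantities.

Symbols and units follow photodynamic-dosimetry convention:

* ``P``  laser output power, mW
* ``d``  beam diameter at the sample, mm (uniform "top-hat" disc assumed)
* ``A``  illuminated spot area, cm^2
* ``E``  irradiance (power density), mW cm^-2, E = P / A
* ``H``  light dose (fluence), J cm^-2, H = E * t / 1000
* ``t``  exposure time, s

Calibration tables (drive current -> output power, distance below lens ->
beam diameter, attenuator setting -> transmittance) are strictly tabulated
and interpolated piecewise-linearly.  There is no extrapolation: a request
outside a table's domain is a hard error, because the quantity being set is
the light dose delivered to a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationTable",
    "PowerCalibration",
    "BeamModel",
    "AttenuatorCalibration",
    "IrisSetting",
    "OpticalState",
    "StepTarget",
    "DosimetryContext",
    "spot_area_cm2",
    "irradiance",
    "power_for_irradiance",
    "dose",
    "exposure_time",
    "resolve_step_settings",
    "iris_for_well",
    "example_power_calibration",
    "example_beam_model",
    "example_attenuator_calibration",
]

IRIS_MIN_MM = 1.9
IRIS_MAX_MM = 36.0


class CalibrationRangeError(ValueError):
    """A requested value lies outside a calibration table's domain."""


@dataclass(frozen=True)
class CalibrationTable:
    """A two-column monotone lookup table with piecewise-linear interpolation."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    x_name: str = "x"
    y_name: str = "y"

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        if len(self.x) < 2:
            raise ValueError("calibration table needs at least 2 points")
        xs = np.asarray(self.x, dtype=float)
        if not np.all(np.diff(xs) > 0):
            raise ValueError(f"{self.x_name} values must be strictly increasing")

    def __call__(self, x: float) -> float:
        return self.interpolate(x)

    def interpolate(self, x: float) -> float:
        """Forward lookup; exact at knots; errors outside the domain."""
        if not (self.x[0] <= x <= self.x[-1]):
            raise CalibrationRangeError(
                f"{self.x_name}={x:g} outside calibration range "
                f"[{self.x[0]:g}, {self.x[-1]:g}]"
            )
        return float(np.interp(x, self.x, self.y))

    def inverse(self, y: float) -> float:
        """Inverse lookup (requires strictly monotone y)."""
        ys = np.asarray(self.y, dtype=float)
        dy = np.diff(ys)
        if np.all(dy > 0):
            xs, ys_ = self.x, ys
        elif np.all(dy < 0):
            xs, ys_ = self.x[::-1], ys[::-1]
        else:
            raise ValueError(f"{self.y_name} not strictly monotone; no inverse")
        if not (ys_[0] <= y <= ys_[-1]):
            raise CalibrationRangeError(
                f"{self.y_name}={y:g} outside calibration range "
                f"[{min(ys_):g}, {max(ys_):g}]"
            )
        return float(np.interp(y, ys_, xs))

    @property
    def y_min(self) -> float:
        return float(min(self.y))

    @property
    def y_max(self) -> float:
        return float(max(self.y))

    def to_file(self, path: str | Path) -> None:
        """Write as two-column whitespace-separated text with a header line."""
        lines = [f"# platelight-calibration v1: {self.x_name}\t{self.y_name}"]
        lines += [f"{x:.9g}\t{y:.9g}" for x, y in zip(self.x, self.y)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(
        cls, path: str | Path, x_name: str = "x", y_name: str = "y"
    ) -> "CalibrationTable":
        xs: list[float] = []
        ys: list[float] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise ValueError(f"malformed calibration line {line!r}")
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        return cls(tuple(xs), tuple(ys), x_name=x_name, y_name=y_name)


class PowerCalibration(CalibrationTable):
    """Drive current (A) -> fiber output power (mW), strictly increasing."""

    def __init__(self, points: Sequence[tuple[float, float]]):
        xs, ys = zip(*points)
        if not all(b > a for a, b in zip(ys, ys[1:])):
            raise ValueError("output power must be strictly increasing with current")
        if min(ys) < 0:
            raise ValueError("output power cannot be negative")
        super().__init__(tuple(xs), tuple(ys), "drive_current_A", "output_power_mW")

    def current_for_power(self, power_mW: float) -> float:
        return self.inverse(power_mW)


class BeamModel(CalibrationTable):
    """Distance below the lens tube (mm) -> beam diameter (mm), non-decreasing."""

    def __init__(self, points: Sequence[tuple[float, float]]):
        xs, ys = zip(*points)
        if not all(b >= a for a, b in zip(ys, ys[1:])):
            raise ValueError("beam diameter must be non-decreasing with distance")
        if min(ys) <= 0:
            raise ValueError("beam diameter must be positive")
        super().__init__(tuple(xs), tuple(ys), "distance_mm", "beam_diameter_mm")

    def diameter_at(self, z_mm: float) -> float:
        return self.interpolate(z_mm)


class AttenuatorCalibration(CalibrationTable):
    """Attenuator setting -> transmittance fraction in [0, 1], monotone."""

    def __init__(self, points: Sequence[tuple[float, float]]):
        xs, ys = zip(*points)
        if min(ys) < 0 or max(ys) > 1:
            raise ValueError("transmittance must lie in [0, 1]")
        dy = np.diff(ys)
        if not (np.all(dy > 0) or np.all(dy < 0)):
            raise ValueError("transmittance must be strictly monotone in setting")
        super().__init__(tuple(xs), tuple(ys), "setting", "transmittance")

    def setting_for_transmittance(self, t: float) -> float:
        return self.inverse(t)


@dataclass(frozen=True)
class IrisSetting:
    """Mechanical iris aperture, clamped to the hardware range 1.9-36.0 mm."""

    aperture_mm: float
    spill_warning: bool = False

    def __post_init__(self) -> None:
        if not (IRIS_MIN_MM <= self.aperture_mm <= IRIS_MAX_MM):
            raise ValueError(
                f"iris aperture {self.aperture_mm} mm outside "
                f"[{IRIS_MIN_MM}, {IRIS_MAX_MM}] mm"
            )


@dataclass(frozen=True)
class OpticalState:
    """Resolved optical quantities for one illumination step."""

    power_mW: float
    beam_diameter_mm: float
    irradiance_mW_cm2: float
    dose_J_cm2: float
    time_s: float
    drive_current_A: float | None = None
    attenuator_setting: float | None = None
    attenuator_transmittance: float = 1.0

    def __post_init__(self) -> None:
        for name in ("power_mW", "beam_diameter_mm", "irradiance_mW_cm2",
                     "dose_J_cm2", "time_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive when resolved")


def spot_area_cm2(d_mm: float) -> float:
    """Area of a uniform circular spot of diameter ``d_mm`` mm, in cm^2."""
    if d_mm <= 0:
        raise ValueError("beam diameter must be positive")
    return math.pi * (d_mm / 20.0) ** 2


def irradiance(power_mW: float, d_mm: float) -> float:
    """E = P / A, in mW cm^-2."""
    if power_mW <= 0:
        raise ValueError("power must be positive")
    return power_mW / spot_area_cm2(d_mm)


def power_for_irradiance(E_mW_cm2: float, d_mm: float) -> float:
    """Exact inverse of :func:`irradiance` at fixed beam diameter."""
    if E_mW_cm2 <= 0:
        raise ValueError("irradiance must be positive")
    return E_mW_cm2 * spot_area_cm2(d_mm)


def dose(E_mW_cm2: float, t_s: float) -> float:
    """Light dose H = E * t / 1000, in J cm^-2."""
    if E_mW_cm2 <= 0:
        raise ValueError("irradiance must be positive")
    if t_s < 0:
        raise ValueError("exposure time cannot be negative")
    return E_mW_cm2 * t_s / 1000.0


def exposure_time(H_J_cm2: float, E_mW_cm2: float) -> float:
    """Exact inverse of :func:`dose`: t = 1000 * H / E, in s."""
    if E_mW_cm2 <= 0:
        raise ValueError("irradiance must be positive")
    if H_J_cm2 < 0:
        raise ValueError("dose cannot be negative")
    return 1000.0 * H_J_cm2 / E_mW_cm2


_REL_TOL = 1e-9


@dataclass(frozen=True)
class StepTarget:
    """What one illumination step asks for.

    Exactly one consistent specification of (E, H, t) must be derivable:
    either irradiance plus one of time/dose, or power plus time (with the
    beam diameter coming from the beam model).  Giving E, H and t together
    is accepted only when mutually consistent to 1e-9 relative.
    """

    irradiance_mW_cm2: float | None = None
    time_s: float | None = None
    dose_J_cm2: float | None = None
    power_mW: float | None = None

    def __post_init__(self) -> None:
        has_E = self.irradiance_mW_cm2 is not None
        has_P = self.power_mW is not None
        if has_E and has_P:
            raise ValueError("give either irradiance or power, not both")
        if not has_E and not has_P:
            raise ValueError("target needs an irradiance or a power")
        n_time_like = (self.time_s is not None) + (self.dose_J_cm2 is not None)
        if has_P and self.time_s is None:
            raise ValueError("a power target needs an exposure time")
        if has_E and n_time_like == 0:
            raise ValueError("an irradiance target needs a time or a dose")


@dataclass(frozen=True)
class DosimetryContext:
    """Beam model plus device calibrations used to resolve protocol steps."""

    beam: BeamModel
    power_cal: PowerCalibration
    attenuator_cal: AttenuatorCalibration | None = None


def resolve_step_settings(
    target: StepTarget,
    beam: BeamModel,
    z_mm: float,
    power_cal: PowerCalibration,
    attenuator_cal: AttenuatorCalibration | None = None,
) -> OpticalState:
    """Resolve a step target into a fully consistent :class:`OpticalState`.

    The beam diameter comes from the beam model at the working height
    ``z_mm``.  The required output power maps back to a drive current by
    inverse interpolation of the power calibration.  When an attenuator is
    configured, coarse power is set by current (the smallest calibrated knot
    at or above the requirement) and fine-tuned multiplicatively by the
    attenuator transmittance.

    The returned state satisfies H = E*t/1000 and E = P/A simultaneously to
    1e-9 relative.
    """
    d = beam.diameter_at(z_mm)
    area = spot_area_cm2(d)

    if target.power_mW is not None:
        P = target.power_mW
        E = P / area
        t = target.time_s
        H = dose(E, t)
        if target.dose_J_cm2 is not None and not math.isclose(
            target.dose_J_cm2, H, rel_tol=_REL_TOL
        ):
            raise ValueError(
                f"inconsistent target: power/time imply H={H:g} J cm^-2 "
                f"but dose {target.dose_J_cm2:g} was requested"
            )
    else:
        E = target.irradiance_mW_cm2
        if target.time_s is not None and target.dose_J_cm2 is not None:
            implied = dose(E, target.time_s)
            if not math.isclose(implied, target.dose_J_cm2, rel_tol=_REL_TOL):
                raise ValueError(
                    f"inconsistent target: E={E:g}, t={target.time_s:g} imply "
                    f"H={implied:g} J cm^-2, not {target.dose_J_cm2:g}"
                )
            t, H = target.time_s, target.dose_J_cm2
        elif target.time_s is not None:
            t = target.time_s
            H = dose(E, t)
        else:
            H = target.dose_J_cm2
            t = exposure_time(H, E)
        P = power_for_irradiance(E, d)

    current: float | None
    att_setting: float | None = None
    att_T = 1.0
    if attenuator_cal is None:
        current = power_cal.current_for_power(P)
    else:
        # Coarse by current: smallest calibrated power knot >= P; fine by T.
        powers = np.asarray(power_cal.y)
        at_or_above = powers[powers >= P * (1 - _REL_TOL)]
        if at_or_above.size == 0:
            raise CalibrationRangeError(
                f"required power {P:g} mW exceeds calibration maximum "
                f"{power_cal.y_max:g} mW"
            )
        P_coarse = float(at_or_above.min())
        current = power_cal.current_for_power(P_coarse)
        att_T = P / P_coarse
        att_setting = attenuator_cal.setting_for_transmittance(att_T)

    return OpticalState(
        power_mW=P,
        beam_diameter_mm=d,
        irradiance_mW_cm2=E,
        dose_J_cm2=H,
        time_s=t,
        drive_current_A=current,
        attenuator_setting=att_setting,
        attenuator_transmittance=att_T,
    )


def iris_for_well(fmt, beam_d_mm: float) -> IrisSetting:
    """Iris aperture matching the beam to the well opening.

    Aperture = min(beam diameter, well opening), clamped to the hardware
    range.  A spill flag is set when the beam is wider than the well pitch,
    since light may then reach neighboring (dark-control) wells.
    """
    if beam_d_mm <= 0:
        raise ValueError("beam diameter must be positive")
    aperture = min(beam_d_mm, fmt.well_diameter)
    aperture = min(max(aperture, IRIS_MIN_MM), IRIS_MAX_MM)
    return IrisSetting(aperture, spill_warning=beam_d_mm > fmt.well_pitch)


def example_power_calibration() -> PowerCalibration:
    """A shipped example current->power table spanning the 10-1200 mW device.

    Knots are a synthetic diode-like response used as a test fixture; they
    are not a claim about any particular laser.
    """
    return PowerCalibration(
        [(0.20, 10.0), (0.40, 150.0), (0.60, 400.0), (0.80, 700.0),
         (1.00, 960.0), (1.20, 1200.0)]
    )


def example_beam_model() -> BeamModel:
    """Shipped example distance->diameter table (10 mm spot at 10 mm below the
    lens, expanding to 24 mm at the far working position); a synthetic fixture."""
    return BeamModel(
        [(10.0, 10.0), (40.0, 13.5), (70.0, 17.0), (100.0, 20.5), (120.0, 24.0)]
    )


def example_attenuator_calibration() -> AttenuatorCalibration:
    """Shipped example attenuator setting->transmittance table (synthetic)."""
    return AttenuatorCalibration(
        [(0.0, 0.01), (25.0, 0.25), (50.0, 0.50), (75.0, 0.75), (100.0, 1.00)]
    )
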