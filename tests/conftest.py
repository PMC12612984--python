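import pytest
from hypothesis import HealthCheck, settings

from platelight.dosimetry import (
    DosimetryContext,
    example_beam_model,
    example_power_calibration,
)
from platelight.plate import PLATE_FORMATS, PlateCalibration

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def fmt96():
    return PLATE_FORMATS["96"]


@pytest.fixture
def cal_origin():
    return PlateCalibration(0.0, 0.0)


@pytest.fixture
def dosimetry_ctx():
    return DosimetryContext(
        beam=example_beam_model(), power_cal=example_power_calibration()
    )


@pytest.fixture
def example_protocol_yaml(tmp_path):
    text = """\
version: 1
plate:
  format: "96"
  a1_machine_x: 14.38
  a1_machine_y: 11.24
temperature_C: 37.0
z_height_mm: 10.0
ordering: serpentine
dark_controls: "H10:H12"
steps:
  - wells: "A1:A3"
    irradiance_mW_cm2: 450.0
    time_s: 10.0
    tag: "rep"
  - wells: "B1:B3"
    irradiance_mW_cm2: 450.0
    dose_J_cm2: 112.5
  - wells: "C1:C3"
    irradiance_mW_cm2: 100.0
    time_s: 250.0
"""
    path = tmp_path / "protocol.yaml"
    path.write_text(text)
    return path
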