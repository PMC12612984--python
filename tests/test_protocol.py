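"""Protocol compilation, G-code emission, streaming execution."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from platelight.dosimetry import DosimetryContext, StepTarget
from platelight.plate import (
    PLATE_FORMATS,
    PlateCalibration,
    WellAddress,
    format_well,
    parse_well,
)
from platelight.protocol import (
    ExecutionTimeout,
    IlluminationStep,
    Protocol,
    compile_protocol,
    dose_report,
    emit_gcode,
    execute,
    load_protocol,
)
from platelight.simulator import GrblSimulator


def _step(well: str, t: float = 10.0, E: float = 450.0) -> IlluminationStep:
    return IlluminationStep(parse_well(well), StepTarget(irradiance_mW_cm2=E, time_s=t))


def _protocol(wells, ordering="as-given", dark=(), fmt_name="96"):
    fmt = PLATE_FORMATS[fmt_name]
    return Protocol(
        fmt=fmt,
        cal=PlateCalibration(0.0, 0.0),
        steps=tuple(_step(w) for w in wells),
        dark_controls=frozenset(parse_well(w, fmt) for w in dark),
        ordering=ordering,
    )


class TestCompile:
    def test_single_step_event_sequence(self, dosimetry_ctx):
        plan = compile_protocol(_protocol(["A1"]), dosimetry_ctx)
        assert len(plan.steps) == 1
        gcode = emit_gcode(plan).strip().split("\n")
        assert gcode == [
            "G21", "G90",
            "G0 X0.000 Y0.000",
            f"M3 S{plan.steps[0].optical.power_mW:.3f}",
            "G4 P10.000",
            "M5",
        ]

    def test_serpentine_order(self, dosimetry_ctx):
        plan = compile_protocol(
            _protocol(["A1", "B1", "A2"], ordering="serpentine"), dosimetry_ctx
        )
        assert [p.well_label for p in plan.steps] == ["A1", "A2", "B1"]

    def test_serpentine_reverses_odd_rows(self, dosimetry_ctx):
        plan = compile_protocol(
            _protocol(["A1", "A2", "B1", "B2"], ordering="serpentine"), dosimetry_ctx
        )
        assert [p.well_label for p in plan.steps] == ["A1", "A2", "B2", "B1"]

    def test_dark_control_collision_rejected(self):
        with pytest.raises(ValueError, match="dark-control"):
            _protocol(["A1"], dark=["A1"])

    def test_total_on_time_matches_requested(self, dosimetry_ctx):
        plan = compile_protocol(_protocol(["A1", "B2", "C3"]), dosimetry_ctx)
        assert plan.total_exposure_s() == pytest.approx(30.0, rel=1e-12)

    @given(
        wells=st.lists(
            st.tuples(st.integers(0, 7), st.integers(1, 12)).map(
                lambda rc: format_well(WellAddress(*rc))
            ),
            min_size=1,
            max_size=20,
            unique=True,
        ),
        ordering=st.sampled_from(["as-given", "serpentine", "nearest-neighbor"]),
    )
    def test_step_multiset_preserved_by_every_policy(self, wells, ordering):
        from platelight.dosimetry import example_beam_model, example_power_calibration

        ctx = DosimetryContext(example_beam_model(), example_power_calibration())
        plan = compile_protocol(_protocol(wells, ordering=ordering), ctx)
        assert sorted(p.well_label for p in plan.steps) == sorted(wells)

    @given(
        wells=st.lists(
            st.tuples(st.integers(0, 7), st.integers(1, 12)).map(
                lambda rc: format_well(WellAddress(*rc))
            ),
            min_size=1,
            max_size=15,
            unique=True,
        )
    )
    def test_nearest_neighbor_never_travels_more_than_as_given(self, wells):
        from platelight.dosimetry import example_beam_model, example_power_calibration

        ctx = DosimetryContext(example_beam_model(), example_power_calibration())
        given_plan = compile_protocol(_protocol(wells, ordering="as-given"), ctx)
        nn_plan = compile_protocol(_protocol(wells, ordering="nearest-neighbor"), ctx)
        assert nn_plan.travel_mm() <= given_plan.travel_mm() + 1e-9


class TestGcode:
    def test_deterministic_bytes(self, dosimetry_ctx):
        prot = _protocol(["A1", "B7", "H12"], ordering="serpentine")
        g1 = emit_gcode(compile_protocol(prot, dosimetry_ctx))
        g2 = emit_gcode(compile_protocol(prot, dosimetry_ctx))
        assert g1 == g2

    def test_coordinate_and_dwell_formats(self, dosimetry_ctx):
        fmt = PLATE_FORMATS["96"]
        prot = Protocol(
            fmt=fmt,
            cal=PlateCalibration(0.0, 0.0),
            steps=(_step("B3"),),
        )
        lines = emit_gcode(compile_protocol(prot, dosimetry_ctx)).splitlines()
        assert "G0 X18.000 Y9.000" in lines
        assert "G4 P10.000" in lines

    def test_empty_plan_rejected(self, dosimetry_ctx):
        from platelight.protocol import ExecutionPlan

        with pytest.raises(ValueError):
            emit_gcode(ExecutionPlan((), _protocol(["A1"])))


class TestExecute:
    def test_clean_run_completes_and_parks_at_last_well(self, dosimetry_ctx):
        plan = compile_protocol(_protocol(["A1", "B3"]), dosimetry_ctx)
        sim = GrblSimulator()
        records = execute(plan, sim)
        assert [r.status for r in records] == ["completed", "completed"]
        last = plan.steps[-1]
        assert (sim.state.x, sim.state.y) == pytest.approx((last.x, last.y))

    def test_device_error_aborts_remaining_steps(self, dosimetry_ctx):
        plan = compile_protocol(_protocol(["A1", "A2", "A3"]), dosimetry_ctx)
        sim = GrblSimulator()
        sim.inject_fault(6, "error:9")  # first command of the second step
        records = execute(plan, sim)
        assert [r.status for r in records] == ["completed", "error", "aborted"]

    def test_silent_device_raises_timeout_with_partial_log(self, dosimetry_ctx):
        plan = compile_protocol(_protocol(["A1", "A2"]), dosimetry_ctx)

        class SilentAfter:
            def __init__(self, n):
                self.n, self.inner = n, GrblSimulator()

            def send(self, line):
                if self.n == 0:
                    return ""
                self.n -= 1
                return self.inner.send(line)

        with pytest.raises(ExecutionTimeout) as exc:
            execute(plan, SilentAfter(6), timeout_s=0.05)
        records = exc.value.records
        assert records[0].status == "completed"

    def test_slow_device_times_out(self, dosimetry_ctx):
        plan = compile_protocol(_protocol(["A1"]), dosimetry_ctx)
        sim = GrblSimulator(response_latency_s=0.05)
        with pytest.raises(ExecutionTimeout):
            execute(plan, sim, timeout_s=0.01)

    def test_simulator_dwell_equals_total_exposure(self, dosimetry_ctx):
        plan = compile_protocol(
            _protocol(["A1", "B2", "C3", "D4"]), dosimetry_ctx
        )
        sim = GrblSimulator()
        execute(plan, sim)
        assert sim.state.elapsed_dwell_s == pytest.approx(
            plan.total_exposure_s(), rel=1e-9
        )


class TestProtocolFile:
    def test_load_and_compile_example(self, example_protocol_yaml, dosimetry_ctx):
        prot = load_protocol(example_protocol_yaml)
        assert len(prot.steps) == 9
        assert prot.temperature_C == 37.0
        plan = compile_protocol(prot, dosimetry_ctx)
        report = dose_report(plan)
        # dose targets: 450*10, 450 dose-specified, 100*250 -> 4.5/112.5/25
        assert sorted(report["dose_J_cm2"].unique()) == pytest.approx(
            [4.5, 25.0, 112.5]
        )

    def test_version_field_required(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("plate: {format: '96', a1_machine_x: 0, a1_machine_y: 0}\nsteps: []\n")
        with pytest.raises(ValueError, match="version"):
            load_protocol(p)


class TestReplay:
    @given(
        fmt_name=st.sampled_from(sorted(PLATE_FORMATS)),
        idx=st.lists(st.integers(0, 10_000), min_size=1, max_size=12, unique=True),
        ordering=st.sampled_from(["as-given", "serpentine", "nearest-neighbor"]),
    )
    def test_gcode_replay_reaches_last_planned_position(self, fmt_name, idx, ordering):
        """Emitted G-code replayed through the simulator parks the head at
        the last planned well center within the 0.1 mm device accuracy."""
        from platelight.dosimetry import example_beam_model, example_power_calibration

        fmt = PLATE_FORMATS[fmt_name]
        wells = [
            format_well(WellAddress((i % fmt.n_wells) // fmt.n_cols,
                                    (i % fmt.n_wells) % fmt.n_cols + 1))
            for i in idx
        ]
        wells = list(dict.fromkeys(wells))
        ctx = DosimetryContext(example_beam_model(), example_power_calibration())
        prot = Protocol(
            fmt=fmt,
            cal=PlateCalibration(3.0, 4.0),
            steps=tuple(_step(w) for w in wells),
            ordering=ordering,
        )
        plan = compile_protocol(prot, ctx)
        sim = GrblSimulator()
        for line in emit_gcode(plan).splitlines():
            assert sim.send(line) == "ok", line
        last = plan.steps[-1]
        assert math.dist((sim.state.x, sim.state.y), (last.x, last.y)) <= 0.1
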