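"""Code emission: structure, golden files, cross-path execution agreement."""

import csv
import os
import subprocess

import numpy as np
import pytest

from mospec.codegen import (
    CodegenError, generate_package, read_dat_files, write_dat_files,
)
from mospec.dialects import DEFAULT_DIALECTS
from mospec.fixtures import make_fixture
from mospec.model import ModelMeta, ModelSpec, VariableDef
from mospec.simulate import TimeGrid, simulate

GOLDEN_DIR = os.path.join(os.path.dirname(__file__), "golden")


def _read_csv(path):
    with open(path) as fh:
        rows = list(csv.reader(fh))
    return rows[0], np.array([[float(v) for v in r] for r in rows[1:]])


def _in_process_matrix(spec):
    res = simulate(spec, "Default", TimeGrid.from_spec(spec), seed=0)
    cols = [res.times] + [res.trajectory(n) for n in res.variable_names]
    return ["time"] + res.variable_names, np.column_stack(cols)


class TestPackageStructure:
    @pytest.mark.parametrize("dialect_id", ("python", "r", "julia"))
    def test_entry_point_naming(self, any_fixture, dialect_id):
        pkg = generate_package(any_fixture, dialect_id, None)
        P = any_fixture.meta.project_name
        ext = DEFAULT_DIALECTS[dialect_id].source_extension
        assert pkg.entry_point == f"{P}AutoTester{ext}"
        assert pkg.entry_point in pkg.files

    @pytest.mark.parametrize("dialect_id", ("python", "r", "julia"))
    def test_routine_names_shared_across_dialects(self, two_lovers, dialect_id):
        pkg = generate_package(two_lovers, dialect_id, None)
        text = "".join(pkg.files.values())
        for routine in ("ModelPars", "ModelRHS", "AlgebraicValues",
                        "InitialConditions", "RK4Step", "TimeGrid",
                        "Integrate", "CheckConstraints"):
            assert routine in text

    def test_headers_carry_version_string_not_timestamps(self, two_lovers):
        pkg = generate_package(two_lovers, "python", None)
        for text in pkg.files.values():
            assert "TwoLovers.MoSpec V02.04.03" in text
            assert text.endswith("\n")

    def test_regeneration_is_byte_identical(self, seir):
        a = generate_package(seir, "julia", None)
        b = generate_package(make_fixture("SEIR"), "julia", None)
        assert a.files == b.files

    def test_generated_python_compiles(self, any_fixture):
        pkg = generate_package(any_fixture, "python", None)
        for name, text in pkg.files.items():
            compile(text, name, "exec")

    def test_unknown_dialect_rejected(self, two_lovers):
        with pytest.raises(CodegenError, match="fortran"):
            generate_package(two_lovers, "fortran", None)
        with pytest.raises(CodegenError, match="no package emitter"):
            generate_package(two_lovers, "matlab", None)


class TestGoldenFiles:
    """Non-host emissions are frozen as reviewed golden text."""

    @pytest.mark.parametrize("dialect_id", ("r", "julia"))
    def test_two_lovers_matches_golden(self, two_lovers, dialect_id):
        pkg = generate_package(two_lovers, dialect_id, None)
        golden_root = os.path.join(GOLDEN_DIR, dialect_id)
        golden_files = sorted(os.listdir(golden_root))
        assert sorted(pkg.files) == golden_files
        for name in golden_files:
            with open(os.path.join(golden_root, name)) as fh:
                assert pkg.files[name] == fh.read(), f"drift in {name}"


class TestExecutionAgreement:
    def test_host_package_reproduces_in_process_simulation(self, toy, tmp_path):
        pkg = generate_package(toy, "python", tmp_path)
        pkg_dir = tmp_path / "python"
        proc = subprocess.run(
            ["python", pkg.entry_point], cwd=pkg_dir, capture_output=True, text=True
        )
        assert proc.returncode == 0, proc.stderr
        header, data = _read_csv(pkg_dir / "ConstrainedToy_trajectory.csv")
        want_header, want = _in_process_matrix(toy)
        assert header == want_header
        assert np.max(np.abs(data - want)) <= 1e-12

    def test_r_package_reproduces_in_process_simulation(self, toy, tmp_path):
        pkg = generate_package(toy, "r", tmp_path)
        pkg_dir = tmp_path / "r"
        proc = subprocess.run(
            ["Rscript", "--vanilla", pkg.entry_point],
            cwd=pkg_dir, capture_output=True, text=True,
        )
        assert proc.returncode == 0, proc.stderr
        header, data = _read_csv(pkg_dir / "ConstrainedToy_trajectory.csv")
        want_header, want = _in_process_matrix(toy)
        assert header == want_header
        assert np.max(np.abs(data - want)) <= 1e-12

    def test_host_autotester_refuses_violating_default(self, toy, tmp_path):
        import copy

        spec = copy.deepcopy(toy)
        spec.configurations[0].overrides = {"k": -2.0}
        pkg = generate_package(spec, "python", tmp_path)
        proc = subprocess.run(
            ["python", pkg.entry_point], cwd=tmp_path / "python",
            capture_output=True, text=True,
        )
        assert proc.returncode == 3
        assert "101" in proc.stdout
        assert not (tmp_path / "python" / "ConstrainedToy_trajectory.csv").exists()


class TestDatFiles:
    def test_record_counts_match_spec(self, any_fixture, tmp_path):
        write_dat_files(any_fixture, tmp_path)
        modpars, variables = read_dat_files(tmp_path, any_fixture.meta.project_name)
        assert len(modpars) == len(any_fixture.parameters)
        assert len(variables) == len(any_fixture.variables)

    def test_round_trip_fields(self, two_lovers, tmp_path):
        write_dat_files(two_lovers, tmp_path)
        modpars, variables = read_dat_files(tmp_path, "TwoLovers")
        by_name = {r["Name"]: r for r in modpars}
        assert by_name["a"]["Kind"] == "free"
        assert float(by_name["a"]["ValueOrDefinition"]) == -0.2
        assert by_name["CouplingGain"]["Kind"] == "determined"
        assert by_name["CouplingGain"]["ValueOrDefinition"] == "b * c"
        vr = {r["Name"]: r for r in variables}
        assert vr["R"]["InitialCondition"] == "R0"
        assert vr["TotalAffection"]["Kind"] == "algebraic"

    def test_empty_parameter_list_gives_header_only(self, tmp_path):
        spec = ModelSpec(
            meta=ModelMeta(project_name="Bare"),
            variables=[VariableDef(name="X", kind="state",
                                   defining_expression="0", initial_condition="1")],
        )
        modpars_path, _ = write_dat_files(spec, tmp_path)
        with open(modpars_path) as fh:
            lines = fh.read().splitlines()
        assert len(lines) == 1 and lines[0].startswith("Name\t")
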