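"""Reading and writing model-specification workbooks.

A model workbook has 11 obligatory sheets — Titles, Variables, Parameters,
Constraints, Configurations, LaTeX controls, four dialect special-code
sheets and GeneralControls — plus the auxiliary ``Instructions`` and
``NotesToDo`` sheets and any number of ignored "support" sheets.  Both
OpenDocument (.ods) and Office Open XML (.xlsx) containers are accepted on
read and producible on write; sheet lookup keys on the leading integer
prefix of the sheet name, so ``2-Variables`` and ``2-Variable`` are the same
sheet.  Cell colours (yellow fill-in cells, purple determined-parameter
rows) are written as decoration but never read as data.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

from . import _ods
from .dialects import DEFAULT_DIALECTS, SHEET_DIALECT_IDS, DialectTable
from .model import (
    OBLIGATORY_SHEETS,
    ConfigurationDef,
    ConstraintDef,
    FigureEntry,
    GeneralControls,
    LatexControls,
    ModelMeta,
    ModelSpec,
    ParameterDef,
    VariableDef,
)

SHEET_INSTRUCTIONS = "Instructions"
SHEET_NOTES = "NotesToDo"


class WorkbookError(ValueError):
    """Structural problem with a workbook file (missing sheet/column, bad cell)."""


@dataclass(frozen=True)
class SheetSchema:
    """Layout of one obligatory sheet: its index, canonical name, header row
    and a one-line description of what each data row holds."""

    index: int
    canonical_name: str
    required_columns: tuple[str, ...]
    row_semantics: str


SHEET_SCHEMAS: tuple[SheetSchema, ...] = (
    SheetSchema(1, OBLIGATORY_SHEETS[0], ("Field", "Value"),
                "one metadata field per row; Changelog rows repeat"),
    SheetSchema(2, OBLIGATORY_SHEETS[1],
                ("Name", "Unit", "Description", "Min", "Max", "Kind",
                 "Definition", "InitialCondition", "LatexName"),
                "one model variable per row (state or algebraic)"),
    SheetSchema(3, OBLIGATORY_SHEETS[2],
                ("Name", "Unit", "Description", "Kind", "ReferenceValue",
                 "Min", "Max", "Definition", "LatexName"),
                "one parameter per row (free or determined)"),
    SheetSchema(4, OBLIGATORY_SHEETS[3], ("Predicate", "ErrorCode", "LatexText"),
                "one parameter constraint per row"),
    SheetSchema(5, OBLIGATORY_SHEETS[4], ("Configuration", "Parameter", "Value"),
                "one free-parameter override per row; a name-only row declares "
                "an empty configuration"),
    SheetSchema(6, OBLIGATORY_SHEETS[5], ("Setting", "Value", "Caption", "Label"),
                "TabLength/NameLength settings and one Figure row per figure"),
    SheetSchema(7, OBLIGATORY_SHEETS[6], ("Pseudocode", "Target"),
                "C++ spellings of pseudocode builtins and operators"),
    SheetSchema(8, OBLIGATORY_SHEETS[7], ("Pseudocode", "Target"),
                "Matlab spellings of pseudocode builtins and operators"),
    SheetSchema(9, OBLIGATORY_SHEETS[8], ("Pseudocode", "Target"),
                "R spellings of pseudocode builtins and operators"),
    SheetSchema(10, OBLIGATORY_SHEETS[9], ("Pseudocode", "Target"),
                "Julia spellings of pseudocode builtins and operators"),
    SheetSchema(11, OBLIGATORY_SHEETS[10], ("Setting", "Value"),
                "time grid, default display variables and default data sets"),
)

_SCHEMA_BY_INDEX = {s.index: s for s in SHEET_SCHEMAS}
_DIALECT_SHEET_INDEX = dict(zip((7, 8, 9, 10), SHEET_DIALECT_IDS))

_META_FIELDS = {
    "projectname": "project_name",
    "modelversion": "model_version",
    "implementationsubversion": "implementation_subversion",
    "editionsubsubversion": "edition_subsubversion",
    "dates": "dates",
}


# ---------------------------------------------------------------------------
# container dispatch


def _load_grids(path) -> dict[str, list[list]]:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".ods":
        return _ods.read_ods(path)
    if ext == ".xlsx":
        return _read_xlsx(path)
    raise WorkbookError(f"unsupported workbook format {ext!r} (use .ods or .xlsx)")


def _save_grids(path, sheets: dict[str, list[list]], styles: dict) -> None:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".ods":
        _ods.write_ods(path, sheets, styles)
    elif ext == ".xlsx":
        _write_xlsx(path, sheets, styles)
    else:
        raise WorkbookError(f"unsupported workbook format {ext!r} (use .ods or .xlsx)")


def _read_xlsx(path) -> dict[str, list[list]]:
    import openpyxl

    wb = openpyxl.load_workbook(path, data_only=True, read_only=True)
    sheets: dict[str, list[list]] = {}
    for ws in wb.worksheets:
        rows: list[list] = []
        for row in ws.iter_rows(values_only=True):
            cells = [
                (float(v) if isinstance(v, (int, float)) and not isinstance(v, bool) else v)
                for v in row
            ]
            while cells and cells[-1] is None:
                cells.pop()
            rows.append(cells)
        while rows and not rows[-1]:
            rows.pop()
        sheets[ws.title] = rows
    wb.close()
    return sheets


_XLSX_FILLS = {"yellow": "FFFFFF00", "purple": "FFCC99FF"}


def _write_xlsx(path, sheets: dict[str, list[list]], styles: dict) -> None:
    import openpyxl
    from openpyxl.styles import PatternFill

    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    fills = {
        k: PatternFill(start_color=v, end_color=v, fill_type="solid")
        for k, v in _XLSX_FILLS.items()
    }
    for name, rows in sheets.items():
        ws = wb.create_sheet(title=name[:31])
        for r, row in enumerate(rows):
            for c, value in enumerate(row):
                if value is None:
                    cell = ws.cell(row=r + 1, column=c + 1)
                else:
                    cell = ws.cell(row=r + 1, column=c + 1, value=value)
                colour = styles.get((name, r, c))
                if colour in fills:
                    cell.fill = fills[colour]
    wb.save(path)


# ---------------------------------------------------------------------------
# grid-level helpers


def _norm(text) -> str:
    return "".join(ch for ch in str(text).lower() if ch.isalnum())


def _sheet_index(name: str) -> int | None:
    digits = ""
    for ch in str(name):
        if ch.isdigit():
            digits += ch
        else:
            break
    return int(digits) if digits else None


def _locate_sheets(grids: dict[str, list[list]]) -> dict[int, tuple[str, list[list]]]:
    located: dict[int, tuple[str, list[list]]] = {}
    for name, rows in grids.items():
        idx = _sheet_index(name)
        if idx in _SCHEMA_BY_INDEX and idx not in located:
            located[idx] = (name, rows)
    missing = [
        f"{s.index} ({s.canonical_name})"
        for s in SHEET_SCHEMAS
        if s.index not in located
    ]
    if missing:
        raise WorkbookError("missing obligatory sheet(s): " + ", ".join(missing))
    return located


def _header_map(schema: SheetSchema, sheet_name: str, rows: list[list]) -> dict[str, int]:
    if not rows:
        raise WorkbookError(f"sheet '{sheet_name}' is empty (header row required)")
    header = rows[0]
    positions = {_norm(h): i for i, h in enumerate(header) if h is not None}
    out: dict[str, int] = {}
    for col in schema.required_columns:
        key = _norm(col)
        if key not in positions:
            raise WorkbookError(f"sheet '{sheet_name}' is missing required column '{col}'")
        out[col] = positions[key]
    return out


def _cell(row: list, idx: int):
    if idx < len(row):
        value = row[idx]
        if isinstance(value, str):
            value = value.strip()
            return value if value != "" else None
        return value
    return None


def _text(row: list, idx: int) -> str | None:
    value = _cell(row, idx)
    if value is None:
        return None
    if isinstance(value, float):
        return f"{int(value)}" if value == int(value) else repr(value)
    return str(value)


def _number(row, idx, sheet, rownum, col) -> float | None:
    value = _cell(row, idx)
    if value is None:
        return None
    if isinstance(value, float):
        return value
    try:
        return float(str(value).strip())
    except ValueError:
        raise WorkbookError(
            f"sheet '{sheet}', row {rownum}, column '{col}': "
            f"expected a number, found {value!r}"
        )


def _integer(row, idx, sheet, rownum, col) -> int | None:
    value = _number(row, idx, sheet, rownum, col)
    if value is None:
        return None
    if not math.isclose(value, round(value)):
        raise WorkbookError(
            f"sheet '{sheet}', row {rownum}, column '{col}': "
            f"expected an integer, found {value!r}"
        )
    return int(round(value))


def _data_rows(rows: list[list]):
    """(1-based row number, row) for non-blank rows below the header."""
    for i, row in enumerate(rows[1:], start=2):
        if any(_cell(row, j) is not None for j in range(len(row))):
            yield i, row


# ---------------------------------------------------------------------------
# read


def read_workbook(path) -> ModelSpec:
    """Read a model workbook (.ods or .xlsx) into a :class:`ModelSpec`.

    Raises :class:`WorkbookError` for structural problems: unreadable file,
    missing obligatory sheet, missing required column, or non-numeric text
    in a numeric column (always naming sheet/row/column).  Semantic problems
    are left to ``validate_spec``.
    """
    if not os.path.exists(str(path)):
        raise WorkbookError(f"workbook not found: {path}")
    try:
        grids = _load_grids(path)
    except WorkbookError:
        raise
    except Exception as exc:
        raise WorkbookError(f"cannot read workbook {path}: {exc}")
    located = _locate_sheets(grids)

    meta = _decode_titles(*located[1])
    variables = _decode_variables(*located[2])
    parameters = _decode_parameters(*located[3])
    constraints = _decode_constraints(*located[4])
    configurations = _decode_configurations(*located[5])
    latex_controls = _decode_latex_controls(*located[6])
    dialects = [
        _decode_dialect(_DIALECT_SHEET_INDEX[i], *located[i]) for i in (7, 8, 9, 10)
    ]
    general_controls = _decode_general_controls(*located[11])

    notes = ""
    for name, rows in grids.items():
        if _norm(name) == _norm(SHEET_NOTES):
            lines = []
            for _, row in _data_rows([[""]] + rows):  # treat all rows as data
                lines.extend(str(v) for v in row if v is not None)
            notes = "\n".join(lines)
    return ModelSpec(
        meta=meta,
        variables=variables,
        parameters=parameters,
        constraints=constraints,
        configurations=configurations,
        dialects=dialects,
        latex_controls=latex_controls,
        general_controls=general_controls,
        notes=notes,
    )


def _decode_titles(sheet, rows) -> ModelMeta:
    cols = _header_map(_SCHEMA_BY_INDEX[1], sheet, rows)
    meta = ModelMeta(project_name="")
    for rownum, row in _data_rows(rows):
        field = _text(row, cols["Field"])
        if field is None:
            continue
        key = _norm(field)
        if key in ("modelversion", "implementationsubversion", "editionsubsubversion"):
            value = _integer(row, cols["Value"], sheet, rownum, "Value")
            setattr(meta, _META_FIELDS[key], value if value is not None else 0)
        elif key in _META_FIELDS:
            setattr(meta, _META_FIELDS[key], _text(row, cols["Value"]) or "")
        elif key == "changelog":
            entry = _text(row, cols["Value"])
            if entry:
                meta.changelog.append(entry)
        # unknown fields are maintenance rows; ignored
    return meta


def _decode_variables(sheet, rows) -> list[VariableDef]:
    cols = _header_map(_SCHEMA_BY_INDEX[2], sheet, rows)
    out = []
    for rownum, row in _data_rows(rows):
        name = _text(row, cols["Name"])
        if name is None:
            continue
        out.append(
            VariableDef(
                name=name,
                unit=_text(row, cols["Unit"]) or "",
                description=_text(row, cols["Description"]) or "",
                range_min=_number(row, cols["Min"], sheet, rownum, "Min"),
                range_max=_number(row, cols["Max"], sheet, rownum, "Max"),
                kind=(_text(row, cols["Kind"]) or "").lower(),
                defining_expression=_text(row, cols["Definition"]) or "",
                initial_condition=_text(row, cols["InitialCondition"]),
                latex_name=_text(row, cols["LatexName"]) or "",
            )
        )
    return out


def _decode_parameters(sheet, rows) -> list[ParameterDef]:
    cols = _header_map(_SCHEMA_BY_INDEX[3], sheet, rows)
    out = []
    for rownum, row in _data_rows(rows):
        name = _text(row, cols["Name"])
        if name is None:
            continue
        out.append(
            ParameterDef(
                name=name,
                unit=_text(row, cols["Unit"]) or "",
                description=_text(row, cols["Description"]) or "",
                kind=(_text(row, cols["Kind"]) or "").lower(),
                reference_value=_number(row, cols["ReferenceValue"], sheet, rownum, "ReferenceValue"),
                min_admissible=_number(row, cols["Min"], sheet, rownum, "Min"),
                max_admissible=_number(row, cols["Max"], sheet, rownum, "Max"),
                defining_expression=_text(row, cols["Definition"]),
                latex_name=_text(row, cols["LatexName"]) or "",
            )
        )
    return out


def _decode_constraints(sheet, rows) -> list[ConstraintDef]:
    cols = _header_map(_SCHEMA_BY_INDEX[4], sheet, rows)
    out = []
    for rownum, row in _data_rows(rows):
        predicate = _text(row, cols["Predicate"])
        if predicate is None:
            continue
        code = _integer(row, cols["ErrorCode"], sheet, rownum, "ErrorCode")
        if code is None:
            raise WorkbookError(
                f"sheet '{sheet}', row {rownum}: constraint is missing its error code"
            )
        out.append(
            ConstraintDef(
                predicate=predicate,
                error_code=code,
                latex_text=_text(row, cols["LatexText"]) or "",
            )
        )
    return out


def _decode_configurations(sheet, rows) -> list[ConfigurationDef]:
    cols = _header_map(_SCHEMA_BY_INDEX[5], sheet, rows)
    order: list[str] = []
    overrides: dict[str, dict[str, float]] = {}
    for rownum, row in _data_rows(rows):
        cname = _text(row, cols["Configuration"])
        if cname is None:
            continue
        if cname not in overrides:
            overrides[cname] = {}
            order.append(cname)
        pname = _text(row, cols["Parameter"])
        if pname is not None:
            value = _number(row, cols["Value"], sheet, rownum, "Value")
            if value is None:
                raise WorkbookError(
                    f"sheet '{sheet}', row {rownum}: override of '{pname}' has no value"
                )
            overrides[cname][pname] = value
    return [ConfigurationDef(name, overrides[name]) for name in order]


def _decode_latex_controls(sheet, rows) -> LatexControls:
    cols = _header_map(_SCHEMA_BY_INDEX[6], sheet, rows)
    lc = LatexControls()
    for rownum, row in _data_rows(rows):
        setting = _norm(_text(row, cols["Setting"]) or "")
        if setting == "tablength":
            lc.table_cell_length = _text(row, cols["Value"]) or lc.table_cell_length
        elif setting == "namelength":
            lc.name_column_length = _text(row, cols["Value"]) or lc.name_column_length
        elif setting == "figure":
            file_name = _text(row, cols["Value"])
            if file_name:
                lc.figure_entries.append(
                    FigureEntry(
                        file_name=file_name,
                        caption=_text(row, cols["Caption"]) or "",
                        label=_text(row, cols["Label"]) or "",
                    )
                )
    return lc


def _decode_dialect(dialect_id: str, sheet, rows) -> DialectTable:
    schema = _SCHEMA_BY_INDEX[{v: k for k, v in _DIALECT_SHEET_INDEX.items()}[dialect_id]]
    cols = _header_map(schema, sheet, rows)
    entries: dict[str, str] = {}
    for _, row in _data_rows(rows):
        key = _text(row, cols["Pseudocode"])
        target = _text(row, cols["Target"])
        if key is not None and target is not None:
            entries[key] = target
    return DEFAULT_DIALECTS[dialect_id].with_overrides(entries)


def _decode_general_controls(sheet, rows) -> GeneralControls:
    cols = _header_map(_SCHEMA_BY_INDEX[11], sheet, rows)
    gc = GeneralControls(default_display_variables=[], default_datasets=[])
    for rownum, row in _data_rows(rows):
        setting = _norm(_text(row, cols["Setting"]) or "")
        if setting == "tstart":
            value = _number(row, cols["Value"], sheet, rownum, "Value")
            gc.t_start = value if value is not None else gc.t_start
        elif setting == "tend":
            value = _number(row, cols["Value"], sheet, rownum, "Value")
            gc.t_end = value if value is not None else gc.t_end
        elif setting == "tstep":
            value = _number(row, cols["Value"], sheet, rownum, "Value")
            gc.t_step = value if value is not None else gc.t_step
        elif setting == "displayvariable":
            name = _text(row, cols["Value"])
            if name:
                gc.default_display_variables.append(name)
        elif setting == "defaultdataset":
            name = _text(row, cols["Value"])
            if name:
                gc.default_datasets.append(name)
        elif setting:
            raise WorkbookError(
                f"sheet '{sheet}', row {rownum}: unknown setting {setting!r}"
            )
    return gc


# ---------------------------------------------------------------------------
# write


def write_workbook(spec: ModelSpec, path) -> str:
    """Write ``spec`` to ``path`` (.ods or .xlsx).

    Round-trip contract: ``read_workbook(write_workbook(spec, p))`` equals
    ``spec`` on all model-content fields; styling (yellow fill-in cells,
    purple determined-parameter rows) is decoration only.
    """
    sheets, styles = _encode(spec)
    _save_grids(path, sheets, styles)
    return str(path)


def _encode(spec: ModelSpec) -> tuple[dict[str, list[list]], dict]:
    sheets: dict[str, list[list]] = {}
    styles: dict = {}

    def add(schema_idx: int, rows: list[list], yellow_cols=None, purple_rows=()):
        name = _SCHEMA_BY_INDEX[schema_idx].canonical_name
        header = list(_SCHEMA_BY_INDEX[schema_idx].required_columns)
        grid = [header] + rows
        sheets[name] = grid
        for r in range(1, len(grid)):
            for c in range(len(grid[r])):
                if r in purple_rows:
                    styles[(name, r, c)] = "purple"
                elif yellow_cols is None or c in yellow_cols:
                    styles[(name, r, c)] = "yellow"
        return name

    meta = spec.meta
    add(1, [
        ["ProjectName", meta.project_name],
        ["ModelVersion", float(meta.model_version)],
        ["ImplementationSubversion", float(meta.implementation_subversion)],
        ["EditionSubsubversion", float(meta.edition_subsubversion)],
        ["Dates", meta.dates or None],
        *[["Changelog", entry] for entry in meta.changelog],
    ])

    add(2, [
        [v.name, v.unit or None, v.description or None, v.range_min, v.range_max,
         v.kind, v.defining_expression, v.initial_condition, v.latex_name or None]
        for v in spec.variables
    ])

    param_rows = [
        [p.name, p.unit or None, p.description or None, p.kind, p.reference_value,
         p.min_admissible, p.max_admissible, p.defining_expression, p.latex_name or None]
        for p in spec.parameters
    ]
    add(3, param_rows,
        purple_rows={i + 1 for i, p in enumerate(spec.parameters) if p.kind == "determined"})

    add(4, [[c.predicate, float(c.error_code), c.latex_text or None] for c in spec.constraints])

    config_rows: list[list] = []
    for cfg in spec.configurations:
        if not cfg.overrides:
            config_rows.append([cfg.name, None, None])
        for pname, value in cfg.overrides.items():
            config_rows.append([cfg.name, pname, float(value)])
    add(5, config_rows)

    lc = spec.latex_controls
    latex_rows: list[list] = [
        ["TabLength", lc.table_cell_length, None, None],
        ["NameLength", lc.name_column_length, None, None],
    ]
    for f in lc.figure_entries:
        latex_rows.append(["Figure", f.file_name, f.caption or None, f.label or None])
    add(6, latex_rows)

    for idx, dialect_id in _DIALECT_SHEET_INDEX.items():
        table = spec.dialect_map.get(dialect_id, DEFAULT_DIALECTS[dialect_id])
        add(idx, _encode_dialect_rows(table))

    gc = spec.general_controls
    gc_rows: list[list] = [
        ["TStart", gc.t_start],
        ["TEnd", gc.t_end],
        ["TStep", gc.t_step],
    ]
    gc_rows += [["DisplayVariable", name] for name in gc.default_display_variables]
    gc_rows += [["DefaultDataset", name] for name in gc.default_datasets]
    add(11, gc_rows)

    sheets[SHEET_INSTRUCTIONS] = _INSTRUCTION_ROWS
    sheets[SHEET_NOTES] = [[line] for line in spec.notes.splitlines()] if spec.notes else []
    return sheets, styles


def _encode_dialect_rows(table: DialectTable) -> list[list]:
    rows: list[list] = [[k, v] for k, v in table.function_map.items()]
    rows += [
        ["^", table.power_template],
        ["and", table.and_template],
        ["or", table.or_template],
        ["not", table.not_template],
        ["If", table.if_template],
        ["==", table.eq_op],
        ["!=", table.ne_op],
        ["assign", table.assign_op],
        ["true", table.true_literal],
        ["false", table.false_literal],
        ["comment", table.comment_prefix],
        ["extension", table.source_extension],
    ]
    return rows


_INSTRUCTION_ROWS = [
    ["How to fill in this model specification workbook"],
    ["Fill only the yellow cells; every sheet must be completed."],
    ["Variables: one row per variable. Kind 'state' rows give a derivative"],
    ["  in the Definition column and require an InitialCondition; kind"],
    ["  'algebraic' rows give a closed-form Definition and no initial condition."],
    ["Parameters: kind 'free' rows carry a ReferenceValue (overridable per"],
    ["  configuration); kind 'determined' rows carry a Definition computed"],
    ["  from other parameters and are shown purple."],
    ["Pseudocode: infix arithmetic with ^ for power, builtins such as Exp,"],
    ["  Ln, Sqrt, Abs, Min, Max, Step, RandUnif(), and the time symbol t."],
    ["  The If(cond, then, else) conditional and the and/or/not logicals are"],
    ["  extensions of this implementation beyond the original pseudocode."],
    ["Constraints: predicates over parameters with a numeric error code each."],
    ["Configurations: one override per row; 'Default' uses reference values."],
]


def write_template(path, project_name: str = "NewProject") -> str:
    """Write a blank workbook: the 11 obligatory sheets with their header
    rows plus Instructions and NotesToDo, fill-in cells styled yellow.

    Re-reading the template yields a structurally valid empty spec (only
    "empty model" validation diagnostics, no structural errors).
    """
    spec = ModelSpec(meta=ModelMeta(project_name=project_name))
    spec.dialects = [DEFAULT_DIALECTS[d] for d in SHEET_DIALECT_IDS]
    spec.configurations = [ConfigurationDef("Default", {})]
    sheets, styles = _encode(spec)
    _save_grids(path, sheets, styles)
    return str(path)
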