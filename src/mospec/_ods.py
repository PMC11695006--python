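"""Minimal OpenDocument Spreadsheet (.ods) read/write backend.

Implements just the slice of the OpenDocument format the workbook layer
needs: named sheets holding float and string cells, with optional cell
background colours on write.  Cell values are the only thing read back —
styling is write-only decoration and never carries semantics.

Sheets are exchanged as ``dict[name -> rows]`` where each row is a list of
``None | float | str``.
"""

from __future__ import annotations

import zipfile
from xml.etree import ElementTree as ET
from xml.sax.saxutils import escape

NS = {
    "office": "urn:oasis:names:tc:opendocument:xmlns:office:1.0",
    "table": "urn:oasis:names:tc:opendocument:xmlns:table:1.0",
    "text": "urn:oasis:names:tc:opendocument:xmlns:text:1.0",
    "style": "urn:oasis:names:tc:opendocument:xmlns:style:1.0",
    "fo": "urn:oasis:names:tc:opendocument:xmlns:xsl-fo-compatible:1.0",
}

MIMETYPE = "application/vnd.oasis.opendocument.spreadsheet"

_MANIFEST = """<?xml version="1.0" encoding="UTF-8"?>
<manifest:manifest xmlns:manifest="urn:oasis:names:tc:opendocument:xmlns:manifest:1.0" manifest:version="1.2">
 <manifest:file-entry manifest:full-path="/" manifest:media-type="application/vnd.oasis.opendocument.spreadsheet"/>
 <manifest:file-entry manifest:full-path="content.xml" manifest:media-type="text/xml"/>
 <manifest:file-entry manifest:full-path="styles.xml" manifest:media-type="text/xml"/>
</manifest:manifest>
"""

_STYLES = """<?xml version="1.0" encoding="UTF-8"?>
<office:document-styles xmlns:office="urn:oasis:names:tc:opendocument:xmlns:office:1.0" office:version="1.2"/>
"""

_CONTENT_HEAD = (
    '<?xml version="1.0" encoding="UTF-8"?>\n'
    "<office:document-content "
    'xmlns:office="urn:oasis:names:tc:opendocument:xmlns:office:1.0" '
    'xmlns:table="urn:oasis:names:tc:opendocument:xmlns:table:1.0" '
    'xmlns:text="urn:oasis:names:tc:opendocument:xmlns:text:1.0" '
    'xmlns:style="urn:oasis:names:tc:opendocument:xmlns:style:1.0" '
    'xmlns:fo="urn:oasis:names:tc:opendocument:xmlns:xsl-fo-compatible:1.0" '
    'office:version="1.2">\n'
    "<office:automatic-styles>\n"
    '<style:style style:name="ceYellow" style:family="table-cell">'
    '<style:table-cell-properties fo:background-color="#ffff00"/></style:style>\n'
    '<style:style style:name="cePurple" style:family="table-cell">'
    '<style:table-cell-properties fo:background-color="#cc99ff"/></style:style>\n'
    "</office:automatic-styles>\n"
    "<office:body><office:spreadsheet>\n"
)

_CONTENT_TAIL = "</office:spreadsheet></office:body></office:document-content>\n"

_STYLE_NAMES = {"yellow": "ceYellow", "purple": "cePurple"}


def write_ods(path, sheets: dict[str, list[list]], styles: dict | None = None) -> None:
    """Write ``sheets`` to ``path``.

    ``styles`` optionally maps ``(sheet_name, row_idx, col_idx)`` (0-based)
    to ``"yellow"`` or ``"purple"`` cell backgrounds.
    """
    styles = styles or {}
    parts = [_CONTENT_HEAD]
    for name, rows in sheets.items():
        parts.append(f'<table:table table:name="{escape(name, {chr(34): "&quot;"})}">\n')
        for r, row in enumerate(rows):
            parts.append("<table:table-row>")
            for c, value in enumerate(row):
                style = _STYLE_NAMES.get(styles.get((name, r, c), ""))
                style_attr = f' table:style-name="{style}"' if style else ""
                if value is None:
                    parts.append(f"<table:table-cell{style_attr}/>")
                elif isinstance(value, (int, float)) and not isinstance(value, bool):
                    parts.append(
                        f'<table:table-cell{style_attr} office:value-type="float" '
                        f'office:value="{float(value):.17g}">'
                        f"<text:p>{float(value):.17g}</text:p></table:table-cell>"
                    )
                else:
                    parts.append(
                        f'<table:table-cell{style_attr} office:value-type="string">'
                        f"<text:p>{escape(str(value))}</text:p></table:table-cell>"
                    )
            parts.append("</table:table-row>\n")
        parts.append("</table:table>\n")
    parts.append(_CONTENT_TAIL)
    content = "".join(parts)

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        # mimetype must be first and stored uncompressed per the OD spec
        zf.writestr(
            zipfile.ZipInfo("mimetype"), MIMETYPE, compress_type=zipfile.ZIP_STORED
        )
        zf.writestr("META-INF/manifest.xml", _MANIFEST)
        zf.writestr("styles.xml", _STYLES)
        zf.writestr("content.xml", content)


def read_ods(path) -> dict[str, list[list]]:
    """Read all sheets of an .ods file as value grids (None | float | str)."""
    with zipfile.ZipFile(path) as zf:
        root = ET.fromstring(zf.read("content.xml"))
    sheets: dict[str, list[list]] = {}
    for table in root.iter(f"{{{NS['table']}}}table"):
        name = table.get(f"{{{NS['table']}}}name", "")
        rows: list[list] = []
        for row_el in table.iter(f"{{{NS['table']}}}table-row"):
            repeat = int(row_el.get(f"{{{NS['table']}}}number-rows-repeated", "1"))
            cells = _read_row(row_el)
            # huge trailing repeats (full-sheet padding) carry no content
            if repeat > 1 and any(v is not None for v in cells):
                rows.extend([list(cells) for _ in range(min(repeat, 10000))])
            else:
                rows.append(cells)
        # drop trailing fully-blank rows
        while rows and all(v is None for v in rows[-1]):
            rows.pop()
        sheets[name] = rows
    return sheets


def _read_row(row_el) -> list:
    cells: list = []
    for cell in row_el:
        tag = cell.tag.rsplit("}", 1)[-1]
        if tag not in ("table-cell", "covered-table-cell"):
            continue
        repeat = int(cell.get(f"{{{NS['table']}}}number-columns-repeated", "1"))
        value = _cell_value(cell) if tag == "table-cell" else None
        if value is None and repeat > 100:
            repeat = 1  # full-width blank padding emitted by office suites
        cells.extend([value] * max(repeat, 1))
    while cells and cells[-1] is None:
        cells.pop()
    return cells


def _cell_value(cell):
    vtype = cell.get(f"{{{NS['office']}}}value-type")
    if vtype in ("float", "percentage", "currency"):
        return float(cell.get(f"{{{NS['office']}}}value"))
    text_parts = []
    for p in cell.iter(f"{{{NS['text']}}}p"):
        text_parts.append("".join(p.itertext()))
    text = "\n".join(text_parts)
    return text if text != "" else None
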