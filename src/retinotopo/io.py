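"""Readers and writers for the on-disk formats.

One retina is two text files:

* geometry JSON — ``{"contour": [[x, y], ...], "on_center": [x, y],
  "eye_side": "left"|"right", "strain": "..."}`` (mm);
* cell CSV — header ``cell_id,x_mm,y_mm,layer,melanopsin,brn3a,ohst,soma_wkt``
  with booleans as ``true``/``false`` and the optional soma outline as a WKT
  POLYGON string in its local µm frame.

Reading validates the data contract (schema, boolean parsing, layer labels,
cells inside the contour) and reports offenders with CSV line numbers.
Writing is deterministic: fixed float formatting and ``\\n`` newlines, so the
same table always serialises to identical bytes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.wkt

from .errors import DataError
from .geometry import CellTable, Layer, RetinaGeometry

logger = logging.getLogger(__name__)

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def write_geometry(geometry: RetinaGeometry, path) -> None:
    doc = {
        "contour": [[round(float(x), 6), round(float(y), 6)] for x, y in geometry.contour],
        "on_center": [round(float(v), 6) for v in geometry.on_center],
        "eye_side": geometry.eye_side,
        "strain": geometry.strain,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_geometry(path) -> RetinaGeometry:
    doc = json.loads(Path(path).read_text())
    try:
        return RetinaGeometry(
            np.asarray(doc["contour"], dtype=float),
            np.asarray(doc["on_center"], dtype=float),
            eye_side=doc.get("eye_side"),
            strain=doc.get("strain", ""),
        )
    except KeyError as exc:
        raise DataError(f"geometry JSON missing field {exc}") from exc


def _soma_to_wkt(soma) -> str:
    if soma is None:
        return ""
    ring = np.vstack([soma, soma[:1]])
    coords = ", ".join(f"{x:.4f} {y:.4f}" for x, y in ring)
    return f"POLYGON (({coords}))"


def _soma_from_wkt(text: str):
    if not text:
        return None
    geom = shapely.wkt.loads(text)
    return np.asarray(geom.exterior.coords)[:-1]


def write_cells(table: CellTable, path) -> None:
    """Serialise a cell table to CSV (deterministic byte layout)."""
    lines = ["cell_id,x_mm,y_mm,layer,melanopsin,brn3a,ohst,soma_wkt"]
    for row in table.cells.itertuples(index=False):
        wkt = _soma_to_wkt(row.soma)
        soma_field = f'"{wkt}"' if wkt else ""
        lines.append(
            f"{row.cell_id},{row.x_mm:.6f},{row.y_mm:.6f},{row.layer},"
            f"{str(bool(row.melanopsin)).lower()},{str(bool(row.brn3a)).lower()},"
            f"{str(bool(row.ohst)).lower()},{soma_field}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_bool(value: str, line: int, column: str, errors: list[str]) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    errors.append(f"line {line}: non-boolean {column} value {value!r}")
    return False


def read_cells(path, geometry: RetinaGeometry) -> CellTable:
    """Read and validate a cell CSV against its retina geometry.

    Layer labels are trimmed and upper-cased (logged when changed); malformed
    rows are collected and reported together with their line numbers.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["cell_id", "x_mm", "y_mm", "layer", "melanopsin", "brn3a", "ohst", "soma_wkt"]
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")

    errors: list[str] = []
    records = []
    valid_layers = {l.value for l in Layer}
    for i, row in enumerate(raw.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            x, y = float(row.x_mm), float(row.y_mm)
        except ValueError:
            errors.append(f"line {line}: non-numeric coordinates ({row.x_mm!r}, {row.y_mm!r})")
            continue
        layer = str(row.layer).strip().upper()
        if layer != row.layer:
            logger.info("line %d: normalized layer label %r -> %r", line, row.layer, layer)
        if layer not in valid_layers:
            errors.append(f"line {line}: unknown layer {row.layer!r}")
            continue
        try:
            soma = _soma_from_wkt(str(row.soma_wkt).strip())
        except Exception:
            errors.append(f"line {line}: unparsable soma WKT")
            continue
        records.append({
            "cell_id": row.cell_id,
            "x_mm": x,
            "y_mm": y,
            "layer": layer,
            "melanopsin": _parse_bool(row.melanopsin, line, "melanopsin", errors),
            "brn3a": _parse_bool(row.brn3a, line, "brn3a", errors),
            "ohst": _parse_bool(row.ohst, line, "ohst", errors),
            "soma": soma,
        })
    if errors:
        raise DataError(f"{path}: " + "; ".join(errors[:20]))
    df = pd.DataFrame(records, columns=["cell_id", "x_mm", "y_mm", "layer",
                                        "melanopsin", "brn3a", "ohst", "soma"])
    return CellTable(geometry, df, canonical=False)


def load_table(cells_csv, geometry_json) -> CellTable:
    """Convenience loader: geometry JSON + cell CSV -> validated CellTable."""
    return read_cells(cells_csv, read_geometry(geometry_json))


def write_table(table: CellTable, cells_csv, geometry_json) -> None:
    write_geometry(table.retina, geometry_json)
    write_cells(table, cells_csv)


def write_csv_with_provenance(df: pd.DataFrame, path, provenance: dict) -> None:
    """Write a result CSV with the configuration recorded as comment headers."""
    header = "".join(f"# {k}: {v}\n" for k, v in provenance.items())
    Path(path).write_text(header + df.to_csv(index=False))
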