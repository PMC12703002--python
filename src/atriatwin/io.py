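"""File formats: CARP-style .pts/.elem/.lon, ASCII VTU, ECG CSV, JSON reports.

The CARP dialect follows the ecosystem conventions: ``.pts`` holds the node
count then ``x y z`` per line in micrometers; ``.elem`` the element count
then ``Tt n0 n1 n2 n3 region`` (tetrahedra only); ``.lon`` one unit fiber
per element.  Internally everything is millimeters; the conversion happens
at the file boundary.  The VTU writer/reader handles the ASCII
UnstructuredGrid flavour with tetrahedral cells and point/cell data arrays.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import ECG12, LEAD_ORDER
from .mesh import REGION_CODES, REGION_NAMES, LabeledMesh

MM_TO_UM = 1000.0


# ---------------------------------------------------------------------------
# CARP dialect
# ---------------------------------------------------------------------------

def write_carp(mesh: LabeledMesh, basename) -> None:
    """Write ``<basename>.pts/.elem`` (and ``.lon`` when fibers exist)."""
    base = Path(basename)
    pts_um = mesh.points * MM_TO_UM
    with open(base.with_suffix(".pts"), "w") as f:
        f.write(f"{mesh.n_nodes}\n")
        np.savetxt(f, pts_um, fmt="%.6f")
    with open(base.with_suffix(".elem"), "w") as f:
        f.write(f"{mesh.n_tets}\n")
        for tet, lab in zip(mesh.tets, mesh.labels):
            f.write(f"Tt {tet[0]} {tet[1]} {tet[2]} {tet[3]} {lab}\n")
    if mesh.fibers is not None:
        with open(base.with_suffix(".lon"), "w") as f:
            f.write("1\n")
            np.savetxt(f, mesh.fibers, fmt="%.8f")
    with open(base.with_suffix(".labels.json"), "w") as f:
        json.dump(REGION_CODES, f, indent=1)


def read_carp(basename) -> LabeledMesh:
    """Read a CARP ``.pts/.elem`` (+ optional ``.lon``) mesh; mm internally."""
    base = Path(basename)
    with open(base.with_suffix(".pts")) as f:
        n = int(f.readline())
        pts = np.loadtxt(f, max_rows=n).reshape(n, 3) / MM_TO_UM
    tets, labels = [], []
    with open(base.with_suffix(".elem")) as f:
        m = int(f.readline())
        for _ in range(m):
            parts = f.readline().split()
            if parts[0] != "Tt":
                raise ValueError(f"only tetrahedral 'Tt' elements supported, got {parts[0]!r}")
            tets.append([int(x) for x in parts[1:5]])
            labels.append(int(parts[5]))
    tets = np.asarray(tets, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if tets.shape[0] != m:
        raise ValueError("element count mismatch in .elem file")
    if tets.max() >= len(pts):
        raise ValueError("element references a node beyond the .pts count")
    fibers = None
    lon = base.with_suffix(".lon")
    if lon.exists():
        with open(lon) as f:
            f.readline()
            fibers = np.loadtxt(f).reshape(m, -1)[:, :3]
    return LabeledMesh(points=pts, tets=tets, labels=labels, fibers=fibers)


# ---------------------------------------------------------------------------
# ASCII VTU
# ---------------------------------------------------------------------------

def _data_array(name, arr, ncomp):
    flat = np.asarray(arr).reshape(-1)
    body = " ".join(f"{v:.9g}" for v in flat)
    typ = "Int64" if np.issubdtype(np.asarray(arr).dtype, np.integer) else "Float64"
    return (f'<DataArray type="{typ}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">{body}</DataArray>')


def write_vtu(mesh: LabeledMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """ASCII VTU with tetrahedral cells, region labels and optional arrays."""
    point_data = dict(point_data or {})
    cell_data = {"region": mesh.labels, **(cell_data or {})}
    if mesh.fibers is not None:
        cell_data.setdefault("fiber", mesh.fibers)
    n, m = mesh.n_nodes, mesh.n_tets
    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
             "<Points>", _data_array("Points", mesh.points, 3), "</Points>",
             "<Cells>",
             _data_array("connectivity", mesh.tets.astype(np.int64), 1),
             _data_array("offsets", 4 * np.arange(1, m + 1, dtype=np.int64), 1),
             _data_array("types", np.full(m, 10, dtype=np.int64), 1),
             "</Cells>"]
    if point_data:
        parts.append("<PointData>")
        for k, v in point_data.items():
            v = np.asarray(v)
            parts.append(_data_array(k, v, v.shape[1] if v.ndim > 1 else 1))
        parts.append("</PointData>")
    parts.append("<CellData>")
    for k, v in cell_data.items():
        v = np.asarray(v)
        parts.append(_data_array(k, v, v.shape[1] if v.ndim > 1 else 1))
    parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def read_vtu(path):
    """Read an ASCII tetrahedral VTU; returns (LabeledMesh, point_data dict)."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")

    def arr(parent_tag, name, dtype=float):
        for da in piece.find(parent_tag).iter("DataArray"):
            if da.get("Name") == name or (parent_tag == "Points" and name == "Points"):
                ncomp = int(da.get("NumberOfComponents", "1"))
                data = np.fromstring(da.text.strip(), sep=" ", dtype=dtype)
                return data.reshape(-1, ncomp) if ncomp > 1 else data
        raise KeyError(name)

    pts = arr("Points", "Points")
    conn = arr("Cells", "connectivity", dtype=np.int64).reshape(-1, 4)
    types = arr("Cells", "types", dtype=np.int64)
    if not np.all(types == 10):
        raise ValueError("only tetrahedral (type 10) VTU cells are supported")
    cd = piece.find("CellData")
    labels = np.zeros(len(conn), dtype=np.int64)
    fibers = None
    if cd is not None:
        for da in cd.iter("DataArray"):
            if da.get("Name") == "region":
                labels = np.fromstring(da.text.strip(), sep=" ", dtype=np.int64)
            if da.get("Name") == "fiber":
                fibers = np.fromstring(da.text.strip(), sep=" ").reshape(-1, 3)
    pdata = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for da in pd_el.iter("DataArray"):
            ncomp = int(da.get("NumberOfComponents", "1"))
            v = np.fromstring(da.text.strip(), sep=" ")
            pdata[da.get("Name")] = v.reshape(-1, ncomp) if ncomp > 1 else v
    mesh = LabeledMesh(points=pts, tets=conn, labels=labels, fibers=fibers)
    return mesh, pdata


# ---------------------------------------------------------------------------
# ECG CSV and reports
# ---------------------------------------------------------------------------

def write_ecg_csv(ecg: ECG12, path) -> None:
    """CSV with a ``time_ms`` column then the 12 leads in panel order."""
    df = pd.DataFrame({"time_ms": ecg.times})
    for lead in LEAD_ORDER:
        df[lead] = ecg.traces[lead]
    df.to_csv(path, index=False, float_format="%.9g")


def read_ecg_csv(path) -> ECG12:
    df = pd.read_csv(path)
    if "time_ms" not in df.columns:
        raise ValueError("ECG CSV must contain a 'time_ms' column")
    traces = {lead: df[lead].to_numpy(float) for lead in LEAD_ORDER if lead in df}
    missing = [lead for lead in LEAD_ORDER if lead not in traces]
    if missing:
        raise ValueError(f"ECG CSV is missing lead(s) {missing}")
    ecg = ECG12(times=df["time_ms"].to_numpy(float), traces=traces)
    # recover aVR from the stored -aVR panel
    ecg.traces.setdefault("aVR", -ecg.traces["-aVR"])
    return ecg


def write_uac_table(frame, path) -> None:
    """Whitespace table: node_id alpha beta gamma side."""
    n = len(frame.alpha)
    with open(path, "w") as f:
        f.write("# node_id alpha beta gamma side\n")
        for i in range(n):
            f.write(f"{i} {frame.alpha[i]:.8f} {frame.beta[i]:.8f} "
                    f"{frame.gamma[i]:.8f} {int(frame.side[i])}\n")


def write_json_report(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=1, default=_default))
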