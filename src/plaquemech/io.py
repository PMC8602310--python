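"""Mesh exchange in VTK XML unstructured-grid (.vtu) and Gmsh MSH 4.1 format.

Both writers store the tissue label per element — as an integer cell-data
field ``tissue`` in VTU, and as one element block per tissue entity with a
matching physical group in MSH. Floats are printed with 17 significant
digits so a write -> read round trip reproduces coordinates bit-exactly.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET

import numpy as np

from .geometry import LabeledMesh
from .tissues import Tissue

#: VTK cell type codes for the supported elements.
VTK_TRI6 = 22
VTK_TET10 = 24

#: Gmsh element type codes.
MSH_TRI6 = 9
MSH_TET10 = 11

# Gmsh orders the last two midside nodes of a 10-node tet opposite to VTK.
_GMSH_FROM_VTK_TET10 = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_mesh(mesh: LabeledMesh, path: str, format: str | None = None) -> None:
    """Write a labeled mesh; format inferred from the extension if omitted."""
    fmt = format or os.path.splitext(path)[1].lstrip(".")
    if fmt == "vtu":
        write_vtu(mesh, path)
    elif fmt == "msh":
        write_msh(mesh, path)
    else:
        raise ValueError(f"unknown mesh format: {fmt!r} (supported: vtu, msh)")


def read_mesh(path: str, format: str | None = None) -> LabeledMesh:
    """Read a labeled mesh; format inferred from the extension if omitted."""
    fmt = format or os.path.splitext(path)[1].lstrip(".")
    if fmt == "vtu":
        return read_vtu(path)
    if fmt == "msh":
        return read_msh(path)
    raise ValueError(f"unknown mesh format: {fmt!r} (supported: vtu, msh)")


# --------------------------------------------------------------------------
# VTK XML unstructured grid
# --------------------------------------------------------------------------


def write_vtu(mesh: LabeledMesh, path: str) -> None:
    n_nodes, n_el = mesh.n_nodes, mesh.n_elements
    pts3 = np.zeros((n_nodes, 3))
    pts3[:, : mesh.dim] = mesh.coords
    nn = mesh.elements.shape[1]
    ctype = VTK_TRI6 if nn == 6 else VTK_TET10

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<FieldData><DataArray type="Int32" Name="dimension" '
        f'NumberOfTuples="1" format="ascii">{mesh.dim}</DataArray></FieldData>',
        f'<Piece NumberOfPoints="{n_nodes}" NumberOfCells="{n_el}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines.extend(" ".join(_fmt(v) for v in row) for row in pts3)
    lines += [
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
    ]
    lines.extend(" ".join(str(v) for v in row) for row in mesh.elements)
    lines += [
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str(nn * (i + 1)) for i in range(n_el)),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(ctype) for _ in range(n_el)),
        "</DataArray>",
        "</Cells>",
        "<CellData>",
        '<DataArray type="Int32" Name="tissue" format="ascii">',
        " ".join(str(int(v)) for v in mesh.labels),
        "</DataArray>",
        "</CellData>",
        "</Piece>",
        "</UnstructuredGrid>",
        "</VTKFile>",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtu(path: str) -> LabeledMesh:
    root = ET.parse(path).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTU unstructured grid")

    def _array(parent, name=None):
        for da in parent.iter("DataArray"):
            if name is None or da.get("Name") == name:
                return np.fromstring(da.text.replace("\n", " "), sep=" ")
        return None

    pts = _array(piece.find("Points"))
    pts = pts.reshape(-1, 3)
    cells = piece.find("Cells")
    conn = _array(cells, "connectivity").astype(np.int64)
    offsets = _array(cells, "offsets").astype(np.int64)
    nn = int(offsets[0])
    if np.any(np.diff(offsets) != nn) or nn not in (6, 10):
        raise ValueError(f"{path}: only uniform 6-node tri / 10-node tet meshes supported")
    elements = conn.reshape(-1, nn)
    cd = piece.find("CellData")
    labels = _array(cd, "tissue") if cd is not None else None
    if labels is None:
        raise ValueError(f"{path}: missing 'tissue' cell-data field")
    fd = root.find("./UnstructuredGrid/FieldData")
    dim = None
    if fd is not None:
        d = _array(fd, "dimension")
        if d is not None:
            dim = int(d[0])
    if dim is None:
        dim = 2 if nn == 6 else 3
    return LabeledMesh(pts[:, :dim], elements, labels.astype(np.int64))


# --------------------------------------------------------------------------
# Gmsh MSH 4.1 (ascii)
# --------------------------------------------------------------------------


def write_msh(mesh: LabeledMesh, path: str) -> None:
    dim = mesh.dim
    etype = MSH_TRI6 if dim == 2 else MSH_TET10
    present = [Tissue(int(c)) for c in np.unique(mesh.labels)]
    pts3 = np.zeros((mesh.n_nodes, 3))
    pts3[:, :dim] = mesh.coords

    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lines += ["$PhysicalNames", str(len(present))]
    lines += [f'{dim} {int(t)} "{t.label}"' for t in present]
    lines += ["$EndPhysicalNames"]
    # one discrete entity per tissue, tagged by its code, carrying the
    # physical group of the same number
    lines += ["$Entities", f"0 0 {len(present) if dim == 2 else 0} "
              f"{len(present) if dim == 3 else 0}"]
    lo = pts3.min(axis=0)
    hi = pts3.max(axis=0)
    box = " ".join(_fmt(v) for v in (*lo, *hi))
    for t in present:
        lines.append(f"{int(t)} {box} 1 {int(t)}" + (" 0" if dim == 3 else " 0"))
    lines += ["$EndEntities"]

    lines += ["$Nodes", f"1 {mesh.n_nodes} 1 {mesh.n_nodes}",
              f"{dim} {int(present[0])} 0 {mesh.n_nodes}"]
    lines += [str(i + 1) for i in range(mesh.n_nodes)]
    lines += [" ".join(_fmt(v) for v in row) for row in pts3]
    lines += ["$EndNodes"]

    blocks = [(t, np.where(mesh.labels == int(t))[0]) for t in present]
    lines += ["$Elements", f"{len(blocks)} {mesh.n_elements} 1 {mesh.n_elements}"]
    conn = mesh.elements
    if etype == MSH_TET10:
        conn = conn[:, _GMSH_FROM_VTK_TET10]
    # element tag = original element index + 1, so readers can restore order
    for t, idx in blocks:
        lines.append(f"{dim} {int(t)} {etype} {len(idx)}")
        for e in idx:
            lines.append(f"{e + 1} " + " ".join(str(v + 1) for v in conn[e]))
    lines += ["$EndElements"]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path: str) -> LabeledMesh:
    with open(path) as fh:
        text = fh.read()

    def _section(name: str) -> list[str]:
        try:
            body = text.split(f"${name}\n", 1)[1].split(f"$End{name}", 1)[0]
        except IndexError:
            raise ValueError(f"{path}: missing ${name} section") from None
        return body.strip().splitlines()

    node_lines = _section("Nodes")
    n_blocks = int(node_lines[0].split()[0])
    n_nodes = int(node_lines[0].split()[1])
    coords = np.zeros((n_nodes, 3))
    tags = np.zeros(n_nodes, dtype=np.int64)
    row = 1
    seen = 0
    for _ in range(n_blocks):
        nb = int(node_lines[row].split()[3])
        row += 1
        btags = [int(node_lines[row + i]) for i in range(nb)]
        row += nb
        for i in range(nb):
            coords[seen + i] = [float(v) for v in node_lines[row + i].split()]
            tags[seen + i] = btags[i]
        row += nb
        seen += nb
    order = np.argsort(tags)
    coords = coords[order]
    tag_to_idx = {int(t): i for i, t in enumerate(tags[order])}

    el_lines = _section("Elements")
    eb = int(el_lines[0].split()[0])
    row = 1
    elems: list[list[int]] = []
    labels: list[int] = []
    eids: list[int] = []
    etype_seen = None
    for _ in range(eb):
        edim, etag, etype, ne = (int(v) for v in el_lines[row].split())
        row += 1
        if etype not in (MSH_TRI6, MSH_TET10):
            raise ValueError(f"{path}: unsupported element type {etype}")
        etype_seen = etype
        for i in range(ne):
            parts = [int(v) for v in el_lines[row + i].split()]
            eids.append(parts[0])
            elems.append([tag_to_idx[t] for t in parts[1:]])
            labels.append(etag)
        row += ne
    order = np.argsort(np.asarray(eids))
    elements = np.asarray(elems, dtype=np.int64)[order]
    labels = list(np.asarray(labels, dtype=np.int64)[order])
    if etype_seen == MSH_TET10:
        elements = elements[:, _GMSH_FROM_VTK_TET10]
        dim = 3
    else:
        dim = 2
    return LabeledMesh(coords[:, :dim], elements, np.asarray(labels, dtype=np.int64))
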