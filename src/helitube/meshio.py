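"""Mesh export/import: ASCII OFF and PLY plus an edge-attribute sidecar CSV.

OFF/PLY carry vertices and faces only, so edge types and binding states (and
triangle parities, which are recoverable but stored for convenience) travel
in a sidecar CSV with columns ``v_lo, v_hi, type, state``.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .mesh import EDGE_TYPES, MeshError, TriangulatedSheet


def _vertex_table(sheet):
    vids = sorted(sheet.positions)
    index = {v: i for i, v in enumerate(vids)}
    return vids, index


def write_off(sheet: TriangulatedSheet, path):
    vids, index = _vertex_table(sheet)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(vids)} {sheet.n_triangles} {len(sheet.edges)}\n")
        for v in vids:
            x, y, z = sheet.positions[v]
            fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
        for tid in sorted(sheet.triangles):
            a, b, c = (index[w] for w in sheet.triangles[tid])
            fh.write(f"3 {a} {b} {c}\n")


def write_ply(sheet: TriangulatedSheet, path):
    vids, index = _vertex_table(sheet)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(vids)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {sheet.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for v in vids:
            x, y, z = sheet.positions[v]
            fh.write(f"{x:.12g} {y:.12g} {z:.12g}\n")
        for tid in sorted(sheet.triangles):
            a, b, c = (index[w] for w in sheet.triangles[tid])
            fh.write(f"3 {a} {b} {c}\n")


def write_edge_table(sheet: TriangulatedSheet, path):
    """Sidecar CSV: v_lo, v_hi, type, state (vertex ids as exported)."""
    vids, index = _vertex_table(sheet)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["v_lo", "v_hi", "type", "state"])
        for eid in sorted(sheet.edges):
            e = sheet.edges[eid]
            a, b = index[e.u], index[e.v]
            lo, hi = (a, b) if a < b else (b, a)
            w.writerow([lo, hi, e.etype, "bound" if e.bound else "free"])


def export_mesh(sheet: TriangulatedSheet, path):
    """Write OFF or PLY (by extension) plus the ``.edges.csv`` sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".off":
        write_off(sheet, path)
    elif path.suffix.lower() == ".ply":
        write_ply(sheet, path)
    else:
        raise ValueError("mesh path must end in .off or .ply")
    write_edge_table(sheet, path.with_suffix(path.suffix + ".edges.csv"))


def _read_off(path):
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise MeshError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = []
    for _ in range(nv):
        verts.append(tuple(float(x) for x in tokens[pos : pos + 3]))
        pos += 3
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise MeshError("only triangle faces supported")
        faces.append(tuple(int(x) for x in tokens[pos + 1 : pos + 4]))
        pos += 4
    return verts, faces


def _read_ply(path):
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    if lines[0] != "ply":
        raise MeshError("not a PLY file")
    nv = nf = 0
    i = 0
    for i, ln in enumerate(lines):
        if ln.startswith("element vertex"):
            nv = int(ln.split()[-1])
        elif ln.startswith("element face"):
            nf = int(ln.split()[-1])
        elif ln == "end_header":
            break
    body = lines[i + 1 :]
    verts = [tuple(float(x) for x in body[j].split()[:3]) for j in range(nv)]
    faces = []
    for j in range(nv, nv + nf):
        parts = body[j].split()
        if parts[0] != "3":
            raise MeshError("only triangle faces supported")
        faces.append(tuple(int(x) for x in parts[1:4]))
    return verts, faces


def import_mesh(path) -> TriangulatedSheet:
    """Rebuild a sheet from OFF/PLY + sidecar; parities are re-derived by
    two-coloring triangles across the recorded edge types."""
    path = Path(path)
    if path.suffix.lower() == ".off":
        verts, faces = _read_off(path)
    elif path.suffix.lower() == ".ply":
        verts, faces = _read_ply(path)
    else:
        raise ValueError("mesh path must end in .off or .ply")
    etypes = {}
    with open(path.with_suffix(path.suffix + ".edges.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            etypes[(int(row["v_lo"]), int(row["v_hi"]))] = int(row["type"])
    tris = []
    for face in faces:
        tris.append((face, _parity_of(face, etypes)))
    return TriangulatedSheet.from_triangles(verts, tris)


def _parity_of(face, etypes):
    a, b, c = face
    key = (a, b) if a < b else (b, a)
    t_ab = etypes[key]
    for parity in (0, 1):
        if EDGE_TYPES[parity][0] == t_ab:
            # confirm with the second slot
            key_bc = (b, c) if b < c else (c, b)
            if etypes[key_bc] == EDGE_TYPES[parity][1]:
                return parity
    raise MeshError(f"edge types of face {face} match no parity")
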