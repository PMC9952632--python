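"""Plain-text export of meshes, surface fields and polylines.

Writers emit ASCII VTK XML (VTU for volume/surface meshes, VTP for
polylines) and Gmsh MSH 2.2, which any standard reader (ParaView, meshio,
gmsh) parses.  ASCII keeps runs diffable and reproducible; these files are
outputs, never inputs, so no readers are provided.
"""

from __future__ import annotations

import numpy as np

from .meshing import LabeledMesh

_VTK_CELL = {4: 10, 3: 5, 2: 3}  # tet, triangle, line


def _fmt(arr, per_line=6):
    flat = np.asarray(arr).ravel()
    return "\n".join(
        " ".join(f"{v:.10g}" for v in flat[i:i + per_line])
        for i in range(0, len(flat), per_line))


def write_vtu(path, nodes, cells, point_data=None, cell_data=None) -> None:
    """ASCII VTU unstructured grid; data dicts map name -> per-entity array."""
    nodes = np.asarray(nodes, dtype=float)
    if nodes.shape[1] == 2:
        nodes = np.column_stack([nodes, np.zeros(len(nodes))])
    cells = np.asarray(cells)
    n, m = len(nodes), len(cells)
    ctype = _VTK_CELL[cells.shape[1]]

    def data_arrays(data, n_items):
        out = []
        for name, arr in (data or {}).items():
            arr = np.asarray(arr, dtype=float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            out.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n'
                f"{_fmt(arr)}\n</DataArray>")
        return "\n".join(out)

    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{n}" NumberOfCells="{m}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">
{_fmt(nodes)}
</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{_fmt(cells)}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{_fmt(np.arange(1, m + 1) * cells.shape[1])}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{_fmt(np.full(m, ctype))}
</DataArray>
</Cells>
<PointData>
{data_arrays(point_data, n)}
</PointData>
<CellData>
{data_arrays(cell_data, m)}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    with open(path, "w") as f:
        f.write(xml)


def write_mesh_vtu(path, mesh: LabeledMesh, point_data=None) -> None:
    write_vtu(path, mesh.nodes, mesh.cells, point_data=point_data)


def write_surface_vtu(path, mesh: LabeledMesh, facet_ids, cell_data=None) -> None:
    """Boundary-facet subset as a surface VTU with per-facet data."""
    facets = mesh.boundary_facets[facet_ids]
    used, inv = np.unique(facets, return_inverse=True)
    write_vtu(path, mesh.nodes[used], inv.reshape(facets.shape),
              cell_data=cell_data)


def write_msh(path, mesh: LabeledMesh) -> None:
    """Gmsh MSH 2.2 ASCII with boundary facets as tagged physical groups."""
    d = mesh.dim
    vol_type = 4 if d == 3 else 2       # tet / triangle
    face_type = 2 if d == 3 else 1      # triangle / line
    nodes = mesh.nodes
    if d == 2:
        nodes = np.column_stack([nodes, np.zeros(len(nodes))])
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames",
             str(len(mesh.tag_names) + 1)]
    for i, name in enumerate(mesh.tag_names):
        lines.append(f'{d - 1} {i + 1} "{name}"')
    lines.append(f'{d} {len(mesh.tag_names) + 1} "lumen"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(len(nodes)))
    for i, p in enumerate(nodes):
        lines.append(f"{i + 1} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(len(mesh.boundary_facets) + len(mesh.cells)))
    eid = 1
    for facet, tag in zip(mesh.boundary_facets, mesh.facet_tags):
        conn = " ".join(str(v + 1) for v in facet)
        lines.append(f"{eid} {face_type} 2 {tag + 1} {tag + 1} {conn}")
        eid += 1
    vol_tag = len(mesh.tag_names) + 1
    for cell in mesh.cells:
        conn = " ".join(str(v + 1) for v in cell)
        lines.append(f"{eid} {vol_type} 2 {vol_tag} {vol_tag} {conn}")
        eid += 1
    lines.append("$EndElements")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def write_vtp_polyline(path, points) -> None:
    """Single polyline as ASCII VTP."""
    points = np.asarray(points, dtype=float)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    n = len(points)
    xml = f"""<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
<PolyData>
<Piece NumberOfPoints="{n}" NumberOfLines="1">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">
{_fmt(points)}
</DataArray>
</Points>
<Lines>
<DataArray type="Int64" Name="connectivity" format="ascii">
{_fmt(np.arange(n))}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{n}
</DataArray>
</Lines>
</Piece>
</PolyData>
</VTKFile>
"""
    with open(path, "w") as f:
        f.write(xml)


def write_pvd(path, entries) -> None:
    """ParaView collection file; entries = [(time, relative_filename), ...]."""
    lines = ['<?xml version="1.0"?>',
             '<VTKFile type="Collection" version="0.1" '
             'byte_order="LittleEndian">', "<Collection>"]
    for t, fname in entries:
        lines.append(f'<DataSet timestep="{t:.6g}" group="" part="0" '
                     f'file="{fname}"/>')
    lines += ["</Collection>", "</VTKFile>", ""]
    with open(path, "w") as f:
        f.write("\n".join(lines))


def write_field_series(outdir, mesh: LabeledMesh, field, max_snapshots=5):
    """Velocity/pressure snapshots as a VTU series plus a PVD collection.

    Writes at most ``max_snapshots`` evenly spaced snapshots of the final
    cycle (ASCII VTU is bulky; the full series lives in memory, not on disk).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = len(field.times)
    idx = np.unique(np.linspace(0, n - 1, min(max_snapshots, n)).astype(int))
    entries = []
    for k, i in enumerate(idx):
        vel = field.velocities[i]
        if vel.shape[1] == 2:
            vel = np.column_stack([vel, np.zeros(len(vel))])
        fname = f"field_{k:04d}.vtu"
        write_vtu(outdir / fname, mesh.nodes, mesh.cells,
                  point_data={"velocity": vel,
                              "pressure": field.pressures[i]})
        entries.append((float(field.times[i]), fname))
    write_pvd(outdir / "fields.pvd", entries)
    return [outdir / f for _, f in entries]
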