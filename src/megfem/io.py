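"""File interfaces: config files, label volumes, field maps, VTK export.

Study configurations are YAML mappings with nested ``phantom``, ``defects``,
``sensors``, ``line`` and ``conductivities`` sections.  Label grids round-trip
as a raw little-endian int16 block plus a JSON sidecar header; meshes and
volumes export to legacy-ASCII VTK files for inspection in ParaView.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .fem import FieldMap
from .hexmesh import HexMesh
from .phantom import DefectSpec, LabeledVoxelGrid, LayerRadii, PhantomConfig, \
    SensorArrayConfig, ShiftLine, Tissue, TissueTable
from .study import StudyConfig


# ---------------------------------------------------------------------------
# label volumes
# ---------------------------------------------------------------------------

def save_label_grid(grid: LabeledVoxelGrid, path: str | Path) -> None:
    """Write ``<path>.json`` (header) and ``<path>.raw`` (int16 labels)."""
    path = Path(path)
    header = {
        "dims": list(grid.dims),
        "voxel_size_mm": grid.voxel_size,
        "origin_mm": grid.origin.tolist(),
        "dtype": "<i2",
        "order": "C",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    grid.labels.astype("<i2").tofile(path.with_suffix(".raw"))


def load_label_grid(path: str | Path) -> LabeledVoxelGrid:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    labels = np.fromfile(path.with_suffix(".raw"),
                         dtype=header["dtype"]).reshape(header["dims"])
    return LabeledVoxelGrid(tuple(header["dims"]), header["voxel_size_mm"],
                            np.asarray(header["origin_mm"]), labels)


# ---------------------------------------------------------------------------
# VTK (legacy ASCII) export
# ---------------------------------------------------------------------------

def write_vtk_image(grid: LabeledVoxelGrid, path: str | Path) -> None:
    """Legacy-VTK structured-points file of the label volume."""
    nx, ny, nz = grid.dims
    lines = [
        "# vtk DataFile Version 3.0", "label volume", "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}",
        f"SPACING {grid.voxel_size} {grid.voxel_size} {grid.voxel_size}",
        f"POINT_DATA {nx * ny * nz}",
        "SCALARS label short 1", "LOOKUP_TABLE default",
    ]
    # VTK expects x fastest; labels are indexed [ix, iy, iz]
    flat = np.transpose(grid.labels, (2, 1, 0)).ravel()
    lines.extend(" ".join(map(str, chunk))
                 for chunk in np.array_split(flat, max(1, len(flat) // 9)))
    Path(path).write_text("\n".join(lines) + "\n")


#: local corner order -> legacy VTK_HEXAHEDRON order
_VTK_HEX_ORDER = (0, 1, 3, 2, 4, 5, 7, 6)


def write_vtk_hexmesh(mesh: HexMesh, path: str | Path,
                      point_data: dict | None = None,
                      cell_data: dict | None = None) -> None:
    """Legacy-VTK unstructured-grid file of the hexahedral mesh."""
    lines = [
        "# vtk DataFile Version 3.0", "hexahedral head mesh", "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} float",
    ]
    lines.extend(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in mesh.nodes)
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}")
    reordered = mesh.elements[:, _VTK_HEX_ORDER]
    lines.extend("8 " + " ".join(map(str, e)) for e in reordered)
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend("12" for _ in range(mesh.n_elements))

    cell_data = dict(cell_data or {})
    cell_data.setdefault("label", mesh.element_label)
    cell_data.setdefault("conductivity", mesh.element_conductivity)
    lines.append(f"CELL_DATA {mesh.n_elements}")
    for name, values in cell_data.items():
        kind = "int" if np.issubdtype(np.asarray(values).dtype, np.integer) \
            else "float"
        lines.append(f"SCALARS {name} {kind} 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(str(v) for v in np.asarray(values))
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.8e}" for v in np.asarray(values))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# field maps
# ---------------------------------------------------------------------------

def write_field_map(fmap: FieldMap, array_positions: np.ndarray,
                    path: str | Path) -> None:
    """Delimited table (channel, x, y, value fT) plus a JSON metadata file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("channel\tx_mm\ty_mm\tvalue_fT\n")
        for i, v in enumerate(fmap.values):
            fh.write(f"{i}\t{array_positions[i, 0]:.3f}"
                     f"\t{array_positions[i, 1]:.3f}\t{v:.6e}\n")
    meta = {k: repr(v) for k, v in fmap.meta.items()}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

def recon_results_to_records(results, config_hash: str = "") -> list[dict]:
    """JSON-ready records of fitted equivalent dipoles."""
    records = []
    for res in results:
        records.append({
            "position_mm": list(res.dipole.pos),
            "moment_uAmm": list(res.dipole.mom),
            "strength_uAmm": res.dipole.strength,
            "explained_variance": res.explained_variance,
            "iterations": res.iterations,
            "model_id": res.model_id,
            "config_hash": config_hash,
        })
    return records


def save_recon_results(results, path: str | Path,
                       config_hash: str = "") -> None:
    Path(path).write_text(
        json.dumps(recon_results_to_records(results, config_hash), indent=1))


# ---------------------------------------------------------------------------
# YAML study configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> StudyConfig:
    """Build a StudyConfig from a nested YAML mapping.

    Sections: ``phantom`` (shape, radii, voxel_size), ``defects`` (list of
    center/radius/axis), ``sensors``, ``line`` (origin, direction,
    n_positions, half_step), ``conductivities`` (tissue-name -> S/m
    overrides) and top-level study keys (seed, snr_db, node_shift, ...).
    """
    raw = yaml.safe_load(Path(path).read_text())
    phantom_raw = dict(raw.get("phantom", {}))
    if "radii" in phantom_raw:
        phantom_raw["radii"] = LayerRadii(**phantom_raw["radii"])
    if "axis_scales" in phantom_raw:
        phantom_raw["axis_scales"] = tuple(phantom_raw["axis_scales"])
    phantom = PhantomConfig(**phantom_raw)

    defects = tuple(
        DefectSpec(center=tuple(d["center"]), radius=d.get("radius", 2.5),
                   axis=tuple(d.get("axis", (0, 0, 1))),
                   fill_label=Tissue[d.get("fill", "agar_defect").upper()])
        for d in raw.get("defects", [])
    )
    sensors_raw = dict(raw.get("sensors", {}))
    for key in ("grid_shape", "center", "base_lengths"):
        if key in sensors_raw and sensors_raw[key] is not None:
            sensors_raw[key] = tuple(sensors_raw[key])
    sensors = SensorArrayConfig(**sensors_raw)

    line_raw = dict(raw["line"])
    line = ShiftLine(origin=tuple(line_raw["origin"]),
                     direction=tuple(line_raw["direction"]),
                     n_positions=line_raw["n_positions"],
                     half_step=line_raw.get("half_step", 0.3455))

    table = TissueTable().with_overrides(**raw.get("conductivities", {}))

    study_keys = {}
    for key in ("node_shift", "truth_defect_conductivity", "source_strength",
                "snr_db", "seed", "under_window", "next_window",
                "solver_method", "solver_tol"):
        if key in raw:
            study_keys[key] = raw[key]
    if "defect_conductivities" in raw:
        study_keys["defect_conductivities"] = tuple(
            raw["defect_conductivities"])
    return StudyConfig(phantom=phantom, defects=defects, sensors=sensors,
                       line=line, tissue_table=table, **study_keys)
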