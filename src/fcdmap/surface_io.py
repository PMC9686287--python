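"""Surface geometry and per-vertex overlay I/O.

Formats are dispatched on extension:

* geometry  — GIFTI (``.gii``, ``.surf.gii``), OFF (``.off``), otherwise
  FreeSurfer binary geometry (``lh.pial``-style paths).
* overlays  — GIFTI (``.gii``), delimited text (``.txt``/``.csv``), otherwise
  FreeSurfer "curv" morphometry format.

All readers/writers go through nibabel; OFF through a small text writer so
synthetic meshes can be inspected with generic mesh viewers.
"""

from __future__ import annotations

import os

import numpy as np
import nibabel as nib
from nibabel import freesurfer as fsio

from .surface import CorticalMap, SurfaceMesh

__all__ = ["read_surface", "write_surface", "read_overlay", "write_overlay"]


def _is_gifti(path: str) -> bool:
    return path.endswith(".gii")


def read_surface(path: str, hemisphere_label: str | None = None) -> SurfaceMesh:
    """Read a triangulated surface from GIFTI, OFF or FreeSurfer geometry."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    label = hemisphere_label or _guess_hemi(path)
    if _is_gifti(path):
        img = nib.load(path)
        coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    elif path.endswith(".off"):
        coords, tris = _read_off(path)
    else:
        coords, tris = fsio.read_geometry(path)
    return SurfaceMesh(
        vertex_coords=np.asarray(coords, float),
        triangles=np.asarray(tris, np.int64),
        hemisphere_label=label,
    )


def write_surface(mesh: SurfaceMesh, path: str) -> None:
    """Write mesh geometry; format chosen from the path's extension."""
    if _is_gifti(path):
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertex_coords.astype(np.float32),
                    intent="NIFTI_INTENT_POINTSET",
                ),
                nib.gifti.GiftiDataArray(
                    mesh.triangles.astype(np.int32),
                    intent="NIFTI_INTENT_TRIANGLE",
                ),
            ]
        )
        nib.save(img, path)
    elif path.endswith(".off"):
        _write_off(mesh, path)
    else:
        fsio.write_geometry(path, mesh.vertex_coords, mesh.triangles)


def read_overlay(path: str, mesh: SurfaceMesh, name: str = "") -> CorticalMap:
    """Read a per-vertex scalar overlay and validate it against the mesh."""
    if _is_gifti(path):
        img = nib.load(path)
        values = np.asarray(img.darrays[0].data, float)
    elif path.endswith((".txt", ".csv")):
        values = np.loadtxt(path, dtype=float)
    else:
        values = np.asarray(fsio.read_morph_data(path), float)
    cmap = CorticalMap(values=values, name=name or os.path.basename(path))
    cmap.check_against(mesh)
    return cmap


def write_overlay(cmap: CorticalMap, path: str) -> None:
    if _is_gifti(path):
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    cmap.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
                )
            ]
        )
        nib.save(img, path)
    elif path.endswith((".txt", ".csv")):
        np.savetxt(path, cmap.values)
    else:
        fsio.write_morph_data(path, cmap.values)


def _guess_hemi(path: str) -> str:
    base = os.path.basename(path)
    for tag in ("lh", "rh"):
        if base.startswith(tag + ".") or f".{tag}." in base:
            return tag
    return "unknown"


def _read_off(path: str) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError(f"{path}: not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    coords = np.array(tokens[pos: pos + 3 * nv], float).reshape(nv, 3)
    pos += 3 * nv
    tris = []
    for _ in range(nf):
        k = int(tokens[pos])
        if k != 3:
            raise ValueError("only triangle faces supported")
        tris.append([int(t) for t in tokens[pos + 1: pos + 4]])
        pos += k + 1
    return coords, np.array(tris, np.int64)


def _write_off(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.triangles)} 0\n")
        for xyz in mesh.vertex_coords:
            fh.write(f"{xyz[0]:.9g} {xyz[1]:.9g} {xyz[2]:.9g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
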