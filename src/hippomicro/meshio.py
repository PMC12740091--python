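"""Surface mesh and per-vertex scalar I/O (GIFTI, PLY, TSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from hippomicro.surface import SurfaceMesh

__all__ = ["read_mesh", "write_mesh", "read_vertex_scalars", "write_vertex_scalars"]


def write_mesh(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    if path.suffix == ".ply":
        import trimesh

        trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                        process=False).export(str(path), encoding="ascii")
    elif "".join(path.suffixes[-2:]) in (".surf.gii", ".gii"):
        import nibabel as nib
        from nibabel import gifti

        img = gifti.GiftiImage(
            darrays=[
                gifti.GiftiDataArray(
                    mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported mesh format: {path.name}")


def read_mesh(path) -> SurfaceMesh:
    path = Path(path)
    if path.suffix == ".ply":
        import trimesh

        tm = trimesh.load(str(path), process=False)
        return SurfaceMesh(vertices=np.array(tm.vertices), faces=np.array(tm.faces))
    if path.suffix == ".gii":
        import nibabel as nib

        img = nib.load(str(path))
        verts = faces = None
        for da in img.darrays:
            if da.intent == 1008:  # POINTSET
                verts = np.asarray(da.data, dtype=float)
            elif da.intent == 1009:  # TRIANGLE
                faces = np.asarray(da.data, dtype=int)
        if verts is None or faces is None:
            raise ValueError(f"{path.name} lacks pointset/triangle arrays")
        return SurfaceMesh(vertices=verts, faces=faces)
    raise ValueError(f"unsupported mesh format: {path.name}")


def write_vertex_scalars(values, path, name: str = "value") -> None:
    """Per-vertex scalars keyed by vertex index, as GIFTI functional file or
    plain TSV."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if path.suffix == ".gii":
        import nibabel as nib
        from nibabel import gifti

        img = gifti.GiftiImage(
            darrays=[gifti.GiftiDataArray(values.astype(np.float32),
                                          intent="NIFTI_INTENT_NONE")]
        )
        nib.save(img, str(path))
    else:
        import pandas as pd

        pd.DataFrame({"vertex": np.arange(len(values)), name: values}).to_csv(
            path, sep="\t", index=False
        )


def read_vertex_scalars(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".gii":
        import nibabel as nib

        img = nib.load(str(path))
        return np.asarray(img.darrays[0].data, dtype=float)
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return df[df.columns[-1]].to_numpy(dtype=float)
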