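"""4D diffusion-weighted volumes with FSL-style gradient tables.

b-values on disk are in s/mm² (FSL convention, one row) and converted to
ms/μm² in memory; bvecs are three rows of unit vectors.  Shells are grouped
with a tolerance of 50 s/mm² to accommodate vendor rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["DwiVolume", "read_dwi", "write_dwi", "group_shells", "SHELL_TOL", "B0_MAX"]

#: shell grouping tolerance in ms/μm² (= 50 s/mm²)
SHELL_TOL = 0.05
#: a shell whose b-value is below this counts as b = 0 (= 25 s/mm²)
B0_MAX = 0.025


def group_shells(bvals: np.ndarray, tol: float = SHELL_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Group b-values into shells within ``tol``.

    Returns ``(shell_bvals, shell_index)`` where ``shell_index[i]`` assigns
    volume ``i`` to ``shell_bvals[shell_index[i]]`` (shells sorted ascending,
    values are per-shell means).
    """
    bvals = np.asarray(bvals, dtype=float)
    order = np.argsort(bvals)
    groups: list[list[int]] = []
    for idx in order:
        if groups and bvals[idx] - bvals[groups[-1][0]] < tol:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    shell_bvals = np.array([bvals[g].mean() for g in groups])
    shell_index = np.empty(len(bvals), dtype=int)
    for j, g in enumerate(groups):
        shell_index[g] = j
    return shell_bvals, shell_index


@dataclass
class DwiVolume:
    """4D image grid + gradient table + affine.

    ``data`` has shape (x, y, z, n_volumes); ``bvals`` are in ms/μm²;
    ``bvecs`` has shape (n_volumes, 3).
    """

    data: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D")
        n = self.data.shape[3]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                f"gradient table length mismatch: {n} volumes, "
                f"{len(self.bvals)} bvals, bvecs {self.bvecs.shape}"
            )

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def shells(self) -> tuple[np.ndarray, np.ndarray]:
        return group_shells(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        """Boolean selector of b ≈ 0 volumes."""
        return self.bvals < B0_MAX


def read_dwi(nifti_path, bvals_path, bvecs_path) -> DwiVolume:
    """Load a NIfTI series with its FSL bvals/bvecs pair.

    bvals are converted from s/mm² to ms/μm²; bvecs of b > 0 volumes must be
    unit-norm to 1e-3.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    bvals = np.loadtxt(str(bvals_path), ndmin=1) / 1000.0
    bvecs = np.loadtxt(str(bvecs_path), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    if data.ndim == 3:
        data = data[..., None]
    if data.shape[3] != len(bvals):
        raise ValueError(
            f"4th dimension ({data.shape[3]}) does not match bvals length ({len(bvals)})"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals >= B0_MAX
    bad = weighted & (np.abs(norms - 1.0) > 1e-3)
    if np.any(bad):
        raise ValueError(f"{bad.sum()} non-unit bvecs for b > 0 volumes")
    return DwiVolume(data=data, bvals=bvals, bvecs=bvecs, affine=img.affine)


def write_dwi(dwi: DwiVolume, nifti_path, bvals_path=None, bvecs_path=None) -> None:
    """Write a NIfTI series and (optionally) its FSL gradient table.

    bvals are written back in s/mm².
    """
    nib.save(nib.Nifti1Image(dwi.data, dwi.affine), str(nifti_path))
    if bvals_path is not None:
        np.savetxt(str(bvals_path), dwi.bvals[None, :] * 1000.0, fmt="%.6g")
    if bvecs_path is not None:
        np.savetxt(str(bvecs_path), dwi.bvecs.T, fmt="%.8f")


def write_map(volume: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D scalar map as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=float), affine), str(path))


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine
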