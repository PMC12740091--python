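"""Self-similarity super-resolution of low-resolution DWI.

A low-resolution diffusion volume is upsampled by nearest-neighbour
replication and then iteratively refined: each high-resolution voxel is
replaced by a weighted average over a cubic search kernel, with weights
derived from the joint self-similarity of 3×3×3 DWI patches and of the
co-registered high-resolution anatomical reference at the two voxel
centers.  Spatial distance between voxels deliberately does not enter the
weight.  After every iteration, data consistency with the acquired
low-resolution volume is restored by adding back the (upsampled) residual
of the block-mean downsampled estimate, which makes the mean-downsample of
the output exactly equal to the input.

The weight for neighbour (x,y,z) of center (i,j,k) at bandwidth h is

    −ln w = h² · [ Σ_patch (DWI_p − DWI'_p)² / (N_patch · k_DWI)
                   + (T1w(x,y,z) − T1w(i,j,k))² / k_T1w ]

with k_DWI and k_T1w the mean squared in-mask intensities of the DWI
volume and of the reference.  Patches truncated by the volume boundary are
normalized by their actual voxel count.  The bandwidth series h grows over
iterations (default 1, 2, 4, 6, 8, 16), moving from conservative to
aggressive smoothing while consistency keeps the output anchored to the
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "SrConfig",
    "NormalizationConstants",
    "nearest_upsample",
    "block_downsample",
    "sr_weight",
    "sr_iteration",
    "data_consistency",
    "super_resolve",
]


@dataclass(frozen=True)
class SrConfig:
    kernel: int = 5
    patch: int = 3
    h_series: tuple[float, ...] = (1.0, 2.0, 4.0, 6.0, 8.0, 16.0)
    upsample_factor: int = 2

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0 or self.patch % 2 == 0:
            raise ValueError("kernel and patch edges must be odd")
        if self.kernel < self.patch:
            raise ValueError("kernel must be at least as large as patch")
        if self.upsample_factor < 1:
            raise ValueError("upsample factor must be >= 1")
        if any(h <= 0 for h in self.h_series):
            raise ValueError("h values must be positive")


@dataclass(frozen=True)
class NormalizationConstants:
    """Mean squared in-mask intensities used to normalize the two weight terms."""

    k_dwi: float
    k_t1w: float

    def __post_init__(self) -> None:
        if self.k_dwi <= 0 or self.k_t1w <= 0:
            raise ValueError("normalization constants must be positive")


def nearest_upsample(volume: np.ndarray, factor: int) -> np.ndarray:
    """Replicate each voxel into its factor³ children."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return np.array(volume, dtype=float, copy=True)
    out = np.asarray(volume, dtype=float)
    for axis in range(3):
        out = np.repeat(out, factor, axis=axis)
    return out


def block_downsample(volume: np.ndarray, factor: int) -> np.ndarray:
    """Mean over each factor³ block (the adjoint of nearest replication)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    vol = np.asarray(volume, dtype=float)
    if factor == 1:
        return vol.copy()
    shape = vol.shape[:3]
    pad = [(0, (-s) % factor) for s in shape]
    if any(p[1] for p in pad):
        vol = np.pad(vol, pad, mode="edge")
        shape = vol.shape[:3]
    nx, ny, nz = (s // factor for s in shape)
    return vol.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))


def sr_weight(ssd_patch, dt1, h, norms: NormalizationConstants, patch_voxels=27):
    """Self-similarity weight in (0, 1]; equals 1 iff both difference terms
    vanish."""
    ssd_patch = np.asarray(ssd_patch, dtype=float)
    dt1 = np.asarray(dt1, dtype=float)
    pv = np.asarray(patch_voxels, dtype=float)
    if np.any(pv < 1):
        raise ValueError("patch_voxels must be >= 1")
    neg_log = h**2 * (ssd_patch / (pv * norms.k_dwi) + dt1**2 / norms.k_t1w)
    out = np.exp(-neg_log)
    return float(out) if out.ndim == 0 else out


def _box_sum(vol: np.ndarray, size: int) -> np.ndarray:
    # uniform_filter with constant-0 padding, rescaled from mean to sum
    return uniform_filter(vol, size=size, mode="constant", cval=0.0) * size**3


def _shift(vol: np.ndarray, offset: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Volume translated by ``offset`` with a validity mask (False where the
    source voxel falls outside the grid)."""
    out = np.zeros_like(vol)
    valid = np.zeros(vol.shape, dtype=bool)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        n = vol.shape[ax]
        if d >= 0:
            src[ax] = slice(0, n - d)
            dst[ax] = slice(d, n)
        else:
            src[ax] = slice(-d, n)
            dst[ax] = slice(0, n + d)
        if abs(d) >= n:
            return out, valid
    out[tuple(dst)] = vol[tuple(src)]
    valid[tuple(dst)] = True
    return out, valid


def sr_iteration(
    dwi_hr: np.ndarray,
    reference: np.ndarray,
    h: float,
    config: SrConfig,
    norms: NormalizationConstants,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """One weighted-average pass over the search kernel.

    In-mask voxels are replaced by the weight-normalized average of their
    kernel neighbours (the center contributes with weight 1); out-of-mask
    voxels are returned untouched.
    """
    vol = np.asarray(dwi_hr, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if vol.shape != ref.shape:
        raise ValueError("reference grid does not match the DWI grid")
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    half = config.kernel // 2
    num = np.zeros_like(vol)
    den = np.zeros_like(vol)
    for offset in product(range(-half, half + 1), repeat=3):
        shifted, valid = _shift(vol, offset)
        ref_shift, _ = _shift(ref, offset)
        diff_sq = np.where(valid, (vol - shifted) ** 2, 0.0)
        ssd = _box_sum(diff_sq, config.patch)
        cnt = _box_sum(valid.astype(float), config.patch)
        cnt = np.maximum(cnt, 1.0)
        dt1 = ref - ref_shift
        w = np.where(
            valid,
            np.exp(-(h**2) * (ssd / (cnt * norms.k_dwi) + dt1**2 / norms.k_t1w)),
            0.0,
        )
        num += w * shifted
        den += w
    out = vol.copy()
    upd = mask & (den > 0)
    out[upd] = num[upd] / den[upd]
    return out


def data_consistency(dwi_hr: np.ndarray, dwi_lr_original: np.ndarray, factor: int) -> np.ndarray:
    """Add back the upsampled residual so the block-mean downsample of the
    output equals the acquired low-resolution volume exactly."""
    hr = np.asarray(dwi_hr, dtype=float)
    lr = np.asarray(dwi_lr_original, dtype=float)
    expected = tuple(s * factor for s in lr.shape)
    if hr.shape != expected:
        raise ValueError(
            f"grid mismatch: HR {hr.shape} is not factor {factor} of LR {lr.shape}"
        )
    residual = lr - block_downsample(hr, factor)
    return hr + nearest_upsample(residual, factor)


def compute_norms(volume: np.ndarray, reference: np.ndarray,
                  mask: np.ndarray | None = None) -> NormalizationConstants:
    """k_DWI per 3D volume and k_T1w from in-mask mean squared intensities."""
    if mask is None:
        mask = np.ones(volume.shape, dtype=bool)
    mask = mask.astype(bool)
    k_dwi = float(np.mean(np.asarray(volume, dtype=float)[mask] ** 2))
    k_t1w = float(np.mean(np.asarray(reference, dtype=float)[mask] ** 2))
    if k_dwi <= 0:
        k_dwi = 1.0  # all-zero volume: weights reduce to the reference term
    return NormalizationConstants(k_dwi=k_dwi, k_t1w=k_t1w)


def super_resolve(
    dwi_lr: np.ndarray,
    reference: np.ndarray,
    config: SrConfig | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Super-resolve a 3D volume or 4D series against a high-resolution
    reference on the target grid.

    Each 3D volume is processed independently: nearest-neighbour
    initialization, then for each h in the series one self-similarity pass
    followed by one data-consistency pass.
    """
    if config is None:
        config = SrConfig()
    lr = np.asarray(dwi_lr, dtype=float)
    squeeze = lr.ndim == 3
    if squeeze:
        lr = lr[..., None]
    factor = config.upsample_factor
    ref = np.asarray(reference, dtype=float)
    out = np.empty(ref.shape[:3] + (lr.shape[3],))
    for v in range(lr.shape[3]):
        vol_lr = lr[..., v]
        hr = nearest_upsample(vol_lr, factor)
        if hr.shape != ref.shape:
            raise ValueError(
                f"upsampled grid {hr.shape} does not match reference {ref.shape}"
            )
        norms = compute_norms(hr, ref, mask)
        for h in config.h_series:
            hr = sr_iteration(hr, ref, h, config, norms, mask)
            hr = data_consistency(hr, vol_lr, factor)
        out[..., v] = hr
    return out[..., 0] if squeeze else out
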