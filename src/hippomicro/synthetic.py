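"""Synthetic phantoms, cohorts and toy meshes with known ground truth.

The study cohort this package emulates is not redistributable, so every
input the pipeline consumes is generated here: labelled six-subfield
parameter phantoms on a 1-mm ground-truth grid, noisy multi-shell DWI at
low and high resolution, a structurally aligned anatomical reference,
age-structured cohorts with configurable cross-sectional effect sizes, and
analytic meshes with known curvature/area/thickness.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hippomicro.dwi import DwiVolume
from hippomicro.sandi import (
    D_RANGE,
    R_SOMA_RANGE,
    AcquisitionProtocol,
    SandiParams,
    sandi_signal_batch,
)
from hippomicro.supres import block_downsample
from hippomicro.surface import SurfaceMesh

__all__ = [
    "PhantomSpec",
    "AgeEffectModel",
    "default_phantom_spec",
    "make_phantom",
    "simulate_subject_dwi",
    "degrade_to_lowres",
    "make_t1_reference",
    "simulate_cohort",
    "make_toy_mesh",
]

#: default region parameters: six pseudo-subfields with distinct microstructure
_DEFAULT_REGIONS = {
    1: SandiParams(0.35, 0.30, 0.35, 7.0, 2.0, 1.2),  # pseudo-subiculum
    2: SandiParams(0.45, 0.25, 0.30, 8.0, 2.2, 1.0),  # pseudo-CA1
    3: SandiParams(0.50, 0.20, 0.30, 9.0, 2.0, 0.9),  # pseudo-CA2
    4: SandiParams(0.40, 0.35, 0.25, 6.5, 1.8, 1.1),  # pseudo-CA3
    5: SandiParams(0.35, 0.40, 0.25, 6.0, 1.6, 1.3),  # pseudo-CA4
    6: SandiParams(0.55, 0.15, 0.30, 8.5, 2.4, 0.8),  # pseudo-DG
}

PARAM_NAMES = ("f_soma", "f_neurite", "f_extra", "r_soma", "d_in", "d_e")


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth phantom: labelled pseudo-subfields on a 1-mm grid."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 1.0
    regions: dict = field(default_factory=lambda: dict(_DEFAULT_REGIONS))
    perturbation_sd: float = 0.0  # smooth within-region parameter jitter
    seed: int = 0


@dataclass(frozen=True)
class AgeEffectModel:
    """Linear cross-sectional age effects for cohort simulation.

    ``targets`` maps a parameter name to (target_r, subject_noise_sd): the
    slope per year is calibrated so that at the configured age spread the
    population Pearson correlation between age and the parameter equals
    target_r given the subject-level noise.
    """

    targets: dict = field(default_factory=dict)
    age_range: tuple[float, float] = (19.0, 85.0)
    n_males: int = 32
    n_females: int = 40


def default_phantom_spec(shape=(32, 32, 32), seed: int = 0) -> PhantomSpec:
    return PhantomSpec(shape=tuple(shape), seed=seed)


def make_phantom(spec: PhantomSpec) -> dict:
    """Build label and parameter volumes.

    The foreground is an ellipsoid filling ~80% of the grid, partitioned
    into six slabs along x (the pseudo-subfields).  Returns a dict with
    ``labels``, ``mask``, one volume per parameter, and ``affine``.
    """
    labels = np.zeros(spec.shape, dtype=int)
    nx, ny, nz = spec.shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ellips = (
        ((x - cx) / (0.45 * nx)) ** 2
        + ((y - cy) / (0.4 * ny)) ** 2
        + ((z - cz) / (0.4 * nz)) ** 2
    ) <= 1.0
    region_ids = sorted(spec.regions)
    edges = np.linspace(x[ellips].min(), x[ellips].max() + 1, len(region_ids) + 1)
    for rid, lo, hi in zip(region_ids, edges[:-1], edges[1:]):
        labels[ellips & (x >= lo) & (x < hi)] = rid
    mask = labels > 0

    rng = np.random.default_rng(spec.seed)
    maps = {name: np.zeros(spec.shape) for name in PARAM_NAMES}
    for rid in region_ids:
        p = spec.regions[rid]
        sel = labels == rid
        for name in PARAM_NAMES:
            maps[name][sel] = getattr(p, name)
    if spec.perturbation_sd > 0:
        from scipy.ndimage import gaussian_filter

        for name in ("r_soma", "d_in", "d_e"):
            noise = gaussian_filter(
                rng.normal(0.0, spec.perturbation_sd, spec.shape), sigma=2.0
            )
            lo, hi = (R_SOMA_RANGE if name == "r_soma" else D_RANGE)
            maps[name][mask] = np.clip(maps[name][mask] + noise[mask], lo, hi)
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    return {"labels": labels, "mask": mask, "affine": affine, **maps}


def _shell_directions(n: int, shell_index: int) -> np.ndarray:
    """Quasi-uniform unit vectors (deterministic per shell)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i + 0.37 * shell_index
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def build_gradient_table(protocol: AcquisitionProtocol) -> tuple[np.ndarray, np.ndarray]:
    """bvals (ms/μm²) and unit bvecs with b = 0 volumes interleaved every 16
    diffusion-weighted volumes."""
    bvals, bvecs = [], []
    pending = 0
    b0_left = protocol.b0_count
    for s, (b, nd) in enumerate(zip(protocol.shells, protocol.directions_per_shell)):
        dirs = _shell_directions(nd, s)
        for d in range(nd):
            if pending % 16 == 0 and b0_left > 0:
                bvals.append(0.0)
                bvecs.append(np.zeros(3))
                b0_left -= 1
            bvals.append(b)
            bvecs.append(dirs[d])
            pending += 1
    while b0_left > 0:
        bvals.append(0.0)
        bvecs.append(np.zeros(3))
        b0_left -= 1
    return np.array(bvals), np.array(bvecs)


def simulate_subject_dwi(
    param_maps: dict,
    protocol: AcquisitionProtocol,
    snr: float | None = None,
    seed: int = 0,
    s0: float = 1.0,
) -> tuple[DwiVolume, DwiVolume]:
    """Forward-simulate a 4D DWI series from voxelwise parameter maps.

    Each direction of a shell carries the shell's spherical-mean signal (no
    orientation dispersion is modelled — every downstream consumer uses
    spherical means).  Rician noise uses σ = s0/snr, referenced to the b = 0
    intensity.  Returns ``(noisy, noise_free)``; without ``snr`` the two are
    identical.
    """
    mask = param_maps["mask"]
    bvals, bvecs = build_gradient_table(protocol)
    shape = mask.shape
    data = np.zeros(shape + (len(bvals),))
    flat_mask = mask.ravel()
    fs = param_maps["f_soma"].ravel()[flat_mask]
    fn = param_maps["f_neurite"].ravel()[flat_mask]
    rs = param_maps["r_soma"].ravel()[flat_mask]
    di = param_maps["d_in"].ravel()[flat_mask]
    de = param_maps["d_e"].ravel()[flat_mask]
    shell_sig = sandi_signal_batch(fs, fn, rs, di, de, protocol)  # (nvox, nshells)
    shell_of = {b: j for j, b in enumerate(protocol.shells)}
    flat = data.reshape(-1, len(bvals))
    for v, b in enumerate(bvals):
        if b == 0:
            flat[flat_mask, v] = s0
        else:
            flat[flat_mask, v] = s0 * shell_sig[:, shell_of[b]]
    affine = param_maps.get("affine", np.eye(4))
    clean = DwiVolume(data=data.copy(), bvals=bvals, bvecs=bvecs, affine=affine)
    if snr is None:
        return clean, clean
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    e1 = rng.normal(0.0, sigma, data.shape)
    e2 = rng.normal(0.0, sigma, data.shape)
    noisy = np.sqrt((data + e1) ** 2 + e2**2)
    return DwiVolume(data=noisy, bvals=bvals, bvecs=bvecs, affine=affine), clean


def degrade_to_lowres(
    dwi_hr: DwiVolume, factor: int = 2, snr: float | None = None, seed: int = 0,
    s0: float = 1.0,
) -> DwiVolume:
    """Block-mean downsample a high-resolution series and add Rician noise —
    the scanner-acquisition stand-in that creates super-resolution test
    pairs."""
    if factor < 2:
        raise ValueError("degradation factor must be >= 2")
    lr = np.stack(
        [block_downsample(dwi_hr.data[..., v], factor) for v in range(dwi_hr.data.shape[3])],
        axis=-1,
    )
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        e1 = rng.normal(0.0, sigma, lr.shape)
        e2 = rng.normal(0.0, sigma, lr.shape)
        lr = np.sqrt((lr + e1) ** 2 + e2**2)
    affine = dwi_hr.affine.copy()
    affine[:3, :3] *= factor
    return DwiVolume(data=lr, bvals=dwi_hr.bvals, bvecs=dwi_hr.bvecs, affine=affine)


def make_t1_reference(
    labels: np.ndarray,
    contrast: dict | None = None,
    noise_sd: float = 0.0,
    bias_amplitude: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Piecewise-constant anatomical reference aligned to the label grid,
    with optional smooth multiplicative bias field and Gaussian noise."""
    labels = np.asarray(labels)
    if contrast is None:
        ids = [int(u) for u in np.unique(labels)]
        contrast = {u: 20.0 + 15.0 * i for i, u in enumerate(ids)}
    out = np.zeros(labels.shape, dtype=float)
    for u, val in contrast.items():
        out[labels == u] = val
    rng = np.random.default_rng(seed)
    if bias_amplitude > 0:
        nx, ny, nz = labels.shape
        x, y, z = np.meshgrid(
            np.linspace(0, np.pi, nx),
            np.linspace(0, np.pi, ny),
            np.linspace(0, np.pi, nz),
            indexing="ij",
        )
        out *= 1.0 + bias_amplitude * np.sin(x) * np.sin(y) * np.sin(z)
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, labels.shape)
    return out


def _calibrated_slope(target_r: float, noise_sd: float, age_sd: float) -> float:
    """Slope per year giving population Pearson r = target_r for additive
    subject noise of the given sd: r² = s²σ_a²/(s²σ_a² + σ_n²)."""
    if abs(target_r) >= 1.0:
        raise ValueError("target r must be inside (−1, 1)")
    if target_r == 0.0:
        return 0.0
    return target_r / np.sqrt(1.0 - target_r**2) * noise_sd / age_sd


def simulate_cohort(
    n_subjects: int = 72,
    age_effect: AgeEffectModel | None = None,
    spec: PhantomSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort with linear age trends in region microstructure.

    Ages are uniform over the configured range; sex is assigned with the
    configured split.  Each subject's region parameters are the phantom
    baseline plus calibrated slope·(age − mean age) plus subject noise,
    clamped to valid ranges.  Returns ``(table, provenance)``: the table has
    one row per subject with columns subject, age, sex (1 = male) and one
    column per (region, parameter); provenance records slopes and clamping.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    if age_effect is None:
        age_effect = AgeEffectModel()
    if spec is None:
        spec = default_phantom_spec()
    rng = np.random.default_rng(seed)
    lo, hi = age_effect.age_range
    ages = rng.uniform(lo, hi, n_subjects)
    n_m = int(round(n_subjects * age_effect.n_males
                    / (age_effect.n_males + age_effect.n_females)))
    sexes = np.zeros(n_subjects, dtype=int)
    sexes[rng.choice(n_subjects, size=n_m, replace=False)] = 1
    age_sd = (hi - lo) / np.sqrt(12.0)
    age_mean = (lo + hi) / 2.0

    bounds = {
        "f_soma": (0.0, 1.0),
        "f_neurite": (0.0, 1.0),
        "f_extra": (0.0, 1.0),
        "r_soma": R_SOMA_RANGE,
        "d_in": D_RANGE,
        "d_e": D_RANGE,
    }
    cols = {"subject": [f"sub-{i:03d}" for i in range(n_subjects)],
            "age": ages, "sex": sexes}
    slopes = {}
    clamp_frac = {}
    for rid in sorted(spec.regions):
        base = spec.regions[rid]
        for name in PARAM_NAMES:
            key = f"roi{rid}_{name}"
            target = age_effect.targets.get(name)
            if target is None:
                slope, noise_sd = 0.0, 0.0
            else:
                target_r, noise_sd = target
                slope = _calibrated_slope(target_r, noise_sd, age_sd)
            vals = (
                getattr(base, name)
                + slope * (ages - age_mean)
                + (rng.normal(0.0, noise_sd, n_subjects) if noise_sd > 0 else 0.0)
            )
            b_lo, b_hi = bounds[name]
            clamped = (vals < b_lo) | (vals > b_hi)
            vals = np.clip(vals, b_lo, b_hi)
            cols[key] = vals
            slopes[key] = slope
            clamp_frac[key] = float(clamped.mean())
    table = pd.DataFrame(cols)
    warnings = [k for k, frac in clamp_frac.items() if frac > 0.2]
    provenance = {
        "seed": seed,
        "slopes": slopes,
        "clamp_fraction": clamp_frac,
        "saturated_params": warnings,
        "age_range": age_effect.age_range,
        "n_males": int(sexes.sum()),
        "n_females": int(n_subjects - sexes.sum()),
    }
    return table, provenance


def _grid_mesh(nx: int, ny: int, fx, fy, fz) -> SurfaceMesh:
    """Parametric sheet mesh over a regular (nx, ny) grid of (u, v)."""
    u, v = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                       indexing="ij")
    verts = np.column_stack([fx(u, v).ravel(), fy(u, v).ravel(), fz(u, v).ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = a + 1
            c = a + ny
            d = c + 1
            faces.append([a, c, b])
            faces.append([b, c, d])
    return SurfaceMesh(vertices=verts, faces=np.array(faces))


def make_toy_mesh(kind: str, **params):
    """Analytic test meshes.

    kinds: ``sphere`` (radius, subdivisions), ``plane`` (n, spacing),
    ``cylinder`` (radius, height, n_theta, n_z — open, no caps),
    ``sinusoid`` (amplitude, wavenumber, n, spacing) with its flat
    projection as correspondence, ``concentric_pair`` (r_inner, r_outer,
    subdivisions) with radial correspondence.  Returns a SurfaceMesh or a
    tuple of corresponding meshes.
    """
    import trimesh

    if kind == "sphere":
        radius = params.get("radius", 1.0)
        sub = params.get("subdivisions", 5)
        tm = trimesh.creation.icosphere(subdivisions=sub, radius=radius)
        return SurfaceMesh(vertices=np.array(tm.vertices), faces=np.array(tm.faces))
    if kind == "plane":
        n = params.get("n", 30)
        sp = params.get("spacing", 1.0)
        return _grid_mesh(n, n, lambda u, v: u * sp, lambda u, v: v * sp,
                          lambda u, v: 0.0 * u)
    if kind == "cylinder":
        radius = params.get("radius", 2.0)
        height = params.get("height", 20.0)
        n_t = params.get("n_theta", 120)
        n_z = params.get("n_z", 60)
        theta = 2 * np.pi / n_t
        dz = height / (n_z - 1)
        mesh = _grid_mesh(
            n_z, n_t + 1,
            lambda u, v: radius * np.cos(v * theta),
            lambda u, v: radius * np.sin(v * theta),
            lambda u, v: u * dz,
        )
        # weld the seam (v = n_t duplicates v = 0)
        n_col = n_t + 1
        remap = np.arange(mesh.n_vertices)
        for i in range(n_z):
            remap[i * n_col + n_t] = i * n_col
        faces = remap[mesh.faces]
        keep = np.ones(mesh.n_vertices, dtype=bool)
        keep[np.arange(n_z) * n_col + n_t] = False
        new_index = np.cumsum(keep) - 1
        # flip winding so normals point radially outward
        return SurfaceMesh(vertices=mesh.vertices[keep],
                           faces=new_index[faces][:, [0, 2, 1]])
    if kind == "sinusoid":
        a = params.get("amplitude", 1.0)
        k = params.get("wavenumber", 0.5)
        n = params.get("n", 60)
        sp = params.get("spacing", 0.25)
        folded = _grid_mesh(n, n, lambda u, v: u * sp, lambda u, v: v * sp,
                            lambda u, v: a * np.sin(k * u * sp))
        flat = _grid_mesh(n, n, lambda u, v: u * sp, lambda u, v: v * sp,
                          lambda u, v: 0.0 * u)
        return folded, flat
    if kind == "concentric_pair":
        r_in = params.get("r_inner", 10.0)
        r_out = params.get("r_outer", 12.0)
        sub = params.get("subdivisions", 3)
        inner = make_toy_mesh("sphere", radius=r_in, subdivisions=sub)
        outer = SurfaceMesh(
            vertices=inner.vertices * (r_out / r_in), faces=inner.faces.copy()
        )
        return inner, outer
    raise ValueError(f"unknown toy mesh kind {kind!r}")
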