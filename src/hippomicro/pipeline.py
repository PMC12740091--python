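"""End-to-end phantom pipeline: simulate → super-resolve → fit → surface → regress.

Every stage is a pure function of its inputs and the run seed; the run
report records seeds, stage provenance and every FDR decision with its raw
p-value, so a rerun with the same configuration reproduces the report
exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

import hippomicro
from hippomicro.config import RunConfig
from hippomicro.dwi import DwiVolume, write_dwi, write_map
from hippomicro.dki import fit_dki
from hippomicro.inversion import (
    build_training_set,
    fit_sandi,
    spherical_mean_shells,
    train_inverter,
)
from hippomicro.sandi import AcquisitionProtocol, SandiParams
from hippomicro.stats import bh_fdr, ols_age_model, roi_summary, vertexwise_regression
from hippomicro.supres import SrConfig, nearest_upsample, super_resolve
from hippomicro.surface import (
    SurfaceMesh,
    gyrification,
    mean_curvature,
    sample_at_vertices,
    thickness,
)
from hippomicro.synthetic import (
    AgeEffectModel,
    PhantomSpec,
    _DEFAULT_REGIONS,
    PARAM_NAMES,
    degrade_to_lowres,
    make_phantom,
    make_t1_reference,
    make_toy_mesh,
    simulate_cohort,
    simulate_subject_dwi,
)

__all__ = ["run_pipeline"]


def _protocol_from_config(cfg: RunConfig) -> AcquisitionProtocol:
    base = AcquisitionProtocol.default()
    if cfg.directions_per_shell is None:
        return AcquisitionProtocol(
            shells=base.shells,
            directions_per_shell=base.directions_per_shell,
            delta_small=cfg.delta_small,
            delta_big=cfg.delta_big,
            b0_count=base.b0_count,
        )
    nd = int(cfg.directions_per_shell)
    return AcquisitionProtocol(
        shells=base.shells,
        directions_per_shell=(nd,) * len(base.shells),
        delta_small=cfg.delta_small,
        delta_big=cfg.delta_big,
        b0_count=max(1, nd * len(base.shells) // 16),
    )


def _subject_spec(base_spec: PhantomSpec, row: pd.Series) -> PhantomSpec:
    """Phantom spec with this subject's per-region parameter values."""
    regions = {}
    for rid in sorted(base_spec.regions):
        kw = {}
        for name in PARAM_NAMES:
            kw[name] = float(row[f"roi{rid}_{name}"])
        # re-impose the simplex exactly after clamping
        total = kw["f_soma"] + kw["f_neurite"] + kw["f_extra"]
        for k in ("f_soma", "f_neurite", "f_extra"):
            kw[k] /= total
        regions[rid] = SandiParams(**kw)
    return PhantomSpec(
        shape=base_spec.shape,
        voxel_size=base_spec.voxel_size,
        regions=regions,
        perturbation_sd=base_spec.perturbation_sd,
        seed=base_spec.seed,
    )


def _sheet_meshes(shape: tuple[int, int, int], labels_from_x) -> dict:
    """A folded sheet spanning the phantom, with unfolded/inner/outer pairs
    and six x-band subfield labels."""
    nx, ny, nz = shape
    n = 24
    span_x = np.linspace(0.15 * nx, 0.85 * nx, n)
    span_y = np.linspace(0.15 * ny, 0.85 * ny, n)
    u, v = np.meshgrid(span_x, span_y, indexing="ij")
    amp, k = 0.08 * nz, 2.0 * np.pi / (0.7 * nx)
    z_mid = 0.5 * nz + amp * np.sin(k * (u - span_x[0]))
    mid = _sheet_from_xyz(u, v, z_mid)
    flat = _sheet_from_xyz(u, v, np.full_like(z_mid, 0.5 * nz))
    # offset along z for inner/outer (constant 1-voxel half-thickness)
    inner = _sheet_from_xyz(u, v, z_mid - 0.5)
    outer = _sheet_from_xyz(u, v, z_mid + 0.5)
    labels = labels_from_x(mid.vertices[:, 0])
    for m in (mid, flat, inner, outer):
        m.labels = labels
    return {"mid": mid, "unfolded": flat, "inner": inner, "outer": outer}


def _sheet_from_xyz(u, v, z) -> SurfaceMesh:
    n, m = u.shape
    verts = np.column_stack([u.ravel(), v.ravel(), np.asarray(z).ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(m - 1):
            a = i * m + j
            faces.append([a, a + m, a + 1])
            faces.append([a + 1, a + m, a + m + 1])
    return SurfaceMesh(vertices=verts, faces=np.array(faces))


def run_pipeline(cfg: RunConfig, quiet: bool = False) -> dict:
    """Execute the full phantom pipeline described by ``cfg``.

    Writes NIfTI maps, TSV tables and a JSON report under
    ``cfg.output_dir`` and returns the report dict.
    """
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    rng_seed = int(cfg.seed)
    report: dict = {
        "package_version": hippomicro.__version__,
        "seed": rng_seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "stages": {},
    }

    def _stage(name):
        if not quiet:
            print(f"[hippomicro] stage: {name}", flush=True)
        return time.time()

    protocol = _protocol_from_config(cfg)

    # ---- simulate cohort ----
    t0 = _stage("simulate")
    try:
        base_spec = PhantomSpec(shape=tuple(cfg.phantom_shape), seed=rng_seed)
        effects = AgeEffectModel(
            targets={k: tuple(v) for k, v in cfg.age_effects.items()}
        )
        cohort, prov = simulate_cohort(
            n_subjects=cfg.n_subjects, age_effect=effects, spec=base_spec,
            seed=rng_seed,
        )
        cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
        report["stages"]["simulate"] = {
            "n_subjects": cfg.n_subjects,
            "provenance": {k: v for k, v in prov.items() if k != "slopes"},
            "elapsed_s": round(time.time() - t0, 2),
        }
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(f"stage 'simulate' failed (seed {rng_seed})") from err

    base_phantom = make_phantom(base_spec)
    labels_hr = base_phantom["labels"]
    region_ids = sorted(base_spec.regions)

    def labels_from_x(xs):
        # map world x to the phantom's x-slab subfields
        fg_x = np.flatnonzero(labels_hr.max(axis=(1, 2)) > 0)
        edges = np.linspace(fg_x.min(), fg_x.max() + 1, len(region_ids) + 1)
        out = np.zeros(len(xs), dtype=int)
        for rid, lo, hi in zip(region_ids, edges[:-1], edges[1:]):
            out[(xs >= lo) & (xs < hi)] = rid
        return out

    meshes = _sheet_meshes(base_spec.shape, labels_from_x)

    # ---- train the inverter once ----
    t0 = _stage("train-inverter")
    ts = build_training_set(cfg.n_train, protocol, snr=cfg.train_snr, seed=rng_seed)
    model = train_inverter(ts, n_trees=cfg.n_trees)

    sr_cfg = SrConfig(
        kernel=cfg.sr_kernel, patch=cfg.sr_patch,
        h_series=tuple(cfg.sr_h_series), upsample_factor=cfg.sr_factor,
    )
    report["stages"]["train-inverter"] = {
        "n_train": cfg.n_train, "n_trees": cfg.n_trees, "snr": cfg.train_snr,
        "elapsed_s": round(time.time() - t0, 2),
    }

    # ---- per-subject imaging chain ----
    t0 = _stage("imaging")
    metric_names = ["f_soma", "f_neurite", "f_extra", "r_soma", "d_in", "d_e",
                    "md", "fa", "mk"]
    vertex_maps = {m: [] for m in metric_names}
    struct_names = ["thickness", "gyrification", "curvature"]
    for m in struct_names:
        vertex_maps[m] = []
    mid = meshes["mid"]
    gyr = gyrification(mid, meshes["unfolded"])
    thick = thickness(meshes["inner"], meshes["outer"])
    curv = mean_curvature(mid)
    for _, row in cohort.iterrows():
        sid = row["subject"]
        try:
            spec_s = _subject_spec(base_spec, row)
            maps_s = make_phantom(spec_s)
            dwi_hr, _ = simulate_subject_dwi(maps_s, protocol, snr=None)
            sub_seed = rng_seed + 1000 + int(sid.split("-")[1])
            dwi_lr = degrade_to_lowres(dwi_hr, cfg.sr_factor, snr=cfg.snr,
                                       seed=sub_seed)
            ref = make_t1_reference(maps_s["labels"])
            sr_data = super_resolve(dwi_lr.data, ref, sr_cfg,
                                    mask=None)
            dwi_sr = DwiVolume(data=sr_data, bvals=dwi_lr.bvals,
                               bvecs=dwi_lr.bvecs, affine=dwi_hr.affine)
            shell_b, means = spherical_mean_shells(dwi_sr)
            sandi_maps = fit_sandi(means, model, mask=maps_s["mask"])
            dki = fit_dki(dwi_sr.data, dwi_sr.bvals, dwi_sr.bvecs,
                          mask=maps_s["mask"], b_max=cfg.dki_b_max)
            all_maps = {**sandi_maps, "md": dki.md, "fa": dki.fa, "mk": dki.mk}
            for m in metric_names:
                vertex_maps[m].append(
                    sample_at_vertices(all_maps[m], maps_s["affine"], mid)
                )
            vertex_maps["thickness"].append(thick)
            vertex_maps["gyrification"].append(gyr)
            vertex_maps["curvature"].append(curv)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(
                f"stage 'imaging' failed for subject {sid} (seed {rng_seed})"
            ) from err
    # persist the last subject's maps as example outputs
    for name, vol in all_maps.items():
        write_map(np.nan_to_num(vol), maps_s["affine"], out_dir / f"{name}.nii.gz")
    report["stages"]["imaging"] = {
        "n_subjects": int(len(cohort)),
        "shells": [float(b) for b in shell_b],
        "elapsed_s": round(time.time() - t0, 2),
    }

    # ---- statistics ----
    t0 = _stage("regress")
    ages = cohort["age"].to_numpy()
    sexes = cohort["sex"].to_numpy()
    roi_rows = []
    vertex_summary = {}
    from hippomicro.surface import SUBFIELD_NAMES

    for metric in metric_names + struct_names:
        stack = np.vstack(vertex_maps[metric])
        rois = roi_summary(stack, mid.labels, SUBFIELD_NAMES)
        pvals, rows = [], []
        for roi_name in rois.columns:
            y = rois[roi_name].to_numpy()
            if np.any(np.isnan(y)):
                continue
            res = ols_age_model(y, ages, sexes, model=cfg.stats_model)
            rows.append({"metric": metric, "roi": roi_name, "r": res.r,
                         "t": res.t_age, "p": res.p_age})
            pvals.append(res.p_age)
        if rows:
            adj = bh_fdr(np.array(pvals))
            for row_d, ap in zip(rows, adj):
                row_d["fdr_p"] = float(ap)
                row_d["significant"] = bool(ap < cfg.alpha)
            roi_rows.extend(rows)
        vw = vertexwise_regression(np.nan_to_num(stack), ages, sexes,
                                   alpha=cfg.alpha, model=cfg.stats_model)
        vertex_summary[metric] = {
            "n_vertices": int(stack.shape[1]),
            "significant_fraction": float(vw["significant"].mean()),
            "mean_r": float(np.mean(vw["r"])),
        }
    roi_table = pd.DataFrame(roi_rows)
    roi_table.to_csv(out_dir / "roi_age_regression.tsv", sep="\t", index=False)
    report["stages"]["regress"] = {
        "model": cfg.stats_model,
        "alpha": cfg.alpha,
        "roi_tests": roi_rows,
        "vertexwise": vertex_summary,
        "elapsed_s": round(time.time() - t0, 2),
    }

    report["elapsed_s"] = round(time.time() - t_start, 2)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
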