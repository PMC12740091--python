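"""Quantitative validation benchmarks for the full pipeline.

Each function regenerates its own synthetic inputs from a seed, runs the
relevant package operations, and returns measured quantities (errors,
RMSEs, coverage rates).  They back both the acceptance test suite and the
standalone acceptance script.
"""

from __future__ import annotations

import numpy as np

from hippomicro.dki import fibonacci_sphere, fit_dki
from hippomicro.inversion import (
    add_rician_noise,
    build_training_set,
    train_inverter,
)
from hippomicro.randwalk import mc_sphere_signal
from hippomicro.sandi import AcquisitionProtocol, SandiParams, sphere_gpd_signal, sphmean_stick
from hippomicro.stats import (
    bh_fdr,
    ols_age_model,
    pooled_t_from_summary,
    vertexwise_regression,
)
from hippomicro.supres import SrConfig, block_downsample, nearest_upsample, super_resolve
from hippomicro.surface import SurfaceMesh, gyrification, mean_curvature, thickness
from hippomicro.synthetic import (
    AgeEffectModel,
    PhantomSpec,
    degrade_to_lowres,
    make_phantom,
    make_t1_reference,
    make_toy_mesh,
    simulate_cohort,
    simulate_subject_dwi,
)

__all__ = [
    "sex_balance_t",
    "gpd_vs_monte_carlo",
    "stick_vs_quadrature",
    "sr_consistency_and_benefit",
    "sandi_closed_loop",
    "dki_sanity",
    "surface_sanity",
    "stats_sanity",
    "cohort_recovery",
]

#: printed male/female age summaries of the emulated cohort
SEX_SUMMARY = dict(n1=32, mean1=42.25, sd1=17.99, n2=40, mean2=40.75, sd2=17.98)


def sex_balance_t() -> dict:
    """Two-sample t for the male/female age balance from group summaries."""
    t, dof, p = pooled_t_from_summary(**SEX_SUMMARY)
    return {"t": t, "p": p, "dof": dof}


def gpd_vs_monte_carlo(
    n_walkers: int = 100_000, b: float = 3.45, seed: int = 0
) -> dict:
    """Relative error of the GPD sphere signal against the reflected random
    walk, per soma radius, at the 8-shell protocol's timings."""
    proto = AcquisitionProtocol.default()
    out = {}
    for i, radius in enumerate((2.0, 5.0, 8.0, 11.0)):
        gpd = sphere_gpd_signal(proto, b, radius)
        mc = mc_sphere_signal(
            b, radius, 3.0, proto.delta_small, proto.delta_big,
            n_walkers=n_walkers, seed=seed + i,
        )
        out[radius] = abs(gpd - mc) / mc
    return out


def stick_vs_quadrature(n_grid: int = 20) -> float:
    """Max abs deviation of the closed-form stick spherical mean from
    Gauss–Legendre quadrature over a (b, D_in) grid."""
    x, w = np.polynomial.legendre.leggauss(400)
    bs = np.linspace(0.05, 6.0, n_grid)
    ds = np.linspace(0.25, 3.0, n_grid)
    worst = 0.0
    for b in bs:
        for d in ds:
            quad = float(np.sum(w * np.exp(-b * d * x**2)) / 2.0)
            worst = max(worst, abs(sphmean_stick(b, d) - quad))
    return worst


def _sr_protocol() -> AcquisitionProtocol:
    base = AcquisitionProtocol.default()
    return AcquisitionProtocol(
        shells=base.shells,
        directions_per_shell=(1,) * len(base.shells),
        delta_small=base.delta_small,
        delta_big=base.delta_big,
        b0_count=1,
    )


def sr_consistency_and_benefit(seed: int = 0) -> dict:
    """Super-resolution on the seeded two-tissue 32³ phantom.

    Returns the worst data-consistency deviation observed after every
    iteration, and masked RMSE vs ground truth for the super-resolved
    output and the nearest-neighbour baseline.
    """
    from hippomicro.supres import compute_norms, data_consistency, sr_iteration

    regions = {
        1: SandiParams(0.5, 0.2, 0.3, 8.0, 2.0, 1.0),
        2: SandiParams(0.2, 0.3, 0.5, 4.0, 1.5, 2.0),
    }
    spec = PhantomSpec(shape=(32, 32, 32), regions=regions, seed=seed)
    maps = make_phantom(spec)
    proto = _sr_protocol()  # one direction per shell + b0: 9 volumes
    dwi_hr, _ = simulate_subject_dwi(maps, proto, snr=None)
    dwi_lr = degrade_to_lowres(dwi_hr, 2, snr=50, seed=seed)
    ref = make_t1_reference(maps["labels"])
    cfg = SrConfig()
    mask = maps["mask"]

    worst_dev = 0.0
    sr = np.empty_like(dwi_hr.data)
    for v in range(dwi_lr.data.shape[3]):
        lr = dwi_lr.data[..., v]
        hr = nearest_upsample(lr, cfg.upsample_factor)
        norms = compute_norms(hr, ref, mask)
        for h in cfg.h_series:
            hr = sr_iteration(hr, ref, h, cfg, norms, mask)
            hr = data_consistency(hr, lr, cfg.upsample_factor)
            dev = float(np.max(np.abs(block_downsample(hr, 2) - lr)))
            worst_dev = max(worst_dev, dev)
        sr[..., v] = hr

    gt = dwi_hr.data
    nn = np.stack(
        [nearest_upsample(dwi_lr.data[..., v], 2) for v in range(gt.shape[3])],
        axis=-1,
    )

    def rmse(a):
        return float(np.sqrt(np.mean((a[mask] - gt[mask]) ** 2)))

    return {
        "max_consistency_dev": worst_dev,
        "sr_rmse": rmse(sr),
        "nn_rmse": rmse(nn),
    }


def sandi_closed_loop(
    n_train: int = 10_000, n_trees: int = 50, n_test: int = 2000, seed: int = 0
) -> dict:
    """Build → train → fit on fresh simulated voxels.

    Noiseless branch: held-out f_soma RMSE.  SNR-50 branch: model trained
    on Rician-noised signals applied to noisy test signals; fraction RMSEs
    and R_soma median absolute error for true radii in [3, 10] μm.
    """
    proto = AcquisitionProtocol.default()
    ts = build_training_set(n_train, proto, snr=None, seed=seed + 1)
    model = train_inverter(ts, n_trees=n_trees)
    test = build_training_set(n_test, proto, snr=None, seed=seed + 2)
    pred = model.predict(test.signals)
    rmse_fsoma = float(np.sqrt(np.mean((pred["f_soma"] - test.targets[:, 0]) ** 2)))

    ts50 = build_training_set(n_train, proto, snr=50.0, seed=seed + 3)
    model50 = train_inverter(ts50, n_trees=n_trees)
    test50 = build_training_set(n_test, proto, snr=None, seed=seed + 4)
    rng = np.random.default_rng(seed + 5)
    noisy = add_rician_noise(test50.signals, 50.0, rng)
    pred50 = model50.predict(noisy)
    rmse50_fsoma = float(
        np.sqrt(np.mean((pred50["f_soma"] - test50.targets[:, 0]) ** 2))
    )
    rmse50_fneurite = float(
        np.sqrt(np.mean((pred50["f_neurite"] - test50.targets[:, 1]) ** 2))
    )
    sel = (test50.targets[:, 2] >= 3.0) & (test50.targets[:, 2] <= 10.0)
    mae_rsoma = float(
        np.median(np.abs(pred50["r_soma"][sel] - test50.targets[sel, 2]))
    )
    return {
        "noiseless_fsoma_rmse": rmse_fsoma,
        "snr50_fsoma_rmse": rmse50_fsoma,
        "snr50_fneurite_rmse": rmse50_fneurite,
        "snr50_rsoma_mae_um": mae_rsoma,
    }


def dki_sanity() -> dict:
    """Isotropic mono-exponential input: MD/FA/MK errors of the kurtosis fit."""
    nd = 30
    shells = (0.8, 1.5, 2.4, 3.45)
    bvals = np.concatenate([[0.0], np.repeat(shells, nd)])
    bvecs = np.vstack([[0, 0, 0], np.tile(fibonacci_sphere(nd), (len(shells), 1))])
    sig = np.exp(-bvals * 1.0)[None, None, None, :]
    m = fit_dki(sig, bvals, bvecs)
    return {
        "md_err": float(abs(m.md.ravel()[0] - 1.0)),
        "fa_err": float(abs(m.fa.ravel()[0])),
        "mk_err": float(abs(m.mk.ravel()[0])),
    }


def surface_sanity() -> dict:
    """Unit-sphere curvature, identity gyrification, parallel-plane thickness."""
    sphere = make_toy_mesh("sphere", radius=1.0, subdivisions=5)
    h = mean_curvature(sphere)
    curv_err = float(np.nanmax(np.abs(h - 1.0)))

    copy = SurfaceMesh(vertices=sphere.vertices.copy(), faces=sphere.faces.copy())
    gyr = gyrification(sphere, copy)
    gyr_dev = float(np.max(np.abs(gyr - 1.0)))

    plane = make_toy_mesh("plane", n=12)
    shifted = SurfaceMesh(
        vertices=plane.vertices + np.array([0.0, 0.0, 2.0]), faces=plane.faces.copy()
    )
    thick = thickness(plane, shifted)
    thick_err = float(np.max(np.abs(thick - 2.0)))
    return {
        "sphere_curvature_max_rel_err": curv_err,
        "gyrification_identity_dev": gyr_dev,
        "plane_thickness_err": thick_err,
    }


def _brute_force_bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj


def stats_sanity(seed: int = 0, n_vectors: int = 1000, n_null: int = 200) -> dict:
    """BH-FDR vs brute-force oracle, r↔t identity, and the null-cohort
    vertexwise false-positive vertex fraction."""
    rng = np.random.default_rng(seed)
    bh_dev = 0.0
    for _ in range(n_vectors):
        p = rng.random(rng.integers(1, 50))
        bh_dev = max(bh_dev, float(np.max(np.abs(bh_fdr(p) - _brute_force_bh(p)))))

    ident_dev = 0.0
    ages = rng.uniform(19, 85, 72)
    for _ in range(50):
        y = rng.normal(size=72) + rng.uniform(-0.05, 0.05) * ages
        res = ols_age_model(y, ages, model="M1")
        t_from_r = res.r * np.sqrt(res.n - 2) / np.sqrt(1 - res.r**2)
        ident_dev = max(ident_dev, float(abs(t_from_r - res.t_age)))

    sexes = np.r_[np.ones(32), np.zeros(40)]
    fracs = []
    for _ in range(n_null):
        maps = rng.normal(size=(72, 100))
        out = vertexwise_regression(maps, ages, sexes)
        fracs.append(float(out["significant"].mean()))
    return {
        "bh_vs_bruteforce_max_dev": bh_dev,
        "r_t_identity_max_dev": ident_dev,
        "null_fdr_positive_fraction": float(np.mean(fracs)),
    }


def cohort_recovery(seed: int = 0, n_reps: int = 200) -> dict:
    """Fraction of synthetic cohorts whose estimated age correlation falls
    inside the Fisher-z ± 2/√(n−3) band around the target, at n = 72."""
    out = {}
    for target in (-0.6, -0.3, 0.0):
        eff = AgeEffectModel(targets={"f_soma": (target, 0.05)})
        inside = 0
        for rep in range(n_reps):
            table, _ = simulate_cohort(72, eff, seed=seed + 7000 + rep)
            r = float(np.corrcoef(table["age"], table["roi1_f_soma"])[0, 1])
            inside += abs(np.arctanh(r) - np.arctanh(target)) <= 2.0 / np.sqrt(72 - 3)
        out[target] = inside / n_reps
    return out
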