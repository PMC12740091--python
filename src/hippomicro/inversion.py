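"""SANDI parameter estimation from spherical-mean shell signals.

The inversion follows the machine-learning strategy of the SANDI toolbox:
simulate a large training set of noisy spherical-mean signals over the
physiological parameter ranges, train one random-forest regressor per
parameter, and apply the ensemble voxelwise.  The extracellular fraction is
recovered from the simplex constraint f_soma + f_neurite + f_extra = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from hippomicro.dwi import B0_MAX, DwiVolume, group_shells
from hippomicro.sandi import (
    D_RANGE,
    R_SOMA_RANGE,
    AcquisitionProtocol,
    sandi_signal_batch,
)

__all__ = [
    "TrainingSet",
    "InverterModel",
    "SnrMap",
    "spherical_mean_shells",
    "estimate_snr",
    "build_training_set",
    "train_inverter",
    "fit_sandi",
    "add_rician_noise",
]

#: order of regression targets throughout this module
TARGET_NAMES = ("f_soma", "f_neurite", "r_soma", "d_in", "d_e")

TARGET_RANGES = {
    "f_soma": (0.0, 1.0),
    "f_neurite": (0.0, 1.0),
    "r_soma": R_SOMA_RANGE,
    "d_in": D_RANGE,
    "d_e": D_RANGE,
}

DEFAULT_SEED = 20250101


def add_rician_noise(signals: np.ndarray, snr: float, rng: np.random.Generator) -> np.ndarray:
    """Rician-perturb b0-normalized signals: √((S+ε₁)² + ε₂²), ε ~ N(0, σ²)
    with σ = 1/snr (the b0 level of normalized signals is 1)."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    sigma = 1.0 / snr
    e1 = rng.normal(0.0, sigma, size=signals.shape)
    e2 = rng.normal(0.0, sigma, size=signals.shape)
    return np.sqrt((signals + e1) ** 2 + e2**2)


@dataclass
class TrainingSet:
    """Simulated (signal, parameter) pairs for supervised inversion."""

    signals: np.ndarray  # (n, n_shells)
    targets: np.ndarray  # (n, 5) columns in TARGET_NAMES order
    shells: np.ndarray  # shell b-values, ms/μm²
    seed: int
    snr: float | None


@dataclass
class InverterModel:
    """One fitted tree-ensemble regressor per SANDI parameter."""

    regressors: dict
    shells: np.ndarray
    n_trees: int
    seed: int
    snr: float | None

    def predict(self, signals: np.ndarray) -> dict:
        """Predict all parameters for (n, n_shells) signals, clipped to the
        training ranges."""
        signals = np.asarray(signals, dtype=float)
        if signals.ndim != 2 or signals.shape[1] != len(self.shells):
            raise ValueError(
                f"expected (n, {len(self.shells)}) signals, got {signals.shape}"
            )
        out = {}
        for name in TARGET_NAMES:
            lo, hi = TARGET_RANGES[name]
            out[name] = np.clip(self.regressors[name].predict(signals), lo, hi)
        return out

    def save(self, path) -> None:
        joblib.dump(self, str(path))

    @classmethod
    def load(cls, path) -> "InverterModel":
        return joblib.load(str(path))


@dataclass
class SnrMap:
    """Voxelwise SNR = mean b0 / noise σ, plus a scalar in-mask summary."""

    map: np.ndarray
    mask: np.ndarray
    median: float


def spherical_mean_shells(
    dwi: DwiVolume, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel spherical-mean signal of each non-zero shell, normalized by
    the mean b = 0 signal.

    Returns ``(shell_bvals, means)`` with ``means`` of shape
    (x, y, z, n_shells); voxels with non-positive b0 (or outside ``mask``)
    are NaN.
    """
    shell_bvals, shell_index = dwi.shells()
    if not np.any(shell_bvals < B0_MAX):
        raise ValueError("no b = 0 volumes in the series")
    b0 = dwi.data[..., dwi.b0_mask].mean(axis=-1)
    nz_shells = shell_bvals[shell_bvals >= B0_MAX]
    means = np.empty(dwi.shape3d + (len(nz_shells),))
    for j, b in enumerate(np.flatnonzero(shell_bvals >= B0_MAX)):
        sel = shell_index == b
        if not np.any(sel):
            raise ValueError(f"shell {shell_bvals[b]} has no directions")
        means[..., j] = dwi.data[..., sel].mean(axis=-1)
    valid = b0 > 0
    if mask is not None:
        valid &= mask.astype(bool)
    means[valid] /= b0[valid, None]
    means[~valid] = np.nan
    return nz_shells, means


def estimate_snr(
    b0_volumes: np.ndarray,
    noise_sigma_map: np.ndarray,
    upsample_factor: int = 1,
    mask: np.ndarray | None = None,
) -> SnrMap:
    """Voxelwise SNR of the b = 0 images.

    The variance map σ² (not σ) is upsampled by nearest-neighbour
    replication and re-rooted, so that the variance bookkeeping survives
    interpolation of i.i.d.-noise maps; SNR = mean(b0)/σ on the target grid.
    """
    from hippomicro.supres import nearest_upsample

    b0_volumes = np.asarray(b0_volumes, dtype=float)
    if b0_volumes.ndim == 3:
        b0_volumes = b0_volumes[..., None]
    mean_b0 = b0_volumes.mean(axis=-1)
    sigma_hr = np.sqrt(nearest_upsample(np.asarray(noise_sigma_map, dtype=float) ** 2,
                                        upsample_factor))
    if sigma_hr.shape != mean_b0.shape:
        raise ValueError(
            f"σ map shape {sigma_hr.shape} does not match b0 shape {mean_b0.shape}"
        )
    if mask is None:
        mask = np.ones(mean_b0.shape, dtype=bool)
    mask = mask.astype(bool)
    n_zero = int(np.count_nonzero(sigma_hr[mask] <= 0))
    if n_zero:
        raise ValueError(f"σ = 0 at {n_zero} in-mask voxels")
    snr = np.full(mean_b0.shape, np.nan)
    snr[mask] = mean_b0[mask] / sigma_hr[mask]
    return SnrMap(map=snr, mask=mask, median=float(np.median(snr[mask])))


def build_training_set(
    n_samples: int,
    protocol: AcquisitionProtocol,
    snr: float | None = None,
    seed: int = DEFAULT_SEED,
) -> TrainingSet:
    """Uniformly sample parameters and simulate their shell signals.

    f_soma and f_neurite are uniform on [0, 1] restricted to
    f_soma + f_neurite ≤ 1 (uniform over the simplex triangle, by
    rejection); f_extra is the remainder.  R_soma, D_in, D_e are uniform on
    their physiological ranges.  With ``snr`` set, signals receive Rician
    noise with σ = 1/snr.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    rng = np.random.default_rng(seed)
    f_soma = np.empty(n_samples)
    f_neurite = np.empty(n_samples)
    need = np.ones(n_samples, dtype=bool)
    while np.any(need):
        k = int(need.sum())
        fs = rng.random(k)
        fn = rng.random(k)
        ok = fs + fn <= 1.0
        idx = np.flatnonzero(need)[ok]
        f_soma[idx] = fs[ok]
        f_neurite[idx] = fn[ok]
        need[idx] = False
    r_soma = rng.uniform(*R_SOMA_RANGE, size=n_samples)
    d_in = rng.uniform(*D_RANGE, size=n_samples)
    d_e = rng.uniform(*D_RANGE, size=n_samples)
    signals = sandi_signal_batch(f_soma, f_neurite, r_soma, d_in, d_e, protocol)
    if snr is not None:
        signals = add_rician_noise(signals, snr, rng)
    targets = np.column_stack([f_soma, f_neurite, r_soma, d_in, d_e])
    return TrainingSet(
        signals=signals,
        targets=targets,
        shells=protocol.b_values,
        seed=seed,
        snr=snr,
    )


def train_inverter(training_set: TrainingSet, n_trees: int = 200) -> InverterModel:
    """Fit one random-forest regressor per SANDI parameter.

    Forest hyper-parameters beyond the tree count are the library defaults;
    they are recorded in the model metadata via the fitted estimators.
    """
    if len(training_set.signals) == 0:
        raise ValueError("empty training set")
    regs = {}
    for j, name in enumerate(TARGET_NAMES):
        y = training_set.targets[:, j]
        if np.ptp(y) == 0:
            raise ValueError(f"target {name} is constant; cannot train")
        reg = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=training_set.seed + j,
            n_jobs=1,
        )
        reg.fit(training_set.signals, y)
        regs[name] = reg
    return InverterModel(
        regressors=regs,
        shells=training_set.shells,
        n_trees=n_trees,
        seed=training_set.seed,
        snr=training_set.snr,
    )


def fit_sandi(
    shell_means: np.ndarray, model: InverterModel, mask: np.ndarray | None = None
) -> dict:
    """Apply a trained inverter to a (..., n_shells) map of shell means.

    Returns a dict of parameter maps (f_soma, f_neurite, f_extra, r_soma,
    d_in, d_e) with NaN at masked/invalid voxels.  f_extra is the simplex
    remainder; negative remainders are clipped to 0 and the (f_soma,
    f_neurite) pair rescaled to sum to 1.
    """
    shell_means = np.asarray(shell_means, dtype=float)
    spatial = shell_means.shape[:-1]
    flat = shell_means.reshape(-1, shell_means.shape[-1])
    valid = ~np.any(np.isnan(flat), axis=1)
    if mask is not None:
        valid &= mask.astype(bool).ravel()
    out = {name: np.full(flat.shape[0], np.nan) for name in
           ("f_soma", "f_neurite", "f_extra", "r_soma", "d_in", "d_e")}
    if np.any(valid):
        pred = model.predict(flat[valid])
        fs, fn = pred["f_soma"], pred["f_neurite"]
        fe = 1.0 - fs - fn
        neg = fe < 0
        if np.any(neg):
            fe[neg] = 0.0
            total = fs[neg] + fn[neg]
            fs[neg] /= total
            fn[neg] /= total
        out["f_soma"][valid] = fs
        out["f_neurite"][valid] = fn
        out["f_extra"][valid] = fe
        for name in ("r_soma", "d_in", "d_e"):
            out[name][valid] = pred[name]
    return {name: arr.reshape(spatial) for name, arr in out.items()}
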