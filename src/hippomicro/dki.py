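"""Constrained diffusion kurtosis imaging (DKI) fit on the low-b shells.

The signal representation is

    ln S(b, n) = ln S0 − b · D(n) + (b²/6) · V(n),     V(n) = MD̄² · K(n)

with D(n) = nᵀDn the apparent diffusivity along unit direction n and V the
fourth-order (kurtosis × MD²) tensor contraction — 22 linear coefficients
(1 + 6 + 15).  The fit is weighted linear least squares; physical
constraints (non-negative apparent diffusivity and kurtosis, and monotonic
signal decay over the fitted b-range) are linear in the coefficients and
enforced by quadratic-programming projection on the voxels that violate
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["DkiMetrics", "fit_dki", "dki_design_matrix", "fibonacci_sphere"]

# unique index pairs of the symmetric 3x3 tensor, with multiplicities
_D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_D_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

# unique index quadruples of the fully symmetric rank-4 tensor
_W_IDX = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1),
    (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
_W_MULT = np.array([1.0, 1.0, 1.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0,
                    6.0, 6.0, 6.0, 12.0, 12.0, 12.0])


@dataclass
class DkiMetrics:
    """Per-voxel tensor and kurtosis summaries.

    Diffusivities in μm²/ms; FA and kurtosis dimensionless.
    """

    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    fa: np.ndarray
    mk: np.ndarray
    ak: np.ndarray
    rk: np.ndarray

    def as_dict(self) -> dict:
        return {"md": self.md, "ad": self.ad, "rd": self.rd, "fa": self.fa,
                "mk": self.mk, "ak": self.ak, "rk": self.rk}


def fibonacci_sphere(n: int = 60) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _dir_basis(bvecs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-direction rows mapping coefficient vectors to D(n) and V(n)."""
    bvecs = np.asarray(bvecs, dtype=float)
    d_rows = np.stack(
        [_D_MULT[k] * bvecs[:, i] * bvecs[:, j] for k, (i, j) in enumerate(_D_IDX)],
        axis=1,
    )
    v_rows = np.stack(
        [
            _W_MULT[k] * bvecs[:, i] * bvecs[:, j] * bvecs[:, l] * bvecs[:, m]
            for k, (i, j, l, m) in enumerate(_W_IDX)
        ],
        axis=1,
    )
    return d_rows, v_rows


def dki_design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """(n_meas, 22) design: columns = [1, −b·D-basis(6), (b²/6)·V-basis(15)]."""
    bvals = np.asarray(bvals, dtype=float)
    d_rows, v_rows = _dir_basis(bvecs)
    return np.column_stack(
        [
            np.ones(len(bvals)),
            -bvals[:, None] * d_rows,
            (bvals[:, None] ** 2 / 6.0) * v_rows,
        ]
    )


def _constraint_matrix(bvecs: np.ndarray, b_max: float) -> np.ndarray:
    """Linear constraints A·β ≥ 0 at each test direction:

    D(n) ≥ 0, V(n) ≥ 0, and D(n) − (b_max/3)·V(n) ≥ 0 (monotonic decay of
    ln S in b over [0, b_max])."""
    d_rows, v_rows = _dir_basis(bvecs)
    z6 = np.zeros_like(d_rows)
    z15 = np.zeros_like(v_rows)
    one = np.zeros((len(bvecs), 1))
    a_d = np.hstack([one, d_rows, z15])
    a_v = np.hstack([one, z6, v_rows])
    a_mono = np.hstack([one, d_rows, -(b_max / 3.0) * v_rows])
    return np.vstack([a_d, a_v, a_mono])


def _summaries(beta: np.ndarray, n_mk: int = 200) -> tuple[float, ...]:
    d_tensor = np.empty((3, 3))
    for k, (i, j) in enumerate(_D_IDX):
        d_tensor[i, j] = d_tensor[j, i] = beta[1 + k]
    evals, evecs = np.linalg.eigh(d_tensor)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]
    md = float(evals.mean())
    ad = float(evals[0])
    rd = float((evals[1] + evals[2]) / 2.0)
    denom = np.sqrt((evals**2).sum())
    fa = 0.0 if denom == 0 else float(
        np.sqrt(1.5 * ((evals - md) ** 2).sum()) / denom
    )

    v_coef = beta[7:]

    def k_app(dirs: np.ndarray) -> np.ndarray:
        d_rows, v_rows = _dir_basis(dirs)
        d_app = d_rows @ beta[1:7]
        v_app = v_rows @ v_coef
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(d_app > 1e-12, v_app / np.maximum(d_app, 1e-12) ** 2, 0.0)
        return k

    mk = float(k_app(fibonacci_sphere(n_mk)).mean())
    ak = float(k_app(evecs[:, :1].T)[0])
    ang = np.linspace(0.0, np.pi, 30, endpoint=False)
    perp = np.outer(np.cos(ang), evecs[:, 1]) + np.outer(np.sin(ang), evecs[:, 2])
    rk = float(k_app(perp).mean())
    return md, ad, rd, fa, mk, ak, rk


def fit_dki(
    data: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    mask: np.ndarray | None = None,
    b_max: float = 3.5,
    use_shells: tuple | None = (0.0, 0.8, 1.5, 2.4, 3.45),
    constrain: bool = True,
) -> DkiMetrics:
    """Fit the kurtosis representation voxelwise on the low-b shells.

    By default only the b = 0, 0.8, 1.5, 2.4 and 3.45 ms/μm² shells enter
    the fit (the two lowest diffusion weightings are excluded); pass
    ``use_shells=None`` to fit every shell with b ≤ ``b_max`` instead.
    ``data`` is (..., n_meas) signal (not log); weights are the squared
    signals (the standard log-linear WLS weighting).  Requires at least two
    non-zero shells and 15 directions after shell restriction.
    """
    data = np.asarray(data, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if use_shells is not None:
        keep = np.any(
            np.abs(bvals[:, None] - np.asarray(use_shells)[None, :]) < 0.025, axis=1
        )
        b_max = float(max(use_shells))
    else:
        keep = bvals <= b_max + 1e-9
    bvals, bvecs, data = bvals[keep], bvecs[keep], data[..., keep]
    nz = np.unique(np.round(bvals[bvals >= 0.025], 3))
    if len(nz) < 2:
        raise ValueError("need at least two non-zero shells for the kurtosis fit")
    if np.count_nonzero(bvals >= 0.025) < 15:
        raise ValueError("need at least 15 diffusion-weighted directions")

    design = dki_design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        u, s, vt = np.linalg.svd(design)
        deficient = np.flatnonzero(s < 1e-10 * s[0])
        raise ValueError(
            f"rank-deficient kurtosis design ({design.shape[1] - len(deficient)} of "
            f"{design.shape[1]} identifiable); add gradient directions"
        )

    constraints = _constraint_matrix(
        np.vstack([bvecs[bvals >= 0.025], fibonacci_sphere(60)]), b_max
    ) if constrain else None

    spatial = data.shape[:-1]
    flat = data.reshape(-1, data.shape[-1])
    if mask is None:
        valid = np.all(flat > 0, axis=1)
    else:
        valid = mask.astype(bool).ravel() & np.all(flat > 0, axis=1)

    maps = {k: np.full(flat.shape[0], np.nan) for k in
            ("md", "ad", "rd", "fa", "mk", "ak", "rk")}
    for idx in np.flatnonzero(valid):
        s = flat[idx]
        y = np.log(s)
        w = s**2
        xtw = design.T * w
        beta = np.linalg.solve(xtw @ design, xtw @ y)
        if constraints is not None and np.any(constraints @ beta < -1e-10):
            beta = _project_constrained(design, y, w, constraints, beta)
        md, ad, rd, fa, mk, ak, rk = _summaries(beta)
        for key, val in zip(("md", "ad", "rd", "fa", "mk", "ak", "rk"),
                            (md, ad, rd, fa, mk, ak, rk)):
            maps[key][idx] = val
    return DkiMetrics(**{k: v.reshape(spatial) for k, v in maps.items()})


def _project_constrained(design, y, w, constraints, beta0) -> np.ndarray:
    """Weighted least squares subject to A·β ≥ 0, via SLSQP from the
    unconstrained solution."""
    xtw = design.T * w

    def cost(beta):
        r = design @ beta - y
        return float(r @ (w * r))

    def grad(beta):
        return 2.0 * (xtw @ (design @ beta - y))

    res = minimize(
        cost,
        beta0,
        jac=grad,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": lambda b: constraints @ b,
                      "jac": lambda b: constraints}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return res.x
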