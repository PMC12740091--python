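"""SANDI forward model for spherical-mean (powder-averaged) diffusion signals.

The model decomposes the gray-matter diffusion signal into three
compartments: restricted diffusion inside impermeable spheres (cell
somas), one-dimensional diffusion inside sticks (neurites), and isotropic
Gaussian diffusion outside cells.  Exchange between compartments is
neglected, which is a good approximation at short diffusion times.

Internal units keep magnitudes O(1):

========  ===========  =========================
quantity  unit         typical range
========  ===========  =========================
b-value   ms/μm²       0.05 – 6  (50–6000 s/mm²)
D         μm²/ms       0.25 – 3
R_soma    μm           1 – 12
δ, Δ      ms           8, 19
========  ===========  =========================

External FSL-style b-values in s/mm² are divided by 1000 on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, jv, jvp

__all__ = [
    "D_IS_DEFAULT",
    "R_SOMA_RANGE",
    "D_RANGE",
    "AcquisitionProtocol",
    "SandiParams",
    "GpdRootTable",
    "gpd_roots",
    "sphmean_stick",
    "sphmean_ball",
    "sphere_gpd_signal",
    "sandi_signal",
    "sandi_signal_batch",
]

#: intra-soma diffusivity, fixed during training (μm²/ms)
D_IS_DEFAULT = 3.0
#: uniform sampling range of the soma radius (μm)
R_SOMA_RANGE = (1.0, 12.0)
#: uniform sampling range of the intra-neurite and extracellular diffusivities (μm²/ms)
D_RANGE = (0.25, 3.0)

_B_EPS = 1e-8  # b below this is treated as b = 0


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Multi-shell PGSE acquisition: shell b-values, direction counts, timings.

    ``shells`` are the non-zero b-values in ms/μm² (a 0 entry is allowed and
    yields unit signal).  ``delta_small`` (δ) is the gradient pulse duration,
    ``delta_big`` (Δ) the pulse separation / diffusion time, both in ms.
    """

    shells: tuple[float, ...]
    directions_per_shell: tuple[int, ...]
    delta_small: float
    delta_big: float
    b0_count: int = 1

    def __post_init__(self) -> None:
        if len(self.shells) != len(self.directions_per_shell):
            raise ValueError("shells and directions_per_shell lengths differ")
        if any(b < 0 for b in self.shells):
            raise ValueError("b-values must be non-negative")
        if not self.delta_small < self.delta_big:
            raise ValueError(f"require δ < Δ, got δ={self.delta_small}, Δ={self.delta_big}")
        if self.delta_small <= 0:
            raise ValueError("pulse duration δ must be positive")
        if any(n < 1 for b, n in zip(self.shells, self.directions_per_shell) if b > 0):
            raise ValueError("each b > 0 shell needs at least one direction")
        if self.b0_count < 0:
            raise ValueError("b0_count must be non-negative")

    @classmethod
    def default(cls) -> "AcquisitionProtocol":
        """The 8-shell Connectome protocol: b = 50…6000 s/mm², δ = 8 ms,
        Δ = 19 ms, 32 directions below b = 2.3 ms/μm² and 64 above, with a
        b = 0 image interleaved every 16 diffusion-weighted volumes."""
        shells = (0.05, 0.35, 0.8, 1.5, 2.4, 3.45, 4.75, 6.0)
        dirs = tuple(32 if b < 2.3 else 64 for b in shells)
        return cls(
            shells=shells,
            directions_per_shell=dirs,
            delta_small=8.0,
            delta_big=19.0,
            b0_count=sum(dirs) // 16,
        )

    @property
    def b_values(self) -> np.ndarray:
        return np.asarray(self.shells, dtype=float)


@dataclass(frozen=True)
class SandiParams:
    """One voxel's compartment parameters.

    Signal fractions sum to one; ``d_is`` is held at its training constant
    unless explicitly overridden.
    """

    f_soma: float
    f_neurite: float
    f_extra: float
    r_soma: float
    d_in: float
    d_e: float
    d_is: float = D_IS_DEFAULT

    def __post_init__(self) -> None:
        total = self.f_soma + self.f_neurite + self.f_extra
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"signal fractions must sum to 1, got {total!r}")
        for name, f in (("f_soma", self.f_soma), ("f_neurite", self.f_neurite),
                        ("f_extra", self.f_extra)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {f}")
        if not R_SOMA_RANGE[0] <= self.r_soma <= R_SOMA_RANGE[1]:
            raise ValueError(f"r_soma outside {R_SOMA_RANGE}: {self.r_soma}")
        for name, d in (("d_in", self.d_in), ("d_e", self.d_e)):
            if not D_RANGE[0] <= d <= D_RANGE[1]:
                raise ValueError(f"{name} outside {D_RANGE}: {d}")
        if self.d_is <= 0:
            raise ValueError("d_is must be positive")

    def as_array(self) -> np.ndarray:
        """(f_soma, f_neurite, r_soma, d_in, d_e) — the five free parameters."""
        return np.array([self.f_soma, self.f_neurite, self.r_soma, self.d_in, self.d_e])


@dataclass(frozen=True)
class GpdRootTable:
    """Dimensionless eigenvalue roots x_m of the reflecting-sphere boundary
    condition x·J'_{3/2}(x) = ½·J_{3/2}(x); α_m = x_m / R."""

    roots: np.ndarray

    @property
    def count(self) -> int:
        return len(self.roots)


def _sphere_boundary_residual(x: float) -> float:
    # x J'_{3/2}(x) − ½ J_{3/2}(x) = 0  ⇔  j₁'(x) = 0 (spherical Bessel)
    return x * jvp(1.5, x) - 0.5 * jv(1.5, x)


@lru_cache(maxsize=None)
def _gpd_roots_cached(n: int) -> tuple[float, ...]:
    roots: list[float] = []
    step = 0.05
    lo = step
    f_lo = _sphere_boundary_residual(lo)
    x = lo
    while len(roots) < n:
        x_next = x + step
        f_next = _sphere_boundary_residual(x_next)
        if f_lo == 0.0:
            roots.append(x)
        elif np.sign(f_lo) != np.sign(f_next):
            r = brentq(_sphere_boundary_residual, x, x_next, xtol=1e-14, rtol=1e-15)
            if abs(_sphere_boundary_residual(r)) >= 1e-10:
                raise RuntimeError(
                    f"root refinement failed on interval ({x:.4f}, {x_next:.4f})"
                )
            roots.append(r)
        x, f_lo = x_next, f_next
        if x > 20.0 + np.pi * n:  # roots are asymptotically π-spaced
            raise RuntimeError(f"root bracketing ran past x={x:.1f} with {len(roots)}/{n} roots")
    return tuple(roots)


def gpd_roots(n: int = 20) -> GpdRootTable:
    """First ``n`` positive roots of the sphere boundary condition, cached.

    The first root is ≈ 2.0816; successive gaps approach π.
    """
    if n < 1:
        raise ValueError("need at least one root")
    return GpdRootTable(roots=np.array(_gpd_roots_cached(n)))


def sphmean_stick(b, d_in):
    """Spherical mean of the stick (zero-radius cylinder) compartment.

    Averaging exp(−b·D_in·cos²θ) over the unit sphere gives the closed form
    S = √(π/(4·b·D_in)) · erf(√(b·D_in)), continuous at b → 0 with limit 1.
    """
    b = np.asarray(b, dtype=float)
    d_in = np.asarray(d_in, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    if np.any(d_in <= 0):
        raise ValueError("d_in must be positive")
    bd = b * d_in
    out = np.ones(np.broadcast_shapes(b.shape, d_in.shape))
    nz = np.broadcast_to(bd, out.shape) > _B_EPS
    bd_nz = np.broadcast_to(bd, out.shape)[nz]
    out[nz] = np.sqrt(np.pi / (4.0 * bd_nz)) * erf(np.sqrt(bd_nz))
    if out.ndim == 0 or (np.isscalar(b) and np.isscalar(d_in)):
        return float(out) if out.ndim == 0 else out
    return out


def sphmean_ball(b, d_e):
    """Isotropic Gaussian (ball) compartment: S = exp(−b·D_e).

    The spherical mean equals the per-direction signal because the
    compartment is isotropic.
    """
    b = np.asarray(b, dtype=float)
    d_e = np.asarray(d_e, dtype=float)
    if np.any(b < 0) or np.any(d_e < 0):
        raise ValueError("b and d_e must be non-negative")
    out = np.exp(-b * d_e)
    return float(out) if out.ndim == 0 else out


def sphere_gpd_signal(protocol, b, r_soma, d_is=D_IS_DEFAULT, roots=None):
    """Murday–Cotts (Gaussian phase distribution) signal of spins restricted
    in an impermeable sphere of radius ``r_soma`` under a PGSE sequence.

    With α_m = x_m/R (x_m the boundary-condition roots), τ_m = α_m²·D_is and
    (γg)² recovered from b = (γg)²·δ²·(Δ − δ/3):

        −ln S = 2(γg)² Σ_m [1 / (α_m²(α_m²R² − 2))] ·
                [2δ/τ_m − (2 + e^{−τ(Δ−δ)} − 2e^{−τδ} − 2e^{−τΔ}
                           + e^{−τ(Δ+δ)}) / τ²]

    The signal is orientation-independent, so it equals its own spherical
    mean.  ``r_soma`` may be an array; the return broadcasts accordingly.
    """
    if roots is None:
        roots = gpd_roots()
    b = float(b)
    if b < 0:
        raise ValueError("b must be non-negative")
    if d_is <= 0:
        raise ValueError("d_is must be positive")
    r = np.asarray(r_soma, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r_soma must be positive")
    delta, bigdelta = protocol.delta_small, protocol.delta_big
    if b > _B_EPS and not delta < bigdelta:
        raise ValueError("degenerate PGSE timings: require δ < Δ")
    if b <= _B_EPS:
        out = np.ones_like(r)
        return float(out) if out.ndim == 0 else out

    gg2 = b / (delta**2 * (bigdelta - delta / 3.0))  # (γg)², 1/(ms²·μm²)
    x = roots.roots  # (m,)
    rr = r[..., None]  # (..., 1)
    alpha2 = (x / rr) ** 2  # (..., m)
    tau = alpha2 * d_is
    expm = np.exp
    series_t = (
        2.0 * delta / tau
        - (
            2.0
            + expm(-tau * (bigdelta - delta))
            - 2.0 * expm(-tau * delta)
            - 2.0 * expm(-tau * bigdelta)
            + expm(-tau * (bigdelta + delta))
        )
        / tau**2
    )
    # the bracket suffers catastrophic cancellation as τ → 0 (frozen spins /
    # vanishing restriction); switch to its Taylor expansion there
    small = tau * (bigdelta + delta) < 1e-3
    if np.any(small):
        series_small = (
            tau * delta**2 * (bigdelta - delta / 3.0)
            - tau**2 * bigdelta**2 * delta**2 / 2.0
        )
        series_t = np.where(small, series_small, series_t)
    coef = 1.0 / (alpha2 * (x**2 - 2.0))
    neg_log_s = 2.0 * gg2 * np.sum(coef * series_t, axis=-1)
    out = np.exp(-neg_log_s)
    return float(out) if out.ndim == 0 else out


def sandi_signal(params: SandiParams, protocol: AcquisitionProtocol,
                 roots: GpdRootTable | None = None) -> np.ndarray:
    """b0-normalized spherical-mean signal of the three-compartment mixture,
    one value per protocol shell:

        S(b) = f_soma·S_sphere(b) + f_neurite·S_stick(b) + f_extra·S_ball(b)
    """
    out = sandi_signal_batch(
        np.array([params.f_soma]),
        np.array([params.f_neurite]),
        np.array([params.r_soma]),
        np.array([params.d_in]),
        np.array([params.d_e]),
        protocol,
        d_is=params.d_is,
        roots=roots,
    )
    return out[0]


def sandi_signal_batch(f_soma, f_neurite, r_soma, d_in, d_e,
                       protocol: AcquisitionProtocol,
                       d_is: float = D_IS_DEFAULT,
                       roots: GpdRootTable | None = None) -> np.ndarray:
    """Vectorized forward model: (n,) parameter arrays → (n, n_shells) signals.

    Used to generate regression training sets at scale; f_extra is the
    remainder 1 − f_soma − f_neurite (must be non-negative).
    """
    if roots is None:
        roots = gpd_roots()
    f_soma = np.asarray(f_soma, dtype=float)
    f_neurite = np.asarray(f_neurite, dtype=float)
    r_soma = np.asarray(r_soma, dtype=float)
    d_in = np.asarray(d_in, dtype=float)
    d_e = np.asarray(d_e, dtype=float)
    f_extra = 1.0 - f_soma - f_neurite
    if np.any(f_extra < -1e-9) or np.any(f_soma < 0) or np.any(f_neurite < 0):
        raise ValueError("signal fractions must be non-negative and sum to at most 1")
    f_extra = np.clip(f_extra, 0.0, 1.0)
    bvals = protocol.b_values
    out = np.empty((len(f_soma), len(bvals)))
    for j, b in enumerate(bvals):
        if b <= _B_EPS:
            out[:, j] = 1.0
            continue
        s_sphere = sphere_gpd_signal(protocol, b, r_soma, d_is=d_is, roots=roots)
        s_stick = sphmean_stick(b, d_in)
        s_ball = sphmean_ball(b, d_e)
        out[:, j] = f_soma * s_sphere + f_neurite * s_stick + f_extra * s_ball
    return out
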