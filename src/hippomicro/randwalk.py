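"""Monte-Carlo PGSE simulation of diffusion inside a reflecting sphere.

Random walkers diffuse inside an impermeable sphere; each accumulates the
spin phase imparted by a pulsed-gradient spin-echo sequence (gradient on
during [0, δ) with one sign and during [Δ, Δ+δ) with the opposite sign).
The echo signal is the ensemble average of cos(phase).

This simulator shares no code with the Gaussian-phase-distribution closed
form in :mod:`hippomicro.sandi`: it works directly from the stochastic
dynamics and serves as an independent reference for the restricted-sphere
signal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["mc_sphere_signal"]


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    """Length of the intersection of intervals [a0,a1] and [b0,b1]."""
    return max(0.0, min(a1, b1) - max(a0, b0))


def mc_sphere_signal(
    b: float,
    radius: float,
    d_is: float,
    delta_small: float,
    delta_big: float,
    n_walkers: int = 100_000,
    dt: float | None = None,
    seed: int = 0,
) -> float:
    """Echo signal of spins restricted in a reflecting sphere, by simulation.

    Parameters
    ----------
    b : diffusion weighting in ms/μm²; the gradient amplitude is recovered
        from b = (γg)²·δ²·(Δ − δ/3).
    radius : sphere radius in μm.
    d_is : intrinsic diffusivity in μm²/ms.
    delta_small, delta_big : PGSE δ and Δ in ms.
    n_walkers : ensemble size.
    dt : time step in ms; defaults to a step small enough that the rms
        displacement per step is ≲ 7.5% of the radius.
    seed : RNG seed.

    Returns the normalized signal E[cos φ] ∈ (0, 1].
    """
    if b < 0 or radius <= 0 or d_is <= 0:
        raise ValueError("b must be >= 0, radius and d_is positive")
    if not delta_small < delta_big:
        raise ValueError("require δ < Δ")
    if b == 0:
        return 1.0

    t_end = delta_big + delta_small
    if dt is None:
        # rms step sqrt(6 D dt) <= 0.15 R keeps the reflection bias well below
        # the Monte-Carlo noise floor at ensemble sizes used here
        dt = min(0.05, (0.15 * radius) ** 2 / (6.0 * d_is))
    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps

    gamma_g = np.sqrt(b / (delta_small**2 * (delta_big - delta_small / 3.0)))
    rng = np.random.default_rng(seed)

    # uniform initial positions in the sphere
    pos = rng.standard_normal((n_walkers, 3))
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    pos *= radius * rng.random(n_walkers)[:, None] ** (1.0 / 3.0)

    sd = np.sqrt(2.0 * d_is * dt)
    phase = np.zeros(n_walkers)
    z_old = pos[:, 2].copy()
    for i in range(n_steps):
        t0, t1 = i * dt, (i + 1) * dt
        pos += rng.standard_normal((n_walkers, 3)) * sd
        r = np.linalg.norm(pos, axis=1)
        outside = r > radius
        if np.any(outside):
            # radial mirror reflection: r -> 2R − r
            pos[outside] *= ((2.0 * radius - r[outside]) / r[outside])[:, None]
        z_new = pos[:, 2]
        # gradient weight of this step: fractional overlap with each pulse
        w = _overlap(t0, t1, 0.0, delta_small) - _overlap(
            t0, t1, delta_big, t_end
        )
        if w != 0.0:
            phase += w * 0.5 * (z_old + z_new)  # trapezoidal ∫z dt
        z_old = z_new.copy()

    phase *= gamma_g
    return float(np.mean(np.cos(phase)))
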