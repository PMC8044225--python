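"""Hertz contact mechanics for a paraboloidal tip, with the bottom-effect
(finite-thickness) correction for a sample bonded to a rigid substrate.

The force on a paraboloidal indenter of radius ``R`` pressed a depth
``delta`` into an incompressible elastic layer of thickness ``h`` is

    F(delta) = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2) * f(chi)

with ``chi = sqrt(R * delta) / h`` and ``f`` a quartic polynomial correction
that tends to 1 as the layer becomes thick (``h -> inf``), where the plain
Hertz half-space law is recovered.  All functions here work in SI units
(m, N, Pa); unit conversion is the caller's job.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BOTTOM_EFFECT_COEFFS",
    "bottom_effect_factor",
    "hertz_prefactor",
    "contact_force",
    "indentation_at_force",
    "solve_indentation",
]

#: Coefficients of the bonded-sample, paraboloidal-tip thin-layer correction
#: f(chi) = 1 + c1*chi + c2*chi^2 + c3*chi^3 + c4*chi^4.
BOTTOM_EFFECT_COEFFS = (1.133, 1.283, 0.769, 0.0975)


def bottom_effect_factor(chi):
    """Thin-sample correction factor f(chi), chi = sqrt(R*delta)/h.

    f(0) = 1 (half-space limit) and f is strictly increasing for chi > 0:
    indenting a thinner bonded layer takes more force at equal depth.

    Parameters
    ----------
    chi : float or array-like
        Dimensionless thickness ratio, must be >= 0 (0 for h = inf).
    """
    chi = np.asarray(chi, dtype=float)
    if np.any(chi < 0):
        raise ValueError("chi must be >= 0")
    c1, c2, c3, c4 = BOTTOM_EFFECT_COEFFS
    out = 1.0 + chi * (c1 + chi * (c2 + chi * (c3 + chi * c4)))
    return out if out.ndim else float(out)


def hertz_prefactor(modulus_pa: float, poisson_ratio: float, tip_radius_m: float) -> float:
    """Prefactor A such that F = A * delta^(3/2) for the half-space Hertz law."""
    return (4.0 / 3.0) * modulus_pa / (1.0 - poisson_ratio**2) * np.sqrt(tip_radius_m)


def contact_force(delta_m, modulus_pa, poisson_ratio, tip_radius_m, thickness_m=np.inf):
    """Contact force (N) at indentation depth ``delta_m`` (m).

    ``thickness_m = inf`` gives the plain Hertz law; finite thickness applies
    the bottom-effect factor.  Vectorized over ``delta_m``.
    """
    delta = np.asarray(delta_m, dtype=float)
    a = hertz_prefactor(modulus_pa, poisson_ratio, tip_radius_m)
    if np.isinf(thickness_m):
        f = 1.0
    else:
        f = bottom_effect_factor(np.sqrt(tip_radius_m * np.maximum(delta, 0.0)) / thickness_m)
    out = a * np.maximum(delta, 0.0) ** 1.5 * f
    return out if out.ndim else float(out)


def indentation_at_force(force_n, modulus_pa, poisson_ratio, tip_radius_m,
                         thickness_m=np.inf, rtol=1e-12):
    """Invert F(delta) = force_n for the depth delta (m), by bisection.

    F is strictly increasing in delta, so the root is unique.
    """
    if force_n <= 0:
        return 0.0
    hi = 1e-9
    while contact_force(hi, modulus_pa, poisson_ratio, tip_radius_m, thickness_m) < force_n:
        hi *= 2.0
        if hi > 1.0:  # > 1 m indentation: nonsense input
            raise ValueError("cannot bracket indentation for requested force")
    lo = 0.0
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if contact_force(mid, modulus_pa, poisson_ratio, tip_radius_m, thickness_m) < force_n:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def solve_indentation(z_rel_m, modulus_pa, poisson_ratio, tip_radius_m,
                      spring_constant_n_per_m, thickness_m=np.inf, rtol=1e-9,
                      max_iter=80):
    """Indentation depth delta (m) for each piezo travel past contact.

    The cantilever deflects by F/k, so for piezo travel ``z_rel = z - z0`` past
    the contact point the depth satisfies the implicit balance

        delta = z_rel - F(delta) / k

    Solved per sample by vectorized bisection on ``g(delta) = F(delta) -
    k*(z_rel - delta)`` which is strictly increasing with ``g(0) <= 0`` and
    ``g(z_rel) >= 0``.  Entries with ``z_rel <= 0`` return 0.

    ``rtol`` is the relative tolerance on delta.
    """
    z_rel = np.atleast_1d(np.asarray(z_rel_m, dtype=float))
    k = spring_constant_n_per_m
    lo = np.zeros_like(z_rel)
    hi = np.maximum(z_rel, 0.0)
    active = hi > 0
    for _ in range(max_iter):
        if not np.any(active):
            break
        mid = 0.5 * (lo + hi)
        f_mid = contact_force(mid, modulus_pa, poisson_ratio, tip_radius_m, thickness_m)
        g_pos = f_mid - k * (z_rel - mid) >= 0.0
        hi = np.where(active & g_pos, mid, hi)
        lo = np.where(active & ~g_pos, mid, lo)
        active = active & (hi - lo > rtol * np.maximum(hi, 1e-300))
    delta = 0.5 * (lo + hi)
    delta[z_rel <= 0] = 0.0
    if np.isscalar(z_rel_m) or np.ndim(z_rel_m) == 0:
        return float(delta[0])
    return delta
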