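"""Independent numerical oracles used to validate the closed-form integrals.

These deliberately avoid the erf/exp expressions under test: shell charges
are recomputed by adaptive quadrature over the angular-reduced 3-D integral
and by Monte-Carlo sampling of each atom's Gaussian.  They are test-only
code — slow, but trustworthy.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate


def centered_shell_charge_quad(R: float, a: float = 1.0) -> float:
    """Charge of a centred unit Gaussian inside radius R by 1-D quadrature."""
    def radial(r):
        return (4 * math.pi * a * a) ** -1.5 * math.exp(-((r / (2 * a)) ** 2)) * 4 * math.pi * r * r

    val, _ = integrate.quad(radial, 0.0, R, epsabs=1e-13, epsrel=1e-13)
    return val


def shell_charge_quadrature(model, r1: float, r2: float) -> float:
    """Shell charge by per-atom adaptive quadrature.

    For each atom the sphere is rotated so the atom lies on +z (the shell
    domain is spherically symmetric, so only the centre distance d matters);
    the azimuthal integral is then a constant 2π and the remaining (r, cosθ)
    integral is evaluated with scipy's adaptive dblquad.
    """
    total = 0.0
    for q, d, a in zip(model.charges, model.distances, model.widths):
        pref = (4 * math.pi * a * a) ** -1.5 * 2 * math.pi

        def integrand(u, r, d=d, a=a, pref=pref):
            return pref * r * r * math.exp(-(r * r + d * d - 2 * r * d * u) / (4 * a * a))

        val, _ = integrate.dblquad(
            integrand, r1, r2, -1.0, 1.0, epsabs=1e-10, epsrel=1e-10
        )
        total += q * val
    return total


def shell_charge_montecarlo(model, r1: float, r2: float, n_samples: int, rng):
    """Shell charge by exact Gaussian sampling; returns (estimate, std_error).

    Each atom's normalised density is N(r_i, 2a² I); sampling it and counting
    the fraction of radii falling in [r1, r2] estimates that atom's shell
    fraction with binomial error.
    """
    n_atoms = len(model.charges)
    m = max(1, int(math.ceil(n_samples / n_atoms)))
    est = 0.0
    var = 0.0
    for q, pos, a in zip(model.charges, model.positions, model.widths):
        pts = rng.normal(loc=pos, scale=a * math.sqrt(2.0), size=(m, 3))
        r = np.linalg.norm(pts, axis=1)
        p = float(np.mean((r >= r1) & (r < r2)))
        est += q * p
        var += q * q * p * (1.0 - p) / m
    return est, math.sqrt(var)


def planar_integral_quadrature(model, extent: float) -> float:
    """∫ρ dA over the z=0 square [-extent, extent]² by adaptive 2-D quadrature."""
    def integrand(y, x):
        return model.density_at(np.array([x, y, 0.0]))

    val, _ = integrate.dblquad(
        integrand, -extent, extent, -extent, extent, epsabs=1e-10, epsrel=1e-8
    )
    return val
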