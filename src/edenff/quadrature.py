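"""Independent numerical cross-checks for the closed-form integrals.

Every two-center integral between spherical Gaussians reduces, through
the Fourier representation (a Gaussian transforms to a Gaussian, the
Coulomb kernel to 4π/q², and Δ^k to (−q²)^k), to a one-dimensional
radial integral

    I = C ∫₀^∞ q² K(q) e^{−sq²} sinc(qd) dq

evaluated here by adaptive quadrature. These routines share no code
with the erf/polynomial closed forms in :mod:`edenff.electrostatics`
and :mod:`edenff.xc`; they exist to validate them and are far slower.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.integrate import IntegrationWarning, quad

from .density import GaussianShell

__all__ = [
    "coulomb_shell_shell_quadrature",
    "coulomb_shell_point_quadrature",
    "laplacian_overlap_quadrature",
    "laplacian_density_at_quadrature",
]


def _sinc(qd):
    return np.sinc(qd / np.pi)  # sin(x)/x with numpy's normalized sinc


def _radial_fourier(kernel, s: float, d: float) -> float:
    """∫₀^∞ kernel(q) e^{−s q²} sinc(q d) dq with adaptive quadrature."""
    q_scale = 1.0 / np.sqrt(s)

    def integrand(q):
        return kernel(q) * np.exp(-s * q * q) * _sinc(q * d)

    # split at the Gaussian width: the tail carries the sinc oscillations.
    # Roundoff warnings near the 1e-13 tolerance are expected for high-k
    # integrands (q^14 e^{-sq²}); achieved accuracy stays far below the
    # 1e-6 comparison tolerance these oracles serve.
    total = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", IntegrationWarning)
        for lo, hi in ((0.0, 3.0 * q_scale), (3.0 * q_scale, 30.0 * q_scale)):
            part, _ = quad(integrand, lo, hi, limit=800, epsabs=1e-13, epsrel=1e-11)
            total += part
    return total


def coulomb_shell_shell_quadrature(a: GaussianShell, b: GaussianShell) -> float:
    """∫∫ g_a(r) g_b(r′) / |r−r′| d³r d³r′ via the 1-D Fourier integral."""
    d = float(np.linalg.norm(np.asarray(a.center) - np.asarray(b.center)))
    s = 1.0 / (4 * a.exponent) + 1.0 / (4 * b.exponent)
    return a.weight * b.weight * (2.0 / np.pi) * _radial_fourier(lambda q: 1.0, s, d)


def coulomb_shell_point_quadrature(a: GaussianShell, Z: float, P) -> float:
    """Z ∫ g_a(r)/|r−P| d³r via the 1-D Fourier integral."""
    d = float(np.linalg.norm(np.asarray(a.center) - np.asarray(P, dtype=float)))
    s = 1.0 / (4 * a.exponent)
    return a.weight * Z * (2.0 / np.pi) * _radial_fourier(lambda q: 1.0, s, d)


def laplacian_overlap_quadrature(a: GaussianShell, b: GaussianShell, k: int) -> float:
    """∫ (Δ^k g_a)(r) g_b(r) d³r via the 1-D Fourier integral
    ((−q²)^k under the transform)."""
    d = float(np.linalg.norm(np.asarray(a.center) - np.asarray(b.center)))
    s = 1.0 / (4 * a.exponent) + 1.0 / (4 * b.exponent)
    val = _radial_fourier(lambda q: q**2 * (-(q * q)) ** k, s, d)
    return a.weight * b.weight * val / (2.0 * np.pi**2)


def laplacian_density_at_quadrature(a: GaussianShell, P, k: int) -> float:
    """(Δ^k g_a)(P) via the 1-D Fourier integral."""
    d = float(np.linalg.norm(np.asarray(a.center) - np.asarray(P, dtype=float)))
    s = 1.0 / (4 * a.exponent)
    val = _radial_fourier(lambda q: q**2 * (-(q * q)) ** k, s, d)
    return a.weight * val / (2.0 * np.pi**2)
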