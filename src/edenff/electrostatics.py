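"""Closed-form Coulomb interaction between two frozen Gaussian densities.

The pair interaction of the "naïve" model — electrons of each monomer
assumed independent of the partner's — splits into three classical
terms: electron–electron repulsion between the two densities,
electron–nuclear attraction across monomers, and nuclear–nuclear
repulsion. For unit-normalized s-type Gaussians every integral reduces
to erf(γd)/d with γ built from the exponents, so the whole naïve energy
is a short double sum with no numerical quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .density import GaussianShell, MoleculeDensity

__all__ = [
    "NaiveEnergyBreakdown",
    "coulomb_shell_shell",
    "coulomb_shell_point",
    "nuclear_repulsion",
    "electron_nuclear_attraction",
    "electron_electron_repulsion",
    "naive_interaction_energy",
]

# Below γd = 1e-4 the Maclaurin series of erf(γd)/d is exact to machine
# precision and avoids the 0/0 cancellation of the closed form.
_SMALL_X = 1e-4
_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


def erf_over_d(gamma, d):
    """erf(γd)/d, elementwise, continuous through d = 0.

    For γd < 1e-4 uses the series (2γ/√π)(1 − x²/3 + x⁴/10 − x⁶/42),
    x = γd, whose truncation error is below machine epsilon there.
    """
    gamma = np.asarray(gamma, dtype=float)
    d = np.asarray(d, dtype=float)
    x = gamma * d
    small = x < _SMALL_X
    d_safe = np.where(small, 1.0, d)
    x2 = x * x
    series = _TWO_OVER_SQRT_PI * gamma * (1.0 - x2 / 3.0 + x2 * x2 / 10.0 - x2 * x2 * x2 / 42.0)
    out = np.where(small, series, erf(x) / d_safe)
    return out if out.ndim else float(out)


def coulomb_shell_shell(a: GaussianShell, b: GaussianShell) -> float:
    """Coulomb repulsion energy of two unit-normalized s-Gaussian charge
    clouds (hartree): w_a w_b erf(√(αβ/(α+β)) d)/d."""
    alpha, beta = a.exponent, b.exponent
    gamma = np.sqrt(alpha * beta / (alpha + beta))
    d = float(np.linalg.norm(np.asarray(a.center) - np.asarray(b.center)))
    return a.weight * b.weight * float(erf_over_d(gamma, d))


def coulomb_shell_point(a: GaussianShell, Z: float, P) -> float:
    """Coulomb energy of a Gaussian cloud with a point charge Z at P
    (hartree, positive for like charges): w Z erf(√α d)/d."""
    d = float(np.linalg.norm(np.asarray(a.center) - np.asarray(P, dtype=float)))
    return a.weight * Z * float(erf_over_d(np.sqrt(a.exponent), d))


def _pack_shells(mol: MoleculeDensity):
    shells = mol.shells
    w = np.array([s.weight for s in shells])
    alpha = np.array([s.exponent for s in shells])
    centers = np.array([s.center for s in shells]).reshape(len(shells), 3)
    return w, alpha, centers


def nuclear_repulsion(A: MoleculeDensity, B: MoleculeDensity) -> float:
    """Σ Z_a Z_b / d_ab over intermolecular nuclear pairs (hartree)."""
    Ra, Rb = A.nuclear_coords, B.nuclear_coords
    d = np.linalg.norm(Ra[:, None, :] - Rb[None, :, :], axis=-1)
    if (d < 1e-12).any():
        raise ValueError("coincident intermolecular nuclei (d = 0)")
    return float((A.effective_Zs[:, None] * B.effective_Zs[None, :] / d).sum())


def _en_one_way(wA, alphaA, cA, ZB, RB) -> float:
    # attraction of A's density to B's nuclei; returned positive, sign applied by caller
    d = np.linalg.norm(cA[:, None, :] - RB[None, :, :], axis=-1)
    g = erf_over_d(np.sqrt(alphaA)[:, None], d)
    return float((wA[:, None] * ZB[None, :] * g).sum())


def electron_nuclear_attraction(A: MoleculeDensity, B: MoleculeDensity) -> float:
    """−Σ (A-density ↔ B-nuclei) − Σ (B-density ↔ A-nuclei), hartree."""
    wA, aA, cA = _pack_shells(A)
    wB, aB, cB = _pack_shells(B)
    return -(_en_one_way(wA, aA, cA, B.effective_Zs, B.nuclear_coords)
             + _en_one_way(wB, aB, cB, A.effective_Zs, A.nuclear_coords))


def electron_electron_repulsion(A: MoleculeDensity, B: MoleculeDensity) -> float:
    """Σ over intermolecular shell pairs of the Gaussian–Gaussian Coulomb
    integral (hartree)."""
    wA, aA, cA = _pack_shells(A)
    wB, aB, cB = _pack_shells(B)
    gamma = np.sqrt(aA[:, None] * aB[None, :] / (aA[:, None] + aB[None, :]))
    d = np.linalg.norm(cA[:, None, :] - cB[None, :, :], axis=-1)
    return float((wA[:, None] * wB[None, :] * erf_over_d(gamma, d)).sum())


@dataclass(frozen=True)
class NaiveEnergyBreakdown:
    """The three Coulomb components of the naïve pair energy, hartree."""

    e_ee: float
    e_en: float
    e_nn: float

    @property
    def total(self) -> float:
        return self.e_ee + self.e_en + self.e_nn


def naive_interaction_energy(A: MoleculeDensity, B: MoleculeDensity) -> NaiveEnergyBreakdown:
    """Naïve (frozen-density, exchange-free) interaction energy of two
    monomers, broken into ee / en / nn components."""
    return NaiveEnergyBreakdown(
        e_ee=electron_electron_repulsion(A, B),
        e_en=electron_nuclear_attraction(A, B),
        e_nn=nuclear_repulsion(A, B),
    )
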