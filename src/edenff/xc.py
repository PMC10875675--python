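"""Iterated-Laplacian exchange–correlation correction.

The naïve frozen-density Coulomb model misses exchange and correlation
between the two monomers' electron clouds. The correction used here is a
linear combination of density functionals built by applying the Laplace
operator k = 0..K consecutive times to one monomer density and
contracting with the partner:

    ee functionals:  F_ee^(k) = ∫ (Δ^k ρ_A)(r) ρ_B(r) d³r
    en functionals:  F_en^(k) = Σ_b Z_b (Δ^k ρ_A)(R_b) + Σ_a Z_a (Δ^k ρ_B)(R_a)

    E_xc = Σ_k  c_k F_ee^(k) + d_k F_en^(k)

Restricting to even derivative orders (iterated Laplacians) makes every
term symmetric under interchange of the monomers — integration by parts
moves Δ^k from one density to the other without changing the value — as
the interaction energy must be. For s-Gaussian densities each functional
is closed-form: Δ^k of a Gaussian is an even polynomial times the same
Gaussian, and the ee contraction is the same polynomial applied to the
Gaussian convolution of the pair.

The weights c_k, d_k carry the bohr dimensions of their functionals so
that E_xc is in hartree; they are calibrated against reference
interaction energies (see :mod:`edenff.calibration`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import sympy
import yaml

from .density import MoleculeDensity
from .electrostatics import _pack_shells, naive_interaction_energy

__all__ = [
    "XCCoefficients",
    "laplacian_polynomial",
    "xc_ee_term",
    "xc_en_term",
    "xc_energy",
    "featurize",
    "total_interaction_energy",
]


# ---------------------------------------------------------------------------
# Δ^k of a Gaussian: symbolic once, numeric thereafter


@lru_cache(maxsize=None)
def _laplacian_poly_symbolic(k: int):
    """Coefficients (ascending in u = d²) of P_k with
    Δ^k e^{−a u} = P_k(u) e^{−a u}; exact rationals in the symbol a.

    For a radial function f(u), u = d², the 3-D Laplacian is
    Δf = 4u f''(u) + 6 f'(u); applied k times to P e^{−au} this gives the
    polynomial recursion below.
    """
    a, u = sympy.symbols("a u", positive=True)
    P = sympy.Integer(1)
    for _ in range(k):
        dP, d2P = P.diff(u), P.diff(u, 2)
        P = sympy.expand(4 * u * (d2P - 2 * a * dP + a**2 * P) + 6 * (dP - a * P))
    poly = sympy.Poly(P, u)
    return tuple(reversed(poly.all_coeffs()))  # ascending powers of u


@lru_cache(maxsize=None)
def _laplacian_coeff_fns(k: int):
    """Vectorized numeric evaluators a ↦ coefficient, ascending in u."""
    a = sympy.symbols("a", positive=True)
    return tuple(sympy.lambdify(a, c, "numpy") for c in _laplacian_poly_symbolic(k))


def laplacian_polynomial(alpha: float, k: int) -> np.ndarray:
    """Coefficients (ascending powers of d²) of the even polynomial P_k with
    Δ^k exp(−α d²) = P_k(d²) exp(−α d²)."""
    if k < 0:
        raise ValueError("k must be ≥ 0")
    fns = _laplacian_coeff_fns(k)
    return np.array([float(fn(alpha)) for fn in fns])


def _eval_lap_poly(k: int, alpha, d2):
    """P_k(d²; α) with broadcasting over arrays ``alpha`` and ``d2``."""
    fns = _laplacian_coeff_fns(k)
    alpha = np.asarray(alpha, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    out = np.zeros(np.broadcast(alpha, d2).shape)
    pw = np.ones_like(out)
    for fn in fns:
        out = out + np.asarray(fn(alpha), dtype=float) * pw
        pw = pw * d2
    return out


# ---------------------------------------------------------------------------
# Functional values


def xc_ee_term(A: MoleculeDensity, B: MoleculeDensity, k: int) -> float:
    """∫ (Δ^k ρ_A) ρ_B d³r over intermolecular shell pairs (bohr-dimensioned).

    For a shell pair the contraction is the Gaussian convolution
    S₀(d) = w_a w_b (μ/π)^{3/2} e^{−μd²}, μ = αβ/(α+β), with Δ_d^k applied —
    i.e. S₀(d)·P_k(d²; μ).
    """
    if k < 0:
        raise ValueError("k must be ≥ 0")
    wA, aA, cA = _pack_shells(A)
    wB, aB, cB = _pack_shells(B)
    mu = aA[:, None] * aB[None, :] / (aA[:, None] + aB[None, :])
    d2 = ((cA[:, None, :] - cB[None, :, :]) ** 2).sum(-1)
    s0 = wA[:, None] * wB[None, :] * (mu / np.pi) ** 1.5 * np.exp(-mu * d2)
    return float((s0 * _eval_lap_poly(k, mu, d2)).sum())


def xc_en_term(A: MoleculeDensity, B: MoleculeDensity, k: int) -> float:
    """Σ_b Z_b (Δ^k ρ_A)(R_b) + Σ_a Z_a (Δ^k ρ_B)(R_a)  (bohr-dimensioned)."""
    if k < 0:
        raise ValueError("k must be ≥ 0")

    def one_way(mol, Zs, R):
        w, alpha, c = _pack_shells(mol)
        d2 = ((c[:, None, :] - R[None, :, :]) ** 2).sum(-1)  # (shells, nuclei)
        g = w[:, None] * (alpha[:, None] / np.pi) ** 1.5 * np.exp(-alpha[:, None] * d2)
        return float((Zs[None, :] * g * _eval_lap_poly(k, alpha[:, None], d2)).sum())

    return (one_way(A, B.effective_Zs, B.nuclear_coords)
            + one_way(B, A.effective_Zs, A.nuclear_coords))


# ---------------------------------------------------------------------------
# Coefficients and assembled energies


@dataclass
class XCCoefficients:
    """Fitted weights of the ee and en functional series up to order K.

    ``ee_weights[k]`` (c_k) and ``en_weights[k]`` (d_k) each have K+1
    entries, k = 0..K inclusive; units absorb the bohr dimensions of the
    functionals so the XC energy comes out in hartree.
    """

    order: int
    ee_weights: list[float]
    en_weights: list[float]
    basis_mode: str = "ecp"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("order must be ≥ 0")
        self.ee_weights = [float(v) for v in self.ee_weights]
        self.en_weights = [float(v) for v in self.en_weights]
        if len(self.ee_weights) != self.order + 1 or len(self.en_weights) != self.order + 1:
            raise ValueError(f"order {self.order} requires {self.order + 1} ee and en weights")

    @property
    def stacked(self) -> np.ndarray:
        """[c_0..c_K, d_0..d_K] — matches :func:`featurize` ordering."""
        return np.array(self.ee_weights + self.en_weights)

    @classmethod
    def zeros(cls, order: int, basis_mode: str = "ecp") -> "XCCoefficients":
        return cls(order=order, ee_weights=[0.0] * (order + 1),
                   en_weights=[0.0] * (order + 1), basis_mode=basis_mode)

    @classmethod
    def from_stacked(cls, weights, basis_mode: str = "ecp",
                     metadata: dict | None = None) -> "XCCoefficients":
        weights = list(np.asarray(weights, dtype=float))
        if len(weights) % 2:
            raise ValueError("stacked weights must have even length 2(K+1)")
        K = len(weights) // 2 - 1
        return cls(order=K, ee_weights=weights[: K + 1], en_weights=weights[K + 1:],
                   basis_mode=basis_mode, metadata=metadata or {})

    def save(self, path) -> None:
        doc = {
            "basis_mode": self.basis_mode,
            "order": self.order,
            "units": "weights map bohr-dimensioned functional values to hartree",
            "ee_weights": self.ee_weights,
            "en_weights": self.en_weights,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "XCCoefficients":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(order=int(doc["order"]), ee_weights=doc["ee_weights"],
                   en_weights=doc["en_weights"], basis_mode=doc["basis_mode"],
                   metadata=doc.get("metadata") or {})


def featurize(A: MoleculeDensity, B: MoleculeDensity, K: int) -> np.ndarray:
    """Feature vector [F_ee^(0..K), F_en^(0..K)] of length 2(K+1); the XC
    energy is exactly ``coeffs.stacked @ featurize(A, B, K)``."""
    if K < 0:
        raise ValueError("K must be ≥ 0")
    ee = [xc_ee_term(A, B, k) for k in range(K + 1)]
    en = [xc_en_term(A, B, k) for k in range(K + 1)]
    return np.array(ee + en)


def xc_energy(A: MoleculeDensity, B: MoleculeDensity, coeffs: XCCoefficients) -> float:
    """Exchange–correlation correction energy, hartree."""
    total = 0.0
    for k in range(coeffs.order + 1):
        ck, dk = coeffs.ee_weights[k], coeffs.en_weights[k]
        if ck:
            total += ck * xc_ee_term(A, B, k)
        if dk:
            total += dk * xc_en_term(A, B, k)
    return total


def total_interaction_energy(A: MoleculeDensity, B: MoleculeDensity,
                             coeffs: XCCoefficients) -> float:
    """Corrected pair interaction energy: naïve Coulomb + XC, hartree."""
    for mol in (A, B):
        if mol.basis_mode != coeffs.basis_mode:
            raise ValueError(
                f"basis_mode mismatch: coefficients are {coeffs.basis_mode!r}, "
                f"molecule {mol.name!r} is {mol.basis_mode!r}")
    return naive_interaction_energy(A, B).total + xc_energy(A, B, coeffs)
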