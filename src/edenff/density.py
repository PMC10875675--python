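"""Atomic electron densities as linear combinations of s-type Gaussians.

Each atom's (valence or all-electron) density is expanded in a few
spherically symmetric, unit-normalized Gaussian primitives

    g(r) = w (α/π)^{3/2} exp(−α |r − R|²),

which integrates to exactly ``w`` electrons. The expansion is fitted to
a sampled radial density with a global (evolutionary + quasi-Newton)
optimizer, the total electron count is pinned to the effective atomic
number minus the atom's Mulliken charge, and the resulting frozen
monomer densities feed the closed-form interaction-energy integrals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import differential_evolution, minimize, nnls

from .units import BOHR_PER_ANGSTROM

__all__ = [
    "GaussianShell",
    "AtomDensity",
    "MoleculeDensity",
    "DensityTable",
    "fit_radial_density",
    "scale_to_population",
    "density_at",
    "ECP_EFFECTIVE_Z",
    "FULL_Z",
    "effective_atomic_number",
    "read_mulliken_charges",
    "write_mulliken_charges",
]

# Full atomic numbers, first three rows.
FULL_Z = {
    "H": 1, "He": 2,
    "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
    "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17, "Ar": 18,
}

# Effective (valence) atomic numbers under a CEP-31G-style effective core
# potential: 1s core removed for Li–Ne, 1s2s2p core removed for Na–Ar.
ECP_EFFECTIVE_Z = {
    "H": 1, "He": 2,
    "Li": 1, "Be": 2, "B": 3, "C": 4, "N": 5, "O": 6, "F": 7, "Ne": 8,
    "Na": 1, "Mg": 2, "Al": 3, "Si": 4, "P": 5, "S": 6, "Cl": 7, "Ar": 8,
}


def effective_atomic_number(element: str, basis_mode: str = "ecp") -> float:
    """Nuclear charge seen by the model: valence charge (ecp) or full Z."""
    table = ECP_EFFECTIVE_Z if basis_mode == "ecp" else FULL_Z
    if basis_mode not in ("ecp", "full"):
        raise ValueError(f"unknown basis_mode {basis_mode!r}")
    if element not in table:
        raise KeyError(f"no effective atomic number for element {element!r}")
    return float(table[element])


@dataclass(frozen=True)
class GaussianShell:
    """One s-type Gaussian term of a density.

    ``weight`` is in electrons (the shell integrates to exactly this many),
    ``exponent`` in bohr⁻², ``center`` a 3-vector in bohr.
    """

    weight: float
    exponent: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not np.isfinite(self.weight):
            raise ValueError("shell weight must be finite")
        if not (np.isfinite(self.exponent) and self.exponent > 0):
            raise ValueError("shell exponent must be positive and finite")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def at(self, points: np.ndarray) -> np.ndarray:
        """Density value(s) at ``points`` (…, 3), bohr."""
        points = np.asarray(points, dtype=float)
        d2 = ((points - np.asarray(self.center)) ** 2).sum(axis=-1)
        a = self.exponent
        return self.weight * (a / np.pi) ** 1.5 * np.exp(-a * d2)


@dataclass
class AtomDensity:
    """One atom: effective nuclear charge, Mulliken charge and Gaussian shells.

    All shells share the atom's center; ``effective_Z`` is the nuclear (or
    ECP valence) charge entering the electron–nuclear and nuclear–nuclear
    terms; the electron population carried by the shells is
    ``effective_Z − mulliken_charge`` after :func:`scale_to_population`.
    """

    element: str
    effective_Z: float
    shells: list[GaussianShell]
    mulliken_charge: float = 0.0

    def __post_init__(self):
        if self.effective_Z <= 0:
            raise ValueError("effective_Z must be positive")
        centers = {s.center for s in self.shells}
        if len(centers) > 1:
            raise ValueError("all shells of an atom must share one center")

    @property
    def center(self) -> np.ndarray:
        if not self.shells:
            raise ValueError("atom has no shells")
        return np.asarray(self.shells[0].center)

    @property
    def electron_count(self) -> float:
        """Target population: effective_Z − mulliken_charge."""
        return self.effective_Z - self.mulliken_charge

    @property
    def shell_weight_sum(self) -> float:
        return float(sum(s.weight for s in self.shells))

    def translated(self, center_bohr) -> "AtomDensity":
        c = tuple(float(x) for x in center_bohr)
        shells = [dataclasses.replace(s, center=c) for s in self.shells]
        return dataclasses.replace(self, shells=shells)


@dataclass
class MoleculeDensity:
    """A frozen monomer density: ordered atoms with atom-centered shells."""

    atoms: list[AtomDensity]
    name: str = ""
    basis_mode: str = "ecp"

    @property
    def nuclear_coords(self) -> np.ndarray:
        """(n_atoms, 3) nuclear positions, bohr."""
        return np.array([a.center for a in self.atoms])

    @property
    def effective_Zs(self) -> np.ndarray:
        return np.array([a.effective_Z for a in self.atoms])

    @property
    def shells(self) -> list[GaussianShell]:
        return [s for a in self.atoms for s in a.shells]

    @property
    def total_electrons(self) -> float:
        return float(sum(a.electron_count for a in self.atoms))

    @property
    def net_charge(self) -> float:
        """Σ effective_Z − Σ shell weights (0 for population-scaled neutral atoms)."""
        return float(sum(a.effective_Z - a.shell_weight_sum for a in self.atoms))


def density_at(mol: MoleculeDensity, point) -> float | np.ndarray:
    """Electron density of ``mol`` at ``point`` (3-vector or (…, 3)), e/bohr³."""
    point = np.asarray(point, dtype=float)
    if not np.isfinite(point).all():
        raise ValueError("point must be finite")
    out = sum(s.at(point) for s in mol.shells)
    return float(out) if point.ndim == 1 else out


def scale_to_population(atom: AtomDensity) -> AtomDensity:
    """Uniformly rescale shell weights so the atom carries
    ``effective_Z − mulliken_charge`` electrons.

    This is the Mulliken-charge compensation step: intramolecular charge
    redistribution in the isolated monomer is absorbed by scaling each
    atom's density amplitude, leaving the radial shape and exponents
    untouched.
    """
    target = atom.electron_count
    if target <= 0:
        raise ValueError(
            f"{atom.element}: target population {target} ≤ 0; a bare cation core "
            "cannot be represented by scaled shells")
    total = atom.shell_weight_sum
    if total <= 0:
        raise ValueError(f"{atom.element}: shells have non-positive total weight {total}")
    factor = target / total
    shells = [dataclasses.replace(s, weight=s.weight * factor) for s in atom.shells]
    return dataclasses.replace(atom, shells=shells)


def _weights_for_exponents(alphas, r, rho, target, nonnegative):
    """Radial least-squares weights for fixed exponents, rescaled to `target`.

    The residual is weighted by the spherical volume element r², i.e. the
    fit targets the radial distribution 4πr²ρ(r).
    """
    design = (alphas[None, :] / np.pi) ** 1.5 * np.exp(-alphas[None, :] * r[:, None] ** 2)
    wgt = r  # sqrt of the r² residual weight
    A = design * wgt[:, None]
    b = rho * wgt
    if nonnegative:
        w, _ = nnls(A, b)
    else:
        w = np.linalg.lstsq(A, b, rcond=None)[0]
    s = w.sum()
    if s <= 0 or not np.isfinite(s):
        return None, np.inf
    w = w * (target / s)
    resid = float(((design @ w - rho) ** 2 * r**2).sum())
    return w, resid


def fit_radial_density(radial_samples, n_gaussians: int, target_electrons: float,
                       seed: int = 0, nonnegative: bool = True,
                       log_alpha_bounds=(-4.0, 9.0)) -> list[GaussianShell]:
    """Fit ``n_gaussians`` s-type Gaussians to a sampled radial density.

    ``radial_samples`` is a sequence of (r bohr, ρ(r) e/bohr³) pairs. The
    r²-weighted least-squares residual is minimized over exponents by a
    seeded differential-evolution global stage followed by quasi-Newton
    polish; for fixed exponents the weights are the (optionally
    non-negative) linear least-squares solution, uniformly rescaled so
    that Σ weights = ``target_electrons``. Deterministic for a fixed seed.
    """
    samples = np.asarray(radial_samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or samples.shape[0] == 0:
        raise ValueError("radial_samples must be a non-empty list of (r, rho) pairs")
    if not np.isfinite(samples).all():
        raise ValueError("radial_samples contain non-finite values")
    r, rho = samples[:, 0], samples[:, 1]
    if (r < 0).any() or (rho < 0).any():
        raise ValueError("radii and densities must be non-negative")
    if n_gaussians < 1:
        raise ValueError("n_gaussians must be ≥ 1")
    if samples.shape[0] < 2 * n_gaussians:
        raise ValueError(
            f"{samples.shape[0]} samples cannot determine {2 * n_gaussians} "
            "free parameters (weights + exponents)")
    if target_electrons <= 0:
        raise ValueError("target_electrons must be positive")

    def objective(log_alphas):
        alphas = np.exp(np.asarray(log_alphas))
        _, resid = _weights_for_exponents(alphas, r, rho, target_electrons, nonnegative)
        return resid

    bounds = [tuple(log_alpha_bounds)] * n_gaussians
    de = differential_evolution(objective, bounds, seed=seed, maxiter=200, tol=1e-12,
                                popsize=20, polish=False, init="sobol")
    polish = minimize(objective, de.x, method="BFGS",
                      options={"gtol": 1e-14, "maxiter": 500})
    x = polish.x if polish.fun <= de.fun else de.x
    alphas = np.exp(x)
    w, _ = _weights_for_exponents(alphas, r, rho, target_electrons, nonnegative)
    order = np.argsort(-alphas)
    return [GaussianShell(weight=float(w[i]), exponent=float(alphas[i]))
            for i in order]


# ---------------------------------------------------------------------------
# Parameter tables and molecule construction


@dataclass
class DensityTable:
    """Per-element Gaussian density parameters for one basis mode.

    ``elements`` maps a chemical symbol to ``(effective_Z,
    [(weight, exponent), ...])`` with exponents in bohr⁻².
    """

    basis_mode: str
    elements: dict[str, tuple[float, list[tuple[float, float]]]] = field(default_factory=dict)

    def add_element(self, symbol: str, effective_Z: float, shells) -> None:
        self.elements[symbol] = (float(effective_Z),
                                 [(float(w), float(a)) for w, a in shells])

    def atom(self, symbol: str, center_bohr, mulliken_charge: float = 0.0) -> AtomDensity:
        if symbol not in self.elements:
            raise KeyError(f"element {symbol!r} not in density table ({self.basis_mode})")
        eff_z, shells = self.elements[symbol]
        c = tuple(float(x) for x in center_bohr)
        atom = AtomDensity(
            element=symbol, effective_Z=eff_z,
            shells=[GaussianShell(weight=w, exponent=a, center=c) for w, a in shells],
            mulliken_charge=float(mulliken_charge))
        return scale_to_population(atom)

    def molecule(self, symbols, coords_angstrom, mulliken_charges=None,
                 name: str = "") -> MoleculeDensity:
        """Build a population-scaled MoleculeDensity from Å coordinates."""
        coords = np.asarray(coords_angstrom, dtype=float) * BOHR_PER_ANGSTROM
        if mulliken_charges is None:
            mulliken_charges = [0.0] * len(symbols)
        if len(mulliken_charges) != len(symbols):
            raise ValueError("one Mulliken charge per atom required")
        atoms = [self.atom(sym, xyz, q)
                 for sym, xyz, q in zip(symbols, coords, mulliken_charges)]
        return MoleculeDensity(atoms=atoms, name=name, basis_mode=self.basis_mode)

    def save(self, path) -> None:
        doc = {"basis_mode": self.basis_mode, "elements": {}}
        for sym, (eff_z, shells) in sorted(self.elements.items()):
            doc["elements"][sym] = {
                "effective_Z": eff_z,
                "shells": [{"weight": w, "exponent": a} for w, a in shells],
            }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "DensityTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        table = cls(basis_mode=doc["basis_mode"])
        for sym, rec in doc["elements"].items():
            table.add_element(sym, rec["effective_Z"],
                              [(s["weight"], s["exponent"]) for s in rec["shells"]])
        return table


def read_mulliken_charges(path) -> dict[int, float]:
    """Read an 'atom_index charge' two-column text file (0-based indices)."""
    charges = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {ln}: expected 'index charge'")
            charges[int(parts[0])] = float(parts[1])
    return charges


def write_mulliken_charges(path, charges: dict[int, float]) -> None:
    with open(path, "w") as fh:
        fh.write("# atom_index mulliken_charge (electrons)\n")
        for idx in sorted(charges):
            fh.write(f"{idx} {charges[idx]:.10f}\n")
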