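"""Bundled per-element density parameters.

The shipped radial-density samples are SYNTHETIC Slater-type stand-ins
for DFT valence densities (the published per-element densities are not
printed in text form): hydrogen uses the exact hydrogenic 1s density
e^{−2r}/π, and second-row elements use an n = 2 Slater-orbital density
∝ r² e^{−2ζr} with Slater-rule exponents, normalized to the ECP valence
electron count. The shipped Gaussian parameter table
(``gaussian_params_ecp.yaml``) is produced from those samples by
:func:`edenff.density.fit_radial_density` with three Gaussians per
element and can be regenerated with :func:`regenerate_builtin_table`.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from ..density import DensityTable, ECP_EFFECTIVE_Z, fit_radial_density

__all__ = [
    "synthetic_radial_density",
    "load_radial_samples",
    "builtin_density_table",
    "regenerate_builtin_table",
]

# Slater-rule effective exponents ζ for the n = 2 valence shell.
_SLATER_ZETA = {"Li": 0.650, "Be": 0.975, "B": 1.300, "C": 1.625,
                "N": 1.950, "O": 2.275, "F": 2.600, "Ne": 2.925}

_SAMPLED_ELEMENTS = ("H", "O")


def synthetic_radial_density(element: str, r: np.ndarray) -> np.ndarray:
    """Synthetic spherically averaged valence density ρ(r), e/bohr³."""
    r = np.asarray(r, dtype=float)
    n_el = ECP_EFFECTIVE_Z[element]
    if element == "H":
        return n_el * np.exp(-2.0 * r) / np.pi
    if element == "He":
        zeta = 1.6875
        return n_el * zeta**3 * np.exp(-2.0 * zeta * r) / np.pi
    if element in _SLATER_ZETA:
        a = 2.0 * _SLATER_ZETA[element]
        # normalized n=2 Slater density: ∫ 4π r² · C r² e^{−ar} dr = n_el
        c = n_el * a**5 / (96.0 * np.pi)
        return c * r**2 * np.exp(-a * r)
    raise KeyError(f"no synthetic radial density for element {element!r}")


def _sample_grid(r_max: float = 8.0, n_points: int = 240) -> np.ndarray:
    return np.linspace(0.0, r_max, n_points)


def load_radial_samples(element: str) -> np.ndarray:
    """(n, 2) array of (r bohr, ρ e/bohr³) from the bundled sample file."""
    name = f"radial_samples_{element}.txt"
    with resources.files(__package__).joinpath(name).open() as fh:
        return np.loadtxt(fh)


def builtin_density_table() -> DensityTable:
    """The shipped ECP-mode Gaussian parameter table (H and O)."""
    path = resources.files(__package__).joinpath("gaussian_params_ecp.yaml")
    with resources.as_file(path) as p:
        return DensityTable.load(p)


def regenerate_builtin_table(out_dir=None, n_gaussians: int = 3, seed: int = 7):
    """Rebuild the bundled sample files and fitted parameter table.

    Writes ``radial_samples_<El>.txt`` and ``gaussian_params_ecp.yaml``
    into ``out_dir`` (default: the data directory itself) and returns
    the fitted table.
    """
    from pathlib import Path

    if out_dir is None:
        out_dir = Path(str(resources.files(__package__)))
    out_dir = Path(out_dir)
    table = DensityTable(basis_mode="ecp")
    r = _sample_grid()
    for element in _SAMPLED_ELEMENTS:
        rho = synthetic_radial_density(element, r)
        samples = np.column_stack([r, rho])
        np.savetxt(out_dir / f"radial_samples_{element}.txt", samples,
                   header=("synthetic Slater-type valence density (stand-in for a "
                           "DFT/ECP density)\nr_bohr rho_e_per_bohr3"))
        # signed weights: the off-origin peak of n=2 Slater densities needs a
        # small negative tight Gaussian; the summed density stays positive
        shells = fit_radial_density(samples, n_gaussians=n_gaussians,
                                    target_electrons=ECP_EFFECTIVE_Z[element], seed=seed,
                                    nonnegative=False)
        table.add_element(element, ECP_EFFECTIVE_Z[element],
                          [(s.weight, s.exponent) for s in shells])
    table.save(out_dir / "gaussian_params_ecp.yaml")
    return table
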