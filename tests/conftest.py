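import numpy as np
import pytest

from edenff.data import builtin_density_table
from edenff.density import AtomDensity, GaussianShell, MoleculeDensity
from edenff.geometry import DimerGeometry
from edenff.scans import WATER_HOH_DEG, WATER_R_OH


@pytest.fixture(scope="session")
def table():
    """Bundled ECP density table (H, O)."""
    return builtin_density_table()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_shell(rng, center_scale=3.0, alpha_range=(0.3, 3.0), weight_range=(0.2, 2.0)):
    return GaussianShell(
        weight=float(rng.uniform(*weight_range)),
        exponent=float(rng.uniform(*alpha_range)),
        center=tuple(rng.uniform(-center_scale, center_scale, 3)),
    )


def random_molecule(rng, n_atoms=2, basis_mode="ecp", net_neutral=True):
    """Small random molecule: each atom one shell; neutral if requested."""
    atoms = []
    for _ in range(n_atoms):
        center = tuple(rng.uniform(-1.5, 1.5, 3))
        z = float(rng.uniform(1.0, 6.0))
        weight = z if net_neutral else float(rng.uniform(0.5, z))
        shells = [GaussianShell(weight=weight, exponent=float(rng.uniform(0.3, 3.0)),
                                center=center)]
        atoms.append(AtomDensity(element="X", effective_Z=z, shells=shells))
    return MoleculeDensity(atoms=atoms, name="random", basis_mode=basis_mode)


def water_coords(r_oh=WATER_R_OH, hoh_deg=WATER_HOH_DEG):
    """Rigid water in Å: O at origin, C2 axis +z."""
    h = np.deg2rad(hoh_deg) / 2
    return np.array([[0, 0, 0],
                     [r_oh * np.sin(h), 0, r_oh * np.cos(h)],
                     [-r_oh * np.sin(h), 0, r_oh * np.cos(h)]], dtype=float)


@pytest.fixture
def water_dimer_geometry():
    """Water dimer at O···O = 3 Å along x, second monomer flipped."""
    w = water_coords()
    flipped = w * np.array([-1.0, 1.0, 1.0]) + np.array([3.0, 0.0, 0.0])
    return DimerGeometry(("O", "H", "H"), w, ("O", "H", "H"), flipped, label="fixture")


@pytest.fixture
def water_pair(table, water_dimer_geometry):
    """(A, B) MoleculeDensity pair for the 3 Å water dimer."""
    g = water_dimer_geometry
    A = table.molecule(g.symbols_a, g.coords_a, name="A")
    B = table.molecule(g.symbols_b, g.coords_b, name="B")
    return A, B
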