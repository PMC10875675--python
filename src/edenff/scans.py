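"""Rigid-monomer dimer scan generators and synthetic reference energies.

Three scan families mirror the calibration design: water dimers in
"oxygen-bonded" configurations (O···O distance probed), water dimers in
"hydrogen-bonded" configurations (intermolecular O···H distance
probed), and colinear O₂ dimers (inner-atom gap probed). The water
families use a distance × angle grid (100 × 50 = 5000 configurations
each by default, 10,000 total); the O₂ family is a 300-point
distance-only grid by default.

Monomers are rigid: r(OH) = 0.9572 Å, ∠HOH = 104.52° (standard
gas-phase water), O₂ bond length 1.208 Å. The angular coordinate is a
tilt of the far monomer about an axis through its probe atom,
perpendicular to the intermolecular axis, sweeping between the two
endpoint orientations of each family; an optional fixed roll about the
intermolecular axis is exposed through ``monomer_geometry``.

Since the CCSD(T) reference energies behind the published calibration
require quantum-chemistry runs, :func:`synthetic_reference_energies`
manufactures a reference set from known ground-truth coefficients plus
optional Gaussian noise, which closes the generate → calibrate →
evaluate loop for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DimerGeometry
from .reference import RefEntry, ReferenceSet

__all__ = [
    "ScanSpec",
    "water_dimer_scan",
    "o2_dimer_scan",
    "synthetic_reference_energies",
    "WATER_R_OH",
    "WATER_HOH_DEG",
    "O2_BOND",
]

WATER_R_OH = 0.9572      # Å
WATER_HOH_DEG = 104.52   # degrees
O2_BOND = 1.208          # Å

FAMILIES = ("oxygen_scan", "hydrogen_scan", "o2_colinear")

_DEFAULT_RANGES = {
    "oxygen_scan": (2.0, 4.0),
    "hydrogen_scan": (1.5, 3.5),
    "o2_colinear": (1.5, 6.0),
}


@dataclass
class ScanSpec:
    """One scan family on an evenly spaced distance (× angle) grid.

    ``distance_range`` is (min, max) in Å of the probed intermolecular
    coordinate; ``n_angular`` is ignored for the colinear O₂ family.
    ``monomer_geometry`` overrides the rigid internal coordinates
    (keys: r_oh, hoh_deg, o2_bond, roll_deg, tilt_max_deg).
    """

    family: str
    distance_range: tuple[float, float] = None
    n_distance: int = 100
    n_angular: int = 50
    monomer_geometry: dict = field(default_factory=dict)
    seed: int = 0
    clash_floor: float = 0.5  # Å, minimum allowed intermolecular atom distance

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown scan family {self.family!r}; expected one of {FAMILIES}")
        if self.distance_range is None:
            self.distance_range = _DEFAULT_RANGES[self.family]
        lo, hi = self.distance_range
        if not (lo > 0 and hi >= lo):
            raise ValueError(f"invalid distance_range {self.distance_range}")
        if self.n_distance < 1 or self.n_angular < 1:
            raise ValueError("n_distance and n_angular must be ≥ 1")

    def distances(self) -> np.ndarray:
        lo, hi = self.distance_range
        if self.n_distance == 1:
            return np.array([lo])
        return np.linspace(lo, hi, self.n_distance)

    def geometry_param(self, key: str, default: float) -> float:
        return float(self.monomer_geometry.get(key, default))


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _water(r_oh: float, hoh_deg: float) -> np.ndarray:
    """Rigid water in its local frame: O at the origin, C2 axis = +z,
    H atoms in the xz-plane on the +z side. Rows: O, H, H."""
    h = np.deg2rad(hoh_deg) / 2.0
    return np.array([
        [0.0, 0.0, 0.0],
        [r_oh * np.sin(h), 0.0, r_oh * np.cos(h)],
        [-r_oh * np.sin(h), 0.0, r_oh * np.cos(h)],
    ])


def _check_clash(dimer: DimerGeometry, floor: float) -> DimerGeometry:
    dmin = dimer.min_intermolecular_distance()
    if dmin < floor:
        raise ValueError(
            f"generated dimer has intermolecular contact {dmin:.3f} Å "
            f"below the clash floor {floor} Å ({dimer.label})")
    return dimer


def water_dimer_scan(spec: ScanSpec) -> list[DimerGeometry]:
    """Water-dimer grid for the oxygen-bonded or hydrogen-bonded family.

    Monomer A sits with its O at the origin and both H atoms pointing
    away from B (−x). For ``oxygen_scan`` the O···O distance is probed
    and the angular coordinate tilts monomer B about its own O from
    O-facing (tilt 0) to H-facing (tilt 180°). For ``hydrogen_scan`` the
    O_A···H_B distance is probed, with B's donating H on the axis and
    the angular coordinate tilting B's O–H bond off the axis (0–120° by
    default). Configuration count is n_distance × n_angular.
    """
    if spec.family not in ("oxygen_scan", "hydrogen_scan"):
        raise ValueError(f"water_dimer_scan cannot generate family {spec.family!r}")
    r_oh = spec.geometry_param("r_oh", WATER_R_OH)
    hoh = spec.geometry_param("hoh_deg", WATER_HOH_DEG)
    roll = np.deg2rad(spec.geometry_param("roll_deg", 0.0))
    base = _water(r_oh, hoh)
    symbols = ("O", "H", "H")

    # monomer A: C2 axis rotated z → −x, H atoms point away from B
    mono_a = base @ _rot_y(-np.pi / 2).T

    if spec.family == "oxygen_scan":
        tilt_max = np.deg2rad(spec.geometry_param("tilt_max_deg", 180.0))
        # B in its local frame with C2 axis along +x (H atoms away from A at tilt 0)
        mono_b0 = base @ _rot_y(np.pi / 2).T
        pivot = np.zeros(3)  # tilt about B's oxygen
        offset_is_oxygen = True
    else:
        tilt_max = np.deg2rad(spec.geometry_param("tilt_max_deg", 120.0))
        # B with its donating H at the local origin and the O–H bond along +x
        h1 = base[1]
        shifted = base - h1  # donating H at origin
        # rotate so the H→O direction lies along +x
        ho = -h1 / np.linalg.norm(h1)  # H→O direction in the local frame
        # build rotation sending ho → +x within the xz-plane
        ang = np.arctan2(ho[2], ho[0])
        mono_b0 = shifted @ _rot_y(-ang).T
        pivot = np.zeros(3)  # tilt about the donating H
        offset_is_oxygen = False

    if spec.n_angular == 1:
        tilts = np.array([0.0])
    else:
        tilts = np.linspace(0.0, tilt_max, spec.n_angular)

    dimers = []
    for d in spec.distances():
        shift = np.array([d, 0.0, 0.0])
        for j, t in enumerate(tilts):
            rot = _rot_x(roll) @ _rot_y(t)
            coords_b = (mono_b0 - pivot) @ rot.T + pivot + shift
            label = f"family={spec.family} d={d:.6f} ia={j}"
            dimer = DimerGeometry(symbols, mono_a, symbols, coords_b, label=label)
            dimers.append(_check_clash(dimer, spec.clash_floor))
    if offset_is_oxygen:
        pass  # O···O distance equals d by construction; H···O likewise for the other family
    return dimers


def o2_dimer_scan(spec: ScanSpec) -> list[DimerGeometry]:
    """Colinear O₂ dimer scan: all four atoms on the x-axis, the gap
    between the two facing atoms taking n_distance evenly spaced values."""
    if spec.family != "o2_colinear":
        raise ValueError(f"o2_dimer_scan cannot generate family {spec.family!r}")
    bond = spec.geometry_param("o2_bond", O2_BOND)
    symbols = ("O", "O")
    coords_a = np.array([[0.0, 0.0, 0.0], [bond, 0.0, 0.0]])
    dimers = []
    for d in spec.distances():
        coords_b = np.array([[bond + d, 0.0, 0.0], [2 * bond + d, 0.0, 0.0]])
        label = f"family={spec.family} d={d:.6f} ia=0"
        dimer = DimerGeometry(symbols, coords_a, symbols, coords_b, label=label)
        dimers.append(_check_clash(dimer, spec.clash_floor))
    return dimers


def generate_scan(spec: ScanSpec) -> list[DimerGeometry]:
    """Dispatch to the family's generator."""
    if spec.family == "o2_colinear":
        return o2_dimer_scan(spec)
    return water_dimer_scan(spec)


def synthetic_reference_energies(geometries, table, true_coeffs, noise_sd: float = 0.0,
                                 seed: int = 0, tag: str = "other") -> ReferenceSet:
    """Manufacture a reference set from ground-truth coefficients.

    Each energy is the model's corrected interaction energy under
    ``true_coeffs`` plus Normal(0, ``noise_sd``) noise (kJ/mol), with the
    generating parameters recorded in the provenance. Refitting with
    zero noise must recover ``true_coeffs`` exactly.
    """
    from .calibration import build_design_matrix  # deferred: avoids an import cycle
    from .units import KJ_PER_MOL_PER_HARTREE

    if noise_sd < 0:
        raise ValueError("noise_sd must be ≥ 0")
    geometries = list(geometries)
    X = build_design_matrix(geometries, table, true_coeffs.order)
    energies_hartree = X[:, 0] + X[:, 1:] @ true_coeffs.stacked
    energies = energies_hartree * KJ_PER_MOL_PER_HARTREE
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        energies = energies + rng.normal(0.0, noise_sd, size=len(energies))
    provenance = (
        f"synthetic reference energies; order={true_coeffs.order} "
        f"basis_mode={true_coeffs.basis_mode} noise_sd={noise_sd} seed={seed}\n"
        f"ee_weights={list(true_coeffs.ee_weights)}\n"
        f"en_weights={list(true_coeffs.en_weights)}")
    entries = [RefEntry(geometry=g, energy_kj_mol=float(e), tag=tag)
               for g, e in zip(geometries, energies)]
    return ReferenceSet(entries=entries, provenance=provenance)
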