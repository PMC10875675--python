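# edenff

An electron-density pair force field for intermolecular interaction
energies, aimed at the strongly repulsive ("high-temperature") parts of
potential energy surfaces where conventional Lennard-Jones-style force
fields are unreliable — hot gases, plasma–wall modeling, forced close
contacts.

## The model

Each isolated monomer's electron density is expanded in a few
atom-centered s-type Gaussians,
ρ(r) = Σᵢ wᵢ (αᵢ/π)^{3/2} e^{−αᵢ|r−Rᵢ|²}, with Mulliken-charge-scaled
populations and (optionally) ECP effective atomic numbers. Two energies
are then computed in closed form, with no numerical quadrature:

1. **Naïve Coulomb energy** — the classical interaction of the two
   frozen clouds and their nuclei:
   E_naive = E_ee + E_en + E_nn, each term an erf(γd)/d kernel over
   shell/nucleus pairs.
2. **Exchange–correlation correction** — a linear combination of
   iterated-Laplacian density functionals,

       E_xc = Σ_{k=0}^{K} [ c_k ∫(Δᵏρ_A)ρ_B dr
                          + d_k ( Σ_b Z_b(Δᵏρ_A)(R_b) + Σ_a Z_a(Δᵏρ_B)(R_a) ) ],

   whose weights (c_k, d_k) are calibrated by least squares against
   reference interaction energies. Δᵏ of a Gaussian is a polynomial
   times the same Gaussian, so these terms are closed-form too, and the
   even derivative order makes every term exactly symmetric under
   monomer interchange.

The package provides the density model and per-element parameter
fitting, the closed-form integrals, the calibration machinery (a
scikit-learn estimator plus convenience wrappers, with the RAE error
metric Σ|ΔE|/Σ|E_ref|), rigid-monomer scan generators for the
calibration design (two 5,000-configuration water-dimer families and a
300-point colinear O₂ scan), a synthetic reference-energy generator
that closes the pipeline for testing, and a CLI. Independent
quadrature oracles for every closed form live in `edenff.quadrature`.

## Worked example

Energy of a water dimer at O···O = 3 Å (first 3 atoms = monomer A),
using the bundled ECP density table and no XC correction:

```bash
$ edenff energy dimer.xyz --na 3
# units: kj/mol
E_ee    +3.036972116017e+04
E_en    -6.081774771732e+04
E_nn    +3.041747614763e+04
E_naive -3.055040951972e+01
E_xc    +0.000000000000e+00
E_total -3.055040951972e+01
```

The three naïve components are huge and nearly cancel — the physical
content is the ~-30 kJ/mol balance, attractive here because the
electron clouds screen the nuclei imperfectly at 3 Å.

Calibrating the XC weights on synthetic references (generated from
known order-3 coefficients) and recovering them:

```python
import numpy as np
from edenff import (ScanSpec, water_dimer_scan, synthetic_reference_energies,
                    fit_xc_coefficients, XCCoefficients)
from edenff.data import builtin_density_table

table = builtin_density_table()
dimers = water_dimer_scan(ScanSpec(family="oxygen_scan", n_distance=50, n_angular=20))
truth = XCCoefficients(order=3, ee_weights=[0.5, -0.05, 0.004, -0.0002],
                       en_weights=[0.3, -0.02, 0.001, -0.00005])

clean = synthetic_reference_energies(dimers, table, truth, noise_sd=0.0, seed=0)
exact = fit_xc_coefficients(clean, K=3, table=table, method="linear", seed=0)
err = np.max(np.abs(exact.coefficients.stacked - truth.stacked) / np.abs(truth.stacked))
print(f"configurations:            {len(clean)}")
print(f"noiseless training RAE:    {exact.rae:.2e}")
print(f"max coefficient rel. err.: {err:.2e}")

noisy = synthetic_reference_energies(dimers, table, truth, noise_sd=1.0, seed=0)
report = fit_xc_coefficients(noisy, K=3, table=table, method="linear", seed=0)
print(f"noisy (1 kJ/mol) RAE:      {report.rae:.4f}")
```

prints

```
configurations:            1000
noiseless training RAE:    3.65e-16
max coefficient rel. err.: 6.71e-14
noisy (1 kJ/mol) RAE:      0.0491
```

— the exact linear solver recovers the generating coefficients to
machine precision on noiseless data, and with 1 kJ/mol of synthetic
noise the training RAE settles at the noise-to-signal ratio of the set.
To calibrate against real ab initio energies, load them as a
`ReferenceSet` (multi-frame XYZ + CSV table, see `edenff.reference`)
and call the same function.

## Layout

- `edenff.density` — Gaussian shells, atom/molecule densities, radial
  fitting, parameter tables, Mulliken scaling
- `edenff.electrostatics` — closed-form naïve Coulomb components
- `edenff.xc` — Laplacian polynomials, XC functionals, corrected energy
- `edenff.calibration` — `LaplacianXCRegressor`, RAE, order scans
- `edenff.scans` / `edenff.reference` — scan generators, reference sets
- `edenff.quadrature` — independent numerical oracles
- `edenff.cli` — `edenff` command (fit-density, energy, scan,
  calibrate, evaluate)
- `docs/methods.md` — model assumptions, numerics, design choices
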