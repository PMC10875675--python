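# Methods

## The model

`edenff` computes the interaction energy of a pair of molecules from the
electron densities of the *isolated* monomers. Each atom's (valence)
density is a short linear combination of unit-normalized s-type
Gaussians centered on the nucleus,

    ρ_atom(r) = Σ_i w_i (α_i/π)^{3/2} exp(−α_i |r − R|²),

so a monomer density ρ_A is frozen the moment its geometry is fixed —
the model is deliberately nonpolarizable and contains no charge
transfer between monomers.

**Naïve Coulomb energy.** Treating the two electron clouds as mutually
independent classical charge distributions, the pair energy splits into
three closed-form terms:

- electron–electron repulsion `E_ee = ∫∫ ρ_A(r) ρ_B(r′)/|r−r′| dr dr′`,
  which for s-Gaussian pairs reduces to `w_a w_b erf(γd)/d` with
  `γ = √(αβ/(α+β))` and `d` the center separation;
- electron–nuclear attraction `E_en` (the same erf kernel against point
  charges), and
- nuclear–nuclear repulsion `E_nn = Σ Z_a Z_b / d_ab`.

Nuclear charges are *effective* atomic numbers: full Z in all-electron
mode, valence charge in ECP mode (1s core subtracted for Li–Ne, 1s2s2p
for Na–Ar). Intramolecular charge redistribution is absorbed by
Mulliken charges: each atom's shell weights are scaled by one common
factor so the atom carries `Z_eff − q_Mulliken` electrons; exponents and
radial shape are untouched.

**Exchange–correlation correction.** The naïve model ignores exchange
and correlation between the clouds. The correction is a linear
combination of iterated-Laplacian density functionals, orders
k = 0..K:

    F_ee^(k) = ∫ (Δ^k ρ_A) ρ_B dr
    F_en^(k) = Σ_b Z_b (Δ^k ρ_A)(R_b) + Σ_a Z_a (Δ^k ρ_B)(R_a)
    E_xc     = Σ_k c_k F_ee^(k) + d_k F_en^(k)

Restricting to even derivative orders makes every term exactly
symmetric under monomer interchange (integration by parts moves Δ^k
across the contraction without changing the value — verified here to
1e-10 on randomized shell pairs). For Gaussians each functional is
closed-form: Δ^k e^{−αd²} = P_k(d²) e^{−αd²} with P_k an even
polynomial obtained from the radial recursion
Δf(u) = 4u f″(u) + 6 f′(u), u = d², applied symbolically (sympy) once
per k and cached; the ee contraction applies the same polynomial to the
Gaussian convolution S₀(d) = w_a w_b (μ/π)^{3/2} e^{−μd²},
μ = αβ/(α+β). k = 0 is the pure overlap term, so "order K" means
2(K+1) coefficients (order six ⇒ 14, order four ⇒ 10).

The en functional is implemented as the Z-weighted evaluation of the
iterated-Laplacian density at the partner nuclei, symmetrized over the
two monomers. This is the natural en analogue of the ee contraction and
is symmetric by construction; an alternative integral kernel could be
substituted behind the same operation contract without touching the
calibration machinery.

The weights c_k, d_k carry the bohr dimensions of their functionals, so
`E_xc` is in hartree; coefficient files record this convention.

## Units and numerics

- Internal units are atomic (bohr, hartree); I/O uses Å and kJ/mol with
  1 bohr = 0.52917721067 Å and 1 hartree = 2625.4996394798 kJ/mol.
- `erf(γd)/d` switches to its Maclaurin series below γd = 1e-4, where
  the truncation error of the 4-term series is below machine epsilon;
  the kernel is therefore continuous through d = 0 (coincident
  shell centers are legal; coincident *nuclei* across monomers are an
  error in `E_nn`).
- Laplacian polynomials are exact rationals in the exponent
  (symbolically derived, lru-cached) and evaluated vectorized over
  shell-pair arrays; the 10,000-dimer order-6 design matrix builds in
  well under a minute on one core.
- Degenerate inputs: bare-cation atoms (target population ≤ 0) are
  rejected by the Mulliken scaling; underdetermined radial fits (fewer
  samples than free parameters) are rejected; rank-deficient calibration
  matrices raise an error naming the degenerate functional columns.

## Density fitting

`fit_radial_density` fits n Gaussians to a sampled radial density by
minimizing the r²-weighted least-squares residual (i.e. it targets the
radial distribution 4πr²ρ, the physically relevant quantity). For fixed
exponents the weights are the linear least-squares solution —
non-negative by default, signed on request — rescaled uniformly to pin
Σw to the target electron count; exponents are optimized globally by
seeded differential evolution and polished with BFGS. The fit is
deterministic for a fixed seed and scale-equivariant (scaling the
samples by c scales the weights by c).

The bundled parameter table (`edenff.data`) covers H and O in ECP mode
with three Gaussians each, fitted to **synthetic** Slater-type radial
densities (hydrogenic 1s for H; an n = 2 Slater density with
Slater-rule exponent ζ = 2.275 normalized to 6 valence electrons for
O). These stand in for DFT-derived densities, which cannot be shipped
as text; any user-supplied table in the same YAML schema drops in. The
oxygen fit uses signed weights: the off-origin peak of an n = 2 density
needs a small negative tight Gaussian (the summed density remains
positive everywhere on the sample grid), and the signed fit lowers the
relative radial residual from ~13% to ~0.9%.

## Calibration

The corrected energy is linear in (c, d), so calibration is ordinary
least squares: `LaplacianXCRegressor` is a scikit-learn estimator whose
design matrix holds the naïve energy as a fixed offset column followed
by the 2(K+1) functional values (all hartree). The default `linear`
solver is exact (lstsq after column equilibration) and reports
linear-model standard errors; `ga_bfgs` — a seeded genetic algorithm
with blend crossover followed by BFGS polish on the equilibrated
quadratic — is retained for parity with nonlinear extensions and agrees
with the exact solver to well below 1e-4 on noiseless problems.
Residual weighting is uniform by default, with an optional
Boltzmann-style `exp(−β|E_ref|)` weighting behind a flag.

The error metric is the relative absolute error
RAE = Σ|E_model − E_ref| / Σ|E_ref|, aggregated over the set (stable
when individual reference energies cross zero); a per-point
mean-of-ratios variant is available behind a flag for sensitivity
checks. One subtlety: nested least squares guarantees monotone
non-increase of the **L2** objective across orders, not of the L1-ratio
RAE. `order_scan` therefore reports both the RAE and the normalized L2
error (`nrmse` = ‖err‖₂/‖ref‖₂); on noiseless references the RAE is
monotone too, while on noisy references it can fluctuate by ~1e-6 at
the noise floor. No train/test split is applied by default (training
RAE is the reported quantity); a seeded holdout fraction is available.

## Scan generators and synthetic references

Three families reproduce the calibration design: water dimers probing
the O···O distance ("oxygen-bonded"), water dimers probing the
intermolecular O···H distance ("hydrogen-bonded"), and colinear O₂
dimers probing the inner-atom gap. Defaults are 100 distances × 50
angles per water family (5,000 configurations each, 10,000 total) and
300 O₂ points. Monomers are rigid: r(OH) = 0.9572 Å, ∠HOH = 104.52°,
r(O₂) = 1.208 Å — standard gas-phase values, since the original
monomer geometries are not printed. The angular coordinate is a tilt of
the far monomer about an axis through its probe atom (O-facing →
H-facing over 0–180° for the oxygen family; the O–H bond tilting 0–120°
off-axis for the hydrogen family), with an optional roll about the
intermolecular axis; distance ranges (2.0–4.0 Å O···O, 1.5–3.5 Å O···H,
1.5–6.0 Å O₂ gap) are defaults chosen to straddle the repulsive wall
and the attractive tail, and are configurable. Every generated dimer is
checked against a 0.5 Å intermolecular clash floor, and regeneration
under a fixed seed is bit-identical.

High-accuracy ab initio reference energies cannot be computed here, so
`synthetic_reference_energies` manufactures them: the model's own
corrected energy under known ground-truth coefficients plus seeded
Gaussian noise, provenance recorded. This closes the loop — generate,
calibrate, evaluate — and makes parameter recovery exactly checkable.
What passing these tests shows is that the machinery (integrals,
featurization, least squares) is correct and self-consistent; it does
**not** show that the calibrated model reproduces real coupled-cluster
surfaces, which requires external reference data in the documented
CSV + XYZ format.

## Problem sizes used in validation

The shipped test-and-acceptance runs use the design counts above
(10,000 water dimers, 300 O₂ points) for generator and calibration
checks, 2,000 configurations for the noisy-recovery check
(σ = 1 kJ/mol), and 100–140 random instances per integral family for
the quadrature-oracle comparisons. The oracles are one-dimensional
Fourier-representation integrals evaluated by adaptive quadrature —
an independent route sharing no code with the erf/polynomial closed
forms.

## Known limitations

- Nonpolarizable, pairwise, frozen-density: no charge transfer, no
  many-body terms, no bond making/breaking. Interactions involving
  anionic species are outside the model's validated envelope.
- Higher-order ee functionals oscillate in sign along a distance scan
  (k ≥ 2 provably changes sign); high-order calibrated models can
  therefore oscillate unphysically when extrapolated to very short
  separations.
- The bundled densities are synthetic stand-ins; quantitative accuracy
  against ab initio surfaces depends entirely on the quality of the
  density table and reference set supplied.
- Energies only; no analytic gradients.
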