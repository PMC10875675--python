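"""Iterated-Laplacian functionals: closed forms vs oracles, symmetries, linearity."""

import numpy as np
import pytest

from edenff.density import AtomDensity, GaussianShell, MoleculeDensity, density_at
from edenff.quadrature import (laplacian_density_at_quadrature,
                               laplacian_overlap_quadrature)
from edenff.xc import (XCCoefficients, featurize, laplacian_polynomial,
                       total_interaction_energy, xc_ee_term, xc_en_term, xc_energy)
from edenff.electrostatics import naive_interaction_energy

from conftest import random_molecule


def shell_pair_molecules(a: GaussianShell, b: GaussianShell):
    """Wrap two shells as single-atom molecules (unit effective Z)."""
    A = MoleculeDensity(atoms=[AtomDensity(element="X", effective_Z=1.0, shells=[a])])
    B = MoleculeDensity(atoms=[AtomDensity(element="X", effective_Z=1.0, shells=[b])])
    return A, B


class TestLaplacianPolynomial:
    def test_identity_at_order_zero(self):
        np.testing.assert_array_equal(laplacian_polynomial(1.7, 0), [1.0])

    def test_first_order_closed_form(self):
        """One radial Laplacian of e^{-a d^2}: P_1(u) = 4a^2 u - 6a."""
        for alpha in (0.5, 1.0, 2.3):
            np.testing.assert_allclose(laplacian_polynomial(alpha, 1),
                                       [-6 * alpha, 4 * alpha**2], rtol=1e-14)

    def test_degree_grows_by_one(self):
        for k in range(7):
            assert len(laplacian_polynomial(0.8, k)) == k + 1

    def test_third_order_matches_finite_difference_of_second(self):
        """Applying an FD radial Laplacian to the k=2 profile reproduces k=3."""
        alpha = 0.8
        p2 = laplacian_polynomial(alpha, 2)
        p3 = laplacian_polynomial(alpha, 3)

        def f2(d):
            return np.polyval(p2[::-1], d**2) * np.exp(-alpha * d**2)

        h = 1e-4
        for d in (0.7, 1.3, 2.1):
            lap_fd = (f2(d + h) - 2 * f2(d) + f2(d - h)) / h**2 \
                + (2.0 / d) * (f2(d + h) - f2(d - h)) / (2 * h)
            exact = np.polyval(p3[::-1], d**2) * np.exp(-alpha * d**2)
            assert lap_fd == pytest.approx(exact, rel=1e-6)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            laplacian_polynomial(1.0, -1)


class TestEeTerm:
    def test_zero_order_coincident_value(self):
        a = GaussianShell(1.0, 1.0, (0, 0, 0))
        b = GaussianShell(1.0, 1.0, (0, 0, 0))
        A, B = shell_pair_molecules(a, b)
        assert xc_ee_term(A, B, 0) == pytest.approx((1 / (2 * np.pi)) ** 1.5, rel=1e-14)

    @pytest.mark.parametrize("k", range(7))
    def test_matches_fourier_quadrature_oracle(self, k, rng):
        for _ in range(20):
            a = GaussianShell(float(rng.uniform(0.2, 2)), float(rng.uniform(0.3, 3)),
                              tuple(rng.uniform(-1.5, 1.5, 3)))
            b = GaussianShell(float(rng.uniform(0.2, 2)), float(rng.uniform(0.3, 3)),
                              tuple(rng.uniform(-1.5, 1.5, 3)))
            A, B = shell_pair_molecules(a, b)
            oracle = laplacian_overlap_quadrature(a, b, k)
            assert xc_ee_term(A, B, k) == pytest.approx(oracle, rel=1e-6)

    @pytest.mark.parametrize("k", range(7))
    def test_integration_by_parts_symmetry(self, k, rng):
        """Moving Delta^k from one density to the other changes nothing:
        the swap A<->B leaves every ee functional invariant."""
        for _ in range(15):
            A = random_molecule(rng, 2)
            B = random_molecule(rng, 2)
            ab, ba = xc_ee_term(A, B, k), xc_ee_term(B, A, k)
            assert ab == pytest.approx(ba, rel=1e-10)

    def test_higher_order_terms_oscillate_in_sign(self):
        """For k >= 2 the ee functional changes sign along a distance scan."""
        for k in (2, 3, 4):
            vals = []
            for d in np.linspace(0.05, 6.0, 200):
                a = GaussianShell(1.0, 1.0, (0, 0, 0))
                b = GaussianShell(1.0, 1.0, (d, 0, 0))
                A, B = shell_pair_molecules(a, b)
                vals.append(xc_ee_term(A, B, k))
            signs = np.sign(vals)
            assert (np.diff(signs) != 0).any()


class TestEnTerm:
    def test_zero_order_is_density_at_partner_nuclei(self, water_pair):
        A, B = water_pair
        expected = (sum(z * density_at(A, r)
                        for z, r in zip(B.effective_Zs, B.nuclear_coords))
                    + sum(z * density_at(B, r)
                          for z, r in zip(A.effective_Zs, A.nuclear_coords)))
        assert xc_en_term(A, B, 0) == pytest.approx(expected, rel=1e-12)

    def test_swap_symmetry(self, rng):
        for k in range(4):
            A = random_molecule(rng, 2)
            B = random_molecule(rng, 3)
            assert xc_en_term(A, B, k) == pytest.approx(xc_en_term(B, A, k), rel=1e-12)

    def test_first_order_matches_finite_difference(self, water_pair):
        """k=1 en term equals the FD Laplacian of the density at partner nuclei."""
        A, B = water_pair
        h = 1e-3

        def fd_laplacian(mol, p):
            p = np.asarray(p, dtype=float)
            total = -6.0 * density_at(mol, p)
            for i in range(3):
                for s in (-1, 1):
                    q = p.copy()
                    q[i] += s * h
                    total += density_at(mol, q)
            return total / h**2

        expected = (sum(z * fd_laplacian(A, r)
                        for z, r in zip(B.effective_Zs, B.nuclear_coords))
                    + sum(z * fd_laplacian(B, r)
                          for z, r in zip(A.effective_Zs, A.nuclear_coords)))
        assert xc_en_term(A, B, 1) == pytest.approx(expected, rel=1e-5)

    @pytest.mark.parametrize("k", range(7))
    def test_matches_fourier_quadrature_oracle(self, k, rng):
        for _ in range(15):
            A = random_molecule(rng, 2)
            B = random_molecule(rng, 2)
            oracle = (sum(z * sum(laplacian_density_at_quadrature(s, r, k)
                                  for s in A.shells)
                          for z, r in zip(B.effective_Zs, B.nuclear_coords))
                      + sum(z * sum(laplacian_density_at_quadrature(s, r, k)
                                    for s in B.shells)
                            for z, r in zip(A.effective_Zs, A.nuclear_coords)))
            assert xc_en_term(A, B, k) == pytest.approx(oracle, rel=1e-6)


class TestXCEnergy:
    def test_zero_coefficients_give_zero(self, water_pair):
        A, B = water_pair
        assert xc_energy(A, B, XCCoefficients.zeros(3)) == 0.0

    def test_single_weight_selects_one_functional(self, water_pair):
        A, B = water_pair
        coeffs = XCCoefficients(order=0, ee_weights=[1.0], en_weights=[0.0])
        assert xc_energy(A, B, coeffs) == pytest.approx(xc_ee_term(A, B, 0), rel=1e-14)

    def test_dot_product_identity_with_featurize(self, rng):
        """xc_energy equals weights . featurize exactly (two code paths)."""
        for _ in range(5):
            A = random_molecule(rng, 2)
            B = random_molecule(rng, 2)
            K = 4
            w = rng.normal(size=2 * (K + 1))
            coeffs = XCCoefficients.from_stacked(w)
            feats = featurize(A, B, K)
            assert xc_energy(A, B, coeffs) == pytest.approx(float(w @ feats), rel=1e-12)

    def test_linearity_superposition(self, water_pair, rng):
        A, B = water_pair
        w1, w2 = rng.normal(size=8), rng.normal(size=8)
        e1 = xc_energy(A, B, XCCoefficients.from_stacked(w1))
        e2 = xc_energy(A, B, XCCoefficients.from_stacked(w2))
        e12 = xc_energy(A, B, XCCoefficients.from_stacked(w1 + 2 * w2))
        assert e12 == pytest.approx(e1 + 2 * e2, rel=1e-10)

    def test_features_vanish_at_large_separation(self, table):
        A = table.molecule(["O", "H", "H"],
                           np.array([[0, 0, 0], [0.76, 0, 0.59], [-0.76, 0, 0.59]]))
        B = table.molecule(["O", "H", "H"],
                           np.array([[26.5, 0, 0], [27.26, 0, 0.59], [25.74, 0, 0.59]]))
        feats = featurize(A, B, 2)  # 50 bohr separation
        assert (np.abs(feats) < 1e-20).all()


class TestTotalInteractionEnergy:
    def test_zero_coeffs_equal_naive(self, water_pair):
        A, B = water_pair
        total = total_interaction_energy(A, B, XCCoefficients.zeros(2))
        assert total == pytest.approx(naive_interaction_energy(A, B).total, rel=1e-14)

    def test_swap_symmetry(self, water_pair, rng):
        A, B = water_pair
        coeffs = XCCoefficients.from_stacked(rng.normal(size=6) * 0.1)
        assert total_interaction_energy(A, B, coeffs) == pytest.approx(
            total_interaction_energy(B, A, coeffs), rel=1e-12)

    def test_basis_mode_mismatch_rejected(self, water_pair):
        A, B = water_pair
        coeffs = XCCoefficients.zeros(1, basis_mode="full")
        with pytest.raises(ValueError, match="basis_mode"):
            total_interaction_energy(A, B, coeffs)

    def test_neutral_monomers_vanish_at_large_separation(self, table):
        w = np.array([[0, 0, 0], [0.76, 0, 0.59], [-0.76, 0, 0.59]])
        A = table.molecule(["O", "H", "H"], w)
        B = table.molecule(["O", "H", "H"], w + np.array([25.0, 0, 0]))
        coeffs = XCCoefficients(order=1, ee_weights=[0.5, -0.01],
                                en_weights=[0.2, -0.005])
        assert abs(total_interaction_energy(A, B, coeffs)) < 1e-6


class TestXCCoefficients:
    def test_length_validation(self):
        with pytest.raises(ValueError):
            XCCoefficients(order=2, ee_weights=[1.0], en_weights=[0.0, 0.0, 0.0])

    def test_order_zero_permitted(self):
        c = XCCoefficients(order=0, ee_weights=[0.3], en_weights=[0.1])
        assert c.stacked.tolist() == [0.3, 0.1]

    def test_file_round_trip(self, tmp_path):
        c = XCCoefficients(order=2, ee_weights=[0.5, -0.05, 0.002],
                           en_weights=[0.3, -0.01, 0.001], basis_mode="ecp",
                           metadata={"seed": 7, "calibration_set_hash": "abc123"})
        path = tmp_path / "coeffs.yaml"
        c.save(path)
        loaded = XCCoefficients.load(path)
        assert loaded.order == 2
        assert loaded.ee_weights == c.ee_weights
        assert loaded.en_weights == c.en_weights
        assert loaded.basis_mode == "ecp"
        assert loaded.metadata["seed"] == 7
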