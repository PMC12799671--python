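"""Constitutive layer: constants, tensor assembly, criterion evaluations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fabricopt import (
    DomainError,
    ElasticConstants,
    FabricTensor,
    InfeasibleDensityError,
    StressState,
    YieldConstants,
    build_compliance,
    build_stiffness,
    build_yield_tensors,
    cfe_value,
    gyc_value,
    lame_from_engineering,
    normalise_fabric,
    pse_strain,
    recover_density,
)
from fabricopt.constitutive import mandel_basis, sym_to_mandel

from conftest import random_fabric


class TestLameFromEngineering:
    @pytest.mark.parametrize(
        "eps0, nu0, d, expected",
        [
            (10000.0, 0.25, 3, (4000.0, 4000.0)),  # representative bone constants
            (7000.0, 0.0, 3, (0.0, 3500.0)),       # zero Poisson decouples
            (7000.0, 0.0, 2, (0.0, 3500.0)),
        ],
    )
    def test_closed_form(self, eps0, nu0, d, expected):
        lam0, mu0 = lame_from_engineering(eps0, nu0, d)
        assert lam0 == pytest.approx(expected[0], rel=1e-12, abs=1e-12)
        assert mu0 == pytest.approx(expected[1], rel=1e-12)

    def test_inadmissible_poisson_names_bound(self):
        with pytest.raises(DomainError, match="1/\\(d-1\\)"):
            lame_from_engineering(10000.0, 0.6, 3)

    def test_consistency_enforced_at_construction(self):
        with pytest.raises(DomainError):
            ElasticConstants(eps0=10000.0, nu0=0.25, mu0=3000.0, lambda0=4000.0)


class TestNormaliseFabricProperties:
    @given(
        raw=st.lists(st.floats(0.05, 20.0), min_size=3, max_size=3),
        n=st.floats(0.25, 3.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_trace_and_order_preserved(self, raw, n):
        m = normalise_fabric(raw, n)
        assert m.sum() == pytest.approx(3.0, abs=1e-9)
        assert np.all(m > 0)
        assert np.array_equal(np.argsort(m), np.argsort(raw))


class TestNormaliseFabric:
    def test_isotropic_fixed_point(self):
        for n in (0.5, 1.0, 2.0):
            assert normalise_fabric([1.0, 1.0, 1.0], n) == pytest.approx([1, 1, 1])

    def test_identity_when_already_normalised(self):
        m = np.array([0.7, 1.0, 1.3])
        assert normalise_fabric(m, 1.0) == pytest.approx(m)

    def test_power_transform(self):
        # direct evaluation at eigenvalues (1, 2, 3), exponent 1/2
        expected = 3.0 * np.sqrt([1.0, 2.0, 3.0]) / (1 + math.sqrt(2) + math.sqrt(3))
        assert normalise_fabric([1.0, 2.0, 3.0], 0.5) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            normalise_fabric([1.0, 0.0, 2.0], 1.0)


class TestStiffnessCompliance:
    def test_isotropic_matrix_entries(self, elastic):
        # isotropic Hooke law: normal diag lambda0+2mu0, off-diag lambda0,
        # shear diag 2mu0 in the orthonormal (Mandel) basis
        S = build_stiffness(1.0, FabricTensor.isotropic(3), elastic).matrix
        assert np.allclose(np.diag(S)[:3], 12000.0)
        assert S[0, 1] == pytest.approx(4000.0)
        assert S[0, 2] == pytest.approx(4000.0)
        assert np.allclose(np.diag(S)[3:], 8000.0)
        assert np.allclose(S[:3, 3:], 0.0)

    def test_density_scaling_is_multiplicative(self, elastic):
        M = random_fabric(np.random.default_rng(0))
        S1 = build_stiffness(1.0, M, elastic).matrix
        S_half = build_stiffness(0.5, M, elastic).matrix
        assert np.allclose(S_half, 0.25 * S1)  # f(rho) = rho^2

    @pytest.mark.parametrize("d", [2, 3])
    def test_inverse_pair_random(self, d):
        c = ElasticConstants.from_engineering(10000.0, 0.25, d=d)
        rng = np.random.default_rng(7)
        n = d * (d + 1) // 2
        for _ in range(50):
            M = random_fabric(rng, d)
            rho = rng.uniform(0.05, 1.0)
            S = build_stiffness(rho, M, c)
            E = build_compliance(rho, M, c)
            assert np.allclose(S.matrix @ E.matrix, np.eye(n), atol=1e-9)
            assert np.all(S.eigenvalues() > 0)
            assert np.allclose(S.matrix, S.matrix.T)

    def test_normal_shear_decoupling_in_fabric_basis(self, elastic):
        M = FabricTensor.from_eigenvalues([0.7, 1.0, 1.3])
        S = build_stiffness(1.0, M, elastic).matrix
        assert np.max(np.abs(S[:3, 3:])) < 1e-12

    def test_axial_compliance_in_fabric_basis(self, elastic):
        # diagonal of the compliance normal block is m_i^-2 / eps0
        m = np.array([0.7, 1.0, 1.3])
        E = build_compliance(1.0, FabricTensor.from_eigenvalues(m), elastic).matrix
        assert np.diag(E)[:3] == pytest.approx(1.0 / (elastic.eps0 * m**2))

    def test_uniaxial_strain_engineering_constants(self, elastic):
        sigma = 10.0
        S = StressState.from_principal([0.0, 0.0, sigma])
        E = pse_strain(S, 1.0, FabricTensor.isotropic(3), elastic)
        eps = np.sort(E.sigma)
        assert eps[-1] == pytest.approx(sigma / elastic.eps0)
        assert eps[0] == pytest.approx(-elastic.nu0 * sigma / elastic.eps0)

    def test_rotation_invariance(self, elastic):
        # stiffness assembled in a rotated frame equals the rotated stiffness
        rng = np.random.default_rng(3)
        from conftest import random_direction
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m = np.array([0.6, 1.0, 1.4])
        M_rot = FabricTensor(m=m, axes=Q.T)
        X = rng.normal(size=(3, 3)); X = X + X.T
        S_rot = build_stiffness(1.0, M_rot, elastic).apply(X)
        # transform X to the fabric frame, apply the aligned stiffness, rotate back
        Xf = Q.T @ X @ Q
        S_aligned = build_stiffness(1.0, FabricTensor.from_eigenvalues(m), elastic).apply(Xf)
        assert np.allclose(S_rot, Q @ S_aligned @ Q.T, atol=1e-8)

    def test_rejects_invalid_density(self, elastic):
        with pytest.raises(DomainError):
            build_stiffness(0.0, FabricTensor.isotropic(3), elastic)
        with pytest.raises(DomainError):
            build_compliance(1.2, FabricTensor.isotropic(3), elastic)


class TestYieldTensors:
    def test_asymmetry_coefficients(self, yield_constants):
        assert yield_constants.f0 == pytest.approx(0.5 * (1 / 54 - 1 / 72))
        assert yield_constants.F0 == pytest.approx(0.5 * (1 / 54 + 1 / 72))

    def test_shear_yield_stress_consistent(self, yield_constants):
        assert yield_constants.tau0_consistent == pytest.approx(38.27, rel=1e-3)

    def test_identity_fabric_gives_isotropic_F(self, yield_constants):
        F, _ = build_yield_tensors(1.0, FabricTensor.isotropic(3), yield_constants)
        assert np.allclose(F, yield_constants.f0 * np.eye(3))

    def test_density_scaling(self, yield_constants):
        M = FabricTensor.from_eigenvalues([0.8, 1.0, 1.2])
        F1, FF1 = build_yield_tensors(1.0, M, yield_constants)
        F2, FF2 = build_yield_tensors(0.5, M, yield_constants)
        assert np.allclose(F2, 4.0 * F1)       # 1/fhat with p = 2
        assert np.allclose(FF2.matrix, 16.0 * FF1.matrix)

    def test_quadric_positive_definite(self, yield_constants):
        rng = np.random.default_rng(11)
        for _ in range(20):
            M = random_fabric(rng)
            _, FF = build_yield_tensors(1.0, M, yield_constants)
            assert np.all(FF.eigenvalues() > 0)

    def test_inconsistent_tau0_rejected(self):
        with pytest.raises(DomainError):
            YieldConstants(sigma0_plus=54.0, sigma0_minus=72.0, zeta0=0.30, tau0=40.0)


class TestCriteria:
    def test_cfe_uniaxial_set_point(self, elastic):
        # 72 MPa uniaxial at full density: the CFE set-point 0.2592 MPa
        S = StressState.from_principal([0.0, 0.0, 72.0])
        psi = cfe_value(S, 1.0, FabricTensor.isotropic(3), elastic)
        assert psi == pytest.approx(0.2592)

    def test_cfe_even_and_quadratic(self, elastic, rng):
        M = random_fabric(rng)
        sigma = rng.normal(size=3)
        S = StressState.from_principal(sigma)
        Sn = StressState.from_principal(-sigma)
        S2 = StressState.from_principal(2.5 * sigma)
        psi = cfe_value(S, 0.4, M, elastic)
        assert cfe_value(Sn, 0.4, M, elastic) == pytest.approx(psi, rel=1e-10)
        assert cfe_value(S2, 0.4, M, elastic) == pytest.approx(2.5**2 * psi, rel=1e-10)

    def test_cfe_density_scaling_identity(self, elastic, rng):
        M = random_fabric(rng)
        S = StressState.from_principal(rng.normal(size=3))
        rho = 0.3
        lhs = cfe_value(S, 1.0, M, elastic)
        rhs = elastic.f(rho) ** 2 * cfe_value(S, rho, M, elastic)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    @pytest.mark.parametrize(
        "sigma, expected",
        [([0.0, 0.0, 54.0], 1.0), ([0.0, 0.0, -72.0], 1.0)],
    )
    def test_gyc_uniaxial_yield(self, yield_constants, sigma, expected):
        S = StressState.from_principal(sigma)
        y = gyc_value(S, 1.0, FabricTensor.isotropic(3), yield_constants)
        assert y == pytest.approx(expected, rel=1e-12)

    def test_gyc_pure_shear_yield(self, yield_constants):
        tau = 38.27
        S = StressState.from_matrix(
            np.array([[0.0, tau, 0.0], [tau, 0.0, 0.0], [0.0, 0.0, 0.0]])
        )
        y = gyc_value(S, 1.0, FabricTensor.isotropic(3), yield_constants)
        assert y == pytest.approx(1.0, rel=1e-3)

    def test_gyc_homogeneous_degree_one_and_density_scaling(
        self, yield_constants, rng
    ):
        M = random_fabric(rng)
        S = StressState.from_principal(rng.normal(size=3))
        S3 = StressState.from_principal(3.0 * S.sigma)
        rho = 0.35
        y = gyc_value(S, 1.0, M, yield_constants)
        assert gyc_value(S3, 1.0, M, yield_constants) == pytest.approx(3 * y, rel=1e-10)
        assert y == pytest.approx(
            yield_constants.fhat(rho) * gyc_value(S, rho, M, yield_constants),
            rel=1e-10,
        )

    def test_gyc_tension_compression_asymmetry(self, yield_constants, rng):
        M = random_fabric(rng)
        S = StressState.from_principal(np.array([0.5, 0.8, 1.0]))
        Sn = StressState.from_principal(-S.sigma)
        assert gyc_value(S, 1.0, M, yield_constants) != pytest.approx(
            gyc_value(Sn, 1.0, M, yield_constants), rel=1e-6
        )
        symmetric = YieldConstants(sigma0_plus=60.0, sigma0_minus=60.0, zeta0=0.30)
        assert gyc_value(S, 1.0, M, symmetric) == pytest.approx(
            gyc_value(Sn, 1.0, M, symmetric), rel=1e-10
        )

    def test_pse_strain_orthotropic_decoupling(self, elastic):
        M = FabricTensor.from_eigenvalues([0.7, 1.0, 1.3])
        S = StressState.from_principal([1.0, -2.0, 0.5])
        E = pse_strain(S, 1.0, M, elastic)
        # strain shares the fabric eigenbasis: off-diagonal components vanish
        assert np.max(np.abs(E.matrix() - np.diag(np.diag(E.matrix())))) < 1e-12

    def test_pse_strain_hydrostatic(self, elastic):
        S = StressState.from_principal([-144.0, -144.0, -144.0])
        E = pse_strain(S, 1.0, FabricTensor.isotropic(3), elastic)
        assert E.sigma == pytest.approx([-0.0072] * 3)


class TestRecoverDensity:
    def test_power_law_inversion(self):
        assert recover_density(0.5, 0.5, 2.0) == pytest.approx(0.5)
        assert recover_density(1.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_infeasible_intensity(self):
        with pytest.raises(InfeasibleDensityError):
            recover_density(1.0, 1.2, 2.0)


class TestStressState:
    def test_normalisation_reconstructs(self, rng):
        sigma = rng.normal(size=3) * 40
        S = StressState.from_principal(sigma)
        assert np.allclose(
            S.normalised().matrix() * S.lambda_S, S.matrix(), atol=1e-10 * 40
        )
        assert np.abs(S.normalised().sigma).sum() == pytest.approx(3.0, abs=1e-12)

    def test_normalisation_homogeneous_in_sign(self, rng):
        sigma = rng.normal(size=3)
        S = StressState.from_principal(sigma)
        Sm = StressState.from_principal(-2.0 * sigma)
        assert np.allclose(Sm.normalised().sigma, -S.normalised().sigma)

    def test_zero_stress_rejected(self):
        with pytest.raises(DomainError):
            StressState.from_principal([0.0, 0.0, 0.0]).normalised()


class TestFabricTensor:
    def test_invariants(self):
        M = FabricTensor.from_eigenvalues([0.9, 1.5, 0.6], normalise=True)
        assert M.m.sum() == pytest.approx(3.0, abs=1e-12)
        assert M.DA == pytest.approx(1.5 / 0.6)

    def test_da_invariant_under_trace_rescaling(self):
        raw = np.array([0.4, 1.0, 1.6])
        M1 = FabricTensor.from_eigenvalues(raw, normalise=True)
        M2 = FabricTensor.from_eigenvalues(5 * raw, normalise=True)
        assert M1.DA == pytest.approx(M2.DA)

    def test_rejects_bad_eigenvalues(self):
        with pytest.raises(DomainError):
            FabricTensor.from_eigenvalues([0.0, 1.0, 2.0])
        with pytest.raises(DomainError):
            FabricTensor.from_eigenvalues([0.5, 1.0, 1.0])  # trace != 3

    def test_matrix_round_trip(self, rng):
        M = random_fabric(rng)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        M_rot = FabricTensor(m=M.m, axes=Q.T)
        back = FabricTensor.from_matrix(M_rot.matrix())
        assert np.allclose(np.sort(back.m), np.sort(M.m), atol=1e-12)


class TestMandelBasis:
    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_orthonormal(self, d):
        basis = mandel_basis(d)
        n = d * (d + 1) // 2
        assert len(basis) == n
        gram = np.array([[np.tensordot(A, B) for B in basis] for A in basis])
        assert np.allclose(gram, np.eye(n), atol=1e-14)

    def test_double_contraction_is_dot_product(self, rng):
        X = rng.normal(size=(3, 3)); X = X + X.T
        Y = rng.normal(size=(3, 3)); Y = Y + Y.T
        assert np.tensordot(X, Y) == pytest.approx(
            sym_to_mandel(X) @ sym_to_mandel(Y), rel=1e-12
        )
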