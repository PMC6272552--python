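import math

import numpy as np
import pytest

from auxqmmm import adft_scf as scf
from auxqmmm.chem_model import Atom, PointCharge
from auxqmmm.grids import GridSpec, molecular_grid
from auxqmmm.gto_integrals import (
    AuxBasis,
    ContractedGTO,
    HermiteAuxFunction,
    build_ao_basis,
    build_aux_basis,
    eri4,
)
from auxqmmm.reference import reference_scf


def _eri3_tensor(basis, aux):
    provider = scf.ERI3Provider(basis, aux, "conventional", 1e-10, 8)
    return provider.tensor()


def _exact_coulomb(P, T4):
    return 0.5 * float(np.einsum("ab,cd,abcd->", P, P, T4))


def _fitted_coulomb(P, T3, G):
    x = scf.fit_density(P, T3, G).x
    J = np.einsum("abc,ab->c", T3, P)
    return scf.fitted_coulomb_energy(x, J, G)


# ---------------------------------------------------------------------------
# variational density fit
# ---------------------------------------------------------------------------

def test_fit_in_span_density_is_exact():
    # density of one normalized s orbital is a single Hermite s of exponent 2z
    z = 0.9
    a = ContractedGTO([0, 0, 0], (0, 0, 0), [z], [1.0])
    from auxqmmm.gto_integrals import AOBasis, Shell

    basis = AOBasis(shells=[Shell(0, np.zeros(3), 0, np.array([z]), np.array([1.0]))])
    aux = AuxBasis(functions=[HermiteAuxFunction(np.zeros(3), 2.0 * z)])
    T3 = _eri3_tensor(basis, aux)
    G = aux.metric()
    P = np.array([[1.0]])
    exact = eri4(a, a, a, a)
    assert _fitted_coulomb(P, T3, G) * 2.0 == pytest.approx(exact, abs=1e-10)


def test_variational_bound_random_densities(water_minimal, eri4_tensor_water):
    basis, aux = water_minimal
    T3 = _eri3_tensor(basis, aux)
    G = aux.metric()
    rng = np.random.default_rng(9)
    n = basis.n_functions
    for _ in range(50):
        M = rng.standard_normal((n, n))
        P = M @ M.T / n  # symmetric PSD density-like matrix
        ej_fit = _fitted_coulomb(P, T3, G)
        ej_exact = _exact_coulomb(P, eri4_tensor_water)
        assert ej_fit <= ej_exact + 1e-10


def test_aux_superset_never_decreases_fit(water_minimal, water_atoms, minimal_lib):
    basis, aux = water_minimal
    G = aux.metric()
    T3 = _eri3_tensor(basis, aux)
    # a strict superset: add intermediate even-tempered exponents on O
    extra = [
        HermiteAuxFunction(water_atoms[0].position, z) for z in (0.55, 5.0, 42.0)
    ]
    aux2 = AuxBasis(functions=list(aux.functions) + extra)
    T3b = _eri3_tensor(basis, aux2)
    G2 = aux2.metric()
    rng = np.random.default_rng(10)
    n = basis.n_functions
    for _ in range(10):
        M = rng.standard_normal((n, n))
        P = M @ M.T / n
        assert _fitted_coulomb(P, T3b, G2) >= _fitted_coulomb(P, T3, G) - 1e-10


def test_fit_rejects_indefinite_metric(water_minimal):
    basis, aux = water_minimal
    T3 = _eri3_tensor(basis, aux)
    G = -np.eye(aux.n_functions)
    with pytest.raises(RuntimeError, match="positive semidefinite"):
        scf.fit_density(np.eye(basis.n_functions), T3, G)


# ---------------------------------------------------------------------------
# grid and LDA
# ---------------------------------------------------------------------------

def test_grid_normalizes_s_gaussian(water_atoms):
    grid = molecular_grid(water_atoms)
    for z, center in ((0.5, water_atoms[0].position), (3.0, water_atoms[1].position)):
        N2 = (2.0 * z / math.pi) ** 1.5
        r2 = np.sum((grid.points - center) ** 2, axis=1)
        assert grid.integrate(N2 * np.exp(-2.0 * z * r2)) == pytest.approx(
            1.0, abs=1e-6
        )


def test_dirac_exchange_closed_form():
    rho = np.array([1e-3, 0.1, 1.0, 7.5])
    eps, v = scf.lda_energy_density(rho)
    eps_x = -(3.0 / 4.0) * (3.0 / math.pi) ** (1.0 / 3.0) * rho ** (1.0 / 3.0)
    # correlation is negative and much smaller than exchange
    assert np.all(eps < eps_x) and np.all(eps > 1.6 * eps_x)


def test_lda_potential_is_energy_derivative():
    # v_xc = d(rho * eps_xc)/d rho, checked by central differences
    rho = np.array([0.05, 0.4, 2.0])
    h = 1e-6
    ep, _ = scf.lda_energy_density(rho + h)
    em, _ = scf.lda_energy_density(rho - h)
    fd = ((rho + h) * ep - (rho - h) * em) / (2 * h)
    _, v = scf.lda_energy_density(rho)
    assert np.allclose(v, fd, atol=1e-8)


def test_xc_zero_density():
    grid = molecular_grid([Atom("H", 1, [0, 0, 0], 1.0)], GridSpec(n_radial=10, n_theta=6, n_phi=12))
    vals = np.zeros((1, len(grid.points)))
    E, v, clamped = scf.xc_lda(np.zeros(1), grid, vals)
    assert E == 0.0 and np.allclose(v, 0.0)


def test_fitted_density_norm_matches_analytic(water_atoms, water_minimal):
    basis, aux = water_minimal
    T3 = _eri3_tensor(basis, aux)
    G = aux.metric()
    res = scf.run_scf(water_atoms, basis, aux=aux,
                      settings=scf.SCFSettings(scheme="conventional"))
    x = res.fit.x
    grid = molecular_grid(water_atoms)
    vals = np.stack([f.values(grid.points) for f in aux.functions])
    n_grid = grid.integrate(x @ vals)
    n_analytic = sum(
        xi * f.moment_integral() for xi, f in zip(x, aux.functions)
    )
    assert n_grid == pytest.approx(n_analytic, abs=1e-5)


# ---------------------------------------------------------------------------
# Kohn-Sham matrix = energy derivative
# ---------------------------------------------------------------------------

def test_ks_matrix_is_fd_derivative_heh_plus(minimal_lib):
    atoms = [Atom("He", 2, [0, 0, 0], 4.0), Atom("H", 1, [0, 0, 1.46], 1.0)]
    basis = build_ao_basis(atoms, minimal_lib)
    aux = build_aux_basis(atoms, minimal_lib)
    S, T, H = scf.core_hamiltonian_matrices(atoms, basis)
    G = aux.metric()
    G_eig = np.linalg.eigh(G)
    T3 = _eri3_tensor(basis, aux)
    grid = molecular_grid(atoms)
    vals = np.stack([f.values(grid.points) for f in aux.functions])
    res = scf.run_scf(atoms, basis, aux=aux, charge=1,
                      settings=scf.SCFSettings(scheme="conventional", tol=1e-9))
    P = res.density
    E, K = scf.energy_and_ks(P, H, T3, G, G_eig, grid, vals)
    h = 1e-5
    for a in range(basis.n_functions):
        for b in range(basis.n_functions):
            Pp = P.copy(); Pp[a, b] += h
            Pm = P.copy(); Pm[a, b] -= h
            fd = (
                scf.scf_energy_of_density(Pp, H, T3, G, G_eig, grid, vals)
                - scf.scf_energy_of_density(Pm, H, T3, G, G_eig, grid, vals)
            ) / (2 * h)
            assert abs(K[a, b] - fd) <= 1e-6
    assert np.allclose(K, K.T, atol=1e-10)


def test_ks_zero_charge_zero_density_is_core(water_minimal, water_atoms):
    basis, aux = water_minimal
    S, T, H = scf.core_hamiltonian_matrices(water_atoms, basis)
    T3 = _eri3_tensor(basis, aux)
    G = aux.metric()
    P = np.zeros((basis.n_functions, basis.n_functions))
    K = scf.build_ks_matrix(P, np.zeros(aux.n_functions), H,
                            np.zeros(aux.n_functions), T3)
    assert np.array_equal(K, H)


# ---------------------------------------------------------------------------
# SCF driver
# ---------------------------------------------------------------------------

def test_scf_matches_naive_reference(minimal_lib):
    he = [Atom("He", 2, [0, 0, 0], 4.0)]
    h2 = [Atom("H", 1, [0, 0, 0], 1.0), Atom("H", 1, [0, 0, 1.4], 1.0)]
    for atoms in (he, h2):
        basis = build_ao_basis(atoms, minimal_lib)
        aux = build_aux_basis(atoms, minimal_lib)
        res = scf.run_scf(atoms, basis, aux=aux,
                          settings=scf.SCFSettings(scheme="conventional", tol=1e-10))
        assert res.converged
        e_ref = reference_scf(atoms, basis, aux)
        assert abs(res.E_total - e_ref) <= 1e-10


def test_scf_cross_scheme_equality(minimal_lib):
    h2 = [Atom("H", 1, [0, 0, 0], 1.0), Atom("H", 1, [0, 0, 1.4], 1.0)]
    energies = {}
    for scheme in ("conventional", "direct", "mixed"):
        r = scf.run_scf(h2, minimal_lib,
                        settings=scf.SCFSettings(scheme=scheme, tol=1e-9))
        assert r.converged
        energies[scheme] = r.E_total
    assert max(energies.values()) - min(energies.values()) <= 1e-8


def test_scf_zero_charge_embedding_is_gas_phase(water_atoms, minimal_lib):
    gas = scf.run_scf(water_atoms, minimal_lib,
                      settings=scf.SCFSettings(scheme="mixed", tol=1e-8))
    zeros = [PointCharge(np.array([9.0, 0, 0]), 0.0),
             PointCharge(np.array([0, 9.0, 0]), 0.0)]
    emb = scf.run_scf(water_atoms, minimal_lib, embedding=zeros,
                      settings=scf.SCFSettings(scheme="mixed", tol=1e-8))
    assert emb.E_total == pytest.approx(gas.E_total, abs=1e-10)


def test_scf_result_components_sum(water_atoms, minimal_lib):
    res = scf.run_scf(water_atoms, minimal_lib,
                      settings=scf.SCFSettings(scheme="conventional"))
    assert res.E_total == pytest.approx(sum(res.components.values()), abs=1e-12)
    assert res.converged and len(res.cycles) >= 1
    # electron count from the converged density
    S, _, _ = scf.core_hamiltonian_matrices(water_atoms, res.basis)
    assert np.einsum("ab,ab->", res.density, S) == pytest.approx(10.0, abs=1e-8)


def test_scf_rejects_open_shell(minimal_lib):
    h = [Atom("H", 1, [0, 0, 0], 1.0)]
    with pytest.raises(ValueError, match="even electron"):
        scf.run_scf(h, minimal_lib)


def test_scf_nonconvergence_reports_not_raises(water_atoms, minimal_lib):
    res = scf.run_scf(water_atoms, minimal_lib,
                      settings=scf.SCFSettings(scheme="conventional", max_iter=1,
                                               tol=1e-14))
    assert not res.converged
    assert len(res.cycles) == 1
    assert np.isfinite(res.E_total)


# ---------------------------------------------------------------------------
# embedded nuclear repulsion
# ---------------------------------------------------------------------------

def test_nuclear_repulsion_cases():
    p1 = Atom("H", 1, [0, 0, 0], 1.0)
    p2 = Atom("H", 1, [0, 0, 1.0], 1.0)
    assert scf.nuclear_embedded_repulsion([p1, p2], []) == pytest.approx(1.0)
    q = PointCharge(np.array([0, 0, 2.0]), -1.0)
    assert scf.nuclear_embedded_repulsion([p1], [q]) == pytest.approx(-0.5)
    # translation invariance
    shift = np.array([3.0, -1.0, 2.0])
    p1t = Atom("H", 1, shift, 1.0)
    p2t = Atom("H", 1, shift + [0, 0, 1.0], 1.0)
    qt = PointCharge(shift + [0, 0, 2.0], -1.0)
    assert scf.nuclear_embedded_repulsion([p1t, p2t], [qt]) == pytest.approx(
        scf.nuclear_embedded_repulsion([p1, p2], [q]), abs=1e-12
    )
    with pytest.raises(ZeroDivisionError):
        scf.nuclear_embedded_repulsion([p1, Atom("H", 1, [0, 0, 0], 1.0)], [])


# ---------------------------------------------------------------------------
# density-fitted exact exchange (full-domain limit)
# ---------------------------------------------------------------------------

def _product_spanning_aux(basis):
    """All primitive s products of an s-only basis as Hermite auxiliaries."""
    funcs = {}
    for sh1 in basis.shells:
        for sh2 in basis.shells:
            for z1 in sh1.exponents:
                for z2 in sh2.exponents:
                    p = z1 + z2
                    P = (z1 * sh1.center + z2 * sh2.center) / p
                    funcs[(round(p, 10), tuple(np.round(P, 10)))] = HermiteAuxFunction(P, p)
    return AuxBasis(functions=list(funcs.values()))


def test_fitted_exchange_matches_four_center(minimal_lib):
    h2 = [Atom("H", 1, [0, 0, 0], 1.0), Atom("H", 1, [0, 0, 1.4], 1.0)]
    basis = build_ao_basis(h2, minimal_lib)
    aux = _product_spanning_aux(basis)
    res = scf.run_scf(h2, basis, aux=build_aux_basis(h2, minimal_lib),
                      settings=scf.SCFSettings(scheme="conventional", tol=1e-9))
    C_occ = res.mo_coefficients[:, : res.n_occupied]
    E_x, X = scf.fitted_exchange(C_occ, basis, aux)
    # brute-force exchange: -1/4 sum P K with K from the 4-center tensor
    from auxqmmm.gto_integrals import eri4

    fns = basis.functions
    n = len(fns)
    T4 = np.zeros((n, n, n, n))
    for i in range(n):
        for j in range(n):
            for k in range(n):
                for l in range(n):
                    T4[i, j, k, l] = eri4(fns[i], fns[j], fns[k], fns[l])
    P = 2.0 * C_occ @ C_occ.T
    Kx = np.einsum("cd,acbd->ab", P, T4)
    E_ref = -0.25 * float(np.einsum("ab,ab->", P, Kx))
    assert E_x == pytest.approx(E_ref, abs=1e-8)
    assert E_x <= 0.0


def test_fitted_exchange_two_electron_single_orbital(minimal_lib):
    # one doubly occupied MO: exchange equals minus half the Coulomb energy
    he = [Atom("He", 2, [0, 0, 0], 4.0)]
    basis = build_ao_basis(he, minimal_lib)
    aux = _product_spanning_aux(basis)
    res = scf.run_scf(he, basis, aux=build_aux_basis(he, minimal_lib),
                      settings=scf.SCFSettings(scheme="conventional"))
    C_occ = res.mo_coefficients[:, :1]
    E_x, _ = scf.fitted_exchange(C_occ, basis, aux)
    a = basis.functions[0]
    from auxqmmm.gto_integrals import eri4

    P = 2.0 * C_occ @ C_occ.T
    E_J = 0.5 * P[0, 0] ** 2 * eri4(a, a, a, a)
    assert E_x == pytest.approx(-0.5 * E_J, abs=1e-8)
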