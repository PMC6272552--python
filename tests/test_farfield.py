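import math

import numpy as np
import pytest

from auxqmmm import farfield as ff
from auxqmmm.chem_model import PointCharge
from auxqmmm.gto_integrals import (
    ContractedGTO,
    HermiteAuxFunction,
    build_ao_basis,
    build_aux_basis,
    eri3,
    nai_exact,
    overlap,
)
from helpers import random_primitive


# ---------------------------------------------------------------------------
# extents
# ---------------------------------------------------------------------------

def test_shell_extent_unit_s_closed_form():
    s = ContractedGTO([0, 0, 0], (0, 0, 0), [1.0], [1.0])
    tau = 1e-10
    N = (2.0 / math.pi) ** 0.75
    assert ff.shell_extent(s, tau) == pytest.approx(
        math.sqrt(math.log(N / tau)), abs=1e-6
    )


def test_extent_monotone_in_tau_and_exponent():
    s = ContractedGTO([0, 0, 0], (0, 0, 0), [1.0], [1.0])
    assert ff.shell_extent(s, 1e-12) > ff.shell_extent(s, 1e-8)
    tight = ContractedGTO([0, 0, 0], (0, 0, 0), [1000.0], [1.0])
    diffuse = ContractedGTO([0, 0, 0], (0, 0, 0), [0.1], [1.0])
    assert ff.shell_extent(tight, 1e-10) < ff.shell_extent(diffuse, 1e-10)


def test_extent_rejects_bad_tau():
    s = ContractedGTO([0, 0, 0], (0, 0, 0), [1.0], [1.0])
    with pytest.raises(ValueError):
        ff.shell_extent(s, 0.0)
    with pytest.raises(ValueError):
        ff.shell_extent(s, 1.0)


def test_aux_potential_extent_monotone():
    a = HermiteAuxFunction([0, 0, 0], 1.0)
    r1 = ff.aux_potential_extent(a, 1e-10)
    r2 = ff.aux_potential_extent(a, 1e-6)
    assert r1 > r2 > 0


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classification_extremes(water_atoms, minimal_lib):
    basis = build_ao_basis(water_atoms, minimal_lib)
    sites = np.array([[1e3, 0.0, 0.0], water_atoms[0].position])
    nf = ff.classify_mm(basis, sites, 1e-10)
    assert not nf.shell_near[:, 0].any()   # remote charge far for every shell
    assert nf.shell_near[:, 1].any()       # on-nucleus charge near


def test_classification_matches_brute_force(water_atoms, minimal_lib):
    basis = build_ao_basis(water_atoms, minimal_lib)
    rng = np.random.default_rng(17)
    sites = rng.uniform(-12, 12, (1000, 3))
    nf = ff.classify_mm(basis, sites, 1e-10)
    ext = ff.ExtentTable.build(basis, 1e-10)
    n_shell = len(basis.shells)
    brute_pair_near = 0
    map_pair_near = 0
    for s1 in range(n_shell):
        for s2 in range(s1 + 1):
            for d in range(len(sites)):
                near1 = (
                    np.linalg.norm(sites[d] - basis.shells[s1].center)
                    <= ext.shell_extents[s1]
                )
                near2 = (
                    np.linalg.norm(sites[d] - basis.shells[s2].center)
                    <= ext.shell_extents[s2]
                )
                brute_pair_near += int(near1 or near2)
            map_pair_near += int(nf.pair_near(s1, s2).sum())
    assert brute_pair_near == map_pair_near
    # near/far partition is exact and disjoint
    for s in range(n_shell):
        assert nf.shell_near[s].sum() + (~nf.shell_near[s]).sum() == len(sites)


# ---------------------------------------------------------------------------
# T tensors
# ---------------------------------------------------------------------------

def test_t_tensor_low_orders_closed_form():
    A = np.array([0.0, 0.0, 0.0])
    D = np.array([3.0, 0.0, 0.0])
    T = ff.t_tensor(A, D, 2)
    assert T[(0, 0, 0)] == pytest.approx(1.0 / 3.0, abs=1e-14)
    assert T[(1, 0, 0)] == pytest.approx((A[0] - D[0]) / 27.0, abs=1e-14)
    lap = T[(2, 0, 0)] + T[(0, 2, 0)] + T[(0, 0, 2)]
    assert abs(lap) <= 1e-10 * abs(T[(2, 0, 0)])


def test_t_tensor_against_symbolic_oracle():
    sympy = pytest.importorskip("sympy")
    dx, dy, dz = sympy.symbols("dx dy dz")
    Ax, Ay, Az = 0.31, -0.77, 1.19
    expr = 1 / sympy.sqrt((Ax - dx) ** 2 + (Ay - dy) ** 2 + (Az - dz) ** 2)
    Dv = {dx: 2.4, dy: -1.1, dz: 0.6}
    T = ff.t_tensor(np.array([Ax, Ay, Az]), np.array([2.4, -1.1, 0.6]), 8)
    cases = [m for m in T.values if sum(m) <= 4]
    cases += [(8, 0, 0), (4, 2, 2), (3, 3, 2), (0, 0, 8), (2, 2, 2), (5, 1, 0)]
    for m in cases:
        d = sympy.diff(expr, dx, m[0], dy, m[1], dz, m[2])
        ref = float(d.subs(Dv))
        scale = max(abs(ref), 1e-30)
        assert abs(T[m] - ref) <= 1e-10 * scale, m


def test_t_tensor_singularity():
    with pytest.raises(ZeroDivisionError):
        ff.t_tensor(np.zeros(3), np.zeros(3), 2)


def test_laplacian_identity_all_orders():
    rng = np.random.default_rng(3)
    A, D = rng.uniform(-2, 2, (2, 3))
    T = ff.t_tensor(A, D, 8)
    for m in T.values:
        if sum(m) <= 6:
            lap = (
                T[(m[0] + 2, m[1], m[2])]
                + T[(m[0], m[1] + 2, m[2])]
                + T[(m[0], m[1], m[2] + 2)]
            )
            scale = max(abs(T[(m[0] + 2, m[1], m[2])]), 1e-30)
            assert abs(lap) <= 1e-9 * scale


# ---------------------------------------------------------------------------
# asymptotic NAI
# ---------------------------------------------------------------------------

def test_nai_asymptotic_far_site_machine_accuracy():
    rng = np.random.default_rng(21)
    a, b = random_primitive(rng, zlo=0.3, zhi=5), random_primitive(rng, zlo=0.3, zhi=5)
    D = np.array([50.0, 3.0, -7.0])
    assert ff.nai_asymptotic(a, b, D, 8) == pytest.approx(
        nai_exact(a, b, D), abs=1e-10
    )


def test_nai_asymptotic_order0_is_overlap_over_R():
    a = ContractedGTO([0, 0, 0], (0, 0, 0), [1.2], [1.0])
    b = ContractedGTO([0, 0, 0], (0, 0, 0), [800.0], [1.0])  # point-like on a's center
    D = np.array([0.0, 0.0, 30.0])
    assert ff.nai_asymptotic(a, b, D, 0) == pytest.approx(
        overlap(a, b) / 30.0, abs=1e-14
    )


def test_nai_asymptotic_error_decreases_with_order():
    a = ContractedGTO([0, 0, 0], (1, 0, 0), [0.8], [1.0])
    b = ContractedGTO([0.9, 0.2, 0], (0, 0, 1), [1.1], [1.0])
    D = np.array([20.0, 1.0, 2.0])
    exact = nai_exact(a, b, D)
    errs = [abs(ff.nai_asymptotic(a, b, D, o) - exact) for o in (2, 4, 6, 8)]
    assert errs[0] > errs[1] > errs[2] > errs[3]


def test_nai_asymptotic_center_b_variant():
    rng = np.random.default_rng(22)
    a, b = random_primitive(rng, zlo=0.5, zhi=5), random_primitive(rng, zlo=0.5, zhi=5)
    D = np.array([-40.0, 10.0, 5.0])
    ex = nai_exact(a, b, D)
    assert ff.nai_asymptotic(a, b, D, 8, center="b") == pytest.approx(ex, abs=1e-10)


def test_asymptotic_matches_exact_outside_extents_randomized():
    rng = np.random.default_rng(23)
    tau = 1e-10
    for _ in range(40):
        a = random_primitive(rng, zlo=0.1, zhi=50, box=1.0)
        b = random_primitive(rng, zlo=0.1, zhi=50, box=1.0)
        ra, rb = ff.shell_extent(a, tau), ff.shell_extent(b, tau)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        base = a.center if float(np.min(a.exponents)) >= float(np.min(b.exponents)) else b.center
        D = base + u * (max(ra + np.linalg.norm(a.center - base),
                            rb + np.linalg.norm(b.center - base)) + rng.uniform(0, 3))
        center = "a" if float(np.min(a.exponents)) >= float(np.min(b.exponents)) else "b"
        err = abs(ff.nai_asymptotic(a, b, D, 8, center=center) - nai_exact(a, b, D))
        assert err <= 1e-8, (a.momentum, b.momentum, err)


# ---------------------------------------------------------------------------
# asymptotic 3-center ERIs
# ---------------------------------------------------------------------------

def test_eri3_asymptotic_far_aux_machine_accuracy():
    rng = np.random.default_rng(31)
    a, b = random_primitive(rng, zlo=0.3, zhi=5), random_primitive(rng, zlo=0.3, zhi=5)
    for idx in ((0, 0, 0), (0, 1, 0), (1, 0, 1), (0, 0, 2)):
        c = HermiteAuxFunction([50.0, -4.0, 6.0], 0.7, idx)
        assert ff.eri3_asymptotic(a, b, c, 8) == pytest.approx(
            eri3(a, b, c), abs=1e-10
        )


def test_eri3_asymptotic_order0_leading_term():
    a = ContractedGTO([0, 0, 0], (0, 0, 0), [1.0], [1.0])
    b = ContractedGTO([0, 0, 0], (0, 0, 0), [2.0], [1.0])
    zc, R = 0.9, 40.0
    c = HermiteAuxFunction([0, 0, R], zc, normalized=False)
    assert ff.eri3_asymptotic(a, b, c, 0) == pytest.approx(
        overlap(a, b) * (math.pi / zc) ** 1.5 / R, abs=1e-12
    )


def test_eri3_asymptotic_hermite_index_is_center_derivative():
    a = ContractedGTO([0, 0, 0], (1, 0, 0), [0.9], [1.0])
    b = ContractedGTO([0.5, 0.1, -0.2], (0, 0, 0), [1.3], [1.0])
    zc = 0.8
    C = np.array([25.0, 2.0, -3.0])
    h = 1e-4
    for dim in range(3):
        idx = tuple(1 if d == dim else 0 for d in range(3))
        c1 = HermiteAuxFunction(C, zc, idx, normalized=False)
        cp = HermiteAuxFunction(C + h * np.eye(3)[dim], zc, normalized=False)
        cm = HermiteAuxFunction(C - h * np.eye(3)[dim], zc, normalized=False)
        fd = (ff.eri3_asymptotic(a, b, cp, 8) - ff.eri3_asymptotic(a, b, cm, 8)) / (2 * h)
        assert ff.eri3_asymptotic(a, b, c1, 8) == pytest.approx(fd, abs=1e-8)


def test_eri3_asymptotic_order_sweep_monotone():
    a = ContractedGTO([0, 0, 0], (0, 1, 0), [0.7], [1.0])
    b = ContractedGTO([1.0, 0, 0], (0, 0, 0), [1.1], [1.0])
    c = HermiteAuxFunction([20.0, 3.0, 1.0], 0.9)
    exact = eri3(a, b, c)
    errs = [abs(ff.eri3_asymptotic(a, b, c, o) - exact) for o in (2, 4, 6, 8)]
    assert errs[0] > errs[1] > errs[2] > errs[3]


def test_eri3_asymptotic_order_overflow():
    a = ContractedGTO([0, 0, 0], (0, 0, 0), [1.0], [1.0])
    c = HermiteAuxFunction([20, 0, 0], 1.0)
    with pytest.raises(ValueError):
        ff.eri3_asymptotic(a, a, c, 13)


# ---------------------------------------------------------------------------
# embedded core Hamiltonian
# ---------------------------------------------------------------------------

def _exact_embedding(H0, basis, sites, qs):
    H = H0.copy()
    fns = basis.functions
    for i in range(len(fns)):
        for j in range(i + 1):
            v = -float(np.dot(nai_exact(fns[i], fns[j], sites), qs))
            H[i, j] += v
            if i != j:
                H[j, i] += v
    return H


def test_embed_zero_charges_identity(water_atoms, minimal_lib):
    basis = build_ao_basis(water_atoms, minimal_lib)
    H0 = np.zeros((basis.n_functions, basis.n_functions))
    H = ff.embed_core_hamiltonian(H0, basis, [])
    assert np.array_equal(H, H0)


def test_embed_single_far_charge_is_asymptotic_shift(water_atoms, minimal_lib):
    basis = build_ao_basis(water_atoms, minimal_lib)
    n = basis.n_functions
    H0 = np.zeros((n, n))
    q = -0.7
    D = np.array([80.0, 5.0, 2.0])
    H = ff.embed_core_hamiltonian(H0, basis, [PointCharge(D, q)])
    fns = basis.functions
    for i in range(n):
        for j in range(i + 1):
            assert H[i, j] == pytest.approx(
                -q * nai_exact(fns[i], fns[j], D), abs=1e-10
            )


def test_embed_mixed_vs_all_exact(water_atoms, minimal_lib):
    basis = build_ao_basis(water_atoms, minimal_lib)
    rng = np.random.default_rng(41)
    sites = rng.uniform(-20, 20, (500, 3))
    keep = np.linalg.norm(sites, axis=1) > 0.5
    sites = sites[keep]
    qs = rng.uniform(-0.8, 0.8, len(sites))
    n = basis.n_functions
    H0 = np.zeros((n, n))
    nf = ff.classify_mm(basis, sites, 1e-10, mm_charges=qs)
    H = ff.embed_core_hamiltonian(H0, basis, None, near_far=nf)
    He = _exact_embedding(H0, basis, sites, qs)
    assert np.abs(H - He).max() <= len(sites) * 1e-10


def test_embed_factorization_invariance(water_atoms, minimal_lib):
    basis = build_ao_basis(water_atoms, minimal_lib)
    rng = np.random.default_rng(42)
    sites = rng.uniform(-15, 15, (200, 3))
    qs = rng.uniform(-0.5, 0.5, 200)
    n = basis.n_functions
    H0 = np.zeros((n, n))
    nf = ff.classify_mm(basis, sites, 1e-10, mm_charges=qs)
    H1 = ff.embed_core_hamiltonian(H0, basis, None, near_far=nf, factorized=True)
    H2 = ff.embed_core_hamiltonian(H0, basis, None, near_far=nf, factorized=False)
    assert np.abs(H1 - H2).max() <= 1e-12


# ---------------------------------------------------------------------------
# near-field ERI bookkeeping
# ---------------------------------------------------------------------------

def test_nearfield_eri_count_grows_linearly(minimal_lib):
    from auxqmmm.chem_model import make_fixture

    counts = {}
    for n in (8, 16, 32):
        s = make_fixture("alkane", {"n_carbons": n})
        basis = build_ao_basis(s.atoms, minimal_lib)
        aux = build_aux_basis(s.atoms, minimal_lib)
        counts[n] = ff.count_nearfield_eri(basis, aux, 1e-10)
    assert 1.8 <= counts[16] / counts[8] <= 2.3
    assert 1.8 <= counts[32] / counts[16] <= 2.3
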