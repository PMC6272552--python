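"""Auxiliary-density-fitted Kohn-Sham SCF with point-charge embedding.

The SCF energy is

    E = sum_ab P_ab H_ab + x.J - 1/2 x.G.x + Exc[rho_fit]  (+ E_NN embedded)

where x are the variational Coulomb-fitting coefficients (G x = J with
J_c = sum_ab P_ab <ab||c>), and the exchange-correlation functional (local
Dirac exchange + VWN correlation) is evaluated on the *fitted* density.
Because the fit is variational, the fitted Coulomb energy approaches the
exact Coulomb repulsion from below.

Three integral schemes share one fixed point: ``conventional`` stores all
3-center ERIs computed exactly; ``direct`` recomputes them every cycle with
the near-field integrals exact and the far-field ones through the double
asymptotic expansion; ``mixed`` stores the near-field integrals in memory
once and recomputes only the far-field part each cycle.  Restricted
closed-shell only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import farfield
from .grids import GridSpec, MolecularGrid, molecular_grid
from .gto_integrals import (
    AOBasis,
    AuxBasis,
    BasisSetLibrary,
    build_ao_basis,
    build_aux_basis,
    eri2_matrix,
    eri3,
    kinetic,
    nai_exact,
    overlap,
)


# ---------------------------------------------------------------------------
# settings / results
# ---------------------------------------------------------------------------

@dataclass
class SCFSettings:
    scheme: str = "mixed"  # conventional | direct | mixed
    max_iter: int = 120
    tol: float = 1e-7      # RMS density change
    diis_depth: int = 8
    damping: float = 0.0
    tau: float = farfield.DEFAULT_TAU
    order: int = farfield.DEFAULT_ORDER
    grid: GridSpec = field(default_factory=GridSpec)
    metric_cutoff: float = 1e-10  # relative eigenvalue cutoff of G

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("convergence tolerance must be positive")
        if self.scheme not in ("conventional", "direct", "mixed"):
            raise ValueError(f"unknown SCF scheme {self.scheme!r}")


@dataclass
class FitCoefficients:
    x: np.ndarray


@dataclass
class SCFResult:
    converged: bool
    E_total: float
    components: dict
    mo_coefficients: np.ndarray
    mo_energies: np.ndarray
    n_occupied: int
    density: np.ndarray
    fit: FitCoefficients
    cycles: list
    basis: AOBasis
    aux: AuxBasis

    @property
    def energy_breakdown(self):
        return dict(self.components)


# ---------------------------------------------------------------------------
# variational Coulomb fit
# ---------------------------------------------------------------------------

def _pseudo_solve(G_eig, rhs):
    w, V = G_eig
    wmax = float(np.max(np.abs(w)))
    inv = np.where(np.abs(w) > 1e-10 * wmax, 1.0 / w, 0.0)
    return V @ (inv * (V.T @ rhs))


def fit_density(P: np.ndarray, eri3_tensor: np.ndarray, G: np.ndarray,
                cutoff: float = 1e-10) -> FitCoefficients:
    """Solve G x = J with J_c = sum_ab P_ab <ab||c> (eigen-pseudoinverse).

    The cutoff is relative to the largest metric eigenvalue.  A metric with
    significantly negative eigenvalues is reported as a numerical error.
    """
    w, V = np.linalg.eigh(G)
    wmax = float(np.max(np.abs(w)))
    if np.min(w) < -1e-8 * max(wmax, 1.0):
        raise RuntimeError(
            f"fitting metric not positive semidefinite (min eig {np.min(w):.3e})"
        )
    J = np.einsum("abc,ab->c", eri3_tensor, P)
    inv = np.where(w > cutoff * wmax, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    x = V @ (inv * (V.T @ J))
    return FitCoefficients(x=x)


def fitted_coulomb_energy(x: np.ndarray, J: np.ndarray, G: np.ndarray) -> float:
    return float(x @ J - 0.5 * x @ G @ x)


# ---------------------------------------------------------------------------
# LDA on the fitted density
# ---------------------------------------------------------------------------

_CX = -(3.0 / 4.0) * (3.0 / math.pi) ** (1.0 / 3.0)

# VWN (form V) paramagnetic parameters
_VWN_A, _VWN_X0, _VWN_B, _VWN_C = 0.0310907, -0.10498, 3.72744, 12.9352


def lda_energy_density(rho):
    """(eps_xc, v_xc) per point for the spin-compensated local functional."""
    rho = np.asarray(rho, dtype=float)
    eps = np.zeros_like(rho)
    v = np.zeros_like(rho)
    pos = rho > 1e-300
    r = rho[pos]
    # Dirac exchange
    r13 = r ** (1.0 / 3.0)
    eps_x = _CX * r13
    v_x = (4.0 / 3.0) * _CX * r13
    # VWN correlation
    rs = (3.0 / (4.0 * math.pi * r)) ** (1.0 / 3.0)
    x = np.sqrt(rs)
    A, x0, b, c = _VWN_A, _VWN_X0, _VWN_B, _VWN_C
    Q = math.sqrt(4.0 * c - b * b)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    at = np.arctan(Q / (2.0 * x + b))
    eps_c = A * (
        np.log(x * x / X)
        + 2.0 * b / Q * at
        - (b * x0 / X0)
        * (np.log((x - x0) ** 2 / X) + 2.0 * (b + 2.0 * x0) / Q * at)
    )
    dX = 2.0 * x + b
    dat = -2.0 * Q / (Q * Q + dX * dX)
    deps_dx = A * (
        2.0 / x
        - dX / X
        + 2.0 * b / Q * dat
        - (b * x0 / X0)
        * (2.0 / (x - x0) - dX / X + 2.0 * (b + 2.0 * x0) / Q * dat)
    )
    v_c = eps_c - (x / 6.0) * deps_dx
    eps[pos] = eps_x + eps_c
    v[pos] = v_x + v_c
    return eps, v


class _AuxGridCache:
    """Auxiliary-function values on the molecular grid, computed once."""

    def __init__(self, aux: AuxBasis, grid: MolecularGrid):
        self.grid = grid
        self.values = np.stack(
            [f.values(grid.points) for f in aux.functions]
        )  # (naux, npts)


def xc_lda(x: np.ndarray, grid: MolecularGrid, aux_values: np.ndarray):
    """E_xc and its auxiliary-space potential on the fitted density.

    Grid points where the fitted density is negative are clamped to zero and
    counted; the clamp count is returned as the third element.
    """
    if grid.points.size == 0:
        raise ValueError("empty integration grid")
    rho = x @ aux_values
    clamped = int(np.count_nonzero(rho < 0.0))
    rho = np.maximum(rho, 0.0)
    eps, v = lda_energy_density(rho)
    w = grid.weights
    E_xc = float(np.dot(w, eps * rho))
    v_vec = aux_values @ (w * v)
    return E_xc, v_vec, clamped


# ---------------------------------------------------------------------------
# 3-center ERI providers (conventional / direct / mixed)
# ---------------------------------------------------------------------------

class ERI3Provider:
    """Builds the (nbf, nbf, naux) Coulomb 3-index tensor under a scheme."""

    def __init__(self, basis: AOBasis, aux: AuxBasis, scheme: str,
                 tau: float, order: int):
        self.basis = basis
        self.aux = aux
        self.scheme = scheme
        self.tau = tau
        self.order = order
        self._cache = None
        self._near_cache = None
        if scheme != "conventional":
            self.extents = farfield.ExtentTable.build(basis, tau, aux=aux)
            self.pairs, self.near = farfield.classify_eri3(
                basis, aux, tau, extents=self.extents
            )
        else:
            self.pairs = [(s1, s2) for s1 in range(len(basis.shells))
                          for s2 in range(s1 + 1)]
            self.near = None
        # auxiliary groups: indices sharing (exponent, hermite index, norm)
        groups: dict[tuple, list[int]] = {}
        for k, f in enumerate(aux.functions):
            groups.setdefault((f.exponent, f.index, f.norm), []).append(k)
        self.groups = groups
        self.near_count = (
            int(sum(self.near[k].sum() for k in range(len(self.pairs))))
            if self.near is not None else None
        )

    def _exact_full(self):
        basis, aux = self.basis, self.aux
        nbf, naux = basis.n_functions, aux.n_functions
        T = np.zeros((nbf, nbf, naux))
        fns = basis.functions
        for (s1, s2) in self.pairs:
            for i in _shell_fn_range(basis, s1):
                for j in _shell_fn_range(basis, s2):
                    if s1 == s2 and j > i:
                        continue
                    vals = eri3(fns[i], fns[j], aux.functions)
                    T[i, j] = vals
                    T[j, i] = vals
        return T

    def _split_tensor(self, near_only=False, far_only=False):
        basis, aux = self.basis, self.aux
        nbf, naux = basis.n_functions, aux.n_functions
        T = np.zeros((nbf, nbf, naux))
        fns = basis.functions
        zmin = [float(np.min(sh.exponents)) for sh in basis.shells]
        for k, (s1, s2) in enumerate(self.pairs):
            nearmask = self.near[k]
            farmask = ~nearmask
            near_idx = np.nonzero(nearmask)[0]
            # expand about the tighter shell's center (product localization)
            swap = zmin[s2] > zmin[s1]
            for i in _shell_fn_range(basis, s1):
                for j in _shell_fn_range(basis, s2):
                    if s1 == s2 and j > i:
                        continue
                    row = np.zeros(naux)
                    if not far_only and len(near_idx):
                        row[near_idx] = eri3(
                            fns[i], fns[j], [aux.functions[m] for m in near_idx]
                        )
                    if not near_only and farmask.any():
                        fa, fb = (fns[j], fns[i]) if swap else (fns[i], fns[j])
                        O = farfield.shifted_overlaps(fa, fb, self.order)
                        for key, members in self.groups.items():
                            mem = [m for m in members if farmask[m]]
                            if not mem:
                                continue
                            row[mem] = _eri3_far_from_overlaps(
                                O, fa.center,
                                np.array([aux.functions[m].center for m in mem]),
                                key, self.order,
                            )
                    T[i, j] += row
                    if i != j:
                        T[j, i] += row
        return T

    def tensor(self) -> np.ndarray:
        if self.scheme == "conventional":
            if self._cache is None:
                self._cache = self._exact_full()
            return self._cache
        if self.scheme == "direct":
            return self._split_tensor()
        # mixed: near-field stored in memory, far-field recomputed
        if self._near_cache is None:
            self._near_cache = self._split_tensor(near_only=True)
        return self._near_cache + self._split_tensor(far_only=True)


def _shell_fn_range(basis: AOBasis, s: int):
    from .gto_integrals import _CART

    off = basis.shell_offsets[s]
    return range(off, off + len(_CART[basis.shells[s].l]))


def _eri3_far_from_overlaps(O, a_center, centers, group_key, order):
    """Far-field <ab||c> for one auxiliary group from precomputed <a+m|b>."""
    z, idx, norm = group_key
    lc = sum(idx)
    raw = farfield._inv_r_derivatives(order + lc, a_center[None, :] - centers)
    total = np.zeros(len(centers))
    sign_c = (-1.0) ** lc
    F = farfield._FACTORIALS
    for mx in range(order + 1):
        for my in range(order + 1 - mx):
            for mz in range(order + 1 - mx - my):
                o = O[mx, my, mz]
                if o == 0.0:
                    continue
                total += (o / (F[mx] * F[my] * F[mz])) * (
                    sign_c * raw[(mx + idx[0], my + idx[1], mz + idx[2])]
                )
    return norm * (math.pi / z) ** 1.5 * total


# ---------------------------------------------------------------------------
# core Hamiltonian and nuclear terms
# ---------------------------------------------------------------------------

def core_hamiltonian_matrices(atoms, basis: AOBasis):
    """Overlap S, kinetic T and bare core H0 = T + V_ne over QM nuclei."""
    fns = basis.functions
    nbf = len(fns)
    S = np.empty((nbf, nbf))
    T = np.empty((nbf, nbf))
    nuclei = np.array([a.position for a in atoms if a.Z >= 1])
    zs = np.array([float(a.Z) for a in atoms if a.Z >= 1])
    H = np.empty((nbf, nbf))
    for i in range(nbf):
        for j in range(i + 1):
            S[i, j] = S[j, i] = overlap(fns[i], fns[j])
            T[i, j] = T[j, i] = kinetic(fns[i], fns[j])
            v = -float(np.dot(nai_exact(fns[i], fns[j], nuclei), zs))
            H[i, j] = H[j, i] = T[i, j] + v
    return S, T, H


def nuclear_embedded_repulsion(qm_atoms, mm_charges) -> float:
    """sum_{A>B} Z_A Z_B / R_AB + sum_A sum_D Z_A Q_D / R_AD (hartree)."""
    pos = np.array([a.position for a in qm_atoms if a.Z >= 1])
    Z = np.array([float(a.Z) for a in qm_atoms if a.Z >= 1])
    E = 0.0
    for i in range(len(pos)):
        for j in range(i):
            r = np.linalg.norm(pos[i] - pos[j])
            if r == 0.0:
                raise ZeroDivisionError("coincident nuclei")
            E += Z[i] * Z[j] / r
    if mm_charges:
        sites = np.array([pc.position for pc in mm_charges])
        qs = np.array([pc.q for pc in mm_charges])
        d = np.linalg.norm(pos[:, None, :] - sites[None, :, :], axis=-1)
        if np.any(d == 0.0):
            raise ZeroDivisionError("MM charge coincident with a QM nucleus")
        E += float(np.sum(Z[:, None] * qs[None, :] / d))
    return E


def build_ks_matrix(P, x, H_embedded, z_xc, eri3_tensor):
    """K_ab = H_ab + sum_c (x_c + z_c) <ab||c>; equals dE/dP_ab."""
    return H_embedded + np.einsum("abc,c->ab", eri3_tensor, x + z_xc)


# ---------------------------------------------------------------------------
# the SCF driver
# ---------------------------------------------------------------------------

class _DIIS:
    def __init__(self, depth):
        self.depth = depth
        self.F = []
        self.E = []

    def extrapolate(self, F, err):
        self.F.append(F.copy())
        self.E.append(err.ravel().copy())
        if len(self.F) > self.depth:
            self.F.pop(0)
            self.E.pop(0)
        n = len(self.F)
        if n < 2:
            return F
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = np.dot(self.E[i], self.E[j])
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return F
        return sum(ci * Fi for ci, Fi in zip(c, self.F))


def _scf_energy_terms(P, H, eri3_tensor, G, G_eig, grid, aux_values, cutoff):
    J = np.einsum("abc,ab->c", eri3_tensor, P)
    w, V = G_eig
    wmax = float(np.max(np.abs(w)))
    inv = np.where(w > cutoff * wmax, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    x = V @ (inv * (V.T @ J))
    E_core = float(np.einsum("ab,ab->", P, H))
    E_J = float(x @ J - 0.5 * x @ G @ x)
    E_xc, v_vec, clamped = xc_lda(x, grid, aux_values)
    z = V @ (inv * (V.T @ v_vec))
    return E_core, E_J, E_xc, x, z, J, clamped


def scf_energy_of_density(P, H, eri3_tensor, G, G_eig, grid, aux_values,
                          cutoff=1e-10) -> float:
    """The ADFT energy functional E(P) for an arbitrary density matrix."""
    E_core, E_J, E_xc, *_ = _scf_energy_terms(
        P, H, eri3_tensor, G, G_eig, grid, aux_values, cutoff
    )
    return E_core + E_J + E_xc


def energy_and_ks(P, H, eri3_tensor, G, G_eig, grid, aux_values, cutoff=1e-10):
    """(E(P), K(P)) with K_ab = dE/dP_ab — the ADFT consistency pair."""
    E_core, E_J, E_xc, x, z, J, _ = _scf_energy_terms(
        P, H, eri3_tensor, G, G_eig, grid, aux_values, cutoff
    )
    return E_core + E_J + E_xc, build_ks_matrix(P, x, H, z, eri3_tensor)


def run_scf(atoms, basis, aux=None, embedding=None, settings: SCFSettings | None = None,
            charge: int = 0) -> SCFResult:
    """Restricted closed-shell ADFT SCF.

    ``atoms``: QM atoms (chem_model.Atom, link atoms included); ``basis``: a
    BasisSetLibrary or prebuilt AOBasis; ``aux``: AuxBasis (default: built-in
    even-tempered s set); ``embedding``: list of PointCharge seen by the
    one-electron Hamiltonian and the nuclear repulsion.
    """
    settings = settings or SCFSettings()
    embedding = embedding or []
    real = [a for a in atoms if a.Z >= 1]
    nelec = int(sum(a.Z for a in real)) - charge
    if nelec <= 0 or nelec % 2:
        raise ValueError(
            f"restricted closed-shell SCF needs a positive even electron count, got {nelec}"
        )
    nocc = nelec // 2
    if isinstance(basis, BasisSetLibrary):
        basis = build_ao_basis(real, basis)
    if aux is None:
        lib = BasisSetLibrary.builtin("minimal")
        aux = build_aux_basis(real, lib)

    S, T, H0 = core_hamiltonian_matrices(real, basis)
    if embedding:
        sites = np.array([pc.position for pc in embedding])
        qs = np.array([pc.q for pc in embedding])
        if settings.scheme == "conventional":
            H = H0.copy()
            fns = basis.functions
            for i in range(len(fns)):
                for j in range(i + 1):
                    v = -float(np.dot(nai_exact(fns[i], fns[j], sites), qs))
                    H[i, j] += v
                    if i != j:
                        H[j, i] += v
            nf_counts = (len(sites) * basis.n_functions ** 2, 0)
        else:
            nf = farfield.classify_mm(basis, sites, settings.tau, mm_charges=qs)
            H = farfield.embed_core_hamiltonian(
                H0, basis, None, near_far=nf, order=settings.order, tau=settings.tau
            )
            nf_counts = nf.counts()
    else:
        H = H0
        nf_counts = (0, 0)

    G = aux.metric()
    G_eig = np.linalg.eigh(G)
    provider = ERI3Provider(basis, aux, settings.scheme, settings.tau, settings.order)
    grid = molecular_grid(real, settings.grid)
    aux_values = _AuxGridCache(aux, grid).values

    E_NN = nuclear_embedded_repulsion(real, embedding)

    # core guess
    eps, C = scipy.linalg.eigh(H, S)
    P = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    diis = _DIIS(settings.diis_depth)
    cycles = []
    E_old = None
    converged = False
    cutoff = settings.metric_cutoff
    for it in range(settings.max_iter):
        eri3_tensor = provider.tensor()
        E_core, E_J, E_xc, x, z, J, clamped = _scf_energy_terms(
            P, H, eri3_tensor, G, G_eig, grid, aux_values, cutoff
        )
        E = E_core + E_J + E_xc
        K = build_ks_matrix(P, x, H, z, eri3_tensor)
        err = K @ P @ S - S @ P @ K
        K_use = diis.extrapolate(K, err)
        eps, C = scipy.linalg.eigh(K_use, S)
        P_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        if settings.damping > 0:
            P_new = (1.0 - settings.damping) * P_new + settings.damping * P
        rms = float(np.sqrt(np.mean((P_new - P) ** 2)))
        cycles.append(
            {
                "cycle": it + 1,
                "energy": E + E_NN,
                "rms_dP": rms,
                "diis_error": float(np.max(np.abs(err))),
                "clamped_grid_points": clamped,
                "near_embedding": nf_counts[0],
                "far_embedding": nf_counts[1],
                "near_eri": provider.near_count,
            }
        )
        P = P_new
        if rms <= settings.tol and (E_old is None or abs(E - E_old) <= max(settings.tol, 1e-9) * 10):
            converged = True
            break
        E_old = E

    # final consistent energy at the converged density
    eri3_tensor = provider.tensor()
    E_core, E_J, E_xc, x, z, J, clamped = _scf_energy_terms(
        P, H, eri3_tensor, G, G_eig, grid, aux_values, cutoff
    )
    components = {
        "E_core": E_core,
        "E_J_fitted": E_J,
        "E_xc": E_xc,
        "E_NN_embedded": E_NN,
    }
    return SCFResult(
        converged=converged,
        E_total=E_core + E_J + E_xc + E_NN,
        components=components,
        mo_coefficients=C,
        mo_energies=eps,
        n_occupied=nocc,
        density=P,
        fit=FitCoefficients(x=x),
        cycles=cycles,
        basis=basis,
        aux=aux,
    )


# ---------------------------------------------------------------------------
# density-fitted exact exchange (full-domain limit)
# ---------------------------------------------------------------------------

def fitted_exchange(C_occ: np.ndarray, basis: AOBasis, aux: AuxBasis,
                    eri3_tensor: np.ndarray | None = None,
                    cutoff: float = 1e-10):
    """Density-fitted exact exchange in the full-domain (non-local) limit.

    X_ab = sum_i sum_cd <ai||c> Ginv_cd <d||ib>, E_x = -1/2 sum_ab P_ab X_ab
    with P = 2 C_occ C_occ^T.  With an auxiliary set spanning all orbital
    products this equals the brute-force four-center exchange.
    """
    if eri3_tensor is None:
        provider = ERI3Provider(basis, aux, "conventional",
                                farfield.DEFAULT_TAU, farfield.DEFAULT_ORDER)
        eri3_tensor = provider.tensor()
    G = aux.metric()
    w, V = np.linalg.eigh(G)
    wmax = float(np.max(np.abs(w)))
    inv = np.where(w > cutoff * wmax, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    t = np.einsum("abc,bi->aic", eri3_tensor, C_occ)
    th = np.einsum("aic,c,dc->aid", t @ V, inv, V)  # t . Ginv (half-transformed)
    X = np.einsum("aid,bid->ab", th, t)
    P = 2.0 * C_occ @ C_occ.T
    E_x = -0.5 * float(np.einsum("ab,ab->", P, X))
    return E_x, X
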