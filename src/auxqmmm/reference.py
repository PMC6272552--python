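"""Naive dense reference implementation of the fitted-density SCF model.

Independent validation path for s-orbital systems (He, H2, HeH+): every
integral is written from its textbook closed form for s Gaussians (no Hermite
recurrences, no near/far machinery, no Boys-table code shared with the main
engine), the density fit is solved with the same pseudo-inverse convention,
the local functional is re-derived here from its published parameterization,
and the SCF is a plain damped fixed-point loop over dense matrices.

It deliberately shares the quadrature grid points with the main path: the
grid is part of the model definition being cross-checked, not of the
machinery under test.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg
from scipy.special import erf

from .grids import GridSpec, molecular_grid


def _f0(x):
    """Lowest-order Coulomb kernel integral via the error function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-12
    out[small] = 1.0 - x[small] / 3.0
    xs = x[~small]
    out[~small] = 0.5 * np.sqrt(np.pi / xs) * erf(np.sqrt(xs))
    return out


def _s_norm(z):
    return (2.0 * z / math.pi) ** 0.75


class SRef:
    """An s-type contracted function: centers, exponents, coefficients."""

    def __init__(self, center, exponents, coefficients):
        self.center = np.asarray(center, dtype=float)
        self.z = np.asarray(exponents, dtype=float)
        d = np.asarray(coefficients, dtype=float) * _s_norm(self.z)
        # normalize the contraction
        s = 0.0
        for di, zi in zip(d, self.z):
            for dj, zj in zip(d, self.z):
                s += di * dj * (math.pi / (zi + zj)) ** 1.5
        self.d = d / math.sqrt(s)


def _pairs(a: SRef, b: SRef):
    AB2 = float(np.sum((a.center - b.center) ** 2))
    for da, za in zip(a.d, a.z):
        for db, zb in zip(b.d, b.z):
            p = za + zb
            mu = za * zb / p
            P = (za * a.center + zb * b.center) / p
            yield da * db, za, zb, p, P, math.exp(-mu * AB2), AB2


def ref_overlap(a, b):
    return sum(c * K * (math.pi / p) ** 1.5 for c, za, zb, p, P, K, _ in _pairs(a, b))


def ref_kinetic(a, b):
    tot = 0.0
    for c, za, zb, p, P, K, AB2 in _pairs(a, b):
        mu = za * zb / p
        tot += c * K * mu * (3.0 - 2.0 * mu * AB2) * (math.pi / p) ** 1.5
    return tot


def ref_nai(a, b, D):
    """<ab| 1/|r-D| > for s functions (attraction integral without charge)."""
    D = np.asarray(D, dtype=float)
    tot = 0.0
    for c, za, zb, p, P, K, _ in _pairs(a, b):
        r2 = float(np.sum((P - D) ** 2))
        tot += c * K * (2.0 * math.pi / p) * float(_f0(np.array([p * r2]))[0])
    return tot


def ref_eri2(zc, C, zd, D, nc=1.0, nd=1.0):
    r2 = float(np.sum((np.asarray(C, float) - np.asarray(D, float)) ** 2))
    al = zc * zd / (zc + zd)
    return (
        nc * nd * 2.0 * math.pi ** 2.5 / (zc * zd * math.sqrt(zc + zd))
        * float(_f0(np.array([al * r2]))[0])
    )


def ref_eri3(a, b, zc, C, nc=1.0):
    C = np.asarray(C, dtype=float)
    tot = 0.0
    for c, za, zb, p, P, K, _ in _pairs(a, b):
        al = p * zc / (p + zc)
        r2 = float(np.sum((P - C) ** 2))
        tot += (
            c * K * 2.0 * math.pi ** 2.5 / (p * zc * math.sqrt(p + zc))
            * float(_f0(np.array([al * r2]))[0])
        )
    return nc * tot


def ref_eri4(a, b, c_fn, d_fn):
    tot = 0.0
    for c1, za, zb, p, P, K1, _ in _pairs(a, b):
        for c2, zc, zd, q, Q, K2, _ in _pairs(c_fn, d_fn):
            al = p * q / (p + q)
            r2 = float(np.sum((P - Q) ** 2))
            tot += (
                c1 * c2 * K1 * K2
                * 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
                * float(_f0(np.array([al * r2]))[0])
            )
    return tot


# local functional, re-derived from the published parameterization
def ref_lda(rho):
    rho = np.asarray(rho, dtype=float)
    eps = np.zeros_like(rho)
    v = np.zeros_like(rho)
    m = rho > 1e-300
    r = rho[m]
    cx = -0.75 * (3.0 / math.pi) ** (1.0 / 3.0)
    ex = cx * np.cbrt(r)
    vx = 4.0 / 3.0 * ex
    A, x0, b, c = 0.0310907, -0.10498, 3.72744, 12.9352
    Q = math.sqrt(4 * c - b * b)
    x = (3.0 / (4.0 * math.pi * r)) ** (1.0 / 6.0)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    theta = np.arctan(Q / (2 * x + b))
    ec = A * (
        np.log(x * x / X) + (2 * b / Q) * theta
        - (b * x0 / X0) * (np.log((x - x0) ** 2 / X) + (2 * (b + 2 * x0) / Q) * theta)
    )
    dtheta = -2.0 * Q / (Q * Q + (2 * x + b) ** 2)
    dec = A * (
        2.0 / x - (2 * x + b) / X + (2 * b / Q) * dtheta
        - (b * x0 / X0) * (2.0 / (x - x0) - (2 * x + b) / X + (2 * (b + 2 * x0) / Q) * dtheta)
    )
    vc = ec - (x / 6.0) * dec
    eps[m] = ex + ec
    v[m] = vx + vc
    return eps, v


def reference_scf(atoms, basis, aux, embedding=None, grid_spec: GridSpec | None = None,
                  charge: int = 0, tol: float = 1e-12, max_iter: int = 500):
    """Dense fixed-point SCF for the identical fitted-density model (s only).

    ``basis``: AOBasis restricted to s shells; ``aux``: AuxBasis of s-type
    Hermite auxiliaries.  Returns the converged total electronic + nuclear
    energy (embedded nuclear repulsion included).
    """
    for f in basis.functions:
        if sum(f.momentum) != 0:
            raise ValueError("reference SCF supports s orbitals only")
    for f in aux.functions:
        if sum(f.index) != 0:
            raise ValueError("reference SCF supports s auxiliaries only")
    fns = [
        SRef(sh.center, sh.exponents, sh.coefficients) for sh in basis.shells
    ]
    nb = len(fns)
    na = len(aux.functions)
    real = [a for a in atoms if a.Z >= 1]
    nelec = int(sum(a.Z for a in real)) - charge
    if nelec <= 0 or nelec % 2:
        raise ValueError("closed-shell electron count required")
    nocc = nelec // 2

    S = np.array([[ref_overlap(fns[i], fns[j]) for j in range(nb)] for i in range(nb)])
    T = np.array([[ref_kinetic(fns[i], fns[j]) for j in range(nb)] for i in range(nb)])
    H = T.copy()
    for a in real:
        for i in range(nb):
            for j in range(nb):
                H[i, j] -= a.Z * ref_nai(fns[i], fns[j], a.position)
    for pc in embedding or []:
        for i in range(nb):
            for j in range(nb):
                H[i, j] -= pc.q * ref_nai(fns[i], fns[j], pc.position)

    G = np.array(
        [
            [
                ref_eri2(
                    aux.functions[i].exponent, aux.functions[i].center,
                    aux.functions[j].exponent, aux.functions[j].center,
                    aux.functions[i].norm, aux.functions[j].norm,
                )
                for j in range(na)
            ]
            for i in range(na)
        ]
    )
    I3 = np.array(
        [
            [
                [
                    ref_eri3(fns[i], fns[j], aux.functions[k].exponent,
                             aux.functions[k].center, aux.functions[k].norm)
                    for k in range(na)
                ]
                for j in range(nb)
            ]
            for i in range(nb)
        ]
    )

    grid = molecular_grid(real, grid_spec or GridSpec())
    chi = np.stack(
        [
            f.norm * np.exp(
                -f.exponent * np.sum((grid.points - f.center) ** 2, axis=1)
            )
            for f in aux.functions
        ]
    )
    w, V = np.linalg.eigh(G)
    wmax = float(np.max(np.abs(w)))
    inv = np.where(w > 1e-10 * wmax, 1.0 / np.where(w > 0, w, 1.0), 0.0)

    def gsolve(r):
        return V @ (inv * (V.T @ r))

    # nuclear repulsion with embedding
    E_NN = 0.0
    pos = [a.position for a in real]
    Z = [a.Z for a in real]
    for i in range(len(real)):
        for j in range(i):
            E_NN += Z[i] * Z[j] / np.linalg.norm(pos[i] - pos[j])
        for pc in embedding or []:
            E_NN += Z[i] * pc.q / np.linalg.norm(pos[i] - pc.position)

    eps_mo, C = scipy.linalg.eigh(H, S)
    P = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    E_old = 0.0
    for it in range(max_iter):
        J = np.einsum("ijk,ij->k", I3, P)
        x = gsolve(J)
        rho = np.maximum(x @ chi, 0.0)
        eps_d, v_d = ref_lda(rho)
        E_xc = float(np.dot(grid.weights, eps_d * rho))
        vvec = chi @ (grid.weights * v_d)
        zc = gsolve(vvec)
        K = H + np.einsum("ijk,k->ij", I3, x + zc)
        eps_mo, C = scipy.linalg.eigh(K, S)
        P_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        P = 0.7 * P_new + 0.3 * P
        E = float(np.einsum("ij,ij->", P, H) + x @ J - 0.5 * x @ G @ x + E_xc)
        if abs(E - E_old) < tol and float(np.sqrt(np.mean((P_new - P) ** 2))) < 1e3 * tol:
            P = P_new
            break
        E_old = E

    J = np.einsum("ijk,ij->k", I3, P)
    x = gsolve(J)
    rho = np.maximum(x @ chi, 0.0)
    eps_d, v_d = ref_lda(rho)
    E_xc = float(np.dot(grid.weights, eps_d * rho))
    E = float(np.einsum("ij,ij->", P, H) + x @ J - 0.5 * x @ G @ x + E_xc)
    return E + E_NN
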