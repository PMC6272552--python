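"""Independent numerical oracles for the test suite.

Everything here evaluates basis functions and integrals from their bare
definitions (pointwise products on quadrature grids, error-function
potentials), sharing no recurrence code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erf


def gto_value(fn, points):
    """Pointwise values of a ContractedGTO from its definition."""
    pts = np.atleast_2d(points)
    s = pts - fn.center[None, :]
    poly = s[:, 0] ** fn.momentum[0] * s[:, 1] ** fn.momentum[1] * s[:, 2] ** fn.momentum[2]
    r2 = np.einsum("ij,ij->i", s, s)
    out = np.zeros(len(pts))
    for d, z in fn.primitives:
        out += d * np.exp(-z * r2)
    return poly * out


def shifted_value(fn, points, shift):
    pts = np.atleast_2d(points)
    s = pts - fn.center[None, :]
    extra = s[:, 0] ** shift[0] * s[:, 1] ** shift[1] * s[:, 2] ** shift[2]
    return extra * gto_value(fn, pts)


def gto_gradient(fn, points):
    """Analytic gradient of a contracted Cartesian Gaussian (independent form)."""
    pts = np.atleast_2d(points)
    s = pts - fn.center[None, :]
    r2 = np.einsum("ij,ij->i", s, s)
    grad = np.zeros((len(pts), 3))
    for d, z in fn.primitives:
        e = d * np.exp(-z * r2)
        for dim in range(3):
            i = fn.momentum[dim]
            poly = np.ones(len(pts))
            for o in range(3):
                if o != dim:
                    poly = poly * s[:, o] ** fn.momentum[o]
            dpoly = (
                i * s[:, dim] ** (i - 1) if i > 0 else np.zeros(len(pts))
            ) - 2.0 * z * s[:, dim] ** (i + 1)
            grad[:, dim] += poly * dpoly * e
    return grad


def _product_box(fns, pad=9.0):
    """Per-dimension intersection of the functions' significant supports."""
    lo = np.full(3, -np.inf)
    hi = np.full(3, np.inf)
    for f in fns:
        ext = pad / math.sqrt(float(np.min(f.exponents)))
        lo = np.maximum(lo, f.center - ext)
        hi = np.minimum(hi, f.center + ext)
    return lo, hi


def _box_grid(lo, hi, n=70):
    axes, weights = [], []
    for d in range(3):
        x, w = np.polynomial.legendre.leggauss(n)
        a, b = lo[d], hi[d]
        axes.append(0.5 * (b - a) * x + 0.5 * (a + b))
        weights.append(0.5 * (b - a) * w)
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    W = np.einsum("i,j,k->ijk", *weights).ravel()
    return pts, W


def quad_overlap(a, b, shift=(0, 0, 0), n=70):
    lo, hi = _product_box([a, b])
    if np.any(hi <= lo):
        return 0.0
    pts, W = _box_grid(lo, hi, n=n)
    return float(np.dot(W, shifted_value(a, pts, shift) * gto_value(b, pts)))


def quad_kinetic(a, b, n=70):
    """1/2 int grad(a).grad(b) with analytic (independent) gradients."""
    lo, hi = _product_box([a, b])
    if np.any(hi <= lo):
        return 0.0
    pts, W = _box_grid(lo, hi, n=n)
    ga = gto_gradient(a, pts)
    gb = gto_gradient(b, pts)
    return 0.5 * float(np.dot(W, np.einsum("ij,ij->i", ga, gb)))


def quad_nai(a, b, D, mu=None, n_box=90, n_r=120, n_theta=None, n_phi=None):
    """<ab | 1/|r-D| > by range separation.

    The kernel splits as erf(sqrt(mu) s)/s + erfc(sqrt(mu) s)/s with
    s = |r - D|: the long-range part is smooth everywhere and integrates on
    a box grid over the orbital product's support; the short-range part
    lives inside a small sphere about D where the r dr dOmega measure
    removes the singularity.
    """
    D = np.asarray(D, dtype=float)
    lo, hi = _product_box([a, b])
    if np.any(hi <= lo):
        return 0.0
    width = float(np.max(hi - lo))
    zmax = max(float(np.max(a.exponents)), float(np.max(b.exponents)))
    if mu is None:
        # box spacing must resolve the erf transition scale 1/sqrt(mu)
        mu = min(100.0, max(1.0, (n_box / (2.5 * width)) ** 2))
    sq = math.sqrt(mu)
    rmax_sphere = 6.5 / sq
    if n_theta is None:
        # angular arc at the sphere edge must resolve the tightest feature
        n_theta = max(48, int(math.ceil(math.pi * rmax_sphere * math.sqrt(zmax) / 0.35)))
    if n_phi is None:
        n_phi = n_theta
    # long-range, smooth
    pts, W = _box_grid(lo, hi, n=n_box)
    s = np.linalg.norm(pts - D[None, :], axis=1)
    kern = np.where(s > 1e-10, erf(sq * s) / np.where(s > 0, s, 1.0),
                    2.0 * sq / math.sqrt(math.pi))
    total = float(np.dot(W, gto_value(a, pts) * gto_value(b, pts) * kern))
    # short-range, spherical about D
    rmax = rmax_sphere
    xr, wr = np.polynomial.legendre.leggauss(n_r)
    r = 0.5 * rmax * (xr + 1.0)
    wr = 0.5 * rmax * wr
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    st = np.sqrt(1 - ct * ct)
    phi = 2 * math.pi * np.arange(n_phi) / n_phi
    wphi = 2 * math.pi / n_phi
    dirs = np.stack(
        [
            np.outer(st, np.cos(phi)).ravel(),
            np.outer(st, np.sin(phi)).ravel(),
            np.outer(ct, np.ones(n_phi)).ravel(),
        ],
        axis=1,
    )
    wang = np.outer(wt, np.full(n_phi, wphi)).ravel()
    from scipy.special import erfc

    for ri, wi in zip(r, wr):
        pts = D[None, :] + ri * dirs
        f = gto_value(a, pts) * gto_value(b, pts)
        total += wi * ri * erfc(sq * ri) * float(np.dot(wang, f))
    return total


def s_aux_potential(zc, C, points, norm=1.0):
    """Electrostatic potential of an s Hermite auxiliary (erf closed form)."""
    d = np.linalg.norm(np.atleast_2d(points) - np.asarray(C)[None, :], axis=1)
    small = d < 1e-8
    out = np.empty_like(d)
    out[~small] = (math.pi / zc) ** 1.5 * erf(math.sqrt(zc) * d[~small]) / d[~small]
    out[small] = 2.0 * math.pi / zc  # lim erf(sqrt(z) r)/r = 2 sqrt(z/pi)
    return norm * out


def quad_eri3_s(a, b, zc, C, norm=1.0, n=70):
    """<ab || c> for an s auxiliary via its closed-form potential."""
    lo, hi = _product_box([a, b])
    if np.any(hi <= lo):
        return 0.0
    pts, W = _box_grid(lo, hi, n=n)
    V = s_aux_potential(zc, np.asarray(C), pts, norm=norm)
    return float(np.dot(W, gto_value(a, pts) * gto_value(b, pts) * V))


def brute_force_angles_dihedrals(n_atoms, bonds):
    """Graph enumeration with plain set logic (oracle for connectivity)."""
    import itertools

    adj = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    angles = set()
    for j in range(n_atoms):
        for i, k in itertools.combinations(sorted(adj[j]), 2):
            angles.add((i, j, k))
    dihedrals = set()
    for j, k in bonds:
        for i in adj[j] - {k}:
            for l in adj[k] - {j, i}:
                key = min((i, j, k, l), (l, k, j, i))
                dihedrals.add(key)
    return angles, dihedrals


def random_primitive(rng, lmax=2, zlo=0.1, zhi=50.0, box=2.0):
    """A random normalized contracted-of-one Cartesian Gaussian."""
    from auxqmmm.gto_integrals import ContractedGTO, cartesian_components

    l = int(rng.integers(0, lmax + 1))
    mom = cartesian_components(l)[rng.integers(len(cartesian_components(l)))]
    z = float(np.exp(rng.uniform(np.log(zlo), np.log(zhi))))
    center = rng.uniform(-box, box, 3)
    return ContractedGTO(center, mom, [z], [1.0])
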