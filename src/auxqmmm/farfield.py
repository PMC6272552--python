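"""Near/far-field machinery for QM/MM embedding and density-fitting Coulomb work.

An environment site (point charge or auxiliary-function potential) is *near*
for an orbital pair when it lies inside the numerical extent sphere of either
shell at integral threshold tau; near integrals are evaluated exactly, far
integrals through truncated multipolar (asymptotic) expansions built from
derivative tensors of 1/R.  The far-field charge sums factor out of the
orbital loops: they are accumulated once per (QM atom, derivative index).

Extents are defined operationally: the shell extent is the radius beyond
which the shell's maximal radial amplitude stays below tau, and the potential
extent of an auxiliary function is the radius beyond which its electrostatic
potential differs from the point-multipole limit by less than tau.  Boundary
ties (distance exactly equal to the extent) classify as near.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .gto_integrals import (
    _CART,
    AOBasis,
    AuxBasis,
    ContractedGTO,
    HermiteAuxFunction,
    Shell,
    _e_table,
    _primitive_norm,
)

DEFAULT_TAU = 1e-10
DEFAULT_ORDER = 8


# ---------------------------------------------------------------------------
# extents
# ---------------------------------------------------------------------------

def _shell_amplitude(shell_l, exponents, coefficients, r):
    """Upper bound on the radial amplitude of a contracted shell at radius r."""
    r = np.asarray(r, dtype=float)
    amp = np.zeros_like(r)
    for z, c in zip(exponents, coefficients):
        n = _primitive_norm(z, (shell_l, 0, 0))
        amp = amp + abs(c) * n * r ** shell_l * np.exp(-z * r * r)
    return amp


def shell_extent(shell, tau: float) -> float:
    """Smallest R with amplitude <= tau for all r >= R, by bisection."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tau >= 1:
        raise ValueError("tau >= 1 gives meaningless (zero) extents")
    l = shell.l if hasattr(shell, "l") else sum(shell.momentum)
    exps = np.asarray(shell.exponents, dtype=float)
    if hasattr(shell, "coefficients"):
        coefs = np.asarray(shell.coefficients, dtype=float)
    else:  # a ContractedGTO: raw coefficients already include primitive norms
        coefs = np.asarray(shell._d, dtype=float) / np.array(
            [_primitive_norm(z, shell.momentum) for z in exps]
        )
    zmin = float(exps.min())
    lo = math.sqrt(l / (2.0 * zmin)) if l > 0 else 0.0
    hi = max(2.0 * lo, 1.0)
    while _shell_amplitude(l, exps, coefs, hi) > tau:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("extent search diverged")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _shell_amplitude(l, exps, coefs, mid) > tau:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return hi


def aux_potential_extent(aux: HermiteAuxFunction, tau: float) -> float:
    """Radius beyond which the auxiliary's potential is multipolar to tau.

    For the s-type Hermite the residual against the 1/R limit is
    norm*(pi/z)^{3/2} erfc(sqrt(z) R)/R; every Hermite derivative multiplies
    the exponential tail by a factor of order 2 z R, so the residual bound
    carries (1 + 2 z R^2)^(|index|/2).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    z = aux.exponent
    l = sum(aux.index)
    scale = aux.norm * (math.pi / z) ** 1.5

    def resid(r):
        return (
            scale * erfc(math.sqrt(z) * r) / r
            * (1.0 + 2.0 * z * r * r) ** (l / 2.0)
        )

    lo, hi = 1e-3, 1.0
    while resid(hi) > tau:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if resid(mid) > tau:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return hi


@dataclass
class ExtentTable:
    """Per-shell orbital extents and per-auxiliary potential extents at tau."""

    tau: float
    shell_extents: np.ndarray
    aux_extents: np.ndarray | None = None

    @classmethod
    def build(cls, basis: AOBasis, tau: float = DEFAULT_TAU, aux: AuxBasis | None = None):
        ext = np.array([shell_extent(sh, tau) for sh in basis.shells])
        aext = (
            np.array([aux_potential_extent(f, tau) for f in aux.functions])
            if aux is not None
            else None
        )
        if np.any(ext <= 0) or not np.all(np.isfinite(ext)):
            raise RuntimeError("invalid shell extents")
        return cls(tau=tau, shell_extents=ext, aux_extents=aext)


# ---------------------------------------------------------------------------
# near/far classification
# ---------------------------------------------------------------------------

@dataclass
class NearFarMap:
    """Near/far partition of MM sites, per shell and per QM atom.

    ``shell_near[s, d]`` is True when site d is inside shell s's extent;
    the pair rule is the union of the two shells' masks.  ``atom_near`` is
    the per-atom auxiliary field (union over the atom's shells), precomputed
    before any orbital loop; its complement supports the factorized far-field
    sums.
    """

    sites: np.ndarray
    charges: np.ndarray
    shell_near: np.ndarray
    shell_atom: np.ndarray
    atom_near: dict[int, np.ndarray] = field(default_factory=dict)

    def pair_near(self, s1: int, s2: int) -> np.ndarray:
        return self.shell_near[s1] | self.shell_near[s2]

    def counts(self):
        near = int(self.shell_near.sum())
        total = self.shell_near.size
        return near, total - near


def classify_mm(basis: AOBasis, mm_sites, tau: float = DEFAULT_TAU,
                mm_charges=None, extents: ExtentTable | None = None) -> NearFarMap:
    """Classify MM sites against every shell extent (ties -> near)."""
    sites = np.atleast_2d(np.asarray(mm_sites, dtype=float))
    charges = (
        np.zeros(len(sites)) if mm_charges is None
        else np.asarray(mm_charges, dtype=float)
    )
    if extents is None:
        extents = ExtentTable.build(basis, tau)
    centers = np.array([sh.center for sh in basis.shells])
    if len(sites):
        d = np.linalg.norm(centers[:, None, :] - sites[None, :, :], axis=-1)
        shell_near = d <= extents.shell_extents[:, None]
    else:
        shell_near = np.zeros((len(centers), 0), dtype=bool)
    shell_atom = np.array([sh.atom_index for sh in basis.shells])
    atom_near = {}
    for a in np.unique(shell_atom):
        atom_near[int(a)] = shell_near[shell_atom == a].any(axis=0)
    return NearFarMap(
        sites=sites, charges=charges, shell_near=shell_near,
        shell_atom=shell_atom, atom_near=atom_near,
    )


# ---------------------------------------------------------------------------
# derivative tensors of 1/R
# ---------------------------------------------------------------------------

def _inv_r_derivatives(L: int, R: np.ndarray) -> dict:
    """All Cartesian derivatives (d/dr)^m of 1/|r| at r = R, |m| <= L.

    Same downward recursion as the Boys-based Coulomb tensor, with the
    auxiliary radial sequence f_n = (-1)^n (2n-1)!! / r^(2n+1).
    Vectorized over the leading axis of R (shape (N, 3)).
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    r2 = np.einsum("ij,ij->i", R, R)
    if np.any(r2 == 0.0):
        raise ZeroDivisionError("derivative tensor of 1/R is singular at R = 0")
    r = np.sqrt(r2)
    X, Y, Z = R[:, 0], R[:, 1], R[:, 2]
    fn = [1.0 / r]
    for n in range(1, L + 1):
        fn.append(-fn[-1] * (2 * n - 1) / r2)
    prev = None
    for n in range(L, -1, -1):
        cur = {(0, 0, 0): fn[n]}
        for s in range(1, L - n + 1):
            for t in range(s + 1):
                for u in range(s - t + 1):
                    v = s - t - u
                    if t > 0:
                        val = X * prev[(t - 1, u, v)]
                        if t > 1:
                            val = val + (t - 1) * prev[(t - 2, u, v)]
                    elif u > 0:
                        val = Y * prev[(t, u - 1, v)]
                        if u > 1:
                            val = val + (u - 1) * prev[(t, u - 2, v)]
                    else:
                        val = Z * prev[(t, u, v - 1)]
                        if v > 1:
                            val = val + (v - 1) * prev[(t, u, v - 2)]
                    cur[(t, u, v)] = val
        prev = cur
    return prev


@dataclass
class TTensor:
    """T_AD(m) = (d/dD)^m 1/|A-D| for all |m| <= m_max at one (A, D) pair."""

    A: np.ndarray
    D: np.ndarray
    m_max: int
    values: dict

    def __getitem__(self, m):
        return self.values[tuple(m)]


def t_tensor(A, D, m_max: int = DEFAULT_ORDER) -> TTensor:
    """Derivative tensor of 1/|A - D| with respect to the components of D."""
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.allclose(A, D):
        raise ZeroDivisionError("T tensor singular: coincident A and D")
    raw = _inv_r_derivatives(m_max, (A - D)[None, :])
    vals = {m: float(((-1.0) ** sum(m)) * v[0]) for m, v in raw.items()}
    return TTensor(A=A, D=D, m_max=m_max, values=vals)


def farfield_charge_sums(A, sites, charges, m_max: int) -> dict:
    """F_A(m) = sum_D Q_D (d/dr)^m 1/|r| at r = A - D (the factorized sums).

    Note these carry the derivative with respect to r = A - D; the relation
    to the embedding tensor is T_AD(m) = (-1)^|m| * (that derivative).
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    charges = np.asarray(charges, dtype=float)
    if len(sites) == 0:
        return {m: 0.0 for m in _index_set(m_max)}
    raw = _inv_r_derivatives(m_max, np.asarray(A, float)[None, :] - sites)
    return {m: float(np.dot(v, charges)) for m, v in raw.items()}


def _index_set(order: int):
    out = []
    for t in range(order + 1):
        for u in range(order + 1 - t):
            for v in range(order + 1 - t - u):
                out.append((t, u, v))
    return out


_FACTORIALS = [math.factorial(k) for k in range(16)]


# ---------------------------------------------------------------------------
# shifted overlaps <a+m|b> in bulk
# ---------------------------------------------------------------------------

def shifted_overlaps(a: ContractedGTO, b: ContractedGTO, order: int) -> np.ndarray:
    """O[mx, my, mz] = <a+m|b> for all component shifts 0..order.

    One Hermite E table per dimension and primitive pair yields every raised
    index at once; this is what makes the asymptotic expansions cheap.
    """
    O = np.zeros((order + 1, order + 1, order + 1))
    AB = a.center - b.center
    ab2 = float(AB @ AB)
    for da, za in a.primitives:
        for db, zb in b.primitives:
            p = za + zb
            mu = za * zb / p
            P = (za * a.center + zb * b.center) / p
            cols = []
            for dim in range(3):
                la = a.momentum[dim] + order
                E = _e_table(
                    la, b.momentum[dim],
                    P[dim] - a.center[dim], P[dim] - b.center[dim],
                    p, mu * ab2 if dim == 0 else 0.0,
                )
                cols.append(
                    E[a.momentum[dim] : la + 1, b.momentum[dim], 0]
                    * math.sqrt(math.pi / p)
                )
            O += da * db * np.einsum("i,j,k->ijk", *cols)
    return O


# ---------------------------------------------------------------------------
# asymptotic integrals
# ---------------------------------------------------------------------------

def nai_asymptotic(a: ContractedGTO, b: ContractedGTO, D, order: int = DEFAULT_ORDER,
                   center: str = "a") -> float | np.ndarray:
    """Far-field NAI by the truncated multipolar expansion about one center.

    Value = sum_{|m|<=order} [(-1)^|m| / m!] T_CD(m) <a+m|b>, with C the
    center of a (default) or of b.  Vectorized over (N, 3) sites D.
    """
    if order > 12:
        raise ValueError("expansion order beyond supported T-tensor range")
    if center not in ("a", "b"):
        raise ValueError("center must be 'a' or 'b'")
    if center == "b":
        a, b = b, a
    D = np.asarray(D, dtype=float)
    single = D.ndim == 1
    sites = np.atleast_2d(D)
    O = shifted_overlaps(a, b, order)
    raw = _inv_r_derivatives(order, a.center[None, :] - sites)
    total = np.zeros(len(sites))
    for (mx, my, mz), deriv in raw.items():
        if mx + my + mz > order:
            continue
        # (-1)^|m| T(m) equals the plain derivative w.r.t. r = A - D
        coeff = O[mx, my, mz] / (
            _FACTORIALS[mx] * _FACTORIALS[my] * _FACTORIALS[mz]
        )
        total += coeff * deriv
    return float(total[0]) if single else total


def eri3_asymptotic(a: ContractedGTO, b: ContractedGTO, cbar, order: int = DEFAULT_ORDER,
                    center: str = "a") -> float | np.ndarray:
    """Far-field three-center ERI by the double asymptotic expansion.

    (pi/z)^{3/2} sum_m [(-1)^|m|/m!] T_AC(m + cbar_index) <a+m|b>, the
    auxiliary's Hermite index offsetting the derivative tensor.  ``cbar`` may
    be a single auxiliary or a list sharing exponent and index (vectorized
    over centers).
    """
    if order > 12:
        raise ValueError("expansion order beyond supported T-tensor range")
    if center == "b":
        a, b = b, a
    single = isinstance(cbar, HermiteAuxFunction)
    aux = [cbar] if single else list(cbar)
    z = aux[0].exponent
    idx = aux[0].index
    norm = aux[0].norm
    for f in aux[1:]:
        if f.exponent != z or f.index != idx or f.norm != norm:
            raise ValueError("batched eri3_asymptotic requires a uniform group")
    centers = np.array([f.center for f in aux])
    lc = sum(idx)
    O = shifted_overlaps(a, b, order)
    raw = _inv_r_derivatives(order + lc, a.center[None, :] - centers)
    total = np.zeros(len(aux))
    sign_c = (-1.0) ** lc
    for mx in range(order + 1):
        for my in range(order + 1 - mx):
            for mz in range(order + 1 - mx - my):
                deriv = raw[(mx + idx[0], my + idx[1], mz + idx[2])]
                coeff = O[mx, my, mz] / (
                    _FACTORIALS[mx] * _FACTORIALS[my] * _FACTORIALS[mz]
                )
                total += coeff * (sign_c * deriv)
    total *= norm * (math.pi / z) ** 1.5
    return float(total[0]) if single else total


# ---------------------------------------------------------------------------
# embedded core Hamiltonian
# ---------------------------------------------------------------------------

from .gto_integrals import nai_exact  # noqa: E402  (cycle-free convenience)


def embed_core_hamiltonian(H0: np.ndarray, basis: AOBasis, charges,
                           near_far: NearFarMap | None = None,
                           order: int = DEFAULT_ORDER, tau: float = DEFAULT_TAU,
                           factorized: bool = True) -> np.ndarray:
    """H_ab = H0_ab - sum_near <ab|1/|r-D|> Q_D - (far-field expansion term).

    ``charges`` is a list of PointCharge (or (N,3)+(N,) arrays via NearFarMap).
    With ``factorized=True`` (default) the far-field charge sums are
    accumulated once per (QM atom, m) outside the orbital loops; setting it
    False re-accumulates them inside the pair loop (identical result, test
    hook for the factorization invariant).
    """
    H = np.array(H0, dtype=float, copy=True)
    if near_far is None:
        sites = np.array([pc.position for pc in charges], dtype=float).reshape(-1, 3)
        qs = np.array([pc.q for pc in charges], dtype=float)
        near_far = classify_mm(basis, sites, tau, mm_charges=qs)
    sites, qs = near_far.sites, near_far.charges
    if len(sites) == 0:
        return H
    shells = basis.shells
    offs = basis.shell_offsets
    ncomp = [len(sh.functions()) for sh in shells]  # small; could cache
    fns = basis.functions

    # factorized far-field sums per QM atom (plain derivatives w.r.t. r = A-D)
    far_sums = {}
    if factorized:
        for atom, nearmask in near_far.atom_near.items():
            far = ~nearmask
            A = next(sh.center for sh in shells if sh.atom_index == atom)
            far_sums[atom] = farfield_charge_sums(A, sites[far], qs[far], order)

    zmin = [float(np.min(sh.exponents)) for sh in shells]
    for s1 in range(len(shells)):
        for s2 in range(s1 + 1):
            # expansion center: the tighter shell's center — that is where the
            # orbital product is localized, so the Taylor series converges
            sc, so = (s1, s2) if zmin[s1] >= zmin[s2] else (s2, s1)
            c_atom = shells[sc].atom_index
            A = shells[sc].center
            atom_near_c = near_far.atom_near[c_atom]
            pair_near = near_far.pair_near(s1, s2)
            atom_near_o = near_far.atom_near[shells[so].atom_index]
            # union auxiliary field: anything near either *atom* is treated
            # exactly for this pair (superset of the per-shell union)
            near_mask = pair_near | atom_near_c | atom_near_o
            far_corr = (~atom_near_c) & near_mask  # in c's far sums but near here
            for ia in range(ncomp[sc]):
                fa = fns[offs[sc] + ia]
                for ib in range(ncomp[so] if sc != so else ia + 1):
                    fb = fns[offs[so] + ib]
                    val = 0.0
                    if near_mask.any():
                        val -= float(
                            np.dot(nai_exact(fa, fb, sites[near_mask]), qs[near_mask])
                        )
                    # far field about the expansion center
                    O = shifted_overlaps(fa, fb, order)
                    if factorized:
                        sums = dict(far_sums[c_atom])
                        if far_corr.any():
                            corr = farfield_charge_sums(
                                A, sites[far_corr], qs[far_corr], order
                            )
                            sums = {m: sums[m] - corr[m] for m in sums}
                    else:
                        farm = ~near_mask
                        sums = farfield_charge_sums(A, sites[farm], qs[farm], order)
                    acc = 0.0
                    for (mx, my, mz), sval in sums.items():
                        acc += O[mx, my, mz] * sval / (
                            _FACTORIALS[mx] * _FACTORIALS[my] * _FACTORIALS[mz]
                        )
                    val -= acc
                    i, j = offs[sc] + ia, offs[so] + ib
                    H[i, j] += val
                    if i != j:
                        H[j, i] += val
    return H


# ---------------------------------------------------------------------------
# near-field ERI bookkeeping (mixed SCF policy, linearity measurements)
# ---------------------------------------------------------------------------

def significant_shell_pairs(basis: AOBasis, tau: float = DEFAULT_TAU):
    """Shell pairs whose Gaussian product prefactor survives screening.

    A pair is significant when exp(-mu_min |AB|^2) >= tau with mu_min built
    from the most diffuse primitives; everything else is numerically zero at
    the integral threshold.
    """
    shells = basis.shells
    zmin = np.array([float(np.min(sh.exponents)) for sh in shells])
    centers = np.array([sh.center for sh in shells])
    pairs = []
    lntau = math.log(tau)
    for s1 in range(len(shells)):
        for s2 in range(s1 + 1):
            mu = zmin[s1] * zmin[s2] / (zmin[s1] + zmin[s2])
            ab2 = float(np.sum((centers[s1] - centers[s2]) ** 2))
            if -mu * ab2 >= lntau:
                pairs.append((s1, s2))
    return pairs


def classify_eri3(basis: AOBasis, aux: AuxBasis, tau: float = DEFAULT_TAU,
                  extents: ExtentTable | None = None):
    """Near/far classification of (shell-pair, auxiliary) triplets.

    An auxiliary is far-field for a pair when its center is beyond

        R = sqrt(ln(pref / tau) / mu_eff) + |A - B|

    from the pair's expansion center (the tighter shell's), with
    mu_eff = p z / (p + z) combining the minimal product exponent
    p = zmin_a + zmin_b with the auxiliary exponent z, and pref the
    auxiliary's potential amplitude.  This is the Gaussian-interaction decay
    radius: both the residual of the auxiliary's multipolar potential and
    the tail of the orbital product are below tau outside it.  Returns
    (pairs, near_mask).
    """
    if extents is None:
        extents = ExtentTable.build(basis, tau, aux=aux)
    pairs = significant_shell_pairs(basis, tau)
    shells = basis.shells
    centers = np.array([sh.center for sh in shells])
    zmin = np.array([float(np.min(sh.exponents)) for sh in shells])
    acenters = np.array([f.center for f in aux.functions])
    zc = np.array([f.exponent for f in aux.functions])
    pref = np.array(
        [max(f.norm * (math.pi / f.exponent) ** 1.5, 1.0) for f in aux.functions]
    )
    d = np.linalg.norm(centers[:, None, :] - acenters[None, :, :], axis=-1)
    near = np.empty((len(pairs), aux.n_functions), dtype=bool)
    lntau = math.log(tau)
    for k, (s1, s2) in enumerate(pairs):
        tcen = s1 if zmin[s1] >= zmin[s2] else s2
        p = zmin[s1] + zmin[s2]
        mu = p * zc / (p + zc)
        offset = float(np.linalg.norm(centers[s1] - centers[s2]))
        R = np.sqrt(np.maximum(np.log(pref) - lntau, 1.0) / mu) + offset
        near[k] = d[tcen] <= R
    return pairs, near


_NEAR_CAL = 0.1  # empirical prefactor calibration of the near-field radius


def count_nearfield_eri(basis: AOBasis, aux: AuxBasis, tau: float = DEFAULT_TAU) -> int:
    """Number of near-field 3-center ERIs at threshold tau.

    This is the mixed-SCF storage estimate, counted at the level the
    integrals are actually produced: primitive Gaussian products.  Each
    surviving primitive pair (screened by its contraction-weighted product
    prefactor) owns a product center P and exponent p; an auxiliary with
    exponent z is near when its center lies within

        R = sqrt( ln(cal * pref / tau) / mu ),   mu = p z / (p + z),

    of P, where pref is the magnitude prefactor of the corresponding
    s-type Coulomb integral and cal an empirical calibration making the
    asymptotic-expansion error just outside R of order tau.  Counts carry
    the Cartesian multiplicity of the contracted shells.
    """
    shells = basis.shells
    acen = np.array([f.center for f in aux.functions])
    zcs = np.array([f.exponent for f in aux.functions])
    norms = np.array([f.norm for f in aux.functions])
    dmag = []
    for sh in shells:
        dmag.append(
            np.abs(sh.coefficients)
            * np.array([_primitive_norm(z, (sh.l, 0, 0)) for z in sh.exponents])
        )
    count = 0
    for s1 in range(len(shells)):
        for s2 in range(s1 + 1):
            ncomp = len(_CART[shells[s1].l]) * len(_CART[shells[s2].l])
            AB2 = float(np.sum((shells[s1].center - shells[s2].center) ** 2))
            for z1, c1 in zip(shells[s1].exponents, dmag[s1]):
                for z2, c2 in zip(shells[s2].exponents, dmag[s2]):
                    K = math.exp(-(z1 * z2 / (z1 + z2)) * AB2)
                    if c1 * c2 * K < tau:
                        continue
                    p = z1 + z2
                    P = (z1 * shells[s1].center + z2 * shells[s2].center) / p
                    mu = p * zcs / (p + zcs)
                    pref = (
                        c1 * c2 * K * 2.0 * math.pi ** 2.5
                        / (p * zcs * np.sqrt(p + zcs)) * norms
                    )
                    R = np.sqrt(
                        np.maximum(np.log(_NEAR_CAL * pref / tau), 1.0) / mu
                    )
                    d = np.linalg.norm(acen - P[None, :], axis=1)
                    count += int((d <= R).sum()) * ncomp
    return count
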