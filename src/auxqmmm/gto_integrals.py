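"""Molecular integrals over contracted Cartesian Gaussians and Hermite auxiliaries.

The engine is a McMurchie–Davidson scheme: Cartesian orbital products are
expanded in Hermite Gaussians (E coefficients), and Coulomb-type integrals
contract those against derivative tensors of the Boys function (R tensors).
All Coulomb-kernel routines are vectorized over the last argument (point
charges, auxiliary centers), which is where QM/MM embedding spends its time.

Supported angular momentum: s, p, d orbitals; Hermite auxiliary index of
total order <= 2.  Overlap integrals with a raised index <a+m|b> are used by
the far-field asymptotic expansions and support arbitrary shifts m.

Auxiliary-function convention (documented here, used consistently by eri2,
eri3, the density fit and the grid code): a Hermite auxiliary with index
(t,u,v) and exponent z is

    c(r) = norm * (d/dCx)^t (d/dCy)^u (d/dCz)^v exp(-z |r-C|^2),

with norm = (2z/pi)^(3/4) * (2z)^((t+u+v)/2) when ``normalized=True``
(the default; a pure scale fixing the conditioning of the fitting metric)
and norm = 1 otherwise.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import gammainc, gammaln

MAX_L = 2  # d functions

_CART = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}

_SHELL_LETTER = {0: "S", 1: "P", 2: "D"}


def cartesian_components(l: int):
    return list(_CART[l])


def _double_factorial(n: int) -> float:
    if n <= 0:
        return 1.0
    r = 1.0
    while n > 1:
        r *= n
        n -= 2
    return r


# ---------------------------------------------------------------------------
# Boys function
# ---------------------------------------------------------------------------

_BOYS_SERIES_TERMS = 30


def boys_array(nmax: int, x) -> np.ndarray:
    """F_n(x) for n = 0..nmax; shape (nmax+1,) + x.shape.

    Small arguments (x < 1) use the Taylor series of the top order; larger
    arguments evaluate the top order through the regularized lower incomplete
    gamma function.  Lower orders follow by downward recursion, which is
    stable in both regimes.  Absolute accuracy ~1e-14 for n <= 32, x <= 200.
    """
    if nmax < 0:
        raise ValueError("Boys order must be >= 0")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0):
        raise ValueError("Boys argument must be >= 0")
    out = np.empty((nmax + 1,) + x.shape)
    top = np.empty_like(x)
    small = x < 1.0
    if small.any():
        xs = x[small]
        acc = np.zeros_like(xs)
        term = np.ones_like(xs)
        for k in range(_BOYS_SERIES_TERMS):
            acc += term / (2 * nmax + 2 * k + 1)
            term *= -xs / (k + 1)
        top[small] = acc
    if (~small).any():
        xl = x[~small]
        a = nmax + 0.5
        # F_n(x) = Gamma(n+1/2) * P(n+1/2, x) / (2 x^(n+1/2))
        top[~small] = 0.5 * np.exp(gammaln(a) - a * np.log(xl)) * gammainc(a, xl)
    out[nmax] = top
    if nmax > 0:
        ex = np.exp(-x)
        for n in range(nmax, 0, -1):
            out[n - 1] = (2.0 * x * out[n] + ex) / (2 * n - 1)
    return out[:, 0] if scalar else out


def boys(n: int, x) -> float | np.ndarray:
    """The Boys function F_n(x) = int_0^1 t^(2n) exp(-x t^2) dt."""
    return boys_array(n, x)[n]


# ---------------------------------------------------------------------------
# Hermite expansion (E) and Coulomb derivative (R) tensors
# ---------------------------------------------------------------------------

def _e_table(la: int, lb: int, pa: float, pb: float, p: float, mu_xab2: float):
    """1-D Hermite expansion coefficients E[i, j, t], i<=la, j<=lb.

    E[0,0,0] carries the Gaussian-product prefactor exp(-mu*Xab^2) for this
    dimension; pa = Px-Ax, pb = Px-Bx.
    """
    E = np.zeros((la + 1, lb + 1, la + lb + 1))
    E[0, 0, 0] = math.exp(-mu_xab2)
    o2p = 0.5 / p
    for i in range(1, la + 1):
        for t in range(i + 1):
            val = pa * E[i - 1, 0, t]
            if t > 0:
                val += o2p * E[i - 1, 0, t - 1]
            if t + 1 <= i - 1:
                val += (t + 1) * E[i - 1, 0, t + 1]
            E[i, 0, t] = val
    for j in range(1, lb + 1):
        for i in range(la + 1):
            for t in range(i + j + 1):
                val = pb * E[i, j - 1, t]
                if t > 0:
                    val += o2p * E[i, j - 1, t - 1]
                if t + 1 <= i + j - 1:
                    val += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = val
    return E


def _r_tensor(L: int, p: float, PC: np.ndarray) -> dict:
    """Hermite Coulomb integrals R_{tuv}(p, PC) for t+u+v <= L.

    PC has shape (N, 3); every entry of the returned dict is an (N,) array.
    R_{000} at auxiliary order n is (-2p)^n F_n(p |PC|^2) and higher indices
    follow the McMurchie–Davidson downward recursion.
    """
    PC = np.atleast_2d(np.asarray(PC, dtype=float))
    r2 = np.einsum("ij,ij->i", PC, PC)
    F = boys_array(L, p * r2)
    X, Y, Z = PC[:, 0], PC[:, 1], PC[:, 2]
    prev = None
    for n in range(L, -1, -1):
        cur = {(0, 0, 0): ((-2.0 * p) ** n) * F[n]}
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


# ---------------------------------------------------------------------------
# basis function objects
# ---------------------------------------------------------------------------

def _primitive_norm(zeta: float, momentum) -> float:
    ax, ay, az = momentum
    l = ax + ay + az
    num = (2.0 * zeta / math.pi) ** 0.75 * (4.0 * zeta) ** (l / 2.0)
    den = math.sqrt(
        _double_factorial(2 * ax - 1)
        * _double_factorial(2 * ay - 1)
        * _double_factorial(2 * az - 1)
    )
    return num / den


@dataclass
class PrimitiveCartesianGTO:
    """A single normalized Cartesian Gaussian x^ax y^ay z^az exp(-zeta r^2)."""

    center: np.ndarray
    exponent: float
    momentum: tuple[int, int, int]

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if any(m < 0 for m in self.momentum):
            raise ValueError("angular momentum indices must be >= 0")
        self.momentum = tuple(int(m) for m in self.momentum)
        self.norm = _primitive_norm(self.exponent, self.momentum)

    def contracted(self) -> "ContractedGTO":
        return ContractedGTO(
            self.center, self.momentum, [self.exponent], [1.0]
        )


class ContractedGTO:
    """Contraction of primitives sharing a center and Cartesian momentum.

    ``coefficients`` refer to normalized primitives; the contraction is then
    rescaled so the self-overlap is one.
    """

    def __init__(self, center, momentum, exponents, coefficients, normalize=True):
        self.center = np.asarray(center, dtype=float)
        self.momentum = tuple(int(m) for m in momentum)
        if sum(self.momentum) > MAX_L:
            raise ValueError(
                f"angular momentum {self.momentum} beyond supported maximum (d)"
            )
        self.exponents = np.asarray(exponents, dtype=float)
        coefficients = np.asarray(coefficients, dtype=float)
        if len(self.exponents) == 0 or len(self.exponents) != len(coefficients):
            raise ValueError("need matching, non-empty exponent/coefficient lists")
        if np.any(self.exponents <= 0):
            raise ValueError("exponents must be positive")
        norms = np.array(
            [_primitive_norm(z, self.momentum) for z in self.exponents]
        )
        self._d = coefficients * norms  # raw polynomial-Gaussian coefficients
        if normalize:
            s = overlap(self, self)
            self._d /= math.sqrt(s)

    @property
    def l(self) -> int:
        return sum(self.momentum)

    @property
    def primitives(self):
        return list(zip(self._d, self.exponents))

    def translated(self, shift) -> "ContractedGTO":
        out = ContractedGTO.__new__(ContractedGTO)
        out.center = self.center + np.asarray(shift, dtype=float)
        out.momentum = self.momentum
        out.exponents = self.exponents.copy()
        out._d = self._d.copy()
        return out


@dataclass
class HermiteAuxFunction:
    """Primitive Hermite Gaussian auxiliary function (see module docstring)."""

    center: np.ndarray
    exponent: float
    index: tuple[int, int, int] = (0, 0, 0)
    normalized: bool = True

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.exponent <= 0:
            raise ValueError("auxiliary exponent must be positive")
        self.index = tuple(int(i) for i in self.index)
        if any(i < 0 for i in self.index):
            raise ValueError("Hermite index must be >= 0")
        if sum(self.index) > MAX_L:
            raise ValueError(
                f"Hermite auxiliary index {self.index} beyond supported order {MAX_L}"
            )
        z = self.exponent
        self.norm = (
            (2.0 * z / math.pi) ** 0.75 * (2.0 * z) ** (sum(self.index) / 2.0)
            if self.normalized
            else 1.0
        )

    def values(self, points: np.ndarray) -> np.ndarray:
        """Function values on (N, 3) points (used by the XC grid code)."""
        pts = np.atleast_2d(points)
        s = pts - self.center[None, :]
        z = self.exponent
        out = np.exp(-z * np.einsum("ij,ij->i", s, s))
        for dim in range(3):
            t = self.index[dim]
            if t == 0:
                continue
            # f_t = (d/dC)^t exp(-z s^2): f_1 = 2 z s f_0, f_{t+1} = 2z(s f_t - t f_{t-1})
            f0 = np.ones_like(out)
            f1 = 2.0 * z * s[:, dim]
            if t == 1:
                out = out * f1
            else:
                f2 = 2.0 * z * (s[:, dim] * f1 - f0)
                out = out * f2
        return self.norm * out

    def moment_integral(self) -> float:
        """int c(r) d^3r — nonzero only for the s-type auxiliary."""
        if sum(self.index) > 0:
            return 0.0
        return self.norm * (math.pi / self.exponent) ** 1.5


# ---------------------------------------------------------------------------
# integral drivers
# ---------------------------------------------------------------------------

def _pair_data(a: ContractedGTO, b: ContractedGTO):
    AB = a.center - b.center
    ab2 = float(AB @ AB)
    for da, za in a.primitives:
        for db, zb in b.primitives:
            p = za + zb
            mu = za * zb / p
            P = (za * a.center + zb * b.center) / p
            yield da * db, za, zb, p, P, mu * ab2


def overlap(a: ContractedGTO, b: ContractedGTO, shift=(0, 0, 0)) -> float:
    """<a+m|b>: overlap with the angular index of a raised by ``shift``."""
    mx, my, mz = (int(m) for m in shift)
    if min(mx, my, mz) < 0:
        raise ValueError("overlap shift components must be >= 0")
    am = (a.momentum[0] + mx, a.momentum[1] + my, a.momentum[2] + mz)
    total = 0.0
    for c, za, zb, p, P, mu_ab2 in _pair_data(a, b):
        sfac = math.sqrt(math.pi / p)
        val = c
        for dim in range(3):
            E = _e_table(
                am[dim], b.momentum[dim],
                P[dim] - a.center[dim], P[dim] - b.center[dim],
                p, mu_ab2 if dim == 0 else 0.0,
            )
            val *= E[am[dim], b.momentum[dim], 0] * sfac
        total += val
    return total


def kinetic(a: ContractedGTO, b: ContractedGTO) -> float:
    """Kinetic-energy matrix element <a| -1/2 nabla^2 |b>."""
    total = 0.0
    for c, za, zb, p, P, mu_ab2 in _pair_data(a, b):
        sfac = math.sqrt(math.pi / p)
        S = []
        for dim in range(3):
            la, lb = a.momentum[dim], b.momentum[dim]
            E = _e_table(
                la, lb + 2,
                P[dim] - a.center[dim], P[dim] - b.center[dim],
                p, mu_ab2 if dim == 0 else 0.0,
            )
            sij = E[la, lb, 0] * sfac
            sijp2 = E[la, lb + 2, 0] * sfac
            sijm2 = E[la, lb - 2, 0] * sfac if lb >= 2 else 0.0
            tij = (
                -2.0 * zb * zb * sijp2
                + zb * (2 * lb + 1) * sij
                - 0.5 * lb * (lb - 1) * sijm2
            )
            S.append((sij, tij))
        total += c * (
            S[0][1] * S[1][0] * S[2][0]
            + S[0][0] * S[1][1] * S[2][0]
            + S[0][0] * S[1][0] * S[2][1]
        )
    return total


def _e_xyz(a, b, p, P, mu_ab2, shift=(0, 0, 0)):
    """Per-dimension E tables for a (possibly shifted) contracted pair."""
    out = []
    for dim in range(3):
        la = a.momentum[dim] + shift[dim]
        E = _e_table(
            la, b.momentum[dim],
            P[dim] - a.center[dim], P[dim] - b.center[dim],
            p, mu_ab2 if dim == 0 else 0.0,
        )
        out.append(E[la, b.momentum[dim], :])
    return out


def nai_exact(a: ContractedGTO, b: ContractedGTO, D) -> float | np.ndarray:
    """Nuclear-attraction integrals <ab| 1/|r-D| > for one site or (N,3) sites."""
    D = np.asarray(D, dtype=float)
    single = D.ndim == 1
    sites = np.atleast_2d(D)
    if not np.all(np.isfinite(sites)):
        raise ValueError("NAI sites must be finite")
    L = a.l + b.l
    total = np.zeros(len(sites))
    for c, za, zb, p, P, mu_ab2 in _pair_data(a, b):
        Ex, Ey, Ez = _e_xyz(a, b, p, P, mu_ab2)
        R = _r_tensor(L, p, P[None, :] - sites)
        acc = np.zeros(len(sites))
        for t in range(len(Ex)):
            if Ex[t] == 0.0:
                continue
            for u in range(len(Ey)):
                if Ey[u] == 0.0:
                    continue
                for v in range(len(Ez)):
                    if Ez[v] == 0.0:
                        continue
                    acc += Ex[t] * Ey[u] * Ez[v] * R[(t, u, v)]
        total += c * (2.0 * math.pi / p) * acc
    return float(total[0]) if single else total


def eri2(c: HermiteAuxFunction, d: HermiteAuxFunction) -> float:
    """Two-center repulsion <c || d> between Hermite auxiliaries."""
    zc, zd = c.exponent, d.exponent
    alpha = zc * zd / (zc + zd)
    L = sum(c.index) + sum(d.index)
    R = _r_tensor(L, alpha, (c.center - d.center)[None, :])
    idx = tuple(ci + di for ci, di in zip(c.index, d.index))
    pref = 2.0 * math.pi ** 2.5 / (zc * zd * math.sqrt(zc + zd))
    sign = (-1.0) ** sum(d.index)
    return float(c.norm * d.norm * sign * pref * R[idx][0])


def eri2_matrix(aux_functions) -> np.ndarray:
    """The fitting metric G with entries <c || d>; symmetric PSD."""
    n = len(aux_functions)
    G = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            G[i, j] = G[j, i] = eri2(aux_functions[i], aux_functions[j])
    return G


def eri3(a: ContractedGTO, b: ContractedGTO, cbar) -> float | np.ndarray:
    """Three-center repulsion <ab || c> for one auxiliary or a list.

    Lists are grouped internally by (exponent, index) so the Coulomb tensor
    is evaluated vectorized over auxiliary centers.
    """
    single = isinstance(cbar, HermiteAuxFunction)
    aux = [cbar] if single else list(cbar)
    out = np.zeros(len(aux))
    groups: dict[tuple, list[int]] = {}
    for k, c in enumerate(aux):
        groups.setdefault((c.exponent, c.index, c.norm), []).append(k)
    pair = list(_pair_data(a, b))
    for (zc, idx, norm), members in groups.items():
        centers = np.array([aux[k].center for k in members])
        lc = sum(idx)
        sign = (-1.0) ** lc
        L = a.l + b.l + lc
        vals = np.zeros(len(members))
        for c, za, zb, p, P, mu_ab2 in pair:
            Ex, Ey, Ez = _e_xyz(a, b, p, P, mu_ab2)
            alpha = p * zc / (p + zc)
            pref = 2.0 * math.pi ** 2.5 / (p * zc * math.sqrt(p + zc))
            R = _r_tensor(L, alpha, P[None, :] - centers)
            acc = np.zeros(len(members))
            for t in range(len(Ex)):
                if Ex[t] == 0.0:
                    continue
                for u in range(len(Ey)):
                    if Ey[u] == 0.0:
                        continue
                    for v in range(len(Ez)):
                        if Ez[v] == 0.0:
                            continue
                        acc += Ex[t] * Ey[u] * Ez[v] * R[
                            (t + idx[0], u + idx[1], v + idx[2])
                        ]
            vals += c * sign * pref * acc
        out[members] = norm * vals
    return float(out[0]) if single else out


def eri4(a: ContractedGTO, b: ContractedGTO, c: ContractedGTO, d: ContractedGTO) -> float:
    """Brute-force four-center ERI (ab|cd); test oracle and exact-exchange path."""
    L = a.l + b.l + c.l + d.l
    total = 0.0
    for c1, za, zb, p, P, mu_ab2 in _pair_data(a, b):
        Ex1, Ey1, Ez1 = _e_xyz(a, b, p, P, mu_ab2)
        for c2, zc, zd, q, Q, mu_cd2 in _pair_data(c, d):
            Ex2, Ey2, Ez2 = _e_xyz(c, d, q, Q, mu_cd2)
            alpha = p * q / (p + q)
            pref = 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
            R = _r_tensor(L, alpha, (P - Q)[None, :])
            acc = 0.0
            for t in range(len(Ex1)):
                for u in range(len(Ey1)):
                    for v in range(len(Ez1)):
                        e1 = Ex1[t] * Ey1[u] * Ez1[v]
                        if e1 == 0.0:
                            continue
                        for tt in range(len(Ex2)):
                            for uu in range(len(Ey2)):
                                for vv in range(len(Ez2)):
                                    e2 = Ex2[tt] * Ey2[uu] * Ez2[vv]
                                    if e2 == 0.0:
                                        continue
                                    acc += (
                                        e1
                                        * e2
                                        * (-1.0) ** (tt + uu + vv)
                                        * R[(t + tt, u + uu, v + vv)][0]
                                    )
            total += c1 * c2 * pref * acc
    return total


# ---------------------------------------------------------------------------
# basis-set library (Gaussian94-style text dialect)
# ---------------------------------------------------------------------------

@dataclass
class Shell:
    """A contracted shell: all Cartesian components sharing radial parts."""

    atom_index: int
    center: np.ndarray
    l: int
    exponents: np.ndarray
    coefficients: np.ndarray  # for normalized primitives

    def functions(self):
        return [
            ContractedGTO(self.center, m, self.exponents, self.coefficients)
            for m in _CART[self.l]
        ]


@dataclass
class BasisSetLibrary:
    """Per-element contracted shells parsed from Gaussian94-style text."""

    shells_by_element: dict[str, list[tuple[int, np.ndarray, np.ndarray]]]
    provenance: str = ""

    @classmethod
    def from_text(cls, text: str, provenance: str = "") -> "BasisSetLibrary":
        shells: dict[str, list] = {}
        element = None
        lines = [
            ln for ln in text.splitlines()
            if ln.strip() and not ln.strip().startswith("!")
        ]
        i = 0
        letter_to_l = {"S": 0, "P": 1, "D": 2}
        while i < len(lines):
            ln = lines[i].strip()
            if ln.startswith("****"):
                element = None
                i += 1
                continue
            parts = ln.split()
            if element is None:
                element = parts[0].capitalize()
                shells.setdefault(element, [])
                i += 1
                continue
            kind = parts[0].upper()
            nprim = int(parts[1])
            rows = [lines[i + 1 + k].replace("D", "E").replace("d", "e").split()
                    for k in range(nprim)]
            i += 1 + nprim
            exps = np.array([float(r[0]) for r in rows])
            if kind == "SP":
                cs = np.array([float(r[1]) for r in rows])
                cp = np.array([float(r[2]) for r in rows])
                shells[element].append((0, exps, cs))
                shells[element].append((1, exps, cp))
            else:
                if kind not in letter_to_l:
                    raise ValueError(f"unsupported shell type {kind!r} (max is d)")
                co = np.array([float(r[1]) for r in rows])
                shells[element].append((letter_to_l[kind], exps, co))
        return cls(shells_by_element=shells, provenance=provenance)

    @classmethod
    def from_file(cls, path) -> "BasisSetLibrary":
        path = Path(path)
        return cls.from_text(path.read_text(), provenance=str(path))

    @classmethod
    def builtin(cls, name: str) -> "BasisSetLibrary":
        data = Path(__file__).parent / "data" / f"{name}.gbs"
        if not data.exists():
            avail = sorted(p.stem for p in (Path(__file__).parent / "data").glob("*.gbs"))
            raise ValueError(f"no built-in basis {name!r}; available: {avail}")
        return cls.from_file(data)

    def shells_for(self, element: str):
        if element not in self.shells_by_element:
            raise ValueError(
                f"basis set {self.provenance!r} has no entry for element {element!r}"
            )
        return self.shells_by_element[element]


@dataclass
class AOBasis:
    """Orbital basis for a concrete geometry: shells and flattened functions."""

    shells: list[Shell]
    functions: list[ContractedGTO] = field(default_factory=list)
    shell_offsets: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.functions:
            off = 0
            for sh in self.shells:
                self.shell_offsets.append(off)
                fns = sh.functions()
                self.functions.extend(fns)
                off += len(fns)

    @property
    def n_functions(self) -> int:
        return len(self.functions)

    def function_shell_index(self) -> np.ndarray:
        idx = np.empty(self.n_functions, dtype=int)
        for s, off in enumerate(self.shell_offsets):
            n = len(_CART[self.shells[s].l])
            idx[off : off + n] = s
        return idx


def build_ao_basis(atoms, library: BasisSetLibrary, indices=None) -> AOBasis:
    """Instantiate the orbital basis on (a subset of) a system's atoms.

    ``atoms`` is a list of chem_model.Atom; ``indices`` restricts to a subset
    (e.g. the QM region) while keeping original atom indices in the shells.
    """
    shells = []
    use = range(len(atoms)) if indices is None else indices
    for i in use:
        a = atoms[i]
        for (l, exps, coefs) in library.shells_for(a.element):
            shells.append(Shell(i, np.asarray(a.position, float), l, exps, coefs))
    return AOBasis(shells=shells)


# ---------------------------------------------------------------------------
# auxiliary basis generation (even-tempered Hermite sets)
# ---------------------------------------------------------------------------

@dataclass
class AuxBasis:
    functions: list[HermiteAuxFunction]

    @property
    def n_functions(self) -> int:
        return len(self.functions)

    def metric(self) -> np.ndarray:
        return eri2_matrix(self.functions)


def even_tempered_exponents(zmin: float, zmax: float, beta: float = 3.0):
    """Geometric exponent ladder covering the density exponent range [2 zmin, 2 zmax]."""
    lo, hi = 2.0 * zmin, 2.0 * zmax
    n = max(2, int(math.ceil(math.log(hi / lo) / math.log(beta))) + 1)
    return [lo * beta ** k for k in range(n)] if n > 1 else [lo]


def build_aux_basis(atoms, library: BasisSetLibrary, indices=None,
                    beta: float = 3.0, spd: bool = False) -> AuxBasis:
    """Even-tempered s (optionally s+p+d) Hermite auxiliaries per atom.

    Exponents are derived from the orbital exponent range of each element;
    the fitted density they span is validated only through the variational
    bound and SCF cross-checks, not against any published auxiliary set.
    """
    funcs = []
    use = range(len(atoms)) if indices is None else indices
    for i in use:
        a = atoms[i]
        exps = np.concatenate(
            [np.asarray(e) for (_, e, _) in library.shells_for(a.element)]
        )
        ladder = even_tempered_exponents(float(exps.min()), float(exps.max()), beta)
        for z in ladder:
            funcs.append(HermiteAuxFunction(np.asarray(a.position, float), z))
            if spd:
                for idx in _CART[1] + _CART[2]:
                    funcs.append(
                        HermiteAuxFunction(np.asarray(a.position, float), z, idx)
                    )
    return AuxBasis(functions=funcs)
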