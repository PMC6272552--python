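"""Molecular-mechanics energies, analytic gradients, QM-MM Lennard-Jones
coupling and Drude polarizable self-energy.

Functional forms are the generic class-I ones: harmonic bonds, angles and
Urey-Bradley 1-3 terms (all with the 1/2 k convention), cosine dihedrals
V_n (1 + cos(n phi - delta)), 12-6 van der Waals written as
eps [(Rmin/r)^12 - 2 (Rmin/r)^6] with Lorentz (arithmetic Rmin) / geometric
(eps) combination, and bare Coulomb.  Nonbonded interactions run over full
double loops without a cutoff; 1-2 and 1-3 pairs are excluded and 1-4 pairs
are included at full strength (both configurable).  Parameter files use
kcal/mol, Å and degrees and are converted to atomic units on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_model import MolecularSystem
from .units import ANGSTROM_TO_BOHR, DEG_TO_RAD, KCALMOL_TO_HARTREE


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _bkey(t1, t2):
    return tuple(sorted((t1, t2)))


def _akey(t1, t2, t3):
    return (t1, t2, t3) if (t1,) <= (t3,) else (t3, t2, t1)


def _dkey(t1, t2, t3, t4):
    return (t1, t2, t3, t4) if (t2, t1) <= (t3, t4) else (t4, t3, t2, t1)


@dataclass
class FFParameters:
    """Bonded/nonbonded parameter tables in atomic units.

    bond: (t1,t2) -> (k_b [Eh/bohr^2], r0 [bohr]);
    angle: (t1,t2,t3) -> (k_th [Eh/rad^2], th0 [rad]);
    dihedral: (t1..t4) -> list of (V_n [Eh], n, delta [rad]), wildcard "X";
    urey: angle key -> (k_u, s0).  Per-type nonbonded parameters live on the
    atoms themselves (mm_charge, lj_epsilon, lj_rmin).
    """

    bond: dict = field(default_factory=dict)
    angle: dict = field(default_factory=dict)
    dihedral: dict = field(default_factory=dict)
    urey: dict = field(default_factory=dict)
    exclude_12: bool = True
    exclude_13: bool = True
    scale_14: float = 1.0

    def bond_param(self, t1, t2):
        try:
            return self.bond[_bkey(t1, t2)]
        except KeyError:
            raise KeyError(f"no bond parameters for type pair ({t1}, {t2})") from None

    def angle_param(self, t1, t2, t3):
        try:
            return self.angle[_akey(t1, t2, t3)]
        except KeyError:
            raise KeyError(
                f"no angle parameters for type triple ({t1}, {t2}, {t3})"
            ) from None

    def urey_param(self, t1, t2, t3):
        return self.urey.get(_akey(t1, t2, t3))

    def dihedral_param(self, t1, t2, t3, t4):
        for key in (
            _dkey(t1, t2, t3, t4),
            _dkey("X", t2, t3, "X"),
        ):
            if key in self.dihedral:
                return self.dihedral[key]
        raise KeyError(
            f"no dihedral parameters for type quadruple ({t1}, {t2}, {t3}, {t4})"
        )

    @classmethod
    def from_file(cls, path) -> "FFParameters":
        """Parse the plain-text parameter dialect (sections BONDS/ANGLES/
        DIHEDRALS/UREY; kcal/mol, Å, degrees)."""
        params = cls()
        section = None
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            upper = line.upper()
            if upper in ("BONDS", "ANGLES", "DIHEDRALS", "UREY"):
                section = upper
                continue
            parts = line.split()
            try:
                if section == "BONDS":
                    t1, t2, k, r0 = parts[0], parts[1], float(parts[2]), float(parts[3])
                    params.bond[_bkey(t1, t2)] = (
                        k * KCALMOL_TO_HARTREE / ANGSTROM_TO_BOHR ** 2,
                        r0 * ANGSTROM_TO_BOHR,
                    )
                elif section == "ANGLES":
                    t1, t2, t3 = parts[:3]
                    k, th0 = float(parts[3]), float(parts[4])
                    params.angle[_akey(t1, t2, t3)] = (
                        k * KCALMOL_TO_HARTREE, th0 * DEG_TO_RAD
                    )
                elif section == "UREY":
                    t1, t2, t3 = parts[:3]
                    k, s0 = float(parts[3]), float(parts[4])
                    params.urey[_akey(t1, t2, t3)] = (
                        k * KCALMOL_TO_HARTREE / ANGSTROM_TO_BOHR ** 2,
                        s0 * ANGSTROM_TO_BOHR,
                    )
                elif section == "DIHEDRALS":
                    t1, t2, t3, t4 = parts[:4]
                    v, n, d = float(parts[4]), int(parts[5]), float(parts[6])
                    params.dihedral.setdefault(_dkey(t1, t2, t3, t4), []).append(
                        (v * KCALMOL_TO_HARTREE, n, d * DEG_TO_RAD)
                    )
                else:
                    raise ValueError("data before any section header")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from exc
        return params

    @classmethod
    def builtin(cls) -> "FFParameters":
        return cls.from_file(Path(__file__).parent / "data" / "standard.ff")


@dataclass
class MMEnergyBreakdown:
    E_bond: float = 0.0
    E_bend: float = 0.0
    E_tors: float = 0.0
    E_urey: float = 0.0
    E_vdW: float = 0.0
    E_QQ: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.E_bond + self.E_bend + self.E_tors
            + self.E_urey + self.E_vdW + self.E_QQ
        )


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def build_exclusions(system: MolecularSystem, params: FFParameters) -> set:
    """Set of excluded (i, j) pairs (i < j) from the bond graph."""
    excl = set()
    if params.exclude_12:
        for (i, j) in system.bonds:
            excl.add((min(i, j), max(i, j)))
    if params.exclude_13:
        for (i, j, k) in system.angles:
            excl.add((min(i, k), max(i, k)))
    return excl


# ---------------------------------------------------------------------------
# MM energy and gradient
# ---------------------------------------------------------------------------

def _angle_terms(pos, i, j, k):
    rij = pos[i] - pos[j]
    rkj = pos[k] - pos[j]
    nij, nkj = np.linalg.norm(rij), np.linalg.norm(rkj)
    cosv = float(np.dot(rij, rkj) / (nij * nkj))
    cosv = min(1.0, max(-1.0, cosv))
    theta = math.acos(cosv)
    sinv = math.sqrt(max(1.0 - cosv * cosv, 1e-14))
    dth_di = (cosv * rij / nij - rkj / nkj) / (nij * sinv)
    dth_dk = (cosv * rkj / nkj - rij / nij) / (nkj * sinv)
    return theta, dth_di, dth_dk


def _dihedral_terms(pos, i, j, k, l):
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = math.atan2(float(np.dot(np.cross(n1, n2), b2) / nb2), float(np.dot(n1, n2)))
    sq1 = float(np.dot(n1, n1))
    sq2 = float(np.dot(n2, n2))
    dphi_di = -nb2 / sq1 * n1
    dphi_dl = nb2 / sq2 * n2
    s = float(np.dot(b1, b2)) / (nb2 * nb2)
    t = float(np.dot(b3, b2)) / (nb2 * nb2)
    dphi_dj = -(1.0 + s) * dphi_di + t * dphi_dl
    dphi_dk = s * dphi_di - (1.0 + t) * dphi_dl
    return phi, dphi_di, dphi_dj, dphi_dk, dphi_dl


def mm_energy_gradient(system: MolecularSystem, params: FFParameters,
                       exclusions: set | None = None):
    """Eq.-of-state of the MM region: (MMEnergyBreakdown, gradient (N,3)).

    Double-loop nonbonded evaluation (no cutoff); analytic gradients
    throughout.  Atoms with Z = 0 (Drude/virtual) participate only through
    their charges; they carry no LJ or bonded terms here (see drude_energy
    for the oscillator self-energy).
    """
    pos = system.positions
    n = system.n_atoms
    grad = np.zeros((n, 3))
    br = MMEnergyBreakdown()
    types = [a.mm_type for a in system.atoms]

    for (i, j) in system.bonds:
        kb, r0 = params.bond_param(types[i], types[j])
        rij = pos[i] - pos[j]
        r = np.linalg.norm(rij)
        br.E_bond += 0.5 * kb * (r - r0) ** 2
        f = kb * (r - r0) * rij / r
        grad[i] += f
        grad[j] -= f

    for (i, j, k) in system.angles:
        kth, th0 = params.angle_param(types[i], types[j], types[k])
        theta, dth_di, dth_dk = _angle_terms(pos, i, j, k)
        br.E_bend += 0.5 * kth * (theta - th0) ** 2
        g = kth * (theta - th0)
        grad[i] += g * dth_di
        grad[k] += g * dth_dk
        grad[j] -= g * (dth_di + dth_dk)
        up = params.urey_param(types[i], types[j], types[k])
        if up is not None:
            ku, s0 = up
            rik = pos[i] - pos[k]
            s = np.linalg.norm(rik)
            br.E_urey += 0.5 * ku * (s - s0) ** 2
            f = ku * (s - s0) * rik / s
            grad[i] += f
            grad[k] -= f

    for (i, j, k, l) in system.dihedrals:
        terms = params.dihedral_param(types[i], types[j], types[k], types[l])
        phi, di, dj, dk, dl = _dihedral_terms(pos, i, j, k, l)
        for (v, nper, delta) in terms:
            br.E_tors += v * (1.0 + math.cos(nper * phi - delta))
            g = -v * nper * math.sin(nper * phi - delta)
            grad[i] += g * di
            grad[j] += g * dj
            grad[k] += g * dk
            grad[l] += g * dl

    # nonbonded: full double loop with exclusion mask
    if exclusions is None:
        exclusions = build_exclusions(system, params)
    q = system.charges
    eps = np.array([a.lj_epsilon for a in system.atoms])
    rmin = np.array([a.lj_rmin for a in system.atoms])
    if n > 1:
        diff = pos[:, None, :] - pos[None, :, :]
        r = np.linalg.norm(diff, axis=-1)
        mask = np.triu(np.ones((n, n), dtype=bool), 1)
        for (i, j) in exclusions:
            mask[i, j] = False
        with np.errstate(divide="ignore", invalid="ignore"):
            ii, jj = np.nonzero(mask)
            rr = r[ii, jj]
            # Coulomb
            qq = q[ii] * q[jj]
            br.E_QQ += float(np.sum(qq / rr))
            fq = (qq / rr ** 3)[:, None] * diff[ii, jj]
            np.add.at(grad, ii, -fq)
            np.add.at(grad, jj, fq)
            # Lennard-Jones
            e = np.sqrt(eps[ii] * eps[jj])
            rm = 0.5 * (rmin[ii] + rmin[jj])
            act = e > 0
            if act.any():
                x6 = (rm[act] / rr[act]) ** 6
                br.E_vdW += float(np.sum(e[act] * (x6 * x6 - 2.0 * x6)))
                dEdr = e[act] * (-12.0 * x6 * x6 + 12.0 * x6) / rr[act]
                fv = (dEdr / rr[act])[:, None] * diff[ii[act], jj[act]]
                np.add.at(grad, ii[act], fv)
                np.add.at(grad, jj[act], -fv)
    return br, grad


# ---------------------------------------------------------------------------
# QM-MM Lennard-Jones coupling
# ---------------------------------------------------------------------------

def qm_mm_lj(system: MolecularSystem, partition, exclusions: set | None = None):
    """Pairwise 12-6 coupling between QM and MM atoms.

    Uses each atom's assigned MM type parameters (QM atoms must be typed);
    Rmin by the arithmetic (Lorentz) rule, eps by the geometric rule.
    Bonded 1-2/1-3 pairs across the boundary are excluded (same convention
    as the MM nonbonded terms).  Returns (energy, gradient over all atoms).
    """
    pos = system.positions
    grad = np.zeros_like(pos)
    E = 0.0
    for iq in partition.qm_indices:
        a = system.atoms[iq]
        if not a.mm_type:
            raise ValueError(f"QM atom {iq + 1} has no MM type for LJ coupling")
    qm = np.array(partition.qm_indices, dtype=int)
    mm = np.array(partition.mm_indices, dtype=int)
    if len(qm) == 0 or len(mm) == 0:
        return 0.0, grad
    if exclusions is None:
        excl_sys = MolecularSystem(atoms=system.atoms, bonds=system.bonds,
                                   angles=system.angles)
        exclusions = build_exclusions(excl_sys, FFParameters())
    eps = np.array([a.lj_epsilon for a in system.atoms])
    rmin = np.array([a.lj_rmin for a in system.atoms])
    diff = pos[qm][:, None, :] - pos[mm][None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    e = np.sqrt(eps[qm][:, None] * eps[mm][None, :])
    rm = 0.5 * (rmin[qm][:, None] + rmin[mm][None, :])
    act = e > 0
    for ia, i in enumerate(qm):
        for ja, j in enumerate(mm):
            if (min(i, j), max(i, j)) in exclusions:
                act[ia, ja] = False
    x6 = np.zeros_like(r)
    x6[act] = (rm[act] / r[act]) ** 6
    E = float(np.sum(e[act] * (x6[act] ** 2 - 2.0 * x6[act])))
    dEdr = np.zeros_like(r)
    dEdr[act] = e[act] * (-12.0 * x6[act] ** 2 + 12.0 * x6[act]) / r[act]
    f = (dEdr / np.where(r > 0, r, 1.0))[:, :, None] * diff
    np.add.at(grad, qm, f.sum(axis=1))
    np.add.at(grad, mm, -f.sum(axis=0))
    return E, grad


# ---------------------------------------------------------------------------
# Drude oscillators
# ---------------------------------------------------------------------------

@dataclass
class DrudeSet:
    """Drude particles attached to heavy atoms by harmonic springs.

    attachments: heavy-atom index -> Drude particle index; q_drude and
    k_drude are per-Drude charge (e) and spring constant (Eh/bohr^2).
    The harmonic spring models an induced dipole with polarizability
    alpha = q'^2 / k.
    """

    attachments: dict[int, int]
    q_drude: dict[int, float]
    k_drude: dict[int, float]

    def validate(self, n_particles: int):
        seen = set()
        for heavy, dr in self.attachments.items():
            if not (0 <= heavy < n_particles and 0 <= dr < n_particles):
                raise ValueError("Drude attachment index out of range")
            if dr in seen:
                raise ValueError("a Drude particle bound to two anchors")
            seen.add(dr)
            if self.k_drude[dr] <= 0:
                raise ValueError("Drude spring constant must be positive")

    @property
    def drude_indices(self):
        return sorted(self.attachments.values())

    def anchor_of(self, drude_index):
        for heavy, dr in self.attachments.items():
            if dr == drude_index:
                return heavy
        raise KeyError(f"particle {drude_index} is not an attached Drude")


def drude_energy(positions, drudes: DrudeSet, charges,
                 exclusions: set | None = None,
                 uniform_field=None) -> float:
    """Electrostatic energy of reals + Drudes plus oscillator self-energy.

    All particle pairs interact by Coulomb except excluded ones; exclusions
    are inherited through the anchor (a Drude never sees its own anchor, and
    pairs whose anchors are excluded are excluded too).  ``uniform_field``
    adds -sum q_i E.r_i for an external homogeneous field.
    """
    pos = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    n = len(pos)
    drudes.validate(n)
    parent = np.arange(n)
    for heavy, dr in drudes.attachments.items():
        parent[dr] = heavy
    excl = exclusions or set()
    E = 0.0
    for i in range(n):
        for j in range(i):
            pi, pj = parent[i], parent[j]
            if pi == pj:
                continue
            if (min(pi, pj), max(pi, pj)) in excl:
                continue
            E += q[i] * q[j] / np.linalg.norm(pos[i] - pos[j])
    for heavy, dr in drudes.attachments.items():
        d = np.linalg.norm(pos[dr] - pos[heavy])
        E += 0.5 * drudes.k_drude[dr] * d * d
    if uniform_field is not None:
        E -= float(np.einsum("i,ij,j->", q, pos, np.asarray(uniform_field, float)))
    return float(E)


def relax_drudes(positions, drudes: DrudeSet, charges,
                 exclusions: set | None = None, uniform_field=None,
                 gtol: float = 1e-8, max_iter: int = 200):
    """Minimize the Drude energy over Drude positions at fixed real atoms.

    Self-consistent field iteration: each Drude is placed at the harmonic
    displacement q' E / k in the field of everything else, repeated to
    convergence (gradient norm <= gtol).  Replaces extended-Lagrangian
    propagation.
    """
    pos = np.asarray(positions, dtype=float).copy()
    q = np.asarray(charges, dtype=float)
    n = len(pos)
    drudes.validate(n)
    parent = np.arange(n)
    for heavy, dr in drudes.attachments.items():
        parent[dr] = heavy
    excl = exclusions or set()
    dr_idx = drudes.drude_indices

    def field_at(i):
        """Electric field at particle i from all non-excluded others."""
        Efield = np.zeros(3)
        for j in range(n):
            if j == i or parent[j] == parent[i]:
                continue
            if (min(parent[i], parent[j]), max(parent[i], parent[j])) in excl:
                continue
            rij = pos[i] - pos[j]
            r = np.linalg.norm(rij)
            Efield += q[j] * rij / r ** 3
        if uniform_field is not None:
            Efield = Efield + np.asarray(uniform_field, float)
        return Efield

    for _ in range(max_iter):
        gmax = 0.0
        for dr in dr_idx:
            heavy = parent[dr]
            k = drudes.k_drude[dr]
            Ef = field_at(dr)
            target = pos[heavy] + q[dr] * Ef / k
            # residual force on the Drude before the move
            gmax = max(gmax, float(np.linalg.norm(
                q[dr] * Ef - k * (pos[dr] - pos[heavy])
            )))
            pos[dr] = target
        if gmax <= gtol:
            return pos
    raise RuntimeError(
        f"Drude relaxation did not converge: residual force {gmax:.3e}"
    )
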