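"""Additive and subtractive (ONIOM) QM/MM coupling.

The additive total energy is E = E_QM + E_QMMM + E_MM with E_QM the embedded
SCF energy plus the MM-augmented nuclear repulsion, E_QMMM the QM-MM 12-6
coupling and E_MM the force-field energy of the MM region.  The subtractive
scheme is E = E_MM(system) - E_MM(model) + E_QM(model) with the embedding
point charges included identically in both model calculations so their
electrostatics cancel.

Boundary bonds are capped with hydrogen link atoms at the fractional
position R_LA = R_QBA + alpha (R_MBA - R_QBA); forces on a link atom are
projected back onto its hosts by the chain rule of that definition
(F_QBA += (1-alpha) F_LA, F_MBA += alpha F_LA).

QM nuclear gradients are obtained by central finite differences of the
embedded SCF energy (link atoms re-placed at every displacement);
gradients on embedding charges are analytic Hellmann-Feynman terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import elements
from .adft_scf import SCFSettings, nuclear_embedded_repulsion, run_scf
from .chem_model import Atom, MolecularSystem, PointCharge, QMMMPartition
from .gto_integrals import BasisSetLibrary
from .mm_forcefield import FFParameters, mm_energy_gradient, qm_mm_lj
from .units import ANGSTROM_TO_BOHR


# equilibrium bond lengths (Å) used for the default link-atom ratios
_EQ_BOND_ANG = {
    ("C", "H"): 1.090, ("C", "C"): 1.530, ("C", "N"): 1.470,
    ("C", "O"): 1.430, ("N", "H"): 1.010, ("O", "H"): 0.960,
}


def _eq_bond(e1, e2):
    key = (e1, e2) if (e1, e2) in _EQ_BOND_ANG else (e2, e1)
    return _EQ_BOND_ANG.get(key)


@dataclass
class LinkAtom:
    qba: int
    mba: int
    alpha: float
    element: str = "H"
    position: np.ndarray | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("link-atom alpha must lie in (0, 1)")


def default_alpha(system: MolecularSystem, qba: int, mba: int) -> float:
    """Ratio of equilibrium bond lengths r_eq(QBA-H) / r_eq(QBA-MBA)."""
    eq_qh = _eq_bond(system.atoms[qba].element, "H")
    eq_qm = _eq_bond(system.atoms[qba].element, system.atoms[mba].element)
    if eq_qh is None or eq_qm is None:
        return 0.712  # generic C-C cut ratio
    return eq_qh / eq_qm


def place_link_atoms(system: MolecularSystem, partition: QMMMPartition,
                     alpha_table: dict | None = None) -> list[LinkAtom]:
    """Hydrogen caps on every boundary bond, collinear with QBA -> MBA."""
    links = []
    for (qba, mba) in partition.boundary_pairs:
        rq = system.atoms[qba].position
        rm = system.atoms[mba].position
        if np.allclose(rq, rm):
            raise ValueError(f"coincident boundary atoms {qba + 1}/{mba + 1}")
        alpha = (
            alpha_table.get((qba, mba)) if alpha_table and (qba, mba) in alpha_table
            else default_alpha(system, qba, mba)
        )
        links.append(
            LinkAtom(qba=qba, mba=mba, alpha=alpha, position=rq + alpha * (rm - rq))
        )
    partition.link_atoms = links
    return links


def project_link_forces(F_LA, alpha: float):
    """Chain-rule force increments (F_QBA_inc, F_MBA_inc) from a link force."""
    F_LA = np.asarray(F_LA, dtype=float)
    return (1.0 - alpha) * F_LA, alpha * F_LA


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

@dataclass
class AdditiveEnergy:
    E_QM: float
    E_QMMM: float
    E_MM: float

    @property
    def E_total(self) -> float:
        return self.E_QM + self.E_QMMM + self.E_MM


@dataclass
class ONIOMEnergy:
    E_MM_system: float
    E_MM_model: float
    E_QM_model: float

    @property
    def E_total(self) -> float:
        return self.E_MM_system - self.E_MM_model + self.E_QM_model


@dataclass
class EmbeddingField:
    charges: list
    cutoff: float | None = None
    excluded_indices: set = field(default_factory=set)


@dataclass
class QMMMSettings:
    """Configuration of a coupled calculation.

    ``qm_engine`` is "scf" or a callable
    ``engine(qm_atoms, embedding) -> (E, grad_qm, grad_sites)`` (gradients
    may be None when only energies are needed); using an MM evaluator as the
    engine reproduces pure-MM results exactly and is the standard regression
    hook.
    """

    qm_engine: object = "scf"
    basis: object = None           # BasisSetLibrary (or name) for SCF engines
    aux: object = None
    scf: SCFSettings = field(default_factory=SCFSettings)
    ff: FFParameters = field(default_factory=FFParameters.builtin)
    charge: int = 0
    embedding_cutoff: float | None = None
    exclude_mba_charge: bool = True
    link_alpha_table: dict | None = None
    link_mm_type: str = "HA"       # MM type of link caps in model MM calcs
    fd_step: float = 1e-3          # bohr, for QM nuclear gradients


def _resolve_basis(settings: QMMMSettings):
    b = settings.basis or "minimal"
    return BasisSetLibrary.builtin(b) if isinstance(b, str) else b


def build_embedding_field(system: MolecularSystem, partition: QMMMPartition,
                          settings: QMMMSettings) -> EmbeddingField:
    """MM point charges visible to the QM region.

    QM charges never appear; the MM boundary atom's charge is excluded by
    default (closest-charge overpolarization guard); optional distance
    cutoff about the QM centroid.
    """
    excluded = set()
    if settings.exclude_mba_charge:
        excluded |= {mba for (_, mba) in partition.boundary_pairs}
    qm_pos = np.array([system.atoms[i].position for i in partition.qm_indices])
    centroid = qm_pos.mean(axis=0)
    charges = []
    idx = []
    for i in partition.mm_indices:
        if i in excluded:
            continue
        a = system.atoms[i]
        if a.mm_charge == 0.0:
            continue
        if (
            settings.embedding_cutoff is not None
            and np.linalg.norm(a.position - centroid) > settings.embedding_cutoff
        ):
            continue
        charges.append(PointCharge(a.position.copy(), a.mm_charge))
        idx.append(i)
    f = EmbeddingField(charges=charges, cutoff=settings.embedding_cutoff,
                       excluded_indices=excluded)
    f.source_indices = idx
    return f


def _qm_atoms_with_links(system: MolecularSystem, partition: QMMMPartition,
                         links: list[LinkAtom], link_mm_type: str) -> list[Atom]:
    atoms = [system.atoms[i] for i in partition.qm_indices]
    for la in links:
        atoms.append(
            Atom("H", 1, la.position, mass=elements.mass_of("H"),
                 region="LINK", mm_type=link_mm_type)
        )
    return atoms


def _scf_engine(settings: QMMMSettings):
    lib = _resolve_basis(settings)

    def engine(qm_atoms, embedding):
        res = run_scf(qm_atoms, lib, aux=settings.aux, embedding=embedding,
                      settings=settings.scf, charge=settings.charge)
        if not res.converged:
            raise RuntimeError("embedded SCF did not converge inside QM/MM")
        grad_sites = _embedding_site_gradient(res, qm_atoms, embedding)
        return res.E_total, None, grad_sites

    return engine


def _embedding_site_gradient(res, qm_atoms, embedding):
    """Analytic Hellmann-Feynman gradient on embedding charges."""
    if not embedding:
        return np.zeros((0, 3))
    from .gto_integrals import _r_tensor, _e_xyz, _pair_data

    sites = np.array([pc.position for pc in embedding])
    qs = np.array([pc.q for pc in embedding])
    fns = res.basis.functions
    P = res.density
    g = np.zeros((len(sites), 3))
    # electronic part: dV_ab/dD = -(2 pi / p) sum E * R_{m+e_x} etc.
    for i in range(len(fns)):
        for j in range(i + 1):
            w = P[i, j] * (1.0 if i == j else 2.0)
            if abs(w) < 1e-12:
                continue
            L = fns[i].l + fns[j].l
            acc = np.zeros((len(sites), 3))
            for c, za, zb, p, Pc, mu_ab2 in _pair_data(fns[i], fns[j]):
                Ex, Ey, Ez = _e_xyz(fns[i], fns[j], p, Pc, mu_ab2)
                R = _r_tensor(L + 1, p, Pc[None, :] - sites)
                for t in range(len(Ex)):
                    for u in range(len(Ey)):
                        for v in range(len(Ez)):
                            e = Ex[t] * Ey[u] * Ez[v]
                            if e == 0.0:
                                continue
                            f = c * (2.0 * math.pi / p) * e
                            acc[:, 0] -= f * R[(t + 1, u, v)]
                            acc[:, 1] -= f * R[(t, u + 1, v)]
                            acc[:, 2] -= f * R[(t, u, v + 1)]
            # H contribution is -q * V_ab; energy term w * (-q * V) -> gradient
            g += -w * qs[:, None] * acc
    # nuclear part: d/dD sum_A Z_A q / |A - D|
    for a in qm_atoms:
        if a.Z < 1:
            continue
        d = sites - a.position[None, :]
        r = np.linalg.norm(d, axis=1)
        g += (a.Z * qs / r ** 3)[:, None] * d
    return g


def _mm_region_energy(system: MolecularSystem, partition: QMMMPartition,
                      params: FFParameters):
    """Force-field terms of the MM region: bonded terms with >= 1 MM atom,
    nonbonded among MM atoms only."""
    qm = set(partition.qm_indices)
    sub = system.copy()
    sub.bonds = [b for b in system.bonds if not set(b) <= qm]
    sub.angles = [a for a in system.angles if not set(a) <= qm]
    sub.dihedrals = [d for d in system.dihedrals if not set(d) <= qm]
    sub.urey_terms = list(system.urey_terms)
    for i in qm:
        sub.atoms[i].mm_charge = 0.0
        sub.atoms[i].lj_epsilon = 0.0
    # exclusions from the *full* bond graph so 1-2/1-3 bookkeeping is unchanged
    from .mm_forcefield import build_exclusions

    excl = build_exclusions(system, params)
    return mm_energy_gradient(sub, params, exclusions=excl)


def additive_qmmm(system: MolecularSystem, partition: QMMMPartition,
                  settings: QMMMSettings | None = None,
                  compute_gradient: bool = False):
    """Additive QM/MM energy (and optionally the total nuclear gradient)."""
    settings = settings or QMMMSettings()
    links = place_link_atoms(system, partition, settings.link_alpha_table)
    fieldobj = build_embedding_field(system, partition, settings)
    qm_atoms = _qm_atoms_with_links(system, partition, links, settings.link_mm_type)
    engine = (
        _scf_engine(settings) if settings.qm_engine == "scf" else settings.qm_engine
    )
    E_qm, grad_qm, grad_sites = engine(qm_atoms, fieldobj.charges)
    E_lj, grad_lj = qm_mm_lj(system, partition)
    mm_break, grad_mm = _mm_region_energy(system, partition, settings.ff)
    energy = AdditiveEnergy(E_QM=E_qm, E_QMMM=E_lj, E_MM=mm_break.total)
    if not compute_gradient:
        return energy, None
    grad = grad_lj + grad_mm
    nq = len(partition.qm_indices)
    if grad_qm is None:
        grad_qm = _fd_qm_gradient(engine, qm_atoms, fieldobj.charges, links,
                                  partition, settings.fd_step)
    # QM-region atoms
    for k, i in enumerate(partition.qm_indices):
        grad[i] += grad_qm[k]
    # link-atom forces projected onto their hosts
    for m, la in enumerate(links):
        g_la = grad_qm[nq + m]
        g_q, g_m = project_link_forces(-g_la, la.alpha)  # forces, then back
        grad[la.qba] -= g_q
        grad[la.mba] -= g_m
    # embedding charges follow their MM atoms
    if grad_sites is not None:
        for g, i in zip(grad_sites, fieldobj.source_indices):
            grad[i] += g
    return energy, grad


def _fd_qm_gradient(engine, qm_atoms, embedding, links, partition, h):
    """Central-difference gradient of the QM energy over QM + link atoms."""
    g = np.zeros((len(qm_atoms), 3))
    for k in range(len(qm_atoms)):
        for d in range(3):
            for s, sign in ((h, 1.0), (-h, -1.0)):
                atoms2 = [
                    Atom(a.element, a.Z, a.position.copy(), a.mass, a.region,
                         a.mm_type, a.mm_charge, a.lj_epsilon, a.lj_rmin)
                    for a in qm_atoms
                ]
                atoms2[k].position[d] += s
                e, _, _ = engine(atoms2, embedding)
                g[k, d] += sign * e / (2.0 * h)
    return g


def subtractive_oniom(system: MolecularSystem, partition: QMMMPartition,
                      settings: QMMMSettings | None = None,
                      compute_gradient: bool = False):
    """ONIOM subtractive energy E_MM(system) - E_MM(model) + E_QM(model).

    The embedding field enters both model calculations: the model MM energy
    gains the Coulomb interaction of the model charges with the field, which
    cancels the same physics double-counted in the embedded QM energy.
    """
    settings = settings or QMMMSettings()
    links = place_link_atoms(system, partition, settings.link_alpha_table)
    fieldobj = build_embedding_field(system, partition, settings)
    qm_atoms = _qm_atoms_with_links(system, partition, links, settings.link_mm_type)

    mm_sys_break, grad_mm_sys = mm_energy_gradient(system, settings.ff)

    model = _model_system(system, partition, qm_atoms)
    mm_model_break, grad_mm_model = mm_energy_gradient(model, settings.ff)
    E_mm_model = mm_model_break.total
    # model charges interacting with the embedding field (both model calcs)
    E_field, grad_model_field, grad_sites_mm = _charge_field_interaction(
        model, fieldobj.charges
    )
    E_mm_model += E_field

    engine = (
        _scf_engine(settings) if settings.qm_engine == "scf" else settings.qm_engine
    )
    E_qm, grad_qm, grad_sites_qm = engine(qm_atoms, fieldobj.charges)

    energy = ONIOMEnergy(
        E_MM_system=mm_sys_break.total,
        E_MM_model=E_mm_model,
        E_QM_model=E_qm,
    )
    if not compute_gradient:
        return energy, None
    if grad_qm is None:
        grad_qm = _fd_qm_gradient(engine, qm_atoms, fieldobj.charges, links,
                                  partition, settings.fd_step)
    grad = grad_mm_sys.copy()
    nq = len(partition.qm_indices)
    model_grad = grad_qm - (grad_mm_model + grad_model_field)
    for k, i in enumerate(partition.qm_indices):
        grad[i] += model_grad[k]
    for m, la in enumerate(links):
        g_la = model_grad[nq + m]
        inc_q, inc_m = project_link_forces(g_la, la.alpha)
        grad[la.qba] += inc_q
        grad[la.mba] += inc_m
    if grad_sites_qm is None:
        grad_sites_qm = np.zeros_like(grad_sites_mm)
    for gq, gm, i in zip(grad_sites_qm, grad_sites_mm, fieldobj.source_indices):
        grad[i] += gq - gm
    return energy, grad


def _model_system(system, partition, qm_atoms) -> MolecularSystem:
    """The capped QM region as a standalone MM-parameterizable system."""
    model = MolecularSystem(atoms=[
        Atom(a.element, a.Z, a.position.copy(), a.mass, a.region,
             a.mm_type, a.mm_charge, a.lj_epsilon, a.lj_rmin)
        for a in qm_atoms
    ])
    index_map = {i: k for k, i in enumerate(partition.qm_indices)}
    qm = set(partition.qm_indices)
    model.bonds = [
        (index_map[i], index_map[j]) for (i, j) in system.bonds if set((i, j)) <= qm
    ]
    nq = len(partition.qm_indices)
    for m, la in enumerate(partition.link_atoms):
        model.bonds.append(tuple(sorted((index_map[la.qba], nq + m))))
    from .chem_model import enumerate_bonded_terms

    model.angles, model.dihedrals = enumerate_bonded_terms(
        len(model.atoms), model.bonds
    )
    return model


def _charge_field_interaction(model: MolecularSystem, charges):
    """Coulomb energy/gradients between model atoms and external charges."""
    if not charges:
        return 0.0, np.zeros((model.n_atoms, 3)), np.zeros((0, 3))
    pos = model.positions
    q = model.charges
    sites = np.array([pc.position for pc in charges])
    qs = np.array([pc.q for pc in charges])
    diff = pos[:, None, :] - sites[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    E = float(np.sum(q[:, None] * qs[None, :] / r))
    f = (q[:, None] * qs[None, :] / r ** 3)[:, :, None] * diff
    return E, -f.sum(axis=1), f.sum(axis=0)


def spherical_container(positions, center, radius: float, k: float,
                        atom_indices=None):
    """Harmonic wall keeping a droplet together: E = k/2 (r - R)^2 for r > R.

    The standard companion of a flexible-boundary droplet simulation — a
    non-periodic cluster at finite temperature evaporates without it.
    """
    pos = np.asarray(positions, dtype=float)
    idx = range(len(pos)) if atom_indices is None else atom_indices
    E = 0.0
    grad = np.zeros_like(pos)
    c = np.asarray(center, dtype=float)
    for i in idx:
        rv = pos[i] - c
        r = np.linalg.norm(rv)
        if r > radius:
            E += 0.5 * k * (r - radius) ** 2
            grad[i] += k * (r - radius) * rv / r
    return float(E), grad


# ---------------------------------------------------------------------------
# FIRES flexible boundary
# ---------------------------------------------------------------------------

@dataclass
class FIRESState:
    """Flexible Inner Region Ensemble Separator bookkeeping.

    ``inner_tags``/``outer_tags`` are tag-atom indices (e.g. water oxygens)
    of the inner (QM) and outer (MM) solvent molecules; ``reference`` is the
    fixed central atom.  R_in is the largest inner tag distance; outer tags
    penetrating the R_in sphere feel a half-harmonic push outward and the
    boundary inner molecule feels the opposite total force.  With
    ``symmetric`` the mirrored restraint also acts on inner tags
    that drift beyond the innermost outer tag — this is what keeps the inner
    solvent molecules nearest to the reference.

    ``reaction`` selects where the equal-and-opposite restraint force lands:
    "boundary" puts it all on the boundary tag atom (the literal recipe);
    "distributed" spreads it uniformly over the opposing tag set, which
    avoids catapulting a single molecule when several intruders push at
    once — the stable choice for droplet dynamics.  Net restraint force is
    zero either way.
    """

    inner_tags: list[int]
    outer_tags: list[int]
    reference: int
    k_fires: float  # hartree/bohr^2
    symmetric: bool = False
    reaction: str = "boundary"  # boundary | distributed

    def __post_init__(self):
        if not self.inner_tags:
            raise ValueError("FIRES needs a non-empty inner set")
        if set(self.inner_tags) & set(self.outer_tags):
            raise ValueError("inner and outer FIRES sets overlap")
        if self.reaction not in ("boundary", "distributed"):
            raise ValueError(f"unknown reaction mode {self.reaction!r}")


def fires_energy_gradient(state: FIRESState, positions: np.ndarray):
    """FIRES restraint energy and gradient (zero net force by construction)."""
    pos = np.asarray(positions, dtype=float)
    ref = pos[state.reference]
    inner_d = np.array([np.linalg.norm(pos[i] - ref) for i in state.inner_tags])
    b = int(np.argmax(inner_d))
    R_in = float(inner_d[b])
    boundary_atom = state.inner_tags[b]
    E = 0.0
    grad = np.zeros_like(pos)
    gsum = np.zeros(3)
    k = state.k_fires
    for j in state.outer_tags:
        rj_vec = pos[j] - ref
        rj = np.linalg.norm(rj_vec)
        if rj >= R_in:
            continue
        E += 0.5 * k * (rj - R_in) ** 2
        gj = k * (rj - R_in) * rj_vec / rj
        grad[j] += gj
        gsum += gj
    # reaction: minus the total intruder force, so the restraint imparts no
    # net force on the system
    if state.reaction == "boundary":
        grad[boundary_atom] -= gsum
    else:
        for i in state.inner_tags:
            grad[i] -= gsum / len(state.inner_tags)

    if state.symmetric and state.outer_tags:
        outer_d = np.array([np.linalg.norm(pos[j] - ref) for j in state.outer_tags])
        ob = int(np.argmin(outer_d))
        R_out = float(outer_d[ob])
        outer_boundary = state.outer_tags[ob]
        gsum_in = np.zeros(3)
        for i in state.inner_tags:
            ri_vec = pos[i] - ref
            ri = np.linalg.norm(ri_vec)
            if ri <= R_out:
                continue
            E += 0.5 * k * (ri - R_out) ** 2
            gi = k * (ri - R_out) * ri_vec / ri
            grad[i] += gi
            gsum_in += gi
        if state.reaction == "boundary":
            grad[outer_boundary] -= gsum_in
        else:
            for j in state.outer_tags:
                grad[j] -= gsum_in / len(state.outer_tags)
    return float(E), grad
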