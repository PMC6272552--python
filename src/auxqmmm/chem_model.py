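"""Molecular system representation, file I/O, connectivity and QM/MM partitioning.

Positions are stored in bohr; XYZ/PDB/point-charge files are read and written
in Å.  Indices are 0-based internally and 1-based in user-facing reports.
Systems are non-periodic clusters (droplets, chains); there is no box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import elements
from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, DEG_TO_RAD


@dataclass
class Atom:
    """A (real or virtual) particle.

    ``Z = 0`` is reserved for Drude particles and virtual sites; those are
    excluded from automatic connectivity detection.  ``mm_charge`` is the
    fixed point charge Q_D seen by the QM region when the atom is embedded;
    ``lj_epsilon``/``lj_rmin`` parameterize the 12-6 potential written as
    eps*[(Rmin/r)^12 - 2*(Rmin/r)^6] (hartree / bohr).
    """

    element: str
    Z: int
    position: np.ndarray
    mass: float = 0.0
    region: str = "MM"  # QM | MM | LINK
    mm_type: str = ""
    mm_charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be >= 0")
        if self.Z < 0:
            raise ValueError("nuclear charge must be >= 0")


@dataclass
class MolecularSystem:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    urey_terms: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of positions in bohr (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_positions(self, pos: np.ndarray) -> None:
        pos = np.asarray(pos, dtype=float).reshape(len(self.atoms), 3)
        for a, p in zip(self.atoms, pos):
            a.position = p.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.mm_charge for a in self.atoms], dtype=float)

    def validate(self) -> None:
        n = self.n_atoms
        seen = set()
        for (i, j) in self.bonds:
            if not (0 <= i < j < n):
                raise ValueError(f"invalid bond ({i}, {j}) for {n} atoms")
            if (i, j) in seen:
                raise ValueError(f"duplicate bond ({i}, {j})")
            seen.add((i, j))

    def copy(self) -> "MolecularSystem":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass
class PointCharge:
    position: np.ndarray
    q: float

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not (np.all(np.isfinite(self.position)) and math.isfinite(self.q)):
            raise ValueError("point charge must be finite")


@dataclass
class QMMMPartition:
    """Disjoint, jointly exhaustive split of real atoms into QM and MM.

    ``boundary_pairs`` lists (QM boundary atom, MM boundary atom) index pairs,
    one per covalent bond crossing the partition.  ``link_atoms`` is populated
    by the coupling layer (see :mod:`auxqmmm.qmmm_coupling`).
    """

    qm_indices: list[int]
    mm_indices: list[int]
    boundary_pairs: list[tuple[int, int]] = field(default_factory=list)
    link_atoms: list = field(default_factory=list)

    def validate(self, system: MolecularSystem) -> None:
        qm, mm = set(self.qm_indices), set(self.mm_indices)
        if qm & mm:
            raise ValueError("QM and MM index sets overlap")
        real = {i for i, a in enumerate(system.atoms) if a.Z >= 1}
        if (qm | mm) != real:
            raise ValueError("QM and MM sets must cover all real atoms")
        bondset = {tuple(sorted(b)) for b in system.bonds}
        for (qba, mba) in self.boundary_pairs:
            if qba not in qm or mba not in mm:
                raise ValueError(f"boundary pair ({qba}, {mba}) misassigned")
            if tuple(sorted((qba, mba))) not in bondset:
                raise ValueError(f"boundary pair ({qba}, {mba}) is not bonded")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_xyz(path) -> MolecularSystem:
    """Read a standard XYZ file (Å) into a system with positions in bohr."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: malformed atom count") from None
    if len(lines) < count + 2:
        raise ValueError(f"{path}: expected {count} atom records, file too short")
    atoms = []
    for ln in range(2, 2 + count):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {ln + 1}: malformed atom record")
        sym = parts[0].capitalize() if len(parts[0]) > 1 else parts[0].upper()
        try:
            xyz = np.array([float(v) for v in parts[1:4]])
        except ValueError:
            raise ValueError(f"{path}: line {ln + 1}: non-numeric coordinate") from None
        z = elements.z_of(sym)
        atoms.append(
            Atom(sym, z, xyz * ANGSTROM_TO_BOHR, mass=elements.mass_of(sym))
        )
    return MolecularSystem(atoms=atoms)


def write_xyz(system: MolecularSystem, path, comment: str = "") -> None:
    """Write a system as standard XYZ (Å, 6 decimals); deterministic output."""
    if system.n_atoms == 0:
        raise ValueError("refusing to write an empty system")
    with open(path, "w") as fh:
        fh.write(f"{system.n_atoms}\n{comment}\n")
        for a in system.atoms:
            x, y, z = a.position * BOHR_TO_ANGSTROM
            fh.write(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def write_xyz_frames(frames, elements_, path, comments=None) -> None:
    """Write a multi-frame XYZ trajectory from (n_frames, N, 3) bohr positions."""
    frames = np.asarray(frames, dtype=float)
    with open(path, "w") as fh:
        for f, pos in enumerate(frames):
            note = comments[f] if comments is not None else f"frame {f}"
            fh.write(f"{len(elements_)}\n{note}\n")
            for sym, p in zip(elements_, pos * BOHR_TO_ANGSTROM):
                fh.write(f"{sym:<2s} {p[0]:14.6f} {p[1]:14.6f} {p[2]:14.6f}\n")


def read_point_charges(path) -> list[PointCharge]:
    """Read whitespace-separated "x y z q" rows (Å, e) -> charges in bohr."""
    out = []
    with open(path) as fh:
        for row, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}: row {row}: expected 'x y z q'")
            try:
                x, y, z, q = (float(v) for v in parts[:4])
            except ValueError:
                raise ValueError(f"{path}: row {row}: non-numeric token") from None
            out.append(PointCharge(np.array([x, y, z]) * ANGSTROM_TO_BOHR, q))
    return out


def write_point_charges(charges, path) -> None:
    with open(path, "w") as fh:
        for pc in charges:
            x, y, z = pc.position * BOHR_TO_ANGSTROM
            fh.write(f"{x:14.6f} {y:14.6f} {z:14.6f} {pc.q:12.6f}\n")


def read_pdb(path) -> MolecularSystem:
    """Minimal PDB v3.3 reader: ATOM/HETATM records only.

    Occupancy and B-factor columns are ignored.  The element is taken from
    columns 77-78 when present, otherwise guessed from the atom-name field.
    """
    atoms = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError:
                raise ValueError(f"{path}: line {ln}: bad coordinates") from None
            sym = line[76:78].strip().capitalize()
            if not sym:
                name = line[12:16].strip()
                sym = name[:2].capitalize() if name[:2].capitalize() in elements.SYMBOL_TO_Z else name[:1].upper()
            z = elements.z_of(sym)
            atoms.append(
                Atom(sym, z, xyz * ANGSTROM_TO_BOHR, mass=elements.mass_of(sym))
            )
    return MolecularSystem(atoms=atoms)


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def build_connectivity(system: MolecularSystem, scale: float = 1.3) -> list[tuple[int, int]]:
    """Distance-based bond detection and bonded-term enumeration.

    A bond (i, j) exists iff |r_i - r_j| <= scale * (r_cov,i + r_cov,j).
    Drude/virtual sites (Z = 0) never bond.  Angles and dihedrals are derived
    from the bond graph and stored on the system.
    """
    pos = system.positions
    n = system.n_atoms
    radii = np.empty(n)
    for i, a in enumerate(system.atoms):
        radii[i] = 0.0 if a.Z == 0 else (
            elements.covalent_radius_ang(a.element) * ANGSTROM_TO_BOHR
        )
    bonds = []
    if n > 1:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        thresh = scale * (radii[:, None] + radii[None, :])
        real = np.array([a.Z >= 1 for a in system.atoms])
        mask = (d <= thresh) & real[:, None] & real[None, :]
        np.fill_diagonal(mask, False)
        ii, jj = np.nonzero(np.triu(mask, 1))
        bonds = [(int(i), int(j)) for i, j in zip(ii, jj)]
    system.bonds = bonds
    system.angles, system.dihedrals = enumerate_bonded_terms(n, bonds)
    return bonds


def enumerate_bonded_terms(n_atoms, bonds):
    """Angles (i, j, k) with j the apex, and proper dihedrals (i, j, k, l)."""
    nbr = [[] for _ in range(n_atoms)]
    for (i, j) in bonds:
        nbr[i].append(j)
        nbr[j].append(i)
    angles = []
    for j in range(n_atoms):
        ns = sorted(nbr[j])
        for a in range(len(ns)):
            for b in range(a + 1, len(ns)):
                angles.append((ns[a], j, ns[b]))
    dihedrals = set()
    for (j, k) in bonds:
        for i in nbr[j]:
            if i == k:
                continue
            for l in nbr[k]:
                if l == j or l == i:
                    continue
                dihedrals.add(min((i, j, k, l), (l, k, j, i)))
    return angles, sorted(dihedrals)


# ---------------------------------------------------------------------------
# QM/MM partitioning
# ---------------------------------------------------------------------------

def partition_by_selection(system: MolecularSystem, qm_selector) -> QMMMPartition:
    """Split real atoms into QM and MM regions.

    ``qm_selector`` is either an iterable of 0-based atom indices, or a tuple
    ``("within", radius_bohr, center)`` where ``center`` is an atom index or a
    3-vector; the distance criterion selects whole atoms, not molecules.
    Boundary pairs are exactly the bonds crossing the partition.
    """
    real = [i for i, a in enumerate(system.atoms) if a.Z >= 1]
    if isinstance(qm_selector, tuple) and len(qm_selector) == 3 and qm_selector[0] == "within":
        _, radius, center = qm_selector
        cpos = (
            system.atoms[int(center)].position
            if np.isscalar(center) or isinstance(center, int)
            else np.asarray(center, dtype=float)
        )
        qm = [
            i for i in real
            if np.linalg.norm(system.atoms[i].position - cpos) <= radius
        ]
    else:
        qm = sorted(int(i) for i in qm_selector)
    if not qm:
        raise ValueError("QM selector selected zero atoms")
    qmset = set(qm)
    if not qmset.issubset(set(real)):
        raise ValueError("QM selection contains virtual sites or bad indices")
    mm = [i for i in real if i not in qmset]
    boundary = []
    for (i, j) in system.bonds:
        if (i in qmset) != (j in qmset):
            qba, mba = (i, j) if i in qmset else (j, i)
            boundary.append((qba, mba))
    part = QMMMPartition(qm_indices=qm, mm_indices=mm, boundary_pairs=boundary)
    part.validate(system)
    return part


def embedding_charges_from_partition(
    system: MolecularSystem,
    partition: QMMMPartition,
    cutoff: float | None = None,
    exclude_indices=(),
) -> list[PointCharge]:
    """Point charges of MM atoms visible to the QM calculation.

    QM-region charges are excluded by construction; further exclusions (link
    hosts) and an optional distance cutoff from the QM centroid can be applied.
    """
    excl = set(exclude_indices)
    qm_pos = np.array([system.atoms[i].position for i in partition.qm_indices])
    centroid = qm_pos.mean(axis=0)
    out = []
    for i in partition.mm_indices:
        if i in excl:
            continue
        a = system.atoms[i]
        if a.mm_charge == 0.0:
            continue
        if cutoff is not None and np.linalg.norm(a.position - centroid) > cutoff:
            continue
        out.append(PointCharge(a.position.copy(), a.mm_charge))
    return out


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

# rigid 3-site water geometry and SPC charges
WATER_R_OH_ANG = 0.9572
WATER_ANGLE_DEG = 104.52
SPC_Q_O = -0.82
SPC_Q_H = 0.41
# 12-6 parameters (kcal/mol, Å for Rmin/2), CHARMM-style conventions
_NONBONDED_ANG_KCAL = {
    "OW": (0.1554, 1.7766),
    # small H well (CHARMM-style) keeps bare protons off neighboring oxygens
    "HW": (0.046, 0.2245),
    "CT3": (0.0780, 2.040),   # methyl carbon
    "CT2": (0.0560, 2.010),   # methylene carbon
    "HA": (0.0240, 1.340),
    "SOD": (0.0469, 1.41075),
    "POT": (0.0870, 1.76375),
    "CLA": (0.1500, 2.27),
    "BRA": (0.1200, 2.40),
}
_ION_TYPES = {"Na": ("SOD", 1.0), "K": ("POT", 1.0), "Cl": ("CLA", -1.0), "Br": ("BRA", -1.0)}


def _mk_atom(sym, pos_ang, mm_type, q):
    from .units import KCALMOL_TO_HARTREE

    eps_kcal, rmin_half_ang = _NONBONDED_ANG_KCAL[mm_type]
    return Atom(
        sym,
        elements.z_of(sym),
        np.asarray(pos_ang) * ANGSTROM_TO_BOHR,
        mass=elements.mass_of(sym),
        mm_type=mm_type,
        mm_charge=q,
        lj_epsilon=eps_kcal * KCALMOL_TO_HARTREE,
        lj_rmin=2.0 * rmin_half_ang * ANGSTROM_TO_BOHR,
    )


def _water_template_ang():
    """O at origin, H's in the xz-plane: rigid 3-site geometry (Å)."""
    th = 0.5 * WATER_ANGLE_DEG * DEG_TO_RAD
    h1 = np.array([WATER_R_OH_ANG * math.sin(th), 0.0, WATER_R_OH_ANG * math.cos(th)])
    h2 = np.array([-WATER_R_OH_ANG * math.sin(th), 0.0, WATER_R_OH_ANG * math.cos(th)])
    return np.array([[0.0, 0.0, 0.0], h1, h2])


def _random_rotation(rng):
    # uniform over SO(3) via normalized quaternion
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _pack_waters(n, rng, occupied_ang=None, min_sep_ang=1.5, center_clear_ang=2.6):
    """Rejection-sample rigid waters at liquid-like density inside a sphere.

    Besides the global 1.5 Å intermolecular clearance, O-O contacts keep a
    liquid-like 2.6 Å and O-H contacts 1.8 Å so the droplets start near the
    repulsive wall instead of on it.
    """
    vol_per_water = 29.9  # Å^3 per molecule at ~0.997 g/cm^3
    radius = max((3.0 * n * vol_per_water / (4.0 * math.pi)) ** (1.0 / 3.0), 2.0)
    template = _water_template_ang()
    # pairwise minimum distances between atom slots (0 = O, 1/2 = H)
    sep = np.full((3, 3), min_sep_ang)
    sep[0, 0] = 2.6
    sep[0, 1:] = sep[1:, 0] = 1.8
    placed = []  # (3, 3) Å blocks
    existing = None if occupied_ang is None else np.asarray(occupied_ang)
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200000:
            radius *= 1.05
            attempts = 0
        center = rng.uniform(-radius, radius, 3)
        if np.linalg.norm(center) > radius:
            continue
        mol = template @ _random_rotation(rng).T + center
        ok = True
        if existing is not None and np.min(
            np.linalg.norm(mol[:, None, :] - existing[None, :, :], axis=-1)
        ) < center_clear_ang:
            ok = False
        for other in placed:
            if not ok:
                break
            d = np.linalg.norm(mol[:, None, :] - other[None, :, :], axis=-1)
            if np.any(d < sep):
                ok = False
        if ok:
            placed.append(mol)
    return placed


def _water_system(mol_blocks_ang, extra_atoms=None):
    atoms = [] if extra_atoms is None else list(extra_atoms)
    bonds = []
    angles = []
    for mol in mol_blocks_ang:
        o = len(atoms)
        atoms.append(_mk_atom("O", mol[0], "OW", SPC_Q_O))
        atoms.append(_mk_atom("H", mol[1], "HW", SPC_Q_H))
        atoms.append(_mk_atom("H", mol[2], "HW", SPC_Q_H))
        bonds += [(o, o + 1), (o, o + 2)]
        angles.append((o + 1, o, o + 2))
    return MolecularSystem(atoms=atoms, bonds=bonds, angles=angles)


def _alkane_system(n_carbons):
    """Ideal tetrahedral all-anti n-alkane CnH(2n+2), OPLS-like charges."""
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    r_cc, r_ch = 1.530, 1.090
    tet = math.acos(-1.0 / 3.0)
    if n_carbons == 1:
        # methane
        s = r_ch / math.sqrt(3.0)
        hs = np.array([[s, s, s], [s, -s, -s], [-s, s, -s], [-s, -s, s]])
        atoms = [_mk_atom("C", [0, 0, 0], "CT3", -0.24)]
        atoms += [_mk_atom("H", h, "HA", 0.06) for h in hs]
        sysm = MolecularSystem(atoms=atoms, bonds=[(0, i) for i in range(1, 5)])
        sysm.angles, sysm.dihedrals = enumerate_bonded_terms(5, sysm.bonds)
        return sysm

    dx = r_cc * math.sin(tet / 2.0)
    dz = r_cc * math.cos(tet / 2.0)
    cpos = np.array([[i * dx, 0.0, (i % 2) * dz] for i in range(n_carbons)])
    atoms = []
    hpos_per_c = []
    for i in range(n_carbons):
        nb = []
        if i > 0:
            nb.append(cpos[i - 1] - cpos[i])
        if i < n_carbons - 1:
            nb.append(cpos[i + 1] - cpos[i])
        nb = [v / np.linalg.norm(v) for v in nb]
        if len(nb) == 2:
            bis = -(nb[0] + nb[1])
            bis /= np.linalg.norm(bis)
            perp = np.cross(nb[0], nb[1])
            perp /= np.linalg.norm(perp)
            half = tet / 2.0
            hs = [
                cpos[i] + r_ch * (bis * math.cos(half) + perp * math.sin(half)),
                cpos[i] + r_ch * (bis * math.cos(half) - perp * math.sin(half)),
            ]
        else:
            # terminal CH3: three H staggered around the single C-C axis
            axis = -nb[0]
            ref = np.array([0.0, 1.0, 0.0])
            if abs(np.dot(ref, axis)) > 0.9:
                ref = np.array([0.0, 0.0, 1.0])
            e1 = np.cross(axis, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(axis, e1)
            hs = []
            for k in range(3):
                phi = 2.0 * math.pi * k / 3.0 + (math.pi if i % 2 else 0.0)
                d = axis * math.cos(math.pi - tet) + (
                    e1 * math.cos(phi) + e2 * math.sin(phi)
                ) * math.sin(math.pi - tet)
                hs.append(cpos[i] + r_ch * d)
        hpos_per_c.append(hs)

    bonds = []
    for i in range(n_carbons):
        ctype = "CT3" if i in (0, n_carbons - 1) else "CT2"
        qc = -0.18 if ctype == "CT3" else -0.12
        atoms.append(_mk_atom("C", cpos[i], ctype, qc))
    for i in range(n_carbons - 1):
        bonds.append((i, i + 1))
    for i, hs in enumerate(hpos_per_c):
        for h in hs:
            atoms.append(_mk_atom("H", h, "HA", 0.06))
            bonds.append((i, len(atoms) - 1))
    sysm = MolecularSystem(atoms=atoms, bonds=sorted(bonds))
    sysm.angles, sysm.dihedrals = enumerate_bonded_terms(len(atoms), sysm.bonds)
    return sysm


def assign_water_types(system: MolecularSystem) -> None:
    """Assign fixture MM types/charges to a water (+ monatomic ion) system.

    Covers systems read from plain XYZ files: O -> OW, H -> HW with SPC
    charges, and the supported ions.  Any other element is an error — richer
    typing goes through the library API / parameter files.
    """
    from .units import KCALMOL_TO_HARTREE

    for i, a in enumerate(system.atoms):
        if a.element == "O":
            mm_type, q = "OW", SPC_Q_O
        elif a.element == "H":
            mm_type, q = "HW", SPC_Q_H
        elif a.element in _ION_TYPES:
            mm_type, q = _ION_TYPES[a.element]
        else:
            raise ValueError(
                f"cannot auto-type atom {i + 1} ({a.element}); "
                "only water and monatomic ions are auto-typed"
            )
        eps_kcal, rmin_half_ang = _NONBONDED_ANG_KCAL[mm_type]
        a.mm_type = mm_type
        a.mm_charge = q
        a.lj_epsilon = eps_kcal * KCALMOL_TO_HARTREE
        a.lj_rmin = 2.0 * rmin_half_ang * ANGSTROM_TO_BOHR


@dataclass
class HarmonicToy:
    """Isotropic harmonic well: E = k/2 |x|^2 in n_dim dimensions (a.u.)."""

    k: float
    n_dim: int
    mass: float = 1.0

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.k * float(np.dot(x.ravel(), x.ravel()))

    def gradient(self, x):
        return self.k * np.asarray(x, dtype=float)


def make_fixture(kind: str, params=None, seed: int = 0):
    """Deterministic test systems.

    kinds: ``water_droplet`` (n), ``alkane`` (n_carbons), ``ion_droplet``
    (ion, n_waters), ``harmonic_toy`` (k, n_dim).  Droplets are packed by
    rejection sampling at liquid-like density with a 1.5 Å intermolecular
    clearance; water uses the rigid 3-site geometry (0.9572 Å, 104.52°) with
    SPC charges; alkanes are ideal tetrahedral chains.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "water_droplet":
        n = int(params.get("n", 21))
        if n <= 0:
            raise ValueError("n must be positive")
        return _water_system(_pack_waters(n, rng))
    if kind == "alkane":
        n = int(params.get("n_carbons", 4))
        if n <= 0:
            raise ValueError("n_carbons must be positive")
        return _alkane_system(n)
    if kind == "ion_droplet":
        ion = params.get("ion", "Na")
        n = int(params.get("n_waters", 21))
        if n <= 0:
            raise ValueError("n_waters must be positive")
        if ion not in _ION_TYPES:
            raise ValueError(f"unsupported ion: {ion!r}")
        mm_type, q = _ION_TYPES[ion]
        ion_atom = _mk_atom(ion, [0.0, 0.0, 0.0], mm_type, q)
        blocks = _pack_waters(n, rng, occupied_ang=np.zeros((1, 3)))
        return _water_system(blocks, extra_atoms=[ion_atom])
    if kind == "harmonic_toy":
        k = float(params.get("k", 1.0))
        if k <= 0:
            raise ValueError("k must be positive")
        return HarmonicToy(k=k, n_dim=int(params.get("n_dim", 1)))
    raise ValueError(f"unknown fixture kind: {kind!r}")
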